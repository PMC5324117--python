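"""Readers and writers for the external formats the pipeline touches.

Every coordinate handed to the rest of the package is 0-based, half-open
``[start, end)``. Conversion to and from the 1-based inclusive conventions
of GTF and BLAST tabular output happens here and only here. UCSC chain
query coordinates given on the reverse strand are flipped to the forward
strand at parse time, so downstream code never sees raw reverse
coordinates.

Writers emit a canonical byte layout; ``write(read(x))`` is byte-identical
for files produced by :mod:`lncmap.simulate`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

STRANDS = ("+", "-", ".")

BIOTYPES = ("protein_coding", "annotated_lncRNA", "novel", "other")


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A genomic interval, 0-based half-open, with optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(
                f"interval start must be < end, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Strand-blind overlap of at least 1 nt."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def distance(self, other: "GenomicInterval") -> int:
        """Gap between two intervals on the same chromosome (0 if touching/overlapping)."""
        if self.chrom != other.chrom:
            raise ValueError("distance undefined across chromosomes")
        return max(self.start, other.start) - min(self.end, other.end) if not self.overlaps(other) else 0

    def shift(self, offset: int) -> "GenomicInterval":
        return GenomicInterval(self.chrom, self.start + offset, self.end + offset, self.strand)


@dataclass(frozen=True)
class TranscriptModel:
    """An exon-structured transcript; the unit flowing through the pipeline.

    Exons must share one chromosome and strand, be sorted by start and be
    non-overlapping; the transcript span is derived from the exon union.
    """

    transcript_id: str
    gene_id: str
    exons: tuple[GenomicInterval, ...]
    biotype: str = "novel"

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript needs >= 1 exon")
        if self.biotype not in BIOTYPES:
            raise ValueError(f"{self.transcript_id}: unknown biotype {self.biotype!r}")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) != 1 or len(strands) != 1:
            raise ValueError(f"{self.transcript_id}: exons span multiple chroms/strands")
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(f"{self.transcript_id}: exons overlap or are unsorted")

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.exons[0].start, self.exons[-1].end, self.strand)

    @property
    def exonic_length(self) -> int:
        return sum(e.length for e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)


@dataclass(frozen=True)
class ChainBlock:
    """One ungapped alignment block, both sides forward-strand 0-based half-open."""

    target: GenomicInterval
    query: GenomicInterval
    chain_id: int
    score: float


@dataclass
class Chain:
    """One chain record; blocks stored with forward-normalized query coordinates."""

    chain_id: int
    score: float
    t_name: str
    t_size: int
    t_start: int
    t_end: int
    q_name: str
    q_size: int
    q_strand: str
    q_start: int  # original chain coordinates (reverse-strand based if q_strand == '-')
    q_end: int
    blocks: list[tuple[int, int, int, int]] = field(default_factory=list)
    # each block: (t0, t1, qf0, qf1) with qf* on the forward strand


@dataclass
class ChainAlignmentSet:
    """All chains of one pairwise genome alignment (one species pair)."""

    species_pair: str
    chains: list[Chain] = field(default_factory=list)

    def target_blocks(self, chrom: str) -> np.ndarray:
        """(n, 2) array of target-side block coordinates on ``chrom`` (unsorted)."""
        out = [
            (t0, t1)
            for c in self.chains
            if c.t_name == chrom
            for (t0, t1, _, _) in c.blocks
        ]
        return np.asarray(out, dtype=np.int64).reshape(-1, 2)

    def iter_blocks(self) -> Iterable[ChainBlock]:
        for c in self.chains:
            for t0, t1, q0, q1 in c.blocks:
                yield ChainBlock(
                    GenomicInterval(c.t_name, t0, t1, "+"),
                    GenomicInterval(c.q_name, q0, q1, c.q_strand),
                    c.chain_id,
                    c.score,
                )


HIT_COLUMNS = [
    "query_id",
    "subject_id",
    "pct_identity",
    "alignment_length",
    "mismatches",
    "gap_opens",
    "query_start",
    "query_end",
    "subject_start",
    "subject_end",
    "e_value",
    "bit_score",
]


@dataclass
class HitTable:
    """BLAST tabular (outfmt-6 order) hits with query coordinates normalized
    to 0-based half-open, ``query_start <= query_end``."""

    rows: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in HIT_COLUMNS if c not in self.rows.columns]
        if missing:
            raise ValueError(f"hit table missing columns: {missing}")
        if len(self.rows) and (self.rows["alignment_length"] < 1).any():
            raise ValueError("alignment_length must be >= 1")
        if len(self.rows) and (self.rows["query_start"] > self.rows["query_end"]).any():
            raise ValueError("query_start must be <= query_end after normalization")

    def for_query(self, query_id: str) -> pd.DataFrame:
        return self.rows[self.rows["query_id"] == query_id]


@dataclass
class CountMatrix:
    """Read(-pair) counts, transcripts x samples, with per-sample library sizes."""

    counts: pd.DataFrame
    library_sizes: pd.Series

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if list(self.library_sizes.index) != list(self.counts.columns):
            raise ValueError("library_sizes index must match count columns")
        if (self.library_sizes <= 0).any():
            raise ValueError("library sizes must be positive")
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise ValueError(f"duplicate transcript row: {dup}")

    @property
    def sample_labels(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.counts.index)


# ---------------------------------------------------------------------------
# GTF

_ATTR_RE = re.compile(r'(\w+) "([^"]*)";?')


def _parse_attributes(attr_field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(attr_field))


def read_gtf(path: str | Path) -> list[TranscriptModel]:
    """Read exon features from a GTF file into transcript models.

    GTF 1-based inclusive coordinates are converted to 0-based half-open.
    Exons are grouped per transcript and sorted by start. Non-exon features
    are ignored.
    """
    exons_by_tx: dict[str, list[GenomicInterval]] = {}
    meta: dict[str, tuple[str, str]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 tab-separated fields")
            chrom, _source, feature, start, end, _score, strand, _frame, attrs = fields
            if feature != "exon":
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start_i > end_i:
                raise FormatError(f"{path}:{lineno}: start > end")
            attributes = _parse_attributes(attrs)
            if "transcript_id" not in attributes:
                raise FormatError(f"{path}:{lineno}: exon without transcript_id")
            tid = attributes["transcript_id"]
            gid = attributes.get("gene_id", tid)
            biotype = attributes.get("biotype", attributes.get("gene_biotype", "novel"))
            if tid not in exons_by_tx:
                exons_by_tx[tid] = []
                order.append(tid)
                meta[tid] = (gid, biotype if biotype in BIOTYPES else "other")
            exons_by_tx[tid].append(GenomicInterval(chrom, start_i - 1, end_i, strand))
    transcripts = []
    for tid in order:
        gid, biotype = meta[tid]
        exons = tuple(sorted(exons_by_tx[tid], key=lambda e: e.start))
        transcripts.append(TranscriptModel(tid, gid, exons, biotype))
    return transcripts


def write_gtf(transcripts: Sequence[TranscriptModel], path: str | Path, source: str = "lncmap") -> None:
    """Write transcripts as GTF exon features (1-based inclusive), canonical layout."""
    with open(path, "w") as fh:
        for t in transcripts:
            for e in t.exons:
                attrs = (
                    f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                    f'biotype "{t.biotype}";'
                )
                fh.write(
                    f"{e.chrom}\t{source}\texon\t{e.start + 1}\t{e.end}\t.\t{e.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# UCSC chain


def read_chain(path: str | Path, species_pair: str | None = None) -> ChainAlignmentSet:
    """Parse a UCSC chain file.

    Each ungapped block becomes one target/query interval pair; query
    coordinates of '-'-strand chains are converted to the forward strand.
    Block sizes not summing to the header spans raise :class:`FormatError`.
    """
    if species_pair is None:
        species_pair = Path(path).stem
    chains: list[Chain] = []
    current: Chain | None = None
    t_cursor = q_cursor = 0
    closed = True

    def _close(chain: Chain, lineno: int) -> None:
        if t_cursor != chain.t_end or q_cursor != chain.q_end:
            raise FormatError(
                f"{path}:{lineno}: block sizes do not sum to header span "
                f"(target {t_cursor} != {chain.t_end} or query {q_cursor} != {chain.q_end})"
            )

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("chain"):
                if current is not None and not closed:
                    raise FormatError(f"{path}:{lineno}: chain header before previous chain ended")
                parts = line.split()
                if len(parts) != 13:
                    raise FormatError(f"{path}:{lineno}: chain header needs 13 fields")
                (_, score, t_name, t_size, t_strand, t_start, t_end,
                 q_name, q_size, q_strand, q_start, q_end, chain_id) = parts
                if t_strand != "+":
                    raise FormatError(f"{path}:{lineno}: target strand must be '+'")
                if q_strand not in "+-":
                    raise FormatError(f"{path}:{lineno}: bad query strand {q_strand!r}")
                current = Chain(
                    chain_id=int(chain_id), score=float(score),
                    t_name=t_name, t_size=int(t_size), t_start=int(t_start), t_end=int(t_end),
                    q_name=q_name, q_size=int(q_size), q_strand=q_strand,
                    q_start=int(q_start), q_end=int(q_end),
                )
                t_cursor, q_cursor = current.t_start, current.q_start
                closed = False
                chains.append(current)
                continue
            if current is None:
                raise FormatError(f"{path}:{lineno}: alignment line outside a chain")
            parts = line.split()
            try:
                nums = [int(p) for p in parts]
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer alignment line") from exc
            if len(nums) == 1:
                size, dt, dq = nums[0], 0, 0
                last = True
            elif len(nums) == 3:
                size, dt, dq = nums
                last = False
            else:
                raise FormatError(f"{path}:{lineno}: alignment line needs 1 or 3 integers")
            t0, t1 = t_cursor, t_cursor + size
            q0, q1 = q_cursor, q_cursor + size
            if current.q_strand == "-":
                qf0, qf1 = current.q_size - q1, current.q_size - q0
            else:
                qf0, qf1 = q0, q1
            current.blocks.append((t0, t1, qf0, qf1))
            t_cursor = t1 + dt
            q_cursor = q1 + dq
            if last:
                _close(current, lineno)
                closed = True
    if current is not None and not closed:
        raise FormatError(f"{path}: truncated final chain")
    return ChainAlignmentSet(species_pair=species_pair, chains=chains)


def write_chain(aln: ChainAlignmentSet, path: str | Path) -> None:
    """Write chains back to UCSC chain format (canonical layout)."""
    with open(path, "w") as fh:
        for c in aln.chains:
            score = int(c.score) if float(c.score).is_integer() else c.score
            fh.write(
                f"chain {score} {c.t_name} {c.t_size} + {c.t_start} {c.t_end} "
                f"{c.q_name} {c.q_size} {c.q_strand} {c.q_start} {c.q_end} {c.chain_id}\n"
            )
            # reconstruct chain-local query coordinates for gap computation
            local = []
            for t0, t1, qf0, qf1 in c.blocks:
                if c.q_strand == "-":
                    local.append((t0, t1, c.q_size - qf1, c.q_size - qf0))
                else:
                    local.append((t0, t1, qf0, qf1))
            for i, (t0, t1, q0, q1) in enumerate(local):
                size = t1 - t0
                if i + 1 < len(local):
                    nt0, _, nq0, _ = local[i + 1]
                    fh.write(f"{size} {nt0 - t1} {nq0 - q1}\n")
                else:
                    fh.write(f"{size}\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# BED


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED6 into intervals (already 0-based half-open)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: BED needs >= 3 fields")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            strand = fields[5] if len(fields) >= 6 else "."
            out.append(GenomicInterval(chrom, start, end, strand))
    return out


def write_bed(intervals: Sequence[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            if iv.strand == ".":
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# counts TSV

_LIBSIZE_TAG = "#library_sizes:"


def read_counts(path: str | Path) -> CountMatrix:
    """Read a counts TSV: a ``#library_sizes:`` header line, a sample-label
    header row, then one row per transcript."""
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if not first.startswith(_LIBSIZE_TAG):
            raise FormatError(f"{path}:1: expected '{_LIBSIZE_TAG}' header line")
        libsizes = [int(x) for x in first[len(_LIBSIZE_TAG):].strip().split("\t")]
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise FormatError(f"{path}:2: header row needs transcript_id + samples")
        samples = header[1:]
        if len(libsizes) != len(samples):
            raise FormatError(f"{path}: {len(libsizes)} library sizes for {len(samples)} samples")
        ids, rows = [], []
        seen: set[str] = set()
        for lineno, line in enumerate(fh, start=3):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(samples) + 1:
                raise FormatError(f"{path}:{lineno}: wrong number of columns")
            if fields[0] in seen:
                raise FormatError(f"{path}:{lineno}: duplicate transcript {fields[0]}")
            seen.add(fields[0])
            vals = [int(x) for x in fields[1:]]
            if any(v < 0 for v in vals):
                raise FormatError(f"{path}:{lineno}: negative count")
            ids.append(fields[0])
            rows.append(vals)
    counts = pd.DataFrame(rows, index=ids, columns=samples, dtype=np.int64)
    return CountMatrix(counts, pd.Series(libsizes, index=samples, dtype=np.int64))


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(_LIBSIZE_TAG + "\t" + "\t".join(str(int(x)) for x in cm.library_sizes) + "\n")
        fh.write("transcript_id\t" + "\t".join(cm.sample_labels) + "\n")
        for tid, row in cm.counts.iterrows():
            fh.write(tid + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# BLAST tabular hits


def read_hits(path: str | Path) -> HitTable:
    """Read 12-column BLAST tabular output; 1-based inclusive query/subject
    coordinates become 0-based half-open, and reversed query coordinates are
    re-oriented so query_start <= query_end."""
    df = pd.read_csv(path, sep="\t", names=HIT_COLUMNS, comment="#")
    if len(df):
        qs = df["query_start"].to_numpy().copy()
        qe = df["query_end"].to_numpy().copy()
        flip = qs > qe
        qs[flip], qe[flip] = qe[flip], qs[flip]
        df["query_start"] = qs - 1
        df["query_end"] = qe
        ss = df["subject_start"].to_numpy().copy()
        se = df["subject_end"].to_numpy().copy()
        flip = ss > se
        ss[flip], se[flip] = se[flip], ss[flip]
        df["subject_start"] = ss - 1
        df["subject_end"] = se
    return HitTable(df)


def write_hits(hits: HitTable, path: str | Path) -> None:
    df = hits.rows.copy()
    df["query_start"] = df["query_start"] + 1
    df["subject_start"] = df["subject_start"] + 1
    df.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# GO map and simple verdict tables


def read_go(path: str | Path) -> dict[str, frozenset[str]]:
    """Read a two-column gene->term TSV; duplicate memberships deduplicate."""
    mapping: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(f"{path}:{lineno}: expected gene_id TAB term_id")
            mapping.setdefault(fields[0], set()).add(fields[1])
    return {g: frozenset(t) for g, t in mapping.items()}


def write_go(mapping: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(mapping):
            for term in sorted(set(mapping[gene])):
                fh.write(f"{gene}\t{term}\n")


def read_coding_table(path: str | Path) -> dict[str, dict[str, str]]:
    """Read per-caller coding-potential verdicts: transcript_id, caller, verdict."""
    table: dict[str, dict[str, str]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:1] != ["transcript_id"]:
            raise FormatError(f"{path}:1: expected 'transcript_id' + caller columns")
        callers = header[1:]
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(callers) + 1:
                raise FormatError(f"{path}:{lineno}: wrong number of columns")
            verdicts = {}
            for caller, v in zip(callers, fields[1:]):
                if v not in ("coding", "noncoding"):
                    raise FormatError(f"{path}:{lineno}: verdict must be coding/noncoding")
                verdicts[caller] = v
            table[fields[0]] = verdicts
    return table


def write_coding_table(table: Mapping[str, Mapping[str, str]], path: str | Path) -> None:
    callers = sorted({c for v in table.values() for c in v})
    with open(path, "w") as fh:
        fh.write("transcript_id\t" + "\t".join(callers) + "\n")
        for tid in table:
            fh.write(tid + "\t" + "\t".join(table[tid].get(c, "noncoding") for c in callers) + "\n")


def read_ncrna_table(path: str | Path) -> dict[str, frozenset[str]]:
    """Read transcript -> matched ncRNA family classes (possibly empty)."""
    mapping: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(f"{path}:{lineno}: expected transcript_id TAB family_class")
            mapping.setdefault(fields[0], set()).add(fields[1])
    return {t: frozenset(f) for t, f in mapping.items()}


def write_ncrna_table(mapping: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for tid in sorted(mapping):
            for fam in sorted(set(mapping[tid])):
                fh.write(f"{tid}\t{fam}\n")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")
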