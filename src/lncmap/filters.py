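"""Hierarchical lncRNA discovery filter and positional classification.

Assembled transcripts are passed through six ordered filtering steps:

1. ``multi_exon``        – drop mono-exonic transcripts (assembly artefacts);
2. ``annotated_overlap`` – drop transcripts whose exons overlap any annotated
   exon on the same strand (known lncRNAs are kept and flagged non-novel);
3. ``length``            – drop transcripts with exonic length < 200 nt;
4. ``coding_potential``  – drop transcripts any upstream caller deems coding;
5. ``ncrna_homology``    – drop transcripts homologous to canonical structural
   RNAs (tRNA, rRNA, snoRNA, ...); transcripts matching only curated lncRNA
   family models are kept;
6. survivors are lncRNAs and are positionally classified.

Each removed transcript records the *first* step that fired. Retained
transcripts fall into four mutually exclusive positional categories with
precedence antisense > intronic > cis_regulatory > intergenic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

from .intervals import merge_intervals, overlap_length
from .io import GenomicInterval, TranscriptModel

CATEGORIES = ("intergenic", "antisense", "intronic", "cis_regulatory")
STEPS = ("multi_exon", "annotated_overlap", "length", "coding_potential", "ncrna_homology", "retained")

STRUCTURAL_FAMILIES = frozenset({"miRNA", "tRNA", "snoRNA", "rRNA", "other_structural"})
LNCRNA_MODEL_FAMILY = "lncRNA_model"


@dataclass(frozen=True)
class FilterVerdict:
    transcript_id: str
    fate: Literal["retained", "removed"]
    step: str
    category: str | None = None
    novel: bool = True
    strand_relation: str | None = None  # metadata for cis_regulatory audits

    def __post_init__(self) -> None:
        if self.fate == "removed" and self.step == "retained":
            raise ValueError("removed transcripts need a removal step")
        if self.fate == "retained" and self.category not in CATEGORIES:
            raise ValueError("retained transcripts need a category")


class _AnnotationIndex:
    """Per-chromosome merged exon unions and gene spans of an annotation."""

    def __init__(self, annotation: Sequence[TranscriptModel]):
        exons_fwd: dict[str, list[tuple[int, int]]] = {}
        exons_rev: dict[str, list[tuple[int, int]]] = {}
        self.exons_by_gene: dict[str, list[tuple[str, str, int, int]]] = {}
        spans: dict[str, list[int | str]] = {}
        self.annotated_lnc_ids = set()
        for t in annotation:
            if t.biotype == "annotated_lncRNA":
                self.annotated_lnc_ids.add(t.transcript_id)
            side = exons_fwd if t.strand == "+" else exons_rev
            side.setdefault(t.chrom, []).extend((e.start, e.end) for e in t.exons)
            rec = spans.setdefault(t.gene_id, [t.chrom, t.strand, t.interval.start, t.interval.end])
            rec[2] = min(rec[2], t.interval.start)
            rec[3] = max(rec[3], t.interval.end)
            self.exons_by_gene.setdefault(t.gene_id, []).extend(
                (t.chrom, t.strand, e.start, e.end) for e in t.exons
            )
        self.exons = {
            "+": {c: merge_intervals(v) for c, v in exons_fwd.items()},
            "-": {c: merge_intervals(v) for c, v in exons_rev.items()},
        }
        self.gene_spans: dict[str, tuple[str, str, int, int]] = {
            g: (c, s, int(a), int(b)) for g, (c, s, a, b) in spans.items()
        }

    def exon_overlap(self, t: TranscriptModel, strand: str) -> bool:
        """Does any exon of t overlap a merged annotated exon on ``strand``?"""
        pool = self.exons[strand].get(t.chrom, [])
        if not pool:
            return False
        tx = [(e.start, e.end) for e in t.exons]
        return overlap_length(tx, pool) > 0


def run_filter_pipeline(
    transcripts: Sequence[TranscriptModel],
    annotation: Sequence[TranscriptModel],
    coding: Mapping[str, Mapping[str, str]],
    ncrna: Mapping[str, Iterable[str]],
    min_length: int = 200,
    window: int = 2000,
    missing_coding: Literal["error", "noncoding"] = "error",
) -> list[FilterVerdict]:
    """Apply the six-step discovery filter; verdicts in input order.

    ``coding`` maps transcript_id -> {caller: 'coding'|'noncoding'}; a
    transcript is treated as coding if *any* caller flags it (the stringent
    union rule). ``ncrna`` maps transcript_id -> matched family classes.
    """
    index = _AnnotationIndex(annotation)
    verdicts = []
    for t in transcripts:
        verdicts.append(
            _filter_one(t, index, coding, ncrna, min_length, window, missing_coding)
        )
    return verdicts


def _filter_one(
    t: TranscriptModel,
    index: _AnnotationIndex,
    coding: Mapping[str, Mapping[str, str]],
    ncrna: Mapping[str, Iterable[str]],
    min_length: int,
    window: int,
    missing_coding: str,
) -> FilterVerdict:
    # 1: multi-exon requirement
    if t.n_exons < 2:
        return FilterVerdict(t.transcript_id, "removed", "multi_exon")
    # 2: same-strand overlap with annotated exons; known lncRNAs bypass
    annotated_lnc = (
        t.biotype == "annotated_lncRNA" or t.transcript_id in index.annotated_lnc_ids
    )
    if not annotated_lnc and index.exon_overlap(t, t.strand):
        return FilterVerdict(t.transcript_id, "removed", "annotated_overlap")
    # 3: exonic length
    if t.exonic_length < min_length:
        return FilterVerdict(t.transcript_id, "removed", "length")
    # 4: coding potential (union over callers)
    if t.transcript_id not in coding:
        if missing_coding == "error":
            raise KeyError(
                f"{t.transcript_id}: no coding-potential verdict "
                "(pass missing_coding='noncoding' to default-retain)"
            )
    elif any(v == "coding" for v in coding[t.transcript_id].values()):
        return FilterVerdict(t.transcript_id, "removed", "coding_potential")
    # 5: canonical structural-ncRNA homology; lncRNA-model-only matches survive
    families = set(ncrna.get(t.transcript_id, ()))
    if families & STRUCTURAL_FAMILIES:
        return FilterVerdict(t.transcript_id, "removed", "ncrna_homology")
    # 6: retained -> positional category
    category, strand_relation = classify_position(
        t, index, window=window, return_strand_relation=True
    )
    return FilterVerdict(
        t.transcript_id,
        "retained",
        "retained",
        category=category,
        novel=not annotated_lnc,
        strand_relation=strand_relation,
    )


def classify_position(
    t: TranscriptModel,
    annotation: Sequence[TranscriptModel] | _AnnotationIndex,
    window: int = 2000,
    return_strand_relation: bool = False,
):
    """Positional category of a retained lncRNA relative to annotated genes.

    Precedence: antisense > intronic > cis_regulatory > intergenic.
    Annotated transcripts sharing the query's transcript id (the query
    itself, for known lncRNAs) are ignored; distances are measured between
    the transcript span and gene spans on either strand.
    """
    index = annotation if isinstance(annotation, _AnnotationIndex) else _AnnotationIndex(annotation)
    span = t.interval
    tx_exons = [(e.start, e.end) for e in t.exons]
    opposite = "-" if t.strand == "+" else "+"

    # antisense: exon-exon overlap on the opposite strand
    if index.exon_overlap(t, opposite):
        result = ("antisense", "antisense")
        return result if return_strand_relation else result[0]

    # intronic: wholly inside a gene span with no exon overlap on either strand
    near_relation = None
    min_distance = None
    for gene_id, (chrom, gstrand, gstart, gend) in index.gene_spans.items():
        if chrom != span.chrom or gene_id == t.gene_id and t.transcript_id in index.annotated_lnc_ids:
            continue
        if gstart <= span.start and span.end <= gend:
            gene_exons = [
                (a, b) for (c, s, a, b) in index.exons_by_gene[gene_id] if c == chrom
            ]
            if overlap_length(tx_exons, gene_exons) == 0:
                result = ("intronic", "sense" if gstrand == t.strand else "antisense")
                return result if return_strand_relation else result[0]
        # span-to-span distance for the cis/intergenic decision
        d = max(gstart, span.start) - min(gend, span.end)
        d = max(d, 0)
        if min_distance is None or d < min_distance:
            min_distance = d
            near_relation = "sense" if gstrand == t.strand else "antisense"

    if min_distance is not None and min_distance < window:
        result = ("cis_regulatory", near_relation)
    else:
        result = ("intergenic", None)
    return result if return_strand_relation else result[0]


def interval_overlap_fraction(
    t: TranscriptModel, features: Sequence[GenomicInterval]
) -> float:
    """Fraction of t's exonic nucleotides covered by the union of features."""
    feats = [(f.start, f.end) for f in features if f.chrom == t.chrom]
    if not feats:
        return 0.0
    covered = overlap_length([(e.start, e.end) for e in t.exons], feats)
    return covered / t.exonic_length


def verdicts_to_frame(verdicts: Sequence[FilterVerdict]):
    """Tabulate verdicts (fixed column order, used by the CLI writer)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "transcript_id": [v.transcript_id for v in verdicts],
            "fate": [v.fate for v in verdicts],
            "step": [v.step for v in verdicts],
            "category": [v.category or "" for v in verdicts],
            "novel": [v.novel for v in verdicts],
            "strand_relation": [v.strand_relation or "" for v in verdicts],
        }
    )
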