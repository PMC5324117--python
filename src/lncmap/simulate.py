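"""Self-consistent miniature dataset with planted ground truth.

The generator emulates the study design the pipeline targets: an annotated
genome of multi-exon protein-coding genes; planted lncRNAs of the four
positional categories (intergenic >= 2 kb from genes, exon-antisense,
intronic, cis-regulatory within 2 kb) plus decoys that each trip exactly
one discovery-filter step; an 11-sample expression panel (9 organs plus
skeletal muscle at three postnatal stages) with planted tissue-specific,
ubiquitous and stage-differential transcripts; a 30-sample co-expression
panel with block-correlated modules tied to a binary muscle trait;
pairwise-alignment chain files and BLAST-style hit tables with planted
conservation classes; SNPs, coding-potential verdicts, structural-RNA
homology calls and a GO map.

Counts are negative-binomial around mean = RPKM x exonic_kb x library
millions (Poisson in the dispersion -> 0 limit). Everything is
deterministic given the seed; files written by :func:`emit_dataset` are
byte-identical across runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as lio
from .io import Chain, ChainAlignmentSet, CountMatrix, GenomicInterval, HitTable, TranscriptModel

TISSUES = (
    "adipose", "heart", "kidney", "liver", "lung", "ovary",
    "spleen", "testis", "muscle_d0", "muscle_d30", "muscle_d240",
)
MUSCLE_SAMPLES = ("muscle_d0", "muscle_d30", "muscle_d240")

CATEGORIES = ("intergenic", "antisense", "intronic", "cis_regulatory")
DECOY_CLASSES = ("mono_exonic", "short", "coding", "annotated_overlap")
DECOY_STEP = {
    "mono_exonic": "multi_exon",
    "short": "length",
    "coding": "coding_potential",
    "annotated_overlap": "annotated_overlap",
}

GENES_PER_CHROM = 50
GENE_SLOT = 12_000          # distance between consecutive gene starts
GENE_MARGIN = 1_000
# gene body: 4 exons over a 3 kb span (coordinates relative to gene start)
GENE_EXONS = ((0, 300), (700, 1000), (1600, 1900), (2700, 3000))
GENE_SPAN = 3_000

# empirical GC levels used for the emitted sequences
GC_BY_BIOTYPE = {"protein_coding": 0.522, "annotated_lncRNA": 0.483, "novel": 0.478, "other": 0.45}


@dataclass(frozen=True)
class ModuleSpec:
    size: int
    within_correlation: float
    trait_linked: bool

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("module size must be >= 1")
        if not 0.0 < self.within_correlation <= 1.0:
            raise ValueError("within-correlation must be in (0, 1]")


@dataclass
class SimulationConfig:
    seed: int = 42
    n_pcg: int = 200
    n_lnc_per_category: int = 20
    n_decoys_per_class: int = 10
    n_annotated_lnc: int = 5
    n_tissues: int = 11
    library_size: int = 20_000_000
    dispersion: float = 0.05
    specific_fraction: float = 0.5
    de_log2fc: float = 2.0
    module_spec: tuple[ModuleSpec, ...] = (
        ModuleSpec(50, 0.8, True),
        ModuleSpec(50, 0.8, False),
        ModuleSpec(50, 0.8, False),
    )
    n_network_samples: int = 30
    snp_rate_lnc: float = 15.47   # SNPs per exonic kb
    snp_rate_pcg: float = 8.57
    conservation_probs: tuple[float, float, float, float] = (0.575, 0.067, 0.128, 0.230)
    homology_prob: tuple[float, float] = (0.45, 0.29)

    def __post_init__(self) -> None:
        if self.n_tissues != len(TISSUES):
            raise ValueError(f"the tissue panel is fixed at {len(TISSUES)} samples")
        for name in ("n_pcg", "n_lnc_per_category", "n_decoys_per_class", "library_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        needed = self._slots_needed()
        if self.n_pcg < needed:
            raise ValueError(
                f"geometry impossible: {self.n_pcg} protein-coding genes cannot host "
                f"{needed} planted features; raise n_pcg to >= {needed}"
            )

    def _slots_needed(self) -> int:
        return (
            4 * self.n_lnc_per_category
            + 4 * self.n_decoys_per_class
            + self.n_annotated_lnc
        )


@dataclass
class SyntheticTruth:
    """Planted ground truth for every downstream analysis stage."""

    tissues: list[str] = field(default_factory=lambda: list(TISSUES))
    muscle_samples: list[str] = field(default_factory=lambda: list(MUSCLE_SAMPLES))
    lncrna_category: dict[str, str] = field(default_factory=dict)
    lncrna_novel: dict[str, bool] = field(default_factory=dict)
    decoy_step: dict[str, str] = field(default_factory=dict)
    pcg_gene_ids: list[str] = field(default_factory=list)
    pcg_transcript_ids: list[str] = field(default_factory=list)
    specificity: dict[str, str] = field(default_factory=dict)
    planted_rpkm: dict[str, list[float]] = field(default_factory=dict)
    de_log2fc: dict[str, dict[str, float]] = field(default_factory=dict)
    conservation_class: dict[str, str] = field(default_factory=dict)
    conservation_fractions: dict[str, list[float]] = field(default_factory=dict)
    transcript_homology: dict[str, list[bool]] = field(default_factory=dict)
    module_label: dict[str, str] = field(default_factory=dict)
    trait_linked_modules: list[str] = field(default_factory=list)
    module_go_term: dict[str, str] = field(default_factory=dict)
    neighbor_gene: dict[str, str] = field(default_factory=dict)

    @property
    def lncrna_ids(self) -> list[str]:
        return list(self.lncrna_category)

    @property
    def decoy_ids(self) -> list[str]:
        return list(self.decoy_step)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _gene_coords(i: int) -> tuple[str, int, str]:
    chrom = f"chr{i // GENES_PER_CHROM + 1}"
    start = GENE_MARGIN + (i % GENES_PER_CHROM) * GENE_SLOT
    strand = "+" if i % 2 == 0 else "-"
    return chrom, start, strand


def _flip(strand: str) -> str:
    return "-" if strand == "+" else "+"


def _tx(tid: str, gid: str, chrom: str, strand: str, exons, biotype="novel") -> TranscriptModel:
    return TranscriptModel(
        tid, gid, tuple(GenomicInterval(chrom, a, b, strand) for a, b in exons), biotype
    )


def generate_annotation(
    config: SimulationConfig,
) -> tuple[list[TranscriptModel], list[TranscriptModel], dict[str, str], SyntheticTruth]:
    """Annotated genome, assembled-transcript input set, sequences and truth.

    Returns ``(annotation, transcripts, sequences, truth)``. The annotation
    holds the protein-coding genes and known lncRNAs; ``transcripts`` is the
    assembled consensus input to the discovery filter (planted lncRNAs,
    decoys, known lncRNAs and re-assembled coding transcripts).
    """
    rng = np.random.default_rng(config.seed)
    truth = SyntheticTruth()
    annotation: list[TranscriptModel] = []
    transcripts: list[TranscriptModel] = []

    for i in range(config.n_pcg):
        chrom, start, strand = _gene_coords(i)
        gid = f"g{i:04d}"
        exons = [(start + a, start + b) for a, b in GENE_EXONS]
        annotation.append(_tx(f"{gid}.t1", gid, chrom, strand, exons, "protein_coding"))
        truth.pcg_gene_ids.append(gid)
        # the assembler re-reports known coding transcripts under fresh ids
        transcripts.append(_tx(f"asm_{gid}", f"asm_{gid}", chrom, strand, exons, "novel"))
        truth.pcg_transcript_ids.append(f"asm_{gid}")

    slot = 0  # consumes host genes / intergenic gaps left to right

    def _next_slot() -> tuple[str, int, str]:
        nonlocal slot
        coords = _gene_coords(slot)
        slot += 1
        return coords

    n = config.n_lnc_per_category
    for j in range(n):  # antisense: first exon overlaps the host's first exon
        chrom, g, strand = _next_slot()
        exons = [(g - 100, g + 150), (g + 350, g + 600)]
        tid = f"lnc_antisense_{j:03d}"
        transcripts.append(_tx(tid, tid, chrom, _flip(strand), exons))
        truth.lncrna_category[tid] = "antisense"
    for j in range(n):  # intronic: wholly inside intron 2, same strand
        chrom, g, strand = _next_slot()
        exons = [(g + 1020, g + 1220), (g + 1380, g + 1580)]
        tid = f"lnc_intronic_{j:03d}"
        transcripts.append(_tx(tid, tid, chrom, strand, exons))
        truth.lncrna_category[tid] = "intronic"
    for j in range(n):  # cis-regulatory: 500 nt downstream of the host span
        chrom, g, strand = _next_slot()
        exons = [(g + 3500, g + 3800), (g + 4000, g + 4300)]
        tid = f"lnc_cis_{j:03d}"
        transcripts.append(_tx(tid, tid, chrom, _flip(strand), exons))
        truth.lncrna_category[tid] = "cis_regulatory"
    for j in range(n):  # intergenic: >= 2 kb from both flanking genes
        chrom, g, strand = _next_slot()
        jitter = int(rng.integers(0, 800))
        a = g + 6000 + jitter
        exons = [(a, a + 300), (a + 500, a + 900)]
        tid = f"lnc_intergenic_{j:03d}"
        transcripts.append(_tx(tid, tid, chrom, "+" if j % 2 == 0 else "-", exons))
        truth.lncrna_category[tid] = "intergenic"
        truth.neighbor_gene[tid] = f"g{slot - 1:04d}"  # nearest gene: the gap's left gene

    for j in range(config.n_decoys_per_class):  # mono-exonic
        chrom, g, strand = _next_slot()
        tid = f"decoy_mono_{j:03d}"
        transcripts.append(_tx(tid, tid, chrom, "+", [(g + 6000, g + 6400)]))
        truth.decoy_step[tid] = DECOY_STEP["mono_exonic"]
    for j in range(config.n_decoys_per_class):  # exonic length 160 < 200
        chrom, g, strand = _next_slot()
        tid = f"decoy_short_{j:03d}"
        transcripts.append(_tx(tid, tid, chrom, "+", [(g + 6000, g + 6080), (g + 6200, g + 6280)]))
        truth.decoy_step[tid] = DECOY_STEP["short"]
    for j in range(config.n_decoys_per_class):  # flagged coding by one caller
        chrom, g, strand = _next_slot()
        tid = f"decoy_coding_{j:03d}"
        transcripts.append(_tx(tid, tid, chrom, "-", [(g + 6000, g + 6250), (g + 6400, g + 6650)]))
        truth.decoy_step[tid] = DECOY_STEP["coding"]
    for j in range(config.n_decoys_per_class):  # same-strand overlap with host exon 1
        chrom, g, strand = _next_slot()
        tid = f"decoy_overlap_{j:03d}"
        transcripts.append(_tx(tid, tid, chrom, strand, [(g + 100, g + 400), (g + 450, g + 650)]))
        truth.decoy_step[tid] = DECOY_STEP["annotated_overlap"]

    for j in range(config.n_annotated_lnc):  # known lncRNAs: annotated + re-assembled
        chrom, g, strand = _next_slot()
        tid = f"lnc_known_{j:03d}"
        exons = [(g + 6000, g + 6300), (g + 6600, g + 6900)]
        known = _tx(tid, tid, chrom, "+", exons, "annotated_lncRNA")
        annotation.append(known)
        transcripts.append(known)
        truth.lncrna_category[tid] = "intergenic"
        truth.lncrna_novel[tid] = False

    for tid in truth.lncrna_category:
        truth.lncrna_novel.setdefault(tid, True)

    sequences = {
        t.transcript_id: _random_sequence(rng, t.exonic_length, GC_BY_BIOTYPE[t.biotype])
        for t in annotation + transcripts
        if not t.transcript_id.startswith("asm_")
    }
    _plant_expression_design(rng, truth, config)
    _plant_conservation_design(rng, truth, transcripts, config)
    return annotation, transcripts, sequences, truth


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=probs))


def _plant_expression_design(rng: np.random.Generator, truth: SyntheticTruth, config: SimulationConfig) -> None:
    """Assign per-transcript planted RPKM profiles over the 11-tissue panel."""
    lnc_ids = sorted(truth.lncrna_category)
    n_specific = int(round(config.specific_fraction * len(lnc_ids)))
    chosen = list(rng.permutation(lnc_ids))
    specific_ids, ubiquitous_ids = chosen[:n_specific], chosen[n_specific:]

    nt = len(TISSUES)
    organs = [s for s in TISSUES if s not in MUSCLE_SAMPLES]
    targets = organs + ["skeletal_muscle"]
    muscle_idx = [TISSUES.index(s) for s in MUSCLE_SAMPLES]
    stage_cursor = 0
    for k, tid in enumerate(sorted(specific_ids)):
        target = targets[k % len(targets)]
        level = float(rng.uniform(8.0, 40.0))
        profile = [0.0] * nt
        if target == "skeletal_muscle":
            # specific to one developmental stage, low-level in the others
            dominant = muscle_idx[stage_cursor % len(muscle_idx)]
            stage_cursor += 1
            for idx in muscle_idx:
                profile[idx] = level if idx == dominant else level / 4.0
        else:
            profile[TISSUES.index(target)] = level
        truth.planted_rpkm[tid] = profile
        truth.specificity[tid] = target
    for tid in sorted(ubiquitous_ids):
        level = float(rng.uniform(4.0, 20.0))
        truth.planted_rpkm[tid] = [level] * nt
        truth.specificity[tid] = "ubiquitous"

    # stage-differential transcripts: ubiquitous lncRNAs elevated at day 0
    d0 = TISSUES.index("muscle_d0")
    de_ids = sorted(ubiquitous_ids)[: max(len(ubiquitous_ids) // 2, 1)]
    for tid in de_ids:
        profile = truth.planted_rpkm[tid]
        profile[d0] = profile[d0] * 2.0 ** config.de_log2fc
        truth.de_log2fc[tid] = {
            "muscle_d0|muscle_d30": config.de_log2fc,
            "muscle_d0|muscle_d240": config.de_log2fc,
            "muscle_d30|muscle_d240": 0.0,
        }

    # protein-coding genes: mildly varying baseline profiles
    for gid in truth.pcg_gene_ids:
        base = float(rng.lognormal(np.log(20.0), 0.6))
        wiggle = rng.normal(0.0, 0.4, size=nt)
        truth.planted_rpkm[gid] = list(base * 2.0 ** wiggle)
        truth.specificity[gid] = "ubiquitous"

    # planted positive lncRNA/neighbor-gene co-expression: the nearest gene of
    # each intergenic lncRNA tracks the lncRNA's planted profile
    for tid, gid in truth.neighbor_gene.items():
        lnc_profile = np.asarray(truth.planted_rpkm[tid], dtype=float)
        base = float(rng.uniform(10.0, 30.0))
        shape = np.log2(lnc_profile + 1.0)
        shape = (shape - shape.mean()) / (shape.std() or 1.0)
        noise = rng.normal(0.0, 0.8, size=nt)
        truth.planted_rpkm[gid] = list(base * 2.0 ** (1.0 * shape + noise))

    # decoys: faint uniform expression (they never reach downstream stages)
    for tid in truth.decoy_step:
        truth.planted_rpkm[tid] = [float(rng.uniform(0.5, 3.0))] * nt

    # co-expression modules over coding genes + a few conserved lncRNAs
    neighbor_genes = set(truth.neighbor_gene.values())
    pool_pcg = [g for g in truth.pcg_gene_ids if g not in neighbor_genes]
    pool_lnc = [t for t in sorted(ubiquitous_ids) if t not in de_ids]
    n_lnc_per_module = min(5, max(len(pool_lnc) // max(len(config.module_spec), 1), 1))
    cursor_g = cursor_l = 0
    for m, spec in enumerate(config.module_spec):
        name = f"mod{m + 1}"
        n_from_lnc = min(n_lnc_per_module, spec.size, len(pool_lnc) - cursor_l)
        members = pool_lnc[cursor_l:cursor_l + n_from_lnc]
        cursor_l += n_from_lnc
        n_from_pcg = spec.size - len(members)
        if cursor_g + n_from_pcg > len(pool_pcg):
            raise ValueError("module_spec requires more protein-coding genes than available")
        members += pool_pcg[cursor_g:cursor_g + n_from_pcg]
        cursor_g += n_from_pcg
        for gene in members:
            truth.module_label[gene] = name
        if spec.trait_linked:
            truth.trait_linked_modules.append(name)
        truth.module_go_term[name] = f"GO:{7000000 + m + 1}"


def _plant_conservation_design(
    rng: np.random.Generator, truth: SyntheticTruth, transcripts: list[TranscriptModel], config: SimulationConfig
) -> None:
    lengths = {t.transcript_id: t.exonic_length for t in transcripts}
    classes = np.asarray(["three_way", "A_only", "B_only", "species_specific"])
    probs = np.asarray(config.conservation_probs, dtype=float)
    probs = probs / probs.sum()
    module_members = set(truth.module_label)
    for tid in sorted(truth.lncrna_category):
        if tid in module_members:
            cls = "three_way"  # the network stage consumes conserved lncRNAs
        else:
            cls = str(rng.choice(classes, p=probs))
        length = lengths[tid]

        def _frac(conserved: bool) -> float:
            if cls == "species_specific":
                return 0.0
            target = rng.uniform(0.55, 0.95) if conserved else rng.uniform(0.05, 0.45)
            return round(target * length) / length  # achievable exactly in whole nt

        fa = _frac(cls in ("three_way", "A_only"))
        fb = _frac(cls in ("three_way", "B_only"))
        truth.conservation_class[tid] = cls
        truth.conservation_fractions[tid] = [fa, fb]
        truth.transcript_homology[tid] = [
            bool(rng.random() < config.homology_prob[0]),
            bool(rng.random() < config.homology_prob[1]),
        ]


# ---------------------------------------------------------------------------
# expression


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    mean = np.clip(mean, 0.0, None)
    if dispersion < 1e-8:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = 1.0 / (1.0 + dispersion * mean)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    out[pos] = rng.negative_binomial(r, p[pos])
    return out


def generate_expression(
    transcripts: list[TranscriptModel],
    annotation: list[TranscriptModel],
    truth: SyntheticTruth,
    config: SimulationConfig,
) -> CountMatrix:
    """Counts over the 11-tissue panel for lncRNAs, decoys and coding genes.

    Mean count = planted RPKM x exonic_kb x library millions; the draw is
    negative binomial with the configured dispersion. Co-expression-module
    members additionally share a latent per-sample factor (the trait-linked
    module's factor follows the binary muscle vector).
    """
    rng = np.random.default_rng(config.seed + 1)
    lengths = {t.transcript_id: t.exonic_length for t in transcripts}
    for t in annotation:
        lengths.setdefault(t.gene_id, t.exonic_length)

    lib = np.round(config.library_size * rng.uniform(0.92, 1.08, size=len(TISSUES))).astype(np.int64)
    trait = np.asarray([1.0 if s in MUSCLE_SAMPLES else 0.0 for s in TISSUES])
    factors = _module_factors(rng, truth, config, len(TISSUES), trait)

    ids = [tid for tid in truth.planted_rpkm if tid in lengths]
    rows = []
    for tid in ids:
        rpkm = np.asarray(truth.planted_rpkm[tid], dtype=float)
        rpkm = _apply_module_structure(rng, tid, rpkm, truth, config, factors)
        mean = rpkm * (lengths[tid] / 1e3) * (lib / 1e6)
        rows.append(_nb_counts(rng, mean, config.dispersion))
    counts = pd.DataFrame(np.vstack(rows), index=ids, columns=list(TISSUES))
    return CountMatrix(counts, pd.Series(lib, index=list(TISSUES)))


def _module_factors(
    rng: np.random.Generator,
    truth: SyntheticTruth,
    config: SimulationConfig,
    n_samples: int,
    trait: np.ndarray,
) -> dict[str, np.ndarray]:
    factors = {}
    trait_std = (trait - trait.mean()) / (trait.std() or 1.0)
    for m, spec in enumerate(config.module_spec):
        name = f"mod{m + 1}"
        if spec.trait_linked:
            factors[name] = trait_std + rng.normal(0.0, 0.3, size=n_samples)
        else:
            factors[name] = rng.normal(0.0, 1.0, size=n_samples)
    return factors


def _apply_module_structure(
    rng: np.random.Generator,
    tid: str,
    rpkm: np.ndarray,
    truth: SyntheticTruth,
    config: SimulationConfig,
    factors: dict[str, np.ndarray],
) -> np.ndarray:
    module = truth.module_label.get(tid)
    if module is None:
        return rpkm
    spec = config.module_spec[int(module[3:]) - 1]
    rho = spec.within_correlation
    latent = np.sqrt(rho) * factors[module] + np.sqrt(1.0 - rho) * rng.normal(
        0.0, 1.0, size=rpkm.size
    )
    # half-amplitude on the 11-tissue panel keeps module members from
    # masquerading as tissue-specific transcripts
    return np.maximum(rpkm.mean(), 1.0) * 2.0 ** (0.5 * latent)


def generate_network_expression(
    transcripts: list[TranscriptModel],
    annotation: list[TranscriptModel],
    truth: SyntheticTruth,
    config: SimulationConfig,
) -> tuple[CountMatrix, pd.Series]:
    """Counts for the enlarged co-expression panel plus its muscle trait.

    Emulates pooling the 11-tissue panel with extra ovary and published
    samples to reach ``n_network_samples``; 5 samples are skeletal muscle
    (trait = 1).
    """
    if config.n_network_samples < 8:
        raise ValueError("network panel needs >= 8 samples")
    rng = np.random.default_rng(config.seed + 2)
    n = config.n_network_samples
    extra = n - len(TISSUES)
    if extra < 2:
        raise ValueError("network panel must extend the 11-tissue panel")
    names = list(TISSUES) + ["muscle_x1", "muscle_x2"] + [f"extra_{k:02d}" for k in range(extra - 2)]
    trait = pd.Series(
        [1.0 if s in MUSCLE_SAMPLES or s.startswith("muscle_x") else 0.0 for s in names],
        index=names,
    )
    lengths = {t.transcript_id: t.exonic_length for t in transcripts}
    for t in annotation:
        lengths.setdefault(t.gene_id, t.exonic_length)

    lib = np.round(config.library_size * rng.uniform(0.92, 1.08, size=n)).astype(np.int64)
    factors = _module_factors(rng, truth, config, n, trait.to_numpy())

    # universe: conserved lncRNAs plus all coding genes
    ids = [
        tid for tid, cls in sorted(truth.conservation_class.items()) if cls != "species_specific"
    ] + list(truth.pcg_gene_ids)
    rows = []
    for tid in ids:
        module = truth.module_label.get(tid)
        base = float(np.mean(truth.planted_rpkm.get(tid, [20.0])))
        base = max(base, 5.0)
        if module is not None:
            spec = config.module_spec[int(module[3:]) - 1]
            rho = spec.within_correlation
            latent = np.sqrt(rho) * factors[module] + np.sqrt(1.0 - rho) * rng.normal(0, 1, n)
        else:
            latent = rng.normal(0.0, 0.8, size=n)
        rpkm = base * 2.0 ** latent
        mean = rpkm * (lengths[tid] / 1e3) * (lib / 1e6)
        rows.append(_nb_counts(rng, mean, min(config.dispersion, 0.02)))
    counts = pd.DataFrame(np.vstack(rows), index=ids, columns=names)
    return CountMatrix(counts, pd.Series(lib, index=names)), trait


# ---------------------------------------------------------------------------
# conservation files


def _cover_prefix(exons: list[tuple[int, int]], needed: int) -> list[tuple[int, int]]:
    segments = []
    for a, b in exons:
        if needed <= 0:
            break
        take = min(b - a, needed)
        segments.append((a, a + take))
        needed -= take
    return segments


def _build_chain(
    chain_id: int, chrom: str, chrom_size: int, segments: list[tuple[int, int]], q_name: str,
    q_strand: str, q_size: int = 10_000_000,
) -> Chain:
    q_local = 1_000
    blocks_local = []
    prev_end = None
    for a, b in segments:
        if prev_end is not None:
            q_local += a - prev_end  # dq mirrors dt
        blocks_local.append((a, b, q_local, q_local + (b - a)))
        q_local += b - a
        prev_end = b
    q_start, q_end = 1_000, q_local
    blocks = []
    for a, b, qa, qb in blocks_local:
        if q_strand == "-":
            blocks.append((a, b, q_size - qb, q_size - qa))
        else:
            blocks.append((a, b, qa, qb))
    return Chain(
        chain_id=chain_id, score=1000.0 + chain_id, t_name=chrom, t_size=chrom_size,
        t_start=segments[0][0], t_end=segments[-1][1], q_name=q_name, q_size=q_size,
        q_strand=q_strand, q_start=q_start, q_end=q_end, blocks=blocks,
    )


def chromosome_sizes(config: SimulationConfig) -> dict[str, int]:
    n_chrom = (config.n_pcg + GENES_PER_CHROM - 1) // GENES_PER_CHROM
    size = GENE_MARGIN + GENES_PER_CHROM * GENE_SLOT + 8_000
    return {f"chr{c + 1}": size for c in range(n_chrom)}


def generate_conservation(
    transcripts: list[TranscriptModel],
    truth: SyntheticTruth,
    config: SimulationConfig,
) -> tuple[ChainAlignmentSet, ChainAlignmentSet, HitTable, HitTable]:
    """Chain files (two comparison species) and hit tables realizing the
    planted covered fractions and homology flags exactly."""
    rng = np.random.default_rng(config.seed + 3)
    sizes = chromosome_sizes(config)
    by_id = {t.transcript_id: t for t in transcripts}
    chains_a, chains_b = [], []
    hit_rows_a, hit_rows_b = [], []
    chain_counter = 1
    for idx, tid in enumerate(sorted(truth.conservation_class)):
        t = by_id[tid]
        exons = [(e.start, e.end) for e in t.exons]
        length = t.exonic_length
        fa, fb = truth.conservation_fractions[tid]
        for frac, bucket, q_name in (
            (fa, chains_a, "hchr1"),
            (fb, chains_b, "mchr1"),
        ):
            needed = int(round(frac * length))
            if needed <= 0:
                continue
            segments = _cover_prefix(exons, needed)
            strand = "+" if idx % 2 == 0 else "-"
            bucket.append(
                _build_chain(chain_counter, t.chrom, sizes[t.chrom], segments, q_name, strand)
            )
            chain_counter += 1
        hom_a, hom_b = truth.transcript_homology[tid]
        for hom, rows, subject in ((hom_a, hit_rows_a, "HUMAN_LNC"), (hom_b, hit_rows_b, "MOUSE_LNC")):
            if hom:
                span = int(np.ceil(0.30 * length))
                start = 0
            elif rng.random() < 0.5:
                span = max(int(0.10 * length), 1)
                start = 0
            else:
                continue
            identity = float(np.round(rng.uniform(80, 98), 1))
            rows.append(
                (
                    tid, f"{subject}_{idx:04d}", identity, span, int(span * (1 - identity / 100)),
                    0, start, start + span, 100, 100 + span, 1e-6, float(np.round(span * 1.8, 1)),
                )
            )

    def _table(rows) -> HitTable:
        return HitTable(pd.DataFrame(rows, columns=lio.HIT_COLUMNS))

    return (
        ChainAlignmentSet("pig2human", chains_a),
        ChainAlignmentSet("pig2mouse", chains_b),
        _table(hit_rows_a),
        _table(hit_rows_b),
    )


# ---------------------------------------------------------------------------
# ancillary tables


def generate_coding_table(transcripts: list[TranscriptModel], truth: SyntheticTruth) -> dict:
    table = {}
    for t in transcripts:
        tid = t.transcript_id
        if tid in truth.pcg_transcript_ids:
            table[tid] = {"CNCI": "coding", "CPC": "coding"}
        elif truth.decoy_step.get(tid) == "coding_potential":
            table[tid] = {"CNCI": "coding", "CPC": "noncoding"}  # union rule: one caller suffices
        else:
            table[tid] = {"CNCI": "noncoding", "CPC": "noncoding"}
    return table


def generate_ncrna_table(truth: SyntheticTruth) -> dict[str, frozenset[str]]:
    # a few planted lncRNAs match curated lncRNA family models only (retained)
    chosen = sorted(truth.lncrna_category)[:3]
    return {tid: frozenset({"lncRNA_model"}) for tid in chosen}


def generate_snps(
    transcripts: list[TranscriptModel],
    annotation: list[TranscriptModel],
    truth: SyntheticTruth,
    config: SimulationConfig,
) -> list[GenomicInterval]:
    """SNP positions with planted exonic densities (per kb) by gene class."""
    rng = np.random.default_rng(config.seed + 4)
    snps = []
    lnc_ids = set(truth.lncrna_category)
    for t in sorted(transcripts + annotation, key=lambda x: x.transcript_id):
        if t.transcript_id in lnc_ids:
            rate = config.snp_rate_lnc
        elif t.biotype == "protein_coding":
            rate = config.snp_rate_pcg
        else:
            continue
        n = rng.poisson(rate * t.exonic_length / 1e3)
        positions = np.concatenate([np.arange(e.start, e.end) for e in t.exons])
        n = min(n, positions.size)
        if n == 0:
            continue
        for pos in sorted(rng.choice(positions, size=n, replace=False)):
            snps.append(GenomicInterval(t.chrom, int(pos), int(pos) + 1, "."))
    return sorted(snps, key=lambda s: (s.chrom, s.start))


def generate_go_map(truth: SyntheticTruth, config: SimulationConfig) -> dict[str, set[str]]:
    """GO annotation over coding genes; each module has a hallmark term
    carried by ~80% of its coding members and rarely elsewhere."""
    rng = np.random.default_rng(config.seed + 5)
    generic = [f"GO:{1000000 + k}" for k in range(30)]
    mapping: dict[str, set[str]] = {}
    for gid in truth.pcg_gene_ids:
        terms = set(rng.choice(generic, size=2, replace=False))
        module = truth.module_label.get(gid)
        if module is not None and rng.random() < 0.8:
            terms.add(truth.module_go_term[module])
        elif rng.random() < 0.03:
            terms.add(truth.module_go_term[f"mod{1 + int(rng.integers(len(config.module_spec)))}"])
        mapping[gid] = terms
    return mapping


# ---------------------------------------------------------------------------
# two-library sampling for the MA-plot test calibration


def simulate_two_library_counts(
    n_genes: int,
    library_size: int = 10_000_000,
    planted_fraction: float = 0.0,
    planted_log2fc: float = 2.0,
    mean_range: tuple[float, float] = (100.0, 2000.0),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Binomial two-library counts under the random-sampling null, with an
    optional planted fraction of genes changed by ``planted_log2fc``.

    Returns ``(c1, c2, is_de)``.
    """
    rng = np.random.default_rng(seed)
    lam = np.exp(rng.uniform(np.log(mean_range[0]), np.log(mean_range[1]), size=n_genes))
    is_de = np.zeros(n_genes, dtype=bool)
    n_de = int(round(planted_fraction * n_genes))
    if n_de:
        is_de[rng.choice(n_genes, size=n_de, replace=False)] = True
    p1 = lam / library_size
    fold = 2.0 ** planted_log2fc
    p2 = np.where(is_de, p1 * fold, p1)
    if (p2 >= 1).any():
        raise ValueError("library size too small for requested means")
    c1 = rng.binomial(library_size, p1)
    c2 = rng.binomial(library_size, p2)
    return c1, c2, is_de


def simulate_coexpression(
    module_spec: tuple[ModuleSpec, ...] = (
        ModuleSpec(50, 0.8, True),
        ModuleSpec(50, 0.8, False),
        ModuleSpec(50, 0.8, False),
    ),
    n_samples: int = 30,
    n_background: int = 0,
    n_trait_positive: int = 5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, np.ndarray]:
    """Block-correlated expression with planted modules and a binary trait.

    Module genes follow x = sqrt(rho) f + sqrt(1 - rho) e with a shared
    per-module factor f; the trait-linked module's factor is the
    standardized trait plus N(0, 0.3) noise. Returns
    ``(expression, planted_labels, trait_vector)``.
    """
    rng = np.random.default_rng(seed)
    trait = np.zeros(n_samples)
    trait[rng.choice(n_samples, size=n_trait_positive, replace=False)] = 1.0
    trait_std = (trait - trait.mean()) / trait.std()
    rows, labels, names = [], [], []
    for m, spec in enumerate(module_spec):
        name = f"planted{m + 1}"
        f = trait_std + rng.normal(0, 0.3, n_samples) if spec.trait_linked else rng.normal(0, 1, n_samples)
        rho = spec.within_correlation
        for g in range(spec.size):
            rows.append(np.sqrt(rho) * f + np.sqrt(1 - rho) * rng.normal(0, 1, n_samples))
            labels.append(name)
            names.append(f"{name}_g{g:03d}")
    for g in range(n_background):
        rows.append(rng.normal(0, 1, n_samples))
        labels.append("background")
        names.append(f"bg_g{g:03d}")
    expr = pd.DataFrame(np.vstack(rows), index=names, columns=[f"s{j:02d}" for j in range(n_samples)])
    return expr, pd.Series(labels, index=names, name="module"), trait


# ---------------------------------------------------------------------------
# dataset emission


def emit_dataset(config: SimulationConfig, outdir: str | Path) -> SyntheticTruth:
    """Write the complete synthetic dataset to ``outdir`` in the formats the
    pipeline reads, plus ``truth.json``. Deterministic given the seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    annotation, transcripts, sequences, truth = generate_annotation(config)
    counts = generate_expression(transcripts, annotation, truth, config)
    net_counts, trait = generate_network_expression(transcripts, annotation, truth, config)
    chains_a, chains_b, hits_a, hits_b = generate_conservation(transcripts, truth, config)

    lio.write_gtf(annotation, outdir / "annotation.gtf")
    lio.write_gtf(transcripts, outdir / "transcripts.gtf")
    lio.write_fasta(sequences, outdir / "transcripts.fa")
    lio.write_counts(counts, outdir / "counts.tsv")
    lio.write_counts(net_counts, outdir / "network_counts.tsv")
    trait.to_frame("muscle").to_csv(outdir / "muscle_vector.tsv", sep="\t")
    lio.write_chain(chains_a, outdir / "pig2human.chain")
    lio.write_chain(chains_b, outdir / "pig2mouse.chain")
    lio.write_hits(hits_a, outdir / "hits_human.tsv")
    lio.write_hits(hits_b, outdir / "hits_mouse.tsv")
    lio.write_coding_table(generate_coding_table(transcripts, truth), outdir / "coding.tsv")
    lio.write_ncrna_table(generate_ncrna_table(truth), outdir / "ncrna.tsv")
    lio.write_bed(generate_snps(transcripts, annotation, truth, config), outdir / "snps.bed")
    lio.write_go(
        {g: sorted(t) for g, t in generate_go_map(truth, config).items()}, outdir / "go_map.tsv"
    )
    truth.to_json(outdir / "truth.json")
    return truth
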