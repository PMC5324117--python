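"""Genome-alignment and transcript-homology conservation classification.

A transcript is sequence-level conserved toward a species when at least
50% of its exonic nucleotides fall inside the union of aligned chain
blocks toward that species, each nucleotide counted at most once however
many chains cover it. Combining two comparison species gives a four-way
class: conserved in both (``three_way``, i.e. shared by all three
genomes), in exactly one (``A_only`` / ``B_only``), or in neither
(``species_specific``).

Transcript-level homology instead asks whether the union of BLAST hit
intervals on the query covers at least 20% of the query length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import merge_intervals, overlap_length
from .io import ChainAlignmentSet, HitTable, TranscriptModel

logger = logging.getLogger(__name__)

GENOME_CLASSES = ("three_way", "A_only", "B_only", "species_specific")


@dataclass(frozen=True)
class ConservationCall:
    transcript_id: str
    covered_fraction_a: float
    covered_fraction_b: float
    genome_class: str
    transcript_homology_a: bool | None = None
    transcript_homology_b: bool | None = None


def chain_coverage(
    t: TranscriptModel, chains: ChainAlignmentSet, span_based: bool = False
) -> float:
    """Fraction of t's exonic nucleotides inside the union of chain target
    blocks (``span_based=True`` measures over the genomic span instead)."""
    blocks = chains.target_blocks(t.chrom)
    if blocks.size == 0:
        logger.debug("no chain blocks on %s for %s", t.chrom, t.transcript_id)
        return 0.0
    if span_based:
        region = [(t.interval.start, t.interval.end)]
        denom = t.interval.length
    else:
        region = [(e.start, e.end) for e in t.exons]
        denom = t.exonic_length
    covered = overlap_length(region, [tuple(b) for b in blocks])
    return covered / denom


def classify_genome_conservation(frac_a: float, frac_b: float, threshold: float = 0.5) -> str:
    """Four-way class from the two covered fractions (comparisons are >=)."""
    for f in (frac_a, frac_b):
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"covered fraction outside [0, 1]: {f}")
    a, b = frac_a >= threshold, frac_b >= threshold
    if a and b:
        return "three_way"
    if a:
        return "A_only"
    if b:
        return "B_only"
    return "species_specific"


def transcript_homology(
    t_id: str, query_length: int, hits: HitTable, min_cov: float = 0.2,
    mode: str = "union",
) -> bool:
    """Is >= ``min_cov`` of the query covered by its BLAST hits?

    ``mode='union'`` merges hit query intervals (default); ``'best'`` uses the
    single longest hit.
    """
    rows = hits.for_query(t_id)
    if len(rows) == 0:
        return False
    if (rows["query_end"] > query_length).any():
        raise ValueError(f"{t_id}: hit coordinates exceed query length {query_length}")
    pairs = list(zip(rows["query_start"], rows["query_end"]))
    if mode == "union":
        covered = sum(b - a for a, b in merge_intervals(pairs))
    elif mode == "best":
        covered = max(b - a for a, b in pairs)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return covered / query_length >= min_cov


def call_conservation(
    transcripts: list[TranscriptModel],
    chains_a: ChainAlignmentSet,
    chains_b: ChainAlignmentSet,
    hits_a: HitTable | None = None,
    hits_b: HitTable | None = None,
    threshold: float = 0.5,
    min_hit_cov: float = 0.2,
) -> list[ConservationCall]:
    """Per-transcript genome-alignment classes plus optional hit homology."""
    calls = []
    for t in transcripts:
        fa = chain_coverage(t, chains_a)
        fb = chain_coverage(t, chains_b)
        ha = (
            transcript_homology(t.transcript_id, t.exonic_length, hits_a, min_hit_cov)
            if hits_a is not None
            else None
        )
        hb = (
            transcript_homology(t.transcript_id, t.exonic_length, hits_b, min_hit_cov)
            if hits_b is not None
            else None
        )
        calls.append(
            ConservationCall(
                t.transcript_id, fa, fb, classify_genome_conservation(fa, fb, threshold), ha, hb
            )
        )
    return calls


def conservation_vs_specificity(
    calls: list[ConservationCall], js_scores: pd.Series
) -> dict:
    """Specificity-score distributions per conservation class, with a
    two-sided Mann-Whitney comparison of the fully conserved vs
    species-specific classes (skipped when a class has < 2 members)."""
    per_class: dict[str, np.ndarray] = {}
    for cls in GENOME_CLASSES:
        ids = [c.transcript_id for c in calls if c.genome_class == cls]
        vals = js_scores.reindex(ids).dropna().to_numpy()
        per_class[cls] = vals
    summary = {
        cls: {
            "n": int(v.size),
            "median_js": float(np.median(v)) if v.size else float("nan"),
            "mean_js": float(np.mean(v)) if v.size else float("nan"),
        }
        for cls, v in per_class.items()
    }
    a, b = per_class["three_way"], per_class["species_specific"]
    if a.size >= 2 and b.size >= 2:
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        comparison = {"skipped": False, "u_statistic": float(stat), "p_value": float(p)}
    else:
        comparison = {"skipped": True}
    return {"per_class": summary, "three_way_vs_specific": comparison}


def calls_to_frame(calls: list[ConservationCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "transcript_id": [c.transcript_id for c in calls],
            "covered_fraction_a": [c.covered_fraction_a for c in calls],
            "covered_fraction_b": [c.covered_fraction_b for c in calls],
            "genome_class": [c.genome_class for c in calls],
            "transcript_homology_a": [c.transcript_homology_a for c in calls],
            "transcript_homology_b": [c.transcript_homology_b for c in calls],
        }
    )
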