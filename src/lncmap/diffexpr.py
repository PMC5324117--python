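"""Replicate-free differential expression between two libraries (MA-plot
random-sampling test), BH correction, DE calling over stage pairs, and
lncRNA/neighbor-gene expression correlation.

The two-library test models counts as binomial draws with a shared
per-transcript probability: C1 ~ Bin(n1, p), C2 ~ Bin(n2, p) with library
sizes n1, n2. On the MA plane (M = log2 C1 - log2 C2,
A = (log2 C1 + log2 C2)/2) the null conditional distribution of M given A
is approximately normal with

    E[M | A]   = log2(n1 / n2)
    Var[M | A] = 4 (1 - p̂) sqrt(n1 n2) / (ln^2 2 · (n1 + n2) · 2^A),
    p̂         = 2^A / sqrt(n1 n2)

obtained by the delta method (these moments are validated against a
Monte-Carlo conditional-moment simulation in the test suite). The reported
fold change is the library-size-normalized ratio, log2FC = M - log2(n1/n2),
so the FC >= 2 rule is depth-independent. Zero counts are replaced by a
pseudocount of 1 before logs; transcripts with zero counts in both
libraries are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionMatrix
from .filters import FilterVerdict
from .io import CountMatrix, TranscriptModel

LN2 = np.log(2.0)


def mars_test(c1, c2, n1: float, n2: float):
    """MA-plot random-sampling test for two libraries (vectorized).

    Parameters are counts in the two libraries and the two library sizes;
    returns ``(M, A, z, p)`` arrays. Zero counts get a pseudocount of 1.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library sizes must be positive")
    c1 = np.maximum(np.asarray(c1, dtype=float), 1.0)
    c2 = np.maximum(np.asarray(c2, dtype=float), 1.0)
    M = np.log2(c1) - np.log2(c2)
    A = 0.5 * (np.log2(c1) + np.log2(c2))
    geo = np.sqrt(n1 * n2)
    p_hat = np.minimum(2.0 ** A / geo, 1.0 - 1e-12)
    mu = np.log2(n1 / n2)
    var = 4.0 * (1.0 - p_hat) * geo / (LN2 ** 2 * (n1 + n2) * 2.0 ** A)
    z = (M - mu) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(np.abs(z))
    return M, A, z, p


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return stats.false_discovery_control(p, method="bh")


@dataclass
class DEResult:
    """Per-transcript two-library test results for one stage pair."""

    pair: tuple[str, str]
    table: pd.DataFrame  # columns: count_1 count_2 M A z p q log2FC significant

    @property
    def significant_ids(self) -> set[str]:
        return set(self.table.index[self.table["significant"]])


def de_pair(
    counts: CountMatrix,
    sample_1: str,
    sample_2: str,
    min_fc: float = 2.0,
    max_q: float = 0.05,
) -> DEResult:
    """Test one pair of single-sample libraries; FC rule on normalized M."""
    c1 = counts.counts[sample_1].to_numpy()
    c2 = counts.counts[sample_2].to_numpy()
    n1 = float(counts.library_sizes[sample_1])
    n2 = float(counts.library_sizes[sample_2])
    keep = (c1 > 0) | (c2 > 0)
    ids = counts.counts.index[keep]
    M, A, z, p = mars_test(c1[keep], c2[keep], n1, n2)
    q = bh_adjust(p)
    log2fc = M - np.log2(n1 / n2)
    significant = (np.abs(log2fc) >= np.log2(min_fc)) & (q < max_q)
    table = pd.DataFrame(
        {
            "count_1": c1[keep],
            "count_2": c2[keep],
            "M": M,
            "A": A,
            "z": z,
            "p": p,
            "q": q,
            "log2FC": log2fc,
            "significant": significant,
        },
        index=ids,
    )
    return DEResult((sample_1, sample_2), table)


def call_de(
    counts: CountMatrix,
    stage_samples: Sequence[str],
    min_fc: float = 2.0,
    max_q: float = 0.05,
) -> dict:
    """DE calls for every pair of developmental stages plus the Venn split.

    ``stage_samples`` are the single-sample stage columns in temporal order,
    e.g. ``("muscle_d0", "muscle_d30", "muscle_d240")``.
    """
    pairs = list(combinations(stage_samples, 2))
    results = {p: de_pair(counts, *p, min_fc=min_fc, max_q=max_q) for p in pairs}
    sig_sets = {p: r.significant_ids for p, r in results.items()}
    union = set().union(*sig_sets.values()) if sig_sets else set()
    venn = {}
    for tid in union:
        key = tuple(sorted("%s|%s" % p for p in pairs if tid in sig_sets[p]))
        venn.setdefault(key, set()).add(tid)
    return {
        "results": results,
        "significant_per_pair": {p: sorted(s) for p, s in sig_sets.items()},
        "union": sorted(union),
        "venn": {k: sorted(v) for k, v in venn.items()},
    }


@dataclass(frozen=True)
class NeighborPair:
    lnc_id: str
    pcg_id: str
    relation: str  # nearest_intergenic | overlapped_intragenic
    distance: int
    pearson_r: float


def neighbor_correlation(
    lnc_transcripts: Sequence[TranscriptModel],
    pcg_transcripts: Sequence[TranscriptModel],
    expr: ExpressionMatrix | pd.DataFrame,
    verdicts: Mapping[str, FilterVerdict] | Mapping[str, str],
    pseudocount: float = 1.0,
) -> dict:
    """Correlate lncRNAs with their neighboring/overlapped protein-coding genes.

    Intergenic lncRNAs pair with the nearest gene on their chromosome
    (span-to-span distance); antisense/intronic/cis-regulatory lncRNAs pair
    with the closest overlapped-or-adjacent gene. Pearson r is computed on
    log2(RPKM + pseudocount) across samples. lncRNAs with no gene on their
    chromosome are skipped and counted.
    """
    rpkm = expr.rpkm if isinstance(expr, ExpressionMatrix) else expr
    log = np.log2(rpkm.astype(float) + pseudocount)

    def _category(tid: str) -> str:
        v = verdicts[tid]
        return v.category if isinstance(v, FilterVerdict) else v

    genes_by_chrom: dict[str, list[TranscriptModel]] = {}
    for g in pcg_transcripts:
        genes_by_chrom.setdefault(g.chrom, []).append(g)

    pairs: list[NeighborPair] = []
    skipped = 0
    for lnc in lnc_transcripts:
        if lnc.transcript_id not in log.index:
            continue
        candidates = genes_by_chrom.get(lnc.chrom, [])
        if not candidates:
            skipped += 1
            continue
        span = lnc.interval
        best, best_d = None, None
        for g in candidates:
            gs = g.interval
            d = max(max(gs.start, span.start) - min(gs.end, span.end), 0)
            if best_d is None or d < best_d:
                best, best_d = g, d
        if best.transcript_id not in log.index and best.gene_id not in log.index:
            skipped += 1
            continue
        gene_key = best.transcript_id if best.transcript_id in log.index else best.gene_id
        x = log.loc[lnc.transcript_id].to_numpy()
        y = log.loc[gene_key].to_numpy()
        if x.std() == 0 or y.std() == 0:
            skipped += 1
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        relation = (
            "nearest_intergenic" if _category(lnc.transcript_id) == "intergenic"
            else "overlapped_intragenic"
        )
        pairs.append(NeighborPair(lnc.transcript_id, best.gene_id, relation, int(best_d), r))

    out: dict = {"pairs": pairs, "n_skipped": skipped}
    for relation in ("nearest_intergenic", "overlapped_intragenic"):
        rs = [p.pearson_r for p in pairs if p.relation == relation]
        out[relation] = {
            "n": len(rs),
            "mean_r": float(np.mean(rs)) if rs else float("nan"),
            "fraction_positive": float(np.mean([r > 0 for r in rs])) if rs else float("nan"),
        }
    return out
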