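"""Expression-level summaries: RPKM, breadth, GC content, SNP density and
correlation-based sample clustering.

RPKM is computed on read pairs (fragments): counts / (exonic kb) /
(millions of mapped pairs). Sample clustering uses average linkage on
1 - Pearson correlation of log2(RPKM + 1) profiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .intervals import merge_intervals
from .io import CountMatrix, GenomicInterval, TranscriptModel


@dataclass
class ExpressionMatrix:
    """RPKM values alongside the counts and lengths they derive from."""

    rpkm: pd.DataFrame
    counts: CountMatrix
    exonic_lengths: pd.Series

    @property
    def sample_labels(self) -> list[str]:
        return list(self.rpkm.columns)

    def rpkm_max(self) -> pd.Series:
        """Per-transcript maximum RPKM across samples (expression-level summary)."""
        return self.rpkm.max(axis=1)


def compute_rpkm(counts: CountMatrix, lengths: Mapping[str, int] | pd.Series) -> ExpressionMatrix:
    """RPKM = count / (exonic length / 1e3) / (library size / 1e6)."""
    lengths = pd.Series(lengths, dtype=float)
    missing = [t for t in counts.transcript_ids if t not in lengths.index]
    if missing:
        raise KeyError(f"no exonic length for counted transcripts: {missing[:5]}")
    lengths = lengths.loc[counts.transcript_ids]
    if (lengths <= 0).any():
        raise ValueError("exonic lengths must be positive")
    kb = lengths.to_numpy()[:, None] / 1e3
    millions = counts.library_sizes.to_numpy(dtype=float)[None, :] / 1e6
    rpkm = counts.counts.to_numpy(dtype=float) / kb / millions
    rpkm_df = pd.DataFrame(rpkm, index=counts.counts.index, columns=counts.counts.columns)
    return ExpressionMatrix(rpkm_df, counts, lengths.astype(int))


def expression_breadth(expr: ExpressionMatrix | pd.DataFrame, threshold: float = 0.0) -> pd.Series:
    """Number of samples in which each transcript exceeds ``threshold`` RPKM."""
    rpkm = expr.rpkm if isinstance(expr, ExpressionMatrix) else expr
    return (rpkm > threshold).sum(axis=1)


def breadth_summary(breadth: pd.Series, n_samples: int, restricted_below: int = 3) -> dict[str, float]:
    """Fractions of transcripts with restricted (<3 samples, among expressed)
    and ubiquitous (all samples) expression."""
    n = len(breadth)
    return {
        "n_transcripts": n,
        "fraction_restricted": float((breadth < restricted_below).mean()) if n else np.nan,
        "fraction_ubiquitous": float((breadth == n_samples).mean()) if n else np.nan,
    }


def gc_content(seq: str) -> float:
    """GC percentage; N bases are excluded from the denominator.

    Returns NaN for empty or all-N sequences.
    """
    s = seq.upper()
    counts = {b: s.count(b) for b in "ACGT"}
    denom = sum(counts.values())
    if denom == 0:
        return float("nan")
    return 100.0 * (counts["G"] + counts["C"]) / denom


def snp_density(t: TranscriptModel, snps: Sequence[GenomicInterval]) -> float:
    """SNPs per kb of exonic sequence (SNPs are 1-nt intervals)."""
    exons = merge_intervals((e.start, e.end) for e in t.exons)
    n = 0
    for s in snps:
        if s.chrom != t.chrom:
            continue
        pos = s.start
        n += any(a <= pos < b for a, b in exons)
    return n / (t.exonic_length / 1e3)


@dataclass
class SampleTree:
    """Average-linkage sample dendrogram on 1 - Pearson correlation."""

    linkage: np.ndarray
    labels: list[str]
    correlation: pd.DataFrame

    def merge_order(self) -> list[tuple[frozenset[str], frozenset[str], float]]:
        """Leaf-label sets joined at each merge, with merge heights."""
        n = len(self.labels)
        members: dict[int, frozenset[str]] = {i: frozenset([self.labels[i]]) for i in range(n)}
        order = []
        for i, (a, b, height, _) in enumerate(self.linkage):
            sa, sb = members[int(a)], members[int(b)]
            order.append((sa, sb, float(height)))
            members[n + i] = sa | sb
        return order

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def _fmt(node, parent_dist):
            length = parent_dist - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6f}"
            left = _fmt(node.left, node.dist)
            right = _fmt(node.right, node.dist)
            return f"({left},{right}):{length:.6f}"

        return f"({_fmt(tree.left, tree.dist)},{_fmt(tree.right, tree.dist)});"


def cluster_samples(
    expr: ExpressionMatrix | pd.DataFrame,
    subset: Sequence[str] | None = None,
    pseudocount: float = 1.0,
) -> SampleTree:
    """Cluster samples by expression correlation over a transcript subset."""
    rpkm = expr.rpkm if isinstance(expr, ExpressionMatrix) else expr
    if subset is not None:
        rpkm = rpkm.loc[list(subset)]
    if rpkm.shape[1] < 3:
        raise ValueError("sample clustering needs >= 3 samples")
    log = np.log2(rpkm.to_numpy(dtype=float) + pseudocount)
    sds = log.std(axis=0)
    for j, sd in enumerate(sds):
        if sd == 0:
            raise ValueError(f"zero-variance sample: {rpkm.columns[j]}")
    corr = np.corrcoef(log.T)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    condensed = dist[np.triu_indices_from(dist, k=1)]
    linkage = hierarchy.linkage(condensed, method="average")
    return SampleTree(
        linkage, list(rpkm.columns), pd.DataFrame(corr, index=rpkm.columns, columns=rpkm.columns)
    )
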