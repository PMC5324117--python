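"""Weighted co-expression network: soft threshold, adjacency, topological
overlap, module detection, eigengenes, trait correlation, hubs and
guilt-by-association function inference.

The network is unsigned: adjacency a_ij = |cor(x_i, x_j)|^beta with the
soft-threshold power beta chosen to maximize scale-free topology fit.
Similarity is then the topological overlap

    TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)

with connectivity k_i = sum_{u != i} a_iu and TOM_ii = 1. Modules are cut
from average-linkage clustering of 1 - TOM; each module's eigengene is the
first principal component of its standardized member profiles, oriented to
correlate positively with the module's average profile. Module relevance
to a binary trait (e.g. muscle samples encoded 1, others 0) is the Pearson
correlation between eigengene and trait.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .diffexpr import bh_adjust
from .enrichment import EnrichmentResult, hypergeom_enrich

logger = logging.getLogger(__name__)

UNASSIGNED = "unassigned"

DEFAULT_POWERS = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 14, 16, 18, 20)


def _correlation(expr: pd.DataFrame) -> np.ndarray:
    X = expr.to_numpy(dtype=float)
    sds = X.std(axis=1)
    bad = np.flatnonzero(sds == 0)
    if bad.size:
        raise ValueError(f"constant expression rows: {list(expr.index[bad][:5])}")
    corr = np.corrcoef(X)
    if not np.isfinite(corr).all():
        i, j = np.argwhere(~np.isfinite(corr))[0]
        raise ValueError(f"non-finite correlation for pair ({expr.index[i]}, {expr.index[j]})")
    return corr


def adjacency_matrix(expr: pd.DataFrame, beta: int) -> np.ndarray:
    """Unsigned weighted adjacency |pearson|^beta with unit diagonal."""
    if beta < 1:
        raise ValueError("beta must be >= 1")
    adj = np.abs(_correlation(expr)) ** beta
    np.fill_diagonal(adj, 1.0)
    return adj


def tom_from_adjacency(adj: np.ndarray) -> np.ndarray:
    """Standard unsigned topological overlap matrix of an adjacency."""
    a = np.asarray(adj, dtype=float)
    k = a.sum(axis=0) - 1.0  # connectivity excludes the unit diagonal
    shared = a @ a - 2.0 * a  # sum over u != i,j of a_iu a_uj (diag of a is 1)
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (shared + a) / denom
    tom = np.where(denom > 0, tom, 1.0)
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of the log-log degree-distribution regression."""
    k = np.asarray(connectivity, dtype=float)
    k = k[k > 0]
    if k.size < n_bins:
        return float("nan")
    edges = np.linspace(k.min(), k.max() + 1e-9, n_bins + 1)
    which = np.digitize(k, edges) - 1
    xs, ys = [], []
    for b in range(n_bins):
        members = k[which == b]
        if members.size == 0:
            continue
        xs.append(np.log10(members.mean()))
        ys.append(np.log10(members.size / k.size))
    if len(xs) < 3:
        return float("nan")
    slope, _, r, _, _ = stats.linregress(xs, ys)
    r2 = r ** 2
    return float(-r2 if slope > 0 else r2)


def pick_soft_threshold(
    expr: pd.DataFrame,
    candidate_powers: Sequence[int] = DEFAULT_POWERS,
    fit_min: float = 0.8,
    fallback: int = 6,
) -> tuple[int, pd.DataFrame]:
    """Smallest power whose scale-free fit index reaches ``fit_min``.

    Falls back to power 6 (with a warning) when no candidate reaches the
    fit threshold. Constant rows are removed before correlation.
    """
    sds = expr.to_numpy(dtype=float).std(axis=1)
    if (sds == 0).any():
        dropped = list(expr.index[sds == 0])
        logger.warning("dropping %d constant rows: %s...", len(dropped), dropped[:3])
        expr = expr.loc[sds > 0]
    abs_corr = np.abs(_correlation(expr))
    rows = []
    chosen = None
    for power in candidate_powers:
        adj = abs_corr ** power
        np.fill_diagonal(adj, 1.0)
        k = adj.sum(axis=0) - 1.0
        fit = scale_free_fit(k)
        rows.append({"power": power, "fit": fit, "mean_k": float(k.mean()), "max_k": float(k.max())})
        if chosen is None and np.isfinite(fit) and fit >= fit_min:
            chosen = power
    table = pd.DataFrame(rows)
    if chosen is None:
        logger.warning("no power reached scale-free fit %.2f; defaulting to %d", fit_min, fallback)
        chosen = fallback
    return chosen, table


@dataclass
class CoexpressionNetwork:
    """Adjacency/TOM plus everything derived from them."""

    gene_ids: list[str]
    beta: int
    adjacency: np.ndarray
    tom: np.ndarray
    expr: pd.DataFrame
    module_labels: pd.Series | None = None
    eigengenes: pd.DataFrame | None = None
    kme: pd.Series | None = None
    module_trait: pd.DataFrame | None = None
    hubs: pd.Series | None = None
    linkage: np.ndarray | None = None


def adjacency_tom(expr: pd.DataFrame, beta: int) -> CoexpressionNetwork:
    adj = adjacency_matrix(expr, beta)
    return CoexpressionNetwork(
        gene_ids=list(expr.index),
        beta=beta,
        adjacency=adj,
        tom=tom_from_adjacency(adj),
        expr=expr,
    )


def detect_modules(
    tom: np.ndarray,
    gene_ids: Sequence[str],
    min_module_size: int = 30,
    cut_height: float = 0.99,
) -> tuple[pd.Series, np.ndarray]:
    """Average-linkage clustering of 1 - TOM with a static cut.

    The tree is cut at ``cut_height`` x the maximum merge height; clusters
    smaller than ``min_module_size`` become ``unassigned``. Labels are
    ``M1, M2, ...`` sorted by size, largest first.
    """
    dissim = 1.0 - np.asarray(tom, dtype=float)
    np.fill_diagonal(dissim, 0.0)
    condensed = dissim[np.triu_indices_from(dissim, k=1)]
    Z = hierarchy.linkage(condensed, method="average")
    height = cut_height * Z[:, 2].max()
    raw = hierarchy.fcluster(Z, t=height, criterion="distance")
    sizes = pd.Series(raw).value_counts()
    kept = sizes[sizes >= min_module_size]
    if len(kept) <= 1:
        logger.warning("static cut produced %d module(s)", len(kept))
    order = kept.sort_values(ascending=False).index
    rename = {cluster: f"M{rank + 1}" for rank, cluster in enumerate(order)}
    labels = pd.Series(
        [rename.get(c, UNASSIGNED) for c in raw], index=list(gene_ids), name="module"
    )
    return labels, Z


def module_eigengenes(
    expr: pd.DataFrame, module_labels: pd.Series
) -> tuple[pd.DataFrame, pd.Series, dict[str, float]]:
    """First-PC eigengene per module, per-gene module membership (kME), and
    the variance fraction each eigengene explains.

    Member profiles are standardized across samples before the SVD; the
    eigengene is sign-oriented to correlate positively with the module's
    average standardized profile and has unit norm.
    """
    def _key(m: str):
        return (0, int(m[1:])) if m.startswith("M") and m[1:].isdigit() else (1, m)

    eigengenes = {}
    var_explained = {}
    kme = pd.Series(np.nan, index=expr.index, dtype=float)
    modules = [m for m in module_labels.unique() if m != UNASSIGNED]
    for module in sorted(modules, key=_key):
        members = module_labels.index[module_labels == module]
        X = expr.loc[members].to_numpy(dtype=float)
        if X.shape[0] < 2:
            raise ValueError(f"module {module} has < 2 members")
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, keepdims=True)
        if (sd == 0).any():
            raise ValueError(f"module {module} contains a constant profile")
        Xs = (X - mu) / sd
        U, S, Vt = np.linalg.svd(Xs, full_matrices=False)
        if S[0] == 0:
            raise ValueError(f"module {module} is rank 0")
        eig = Vt[0]
        avg = Xs.mean(axis=0)
        if np.dot(eig, avg) < 0:
            eig = -eig
        eigengenes[module] = eig
        var_explained[module] = float(S[0] ** 2 / (S ** 2).sum())
        centered = eig - eig.mean()
        for gene, row in zip(members, Xs):
            kme.loc[gene] = float(
                np.dot(row - row.mean(), centered)
                / (np.linalg.norm(row - row.mean()) * np.linalg.norm(centered))
            )
    eg = pd.DataFrame(eigengenes, index=expr.columns).T
    eg = eg.loc[sorted(eg.index, key=_key)]
    return eg, kme, var_explained


def module_trait_correlation(
    eigengenes: pd.DataFrame, trait_vector: Sequence[float] | pd.Series
) -> pd.DataFrame:
    """Pearson r (and two-sided t-test p) of each eigengene with a trait."""
    trait = np.asarray(trait_vector, dtype=float)
    if trait.size != eigengenes.shape[1]:
        raise ValueError("trait length must equal the number of samples")
    if np.std(trait) == 0:
        raise ValueError("trait vector is constant")
    rows = []
    for module, eig in eigengenes.iterrows():
        r, p = stats.pearsonr(eig.to_numpy(), trait)
        rows.append({"module": module, "r": float(r), "p": float(p)})
    df = pd.DataFrame(rows).set_index("module")
    return df.reindex(df["r"].abs().sort_values(ascending=False).index)


def identify_hubs(
    kme: pd.Series, module_labels: pd.Series, kme_min: float = 0.9
) -> pd.Series:
    """Hub flag: |kME| >= threshold within an assigned module."""
    assigned = module_labels != UNASSIGNED
    return (kme.abs() >= kme_min) & assigned & kme.notna()


@dataclass
class GuiltByAssociation:
    lnc_id: str
    assessed: bool
    n_correlated: int
    correlated_genes: list[str] = field(default_factory=list)
    enriched_terms: list[EnrichmentResult] = field(default_factory=list)


def guilt_by_association(
    lnc_id: str,
    expr: pd.DataFrame,
    pcg_ids: Sequence[str],
    go_map: Mapping[str, Iterable[str]],
    min_genes: int = 30,
    alpha: float = 0.05,
) -> GuiltByAssociation:
    """Function inference for one lncRNA from its correlated coding genes.

    Protein-coding genes whose expression correlates with the lncRNA at
    BH-adjusted p < alpha form the study set; with fewer than ``min_genes``
    correlated genes the lncRNA is "not assessed", otherwise the study set
    is tested for term over-representation against all ``pcg_ids``.
    """
    if lnc_id not in expr.index:
        raise KeyError(f"lncRNA {lnc_id} absent from expression matrix")
    pcg_ids = [g for g in pcg_ids if g in expr.index]
    x = expr.loc[lnc_id].to_numpy(dtype=float)
    Y = expr.loc[pcg_ids].to_numpy(dtype=float)
    n = x.size
    xc = (x - x.mean()) / (x.std() or 1.0)
    sds = Y.std(axis=1)
    Yc = (Y - Y.mean(axis=1, keepdims=True)) / np.where(sds > 0, sds, 1.0)[:, None]
    r = (Yc @ xc) / n
    r[sds == 0] = 0.0
    r = np.clip(r, -0.9999999, 0.9999999)
    tstat = r * np.sqrt((n - 2) / (1.0 - r ** 2))
    p = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
    q = bh_adjust(p)
    correlated = [g for g, qi in zip(pcg_ids, q) if qi < alpha]
    if len(correlated) < min_genes:
        return GuiltByAssociation(lnc_id, False, len(correlated), correlated)
    enriched = hypergeom_enrich(correlated, pcg_ids, go_map)
    return GuiltByAssociation(lnc_id, True, len(correlated), correlated, enriched)


def build_network(
    expr: pd.DataFrame,
    beta: int | None = None,
    min_module_size: int = 30,
    cut_height: float = 0.99,
    trait_vector: Sequence[float] | None = None,
    kme_min: float = 0.9,
) -> CoexpressionNetwork:
    """One-call pipeline: threshold, adjacency/TOM, modules, eigengenes,
    trait correlations and hubs."""
    if beta is None:
        beta, _ = pick_soft_threshold(expr)
    net = adjacency_tom(expr, beta)
    net.module_labels, net.linkage = detect_modules(
        net.tom, net.gene_ids, min_module_size, cut_height
    )
    if (net.module_labels != UNASSIGNED).any():
        net.eigengenes, net.kme, _ = module_eigengenes(expr, net.module_labels)
        net.hubs = identify_hubs(net.kme, net.module_labels, kme_min)
        if trait_vector is not None:
            net.module_trait = module_trait_correlation(net.eigengenes, trait_vector)
    return net
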