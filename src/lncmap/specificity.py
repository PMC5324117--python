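"""Jensen-Shannon tissue-specificity scoring and tissue association.

The specificity score of an expression profile ``e`` over ``n`` tissues is

    score = max_t [ 1 - sqrt(JSD(p, q_t)) ]

where ``p`` is ``e`` normalized to a probability vector, ``q_t`` the extreme
pattern expressed in tissue ``t`` only, and JSD the Jensen-Shannon
divergence in bits (log base 2), so the score lies in [0, 1] and equals 1
exactly when expression is confined to one tissue.

Tissue association follows the conjunctive rule Z >= 1.5 and RPKM >= 0.5
(Z computed across tissues on raw RPKM with the n-1 sample deviation);
associations with any skeletal-muscle developmental stage are merged into a
single "skeletal muscle" label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix

DEFAULT_MUSCLE_LABEL = "skeletal_muscle"


@dataclass(frozen=True)
class SpecificityResult:
    transcript_id: str
    js_score: float
    best_tissue: str | None
    tied: bool
    z_scores: dict[str, float]
    associated_tissues: frozenset[str]


def _jsd_to_indicators(p: np.ndarray) -> np.ndarray:
    """JSD (bits) between probability vector p and each one-tissue indicator.

    With q_t the indicator of tissue t, the mixture is m = p/2 off t and
    (p_t + 1)/2 at t; the two KL terms collapse to closed forms in p_t.
    """
    pt = p  # per-tissue target entry
    with np.errstate(divide="ignore", invalid="ignore"):
        kl_p = (1.0 - pt) + pt * np.log2(2.0 * pt / (pt + 1.0))
    kl_p = np.where(pt > 0, kl_p, 1.0 - pt)  # 0*log0 = 0
    kl_q = np.log2(2.0 / (pt + 1.0))
    return 0.5 * (kl_p + kl_q)


def js_specificity(expr_vector, labels=None) -> tuple[float, str | None, bool]:
    """Specificity score and best tissue for one expression vector.

    Returns ``(js_score, best_tissue, tied)``; an all-zero vector yields
    ``(nan, None, False)``. Ties on the maximum go to the lexicographically
    smallest label and are flagged.
    """
    e = np.asarray(expr_vector, dtype=float)
    if e.ndim != 1 or e.size < 2:
        raise ValueError("expression vector must be 1-D with >= 2 tissues")
    if (e < 0).any():
        raise ValueError("negative expression")
    if labels is None:
        labels = [str(i) for i in range(e.size)]
    total = e.sum()
    if total == 0:
        return float("nan"), None, False
    p = e / total
    spec = 1.0 - np.sqrt(_jsd_to_indicators(p))
    best = float(spec.max())
    winners = sorted(np.asarray(labels)[spec >= best - 1e-15].tolist())
    return best, winners[0], len(winners) > 1


def js_specificity_matrix(rpkm: pd.DataFrame) -> pd.DataFrame:
    """Vectorized scores for a transcripts x tissues RPKM frame."""
    X = rpkm.to_numpy(dtype=float)
    totals = X.sum(axis=1, keepdims=True)
    ok = totals[:, 0] > 0
    P = np.divide(X, totals, out=np.zeros_like(X), where=totals > 0)
    spec = 1.0 - np.sqrt(_jsd_to_indicators(P))
    js = np.full(len(rpkm), np.nan)
    best = np.full(len(rpkm), None, dtype=object)
    js[ok] = spec[ok].max(axis=1)
    cols = np.asarray(rpkm.columns)
    # lexicographically smallest label among ties
    order = np.argsort(cols, kind="stable")
    spec_sorted = spec[:, order]
    idx = np.argmax(spec_sorted >= (spec.max(axis=1, keepdims=True) - 1e-15), axis=1)
    best[ok] = cols[order][idx[ok]]
    n_ties = (spec >= spec.max(axis=1, keepdims=True) - 1e-15).sum(axis=1)
    return pd.DataFrame(
        {"js_score": js, "best_tissue": best, "tied": (n_ties > 1) & ok},
        index=rpkm.index,
    )


def tissue_association(
    expr: ExpressionMatrix | pd.DataFrame,
    z_min: float = 1.5,
    rpkm_min: float = 0.5,
    muscle_samples: tuple[str, ...] | None = None,
    muscle_label: str = DEFAULT_MUSCLE_LABEL,
) -> dict[str, frozenset[str]]:
    """Associated tissues per transcript under the Z/RPKM conjunctive rule.

    ``muscle_samples`` names the skeletal-muscle developmental-stage columns;
    associations with any of them collapse to ``muscle_label``. Constant rows
    (zero deviation) yield no associations.
    """
    rpkm = expr.rpkm if isinstance(expr, ExpressionMatrix) else expr
    X = rpkm.to_numpy(dtype=float)
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (X - mean) / sd
    hit = (z >= z_min) & (X >= rpkm_min) & (sd > 0)
    muscle = set(muscle_samples or ())
    out: dict[str, frozenset[str]] = {}
    cols = list(rpkm.columns)
    for i, tid in enumerate(rpkm.index):
        tissues = set()
        for j, col in enumerate(cols):
            if hit[i, j]:
                tissues.add(muscle_label if col in muscle else col)
        out[tid] = frozenset(tissues)
    return out


def z_scores(expr: ExpressionMatrix | pd.DataFrame) -> pd.DataFrame:
    rpkm = expr.rpkm if isinstance(expr, ExpressionMatrix) else expr
    X = rpkm.to_numpy(dtype=float)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        Z = (X - X.mean(axis=1, keepdims=True)) / sd
    return pd.DataFrame(Z, index=rpkm.index, columns=rpkm.columns)


def specificity_report(associations: dict[str, frozenset[str]]) -> dict:
    """Counts of tissue-specific transcripts and the single-tissue fraction."""
    specific = {t: a for t, a in associations.items() if a}
    single = sum(1 for a in specific.values() if len(a) == 1)
    per_tissue: dict[str, int] = {}
    for a in specific.values():
        for tissue in a:
            per_tissue[tissue] = per_tissue.get(tissue, 0) + 1
    return {
        "n_transcripts": len(associations),
        "n_specific": len(specific),
        "fraction_specific": len(specific) / len(associations) if associations else float("nan"),
        "single_tissue_fraction": single / len(specific) if specific else float("nan"),
        "per_tissue_counts": dict(sorted(per_tissue.items())),
    }
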