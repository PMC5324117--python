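"""Hypergeometric over-representation testing with BH correction.

For a study set of n genes drawn from a background of N genes of which K
carry a term, the enrichment p-value of observing k or more carriers is
the upper tail of the hypergeometric distribution,

    p = sum_{j >= k} C(K, j) C(N - K, n - j) / C(N, n).

Only over-representation is tested; the background defaults to all genes
entering the relevant analysis stage, not the whole genome.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    study_hits: int
    study_size: int
    background_hits: int
    background_size: int
    p: float
    q: float
    fold: float


def hypergeom_enrich(
    study: Iterable[str],
    background: Iterable[str],
    term_map: Mapping[str, Iterable[str]],
    sort: bool = True,
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric enrichment of a study set per term.

    Terms are taken from ``term_map`` (gene -> terms) restricted to the
    background; only terms with at least one study hit are tested. BH
    adjustment runs across the tested terms. Study genes missing from the
    background raise an error.
    """
    study = set(study)
    background = set(background)
    offenders = sorted(study - background)
    if offenders:
        raise ValueError(f"study genes absent from background: {offenders[:10]}")
    if not background:
        raise ValueError("background is empty")

    term_to_background: dict[str, set[str]] = {}
    for gene in background:
        for term in term_map.get(gene, ()):
            term_to_background.setdefault(term, set()).add(gene)

    N, n = len(background), len(study)
    rows = []
    for term in sorted(term_to_background):
        carriers = term_to_background[term]
        k = len(study & carriers)
        if k == 0:
            continue
        K = len(carriers)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        fold = (k / n) / (K / N)
        rows.append((term, k, n, K, N, min(p, 1.0), fold))
    if not rows:
        return []
    qvals = bh_adjust([r[5] for r in rows])
    results = [
        EnrichmentResult(term, k, n, K, N, p, float(q), fold)
        for (term, k, n, K, N, p, fold), q in zip(rows, qvals)
    ]
    if sort:
        results.sort(key=lambda r: (r.q, r.p, r.term_id))
    return results


def enrichment_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "term_id": [r.term_id for r in results],
            "study_hits": [r.study_hits for r in results],
            "study_size": [r.study_size for r in results],
            "background_hits": [r.background_hits for r in results],
            "background_size": [r.background_size for r in results],
            "p": [r.p for r in results],
            "q": [r.q for r in results],
            "fold": [r.fold for r in results],
        }
    )
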