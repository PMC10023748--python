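"""Pathway over-representation among enzymes with corrected kcats.

One-sided hypergeometric tests against the background of enzymes measured
in all conditions, Benjamini-Hochberg step-up control at FDR 0.05, and a
filter keeping only terms annotated to at least two corrected enzymes.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

logger = logging.getLogger("presto")

DEFAULT_FDR = 0.05
MIN_CORRECTED_PER_TERM = 2

__all__ = [
    "hypergeom_pvalue",
    "bh_adjust",
    "enrich_pathways",
    "DEFAULT_FDR",
]


def hypergeom_pvalue(
    x: int, K: int, N: int, M_total: int, mode: str = "standard"
) -> float:
    """Enrichment p-value for observing x of N drawn enzymes in a term of
    size K, from a background of M_total.

    ``mode="standard"``: the upper tail P(X >= x).
    ``mode="as_printed"``: 1 - sum_{i=1}^{x-1} pmf(i), i.e. the upper tail
    plus P(X = 0) — kept for fidelity to a common misprint of the formula.
    """
    for name, v in (("x", x), ("K", K), ("N", N), ("M_total", M_total)):
        if int(v) != v or v < 0:
            raise ValueError(f"{name} must be a non-negative integer")
    if K > M_total or N > M_total:
        raise ValueError("K and N cannot exceed M_total")
    if x > min(K, N):
        raise ValueError("x cannot exceed min(K, N)")
    dist = hypergeom(M_total, K, N)
    p = float(dist.sf(x - 1))  # P(X >= x)
    if mode == "standard":
        return min(p, 1.0)
    if mode == "as_printed":
        return min(p + float(dist.pmf(0)), 1.0) if x >= 1 else 1.0
    raise ValueError(f"unknown mode {mode!r}")


def bh_adjust(
    pvalues: Sequence[float], fdr: float = DEFAULT_FDR
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: q_(r) = min_{j>=r} p_(j) * m / j.

    Returns (q-values, significance flags at ``fdr``), in input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q, q <= fdr


def enrich_pathways(
    corrected: Iterable[str],
    annotation: Mapping[str, Iterable[str]] | pd.DataFrame,
    background: Iterable[str],
    fdr: float = DEFAULT_FDR,
    min_corrected: int = MIN_CORRECTED_PER_TERM,
    mode: str = "standard",
) -> pd.DataFrame:
    """Per-term enrichment table, sorted by adjusted q.

    ``annotation`` maps enzymes to pathway terms (mapping of enzyme ->
    terms, or a two-column DataFrame enzyme/term). The background is the
    set of enzymes measured in all conditions; annotations outside it are
    ignored. Terms with fewer than ``min_corrected`` corrected enzymes are
    excluded before testing, and BH runs over the tested terms only.
    """
    background = set(background)
    requested = set(corrected)
    corrected = requested & background
    if requested - background:
        logger.warning("enrich_pathways: corrected enzymes outside background ignored")

    term_members: dict[str, set[str]] = {}
    if isinstance(annotation, pd.DataFrame):
        pairs = annotation.iloc[:, :2].itertuples(index=False)
        for enzyme, term in pairs:
            term_members.setdefault(str(term), set()).add(str(enzyme))
    else:
        for enzyme, terms in annotation.items():
            for term in terms:
                term_members.setdefault(str(term), set()).add(str(enzyme))

    M_total = len(background)
    N = len(corrected)
    rows = []
    for term, members in sorted(term_members.items()):
        members = members & background
        x = len(members & corrected)
        if x < min_corrected:
            continue
        K = len(members)
        rows.append(
            {
                "term": term,
                "x": x,
                "K": K,
                "N": N,
                "M_total": M_total,
                "p": hypergeom_pvalue(x, K, N, M_total, mode=mode),
            }
        )
    table = pd.DataFrame(rows)
    if table.empty:
        return pd.DataFrame(
            columns=["term", "x", "K", "N", "M_total", "p", "q", "significant"]
        )
    q, sig = bh_adjust(table["p"].to_numpy(), fdr=fdr)
    table["q"] = q
    table["significant"] = sig
    return table.sort_values("q", kind="stable").reset_index(drop=True)
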