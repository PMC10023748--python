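"""Repeated K-fold cross-validation over the regularization grid.

For each lambda on a log-spaced grid, corrections are fitted on K-1 folds
of conditions and validated on the held-out fold by FBA under the pool
constraint and measured uptake rates (no abundance bounds). The per-lambda
score s_lambda is the average, over iterations, of the product of the
min-max-scaled validation error and the min-max-scaled (log10) total
correction; the chosen lambda sits at the first sign change of the second
numerical gradient of s_lambda, scanning from the largest lambda downward.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .conditions import ConditionRecord, ScenarioSpec, make_condition_model
from .model import PcModel, apply_kcat_corrections
from .presto_lp import DEFAULT_THETA, build_presto_lp, relative_error, solve_presto
from .validation import predict_growth

logger = logging.getLogger("presto")

#: default lambda grid: one point per decade from 1e-14 to 1e-1
DEFAULT_GRID = tuple(10.0 ** k for k in range(-14, 0))
DELTA_FLOOR = 1e-12

__all__ = [
    "CVReport",
    "DEFAULT_GRID",
    "make_cv_folds",
    "run_cv",
    "cv_score",
    "select_lambda",
    "jaccard_distance",
    "fold_overlap",
    "robustness_subsample",
]


@dataclass
class CVReport:
    grid: list[float]
    #: iterations x grid tables
    omega: pd.DataFrame
    total_correction: pd.DataFrame
    scores: np.ndarray
    lambda_star: float
    folds: list[list[list[str]]]
    seed: int
    #: per (lambda, iteration, fold) sets of corrected enzymes
    corrected_sets: dict[float, list[set[str]]] = field(default_factory=dict)


def make_cv_folds(
    conditions: Sequence[ConditionRecord],
    k: int = 3,
    iterations: int = 10,
    seed: int = 0,
) -> list[list[list[str]]]:
    """Per iteration, a random balanced K-partition of condition ids."""
    ids = [c.id for c in conditions]
    if k > len(ids):
        raise ValueError(f"K={k} exceeds the number of conditions ({len(ids)})")
    rng = np.random.default_rng(seed)
    plans = []
    for _ in range(iterations):
        perm = [ids[i] for i in rng.permutation(len(ids))]
        plans.append([list(part) for part in np.array_split(perm, k)])
    return plans


def cv_score(
    omega_table: np.ndarray, delta_table: np.ndarray
) -> np.ndarray:
    """Per-lambda score: mean over iterations of scaled-omega x scaled-logDelta.

    Tables are iterations x lambdas. Degenerate scaling (max == min over
    the lambda axis) contributes 0 for that factor; zero total corrections
    are floored at 1e-12 before log-scaling.
    """
    omega_table = np.asarray(omega_table, dtype=float)
    delta_table = np.asarray(delta_table, dtype=float)
    if omega_table.shape != delta_table.shape:
        raise ValueError("omega and delta tables must have matching shapes")
    T, L = omega_table.shape
    scores = np.zeros(L)
    for t in range(T):
        w = omega_table[t]
        d = np.maximum(delta_table[t], DELTA_FLOOR)
        if (delta_table[t] < DELTA_FLOOR).any():
            logger.info("cv_score: zero total correction floored at %g", DELTA_FLOOR)
        w_rng = w.max() - w.min()
        sw = (w - w.min()) / w_rng if w_rng > 0 else np.zeros(L)
        ld = np.log10(d)
        d_rng = ld.max() - ld.min()
        sd = (ld - ld.min()) / d_rng if d_rng > 0 else np.zeros(L)
        scores += sw * sd
    return scores / T


def select_lambda(scores: Sequence[float], grid: Sequence[float]) -> float:
    """First sign change of the second numerical gradient, scanning from
    the largest lambda downward; falls back to argmin(s) when the
    curvature never changes sign."""
    s = np.asarray(scores, dtype=float)
    grid = list(grid)
    n = len(s)
    if n < 4:
        raise ValueError("lambda selection needs at least 4 grid points")
    g2 = np.empty(n)
    g2[1:-1] = s[2:] - 2 * s[1:-1] + s[:-2]
    g2[0] = s[2] - 2 * s[1] + s[0]
    g2[-1] = s[-1] - 2 * s[-2] + s[-3]
    g2[np.abs(g2) < 1e-12 * max(1.0, np.abs(s).max())] = 0.0
    for k in range(n - 2, -1, -1):
        if g2[k] * g2[k + 1] < 0:
            return grid[k]
    logger.info("select_lambda: no curvature sign change; falling back to argmin")
    return grid[int(np.argmin(s))]


def run_cv(
    pc: PcModel,
    conditions: Sequence[ConditionRecord],
    grid: Sequence[float] = DEFAULT_GRID,
    k: int = 3,
    iterations: int = 10,
    seed: int = 0,
    theta: float = DEFAULT_THETA,
    default_uptake: float = 1000.0,
    **lp_kwargs,
) -> CVReport:
    """Full cross-validation loop: fit on K-1 folds, validate on the rest.

    Validation predicts growth of the held-out conditions with the
    training corrections applied, constraining only the protein pool and
    measured uptake rates.
    """
    conditions = list(conditions)
    by_id = {c.id: c for c in conditions}
    folds = make_cv_folds(conditions, k=k, iterations=iterations, seed=seed)
    grid = list(grid)
    omega_tbl = np.zeros((iterations, len(grid)))
    delta_tbl = np.zeros((iterations, len(grid)))
    corrected_sets: dict[float, list[set[str]]] = {lam: [] for lam in grid}

    for t, plan in enumerate(folds):
        for li, lam in enumerate(grid):
            val_errors: list[float] = []
            fold_deltas: list[float] = []
            for held_out in range(len(plan)):
                train = [
                    by_id[cid]
                    for fi, fold in enumerate(plan)
                    if fi != held_out
                    for cid in fold
                ]
                problem = build_presto_lp(
                    pc, train, lam, theta=theta,
                    default_uptake=default_uptake, **lp_kwargs,
                )
                result = solve_presto(problem)
                fold_deltas.append(result.total_correction)
                corrected_sets[lam].append(result.corrected_enzymes)
                corrected = apply_kcat_corrections(pc, result.delta)
                for cid in plan[held_out]:
                    cond = by_id[cid]
                    cm = make_condition_model(
                        corrected, cond,
                        ScenarioSpec("pool_plus_uptake", default_uptake=default_uptake),
                    )
                    v = predict_growth(cm)
                    if math.isnan(v):
                        logger.info("cv: infeasible validation model for %s", cid)
                        continue
                    val_errors.append(relative_error(cond.growth_rate, v))
            omega_tbl[t, li] = float(np.mean(val_errors)) if val_errors else math.nan
            delta_tbl[t, li] = float(np.mean(fold_deltas))

    scores = cv_score(omega_tbl, delta_tbl)
    lam_star = select_lambda(scores, grid)
    # soft sanity check of the trade-off selection (logged, not asserted)
    star = grid.index(lam_star)
    if np.nanmean(omega_tbl[:, star]) > max(
        np.nanmean(omega_tbl[:, 0]), np.nanmean(omega_tbl[:, -1])
    ):
        logger.info(
            "cv: validation error at lambda* exceeds both grid extremes — "
            "inspect the score curve"
        )
    return CVReport(
        grid=grid,
        omega=pd.DataFrame(omega_tbl, columns=grid),
        total_correction=pd.DataFrame(delta_tbl, columns=grid),
        scores=scores,
        lambda_star=lam_star,
        folds=folds,
        seed=seed,
        corrected_sets=corrected_sets,
    )


def jaccard_distance(a: set, b: set) -> float:
    union = a | b
    if not union:
        return 0.0
    return 1.0 - len(a & b) / len(union)


def fold_overlap(sets: Sequence[set]) -> float:
    """Mean pairwise Jaccard distance of corrected-enzyme sets."""
    sets = list(sets)
    if len(sets) < 2:
        raise ValueError("need at least two sets")
    pairs = list(combinations(range(len(sets)), 2))
    return float(np.mean([jaccard_distance(sets[i], sets[j]) for i, j in pairs]))


def robustness_subsample(
    pc: PcModel,
    conditions: Sequence[ConditionRecord],
    lam: float,
    sizes: Sequence[int] = (3, 5, 10, 15),
    draws: int = 10,
    seed: int = 0,
    min_overlap: int = 3,
    **lp_kwargs,
) -> pd.DataFrame:
    """Concordance of corrections from condition subcollections vs. all.

    For each subcollection size and draw, PRESTO runs at ``lam``; reported
    are the Jaccard distance between corrected-enzyme sets and the Pearson
    correlation of log10 corrected kcats over the intersection of corrected
    enzymes (undefined — NaN — when the intersection has fewer than
    ``min_overlap`` enzymes). Infeasible draws are recorded as missing.
    """
    conditions = list(conditions)
    if max(sizes) > len(conditions):
        raise ValueError("subcollection size exceeds the number of conditions")
    rng = np.random.default_rng(seed)
    kmins = pc.kcat_min_all()

    ref = solve_presto(build_presto_lp(pc, conditions, lam, **lp_kwargs))
    ref_set = ref.corrected_enzymes

    rows = []
    for m in sizes:
        for d in range(draws):
            idx = rng.choice(len(conditions), size=m, replace=False)
            subset = [conditions[i] for i in sorted(idx)]
            try:
                res = solve_presto(build_presto_lp(pc, subset, lam, **lp_kwargs))
            except RuntimeError:
                logger.warning("robustness: infeasible subproblem (m=%d draw %d)", m, d)
                rows.append(
                    {"size": m, "draw": d, "jaccard_distance": math.nan,
                     "pearson_log10": math.nan, "n_overlap": 0}
                )
                continue
            sub_set = res.corrected_enzymes
            overlap = sorted(ref_set & sub_set)
            if len(overlap) >= min_overlap:
                x = np.log10([kmins[e] + ref.delta[e] for e in overlap])
                y = np.log10([kmins[e] + res.delta[e] for e in overlap])
                if np.std(x) > 0 and np.std(y) > 0:
                    pearson = float(np.corrcoef(x, y)[0, 1])
                else:
                    pearson = math.nan
            else:
                pearson = math.nan
            rows.append(
                {
                    "size": m,
                    "draw": d,
                    "jaccard_distance": jaccard_distance(ref_set, sub_set),
                    "pearson_log10": pearson,
                    "n_overlap": len(overlap),
                }
            )
    return pd.DataFrame(rows)
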