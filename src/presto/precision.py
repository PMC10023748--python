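"""Post-optimal variability of the corrections and sampling of alternatives.

With the optimum's per-condition errors fixed within +/-1% and the total
correction fixed within +/-1e-3 (internal kcat units), each delta_i is
minimized and maximized over the remaining solution space. Alternative
optimal corrections are then sampled by drawing uniformly within the
per-enzyme intervals and projecting each draw onto the restricted polytope
by minimizing the L1 distance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import sparse

from .presto_lp import CorrectionResult, PrestoProblem, check_solution
from .validation import DEFAULT_FEAS_TOL, solve_lp

logger = logging.getLogger("presto")

__all__ = [
    "VariabilityResult",
    "SampleSet",
    "delta_variability",
    "sample_corrections",
    "precision_summary",
]


@dataclass
class VariabilityResult:
    delta_min: dict[str, float]
    delta_max: dict[str, float]
    omega_opt: dict[str, float]
    delta_opt_total: float
    omega_tol: float
    delta_tol: float


@dataclass
class SampleSet:
    #: draws x enzymes matrix of projected corrections (s^-1)
    samples: pd.DataFrame
    seed: int
    n_requested: int
    n_feasible: int
    diagnostics: dict = field(default_factory=dict)


def _restricted_arrays(
    problem: PrestoProblem,
    result: CorrectionResult,
    omega_tol: float,
    delta_tol: float,
):
    """LP data with the optimum-fixing windows of the variability analysis."""
    bounds = list(problem.bounds)
    omega_window = {}
    for cond in problem.conditions:
        w = result.omega[cond.id]
        lo = max(0.0, (1.0 - omega_tol) * w)
        hi = min(problem.theta, (1.0 + omega_tol) * w)
        bounds[problem.omega_idx[cond.id]] = (lo, hi)
        omega_window[cond.id] = (lo, hi)

    nvar = problem.nvar
    drow = np.zeros(nvar)
    for i in problem.delta_idx.values():
        drow[i] = 1.0
    total = result.total_correction
    A_extra = sparse.csr_matrix(np.vstack([drow, -drow]))
    b_extra = np.array([total + delta_tol, -(total - delta_tol)])
    A_ub = sparse.vstack([problem.A_ub, A_extra]).tocsr()
    b_ub = np.concatenate([problem.b_ub, b_extra])
    delta_window = (total - delta_tol, total + delta_tol)
    return A_ub, b_ub, bounds, omega_window, delta_window


def delta_variability(
    problem: PrestoProblem,
    result: CorrectionResult,
    omega_tol: float = 0.01,
    delta_tol: float = 1e-3,
    feas_tol: float = DEFAULT_FEAS_TOL,
) -> VariabilityResult:
    """Per-enzyme [delta_min, delta_max] over alternative optima.

    If the fixed-optimum polytope is numerically empty the tolerances are
    widened once (x10) with a warning.
    """
    for attempt, (wt, dt) in enumerate(
        [(omega_tol, delta_tol), (10 * omega_tol, 10 * delta_tol)]
    ):
        A_ub, b_ub, bounds, _, _ = _restricted_arrays(problem, result, wt, dt)
        dmin: dict[str, float] = {}
        dmax: dict[str, float] = {}
        ok = True
        for e, col in problem.delta_idx.items():
            c = np.zeros(problem.nvar)
            c[col] = 1.0
            lo = solve_lp(c, A_ub, b_ub, problem.A_eq, problem.b_eq, bounds, feas_tol)
            hi = solve_lp(-c, A_ub, b_ub, problem.A_eq, problem.b_eq, bounds, feas_tol)
            if lo.status != 0 or hi.status != 0:
                ok = False
                break
            cap = problem.delta_upper(e)
            dmin[e] = min(max(float(lo.x[col]), 0.0), cap)
            dmax[e] = min(max(float(hi.x[col]), 0.0), cap)
        if ok:
            if attempt == 1:
                logger.warning(
                    "delta_variability: fixed-optimum polytope empty at the "
                    "requested tolerances; widened once (x10)"
                )
            return VariabilityResult(
                delta_min=dmin,
                delta_max=dmax,
                omega_opt=dict(result.omega),
                delta_opt_total=result.total_correction,
                omega_tol=wt,
                delta_tol=dt,
            )
    raise RuntimeError("variability analysis infeasible even after widening tolerances")


class _ProjectionWorkspace:
    """Reusable LP data for L1 projections onto the fixed-optimum polytope.

    Variables are [original LP variables, p, q] with split constraints
    delta_i - p_i + q_i = delta*_i; the L1 distance is sum(p + q).
    """

    def __init__(self, problem: PrestoProblem, result: CorrectionResult,
                 omega_tol: float, delta_tol: float):
        self.problem = problem
        self.enzymes = sorted(problem.delta_idx)
        nM = len(self.enzymes)
        nvar = problem.nvar
        A_ub0, b_ub0, bounds0, self.omega_window, self.delta_window = _restricted_arrays(
            problem, result, omega_tol, delta_tol
        )
        ext = 2 * nM
        self.nvar, self.nM, self.ext = nvar, nM, ext
        self.A_ub = sparse.hstack(
            [A_ub0, sparse.csr_matrix((A_ub0.shape[0], ext))]
        ).tocsr()
        self.b_ub = b_ub0
        eq_rows = sparse.lil_matrix((nM, nvar + ext))
        for k, e in enumerate(self.enzymes):
            eq_rows[k, problem.delta_idx[e]] = 1.0
            eq_rows[k, nvar + k] = -1.0
            eq_rows[k, nvar + nM + k] = 1.0
        if problem.A_eq is not None:
            self.A_eq = sparse.vstack(
                [
                    sparse.hstack(
                        [problem.A_eq, sparse.csr_matrix((problem.A_eq.shape[0], ext))]
                    ),
                    eq_rows,
                ]
            ).tocsr()
            self.b_eq_base = np.concatenate([problem.b_eq, np.zeros(nM)])
        else:
            self.A_eq = eq_rows.tocsr()
            self.b_eq_base = np.zeros(nM)
        self.bounds = list(bounds0) + [(0.0, None)] * ext
        self.c_l1 = np.zeros(nvar + ext)
        self.c_l1[nvar:] = 1.0

    def project(self, target: np.ndarray, tie_break: str, feas_tol: float):
        """Returns (delta vector, full x, L1 distance) or None if infeasible."""
        b_eq = self.b_eq_base.copy()
        b_eq[-self.nM :] = target
        res = solve_lp(
            self.c_l1, self.A_ub, self.b_ub, self.A_eq, b_eq, self.bounds, feas_tol
        )
        if res.status != 0:
            return None
        x = res.x
        dist = float(x[self.nvar :].sum())
        if tie_break == "lex":
            # fix the distance, then minimize each delta in identifier order
            dist_row = sparse.csr_matrix(self.c_l1)
            A_fix = sparse.vstack([self.A_ub, dist_row]).tocsr()
            b_fix = np.concatenate([self.b_ub, [dist + 1e-9 * max(1.0, dist)]])
            bnd = list(self.bounds)
            for e in self.enzymes:
                col = self.problem.delta_idx[e]
                c2 = np.zeros(self.nvar + self.ext)
                c2[col] = 1.0
                r2 = solve_lp(c2, A_fix, b_fix, self.A_eq, b_eq, bnd, feas_tol)
                if r2.status != 0:
                    break
                val = float(r2.x[col])
                bnd[col] = (bnd[col][0], val + 1e-12)
                x = r2.x
        delta = np.array([x[self.problem.delta_idx[e]] for e in self.enzymes])
        return delta, x, dist


def project_correction(
    problem: PrestoProblem,
    variability: VariabilityResult,
    result: CorrectionResult,
    target: Mapping[str, float],
    tie_break: str = "lex",
    feas_tol: float = DEFAULT_FEAS_TOL,
) -> dict[str, float]:
    """L1-project one candidate correction vector onto the fixed-optimum
    polytope; an interior (feasible) target is returned unchanged."""
    ws = _ProjectionWorkspace(problem, result, variability.omega_tol, variability.delta_tol)
    t = np.array([target[e] for e in ws.enzymes])
    out = ws.project(t, tie_break, feas_tol)
    if out is None:
        raise RuntimeError("projection LP infeasible")
    return dict(zip(ws.enzymes, map(float, out[0])))


def sample_corrections(
    problem: PrestoProblem,
    variability: VariabilityResult,
    result: CorrectionResult,
    n: int = 10000,
    seed: int = 0,
    tie_break: str = "lex",
    feas_tol: float = DEFAULT_FEAS_TOL,
) -> SampleSet:
    """Interval draws projected onto the fixed-optimum polytope (L1).

    Each random vector delta* (uniform within [delta_min, delta_max]) is
    projected by minimizing sum_i |delta_i - delta*_i| via split variables.
    ``tie_break="lex"`` refines ties to the lexicographically least optimal
    vertex (enzymes in identifier order); ``"none"`` returns the solver's
    vertex directly. Every accepted row is re-verified by the independent
    constraint checker; the worst violation is reported in diagnostics.
    """
    if tie_break not in ("lex", "none"):
        raise ValueError(f"unknown tie_break {tie_break!r}")
    rng = np.random.default_rng(seed)
    ws = _ProjectionWorkspace(problem, result, variability.omega_tol, variability.delta_tol)
    lows = np.array([variability.delta_min[e] for e in ws.enzymes])
    highs = np.array([variability.delta_max[e] for e in ws.enzymes])

    rows = []
    skipped = 0
    max_violation = 0.0
    for _ in range(n):
        target = lows + (highs - lows) * rng.random(ws.nM)
        out = ws.project(target, tie_break, feas_tol)
        if out is None:
            skipped += 1
            logger.warning("sample_corrections: projection LP infeasible; row skipped")
            continue
        delta, x, _ = out
        viol = check_solution(
            problem,
            x[: ws.nvar],
            omega_window=ws.omega_window,
            delta_window=ws.delta_window,
        )
        max_violation = max(max_violation, viol)
        rows.append(list(map(float, delta)))

    samples = pd.DataFrame(rows, columns=ws.enzymes)
    return SampleSet(
        samples=samples,
        seed=seed,
        n_requested=n,
        n_feasible=len(rows),
        diagnostics={
            "skipped": skipped,
            "max_violation": max_violation,
            "omega_window": ws.omega_window,
            "delta_window": ws.delta_window,
        },
    )


def precision_summary(
    samples: pd.DataFrame, kcat_min: Mapping[str, float] | None = None
) -> pd.DataFrame:
    """Per-enzyme spread of sampled corrections.

    Reports the mean, 25th/75th percentiles, and the mean Euclidean
    distance of the sampled values to their mean. With ``kcat_min`` given,
    statistics are computed on corrected kcats (kcat_min + delta) rather
    than on the raw corrections.
    """
    if len(samples) < 2:
        raise ValueError("need at least two samples")
    rows = []
    for e in samples.columns:
        vals = samples[e].to_numpy(dtype=float)
        if kcat_min is not None:
            vals = vals + kcat_min[e]
        mean = float(np.mean(vals))
        rows.append(
            {
                "enzyme": e,
                "mean": mean,
                "p25": float(np.percentile(vals, 25)),
                "p75": float(np.percentile(vals, 75)),
                "mean_distance": float(np.mean(np.abs(vals - mean))),
            }
        )
    return pd.DataFrame(rows).set_index("enzyme")
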