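"""The multi-condition kcat-correction linear program.

One shared, non-negative correction delta_i (s^-1) is fitted per enzyme i
in the set M (measured in every condition). Per condition j the LP carries
a flux block v^j (steady state, condition uptake bounds), usage variables
for unmeasured enzymes limited by the protein pool, per-enzyme capacity
constraints sum_{r: i in GPR(r)} v_r^j <= (kcat_i^min + delta_i)*3600*E_i^j
for i in M, and an error variable omega_j tied to the biomass flux through
the linear surrogate mu_exp * omega_j >= |mu_exp - v_bio^j|. The objective
trades the mean error against the mean correction:

    min  (1/|C|) sum_j omega_j  +  (lambda/|M|) sum_i delta_i
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import sparse

from .conditions import (
    ConditionModel,
    ConditionRecord,
    ScenarioSpec,
    make_condition_model,
    measured_in_all,
)
from .model import (
    DEFAULT_EPSILON,
    DEFAULT_KCAT_MAX,
    PcModel,
    SECONDS_PER_HOUR,
    apply_kcat_corrections,
)
from .validation import DEFAULT_FEAS_TOL, fba_arrays, predict_growth, solve_lp

logger = logging.getLogger("presto")

DEFAULT_THETA = 0.6

__all__ = [
    "PrestoProblem",
    "CorrectionResult",
    "build_presto_lp",
    "solve_presto",
    "negative_correction_step",
    "relative_error",
    "check_solution",
    "DEFAULT_THETA",
]


def relative_error(mu_exp: float, v_bio: float, convention: str = "measured") -> float:
    """Relative growth error.

    ``convention="measured"`` (reporting default): |mu - v| / mu.
    ``convention="predicted"``: |mu - v| / v (diagnostic variant; requires
    a positive prediction).
    """
    if not mu_exp > 0:
        raise ValueError("mu_exp must be positive")
    if convention == "measured":
        return abs(mu_exp - v_bio) / mu_exp
    if convention == "predicted":
        if not v_bio > 0:
            raise ValueError("predicted-denominator error undefined for v_bio <= 0")
        return abs(mu_exp - v_bio) / v_bio
    raise ValueError(f"unknown convention {convention!r}")


@dataclass
class PrestoProblem:
    pc: PcModel
    conditions: list[ConditionRecord]
    measured: list[str]
    lam: float
    theta: float
    epsilon: float
    kcat_max: float
    capacity_indexing: str
    default_uptake: float
    # assembled LP
    c: np.ndarray = field(repr=False, default=None)
    A_ub: sparse.csr_matrix = field(repr=False, default=None)
    b_ub: np.ndarray = field(repr=False, default=None)
    A_eq: sparse.csr_matrix = field(repr=False, default=None)
    b_eq: np.ndarray = field(repr=False, default=None)
    bounds: list = field(repr=False, default=None)
    delta_idx: dict[str, int] = field(default_factory=dict)
    omega_idx: dict[str, int] = field(default_factory=dict)
    vbio_idx: dict[str, int] = field(default_factory=dict)
    v_offset: dict[str, int] = field(default_factory=dict)
    rxn_order: list[str] = field(default_factory=list)
    kcat_min: dict[str, float] = field(default_factory=dict)
    row_scaling: bool = True

    @property
    def nvar(self) -> int:
        return len(self.c)

    def delta_upper(self, enzyme: str) -> float:
        kmin = self.kcat_min[enzyme]
        return min((self.epsilon - 1.0) * kmin, self.kcat_max - kmin)


@dataclass
class CorrectionResult:
    delta: dict[str, float]
    omega: dict[str, float]
    omega_predicted: dict[str, float]
    v_bio: dict[str, float]
    total_correction: float
    lam: float
    status: dict[str, str]
    max_violation: float = 0.0
    apparent_rates: bool = False
    x: np.ndarray | None = field(repr=False, default=None)

    @property
    def corrected_enzymes(self) -> set[str]:
        return {e for e, d in self.delta.items() if abs(d) > 1e-9}


def build_presto_lp(
    pc: PcModel,
    conditions: Sequence[ConditionRecord],
    lam: float,
    theta: float = DEFAULT_THETA,
    epsilon: float = DEFAULT_EPSILON,
    kcat_max: float = DEFAULT_KCAT_MAX,
    default_uptake: float = 1000.0,
    capacity_indexing: str = "per_enzyme",
    measured: Sequence[str] | None = None,
    row_scaling: bool = True,
) -> PrestoProblem:
    """Assemble the correction LP over all conditions.

    ``capacity_indexing`` selects between the per-enzyme capacity reading
    (default; one row summing fluxes over all reactions the enzyme
    catalyzes) and the literal per-reaction reading (one row per
    (reaction, enzyme) pair).
    """
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    if capacity_indexing not in ("per_enzyme", "per_reaction"):
        raise ValueError(f"unknown capacity indexing {capacity_indexing!r}")
    conditions = list(conditions)
    if measured is None:
        m = measured_in_all(conditions) & set(pc.mw)
        if pc.measured:
            m &= pc.measured
        measured = sorted(m)
    else:
        measured = sorted(measured)
    if not measured:
        raise ValueError("the measured-enzyme set M is empty")

    net = pc.network
    N, _, rxn_idx = net.stoich_matrix()
    nr = len(net.reactions)
    rxn_order = [r.id for r in net.reactions]
    kmins = pc.kcat_min_all()
    unmeasured = [e for e in pc.enzymes if e not in set(measured)]
    enz_rxns = pc.enzyme_rxns

    nM, nC, nu = len(measured), len(conditions), len(unmeasured)
    delta_idx = {e: i for i, e in enumerate(measured)}
    omega_idx = {c.id: nM + j for j, c in enumerate(conditions)}
    block0 = nM + nC
    block_size = nr + nu

    nvar = block0 + nC * block_size
    c = np.zeros(nvar)
    for e in measured:
        c[delta_idx[e]] = lam / nM
    for cond in conditions:
        c[omega_idx[cond.id]] = 1.0 / nC

    eq_rows: list[sparse.csr_matrix] = []
    ub_rows, ub_cols, ub_vals, b_ub_list = [], [], [], []
    nrow = 0
    bounds: list[tuple[float, float | None]] = []
    for e in measured:
        kmin = kmins[e]
        dmax = min((epsilon - 1.0) * kmin, kcat_max - kmin)
        bounds.append((0.0, dmax))
    for cond in conditions:
        bounds.append((0.0, theta))

    v_offset: dict[str, int] = {}
    vbio_idx: dict[str, int] = {}
    A_eq_blocks = []

    for j, cond in enumerate(conditions):
        off = block0 + j * block_size
        v_offset[cond.id] = off
        vbio_idx[cond.id] = off + rxn_idx[net.biomass_id]
        cm = make_condition_model(
            pc, cond, ScenarioSpec("pool_plus_uptake", default_uptake=default_uptake)
        )
        # steady state
        blk = sparse.lil_matrix((N.shape[0], nvar))
        blk[:, off : off + nr] = N
        A_eq_blocks.append(blk.tocsr())

        # capacity rows for measured enzymes (abundances enter as constants)
        for e in measured:
            E = cond.abundance[e]
            cap_rhs = SECONDS_PER_HOUR * E * kmins[e]
            if capacity_indexing == "per_enzyme":
                groups = [enz_rxns.get(e, [])]
            else:
                groups = [[rid] for rid in enz_rxns.get(e, [])]
            for rids in groups:
                if not rids:
                    continue
                for rid in rids:
                    ub_rows.append(nrow)
                    ub_cols.append(off + rxn_idx[rid])
                    ub_vals.append(pc.coef(e))
                ub_rows.append(nrow)
                ub_cols.append(delta_idx[e])
                ub_vals.append(-SECONDS_PER_HOUR * E)
                b_ub_list.append(cap_rhs)
                nrow += 1

        # GECKO usage coupling + pool for unmeasured enzymes
        for u_i, e in enumerate(unmeasured):
            col_e = off + nr + u_i
            touched = False
            for rid in enz_rxns.get(e, []):
                ub_rows.append(nrow)
                ub_cols.append(off + rxn_idx[rid])
                ub_vals.append(pc.coef(e) / (SECONDS_PER_HOUR * pc.kcat[(e, rid)]))
                touched = True
            if touched:
                ub_rows.append(nrow)
                ub_cols.append(col_e)
                ub_vals.append(-1.0)
                b_ub_list.append(0.0)
                nrow += 1
        if unmeasured:
            for u_i, e in enumerate(unmeasured):
                ub_rows.append(nrow)
                ub_cols.append(off + nr + u_i)
                ub_vals.append(pc.mw[e])
            b_ub_list.append(cm.pool_cap)
            nrow += 1

        # error linearization: mu*omega >= mu - v_bio and mu*omega >= v_bio - mu
        mu = cond.growth_rate
        wcol = omega_idx[cond.id]
        bcol = vbio_idx[cond.id]
        ub_rows += [nrow, nrow]
        ub_cols += [bcol, wcol]
        ub_vals += [-1.0, -mu]
        b_ub_list.append(-mu)
        nrow += 1
        ub_rows += [nrow, nrow]
        ub_cols += [bcol, wcol]
        ub_vals += [1.0, -mu]
        b_ub_list.append(mu)
        nrow += 1

        # flux and usage bounds for this block
        for r in net.reactions:
            ub = cm.flux_ub.get(r.id, r.ub)
            bounds.append((r.lb, None if ub == math.inf else ub))
        for e in unmeasured:
            bounds.append((0.0, None))

    A_ub = sparse.csr_matrix((ub_vals, (ub_rows, ub_cols)), shape=(nrow, nvar))
    b_ub = np.asarray(b_ub_list)
    A_eq = sparse.vstack(A_eq_blocks).tocsr() if A_eq_blocks else None
    b_eq = np.zeros(A_eq.shape[0]) if A_eq is not None else None

    if row_scaling:
        scale = np.maximum(np.abs(A_ub).max(axis=1).toarray().ravel(), 1e-300)
        D = sparse.diags(1.0 / scale)
        A_ub = D @ A_ub
        b_ub = b_ub / scale

    return PrestoProblem(
        pc=pc,
        conditions=conditions,
        measured=list(measured),
        lam=lam,
        theta=theta,
        epsilon=epsilon,
        kcat_max=kcat_max,
        capacity_indexing=capacity_indexing,
        default_uptake=default_uptake,
        c=c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=bounds,
        delta_idx=delta_idx,
        omega_idx=omega_idx,
        vbio_idx=vbio_idx,
        v_offset=v_offset,
        rxn_order=rxn_order,
        kcat_min={e: kmins[e] for e in pc.mw if e in kmins},
        row_scaling=row_scaling,
    )


def check_solution(
    problem: PrestoProblem,
    x: np.ndarray,
    omega_window: Mapping[str, tuple[float, float]] | None = None,
    delta_window: tuple[float, float] | None = None,
) -> float:
    """Independent constraint verification; returns the maximum violation.

    Re-derives every constraint family from the model/condition objects
    rather than trusting the assembled matrices or the solver status.
    Optional windows check the variability-analysis restrictions
    (per-condition omega interval, total-correction interval).
    """
    pc = problem.pc
    net = pc.network
    kmins = pc.kcat_min_all()
    enz_rxns = pc.enzyme_rxns
    measured = set(problem.measured)
    unmeasured = [e for e in pc.enzymes if e not in measured]
    nr = len(net.reactions)
    worst = 0.0

    delta = {e: x[i] for e, i in problem.delta_idx.items()}
    for e, d in delta.items():
        worst = max(worst, -d, d - problem.delta_upper(e))

    for j, cond in enumerate(problem.conditions):
        off = problem.v_offset[cond.id]
        v = {r.id: x[off + k] for k, r in enumerate(net.reactions)}
        e_usage = {e: x[off + nr + k] for k, e in enumerate(unmeasured)}
        cm = make_condition_model(
            pc, cond, ScenarioSpec("pool_plus_uptake", default_uptake=problem.default_uptake)
        )
        # steady state
        balance: dict[str, float] = {}
        for r in net.reactions:
            for m, coef in r.stoich.items():
                balance[m] = balance.get(m, 0.0) + coef * v[r.id]
        for m, val in balance.items():
            worst = max(worst, abs(val))
        # flux bounds
        for r in net.reactions:
            ub = cm.flux_ub.get(r.id, r.ub)
            worst = max(worst, r.lb - v[r.id])
            if ub != math.inf:
                worst = max(worst, v[r.id] - ub)
        # measured capacities
        for e in measured:
            flux = sum(pc.coef(e) * v[rid] for rid in enz_rxns.get(e, []))
            cap = SECONDS_PER_HOUR * (kmins[e] + delta[e]) * cond.abundance[e]
            scale = max(1.0, abs(cap))
            worst = max(worst, (flux - cap) / scale)
        # unmeasured usage + pool
        pool = 0.0
        for e in unmeasured:
            need = sum(
                pc.coef(e) * v[rid] / (SECONDS_PER_HOUR * pc.kcat[(e, rid)])
                for rid in enz_rxns.get(e, [])
            )
            worst = max(worst, need - e_usage[e], -e_usage[e])
            pool += pc.mw[e] * e_usage[e]
        if unmeasured:
            worst = max(worst, pool - cm.pool_cap)
        # omega surrogate
        mu = cond.growth_rate
        w = x[problem.omega_idx[cond.id]]
        vb = x[problem.vbio_idx[cond.id]]
        worst = max(worst, abs(mu - vb) - mu * w, -w, w - problem.theta)
        if omega_window is not None:
            lo, hi = omega_window[cond.id]
            worst = max(worst, lo - w, w - hi)

    if delta_window is not None:
        total = sum(delta.values())
        worst = max(worst, delta_window[0] - total, total - delta_window[1])
    return worst


def _scaled_objective(c: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    nz = np.abs(c[c != 0])
    if nz.size == 0 or nz.min() >= floor:
        return c
    return c * (floor / nz.min())


def solve_presto(
    problem: PrestoProblem, feas_tol: float = DEFAULT_FEAS_TOL
) -> CorrectionResult:
    """Solve the correction LP and return the fitted corrections.

    On a numerical failure the problem is re-assembled with the opposite
    row-scaling setting and retried once before reporting.

    The objective vector is rescaled so its smallest nonzero coefficient
    stays above the solver's dual feasibility tolerance (tiny lambda values
    would otherwise make the correction penalty numerically invisible);
    the rescaling leaves the argmin unchanged.
    """
    c = _scaled_objective(problem.c)
    res = solve_lp(
        c, problem.A_ub, problem.b_ub, problem.A_eq, problem.b_eq,
        problem.bounds, feas_tol,
    )
    if res.status != 0:
        logger.warning(
            "PRESTO LP solve failed (status %s: %s); retrying with row scaling %s",
            res.status, res.message, not problem.row_scaling,
        )
        retry = build_presto_lp(
            problem.pc, problem.conditions, problem.lam, problem.theta,
            problem.epsilon, problem.kcat_max, problem.default_uptake,
            problem.capacity_indexing, problem.measured,
            row_scaling=not problem.row_scaling,
        )
        res = solve_lp(
            _scaled_objective(retry.c), retry.A_ub, retry.b_ub, retry.A_eq,
            retry.b_eq, retry.bounds, feas_tol,
        )
        if res.status != 0:
            raise RuntimeError(
                f"PRESTO LP could not be solved: status {res.status} ({res.message})"
            )
        problem = retry

    x = res.x
    delta = {e: float(x[i]) for e, i in problem.delta_idx.items()}
    v_bio = {cid: float(x[i]) for cid, i in problem.vbio_idx.items()}
    omega = {
        cond.id: relative_error(cond.growth_rate, v_bio[cond.id])
        for cond in problem.conditions
    }
    omega_pred = {}
    for cond in problem.conditions:
        vb = v_bio[cond.id]
        omega_pred[cond.id] = (
            relative_error(cond.growth_rate, vb, "predicted") if vb > 0 else math.inf
        )
    violation = check_solution(problem, x)
    if violation > 1e-6:
        logger.warning("PRESTO solution violates constraints by %.3g", violation)
    return CorrectionResult(
        delta=delta,
        omega=omega,
        omega_predicted=omega_pred,
        v_bio=v_bio,
        total_correction=float(sum(delta.values())),
        lam=problem.lam,
        status={cond.id: "optimal" for cond in problem.conditions},
        max_violation=float(violation),
        x=x,
    )


# ---------------------------------------------------------------------------
# Optional second stage: negative corrections (apparent catalytic rates)
# ---------------------------------------------------------------------------

def negative_correction_step(
    result: CorrectionResult,
    pc: PcModel,
    conditions: Sequence[ConditionRecord],
    default_uptake: float = 1000.0,
    max_rounds: int = 15,
    growth_tol: float = 1e-6,
    feas_tol: float = DEFAULT_FEAS_TOL,
) -> CorrectionResult:
    """Reduce kcats of measured enzymes to curb pool-only overprediction.

    A cutting-plane scheme over reciprocal turnover numbers rho_i = 1/kcat_i:
    each scenario-(i) FBA optimum that overshoots mu_exp contributes a linear
    pool-cost cut forcing the growth achievable along that flux direction
    down to mu_exp; conditions already at or below mu_exp contribute
    protective cuts keeping their optima feasible. Per-enzyme upper bounds
    on rho keep every stored scenario-(iii) optimal flux pattern feasible, so
    scenario-(iii) predictions (and errors) are preserved exactly. The
    merged corrections are apparent catalytic rates, not condition-
    independent turnover numbers, and are flagged as such.
    """
    measured = sorted(result.delta)
    base_kmin = pc.kcat_min_all()
    model_pos = apply_kcat_corrections(pc, result.delta)
    kpos = model_pos.kcat_min_all()
    enz_rxns = pc.enzyme_rxns

    # scenario-(iii) optimal patterns pin per-enzyme lower kcat bounds
    klb = {e: feas_tol for e in measured}
    v3_ref: dict[str, float] = {}
    for cond in conditions:
        cm3 = make_condition_model(
            model_pos, cond, ScenarioSpec("pool_uptake_abundance", default_uptake=default_uptake)
        )
        v3, sol = predict_growth(cm3, return_solution=True)
        v3_ref[cond.id] = v3
        if sol is None:
            continue
        for e in measured:
            E = cond.abundance.get(e, 0.0)
            if E <= 0:
                continue
            flux = sum(pc.coef(e) * sol.fluxes[rid] for rid in enz_rxns.get(e, []))
            klb[e] = max(klb[e], flux / (SECONDS_PER_HOUR * E))
    for e in measured:
        klb[e] = min(klb[e], kpos[e])  # numerical safety

    rho0 = {e: 1.0 / kpos[e] for e in measured}
    rho_hi = {e: 1.0 / klb[e] for e in measured}
    unmeasured = [e for e in pc.enzymes if e not in set(measured)]

    def scenario1_models(kcats: Mapping[str, float]):
        over = apply_kcat_corrections(
            pc, {e: kcats[e] - base_kmin[e] for e in measured}, allow_negative=True
        )
        return {
            cond.id: make_condition_model(
                over, cond, ScenarioSpec("pool_only", default_uptake=default_uptake)
            )
            for cond in conditions
        }

    def pool_cut(cond, sol, v_ref):
        """Coefficients of the pool cost per unit growth along sol's direction."""
        coefs = np.zeros(len(measured))
        const = 0.0
        for i, e in enumerate(measured):
            flux = sum(pc.coef(e) * sol.fluxes[rid] for rid in enz_rxns.get(e, []))
            coefs[i] = pc.mw[e] * flux / (SECONDS_PER_HOUR * v_ref)
        for e in unmeasured:
            flux = sum(
                pc.coef(e) * sol.fluxes[rid] / (SECONDS_PER_HOUR * pc.kcat[(e, rid)])
                for rid in enz_rxns.get(e, [])
            )
            const += pc.mw[e] * flux / v_ref
        return coefs, const

    kcur = dict(kpos)
    cuts: list[tuple[np.ndarray, float, float, str]] = []  # coefs, const, rhs, kind
    v1_final: dict[str, float] = {}
    changed = False

    for _ in range(max_rounds):
        cms = scenario1_models(kcur)
        new_cuts = 0
        for cond in conditions:
            cap = cond.pool_cap
            v1, sol = predict_growth(cms[cond.id], return_solution=True)
            v1_final[cond.id] = v1
            if sol is None or math.isnan(v1) or v1 <= 0:
                continue
            mu = cond.growth_rate
            if v1 > mu * (1 + growth_tol):
                coefs, const = pool_cut(cond, sol, v1)
                cuts.append((coefs, const, cap / mu, "force"))
                new_cuts += 1
            else:
                coefs, const = pool_cut(cond, sol, v1)
                cuts.append((coefs, const, cap / v1, "protect"))
        if new_cuts == 0:
            break
        # master LP over rho
        n = len(measured)
        forces = [c for c in cuts if c[3] == "force"]
        protects = [c for c in cuts if c[3] == "protect"]
        ns = len(forces)
        nvar = n + ns
        c_obj = np.zeros(nvar)
        c_obj[n:] = 1.0
        c_obj[:n] = 1e-9  # tiny preference for the smallest reductions
        rows, b = [], []
        for k, (coefs, const, rhs, _) in enumerate(forces):
            row = np.zeros(nvar)
            row[:n] = -coefs
            row[n + k] = -rhs
            rows.append(row)
            b.append(const - rhs)
        for coefs, const, rhs, _ in protects:
            row = np.zeros(nvar)
            row[:n] = coefs
            rows.append(row)
            b.append(rhs - const)
        bnds = [(rho0[e], rho_hi[e]) for e in measured] + [(0.0, 1.0)] * ns
        res = solve_lp(
            c_obj, sparse.csr_matrix(np.array(rows)), np.array(b), None, None, bnds, feas_tol
        )
        if res.status != 0:
            logger.warning(
                "negative-correction master LP infeasible (status %s); "
                "returning the positive-correction result", res.status,
            )
            return result
        knew = {e: 1.0 / max(res.x[i], rho0[e]) for i, e in enumerate(measured)}
        if max(abs(knew[e] - kcur[e]) / kcur[e] for e in measured) < 1e-9:
            break
        kcur = knew
        changed = True

    if not changed:
        logger.info("negative-correction step: no overprediction to correct")
        return result

    delta_total = {e: kcur[e] - base_kmin[e] for e in measured}
    model_new = apply_kcat_corrections(pc, delta_total, allow_negative=True)
    omega3, v3_new = {}, {}
    for cond in conditions:
        cm3 = make_condition_model(
            model_new, cond, ScenarioSpec("pool_uptake_abundance", default_uptake=default_uptake)
        )
        v3_new[cond.id] = predict_growth(cm3)
        omega3[cond.id] = relative_error(cond.growth_rate, v3_new[cond.id])
    drift = max(
        abs(omega3[c.id] - relative_error(c.growth_rate, v3_ref[c.id]))
        for c in conditions
    )
    if drift > 1e-6:
        logger.warning(
            "negative-correction step changed scenario-(iii) errors by %.3g; "
            "returning the positive-correction result", drift,
        )
        return result
    omega_pred = {
        c.id: relative_error(c.growth_rate, v3_new[c.id], "predicted")
        if v3_new[c.id] > 0 else math.inf
        for c in conditions
    }
    return CorrectionResult(
        delta=delta_total,
        omega=omega3,
        omega_predicted=omega_pred,
        v_bio=v3_new,
        total_correction=float(sum(delta_total.values())),
        lam=result.lam,
        status={c.id: "optimal" for c in conditions},
        apparent_rates=True,
    )
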