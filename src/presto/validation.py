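"""Flux balance analysis on condition-constrained models and error tables.

The LP solved here is the GECKO-form FBA: maximize biomass flux subject to
steady state N v = 0, flux bounds, per-enzyme capacity rows
sum_r coef_i * v_r / (3600 * kcat_ir) <= e_i, optional usage bounds
e_i <= E_i, and the protein pool row sum_i MW_i * e_i <= Ptot*f*sigma.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import linprog

from .conditions import ConditionModel, ConditionRecord, ScenarioSpec, make_condition_model
from .model import PcModel, SECONDS_PER_HOUR

logger = logging.getLogger("presto")

DEFAULT_FEAS_TOL = 1e-9

__all__ = [
    "FluxSolution",
    "fba_arrays",
    "solve_lp",
    "predict_growth",
    "evaluate_conditions",
    "DEFAULT_FEAS_TOL",
]


@dataclass
class FluxSolution:
    objective: float
    fluxes: dict[str, float]
    usage: dict[str, float]


def solve_lp(c, A_ub, b_ub, A_eq, b_eq, bounds, feas_tol: float = DEFAULT_FEAS_TOL):
    """Thin wrapper over scipy's HiGHS interface with the package tolerance."""
    return linprog(
        c,
        A_ub=A_ub if A_ub is not None and A_ub.shape[0] else None,
        b_ub=b_ub if A_ub is not None and A_ub.shape[0] else None,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=bounds,
        method="highs",
        options={
            "primal_feasibility_tolerance": feas_tol,
            "dual_feasibility_tolerance": max(feas_tol, 1e-9),
        },
    )


def fba_arrays(
    cm: ConditionModel,
    kcat_override: Mapping[tuple[str, str], float] | None = None,
):
    """Assemble FBA matrices for a condition model.

    Variables are [v (reactions), e (enzymes)]. Returns a dict with the
    matrices, bounds, and index maps.
    """
    pc = cm.pc
    net = pc.network
    N, met_idx, rxn_idx = net.stoich_matrix()
    nr = len(net.reactions)
    enzymes = pc.enzymes
    enz_idx = {e: nr + i for i, e in enumerate(enzymes)}
    nvar = nr + len(enzymes)

    kcat = dict(pc.kcat)
    if kcat_override:
        kcat.update(kcat_override)

    A_eq = sparse.hstack(
        [N, sparse.csr_matrix((N.shape[0], len(enzymes)))]
    ).tocsr()
    b_eq = np.zeros(N.shape[0])

    rows, cols, vals = [], [], []
    nrow = 0
    for e in enzymes:
        touched = False
        for (enz, rid), k in kcat.items():
            if enz != e:
                continue
            rows.append(nrow)
            cols.append(rxn_idx[rid])
            vals.append(pc.coef(e) / (SECONDS_PER_HOUR * k))
            touched = True
        if touched:
            rows.append(nrow)
            cols.append(enz_idx[e])
            vals.append(-1.0)
            nrow += 1
    # protein pool row over all enzymes (omitted when the cap is infinite)
    pool_row = None
    if cm.pool_cap != math.inf:
        pool_row = nrow
        for e in enzymes:
            rows.append(pool_row)
            cols.append(enz_idx[e])
            vals.append(pc.mw[e])
        nrow += 1
    A_ub = sparse.csr_matrix((vals, (rows, cols)), shape=(nrow, nvar))
    b_ub = np.zeros(nrow)
    if pool_row is not None:
        b_ub[pool_row] = cm.pool_cap

    bounds = []
    for r in net.reactions:
        ub = cm.flux_ub.get(r.id, r.ub)
        bounds.append((r.lb, None if ub == math.inf else ub))
    for e in enzymes:
        ub = cm.usage_ub.get(e, math.inf)
        bounds.append((0.0, None if ub == math.inf else ub))

    return {
        "A_eq": A_eq,
        "b_eq": b_eq,
        "A_ub": A_ub,
        "b_ub": b_ub,
        "bounds": bounds,
        "rxn_idx": rxn_idx,
        "enz_idx": enz_idx,
        "nvar": nvar,
        "biomass_col": rxn_idx[net.biomass_id],
    }


def predict_growth(
    cm: ConditionModel,
    kcat_override: Mapping[tuple[str, str], float] | None = None,
    return_solution: bool = False,
    parsimonious_weights: Mapping[str, float] | None = None,
    feas_tol: float = DEFAULT_FEAS_TOL,
):
    """FBA-maximal biomass flux (h^-1); NaN when infeasible.

    With ``parsimonious_weights``, a second LP fixes the optimal growth and
    minimizes the weighted total flux, yielding a reproducible flux pattern.
    An unbounded objective (missing pool cap) raises ``ValueError``.
    """
    arr = fba_arrays(cm, kcat_override)
    c = np.zeros(arr["nvar"])
    c[arr["biomass_col"]] = -1.0
    res = solve_lp(c, arr["A_ub"], arr["b_ub"], arr["A_eq"], arr["b_eq"], arr["bounds"], feas_tol)
    if res.status == 3:
        raise ValueError(
            "unbounded biomass objective — the model lacks a pool cap or uptake bound"
        )
    if res.status != 0:
        logger.info("predict_growth: infeasible condition model (%s)", cm.condition.id)
        return (math.nan, None) if return_solution else math.nan
    v_bio = float(res.x[arr["biomass_col"]])

    x = res.x
    if parsimonious_weights is not None:
        c2 = np.zeros(arr["nvar"])
        for rid, j in arr["rxn_idx"].items():
            c2[j] = parsimonious_weights.get(rid, 1.0)
        bounds2 = list(arr["bounds"])
        j = arr["biomass_col"]
        bounds2[j] = (v_bio * (1 - 1e-9) - feas_tol, bounds2[j][1])
        res2 = solve_lp(c2, arr["A_ub"], arr["b_ub"], arr["A_eq"], arr["b_eq"], bounds2, feas_tol)
        if res2.status == 0:
            x = res2.x

    if not return_solution:
        return v_bio
    fluxes = {rid: float(x[j]) for rid, j in arr["rxn_idx"].items()}
    usage = {e: float(x[j]) for e, j in arr["enz_idx"].items()}
    return v_bio, FluxSolution(v_bio, fluxes, usage)


def evaluate_conditions(
    models: Mapping[str, PcModel] | PcModel,
    conditions: Sequence[ConditionRecord],
    scenarios: Sequence[str] = ("i", "ii", "iii"),
    default_uptake: float = 1000.0,
) -> pd.DataFrame:
    """Growth predictions and relative errors per (model, condition, scenario).

    Relative error is |v_bio - mu_exp| / mu_exp; infeasible models are
    reported with ``feasible=False`` and NaN entries, never zero-filled.
    """
    if isinstance(models, PcModel):
        models = {"model": models}
    rows = []
    for name, pc in models.items():
        for cond in conditions:
            for sc in scenarios:
                spec = ScenarioSpec(sc, default_uptake=default_uptake)
                cm = make_condition_model(pc, cond, spec)
                v = predict_growth(cm)
                feasible = not math.isnan(v)
                rows.append(
                    {
                        "model": name,
                        "condition": cond.id,
                        "scenario": spec.tag,
                        "v_bio": v,
                        "mu_exp": cond.growth_rate,
                        "rel_error": abs(v - cond.growth_rate) / cond.growth_rate
                        if feasible
                        else math.nan,
                        "feasible": feasible,
                    }
                )
    return pd.DataFrame(rows)
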