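"""Shared fixtures: hand-built toy models and an independent FBA oracle.

The oracle implementations here deliberately avoid the package's LP
assembly: dense matrices, explicit loops, and usage variables eliminated
by substitution, so that agreement between the two routes is meaningful.
"""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy.optimize import linprog

from presto import (
    ConditionRecord,
    EnzymeTable,
    MetabolicNetwork,
    Reaction,
    build_pc_model,
    parse_gpr,
)
from presto.model import SECONDS_PER_HOUR
from presto.synth import make_synthetic_instance

HOUR = SECONDS_PER_HOUR


# ---------------------------------------------------------------------------
# hand-built models
# ---------------------------------------------------------------------------

def linear_chain(enzyme_kcats: dict[str, float], mws: dict[str, float] | None = None):
    """Uptake -> chain with one enzyme per reaction -> biomass.

    ``enzyme_kcats`` maps enzyme ids (in chain order) to kcats in s^-1.
    """
    names = list(enzyme_kcats)
    reactions = [Reaction("EX_S", {"M0": 1.0}, 0.0, math.inf)]
    for k, e in enumerate(names, start=1):
        reactions.append(
            Reaction(f"R{k}", {f"M{k-1}": -1.0, f"M{k}": 1.0}, 0.0, math.inf,
                     parse_gpr(e))
        )
    reactions.append(Reaction("BIOMASS", {f"M{len(names)}": -1.0}, 0.0, math.inf))
    network = MetabolicNetwork(reactions, "BIOMASS", ["EX_S"])
    mws = mws or {e: 50.0 for e in names}
    table = EnzymeTable(
        kcat={(e, f"R{k}"): v for k, (e, v) in enumerate(enzyme_kcats.items(), start=1)},
        mw=mws,
        measured_in_all=set(names),
    )
    return network, table


def chain_condition(
    cid: str,
    abundance: dict[str, float],
    mu: float,
    uptake: float = 100.0,
    ptot: float = 10.0,
    f: float = 0.5,
    sigma: float = 0.5,
) -> ConditionRecord:
    return ConditionRecord(
        id=cid, abundance=abundance, growth_rate=mu,
        exchange={"EX_S": uptake}, ptot=ptot, f=f, sigma=sigma, media={"EX_S"},
    )


@pytest.fixture(scope="session")
def chain3():
    """The single-enzyme 3-reaction chain: capacity 0.36 h^-1 at E=1e-4."""
    network, table = linear_chain({"e1": 1.0})
    return network, table, build_pc_model(network, table)


@pytest.fixture(scope="session")
def recovery_instance():
    """Noise-free instance with three deflated enzymes and known truth."""
    return make_synthetic_instance(
        n_linear=5, n_parallel=0, n_conditions=6,
        deflate={"e1": 4.0, "e4": 2.0, "e5": 3.0},
        noise_cv=0.0, headroom=1.0, seed=3,
    )


@pytest.fixture(scope="session")
def parallel_routes():
    """Two parallel isozyme-like routes with only the sum of corrections
    pinned: requirement delta_1 + delta_2 = 2 s^-1."""
    reactions = [
        Reaction("EX_S", {"A": 1.0}, 0.0, math.inf),
        Reaction("R1", {"A": -1.0, "B": 1.0}, 0.0, math.inf, parse_gpr("e1")),
        Reaction("R2", {"A": -1.0, "B": 1.0}, 0.0, math.inf, parse_gpr("e2")),
        Reaction("BIOMASS", {"B": -1.0}, 0.0, math.inf),
    ]
    network = MetabolicNetwork(reactions, "BIOMASS", ["EX_S"])
    table = EnzymeTable(
        kcat={("e1", "R1"): 1.0, ("e2", "R2"): 1.0},
        mw={"e1": 50.0, "e2": 50.0},
        measured_in_all={"e1", "e2"},
    )
    pc = build_pc_model(network, table)
    E = 1e-4
    # total capacity 2*0.36*(1+delta/2); mu demands delta1+delta2 = 2
    mu = HOUR * E * (1.0 + 1.0) * 2.0  # = 1.44
    cond = chain_condition("c1", {"e1": E, "e2": E}, mu)
    return pc, cond


def graded_demand_fixture():
    """Single enzyme (kcat 10 s^-1), three conditions needing delta >= 2, 5, 9
    s^-1 for zero error — a non-trivial regularization path."""
    network, table = linear_chain({"e1": 10.0})
    pc = build_pc_model(network, table)
    E = 1e-4
    conds = [
        chain_condition(f"c{k}", {"e1": E}, HOUR * E * (10.0 + d))
        for k, d in enumerate((2.0, 5.0, 9.0), start=1)
    ]
    return pc, conds


def overprediction_fixture():
    """Pool-only growth overshoots ~2x while scenario (iii) is limited by a
    pool-negligible enzyme's abundance — the negative-correction regime."""
    network, table = linear_chain(
        {"e_big": 10.0, "e_small": 10.0}, mws={"e_big": 100.0, "e_small": 0.001}
    )
    pc = build_pc_model(network, table)
    mu = 0.5
    E_small = mu / (HOUR * 10.0)
    cond = chain_condition(
        "c1", {"e_big": 2 * E_small, "e_small": E_small}, mu,
        ptot=2.8e-3 / 0.25, f=0.5, sigma=0.5,
    )
    return pc, cond


def random_small_instance(rng):
    """A random chain instance with <=3 measured enzymes and <=2 conditions,
    suitable for dense grid search over the corrections."""
    n_enz = int(rng.choice([1, 2, 3], p=[0.4, 0.4, 0.2]))
    kcats = {f"e{k}": float(rng.uniform(1.0, 20.0)) for k in range(1, n_enz + 1)}
    network, table = linear_chain(kcats)
    pc = build_pc_model(network, table)
    conds = []
    for j in range(int(rng.integers(1, 3))):
        E = {e: float(10 ** rng.uniform(-4.5, -3.5)) for e in kcats}
        vmax0 = min(HOUR * E[e] * kcats[e] for e in kcats)
        mu = float(rng.uniform(0.8, 1.9)) * vmax0
        conds.append(chain_condition(f"c{j+1}", E, mu))
    lam = float(10 ** rng.uniform(-4.0, -2.0))
    highs = {}
    for e, k in kcats.items():
        need = max(
            (c.growth_rate / (HOUR * c.abundance[e]) - k) for c in conds
        )
        highs[e] = 2.0 * max(need, 0.0) + 0.5
    return pc, conds, list(kcats), highs, lam


# ---------------------------------------------------------------------------
# independent oracle: dense FBA with usage eliminated by substitution
# ---------------------------------------------------------------------------

def oracle_max_growth(pc, cond, measured, delta, theta=None, default_uptake=1000.0):
    """Maximal biomass flux under the correction-LP semantics for fixed delta.

    Measured enzymes: sum of catalyzed fluxes <= 3600*(kcat_min+delta)*E.
    Unmeasured enzymes: usage eliminated, contributing MW-weighted demand
    to the pool row. Returns NaN when infeasible.
    """
    net = pc.network
    rxns = net.reactions
    n = len(rxns)
    idx = {r.id: j for j, r in enumerate(rxns)}
    mets = net.metabolites
    A_eq = np.zeros((len(mets), n))
    for j, r in enumerate(rxns):
        for m, coef in r.stoich.items():
            A_eq[mets.index(m), j] = coef
    kmins = pc.kcat_min_all()
    enz_rxns = pc.enzyme_rxns

    A_ub, b_ub = [], []
    for e in measured:
        row = np.zeros(n)
        for rid in enz_rxns.get(e, []):
            row[idx[rid]] = pc.coef(e)
        A_ub.append(row)
        b_ub.append(HOUR * (kmins[e] + delta.get(e, 0.0)) * cond.abundance[e])
    pool = np.zeros(n)
    has_unmeasured = False
    for e in pc.enzymes:
        if e in measured:
            continue
        has_unmeasured = True
        for rid in enz_rxns.get(e, []):
            pool[idx[rid]] += pc.mw[e] * pc.coef(e) / (HOUR * pc.kcat[(e, rid)])
    if has_unmeasured:
        A_ub.append(pool)
        b_ub.append(cond.pool_cap)

    bounds = []
    for r in rxns:
        ub = r.ub
        if r.source in cond.media or r.source in cond.exchange:
            if len(r.stoich) == 1 and next(iter(r.stoich.values())) > 0:
                ub = cond.exchange.get(r.source, default_uptake)
        elif r.source in net.exchange_ids and cond.media:
            if len(r.stoich) == 1 and next(iter(r.stoich.values())) > 0:
                ub = 0.0
        bounds.append((r.lb, None if ub == math.inf else ub))

    c = np.zeros(n)
    c[idx[net.biomass_id]] = -1.0
    res = linprog(c, A_ub=np.array(A_ub) if A_ub else None,
                  b_ub=np.array(b_ub) if A_ub else None,
                  A_eq=A_eq, b_eq=np.zeros(len(mets)), bounds=bounds,
                  method="highs")
    if res.status != 0:
        return math.nan
    return float(res.x[idx[net.biomass_id]])


def oracle_objective(pc, conditions, measured, delta, lam, theta=0.6):
    """Correction-LP objective for a fixed delta; None when infeasible."""
    omegas = []
    for cond in conditions:
        v = oracle_max_growth(pc, cond, measured, delta)
        if math.isnan(v):
            return None
        w = max(0.0, (cond.growth_rate - v) / cond.growth_rate)
        if w > theta + 1e-9:
            return None
        omegas.append(w)
    return float(np.mean(omegas)) + lam / len(measured) * sum(delta.values())


def oracle_grid_search(pc, conditions, measured, highs, lam, theta=0.6,
                       points=10, rounds=3):
    """Multi-resolution grid minimization of the correction objective.

    The objective is convex in delta (max-growth is concave in the
    capacity right-hand sides), so successive refinement around the best
    grid point converges to the optimum.
    """
    measured = list(measured)
    lo = np.zeros(len(measured))
    hi = np.array([highs[e] for e in measured])
    best, best_obj = None, None
    for _ in range(rounds):
        axes = [np.linspace(lo[i], hi[i], points) for i in range(len(measured))]
        grids = np.meshgrid(*axes, indexing="ij")
        flat = np.stack([g.ravel() for g in grids], axis=1)
        for row in flat:
            obj = oracle_objective(
                pc, conditions, measured, dict(zip(measured, row)), lam, theta
            )
            if obj is not None and (best_obj is None or obj < best_obj):
                best_obj, best = obj, row.copy()
        if best is None:
            return None, None
        step = (hi - lo) / (points - 1)
        lo = np.maximum(best - step, 0.0)
        hi = best + step
    return dict(zip(measured, best)), best_obj
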