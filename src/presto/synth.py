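"""Synthetic toy models and condition data with known ground-truth deflations.

The generator emulates the inputs the correction pipeline consumes: a small
uptake -> linear chain -> (optional parallel branches) -> biomass network
with per-reaction enzymes (including one two-subunit complex and one
isozyme pair), an enzyme table with "true" turnover numbers, and
per-condition records whose growth rates and abundances are produced by
FBA with the true kcats. Deflating selected kcats by known factors then
yields instances where the correction an LP should recover is known
exactly: delta_true = kcat_true - kcat_deflated.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .conditions import ConditionModel, ConditionRecord, ScenarioSpec
from .model import (
    EnzymeTable,
    MetabolicNetwork,
    PcModel,
    Reaction,
    SECONDS_PER_HOUR,
    build_pc_model,
    parse_gpr,
)
from .validation import predict_growth

logger = logging.getLogger("presto")

#: multiplicative slack between generated abundances and the usage an
#: optimal flux distribution requires; >1 puts the binding constraint on
#: abundances rather than the pool, the regime the correction LP targets
DEFAULT_HEADROOM = 1.2
ABUNDANCE_FLOOR = 1e-6  # mmol gDW^-1, for enzymes unused at the optimum

__all__ = [
    "SyntheticInstance",
    "make_toy_network",
    "simulate_conditions",
    "deflate_kcats",
    "make_synthetic_instance",
    "DEFAULT_HEADROOM",
]


@dataclass
class SyntheticInstance:
    network: MetabolicNetwork
    enzymes_true: EnzymeTable
    enzymes_deflated: EnzymeTable
    true_delta: dict[str, float]
    conditions: list[ConditionRecord]
    seed: int
    noise_cv: float
    headroom: float

    @property
    def pc_true(self) -> PcModel:
        return build_pc_model(self.network, self.enzymes_true)

    @property
    def pc_deflated(self) -> PcModel:
        return build_pc_model(self.network, self.enzymes_deflated)


def make_toy_network(
    n_linear: int = 3,
    n_parallel: int = 2,
    seed: int = 0,
) -> tuple[MetabolicNetwork, EnzymeTable]:
    """A toy chain topology with one two-subunit complex and one isozyme pair.

    Reactions: uptake EX_S -> M0; chain R1..Rn (M_{k-1} -> M_k); optional
    parallel branches P1..Pm (M_n -> B); biomass drain. kcats are
    log-uniform in [0.1, 100] s^-1, molecular weights uniform in
    [20, 200] g mmol^-1. Every enzyme is flagged measured-in-all.
    """
    if n_linear < 1 or n_parallel < 0:
        raise ValueError("n_linear >= 1 and n_parallel >= 0 required")
    rng = np.random.default_rng(seed)

    reactions: list[Reaction] = [Reaction("EX_S", {"M0": 1.0}, 0.0, math.inf)]
    gprs: dict[str, str] = {}
    for k in range(1, n_linear + 1):
        rid = f"R{k}"
        if k == 2:
            gprs[rid] = f"(cplx{k}a and cplx{k}b)"
        elif k == 3:
            gprs[rid] = f"e{k}a or e{k}b"
        else:
            gprs[rid] = f"e{k}"
        reactions.append(
            Reaction(rid, {f"M{k-1}": -1.0, f"M{k}": 1.0}, 0.0, math.inf, parse_gpr(gprs[rid]))
        )
    last = f"M{n_linear}"
    if n_parallel > 0:
        for k in range(1, n_parallel + 1):
            rid = f"P{k}"
            gprs[rid] = f"p{k}"
            reactions.append(
                Reaction(rid, {last: -1.0, "B": 1.0}, 0.0, math.inf, parse_gpr(gprs[rid]))
            )
        last = "B"
    reactions.append(Reaction("BIOMASS", {last: -1.0}, 0.0, math.inf))

    network = MetabolicNetwork(reactions, biomass_id="BIOMASS", exchange_ids=["EX_S"])
    network.validate()

    kcat: dict[tuple[str, str], float] = {}
    mw: dict[str, float] = {}
    for rid, rule in gprs.items():
        genes = sorted(parse_gpr(rule).genes())
        shared = None
        if rule.startswith("("):  # complex: subunits share the reaction kcat
            shared = float(10 ** rng.uniform(-1, 2))
        for g in genes:
            kcat[(g, rid)] = shared if shared is not None else float(10 ** rng.uniform(-1, 2))
            if g not in mw:
                mw[g] = float(rng.uniform(20, 200))
    enzymes = EnzymeTable(kcat=kcat, mw=mw, measured_in_all=set(mw))
    return network, enzymes


def simulate_conditions(
    network: MetabolicNetwork,
    enzymes: EnzymeTable,
    n_conditions: int,
    noise_cv: float = 0.0,
    headroom: float = DEFAULT_HEADROOM,
    seed: int = 0,
    uptake_range: tuple[float, float] = (1.0, 10.0),
    pool_slack: float = 1.5,
    f: float = 0.5,
    sigma: float = 0.5,
) -> list[ConditionRecord]:
    """Generate condition records from the true-kcat model.

    Per condition: a substrate uptake bound is drawn, FBA with the true
    kcats sets mu_exp, and abundances are the usage the optimal fluxes
    require, times the headroom factor, times multiplicative lognormal
    noise with coefficient of variation ``noise_cv``. Ptot, f and sigma
    are set so the pool constraint holds with slack ``pool_slack``.
    """
    if n_conditions < 1:
        raise ValueError("need at least one condition")
    rng = np.random.default_rng(seed)
    pc = build_pc_model(network, enzymes)
    enz_rxns = pc.enzyme_rxns
    sigma_ln = math.sqrt(math.log(1.0 + noise_cv**2)) if noise_cv > 0 else 0.0

    records: list[ConditionRecord] = []
    for j in range(n_conditions):
        for _ in range(20):  # bounded retries for infeasible draws
            uptake = float(rng.uniform(*uptake_range))
            up_rxn = pc.uptake_reaction("EX_S")
            stub = ConditionRecord(
                id=f"c{j+1}", abundance={}, growth_rate=1.0, ptot=1.0, f=f, sigma=sigma
            )
            cm = ConditionModel(
                pc=pc,
                condition=stub,
                scenario=ScenarioSpec("pool_plus_uptake"),
                flux_ub={up_rxn: uptake},
                pool_cap=math.inf,
            )
            weights = {
                r.id: 1.0 + 1e-3 * float(rng.random()) for r in pc.network.reactions
            }
            v_bio, sol = predict_growth(cm, return_solution=True, parsimonious_weights=weights)
            if not math.isnan(v_bio) and v_bio > 0:
                # record the growth the returned flux pattern itself attains,
                # so abundances and mu_exp are exactly consistent
                v_bio = sol.fluxes[pc.network.biomass_id]
                break
        else:
            raise RuntimeError("could not draw a feasible condition")

        usage_req = {
            e: sum(
                pc.coef(e) * sol.fluxes[rid] / (SECONDS_PER_HOUR * pc.kcat[(e, rid)])
                for rid in enz_rxns.get(e, [])
            )
            for e in pc.enzymes
        }
        abundance = {}
        for e, req in usage_req.items():
            noise = (
                float(rng.lognormal(-0.5 * sigma_ln**2, sigma_ln)) if sigma_ln > 0 else 1.0
            )
            abundance[e] = max(req, ABUNDANCE_FLOOR) * headroom * noise
        pool_need = sum(pc.mw[e] * u for e, u in usage_req.items())
        ptot = max(pool_need, ABUNDANCE_FLOOR) * pool_slack * headroom / (f * sigma)
        records.append(
            ConditionRecord(
                id=f"c{j+1}",
                abundance=abundance,
                growth_rate=v_bio,
                exchange={"EX_S": uptake},
                ptot=ptot,
                f=f,
                sigma=sigma,
                gam=0.0,
                media={"EX_S"},
            )
        )
    return records


def deflate_kcats(
    enzymes: EnzymeTable, factors: Mapping[str, float]
) -> tuple[EnzymeTable, dict[str, float]]:
    """Divide targeted enzymes' kcats by known factors (> 1).

    Returns the deflated table plus the ground-truth corrections
    delta_i = kcat_i^min(true) - kcat_i^min(deflated), in s^-1.
    """
    for e, fac in factors.items():
        if not fac > 1:
            raise ValueError(f"deflation factor for {e} must exceed 1")
        if e not in enzymes.mw:
            raise KeyError(f"unknown enzyme {e}")
    kcat = {
        (e, r): (v / factors[e] if e in factors else v)
        for (e, r), v in enzymes.kcat.items()
    }
    deflated = EnzymeTable(
        kcat=kcat, mw=dict(enzymes.mw), measured_in_all=set(enzymes.measured_in_all)
    )
    true_delta = {
        e: enzymes.kcat_min(e) - deflated.kcat_min(e) for e in factors
    }
    return deflated, true_delta


def make_synthetic_instance(
    n_linear: int = 5,
    n_parallel: int = 0,
    n_conditions: int = 6,
    deflate: Mapping[str, float] | None = None,
    noise_cv: float = 0.0,
    headroom: float = 1.0,
    seed: int = 0,
    **sim_kwargs,
) -> SyntheticInstance:
    """Compose network, conditions, and deflation into one instance."""
    network, enzymes = make_toy_network(n_linear, n_parallel, seed=seed)
    records = simulate_conditions(
        network, enzymes, n_conditions, noise_cv=noise_cv,
        headroom=headroom, seed=seed + 1, **sim_kwargs,
    )
    if deflate is None:
        deflate = {}
    deflated, true_delta = deflate_kcats(enzymes, deflate)
    return SyntheticInstance(
        network=network,
        enzymes_true=enzymes,
        enzymes_deflated=deflated,
        true_delta=true_delta,
        conditions=records,
        seed=seed,
        noise_cv=noise_cv,
        headroom=headroom,
    )
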