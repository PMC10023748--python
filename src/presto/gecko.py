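"""The objective-control-coefficient kcat-correction heuristic (baseline).

The control coefficient of an enzyme is the relative gain in FBA-predicted
growth when its turnover number is raised 1000-fold, all else fixed, on
the pool-constrained (no abundance bounds) condition model. Enzymes are
corrected greedily — highest coefficient first, kcat set to a database
maximum, never decreased — until predicted growth is within 10% of the
measured rate or no coefficient exceeds 0.001.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .conditions import ConditionRecord, ScenarioSpec, make_condition_model
from .model import PcModel
from .validation import predict_growth

logger = logging.getLogger("presto")

PERTURBATION_FACTOR = 1000.0
COEFFICIENT_THRESHOLD = 0.001
GROWTH_TOLERANCE = 0.1

__all__ = [
    "HeuristicTrace",
    "control_coefficients",
    "gecko_correct_condition",
    "aggregate_union_max",
    "PERTURBATION_FACTOR",
    "COEFFICIENT_THRESHOLD",
    "GROWTH_TOLERANCE",
]


@dataclass
class HeuristicTrace:
    #: (enzyme, control coefficient, old kcat_min, new kcat) per iteration
    steps: list[tuple[str, float, float, float]] = field(default_factory=list)
    stop_reason: str = ""
    final_growth: float = math.nan
    growth_path: list[float] = field(default_factory=list)


def control_coefficients(
    pc: PcModel,
    cond: ConditionRecord,
    factor: float = PERTURBATION_FACTOR,
    default_uptake: float = 1000.0,
    mode: str = "relative",
) -> dict[str, float]:
    """Per-enzyme growth response to a ``factor``-fold kcat increase.

    ``mode="relative"`` (default): (v' - v0) / v0; ``mode="absolute"``:
    v' - v0. Computed one enzyme at a time on the pool-only model.
    """
    if mode not in ("relative", "absolute"):
        raise ValueError(f"unknown mode {mode!r}")
    cm = make_condition_model(pc, cond, ScenarioSpec("pool_only", default_uptake=default_uptake))
    v0 = predict_growth(cm)
    if math.isnan(v0):
        raise RuntimeError(f"base FBA infeasible for condition {cond.id}")
    coefs: dict[str, float] = {}
    enz_rxns = pc.enzyme_rxns
    for e in pc.enzymes:
        override = {(e, rid): pc.kcat[(e, rid)] * factor for rid in enz_rxns.get(e, [])}
        if not override:
            coefs[e] = 0.0
            continue
        v = predict_growth(cm, kcat_override=override)
        gain = v - v0
        coefs[e] = gain / v0 if mode == "relative" else gain
    return coefs


def gecko_correct_condition(
    pc: PcModel,
    cond: ConditionRecord,
    kcat_db: Mapping[str, float],
    growth_tolerance: float = GROWTH_TOLERANCE,
    threshold: float = COEFFICIENT_THRESHOLD,
    factor: float = PERTURBATION_FACTOR,
    default_uptake: float = 1000.0,
) -> tuple[HeuristicTrace, PcModel]:
    """Greedy condition-specific correction; returns the trace and model.

    ``kcat_db`` maps enzymes to the maximum turnover number found across
    organisms; kcats are only ever increased. Ties between equal
    coefficients break by enzyme identifier.
    """
    model = pc.copy()
    trace = HeuristicTrace()
    mu = cond.growth_rate
    tried: set[str] = set()

    while True:
        cm = make_condition_model(
            model, cond, ScenarioSpec("pool_only", default_uptake=default_uptake)
        )
        v = predict_growth(cm)
        trace.growth_path.append(v)
        if v >= (1.0 - growth_tolerance) * mu:
            trace.stop_reason = "growth_within_tolerance"
            trace.final_growth = v
            return trace, model
        if len(trace.steps) >= len(pc.enzymes):  # cycle guard
            break
        coefs = control_coefficients(
            model, cond, factor=factor, default_uptake=default_uptake
        )
        candidates = [
            (c, e) for e, c in coefs.items() if e not in tried and c > threshold
        ]
        if not candidates:
            trace.stop_reason = "no_coefficient_above_threshold"
            trace.final_growth = v
            return trace, model
        # deterministic pick: highest coefficient, ties broken by enzyme id
        best_coef = max(c for c, _ in candidates)
        best = min(e for c, e in candidates if c == best_coef)
        tried.add(best)
        old = model.kcat_min(best)
        new = max(kcat_db.get(best, old), old)  # never decrease
        if best not in kcat_db:
            logger.info(
                "gecko heuristic: enzyme %s missing from the kcat database; skipped",
                best,
            )
        for key in list(model.kcat):
            if key[0] == best:
                model.kcat[key] = max(model.kcat[key], new)
        trace.steps.append((best, best_coef, old, new))

    trace.final_growth = trace.growth_path[-1]
    trace.stop_reason = "max_iterations"
    return trace, model


def aggregate_union_max(models: Sequence[PcModel]) -> PcModel:
    """Union model: per (enzyme, reaction), the maximum kcat over models."""
    if not models:
        raise ValueError("no models to aggregate")
    out = models[0].copy()
    for m in models[1:]:
        if set(m.kcat) != set(out.kcat):
            raise ValueError("models must share the same (enzyme, reaction) pairs")
        for key, v in m.kcat.items():
            if v > out.kcat[key]:
                out.kcat[key] = v
    return out
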