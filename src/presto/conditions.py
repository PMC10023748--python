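"""Condition-specific experimental data and constrained condition models.

A :class:`ConditionRecord` carries one experiment's enzyme abundances
(mmol gDW^-1), measured specific growth rate (h^-1), nutrient exchange
rates (mmol gDW^-1 h^-1), total protein content Ptot (g gDW^-1), enzyme
mass fraction f, average saturation sigma, and GAM. Condition models come
in three constraint scenarios:

(i)   protein pool constraint only, default uptake rates;
(ii)  pool constraint plus measured uptake rates;
(iii) scenario (ii) plus per-enzyme usage bounds e_i <= E_i.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model import PcModel

logger = logging.getLogger("presto")

#: default uptake bound for medium nutrients without a measured rate
DEFAULT_UPTAKE = 1000.0

SCENARIO_ALIASES = {
    "i": "pool_only",
    "ii": "pool_plus_uptake",
    "iii": "pool_uptake_abundance",
    "pool_only": "pool_only",
    "pool_plus_uptake": "pool_plus_uptake",
    "pool_uptake_abundance": "pool_uptake_abundance",
}

__all__ = [
    "ConditionRecord",
    "ScenarioSpec",
    "ConditionModel",
    "load_conditions",
    "aggregate_replicates",
    "make_condition_model",
    "measured_in_all",
    "DEFAULT_UPTAKE",
]


@dataclass
class ConditionRecord:
    id: str
    #: enzyme -> abundance in mmol gDW^-1; enzymes missing from the mapping
    #: were not quantified in this condition
    abundance: dict[str, float]
    growth_rate: float
    exchange: dict[str, float] = field(default_factory=dict)
    ptot: float = 0.5
    f: float = 0.5
    sigma: float = 0.5
    gam: float = 0.0
    #: exchange reactions of nutrients present in the culture medium
    media: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.growth_rate > 0:
            raise ValueError(f"condition {self.id}: growth rate must be positive")
        if not self.ptot > 0:
            raise ValueError(f"condition {self.id}: Ptot must be positive")
        if not (0 < self.f <= 1) or not (0 < self.sigma <= 1):
            raise ValueError(f"condition {self.id}: f and sigma must lie in (0, 1]")
        for e, a in self.abundance.items():
            if a < 0:
                raise ValueError(f"condition {self.id}: negative abundance for {e}")

    @property
    def pool_cap(self) -> float:
        """Protein pool capacity Ptot * f * sigma, in g gDW^-1."""
        return self.ptot * self.f * self.sigma


@dataclass
class ScenarioSpec:
    tag: str
    default_uptake: float = DEFAULT_UPTAKE

    def __post_init__(self) -> None:
        self.tag = SCENARIO_ALIASES.get(self.tag, self.tag)
        if self.tag not in SCENARIO_ALIASES.values():
            raise ValueError(f"unknown scenario {self.tag!r}")
        if not self.default_uptake > 0:
            raise ValueError("default uptake bound must be positive")


@dataclass
class ConditionModel:
    """A PcModel with condition-specific bounds attached (not yet an LP)."""

    pc: PcModel
    condition: ConditionRecord
    scenario: ScenarioSpec
    #: split-reaction id -> upper flux bound override
    flux_ub: dict[str, float] = field(default_factory=dict)
    #: enzyme -> usage upper bound (scenario iii only)
    usage_ub: dict[str, float] = field(default_factory=dict)
    pool_cap: float = math.inf


def measured_in_all(records: Sequence[ConditionRecord]) -> set[str]:
    """The set M of enzymes quantified in every condition."""
    if not records:
        return set()
    m = set(records[0].abundance)
    for rec in records[1:]:
        m &= set(rec.abundance)
    return m


def aggregate_replicates(
    abundance: pd.DataFrame,
    growth_rates: Sequence[float],
    exchange: pd.DataFrame | None = None,
) -> tuple[pd.Series, float, pd.Series]:
    """Collapse replicate measurements of one condition.

    ``abundance``: proteins x replicates (mmol gDW^-1); aggregated as the
    per-protein maximum over replicates. ``growth_rates`` and per-nutrient
    ``exchange`` rates (nutrients x replicates) are averaged. Replicates
    with inconsistent protein sets are united, missing entries treated as
    absent (NaN) and logged.
    """
    if abundance.shape[1] < 1:
        raise ValueError("at least one replicate required")
    if abundance.isna().any().any():
        logger.warning(
            "aggregate_replicates: inconsistent protein sets across replicates; "
            "missing entries treated as absent"
        )
    abund = abundance.max(axis=1, skipna=True)
    growth = float(np.mean(list(growth_rates)))
    exch = (
        exchange.mean(axis=1, skipna=True)
        if exchange is not None
        else pd.Series(dtype=float)
    )
    return abund, growth, exch


def load_conditions(
    abundance_path: str | Path,
    metadata_path: str | Path,
    exchange_path: str | Path | None = None,
    media: Mapping[str, Iterable[str]] | Iterable[str] | str | Path | None = None,
    include: Iterable[str] | None = None,
    ptot_fill: str = "max",
) -> list[ConditionRecord]:
    """Load condition records from TSV inputs.

    ``abundance_path``: enzymes x conditions matrix (first column = enzyme id).
    ``metadata_path``: one row per condition with columns
    condition, growth_rate, ptot, f, sigma[, gam].
    ``exchange_path``: optional long table (condition, reaction, rate).
    ``media``: per-condition (mapping) or global (list / JSON file) list of
    medium-nutrient exchange reactions.
    ``include``: explicit include-list of condition ids (others dropped).
    Missing Ptot values follow ``ptot_fill`` ("max": maximum over measured
    conditions — logged).
    """
    abund = pd.read_csv(abundance_path, sep="\t", index_col=0)
    if abund.empty:
        raise ValueError("empty abundance matrix")
    meta = pd.read_csv(metadata_path, sep="\t").set_index("condition")

    if isinstance(media, (str, Path)):
        media = json.loads(Path(media).read_text())
    if media is None:
        media_map: dict[str, set[str]] = {}
    elif isinstance(media, Mapping):
        media_map = {c: set(v) for c, v in media.items()}
    else:
        media_map = {c: set(media) for c in meta.index}

    exch_map: dict[str, dict[str, float]] = {}
    if exchange_path is not None:
        exch = pd.read_csv(exchange_path, sep="\t")
        for row in exch.itertuples():
            exch_map.setdefault(str(row.condition), {})[str(row.reaction)] = float(row.rate)

    conditions = [c for c in meta.index if include is None or c in set(include)]
    if include is not None:
        dropped = sorted(set(meta.index) - set(conditions))
        if dropped:
            logger.info("load_conditions: excluded conditions %s", dropped)

    if "ptot" in meta.columns and meta.loc[conditions, "ptot"].isna().any():
        if ptot_fill != "max":
            raise ValueError(f"unknown ptot fill policy {ptot_fill!r}")
        fill = float(meta.loc[conditions, "ptot"].max(skipna=True))
        for c in conditions:
            if pd.isna(meta.at[c, "ptot"]):
                logger.warning(
                    "condition %s: missing Ptot filled with maximum over "
                    "measured conditions (%.4g g/gDW)", c, fill,
                )
                meta.at[c, "ptot"] = fill

    records: list[ConditionRecord] = []
    for c in conditions:
        if c not in abund.columns:
            raise ValueError(f"condition {c} missing from the abundance matrix")
        row = meta.loc[c]
        if "growth_rate" not in meta.columns or pd.isna(row["growth_rate"]):
            raise ValueError(f"condition {c}: missing growth rate")
        col = abund[c].dropna()
        if (col < 0).any():
            raise ValueError(f"condition {c}: negative abundance")
        records.append(
            ConditionRecord(
                id=str(c),
                abundance={str(e): float(v) for e, v in col.items()},
                growth_rate=float(row["growth_rate"]),
                exchange=exch_map.get(str(c), {}),
                ptot=float(row.get("ptot", 0.5)),
                f=float(row.get("f", 0.5)),
                sigma=float(row.get("sigma", 0.5)),
                gam=float(row.get("gam", 0.0)) if not pd.isna(row.get("gam", 0.0)) else 0.0,
                media=media_map.get(str(c), set()),
            )
        )
    return records


def make_condition_model(
    pc: PcModel,
    cond: ConditionRecord,
    scenario: ScenarioSpec | str,
) -> ConditionModel:
    """Attach condition-specific constraints to a PcModel for one scenario.

    The protein pool is capped at Ptot*f*sigma over all enzymes (measured
    and unmeasured). Uptake bounds: scenario (i) sets every medium
    nutrient to the default; scenario (ii)/(iii) apply measured rates and
    default unmeasured medium nutrients; non-medium uptakes are closed
    whenever a medium is declared. Scenario (iii) additionally bounds
    usage by measured abundance.
    """
    if isinstance(scenario, str):
        scenario = ScenarioSpec(scenario)

    flux_ub: dict[str, float] = {}
    medium = set(cond.media)
    measured_nutrients = set(cond.exchange)
    for rid in measured_nutrients:
        if rid not in {r.source for r in pc.network.reactions}:
            raise ValueError(
                f"condition {cond.id}: measured nutrient {rid} has no exchange "
                "reaction in the model"
            )
    if medium or measured_nutrients:
        relevant = medium | measured_nutrients
        for ex in pc.network.exchange_ids:
            up = pc.uptake_reaction(ex)
            if up is None:
                continue
            if ex not in relevant:
                flux_ub[up] = 0.0
            elif scenario.tag == "pool_only":
                flux_ub[up] = scenario.default_uptake
            else:
                if ex in measured_nutrients:
                    flux_ub[up] = abs(cond.exchange[ex])
                else:
                    logger.info(
                        "condition %s: unmeasured medium nutrient %s defaulted "
                        "to %g mmol/gDW/h", cond.id, ex, scenario.default_uptake,
                    )
                    flux_ub[up] = scenario.default_uptake

    usage_ub: dict[str, float] = {}
    if scenario.tag == "pool_uptake_abundance":
        for e, a in cond.abundance.items():
            if e in pc.mw:
                usage_ub[e] = a

    cap = cond.pool_cap
    measured_mass = sum(
        pc.mw[e] * a for e, a in cond.abundance.items() if e in pc.mw
    )
    if measured_mass > cap:
        logger.warning(
            "condition %s: measured enzyme mass (%.4g g/gDW) exceeds the pool "
            "cap (%.4g g/gDW) — inconsistent data", cond.id, measured_mass, cap,
        )

    return ConditionModel(
        pc=pc, condition=cond, scenario=scenario,
        flux_ub=flux_ub, usage_ub=usage_ub, pool_cap=cap,
    )
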