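"""Metabolic network data model and its protein-constrained (GECKO-style) augmentation.

The central object is :class:`PcModel`: a metabolic network whose reversible
reactions have been split into irreversible pairs and whose isozyme
alternatives (OR branches of a GPR rule) have been split into separate
reaction copies, together with per-(enzyme, reaction) turnover numbers.
Enzyme usage variables (mmol gDW^-1) couple flux to abundance through
capacity constraints of the form  v <= 3600 * kcat * e  (kcat stored in
s^-1, fluxes in mmol gDW^-1 h^-1, hence the 3600).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

logger = logging.getLogger("presto")

SECONDS_PER_HOUR = 3600.0

#: default cap on the allowed kcat fold change introduced by a correction
DEFAULT_EPSILON = 1e5
#: absolute cap on any corrected kcat, in s^-1 (fastest known enzyme)
DEFAULT_KCAT_MAX = 5.75e7

__all__ = [
    "GprNode",
    "parse_gpr",
    "gpr_to_string",
    "Reaction",
    "MetabolicNetwork",
    "EnzymeTable",
    "PcModel",
    "load_network",
    "write_network",
    "build_pc_model",
    "apply_kcat_corrections",
    "substitute_external_kcats",
    "write_kcat_table",
    "read_kcat_table",
    "SECONDS_PER_HOUR",
    "DEFAULT_EPSILON",
    "DEFAULT_KCAT_MAX",
]


# ---------------------------------------------------------------------------
# GPR rules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GprNode:
    """Node of a boolean gene-protein-reaction expression tree.

    ``op`` is ``"gene"`` (leaf, ``name`` set), ``"and"`` (complex subunits)
    or ``"or"`` (isozymes).
    """

    op: str
    name: str | None = None
    children: tuple["GprNode", ...] = ()

    def genes(self) -> set[str]:
        if self.op == "gene":
            return {self.name}  # type: ignore[arg-type]
        out: set[str] = set()
        for c in self.children:
            out |= c.genes()
        return out


def _tokenize(rule: str) -> list[str]:
    tokens: list[str] = []
    buf: list[str] = []
    for ch in rule:
        if ch in "()":
            if buf:
                tokens.append("".join(buf))
                buf = []
            tokens.append(ch)
        elif ch.isspace():
            if buf:
                tokens.append("".join(buf))
                buf = []
        else:
            buf.append(ch)
    if buf:
        tokens.append("".join(buf))
    return tokens


class _GprParser:
    """Recursive-descent parser: OR binds loosest, AND tighter, parens group."""

    def __init__(self, tokens: list[str]):
        self.tokens = tokens
        self.pos = 0

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self) -> str:
        tok = self.tokens[self.pos]
        self.pos += 1
        return tok

    def parse_or(self) -> GprNode:
        terms = [self.parse_and()]
        while self.peek() is not None and self.peek().lower() == "or":
            self.take()
            terms.append(self.parse_and())
        if len(terms) == 1:
            return terms[0]
        return GprNode("or", children=tuple(terms))

    def parse_and(self) -> GprNode:
        terms = [self.parse_atom()]
        while self.peek() is not None and self.peek().lower() == "and":
            self.take()
            terms.append(self.parse_atom())
        if len(terms) == 1:
            return terms[0]
        return GprNode("and", children=tuple(terms))

    def parse_atom(self) -> GprNode:
        tok = self.peek()
        if tok is None:
            raise ValueError("unexpected end of GPR rule")
        if tok == "(":
            self.take()
            node = self.parse_or()
            if self.peek() != ")":
                raise ValueError("unbalanced parentheses in GPR rule")
            self.take()
            return node
        if tok.lower() in ("and", "or", ")"):
            raise ValueError(f"unexpected token {tok!r} in GPR rule")
        return GprNode("gene", name=self.take())


def parse_gpr(rule: str | None) -> GprNode | None:
    """Parse a GPR string ("(g1 and g2) or g3") into an expression tree."""
    if rule is None:
        return None
    rule = rule.strip()
    if not rule:
        return None
    parser = _GprParser(_tokenize(rule))
    node = parser.parse_or()
    if parser.peek() is not None:
        raise ValueError(f"trailing tokens in GPR rule {rule!r}")
    return node


def gpr_to_string(node: GprNode | None) -> str:
    if node is None:
        return ""
    if node.op == "gene":
        return node.name  # type: ignore[return-value]
    sep = f" {node.op} "
    parts = []
    for c in node.children:
        s = gpr_to_string(c)
        if c.op != "gene" and c.op != node.op:
            s = f"({s})"
        parts.append(s)
    return sep.join(parts)


def gpr_dnf(node: GprNode, max_terms: int = 256) -> list[frozenset[str]]:
    """Disjunctive normal form: list of subunit sets, one per isozyme alternative."""
    if node.op == "gene":
        return [frozenset([node.name])]  # type: ignore[list-item]
    if node.op == "and":
        terms: list[frozenset[str]] = [frozenset()]
        for c in node.children:
            sub = gpr_dnf(c, max_terms)
            terms = [t | s for t in terms for s in sub]
            if len(terms) > max_terms:
                raise ValueError("GPR rule too large to expand to DNF")
        return terms
    # or
    out: list[frozenset[str]] = []
    for c in node.children:
        for t in gpr_dnf(c, max_terms):
            if t not in out:
                out.append(t)
    return out


# ---------------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------------

@dataclass
class Reaction:
    id: str
    stoich: dict[str, float]
    lb: float = 0.0
    ub: float = math.inf
    gpr: GprNode | None = None
    #: identifier of the pre-split reaction this (copy) derives from
    source: str | None = None

    def __post_init__(self) -> None:
        if self.source is None:
            self.source = self.id


@dataclass
class MetabolicNetwork:
    """Stoichiometric model: reactions, bounds, biomass/exchange roles, GPRs."""

    reactions: list[Reaction]
    biomass_id: str
    exchange_ids: list[str] = field(default_factory=list)

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def metabolites(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.reactions:
            for m in r.stoich:
                seen.setdefault(m)
        return list(seen)

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def genes(self) -> set[str]:
        out: set[str] = set()
        for r in self.reactions:
            if r.gpr is not None:
                out |= r.gpr.genes()
        return out

    def stoich_matrix(self) -> tuple[sparse.csr_matrix, dict[str, int], dict[str, int]]:
        mets = self.metabolites
        met_idx = {m: i for i, m in enumerate(mets)}
        rxn_idx = {r.id: j for j, r in enumerate(self.reactions)}
        rows, cols, vals = [], [], []
        for j, r in enumerate(self.reactions):
            for m, coef in r.stoich.items():
                rows.append(met_idx[m])
                cols.append(j)
                vals.append(coef)
        N = sparse.csr_matrix(
            (vals, (rows, cols)), shape=(len(mets), len(self.reactions))
        )
        return N, met_idx, rxn_idx

    def validate(self) -> None:
        ids = self.reaction_ids
        if len(ids) != len(set(ids)):
            dupes = {i for i in ids if ids.count(i) > 1}
            raise ValueError(f"duplicate reaction identifiers: {sorted(dupes)}")
        if self.biomass_id not in ids:
            raise ValueError(f"biomass reaction {self.biomass_id!r} not in network")
        for r in self.reactions:
            if not r.stoich:
                raise ValueError(f"reaction {r.id} has an all-zero stoichiometry column")
            if r.lb > r.ub:
                raise ValueError(f"reaction {r.id}: lb > ub")
        for ex in self.exchange_ids:
            rxn = self.reaction(ex)
            if len(rxn.stoich) != 1:
                raise ValueError(
                    f"exchange reaction {ex} must have a single nonzero stoichiometric entry"
                )


# ---------------------------------------------------------------------------
# Enzyme table
# ---------------------------------------------------------------------------

@dataclass
class EnzymeTable:
    """Per-(enzyme, reaction) turnover numbers plus molecular weights.

    kcat values are in s^-1, keyed by (enzyme id, pre-split reaction id);
    MW in g mmol^-1. ``measured_in_all`` flags membership in the set M of
    enzymes quantified in every experimental condition.
    """

    kcat: dict[tuple[str, str], float]
    mw: dict[str, float]
    measured_in_all: set[str] = field(default_factory=set)

    @property
    def enzymes(self) -> list[str]:
        return sorted(self.mw)

    def kcat_min(self, enzyme: str) -> float:
        vals = [v for (e, _), v in self.kcat.items() if e == enzyme]
        if not vals:
            raise KeyError(f"no kcat entries for enzyme {enzyme}")
        return min(vals)

    def validate(self, network: MetabolicNetwork | None = None) -> None:
        for (e, r), v in self.kcat.items():
            if not v > 0:
                raise ValueError(f"nonpositive kcat for ({e}, {r}): {v}")
            if e not in self.mw:
                raise ValueError(f"enzyme {e} has kcat entries but no molecular weight")
        for e, w in self.mw.items():
            if not w > 0:
                raise ValueError(f"nonpositive molecular weight for {e}: {w}")
        if network is not None:
            genes = network.genes()
            orphans = set(self.mw) - genes
            if orphans:
                raise ValueError(
                    f"enzymes absent from every GPR rule: {sorted(orphans)}"
                )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "EnzymeTable":
        df = pd.read_csv(path, sep="\t")
        required = {"enzyme", "reaction", "kcat_s", "MW_g_per_mmol"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"enzyme table missing columns: {sorted(missing)}")
        kcat = {
            (str(row.enzyme), str(row.reaction)): float(row.kcat_s)
            for row in df.itertuples()
        }
        mw = {str(r.enzyme): float(r.MW_g_per_mmol) for r in df.itertuples()}
        measured = set()
        if "measured_in_all" in df.columns:
            measured = {
                str(r.enzyme)
                for r in df.itertuples()
                if bool(r.measured_in_all)
            }
        return cls(kcat=kcat, mw=mw, measured_in_all=measured)

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {
                "enzyme": e,
                "reaction": r,
                "kcat_s": v,
                "MW_g_per_mmol": self.mw[e],
                "measured_in_all": e in self.measured_in_all,
            }
            for (e, r), v in sorted(self.kcat.items())
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Protein-constrained model
# ---------------------------------------------------------------------------

@dataclass
class PcModel:
    """Split network plus enzyme kinetics.

    ``kcat`` is keyed by (enzyme, split reaction id); ``enzyme_rxns`` maps
    each enzyme to the split reactions it catalyzes; ``subunit_coef`` holds
    per-enzyme complex stoichiometries (usage demanded per unit flux is
    coef / (3600 kcat)).
    """

    network: MetabolicNetwork
    kcat: dict[tuple[str, str], float]
    mw: dict[str, float]
    measured: set[str] = field(default_factory=set)
    subunit_coef: dict[str, float] = field(default_factory=dict)

    @property
    def enzymes(self) -> list[str]:
        return sorted(self.mw)

    @property
    def enzyme_rxns(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {e: [] for e in self.mw}
        for (e, r) in self.kcat:
            out[e].append(r)
        for e in out:
            out[e].sort()
        return out

    def kcat_min(self, enzyme: str) -> float:
        vals = [v for (e, _), v in self.kcat.items() if e == enzyme]
        if not vals:
            raise KeyError(f"no kcat entries for enzyme {enzyme}")
        return min(vals)

    def kcat_min_all(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for (e, _), v in self.kcat.items():
            if e not in out or v < out[e]:
                out[e] = v
        return out

    def coef(self, enzyme: str) -> float:
        return self.subunit_coef.get(enzyme, 1.0)

    def uptake_reaction(self, exchange_source_id: str) -> str | None:
        """Split-reaction id of the uptake-direction copy of an exchange reaction.

        Uptake means the copy whose single stoichiometric entry is positive
        (mass flows into the network).
        """
        for r in self.network.reactions:
            if r.source == exchange_source_id and len(r.stoich) == 1:
                if next(iter(r.stoich.values())) > 0:
                    return r.id
        return None

    def copy(self) -> "PcModel":
        net = MetabolicNetwork(
            reactions=[replace(r, stoich=dict(r.stoich)) for r in self.network.reactions],
            biomass_id=self.network.biomass_id,
            exchange_ids=list(self.network.exchange_ids),
        )
        return PcModel(
            network=net,
            kcat=dict(self.kcat),
            mw=dict(self.mw),
            measured=set(self.measured),
            subunit_coef=dict(self.subunit_coef),
        )


def _split_reversible(network: MetabolicNetwork) -> MetabolicNetwork:
    reactions: list[Reaction] = []
    for r in network.reactions:
        if r.lb < 0 and r.ub > 0:
            reactions.append(
                Reaction(f"{r.id}_fwd", dict(r.stoich), 0.0, r.ub, r.gpr, r.source)
            )
            reactions.append(
                Reaction(
                    f"{r.id}_rev",
                    {m: -c for m, c in r.stoich.items()},
                    0.0,
                    -r.lb,
                    r.gpr,
                    r.source,
                )
            )
        elif r.ub <= 0:
            reactions.append(
                Reaction(
                    f"{r.id}_rev",
                    {m: -c for m, c in r.stoich.items()},
                    max(0.0, -r.ub),
                    -r.lb,
                    r.gpr,
                    r.source,
                )
            )
        else:
            reactions.append(
                Reaction(r.id, dict(r.stoich), max(0.0, r.lb), r.ub, r.gpr, r.source)
            )
    return MetabolicNetwork(
        reactions=reactions,
        biomass_id=network.biomass_id,
        exchange_ids=list(network.exchange_ids),
    )


def build_pc_model(
    network: MetabolicNetwork,
    enzymes: EnzymeTable,
    kinetics_free: Iterable[str] = (),
    subunit_coef: Mapping[str, float] | None = None,
) -> PcModel:
    """Assemble the protein-constrained model.

    Reversible reactions are split into irreversible forward/backward pairs,
    OR rules into one reaction copy per isozyme alternative (suffix
    ``_izN``); AND rules couple every subunit's usage to the same reaction.
    Genes listed in ``kinetics_free`` carry no kinetic constraint.
    """
    network.validate()
    enzymes.validate(network)
    kinetics_free = set(kinetics_free)

    unknown = network.genes() - set(enzymes.mw) - kinetics_free
    if unknown:
        raise ValueError(
            "GPR genes without an enzyme-table entry (and not kinetics-free): "
            f"{sorted(unknown)}"
        )

    split = _split_reversible(network)
    reactions: list[Reaction] = []
    kcat: dict[tuple[str, str], float] = {}

    for r in split.reactions:
        if r.gpr is None:
            reactions.append(r)
            continue
        terms = gpr_dnf(r.gpr)
        multi = len(terms) > 1
        for n, term in enumerate(terms, start=1):
            rid = f"{r.id}_iz{n}" if multi else r.id
            subunits = sorted(term - kinetics_free)
            gpr = (
                GprNode("and", children=tuple(GprNode("gene", name=s) for s in sorted(term)))
                if len(term) > 1
                else GprNode("gene", name=next(iter(term)))
            )
            reactions.append(Reaction(rid, dict(r.stoich), r.lb, r.ub, gpr, r.source))
            for s in subunits:
                key = (s, r.source)
                if key not in enzymes.kcat:
                    raise ValueError(
                        f"no kcat for enzyme {s} on reaction {r.source} "
                        f"(required by its GPR rule)"
                    )
                kcat[(s, rid)] = enzymes.kcat[key]

    out_net = MetabolicNetwork(
        reactions=reactions,
        biomass_id=split.biomass_id,
        exchange_ids=list(split.exchange_ids),
    )
    pc = PcModel(
        network=out_net,
        kcat=kcat,
        mw=dict(enzymes.mw),
        measured=set(enzymes.measured_in_all),
        subunit_coef=dict(subunit_coef or {}),
    )
    return pc


def apply_kcat_corrections(
    model: PcModel,
    delta: Mapping[str, float],
    allow_negative: bool = False,
    epsilon: float = DEFAULT_EPSILON,
    kcat_max: float = DEFAULT_KCAT_MAX,
) -> PcModel:
    """Return a copy with every reaction-specific kcat of enzyme i set to
    kcat_i^min + delta_i (uniform per enzyme). delta in s^-1."""
    kmins = model.kcat_min_all()
    new = model.copy()
    for e, d in delta.items():
        if e not in kmins:
            raise KeyError(f"correction for unknown enzyme {e}")
        if d < 0 and not allow_negative:
            raise ValueError(f"negative correction for {e} without allow_negative")
        if d > (epsilon - 1.0) * kmins[e]:
            raise ValueError(
                f"correction for {e} exceeds the (epsilon-1)*kcat_min fold-change cap"
            )
        knew = kmins[e] + d
        if knew > kcat_max:
            raise ValueError(f"corrected kcat for {e} exceeds K_max ({kcat_max} s^-1)")
        if knew <= 0:
            raise ValueError(f"corrected kcat for {e} is nonpositive")
        for key in list(new.kcat):
            if key[0] == e:
                new.kcat[key] = knew
    return new


def substitute_external_kcats(
    model: PcModel, table: Mapping[str, float]
) -> PcModel:
    """Substitute per-reaction external kcat estimates (s^-1).

    Single-enzyme and isozyme reaction copies receive the table value;
    complex-catalyzed reactions (AND rules, >1 subunit) are left untouched.
    Table keys are pre-split reaction identifiers; unknown ids are skipped
    with a warning.
    """
    new = model.copy()
    sources = {r.source for r in model.network.reactions}
    by_rxn: dict[str, list[str]] = {}
    for (e, rid) in model.kcat:
        by_rxn.setdefault(rid, []).append(e)
    for src, val in table.items():
        if src not in sources:
            logger.warning("external kcat table: unknown reaction %s skipped", src)
            continue
        if not val > 0:
            raise ValueError(f"nonpositive external kcat for {src}")
        for r in new.network.reactions:
            if r.source != src:
                continue
            enzymes_here = by_rxn.get(r.id, [])
            if len(enzymes_here) > 1:  # complex: not corrected
                continue
            for e in enzymes_here:
                new.kcat[(e, r.id)] = float(val)
    return new


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _infer_format(path: str | Path, fmt: str | None) -> str:
    if fmt is not None and fmt != "auto":
        return fmt
    suffix = Path(path).suffix.lower()
    if suffix in (".xml", ".sbml"):
        return "sbml"
    if suffix == ".json":
        return "json"
    raise ValueError(f"cannot infer network format from {path}")


def _to_cobra(network: MetabolicNetwork):
    import cobra

    model = cobra.Model("presto_network")
    mets = {m: cobra.Metabolite(m, compartment="c") for m in network.metabolites}
    for r in network.reactions:
        rxn = cobra.Reaction(r.id)
        rxn.lower_bound = r.lb
        rxn.upper_bound = r.ub
        model.add_reactions([rxn])
        rxn.add_metabolites({mets[m]: c for m, c in r.stoich.items()})
        if r.gpr is not None:
            rxn.gene_reaction_rule = gpr_to_string(r.gpr)
    model.objective = network.biomass_id
    for ex in network.exchange_ids:
        model.reactions.get_by_id(ex).annotation["sbo"] = "SBO:0000627"
    return model


def _from_cobra(model) -> MetabolicNetwork:
    import cobra.util.solver as sutil

    reactions = []
    for rxn in model.reactions:
        stoich = {m.id: c for m, c in rxn.metabolites.items()}
        gpr = parse_gpr(rxn.gene_reaction_rule) if rxn.gene_reaction_rule else None
        reactions.append(Reaction(rxn.id, stoich, rxn.lower_bound, rxn.upper_bound, gpr))
    objective = sutil.linear_reaction_coefficients(model)
    if len(objective) != 1:
        raise ValueError("network must declare exactly one biomass (objective) reaction")
    biomass_id = next(iter(objective)).id
    exchange_ids = [
        r.id for r in model.reactions
        if len(r.metabolites) == 1 and r.id != biomass_id
    ]
    return MetabolicNetwork(reactions, biomass_id, exchange_ids)


def load_network(path: str | Path, format: str = "auto") -> MetabolicNetwork:
    """Read a network from SBML (via cobrapy) or the package's JSON dialect."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    if fmt == "sbml":
        from cobra.io import read_sbml_model

        net = _from_cobra(read_sbml_model(str(path)))
    elif fmt == "json":
        data = json.loads(path.read_text())
        reactions = [
            Reaction(
                d["id"],
                {m: float(c) for m, c in d["stoich"].items()},
                float(d.get("lb", 0.0)),
                float(d["ub"]) if d.get("ub") is not None else math.inf,
                parse_gpr(d.get("gpr")),
                d.get("source"),
            )
            for d in data["reactions"]
        ]
        net = MetabolicNetwork(reactions, data["biomass"], list(data.get("exchanges", [])))
    else:
        raise ValueError(f"unknown network format {fmt!r}")
    net.validate()
    return net


def write_network(network: MetabolicNetwork, path: str | Path, format: str = "auto") -> None:
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "sbml":
        from cobra.io import write_sbml_model

        write_sbml_model(_to_cobra(network), str(path))
    elif fmt == "json":
        data = {
            "biomass": network.biomass_id,
            "exchanges": list(network.exchange_ids),
            "reactions": [
                {
                    "id": r.id,
                    "stoich": r.stoich,
                    "lb": r.lb,
                    "ub": None if r.ub == math.inf else r.ub,
                    "gpr": gpr_to_string(r.gpr) or None,
                    "source": r.source,
                }
                for r in network.reactions
            ],
        }
        path.write_text(json.dumps(data, indent=1))
    else:
        raise ValueError(f"unknown network format {fmt!r}")


def write_kcat_table(model: PcModel, path: str | Path) -> None:
    """Export the (enzyme, split reaction) kcat values, in s^-1."""
    rows = [
        {
            "enzyme": e,
            "reaction": r,
            "source_reaction": model.network.reaction(r).source,
            "kcat_s": v,
            "MW_g_per_mmol": model.mw[e],
            "measured_in_all": e in model.measured,
        }
        for (e, r), v in sorted(model.kcat.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_kcat_table(path: str | Path) -> dict[tuple[str, str], float]:
    df = pd.read_csv(path, sep="\t")
    return {
        (str(r.enzyme), str(r.reaction)): float(r.kcat_s) for r in df.itertuples()
    }
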