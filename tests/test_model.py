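"""Network model, GPR parsing, splitting, corrections, and I/O."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import linprog

from presto import (
    EnzymeTable,
    MetabolicNetwork,
    Reaction,
    apply_kcat_corrections,
    build_pc_model,
    load_network,
    parse_gpr,
    read_kcat_table,
    substitute_external_kcats,
    write_kcat_table,
    write_network,
)
from presto.model import GprNode, gpr_dnf, gpr_to_string
from presto.conditions import ScenarioSpec, make_condition_model
from presto.validation import fba_arrays

from conftest import chain_condition, linear_chain


class TestGpr:
    def test_or_over_and_tree(self):
        node = parse_gpr("(g1 and g2) or g3")
        assert node.op == "or" and len(node.children) == 2
        ops = {c.op for c in node.children}
        assert ops == {"and", "gene"}
        and_node = next(c for c in node.children if c.op == "and")
        assert {c.name for c in and_node.children} == {"g1", "g2"}

    def test_round_trip(self):
        for rule in ("e1", "a and b", "a or b or c", "(a and b) or (c and d)"):
            assert gpr_to_string(parse_gpr(rule)) == rule

    def test_dnf(self):
        terms = gpr_dnf(parse_gpr("(g1 and g2) or g3"))
        assert sorted(map(sorted, terms)) == [["g1", "g2"], ["g3"]]

    @pytest.mark.parametrize("bad", ["a and", "(a or b", "a b", "and a"])
    def test_malformed_rules_rejected(self, bad):
        with pytest.raises(ValueError):
            parse_gpr(bad)

    @staticmethod
    def _trees():
        leaves = st.sampled_from("abcdefgh").map(
            lambda g: GprNode("gene", name=g)
        )

        def compound(children):
            return st.tuples(
                st.sampled_from(["and", "or"]),
                st.lists(children, min_size=2, max_size=3),
            ).map(lambda t: GprNode(t[0], children=tuple(t[1])))

        return st.recursive(leaves, compound, max_leaves=8)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(_trees())
    def test_serialization_round_trip_preserves_semantics(self, tree):
        """Printing and re-parsing a rule preserves its isozyme alternatives."""
        reparsed = parse_gpr(gpr_to_string(tree))
        assert sorted(map(sorted, gpr_dnf(reparsed))) == sorted(
            map(sorted, gpr_dnf(tree))
        )


class TestNetwork:
    def test_chain_shape(self, chain3):
        network, _, _ = chain3
        assert len(network.reactions) == 3
        assert len(network.metabolites) == 2  # M0, M1: internal species only

    def test_duplicate_ids_rejected(self):
        net = MetabolicNetwork(
            [Reaction("R", {"A": 1.0}), Reaction("R", {"A": -1.0})], "R", []
        )
        with pytest.raises(ValueError, match="duplicate"):
            net.validate()

    def test_missing_biomass_rejected(self):
        net = MetabolicNetwork([Reaction("R", {"A": 1.0})], "GROWTH", [])
        with pytest.raises(ValueError, match="biomass"):
            net.validate()

    def test_multi_metabolite_exchange_rejected(self):
        net = MetabolicNetwork(
            [Reaction("EX", {"A": 1.0, "B": -1.0}), Reaction("BIO", {"A": -1.0})],
            "BIO", ["EX"],
        )
        with pytest.raises(ValueError, match="exchange"):
            net.validate()


class TestSplitting:
    @staticmethod
    def _dense_fba(reactions, c):
        mets = sorted({m for r in reactions for m in r.stoich})
        A = np.zeros((len(mets), len(reactions)))
        for j, r in enumerate(reactions):
            for m, coef in r.stoich.items():
                A[mets.index(m), j] = coef
        bounds = [(r.lb, r.ub) for r in reactions]
        res = linprog(-np.asarray(c), A_eq=A, b_eq=np.zeros(len(mets)),
                      bounds=bounds, method="highs")
        assert res.status == 0
        return -res.fun

    def test_flux_polytope_preserved(self):
        reactions = [
            Reaction("EX_A", {"A": 1.0}, 0.0, 10.0),
            Reaction("R1", {"A": -1.0, "B": 1.0}, -5.0, 7.0),
            Reaction("EX_B", {"B": -1.0}, -3.0, 9.0),
        ]
        net = MetabolicNetwork(reactions, "EX_B", ["EX_A"])
        table = EnzymeTable(kcat={}, mw={}, measured_in_all=set())
        pc = build_pc_model(net, table)
        assert all(r.lb >= 0 for r in pc.network.reactions)
        rng = np.random.default_rng(0)
        for _ in range(8):
            c = rng.normal(size=3)
            expected = self._dense_fba(reactions, c)
            split_c = []
            for r in pc.network.reactions:
                base = c[[x.id for x in reactions].index(r.source)]
                split_c.append(-base if r.id.endswith("_rev") else base)
            got = self._dense_fba(pc.network.reactions, split_c)
            assert got == pytest.approx(expected, abs=1e-9)


class TestPcModel:
    def test_kcat_min_is_min_over_reactions(self):
        reactions = [
            Reaction("EX", {"A": 1.0}, 0.0, math.inf),
            Reaction("R1", {"A": -1.0, "B": 1.0}, 0.0, math.inf, parse_gpr("e1")),
            Reaction("R2", {"B": -1.0, "C": 1.0}, 0.0, math.inf, parse_gpr("e1")),
            Reaction("BIO", {"C": -1.0}, 0.0, math.inf),
        ]
        net = MetabolicNetwork(reactions, "BIO", ["EX"])
        table = EnzymeTable(
            kcat={("e1", "R1"): 2.0, ("e1", "R2"): 5.0}, mw={"e1": 40.0},
            measured_in_all={"e1"},
        )
        pc = build_pc_model(net, table)
        assert pc.kcat_min("e1") == 2.0
        # brute force over the kcat table
        assert pc.kcat_min("e1") == min(
            v for (e, _), v in pc.kcat.items() if e == "e1"
        )

    def test_usage_coefficient_ratio(self, chain3):
        """kcat of 1 s^-1 couples flux to usage with ratio 1/3600 (h^-1)."""
        _, _, pc = chain3
        cond = chain_condition("c", {"e1": 1e-4}, 0.5)
        cm = make_condition_model(pc, cond, ScenarioSpec("pool_plus_uptake"))
        arr = fba_arrays(cm)
        row = arr["A_ub"][0].toarray().ravel()
        flux_coef = row[arr["rxn_idx"]["R1"]]
        usage_coef = row[arr["enz_idx"]["e1"]]
        assert flux_coef / usage_coef == pytest.approx(-1.0 / 3600.0)

    def test_isozyme_and_complex_split(self):
        reactions = [
            Reaction("EX", {"A": 1.0}, 0.0, math.inf),
            Reaction("R1", {"A": -1.0, "B": 1.0}, 0.0, math.inf,
                     parse_gpr("(g1 and g2) or g3")),
            Reaction("BIO", {"B": -1.0}, 0.0, math.inf),
        ]
        net = MetabolicNetwork(reactions, "BIO", ["EX"])
        table = EnzymeTable(
            kcat={("g1", "R1"): 3.0, ("g2", "R1"): 3.0, ("g3", "R1"): 7.0},
            mw={"g1": 10.0, "g2": 20.0, "g3": 30.0},
            measured_in_all={"g1", "g2", "g3"},
        )
        pc = build_pc_model(net, table)
        copies = [r.id for r in pc.network.reactions if r.source == "R1"]
        assert sorted(copies) == ["R1_iz1", "R1_iz2"]
        # complex subunits share one copy, the isozyme the other
        by_rxn = {}
        for (e, rid) in pc.kcat:
            by_rxn.setdefault(rid, set()).add(e)
        assert sorted(map(sorted, by_rxn.values())) == [["g1", "g2"], ["g3"]]

    def test_no_gpr_network_unconstrained(self):
        reactions = [
            Reaction("EX", {"A": 1.0}, 0.0, 5.0),
            Reaction("BIO", {"A": -1.0}, 0.0, math.inf),
        ]
        net = MetabolicNetwork(reactions, "BIO", ["EX"])
        pc = build_pc_model(net, EnzymeTable(kcat={}, mw={}))
        assert pc.kcat == {} and pc.enzymes == []

    def test_missing_enzyme_rejected(self):
        reactions = [
            Reaction("EX", {"A": 1.0}, 0.0, math.inf),
            Reaction("R1", {"A": -1.0}, 0.0, math.inf, parse_gpr("ghost")),
        ]
        net = MetabolicNetwork(reactions, "R1", ["EX"])
        with pytest.raises(ValueError, match="ghost"):
            build_pc_model(net, EnzymeTable(kcat={}, mw={}))


class TestCorrections:
    def test_zero_delta_is_identity(self, chain3):
        _, _, pc = chain3
        out = apply_kcat_corrections(pc, {"e1": 0.0})
        assert out.kcat == pc.kcat

    def test_uniform_per_enzyme(self):
        network, table = linear_chain({"e1": 2.0})
        table.kcat[("e1", "R1")] = 2.0
        pc = build_pc_model(network, table)
        out = apply_kcat_corrections(pc, {"e1": 3.0})
        assert all(v == 5.0 for (e, _), v in out.kcat.items() if e == "e1")

    def test_fold_change_cap_boundary(self, chain3):
        _, _, pc = chain3
        eps = 1e5
        at_cap = (eps - 1.0) * pc.kcat_min("e1")
        apply_kcat_corrections(pc, {"e1": at_cap}, epsilon=eps, kcat_max=math.inf)
        with pytest.raises(ValueError, match="fold-change"):
            apply_kcat_corrections(
                pc, {"e1": np.nextafter(at_cap, math.inf)},
                epsilon=eps, kcat_max=math.inf,
            )

    def test_kcat_max_cap(self, chain3):
        _, _, pc = chain3
        with pytest.raises(ValueError, match="K_max"):
            apply_kcat_corrections(pc, {"e1": 10.0}, kcat_max=5.0)

    def test_negative_requires_flag(self, chain3):
        _, _, pc = chain3
        with pytest.raises(ValueError, match="negative"):
            apply_kcat_corrections(pc, {"e1": -0.5})
        out = apply_kcat_corrections(pc, {"e1": -0.5}, allow_negative=True)
        assert out.kcat_min("e1") == pytest.approx(0.5)


class TestExternalSubstitution:
    @pytest.fixture()
    def iso_complex_pc(self):
        reactions = [
            Reaction("EX", {"A": 1.0}, 0.0, math.inf),
            Reaction("R1", {"A": -1.0, "B": 1.0}, 0.0, math.inf, parse_gpr("i1 or i2")),
            Reaction("R2", {"B": -1.0, "C": 1.0}, 0.0, math.inf, parse_gpr("s1 and s2")),
            Reaction("BIO", {"C": -1.0}, 0.0, math.inf),
        ]
        net = MetabolicNetwork(reactions, "BIO", ["EX"])
        table = EnzymeTable(
            kcat={("i1", "R1"): 2.0, ("i2", "R1"): 3.0,
                  ("s1", "R2"): 4.0, ("s2", "R2"): 4.0},
            mw={e: 10.0 for e in ("i1", "i2", "s1", "s2")},
            measured_in_all={"i1", "i2", "s1", "s2"},
        )
        return build_pc_model(net, table)

    def test_isozyme_copies_both_set(self, iso_complex_pc):
        out = substitute_external_kcats(iso_complex_pc, {"R1": 7.0})
        vals = {v for (e, r), v in out.kcat.items() if r.startswith("R1")}
        assert vals == {7.0}

    def test_complex_untouched(self, iso_complex_pc):
        out = substitute_external_kcats(iso_complex_pc, {"R2": 9.0})
        vals = {v for (e, r), v in out.kcat.items() if r.startswith("R2")}
        assert vals == {4.0}

    def test_empty_table_identity(self, iso_complex_pc):
        assert substitute_external_kcats(iso_complex_pc, {}).kcat == iso_complex_pc.kcat

    def test_unknown_reaction_skipped(self, iso_complex_pc, caplog):
        with caplog.at_level("WARNING", logger="presto"):
            out = substitute_external_kcats(iso_complex_pc, {"NOPE": 1.0})
        assert out.kcat == iso_complex_pc.kcat
        assert any("NOPE" in rec.message for rec in caplog.records)


class TestIO:
    def test_json_round_trip(self, chain3, tmp_path):
        network, _, _ = chain3
        path = tmp_path / "net.json"
        write_network(network, path)
        back = load_network(path)
        assert back.reaction_ids == network.reaction_ids
        assert back.biomass_id == network.biomass_id
        for a, b in zip(network.reactions, back.reactions):
            assert a.stoich == b.stoich and a.lb == b.lb and a.ub == b.ub

    def test_sbml_round_trip(self, tmp_path):
        network, _ = linear_chain({"e1": 1.0, "e2": 2.0})
        path = tmp_path / "net.xml"
        write_network(network, path)
        back = load_network(path)
        assert set(back.reaction_ids) == set(network.reaction_ids)
        assert back.biomass_id == network.biomass_id
        r1 = back.reaction("R1")
        assert r1.gpr is not None and r1.gpr.genes() == {"e1"}

    def test_missing_file(self):
        with pytest.raises(FileNotFoundError):
            load_network("does_not_exist.json")

    def test_kcat_table_round_trip(self, recovery_instance, tmp_path):
        pc = recovery_instance.pc_deflated
        path = tmp_path / "kcats.tsv"
        write_kcat_table(pc, path)
        back = read_kcat_table(path)
        assert len(back) == len(pc.kcat)
        for key, v in pc.kcat.items():
            assert back[key] == pytest.approx(v, rel=1e-12)
        # kcat_min reproduced from the re-read table
        for e in pc.enzymes:
            vals = [v for (enz, _), v in back.items() if enz == e]
            assert min(vals) == pytest.approx(pc.kcat_min(e), rel=1e-12)

    def test_enzyme_table_round_trip(self, tmp_path):
        _, table = linear_chain({"e1": 1.5, "e2": 0.3})
        path = tmp_path / "enzymes.tsv"
        table.to_tsv(path)
        back = EnzymeTable.from_tsv(path)
        assert back.kcat == table.kcat
        assert back.mw == table.mw
        assert back.measured_in_all == table.measured_in_all
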