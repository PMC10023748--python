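"""The correction LP: analytic oracles, regularization path, second stage."""

import math

import numpy as np
import pytest

from presto import (
    apply_kcat_corrections,
    build_presto_lp,
    evaluate_conditions,
    negative_correction_step,
    relative_error,
    solve_presto,
)
from presto.presto_lp import check_solution

from conftest import (
    chain_condition,
    linear_chain,
    oracle_grid_search,
    oracle_objective,
)
from presto import build_pc_model


@pytest.fixture(scope="module")
def path_fixture():
    """Single enzyme, three conditions with graded correction demands.

    kcat 10 s^-1, E = 1e-4 mmol/gDW; achieving zero error in condition j
    requires delta >= (2, 5, 9) s^-1 respectively, so the fitted correction
    steps down as the penalty weight grows.
    """
    network, table = linear_chain({"e1": 10.0})
    pc = build_pc_model(network, table)
    E = 1e-4
    conds = [
        chain_condition(f"c{k}", {"e1": E}, 3600 * E * (10.0 + d))
        for k, d in enumerate((2.0, 5.0, 9.0), start=1)
    ]
    return pc, conds


class TestAnalyticChain:
    def test_single_constraint_correction(self, chain3):
        """delta = mu/(3600 E) - kcat on a one-enzyme chain."""
        _, _, pc = chain3
        cond = chain_condition("c1", {"e1": 1e-4}, 0.72)
        res = solve_presto(build_presto_lp(pc, [cond], lam=1e-7))
        assert res.delta["e1"] == pytest.approx(1.0, abs=1e-6)
        assert res.omega["c1"] == pytest.approx(0.0, abs=1e-8)

    def test_zero_correction_when_growth_attained(self, chain3):
        _, _, pc = chain3
        cond = chain_condition("c1", {"e1": 1e-4}, 0.18)  # capacity 0.36 suffices
        res = solve_presto(build_presto_lp(pc, [cond], lam=1e-7))
        assert res.delta["e1"] == pytest.approx(0.0, abs=1e-9)
        assert res.omega["c1"] == pytest.approx(0.0, abs=1e-9)

    def test_shared_delta_takes_larger_requirement(self, chain3):
        """Two conditions demanding 1 and 3 s^-1 share one parameter."""
        _, _, pc = chain3
        conds = [
            chain_condition("c1", {"e1": 1e-4}, 0.72),   # needs delta = 1
            chain_condition("c2", {"e1": 1e-4}, 1.44),   # needs delta = 3
        ]
        res = solve_presto(build_presto_lp(pc, conds, lam=1e-9))
        assert res.delta["e1"] == pytest.approx(3.0, abs=1e-5)
        # brute-force grid over the single delta agrees
        grid_delta, grid_obj = oracle_grid_search(
            pc, conds, ["e1"], {"e1": 6.0}, lam=1e-9, points=25
        )
        assert grid_delta["e1"] == pytest.approx(3.0, abs=0.02)
        lp_obj = float(np.mean(list(res.omega.values()))) + 1e-9 * res.total_correction
        assert abs(lp_obj - grid_obj) <= 1e-3


class TestProblemStructure:
    def test_delta_bounds(self, chain3):
        _, _, pc = chain3
        cond = chain_condition("c1", {"e1": 1e-4}, 0.72)
        prob = build_presto_lp(pc, [cond], lam=1e-7, epsilon=1e5)
        assert prob.delta_upper("e1") == pytest.approx(99_999.0)

    def test_kcat_max_cap_dominates(self):
        network, table = linear_chain({"e1": 5.0e7})
        pc = build_pc_model(network, table)
        cond = chain_condition("c1", {"e1": 1e-4}, 0.5)
        prob = build_presto_lp(pc, [cond], lam=1e-7, kcat_max=5.75e7)
        assert prob.delta_upper("e1") == pytest.approx(7.5e6)

    def test_singleton_objective(self, chain3):
        _, _, pc = chain3
        cond = chain_condition("c1", {"e1": 1e-4}, 0.72)
        prob = build_presto_lp(pc, [cond], lam=0.25)
        assert prob.c[prob.delta_idx["e1"]] == pytest.approx(0.25)
        assert prob.c[prob.omega_idx["c1"]] == pytest.approx(1.0)

    def test_empty_measured_set_rejected(self, chain3):
        _, _, pc = chain3
        cond = chain_condition("c1", {"e1": 1e-4}, 0.72)
        with pytest.raises(ValueError, match="empty|M"):
            build_presto_lp(pc, [cond], lam=1e-7, measured=[])

    def test_negative_lambda_rejected(self, chain3):
        _, _, pc = chain3
        cond = chain_condition("c1", {"e1": 1e-4}, 0.72)
        with pytest.raises(ValueError, match="lambda"):
            build_presto_lp(pc, [cond], lam=-1.0)

    def test_per_reaction_indexing_flag(self, chain3):
        _, _, pc = chain3
        cond = chain_condition("c1", {"e1": 1e-4}, 0.72)
        prob = build_presto_lp(pc, [cond], lam=1e-7, capacity_indexing="per_reaction")
        res = solve_presto(prob)
        # single-reaction enzymes: literal reading coincides with default
        assert res.delta["e1"] == pytest.approx(1.0, abs=1e-6)


class TestRelativeError:
    @pytest.mark.parametrize(
        "mu,v,expected", [(0.4, 0.4, 0.0), (0.4, 0.2, 0.5), (0.4, 1.2, 2.0)]
    )
    def test_measured_denominator(self, mu, v, expected):
        assert relative_error(mu, v) == pytest.approx(expected)

    def test_predicted_denominator_variant(self):
        assert relative_error(0.4, 0.2, "predicted") == pytest.approx(1.0)
        with pytest.raises(ValueError):
            relative_error(0.4, 0.0, "predicted")

    def test_nonpositive_mu_rejected(self):
        with pytest.raises(ValueError):
            relative_error(0.0, 0.1)


class TestPathAndIdempotence:
    def test_lambda_path_monotone_with_movement(self, path_fixture):
        pc, conds = path_fixture
        lams = [0.12, 0.05, 0.03, 0.012, 0.003, 1e-4, 1e-7]
        deltas, omegas = [], []
        for lam in lams:
            r = solve_presto(build_presto_lp(pc, conds, lam=lam))
            deltas.append(r.total_correction)
            omegas.append(float(np.mean(list(r.omega.values()))))
        # descending lambda: Delta grows to the full 9 s^-1, error falls to 0
        assert all(b >= a - 1e-7 for a, b in zip(deltas, deltas[1:]))
        assert all(b <= a + 1e-9 for a, b in zip(omegas, omegas[1:]))
        assert deltas[0] == pytest.approx(0.0, abs=1e-6)
        assert deltas[-1] == pytest.approx(9.0, abs=1e-5)
        assert omegas[-1] == pytest.approx(0.0, abs=1e-8)

    def test_intermediate_plateaus_match_requirements(self, path_fixture):
        """The optimum parks at a per-condition requirement (0, 2, 5 or 9)."""
        pc, conds = path_fixture
        for lam, expected in [(0.05, 2.0), (0.03, 5.0), (0.012, 9.0)]:
            r = solve_presto(build_presto_lp(pc, conds, lam=lam))
            assert r.delta["e1"] == pytest.approx(expected, abs=1e-5)

    def test_idempotence_at_zero_error(self, recovery_instance):
        inst = recovery_instance
        pc = inst.pc_deflated
        res = solve_presto(build_presto_lp(pc, inst.conditions, lam=1e-10))
        assert max(res.omega.values()) <= 1e-8
        corrected = apply_kcat_corrections(pc, res.delta)
        for lam in (1e-12, 1e-7, 1e-2):
            res2 = solve_presto(build_presto_lp(corrected, inst.conditions, lam=lam))
            assert max(abs(d) for d in res2.delta.values()) <= 1e-9


class TestChecker:
    def test_detects_planted_violation(self, chain3):
        _, _, pc = chain3
        cond = chain_condition("c1", {"e1": 1e-4}, 0.72)
        prob = build_presto_lp(pc, [cond], lam=1e-7)
        res = solve_presto(prob)
        assert check_solution(prob, res.x) <= 1e-8
        bad = res.x.copy()
        bad[prob.delta_idx["e1"]] -= 0.5  # capacity now short by 0.5 s^-1
        assert check_solution(prob, bad) > 1e-3


class TestOracleAgreement:
    def test_lp_matches_grid_on_small_instances(self, chain3):
        """Smoke version of the dense-grid equivalence (more in acceptance)."""
        _, _, pc = chain3
        rng = np.random.default_rng(42)
        for _ in range(3):
            mu1 = float(rng.uniform(0.4, 0.9))
            mu2 = float(rng.uniform(0.4, 1.3))
            conds = [
                chain_condition("c1", {"e1": 1e-4}, mu1),
                chain_condition("c2", {"e1": 1e-4}, mu2),
            ]
            lam = float(10 ** rng.uniform(-3, -2))
            res = solve_presto(build_presto_lp(pc, conds, lam=lam))
            lp_obj = float(np.mean(list(res.omega.values()))) + lam * res.total_correction
            _, grid_obj = oracle_grid_search(
                pc, conds, ["e1"], {"e1": 4.0}, lam=lam, points=30
            )
            assert abs(lp_obj - grid_obj) <= 1e-3


class TestNegativeCorrection:
    @pytest.fixture()
    def overprediction_fixture(self):
        """Pool-only growth overshoots ~2x; scenario (iii) is limited by the
        abundance of a pool-negligible enzyme, leaving the heavy enzyme's
        kcat free to shrink."""
        network, table = linear_chain(
            {"e_big": 10.0, "e_small": 10.0}, mws={"e_big": 100.0, "e_small": 0.001}
        )
        pc = build_pc_model(network, table)
        mu = 0.5
        E_small = mu / (3600 * 10.0)          # binds scenario (iii) at mu
        E_big = 2 * E_small                   # twofold slack
        cap = 2.8e-3                          # pool-only growth ~ 1.008 = 2 mu
        cond = chain_condition(
            "c1", {"e_big": E_big, "e_small": E_small}, mu,
            ptot=cap / 0.25, f=0.5, sigma=0.5,
        )
        return pc, cond

    def test_halves_overshooting_kcat(self, overprediction_fixture):
        pc, cond = overprediction_fixture
        res = solve_presto(build_presto_lp(pc, [cond], lam=1e-7))
        assert res.total_correction == pytest.approx(0.0, abs=1e-8)
        before = evaluate_conditions({"m": pc}, [cond], scenarios=["i", "iii"])
        err_i_before = before.query("scenario == 'pool_only'")["rel_error"].iloc[0]
        assert err_i_before > 0.9  # ~ 2x overshoot

        res_neg = negative_correction_step(res, pc, [cond])
        assert res_neg.apparent_rates
        kcat_new = 10.0 + res_neg.delta["e_big"]
        assert kcat_new == pytest.approx(5.0, rel=0.05)

        after_model = apply_kcat_corrections(pc, res_neg.delta, allow_negative=True)
        after = evaluate_conditions({"m": after_model}, [cond], scenarios=["i", "iii"])
        err_i_after = after.query("scenario == 'pool_only'")["rel_error"].iloc[0]
        err_iii_before = before.query("scenario == 'pool_uptake_abundance'")["rel_error"].iloc[0]
        err_iii_after = after.query("scenario == 'pool_uptake_abundance'")["rel_error"].iloc[0]
        assert err_i_after <= 0.01
        assert abs(err_iii_after - err_iii_before) <= 1e-6

    def test_no_overprediction_is_noop(self, chain3):
        _, _, pc = chain3
        cond = chain_condition("c1", {"e1": 1e-4}, 0.72, ptot=4e-5)
        # pool cap 1e-5 g/gDW => pool-limited growth below mu: no reduction
        res = solve_presto(build_presto_lp(pc, [cond], lam=1e-7))
        res_neg = negative_correction_step(res, pc, [cond])
        assert not res_neg.apparent_rates
        assert res_neg.delta == res.delta
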