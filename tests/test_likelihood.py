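"""Cell probabilities, likelihood maximization, LRTs and the model ladder."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import poetrio as pt
from poetrio.family_data import CellCounts, TRIO_CONFIGS, TRIO_INDEX
from poetrio.likelihood import (MATING_TYPES, ModelSpec, RiskParameters,
                                hwe_mating_types)


def mu_het():
    mu = np.zeros(6)
    mu[MATING_TYPES.index((1, 1))] = 1.0
    return mu


positive = st.floats(0.2, 5.0)
simplex6 = st.lists(st.floats(0.01, 1.0), min_size=6, max_size=6).map(
    lambda w: np.array(w) / np.sum(w))


class TestCellProbabilities:
    def test_neutral_risk_reduces_to_mendelian_table(self):
        mu = hwe_mating_types(0.3)
        table = pt.cell_probabilities(RiskParameters(), mu)
        assert table.trio.sum() == pytest.approx(1.0)
        # under no risk effects, P(1,1,c=2) = mu{1,1}/4
        assert table.trio[TRIO_INDEX[(1, 1, 2)]] == pytest.approx(
            mu[MATING_TYPES.index((1, 1))] / 4)
        assert table.normalizer == pytest.approx(1.0)

    def test_imprinting_example_het_by_het(self):
        # hand enumeration: sub-cell weights 1/4*2, 1/4*2, 1/4, 1/4 -> D=1.5
        table = pt.cell_probabilities(RiskParameters(im=2.0), mu_het())
        assert table.normalizer == pytest.approx(1.5)
        assert table.case.tolist() == pytest.approx([1 / 6, 1 / 2, 1 / 3])

    def test_interaction_example_het_by_het(self):
        # both c=1 origin sub-cells doubled -> P(c=1) = 2/3
        table = pt.cell_probabilities(RiskParameters(gamma11=2.0), mu_het())
        assert table.case[1] == pytest.approx(2 / 3)
        assert table.normalizer == pytest.approx(1.5)

    @given(simplex6, positive, positive, positive, positive)
    @settings(max_examples=60, deadline=None)
    def test_normalization(self, mu, r1, r2, s1, im):
        table = pt.cell_probabilities(
            RiskParameters(r1=r1, r2=r2, s1=s1, im=im), mu)
        for block in (table.trio, table.mother_duo, table.father_duo,
                      table.case, table.control):
            assert (block >= 0).all()
        assert table.trio.sum() == pytest.approx(1.0)
        assert table.mother_duo.sum() == pytest.approx(1.0)
        assert table.case.sum() == pytest.approx(1.0)
        assert table.control.sum() == pytest.approx(1.0)

    @given(simplex6, positive, positive)
    @settings(max_examples=40, deadline=None)
    def test_parental_symmetry_without_poe_terms(self, mu, r1, r2):
        # with Im = Ip = 1 and no maternal terms the trio table is invariant
        # under exchanging mother and father
        table = pt.cell_probabilities(RiskParameters(r1=r1, r2=r2), mu)
        for (m, f, c) in TRIO_CONFIGS:
            assert table.trio[TRIO_INDEX[(m, f, c)]] == pytest.approx(
                table.trio[TRIO_INDEX[(f, m, c)]])
        assert np.allclose(table.mother_duo, table.father_duo)

    def test_invalid_mu_rejected(self):
        with pytest.raises(ValueError, match="simplex"):
            pt.cell_probabilities(RiskParameters(), np.ones(6))


class TestTotalLoglik:
    def test_single_cell_is_n_log_p(self):
        mu = hwe_mating_types(0.2)
        table = pt.cell_probabilities(RiskParameters(), mu)
        counts = CellCounts.from_trio_dict({(1, 0, 1): 7})
        expected = 7 * math.log(table.trio[TRIO_INDEX[(1, 0, 1)]])
        assert pt.total_loglik(counts, RiskParameters(), mu) == \
            pytest.approx(expected)

    def test_empty_counts_give_zero(self):
        assert pt.total_loglik(CellCounts(), RiskParameters(),
                               hwe_mating_types(0.1)) == 0.0

    def test_positive_count_on_zero_probability_cell(self):
        mu = np.zeros(6)
        mu[MATING_TYPES.index((0, 0))] = 1.0
        counts = CellCounts.from_trio_dict({(1, 0, 1): 1})
        assert pt.total_loglik(counts, RiskParameters(), mu) == -math.inf

    def test_generating_parameters_maximize_expected_loglik(self):
        # at expected counts the generating point beats perturbations
        cfg = pt.SimulationConfig(q=0.15, r1=2.0, r2=5.0, s1=1.4)
        counts = pt.expected_cell_counts(cfg, 1000)
        mu = hwe_mating_types(cfg.q)
        truth = RiskParameters(r1=cfg.r1, r2=cfg.r2, s1=cfg.s1)
        base = pt.total_loglik(counts, truth, mu)
        rng = np.random.default_rng(5)
        for _ in range(25):
            pert = RiskParameters(
                r1=cfg.r1 * math.exp(rng.normal(0, 0.2)),
                r2=cfg.r2 * math.exp(rng.normal(0, 0.2)),
                s1=cfg.s1 * math.exp(rng.normal(0, 0.2)))
            assert pt.total_loglik(counts, pert, mu) <= base + 1e-9


class TestFitModel:
    def test_recovers_generating_values_from_expected_counts(self):
        cfg = pt.SimulationConfig(q=0.1, r1=2.5, r2=6.0, s1=1.5)
        counts = pt.expected_cell_counts(cfg, 2000)
        fit = pt.fit_model(counts, "mcg")
        assert fit.converged
        assert fit.estimates["r1"] == pytest.approx(2.5, rel=1e-3)
        assert fit.estimates["r2"] == pytest.approx(6.0, rel=1e-3)
        assert fit.estimates["s1"] == pytest.approx(1.5, rel=1e-3)

    def test_nested_models_never_lose_likelihood(self):
        cfg = pt.SimulationConfig(q=0.1, r1=2.0, r2=4.0, s1=1.3)
        counts = pt.expected_cell_counts(cfg, 500)
        lls = [pt.fit_model(counts, name).loglik
               for name in ("null", "cg", "mcg", "full")]
        for small, big in zip(lls, lls[1:]):
            assert big >= small - 1e-6

    def test_boundary_flag_without_homozygous_children(self):
        counts = CellCounts.from_trio_dict({(1, 0, 1): 30, (1, 0, 0): 20,
                                            (0, 0, 0): 50})
        fit = pt.fit_model(counts, "cg")
        assert "r2" in fit.boundary_flags

    def test_empty_counts_error(self):
        with pytest.raises(ValueError, match="empty"):
            pt.fit_model(CellCounts(), "cg")

    def test_grid_search_oracle_on_small_counts(self):
        # independent check that the optimizer found the maximum on a small
        # dataset: (a) it beats a dense Hardy-Weinberg-restricted grid over
        # (q, R1, S1), and (b) on the (R1, S1) slice through its own optimum
        # a dense grid cannot improve on it and peaks within one grid step
        cfg = pt.SimulationConfig(q=0.2, r1=2.0, r2=4.0, s1=1.5)
        counts = pt.expected_cell_counts(cfg, 30)
        counts = CellCounts(trio=np.round(counts.trio))  # <=30 units
        fit = pt.fit_model(counts, "mcg")
        hwe_best = -np.inf
        for q in np.linspace(0.05, 0.5, 19):
            mu = hwe_mating_types(q)
            for r1 in np.exp(np.linspace(0, 1.6, 25)):
                for s1 in np.exp(np.linspace(-0.8, 0.8, 25)):
                    hwe_best = max(hwe_best, pt.total_loglik(
                        counts,
                        RiskParameters(r1=r1, r2=fit.estimates["r2"], s1=s1),
                        mu))
        assert fit.loglik >= hwe_best - 1e-6
        r1_hat, s1_hat = fit.estimates["r1"], fit.estimates["s1"]
        step = 0.02  # log-scale grid resolution
        best = (-np.inf, None)
        for lr1 in np.arange(-0.5, 0.5, step) + math.log(r1_hat):
            for ls1 in np.arange(-0.5, 0.5, step) + math.log(s1_hat):
                ll = pt.total_loglik(
                    counts, RiskParameters(r1=math.exp(lr1),
                                           r2=fit.estimates["r2"],
                                           s1=math.exp(ls1)), fit.mu)
                if ll > best[0]:
                    best = (ll, (lr1, ls1))
        assert fit.loglik >= best[0] - 1e-8
        assert abs(best[1][0] - math.log(r1_hat)) <= step
        assert abs(best[1][1] - math.log(s1_hat)) <= step


class TestLrtAndCi:
    def test_printed_loglik_pairs(self):
        res = pt.lrt_from_logliks(-3378.5, -3209.89, df=2)
        assert res.p == pytest.approx(5.9e-74, rel=0.01)
        res = pt.lrt_from_logliks(-3378.5, -3199.46, df=3)
        assert res.p == pytest.approx(2.7e-77, rel=0.01)
        assert res.log10_p == pytest.approx(math.log10(2.7e-77), abs=0.01)

    def test_equal_logliks(self):
        res = pt.lrt_from_logliks(-10.0, -10.0, df=1)
        assert res.statistic == 0.0
        assert res.p == 1.0

    def test_non_nested_rejected(self):
        cfg = pt.SimulationConfig(q=0.1)
        counts = pt.expected_cell_counts(cfg, 200)
        mcg = pt.fit_model(counts, "mcg")
        im = pt.fit_model(counts, "im")
        with pytest.raises(ValueError, match="not.*nested|nested"):
            pt.lrt(mcg, im)

    def test_different_data_rejected(self):
        cfg = pt.SimulationConfig(q=0.1)
        a = pt.fit_model(pt.expected_cell_counts(cfg, 200), "cg")
        b = pt.fit_model(pt.expected_cell_counts(cfg, 300), "mcg")
        with pytest.raises(ValueError, match="different"):
            pt.lrt(a, b)

    def test_wald_ci_matches_printed_interval(self):
        fit = pt.FitResult(spec=ModelSpec("mcg"),
                           estimates={"r1": 2.57, "r2": 7.97, "s1": 1.55},
                           se_log={"s1": 0.0947, "r1": 0.1, "r2": 0.2},
                           mu=hwe_mating_types(0.1), loglik=0.0,
                           converged=True, boundary_flags={})
        lo, hi, reliable = pt.wald_ci(fit)["s1"]
        assert reliable
        assert lo == pytest.approx(1.29, abs=0.005)
        assert hi == pytest.approx(1.87, abs=0.005)
        # zero SE degenerates to the point estimate; level 0 likewise
        fit.se_log["s1"] = 0.0
        lo, hi, _ = pt.wald_ci(fit)["s1"]
        assert lo == hi == pytest.approx(1.55)
        fit.se_log["s1"] = 0.0947
        lo, hi, _ = pt.wald_ci(fit, level=0.0)["s1"]
        assert lo == hi == pytest.approx(1.55)


class TestLadderAndSwap:
    def test_ladder_monotone_and_discriminates_maternal_effect(self):
        # generated with a maternal effect and no imprinting: adding S1 to
        # the imprinting model should improve fit far more than adding Im
        # to the maternal model
        cfg = pt.SimulationConfig(q=0.1, r1=2.5, r2=6.0, s1=1.5, im=1.0)
        counts = pt.simulate_trio_counts(cfg, 2000,
                                         np.random.default_rng(42))
        ladder = pt.run_ladder(counts)
        lls = [ladder.fits[n].loglik for n in ("null", "cg", "mcg", "full")]
        assert all(b >= s - 1e-6 for s, b in zip(lls, lls[1:]))
        assert ladder.vs_full["im"].statistic > ladder.vs_full["mcg"].statistic
        assert ladder.vs_cg["mcg"].p < 0.01

    def test_interaction_step(self):
        cfg = pt.SimulationConfig(q=0.15, r1=2.0, r2=4.0, s1=1.3)
        counts = pt.expected_cell_counts(cfg, 500)
        ladder = pt.run_ladder(counts, include_interaction=True)
        assert ladder.interaction_vs_mcg is not None
        # no interaction generated: the extra term should add ~nothing
        assert ladder.interaction_vs_mcg.statistic < 1e-4

    def test_swap_moves_cells_and_is_involution(self):
        counts = CellCounts.from_trio_dict({(2, 0, 1): 3, (1, 1, 1): 2,
                                            (1, 0, 0): 5})
        counts.mother_duo[0] = 4
        swapped = pt.swap_parents(counts)
        assert swapped.trio_count(0, 2, 1) == 3
        assert swapped.trio_count(2, 0, 1) == 0
        assert swapped.trio_count(1, 1, 1) == 2
        assert swapped.father_duo[0] == 4
        back = pt.swap_parents(swapped)
        assert np.array_equal(back.trio, counts.trio)
        assert np.array_equal(back.mother_duo, counts.mother_duo)
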