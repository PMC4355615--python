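"""Synthetic-family generator: risk law, ascertainment, oracle, round-trip."""

import numpy as np
import pytest

import poetrio as pt
from poetrio.family_data import TRIO_INDEX
from poetrio.simulate import SensitizationModel


class TestConfigValidation:
    def test_invalid_probability_combination_rejected(self):
        with pytest.raises(ValueError, match="risk law"):
            pt.SimulationConfig(k_baseline=0.2, r2=10.0, s1=1.5)

    def test_bad_q(self):
        with pytest.raises(ValueError):
            pt.SimulationConfig(q=0.0)

    def test_bad_sibship(self):
        with pytest.raises(ValueError):
            pt.SimulationConfig(sibship_probs=(0.5, 0.4))

    def test_variant_freqs_must_sum_to_q(self):
        with pytest.raises(ValueError):
            pt.SimulationConfig(q=0.1, variant_freqs=(0.05, 0.02))


class TestSimulateFamilies:
    def test_null_model_affected_fraction_near_baseline(self):
        cfg = pt.SimulationConfig(q=0.1, k_baseline=0.05, r1=1, r2=1, s1=1,
                                  im=1, n_families=800, min_affected=1,
                                  seed=2)
        _, truth = pt.simulate_families(cfg)
        # Under the null every child is affected with probability K, but
        # ascertainment conditions on >= 1 affected child per family.  The
        # ascertainment-free check: given the first child is affected the
        # family is retained regardless of the second, whose affection rate
        # is therefore exactly K by independence.
        two = truth[truth.groupby("family_id")["child_id"]
                    .transform("count") == 2]
        first = two[two["child_id"] == "c1"].set_index("family_id")
        second = two[two["child_id"] == "c2"].set_index("family_id")
        cond = second.loc[first[first["affected"] == 1].index, "affected"]
        assert len(cond) > 60
        rate = cond.mean()
        assert abs(rate - cfg.k_baseline) < 3 * np.sqrt(
            cfg.k_baseline * (1 - cfg.k_baseline) / len(cond))

    def test_truth_table_consistent_with_families(self, sim_study):
        cfg, families, truth, _, _ = sim_study
        by_key = truth.set_index(["family_id", "child_id"])
        for fam in families:
            m_dos = fam.mother.combined
            for child in fam.children:
                row = by_key.loc[(fam.family_id, child.individual_id)]
                assert row["dosage"] == child.combined
                assert row["mother_dosage"] == m_dos
                assert bool(row["affected"]) == \
                    (child.affection == "affected")
            assert fam.covariates["maternal_sensitization"] == \
                by_key.loc[fam.family_id]["maternal_sensitization"].iloc[0]

    def test_ascertainment_rule_enforced(self):
        cfg = pt.SimulationConfig(n_families=60, min_affected=2, seed=4)
        families, _ = pt.simulate_families(cfg)
        assert all(len(f.affected_children()) >= 2 for f in families)

    def test_maternal_effect_enriches_mothers_over_fathers(self):
        # ascertained families under S1 > 1 show the parental asymmetry
        diffs = []
        for seed in range(6):
            cfg = pt.SimulationConfig(q=0.1, s1=1.6, min_affected=2,
                                      n_families=150, seed=seed)
            families, _ = pt.simulate_families(cfg)
            ff = pt.founder_freq(families)
            diffs.append(ff.mothers - ff.fathers)
        assert np.mean(diffs) > 0
        assert sum(d > 0 for d in diffs) >= 5  # sign test over replicates

    def test_reproducibility(self, tmp_path):
        cfg = pt.SimulationConfig(n_families=40, seed=99)
        fams1, truth1 = pt.simulate_families(cfg)
        fams2, truth2 = pt.simulate_families(cfg)
        pt.write_pedfile(fams1, tmp_path / "a.ped")
        pt.write_pedfile(fams2, tmp_path / "b.ped")
        assert (tmp_path / "a.ped").read_text() == \
            (tmp_path / "b.ped").read_text()
        assert truth1.equals(truth2)


class TestSimulateUnrelated:
    def test_control_frequency_near_q(self):
        cfg = pt.SimulationConfig(q=0.1, n_controls=3000, seed=8)
        _, controls = pt.simulate_unrelated(cfg)
        freq = np.mean([c.combined for c in controls]) / 2
        assert freq == pytest.approx(0.1, abs=0.015)

    def test_cases_enriched_relative_to_controls(self):
        cfg = pt.SimulationConfig(q=0.1, r1=2.5, r2=6.0, n_cases=800,
                                  n_controls=800, seed=8)
        cases, controls = pt.simulate_unrelated(cfg)
        case_freq = np.mean([c.combined for c in cases]) / 2
        ctrl_freq = np.mean([c.combined for c in controls]) / 2
        assert case_freq > ctrl_freq

    def test_zero_cases_empty(self):
        cfg = pt.SimulationConfig(n_cases=0, n_controls=5, seed=1)
        cases, controls = pt.simulate_unrelated(cfg)
        assert cases == [] and len(controls) == 5


class TestExpectedCellCounts:
    def test_counts_sum_to_n(self):
        cfg = pt.SimulationConfig(q=0.1, r1=2.5, r2=6.0, s1=1.5)
        counts = pt.expected_cell_counts(cfg, 500)
        assert counts.trio.sum() == pytest.approx(500)

    def test_neutral_half_frequency_hand_value(self):
        # all risks 1, q = 0.5: het x het matings have probability 1/4 and
        # split children 1/4 : 1/2 : 1/4, so cell (1,1,1) holds 1/8 of trios
        cfg = pt.SimulationConfig(q=0.5, k_baseline=0.05, r1=1, r2=1, s1=1)
        counts = pt.expected_cell_counts(cfg, 1)
        assert counts.trio[TRIO_INDEX[(1, 1, 1)]] == pytest.approx(0.125)

    def test_feeding_oracle_counts_recovers_parameters(self):
        cfg = pt.SimulationConfig(q=0.1, r1=3.0, r2=7.0, s1=1.4, im=1.25)
        counts = pt.expected_cell_counts(cfg, 4000)
        fit = pt.fit_model(counts, "full")
        for name, truth in (("r1", 3.0), ("r2", 7.0), ("s1", 1.4),
                            ("im", 1.25)):
            assert fit.estimates[name] == pytest.approx(truth, rel=2e-3)

    def test_fast_sampler_matches_oracle_distribution(self):
        cfg = pt.SimulationConfig(q=0.12, r1=2.0, r2=5.0, s1=1.4)
        n = 60_000
        sampled = pt.simulate_trio_counts(cfg, n, np.random.default_rng(21))
        expected = pt.expected_cell_counts(cfg, n)
        # chi-square-ish agreement on well-populated cells
        mask = expected.trio > 25
        z = ((sampled.trio[mask] - expected.trio[mask])
             / np.sqrt(expected.trio[mask]))
        assert np.max(np.abs(z)) < 5.0


class TestSensitizationGate:
    def test_maternal_effect_only_in_sensitized_stratum(self):
        cfg = pt.SimulationConfig(
            q=0.1, r1=2.5, r2=6.0, s1=1.6,
            sens=SensitizationModel(p_carrier=0.5, p_noncarrier=0.5,
                                    gates_s1=True),
            n_families=900, min_affected=1, seed=31)
        families, truth = pt.simulate_families(cfg)
        sens = pt.stratify_families(families, "sensitized")
        nons = pt.stratify_families(families, "not_sensitized")
        fit_s = pt.fit_model(pt.tabulate_cells(pt.extract_units(sens)),
                             "mcg")
        fit_n = pt.fit_model(pt.tabulate_cells(pt.extract_units(nons)),
                             "mcg")
        assert fit_s.estimates["s1"] > fit_n.estimates["s1"]
        assert fit_s.estimates["s1"] > 1.2
        assert fit_n.estimates["s1"] < 1.35


class TestWritePedfile:
    def test_four_variant_roundtrip(self, tmp_path):
        cfg = pt.SimulationConfig(
            q=0.105, n_families=60, n_cases=15, n_controls=30, seed=5,
            variant_freqs=(0.059, 0.034, 0.010, 0.002))
        families, _ = pt.simulate_families(cfg)
        cases, controls = pt.simulate_unrelated(cfg)
        ped, mp = tmp_path / "x.ped", tmp_path / "x.map"
        cov = tmp_path / "x.cov.tsv"
        pt.write_pedfile(families, ped, mp, cov, unrelated=cases + controls,
                         panel=cfg.panel)
        fams2, unrel2 = pt.read_pedfile(ped, mp, panel=pt.FLG_PANEL)
        ped2 = tmp_path / "y.ped"
        pt.write_pedfile(fams2, ped2, unrelated=unrel2, panel=cfg.panel)
        assert ped.read_text() == ped2.read_text()

    def test_covariates_match_truth(self, tmp_path, sim_study):
        cfg, families, truth, _, _ = sim_study
        cov = tmp_path / "c.tsv"
        pt.write_pedfile(families, tmp_path / "c.ped",
                         covariates_path=cov)
        df = pt.family_data.read_covariates(cov)
        merged = truth.drop_duplicates("family_id").merge(df, on="family_id",
                                                          suffixes=("", "_f"))
        assert (merged["maternal_sensitization"]
                == merged["maternal_sensitization_f"]).all()

    def test_empty_family_set(self, tmp_path):
        pt.write_pedfile([], tmp_path / "e.ped", tmp_path / "e.map")
        assert (tmp_path / "e.ped").read_text() == ""
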