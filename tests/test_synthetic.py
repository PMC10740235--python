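"""The synthetic trial generator: calibration, determinism, ground truth."""

import json

import numpy as np
import pytest

import cuakit
from cuakit.synthetic import CategorySpec, DEFAULT_CATEGORIES

from conftest import prepared_frame


def _constant_config(**kw):
    cats = tuple(
        CategorySpec(c.name, mean=100.0, sd=0.0, p_use=1.0) for c in DEFAULT_CATEGORIES
    )
    return cuakit.SyntheticTrialConfig(
        categories=cats,
        utility_sd=0.0,
        utility_mean=0.8,
        dropout=False,
        p_missing_baseline=0.0,
        seed=3,
        **kw,
    )


class TestGenerateTrial:
    def test_zero_variance_config_makes_identical_participants(self):
        bundle, _ = cuakit.generate_trial(_constant_config())
        units = bundle.service_use["units"]
        np.testing.assert_allclose(units, 100.0, rtol=1e-12)
        np.testing.assert_allclose(bundle.utilities["utility"], 0.8, atol=1e-9)

    def test_seed_determinism_is_byte_identical(self, tmp_path):
        cfg = cuakit.SyntheticTrialConfig(seed=123)
        for d in ("a", "b"):
            bundle, truth = cuakit.generate_trial(cfg)
            cuakit.write_synthetic_trial(bundle, truth, tmp_path / d)
        for name in ("participants.csv", "service_use.csv", "utilities.csv", "ground_truth.json"):
            a = (tmp_path / "a" / name).read_bytes()
            b = (tmp_path / "b" / name).read_bytes()
            assert a == b, name

    def test_different_seeds_differ(self):
        b1, _ = cuakit.generate_trial(cuakit.SyntheticTrialConfig(seed=1))
        b2, _ = cuakit.generate_trial(cuakit.SyntheticTrialConfig(seed=2))
        assert not b1.service_use["units"].equals(b2.service_use["units"])

    def test_family_and_arm_structure(self):
        cfg = cuakit.SyntheticTrialConfig(seed=10)
        bundle, truth = cuakit.generate_trial(cfg)
        p = bundle.participants
        fams = p.groupby("family_id")
        assert p["family_id"].nunique() == 2 * cfg.n_families_per_arm
        assert fams["arm"].nunique().eq(1).all()
        sizes = fams.size()
        assert set(sizes.unique()) <= {1, 2}
        # mean family size near 1 + p_two_children
        assert sizes.mean() == pytest.approx(1.6, abs=0.15)
        arms = p.drop_duplicates("family_id")["arm"].value_counts()
        assert arms["TAU"] == arms["INT"] == cfg.n_families_per_arm

    def test_costs_nonnegative_and_utilities_bounded(self):
        cfg = cuakit.SyntheticTrialConfig(seed=21)
        bundle, _ = cuakit.generate_trial(cfg)
        assert (bundle.service_use["units"] >= 0).all()
        u = bundle.utilities["utility"].dropna()
        assert u.between(cfg.u_min, cfg.u_max).all()

    def test_skewness_sd_exceeds_mean_under_defaults(self):
        cfg = cuakit.SyntheticTrialConfig(seed=33, dropout=False, p_missing_baseline=0.0)
        bundle, _ = cuakit.generate_trial(cfg)
        uc = cuakit.unit_cost_table_for(cfg)
        panel = cuakit.price_service_use(
            bundle.service_use, uc, participants=bundle.participants["participant_id"]
        )
        base = panel[panel["wave"] == 0]
        for cat in ("inpatient", "institutional_welfare", "school_based", "total"):
            assert base[cat].std() > base[cat].mean()

    def test_marginal_moments_match_targets_at_large_n(self):
        """At 600 families/arm the 6-month total cost mean and SD land
        within 15% of the configured targets."""
        cfg = cuakit.SyntheticTrialConfig(
            seed=44, n_families_per_arm=600, dropout=False, p_missing_baseline=0.0
        )
        bundle, _ = cuakit.generate_trial(cfg)
        uc = cuakit.unit_cost_table_for(cfg)
        panel = cuakit.price_service_use(
            bundle.service_use, uc, participants=bundle.participants["participant_id"]
        )
        target_mean = sum(c.mean for c in cfg.categories)  # 1891.25
        target_sd = np.sqrt(sum(c.sd**2 for c in cfg.categories))  # independent cats
        totals = panel["total"]
        assert totals.mean() == pytest.approx(target_mean, rel=0.15)
        assert totals.std() == pytest.approx(target_sd, rel=0.15)

    def test_mean_baseline_cost_over_replicates_near_study_level(self):
        """Across replicate trials the baseline 6-month mean total cost sits
        within 15% of the €1,891 configured total."""
        means = []
        for seed in range(20):
            cfg = cuakit.SyntheticTrialConfig(seed=500 + seed, dropout=False)
            bundle, _ = cuakit.generate_trial(cfg)
            uc = cuakit.unit_cost_table_for(cfg)
            panel = cuakit.price_service_use(
                bundle.service_use, uc, participants=bundle.participants["participant_id"]
            )
            means.append(panel.loc[panel["wave"] == 0, "total"].mean())
        assert np.mean(means) == pytest.approx(1891.25, rel=0.15)

    def test_utility_marginals_near_targets(self):
        cfg = cuakit.SyntheticTrialConfig(seed=55, n_families_per_arm=600, dropout=False)
        bundle, _ = cuakit.generate_trial(cfg)
        u = bundle.utilities["utility"]
        assert u.mean() == pytest.approx(0.76, abs=0.01)
        assert u.std() == pytest.approx(0.07, rel=0.1)

    def test_infeasible_moments_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            CategorySpec("inpatient", mean=100.0, sd=0.0, p_use=0.5).positive_part()
        with pytest.raises(ValueError):
            CategorySpec("inpatient", mean=100.0, sd=-5.0, p_use=0.5).positive_part()

    def test_item_level_mode_prices_to_the_same_totals(self):
        direct = cuakit.SyntheticTrialConfig(seed=66, dropout=False, p_missing_baseline=0.0)
        itemised = cuakit.SyntheticTrialConfig(
            seed=66, dropout=False, p_missing_baseline=0.0, item_level=True
        )
        panels = {}
        for cfg in (direct, itemised):
            bundle, _ = cuakit.generate_trial(cfg)
            uc = cuakit.unit_cost_table_for(cfg)
            panels[cfg.item_level] = cuakit.price_service_use(
                bundle.service_use, uc, participants=bundle.participants["participant_id"]
            )
        np.testing.assert_allclose(
            panels[True]["total"], panels[False]["total"], rtol=1e-9
        )

    def test_ground_truth_round_trips_to_json(self, tmp_path):
        cfg = cuakit.SyntheticTrialConfig(seed=9, delta_qaly=0.02, delta_cost_per_year=150.0)
        bundle, truth = cuakit.generate_trial(cfg)
        paths = cuakit.write_synthetic_trial(bundle, truth, tmp_path)
        stored = json.loads(paths["ground_truth"].read_text())
        assert stored["delta_qaly"] == 0.02
        assert stored["delta_cost_per_year"] == 150.0
        assert set(stored["planted_wave_missing"]) == {"1", "2", "3"}


class TestInduceDropout:
    def test_zero_probabilities_change_nothing(self):
        cfg = cuakit.SyntheticTrialConfig(seed=12, dropout=False, p_missing_baseline=0.0)
        bundle, _ = cuakit.generate_trial(cfg)
        out, planted = cuakit.induce_dropout(bundle, (0.0, 0.0, 0.0), seed=1)
        assert all(len(v) == 0 for v in planted.values())
        assert out.service_use.equals(bundle.service_use)
        assert out.utilities.equals(bundle.utilities)

    def test_certain_dropout_leaves_only_baseline(self):
        cfg = cuakit.SyntheticTrialConfig(seed=12, dropout=False, p_missing_baseline=0.0)
        bundle, _ = cuakit.generate_trial(cfg)
        out, planted = cuakit.induce_dropout(bundle, (1.0, 1.0, 1.0), seed=1)
        assert set(out.service_use["wave"]) == {0}
        observed = out.utilities[out.utilities["assessed"] == 1]
        assert set(observed["wave"]) == {0}
        n = len(bundle.participants)
        assert all(len(planted[w]) == n for w in (1, 2, 3))

    def test_planted_set_matches_applied_missingness(self):
        cfg = cuakit.SyntheticTrialConfig(seed=13, p_missing_baseline=0.0)
        bundle, truth = cuakit.generate_trial(cfg)
        mask = cuakit.missingness_mask(bundle).set_index(["participant_id", "wave"])
        for w, ids in truth.planted_wave_missing.items():
            for pid in ids:
                assert not mask.loc[(pid, w), "cost_observed"]
                assert not mask.loc[(pid, w), "utility_observed"]

    def test_expected_missing_counts_match_calibration(self):
        """Average missing counts on ~327 children match the 96/172/170
        calibration targets within Monte-Carlo tolerance."""
        fractions = np.zeros(3)
        n_rep = 30
        for seed in range(n_rep):
            cfg = cuakit.SyntheticTrialConfig(seed=700 + seed, p_missing_baseline=0.0)
            bundle, truth = cuakit.generate_trial(cfg)
            n = len(bundle.participants)
            fractions += [len(truth.planted_wave_missing[w]) / n for w in (1, 2, 3)]
        fractions /= n_rep
        targets = np.array([96, 172, 170]) / 327
        # binomial MC tolerance: sd of a mean of 30 fractions is under 0.005
        np.testing.assert_allclose(fractions, targets, atol=0.02)


class TestEffectRecovery:
    def test_qaly_effect_recovered_within_two_se(self):
        cfg = cuakit.SyntheticTrialConfig(
            seed=88, n_families_per_arm=1500, delta_qaly=0.05, dropout=False
        )
        f = prepared_frame(cfg)
        est = cuakit.estimate_difference_ols(f["qaly_total"], f["arm"], f["family_id"])
        assert abs(est.delta - 0.05) < 2 * est.se

    def test_cost_effect_shifts_annual_mean(self):
        cfg = cuakit.SyntheticTrialConfig(
            seed=89, n_families_per_arm=1500, delta_cost_per_year=500.0, dropout=False
        )
        f = prepared_frame(cfg)
        est = cuakit.estimate_difference_ols(f["annual_total"], f["arm"], f["family_id"])
        assert abs(est.delta - 500.0) < 2 * est.se

    def test_null_config_reports_zero_truth(self):
        _, truth = cuakit.generate_trial(cuakit.SyntheticTrialConfig(seed=1))
        assert truth.delta_cost_per_year == 0.0
        assert truth.delta_qaly == 0.0
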