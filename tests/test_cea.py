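"""ICUR point estimates, bootstrap cloud, CEAC and NMB regression."""

import numpy as np
import pandas as pd
import pytest

import cuakit
from cuakit.cea import BootstrapCloud


class TestICURPoint:
    def test_overall_printed_deltas(self):
        """∆C=−516.14, ∆E=0.0037 → ≈ −139,497 €/QALY, −139.50 €/0.001 QALY."""
        r = cuakit.icur_point(-516.14, 0.0037)
        assert r.icur == pytest.approx(-139497.3, abs=0.1)
        assert r.icur_per_milli_qaly == pytest.approx(-139.4973, abs=1e-4)
        assert abs(r.icur_per_milli_qaly - (-139.49)) < 0.01
        assert r.quadrant == "SE"

    @pytest.mark.parametrize(
        "dc,de,expected_milli",
        [(-336.2, 0.0032, -105.06), (-696.05, 0.0028, -248.59)],
    )
    def test_yearly_printed_deltas(self, dc, de, expected_milli):
        r = cuakit.icur_point(dc, de)
        assert round(r.icur_per_milli_qaly, 2) == expected_milli

    def test_zero_cost_difference_sits_on_se_boundary(self):
        r = cuakit.icur_point(0.0, 0.01)
        assert r.icur == 0.0
        assert r.quadrant == "SE"

    def test_zero_qaly_difference_is_undefined_not_thrown(self):
        r = cuakit.icur_point(100.0, 0.0)
        assert not r.defined
        assert np.isnan(r.icur)

    @pytest.mark.parametrize(
        "dc,de,quadrant",
        [(10, 0.01, "NE"), (-10, 0.01, "SE"), (-10, -0.01, "SW"), (10, -0.01, "NW")],
    )
    def test_quadrants_match_signs(self, dc, de, quadrant):
        assert cuakit.icur_point(dc, de).quadrant == quadrant


def _cloud(dc, de):
    dc, de = np.asarray(dc, float), np.asarray(de, float)
    return BootstrapCloud(delta_costs=dc, delta_qalys=de, B=len(dc), seed=0)


class TestBootstrapCloud:
    def _degenerate_frame(self):
        # all participants identical within arm -> cloud collapses to a point
        n = 12
        pid = [f"p{i}" for i in range(n)]
        arm = ["TAU", "INT"] * (n // 2)
        fam = [f"f{i}" for i in range(n)]
        cost = np.where(np.array(arm) == "INT", 900.0, 1000.0)
        qaly = np.where(np.array(arm) == "INT", 0.8, 0.75)
        return pd.DataFrame(
            {"participant_id": pid, "arm": arm, "family_id": fam, "cost": cost, "qaly": qaly}
        )

    def test_degenerate_data_collapse_to_single_point(self):
        f = self._degenerate_frame()
        cloud = cuakit.bootstrap_cloud(
            f["cost"], f["qaly"], f["arm"], f["family_id"], B=300, seed=2
        )
        np.testing.assert_allclose(cloud.delta_costs, -100.0, atol=1e-9)
        np.testing.assert_allclose(cloud.delta_qalys, 0.05, atol=1e-12)
        assert cloud.quadrant_shares["SE"] == 1.0

    def test_seed_reproducibility(self, null_trial_frame):
        f = null_trial_frame
        args = (f["annual_total"], f["qaly_total"], f["arm"], f["family_id"])
        c1 = cuakit.bootstrap_cloud(*args, B=500, seed=77)
        c2 = cuakit.bootstrap_cloud(*args, B=500, seed=77)
        np.testing.assert_array_equal(c1.delta_costs, c2.delta_costs)
        np.testing.assert_array_equal(c1.delta_qalys, c2.delta_qalys)

    def test_quadrant_shares_sum_to_one(self, null_trial_frame):
        f = null_trial_frame
        cloud = cuakit.bootstrap_cloud(
            f["annual_total"], f["qaly_total"], f["arm"], f["family_id"], B=1000, seed=5
        )
        assert sum(cloud.quadrant_shares.values()) == pytest.approx(1.0)


class TestCEAC:
    def test_dominant_single_point_gives_probability_one(self):
        cloud = _cloud([-100.0], [0.01])
        curve = cuakit.ceac(cloud, [0, 1000, 50_000, 125_000])
        assert (curve["prob_ce"] == 1.0).all()

    def test_four_point_cloud_matches_hand_enumeration(self):
        # points: (∆C, ∆E) = (100,0.01), (−100,0.01), (100,−0.01), (−100,−0.01)
        cloud = _cloud([100, -100, 100, -100], [0.01, 0.01, -0.01, -0.01])
        curve = cuakit.ceac(cloud, [0, 10_000, 50_000]).set_index("lambda_")["prob_ce"]
        # λ=0:      nb = −∆C            > 0 for the two cost-saving points → 1/2
        # λ=10,000: nb = 100·∆E·100−∆C → {0, 200, −200, 0}; ties not CE → 1/4
        # λ=50,000: nb = {400, 600, −600, −400} → 1/2
        assert curve[0] == 0.5
        assert curve[10_000] == 0.25
        assert curve[50_000] == 0.5

    def test_mirrored_cloud_complements_probability(self):
        rng = np.random.default_rng(14)
        dc, de = rng.normal(0, 200, 400), rng.normal(0, 0.01, 400)
        lam = [500, 20_000, 100_000]
        p = cuakit.ceac(_cloud(dc, de), lam)["prob_ce"].to_numpy()
        p_mirror = cuakit.ceac(_cloud(-dc, -de), lam)["prob_ce"].to_numpy()
        np.testing.assert_allclose(p + p_mirror, 1.0, atol=1e-12)  # no exact ties here

    def test_probabilities_bounded_and_monotone_for_positive_qaly_gain(self):
        rng = np.random.default_rng(15)
        dc = rng.normal(100, 300, 500)
        de = np.abs(rng.normal(0.01, 0.005, 500))  # every replicate ∆E ≥ 0
        curve = cuakit.ceac(_cloud(dc, de), range(0, 125_001, 5000))
        assert curve["prob_ce"].between(0, 1).all()
        assert (np.diff(curve["prob_ce"]) >= 0).all()

    def test_endpoint_equals_cost_saving_share(self):
        rng = np.random.default_rng(16)
        dc, de = rng.normal(0, 100, 300), rng.normal(0, 0.01, 300)
        curve = cuakit.ceac(_cloud(dc, de), [0])
        assert curve["prob_ce"].iloc[0] == (dc < 0).mean()

    def test_agrees_with_bootstrap_median_net_benefit(self, null_trial_frame):
        """prob_ce(λ) is above/below 0.5 exactly where the bootstrap median
        net benefit is positive/negative."""
        f = null_trial_frame
        cloud = cuakit.bootstrap_cloud(
            f["annual_total"], f["qaly_total"], f["arm"], f["family_id"], B=2000, seed=8
        )
        curve = cuakit.ceac(cloud, range(0, 125_001, 25_000))
        for lam, p in zip(curve["lambda_"], curve["prob_ce"]):
            med = np.median(lam * cloud.delta_qalys - cloud.delta_costs)
            if med > 0:
                assert p >= 0.5
            elif med < 0:
                assert p <= 0.5


class TestNMBRegression:
    def test_at_lambda_zero_nmb_is_negative_cost_delta(self, null_trial_frame):
        f = null_trial_frame
        curve = cuakit.nmb_regression(
            f["annual_total"], f["qaly_total"], f["arm"], f["family_id"], lambdas=[0]
        )
        dc = cuakit.estimate_difference_ols(f["annual_total"], f["arm"], f["family_id"])
        assert curve.table["nmb"].iloc[0] == pytest.approx(-dc.delta, rel=1e-12)

    def test_printed_cost_delta_gives_positive_nmb_at_lambda_zero(self):
        """With an estimated ∆C of −516.14 the λ=0 net benefit is +516.14."""
        # pure identity nmb(0) = −∆C, exercised through a constructed trial
        # whose arm mean difference is exactly −516.14
        n = 8
        arm = np.array(["TAU", "INT"] * (n // 2))
        cost = np.where(arm == "INT", 1000.0 - 516.14, 1000.0)
        fam = [f"f{i}" for i in range(n)]
        curve = cuakit.nmb_regression(cost, np.full(n, 0.76), arm, fam, lambdas=[0])
        assert curve.table["nmb"].iloc[0] == pytest.approx(516.14)

    def test_affine_in_lambda_with_slope_delta_qaly(self, null_trial_frame):
        f = null_trial_frame
        curve = cuakit.nmb_regression(
            f["annual_total"], f["qaly_total"], f["arm"], f["family_id"],
            lambdas=[0, 10_000, 60_000, 125_000],
        )
        t = curve.table
        slopes = np.diff(t["nmb"]) / np.diff(t["lambda_"])
        np.testing.assert_allclose(slopes, curve.delta_qaly, rtol=1e-10)

    def test_internal_consistency_with_incremental_estimates(self, null_trial_frame):
        f = null_trial_frame
        dc = cuakit.estimate_difference_ols(f["annual_total"], f["arm"], f["family_id"])
        de = cuakit.estimate_difference_ols(f["qaly_total"], f["arm"], f["family_id"])
        lam = 30_000.0
        curve = cuakit.nmb_regression(
            f["annual_total"], f["qaly_total"], f["arm"], f["family_id"], lambdas=[lam]
        )
        assert curve.table["nmb"].iloc[0] == pytest.approx(
            lam * de.delta - dc.delta, rel=1e-12
        )

    def test_band_brackets_the_estimate(self, null_trial_frame):
        f = null_trial_frame
        for ci in ("robust", "bootstrap"):
            curve = cuakit.nmb_regression(
                f["annual_total"], f["qaly_total"], f["arm"], f["family_id"],
                lambdas=range(0, 125_001, 25_000), ci=ci, B=400, seed=6,
            )
            t = curve.table
            assert (t["ll"] <= t["nmb"]).all()
            assert (t["nmb"] <= t["ul"]).all()

    def test_negative_wtp_rejected(self, null_trial_frame):
        f = null_trial_frame
        with pytest.raises(ValueError, match="nonnegative"):
            cuakit.nmb_regression(
                f["annual_total"], f["qaly_total"], f["arm"], f["family_id"], lambdas=[-5]
            )

    def test_normal_theory_ceac_matches_band_logic(self, null_trial_frame):
        f = null_trial_frame
        curve = cuakit.nmb_regression(
            f["annual_total"], f["qaly_total"], f["arm"], f["family_id"],
            lambdas=range(0, 125_001, 25_000),
        )
        probs = cuakit.ceac_normal(curve)
        assert probs["prob_ce"].between(0, 1).all()
        # prob > 0.5 exactly where the point estimate is positive
        np.testing.assert_array_equal(
            probs["prob_ce"] > 0.5, curve.table["nmb"] > 0
        )
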