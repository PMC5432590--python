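"""Vulnerability-curve fitting, inversion, linearization and comparison."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from xylemkit import synthetic as syn
from xylemkit.vulnerability import (
    VulnerabilityCurve,
    compare_treatments,
    linearize,
    plc_sigmoid,
    psi_at_plc,
)


class TestSigmoidClosedForms:
    def test_midpoint_is_50(self):
        assert plc_sigmoid(-1.31, 4.32, -1.31) == pytest.approx(50.0)

    def test_asymptotes(self):
        assert plc_sigmoid(50.0, 4.32, -1.31) == pytest.approx(0.0, abs=1e-12)
        assert plc_sigmoid(-50.0, 4.32, -1.31) == pytest.approx(100.0, abs=1e-12)

    def test_level_12_closed_form(self):
        psi = -1.31 + np.log(88.0 / 12.0) / 4.32
        assert plc_sigmoid(psi, 4.32, -1.31) == pytest.approx(12.0)

    def test_psi_at_50_is_plc50(self):
        assert psi_at_plc(50.0, 4.32, -1.31) == pytest.approx(-1.31)

    def test_12_88_symmetric_about_plc50(self):
        lo = psi_at_plc(12.0, 4.32, -1.31)
        hi = psi_at_plc(88.0, 4.32, -1.31)
        assert (lo + hi) / 2 == pytest.approx(-1.31)

    def test_psi88_closed_form_matches_root_finding(self):
        from scipy.optimize import brentq

        target = psi_at_plc(88.0, 4.32, -1.31)
        root = brentq(lambda p: plc_sigmoid(p, 4.32, -1.31) - 88.0, -10.0, 0.0)
        assert target == pytest.approx(-1.31 - np.log(88.0 / 12.0) / 4.32)
        assert target == pytest.approx(root, abs=1e-10)

    @pytest.mark.parametrize("level", [-1.0, 0.0, 100.0, 101.0])
    def test_level_domain(self, level):
        with pytest.raises(ValueError):
            psi_at_plc(level, 4.32, -1.31)

    @given(
        level=st.floats(0.5, 99.5),
        alpha=st.floats(0.5, 10.0),
        plc50=st.floats(-3.0, -0.3),
    )
    @settings(max_examples=100, deadline=None)
    def test_inversion_roundtrip(self, level, alpha, plc50):
        """predict after invert is the identity on (0, 100)."""
        psi = psi_at_plc(level, alpha, plc50)
        assert plc_sigmoid(psi, alpha, plc50) == pytest.approx(level, rel=1e-9)


class TestLinearize:
    def test_midpoint_maps_to_zero(self):
        df = pd.DataFrame({"plc": [50.0]})
        out, n_ex = linearize(df)
        assert out["y"].iloc[0] == pytest.approx(0.0)
        assert n_ex == 0

    def test_boundaries_excluded_and_counted(self):
        df = pd.DataFrame({"plc": [0.0, 100.0, 12.0]})
        out, n_ex = linearize(df)
        assert n_ex == 2
        assert out["y"].iloc[0] == pytest.approx(np.log(88.0 / 12.0))


class TestVulnerabilityCurveFit:
    @pytest.mark.parametrize(
        "alpha, plc50", [(4.32, -1.31), (4.64, -1.09), (2.0, -2.0)]
    )
    def test_noiseless_exact_recovery(self, alpha, plc50):
        sim = syn.simulate_vc(
            syn.VCGenerator(alpha=alpha, plc50=plc50, noise_sd=0.0, n=20, seed=11)
        )
        res = VulnerabilityCurve.from_dataframe(sim.data).fit()
        assert res.alpha == pytest.approx(alpha, rel=1e-6)
        assert res.plc50 == pytest.approx(plc50, rel=1e-6)
        assert np.max(np.abs(res.residuals)) < 1e-6

    def test_slope_is_25_alpha(self):
        sim = syn.simulate_vc(syn.VCGenerator(alpha=4.0, plc50=-1.2, seed=1))
        res = VulnerabilityCurve.from_dataframe(sim.data).fit()
        assert res.slope_at_p50 == pytest.approx(25.0 * res.alpha)

    def test_derived_points_ordered(self):
        sim = syn.simulate_vc(syn.VCGenerator(alpha=4.32, plc50=-1.31, seed=2))
        res = VulnerabilityCurve.from_dataframe(sim.data).fit()
        assert res.psi12 > res.plc50 > res.psi88

    def test_start_params_deterministic_and_data_driven(self):
        sim = syn.simulate_vc(syn.VCGenerator(alpha=4.0, plc50=-1.2, seed=3))
        m = VulnerabilityCurve.from_dataframe(sim.data)
        a0, p0 = m.start_params
        psi = sim.data["psi_stem"].to_numpy()
        plc = sim.data["plc"].to_numpy()
        assert p0 == psi[np.argmin(np.abs(plc - 50))]
        assert a0 == pytest.approx(4.0 / np.ptp(psi))

    def test_degenerate_flat_data_flagged(self):
        df = pd.DataFrame({"psi_stem": [-0.5, -1.0, -1.5, -2.0], "plc": [50.0] * 4})
        with pytest.warns(UserWarning, match="degenerate"):
            res = VulnerabilityCurve.from_dataframe(df).fit()
        assert res.degenerate
        assert -2.0 <= res.plc50 <= -0.5
        assert abs(res.alpha) < 1e-3

    def test_one_sided_data_flagged(self):
        df = pd.DataFrame(
            {"psi_stem": [-0.2, -0.4, -0.6, -0.8], "plc": [1.0, 2.0, 5.0, 9.0]}
        )
        with pytest.warns(UserWarning, match="degenerate"):
            res = VulnerabilityCurve.from_dataframe(df).fit()
        assert res.degenerate

    def test_linearized_backsolve_agrees_with_nls_on_noiseless_data(self):
        sim = syn.simulate_vc(
            syn.VCGenerator(alpha=4.32, plc50=-1.31, noise_sd=0.0, n=25, seed=5)
        )
        res = VulnerabilityCurve.from_dataframe(sim.data).fit()
        lin, _ = linearize(sim.data)
        a, b = np.polyfit(lin["psi_stem"], lin["y"], 1)
        assert a == pytest.approx(res.alpha, rel=1e-6)
        assert -b / a == pytest.approx(res.plc50, rel=1e-6)

    def test_bootstrap_reproducible_and_ci_brackets_estimate(self):
        sim = syn.simulate_vc(syn.VCGenerator(alpha=4.32, plc50=-1.31, seed=6))
        m = VulnerabilityCurve.from_dataframe(sim.data)
        r1 = m.fit(n_bootstrap=100, seed=99)
        r2 = m.fit(n_bootstrap=100, seed=99)
        ci1, ci2 = r1.conf_int(), r2.conf_int()
        pd.testing.assert_frame_equal(ci1, ci2)
        assert ci1.loc["plc50", "lower"] < r1.plc50 < ci1.loc["plc50", "upper"]

    def test_summary_and_dict_report_the_fit(self):
        sim = syn.simulate_vc(syn.VCGenerator(alpha=4.32, plc50=-1.31, seed=7))
        res = VulnerabilityCurve.from_dataframe(sim.data).fit()
        s = res.summary()
        assert "PLC50" in s and "alpha" in s
        d = res.to_dict()
        assert d["plc50"] == pytest.approx(res.plc50)
        assert d["slope_at_p50"] == pytest.approx(25 * res.alpha)

    def test_free_max_fits_three_parameters(self):
        rng = np.random.default_rng(8)
        psi = np.linspace(-2.5, -0.2, 30)
        plc = 90.0 / (1.0 + np.exp(3.5 * (psi + 1.2))) + rng.normal(0, 1, 30)
        df = pd.DataFrame({"psi_stem": psi, "plc": np.clip(plc, 0, 100)})
        res = VulnerabilityCurve.from_dataframe(df, free_max=True).fit()
        assert res.plc_max == pytest.approx(90.0, abs=3.0)

    def test_too_few_observations_rejected(self):
        df = pd.DataFrame({"psi_stem": [-0.5, -1.0, -1.5], "plc": [10.0, 50.0, 90.0]})
        with pytest.raises(ValueError):
            VulnerabilityCurve.from_dataframe(df)


class TestBootstrapCalibration:
    def test_percentile_ci_coverage_near_nominal(self, seeds):
        """95% bootstrap CIs should contain the generating PLC50 ~95% of the
        time (±5 points) over repeated simulations."""
        hits = 0
        n_rep = 200
        for seed in seeds(1234, n_rep):
            sim = syn.simulate_vc(
                syn.VCGenerator(alpha=4.32, plc50=-1.31, n=36, noise_sd=5, seed=seed)
            )
            res = VulnerabilityCurve.from_dataframe(sim.data).fit(
                n_bootstrap=400, seed=seed + 1
            )
            ci = res.conf_int()
            if ci.loc["plc50", "lower"] <= -1.31 <= ci.loc["plc50", "upper"]:
                hits += 1
        assert 0.90 <= hits / n_rep <= 1.0


class TestCompareTreatments:
    def _two_groups(self, offset, seed, n=30):
        a = syn.simulate_vc(
            syn.VCGenerator(alpha=4.32, plc50=-1.31, n=n, noise_sd=5, seed=seed,
                            treatment="A")
        ).data
        b = syn.simulate_vc(
            syn.VCGenerator(alpha=4.32, plc50=-1.31 + offset, n=n, noise_sd=5,
                            seed=seed + 1, treatment="B")
        ).data
        return pd.concat([a, b], ignore_index=True)

    def test_label_invariance(self):
        """The same dataset under two labels gives identical per-group lines."""
        one = syn.simulate_vc(
            syn.VCGenerator(alpha=4.32, plc50=-1.31, n=30, noise_sd=5, seed=21)
        ).data
        dup = pd.concat(
            [one.assign(treatment="A"), one.assign(treatment="B")],
            ignore_index=True,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cmp_res = compare_treatments(dup)
        pa = cmp_res.per_treatment.loc["A"]
        pb = cmp_res.per_treatment.loc["B"]
        assert pa["alpha"] == pytest.approx(pb["alpha"])
        assert pa["plc50"] == pytest.approx(pb["plc50"])

    def test_identical_generating_parameters_rarely_rejected(self, seeds):
        rejections = [
            compare_treatments(self._two_groups(0.0, s)).joint_pvalue < 0.05
            for s in seeds(77, 60)
        ]
        assert np.mean(rejections) <= 0.15

    def test_offset_detected_in_most_replicates(self, seeds):
        rejections = [
            compare_treatments(self._two_groups(0.25, s)).joint_pvalue < 0.05
            for s in seeds(78, 60)
        ]
        assert np.mean(rejections) > 0.8

    def test_requires_two_treatments(self):
        one = syn.simulate_vc(syn.VCGenerator(alpha=4.0, plc50=-1.2, seed=1)).data
        with pytest.raises(ValueError):
            compare_treatments(one)

    def test_backsolved_parameters_near_truth(self):
        df = self._two_groups(0.0, 42, n=200)
        res = compare_treatments(df)
        for trt in ("A", "B"):
            assert res.per_treatment.loc[trt, "plc50"] == pytest.approx(-1.31, abs=0.1)
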