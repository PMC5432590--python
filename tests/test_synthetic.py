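"""Generators: determinism, forward-model algebra, zero-noise fixed points."""

import numpy as np
import pandas as pd
import pytest

from xylemkit import VulnerabilityCurve, derive_conductances
from xylemkit import synthetic as syn
from xylemkit.vulnerability import plc_sigmoid


class TestDeterminism:
    """Identical (parameters, seed) must give bit-identical datasets."""

    def test_vc(self):
        g = syn.VCGenerator(alpha=4.32, plc50=-1.31, seed=42)
        a, b = syn.simulate_vc(g).data, syn.simulate_vc(g).data
        pd.testing.assert_frame_equal(a, b)

    def test_pv(self):
        g = syn.PVGenerator(pi100=-1.1, epsilon=7.0, noise_rel=0.01, seed=42)
        a, b = syn.simulate_pv(g).data, syn.simulate_pv(g).data
        np.testing.assert_array_equal(a.fresh_weight, b.fresh_weight)
        np.testing.assert_array_equal(a.psi_leaf, b.psi_leaf)

    def test_course(self):
        g = syn.CourseGenerator(noise_rel=0.05, seed=42)
        a = syn.simulate_daily_course(g).data
        b = syn.simulate_daily_course(g).data
        pd.testing.assert_frame_equal(a, b)

    def test_vessels(self):
        g = syn.VesselGenerator.from_mean_diameter(20.0, n=100, seed=42)
        a, b = syn.simulate_vessels(g).data, syn.simulate_vessels(g).data
        pd.testing.assert_frame_equal(a, b)


class TestVCGenerator:
    def test_zero_noise_lies_on_curve(self):
        sim = syn.simulate_vc(syn.VCGenerator(alpha=4.0, plc50=-1.2, noise_sd=0, seed=1))
        expected = plc_sigmoid(sim.data["psi_stem"].to_numpy(), 4.0, -1.2)
        np.testing.assert_allclose(sim.data["plc"], expected, rtol=1e-12)

    def test_noise_clamped_to_bounds(self):
        sim = syn.simulate_vc(
            syn.VCGenerator(alpha=4.0, plc50=-1.2, noise_sd=30, n=200, seed=2)
        )
        assert sim.data["plc"].between(0, 100).all()

    def test_truth_recorded(self):
        sim = syn.simulate_vc(syn.VCGenerator(alpha=4.0, plc50=-1.2, seed=3))
        assert sim.truth["alpha"] == 4.0
        assert sim.data.attrs["truth"]["plc50"] == -1.2


class TestPVGenerator:
    def test_full_turgor_psi_is_zero(self):
        sim = syn.simulate_pv(syn.PVGenerator(pi100=-1.0, epsilon=6.0))
        assert sim.data.psi_leaf[0] == pytest.approx(0.0, abs=1e-12)
        assert sim.data.rwc()[0] == pytest.approx(100.0)

    def test_turgor_vanishes_at_analytic_tlp(self):
        """With af = 0 the model's turgor hits zero at R_s = 1 + π100/ε where
        Ψ = π100·ε/(ε + π100)."""
        gen = syn.PVGenerator(pi100=-1.0, epsilon=6.0)
        rs_tlp = 1.0 + gen.pi100 / gen.epsilon
        psi_tlp = gen.pi100 * gen.epsilon / (gen.epsilon + gen.pi100)
        assert gen.analytic_tlp == pytest.approx(psi_tlp)
        assert gen.analytic_rwc_tlp == pytest.approx(100.0 * rs_tlp)

    def test_sd_like_parameters_give_tlp_near_minus_1_3(self):
        gen = syn.PVGenerator(pi100=-1.10, epsilon=7.17)
        assert gen.analytic_tlp == pytest.approx(-1.30, abs=0.005)

    def test_no_turgor_phase_warns(self):
        with pytest.warns(UserWarning, match="turgor"):
            syn.simulate_pv(syn.PVGenerator(pi100=-1.0, epsilon=0.9, rwc_min=95.0))


class TestCourseGenerator:
    def test_no_flow_equilibrium(self):
        t = np.array([6.0, 12.0])
        e = np.array([0.0, 3.0])
        sim = syn.simulate_daily_course(
            syn.CourseGenerator(psi_predawn=-0.15, E_profile=(t, e))
        )
        row = sim.data.iloc[0]
        assert row["psi_leaf"] == pytest.approx(-0.15)
        assert row["psi_stem"] == pytest.approx(-0.15)

    def test_noiseless_inversion_is_exact(self):
        sim = syn.simulate_daily_course(
            syn.CourseGenerator(k_leaf_true=30.0, k_plant_true=10.0)
        )
        df = derive_conductances(sim.data)
        used = df[df["E"] > 0.01]
        np.testing.assert_allclose(used["k_leaf"], 30.0, rtol=1e-9)
        np.testing.assert_allclose(used["k_plant"], 10.0, rtol=1e-9)

    def test_noisy_recovery_within_5_percent(self, seeds):
        means = []
        for seed in seeds(99, 100):
            sim = syn.simulate_daily_course(
                syn.CourseGenerator(noise_rel=0.05, seed=seed)
            )
            df = derive_conductances(sim.data)
            used = df[df["E"] > 0.2]
            means.append(used["k_plant"].mean())
        assert np.mean(means) == pytest.approx(10.0, rel=0.05)


class TestVesselGenerator:
    def test_zero_spread_gives_constant_diameters(self):
        g = syn.VesselGenerator(log_mean=np.log(20.0), log_sd=0.0, n=10, seed=1)
        sim = syn.simulate_vessels(g)
        np.testing.assert_allclose(sim.data["diameter_um"], 20.0)

    def test_sample_mean_approaches_lognormal_moment(self):
        g = syn.VesselGenerator(log_mean=np.log(18.0), log_sd=0.3, n=20000, seed=2)
        sim = syn.simulate_vessels(g)
        expected = np.exp(g.log_mean + g.log_sd**2 / 2.0)
        assert sim.data["diameter_um"].mean() == pytest.approx(expected, rel=0.01)
        assert sim.truth["expected_mean_diameter"] == pytest.approx(expected)


class TestZeroNoiseFixedPoints:
    """analysis(generate(theta, noise=0)) == theta for every generator."""

    def test_vc_fixed_point(self):
        sim = syn.simulate_vc(
            syn.VCGenerator(alpha=4.64, plc50=-1.09, noise_sd=0.0, seed=5)
        )
        res = VulnerabilityCurve.from_dataframe(sim.data).fit()
        assert res.alpha == pytest.approx(sim.truth["alpha"], rel=1e-6)
        assert res.plc50 == pytest.approx(sim.truth["plc50"], rel=1e-6)

    def test_pv_fixed_point(self):
        sim = syn.simulate_pv(
            syn.PVGenerator(pi100=-1.07, epsilon=8.16, apoplastic_fraction=0.1)
        )
        res = sim.data.fit()
        assert res.pi100 == pytest.approx(-1.07, rel=1e-9)
        assert res.epsilon == pytest.approx(8.16, rel=1e-9)
        assert res.apoplastic_fraction == pytest.approx(0.1, abs=1e-9)

    def test_course_fixed_point(self):
        sim = syn.simulate_daily_course(
            syn.CourseGenerator(k_leaf_true=26.0, k_plant_true=8.0)
        )
        df = derive_conductances(sim.data)
        used = df[df["E"] > 0.01]
        assert used["k_leaf"].mean() == pytest.approx(26.0, rel=1e-9)
        assert used["k_plant"].mean() == pytest.approx(8.0, rel=1e-9)


class TestPresetsAndIO:
    def test_presets_cover_all_regimes_and_kinds(self):
        for name in ("WW", "TD", "SD"):
            p = syn.PRESETS[name]
            assert {"vc", "pv", "course", "vessels"} <= set(p)
            assert p["vc"]["plc50"] < 0 and p["pv"]["pi100"] < 0

    def test_write_dataset_emits_truth_sibling(self, tmp_path):
        import json

        sim = syn.simulate_vc(syn.VCGenerator(alpha=4.0, plc50=-1.2, seed=1))
        out = tmp_path / "vc.csv"
        syn.write_dataset(sim, out)
        assert out.exists()
        truth = json.loads((tmp_path / "vc.truth.json").read_text())
        assert truth["plc50"] == -1.2
        sim_pv = syn.simulate_pv(syn.PVGenerator(pi100=-1.0, epsilon=6.0))
        syn.write_dataset(sim_pv, tmp_path / "pv.csv")
        df = pd.read_csv(tmp_path / "pv.csv")
        assert {"fresh_weight", "psi_leaf", "turgid_weight", "dry_weight"} <= set(
            df.columns
        )
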