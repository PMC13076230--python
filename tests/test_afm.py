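"""Force-curve preprocessing and Hertz-model modulus recovery."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pillarmyelin as pm
from pillarmyelin.afm import fit_hertz, preprocess, read_force_curve, write_force_curve
from pillarmyelin.errors import (InsufficientDataError, NoContactError,
                                 ValidationError)

R_BEAD = 12.5e-6


class TestPreprocess:
    def test_contact_point_recovered_noiseless(self):
        c = pm.generate_force_curve(5100.0, R_BEAD, 0.1, contact_z=0.7e-6, seed=0)
        prep = preprocess(c)
        dz = c.z[1] - c.z[0]
        assert abs(prep.contact_z_m - 0.7e-6) <= 2 * dz

    def test_bending_correction_is_force_over_k(self):
        """At 6 nN with k = 0.6 N/m the cantilever bends 10 nm."""
        assert 6e-9 / 0.6 == pytest.approx(10e-9)
        c = pm.generate_force_curve(20000.0, R_BEAD, 0.6, contact_z=0.0, seed=0)
        prep = preprocess(c)
        i = np.argmin(np.abs(prep.force - 6e-9))
        z_here = prep.delta[i] + prep.force[i] / c.k  # undo the correction
        assert z_here - prep.delta[i] == pytest.approx(prep.force[i] / 0.6, rel=1e-6)

    def test_pure_baseline_raises_no_contact(self):
        z = np.linspace(0, 4e-6, 1024)
        c = pm.ForceCurve(z, np.zeros_like(z), k=0.1, R=R_BEAD)
        with pytest.raises(NoContactError):
            preprocess(c)

    def test_noisy_baseline_without_contact_raises(self):
        rng = np.random.default_rng(3)
        z = np.linspace(0, 4e-6, 1024)
        c = pm.ForceCurve(z, rng.normal(0, 1e-11, z.size), k=0.1, R=R_BEAD)
        with pytest.raises(NoContactError):
            preprocess(c)


class TestHertzFit:
    @pytest.mark.parametrize("E", [500.0, 5000.0, 20000.0, 55000.0])
    def test_noiseless_recovery_within_one_percent(self, E):
        c = pm.generate_force_curve(E, R_BEAD, 0.1, contact_z=0.5e-6, seed=0)
        fit = pm.process_curve(c)
        assert fit.E_pa == pytest.approx(E, rel=0.01)

    @pytest.mark.parametrize("k", [0.01, 0.6])
    @pytest.mark.parametrize("R", [12.5e-6, 25e-6])
    def test_probe_sweep_bias(self, k, R):
        """Bias < 2% at zero noise, < 5% at 2% force noise."""
        E = 5100.0
        clean = pm.generate_force_curve(E, R, k, contact_z=0.5e-6, seed=1)
        assert pm.process_curve(clean).E_pa == pytest.approx(E, rel=0.02)
        peak = clean.force.max()
        noisy = pm.generate_force_curve(E, R, k, contact_z=0.5e-6,
                                        noise_sd=0.02 * peak, seed=1)
        assert pm.process_curve(noisy).E_pa == pytest.approx(E, rel=0.05)

    def test_single_point_inversion(self):
        """One sample at delta = 1 µm, F = 6.29 nN inverts to ~1 kPa."""
        delta = np.full(25, 1e-6)
        force = np.full(25, 6.2854e-9)
        fit = fit_hertz(delta, force, R_BEAD, 0.5, delta_max_fit=2e-6)
        assert fit.E_pa == pytest.approx(1000.0, rel=1e-3)

    def test_force_scaling_scales_modulus_linearly(self):
        c = pm.generate_force_curve(5000.0, R_BEAD, 0.1, contact_z=0.5e-6, seed=0)
        prep = preprocess(c)
        base = fit_hertz(prep.delta, prep.force, R_BEAD)
        doubled = fit_hertz(prep.delta, 2.0 * prep.force, R_BEAD)
        assert doubled.E_pa == pytest.approx(2.0 * base.E_pa, rel=1e-9)

    def test_stiff_cantilever_matches_uncorrected_oracle(self):
        """As k -> inf the bending term vanishes: fitting raw (z - z0, F)
        samples directly gives the same modulus."""
        E = 20000.0
        c = pm.generate_force_curve(E, R_BEAD, 1e4, contact_z=0.0, seed=0)
        post = c.z > 0
        oracle = fit_hertz(c.z[post], c.force[post], R_BEAD)
        full = pm.process_curve(c)
        assert full.E_pa == pytest.approx(oracle.E_pa, rel=0.02)

    def test_insufficient_post_contact_data_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_hertz(np.zeros(30), np.zeros(30), R_BEAD)


class TestAggregate:
    def test_constant_and_simple_sd(self):
        assert pm.aggregate_gel([5100.0] * 9) == (5100.0, 0.0)
        mean, sd = pm.aggregate_gel([4000.0, 5000.0, 6000.0])
        assert mean == 5000.0 and sd == pytest.approx(1000.0)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            pm.aggregate_gel([])

    def test_three_gels_of_nine_noisy_curves(self):
        """Grand mean across 3 gels x 9 curves at 5% force noise stays
        within 5% of the true 20.2 kPa."""
        E = 20200.0
        gel_means = []
        for gel in range(3):
            fits = []
            for i in range(9):
                c = pm.generate_force_curve(E, R_BEAD, 0.3, contact_z=0.5e-6,
                                            noise_sd=0.05 * 2e-8,
                                            seed=100 * gel + i)
                fits.append(pm.process_curve(c).E_pa)
            gel_means.append(pm.aggregate_gel(fits)[0])
        assert np.mean(gel_means) == pytest.approx(E, rel=0.05)


class TestCurveIO:
    def test_round_trip_with_probe_header(self, tmp_path):
        c = pm.generate_force_curve(5100.0, R_BEAD, 0.1, seed=2, noise_sd=1e-11)
        path = tmp_path / "curve.csv"
        write_force_curve(path, c)
        back = read_force_curve(path)
        assert back.k == c.k and back.R == c.R and back.nu == c.nu
        np.testing.assert_allclose(back.force, c.force, rtol=1e-6)

    def test_missing_probe_constants_rejected(self, tmp_path):
        path = tmp_path / "bare.csv"
        z = np.linspace(0, 4e-6, 128)
        path.write_text("\n".join(f"{a},{0.0}" for a in z))
        with pytest.raises(ValidationError):
            read_force_curve(path)
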