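"""Lamellar ultrastructure: layer counts, band thickness, regression."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pillarmyelin as pm
from pillarmyelin.errors import DegenerateDataError, ValidationError
from pillarmyelin.lamellae import (LamellaProfile, measurements_table,
                                   read_profile, write_profile)


class TestLayerCounting:
    @pytest.mark.parametrize("n", [1, 2, 3, 4, 6])
    def test_noiseless_counts_exact(self, n):
        p = pm.generate_lamella_profile(n, 13.0, seed=0)
        count, flags = pm.count_layers(p)
        assert count == n and flags == ()

    def test_flat_profile_flagged(self):
        p = LamellaProfile(np.arange(50.0), np.ones(50))
        count, flags = pm.count_layers(p)
        assert count == 0 and "no_myelin" in flags

    @pytest.mark.parametrize("n", [2, 3, 5])
    def test_noisy_counts_survive(self, n):
        p = pm.generate_lamella_profile(n, 13.0, noise_sd=0.05, seed=n)
        assert pm.count_layers(p)[0] == n


class TestThickness:
    def test_four_layers_at_13nm_is_about_52(self):
        p = pm.generate_lamella_profile(4, 13.0, seed=0)
        assert pm.total_thickness(p) == pytest.approx(52.0, abs=2.5)

    def test_single_layer_one_period_width(self):
        p = pm.generate_lamella_profile(1, 13.0, seed=0)
        assert pm.total_thickness(p) == pytest.approx(13.0, abs=2.5)

    def test_no_layers_undefined(self):
        p = LamellaProfile(np.arange(50.0), np.ones(50))
        with pytest.raises(DegenerateDataError):
            pm.total_thickness(p)

    def test_noisy_band_thickness_within_3nm_over_replicates(self):
        """A 46 nm band (4 layers at 11.5 nm) with noise: replicate mean
        within the reported ±3 nm spread."""
        vals = [pm.total_thickness(pm.generate_lamella_profile(
            4, 11.5, noise_sd=0.05, seed=s)) for s in range(12)]
        assert np.mean(vals) == pytest.approx(46.0, abs=3.0)

    def test_measure_profile_definition_closure(self):
        m = pm.measure_profile(pm.generate_lamella_profile(4, 13.0, seed=0))
        assert m.per_lamella_nm * m.n_layers == pytest.approx(m.thickness_nm)


class TestRegression:
    def test_exact_line(self):
        pairs = [(n, 13.0 * n) for n in range(1, 7)]
        slope, intercept, r2 = pm.thickness_layer_regression(pairs)
        assert slope == pytest.approx(13.0)
        assert intercept == pytest.approx(0.0, abs=1e-9)
        assert r2 == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(4)
        x = rng.integers(2, 7, size=10).astype(float)
        y = 13.0 * x + rng.normal(0, 5, 10)
        slope, intercept, r2 = pm.thickness_layer_regression(list(zip(x, y)))
        A = np.vstack([x, np.ones_like(x)]).T
        beta = np.linalg.solve(A.T @ A, A.T @ y)
        resid = y - A @ beta
        r2_oracle = 1 - resid @ resid / np.sum((y - y.mean()) ** 2)
        assert slope == pytest.approx(beta[0], rel=1e-10)
        assert intercept == pytest.approx(beta[1], rel=1e-8)
        assert r2 == pytest.approx(r2_oracle, rel=1e-10)

    def test_noisy_pairs_keep_high_r_squared(self):
        rng = np.random.default_rng(7)
        n = rng.integers(2, 7, size=50).astype(float)
        t = 13.0 * n + rng.normal(0, 5.0, 50)
        _, _, r2 = pm.thickness_layer_regression(list(zip(n, t)))
        assert r2 >= 0.9

    def test_degenerate_x_rejected(self):
        with pytest.raises(DegenerateDataError):
            pm.thickness_layer_regression([(3, 39.0), (3, 40.0), (3, 41.0)])

    @settings(derandomize=True, max_examples=25)
    @given(alpha=st.floats(0.1, 10), seed=st.integers(0, 50))
    def test_scale_equivariance(self, alpha, seed):
        """Rescaling radial positions rescales thickness/slope, not count/R²."""
        rng = np.random.default_rng(seed)
        n = rng.integers(2, 7, size=8).astype(float)
        t = 13.0 * n + rng.normal(0, 2.0, 8)
        s0, _, r0 = pm.thickness_layer_regression(list(zip(n, t)))
        s1, _, r1 = pm.thickness_layer_regression(list(zip(n, alpha * t)))
        assert s1 == pytest.approx(alpha * s0, rel=1e-9)
        assert r1 == pytest.approx(r0, rel=1e-9)


class TestMultilayerFraction:
    def _meas(self, n_layers):
        return pm.LamellaMeasurement(None, n_layers, 13.0 * max(n_layers, 1))

    def test_half_multilayered(self):
        ms = [self._meas(3)] * 60 + [self._meas(1)] * 60
        pct = pm.multilayer_fraction(ms, ["f1"] * 120)
        assert pct["f1"] == 50.0

    def test_all_single_layer(self):
        ms = [self._meas(1)] * 10
        assert pm.multilayer_fraction(ms, ["f1"] * 10)["f1"] == 0.0

    def test_binomial_cohort_recovery(self):
        """3 fields x 120 pillars at 52% multilayer probability: mean per-field
        percentage within ±9 points of the generating rate."""
        rng = np.random.default_rng(1)
        ms, fids = [], []
        for f in range(3):
            for _ in range(120):
                multi = rng.random() < 0.52
                ms.append(self._meas(int(rng.integers(2, 7)) if multi else 1))
                fids.append(f"f{f}")
        pct = pm.multilayer_fraction(ms, fids)
        assert np.mean(pct) == pytest.approx(52.0, abs=9.0)


def test_profile_csv_round_trip(tmp_path):
    p = pm.generate_lamella_profile(3, 13.0, noise_sd=0.02, seed=5)
    path = tmp_path / "profile.csv"
    write_profile(path, p)
    back = read_profile(path, pillar_id="p1")
    np.testing.assert_allclose(back.intensity, p.intensity, atol=1e-6)
    table = measurements_table([pm.measure_profile(back)])
    assert table.loc[0, "n_layers"] == 3
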