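import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import trxss
from trxss.curves import DifferenceCurve, ScatteringCurve
from trxss.dataset import (HEAT_WINDOW, decompose_two_state, guinier,
                           normalize_isosbestic, reject_outliers, remove_heat)
from trxss.synthetic import default_heat_curve, make_trxss_dataset


@pytest.fixture(scope="module")
def q():
    return np.linspace(0.03, 2.5, 400)


def _orthogonalize_to_heat(y, heat, q):
    """Remove the in-window heat projection from a signal shape."""
    m = (q >= HEAT_WINDOW[0]) & (q <= HEAT_WINDOW[1])
    return y - (np.dot(y[m], heat[m]) / np.dot(heat[m], heat[m])) * heat


@pytest.fixture(scope="module")
def bases(q):
    heat = default_heat_curve(q).y
    b1 = _orthogonalize_to_heat(np.sin(8 * q) * np.exp(-q), heat, q)
    b2 = _orthogonalize_to_heat(np.cos(6 * q) * np.exp(-1.5 * q), heat, q)
    return DifferenceCurve(q, b1, "b1"), DifferenceCurve(q, b2, "b2")


class TestNormalize:
    def test_already_normalized_unchanged(self, q):
        y = np.ones_like(q)
        c = normalize_isosbestic(ScatteringCurve(q, y))
        assert np.allclose(c.y, y)

    def test_undoes_scale_factor(self, q):
        y = 2.0 + np.sin(3 * q) ** 2
        a = normalize_isosbestic(ScatteringCurve(q, y))
        b = normalize_isosbestic(ScatteringCurve(q, 7.0 * y))
        assert np.allclose(a.y, b.y, rtol=1e-12)

    def test_reduces_scatter_between_replicas(self, q):
        rng = np.random.default_rng(0)
        truth = 2.0 + np.sin(3 * q) ** 2
        reps = [ScatteringCurve(q, s * (truth + rng.normal(scale=0.01,
                                                           size=q.size)))
                for s in (1.0, 3.0, 0.2)]
        raw_rms = np.sqrt(np.mean((reps[0].y - reps[1].y) ** 2))
        n0, n1 = (normalize_isosbestic(r) for r in reps[:2])
        norm_rms = np.sqrt(np.mean((n0.y - n1.y) ** 2))
        assert norm_rms < raw_rms

    def test_window_outside_grid_rejected(self):
        c = ScatteringCurve(np.linspace(0, 1, 10), np.ones(10))
        with pytest.raises(ValueError):
            normalize_isosbestic(c, q0=1.6)


class TestRejectOutliers:
    def test_identical_curves_all_kept(self, q):
        curves = [ScatteringCurve(q, np.ones_like(q)) for _ in range(6)]
        diffs = [DifferenceCurve(q, np.zeros_like(q)) for _ in range(6)]
        kept_abs, kept_diff = reject_outliers(curves, diffs)
        assert len(kept_abs) == 6 and len(kept_diff) == 6

    def test_scaled_curve_dropped_at_stage_one(self, q):
        base = 1.0 + 0.1 * q
        curves = [ScatteringCurve(q, base) for _ in range(9)]
        curves.append(ScatteringCurve(q, 2.0 * base))
        diffs = [DifferenceCurve(q, np.zeros_like(q)) for _ in range(10)]
        kept_abs, _ = reject_outliers(curves, diffs)
        assert list(kept_abs) == list(range(9))

    def test_planted_outlier_fraction_recovered(self, q):
        rng = np.random.default_rng(4)
        n = 100
        truth = np.sin(2 * q) * 0.01
        diffs, n_bad = [], 0
        for i in range(n):
            y = truth + rng.normal(scale=0.001, size=q.size)
            if rng.uniform() < 0.07:       # plant ~7% gross outliers
                y = y + rng.normal(scale=0.02, size=q.size)
                n_bad += 1
            diffs.append(DifferenceCurve(q, y))
        curves = [ScatteringCurve(q, np.ones_like(q)) for _ in range(n)]
        _, kept = reject_outliers(curves, diffs)
        rejected = n - len(kept)
        assert 0.04 * n <= rejected <= 0.10 * n
        assert rejected >= 0.8 * n_bad     # catches most planted curves


class TestRemoveHeat:
    def test_pure_heat_removed_exactly(self, q):
        ir = default_heat_curve(q)
        dS = DifferenceCurve(q, 2.0 * ir.y)
        alpha, hc = remove_heat(dS, ir)
        assert alpha == pytest.approx(2.0, abs=1e-12)
        assert np.allclose(hc.y, 0.0, atol=1e-12)

    def test_orthogonal_signal_untouched(self, q, bases):
        ir = default_heat_curve(q)
        alpha, hc = remove_heat(bases[0], ir)
        assert alpha == pytest.approx(0.0, abs=1e-10)

    def test_matches_numerical_minimizer(self, q, bases):
        from scipy.optimize import minimize_scalar
        ir = default_heat_curve(q)
        dS = DifferenceCurve(q, bases[0].y + 0.37 * ir.y)
        alpha, _ = remove_heat(dS, ir)
        m = (q >= HEAT_WINDOW[0]) & (q <= HEAT_WINDOW[1])
        res = minimize_scalar(
            lambda a: np.sum((dS.y[m] - a * ir.y[m]) ** 2),
            bounds=(-5, 5), method="bounded",
            options={"xatol": 1e-12})
        assert alpha == pytest.approx(res.x, abs=1e-8)

    def test_idempotent(self, q, bases):
        ir = default_heat_curve(q)
        dS = DifferenceCurve(q, bases[0].y + 0.7 * ir.y)
        _, hc = remove_heat(dS, ir)
        alpha2, _ = remove_heat(hc, ir)
        assert alpha2 == pytest.approx(0.0, abs=1e-12)

    @given(st.floats(0.1, 10.0))
    @settings(max_examples=20, deadline=None)
    def test_commutes_with_global_rescale(self, scale):
        q = np.linspace(0.03, 2.5, 200)
        ir = default_heat_curve(q)
        dS = DifferenceCurve(q, np.sin(5 * q) + 0.7 * ir.y)
        a1, hc1 = remove_heat(dS, ir)
        a2, hc2 = remove_heat(DifferenceCurve(q, scale * dS.y),
                              DifferenceCurve(q, scale * ir.y))
        assert a1 == pytest.approx(a2, rel=1e-9)
        assert np.allclose(scale * hc1.y, hc2.y, rtol=1e-9)

    def test_vanishing_reference_rejected(self, q):
        z = DifferenceCurve(q, np.zeros_like(q))
        with pytest.raises(ZeroDivisionError):
            remove_heat(DifferenceCurve(q, np.ones_like(q)), z)


class TestTwoStateDecomposition:
    delays = np.geomspace(5e-6, 3e-2, 10)

    def test_crossing_recovered(self, bases):
        tau1 = 35e-6 / np.log(2)   # populations cross at 35 us
        ds = make_trxss_dataset(bases[0], bases[1], tau1, self.delays,
                                heat_amplitudes=0.7, seed=1)
        ds.remove_heat()
        dec = decompose_two_state(ds)
        # within one log-time grid step of 35 us
        step = np.log(self.delays[1] / self.delays[0])
        assert abs(np.log(dec.crossing_time / 35e-6)) <= step

    def test_bases_recovered_noise_free(self, bases):
        ds = make_trxss_dataset(bases[0], bases[1], 5e-5, self.delays,
                                heat_amplitudes=0.7, seed=2)
        ds.remove_heat()
        dec = decompose_two_state(ds)
        def cs(a, b):
            return abs(np.dot(a, b)) / np.linalg.norm(a) / np.linalg.norm(b)
        assert cs(dec.basis1, bases[0].y) > 0.999
        assert cs(dec.basis2, bases[1].y) > 0.999

    def test_single_state_second_basis_null(self, bases, q):
        c1 = np.exp(-self.delays / 5e-5)
        curves = np.outer(c1, bases[0].y)
        ds = trxss.TimeSeriesDataset(q, self.delays, curves)
        dec = decompose_two_state(ds)
        assert np.linalg.norm(dec.basis2) < 1e-6 * np.linalg.norm(dec.basis1)

    def test_reconstruction_tracks_noise_floor(self, bases):
        noise = 1e-3
        ds = make_trxss_dataset(bases[0], bases[1], 5e-5, self.delays,
                                noise_sd=noise, seed=3)
        dec = decompose_two_state(ds)
        assert dec.residual <= 2.0 * noise

    def test_heat_scale_alphas_recorded(self, bases):
        ds = make_trxss_dataset(bases[0], bases[1], 5e-5, self.delays,
                                heat_amplitudes=0.7, seed=4)
        ds.remove_heat()
        assert np.allclose(ds.alphas, 0.7, atol=1e-6)
        assert np.allclose(ds.corrected,
                           ds.curves - np.outer(ds.alphas, ds.ir_curve.y))

    def test_too_few_delays_rejected(self, bases, q):
        ds = trxss.TimeSeriesDataset(q, [1e-5, 1e-4],
                                     np.zeros((2, q.size)))
        with pytest.raises(ValueError):
            decompose_two_state(ds)


class TestGuinier:
    def test_exact_guinier_model(self):
        q = np.linspace(0.005, 0.2, 100)
        Rg, I0 = 20.0, 150.0
        c = ScatteringCurve(q, I0 * np.exp(-Rg**2 * q**2 / 3.0))
        rg, i0, diag = guinier(c, q2_window=(0.0, (1.3 / Rg) ** 2))
        assert rg == pytest.approx(Rg, rel=1e-9)
        assert i0 == pytest.approx(I0, rel=1e-9)
        assert diag["linear"]

    def test_flat_curve_zero_radius(self):
        q = np.linspace(0.005, 0.2, 50)
        rg, _, _ = guinier(ScatteringCurve(q, np.full_like(q, 5.0)),
                           q2_window=(0.0, 0.01))
        assert rg == pytest.approx(0.0, abs=1e-6)

    def test_aggregated_mixture_flagged(self):
        q = np.linspace(0.005, 0.2, 200)
        mix = (np.exp(-20.0**2 * q**2 / 3.0)
               + 0.5 * np.exp(-80.0**2 * q**2 / 3.0))
        _, _, diag = guinier(ScatteringCurve(q, mix),
                             q2_window=(0.0, (1.3 / 20.0) ** 2))
        assert not diag["linear"]

    def test_nonpositive_intensities_masked(self):
        q = np.linspace(0.005, 0.2, 50)
        y = np.exp(-100 * q**2)
        y[:48] = 0.0
        with pytest.raises(ValueError):
            guinier(ScatteringCurve(q, y), q2_window=(0.0, 0.04))
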