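"""Baseline extraction, non-negative library regression, full decomposition."""

import itertools

import numpy as np
import pytest

from rrsburn.grid import FrameSequence, SpectralLibrary, Spectrum, WavenumberGrid
from rrsburn.preprocessing import crop
from rrsburn.synthetic import SimulationConfig, simulate_frames
from rrsburn.unmixing import (
    SignalCoefficients,
    decompose,
    fit_baseline,
    fit_libraries,
)


@pytest.fixture
def crop_grid():
    return WavenumberGrid(600, 1700, 2)


class TestFitBaseline:
    def test_pure_polynomial_is_its_own_baseline(self, crop_grid):
        w = crop_grid.values
        u = (w - w.mean()) / 550
        y = 5 + 2 * u - 3 * u**2 + u**5
        baseline, c = fit_baseline(Spectrum(crop_grid, y))
        np.testing.assert_allclose(baseline.intensities, y, rtol=1e-8, atol=1e-8)
        assert c == pytest.approx(y.mean(), rel=1e-8)

    def test_polynomial_plus_peak_recovers_c(self, crop_grid):
        w = crop_grid.values
        u = (w - w.mean()) / 550
        poly = 10 + 3 * u - 2 * u**2
        peak = 8.0 * np.exp(-0.5 * ((w - 1150) / 6) ** 2)
        _, c = fit_baseline(Spectrum(crop_grid, poly + peak))
        assert c == pytest.approx(poly.mean(), rel=0.02)

    def test_all_zero_spectrum(self, crop_grid):
        baseline, c = fit_baseline(Spectrum(crop_grid, np.zeros(len(crop_grid))))
        np.testing.assert_array_equal(baseline.intensities, 0.0)
        assert c == 0.0

    def test_too_few_channels_rejected(self):
        g = WavenumberGrid(600, 610, 2)  # 6 channels < degree + 2
        with pytest.raises(ValueError, match="channels"):
            fit_baseline(Spectrum(g, np.zeros(len(g))))


def brute_force_nnls(design, target, lo=0.0, hi=3.0):
    """Two-stage exhaustive grid search over nonnegative weights (<=2 libs)."""
    assert design.shape[1] == 2
    best, best_err = None, np.inf
    grid1 = np.arange(lo, hi, 0.02)
    for wa, wb in itertools.product(grid1, grid1):
        err = np.sum((design @ np.array([wa, wb]) - target) ** 2)
        if err < best_err:
            best, best_err = (wa, wb), err
    fine = 0.02
    while fine > 1e-5:
        wa0, wb0 = best
        for wa in np.arange(max(lo, wa0 - fine), wa0 + fine, fine / 10):
            for wb in np.arange(max(lo, wb0 - fine), wb0 + fine, fine / 10):
                err = np.sum((design @ np.array([wa, wb]) - target) ** 2)
                if err < best_err:
                    best, best_err = (wa, wb), err
        fine /= 10
    return np.array(best)


class TestFitLibraries:
    def test_exact_member_of_span(self, crop_grid, libs):
        hbo = crop(libs["HbO"], 600, 1700)
        cropped = [
            SpectralLibrary(hbo.grid, crop(l, 600, 1700).intensities, name=l.name)
            for l in libs.values()
        ]
        residual = Spectrum(hbo.grid, 2.0 * hbo.intensities)
        weights, rms, _ = fit_libraries(residual, cropped)
        assert weights["HbO"] == pytest.approx(2.0, abs=1e-8)
        for name in ("HbR", "MitoRed", "MitoOx"):
            assert weights[name] == pytest.approx(0.0, abs=1e-8)

    def test_noisy_mixture_recovered(self, libs, rng):
        cropped = []
        for l in libs.values():
            cl = crop(l, 600, 1700)
            cropped.append(SpectralLibrary(cl.grid, cl.intensities, name=l.name))
        truth = {"HbR": 1.5, "HbO": 0.0, "MitoRed": 0.0, "MitoOx": 0.5}
        target = sum(truth[c.name] * c.intensities for c in cropped)
        target = target + rng.normal(0, 0.01, size=target.shape)
        weights, _, _ = fit_libraries(Spectrum(cropped[0].grid, target), cropped)
        assert weights["HbR"] == pytest.approx(1.5, rel=0.05)
        assert weights["MitoOx"] == pytest.approx(0.5, rel=0.05)

    def test_nonphysical_negative_residual_hits_boundary(self, libs):
        hbo = crop(libs["HbO"], 600, 1700)
        cropped = [
            SpectralLibrary(hbo.grid, crop(l, 600, 1700).intensities, name=l.name)
            for l in libs.values()
        ]
        residual = Spectrum(hbo.grid, -hbo.intensities)
        weights, rms, _ = fit_libraries(residual, cropped)
        assert all(v == 0.0 for v in weights.values())
        assert rms == pytest.approx(
            np.sqrt(np.mean(hbo.intensities**2)), rel=1e-10
        )

    def test_grid_mismatch_rejected(self, libs, crop_grid):
        residual = Spectrum(crop_grid, np.zeros(len(crop_grid)))
        with pytest.raises(ValueError, match="grid"):
            fit_libraries(residual, list(libs.values()))

    def test_collinear_pair_named(self, crop_grid):
        y = np.exp(-0.5 * ((crop_grid.values - 1000) / 20) ** 2)
        a = SpectralLibrary(crop_grid, y, name="A")
        b = SpectralLibrary(crop_grid, y.copy(), name="B")
        with pytest.raises(ValueError, match="'A' and 'B'"):
            fit_libraries(Spectrum(crop_grid, y), [a, b])

    def test_matches_exhaustive_grid_search_on_toy_grid(self, rng):
        # 8-channel toy problem with two synthetic libraries
        g = WavenumberGrid(600, 614, 2)
        d1 = np.array([1, 0.8, 0.3, 0.1, 0, 0, 0.2, 0.5])
        d2 = np.array([0, 0.1, 0.6, 1.0, 0.7, 0.2, 0.1, 0])
        libs = [SpectralLibrary(g, d1, name="L1"), SpectralLibrary(g, d2, name="L2")]
        for true_w in ([0.7, 1.9], [0.0, 1.2], [2.4, 0.0]):
            target = d1 * true_w[0] + d2 * true_w[1] + rng.normal(0, 0.05, 8)
            weights, _, _ = fit_libraries(Spectrum(g, target), libs)
            brute = brute_force_nnls(np.column_stack([d1, d2]), target)
            assert weights["L1"] == pytest.approx(brute[0], abs=1e-3)
            assert weights["L2"] == pytest.approx(brute[1], abs=1e-3)


class TestDecompose:
    def test_noiseless_round_trip(self, libs, lib_list, noiseless_cfg):
        truth = SignalCoefficients(a=1.2, b=3.4, m_r=0.2, m_o=0.1, c=10.0)
        frames = simulate_frames(truth, libs, noiseless_cfg)
        rec = decompose(frames, lib_list)
        for name in ("a", "b", "c"):
            assert getattr(rec, name) == pytest.approx(
                getattr(truth, name), rel=1e-3
            )

    def test_healthy_simulation_has_positive_hemoglobin(self, libs, lib_list, grid):
        truth = SignalCoefficients(a=0.3, b=0.7, m_r=0.05, m_o=0.05, c=5.0)
        cfg = SimulationConfig(grid=grid, noise_sd=0.01, spike_prob=0.01, seed=3)
        rec = decompose(simulate_frames(truth, libs, cfg), lib_list)
        assert rec.hemoglobin_sum > 0

    def test_zero_frames_give_zero_coefficients(self, lib_list, grid):
        frames = FrameSequence(grid, np.zeros((5, len(grid))))
        rec = decompose(frames, lib_list)
        assert rec.a == rec.b == rec.m_r == rec.m_o == rec.c == 0.0

    def test_scale_equivariance(self, libs, lib_list, grid):
        truth = SignalCoefficients(a=0.5, b=1.5, m_r=0.1, m_o=0.1, c=4.0)
        cfg = SimulationConfig(grid=grid, noise_sd=0.002, spike_prob=0.0, seed=11)
        frames = simulate_frames(truth, libs, cfg)
        k = 3.7
        rec1 = decompose(frames, lib_list)
        rec2 = decompose(FrameSequence(grid, k * frames.data), lib_list)
        for name in ("a", "b", "m_r", "m_o", "c"):
            assert getattr(rec2, name) == pytest.approx(
                k * getattr(rec1, name), rel=1e-6, abs=1e-9
            )

    def test_baseline_magnitude_invariance_of_hemoglobin(self, libs, lib_list, grid):
        truth = SignalCoefficients(a=0.5, b=1.5, c=2.0)
        cfg = SimulationConfig(grid=grid, noise_sd=0.001, spike_prob=0.0, seed=12)
        frames = simulate_frames(truth, libs, cfg)
        rec1 = decompose(frames, lib_list)
        # add an extra smooth degree-<=5 offset
        w = grid.values
        u = (w - w.mean()) / (w.max() - w.mean())
        offset = 6.0 + 2.0 * u - 1.0 * u**3
        rec2 = decompose(FrameSequence(grid, frames.data + offset), lib_list)
        assert rec2.c > rec1.c
        assert rec2.hemoglobin_sum == pytest.approx(rec1.hemoglobin_sum, rel=0.02)
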