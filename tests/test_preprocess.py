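"""Baseline, normalization, recalibration and replicate averaging."""

import numpy as np
import pytest

from peptidome.io import NullSpectrumError, Spectrum
from peptidome.preprocess import (
    LM_REFERENCES,
    RM_REFERENCES,
    ReferencePeakSet,
    average_replicates,
    convex_hull_baseline,
    normalize_tic,
    preprocess_cohort,
    recalibrate,
)
from peptidome.synthetic import SimulationConfig, simulate_cohort, simulate_spectrum

from conftest import gaussian_spectrum


class TestConvexHullBaseline:
    def test_constant_spectrum_fully_removed(self, grid):
        s = Spectrum(grid, np.full(grid.size, 7.5))
        baseline, corrected = convex_hull_baseline(s, flatness=1.0)
        np.testing.assert_allclose(baseline, 7.5)
        np.testing.assert_allclose(corrected.intensity, 0.0)

    def test_linear_ramp_is_its_own_hull(self, grid):
        s = Spectrum(grid, np.linspace(2.0, 12.0, grid.size))
        _, corrected = convex_hull_baseline(s, flatness=1.0)
        np.testing.assert_allclose(corrected.intensity, 0.0, atol=1e-9)

    def test_planted_baseline_recovered_under_peaks(self, grid):
        """Oracle: subtract the known planted baseline directly."""
        def planted(mz):
            return 40.0 * np.exp(-(mz - mz[0]) / 1500.0)

        centers = [(1500.0, 300.0), (2600.0, 500.0), (4200.0, 400.0)]
        s = gaussian_spectrum(grid, centers, baseline=planted)
        clean = gaussian_spectrum(grid, centers)
        # pure hull: exact for a convex decaying background
        _, corrected = convex_hull_baseline(s, flatness=1.0)
        for c, _ in centers:
            i = np.argmin(np.abs(grid - c))
            assert corrected.intensity[i] == pytest.approx(clean.intensity[i], rel=0.02)

    def test_corrected_touches_zero_and_is_idempotent(self, grid):
        rng = np.random.default_rng(0)
        s = Spectrum(grid, rng.uniform(5, 50, grid.size))
        _, corrected = convex_hull_baseline(s, flatness=1.0)
        assert corrected.intensity.min() == 0.0
        _, twice = convex_hull_baseline(corrected, flatness=1.0)
        assert np.max(np.abs(twice.intensity - corrected.intensity)) \
            < 1e-9 * corrected.intensity.max()

    def test_tiny_spectrum_identity(self):
        s = Spectrum(np.array([1000.0, 1001.0]), np.array([1.0, 2.0]))
        baseline, corrected = convex_hull_baseline(s)
        np.testing.assert_array_equal(baseline, 0.0)
        np.testing.assert_array_equal(corrected.intensity, s.intensity)

    def test_invalid_flatness_rejected(self, grid):
        s = Spectrum(grid, np.ones(grid.size))
        with pytest.raises(ValueError):
            convex_hull_baseline(s, flatness=0.0)


class TestNormalizeTic:
    def test_already_at_target_unchanged(self, grid):
        y = np.ones(grid.size) / grid.size
        s = Spectrum(grid, y)
        out = normalize_tic(s, target=1.0)
        np.testing.assert_allclose(out.intensity, y, rtol=1e-12)

    def test_scale_invariance(self, grid):
        rng = np.random.default_rng(1)
        y = rng.uniform(0, 10, grid.size)
        a = normalize_tic(Spectrum(grid, y))
        b = normalize_tic(Spectrum(grid, 7.0 * y))
        np.testing.assert_allclose(a.intensity, b.intensity, rtol=1e-12)

    def test_sum_equals_target(self, grid):
        rng = np.random.default_rng(2)
        s = Spectrum(grid, rng.uniform(0, 5, grid.size))
        out = normalize_tic(s, target=3.5)
        assert out.total_intensity() == pytest.approx(3.5, rel=1e-9)

    def test_idempotence(self, grid):
        rng = np.random.default_rng(3)
        s = Spectrum(grid, rng.uniform(0, 5, grid.size))
        once = normalize_tic(s)
        twice = normalize_tic(once)
        np.testing.assert_allclose(twice.intensity, once.intensity, rtol=1e-12)

    def test_all_zero_flagged_null(self, grid):
        with pytest.raises(NullSpectrumError):
            normalize_tic(Spectrum(grid, np.zeros(grid.size)))


class TestRecalibrate:
    def _ref_spectrum(self, grid, ppm=0.0, noise=0.0, seed=0):
        cfg = SimulationConfig(n_cases=1, n_controls=1, mz_range=(grid[0], grid[-1]),
                               baseline_amplitude=0.0, noise_sd=noise, seed=0)
        peaks = [(mz, 500.0) for mz in LM_REFERENCES.reference_mz
                 if grid[0] < mz < grid[-1]]
        return simulate_spectrum(peaks, cfg, seed=seed, calibration_ppm=ppm)

    def test_peaks_on_reference_positions_identity_warp(self, grid):
        s = self._ref_spectrum(grid, ppm=0.0)
        res = recalibrate(s, LM_REFERENCES)
        assert res.ok and res.matched >= 6
        assert res.residual_ppm < 1e-6
        np.testing.assert_allclose(res.spectrum.intensity, s.intensity, rtol=1e-9)

    def test_planted_global_distortion_corrected(self, grid):
        """+500 ppm planted error -> post-warp residual < 50 ppm."""
        s = self._ref_spectrum(grid, ppm=500.0, noise=0.001, seed=4)
        res = recalibrate(s, LM_REFERENCES)
        assert res.ok
        assert res.residual_ppm < 50.0

    def test_no_anchor_peaks_flags_non_recalibratable(self, grid):
        s = gaussian_spectrum(grid, [(1300.0, 100.0), (2550.0, 100.0)])
        res = recalibrate(s, LM_REFERENCES)
        assert not res.ok
        assert res.spectrum is None
        assert res.matched < 4

    def test_rm_reference_set_shape(self):
        assert RM_REFERENCES.reference_mz == (1680.93, 1912.06, 2040.17, 2659.32)
        assert RM_REFERENCES.tolerance_ppm == (100.0, 100.0, 100.0, 200.0)

    def test_reference_set_validation(self):
        with pytest.raises(ValueError):
            ReferencePeakSet("linear", (), ())
        with pytest.raises(ValueError):
            ReferencePeakSet("linear", (1000.0,), (-5.0,))

    def test_warp_bounded_by_tolerance_plus_extrapolation(self, grid):
        s = self._ref_spectrum(grid, ppm=800.0, noise=0.001, seed=5)
        res = recalibrate(s, LM_REFERENCES)
        assert res.ok
        # no matched shift exceeded the matching tolerance, so no grid point
        # moved by more than the max tolerance (constant extrapolation)
        shifts = [abs(o - r) / r * 1e6 for o, r in res.matches]
        assert max(shifts) <= max(LM_REFERENCES.tolerance_ppm)


class TestAverageReplicates:
    def test_identical_replicates_identity(self, grid):
        s = gaussian_spectrum(grid, [(2000.0, 100.0)], subject_id="A")
        out = average_replicates([s, s, s])
        np.testing.assert_allclose(out.intensity, s.intensity)
        assert out.replicate_id == "mean"
        assert out.subject_id == "A"

    def test_two_spectra_pointwise_mean(self, grid):
        rng = np.random.default_rng(0)
        a = Spectrum(grid, rng.uniform(0, 1, grid.size), subject_id="A")
        b = Spectrum(grid, rng.uniform(0, 1, grid.size), subject_id="A")
        out = average_replicates([a, b])
        np.testing.assert_allclose(out.intensity, (a.intensity + b.intensity) / 2)

    def test_mixed_modes_rejected(self, grid):
        a = Spectrum(grid, np.ones(grid.size), mode="linear", subject_id="A")
        b = Spectrum(grid, np.ones(grid.size), mode="reflector", subject_id="A")
        with pytest.raises(ValueError, match="mixed"):
            average_replicates([a, b])

    def test_noise_reduction_scales_sqrt_n(self):
        """Residual sd after averaging n replicates ~ sigma/sqrt(n)."""
        grid = 1000.0 + 0.5 * np.arange(200)
        rng = np.random.default_rng(7)
        sds = {}
        for n in (1, 4):
            resid = []
            for _ in range(100):
                reps = [Spectrum(grid, rng.normal(10.0, 1.0, grid.size), subject_id="A")
                        for _ in range(n)]
                resid.append(np.std(average_replicates(reps).intensity - 10.0))
            sds[n] = np.mean(resid)
        assert sds[1] / sds[4] == pytest.approx(2.0, rel=0.2)


class TestPreprocessCohort:
    def test_counts_consistent_and_null_excluded(self, small_config):
        spectra, metadata, _ = simulate_cohort(small_config)
        zero = Spectrum(spectra[0].mz, np.zeros(len(spectra[0])),
                        subject_id="ZZ", replicate_id="r1")
        means, report = preprocess_cohort(spectra + [zero], recalibrate_spectra=False)
        assert report.spectra_in == len(spectra) + 1
        assert report.excluded_null == 1
        assert report.kept + report.excluded_null \
            + report.excluded_nonrecalibratable == report.spectra_in
        assert len(means) == len(metadata)  # one mean spectrum per subject

    def test_recalibration_exclusion_counted(self, grid):
        # spectra with no peaks near any LM reference
        bad = [gaussian_spectrum(grid, [(1300.0, 100.0)], subject_id=f"S{i}",
                                 noise_sd=0.01, seed=i)
               for i in range(3)]
        means, report = preprocess_cohort(bad)
        assert report.excluded_nonrecalibratable == 3
        assert means == []
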