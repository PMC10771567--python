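"""Preprocessing chain: despiking, smoothing, ModPoly baseline, SNV,
reference normalization, and the composed pipeline."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import spearmanr

import ramanpe as rp
from ramanpe.preprocess import PreprocessParams, modpoly_baseline
from ramanpe.synthetic import pseudo_voigt

GRID = np.arange(600.0, 1801.0)


def spectra_from_matrix(matrix):
    return [
        rp.Spectrum(GRID, row, scan_id=f"s{i}", patient_id="p") for i, row in enumerate(matrix)
    ]


class TestCosmicRayRemoval:
    def test_single_spike_replaced_by_replicate_median(self):
        base = np.full((5, GRID.size), 10.0)
        base[3, 700] = 200.0
        cleaned = rp.remove_cosmic_rays(spectra_from_matrix(base), z_threshold=8.0)
        stack = np.vstack([s.intensities for s in cleaned])
        # median 10, MAD 0 -> limit 10; the 200 must drop to the median
        np.testing.assert_array_equal(stack[:, 700], np.full(5, 10.0))
        assert np.all(stack[:, :700] == 10.0)

    def test_spike_free_noise_rarely_touched(self, rng):
        noise = rng.normal(0.0, 1.0, size=(15, GRID.size))
        cleaned = rp.remove_cosmic_rays(spectra_from_matrix(noise), z_threshold=8.0)
        stack = np.vstack([s.intensities for s in cleaned])
        altered = np.mean(stack != noise)
        assert altered < 1e-3

    def test_idempotent(self, rng):
        base = rng.normal(5.0, 0.5, size=(5, GRID.size))
        base[2, 100] = 80.0
        once = rp.remove_cosmic_rays(spectra_from_matrix(base))
        twice = rp.remove_cosmic_rays(once)
        for a, b in zip(once, twice):
            np.testing.assert_array_equal(a.intensities, b.intensities)

    def test_single_spectrum_fallback_warns_and_despikes(self, rng):
        y = rng.normal(10.0, 0.1, GRID.size)
        y[500] = 100.0
        with pytest.warns(UserWarning, match="fewer than 3"):
            out = rp.remove_cosmic_rays([rp.Spectrum(GRID, y)])
        assert out[0].intensities[500] < 20.0


class TestSmooth:
    def test_polynomial_signal_unchanged(self):
        t = (GRID - 1200.0) / 600.0
        coeffs = np.array([0.3, -1.2, 0.8, 0.5, -0.4, 0.2, 0.1, -0.3, 0.15, 0.05, -0.02])
        y = np.polynomial.polynomial.polyval(t, coeffs)  # degree 10
        out = rp.smooth(rp.Spectrum(GRID, y))
        np.testing.assert_allclose(out.intensities, y, atol=1e-8)

    def test_constant_unchanged(self):
        out = rp.smooth(rp.Spectrum(GRID, np.full(GRID.size, 3.5)))
        np.testing.assert_allclose(out.intensities, 3.5, atol=1e-10)

    def test_noise_variance_reduced(self, rng):
        y = rng.normal(size=GRID.size)
        out = rp.smooth(rp.Spectrum(GRID, y))
        assert out.intensities.var() < y.var()

    @pytest.mark.parametrize("window,order", [(44, 10), (9, 10)])
    def test_invalid_window_rejected(self, window, order):
        with pytest.raises(ValueError):
            rp.smooth(rp.Spectrum(GRID, np.zeros(GRID.size)), window, order)


class TestBaseline:
    @staticmethod
    def degree9_background(scale=100.0):
        t = (GRID - GRID[0]) / (GRID[-1] - GRID[0])
        coeffs = np.array([5.0, -3.0, 8.0, -6.0, 2.0, 1.5, -2.0, 0.8, -0.5, 0.3])
        y = np.polynomial.polynomial.polyval(t, coeffs)
        return scale * (y - y.min() + 0.5)

    def test_pure_polynomial_fully_removed(self):
        y = self.degree9_background()
        corrected, baseline = rp.correct_baseline(rp.Spectrum(GRID, y))
        assert np.max(np.abs(corrected.intensities)) < 1e-3 * np.max(np.abs(y))

    def test_peak_height_recovered(self):
        background = self.degree9_background(scale=5.0)
        peak = 2.0 * np.exp(-4 * np.log(2) * ((GRID - 1002.0) / 12.0) ** 2)
        corrected, _ = rp.correct_baseline(rp.Spectrum(GRID, background + peak))
        height = corrected.intensities[np.argmin(np.abs(GRID - 1002.0))]
        assert abs(height - 2.0) / 2.0 < 0.05

    def test_zero_spectrum_zero_output(self):
        corrected, baseline = rp.correct_baseline(rp.Spectrum(GRID, np.zeros(GRID.size)))
        np.testing.assert_allclose(corrected.intensities, 0.0, atol=1e-10)

    def test_matches_bruteforce_constrained_fit_on_baseline_only(self):
        # with no peaks ModPoly must equal a single unconstrained polyfit
        y = self.degree9_background()
        baseline, ok = modpoly_baseline(y, GRID)
        t = 2.0 * (GRID - GRID[0]) / (GRID[-1] - GRID[0]) - 1.0
        direct = np.polynomial.chebyshev.chebval(
            t, np.polynomial.chebyshev.chebfit(t, y, 9)
        )
        assert ok
        np.testing.assert_allclose(baseline.ravel(), direct, atol=1e-6 * np.abs(y).max())


class TestSNV:
    def test_three_point_example(self):
        out = rp.snv(rp.Spectrum(np.arange(3.0), np.array([1.0, 2.0, 3.0])))
        np.testing.assert_allclose(out.intensities, [-1.0, 0.0, 1.0], atol=1e-12)

    def test_standardized_output(self, rng):
        out = rp.snv(rp.Spectrum(GRID, rng.normal(5, 3, GRID.size)))
        assert abs(out.intensities.mean()) < 1e-12
        assert abs(out.intensities.std(ddof=1) - 1.0) < 1e-12

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        a=st.floats(0.1, 50.0),
        b=st.floats(-100.0, 100.0),
        seed=st.integers(0, 2**16),
    )
    def test_affine_invariance(self, a, b, seed):
        y = np.random.default_rng(seed).normal(size=64)
        wn = np.arange(64.0)
        base = rp.snv(rp.Spectrum(wn, y)).intensities
        scaled = rp.snv(rp.Spectrum(wn, a * y + b)).intensities
        np.testing.assert_allclose(scaled, base, atol=1e-8)

    def test_constant_spectrum_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            rp.snv(rp.Spectrum(np.arange(5.0), np.full(5, 2.0)))


class TestReferenceNormalization:
    @staticmethod
    def example_spectrum():
        y = 0.2 + pseudo_voigt(GRID, 1445.0, 14.0) + 0.5 * pseudo_voigt(GRID, 1002.0, 10.0)
        return rp.Spectrum(GRID, y - 0.1)

    def test_reference_bin_equals_one(self):
        out = rp.normalize_reference(self.example_spectrum())
        mask = np.abs(GRID - 1445.0) <= 4.0
        assert out.intensities[mask].max() == pytest.approx(1.0, abs=1e-12)

    def test_minimum_is_zero(self):
        out = rp.normalize_reference(self.example_spectrum())
        assert out.intensities.min() == pytest.approx(0.0, abs=1e-12)

    def test_idempotent(self):
        once = rp.normalize_reference(self.example_spectrum())
        twice = rp.normalize_reference(once)
        np.testing.assert_allclose(twice.intensities, once.intensities, atol=1e-12)

    def test_reference_outside_grid_rejected(self):
        s = rp.Spectrum(np.arange(600.0, 700.0), np.ones(100))
        with pytest.raises(ValueError, match="outside grid"):
            rp.normalize_reference(s, reference_wavenumber=1445.0)


class TestPipeline:
    def test_known_peaks_survive_and_reference_is_one(self, small_cohort, peak_table):
        _, ds = small_cohort
        reps = [s for s in ds.scans if s.patient_id == ds.scans[0].patient_id]
        out, log = rp.preprocess_pipeline(reps)
        assert [entry["stage"] for entry in log] == [
            "despike",
            "smooth",
            "baseline",
            "snv",
            "normalize",
        ]
        mean = np.mean([s.intensities for s in out], axis=0)
        mask = np.abs(GRID - 1445.0) <= 4.0
        assert mean[mask].max() == pytest.approx(1.0, abs=0.02)
        # the strong phenylalanine band must stand clear of the local floor
        phe = mean[np.abs(GRID - 1002.0) <= 4.0].max()
        floor = np.median(mean)
        assert phe > floor + 0.05

    def test_deterministic(self, small_cohort):
        _, ds = small_cohort
        reps = [s for s in ds.scans if s.patient_id == ds.scans[0].patient_id]
        out1, _ = rp.preprocess_pipeline(reps)
        out2, _ = rp.preprocess_pipeline(reps)
        for a, b in zip(out1, out2):
            np.testing.assert_array_equal(a.intensities, b.intensities)

    def test_disabling_all_stages_is_identity(self, small_cohort):
        _, ds = small_cohort
        reps = [s for s in ds.scans if s.patient_id == ds.scans[0].patient_id]
        out, log = rp.preprocess_pipeline(reps, PreprocessParams(enabled=()))
        assert log == []
        for a, b in zip(out, reps):
            np.testing.assert_array_equal(a.intensities, b.intensities)

    def test_baseline_first_order_also_runs(self, small_cohort):
        _, ds = small_cohort
        reps = [s for s in ds.scans if s.patient_id == ds.scans[0].patient_id]
        out, log = rp.preprocess_pipeline(reps, PreprocessParams(smooth_before_baseline=False))
        stages = [entry["stage"] for entry in log]
        assert stages.index("baseline") < stages.index("smooth")
        assert len(out) == len(reps)

    def test_rank_order_of_planted_amplitudes_preserved(self, peak_table):
        """Pipeline output at a band must track the planted per-patient
        amplitude ordering (Spearman rho > 0.95)."""
        cfg = rp.SyntheticConfig(seed=5, n_patients_per_cell=8, n_replicates=4, effect_map={})
        ds = rp.generate_cohort(cfg)
        truth = ds.truth["amplitudes"]
        from collections import defaultdict

        from ramanpe.quantify import average_patient, extract_peak_intensities

        by = defaultdict(list)
        for s in ds.scans:
            by[s.patient_id].append(s)
        measured, planted = [], []
        t1 = truth[truth["trimester"] == 1]
        for _, row in t1.iterrows():
            out, _ = rp.preprocess_pipeline(by[row["patient_id"]])
            mean = average_patient(out)
            tab = extract_peak_intensities(mean, peak_table)
            measured.append(float(tab.loc[tab.nominal_wavenumber == 1002.0, "intensity"].iloc[0]))
            planted.append(float(row[1002.0]))
        rho = spearmanr(measured, planted).statistic
        assert rho > 0.95
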