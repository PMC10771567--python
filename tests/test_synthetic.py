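"""Synthetic cohort generator: determinism, planted effects, clinical and
ELISA tables, spiking series."""

import numpy as np
import pandas as pd
import pytest

import ramanpe as rp
from ramanpe.synthetic import ElisaParams, _patient_labels, pseudo_voigt


class TestDeterminism:
    def test_same_seed_identical_csv_bytes(self, tmp_path):
        cfg = rp.SyntheticConfig(seed=3, n_patients_per_cell=3, n_replicates=3)
        rp.generate_cohort(cfg).write(tmp_path / "a")
        rp.generate_cohort(cfg).write(tmp_path / "b")
        for name in ("scans.csv", "metadata.csv", "elisa.csv", "truth_amplitudes.csv"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_different_seed_differs(self):
        a = rp.generate_cohort(rp.SyntheticConfig(seed=1, n_patients_per_cell=2, n_replicates=2))
        b = rp.generate_cohort(rp.SyntheticConfig(seed=2, n_patients_per_cell=2, n_replicates=2))
        assert not np.array_equal(a.scans[0].intensities, b.scans[0].intensities)


class TestPlantedEffects:
    def test_effect_shifts_mean_amplitude_by_d_between_sd(self, peak_table):
        cfg = rp.SyntheticConfig(
            seed=9, n_patients_per_cell=4000, n_replicates=2, effect_map={956.0: 2.0}
        )
        labels, amps = rp.generate_patient_amplitudes(cfg, peak_table)
        t1 = labels["trimester"] == 1
        pe = labels["cohort"] == "preeclampsia"
        healthy_mean = amps.loc[t1 & ~pe, 956.0].mean()
        pe_mean = amps.loc[t1 & pe, 956.0].mean()
        base = 0.40  # lipid-class nominal amplitude
        sd = base * cfg.between_patient_cv
        assert (pe_mean - healthy_mean) / sd == pytest.approx(2.0, abs=0.1)

    def test_zero_effect_map_gives_exchangeable_cohorts(self, peak_table):
        cfg = rp.SyntheticConfig(
            seed=10, n_patients_per_cell=2000, n_replicates=2, effect_map={}
        )
        labels, amps = rp.generate_patient_amplitudes(cfg, peak_table)
        pe = labels["cohort"] == "preeclampsia"
        diff = amps.loc[pe, 956.0].mean() - amps.loc[~pe, 956.0].mean()
        assert abs(diff) < 0.01

    def test_effect_map_unknown_band_rejected(self):
        cfg = rp.SyntheticConfig(effect_map={999.0: 1.0})
        with pytest.raises(ValueError, match="999"):
            rp.generate_cohort(cfg)

    def test_grid_not_covering_peaks_rejected(self):
        cfg = rp.SyntheticConfig(grid_min=800.0)
        with pytest.raises(ValueError, match="does not cover"):
            rp.generate_cohort(cfg)

    def test_default_cell_sizes_mirror_study(self):
        labels = _patient_labels(rp.SyntheticConfig())
        counts = labels.groupby(["cohort", "trimester"]).size()
        assert counts[("healthy", 1)] == 23
        assert counts[("preeclampsia", 3)] == 29
        assert counts.sum() == 143


class TestClinical:
    def test_healthy_patients_labelled_healthy(self, small_cohort):
        _, ds = small_cohort
        healthy = ds.metadata[ds.metadata["cohort"] == "healthy"]
        assert (healthy["severity"] == "healthy").all()

    def test_severity_mix_near_57_43(self):
        cfg = rp.SyntheticConfig(seed=12, n_patients_per_cell=1700, n_replicates=2)
        labels = _patient_labels(cfg)
        meta = rp.generate_clinical(cfg, labels, np.random.default_rng(12))
        pe = meta[meta["cohort"] == "preeclampsia"]
        frac_severe = (pe["severity"] == "severe").mean()
        assert frac_severe == pytest.approx(0.57, abs=0.02)

    def test_gestational_age_means(self):
        cfg = rp.SyntheticConfig(seed=13, n_patients_per_cell=1500, n_replicates=2)
        labels = _patient_labels(cfg)
        meta = rp.generate_clinical(cfg, labels, np.random.default_rng(13))
        healthy = meta[meta["cohort"] == "healthy"]["gestational_age_delivery"].mean()
        pe = meta[meta["cohort"] == "preeclampsia"]["gestational_age_delivery"].mean()
        assert healthy == pytest.approx(38.47, abs=0.15)
        assert pe == pytest.approx(36.23, abs=0.15)

    def test_binary_rates(self):
        cfg = rp.SyntheticConfig(seed=14, n_patients_per_cell=1500, n_replicates=2)
        labels = _patient_labels(cfg)
        meta = rp.generate_clinical(cfg, labels, np.random.default_rng(14))
        pe = meta[meta["cohort"] == "preeclampsia"]
        assert (pe["history_pe"] == "yes").mean() == pytest.approx(0.22, abs=0.02)


class TestElisa:
    def test_noise_free_link_recovered_exactly(self, peak_table):
        cfg = rp.SyntheticConfig(seed=15, n_patients_per_cell=5, n_replicates=2)
        labels, amps = rp.generate_patient_amplitudes(cfg, peak_table)
        params = ElisaParams(intercept=4.0, slope=30.0, noise_sd=0.0)
        elisa = rp.generate_elisa(labels, amps, np.random.default_rng(0), params)
        ltr = elisa["lipid_trp_true"].to_numpy()
        ratio = elisa["sflt1_plgf_true"].to_numpy()
        from ramanpe.biomarker import ols_line

        slope, intercept, r2 = ols_line(ltr, ratio)
        assert slope == pytest.approx(30.0, rel=1e-9)
        assert intercept == pytest.approx(4.0, rel=1e-6)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_columns_consistent_with_ratio(self, small_cohort):
        _, ds = small_cohort
        ratio = ds.elisa["sflt1_pg"] / ds.elisa["plgf_pg"]
        np.testing.assert_allclose(ratio, ds.elisa["sflt1_plgf_true"], rtol=1e-12)

    def test_flat_link_gives_near_zero_slope(self, peak_table):
        cfg = rp.SyntheticConfig(seed=16, n_patients_per_cell=6, n_replicates=2)
        labels, amps = rp.generate_patient_amplitudes(cfg, peak_table)
        params = ElisaParams(intercept=20.0, slope=0.0, noise_sd=2.0)
        elisa = rp.generate_elisa(labels, amps, np.random.default_rng(1), params)
        elisa["sflt_plgf"] = elisa["sflt1_pg"] / elisa["plgf_pg"]
        cells = elisa.groupby(["cohort", "trimester"])[["lipid_trp_true", "sflt_plgf"]].mean()
        from ramanpe.biomarker import ols_line

        slope, _, r2 = ols_line(
            cells["lipid_trp_true"].to_numpy(), cells["sflt_plgf"].to_numpy()
        )
        assert r2 < 0.5  # no real association at 6 cells

    def test_nonpositive_tryptophan_rejected(self, peak_table):
        cfg = rp.SyntheticConfig(seed=17, n_patients_per_cell=2, n_replicates=2)
        labels, amps = rp.generate_patient_amplitudes(cfg, peak_table)
        amps.loc[amps.index[0], 1551.0] = 0.0
        with pytest.raises(ValueError, match="tryptophan"):
            rp.generate_elisa(labels, amps, np.random.default_rng(0))

    def test_cytokines_have_no_cohort_effect(self, peak_table):
        cfg = rp.SyntheticConfig(seed=18, n_patients_per_cell=2000, n_replicates=2)
        labels, amps = rp.generate_patient_amplitudes(cfg, peak_table)
        elisa = rp.generate_elisa(labels, amps, np.random.default_rng(2))
        pe = elisa["cohort"] == "preeclampsia"
        rel = abs(elisa.loc[pe, "tnf_pg"].mean() / elisa.loc[~pe, "tnf_pg"].mean() - 1.0)
        assert rel < 0.02


class TestSpikeSeries:
    def test_zero_concentration_unchanged(self, flat_spectrum):
        out = rp.spike_series(flat_spectrum, 1551.0, [0.0])
        np.testing.assert_array_equal(out[0].intensities, flat_spectrum.intensities)

    def test_doubling_concentration_doubles_increment(self, flat_spectrum):
        one, two = rp.spike_series(flat_spectrum, 1551.0, [1.0, 2.0])
        np.testing.assert_allclose(two.intensities, 2.0 * one.intensities, atol=1e-14)

    def test_negative_concentration_rejected(self, flat_spectrum):
        with pytest.raises(ValueError, match="non-negative"):
            rp.spike_series(flat_spectrum, 1551.0, [-1.0])

    def test_off_grid_wavenumber_rejected(self, flat_spectrum):
        with pytest.raises(ValueError, match="not on the spectrum grid"):
            rp.spike_series(flat_spectrum, 2000.0, [1.0])


def test_pseudo_voigt_unit_height_and_fwhm():
    x = np.linspace(-50, 50, 10001)
    y = pseudo_voigt(x, 0.0, 10.0)
    assert y.max() == pytest.approx(1.0, abs=1e-12)
    half = x[y >= 0.5]
    assert half[-1] - half[0] == pytest.approx(10.0, abs=0.05)


def test_dataset_validation_catches_missing_patient(small_cohort):
    _, ds = small_cohort
    broken = rp.CohortDataset(
        scans=ds.scans,
        metadata=ds.metadata[ds.metadata["patient_id"] != "H1_01"],
        elisa=ds.elisa,
        truth=ds.truth,
    )
    with pytest.raises(ValueError, match="missing from metadata"):
        broken.validate()
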