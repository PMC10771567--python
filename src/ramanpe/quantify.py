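"""Peak quantification and per-band cohort statistics.

Patient replicate scans are averaged pointwise, band intensities are read as
the window maximum around each nominal wavenumber of the assignment table,
and cohorts are compared band-by-band with unpaired, two-sided, homoscedastic
(pooled-variance) t-tests. Significance stars follow the usual
0.05 / 0.01 / 0.001 thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .spectra import PeakDefinition, Spectrum


def average_patient(spectra: list[Spectrum]) -> Spectrum:
    """Pointwise mean of one patient's (preprocessed) replicate scans."""
    if not spectra:
        raise ValueError("no replicates to average")
    grid = spectra[0].wavenumbers
    for s in spectra[1:]:
        if not np.array_equal(s.wavenumbers, grid):
            raise ValueError("replicates must share a common grid")
    mean = np.mean([s.intensities for s in spectra], axis=0)
    out = spectra[0].with_intensities(mean)
    out.scan_id = f"{spectra[0].patient_id}_mean"
    return out


def extract_peak_intensities(
    patient_spectrum: Spectrum, peak_table: list[PeakDefinition], window: float = 4.0
) -> pd.DataFrame:
    """Band intensity = max normalized intensity within ±window cm^-1 of the
    nominal wavenumber (robust to small calibration shifts). Bands outside
    the grid are flagged missing (NaN), never zero."""
    wn = patient_spectrum.wavenumbers
    y = patient_spectrum.intensities
    rows = []
    for peak in peak_table:
        w = peak.nominal_wavenumber
        if w < wn[0] or w > wn[-1]:
            value = np.nan
        elif window == 0:
            value = y[np.argmin(np.abs(wn - w))]
        else:
            mask = np.abs(wn - w) <= window
            value = y[mask].max() if mask.any() else np.nan
        rows.append(
            {
                "patient_id": patient_spectrum.patient_id,
                "cohort": patient_spectrum.cohort,
                "trimester": patient_spectrum.trimester,
                "nominal_wavenumber": w,
                "intensity": value,
            }
        )
    return pd.DataFrame(rows)


def peak_table_from_spectra(
    patient_spectra: list[Spectrum], peak_table: list[PeakDefinition], window: float = 4.0
) -> pd.DataFrame:
    """Stack per-patient band intensities into one long table."""
    return pd.concat(
        [extract_peak_intensities(s, peak_table, window) for s in patient_spectra],
        ignore_index=True,
    )


def difference_spectrum(mean_a: Spectrum, mean_b: Spectrum) -> Spectrum:
    """``mean_b − mean_a``: positive lobes mark bands higher in the second group."""
    if not np.array_equal(mean_a.wavenumbers, mean_b.wavenumbers):
        raise ValueError("difference spectrum requires a common grid")
    out = mean_a.with_intensities(mean_b.intensities - mean_a.intensities)
    out.scan_id = f"{mean_b.scan_id}-minus-{mean_a.scan_id}"
    return out


def star_label(p_value: float) -> str:
    if not np.isfinite(p_value):
        return "NS"
    if p_value < 0.001:
        return "***"
    if p_value < 0.01:
        return "**"
    if p_value < 0.05:
        return "*"
    return "NS"


@dataclass(frozen=True)
class TestResult:
    """Pooled-variance two-sample t-test for one band."""

    nominal_wavenumber: float
    t_statistic: float
    p_value: float
    star: str
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    n_a: int
    n_b: int
    degenerate: bool = False  # zero pooled variance: p undefined


def t_test_peak(values_a: np.ndarray, values_b: np.ndarray, wavenumber: float = np.nan) -> TestResult:
    """Unpaired, two-sided, homoscedastic t-test (df = n1 + n2 − 2).

    ``values_a`` is the healthy group; a positive t means group a is higher.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 finite values")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        # zero pooled variance: the t statistic is undefined; flag it
        return TestResult(
            wavenumber, np.nan, np.nan, "NS",
            float(a.mean()), float(b.mean()), 0.0, 0.0, int(a.size), int(b.size),
            degenerate=True,
        )
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return TestResult(
        nominal_wavenumber=wavenumber,
        t_statistic=float(t),
        p_value=float(p),
        star=star_label(float(p)),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sd_a=float(a.std(ddof=1)),
        sd_b=float(b.std(ddof=1)),
        n_a=int(a.size),
        n_b=int(b.size),
    )


def t_test_all_peaks(
    peak_table: pd.DataFrame, group_col: str = "cohort", groups: tuple[str, str] = ("healthy", "preeclampsia")
) -> list[TestResult]:
    """Per-band t-tests between two cohorts over a long peak-intensity table."""
    results = []
    for w, sub in peak_table.groupby("nominal_wavenumber", sort=True):
        a = sub.loc[sub[group_col] == groups[0], "intensity"].to_numpy()
        b = sub.loc[sub[group_col] == groups[1], "intensity"].to_numpy()
        results.append(t_test_peak(a, b, wavenumber=float(w)))
    return results


def results_to_frame(results: list[TestResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def select_significant(
    results: list[TestResult], alpha: float = 0.05, bh_correct: bool = False
) -> list[float]:
    """Bands with p < alpha. No multiple-testing correction by default (the
    screening protocol reports raw per-band p-values); set ``bh_correct`` for
    a Benjamini-Hochberg variant."""
    ps = np.array([r.p_value for r in results], dtype=float)
    ws = np.array([r.nominal_wavenumber for r in results], dtype=float)
    ok = np.isfinite(ps)
    if bh_correct:
        from statsmodels.stats.multitest import multipletests

        reject = np.zeros_like(ok)
        reject[ok] = multipletests(ps[ok], alpha=alpha, method="fdr_bh")[0]
        return sorted(ws[reject].tolist())
    return sorted(ws[ok & (ps < alpha)].tolist())


def power_two_sample(
    n_per_group: int,
    sd: float,
    delta: float,
    alpha: float = 0.05,
    sided: str = "two-sided",
) -> float:
    """Power of an unpaired two-sample t-test via the noncentral t distribution.

    ``delta`` is the raw mean difference and ``sd`` the common standard
    deviation, so the standardized effect is delta/sd.
    """
    if n_per_group < 2 or sd <= 0:
        raise ValueError("need n >= 2 per group and sd > 0")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    df = 2 * n_per_group - 2
    ncp = (delta / sd) / np.sqrt(2.0 / n_per_group)
    if sided == "two-sided":
        crit = stats.t.ppf(1.0 - alpha / 2.0, df)
        return float(stats.nct.sf(crit, df, ncp) + stats.nct.cdf(-crit, df, ncp))
    if sided == "one-sided":
        crit = stats.t.ppf(1.0 - alpha, df)
        return float(stats.nct.sf(crit, df, ncp))
    raise ValueError("sided must be 'two-sided' or 'one-sided'")
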