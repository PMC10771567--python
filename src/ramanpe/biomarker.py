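"""Angiogenic-biomarker analysis: ELISA normalization, the sFlt-1/PlGF
anti-angiogenesis ratio with its clinical dual cut-offs, and the linear link
between the spectral lipid/tryptophan ratio and sFlt-1/PlGF.

The dual cut-off interpretation: a ratio ≤ 33 rules preeclampsia out; a
ratio ≥ 85 (early-onset) or ≥ 110 (late-onset) rules it in; anything between
is indeterminate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

RULE_OUT_CUTOFF = 33.0
RULE_IN_CUTOFF = {"early": 85.0, "late": 110.0}

LIPID_BAND = 956.0
TRP_BAND = 1551.0


def normalize_elisa(analyte_pg, total_protein):
    """Analyte abundance per unit total protein (per patient per trimester)."""
    analyte = np.asarray(analyte_pg, dtype=float)
    protein = np.asarray(total_protein, dtype=float)
    if np.any(protein <= 0):
        raise ValueError("total protein must be positive")
    return analyte / protein


def sflt_plgf_ratio(sflt, plgf):
    """Elementwise sFlt-1/PlGF; non-positive PlGF values come back NaN
    (flagged) rather than raising."""
    sflt = np.asarray(sflt, dtype=float)
    plgf = np.asarray(plgf, dtype=float)
    out = np.full_like(sflt, np.nan)
    ok = plgf > 0
    out[ok] = sflt[ok] / plgf[ok]
    return out


def dual_cutoff_classify(ratio: float, onset: str = "late") -> str:
    """Clinical triage call from the sFlt-1/PlGF ratio."""
    if onset not in RULE_IN_CUTOFF:
        raise ValueError("onset must be 'early' or 'late'")
    if ratio < 0:
        raise ValueError("ratio must be non-negative")
    if ratio <= RULE_OUT_CUTOFF:
        return "rule_out"
    if ratio >= RULE_IN_CUTOFF[onset]:
        return "rule_in"
    return "indeterminate"


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    points: pd.DataFrame  # per-cell means: lipid_trp, sflt_plgf


def ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Ordinary least squares y = a + b·x via the normal equations; returns
    (slope, intercept, R²)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.var(x) == 0:
        raise ValueError("zero-variance predictor")
    xc = x - x.mean()
    slope = float((xc @ (y - y.mean())) / (xc @ xc))
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (intercept + slope * x)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / tss if tss > 0 else 1.0
    return slope, intercept, r2


def lipid_trp_regression(
    peak_table: pd.DataFrame,
    elisa: pd.DataFrame,
    lipid_band: float = LIPID_BAND,
    trp_band: float = TRP_BAND,
    per_patient: bool = False,
) -> RegressionResult:
    """Regress the cohort-trimester mean sFlt-1/PlGF ratio on the mean
    spectral lipid/tryptophan ratio.

    By default the fit uses the six cohort × trimester cell means (one
    sample per patient per trimester); ``per_patient=True`` fits on matched
    per-patient points instead.
    """
    wide = peak_table.pivot_table(
        index=["patient_id", "cohort", "trimester"],
        columns="nominal_wavenumber",
        values="intensity",
    )
    for band in (lipid_band, trp_band):
        if band not in wide.columns:
            raise ValueError(f"band {band} cm^-1 missing from the peak table")
    spec = wide[[lipid_band, trp_band]].reset_index()
    spec["lipid_trp"] = spec[lipid_band] / spec[trp_band]

    el = elisa.copy()
    el["sflt_plgf"] = sflt_plgf_ratio(el["sflt1_pg"], el["plgf_pg"])
    merged = spec.merge(el[["patient_id", "sflt_plgf"]], on="patient_id", how="inner").dropna(
        subset=["lipid_trp", "sflt_plgf"]
    )

    if per_patient:
        points = merged[["patient_id", "cohort", "trimester", "lipid_trp", "sflt_plgf"]]
        x, y = points["lipid_trp"].to_numpy(), points["sflt_plgf"].to_numpy()
    else:
        points = (
            merged.groupby(["cohort", "trimester"], as_index=False)[["lipid_trp", "sflt_plgf"]]
            .mean()
        )
        x, y = points["lipid_trp"].to_numpy(), points["sflt_plgf"].to_numpy()
    if len(x) < 3:
        raise ValueError("need at least 3 cells (or patients) for the regression")
    slope, intercept, r2 = ols_line(x, y)
    return RegressionResult(slope=slope, intercept=intercept, r_squared=r2, points=points)


def cohort_ratio_summary(elisa: pd.DataFrame, onset_by_trimester: dict[int, str] | None = None) -> pd.DataFrame:
    """Per cohort-trimester mean of per-patient sFlt-1/PlGF ratios (mean of
    ratios, not ratio of means) with the dual cut-off call on the mean."""
    onset_by_trimester = onset_by_trimester or {1: "early", 2: "early", 3: "late"}
    el = elisa.copy()
    el["sflt_plgf"] = sflt_plgf_ratio(el["sflt1_pg"], el["plgf_pg"])
    rows = []
    for (cohort, tri), sub in el.groupby(["cohort", "trimester"]):
        mean_ratio = float(sub["sflt_plgf"].mean())
        onset = onset_by_trimester.get(int(tri), "late")
        rows.append(
            {
                "cohort": cohort,
                "trimester": int(tri),
                "mean_sflt_plgf": mean_ratio,
                "onset_rule": onset,
                "call": dual_cutoff_classify(mean_ratio, onset),
                "n": len(sub),
            }
        )
    return pd.DataFrame(rows)
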