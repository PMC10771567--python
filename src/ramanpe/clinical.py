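"""Clinical covariate encoding and Pearson correlation to band intensities.

Severity of preeclampsia is graded 0 (healthy), 1 (low), 2 (mild),
3 (severe, including HELLP and superimposed) and rescaled to [0, 1]; binary
history/hypertension covariates are 0/1; continuous covariates are divided
by their maximum over both cohorts pooled. Correlation strengths are binned
as weak (|r| ≤ 0.29), moderate (0.30–0.50) and strong (0.51–1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

SEVERITY_CODE = {"healthy": 0.0, "low": 1.0 / 3.0, "mild": 2.0 / 3.0, "severe": 1.0}
BINARY_COVARIATES = ["history_pe", "chronic_hypertension", "current_hypertension"]
CONTINUOUS_COVARIATES = [
    "maternal_age",
    "bmi",
    "gravida",
    "parity",
    "pregnancy_loss",
    "gestational_age_delivery",
]


def encode_clinical(metadata: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Encode raw clinical covariates onto the common [0, 1] scale.

    Returns the encoded table and a provenance dict recording the pooled
    maxima used to scale the continuous covariates.
    """
    df = metadata.copy()
    unknown = set(df["severity"]) - set(SEVERITY_CODE)
    if unknown:
        raise ValueError(
            f"unknown severity labels {sorted(unknown)}; allowed: {sorted(SEVERITY_CODE)}"
        )
    out = df[["patient_id", "cohort", "trimester"]].copy()
    out["severity"] = df["severity"].map(SEVERITY_CODE)
    for col in BINARY_COVARIATES:
        if col in df:
            vals = df[col]
            if vals.dtype == object:
                bad = set(vals) - {"yes", "no", 0, 1, "0", "1"}
                if bad:
                    raise ValueError(f"unrecognized values in {col}: {sorted(map(str, bad))}")
                out[col] = vals.map({"yes": 1.0, "no": 0.0, "1": 1.0, "0": 0.0, 1: 1.0, 0: 0.0})
            else:
                out[col] = vals.astype(float)
    maxima = {}
    for col in CONTINUOUS_COVARIATES:
        if col in df:
            m = float(df[col].max())
            maxima[col] = m
            out[col] = df[col].astype(float) / m if m > 0 else 0.0
    return out, {"continuous_maxima": maxima, "severity_code": dict(SEVERITY_CODE)}


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation; raises on constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("pearson_r needs at least 3 paired finite values")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("pearson_r undefined for constant input")
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc)))


def strength_category(r: float) -> str:
    """Correlation-strength bin; |r| is rounded to 2 decimals before binning
    so boundary values such as 0.295 land in the moderate bin."""
    if not -1.0 <= r <= 1.0:
        raise ValueError("r must be in [-1, 1]")
    a = round(abs(r), 2)
    if a <= 0.29:
        return "weak"
    if a <= 0.50:
        return "moderate"
    return "strong"


@dataclass
class CorrelationMatrix:
    labels: list[str]
    r: pd.DataFrame
    n: pd.DataFrame  # pairwise-complete sample sizes


def correlate_to_severity(
    peak_table: pd.DataFrame, encoded: pd.DataFrame, wavenumbers: list[float] | None = None
) -> pd.DataFrame:
    """Signed Pearson r of each band's patient intensities against encoded
    severity (positive = band rises with severity)."""
    wide = peak_table.pivot_table(
        index="patient_id", columns="nominal_wavenumber", values="intensity"
    )
    sev = encoded.set_index("patient_id")["severity"].reindex(wide.index)
    if sev.nunique() < 2:
        raise ValueError("severity is constant; correlation undefined")
    if len(wide) < 3:
        raise ValueError("need at least 3 patients")
    rows = []
    for w in wavenumbers if wavenumbers is not None else wide.columns:
        if w not in wide.columns:
            continue
        vals = wide[w]
        try:
            r = pearson_r(vals.to_numpy(), sev.to_numpy())
            rows.append(
                {"nominal_wavenumber": float(w), "r": r, "category": strength_category(r)}
            )
        except ValueError:
            rows.append({"nominal_wavenumber": float(w), "r": np.nan, "category": "undefined"})
    return pd.DataFrame(rows)


def correlation_heatmap(
    peak_table: pd.DataFrame,
    encoded: pd.DataFrame,
    wavenumbers: list[float] | None = None,
    include_severity: bool = False,
) -> CorrelationMatrix:
    """All-pairs Pearson matrix over bands + clinical covariates.

    Severity is excluded by default (screening before a diagnosis exists);
    include it for third-trimester analyses. Correlations are
    pairwise-complete with per-cell n recorded; rows are ordered bands
    ascending, then covariates.
    """
    wide = peak_table.pivot_table(
        index="patient_id", columns="nominal_wavenumber", values="intensity"
    )
    if wavenumbers is not None:
        wide = wide[[w for w in wavenumbers if w in wide.columns]]
    wide.columns = [f"{float(w):g} cm-1" for w in wide.columns]
    covars = [c for c in BINARY_COVARIATES + CONTINUOUS_COVARIATES if c in encoded.columns]
    if include_severity:
        covars = covars + ["severity"]
    clin = encoded.set_index("patient_id")[covars].reindex(wide.index)
    joint = pd.concat([wide, clin.astype(float)], axis=1)
    r = joint.corr(method="pearson", min_periods=3)
    finite = joint.notna().astype(int)
    n = pd.DataFrame(finite.T.to_numpy() @ finite.to_numpy(), index=r.index, columns=r.columns)
    return CorrelationMatrix(labels=list(joint.columns), r=r, n=n)
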