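"""Seeded synthetic Raman cohorts with known ground truth.

The generator emulates the structure of a longitudinal plasma study of
healthy versus preeclamptic pregnancies: per-patient plasma spectra on a
600-1800 cm^-1 grid composed of pseudo-Voigt metabolite bands on a smooth
fluorescence baseline with detector noise and occasional cosmic-ray spikes;
100 replicate exposures per patient; clinical covariates drawn from the
demographic distributions of the two cohorts; and an ELISA table whose
sFlt-1/PlGF ratio is linearly tied to the spectral lipid/tryptophan ratio.

Every stochastic choice flows from a single seed via ``SeedSequence`` spawns,
so identical configs produce bit-identical datasets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .spectra import Spectrum, PeakDefinition, load_peak_table, scans_to_frame

COHORTS = ("healthy", "preeclampsia")
TRIMESTERS = (1, 2, 3)

#: per-(cohort, trimester) patient counts of the study design this emulates
STUDY_CELL_SIZES: dict[tuple[str, int], int] = {
    ("healthy", 1): 23,
    ("healthy", 2): 25,
    ("healthy", 3): 24,
    ("preeclampsia", 1): 22,
    ("preeclampsia", 2): 20,
    ("preeclampsia", 3): 29,
}

#: reference CH2-bending band: strong and nearly invariant across samples,
#: which is why downstream normalization anchors to it
REFERENCE_BAND = 1445.0
REFERENCE_AMPLITUDE = 1.0
REFERENCE_CV = 0.02

#: nominal mean band amplitudes (arbitrary units, relative to the 1445 band).
#: Class-level defaults with a few stronger named bands; not fitted to data.
_CLASS_AMPLITUDE = {
    "lipid/FA": 0.40,
    "carotenoid/sugar/carbohydrate": 0.35,
    "amino acid": 0.30,
    "protein": 0.45,
    "nucleic acid": 0.25,
    "TCA": 0.30,
    "other": 0.25,
}
_AMPLITUDE_OVERRIDES = {1002.0: 0.60, 1657.0: 0.55, 1551.0: 0.35}


def default_effect_map() -> dict[float, dict[int, float]]:
    """Planted cohort effects: standardized shift (Cohen's d, positive =
    higher in preeclampsia) per band per trimester.

    Directions follow the reported cohort trends (lipids, carotenoids,
    sugars, glycine, tyrosine, DNA and citric acid up in preeclampsia;
    several amino acids, carbohydrates and amide III down); the magnitude
    d = 1 is a package default, as the source trends are unquantified.
    """
    up = [956.0, 701.0, 1154.0, 848.0, 898.0, 835.0, 940.0]
    down = [1317.0, 1551.0, 1031.0, 1340.0, 1243.0, 1017.0]
    effects: dict[float, dict[int, float]] = {}
    for w in up:
        effects[w] = {1: 1.0, 2: 1.0, 3: 1.0}
    for w in down:
        effects[w] = {1: -1.0, 2: -1.0, 3: -1.0}
    effects[1657.0] = {1: 1.0, 2: -1.0, 3: 0.0}  # phospholipids flip sign mid-pregnancy
    effects[1420.0] = {1: 0.0, 2: 1.0, 3: 1.0}  # cell-free DNA rises late
    return effects


@dataclass
class ClinicalParams:
    """Cohort demographic distributions (mean, sd) and event rates."""

    maternal_age: dict = field(
        default_factory=lambda: {"healthy": (31.2, 4.5), "preeclampsia": (32.0, 5.9)}
    )
    bmi: dict = field(
        default_factory=lambda: {"healthy": (30.8, 11.7), "preeclampsia": (28.3, 6.9)}
    )
    gravida: dict = field(
        default_factory=lambda: {"healthy": (2.7, 1.7), "preeclampsia": (1.9, 1.5)}
    )
    parity: dict = field(
        default_factory=lambda: {"healthy": (1.2, 0.9), "preeclampsia": (0.7, 1.2)}
    )
    pregnancy_loss: dict = field(
        default_factory=lambda: {"healthy": (0.5, 0.5), "preeclampsia": (0.3, 0.94)}
    )
    gestational_age: dict = field(
        default_factory=lambda: {"healthy": (38.47, 1.95), "preeclampsia": (36.23, 2.62)}
    )
    chronic_hypertension: dict = field(
        default_factory=lambda: {"healthy": 0.11, "preeclampsia": 0.20}
    )
    current_hypertension: dict = field(
        default_factory=lambda: {"healthy": 0.11, "preeclampsia": 0.10}
    )
    history_pe: dict = field(default_factory=lambda: {"healthy": 0.03, "preeclampsia": 0.22})
    severe_fraction: float = 0.57  # remaining preeclamptic patients are "mild"


@dataclass
class ElisaParams:
    """Synthetic link between the spectral lipid/tryptophan ratio and the
    sFlt-1/PlGF ratio, plus nuisance analytes with no cohort effect."""

    intercept: float = 5.0
    slope: float = 30.0
    noise_sd: float = 3.0
    plgf_base_pg: float = 200.0
    plgf_cv: float = 0.3
    total_protein_mean: float = 50.0
    total_protein_sd: float = 5.0
    tnf_base_pg: float = 8.0
    gmcsf_base_pg: float = 4.0
    cytokine_cv: float = 0.25


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic cohort."""

    seed: int = 0
    grid_min: float = 600.0
    grid_max: float = 1800.0
    grid_step: float = 1.0
    n_patients_per_cell: int | None = None  # None -> STUDY_CELL_SIZES
    n_replicates: int = 100
    noise_sd: float = 0.02
    cosmic_ray_prob: float = 0.05
    cosmic_ray_amplitude_range: tuple[float, float] = (20.0, 60.0)  # × noise_sd
    cosmic_ray_width: int = 1
    baseline_order: int = 5
    baseline_scale: float = 5.0
    baseline_amplitude_range: tuple[float, float] = (0.8, 1.2)
    between_patient_cv: float = 0.15
    within_patient_cv: float = 0.05
    fwhm_range: tuple[float, float] = (8.0, 20.0)
    effect_map: dict | None = None  # None -> default_effect_map(); {} -> null cohort
    severity_link: dict[float, float] = field(default_factory=dict)  # band -> target r
    clinical_params: ClinicalParams = field(default_factory=ClinicalParams)
    elisa_params: ElisaParams = field(default_factory=ElisaParams)

    def grid(self) -> np.ndarray:
        if self.grid_step <= 0 or self.grid_max <= self.grid_min:
            raise ValueError("grid must be ascending: grid_step > 0 and grid_max > grid_min")
        n = int(round((self.grid_max - self.grid_min) / self.grid_step)) + 1
        return self.grid_min + self.grid_step * np.arange(n)

    def cell_sizes(self) -> dict[tuple[str, int], int]:
        if self.n_patients_per_cell is None:
            return dict(STUDY_CELL_SIZES)
        return {(c, t): int(self.n_patients_per_cell) for c in COHORTS for t in TRIMESTERS}

    def resolved_effect_map(self) -> dict[float, dict[int, float]]:
        raw = default_effect_map() if self.effect_map is None else self.effect_map
        out: dict[float, dict[int, float]] = {}
        for w, d in raw.items():
            if isinstance(d, dict):
                out[float(w)] = {int(t): float(d.get(t, 0.0)) for t in TRIMESTERS}
            else:
                out[float(w)] = {t: float(d) for t in TRIMESTERS}
        return out

    def validate(self, peaks: list[PeakDefinition]) -> None:
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if not 0.0 <= self.cosmic_ray_prob <= 1.0:
            raise ValueError("cosmic_ray_prob must be in [0, 1]")
        known = {p.nominal_wavenumber for p in peaks}
        for w in self.resolved_effect_map():
            if w not in known:
                raise ValueError(f"effect_map wavenumber {w} is not an assigned band")
        grid = self.grid()
        for p in peaks:
            if not (grid[0] <= p.nominal_wavenumber <= grid[-1]):
                raise ValueError(f"grid does not cover band at {p.nominal_wavenumber} cm^-1")


@dataclass
class CohortDataset:
    """One generated cohort: scans, clinical metadata, ELISA table, truth."""

    scans: list[Spectrum]
    metadata: pd.DataFrame
    elisa: pd.DataFrame
    truth: dict

    def validate(self) -> None:
        known = set(self.metadata["patient_id"])
        scan_patients = {s.patient_id for s in self.scans}
        if not scan_patients <= known:
            raise ValueError("scan patient_id missing from metadata")
        counts = pd.Series([s.patient_id for s in self.scans]).value_counts()
        if counts.nunique() > 1:
            raise ValueError("unequal replicate counts across patients")

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        scans_to_frame(self.scans).to_csv(outdir / "scans.csv", index=False)
        self.metadata.to_csv(outdir / "metadata.csv", index=False)
        self.elisa.to_csv(outdir / "elisa.csv", index=False)
        truth = dict(self.truth)
        amps = truth.pop("amplitudes")
        amps.to_csv(outdir / "truth_amplitudes.csv", index=False)
        with open(outdir / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=2, sort_keys=True, default=str)


def pseudo_voigt(x: np.ndarray, center: float, fwhm: float, eta: float = 0.5) -> np.ndarray:
    """Unit-height pseudo-Voigt profile: eta·Lorentzian + (1−eta)·Gaussian,
    the usual compromise line shape for Raman bands."""
    u = (x - center) / fwhm
    lorentz = 1.0 / (1.0 + 4.0 * u**2)
    gauss = np.exp(-4.0 * np.log(2.0) * u**2)
    return eta * lorentz + (1.0 - eta) * gauss


def band_amplitude(peak: PeakDefinition) -> float:
    return _AMPLITUDE_OVERRIDES.get(peak.nominal_wavenumber, _CLASS_AMPLITUDE[peak.metabolite_class])


def _patient_labels(config: SyntheticConfig) -> pd.DataFrame:
    rows = []
    for (cohort, trimester), n in sorted(config.cell_sizes().items()):
        for i in range(n):
            rows.append(
                {
                    "patient_id": f"{cohort[0].upper()}{trimester}_{i + 1:02d}",
                    "cohort": cohort,
                    "trimester": trimester,
                }
            )
    return pd.DataFrame(rows)


def generate_patient_amplitudes(
    config: SyntheticConfig,
    peaks: list[PeakDefinition] | None = None,
    rng: np.random.Generator | None = None,
    severity_encoded: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw ground-truth per-patient band amplitudes.

    Between-patient variation is log-normal with CV ``between_patient_cv``;
    preeclamptic patients at effect-map bands are shifted by
    d × (between-patient SD). Returns ``(labels, amplitudes)`` where
    ``amplitudes`` is wide (one column per band, labelled by wavenumber).
    This patient-level stage is also the unit the calibration and power
    simulations operate on.
    """
    peaks = peaks if peaks is not None else load_peak_table()
    config.validate(peaks)
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    labels = _patient_labels(config)
    n = len(labels)
    is_pe = (labels["cohort"] == "preeclampsia").to_numpy()
    effects = config.resolved_effect_map()

    cols: dict[float, np.ndarray] = {}
    for peak in peaks:
        base = band_amplitude(peak)
        sd = base * config.between_patient_cv
        sigma = np.sqrt(np.log1p(config.between_patient_cv**2))
        mu = np.log(base) - 0.5 * sigma**2
        amp = rng.lognormal(mu, sigma, size=n)
        d_by_tri = effects.get(peak.nominal_wavenumber)
        if d_by_tri:
            d = labels["trimester"].map(d_by_tri).to_numpy(float)
            amp = amp + np.where(is_pe, d * sd, 0.0)
        cols[peak.nominal_wavenumber] = amp

    # latent-severity coupling: tilt designated bands along encoded severity
    if config.severity_link and severity_encoded is not None:
        sev = severity_encoded.to_numpy(float)
        sd_sev = sev.std(ddof=1)
        if sd_sev > 0:
            for w, r in config.severity_link.items():
                base = next(band_amplitude(p) for p in peaks if p.nominal_wavenumber == float(w))
                lam = (r / np.sqrt(1.0 - r**2)) * (base * config.between_patient_cv) / sd_sev
                cols[float(w)] = cols[float(w)] + lam * (sev - sev.mean())

    # stable reference band
    sigma_ref = np.sqrt(np.log1p(REFERENCE_CV**2))
    cols[REFERENCE_BAND] = rng.lognormal(
        np.log(REFERENCE_AMPLITUDE) - 0.5 * sigma_ref**2, sigma_ref, size=n
    )
    amplitudes = pd.DataFrame(cols, index=labels.index)
    return labels, amplitudes


def generate_clinical(
    config: SyntheticConfig, labels: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw raw (unencoded) clinical covariates per patient from the
    cohort demographic distributions."""
    p = config.clinical_params
    rows = []
    for rec in labels.to_dict("records"):
        cohort = rec["cohort"]

        def normal(spec, lo, hi):
            mean, sd = spec[cohort]
            x = rng.normal(mean, sd)
            while not (lo <= x <= hi):  # truncate to plausible range by redraw
                x = rng.normal(mean, sd)
            return x

        if cohort == "preeclampsia":
            severity = "severe" if rng.random() < p.severe_fraction else "mild"
        else:
            severity = "healthy"
        rows.append(
            {
                **rec,
                "maternal_age": round(normal(p.maternal_age, 18, 50), 1),
                "bmi": round(normal(p.bmi, 15, 60), 1),
                "gravida": int(max(round(normal(p.gravida, -2, 12)), 1)),
                "parity": int(max(round(normal(p.parity, -3, 10)), 0)),
                "pregnancy_loss": int(max(round(normal(p.pregnancy_loss, -3, 8)), 0)),
                "gestational_age_delivery": round(normal(p.gestational_age, 24, 42), 2),
                "chronic_hypertension": "yes"
                if rng.random() < p.chronic_hypertension[cohort]
                else "no",
                "current_hypertension": "yes"
                if rng.random() < p.current_hypertension[cohort]
                else "no",
                "history_pe": "yes" if rng.random() < p.history_pe[cohort] else "no",
                "severity": severity,
            }
        )
    return pd.DataFrame(rows)


_SEVERITY_CODE = {"healthy": 0.0, "low": 1.0 / 3.0, "mild": 2.0 / 3.0, "severe": 1.0}


def generate_elisa(
    metadata: pd.DataFrame,
    amplitudes: pd.DataFrame,
    rng: np.random.Generator,
    params: ElisaParams | None = None,
    lipid_band: float = 956.0,
    trp_band: float = 1551.0,
) -> pd.DataFrame:
    """ELISA table tied to the spectral lipid/tryptophan ratio.

    ``sFlt-1/PlGF = intercept + slope × (lipid/trp) + noise``; individual
    sFlt-1 and PlGF columns are consistent with the stored ratio, and the
    proinflammatory cytokines carry no cohort effect. Patients with a
    non-positive tryptophan amplitude are rejected (degenerate ratio).
    """
    params = params or ElisaParams()
    lipid = amplitudes[lipid_band].to_numpy(float)
    trp = amplitudes[trp_band].to_numpy(float)
    if np.any(trp <= 0):
        bad = metadata["patient_id"].iloc[int(np.argmax(trp <= 0))]
        raise ValueError(f"non-positive tryptophan amplitude for patient {bad}")
    ltr = lipid / trp
    n = len(metadata)
    ratio = params.intercept + params.slope * ltr + rng.normal(0.0, params.noise_sd, size=n)
    ratio = np.maximum(ratio, 0.05)  # a ratio of concentrations cannot be negative

    sigma = np.sqrt(np.log1p(params.plgf_cv**2))
    plgf = rng.lognormal(np.log(params.plgf_base_pg) - 0.5 * sigma**2, sigma, size=n)
    sig_c = np.sqrt(np.log1p(params.cytokine_cv**2))
    out = pd.DataFrame(
        {
            "patient_id": metadata["patient_id"],
            "cohort": metadata["cohort"],
            "trimester": metadata["trimester"],
            "tnf_pg": rng.lognormal(np.log(params.tnf_base_pg) - 0.5 * sig_c**2, sig_c, n),
            "gmcsf_pg": rng.lognormal(np.log(params.gmcsf_base_pg) - 0.5 * sig_c**2, sig_c, n),
            "sflt1_pg": ratio * plgf,
            "plgf_pg": plgf,
            "total_protein": rng.normal(params.total_protein_mean, params.total_protein_sd, n),
            "lipid_trp_true": ltr,
            "sflt1_plgf_true": ratio,
        }
    )
    return out


def render_scans(
    config: SyntheticConfig,
    labels: pd.DataFrame,
    amplitudes: pd.DataFrame,
    peaks: list[PeakDefinition],
    fwhm: dict[float, float],
    rng: np.random.Generator,
) -> list[Spectrum]:
    """Render replicate scans: bands + fluorescence baseline + noise + spikes."""
    grid = config.grid()
    bands = list(amplitudes.columns)
    profiles = np.vstack([pseudo_voigt(grid, float(w), fwhm[float(w)]) for w in bands])

    # fixed baseline shape (degree `baseline_order` polynomial, positive hump)
    t = np.linspace(0.0, 1.0, grid.size)
    coef = rng.uniform(-1.0, 1.0, size=config.baseline_order + 1)
    shape = np.polynomial.polynomial.polyval(t, coef)
    shape = shape - shape.min() + 0.3 * (shape.max() - shape.min() + 1e-12)
    shape = shape / shape.max() * config.baseline_scale

    scans: list[Spectrum] = []
    n_rep = config.n_replicates
    lo_c, hi_c = config.cosmic_ray_amplitude_range
    for idx, rec in enumerate(labels.to_dict("records")):
        amp = amplitudes.iloc[idx].to_numpy(float)
        base_amp = np.array([band_amplitude(p) for p in peaks] + [REFERENCE_AMPLITUDE])
        jitter = rng.normal(0.0, config.within_patient_cv * base_amp, size=(n_rep, amp.size))
        rep_amp = np.maximum(amp[None, :] + jitter, 0.0)
        signal = rep_amp @ profiles  # (n_rep, n_bins)
        signal += rng.uniform(*config.baseline_amplitude_range, size=(n_rep, 1)) * shape[None, :]
        signal += rng.normal(0.0, config.noise_sd, size=signal.shape)
        hit = rng.random(n_rep) < config.cosmic_ray_prob
        for j in np.where(hit)[0]:
            pos = rng.integers(0, grid.size)
            height = rng.uniform(lo_c, hi_c) * config.noise_sd
            end = min(pos + config.cosmic_ray_width, grid.size)
            signal[j, pos:end] += height
        for j in range(n_rep):
            scans.append(
                Spectrum(
                    wavenumbers=grid,
                    intensities=signal[j],
                    scan_id=f"{rec['patient_id']}_s{j + 1:03d}",
                    patient_id=rec["patient_id"],
                    trimester=rec["trimester"],
                    cohort=rec["cohort"],
                )
            )
    return scans


def generate_cohort(config: SyntheticConfig) -> CohortDataset:
    """Generate a full synthetic cohort (scans + clinical + ELISA + truth)."""
    peaks = load_peak_table()
    config.validate(peaks)
    ss = np.random.SeedSequence(config.seed)
    rng_amp, rng_clin, rng_elisa, rng_render, rng_fwhm = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    labels = _patient_labels(config)
    metadata = generate_clinical(config, labels, rng_clin)
    severity_encoded = metadata["severity"].map(_SEVERITY_CODE)
    labels, amplitudes = generate_patient_amplitudes(
        config, peaks, rng_amp, severity_encoded=severity_encoded
    )

    lo, hi = config.fwhm_range
    fwhm = {p.nominal_wavenumber: float(rng_fwhm.uniform(lo, hi)) for p in peaks}
    fwhm[REFERENCE_BAND] = float(rng_fwhm.uniform(lo, hi))

    scans = render_scans(config, labels, amplitudes, peaks, fwhm, rng_render)
    elisa = generate_elisa(metadata, amplitudes, rng_elisa, config.elisa_params)

    truth = {
        "effect_map": {str(k): v for k, v in config.resolved_effect_map().items()},
        "fwhm": {str(k): v for k, v in fwhm.items()},
        "severity_link": {str(k): v for k, v in config.severity_link.items()},
        "amplitudes": pd.concat([labels, amplitudes], axis=1),
    }
    dataset = CohortDataset(scans=scans, metadata=metadata, elisa=elisa, truth=truth)
    dataset.validate()
    return dataset


def spike_series(
    base_spectrum: Spectrum,
    wavenumber: float,
    concentrations: list[float],
    amplitude_per_unit: float = 0.1,
    fwhm: float = 12.0,
    eta: float = 0.5,
) -> list[Spectrum]:
    """In-silico analogue of a standard-addition spiking experiment: copies of
    ``base_spectrum`` with the target band incremented proportionally to each
    concentration."""
    wn = base_spectrum.wavenumbers
    if not (wn[0] <= wavenumber <= wn[-1]):
        raise ValueError(f"wavenumber {wavenumber} not on the spectrum grid")
    if any(c < 0 for c in concentrations):
        raise ValueError("concentrations must be non-negative")
    profile = pseudo_voigt(wn, wavenumber, fwhm, eta)
    out = []
    for i, c in enumerate(concentrations):
        s = base_spectrum.with_intensities(
            base_spectrum.intensities + amplitude_per_unit * c * profile
        )
        s.scan_id = f"{base_spectrum.scan_id}_spike{i}"
        out.append(s)
    return out
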