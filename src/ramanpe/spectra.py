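"""Data model and I/O for Raman spectra, peak assignments, and pathway maps.

A :class:`Spectrum` is one scan: a strictly ascending Raman-shift grid (cm^-1)
paired with an intensity vector in arbitrary counts. Scans are exchanged as
long-format CSV (one row per ``(scan_id, wavenumber)``); the bundled peak
assignment table maps nominal wavenumbers to plasma metabolites.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

SCAN_COLUMNS = ["scan_id", "patient_id", "trimester", "cohort", "wavenumber_cm1", "intensity"]

#: default wavenumber used for reference-peak renormalization (CH2 bending band)
REFERENCE_WAVENUMBER = 1445.0

PEAK_CLASSES = frozenset(
    {
        "lipid/FA",
        "carotenoid/sugar/carbohydrate",
        "amino acid",
        "protein",
        "nucleic acid",
        "TCA",
        "other",
    }
)


@dataclass
class Spectrum:
    """One Raman scan on an ascending wavenumber grid."""

    wavenumbers: np.ndarray
    intensities: np.ndarray
    scan_id: str = ""
    patient_id: str = ""
    trimester: int = 0
    cohort: str = ""

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavenumbers.shape != self.intensities.shape or self.wavenumbers.ndim != 1:
            raise ValueError("wavenumbers and intensities must be 1-D vectors of equal length")
        if self.wavenumbers.size >= 2 and not np.all(np.diff(self.wavenumbers) > 0):
            raise ValueError("wavenumber grid must be strictly increasing")
        if not np.all(np.isfinite(self.wavenumbers)) or not np.all(np.isfinite(self.intensities)):
            raise ValueError("non-finite values in spectrum")

    def __len__(self) -> int:
        return self.wavenumbers.size

    def with_intensities(self, intensities: np.ndarray) -> "Spectrum":
        """Copy of this spectrum with a new intensity vector on the same grid."""
        return replace(self, intensities=np.asarray(intensities, dtype=float))

    def copy(self) -> "Spectrum":
        return replace(
            self,
            wavenumbers=self.wavenumbers.copy(),
            intensities=self.intensities.copy(),
        )


@dataclass(frozen=True)
class PeakDefinition:
    """One row of the peak-assignment table."""

    nominal_wavenumber: float
    metabolite: str
    vibrational_mode: str
    metabolite_class: str
    compound_id: str
    primary_peak: bool

    @property
    def is_generic(self) -> bool:
        """True for class-level bands (amides, DNA, carbohydrates, ...) that map
        to no single compound and are excluded from enrichment."""
        return self.compound_id == "generic"


def read_scans(path: str | Path) -> list[Spectrum]:
    """Read spectra from long-format CSV, one :class:`Spectrum` per ``scan_id``.

    Required columns: scan_id, patient_id, wavenumber_cm1, intensity.
    Optional: trimester, cohort. Rows are sorted by wavenumber within each scan.
    """
    df = pd.read_csv(path)
    required = {"scan_id", "patient_id", "wavenumber_cm1", "intensity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"scan file {path} is missing columns: {sorted(missing)}")
    for col in ("wavenumber_cm1", "intensity"):
        bad = df.index[~np.isfinite(pd.to_numeric(df[col], errors="coerce"))]
        if len(bad):
            raise ValueError(f"non-numeric or missing {col} at row {bad[0] + 2} of {path}")
    dupes = df.duplicated(subset=["scan_id", "wavenumber_cm1"])
    if dupes.any():
        raise ValueError(
            f"duplicated (scan_id, wavenumber) at row {df.index[dupes][0] + 2} of {path}"
        )

    spectra = []
    for scan_id, group in df.groupby("scan_id", sort=True):
        group = group.sort_values("wavenumber_cm1")
        spectra.append(
            Spectrum(
                wavenumbers=group["wavenumber_cm1"].to_numpy(float),
                intensities=group["intensity"].to_numpy(float),
                scan_id=str(scan_id),
                patient_id=str(group["patient_id"].iloc[0]),
                trimester=int(group["trimester"].iloc[0]) if "trimester" in group else 0,
                cohort=str(group["cohort"].iloc[0]) if "cohort" in group else "",
            )
        )
    return spectra


def scans_to_frame(spectra: list[Spectrum]) -> pd.DataFrame:
    """Long-format DataFrame for a collection of scans."""
    parts = []
    for s in spectra:
        parts.append(
            pd.DataFrame(
                {
                    "scan_id": s.scan_id,
                    "patient_id": s.patient_id,
                    "trimester": s.trimester,
                    "cohort": s.cohort,
                    "wavenumber_cm1": s.wavenumbers,
                    "intensity": s.intensities,
                }
            )
        )
    return pd.concat(parts, ignore_index=True) if parts else pd.DataFrame(columns=SCAN_COLUMNS)


def write_scans(spectra: list[Spectrum], path: str | Path) -> None:
    scans_to_frame(spectra).to_csv(path, index=False)


def resample(spectrum: Spectrum, target_grid: np.ndarray) -> Spectrum:
    """Linear interpolation onto ``target_grid``; extrapolation is refused."""
    grid = np.asarray(target_grid, dtype=float)
    if grid.min() < spectrum.wavenumbers[0] or grid.max() > spectrum.wavenumbers[-1]:
        raise ValueError(
            f"target grid [{grid.min()}, {grid.max()}] outside spectrum range "
            f"[{spectrum.wavenumbers[0]}, {spectrum.wavenumbers[-1]}]"
        )
    values = np.interp(grid, spectrum.wavenumbers, spectrum.intensities)
    return replace(spectrum, wavenumbers=grid, intensities=values)


def load_peak_table(path: str | Path | None = None) -> list[PeakDefinition]:
    """Load a peak-assignment table (TSV); default is the bundled 37-band
    plasma table (681-1672 cm^-1)."""
    if path is None:
        with resources.files("ramanpe.data").joinpath("peak_table.tsv").open("rb") as fh:
            df = pd.read_csv(fh, sep="\t")
        source = "<bundled>"
    else:
        df = pd.read_csv(path, sep="\t")
        source = str(path)
    required = {"wavenumber_cm1", "metabolite", "mode", "class", "compound_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"peak table {source} missing columns: {sorted(missing)}")
    if df["wavenumber_cm1"].duplicated().any():
        dup = df["wavenumber_cm1"][df["wavenumber_cm1"].duplicated()].iloc[0]
        raise ValueError(f"duplicate nominal wavenumber {dup} in peak table {source}")
    unknown = set(df["class"]) - PEAK_CLASSES
    if unknown:
        raise ValueError(f"unknown metabolite classes in {source}: {sorted(unknown)}")
    if "primary_peak" not in df.columns:
        df["primary_peak"] = 1
    return [
        PeakDefinition(
            nominal_wavenumber=float(r["wavenumber_cm1"]),
            metabolite=str(r["metabolite"]),
            vibrational_mode=str(r["mode"]),
            metabolite_class=str(r["class"]),
            compound_id=str(r["compound_id"]),
            primary_peak=bool(int(r["primary_peak"])),
        )
        for r in df.to_dict("records")
    ]
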