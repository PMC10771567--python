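"""Spectral preprocessing chain for plasma Raman scans.

The chain mirrors the standard workflow for fluorescent biofluid spectra:
replicate-based cosmic-ray despiking, Savitzky-Golay smoothing (45-point
window, 10th-order polynomial), iterative modified-polyfit (ModPoly)
fluorescence-baseline removal (degree 9, relative tolerance 1e-4), per-scan
standard normal variate (SNV) scaling, and renormalization so that the stable
CH2-bending reference band at 1445 cm^-1 equals 1 with a spectrum minimum of 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .spectra import REFERENCE_WAVENUMBER, Spectrum

_MAD_TO_SD = 1.4826  # consistency factor: MAD of a normal sample ≈ sd / 1.4826


def remove_cosmic_rays(
    replicates: list[Spectrum], z_threshold: float = 8.0, window: int = 11
) -> list[Spectrum]:
    """Replace single-exposure spike outliers by the replicate median.

    At each wavenumber a replicate exceeding ``median + z * 1.4826 * MAD``
    across the replicate stack is replaced by that median. Cosmic rays are
    uncorrelated between exposures, so the cross-replicate median is a clean
    estimate of the true intensity. With fewer than three replicates a
    rolling-window median test within each spectrum is used instead.
    """
    if len(replicates) < 3:
        warnings.warn(
            "fewer than 3 replicates: falling back to single-spectrum rolling-median despiking",
            stacklevel=2,
        )
        return [_despike_single(s, z_threshold, window) for s in replicates]

    grid = replicates[0].wavenumbers
    for s in replicates[1:]:
        if not np.array_equal(s.wavenumbers, grid):
            raise ValueError("replicates must share a common wavenumber grid")
    stack = np.vstack([s.intensities for s in replicates])
    # iterate to a fixpoint (replacing an outlier tightens the MAD, which can
    # expose a second outlier); this makes the operation idempotent
    for _ in range(10):
        med = np.median(stack, axis=0)
        mad = np.median(np.abs(stack - med), axis=0)
        limit = med + z_threshold * _MAD_TO_SD * mad
        cleaned = np.where(stack > limit, med, stack)
        if np.array_equal(cleaned, stack):
            break
        stack = cleaned
    return [s.with_intensities(row) for s, row in zip(replicates, stack)]


def _despike_single(spectrum: Spectrum, z_threshold: float, window: int) -> Spectrum:
    """Rolling-median spike test for an isolated scan."""
    y = spectrum.intensities
    half = max(window // 2, 1)
    padded = np.pad(y, half, mode="edge")
    windows = np.lib.stride_tricks.sliding_window_view(padded, 2 * half + 1)
    med = np.median(windows, axis=-1)
    mad = np.median(np.abs(windows - med[:, None]), axis=-1)
    limit = med + z_threshold * _MAD_TO_SD * mad
    return spectrum.with_intensities(np.where(y > limit, med, y))


def savgol_weights(window_points: int, poly_order: int) -> np.ndarray:
    """Savitzky-Golay smoothing weights via a Chebyshev basis on window
    positions rescaled to [-1, 1].

    Mathematically identical to the classical least-squares filter, but the
    rescaled orthogonal basis keeps the normal equations well conditioned at
    high polynomial orders (a degree-10 fit on raw sample indices loses ~10
    digits), so polynomials up to ``poly_order`` pass through to ~1e-10.
    """
    half = window_points // 2
    p = np.arange(-half, half + 1) / half
    V = np.polynomial.chebyshev.chebvander(p, poly_order)
    center = np.polynomial.chebyshev.chebvander(np.array([0.0]), poly_order)[0]
    return V @ np.linalg.solve(V.T @ V, center)


def smooth(spectrum: Spectrum, window_points: int = 45, poly_order: int = 10) -> Spectrum:
    """Savitzky-Golay least-squares smoothing (local polynomial fit).

    Edges are handled by evaluating the polynomial fitted to the first/last
    full window, so polynomial signals of degree <= ``poly_order`` pass
    through unchanged.
    """
    if window_points % 2 == 0 or window_points <= poly_order:
        raise ValueError("window must be odd and greater than the polynomial order")
    if len(spectrum) < window_points:
        raise ValueError(f"spectrum length {len(spectrum)} < window {window_points}")
    y = spectrum.intensities
    half = window_points // 2
    w = savgol_weights(window_points, poly_order)
    out = np.empty_like(y)
    out[half:-half] = np.correlate(y, w, mode="valid")

    # edge handling: fit the edge window, evaluate the fit at the edge points
    p = np.arange(-half, half + 1) / half
    V = np.polynomial.chebyshev.chebvander(p, poly_order)
    gram = V.T @ V
    coef_lo = np.linalg.solve(gram, V.T @ y[:window_points])
    coef_hi = np.linalg.solve(gram, V.T @ y[-window_points:])
    out[:half] = V[:half] @ coef_lo
    out[-half:] = V[half + 1 :] @ coef_hi
    return spectrum.with_intensities(out)


def modpoly_baseline(
    y: np.ndarray, x: np.ndarray, poly_degree: int = 9, tol: float = 1e-4, max_iter: int = 500
) -> tuple[np.ndarray, bool]:
    """Iterative modified-polyfit baseline on (possibly stacked) intensities.

    Fit a polynomial, clip the working signal to the elementwise minimum of
    (signal, fit), and repeat until the relative RMS change between successive
    fits drops below ``tol``. Peaks stick out above the fluorescence background
    and are progressively clipped away, so the fit converges onto the baseline.

    ``y`` may be 1-D (one spectrum) or 2-D ``(n_spectra, n_points)``.
    Returns ``(baseline, converged)``; fits use a Chebyshev basis on a
    rescaled grid for numerical stability at degree 9.
    """
    y2 = np.atleast_2d(np.asarray(y, dtype=float)).copy()
    if y2.shape[1] <= poly_degree + 1:
        raise ValueError("spectrum must be longer than poly_degree + 1")
    # map x to [-1, 1] for a well-conditioned Chebyshev fit
    t = 2.0 * (x - x[0]) / (x[-1] - x[0]) - 1.0

    work = y2.T  # chebfit wants (n_points, n_series)
    prev_fit = None
    converged = np.zeros(y2.shape[0], dtype=bool)
    fit = work
    for _ in range(max_iter):
        coef = np.polynomial.chebyshev.chebfit(t, work, poly_degree)
        fit = np.polynomial.chebyshev.chebval(t, coef).T  # -> (n_points, n_series)
        if prev_fit is not None:
            num = np.sqrt(np.mean((fit - prev_fit) ** 2, axis=0))
            den = np.sqrt(np.mean(prev_fit**2, axis=0))
            rel = np.where(den > 0, num / np.maximum(den, 1e-300), num)
            converged = rel < tol
            if converged.all():
                break
        prev_fit = fit
        work = np.minimum(work, fit)
    return fit.T.reshape(y2.shape), bool(np.all(converged))


def correct_baseline(
    spectrum: Spectrum, poly_degree: int = 9, tol: float = 1e-4, max_iter: int = 500
) -> tuple[Spectrum, np.ndarray]:
    """Remove the fluorescence background with the ModPoly iteration.

    Returns the baseline-subtracted spectrum (small negative excursions are
    expected) and the fitted baseline. Non-convergence at ``max_iter`` emits a
    warning rather than failing.
    """
    baseline, ok = modpoly_baseline(
        spectrum.intensities, spectrum.wavenumbers, poly_degree, tol, max_iter
    )
    baseline = baseline.ravel()
    if not ok:
        warnings.warn("ModPoly baseline did not converge within max_iter", stacklevel=2)
    return spectrum.with_intensities(spectrum.intensities - baseline), baseline


def snv(spectrum: Spectrum) -> Spectrum:
    """Standard normal variate: per-spectrum (I - mean) / sd with sample sd.

    Removes multiplicative scatter differences between scans; output has mean
    0 and sd 1.
    """
    sd = np.std(spectrum.intensities, ddof=1)
    if sd == 0:
        raise ValueError("SNV undefined for a constant spectrum (zero variance)")
    return spectrum.with_intensities((spectrum.intensities - spectrum.intensities.mean()) / sd)


def normalize_reference(
    spectrum: Spectrum,
    reference_wavenumber: float = REFERENCE_WAVENUMBER,
    window: float = 4.0,
    min_shift: bool = True,
) -> Spectrum:
    """Scale so the reference band equals 1 (and, by default, the minimum is 0).

    The reference intensity is the maximum within ±``window`` cm^-1 of
    ``reference_wavenumber`` (tolerating small calibration jitter; ties break
    toward the lower wavenumber). ``min_shift=True`` first shifts the spectrum
    minimum to zero, which maps SNV output into a non-negative range.
    """
    wn = spectrum.wavenumbers
    if reference_wavenumber < wn[0] or reference_wavenumber > wn[-1]:
        raise ValueError(f"reference {reference_wavenumber} cm^-1 outside grid")
    y = spectrum.intensities
    if min_shift:
        y = y - y.min()
    mask = np.abs(wn - reference_wavenumber) <= window
    if not mask.any():
        raise ValueError("no grid point within the reference window")
    ref_val = y[mask].max()  # np.max of the slice; argmax ties go to lower wavenumber
    if ref_val <= 0:
        raise ValueError("reference intensity is non-positive after shifting")
    return spectrum.with_intensities(y / ref_val)


@dataclass
class PreprocessParams:
    """Tunable knobs of the preprocessing chain; defaults follow the
    plasma-screening protocol this package implements."""

    z_threshold: float = 8.0
    window_points: int = 45
    poly_order: int = 10
    baseline_degree: int = 9
    baseline_tol: float = 1e-4
    baseline_max_iter: int = 500
    reference_wavenumber: float = REFERENCE_WAVENUMBER
    reference_window: float = 4.0
    min_shift: bool = True
    smooth_before_baseline: bool = True
    enabled: tuple[str, ...] = ("despike", "smooth", "baseline", "snv", "normalize")


def preprocess_pipeline(
    replicates: list[Spectrum], params: PreprocessParams | None = None
) -> tuple[list[Spectrum], list[dict]]:
    """Run the full chain on one patient's replicate scans.

    Order: despike → smooth → baseline → SNV → reference normalization
    (smoothing before the baseline stabilizes the ModPoly fit; set
    ``smooth_before_baseline=False`` for the baseline-first order). Returns
    the processed scans and a per-stage provenance log.
    """
    params = params or PreprocessParams()
    log: list[dict] = []
    stages = list(params.enabled)
    if not params.smooth_before_baseline and "smooth" in stages and "baseline" in stages:
        i, j = stages.index("smooth"), stages.index("baseline")
        stages[i], stages[j] = stages[j], stages[i]

    out = replicates
    for stage in stages:
        if stage == "despike":
            out = remove_cosmic_rays(out, params.z_threshold)
            log.append({"stage": "despike", "z_threshold": params.z_threshold})
        elif stage == "smooth":
            out = [smooth(s, params.window_points, params.poly_order) for s in out]
            log.append(
                {"stage": "smooth", "window": params.window_points, "order": params.poly_order}
            )
        elif stage == "baseline":
            out = [
                correct_baseline(
                    s, params.baseline_degree, params.baseline_tol, params.baseline_max_iter
                )[0]
                for s in out
            ]
            log.append({"stage": "baseline", "degree": params.baseline_degree})
        elif stage == "snv":
            out = [snv(s) for s in out]
            log.append({"stage": "snv"})
        elif stage == "normalize":
            out = [
                normalize_reference(
                    s, params.reference_wavenumber, params.reference_window, params.min_shift
                )
                for s in out
            ]
            log.append({"stage": "normalize", "reference": params.reference_wavenumber})
        else:
            raise ValueError(f"unknown pipeline stage: {stage}")
    return out, log
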