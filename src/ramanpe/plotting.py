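"""Figure helpers for the pipeline's standard outputs.

Each function draws on a provided Axes (or creates one) and returns it, so
figures compose into multi-panel layouts the usual matplotlib way.
"""

from __future__ import annotations

import numpy as np

from .classify import EmbeddingResult, RocResult, auc_mann_whitney
from .clinical import CorrelationMatrix
from .spectra import Spectrum

COHORT_COLORS = {"healthy": "black", "preeclampsia": "#e75480"}


def _axes(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_spectrum(spectrum: Spectrum, ax=None, **kwargs):
    ax = _axes(ax)
    ax.plot(spectrum.wavenumbers, spectrum.intensities, lw=0.8, **kwargs)
    ax.set_xlabel("Raman shift (cm$^{-1}$)")
    ax.set_ylabel("Normalized intensity (a.u.)")
    return ax


def plot_difference_spectrum(diff: Spectrum, ax=None):
    """Signed cohort difference; positive lobes = higher in the second group."""
    ax = _axes(ax)
    ax.axhline(0.0, color="gray", lw=0.5)
    ax.plot(diff.wavenumbers, diff.intensities, color="#444444", lw=0.8)
    ax.set_xlabel("Raman shift (cm$^{-1}$)")
    ax.set_ylabel("Intensity difference (a.u.)")
    return ax


def plot_embedding(result: EmbeddingResult, cohorts: list[str], ax=None):
    ax = _axes(ax)
    coords = result.coordinates
    for cohort in sorted(set(cohorts)):
        mask = np.array([c == cohort for c in cohorts])
        ax.scatter(
            coords[mask, 0],
            coords[mask, 1],
            s=18,
            label=cohort,
            color=COHORT_COLORS.get(cohort),
        )
    ax.set_xlabel("tSNE 1")
    ax.set_ylabel("tSNE 2")
    ax.legend(frameon=False)
    return ax


def plot_roc(result: RocResult, ax=None):
    """Empirical ROC from the pooled out-of-fold scores."""
    ax = _axes(ax)
    order = np.argsort(-result.scores)
    labels = result.labels[order]
    tpr = np.concatenate([[0.0], np.cumsum(labels) / max(labels.sum(), 1)])
    fpr = np.concatenate([[0.0], np.cumsum(1 - labels) / max((1 - labels).sum(), 1)])
    ax.plot(fpr, tpr, color="#e75480", lw=1.2)
    ax.plot([0, 1], [0, 1], ls="--", color="gray", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("Sensitivity")
    ax.set_title(f"AUC = {result.auc:.3f} ({result.ci_low:.3f}-{result.ci_high:.3f})")
    return ax


def plot_correlation_heatmap(matrix: CorrelationMatrix, ax=None):
    ax = _axes(ax)
    im = ax.imshow(matrix.r.to_numpy(), cmap="RdBu_r", vmin=-1, vmax=1)
    ax.set_xticks(range(len(matrix.labels)), matrix.labels, rotation=90, fontsize=6)
    ax.set_yticks(range(len(matrix.labels)), matrix.labels, fontsize=6)
    ax.figure.colorbar(im, ax=ax, label="Pearson r")
    return ax
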