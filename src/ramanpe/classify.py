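"""Cohort embedding and classification.

t-SNE (exact algorithm, cosine distance, PCA pre-reduction) visualizes
patient-level band intensities; a class-weighted linear SVM under repeated
stratified Monte-Carlo cross-validation yields an AUC-ROC with a percentile
confidence interval. The AUC itself is the Mann-Whitney pair-ordering
statistic, computed from pooled out-of-fold decision scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC


@dataclass
class EmbeddingResult:
    patient_ids: list[str]
    coordinates: np.ndarray  # (n_patients, 2), centered at the origin
    settings: dict


@dataclass
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    repeat_aucs: np.ndarray
    scores: np.ndarray  # pooled out-of-fold decision scores
    labels: np.ndarray  # matching 0/1 labels
    n_repeats: int
    settings: dict = field(default_factory=dict)


def tsne_embed(
    feature_matrix: np.ndarray,
    patient_ids: list[str],
    perplexity: float = 11.0,
    n_pca: int = 10,
    exaggeration: float = 2.0,
    seed: int = 0,
) -> EmbeddingResult:
    """Exact t-SNE with cosine distance on PCA-reduced band intensities.

    Deterministic for a fixed seed. The exaggeration factor is applied during
    the early optimization phase. Warns when n_samples < 3 × perplexity, the
    usual rule of thumb for a stable embedding.
    """
    X = np.asarray(feature_matrix, dtype=float)
    n = X.shape[0]
    if perplexity >= n:
        raise ValueError(f"perplexity {perplexity} must be < n_samples {n}")
    if n < 3 * perplexity:
        warnings.warn(f"n_samples {n} < 3 × perplexity {perplexity}", stacklevel=2)
    n_comp = min(n_pca, n, X.shape[1])
    scores = PCA(n_components=n_comp, random_state=seed).fit_transform(X)
    coords = TSNE(
        n_components=2,
        perplexity=perplexity,
        early_exaggeration=exaggeration,
        metric="cosine",
        method="exact",
        init="pca" if n_comp >= 2 else "random",
        random_state=seed,
    ).fit_transform(scores)
    coords = coords - coords.mean(axis=0)
    return EmbeddingResult(
        patient_ids=list(patient_ids),
        coordinates=coords,
        settings={
            "perplexity": perplexity,
            "n_pca_components": n_comp,
            "exaggeration": exaggeration,
            "distance": "cosine",
            "seed": seed,
        },
    )


def auc_mann_whitney(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the fraction of (positive, negative) pairs ranked correctly,
    ties counted 1/2 — the Mann-Whitney U normalization."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(scores)  # midranks handle ties
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def svm_cv_auc(
    peak_matrix: np.ndarray,
    labels: np.ndarray,
    n_repeats: int = 50,
    train_frac: float = 2.0 / 3.0,
    seed: int = 0,
    kernel: str = "linear",
    ci_level: float = 0.95,
) -> RocResult:
    """Class-weighted SVM AUC under repeated stratified Monte-Carlo CV.

    Each repeat holds out ``1 − train_frac`` of patients (stratified by
    class), fits a linear-kernel SVM with balanced class weights on the rest,
    and scores the held-out patients. Pooled out-of-fold scores give the AUC;
    the CI is the percentile interval of per-repeat AUCs.
    """
    X = np.asarray(peak_matrix, dtype=float)
    y = np.asarray(labels).astype(int)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError("labels must contain exactly two classes")
    if counts.min() < 5:
        raise ValueError("need at least 5 patients per class")

    splitter = StratifiedShuffleSplit(
        n_splits=n_repeats, train_size=train_frac, random_state=seed
    )
    all_scores, all_labels, repeat_aucs = [], [], []
    for train, test in splitter.split(X, y):
        model = make_pipeline(
            StandardScaler(), SVC(kernel=kernel, class_weight="balanced", random_state=seed)
        )
        model.fit(X[train], y[train])
        s = model.decision_function(X[test])
        all_scores.append(s)
        all_labels.append(y[test])
        repeat_aucs.append(auc_mann_whitney(s, y[test]))

    scores = np.concatenate(all_scores)
    ys = np.concatenate(all_labels)
    auc = auc_mann_whitney(scores, ys)
    repeat_aucs = np.asarray(repeat_aucs)
    tail = (1.0 - ci_level) / 2.0 * 100.0
    ci_low = float(np.percentile(repeat_aucs, tail))
    ci_high = float(np.percentile(repeat_aucs, 100.0 - tail))
    return RocResult(
        auc=auc,
        ci_low=min(ci_low, auc),
        ci_high=max(ci_high, auc),
        repeat_aucs=repeat_aucs,
        scores=scores,
        labels=ys,
        n_repeats=n_repeats,
        settings={
            "kernel": kernel,
            "class_weight": "balanced",
            "train_frac": train_frac,
            "seed": seed,
            "ci_level": ci_level,
        },
    )


def peak_matrix_from_table(
    peak_table, wavenumbers: list[float], label_map: dict[str, int] | None = None
):
    """Pivot a long peak-intensity table into (matrix, labels, patient_ids)
    over the given bands (typically the significant primary peaks)."""
    wide = peak_table.pivot_table(
        index=["patient_id", "cohort"], columns="nominal_wavenumber", values="intensity"
    )
    cols = [w for w in wavenumbers if w in wide.columns]
    wide = wide[cols].dropna()
    patient_ids = [i[0] for i in wide.index]
    cohorts = [i[1] for i in wide.index]
    label_map = label_map or {"healthy": 0, "preeclampsia": 1}
    y = np.array([label_map[c] for c in cohorts])
    return wide.to_numpy(float), y, patient_ids
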