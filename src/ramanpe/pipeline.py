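"""End-to-end orchestration of the screening pipeline.

``run_all`` executes simulate → preprocess → quantify → stats → embed → roc
→ correlate → enrich → ratio on a seeded synthetic cohort (or user-supplied
scan files), writing every stage's outputs plus a manifest with parameters
and per-file checksums. All stage seeds derive from the single root seed via
``numpy.random.SeedSequence`` spawning, so a run is reproducible
byte-for-byte from its config.
"""

from __future__ import annotations

import hashlib
import json
import sys
from collections import defaultdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .biomarker import cohort_ratio_summary, lipid_trp_regression
from .classify import peak_matrix_from_table, svm_cv_auc, tsne_embed
from .clinical import correlate_to_severity, correlation_heatmap, encode_clinical
from .enrichment import enrichment_to_frame, load_pathway_map, map_peaks_to_compounds, ora_hypergeometric
from .preprocess import PreprocessParams, preprocess_pipeline
from .quantify import (
    average_patient,
    difference_spectrum,
    peak_table_from_spectra,
    results_to_frame,
    select_significant,
    t_test_all_peaks,
)
from .spectra import load_peak_table, scans_to_frame
from .synthetic import SyntheticConfig, generate_cohort

REQUIRED_KEYS = ("seed",)

#: per-trimester embedding defaults (perplexity, PCA components)
TSNE_DEFAULTS = {1: (11, 10), 2: (10, 6), 3: (18, 5)}


def validate_config(config: dict) -> dict:
    """Schema-check a pipeline config; unknown sections are rejected so typos
    fail loudly, and missing required keys are named."""
    allowed = {
        "seed",
        "synthetic",
        "preprocess",
        "stats",
        "embed",
        "roc",
        "correlate",
        "enrich",
        "ratio",
    }
    for key in REQUIRED_KEYS:
        if key not in config:
            raise KeyError(f"config missing required key: '{key}'")
    unknown = set(config) - allowed
    if unknown:
        raise KeyError(f"unknown config keys: {sorted(unknown)}")
    return config


def _child_seed(root: int, index: int) -> int:
    state = np.random.SeedSequence(root).generate_state(index + 1, dtype=np.uint32)
    return int(state[index]) % (2**31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: dict, outdir: str | Path) -> Path:
    """Run the whole pipeline per ``config`` into ``outdir``; returns outdir."""
    validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    peaks = load_peak_table()

    # --- simulate ---------------------------------------------------------
    syn_kwargs = dict(config.get("synthetic", {}))
    syn_kwargs.setdefault("seed", _child_seed(seed, 0))
    syn = SyntheticConfig(**syn_kwargs)
    dataset = generate_cohort(syn)
    (outdir / "synthetic").mkdir(exist_ok=True)
    dataset.write(outdir / "synthetic")

    # --- preprocess + average per patient ---------------------------------
    pp = PreprocessParams(**config.get("preprocess", {}))
    by_patient: dict[str, list] = defaultdict(list)
    for s in dataset.scans:
        by_patient[s.patient_id].append(s)
    patient_means = []
    for pid in sorted(by_patient):
        processed, _ = preprocess_pipeline(by_patient[pid], pp)
        patient_means.append(average_patient(processed))
    (outdir / "processed").mkdir(exist_ok=True)
    scans_to_frame(patient_means).to_csv(outdir / "processed" / "patient_means.csv", index=False)

    # --- quantify ----------------------------------------------------------
    stats_cfg = config.get("stats", {})
    window = float(stats_cfg.get("window", 4.0))
    alpha = float(stats_cfg.get("alpha", 0.05))
    peak_table = peak_table_from_spectra(patient_means, peaks, window=window)
    (outdir / "peaks").mkdir(exist_ok=True)
    peak_table.to_csv(outdir / "peaks" / "peak_table.csv", index=False)

    # --- per-trimester stats / embed / roc ---------------------------------
    encoded, encoding_info = encode_clinical(dataset.metadata)
    pathway_map = load_pathway_map()
    primary = {p.nominal_wavenumber for p in peaks if p.primary_peak and not p.is_generic}
    for sub in ("stats", "embed", "roc", "correlate", "enrich", "ratio"):
        (outdir / sub).mkdir(exist_ok=True)

    significant: dict[int, list[float]] = {}
    auc_summary = {}
    roc_cfg = config.get("roc", {})
    embed_cfg = config.get("embed", {})
    means_by_id = {s.patient_id: s for s in patient_means}
    for tri in sorted(peak_table["trimester"].unique()):
        tri = int(tri)
        tri_table = peak_table[peak_table["trimester"] == tri]
        results = t_test_all_peaks(tri_table)
        results_to_frame(results).to_csv(outdir / "stats" / f"tests_t{tri}.csv", index=False)
        sig = select_significant(results, alpha=alpha)
        significant[tri] = sig

        # cohort difference spectrum (preeclampsia − healthy)
        tri_means = [s for s in patient_means if s.trimester == tri]
        h = [s for s in tri_means if s.cohort == "healthy"]
        p = [s for s in tri_means if s.cohort == "preeclampsia"]
        if h and p:
            diff = difference_spectrum(average_patient(h), average_patient(p))
            pd.DataFrame(
                {"wavenumber_cm1": diff.wavenumbers, "difference": diff.intensities}
            ).to_csv(outdir / "stats" / f"difference_t{tri}.csv", index=False)

        features = [w for w in sig if w in primary]
        if len(features) < 2:  # too few discriminative bands: embed on all primaries
            features = sorted(primary)
        X, y, pids = peak_matrix_from_table(tri_table, features)
        perp_default, pca_default = TSNE_DEFAULTS.get(tri, (10, 5))
        perplexity = float(embed_cfg.get("perplexity", perp_default))
        perplexity = min(perplexity, (len(pids) - 1) / 3.0)  # keep small runs valid
        emb = tsne_embed(
            X,
            pids,
            perplexity=max(perplexity, 2.0),
            n_pca=int(embed_cfg.get("n_pca", pca_default)),
            exaggeration=float(embed_cfg.get("exaggeration", 2.0)),
            seed=_child_seed(seed, 1) + tri,
        )
        pd.DataFrame(
            {
                "patient_id": emb.patient_ids,
                "tsne1": emb.coordinates[:, 0],
                "tsne2": emb.coordinates[:, 1],
            }
        ).to_csv(outdir / "embed" / f"coords_t{tri}.csv", index=False)

        roc = svm_cv_auc(
            X,
            y,
            n_repeats=int(roc_cfg.get("n_repeats", 50)),
            seed=_child_seed(seed, 2) + tri,
        )
        auc_summary[tri] = {"auc": roc.auc, "ci_low": roc.ci_low, "ci_high": roc.ci_high}
        with open(outdir / "roc" / f"roc_t{tri}.json", "w") as fh:
            json.dump(
                {
                    "auc": roc.auc,
                    "ci_low": roc.ci_low,
                    "ci_high": roc.ci_high,
                    "n_repeats": roc.n_repeats,
                    "repeat_aucs": roc.repeat_aucs.tolist(),
                    "settings": roc.settings,
                },
                fh,
                indent=2,
                sort_keys=True,
            )

        # correlation: severity always reported; heatmap includes severity
        # only in the third trimester (diagnosis exists by then)
        tri_encoded = encoded[encoded["trimester"] == tri]
        sev = correlate_to_severity(tri_table, tri_encoded, wavenumbers=sig or None)
        sev.to_csv(outdir / "correlate" / f"severity_t{tri}.csv", index=False)
        heat = correlation_heatmap(
            tri_table, tri_encoded, wavenumbers=sig or None, include_severity=(tri == 3)
        )
        heat.r.to_csv(outdir / "correlate" / f"heatmap_t{tri}.csv")

        compounds = map_peaks_to_compounds(sig, peaks)
        enr = ora_hypergeometric(compounds, pathway_map)
        enrichment_to_frame(enr).to_csv(outdir / "enrich" / f"enrichment_t{tri}.csv", index=False)

    with open(outdir / "stats" / "significant.json", "w") as fh:
        json.dump({str(k): v for k, v in significant.items()}, fh, indent=2, sort_keys=True)

    # --- biomarker ratio ----------------------------------------------------
    reg = lipid_trp_regression(peak_table, dataset.elisa)
    reg.points.to_csv(outdir / "ratio" / "cells.csv", index=False)
    summary = cohort_ratio_summary(dataset.elisa)
    summary.to_csv(outdir / "ratio" / "cohort_ratios.csv", index=False)
    with open(outdir / "ratio" / "regression.json", "w") as fh:
        json.dump(
            {"slope": reg.slope, "intercept": reg.intercept, "r_squared": reg.r_squared},
            fh,
            indent=2,
            sort_keys=True,
        )

    # --- manifest -----------------------------------------------------------
    checksums = {
        str(p.relative_to(outdir)): _sha256(p)
        for p in sorted(outdir.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = {
        "seed": seed,
        "config": _jsonable(config),
        "encoding": encoding_info,
        "auc": auc_summary,
        "significant_counts": {str(k): len(v) for k, v in significant.items()},
        "versions": {
            "ramanpe": __version__,
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "checksums": checksums,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return outdir


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
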