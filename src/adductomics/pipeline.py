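"""Orchestration of the discovery pipeline: preprocess -> PCA arm -> forest
arm -> intersection -> hydrolysis pairs -> site distribution, with recovery
metrics against a planted truth when one is available.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import GroundTruth, IntensityMatrix
from .selection import (
    GiniImportanceSelector,
    PCALoadingSelector,
    PreprocessConfig,
    SelectConfig,
    intersect_biomarkers,
    preprocess,
)
from .stats import find_hydrolysis_pairs, site_distribution

__all__ = ["discover_biomarkers", "stage_seed", "write_report"]


def stage_seed(global_seed: int, stage: int) -> int:
    """Deterministic per-stage seed fan-out from one global seed (< 2^31)."""
    return (global_seed * 10007 + stage) % (2**31 - 1)


def discover_biomarkers(
    matrix: IntensityMatrix,
    truth: GroundTruth | None = None,
    select_cfg: SelectConfig | None = None,
    pre_cfg: PreprocessConfig | None = None,
) -> dict:
    """Run the two-arm biomarker selection on one cohort.

    Exposed-vs-control labels come from the sample metadata (agent !=
    "control").  Returns a report dict with the selected sets, per-fold
    forest accuracies, PCA variance fractions, the hydrolysis-pair table,
    the site-distribution table, and -- when ``truth`` is given -- recall
    and precision of the intersection against the planted features that
    carry the configured adduct chains.
    """
    select_cfg = select_cfg or SelectConfig()
    X = preprocess(matrix, pre_cfg)
    y = (matrix.samples["agent"] != "control").astype(int).to_numpy()
    if y.min() == y.max():
        raise ValueError("cohort must contain exposed and control samples")

    feature_adducts = matrix.features["adduct"].astype(str).to_dict()
    pca_arm = PCALoadingSelector(
        threshold=select_cfg.pc_loading_threshold,
        threshold_side=select_cfg.threshold_side,
        adducts=select_cfg.adducts,
        feature_adducts=feature_adducts,
    ).fit(X, y)
    rf_arm = GiniImportanceSelector(
        n_folds=select_cfg.n_folds,
        n_trees=select_cfg.n_trees,
        max_features=select_cfg.max_features,
        random_state=select_cfg.seed,
    ).fit(X, y)

    pca_set = pca_arm.selected_features()
    rf_set = rf_arm.selected_features()
    biomarkers = intersect_biomarkers(pca_set, rf_set)

    selected_features = matrix.features.loc[sorted(biomarkers)]
    pairs = find_hydrolysis_pairs(matrix.features)
    sites = site_distribution(selected_features) if biomarkers else pd.DataFrame()

    report = {
        "config": asdict(select_cfg),
        "n_samples": int(matrix.values.shape[0]),
        "n_features": int(matrix.values.shape[1]),
        "n_features_preprocessed": int(X.shape[1]),
        "pca_variance_ratio": [float(v) for v in pca_arm.variance_ratio_[:5]],
        "fold_accuracies": rf_arm.fold_accuracies_,
        "pca_set": sorted(pca_set),
        "rf_set_size": len(rf_set),
        "biomarkers": sorted(biomarkers),
        "n_biomarkers": len(biomarkers),
        "hydrolysis_pairs": pairs.to_dict("records"),
        "n_hydrolysis_pairs": int(len(pairs)),
        "site_distribution": sites.to_dict() if not sites.empty else {},
    }
    if truth is not None:
        true_set = {
            fid
            for fid in truth.features.index
            if truth.features.loc[fid, "adduct"] in select_cfg.adducts
        }
        tp = len(biomarkers & true_set)
        report["metrics"] = {
            "n_true": len(true_set),
            "recall": tp / len(true_set) if true_set else float("nan"),
            "precision": tp / len(biomarkers) if biomarkers else float("nan"),
        }
    return report


def write_report(report: dict, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    path.write_text(json.dumps(report, indent=2, default=_default) + "\n")
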