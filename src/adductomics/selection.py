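"""Biomarker selection: preprocessing, PCA-loading and forest-importance
feature selection, and their intersection.

The selection logic follows the two-arm strategy used for adduct biomarker
discovery: (1) PCA on the z-scored intensity matrix with PC1 oriented so
the control group scores positive, selecting modified peptides whose PC1
loading is more negative than a threshold (exposure-driven features point
against PC1); (2) a cross-validated random-forest classifier of exposed vs
control, selecting features with non-zero mean-decrease-Gini importance
averaged over folds.  Biomarkers are the intersection of the two sets.

The estimators are scikit-learn compatible (``fit``/``transform``/
``get_support``); the module-level functions are thin wrappers over them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import SelectorMixin
from sklearn.model_selection import StratifiedKFold

from .cohort import IntensityMatrix

__all__ = [
    "PreprocessConfig",
    "SelectConfig",
    "SelectionResult",
    "CohortPreprocessor",
    "PCALoadingSelector",
    "GiniImportanceSelector",
    "preprocess",
    "run_pca",
    "pca_select",
    "rf_select",
    "intersect_biomarkers",
]


@dataclass(frozen=True)
class PreprocessConfig:
    log_base: float = 2.0
    impute: str = "halfmin"  # half the per-feature observed minimum
    scale: bool = True  # per-feature z-score

    def __post_init__(self):
        if self.impute not in ("halfmin", "none"):
            raise ValueError("impute must be 'halfmin' or 'none'")


@dataclass(frozen=True)
class SelectConfig:
    """Knobs of the two selection arms.

    ``pc_loading_threshold`` is the magnitude cutoff on the
    exposure-pointing (negative) side of PC1; ``threshold_side`` may be set
    to ``"both"`` to select on |loading| instead.  ``adducts`` filters the
    PCA arm to features carrying those chains (HETETE by default).  The
    forest uses ``n_folds``-fold stratified CV with ``n_trees`` trees and
    sqrt(p) features per split; importance is Gini impurity decrease
    averaged over folds, selection keeps strictly positive importance.
    """

    pc_loading_threshold: float = 0.01
    threshold_side: str = "negative"  # or "both"
    adducts: tuple = ("HETETE",)
    n_folds: int = 5
    n_trees: int = 500
    max_features: str = "sqrt"
    seed: int = 0

    def __post_init__(self):
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.pc_loading_threshold <= 0:
            raise ValueError("pc_loading_threshold must be > 0")
        if self.threshold_side not in ("negative", "both"):
            raise ValueError("threshold_side must be 'negative' or 'both'")


@dataclass
class SelectionResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame
    variance_ratio: np.ndarray
    importances: pd.Series
    fold_accuracies: list
    pca_set: set
    rf_set: set
    biomarkers: set = field(default_factory=set)


class CohortPreprocessor(BaseEstimator, TransformerMixin):
    """log2 -> half-minimum imputation -> per-feature z-score.

    Missing values (NaN, below-LOD) are imputed with half the per-feature
    observed minimum on the raw scale prior to the log transform.  Features
    that are all-missing or constant after imputation are dropped with a
    warning.  Input may be raw-scale or already-log2 intensities
    (``values_are_log`` switches the impute arithmetic accordingly).
    """

    def __init__(self, config: PreprocessConfig | None = None, values_are_log: bool = True):
        self.config = config
        self.values_are_log = values_are_log

    def _as_frame(self, X) -> pd.DataFrame:
        if isinstance(X, IntensityMatrix):
            return X.values
        if isinstance(X, pd.DataFrame):
            return X
        return pd.DataFrame(np.asarray(X, dtype=float))

    def fit(self, X, y=None):
        cfg = self.config or PreprocessConfig()
        df = self._as_frame(X)
        if df.shape[0] < 2:
            raise ValueError("need at least 2 samples")
        log = np.log2 if not self.values_are_log else (lambda v: v)
        with np.errstate(divide="ignore", invalid="ignore"):
            logged = pd.DataFrame(
                log(df.to_numpy(dtype=float)), index=df.index, columns=df.columns
            )
        # half the observed minimum: -1 on the log2 scale
        fill = logged.min(axis=0) - np.log2(2.0) / np.log2(cfg.log_base)
        all_missing = logged.isna().all(axis=0)
        if cfg.impute == "halfmin":
            imputed = logged.fillna(fill)
        else:
            imputed = logged
        sd = imputed.std(axis=0, ddof=0)
        constant = (sd == 0) | sd.isna()
        drop = all_missing | constant
        if drop.any():
            warnings.warn(
                f"dropping {int(drop.sum())} all-missing or constant features",
                stacklevel=2,
            )
        self.feature_names_in_ = np.asarray(df.columns, dtype=object)
        self.keep_mask_ = ~drop.to_numpy()
        self.impute_values_ = fill[~drop]
        self.center_ = imputed.loc[:, ~drop].mean(axis=0)
        self.scale_ = sd[~drop] if cfg.scale else pd.Series(1.0, index=self.center_.index)
        self.n_features_in_ = df.shape[1]
        return self

    def transform(self, X) -> pd.DataFrame:
        cfg = self.config or PreprocessConfig()
        df = self._as_frame(X)
        log = np.log2 if not self.values_are_log else (lambda v: v)
        with np.errstate(divide="ignore", invalid="ignore"):
            logged = pd.DataFrame(
                log(df.to_numpy(dtype=float)), index=df.index, columns=df.columns
            )
        kept = logged.loc[:, self.keep_mask_]
        if cfg.impute == "halfmin":
            kept = kept.fillna(self.impute_values_)
        return (kept - self.center_) / self.scale_


def preprocess(
    matrix: IntensityMatrix | pd.DataFrame,
    config: PreprocessConfig | None = None,
    values_are_log: bool = True,
) -> pd.DataFrame:
    """Fit-and-transform convenience wrapper over :class:`CohortPreprocessor`."""
    return CohortPreprocessor(config, values_are_log).fit_transform(matrix)


def run_pca(
    X: pd.DataFrame, control_mask: np.ndarray | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """PCA by SVD of the column-centered matrix.

    Returns (scores, loadings, variance fractions).  Loadings columns are
    orthonormal; variance fractions are non-increasing and sum to <= 1.
    When ``control_mask`` is given, PC1's sign is fixed so the mean control
    score is positive, making exposure-driven loadings negative.
    """
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 samples and 2 features")
    A = X.to_numpy(dtype=float)
    A = A - A.mean(axis=0, keepdims=True)
    if not np.any(A):
        raise ValueError("matrix has rank 0 after centering")
    U, s, Vt = np.linalg.svd(A, full_matrices=False)
    scores = U * s
    loadings = Vt.T
    if control_mask is not None:
        control_mask = np.asarray(control_mask, dtype=bool)
        if control_mask.any() and scores[control_mask, 0].mean() < 0:
            scores[:, 0] *= -1
            loadings[:, 0] *= -1
    var = s**2
    var_frac = var / max(var.sum(), np.finfo(float).tiny)
    k = len(s)
    pcs = [f"PC{i + 1}" for i in range(k)]
    return (
        pd.DataFrame(scores, index=X.index, columns=pcs),
        pd.DataFrame(loadings, index=X.columns, columns=pcs),
        var_frac,
    )


class PCALoadingSelector(SelectorMixin, BaseEstimator):
    """Select modified features by their PC1 loading.

    ``fit(X, y)`` takes the preprocessed matrix and binary labels (1 =
    exposed, 0 = control; the control group orients PC1 positive).
    ``feature_adducts`` maps feature name -> adduct chain ("" for
    unmodified background); only features whose chain is in ``adducts``
    and whose PC1 loading passes the threshold are kept.
    """

    def __init__(
        self,
        threshold: float = 0.01,
        threshold_side: str = "negative",
        adducts: tuple = ("HETETE",),
        feature_adducts: dict | None = None,
    ):
        self.threshold = threshold
        self.threshold_side = threshold_side
        self.adducts = adducts
        self.feature_adducts = feature_adducts

    def fit(self, X, y=None):
        X = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X))
        control_mask = None
        if y is not None:
            y = np.asarray(y)
            control_mask = y == 0
        scores, loadings, var = run_pca(X, control_mask)
        self.scores_ = scores
        self.loadings_ = loadings
        self.variance_ratio_ = var
        pc1 = loadings["PC1"]
        if self.threshold_side == "both":
            passes = pc1.abs() > self.threshold
        else:
            passes = pc1 < -self.threshold
        if self.feature_adducts is not None:
            mod_ok = pd.Series(
                [self.feature_adducts.get(f, "") in self.adducts for f in X.columns],
                index=X.columns,
            )
        else:
            mod_ok = pd.Series(True, index=X.columns)
        self.support_mask_ = (passes & mod_ok).to_numpy()
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]
        return self

    def _get_support_mask(self):
        return self.support_mask_

    def selected_features(self) -> set:
        return set(self.feature_names_in_[self.support_mask_])


class GiniImportanceSelector(SelectorMixin, BaseEstimator):
    """Cross-validated random-forest importance selection.

    Stratified ``n_folds``-fold split; one Gini-criterion forest fit per
    fold on the training portion; per-feature importance is the mean
    decrease in Gini impurity averaged across folds.  Selected features
    have strictly positive mean importance.  Held-out accuracy per fold is
    recorded in ``fold_accuracies_``.
    """

    def __init__(
        self,
        n_folds: int = 5,
        n_trees: int = 500,
        max_features: str = "sqrt",
        random_state: int = 0,
    ):
        self.n_folds = n_folds
        self.n_trees = n_trees
        self.max_features = max_features
        self.random_state = random_state

    def fit(self, X, y):
        Xdf = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X))
        y = np.asarray(y)
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("labels contain a single class")
        A = Xdf.to_numpy(dtype=float)
        skf = StratifiedKFold(
            n_splits=self.n_folds, shuffle=True, random_state=self.random_state
        )
        imp = np.zeros(A.shape[1])
        accs = []
        for fold, (tr, te) in enumerate(skf.split(A, y)):
            rf = RandomForestClassifier(
                n_estimators=self.n_trees,
                criterion="gini",
                max_features=self.max_features,
                random_state=self.random_state + fold,
                n_jobs=1,
            )
            rf.fit(A[tr], y[tr])
            imp += rf.feature_importances_
            accs.append(float(rf.score(A[te], y[te])))
        imp /= self.n_folds
        self.importances_ = pd.Series(imp, index=Xdf.columns)
        self.fold_accuracies_ = accs
        self.support_mask_ = imp > 0
        self.feature_names_in_ = np.asarray(Xdf.columns, dtype=object)
        self.n_features_in_ = Xdf.shape[1]
        return self

    def _get_support_mask(self):
        return self.support_mask_

    def selected_features(self) -> set:
        return set(self.feature_names_in_[self.support_mask_])


def pca_select(
    loadings: pd.DataFrame,
    feature_adducts: dict,
    cfg: SelectConfig | None = None,
) -> set:
    """Apply the loading-threshold + modification filter to fitted loadings."""
    cfg = cfg or SelectConfig()
    pc1 = loadings["PC1"]
    if cfg.threshold_side == "both":
        passes = pc1.abs() > cfg.pc_loading_threshold
    else:
        passes = pc1 < -cfg.pc_loading_threshold
    return {
        f
        for f in loadings.index[passes]
        if feature_adducts.get(f, "") in cfg.adducts
    }


def rf_select(
    X: pd.DataFrame, y, cfg: SelectConfig | None = None
) -> tuple[pd.Series, set, list]:
    """Functional wrapper over :class:`GiniImportanceSelector`."""
    cfg = cfg or SelectConfig()
    sel = GiniImportanceSelector(
        n_folds=cfg.n_folds,
        n_trees=cfg.n_trees,
        max_features=cfg.max_features,
        random_state=cfg.seed,
    ).fit(X, y)
    return sel.importances_, sel.selected_features(), sel.fold_accuracies_


def intersect_biomarkers(pca_set: set, rf_set: set) -> set:
    """The biomarker panel: features both arms agree on."""
    return set(pca_set) & set(rf_set)
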