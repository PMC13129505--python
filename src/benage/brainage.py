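"""Brain-age prediction from BEN features with linear SVR.

The model is trained on healthy controls only, under leave-one-out
cross-validation (LOOCV): for each held-out control the training fold is

1. screened by partial Pearson correlation of each feature with biological
   age, controlling for demographic covariates (sex, education); features
   with |r| > 0.1 survive;
2. z-scored using training-fold statistics;
3. fit with a linear support vector regression whose regularization
   parameter C is selected over {1, 10, 100, 1000} by inner k-fold
   cross-validation (lowest inner RMSE; ties broken by higher inner
   correlation, then smaller C).

Screening and standardization are recomputed inside every training fold so
no information from the held-out subject leaks into model selection. A
non-nested replication mode (one global screen, C picked once on all
controls) is available for comparison with pipelines that screen globally.

The brain-age gap (BAG) is predicted age minus biological age; a trained
model applied to the patient group yields per-subject BAGs whose elevation
over controls quantifies accelerated brain aging.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.model_selection import KFold
from sklearn.svm import SVR

from .entropy import BENFeatureMatrix

logger = logging.getLogger(__name__)


class BrainAgeError(ValueError):
    """Invalid input to a brain-age operation."""


@dataclass
class ScreenParams:
    """Feature-screening parameters.

    Features whose partial correlation with age (controlling for
    ``covariates``) exceeds ``r_threshold`` in absolute value are kept.
    The 0.1 default is deliberately permissive — under the null at n ~ 49
    roughly half of pure-noise features survive it; the SVR is expected to
    do the real shrinkage.
    """

    r_threshold: float = 0.1
    covariates: tuple[str, ...] = ("sex", "education")

    def __post_init__(self):
        if not 0 <= self.r_threshold < 1:
            raise BrainAgeError("r_threshold must lie in [0, 1)")


@dataclass
class SVRConfig:
    """Linear-SVR and model-selection configuration."""

    c_grid: tuple[float, ...] = (1.0, 10.0, 100.0, 1000.0)
    epsilon: float = 0.1
    standardize: bool = True
    inner_cv_folds: int = 5
    seed: int = 0

    def __post_init__(self):
        if not self.c_grid or any(c <= 0 for c in self.c_grid):
            raise BrainAgeError("c_grid must be nonempty with positive entries")


@dataclass
class FoldInfo:
    held_out: str
    selected_c: float
    n_features: int
    inner_rmse: float


@dataclass
class BrainAgeResult:
    """Per-subject predictions and summary metrics for one feature set.

    ``table`` has columns subject_id, group, age, predicted, bag
    (bag = predicted - age). ``r`` is the Pearson correlation between
    predicted and biological age, ``rmse`` in years.
    """

    feature_set: str
    table: pd.DataFrame
    r: float
    r_p: float
    rmse: float
    mean_bag: float
    folds: list[FoldInfo] = field(default_factory=list)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def compute_bag(predicted: np.ndarray, biological: np.ndarray) -> np.ndarray:
    """Brain-age gap in years: predicted minus biological age."""
    predicted = np.asarray(predicted, dtype=float)
    biological = np.asarray(biological, dtype=float)
    if not (np.isfinite(predicted).all() and np.isfinite(biological).all()):
        raise BrainAgeError("ages must be finite")
    return predicted - biological


def _encode_covariates(meta: pd.DataFrame, covariates) -> np.ndarray:
    """Numeric covariate design matrix with intercept (n, k+1)."""
    cols = [np.ones(len(meta))]
    for c in covariates:
        v = meta[c]
        if v.dtype == object or str(v.dtype) == "category":
            v = pd.factorize(v)[0]
        cols.append(np.asarray(v, dtype=float))
    return np.column_stack(cols)


def partial_corr_screen(
    X: pd.DataFrame, meta: pd.DataFrame, params: ScreenParams | None = None
) -> list[str]:
    """Columns of X whose age partial correlation passes the threshold.

    Each feature and age are residualized on the covariates by linear least
    squares; the Pearson correlation of the residuals is the partial r.
    Constant features get r = 0 (excluded) and are logged.
    """
    params = params or ScreenParams()
    if len(X) < len(params.covariates) + 3:
        raise BrainAgeError("too few subjects for partial correlation")
    Z = _encode_covariates(meta, params.covariates)
    age = np.asarray(meta["age"], dtype=float)
    proj = Z @ np.linalg.lstsq(Z, np.column_stack([age, X.to_numpy()]), rcond=None)[0]
    resid = np.column_stack([age, X.to_numpy()]) - proj
    age_r, feat_r = resid[:, 0], resid[:, 1:]
    sd = feat_r.std(axis=0)
    age_sd = age_r.std()
    # a constant column residualizes to numerical dust, not exact zeros
    degenerate = (X.to_numpy().std(axis=0) == 0) | (
        sd <= 1e-10 * np.abs(X.to_numpy()).max(axis=0, initial=1.0)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (feat_r * age_r[:, None]).mean(axis=0) / (sd * age_sd)
    r = np.where(degenerate, 0.0, r)
    if degenerate.any():
        logger.info(
            "screen: %d constant features set to r=0", int(degenerate.sum())
        )
    keep = np.abs(r) > params.r_threshold
    return [c for c, k in zip(X.columns, keep) if k]


def _fit_svr(Xtr, ytr, c, epsilon):
    model = SVR(kernel="linear", C=c, epsilon=epsilon)
    model.fit(Xtr, ytr)
    return model


def _standardize(Xtr: np.ndarray, *others: np.ndarray):
    mu = Xtr.mean(axis=0)
    sd = Xtr.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return tuple((x - mu) / sd for x in (Xtr, *others))


def _select_c(
    X: np.ndarray, y: np.ndarray, svr: SVRConfig
) -> tuple[float, float]:
    """Pick C by inner k-fold CV: min pooled RMSE, ties -> max r -> min C."""
    n = len(y)
    k = min(svr.inner_cv_folds, n)
    cv = KFold(n_splits=k, shuffle=True, random_state=svr.seed)
    best = None
    for c in svr.c_grid:
        pred = np.empty(n)
        for tr, te in cv.split(X):
            Xtr, Xte = X[tr], X[te]
            if svr.standardize:
                Xtr, Xte = _standardize(Xtr, Xte)
            pred[te] = _fit_svr(Xtr, y[tr], c, svr.epsilon).predict(Xte)
        rmse = float(np.sqrt(np.mean((pred - y) ** 2)))
        r = float(np.corrcoef(pred, y)[0, 1]) if np.std(pred) > 0 else 0.0
        key = (round(rmse, 12), -round(r, 12), c)
        if best is None or key < best[0]:
            best = (key, c, rmse)
    return best[1], best[2]


def _screened_matrix(
    features: BENFeatureMatrix | pd.DataFrame, feature_set: str | None
) -> pd.DataFrame:
    if isinstance(features, BENFeatureMatrix):
        cols = (
            features.set_columns(feature_set) if feature_set else features.feature_names
        )
        return features.values[cols]
    return features


def loocv_predict(
    features: BENFeatureMatrix | pd.DataFrame,
    meta: pd.DataFrame,
    svr: SVRConfig | None = None,
    screen: ScreenParams | None = None,
    feature_set: str | None = None,
    nested_screen: bool = True,
) -> BrainAgeResult:
    """LOOCV brain-age prediction within the HC group.

    ``meta`` must contain subject_id, age, group and the screening
    covariates; only rows with group == "HC" are used. With
    ``nested_screen=False`` the screen is computed once on all controls
    (replicating one-shot global screening) instead of per fold.
    """
    svr = svr or SVRConfig()
    screen = screen or ScreenParams()
    meta = meta.set_index("subject_id") if "subject_id" in meta.columns else meta
    hc = meta[meta["group"] == "HC"]
    if len(hc) < 10:
        raise BrainAgeError("need at least 10 HC subjects for LOOCV")
    X_all = _screened_matrix(features, feature_set).loc[hc.index]
    y = hc["age"].to_numpy(dtype=float)

    global_cols = None
    if not nested_screen:
        global_cols = partial_corr_screen(X_all, hc, screen) or list(X_all.columns)

    n = len(hc)
    pred = np.empty(n)
    folds: list[FoldInfo] = []
    for i in range(n):
        tr = np.arange(n) != i
        Xtr_df, meta_tr = X_all.iloc[tr], hc.iloc[tr]
        if nested_screen:
            cols = partial_corr_screen(Xtr_df, meta_tr, screen)
            if not cols:
                logger.warning(
                    "fold %s: empty screen, falling back to all features",
                    hc.index[i],
                )
                cols = list(X_all.columns)
        else:
            cols = global_cols
        Xtr = Xtr_df[cols].to_numpy(dtype=float)
        Xte = X_all.iloc[[i]][cols].to_numpy(dtype=float)
        c, inner_rmse = _select_c(Xtr, y[tr], svr)
        if svr.standardize:
            Xtr_s, Xte_s = _standardize(Xtr, Xte)
        else:
            Xtr_s, Xte_s = Xtr, Xte
        model = _fit_svr(Xtr_s, y[tr], c, svr.epsilon)
        pred[i] = model.predict(Xte_s)[0]
        folds.append(FoldInfo(hc.index[i], c, len(cols), inner_rmse))

    bag = compute_bag(pred, y)
    table = pd.DataFrame(
        {
            "subject_id": hc.index,
            "group": "HC",
            "age": y,
            "predicted": pred,
            "bag": bag,
        }
    )
    if np.std(pred) > 0:
        r, r_p = sps.pearsonr(pred, y)
    else:
        r, r_p = float("nan"), float("nan")
        logger.warning("constant predictions; correlation undefined")
    return BrainAgeResult(
        feature_set=feature_set or "(all columns)",
        table=table,
        r=float(r),
        r_p=float(r_p),
        rmse=float(np.sqrt(np.mean((pred - y) ** 2))),
        mean_bag=float(bag.mean()),
        folds=folds,
    )


def apply_model(
    features: BENFeatureMatrix | pd.DataFrame,
    meta: pd.DataFrame,
    trained: BrainAgeResult,
    svr: SVRConfig | None = None,
    screen: ScreenParams | None = None,
    feature_set: str | None = None,
    test_group: str = "MDD",
    mode: str = "refit",
) -> BrainAgeResult:
    """Apply the HC-trained model to a test group (patients or held-out HC).

    ``mode="refit"`` (default): refit one final model on ALL controls —
    screen on all HC, C = modal selected C across LOOCV folds (ties to the
    smaller C) — and predict each test subject once.
    ``mode="ensemble"``: apply every per-fold model and average the fold
    predictions per test subject.
    """
    svr = svr or SVRConfig()
    screen = screen or ScreenParams()
    meta = meta.set_index("subject_id") if "subject_id" in meta.columns else meta
    hc = meta[meta["group"] == "HC"]
    test = meta[meta["group"] == test_group]
    if test.empty:
        raise BrainAgeError(f"no subjects in test group {test_group!r}")
    X = _screened_matrix(features, feature_set)
    missing = [s for s in test.index if s not in X.index]
    if missing:
        raise BrainAgeError(f"test subjects missing from features: {missing}")
    X_hc, X_te = X.loc[hc.index], X.loc[test.index]
    y_hc = hc["age"].to_numpy(dtype=float)
    y_te = test["age"].to_numpy(dtype=float)

    counts = Counter(f.selected_c for f in trained.folds)
    top = max(counts.values())
    modal_c = min(c for c, k in counts.items() if k == top)

    if mode == "refit":
        cols = partial_corr_screen(X_hc, hc, screen) or list(X.columns)
        Xtr = X_hc[cols].to_numpy(dtype=float)
        Xte = X_te[cols].to_numpy(dtype=float)
        if svr.standardize:
            Xtr, Xte = _standardize(Xtr, Xte)
        pred = _fit_svr(Xtr, y_hc, modal_c, svr.epsilon).predict(Xte)
        folds = [FoldInfo("(refit-all-HC)", modal_c, len(cols), float("nan"))]
    elif mode == "ensemble":
        n = len(hc)
        preds = np.zeros((n, len(test)))
        for i, f in enumerate(trained.folds):
            tr = np.arange(n) != i
            cols = partial_corr_screen(X_hc.iloc[tr], hc.iloc[tr], screen) or list(
                X.columns
            )
            Xtr = X_hc.iloc[tr][cols].to_numpy(dtype=float)
            Xte = X_te[cols].to_numpy(dtype=float)
            if svr.standardize:
                Xtr, Xte = _standardize(Xtr, Xte)
            preds[i] = _fit_svr(Xtr, y_hc[tr], f.selected_c, svr.epsilon).predict(Xte)
        pred = preds.mean(axis=0)
        folds = list(trained.folds)
    else:
        raise BrainAgeError(f"unknown mode {mode!r}")

    bag = compute_bag(pred, y_te)
    table = pd.DataFrame(
        {
            "subject_id": test.index,
            "group": test_group,
            "age": y_te,
            "predicted": pred,
            "bag": bag,
        }
    )
    if np.std(pred) > 0 and np.std(y_te) > 0:
        r, r_p = sps.pearsonr(pred, y_te)
    else:
        r, r_p = float("nan"), float("nan")
    return BrainAgeResult(
        feature_set=trained.feature_set,
        table=table,
        r=float(r),
        r_p=float(r_p),
        rmse=float(np.sqrt(np.mean((pred - y_te) ** 2))),
        mean_bag=float(bag.mean()),
        folds=folds,
    )
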