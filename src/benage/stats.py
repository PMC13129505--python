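"""Group-difference and discrimination statistics.

Pooled two-sample t-tests (from raw samples or from printed summary
statistics), Benjamini-Hochberg FDR adjustment, channel-wise Pearson age
correlations, the 2x2 chi-square, and ROC/AUC evaluation of single features
and linear feature combinations.

The pooled (equal-variance) t form is used throughout because it is the
form that reproduces published group-comparison tables from their printed
(mean, SD, n) summaries; the chi-square is Pearson's, without continuity
correction, for the same reason.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_predict
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


class StatsError(ValueError):
    """Invalid input to a statistical operation."""


@dataclass
class SummaryStats:
    """Printed-table group summary: mean, sample SD, n."""

    mean: float
    sd: float
    n: int

    def __post_init__(self):
        if self.n < 2:
            raise StatsError("need n >= 2")
        if self.sd < 0:
            raise StatsError("sd must be nonnegative")

    @classmethod
    def of(cls, x) -> "SummaryStats":
        x = np.asarray(x, dtype=float)
        return cls(mean=float(x.mean()), sd=float(x.std(ddof=1)), n=len(x))


def t_from_summary(g1: SummaryStats, g2: SummaryStats) -> tuple[float, int, float]:
    """Pooled-variance two-sample t-test from (mean, SD, n) summaries.

    sp^2 = [(n1-1) s1^2 + (n2-1) s2^2] / (n1+n2-2),
    t = (m1 - m2) / (sp * sqrt(1/n1 + 1/n2)), df = n1+n2-2, two-sided p.
    A zero pooled SD yields t = 0 for equal means and signed infinity
    otherwise.
    """
    df = g1.n + g2.n - 2
    sp2 = ((g1.n - 1) * g1.sd**2 + (g2.n - 1) * g2.sd**2) / df
    diff = g1.mean - g2.mean
    if sp2 == 0:
        if diff == 0:
            return 0.0, df, 1.0
        return float(np.sign(diff) * np.inf), df, 0.0
    t = diff / np.sqrt(sp2 * (1 / g1.n + 1 / g2.n))
    p = 2 * sps.t.sf(abs(t), df)
    return float(t), df, float(p)


def t_two_sample(x1, x2) -> tuple[float, int, float]:
    """Pooled two-sample t-test on raw samples.

    Algebraically identical to :func:`t_from_summary` applied to the
    samples' own summaries (asserted in the test suite).
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if len(x1) < 2 or len(x2) < 2:
        raise StatsError("need at least two observations per group")
    return t_from_summary(SummaryStats.of(x1), SummaryStats.of(x2))


def fdr_bh(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals.copy()
    if np.any((pvals < 0) | (pvals > 1)):
        raise StatsError("p-values must lie in [0, 1]")
    return multipletests(pvals, method="fdr_bh")[1]


def corr_with_age(feature, age) -> tuple[float, float]:
    """Pearson r between a feature column and age, with two-sided p."""
    feature = np.asarray(feature, dtype=float)
    age = np.asarray(age, dtype=float)
    if len(feature) < 3:
        raise StatsError("need at least three subjects")
    if feature.std() == 0 or age.std() == 0:
        raise StatsError("correlation undefined for constant input")
    r, p = sps.pearsonr(feature, age)
    return float(r), float(p)


def chi_square_2x2(a: int, b: int, c: int, d: int) -> tuple[float, int, float]:
    """Pearson chi-square on a 2x2 table, WITHOUT continuity correction.

    Table layout: rows are groups, columns are categories: [[a, b], [c, d]].
    """
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table < 0).any():
        raise StatsError("counts must be nonnegative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise StatsError("chi-square undefined with a zero margin")
    chi2, p, df, _ = sps.chi2_contingency(table, correction=False)
    return float(chi2), int(df), float(p)


@dataclass
class ROCResult:
    """ROC curve and pair-counting AUC for one score.

    ``auc`` is oriented so it is always >= 0.5; ``higher_is_positive``
    records whether larger raw scores indicate the positive class.
    """

    auc: float
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    positive_class: object
    higher_is_positive: bool

    @property
    def auc_trapezoid(self) -> float:
        fpr = 1 - self.specificity
        return float(np.trapezoid(self.sensitivity, fpr))


def _rank_auc(scores: np.ndarray, pos: np.ndarray) -> float:
    """Mann-Whitney pair-counting AUC (ties count 1/2) via midranks."""
    n1 = int(pos.sum())
    n0 = len(pos) - n1
    ranks = sps.rankdata(scores)
    return float((ranks[pos].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def roc_auc(scores, labels, positive) -> ROCResult:
    """ROC curve and AUC of a score for discriminating ``positive`` labels.

    AUC is computed by Mann-Whitney pair counting; the threshold-swept
    curve's trapezoid area equals it exactly (including under ties). If the
    raw orientation gives AUC < 0.5 the score is flipped and the flag
    recorded.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == positive
    if pos.all() or not pos.any():
        raise StatsError("both classes must be present")
    auc = _rank_auc(scores, pos)
    higher_is_positive = auc >= 0.5
    if not higher_is_positive:
        scores = -scores
        auc = 1 - auc
    # threshold sweep: predict positive when score >= threshold
    order = np.argsort(-scores, kind="stable")
    s_sorted, p_sorted = scores[order], pos[order]
    distinct = np.flatnonzero(np.diff(s_sorted) != 0)
    cut = np.r_[distinct, len(s_sorted) - 1]
    tp = np.cumsum(p_sorted)[cut]
    fp = np.cumsum(~p_sorted)[cut]
    n1, n0 = pos.sum(), (~pos).sum()
    sens = np.r_[0.0, tp / n1]
    spec = np.r_[1.0, 1 - fp / n0]
    thresholds = np.r_[np.inf, s_sorted[cut]]
    return ROCResult(
        auc=auc,
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        positive_class=positive,
        higher_is_positive=higher_is_positive,
    )


def group_difference_table(
    features: pd.DataFrame,
    labels,
    group1="HC",
    group2="MDD",
    age=None,
    q: float = 0.05,
) -> pd.DataFrame:
    """Per-feature pooled t-tests (group1 vs group2) with BH-FDR columns.

    Optionally adds Pearson age correlations (with their own FDR) when an
    ``age`` vector is supplied. Returns one row per feature with columns
    t, df, p, p_fdr, significant (p_fdr < q), direction.
    """
    labels = np.asarray(labels)
    m1, m2 = labels == group1, labels == group2
    rows = []
    for col in features.columns:
        x = features[col].to_numpy(dtype=float)
        t, df, p = t_two_sample(x[m1], x[m2])
        rows.append({"feature": col, "t": t, "df": df, "p": p})
    out = pd.DataFrame(rows).set_index("feature")
    out["p_fdr"] = fdr_bh(out["p"].to_numpy())
    out["significant"] = out["p_fdr"] < q
    out["direction"] = np.sign(out["t"])
    if age is not None:
        age = np.asarray(age, dtype=float)
        rs, ps = [], []
        for col in features.columns:
            try:
                r, p = corr_with_age(features[col], age)
            except StatsError:
                r, p = np.nan, np.nan
            rs.append(r)
            ps.append(p)
        out["r_age"] = rs
        out["r_age_p"] = ps
        ok = np.isfinite(ps)
        adj = np.full(len(ps), np.nan)
        if ok.any():
            adj[ok] = fdr_bh(np.asarray(ps)[ok])
        out["r_age_p_fdr"] = adj
    return out


def discriminate(
    features: pd.DataFrame,
    labels,
    positive="MDD",
    columns: list[str] | None = None,
    cv_folds: int = 5,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Single-feature AUCs plus a linear-combination discriminant.

    The combination score is a maximum-likelihood (unpenalized) logistic
    regression after z-scoring on the selected ``columns`` (default: all) —
    the classical linear discriminant construction, which with many
    features on few subjects can separate the groups perfectly in-sample.
    Its AUC is therefore reported both in-sample — mirroring how
    combination ROCs are conventionally reported — and under stratified
    k-fold cross-validation, the honest measure of out-of-sample
    discrimination. Constant features are skipped with a log entry.
    """
    labels = np.asarray(labels)
    pos = labels == positive
    if pos.sum() < 2 or (~pos).sum() < 2:
        raise StatsError("need at least two subjects per class")
    rows = []
    for col in features.columns:
        x = features[col].to_numpy(dtype=float)
        if x.std() == 0:
            logger.info("discriminate: skipping constant feature %s", col)
            continue
        rows.append({"feature": col, "auc": roc_auc(x, labels, positive).auc})
    single = pd.DataFrame(rows).set_index("feature").sort_values("auc", ascending=False)

    cols = columns if columns is not None else list(features.columns)
    X = features[cols].to_numpy(dtype=float)
    keep = X.std(axis=0) > 0
    X = X[:, keep]
    model = make_pipeline(
        StandardScaler(),
        LogisticRegression(C=np.inf, max_iter=5000, random_state=seed),
    )
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    with warnings.catch_warnings():
        # perfect in-sample separation leaves the unpenalized likelihood
        # unbounded; the ranking score is still well-defined
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(X, pos)
        score_in = model.predict_proba(X)[:, 1]
        score_cv = cross_val_predict(
            model, X, pos, cv=cv, method="predict_proba"
        )[:, 1]
    auc_in = roc_auc(score_in, labels, positive).auc
    auc_cv = roc_auc(score_cv, labels, positive).auc
    combo = {
        "columns": [c for c, k in zip(cols, keep) if k],
        "auc_in_sample": auc_in,
        "auc_cv": auc_cv,
    }
    return single, combo
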