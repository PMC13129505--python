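"""Permutation-entropy brain-entropy (BEN) features.

Permutation entropy (PE) quantifies the complexity of a time series through
the distribution of ordinal (rank-order) patterns of its delay-embedded
subsequences: with embedding dimension d and lag tau, each vector
``(x_t, x_{t+tau}, ..., x_{t+(d-1)tau})`` is mapped to the permutation that
sorts it, and PE is the Shannon entropy of the pattern frequencies,
normalized by ``ln(d!)`` so values lie in [0, 1]. Because only ranks enter,
PE is invariant to strictly increasing affine transforms of the signal —
a useful property for amplitude-unstable optical recordings.

Two feature families are computed per channel and hemoglobin signal
(HbO / HbR / HbT):

* static BEN — PE of the complete recording (26 retained channels x 3
  signals = 78 static measures per subject);
* dynamic BEN — PE inside sliding windows, summarized (mean by default)
  across windows, capturing fluctuations of temporal complexity.

Nine named feature sets combine these: per-signal static and dynamic sets,
``Static_all``, ``Dynamic_all`` and ``ALL``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import factorial, log

import numpy as np
import pandas as pd

from .preprocess import HemoRecording

logger = logging.getLogger(__name__)

SIGNALS = ("HbO", "HbR", "HbT")
MODES = ("static", "dynamic")

FEATURE_SET_NAMES = (
    "HbO_static",
    "HbR_static",
    "HbT_static",
    "HbO_dynamic",
    "HbR_dynamic",
    "HbT_dynamic",
    "Static_all",
    "Dynamic_all",
    "ALL",
)


class EntropyError(ValueError):
    """Invalid input to an entropy operation."""


class EmptyFeatureError(EntropyError):
    """No retained channels / no features left to compute."""


@dataclass
class PEParams:
    """Permutation-entropy parameters (embedding dimension d, lag tau).

    ``tie_rule`` controls rank assignment inside tied embedded vectors:
    ``"stable-order"`` (default) ranks the earlier sample lower, which makes
    constant segments map to the ascending pattern deterministically;
    ``"noise-jitter"`` breaks ties by adding tiny seeded jitter instead.
    """

    embed_d: int = 3
    lag_tau: int = 1
    normalize: bool = True
    tie_rule: str = "stable-order"

    def __post_init__(self):
        if self.embed_d < 2:
            raise EntropyError("embedding dimension must be >= 2")
        if self.lag_tau < 1:
            raise EntropyError("lag must be >= 1")
        if self.tie_rule not in ("stable-order", "noise-jitter"):
            raise EntropyError(f"unknown tie rule {self.tie_rule!r}")

    @property
    def min_length(self) -> int:
        return (self.embed_d - 1) * self.lag_tau + 2


@dataclass
class WindowParams:
    """Sliding-window parameters for dynamic BEN.

    Defaults: 200-sample windows (about 30 s at the 2000-samples-per-5-min
    rate) advancing by 100 samples (50% overlap), summarized by the mean.
    """

    window_len: int = 200
    step: int = 100
    summary: str = "mean"

    def __post_init__(self):
        if self.step < 1 or self.step > self.window_len:
            raise EntropyError("need 1 <= step <= window_len")
        if self.summary not in ("mean", "sd"):
            raise EntropyError(f"unknown summary {self.summary!r}")


def _embed(x: np.ndarray, d: int, tau: int) -> np.ndarray:
    """Delay embedding along the last axis: (..., n_vec, d)."""
    n = x.shape[-1]
    n_vec = n - (d - 1) * tau
    return np.stack([x[..., k * tau : k * tau + n_vec] for k in range(d)], axis=-1)


def _pattern_codes(x: np.ndarray, params: PEParams) -> np.ndarray:
    """Integer ordinal-pattern code per embedded vector, shape (..., n_vec)."""
    d, tau = params.embed_d, params.lag_tau
    if x.shape[-1] < params.min_length:
        raise EntropyError(
            f"series length {x.shape[-1]} < minimum {params.min_length} "
            f"for d={d}, tau={tau}"
        )
    if not np.isfinite(x).all():
        raise EntropyError("series contains non-finite samples")
    if params.tie_rule == "noise-jitter":
        rng = np.random.default_rng(0)
        scale = np.abs(x).max() or 1.0
        x = x + rng.uniform(-1e-12, 1e-12, size=x.shape) * scale
    emb = _embed(x, d, tau)
    pat = np.argsort(emb, axis=-1, kind="stable")
    code = np.zeros(pat.shape[:-1], dtype=np.int64)
    for k in range(d):
        code = code * d + pat[..., k]
    return code


def _entropy_from_codes(code: np.ndarray, params: PEParams) -> np.ndarray:
    """Shannon entropy of pattern frequencies along the last axis."""
    d = params.embed_d
    n_vec = code.shape[-1]
    lead_shape = code.shape[:-1]
    flat = code.reshape(-1, n_vec)
    n_rows = flat.shape[0]
    base = d**d
    offset = np.arange(n_rows, dtype=np.int64)[:, None] * base
    counts = np.bincount((flat + offset).ravel(), minlength=n_rows * base)
    counts = counts.reshape(n_rows, base)
    p = counts / n_vec
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -np.where(p > 0, p * np.log(p), 0.0).sum(axis=1)
    if params.normalize:
        h = h / log(factorial(d))
    return h.reshape(lead_shape) if lead_shape else float(h[0])


def permutation_entropy(series: np.ndarray, params: PEParams | None = None):
    """Permutation entropy of one or many series.

    ``series`` may be 1D (returns a float) or N-D with time on the last
    axis (returns an array of the leading shape). Entropy is in nats, or a
    fraction of ``ln(d!)`` when ``params.normalize`` (default).
    """
    params = params or PEParams()
    x = np.asarray(series, dtype=float)
    squeeze = x.ndim == 1
    code = _pattern_codes(x, params)
    h = _entropy_from_codes(code if not squeeze else code[None, :], params)
    return float(h[0]) if squeeze else h


def windowed_entropy(
    series: np.ndarray, params: PEParams, win: WindowParams
) -> np.ndarray:
    """PE in each sliding window; windows start at 0, step, 2*step, ...

    Returns shape (..., n_windows). Window starts run while
    ``start + window_len <= n_samples``.
    """
    x = np.asarray(series, dtype=float)
    n = x.shape[-1]
    if win.window_len > n:
        raise EntropyError("window longer than series")
    if win.window_len < params.min_length:
        raise EntropyError("window too short for the embedding")
    starts = range(0, n - win.window_len + 1, win.step)
    cols = [
        np.asarray(permutation_entropy(x[..., s : s + win.window_len], params))
        for s in starts
    ]
    return np.stack(cols, axis=-1)


def static_ben(rec: HemoRecording, params: PEParams | None = None) -> pd.DataFrame:
    """Static BEN: PE of the full series, per retained channel and signal.

    Returns a (n_channels, 3) DataFrame indexed by channel label with
    columns HbO/HbR/HbT; QC-excluded channels are NaN.
    """
    params = params or PEParams()
    if not rec.qc_mask.any():
        raise EmptyFeatureError(f"{rec.subject_id}: no retained channels")
    out = pd.DataFrame(
        np.nan, index=rec.channel_labels, columns=list(SIGNALS), dtype=float
    )
    keep = rec.qc_mask
    for sig in SIGNALS:
        x = rec.signal(sig)[keep]
        out.loc[keep, sig] = permutation_entropy(x, params)
    return out


def dynamic_ben(
    rec: HemoRecording,
    params: PEParams | None = None,
    win: WindowParams | None = None,
) -> pd.DataFrame:
    """Dynamic BEN: summary (mean or sd) of windowed PE per channel/signal."""
    params = params or PEParams()
    win = win or WindowParams()
    if not rec.qc_mask.any():
        raise EmptyFeatureError(f"{rec.subject_id}: no retained channels")
    out = pd.DataFrame(
        np.nan, index=rec.channel_labels, columns=list(SIGNALS), dtype=float
    )
    keep = rec.qc_mask
    for sig in SIGNALS:
        w = windowed_entropy(rec.signal(sig)[keep], params, win)
        # sd uses the population (1/n) form: dispersion of the realized windows
        summary = w.mean(axis=-1) if win.summary == "mean" else w.std(axis=-1)
        out.loc[keep, sig] = summary
    return out


@dataclass
class BENFeatureMatrix:
    """Subjects x features table of BEN values with named feature sets.

    ``values`` is indexed by subject_id with columns named
    ``CH{k}_{HbO|HbR|HbT}_{static|dynamic}``; ``feature_sets`` maps each of
    the nine set names to its column list.
    """

    values: pd.DataFrame
    feature_sets: dict[str, list[str]] = field(default_factory=dict)
    dropped_channels: list[str] = field(default_factory=list)

    @property
    def subjects(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    def set_columns(self, name: str) -> list[str]:
        if name not in self.feature_sets:
            raise KeyError(
                f"unknown feature set {name!r}; expected one of {FEATURE_SET_NAMES}"
            )
        return self.feature_sets[name]

    def to_csv(self, path) -> None:
        self.values.rename_axis("subject_id").to_csv(path)


def _feature_name(channel_label: str, sig: str, mode: str) -> str:
    return f"{channel_label}_{sig}_{mode}"


def build_feature_matrix(
    records: list[HemoRecording],
    params: PEParams | None = None,
    win: WindowParams | None = None,
    modes: tuple[str, ...] = MODES,
) -> BENFeatureMatrix:
    """Assemble the cohort BEN feature matrix with complete-case channels.

    Channels excluded by QC for ANY subject are dropped cohort-wide so all
    feature columns are complete; the drop is logged and recorded.
    ``modes`` restricts the computation (e.g. ``("static",)``); composite
    feature sets are defined only for the modes computed.
    """
    if len(records) < 2:
        raise EntropyError("need at least two subjects")
    if not modes or any(m not in MODES for m in modes):
        raise EntropyError(f"modes must be a nonempty subset of {MODES}")
    params = params or PEParams()
    win = win or WindowParams()
    labels = records[0].channel_labels
    common = np.logical_and.reduce([r.qc_mask for r in records])
    if not common.any():
        raise EmptyFeatureError("no channel retained across all subjects")
    dropped = [lab for lab, ok in zip(labels, common) if not ok]
    if dropped:
        logger.info("dropping channels excluded for some subject: %s", dropped)

    rows = []
    for rec in records:
        tables = {}
        if "static" in modes:
            tables["static"] = static_ben(rec, params)
        if "dynamic" in modes:
            tables["dynamic"] = dynamic_ben(rec, params, win)
        row = {}
        for lab, ok in zip(labels, common):
            if not ok:
                continue
            for sig in SIGNALS:
                for mode, tab in tables.items():
                    row[_feature_name(lab, sig, mode)] = tab.loc[lab, sig]
        rows.append(pd.Series(row, name=rec.subject_id))
    values = pd.DataFrame(rows)

    kept = [lab for lab, ok in zip(labels, common) if ok]
    sets: dict[str, list[str]] = {}
    for sig in SIGNALS:
        for mode in modes:
            sets[f"{sig}_{mode}"] = [_feature_name(l, sig, mode) for l in kept]
    if "static" in modes:
        sets["Static_all"] = sum((sets[f"{s}_static"] for s in SIGNALS), [])
    if "dynamic" in modes:
        sets["Dynamic_all"] = sum((sets[f"{s}_dynamic"] for s in SIGNALS), [])
    if "static" in modes and "dynamic" in modes:
        sets["ALL"] = sets["Static_all"] + sets["Dynamic_all"]
    return BENFeatureMatrix(values=values, feature_sets=sets, dropped_channels=dropped)
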