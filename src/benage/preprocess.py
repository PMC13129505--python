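"""Raw optical intensity -> quality-controlled hemoglobin concentration series.

The pipeline applied to each recording is fixed and logged:

    despike -> lowpass -> mbll -> apply_qc

with channel quality control (coefficient of variation) always computed on
the RAW intensities, independent of spike correction and filtering.

Concentration changes are expressed in micromolar (uM). The modified
Beer-Lambert law (MBLL) relates optical-density change at each wavelength to
the chromophore concentration changes through the molar extinction
coefficients, the source-detector separation and a differential pathlength
factor (DPF) that accounts for scattering-lengthened photon paths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, filtfilt

logger = logging.getLogger(__name__)

#: Molar extinction coefficients, cm^-1 / (mol/L), rows = wavelength
#: (730 nm, 850 nm), columns = chromophore (HbO, HbR).  Values from the
#: standard compiled in-vitro hemoglobin spectra (Prahl/Cope compilation);
#: editable via MBLLParams.extinction.
DEFAULT_EXTINCTION = np.array(
    [
        [390.0, 1102.2],  # 730 nm
        [1058.0, 691.32],  # 850 nm
    ]
)

DEFAULT_WAVELENGTHS = (730.0, 850.0)


class PreprocessError(ValueError):
    """Invalid input to a preprocessing operation."""


@dataclass
class MBLLParams:
    """Geometry and optics of the modified Beer-Lambert conversion.

    Parameters
    ----------
    wavelengths : pair of float
        Nominal wavelengths in nm. Informational; the extinction matrix
        rows must correspond to them.
    extinction : (2, 2) array
        Molar extinction coefficients in cm^-1 M^-1, ``[lambda, chromophore]``
        with chromophore order (HbO, HbR).
    separation : float
        Source-detector separation d in cm.
    dpf : pair of float
        Differential pathlength factor per wavelength (dimensionless).
    i0 : (n_channels, 2) array or None
        Reference intensity per channel and wavelength. ``None`` (default)
        uses the temporal mean of each series, which yields zero-mean
        optical-density changes.
    """

    wavelengths: tuple[float, float] = DEFAULT_WAVELENGTHS
    extinction: np.ndarray = field(default_factory=lambda: DEFAULT_EXTINCTION.copy())
    separation: float = 3.0
    dpf: tuple[float, float] = (6.0, 6.0)
    i0: np.ndarray | None = None

    def __post_init__(self):
        self.extinction = np.asarray(self.extinction, dtype=float)
        if self.extinction.shape != (2, 2):
            raise PreprocessError("extinction matrix must be 2x2")
        if abs(np.linalg.det(self.extinction)) < 1e-12:
            raise np.linalg.LinAlgError("extinction matrix is singular")
        if self.separation <= 0:
            raise PreprocessError("source-detector separation must be positive")
        if any(v <= 0 for v in self.dpf):
            raise PreprocessError("DPF values must be positive")


@dataclass
class RawRecording:
    """Per-subject raw dual-wavelength optical intensities.

    ``intensities`` has shape (n_channels, n_samples, 2) in arbitrary
    units, strictly positive; wavelength axis follows
    :attr:`MBLLParams.wavelengths` order.
    """

    subject_id: str
    intensities: np.ndarray
    fs: float
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 3 or self.intensities.shape[2] != 2:
            raise PreprocessError(
                "intensities must have shape (channels, samples, 2)"
            )
        if np.any(self.intensities <= 0):
            raise PreprocessError("optical intensities must be strictly positive")
        if not self.channel_labels:
            self.channel_labels = [
                f"CH{i + 1}" for i in range(self.intensities.shape[0])
            ]

    @property
    def n_channels(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[1]


@dataclass
class HemoRecording:
    """Per-subject HbO/HbR/HbT concentration-change series (uM).

    ``qc_mask`` is True for retained channels. ``hbt`` always equals
    ``hbo + hbr`` elementwise.
    """

    subject_id: str
    hbo: np.ndarray
    hbr: np.ndarray
    hbt: np.ndarray
    fs: float
    qc_mask: np.ndarray = None
    channel_labels: list[str] = field(default_factory=list)
    preprocessing_log: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.hbo = np.asarray(self.hbo, dtype=float)
        self.hbr = np.asarray(self.hbr, dtype=float)
        self.hbt = np.asarray(self.hbt, dtype=float)
        if self.hbo.shape != self.hbr.shape or self.hbo.shape != self.hbt.shape:
            raise PreprocessError("hbo/hbr/hbt must share one shape")
        if self.qc_mask is None:
            self.qc_mask = np.ones(self.hbo.shape[0], dtype=bool)
        self.qc_mask = np.asarray(self.qc_mask, dtype=bool)
        if self.qc_mask.shape[0] != self.hbo.shape[0]:
            raise PreprocessError("qc_mask length must equal channel count")
        if not self.channel_labels:
            self.channel_labels = [f"CH{i + 1}" for i in range(self.hbo.shape[0])]

    @property
    def n_channels(self) -> int:
        return self.hbo.shape[0]

    @property
    def n_samples(self) -> int:
        return self.hbo.shape[1]

    def signal(self, name: str) -> np.ndarray:
        return {"HbO": self.hbo, "HbR": self.hbr, "HbT": self.hbt}[name]


def compute_cv(intensity: np.ndarray) -> float:
    """Coefficient of variation sigma/mu of an intensity series.

    Uses the population (1/n) standard deviation. The result is a unitless
    fraction (0.075 corresponds to the conventional 7.5% cutoff).
    """
    x = np.asarray(intensity, dtype=float)
    if x.size == 0:
        raise PreprocessError("cannot compute CV of an empty series")
    mu = x.mean()
    if mu == 0:
        raise PreprocessError("CV undefined for zero-mean series")
    return float(x.std() / mu)


def apply_qc(raw: RawRecording, threshold: float = 0.075) -> np.ndarray:
    """Channel retention mask from raw-intensity coefficient of variation.

    A channel is excluded iff CV > ``threshold`` (strict) at EITHER
    wavelength; a channel sitting exactly on the threshold is retained.
    Returns a boolean mask (True = retained) and never mutates the input.
    """
    return ~(cv_table(raw) > threshold).any(axis=1)


def cv_table(raw: RawRecording) -> np.ndarray:
    """Per-channel CV at each wavelength via :func:`compute_cv`, (n_ch, 2)."""
    x = raw.intensities
    return np.array(
        [
            [compute_cv(np.ascontiguousarray(x[c, :, w])) for w in range(2)]
            for c in range(x.shape[0])
        ]
    )


def despike(
    series: np.ndarray,
    z_thresh: float = 5.0,
    max_width: int = 3,
    log: list[str] | None = None,
) -> np.ndarray:
    """Replace short spike runs by linear interpolation.

    Samples whose robust z-score |x - median| / (1.4826 * MAD) exceeds
    ``z_thresh`` in runs of at most ``max_width`` consecutive samples are
    replaced by linear interpolation between the flanking clean samples.
    Longer runs (and runs touching the series boundary with no clean flank)
    are left untouched and logged. If the MAD is zero but some samples still
    deviate (constant series with outliers) the MAD-free rule
    |x - median| > 0 flags them; a fully constant series is returned as is.
    """
    x = np.asarray(series, dtype=float).copy()
    if x.size <= 2 * max_width:
        raise PreprocessError("series too short for despiking")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        # degenerate scale: constant series, possibly with isolated outliers
        flagged = np.abs(x - med) > 0
        if not flagged.any():
            return x
        msg = "despike: MAD=0, using exact-deviation rule"
        logger.warning(msg)
        if log is not None:
            log.append(msg)
    else:
        flagged = np.abs(x - med) / (1.4826 * mad) > z_thresh
    if not flagged.any():
        return x

    # runs of consecutive flagged samples
    idx = np.flatnonzero(flagged)
    splits = np.flatnonzero(np.diff(idx) > 1) + 1
    for run in np.split(idx, splits):
        start, end = run[0], run[-1]
        width = end - start + 1
        if width > max_width or start == 0 or end == x.size - 1:
            msg = (
                f"despike: run of width {width} at [{start}, {end}] left untouched"
            )
            logger.warning(msg)
            if log is not None:
                log.append(msg)
            continue
        lo, hi = x[start - 1], x[end + 1]
        x[start : end + 1] = lo + (hi - lo) * np.arange(1, width + 1) / (width + 1)
    return x


def _despike_array(
    inten: np.ndarray,
    z_thresh: float,
    max_width: int,
    log: list[str] | None = None,
) -> np.ndarray:
    """Despike a (channels, samples, wavelengths) array.

    Medians and MADs are computed for all channel/wavelength series at
    once; only series that actually contain flagged samples go through the
    run-replacement path of :func:`despike`, so clean recordings cost two
    vectorized medians.
    """
    med = np.median(inten, axis=1, keepdims=True)
    mad = np.median(np.abs(inten - med), axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        flagged = np.abs(inten - med) / (1.4826 * mad) > z_thresh
    flagged |= (mad == 0) & (np.abs(inten - med) > 0)
    if not flagged.any():
        return inten
    out = inten.copy()
    for c, w in zip(*np.nonzero(flagged.any(axis=1))):
        out[c, :, w] = despike(
            inten[c, :, w], z_thresh=z_thresh, max_width=max_width, log=log
        )
    return out


def lowpass(
    series: np.ndarray, fs: float, cutoff: float = 0.2, order: int = 3
) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth low-pass filter.

    DC gain is exactly 1; with the default order-3 design the attenuation
    at twice the cutoff exceeds 12 dB. Operates along the last axis.
    """
    if not 0 < cutoff < fs / 2:
        raise PreprocessError(
            f"cutoff {cutoff} Hz must lie in (0, Nyquist={fs / 2} Hz)"
        )
    b, a = butter(order, cutoff / (fs / 2), btype="low")
    return filtfilt(b, a, np.asarray(series, dtype=float), axis=-1)


def mbll(raw: RawRecording, params: MBLLParams | None = None) -> HemoRecording:
    """Invert the modified Beer-Lambert law: intensities -> concentrations.

    Optical-density change per wavelength is
    ``dOD(l, t) = -log10(I(l, t) / I0(l))``; concentration changes solve

        E @ [dHbO; dHbR] = [dOD_1/(d*DPF_1); dOD_2/(d*DPF_2)]

    with E the extinction matrix in cm^-1 M^-1, giving mol/L, reported in
    uM. HbT = HbO + HbR.
    """
    params = params or MBLLParams()
    inten = raw.intensities
    if np.any(inten <= 0):
        raise PreprocessError("optical intensities must be strictly positive")
    if params.i0 is None:
        i0 = inten.mean(axis=1)  # (channels, wavelengths)
    else:
        i0 = np.asarray(params.i0, dtype=float)
    dod = -np.log10(inten / i0[:, None, :])  # (channels, samples, 2)
    rhs = dod / (params.separation * np.asarray(params.dpf))
    # solve the per-sample 2x2 system for all channels/samples in one GEMM
    e_inv = np.linalg.inv(params.extinction)
    conc = (rhs.reshape(-1, 2) @ e_inv.T).reshape(rhs.shape) * 1e6  # mol/L -> uM
    hbo, hbr = conc[..., 0], conc[..., 1]
    return HemoRecording(
        subject_id=raw.subject_id,
        hbo=hbo,
        hbr=hbr,
        hbt=hbo + hbr,
        fs=raw.fs,
        channel_labels=list(raw.channel_labels),
        preprocessing_log=["mbll"],
    )


def preprocess_recording(
    raw: RawRecording,
    params: MBLLParams | None = None,
    cv_threshold: float = 0.075,
    lowpass_cutoff: float | None = 0.2,
    despike_z: float | None = 5.0,
    despike_max_width: int = 3,
) -> HemoRecording:
    """Full standard pipeline: despike -> lowpass -> mbll -> apply_qc.

    QC is computed on the raw (uncorrected) intensities. ``lowpass_cutoff``
    or ``despike_z`` set to None skip the corresponding stage.
    """
    qc_mask = apply_qc(raw, threshold=cv_threshold)
    log: list[str] = []
    inten = raw.intensities
    if despike_z is not None:
        inten = _despike_array(
            inten, z_thresh=despike_z, max_width=despike_max_width, log=log
        )
        log.append(f"despike(z={despike_z}, max_width={despike_max_width})")
    if lowpass_cutoff is not None:
        inten = lowpass(
            np.moveaxis(inten, 1, 2), raw.fs, cutoff=lowpass_cutoff
        )
        inten = np.moveaxis(inten, 2, 1)
        log.append(f"lowpass({lowpass_cutoff} Hz)")
    cleaned = RawRecording(
        subject_id=raw.subject_id,
        intensities=np.clip(inten, 1e-12, None),
        fs=raw.fs,
        channel_labels=list(raw.channel_labels),
    )
    hemo = mbll(cleaned, params)
    hemo.qc_mask = qc_mask
    hemo.preprocessing_log = log + hemo.preprocessing_log + [
        f"apply_qc(threshold={cv_threshold}): retained {int(qc_mask.sum())}"
        f"/{qc_mask.size} channels"
    ]
    return hemo


def from_concentrations(
    subject_id: str,
    hbo: np.ndarray,
    hbr: np.ndarray,
    fs: float,
    qc_mask: np.ndarray | None = None,
    lowpass_cutoff: float | None = None,
    channel_labels: list[str] | None = None,
) -> HemoRecording:
    """Entry point for already-converted HbO/HbR series (MBLL skipped).

    Accepts exported concentration data from acquisition software; an
    optional low-pass can still be applied. HbT is recomputed as HbO + HbR.
    """
    hbo = np.asarray(hbo, dtype=float)
    hbr = np.asarray(hbr, dtype=float)
    log = ["from_concentrations"]
    if lowpass_cutoff is not None:
        hbo = lowpass(hbo, fs, cutoff=lowpass_cutoff)
        hbr = lowpass(hbr, fs, cutoff=lowpass_cutoff)
        log.append(f"lowpass({lowpass_cutoff} Hz)")
    return HemoRecording(
        subject_id=subject_id,
        hbo=hbo,
        hbr=hbr,
        hbt=hbo + hbr,
        fs=fs,
        qc_mask=qc_mask,
        channel_labels=channel_labels or [],
        preprocessing_log=log,
    )
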