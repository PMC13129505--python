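"""Synthetic resting-state fNIRS cohorts with a planted age-complexity structure.

No public dataset accompanies the analysis this package implements, so every
downstream stage is exercised on synthetic cohorts that carry the statistical
structure the analysis assumes:

* a latent per-channel "neural" series built as a noise/oscillation mixture
  ``s(t) = (1 - m) * eps(t) + m * o(t)`` where ``eps`` is band-limited
  Gaussian noise and ``o`` a slow (~0.05 Hz) deterministic oscillation —
  larger mixing ``m`` means a more regular signal, hence lower permutation
  entropy (monotonicity is verified in the test suite);
* a subject-level mixing parameter
  ``m = clip(m0 + beta_age * z(age) + beta_group * 1[MDD] + noise, 0, 0.95)``
  planting a monotone age -> complexity relationship and a group offset for
  the patient cohort;
* raw dual-wavelength intensities produced by the FORWARD modified
  Beer-Lambert model from the latent concentrations, so the preprocessing
  inversion can be round-trip tested;
* optional motion spikes and high-variance (bad-CV) channels to exercise
  artifact correction and channel quality control.

The generator makes no attempt to model cardiac/respiratory physiology,
Mayer waves or optode-scalp coupling; it is a controllable complexity knob,
not a hemodynamics simulator.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import MBLLParams, RawRecording, lowpass

__all__ = [
    "CohortConfig",
    "SubjectRecord",
    "generate_cohort",
    "generate_subject_channels",
    "forward_mbll",
    "write_cohort",
    "ConfigError",
]


class ConfigError(ValueError):
    """Invalid cohort configuration."""


#: uM amplitude of the latent HbO fluctuation (unit-variance latent scaled
#: by this factor); chosen so optical-density changes stay in the small
#: (few-percent) regime typical of continuous-wave recordings.
HBO_SCALE_UM = 0.5

#: HbR is generated anticorrelated with HbO with this factor, mimicking
#: the typical flow-dominated washout of deoxyhemoglobin.
HBR_FACTOR = -0.4

#: Relative sd of the independent noise added to HbR (fraction of HbO sd).
HBR_NOISE_FRAC = 0.1

#: Frequency (Hz) of the slow deterministic oscillation.
OSC_FREQ_HZ = 0.05


@dataclass
class CohortConfig:
    """Study-condition knobs of the synthetic cohort.

    Defaults mirror the acquisition the analysis targets: 26 frontal
    channels, 2000 samples over a 5-minute recording (fs = 2000/300 Hz),
    adults aged 18-65, cohort sizes set per call. ``beta_age`` is the slope
    of the mixing parameter per standardized age; ``beta_group`` the offset
    added for MDD subjects. Betas of the SAME sign ("aligned") make the
    patient group look older to a model trained on controls.
    """

    n_hc: int = 49
    n_mdd: int = 35
    n_channels: int = 26
    n_samples: int = 2000
    fs: float = 2000.0 / 300.0
    age_range: tuple[float, float] = (18.0, 65.0)
    m0: float = 0.5
    beta_age: float = -0.3
    beta_group: float = -0.3
    subject_noise_sd: float = 0.05
    spike_rate: float = 0.0
    bad_channel_prob: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_hc < 0 or self.n_mdd < 0 or self.n_hc + self.n_mdd == 0:
            raise ConfigError("cohort sizes must be nonnegative and not both zero")
        if self.n_channels <= 0 or self.n_samples <= 0:
            raise ConfigError("n_channels and n_samples must be positive")
        if self.fs <= 0:
            raise ConfigError("sampling rate must be positive")
        if not self.age_range[0] < self.age_range[1]:
            raise ConfigError("age_range must be a nonempty interval")
        if self.n_samples < 2 * ((3 - 1) * 1 + 2):
            raise ConfigError("n_samples too short for windowed entropy")


@dataclass
class SubjectRecord:
    """Metadata row for one synthetic subject.

    ``true_mixing`` is the ground-truth mixing parameter (synthetic only;
    real data carry no such column).
    """

    subject_id: str
    age: float
    sex: str
    education: float
    group: str
    true_mixing: float


def _latent_series(
    rng: np.random.Generator, m: float, n_channels: int, n_samples: int, fs: float
) -> np.ndarray:
    """Latent unit-scale neural series per channel, shape (channels, samples)."""
    t = np.arange(n_samples) / fs
    eps = rng.standard_normal((n_channels, n_samples))
    eps = lowpass(eps, fs, cutoff=0.8 * fs / 2)
    eps /= eps.std(axis=1, keepdims=True)
    phases = rng.uniform(0, 2 * np.pi, size=n_channels)
    osc = np.sqrt(2.0) * np.sin(
        2 * np.pi * OSC_FREQ_HZ * t[None, :] + phases[:, None]
    )
    return (1.0 - m) * eps + m * osc


def generate_subject_channels(
    rng: np.random.Generator, m: float, config: CohortConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Ground-truth (hbo, hbr, hbt) in uM for one subject, (channels, samples)."""
    s = _latent_series(rng, m, config.n_channels, config.n_samples, config.fs)
    hbo = HBO_SCALE_UM * s
    hbr = HBR_FACTOR * hbo + HBR_NOISE_FRAC * HBO_SCALE_UM * rng.standard_normal(
        hbo.shape
    )
    return hbo, hbr, hbo + hbr


def forward_mbll(
    hbo: np.ndarray,
    hbr: np.ndarray,
    params: MBLLParams | None = None,
    i0: tuple[float, float] = (1.0, 1.0),
) -> np.ndarray:
    """Forward modified Beer-Lambert model: concentrations (uM) -> intensities.

    ``dOD(l, t) = (e_HbO(l) * dHbO(t) + e_HbR(l) * dHbR(t)) * d * DPF(l)``
    and ``I(l, t) = I0(l) * 10**(-dOD(l, t))``. Exact algebraic inverse of
    :func:`benage.preprocess.mbll` (given matching reference intensities).

    Accepts 1D (samples,) or 2D (channels, samples) concentration arrays and
    returns intensities with a trailing wavelength axis of size 2.
    """
    params = params or MBLLParams()
    hbo = np.asarray(hbo, dtype=float) * 1e-6  # uM -> mol/L
    hbr = np.asarray(hbr, dtype=float) * 1e-6
    conc = np.stack([hbo, hbr], axis=-1)
    dod = (conc.reshape(-1, 2) @ params.extinction.T).reshape(conc.shape)
    dod *= params.separation * np.asarray(params.dpf)
    return np.asarray(i0) * np.exp(-np.log(10.0) * dod)


def _inject_spikes(
    rng: np.random.Generator, inten: np.ndarray, spike_rate: float
) -> np.ndarray:
    """Add short (1-3 sample) spikes of >= 5 sd amplitude to intensities."""
    inten = inten.copy()
    n_channels, n_samples, _ = inten.shape
    for c in range(n_channels):
        n_spikes = rng.poisson(spike_rate)
        for _ in range(n_spikes):
            width = int(rng.integers(1, 4))
            start = int(rng.integers(1, n_samples - width - 1))
            w = int(rng.integers(0, 2))
            sd = inten[c, :, w].std()
            amp = (5.0 + rng.exponential(2.0)) * sd * rng.choice([-1.0, 1.0])
            inten[c, start : start + width, w] += amp
    return inten


def generate_cohort(
    config: CohortConfig,
    mbll_params: MBLLParams | None = None,
    return_truth: bool = False,
):
    """Generate a full synthetic cohort.

    Returns ``(subjects, raws)`` where ``subjects`` is a list of
    :class:`SubjectRecord` (HC first, then MDD) and ``raws`` the matching
    list of :class:`~benage.preprocess.RawRecording`. With
    ``return_truth=True`` a third list of ground-truth ``(hbo, hbr, hbt)``
    concentration triplets is appended. Identical config + seed reproduce
    the cohort bit for bit.
    """
    mbll_params = mbll_params or MBLLParams()
    rng = np.random.default_rng(config.seed)
    n_total = config.n_hc + config.n_mdd
    groups = ["HC"] * config.n_hc + ["MDD"] * config.n_mdd

    lo, hi = config.age_range
    ages = rng.uniform(lo, hi, size=n_total)
    z_age = (ages - ages.mean()) / ages.std() if n_total > 1 else np.zeros(n_total)
    sexes = rng.choice(["male", "female"], size=n_total)
    education = np.round(rng.uniform(6, 18, size=n_total), 1)

    subjects: list[SubjectRecord] = []
    raws: list[RawRecording] = []
    truth = []
    for i in range(n_total):
        is_mdd = groups[i] == "MDD"
        m = (
            config.m0
            + config.beta_age * z_age[i]
            + (config.beta_group if is_mdd else 0.0)
            + config.subject_noise_sd * rng.standard_normal()
        )
        m = float(np.clip(m, 0.0, 0.95))
        sid = f"sub-{i + 1:03d}"
        subjects.append(
            SubjectRecord(
                subject_id=sid,
                age=float(ages[i]),
                sex=str(sexes[i]),
                education=float(education[i]),
                group=groups[i],
                true_mixing=m,
            )
        )
        hbo, hbr, hbt = generate_subject_channels(rng, m, config)
        inten = forward_mbll(hbo, hbr, mbll_params)
        if config.spike_rate > 0:
            inten = _inject_spikes(rng, inten, config.spike_rate)
        if config.bad_channel_prob > 0:
            bad = rng.random(config.n_channels) < config.bad_channel_prob
            noise = 0.12 * rng.standard_normal((int(bad.sum()), config.n_samples, 2))
            inten[bad] = inten[bad] * np.exp(noise)
        raws.append(
            RawRecording(subject_id=sid, intensities=inten, fs=config.fs)
        )
        if return_truth:
            truth.append((hbo, hbr, hbt))
    if return_truth:
        return subjects, raws, truth
    return subjects, raws


def subjects_frame(subjects: list[SubjectRecord]) -> pd.DataFrame:
    """Metadata table (one row per subject)."""
    return pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in subjects],
            "age": [s.age for s in subjects],
            "sex": [s.sex for s in subjects],
            "education": [s.education for s in subjects],
            "group": [s.group for s in subjects],
            "true_mixing": [s.true_mixing for s in subjects],
        }
    )


def write_cohort(
    out_dir: str | Path,
    subjects: list[SubjectRecord],
    raws: list[RawRecording],
    write_raw: bool = True,
) -> Path:
    """Write `subjects.csv` plus one raw-intensity CSV per subject.

    Raw CSVs have columns ``time, ch01_w730, ch01_w850, ch02_w730, ...``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    subjects_frame(subjects).to_csv(out_dir / "subjects.csv", index=False)
    if write_raw:
        for raw in raws:
            t = np.arange(raw.n_samples) / raw.fs
            cols = {"time": t}
            for c in range(raw.n_channels):
                cols[f"ch{c + 1:02d}_w730"] = raw.intensities[c, :, 0]
                cols[f"ch{c + 1:02d}_w850"] = raw.intensities[c, :, 1]
            pd.DataFrame(cols).to_csv(
                out_dir / f"{raw.subject_id}_raw.csv", index=False
            )
    return out_dir


def write_truth_hemo(
    out_dir: str | Path,
    subjects: list[SubjectRecord],
    truth: list[tuple[np.ndarray, np.ndarray, np.ndarray]],
    fs: float,
) -> Path:
    """Write ground-truth concentration CSVs (time, ch01_hbo ... chNN_hbt).

    ``truth`` is the third element returned by
    ``generate_cohort(..., return_truth=True)``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for subj, (hbo, hbr, hbt) in zip(subjects, truth):
        t = np.arange(hbo.shape[1]) / fs
        cols = {"time": t}
        for c in range(hbo.shape[0]):
            cols[f"ch{c + 1:02d}_hbo"] = hbo[c]
            cols[f"ch{c + 1:02d}_hbr"] = hbr[c]
            cols[f"ch{c + 1:02d}_hbt"] = hbt[c]
        pd.DataFrame(cols).to_csv(
            out_dir / f"{subj.subject_id}_hemo.csv", index=False
        )
    return out_dir


def read_hemo_csv(path: str | Path, fs: float):
    """Read a concentration CSV into a :class:`~benage.preprocess.HemoRecording`."""
    from .preprocess import from_concentrations

    df = pd.read_csv(path)
    chans = sorted({c.rsplit("_", 1)[0] for c in df.columns if c != "time"})
    hbo = np.stack([df[f"{ch}_hbo"].to_numpy() for ch in chans])
    hbr = np.stack([df[f"{ch}_hbr"].to_numpy() for ch in chans])
    sid = Path(path).stem.replace("_hemo", "")
    return from_concentrations(sid, hbo, hbr, fs=fs)


def read_raw_csv(path: str | Path, fs: float) -> RawRecording:
    """Read a raw-intensity CSV written by :func:`write_cohort`."""
    df = pd.read_csv(path)
    chans = sorted({c.rsplit("_", 1)[0] for c in df.columns if c != "time"})
    inten = np.stack(
        [
            np.stack([df[f"{ch}_w730"].to_numpy(), df[f"{ch}_w850"].to_numpy()], axis=-1)
            for ch in chans
        ]
    )
    sid = Path(path).stem.replace("_raw", "")
    return RawRecording(subject_id=sid, intensities=inten, fs=fs)
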