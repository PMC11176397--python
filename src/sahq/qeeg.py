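"""Quantitative EEG: epoching, artifact rejection, spectral estimation and
band-power statistics.

The pipeline mirrors standard continuous-EEG practice in experimental
stroke work: recordings from six epidural electrodes (L1-L3, R1-R3) are cut
into non-overlapping 5-min epochs, artifactual epochs are rejected, a
Welch/short-time-Fourier power spectral density with a Hamming window is
estimated per epoch, and band powers are integrated over

    delta 1-4 Hz, theta 4-8 Hz, alpha 8-12 Hz, beta 12-30 Hz,
    broadband 1-20 Hz  (all bands half-open [lo, hi)),

from which the derived statistics are formed:

* relative band variability (RAV for alpha): band power / broadband power,
* alpha-delta ratio  ADR = alpha / delta,
* fast-slow spectral power ratio  SPR = (alpha + beta) / (delta + theta).

Because the broadband range stops at 20 Hz while beta extends to 30 Hz,
``rel_beta`` may exceed 1; the alpha/delta/theta relative powers lie in
[0, 1].  Ratios whose denominator is below 1e-12 uV^2 are reported as NaN
(undefined) rather than clamped, and are excluded from epoch means.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import signal as _sig

logger = logging.getLogger(__name__)

__all__ = [
    "BANDS",
    "BROADBAND",
    "CHANNELS",
    "EEGRecording",
    "Epoch",
    "PSDEstimate",
    "BandPowerSet",
    "segment_epochs",
    "flag_artifacts",
    "compute_psd",
    "band_power",
    "band_metrics",
    "aggregate_timecourse",
]

BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
}
BROADBAND: tuple[float, float] = (1.0, 20.0)
CHANNELS: tuple[str, ...] = ("L1", "L2", "L3", "R1", "R2", "R3")

RATIO_EPS = 1e-12  # uV^2 floor below which a ratio denominator is undefined


@dataclass
class EEGRecording:
    """Multichannel epidural EEG with subject/group/day metadata.

    ``samples`` is (n_channels, n_samples) in microvolts.
    """

    subject_id: str
    group: str
    day: int
    fs_hz: float
    samples: np.ndarray
    channels: tuple[str, ...] = CHANNELS
    start_time: object = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D (channels x samples)")
        if self.samples.shape[0] != len(self.channels):
            raise ValueError(
                f"{self.samples.shape[0]} sample rows for "
                f"{len(self.channels)} channel labels"
            )
        if self.fs_hz <= 60:
            raise ValueError("sampling rate must exceed 60 Hz")

    @property
    def duration_s(self) -> float:
        return self.samples.shape[1] / self.fs_hz


@dataclass
class Epoch:
    channel: str
    t_start_s: float
    duration_s: float
    fs_hz: float
    samples: np.ndarray
    artifact_flag: bool = False
    artifact_reason: str | None = None


def segment_epochs(recording: EEGRecording, epoch_s: float = 300.0) -> list[Epoch]:
    """Tile each channel into non-overlapping [t, t+epoch_s) epochs,
    dropping any trailing partial epoch."""
    n_per = int(round(epoch_s * recording.fs_hz))
    n_total = recording.samples.shape[1]
    n_epochs = n_total // n_per
    if n_epochs < 1:
        raise ValueError(
            f"recording of {recording.duration_s:.1f} s is shorter than one "
            f"{epoch_s:.0f}-s epoch"
        )
    epochs: list[Epoch] = []
    for ci, ch in enumerate(recording.channels):
        for k in range(n_epochs):
            seg = recording.samples[ci, k * n_per : (k + 1) * n_per]
            epochs.append(Epoch(ch, k * epoch_s, epoch_s, recording.fs_hz, seg))
    return epochs


def flag_artifacts(epoch: Epoch, amp_thresh_uv: float = 1000.0,
                   flat_var_uv2: float = 1e-6) -> tuple[bool, str | None]:
    """Artifact predicate: high amplitude, flatline, or single-sample step.

    Sets ``artifact_flag``/``artifact_reason`` on the epoch and returns
    them.  Criteria are the package's own (the acquisition-side rejection
    software is site-specific); all thresholds are configurable.
    """
    x = epoch.samples
    if x.size == 0:
        raise ValueError("empty epoch")
    reason = None
    if np.abs(x).max() > amp_thresh_uv:
        reason = "amplitude"
    elif x.var() < flat_var_uv2:
        reason = "flatline"
    elif x.size > 1 and np.abs(np.diff(x)).max() > amp_thresh_uv:
        reason = "step"
    epoch.artifact_flag = reason is not None
    epoch.artifact_reason = reason
    return epoch.artifact_flag, reason


@dataclass(frozen=True)
class PSDEstimate:
    frequencies_hz: np.ndarray
    power: np.ndarray  # one-sided density, uV^2/Hz
    resolution_hz: float


def compute_psd(epoch: Epoch, window_s: float = 2.0, overlap: float = 0.5) -> PSDEstimate:
    """Welch PSD of one unflagged epoch.

    Hamming-windowed, mean-detrended segments of ``window_s`` seconds with
    fractional ``overlap``, averaged; one-sided density normalised so that
    the integral of the PSD over frequency equals the detrended signal
    variance (window power corrected by scipy's 'density' scaling).
    """
    if epoch.artifact_flag:
        raise ValueError("refusing to estimate PSD of an artifact-flagged epoch")
    nperseg = int(round(window_s * epoch.fs_hz))
    if nperseg < 8:
        raise ValueError("window must span at least 8 samples")
    nperseg = min(nperseg, epoch.samples.size)
    freqs, p = _sig.welch(
        epoch.samples,
        fs=epoch.fs_hz,
        window="hamming",
        nperseg=nperseg,
        noverlap=int(nperseg * overlap),
        detrend="constant",
        scaling="density",
    )
    return PSDEstimate(freqs, p, float(freqs[1] - freqs[0]))


def band_power(psd: PSDEstimate, f_lo: float, f_hi: float) -> float:
    """Rectangle-rule integral of the PSD over bins with centers in
    [f_lo, f_hi)."""
    nyq = float(psd.frequencies_hz[-1])
    if not 0.0 <= f_lo < f_hi:
        raise ValueError(f"need 0 <= f_lo < f_hi, got [{f_lo}, {f_hi})")
    if f_hi > nyq + psd.resolution_hz / 2:
        raise ValueError(f"band edge {f_hi} Hz exceeds Nyquist {nyq} Hz")
    mask = (psd.frequencies_hz >= f_lo) & (psd.frequencies_hz < f_hi)
    return float(psd.power[mask].sum() * psd.resolution_hz)


@dataclass(frozen=True)
class BandPowerSet:
    """Absolute band powers (uV^2) and the derived ratio statistics.

    Undefined ratios (denominator < 1e-12 uV^2) are NaN.
    """

    delta: float
    theta: float
    alpha: float
    beta: float
    broadband: float
    rel_delta: float
    rel_theta: float
    rel_alpha: float
    rel_beta: float
    adr: float
    spr: float

    def as_dict(self) -> dict[str, float]:
        return {
            "delta": self.delta, "theta": self.theta, "alpha": self.alpha,
            "beta": self.beta, "broadband": self.broadband,
            "rel_delta": self.rel_delta, "rel_theta": self.rel_theta,
            "rel_alpha": self.rel_alpha, "rel_beta": self.rel_beta,
            "adr": self.adr, "spr": self.spr,
        }


def _ratio(num: float, den: float) -> float:
    return num / den if den > RATIO_EPS else math.nan


def band_metrics(psd: PSDEstimate) -> BandPowerSet:
    """All band powers plus RAV-style relative powers, ADR and SPR."""
    if psd.frequencies_hz[-1] < BANDS["beta"][1] - psd.resolution_hz / 2:
        raise ValueError("PSD must cover the full 1-30 Hz range")
    p = {name: band_power(psd, lo, hi) for name, (lo, hi) in BANDS.items()}
    bb = band_power(psd, *BROADBAND)
    return BandPowerSet(
        delta=p["delta"], theta=p["theta"], alpha=p["alpha"], beta=p["beta"],
        broadband=bb,
        rel_delta=_ratio(p["delta"], bb),
        rel_theta=_ratio(p["theta"], bb),
        rel_alpha=_ratio(p["alpha"], bb),
        rel_beta=_ratio(p["beta"], bb),
        adr=_ratio(p["alpha"], p["delta"]),
        spr=_ratio(p["alpha"] + p["beta"], p["delta"] + p["theta"]),
    )


DEFAULT_METRICS = ("delta", "theta", "alpha", "beta", "broadband",
                   "rel_alpha", "adr", "spr")


def aggregate_timecourse(recordings: Iterable[EEGRecording],
                         epoch_s: float = 300.0,
                         window_s: float = 2.0,
                         overlap: float = 0.5,
                         metrics: Sequence[str] = DEFAULT_METRICS,
                         amp_thresh_uv: float = 1000.0,
                         flat_var_uv2: float = 1e-6) -> pd.DataFrame:
    """Per-(subject, electrode, day, metric) means over retained epochs.

    Artifact-flagged epochs and undefined (NaN) ratios are excluded; cells
    with no retained value are omitted with a logged warning.  Returns a
    tidy frame with columns subject_id, group, day, electrode, metric,
    value, n_epochs_retained.
    """
    rows = []
    for rec in recordings:
        per_channel: dict[str, list[BandPowerSet]] = {ch: [] for ch in rec.channels}
        for ep in segment_epochs(rec, epoch_s=epoch_s):
            flagged, _ = flag_artifacts(ep, amp_thresh_uv, flat_var_uv2)
            if flagged:
                continue
            per_channel[ep.channel].append(
                band_metrics(compute_psd(ep, window_s=window_s, overlap=overlap))
            )
        for ch, sets in per_channel.items():
            for metric in metrics:
                vals = np.array([s.as_dict()[metric] for s in sets], dtype=float)
                vals = vals[~np.isnan(vals)]
                if vals.size == 0:
                    logger.warning(
                        "no retained epochs for subject=%s electrode=%s day=%s "
                        "metric=%s; cell omitted",
                        rec.subject_id, ch, rec.day, metric,
                    )
                    continue
                rows.append({
                    "subject_id": rec.subject_id,
                    "group": rec.group,
                    "day": rec.day,
                    "electrode": ch,
                    "metric": metric,
                    "value": float(vals.mean()),
                    "n_epochs_retained": int(vals.size),
                })
    return pd.DataFrame(rows, columns=["subject_id", "group", "day", "electrode",
                                       "metric", "value", "n_epochs_retained"])
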