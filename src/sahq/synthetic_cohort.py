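"""Synthetic cohort generator for an experimental SAH study.

Every input the analysis pipeline consumes can be generated here with
known ground truth: multichannel EEG shaped by group/electrode/day band
gains, MRI hypointense-volume summaries, blob-like microglial (Iba-1)
histology images with exact masks, behavior/survival/perfusion outcome
tables rank-coupled to the EEG, and in vitro bead-phagocytosis counts.

Spectral model
--------------
Each EEG channel is a sum of band-limited noises plus a 1/f component:

    x(t) = sum_b g_b * BP_b(w(t)) + g_pink * pink(t),    w ~ N(0, 1) white

where BP_b is an ideal (frequency-domain) band-pass over the half-open
band b, applied by masking the Fourier transform of unit-variance white
noise.  The in-band density is then exactly flat and zero outside, so
with equal gains the summed spectrum is flat over 1-30 Hz and analytic
band-power expectations are simply gain^2 x bandwidth / Nyquist (times
the amplitude scale squared).  Hemorrhage groups raise
the delta gain (most at the electrodes over the bleed, R2/R3/L3) and
depress alpha globally, with an exponential recovery toward the sham
profile over postoperative days:

    g(day) = g_sham * (1 + (f - 1) * exp(-day / tau)).

All generators are pure functions of (parameters, seed): the same seed
yields bit-identical output.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from .qeeg import BANDS, CHANNELS, EEGRecording

logger = logging.getLogger(__name__)

__all__ = [
    "GROUPS",
    "EEGProfile",
    "VhypoParams",
    "HistoParams",
    "HazardParams",
    "BehaviorLinkParams",
    "PhagoParams",
    "CohortConfig",
    "gen_eeg_recording",
    "gen_eeg_cohort",
    "gen_vhypo",
    "gen_histo_image",
    "gen_outcomes",
    "gen_bead_counts",
]

GROUPS: tuple[str, ...] = ("sham", "SAH", "SAH-FTY")


def _subseed(seed: int, *parts) -> np.random.Generator:
    """Deterministic per-entity RNG: stable across processes and runs."""
    ent = [int(seed) & 0x7FFFFFFF]
    for p in parts:
        if isinstance(p, str):
            ent.append(zlib.crc32(p.encode()))
        else:
            ent.append(int(p) & 0xFFFFFFFF)
    return np.random.default_rng(np.random.SeedSequence(ent))


# --------------------------------------------------------------------------
# EEG


@dataclass
class EEGProfile:
    """Group/electrode/day-dependent spectral gain schedule.

    ``base_gains`` are the sham amplitude gains per band (equal gains give
    a flat 1-30 Hz spectrum).  Hemorrhage multiplies delta by
    ``sah_delta_factor_focal`` at the electrodes nearest the bleed and
    ``sah_delta_factor_diffuse`` elsewhere, and alpha by
    ``sah_alpha_factor`` globally, all decaying toward sham with time
    constant ``recovery_tau_days``.  Gains are amplitudes; band power
    scales with gain^2.
    """

    fs_hz: float = 1000.0
    duration_s: float = 1800.0
    amplitude_uv: float = 100.0
    base_gains: dict[str, float] = field(
        default_factory=lambda: {"delta": 1.0, "theta": 1.0, "alpha": 1.0, "beta": 1.0}
    )
    sah_delta_factor_focal: float = 3.0
    sah_delta_factor_diffuse: float = 2.0
    sah_alpha_factor: float = 0.5
    focal_electrodes: tuple[str, ...] = ("R2", "R3", "L3")
    recovery_tau_days: float = 7.0
    pink_gain: float = 0.3
    artifact_rate: float = 0.02
    artifact_amp_uv: float = 2000.0

    def __post_init__(self) -> None:
        if any(g < 0 for g in self.base_gains.values()):
            raise ValueError("band gains must be nonnegative")
        if self.pink_gain < 0:
            raise ValueError("pink_gain must be nonnegative")
        if self.recovery_tau_days <= 0:
            raise ValueError("recovery_tau_days must be positive")
        top = max(hi for _, hi in BANDS.values())
        if self.fs_hz <= 2 * top:
            raise ValueError(f"fs must exceed twice the top band edge ({top} Hz)")

    def band_gain(self, group: str, electrode: str, day: int, band: str) -> float:
        g0 = self.base_gains[band]
        if group == "sham":
            return g0
        if group not in GROUPS:
            raise ValueError(f"unknown group label {group!r}")
        if band == "delta":
            f = (self.sah_delta_factor_focal
                 if electrode in self.focal_electrodes
                 else self.sah_delta_factor_diffuse)
        elif band == "alpha":
            f = self.sah_alpha_factor
        else:
            f = 1.0
        w = float(np.exp(-day / self.recovery_tau_days))
        return g0 * (1.0 + (f - 1.0) * w)


def _shaped_noise(rng: np.random.Generator, n: int, fs: float,
                  band_amps: list[tuple[float, float, float]]) -> np.ndarray:
    """White noise spectrally shaped by an ideal piecewise-flat amplitude
    profile: ``band_amps`` holds (lo_hz, hi_hz, gain) with half-open
    [lo, hi) bands.  Output variance is sum gain^2 * bandwidth/Nyquist."""
    spec = np.fft.rfft(rng.standard_normal(n))
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    amp = np.zeros(len(freqs))
    for lo, hi, g in band_amps:
        amp[(freqs >= lo) & (freqs < hi)] = g
    return np.fft.irfft(spec * amp, n)


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    spec[1:] = spec[1:] / np.sqrt(f[1:])
    spec[0] = 0.0
    x = np.fft.irfft(spec, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def gen_eeg_recording(profile: EEGProfile, subject_id: str, group: str,
                      day: int, seed: int) -> EEGRecording:
    """One recording for one animal on one postoperative day."""
    if group not in GROUPS:
        raise ValueError(f"unknown group label {group!r}")
    rng = _subseed(seed, "eeg", subject_id, day)
    n = int(round(profile.duration_s * profile.fs_hz))
    samples = np.zeros((len(CHANNELS), n))
    for ci, ch in enumerate(CHANNELS):
        band_amps = [(lo, hi, profile.band_gain(group, ch, day, band))
                     for band, (lo, hi) in BANDS.items()]
        x = _shaped_noise(rng, n, profile.fs_hz, band_amps)
        if profile.pink_gain > 0:
            x += profile.pink_gain * _pink_noise(rng, n)
        samples[ci] = x * profile.amplitude_uv
    meta: dict = {"artifacts": []}
    # inject unmistakable square-pulse artifacts, one candidate per 5-min block
    block = int(round(300 * profile.fs_hz))
    fs_i = int(round(profile.fs_hz))
    for start in range(0, n - fs_i + 1, block):
        if rng.random() < profile.artifact_rate:
            ch = int(rng.integers(len(CHANNELS)))
            onset = start + int(rng.integers(max(1, min(block, n - start) - fs_i)))
            t = np.arange(fs_i) / profile.fs_hz
            pulse = profile.artifact_amp_uv * np.sign(np.sin(2 * np.pi * 5 * t))
            samples[ch, onset : onset + fs_i] = pulse
            meta["artifacts"].append({"channel": CHANNELS[ch],
                                      "t_start_s": onset / profile.fs_hz})
    if profile.duration_s < 300:
        meta["short_recording"] = True
        logger.warning("recording %s day %s is shorter than one 5-min epoch",
                       subject_id, day)
    return EEGRecording(subject_id=subject_id, group=group, day=day,
                        fs_hz=profile.fs_hz, samples=samples, meta=meta)


# --------------------------------------------------------------------------
# MRI volumes


@dataclass
class VhypoParams:
    """Group-level Gaussian summaries of the MRI volume measurements
    (mm^3), truncated at zero by resampling.  Defaults reproduce the
    published group means/SDs for hypointense, whole-brain and ventricular
    volume."""

    mean_sah: float = 7.45
    sd_sah: float = 3.86
    mean_sham: float = 1.56
    sd_sham: float = 1.40
    brain_mean_sah: float = 1906.0
    brain_sd_sah: float = 65.6
    brain_mean_sham: float = 1868.0
    brain_sd_sham: float = 48.5
    vent_mean_sah: float = 30.3
    vent_sd_sah: float = 2.3
    vent_mean_sham: float = 17.2
    vent_sd_sham: float = 7.9
    observer_cv: float = 0.03  # proportional inter-observer noise

    def __post_init__(self) -> None:
        for name in ("sd_sah", "sd_sham", "brain_sd_sah", "brain_sd_sham",
                     "vent_sd_sah", "vent_sd_sham"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    out = rng.normal(mean, sd, n)
    while True:
        bad = out < 0
        if not bad.any():
            return out
        out[bad] = rng.normal(mean, sd, int(bad.sum()))


def gen_vhypo(params: VhypoParams, n_sah: int, n_sham: int, seed: int) -> pd.DataFrame:
    """Labeled volume records; v_hypo is the mean of two simulated
    blinded-observer measurements of the latent volume."""
    if n_sah < 1 or n_sham < 1:
        raise ValueError("need n >= 1 per group")
    rng = _subseed(seed, "vhypo")
    rows = []
    for group, n, mu, sd, bmu, bsd, vmu, vsd in (
        ("SAH", n_sah, params.mean_sah, params.sd_sah,
         params.brain_mean_sah, params.brain_sd_sah,
         params.vent_mean_sah, params.vent_sd_sah),
        ("sham", n_sham, params.mean_sham, params.sd_sham,
         params.brain_mean_sham, params.brain_sd_sham,
         params.vent_mean_sham, params.vent_sd_sham),
    ):
        v = _trunc_normal(rng, mu, sd, n)
        # proportional observer noise keeps volumes nonnegative and the
        # observer-averaged mean unbiased relative to the truncated normal
        obs1 = v * np.abs(1.0 + rng.normal(0, params.observer_cv, n))
        obs2 = v * np.abs(1.0 + rng.normal(0, params.observer_cv, n))
        brain = _trunc_normal(rng, bmu, bsd, n)
        vent = _trunc_normal(rng, vmu, vsd, n)
        for i in range(n):
            rows.append({
                "subject_id": f"{group}-{i + 1:02d}",
                "group": group,
                "v_obs1_mm3": obs1[i],
                "v_obs2_mm3": obs2[i],
                "v_hypo_mm3": 0.5 * (obs1[i] + obs2[i]),
                "brain_volume_mm3": brain[i],
                "ventricular_volume_mm3": vent[i],
            })
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Histology


@dataclass
class HistoParams:
    """Parameters of the simulated Iba-1 fields.

    ``densities`` maps (group, day) to ipsilateral cells/mm^2; the
    contralateral hemisphere is scaled by ``contra_factor``.  ROI ids 1-32
    are ipsilateral, 33-64 contralateral.  Cells are rendered as dark
    (DAB-like) discs on a light background.  Default densities give
    percent-positive areas near the published group summaries (~0.8%
    sham, ~2% SAH ipsilateral).
    """

    image_px: tuple[int, int] = (256, 256)
    um_per_px: float = 0.5
    cell_radius_um_mean: float = 4.0
    cell_radius_um_sd: float = 0.4
    background_level: int = 200
    cell_level: int = 70
    noise_sd: float = 8.0
    densities: dict = field(default_factory=lambda: {
        ("sham", 2): 160.0, ("sham", 7): 152.0,
        ("SAH", 2): 410.0, ("SAH", 7): 386.0,
        ("SAH-FTY", 2): 390.0, ("SAH-FTY", 7): 160.0,
    })
    contra_factors: dict = field(default_factory=lambda: {
        "sham": 1.0, "SAH": 0.6, "SAH-FTY": 0.6,
    })

    def __post_init__(self) -> None:
        if self.cell_radius_um_mean <= 0:
            raise ValueError("cell radius must be positive")
        if any(d < 0 for d in self.densities.values()):
            raise ValueError("densities must be nonnegative")

    def density_for(self, group: str, day: int, roi: int) -> float:
        if not 1 <= roi <= 64:
            raise ValueError("roi must lie in 1..64")
        key = (group, day)
        if key not in self.densities:
            raise KeyError(f"no density configured for {key}")
        d = self.densities[key]
        if roi > 32:  # contralateral hemisphere
            d *= self.contra_factors.get(group, 1.0)
        return d

    @staticmethod
    def hemisphere_of(roi: int) -> str:
        return "ipsilateral" if roi <= 32 else "contralateral"

    def expected_percent_area(self, group: str, day: int, roi: int) -> float:
        """Analytic Boolean-model expectation at low coverage:
        density x E[cell area] x 1e-4 (cells/mm^2 x um^2 -> %)."""
        mean_area_um2 = np.pi * (self.cell_radius_um_mean ** 2
                                 + self.cell_radius_um_sd ** 2)
        return self.density_for(group, day, roi) * mean_area_um2 * 1e-4


def gen_histo_image(params: HistoParams, group: str, day: int, roi: int,
                    seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Render one grayscale field and its exact binary ground-truth mask.

    Cell count is Poisson(density x field area); positions uniform;
    radii Gaussian (floored at one pixel).
    """
    rng = _subseed(seed, "histo", group, day, roi)
    rows, cols = params.image_px
    if 2 * params.cell_radius_um_mean / params.um_per_px > min(rows, cols):
        raise ValueError("cell diameter exceeds image size")
    area_mm2 = rows * cols * (params.um_per_px / 1000.0) ** 2
    density = params.density_for(group, day, roi)
    n_cells = int(rng.poisson(density * area_mm2))
    mask = np.zeros((rows, cols), dtype=bool)
    for _ in range(n_cells):
        cy = rng.uniform(0, rows)
        cx = rng.uniform(0, cols)
        r_px = max(rng.normal(params.cell_radius_um_mean,
                              params.cell_radius_um_sd) / params.um_per_px, 1.0)
        y0, y1 = max(int(cy - r_px) - 1, 0), min(int(cy + r_px) + 2, rows)
        x0, x1 = max(int(cx - r_px) - 1, 0), min(int(cx + r_px) + 2, cols)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        mask[y0:y1, x0:x1] |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r_px ** 2
    img = np.full((rows, cols), float(params.background_level))
    img[mask] = params.cell_level
    img += rng.normal(0, params.noise_sd, (rows, cols))
    return np.clip(img, 0, 255).astype(np.uint8), mask


# --------------------------------------------------------------------------
# Outcomes: survival, behavior, perfusion


@dataclass
class HazardParams:
    """Per-day death probabilities (days 1..7) per group, censoring at
    day 7.  Defaults concentrate hazard in the first 48 h and integrate to
    roughly the published cumulative mortalities (~56% SAH, ~7% sham,
    ~17% SAH-FTY)."""

    hazards: dict = field(default_factory=lambda: {
        "sham": (0.01,) * 7,
        "SAH": (0.37, 0.24, 0.03, 0.02, 0.01, 0.01, 0.01),
        "SAH-FTY": (0.10, 0.05, 0.01, 0.01, 0.01, 0.0, 0.0),
    })

    def __post_init__(self) -> None:
        for g, hs in self.hazards.items():
            if len(hs) != 7 or any(not 0.0 <= h <= 1.0 for h in hs):
                raise ValueError(f"hazards for {g!r} must be 7 values in [0,1]")


@dataclass
class BehaviorLinkParams:
    """Monotone link from subject SPR to the 21-point Garcia score:

        score = round(clip(intercept + slope*SPR + eps, floor, 21)).

    The noise SD can be given directly, or derived from a target Spearman
    correlation via the Gaussian-copula relation
    rho_pearson = 2 sin(pi * rho_spearman / 6) applied to the observed SPR
    spread.  Open-field metrics come from group-level Gaussians."""

    intercept: float = 9.0
    slope: float = 3.5
    target_rho: float | None = 0.48
    noise_sd: float | None = None
    floor: int = 3
    ceiling: int = 21
    openfield: dict = field(default_factory=lambda: {
        # metric -> group -> (mean, sd)
        "of_distance_m": {"sham": (40.0, 8.0), "SAH": (25.0, 8.0),
                          "SAH-FTY": (32.0, 8.0)},
        "of_center_time_pct": {"sham": (8.0, 4.0), "SAH": (7.0, 4.0),
                               "SAH-FTY": (7.5, 4.0)},
        "of_vertical_counts": {"sham": (30.0, 8.0), "SAH": (18.0, 8.0),
                               "SAH-FTY": (24.0, 8.0)},
    })

    def resolve_noise_sd(self, spr_values: np.ndarray) -> float:
        if self.noise_sd is not None:
            return float(self.noise_sd)
        rho = self.target_rho
        if rho is None:
            raise ValueError("set either noise_sd or target_rho")
        if not 0.0 < rho <= 1.0:
            raise ValueError("target_rho must lie in (0, 1]")
        if rho >= 1.0:
            return 0.0
        rho_p = 2.0 * np.sin(np.pi * rho / 6.0)
        sx = float(np.std(spr_values))
        return abs(self.slope) * sx * float(np.sqrt(1.0 / rho_p ** 2 - 1.0))


@dataclass
class PhagoParams:
    """Negative-binomial beads-per-cell model per condition; mean m and
    dispersion k give variance m + m^2/k."""

    means: dict = field(default_factory=lambda: {"vehicle": 1.12, "hemin": 6.55})
    dispersions: dict = field(default_factory=lambda: {"vehicle": 50.0, "hemin": 4.9})

    def __post_init__(self) -> None:
        if any(m <= 0 for m in self.means.values()):
            raise ValueError("phagocytosis means must be positive")
        if any(k <= 0 for k in self.dispersions.values()):
            raise ValueError("dispersion must be positive")


@dataclass
class CohortConfig:
    """Everything needed to synthesise one study."""

    n_per_group: int = 6
    days: tuple[int, ...] = (2, 7)
    seed: int = 0
    eeg: EEGProfile = field(default_factory=EEGProfile)
    vhypo: VhypoParams = field(default_factory=VhypoParams)
    histo: HistoParams = field(default_factory=HistoParams)
    survival: HazardParams = field(default_factory=HazardParams)
    behavior: BehaviorLinkParams = field(default_factory=BehaviorLinkParams)
    phago: PhagoParams = field(default_factory=PhagoParams)
    rcbf_drop: dict = field(default_factory=lambda: {
        "sham": (11.6, 5.0), "SAH": (84.8, 5.0), "SAH-FTY": (80.0, 6.0),
    })

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        days = tuple(self.days)
        if list(days) != sorted(days) or any(d < 0 for d in days):
            raise ValueError("days must be ascending and nonnegative")
        self.days = days

    def subjects(self) -> list[tuple[str, str]]:
        return [(f"{g}-{i + 1:02d}", g)
                for g in GROUPS for i in range(self.n_per_group)]


def gen_eeg_cohort(config: CohortConfig) -> list[EEGRecording]:
    """One recording per (subject, postoperative day) for all three arms."""
    recs = []
    for subject_id, group in config.subjects():
        for day in config.days:
            recs.append(gen_eeg_recording(config.eeg, subject_id, group,
                                          day, config.seed))
    return recs


def gen_outcomes(config: CohortConfig, eeg_metrics: pd.DataFrame) -> pd.DataFrame:
    """Joined outcome table: Garcia score rank-coupled to per-subject SPR,
    open-field metrics, survival (censored at day 7) and the rCBF drop.

    ``eeg_metrics`` must hold one row per (subject_id, group, day) with an
    ``spr`` column (e.g. electrode-averaged SPR from the qEEG stage).
    """
    required = {"subject_id", "group", "day", "spr"}
    if not required.issubset(eeg_metrics.columns):
        raise ValueError(f"eeg_metrics needs columns {sorted(required)}")
    rng = _subseed(config.seed, "outcomes")
    idx = eeg_metrics.set_index(["subject_id", "day"])["spr"]
    noise_sd = config.behavior.resolve_noise_sd(eeg_metrics["spr"].to_numpy())
    b = config.behavior
    rows = []
    survival: dict[str, tuple[int, bool]] = {}
    rcbf: dict[str, float] = {}
    for subject_id, group in config.subjects():
        day_of_death = 7
        died = False
        for d, h in enumerate(config.survival.hazards[group], start=1):
            if rng.random() < h:
                day_of_death, died = d, True
                break
        survival[subject_id] = (day_of_death, died)
        mu, sd = config.rcbf_drop[group]
        rcbf[subject_id] = float(rng.normal(mu, sd))
    for subject_id, group in config.subjects():
        for day in config.days:
            try:
                spr = float(idx.loc[(subject_id, day)])
            except KeyError:
                raise KeyError(
                    f"no SPR value for subject {subject_id!r} on day {day}"
                ) from None
            latent = b.intercept + b.slope * spr + rng.normal(0.0, noise_sd)
            garcia = int(np.clip(np.round(latent), b.floor, b.ceiling))
            row = {
                "subject_id": subject_id, "group": group, "day": day,
                "spr": spr, "garcia_latent": latent, "garcia": garcia,
            }
            for metric, per_group in b.openfield.items():
                mu, sd = per_group[group]
                row[metric] = max(float(rng.normal(mu, sd)), 0.0)
            row["of_ccw_cw_ratio"] = float(np.exp(rng.normal(0.0, 0.3)))
            sd_day, died = survival[subject_id]
            row["survival_day"] = sd_day
            row["died"] = died
            row["rcbf_drop_pct"] = rcbf[subject_id]
            rows.append(row)
    return pd.DataFrame(rows)


def gen_bead_counts(params: PhagoParams, n_cells: int, seed: int) -> pd.DataFrame:
    """Per-cell latex bead counts for each assay condition."""
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = _subseed(seed, "phago")
    rows = []
    for cond in params.means:
        m = params.means[cond]
        k = params.dispersions[cond]
        p = k / (k + m)
        counts = rng.negative_binomial(k, p, n_cells)
        for c in counts:
            rows.append({"condition": cond, "beads": int(c)})
    return pd.DataFrame(rows)
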