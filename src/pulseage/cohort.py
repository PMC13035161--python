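"""Synthetic cohort and two-device night-recording generator.

Emulates the statistical structure of a paired overnight PPG study:
a right-skewed 20–70 age distribution, age-dependent pulse morphology
(crest time increasing, systolic–diastolic interval decreasing,
reflection index increasing with age), and systematic device offsets
between a fingertip transmission probe sampled at 256 Hz and a smart
ring sampled at 50 Hz recorded simultaneously.

Each beat is a two-Gaussian pulse (systolic wave + reflected diastolic
wave) on a linear diastolic run-off, so every landmark of the noise-free
waveform is available in closed form; :func:`implied_features` recovers
them by dense grid search and serves as the generator's ground truth for
the downstream pipeline.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

Device = Literal["fingertip", "ring"]

DEVICE_FS = {"fingertip": 256.0, "ring": 50.0}

#: number of samples in a duration-normalized pulse; morphology targets
#: (CT, dT) are expressed on this grid.
PULSE_GRID = 200


def _stable_int(s: str) -> int:
    """Deterministic 32-bit hash of a string (platform-independent)."""
    return zlib.crc32(s.encode("utf-8"))


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Participant:
    id: str
    age: float  # years
    sex: Literal["male", "female"]
    bmi: float  # kg/m^2
    sbp: float  # mmHg
    dbp: float  # mmHg

    def __post_init__(self) -> None:
        if not (20.0 <= self.age <= 70.0):
            raise ValueError(f"age {self.age} outside [20, 70]")
        if self.bmi >= 35.0:
            raise ValueError(f"bmi {self.bmi} >= 35")
        if self.sbp <= 0 or self.dbp <= 0:
            raise ValueError("blood pressure must be positive")


@dataclass(frozen=True)
class PulseMorphology:
    """Two-Gaussian beat shape plus beat-timing parameters.

    Gaussian centers/widths are fractions of the beat duration; the
    linear run-off term ``ramp * (1 - x)`` gives the waveform a sharp,
    well-defined foot at each beat boundary.
    """

    a1: float
    mu1: float
    sigma1: float
    a2: float
    mu2: float
    sigma2: float
    ramp: float
    mean_ibi_s: float
    ibi_jitter_sd_s: float

    def __post_init__(self) -> None:
        if not (0.0 < self.mu1 < self.mu2 < 1.0):
            raise ValueError("require 0 < mu1 < mu2 < 1")
        if self.a1 <= 0 or self.a2 < 0 or self.sigma1 <= 0 or self.sigma2 <= 0:
            raise ValueError("amplitudes/widths must be positive")


@dataclass(frozen=True)
class RecordingTruth:
    """Per-beat ground truth stored for testing, never used by the pipeline."""

    onsets: np.ndarray  # sample indices of beat boundaries (feet)
    beat_durations_s: np.ndarray
    morphology: PulseMorphology
    implied_ct: float  # samples on the 200-grid
    implied_dt: float
    implied_ri: float
    artifact_spans: tuple[tuple[int, int], ...] = ()


@dataclass
class RawRecording:
    participant_id: str
    device: Device
    fs: float
    samples: np.ndarray
    lights_off: int
    lights_on: int
    truth: RecordingTruth | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.lights_off < self.lights_on <= len(self.samples)):
            raise ValueError("require 0 <= lights_off < lights_on <= length")


# ---------------------------------------------------------------------------
# generator configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortConfig:
    """All knobs of the synthetic study.

    Feature trends are expressed on the 200-sample normalized-pulse grid.
    Slopes and between-participant SDs are calibrated so that an N=160
    cohort yields feature–age Pearson correlations near CT 0.64/0.62
    (fingertip/ring), dT −0.51, RI 0.58 fingertip and 0.22 ring.
    """

    # demographics
    age_bin_probs: tuple[float, float, float] = (0.68, 0.21, 0.11)
    age_bin_edges: tuple[float, float, float, float] = (20.0, 40.0, 60.0, 70.0)
    male_fraction: float = 0.49
    bmi_mean: float = 23.0
    bmi_sd: float = 3.0
    sbp_intercept: float = 100.0  # mmHg at age 35
    sbp_age_slope: float = 0.35  # mmHg / year
    sbp_sd: float = 12.0
    dbp_intercept: float = 70.0
    dbp_age_slope: float = 0.15
    dbp_sd: float = 8.0

    # feature–age trends (200-grid samples, ratio units)
    ct_at_20: float = 33.0
    ct_age_slope: float = 0.30  # samples / year
    ct_sd: float = 5.5  # between-participant SD around the trend
    dt_at_20: float = 65.5
    dt_age_slope: float = -0.35
    dt_sd: float = 7.7
    ri_at_20: float = 0.45
    ri_age_slope: float = 0.005
    ri_sd: float = 0.104

    # device offsets and ring-specific degradation
    ring_ct_offset: float = 6.0  # samples (200-grid)
    ring_ri_offset: float = 0.23
    ring_ri_slope_factor: float = 0.4  # attenuated RI–age slope for the ring
    ring_a2_jitter_sd: float = 0.10  # contact-pressure variability on a2

    # waveform shape
    sigma1_fingertip: float = 0.045  # fraction of beat duration
    sigma1_ring: float = 0.065  # rounder systolic peak for the ring
    sigma2: float = 0.09
    ramp: float = 0.08

    # beat timing
    hr_mean_bpm: float = 62.0
    hr_sd_bpm: float = 6.0  # between participants
    ibi_jitter_sd_s: float = 0.03  # beat-to-beat

    # night assembly
    night_duration_s: float = 330.0
    lights_margin_s: float = 5.0
    drift_amplitude: float = 1.5  # units of systolic amplitude
    drift_freq_hz: float = 0.02
    noise_sd_fingertip: float = 0.02
    noise_sd_ring: float = 0.04
    artifact_rate_per_min: float = 0.0
    artifact_amplitude: float = 8.0
    artifact_duration_s: tuple[float, float] = (1.0, 5.0)

    # "saturating" warps the effective age used by all trends through a
    # convex map, so features carry a strongly nonlinear age signal; it
    # also tightens the morphology-age coupling (deviations scaled by
    # saturating_dev_scale), emulating a cohort in which morphology
    # tracks age closely but nonlinearly
    age_map: Literal["linear", "saturating"] = "linear"
    saturating_dev_scale: float = 0.5


DEFAULT_CONFIG = CohortConfig()


# ---------------------------------------------------------------------------
# participants
# ---------------------------------------------------------------------------


def draw_participants(
    n: int, seed: int, cfg: CohortConfig = DEFAULT_CONFIG
) -> list[Participant]:
    """Draw ``n`` synthetic participants; deterministic given ``seed``."""
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng([seed, 101])
    out: list[Participant] = []
    edges = cfg.age_bin_edges
    for i in range(n):
        b = rng.choice(3, p=cfg.age_bin_probs)
        age = float(rng.uniform(edges[b], edges[b + 1]))
        age = float(np.clip(age, 20.0, 70.0))
        sex = "male" if rng.random() < cfg.male_fraction else "female"
        bmi = float(np.clip(rng.normal(cfg.bmi_mean, cfg.bmi_sd), 16.0, 34.9))
        sbp = max(
            70.0,
            cfg.sbp_intercept + cfg.sbp_age_slope * (age - 35.0)
            + rng.normal(0.0, cfg.sbp_sd),
        )
        dbp = max(
            45.0,
            cfg.dbp_intercept + cfg.dbp_age_slope * (age - 35.0)
            + rng.normal(0.0, cfg.dbp_sd),
        )
        out.append(
            Participant(
                id=f"P{i:04d}", age=age, sex=sex, bmi=bmi, sbp=sbp, dbp=dbp
            )
        )
    return out


# ---------------------------------------------------------------------------
# morphology
# ---------------------------------------------------------------------------


def _effective_age(age: float, cfg: CohortConfig) -> float:
    if cfg.age_map == "linear":
        return age
    # convex warp: features nearly flat for younger ages, steep for older
    u = (age - 20.0) / 50.0
    return 20.0 + 50.0 * u * u


#: fraction of the beat over which the diastolic run-off rises at the
#: foot, keeping the waveform continuous across beat boundaries so the
#: composite signal has a sharp minimum exactly at each boundary.
FOOT_RISE_FRAC = 0.06

#: coefficient of the x·(1−x) mid-beat volume term. It keeps the
#: waveform rising monotonically from the foot into the systolic
#: upstroke even for late systolic peaks, and steepens the diastolic
#: tail into the next foot, as in real pulses.
MID_FULLNESS = 0.16


def _mixture(x: np.ndarray, m: PulseMorphology) -> np.ndarray:
    w = m.a1 * np.exp(-0.5 * ((x - m.mu1) / m.sigma1) ** 2)
    w = w + m.a2 * np.exp(-0.5 * ((x - m.mu2) / m.sigma2) ** 2)
    foot = np.clip(x / FOOT_RISE_FRAC, 0.0, 1.0)
    return w + m.ramp * (1.0 - x) * foot + MID_FULLNESS * x * (1.0 - x)


def implied_features(
    m: PulseMorphology, n_grid: int = 8001
) -> tuple[float, float, float]:
    """(CT, dT, RI) of the noise-free beat on the 200-sample grid.

    Landmarks are found by dense grid search over the closed-form
    mixture, mimicking segmentation from beat foot to beat foot followed
    by 0–1 amplitude normalization.
    """
    x = np.linspace(0.0, 1.0, n_grid)
    w = _mixture(x, m)
    d = np.diff(w)
    # interior local maxima
    peaks = np.where((d[:-1] > 0) & (d[1:] <= 0))[0] + 1
    if len(peaks) == 0:
        raise ValueError("mixture has no interior maximum")
    wmin = float(w.min())
    x_sys = float(x[peaks[0]])
    ct = PULSE_GRID * x_sys
    if len(peaks) == 1:
        return ct, float("nan"), float("nan")
    x_dia = float(x[peaks[-1]])
    dt = PULSE_GRID * (x_dia - x_sys)
    ri = (w[peaks[-1]] - wmin) / (w[peaks[0]] - wmin)
    return float(ct), float(dt), float(ri)


def _solve_a2(
    ct: float, dt: float, ri_target: float, sigma1: float, sigma2: float,
    ramp: float, mean_ibi: float, jitter: float,
) -> PulseMorphology:
    """Choose a2 so the implied RI of the mixture matches ``ri_target``."""
    mu1 = ct / PULSE_GRID
    mu2 = (ct + dt) / PULSE_GRID

    def make(a2: float) -> PulseMorphology:
        return PulseMorphology(
            a1=1.0, mu1=mu1, sigma1=sigma1, a2=a2, mu2=mu2, sigma2=sigma2,
            ramp=ramp, mean_ibi_s=mean_ibi, ibi_jitter_sd_s=jitter,
        )

    def ri_of(a2: float) -> float:
        # a unimodal mixture (no diastolic peak) counts as RI below target
        try:
            ri = implied_features(make(a2), 2001)[2]
        except ValueError:
            return -np.inf
        return ri if np.isfinite(ri) else -np.inf

    lo, hi = 0.02, 1.05
    if ri_of(lo) - ri_target > 0:
        return make(lo)
    if ri_of(hi) - ri_target < 0:
        return make(hi)
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        f_mid = ri_of(mid) - ri_target
        if f_mid < 0:
            lo = mid
        else:
            hi = mid
    return make(0.5 * (lo + hi))


def morph_from_age(
    p: Participant,
    device: Device,
    cfg: CohortConfig = DEFAULT_CONFIG,
    seed: int = 0,
) -> PulseMorphology:
    """Pulse morphology for one participant on one device.

    Between-participant deviations around the age trends are derived
    from a stable hash of the participant id, so the fingertip and ring
    morphologies of one participant share the same latent deviation and
    differ only by the configured device offsets (plus the ring's
    contact-pressure jitter on the reflected-wave amplitude).
    """
    if device not in DEVICE_FS:
        raise ValueError(f"unknown device {device!r}")
    rng_p = np.random.default_rng([seed, _stable_int(p.id), 11])
    dev_scale = (
        cfg.saturating_dev_scale if cfg.age_map == "saturating" else 1.0
    )
    dev_ct = rng_p.normal(0.0, cfg.ct_sd) * dev_scale
    dev_dt = rng_p.normal(0.0, cfg.dt_sd) * dev_scale
    dev_ri = rng_p.normal(0.0, cfg.ri_sd) * dev_scale
    hr = float(np.clip(rng_p.normal(cfg.hr_mean_bpm, cfg.hr_sd_bpm), 45.0, 90.0))

    age = _effective_age(p.age, cfg)
    ct = cfg.ct_at_20 + cfg.ct_age_slope * (age - 20.0) + dev_ct
    dt = cfg.dt_at_20 + cfg.dt_age_slope * (age - 20.0) + dev_dt
    if device == "ring":
        ri_slope = cfg.ri_age_slope * cfg.ring_ri_slope_factor
        ri = cfg.ri_at_20 + cfg.ring_ri_offset + ri_slope * (age - 20.0) + dev_ri
        ct = ct + cfg.ring_ct_offset
        sigma1 = cfg.sigma1_ring
        rng_d = np.random.default_rng([seed, _stable_int(p.id), 13])
        a2_jitter = float(
            np.exp(rng_d.normal(0.0, cfg.ring_a2_jitter_sd))
        )
    else:
        ri = cfg.ri_at_20 + cfg.ri_age_slope * (age - 20.0) + dev_ri
        sigma1 = cfg.sigma1_fingertip
        a2_jitter = 1.0

    ct = float(np.clip(ct, 15.0, 70.0))
    dt = float(np.clip(dt, 35.0, min(110.0, 185.0 - ct)))
    ri = float(np.clip(ri, 0.20, 0.97))

    m = _solve_a2(
        ct, dt, ri, sigma1, cfg.sigma2, cfg.ramp, 60.0 / hr,
        cfg.ibi_jitter_sd_s,
    )
    if a2_jitter != 1.0:
        m = replace(m, a2=float(np.clip(m.a2 * a2_jitter, 0.02, 1.1)))
    return m


# ---------------------------------------------------------------------------
# rendering and night assembly
# ---------------------------------------------------------------------------


def render_pulse(
    m: PulseMorphology, duration: float, fs: float
) -> np.ndarray:
    """Render one beat of ``duration`` seconds sampled at ``fs`` Hz."""
    if not (0.4 <= duration <= 2.0):
        raise ValueError(f"duration {duration} outside [0.4, 2.0] s")
    if fs <= 0:
        raise ValueError("fs must be positive")
    n = int(round(duration * fs))
    x = np.arange(n) / n
    return _mixture(x, m)


def _beat_durations(
    p: Participant, m: PulseMorphology, total_s: float, seed: int
) -> np.ndarray:
    """Shared beat-duration sequence: identical for both devices."""
    rng = np.random.default_rng([seed, _stable_int(p.id), 29])
    n_est = int(total_s / max(m.mean_ibi_s, 0.4)) + 8
    d = rng.normal(m.mean_ibi_s, m.ibi_jitter_sd_s, size=n_est)
    d = np.clip(d, 0.45, 1.9)
    while d.sum() < total_s:
        extra = np.clip(
            rng.normal(m.mean_ibi_s, m.ibi_jitter_sd_s, size=16), 0.45, 1.9
        )
        d = np.concatenate([d, extra])
    k = int(np.searchsorted(np.cumsum(d), total_s)) + 1
    return d[:k]


def simulate_recording(
    p: Participant,
    device: Device,
    cfg: CohortConfig = DEFAULT_CONFIG,
    seed: int = 0,
) -> RawRecording:
    """One device-night: concatenated beats + drift + noise + artifacts.

    Beat times depend only on (participant, seed), never on the device,
    so the fingertip and ring recordings of one participant are
    simultaneous. Ground truth (beat feet, implied features) is stored
    on the recording for testing.
    """
    if device not in DEVICE_FS:
        raise ValueError(f"unknown device {device!r}")
    fs = DEVICE_FS[device]
    m = morph_from_age(p, device, cfg, seed)
    durations = _beat_durations(p, m, cfg.night_duration_s, seed)
    starts_s = np.concatenate([[0.0], np.cumsum(durations)])
    n_total = int(round(starts_s[-1] * fs))

    samples = np.zeros(n_total)
    onsets = np.round(starts_s[:-1] * fs).astype(int)
    ends = np.round(starts_s[1:] * fs).astype(int)
    for k in range(len(durations)):
        i0, i1 = onsets[k], min(ends[k], n_total)
        nb = i1 - i0
        if nb <= 0:
            continue
        x = np.arange(nb) / nb
        samples[i0:i1] = _mixture(x, m)

    rng_n = np.random.default_rng(
        [seed, _stable_int(p.id), _stable_int(device), 31]
    )
    t = np.arange(n_total) / fs
    if cfg.drift_amplitude > 0:
        phase = rng_n.uniform(0, 2 * np.pi)
        samples += cfg.drift_amplitude * np.sin(
            2 * np.pi * cfg.drift_freq_hz * t + phase
        )
    noise_sd = (
        cfg.noise_sd_fingertip if device == "fingertip" else cfg.noise_sd_ring
    )
    if noise_sd > 0:
        samples += rng_n.normal(0.0, noise_sd, size=n_total)

    artifact_spans: list[tuple[int, int]] = []
    if cfg.artifact_rate_per_min > 0:
        n_art = rng_n.poisson(
            cfg.artifact_rate_per_min * cfg.night_duration_s / 60.0
        )
        for _ in range(n_art):
            dur = rng_n.uniform(*cfg.artifact_duration_s)
            start = rng_n.uniform(0.0, max(cfg.night_duration_s - dur, 1.0))
            i0, i1 = int(start * fs), min(int((start + dur) * fs), n_total)
            f_a = rng_n.uniform(0.5, 2.0)
            amp = cfg.artifact_amplitude * rng_n.uniform(0.6, 1.2)
            tt = np.arange(i1 - i0) / fs
            samples[i0:i1] += amp * np.sin(2 * np.pi * f_a * tt)
            artifact_spans.append((i0, i1))

    ct, dt, ri = implied_features(m)
    margin = int(round(cfg.lights_margin_s * fs))
    lights_off = min(margin, max(n_total - 2, 0))
    lights_on = max(n_total - margin, lights_off + 1)
    truth = RecordingTruth(
        onsets=onsets,
        beat_durations_s=durations,
        morphology=m,
        implied_ct=ct,
        implied_dt=dt,
        implied_ri=ri,
        artifact_spans=tuple(artifact_spans),
    )
    return RawRecording(
        participant_id=p.id,
        device=device,
        fs=fs,
        samples=samples,
        lights_off=lights_off,
        lights_on=lights_on,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# beat-level pulse datasets (for model experiments)
# ---------------------------------------------------------------------------


def generate_pulse_dataset(
    participants: Sequence[Participant],
    device: Device,
    n_pulses: int,
    cfg: CohortConfig = DEFAULT_CONFIG,
    seed: int = 0,
    noise_sd: float = 0.01,
    n_pulses_by_id: dict[str, int] | None = None,
) -> dict[str, np.ndarray]:
    """Normalized-pulse arrays per participant, bypassing night assembly.

    Renders individual noisy beats and width/amplitude-normalizes them
    to the 200-sample grid — the fast path for model-scale experiments
    where the per-sample signal chain is exercised elsewhere.
    ``n_pulses_by_id`` overrides the pulse count for chosen participants
    (e.g., to emulate participants with too few usable pulses).
    """
    from pulseage.preprocess import normalize_pulse

    out: dict[str, np.ndarray] = {}
    for p in participants:
        m = morph_from_age(p, device, cfg, seed)
        k = (
            n_pulses_by_id.get(p.id, n_pulses)
            if n_pulses_by_id is not None
            else n_pulses
        )
        rng = np.random.default_rng(
            [seed, _stable_int(p.id), _stable_int(device), 47]
        )
        fs = DEVICE_FS[device]
        pulses = np.empty((k, PULSE_GRID), dtype=np.float32)
        for j in range(k):
            d = float(
                np.clip(rng.normal(m.mean_ibi_s, m.ibi_jitter_sd_s), 0.45, 1.9)
            )
            w = render_pulse(m, d, fs)
            if noise_sd > 0:
                w = w + rng.normal(0.0, noise_sd, size=len(w))
            pulses[j] = normalize_pulse(w, d).values
        out[p.id] = pulses
    return out
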