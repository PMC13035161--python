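"""Signal conditioning: from a raw night recording to normalized pulses.

The chain mirrors standard nocturnal-PPG practice: zero-phase 0.05–20 Hz
Chebyshev band-pass, envelope-based motion-artifact masking, 30-second
windowing between the lights-off/lights-on markers, slope-sum beat-onset
detection, physiological plausibility filtering of beat intervals
(0.4–2 s, ≤40 % beat-to-beat change), cubic-spline baseline removal,
width normalization of each beat to 200 samples, 0–1 amplitude scaling,
and a template-correlation quality check.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline
from scipy.ndimage import maximum_filter1d, minimum_filter1d

from pulseage.cohort import PULSE_GRID, RawRecording

log = logging.getLogger(__name__)


class UnsupportedRateError(ValueError):
    """Sampling rate too low for the 0.05–20 Hz passband."""


class DegeneratePulseError(ValueError):
    """Flat (zero-range) pulse segment cannot be amplitude-normalized."""


class InsufficientOnsetsError(ValueError):
    """Baseline spline needs at least four onset knots."""


@dataclass
class SignalWindow:
    participant_id: str
    device: str
    index: int  # window number within the in-bed period
    start: int  # sample index in the recording
    fs: float
    samples: np.ndarray
    artifact: bool = False


@dataclass
class NormalizedPulse:
    values: np.ndarray  # exactly 200 samples, min 0, max 1
    duration_s: float
    onset_index: int = 0
    window_index: int = -1


@dataclass
class QCReport:
    n_accepted: int = 0
    n_rejected: int = 0
    per_window: dict[int, tuple[int, int]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# filtering and artifact masking
# ---------------------------------------------------------------------------


def bandpass(
    x: np.ndarray,
    fs: float,
    low: float = 0.05,
    high: float = 20.0,
    order: int = 4,
    rs: float = 30.0,
) -> np.ndarray:
    """Zero-phase 4th-order Chebyshev (type II) band-pass.

    Applied forward–backward so pulse timing is phase-undistorted; the
    type-II design keeps the passband flat, which feature timing depends
    on. Requires ``fs > 2*high``.
    """
    if fs <= 2.0 * high:
        raise UnsupportedRateError(
            f"fs={fs} Hz cannot support a {high} Hz passband edge"
        )
    sos = sps.cheby2(order, rs, [low, high], btype="bandpass", fs=fs,
                     output="sos")
    x = np.asarray(x, dtype=float)
    return sps.sosfiltfilt(sos, x - x.mean())


def artifact_mask(
    x: np.ndarray,
    fs: float,
    k: float = 3.0,
    env_window_s: float = 2.0,
    pad_s: float = 1.0,
) -> np.ndarray:
    """Boolean mask of large motion artifacts.

    The envelope is the moving peak-to-peak amplitude over
    ``env_window_s``; samples where it exceeds ``k`` times the median
    envelope are masked, and masked spans are padded by ``pad_s`` on
    each side.
    """
    x = np.asarray(x, dtype=float)
    w = max(int(round(env_window_s * fs)), 3)
    env = maximum_filter1d(x, w) - minimum_filter1d(x, w)
    med = float(np.median(env))
    mask = env > k * med
    pad = int(round(pad_s * fs))
    if pad > 0 and mask.any():
        mask = maximum_filter1d(mask.astype(np.uint8), 2 * pad + 1).astype(bool)
    return mask


# ---------------------------------------------------------------------------
# windowing
# ---------------------------------------------------------------------------


def segment_windows(
    rec: RawRecording,
    mask: np.ndarray | None = None,
    window_s: float = 30.0,
    artifact_fraction: float = 0.2,
    samples: np.ndarray | None = None,
) -> list[SignalWindow]:
    """Tile the in-bed period into non-overlapping 30-s windows.

    A trailing partial window is dropped; windows with more than
    ``artifact_fraction`` masked samples are flagged artifactual.
    ``samples`` substitutes filtered samples for the raw ones.
    """
    sig = rec.samples if samples is None else samples
    if not (0 <= rec.lights_off < rec.lights_on <= len(sig)):
        raise ValueError("lights markers out of range")
    wlen = int(round(window_s * rec.fs))
    n_win = (rec.lights_on - rec.lights_off) // wlen
    out = []
    for i in range(int(n_win)):
        i0 = rec.lights_off + i * wlen
        i1 = i0 + wlen
        flagged = False
        if mask is not None:
            flagged = float(mask[i0:i1].mean()) > artifact_fraction
        out.append(
            SignalWindow(
                participant_id=rec.participant_id,
                device=rec.device,
                index=i,
                start=i0,
                fs=rec.fs,
                samples=sig[i0:i1],
                artifact=flagged,
            )
        )
    return out


# ---------------------------------------------------------------------------
# onset detection
# ---------------------------------------------------------------------------


def slope_sum(x: np.ndarray, fs: float, window_s: float = 0.128) -> np.ndarray:
    """Slope-sum transform: trailing-window sum of positive differences."""
    du = np.maximum(np.diff(np.asarray(x, dtype=float), prepend=x[0]), 0.0)
    w = max(int(round(window_s * fs)), 2)
    c = np.cumsum(du)
    ssf = c - np.concatenate([np.zeros(w), c[:-w]])
    return ssf


def _dominant_period(ssf: np.ndarray, fs: float,
                     lo_s: float = 0.4, hi_s: float = 2.0) -> float:
    """Beat period in seconds from the slope-sum autocorrelation."""
    z = ssf - ssf.mean()
    lo = max(int(lo_s * fs), 1)
    hi = min(int(hi_s * fs), len(z) - 2)
    if hi <= lo:
        return lo_s
    ac = sps.correlate(z, z, mode="full", method="fft")[len(z) - 1 :]
    return float((lo + int(np.argmax(ac[lo : hi + 1]))) / fs)


def detect_onsets(
    x: np.ndarray,
    fs: float,
    refractory_fraction: float = 0.55,
    height_floor: float = 0.35,
    search_back_s: float = 0.30,
    edge_anticipation_s: float = 0.02,
) -> np.ndarray:
    """Beat onsets via the slope-sum transform.

    Candidate slope-sum peaks are accepted greedily by descending
    height with a refractory interval of ``refractory_fraction`` times
    the dominant beat period (estimated from the slope-sum
    autocorrelation), which rejects the slower secondary upstroke of a
    large reflected diastolic wave. Accepted peaks far below the median
    accepted height (noise blips) are discarded, and each onset is the
    local minimum of the signal in the ``search_back_s`` span preceding
    its slope-sum peak, shifted forward by ``edge_anticipation_s``: the
    zero-phase band-pass anticipates the pulse upstroke by roughly half
    its step-response rise time (~20 ms at the 20 Hz edge), which would
    otherwise bias every detected foot early by that amount. Returns
    strictly increasing sample indices (possibly empty).
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 8 or np.ptp(x) == 0:
        return np.array([], dtype=int)
    ssf = slope_sum(x, fs)
    peaks, _ = sps.find_peaks(ssf, distance=max(int(0.25 * fs), 1))
    if len(peaks) == 0:
        return np.array([], dtype=int)
    period = _dominant_period(ssf, fs)
    refractory = refractory_fraction * period * fs
    order = np.argsort(ssf[peaks])[::-1]
    accepted: list[int] = []
    for pk in peaks[order]:
        if all(abs(pk - a) >= refractory for a in accepted):
            accepted.append(int(pk))
    heights = ssf[accepted]
    med = float(np.median(heights))
    accepted = [pk for pk, h in zip(accepted, heights)
                if h >= height_floor * med]
    back = max(int(round(search_back_s * fs)), 1)
    shift = int(round(edge_anticipation_s * fs))
    onsets = []
    for pk in accepted:
        if pk < back:
            # clipped search window: the beat's foot likely precedes
            # the window, so the onset would be unreliable
            continue
        o = pk - back + int(np.argmin(x[pk - back : pk + 1])) + shift
        if 0 <= o < len(x):
            onsets.append(o)
    return np.unique(np.asarray(onsets, dtype=int))


# ---------------------------------------------------------------------------
# plausibility filtering
# ---------------------------------------------------------------------------


def plausibility_filter(
    onsets: np.ndarray,
    fs: float,
    min_ibi_s: float = 0.4,
    max_ibi_s: float = 2.0,
    max_change: float = 0.40,
    max_stale: int = 2,
) -> list[tuple[int, int]]:
    """Retain onset-to-onset pulse intervals that are physiological.

    An interval is kept iff its duration lies in [0.4, 2] s and it
    differs from the previously *retained* interval by at most 40 %.
    The first retained interval only needs the duration bounds. If
    ``max_stale`` consecutive intervals pass the duration bounds but
    fail the 40 % rule, the reference interval is considered stale (a
    single aberrant anchor would otherwise reject an entire healthy
    rhythm) and the next bounds-passing interval re-anchors the
    sequence.
    """
    onsets = np.asarray(onsets, dtype=int)
    kept: list[tuple[int, int]] = []
    prev: float | None = None
    stale = 0
    for a, b in zip(onsets[:-1], onsets[1:]):
        d = (b - a) / fs
        if not (min_ibi_s <= d <= max_ibi_s):
            continue
        if (
            prev is None
            or abs(d - prev) / prev <= max_change
            or stale >= max_stale
        ):
            kept.append((int(a), int(b)))
            prev = d
            stale = 0
        else:
            stale += 1
    return kept


# ---------------------------------------------------------------------------
# baseline removal and normalization
# ---------------------------------------------------------------------------


def remove_baseline(x: np.ndarray, onsets: np.ndarray) -> np.ndarray:
    """Subtract a cubic spline through the (onset, value) knots."""
    onsets = np.asarray(onsets, dtype=int)
    if len(onsets) < 4:
        raise InsufficientOnsetsError(
            f"cubic-spline baseline needs >= 4 onsets, got {len(onsets)}"
        )
    x = np.asarray(x, dtype=float)
    spline = CubicSpline(onsets, x[onsets])
    return x - spline(np.arange(len(x)))


def normalize_pulse(segment: np.ndarray, duration_s: float,
                    onset_index: int = 0,
                    window_index: int = -1) -> NormalizedPulse:
    """Width-normalize one beat to 200 samples and amplitude to [0, 1].

    Width normalization uses cubic-spline interpolation so the 50 Hz and
    256 Hz samplings of the same beat land on a common grid.
    """
    segment = np.asarray(segment, dtype=float)
    if len(segment) < 10:
        raise ValueError(f"segment too short ({len(segment)} samples)")
    rng_amp = float(segment.max() - segment.min())
    if rng_amp == 0.0:
        raise DegeneratePulseError("flat segment")
    xs = np.linspace(0.0, 1.0, len(segment))
    resampled = CubicSpline(xs, segment)(np.linspace(0.0, 1.0, PULSE_GRID))
    resampled = (resampled - resampled.min()) / np.ptp(resampled)
    return NormalizedPulse(
        values=resampled,
        duration_s=float(duration_s),
        onset_index=int(onset_index),
        window_index=int(window_index),
    )


def quality_filter(
    pulses: list[NormalizedPulse], threshold: float = 0.90
) -> tuple[list[NormalizedPulse], QCReport]:
    """Keep pulses correlating with the window's mean pulse.

    A pulse is accepted iff its Pearson correlation with the pointwise
    mean of all candidate pulses is at least ``threshold``.
    """
    if not pulses:
        return [], QCReport()
    mat = np.stack([p.values for p in pulses])
    template = mat.mean(axis=0)
    t0 = template - template.mean()
    tn = np.sqrt((t0**2).sum())
    accepted = []
    report = QCReport()
    for p in pulses:
        v0 = p.values - p.values.mean()
        vn = np.sqrt((v0**2).sum())
        r = float(v0 @ t0 / (vn * tn)) if vn > 0 and tn > 0 else 0.0
        ok = r >= threshold
        if ok:
            accepted.append(p)
        report.n_accepted += ok
        report.n_rejected += not ok
        a, b = report.per_window.get(p.window_index, (0, 0))
        report.per_window[p.window_index] = (a + ok, b + (not ok))
    return accepted, report


# ---------------------------------------------------------------------------
# end-to-end convenience
# ---------------------------------------------------------------------------


def extract_pulses(
    rec: RawRecording,
    qc_threshold: float = 0.90,
    artifact_k: float = 3.0,
    window_s: float = 30.0,
) -> tuple[list[NormalizedPulse], QCReport, list[SignalWindow]]:
    """Full chain on one recording: accepted pulses grouped by window.

    Windows flagged artifactual or with fewer than four plausible onsets
    are skipped with a logged reason.
    """
    filt = bandpass(rec.samples, rec.fs)
    mask = artifact_mask(filt, rec.fs, k=artifact_k)
    windows = segment_windows(rec, mask=mask, window_s=window_s, samples=filt)
    all_accepted: list[NormalizedPulse] = []
    report = QCReport()
    for w in windows:
        if w.artifact:
            log.debug("window %d skipped: artifact flag", w.index)
            continue
        onsets = detect_onsets(w.samples, w.fs)
        intervals = plausibility_filter(onsets, w.fs)
        knots = np.unique(
            np.array([i for ab in intervals for i in ab], dtype=int)
        )
        if len(knots) < 4:
            log.debug("window %d skipped: %d onsets", w.index, len(knots))
            continue
        corrected = remove_baseline(w.samples, knots)
        pulses = []
        for a, b in intervals:
            try:
                pulses.append(
                    normalize_pulse(
                        corrected[a:b], (b - a) / w.fs, onset_index=a,
                        window_index=w.index,
                    )
                )
            except (DegeneratePulseError, ValueError):
                continue
        accepted, rep = quality_filter(pulses, threshold=qc_threshold)
        all_accepted.extend(accepted)
        report.n_accepted += rep.n_accepted
        report.n_rejected += rep.n_rejected
        report.per_window[w.index] = (rep.n_accepted, rep.n_rejected)
    return all_accepted, report, windows
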