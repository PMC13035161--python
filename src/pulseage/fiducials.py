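"""Fiducial-point detection and CT / dT / RI pulse features.

A per-window template (pointwise mean of accepted pulses) is fitted with
two Gaussians — systolic and reflected diastolic wave. Fiducials on each
pulse are then read off its smoothed derivatives:

- onset = sample 0, offset = sample 199;
- systolic peak = first positive-to-negative zero crossing of the 1st
  derivative;
- estimated diastolic peak = fitted second-Gaussian center plus 10 % of
  its distance from the onset;
- dicrotic notch = positive-to-negative zero crossing of the 3rd
  derivative nearest the estimated diastolic peak;
- diastolic peak = positive-to-negative zero crossing of the 1st
  derivative between the notch and the estimated diastolic peak,
  falling back to the estimate (flagged) when the reflected wave has
  merged with the direct wave and no crossing exists.

Features: CT = onset→systolic time, dT = systolic→diastolic time (both
in samples on the 200-grid, with seconds variants scaled by the source
beat duration), RI = diastolic/systolic amplitude ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.signal import savgol_filter

from pulseage.cohort import PULSE_GRID
from pulseage.preprocess import NormalizedPulse

log = logging.getLogger(__name__)


class TemplateFitError(RuntimeError):
    """Two-Gaussian template fit failed; the window is dropped."""


@dataclass
class GaussianTemplate:
    waveform: np.ndarray  # 200-sample mean pulse
    a1: float
    mu1: float  # sample units on the 200-grid
    sigma1: float
    a2: float
    mu2: float
    sigma2: float
    residual_rms: float


@dataclass
class FiducialSet:
    onset: int  # always 0
    systolic: int
    notch: int
    diastolic: int
    offset: int  # always 199
    valid: bool
    fallback_diastolic: bool = False


@dataclass
class PulseFeatures:
    ct: float  # samples on the 200-grid
    dt: float
    ri: float
    ct_seconds: float
    dt_seconds: float


# ---------------------------------------------------------------------------
# template
# ---------------------------------------------------------------------------


def _two_gauss(x: np.ndarray, p: np.ndarray) -> np.ndarray:
    a1, mu1, s1, a2, dmu, s2 = p
    return a1 * np.exp(-0.5 * ((x - mu1) / s1) ** 2) + a2 * np.exp(
        -0.5 * ((x - (mu1 + dmu)) / s2) ** 2
    )


def build_template(
    pulses: list[NormalizedPulse] | np.ndarray,
) -> GaussianTemplate:
    """Fit two Gaussians to the window's mean pulse.

    Bounded nonlinear least squares; the first Gaussian is initialized
    at the template's global maximum and the second at the maximum of
    the residual after subtracting the first. The second center is
    parameterized as an offset from the first, which enforces mu2 > mu1.
    Accepts a list of pulses or an (n, 200) matrix.
    """
    if len(pulses) < 5:
        raise TemplateFitError(f"need >= 5 accepted pulses, got {len(pulses)}")
    if isinstance(pulses, np.ndarray):
        tmpl = pulses.mean(axis=0).astype(float)
    else:
        tmpl = np.stack([p.values for p in pulses]).mean(axis=0)
    x = np.arange(PULSE_GRID, dtype=float)

    i1 = int(np.argmax(tmpl))
    a1_0 = float(tmpl[i1])
    g1 = a1_0 * np.exp(-0.5 * ((x - i1) / 10.0) ** 2)
    resid = tmpl - g1
    lo2 = min(i1 + 5, PULSE_GRID - 2)
    i2 = lo2 + int(np.argmax(resid[lo2:]))
    p0 = np.array(
        [a1_0, float(i1), 10.0, max(float(resid[i2]), 0.05),
         float(max(i2 - i1, 2)), 15.0]
    )
    bounds = (
        [0.05, 1.0, 2.0, 0.0, 1.0, 2.0],
        [2.0, 198.0, 80.0, 2.0, 197.0, 120.0],
    )
    p0 = np.clip(p0, bounds[0], bounds[1])
    try:
        fit = least_squares(
            lambda p: _two_gauss(x, p) - tmpl, p0, bounds=bounds,
            max_nfev=2000,
        )
    except Exception as exc:  # pragma: no cover - scipy-internal failures
        raise TemplateFitError(str(exc)) from exc
    if not fit.success and fit.status <= 0:
        raise TemplateFitError(f"fit did not converge (status {fit.status})")
    a1, mu1, s1, a2, dmu, s2 = fit.x
    rms = float(np.sqrt(np.mean(fit.fun**2)))
    return GaussianTemplate(
        waveform=tmpl, a1=float(a1), mu1=float(mu1), sigma1=float(s1),
        a2=float(a2), mu2=float(mu1 + dmu), sigma2=float(s2),
        residual_rms=rms,
    )


# ---------------------------------------------------------------------------
# fiducials
# ---------------------------------------------------------------------------


def _zero_crossings_pn(d: np.ndarray) -> np.ndarray:
    """Positive-to-negative zero crossings, sub-sample interpolated.

    Returns integer sample indices (nearest; ties toward the earlier
    sample).
    """
    idx = np.where((d[:-1] > 0) & (d[1:] <= 0))[0]
    out = []
    for i in idx:
        denom = d[i] - d[i + 1]
        frac = d[i] / denom if denom > 0 else 0.0
        r = i + frac
        lo = np.floor(r)
        # ties toward the earlier sample
        j = int(lo) if (r - lo) <= 0.5 else int(lo) + 1
        out.append(j)
    return np.unique(np.asarray(out, dtype=int))


def detect_fiducials(
    pulse: NormalizedPulse | np.ndarray,
    tmpl: GaussianTemplate,
    smooth_window: int = 9,
    smooth_order: int = 3,
) -> FiducialSet:
    """Locate fiducial points on one normalized pulse.

    Derivatives of orders 1–3 are taken from the same local-polynomial
    (Savitzky–Golay) smooth, so zero crossings of the 3rd derivative are
    well defined on noisy pulses. The detector is invariant to uniform
    amplitude scaling of the input.
    """
    v = pulse.values if isinstance(pulse, NormalizedPulse) else np.asarray(pulse)
    d1 = savgol_filter(v, smooth_window, smooth_order, deriv=1)
    d3 = savgol_filter(v, smooth_window, smooth_order, deriv=3)

    invalid = FiducialSet(0, 0, 0, 0, PULSE_GRID - 1, valid=False)
    c1 = _zero_crossings_pn(d1)
    c1 = c1[(c1 > 0) & (c1 < PULSE_GRID - 1)]
    if len(c1) == 0:
        return invalid
    # the systolic peak is the dominant early peak: skip low-amplitude
    # derivative crossings (foot-knee wiggles) that cannot be it
    vmax = float(v.max())
    vmin = float(v.min())
    dominant = c1[(v[c1] - vmin) >= 0.5 * (vmax - vmin)]
    if len(dominant) == 0:
        return invalid
    systolic = int(dominant[0])

    est_dia = min(tmpl.mu2 * 1.10, PULSE_GRID - 2.0)
    est_hi = int(round(est_dia))
    # the notch precedes the diastolic peak: restrict candidates to the
    # systolic–estimated-diastolic segment
    c3 = _zero_crossings_pn(d3)
    c3 = c3[(c3 > systolic) & (c3 <= est_hi)]
    if len(c3) == 0:
        return invalid
    notch = int(c3[np.argmin(np.abs(c3 - est_dia))])

    seg = c1[(c1 >= notch) & (c1 <= est_hi)]
    if len(seg) > 0:
        diastolic = int(seg[0])
        fallback = False
    else:
        diastolic = int(round(est_dia))
        fallback = True
    valid = 0 < systolic < notch <= diastolic < PULSE_GRID - 1
    return FiducialSet(
        onset=0, systolic=systolic, notch=notch, diastolic=diastolic,
        offset=PULSE_GRID - 1, valid=valid, fallback_diastolic=fallback,
    )


def pulse_features(
    fid: FiducialSet, pulse: NormalizedPulse | np.ndarray,
    duration_s: float | None = None,
) -> PulseFeatures | None:
    """CT / dT / RI from one fiducial set; ``None`` if invalid."""
    if not fid.valid:
        return None
    if isinstance(pulse, NormalizedPulse):
        v = pulse.values
        dur = pulse.duration_s if duration_s is None else duration_s
    else:
        v = np.asarray(pulse)
        dur = duration_s if duration_s is not None else float("nan")
    ct = float(fid.systolic - fid.onset)
    dt = float(fid.diastolic - fid.systolic)
    amp_sys = float(v[fid.systolic])
    if amp_sys <= 0:
        return None
    ri = float(v[fid.diastolic]) / amp_sys
    scale = dur / PULSE_GRID
    return PulseFeatures(
        ct=ct, dt=dt, ri=ri, ct_seconds=ct * scale, dt_seconds=dt * scale
    )


def window_features(features: list[PulseFeatures]) -> PulseFeatures:
    """Componentwise median across one window's valid pulses.

    Even counts use the mean-of-the-two-middle convention of the sample
    median.
    """
    if not features:
        raise ValueError("need at least one valid pulse")
    arr = np.array(
        [[f.ct, f.dt, f.ri, f.ct_seconds, f.dt_seconds] for f in features]
    )
    med = np.median(arr, axis=0)
    return PulseFeatures(*med.tolist())


# ---------------------------------------------------------------------------
# participant-level pairing
# ---------------------------------------------------------------------------

FEATURE_COLS = ["ct", "dt", "ri", "ct_seconds", "dt_seconds"]


def pair_and_sample(
    windows_a: pd.DataFrame,
    windows_b: pd.DataFrame,
    n_pairs: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Pair window-level features across devices and average a sample.

    Inputs are window-level feature frames (columns ``participant``,
    ``window`` and the feature columns) for each device. Windows are
    paired on (participant, window); participants with fewer than
    ``n_pairs`` valid pairs are excluded, mirroring the study's
    inclusion rule. For the rest, ``n_pairs`` pairs are drawn with a
    seeded generator and each device's participant-level value is the
    mean over the sampled pairs.

    Returns a long frame: participant, device, feature columns.
    """
    merged = windows_a.merge(
        windows_b, on=["participant", "window"], suffixes=("_a", "_b")
    )
    rows = []
    for pid, grp in merged.groupby("participant", sort=True):
        if len(grp) < n_pairs:
            continue
        rng = np.random.default_rng([seed, zlib_crc(pid)])
        take = grp.iloc[
            np.sort(rng.choice(len(grp), size=n_pairs, replace=False))
        ]
        for suffix, device in (("_a", "a"), ("_b", "b")):
            row = {"participant": pid, "device": device}
            for c in FEATURE_COLS:
                row[c] = float(take[c + suffix].mean())
            rows.append(row)
    return pd.DataFrame(rows)


def zlib_crc(s: str) -> int:
    import zlib

    return zlib.crc32(str(s).encode("utf-8"))


def participant_feature_table(
    pulses_by_id: dict[str, np.ndarray], max_template_pulses: int = 100
) -> pd.DataFrame:
    """Participant-level median CT/dT/RI from pulse matrices.

    The fast path for model-scale experiments: one template per
    participant (mean of up to ``max_template_pulses`` pulses), fiducial
    detection on every pulse, componentwise median of the valid ones.
    """
    rows = []
    for pid in sorted(pulses_by_id):
        arr = np.asarray(pulses_by_id[pid])
        try:
            tmpl = build_template(arr[:max_template_pulses])
        except TemplateFitError:
            continue
        feats = []
        for row in arr:
            pf = pulse_features(detect_fiducials(row, tmpl), row,
                                duration_s=float("nan"))
            if pf is not None:
                feats.append(pf)
        if not feats:
            continue
        wf = window_features(feats)
        rows.append({"participant": pid, "ct": wf.ct, "dt": wf.dt,
                     "ri": wf.ri, "n_valid": len(feats),
                     "n_pulses": len(arr)})
    return pd.DataFrame(rows)
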