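"""CSV formats, run manifest, and end-to-end pipeline orchestration.

All on-disk formats are plain CSV for inspectability: recordings carry
their metadata as ``# key: value`` header lines above a
``time_s,amplitude`` table; pulses are 200 value columns plus metadata;
features and predictions are ordinary tidy tables. Every pipeline run
writes a manifest recording the configuration snapshot, seeds, per-stage
counts and output hashes, so a run is reproducible from its manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from pulseage import fiducials as fid
from pulseage import models as mdl
from pulseage import preprocess as pre
from pulseage import stats as st
from pulseage.cohort import (
    CohortConfig,
    RawRecording,
    draw_participants,
    simulate_recording,
)
from pulseage.nn import CNNConfig, TrainConfig

log = logging.getLogger(__name__)


class FormatError(ValueError):
    """Malformed input file (missing columns/metadata, bad ordering)."""


# ---------------------------------------------------------------------------
# recordings
# ---------------------------------------------------------------------------

_RECORDING_FIELDS = ("participant", "device", "fs", "lights_off", "lights_on")


def write_recording(rec: RawRecording, path: str | Path) -> Path:
    path = Path(path)
    t = np.arange(len(rec.samples)) / rec.fs
    with open(path, "w") as fh:
        fh.write(f"# participant: {rec.participant_id}\n")
        fh.write(f"# device: {rec.device}\n")
        fh.write(f"# fs: {rec.fs}\n")
        fh.write(f"# lights_off: {rec.lights_off}\n")
        fh.write(f"# lights_on: {rec.lights_on}\n")
        fh.write("time_s,amplitude\n")
        for ti, si in zip(t, rec.samples):
            fh.write(f"{ti:.6f},{si:.6f}\n")
    return path


def read_recording(path: str | Path) -> RawRecording:
    path = Path(path)
    meta: dict[str, str] = {}
    n_header = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_header += 1
            key, _, value = line[1:].partition(":")
            meta[key.strip()] = value.strip()
    for f in _RECORDING_FIELDS:
        if f not in meta:
            raise FormatError(f"{path}: missing metadata field '{f}'")
    df = pd.read_csv(path, skiprows=n_header)
    if not {"time_s", "amplitude"} <= set(df.columns):
        raise FormatError(f"{path}: need columns time_s, amplitude")
    t = df["time_s"].to_numpy()
    bad = np.where(np.diff(t) <= 0)[0]
    if len(bad):
        raise FormatError(
            f"{path}: non-monotone time at data line {int(bad[0]) + 2}"
        )
    return RawRecording(
        participant_id=meta["participant"],
        device=meta["device"],  # type: ignore[arg-type]
        fs=float(meta["fs"]),
        samples=df["amplitude"].to_numpy(),
        lights_off=int(meta["lights_off"]),
        lights_on=int(meta["lights_on"]),
    )


# ---------------------------------------------------------------------------
# pulses / features / predictions
# ---------------------------------------------------------------------------

PULSE_COLS = [f"p{i:03d}" for i in range(200)]


def pulses_to_frame(
    pulses: list[pre.NormalizedPulse], participant: str, device: str
) -> pd.DataFrame:
    rows = []
    for p in pulses:
        row = {
            "participant": participant, "device": device,
            "window": p.window_index, "duration_s": p.duration_s,
            "onset": p.onset_index,
        }
        row.update({c: v for c, v in zip(PULSE_COLS, p.values)})
        rows.append(row)
    return pd.DataFrame(rows)


def write_pulses(frame: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    frame.to_csv(path, index=False, float_format="%.6f")
    return path


def read_pulses(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in PULSE_COLS if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: expected 200 pulse columns, missing {len(missing)} "
            f"(first: {missing[0]})"
        )
    return df


def frame_to_pulse_arrays(frame: pd.DataFrame) -> dict[str, np.ndarray]:
    """Pulse matrices keyed by participant (one device's frame)."""
    out = {}
    for pid, grp in frame.groupby("participant", sort=True):
        out[str(pid)] = grp[PULSE_COLS].to_numpy(dtype=np.float32)
    return out


def write_table(frame: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    frame.to_csv(path, index=False)
    return path


def read_predictions(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    need = {"participant", "fold", "age", "predicted", "raw_delta"}
    if not need <= set(df.columns):
        raise FormatError(f"{path}: missing columns {need - set(df.columns)}")
    return df


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    out_dir: str = "pipeline_out"
    seed: int = 0
    n_participants: int = 20
    cohort: CohortConfig = field(default_factory=CohortConfig)
    qc_threshold: float = 0.90
    n_pairs: int = 20
    n_pulses: int = 50  # per-device inclusion threshold for the models
    run_cnn: bool = False
    cnn_small: bool = True
    cnn_grid: tuple[TrainConfig, ...] = (
        TrainConfig(lr=1e-3, batch_size=128, optimizer="adam",
                    max_epochs=30, patience=8),
    )
    write_recordings: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cohort = CohortConfig(**raw.pop("cohort", {}))
        grid = tuple(
            TrainConfig(**g) for g in raw.pop("cnn_grid", [])
        ) or cls().cnn_grid
        return cls(cohort=cohort, cnn_grid=grid, **raw)


@dataclass
class RunManifest:
    config: dict
    seed: int
    counts: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)  # path -> sha256

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(
                {"config": self.config, "seed": self.seed,
                 "counts": self.counts, "outputs": self.outputs},
                fh, sort_keys=True,
            )
        return path


def window_feature_frame(
    pulses: list[pre.NormalizedPulse], participant: str
) -> pd.DataFrame:
    """Window-level median features for one recording's accepted pulses.

    Windows with fewer than five accepted pulses (no reliable template)
    or no valid fiducial sets are dropped.
    """
    rows = []
    by_window: dict[int, list[pre.NormalizedPulse]] = {}
    for p in pulses:
        by_window.setdefault(p.window_index, []).append(p)
    for widx in sorted(by_window):
        group = by_window[widx]
        try:
            tmpl = fid.build_template(group)
        except fid.TemplateFitError:
            continue
        feats = []
        n_invalid = 0
        for p in group:
            f = fid.detect_fiducials(p, tmpl)
            pf = fid.pulse_features(f, p)
            if pf is None:
                n_invalid += 1
                continue
            feats.append(pf)
        if not feats:
            continue
        wf = fid.window_features(feats)
        rows.append({
            "participant": participant, "window": widx, "ct": wf.ct,
            "dt": wf.dt, "ri": wf.ri, "ct_seconds": wf.ct_seconds,
            "dt_seconds": wf.dt_seconds, "n_pulses": len(feats),
            "n_invalid": n_invalid,
        })
    return pd.DataFrame(rows)


def run_pipeline(cfg: PipelineConfig) -> RunManifest:
    """simulate → preprocess → features → models → evaluate.

    Stage counts mirror the study's inclusion accounting: participants
    lacking enough paired windows drop out of the feature analysis, and
    participants lacking enough accepted pulses on either device drop
    out of the model analysis.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=dataclasses.asdict(cfg), seed=cfg.seed
    )

    # -- simulate ----------------------------------------------------------
    participants = draw_participants(cfg.n_participants, cfg.seed, cfg.cohort)
    ages = {p.id: p.age for p in participants}
    recordings: dict[tuple[str, str], RawRecording] = {}
    for p in participants:
        for device in ("fingertip", "ring"):
            rec = simulate_recording(p, device, cfg.cohort, cfg.seed)
            recordings[(p.id, device)] = rec
            if cfg.write_recordings:
                path = out / f"recording_{p.id}_{device}.csv"
                write_recording(rec, path)
                manifest.outputs[str(path)] = _sha256(path)
    manifest.counts["participants_simulated"] = len(participants)
    log.info("simulate: %d participants", len(participants))

    # -- preprocess --------------------------------------------------------
    pulses: dict[tuple[str, str], list[pre.NormalizedPulse]] = {}
    n_acc = n_rej = 0
    for key, rec in recordings.items():
        acc, rep, _ = pre.extract_pulses(rec, qc_threshold=cfg.qc_threshold)
        pulses[key] = acc
        n_acc += rep.n_accepted
        n_rej += rep.n_rejected
    manifest.counts["pulses_accepted"] = n_acc
    manifest.counts["pulses_rejected"] = n_rej
    log.info("preprocess: %d pulses accepted, %d rejected", n_acc, n_rej)

    # -- features ----------------------------------------------------------
    wf_fingertip = []
    wf_ring = []
    for p in participants:
        wf_fingertip.append(
            window_feature_frame(pulses[(p.id, "fingertip")], p.id)
        )
        wf_ring.append(window_feature_frame(pulses[(p.id, "ring")], p.id))
    wf_a = pd.concat(wf_fingertip, ignore_index=True)
    wf_b = pd.concat(wf_ring, ignore_index=True)
    paired = fid.pair_and_sample(wf_a, wf_b, n_pairs=cfg.n_pairs,
                                 seed=cfg.seed)
    if len(paired):
        paired["device"] = paired["device"].map(
            {"a": "fingertip", "b": "ring"}
        )
        paired["age"] = paired["participant"].map(ages)
    included_features = (
        sorted(paired["participant"].unique()) if len(paired) else []
    )
    manifest.counts["participants_feature_analysis"] = len(included_features)
    p_feat = write_table(paired, out / "features_participant.csv")
    manifest.outputs[str(p_feat)] = _sha256(p_feat)

    # -- models ------------------------------------------------------------
    arrays = {
        device: {
            p.id: np.stack([q.values for q in pulses[(p.id, device)]])
            if pulses[(p.id, device)] else np.empty((0, 200))
            for p in participants
        }
        for device in ("fingertip", "ring")
    }
    excluded: set[str] = set()
    selected: dict[str, dict[str, np.ndarray]] = {}
    for device in ("fingertip", "ring"):
        sel, exc = mdl.select_pulses(arrays[device], n=cfg.n_pulses,
                                     seed=cfg.seed)
        selected[device] = sel
        excluded |= set(exc)
    included_model = sorted(set(ages) - excluded)
    manifest.counts["participants_model_analysis"] = len(included_model)
    log.info(
        "inclusion: %d feature-analysis, %d model-analysis participants",
        len(included_features), len(included_model),
    )

    predictions: dict[str, pd.DataFrame] = {}
    if len(included_model) >= 10:
        folds = mdl.make_folds(included_model, k=min(10, len(included_model)),
                               seed=cfg.seed)
        for device in ("fingertip", "ring"):
            feats_dev = paired[paired["device"] == device]
            feats_dev = feats_dev[
                feats_dev["participant"].isin(included_model)
            ]
            if len(feats_dev) >= 10:
                preds = mdl.regression_cv(feats_dev, folds)
                predictions[f"regression_{device}"] = preds
            if cfg.run_cnn:
                cnn_cfg = (
                    CNNConfig.small() if cfg.cnn_small else CNNConfig()
                )
                sel_dev = {
                    pid: selected[device][pid] for pid in included_model
                }
                preds, _ = mdl.cnn_cv(
                    sel_dev, ages, folds, grid=cfg.cnn_grid, cfg=cnn_cfg,
                    seed=cfg.seed,
                )
                predictions[f"cnn_{device}"] = preds
        for name, preds in predictions.items():
            path = write_table(preds, out / f"predictions_{name}.csv")
            manifest.outputs[str(path)] = _sha256(path)

    # -- evaluate ----------------------------------------------------------
    report_rows = []
    for name, preds in predictions.items():
        fm = st.fold_metrics(preds)
        path = write_table(fm, out / f"metrics_{name}.csv")
        manifest.outputs[str(path)] = _sha256(path)
        report_rows.append({
            "model": name, "mae": fm["mae"].mean(), "rmse": fm["rmse"].mean(),
            "r2": fm["r2"].mean(), "r": fm["r"].mean(),
        })
    if report_rows:
        path = write_table(pd.DataFrame(report_rows), out / "summary.csv")
        manifest.outputs[str(path)] = _sha256(path)

    if len(paired):
        agreement_rows = []
        wide = paired.pivot(index="participant", columns="device")
        for feature in ("ct", "dt", "ri"):
            diff = (
                wide[(feature, "ring")] - wide[(feature, "fingertip")]
            ).to_numpy()
            means = (
                wide[(feature, "ring")] + wide[(feature, "fingertip")]
            ).to_numpy() / 2.0
            ba = st.bland_altman(diff, pair_means=means)
            agreement_rows.append({
                "feature": feature, "bias": ba.bias, "sd": ba.sd,
                "loa_lower": ba.loa_lower, "loa_upper": ba.loa_upper,
            })
        path = write_table(
            pd.DataFrame(agreement_rows), out / "device_agreement.csv"
        )
        manifest.outputs[str(path)] = _sha256(path)

    mpath = manifest.save(out / "manifest.yaml")
    log.info("manifest written to %s", mpath)
    return manifest
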