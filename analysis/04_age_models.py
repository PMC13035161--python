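"""Vascular-age prediction: feature regression vs 1D CNN.

Runs both model families on a 160-participant beat-level cohort (100
width-normalized pulses per participant and device) under 10-fold
participant-level cross-validation, writes per-participant predictions
and per-fold metrics, and saves Grad-CAM relevance maps by age group.

Run from the repository root:  python analysis/04_age_models.py
(about five minutes on one CPU)
"""

from pathlib import Path

import numpy as np
import pandas as pd

from pulseage import cohort, fiducials as fid, io, models as mdl
from pulseage import stats as st
from pulseage.nn import CNN1D, CNNConfig, TrainConfig

OUT = Path("results")
SEED = 42
N = 160
PULSES = 100

GRID = [TrainConfig(lr=1e-3, batch_size=128, optimizer="adam",
                    max_epochs=30, patience=10)]


def main() -> None:
    OUT.mkdir(exist_ok=True)
    participants = cohort.draw_participants(N, SEED)
    ages = {p.id: p.age for p in participants}
    folds = mdl.make_folds(sorted(ages), k=10, seed=SEED)

    for device in ("fingertip", "ring"):
        pulses = cohort.generate_pulse_dataset(
            participants, device, PULSES, seed=SEED)

        feats = fid.participant_feature_table(pulses)
        feats["age"] = feats["participant"].map(ages)
        reg_preds = mdl.regression_cv(feats, folds)
        io.write_table(reg_preds, OUT / f"predictions_regression_{device}.csv")
        io.write_table(st.fold_metrics(reg_preds),
                       OUT / f"metrics_regression_{device}.csv")
        m = st.metrics(reg_preds["age"], reg_preds["predicted"])
        print(f"{device} regression: MAE {m.mae:.2f} y, r {m.r:.3f}")

        if device == "fingertip":
            cnn_preds, outcomes = mdl.cnn_cv(
                pulses, ages, folds, grid=GRID, cfg=CNNConfig.small(),
                seed=SEED)
            io.write_table(cnn_preds, OUT / "predictions_cnn_fingertip.csv")
            io.write_table(st.fold_metrics(cnn_preds),
                           OUT / "metrics_cnn_fingertip.csv")
            m = st.metrics(cnn_preds["age"], cnn_preds["predicted"])
            print(f"{device} cnn: MAE {m.mae:.2f} y, r {m.r:.3f}")

            # Grad-CAM from the last fold's model over all pulses
            model = outcomes[-1].result.model
            stack = np.concatenate([pulses[p] for p in sorted(pulses)])
            age_vec = np.concatenate([
                np.full(len(pulses[p]), ages[p]) for p in sorted(pulses)
            ])
            maps = mdl.grad_cam(model, stack[:4000], age_vec[:4000])
            pd.DataFrame(maps).to_csv(OUT / "gradcam_maps.csv", index=False)
            print("grad-cam maps written (columns: "
                  + ", ".join(maps) + ")")


if __name__ == "__main__":
    main()
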