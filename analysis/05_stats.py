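"""Device comparison and ΔAge statistics.

Consumes the feature table from 03 and the predictions from 04:
Fisher z comparison of feature-age correlations between devices,
corrected resampled t-test on the per-fold regression metrics,
Bland–Altman of predicted vs chronological age with proportional-bias
slope, age-adjusted ΔAge, and the ΔAge-tertile blood-pressure models.

Run from the repository root:  python analysis/05_stats.py
"""

from pathlib import Path

import numpy as np
import pandas as pd

from pulseage import cohort, io, stats as st

OUT = Path("results")
SEED = 42


def main() -> None:
    # --- Fisher z on feature-age correlations (from 03's cohort) -----
    feats = pd.read_csv(OUT / "features_participant.csv")
    rows = []
    for feat in ("ct", "dt", "ri"):
        rs = {}
        for device, sub in feats.groupby("device"):
            rs[device] = float(np.corrcoef(sub["age"], sub[feat])[0, 1])
        n = feats["participant"].nunique()
        res = st.fisher_z_compare(rs["fingertip"], n, rs["ring"], n)
        rows.append({"feature": feat, "r_fingertip": round(rs["fingertip"], 3),
                     "r_ring": round(rs["ring"], 3),
                     "fisher_z": round(res.statistic, 3),
                     "p": round(res.p_value, 4)})
    fisher = pd.DataFrame(rows)
    io.write_table(fisher, OUT / "fisher_z_feature_age.csv")
    print("feature-age correlations by device (Fisher z):")
    print(fisher.to_string(index=False))

    # --- corrected resampled t-test: fingertip vs ring regression ----
    fm_f = pd.read_csv(OUT / "metrics_regression_fingertip.csv")
    fm_r = pd.read_csv(OUT / "metrics_regression_ring.csv")
    panel = st.metric_panel_ttest(fm_f, fm_r, n_train=144, n_test=16)
    io.write_table(panel, OUT / "device_metric_comparison.csv")
    print("\nfingertip vs ring regression metrics "
          "(corrected resampled t-test):")
    print(panel.round(4).to_string(index=False))

    # --- ΔAge analyses on the CNN predictions -------------------------
    preds = io.read_predictions(OUT / "predictions_cnn_fingertip.csv")
    ba = st.bland_altman(preds["raw_delta"].to_numpy(),
                         x_for_slope=preds["age"].to_numpy())
    print(f"\nCNN raw ΔAge: bias {ba.bias:.2f} y (SD {ba.sd:.2f}), "
          f"LoA [{ba.loa_lower:.2f}, {ba.loa_upper:.2f}], "
          f"proportional-bias slope {ba.slope:.3f} "
          f"[{ba.slope_ci[0]:.3f}, {ba.slope_ci[1]:.3f}]")

    adjusted, slope, ci = st.adjust_delta_age(
        preds["raw_delta"].to_numpy(), preds["age"].to_numpy())
    preds["adjusted_delta"] = adjusted
    io.write_table(preds, OUT / "predictions_cnn_fingertip_adjusted.csv")

    # tertile BP models need the cohort's BP/BMI/sex (same seed as 04)
    participants = {p.id: p for p in cohort.draw_participants(160, SEED)}
    meta = preds["participant"].map(participants.get)
    sbp = np.array([p.sbp for p in meta])
    dbp = np.array([p.dbp for p in meta])
    sex = np.array([p.sex for p in meta])
    bmi = np.array([p.bmi for p in meta])
    for name, bp in (("SBP", sbp), ("DBP", dbp)):
        table, tests = st.tertile_bp_analysis(
            adjusted, bp, preds["age"].to_numpy(), sex, bmi)
        io.write_table(table, OUT / f"tertile_{name.lower()}.csv")
        print(f"\n{name} by ΔAge tertile (covariate-adjusted means):")
        print(table.round(2).to_string(index=False))
        for t in tests:
            print(f"  {t.name}: t={t.statistic:.2f}, "
                  f"p={t.p_value:.3f} ({t.correction})")


if __name__ == "__main__":
    main()
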