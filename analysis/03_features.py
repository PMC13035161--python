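"""Fiducial features and device agreement on the demonstration cohort.

Builds per-window Gaussian templates, locates fiducial points, computes
window-median CT/dT/RI, pairs windows across devices, and summarizes
the feature distributions and Bland–Altman device agreement.

Run from the repository root:  python analysis/03_features.py
"""

from pathlib import Path

import numpy as np
import pandas as pd

from pulseage import fiducials as fid, io, stats as st
from pulseage.preprocess import NormalizedPulse

OUT = Path("results")
N_PAIRS = 5  # demo cohort has short nights; the full study uses 20
SEED = 42


def window_frames(pulses_frame: pd.DataFrame) -> dict[str, pd.DataFrame]:
    out = {}
    for device, dev_frame in pulses_frame.groupby("device"):
        frames = []
        for pid, grp in dev_frame.groupby("participant"):
            pulses = [
                NormalizedPulse(
                    values=row[io.PULSE_COLS].to_numpy(dtype=float),
                    duration_s=row["duration_s"],
                    window_index=int(row["window"]),
                )
                for _, row in grp.iterrows()
            ]
            frames.append(io.window_feature_frame(pulses, pid))
        out[device] = pd.concat(frames, ignore_index=True)
    return out


def main() -> None:
    pulses_frame = io.read_pulses(OUT / "pulses.csv")
    manifest = pd.read_csv(OUT / "data" / "cohort_manifest.csv")
    ages = manifest.drop_duplicates("participant").set_index("participant")[
        "age"]

    wf = window_frames(pulses_frame)
    paired = fid.pair_and_sample(wf["fingertip"], wf["ring"],
                                 n_pairs=N_PAIRS, seed=SEED)
    paired["device"] = paired["device"].map({"a": "fingertip", "b": "ring"})
    paired["age"] = paired["participant"].map(ages)
    io.write_table(paired, OUT / "features_participant.csv")

    print("participant-level feature medians by device:")
    print(paired.groupby("device")[["ct", "dt", "ri"]].median().round(2))

    wide = paired.pivot(index="participant", columns="device")
    rows = []
    for feat in ("ct", "dt", "ri"):
        diff = (wide[(feat, "ring")] - wide[(feat, "fingertip")]).to_numpy()
        ba = st.bland_altman(diff)
        rows.append({"feature": feat, "bias": round(ba.bias, 3),
                     "sd": round(ba.sd, 3),
                     "loa_lower": round(ba.loa_lower, 3),
                     "loa_upper": round(ba.loa_upper, 3)})
    agreement = pd.DataFrame(rows)
    io.write_table(agreement, OUT / "device_agreement.csv")
    print("\ndevice agreement (ring - fingertip):")
    print(agreement.to_string(index=False))


if __name__ == "__main__":
    main()
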