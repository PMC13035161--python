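"""Extract quality-controlled normalized pulses from the raw recordings.

Reads the recordings written by 01_simulate.py, runs the signal chain
(band-pass, artifact mask, 30-s windows, onset detection, plausibility
filter, baseline removal, 200-sample width/amplitude normalization,
template-correlation QC) and writes per-device pulse tables plus a QC
summary.

Run from the repository root:  python analysis/02_preprocess.py
"""

from pathlib import Path

import pandas as pd

from pulseage import io
from pulseage import preprocess as pre

DATA = Path("results/data")
OUT = Path("results")


def main() -> None:
    manifest = pd.read_csv(DATA / "cohort_manifest.csv")
    frames = []
    qc_rows = []
    for _, row in manifest.iterrows():
        rec = io.read_recording(DATA / row["file"])
        pulses, report, windows = pre.extract_pulses(rec)
        frames.append(io.pulses_to_frame(pulses, row["participant"],
                                         row["device"]))
        qc_rows.append({
            "participant": row["participant"], "device": row["device"],
            "windows": len(windows),
            "windows_artifact": sum(w.artifact for w in windows),
            "pulses_accepted": report.n_accepted,
            "pulses_rejected": report.n_rejected,
        })
    pulses_frame = pd.concat(frames, ignore_index=True)
    io.write_pulses(pulses_frame, OUT / "pulses.csv")
    qc = pd.DataFrame(qc_rows)
    qc.to_csv(OUT / "qc_summary.csv", index=False)
    print(f"accepted {qc.pulses_accepted.sum()} pulses "
          f"({qc.pulses_rejected.sum()} rejected, "
          f"{qc.windows_artifact.sum()} artifact windows)")
    print(qc.groupby("device")[["pulses_accepted", "windows_artifact"]]
          .sum())


if __name__ == "__main__":
    main()
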