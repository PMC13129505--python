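#!/usr/bin/env python
"""Preprocess the simulated cohort: despike, 0.2 Hz low-pass, MBLL, CV QC.

Reads results/cohort/, writes per-subject HbO/HbR/HbT concentration CSVs
and the channel QC report to results/preprocessed/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from benage.preprocess import cv_table, preprocess_recording
from benage.synth import read_raw_csv

ROOT = Path(__file__).resolve().parent.parent / "results"
FS = 2000 / 300


def main() -> None:
    meta = pd.read_csv(ROOT / "cohort" / "subjects.csv")
    out = ROOT / "preprocessed"
    out.mkdir(parents=True, exist_ok=True)
    qc_rows = []
    for sid in meta["subject_id"]:
        raw = read_raw_csv(ROOT / "cohort" / f"{sid}_raw.csv", fs=FS)
        rec = preprocess_recording(raw)
        cols = {"time": np.arange(rec.n_samples) / rec.fs}
        for c in range(rec.n_channels):
            cols[f"ch{c + 1:02d}_hbo"] = rec.hbo[c]
            cols[f"ch{c + 1:02d}_hbr"] = rec.hbr[c]
            cols[f"ch{c + 1:02d}_hbt"] = rec.hbt[c]
        pd.DataFrame(cols).to_csv(out / f"{sid}_hemo.csv", index=False)
        cvs = cv_table(raw)
        for c, lab in enumerate(raw.channel_labels):
            qc_rows.append(
                {
                    "subject_id": sid,
                    "channel": lab,
                    "cv_w730": cvs[c, 0],
                    "cv_w850": cvs[c, 1],
                    "excluded": not rec.qc_mask[c],
                }
            )
    qc = pd.DataFrame(qc_rows)
    qc.to_csv(out / "qc_report.csv", index=False)
    print(
        f"preprocessed {meta.shape[0]} subjects; "
        f"{int(qc['excluded'].sum())} channel exclusions "
        f"(median CV {qc[['cv_w730', 'cv_w850']].median().median():.4f})"
    )


if __name__ == "__main__":
    main()
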