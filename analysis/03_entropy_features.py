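#!/usr/bin/env python
"""Compute static and dynamic permutation-entropy features per channel.

Reads results/preprocessed/ concentrations, computes PE (d = 3, tau = 1,
normalized) of each full series (static BEN) and the mean of PE over
200-sample windows with 50% overlap (dynamic BEN), for HbO/HbR/HbT on all
retained channels. Writes features.csv (subjects x 156) and the
feature-set column map to results/features/.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from benage.entropy import build_feature_matrix
from benage.preprocess import from_concentrations

ROOT = Path(__file__).resolve().parent.parent / "results"
FS = 2000 / 300


def load_hemo(sid: str, qc: pd.DataFrame):
    df = pd.read_csv(ROOT / "preprocessed" / f"{sid}_hemo.csv")
    chans = sorted({c.rsplit("_", 1)[0] for c in df.columns if c != "time"})
    hbo = np.stack([df[f"{ch}_hbo"].to_numpy() for ch in chans])
    hbr = np.stack([df[f"{ch}_hbr"].to_numpy() for ch in chans])
    mask = ~qc.loc[qc["subject_id"] == sid, "excluded"].to_numpy()
    return from_concentrations(sid, hbo, hbr, fs=FS, qc_mask=mask)


def main() -> None:
    meta = pd.read_csv(ROOT / "cohort" / "subjects.csv")
    qc = pd.read_csv(ROOT / "preprocessed" / "qc_report.csv")
    recs = [load_hemo(sid, qc) for sid in meta["subject_id"]]
    fm = build_feature_matrix(recs)
    out = ROOT / "features"
    out.mkdir(parents=True, exist_ok=True)
    fm.to_csv(out / "features.csv")
    (out / "feature_sets.json").write_text(json.dumps(fm.feature_sets, indent=2))
    vals = fm.values.to_numpy()
    print(
        f"features: {fm.values.shape[0]} subjects x {fm.values.shape[1]} "
        f"(dropped channels: {fm.dropped_channels or 'none'})"
    )
    print(f"normalized PE range: [{vals.min():.3f}, {vals.max():.3f}]")


if __name__ == "__main__":
    main()
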