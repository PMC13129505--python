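#!/usr/bin/env python
"""Channel-wise group statistics, age correlations and ROC discrimination.

Pooled t-tests (synthetic controls vs patients) on every BEN feature with
Benjamini-Hochberg FDR, Pearson correlations with age, single-feature AUCs,
and the logistic combination of significantly group-different features
(in-sample, mirroring conventional reporting, and stratified-CV, the honest
estimate). Also evaluates the brain-age gap of each feature set as an MDD
discriminator. Writes results/stats/.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from benage.entropy import FEATURE_SET_NAMES
from benage.stats import discriminate, group_difference_table, roc_auc

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    meta = pd.read_csv(ROOT / "cohort" / "subjects.csv")
    X = pd.read_csv(ROOT / "features" / "features.csv", index_col=0)
    labels = meta.set_index("subject_id").loc[X.index, "group"].to_numpy()
    age = meta.set_index("subject_id").loc[X.index, "age"].to_numpy()
    out = ROOT / "stats"
    out.mkdir(parents=True, exist_ok=True)

    table = group_difference_table(X, labels, age=age)
    table.to_csv(out / "group_stats.csv")
    sig = list(table.index[table["significant"]])
    n_age = int((table["r_age_p_fdr"] < 0.05).sum())
    print(
        f"{len(sig)}/{len(table)} features differ between groups at q<0.05; "
        f"{n_age} correlate with age after FDR"
    )

    single, combo = discriminate(X, labels, columns=sig or None)
    single.to_csv(out / "roc_table.csv")
    print(
        f"top single-feature AUC: {single['auc'].iloc[0]:.2f} "
        f"({single.index[0]}); combination of significant features: "
        f"in-sample AUC {combo['auc_in_sample']:.2f}, "
        f"5-fold CV AUC {combo['auc_cv']:.2f}"
    )

    bag_rows = []
    for name in FEATURE_SET_NAMES:
        ba = pd.read_csv(ROOT / "brainage" / f"brainage_{name}.csv")
        res = roc_auc(ba["bag"].to_numpy(), ba["group"].to_numpy(), "MDD")
        bag_rows.append({"feature_set": name, "bag_auc": round(res.auc, 3)})
    bag = pd.DataFrame(bag_rows)
    bag.to_csv(out / "bag_auc.csv", index=False)
    (out / "combination_roc.json").write_text(json.dumps(combo, indent=2))
    print("BAG as discriminator, AUC by feature set:")
    print(bag.to_string(index=False))


if __name__ == "__main__":
    main()
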