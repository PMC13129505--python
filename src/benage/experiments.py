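"""Reusable simulation experiments on synthetic cohorts.

These are the package's two headline in-silico studies, shared by the
analysis drivers, the test suite and the results-reproduction script:

* :func:`parameter_recovery` — does the full pipeline (generation ->
  preprocessing -> BEN features -> LOOCV SVR -> BAG -> ROC) recover a
  planted age-complexity gradient and patient offset at the reference
  cohort size (49 HC / 35 MDD, 26 channels, 2000 samples)?
* :func:`null_discovery_rate` — with no planted group effect, how often
  does the channel-wise pooled-t + Benjamini-Hochberg pipeline declare any
  discovery at q = 0.05? (Family-wise validity check of the group-testing
  machinery; expected at or below the nominal q.)

Static BEN features are used for both experiments: they carry the planted
signal just as the dynamic summaries do, at a fraction of the compute.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

from .brainage import apply_model, loocv_predict
from .entropy import build_feature_matrix
from .preprocess import preprocess_recording
from .stats import discriminate, group_difference_table, t_two_sample
from .synth import CohortConfig, generate_cohort, subjects_frame

#: Study conditions for the recovery experiment: reference cohort geometry
#: with the default planted aligned effects (beta_age = -0.3 on the mixing
#: parameter per sd of age; beta_group = -0.3 for the patient group).
RECOVERY_CONFIG = CohortConfig()

#: Null conditions: identical, but no group effect.
NULL_CONFIG = replace(CohortConfig(), beta_group=0.0)


@dataclass
class RecoveryResult:
    """One-seed outcome of the planted-effect recovery experiment."""

    seed: int
    loocv_r: float
    loocv_rmse: float
    hc_mean_bag: float
    mdd_mean_bag: float
    bag_t: float
    bag_p: float
    n_significant_features: int
    combined_auc_in_sample: float
    combined_auc_cv: float


def _static_features(config: CohortConfig):
    subjects, raws = generate_cohort(config)
    recs = [preprocess_recording(raw) for raw in raws]
    fm = build_feature_matrix(recs, modes=("static",))
    return subjects_frame(subjects), fm


def parameter_recovery(
    seed: int, config: CohortConfig = RECOVERY_CONFIG, feature_set: str = "Static_all"
) -> RecoveryResult:
    """Run the full pipeline on one planted-effect cohort.

    Trains the brain-age model on the synthetic controls under LOOCV,
    applies it to the synthetic patients, compares the groups' brain-age
    gaps with a pooled t-test, and evaluates the in-sample and
    cross-validated ROC of the logistic combination of the significantly
    group-different BEN features.
    """
    meta, fm = _static_features(replace(config, seed=seed))
    hc_res = loocv_predict(fm, meta, feature_set=feature_set)
    mdd_res = apply_model(fm, meta, hc_res, feature_set=feature_set)
    bag_t, _, bag_p = t_two_sample(mdd_res.table["bag"], hc_res.table["bag"])

    labels = meta["group"].to_numpy()
    table = group_difference_table(fm.values, labels)
    sig = list(table.index[table["significant"]])
    _, combo = discriminate(fm.values, labels, columns=sig or None, seed=seed)
    return RecoveryResult(
        seed=seed,
        loocv_r=hc_res.r,
        loocv_rmse=hc_res.rmse,
        hc_mean_bag=hc_res.mean_bag,
        mdd_mean_bag=mdd_res.mean_bag,
        bag_t=bag_t,
        bag_p=bag_p,
        n_significant_features=len(sig),
        combined_auc_in_sample=combo["auc_in_sample"],
        combined_auc_cv=combo["auc_cv"],
    )


def recovery_summary(results: list[RecoveryResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])


def null_discovery_rate(
    n_seeds: int = 200,
    base_seed: int = 0,
    config: CohortConfig = NULL_CONFIG,
    q: float = 0.05,
) -> tuple[float, pd.DataFrame]:
    """Fraction of null cohorts with ANY BH discovery at the given q.

    Each seed generates a cohort with ``beta_group = 0`` (group labels
    carry no signal), runs the standard preprocessing and static-BEN
    extraction, performs the 78 channel-wise pooled t-tests and BH
    adjustment, and records whether anything passes q. Under the global
    null the any-discovery probability is at most q (BH controls FDR =
    FWER under the complete null).
    """
    rows = []
    for i in range(n_seeds):
        seed = base_seed + i
        meta, fm = _static_features(replace(config, seed=seed))
        table = group_difference_table(fm.values, meta["group"].to_numpy(), q=q)
        rows.append(
            {
                "seed": seed,
                "n_features": len(table),
                "min_p_fdr": table["p_fdr"].min(),
                "any_discovery": bool(table["significant"].any()),
            }
        )
    df = pd.DataFrame(rows)
    return float(df["any_discovery"].mean()), df
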