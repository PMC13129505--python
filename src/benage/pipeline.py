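"""End-to-end orchestration: synth -> preprocess -> entropy -> brainage -> stats.

A single serializable :class:`RunConfig` drives the whole analysis; the run
directory receives every stage's CSV outputs plus a ``manifest.json``
recording the configuration, seed and per-stage shapes, sufficient to
reproduce any output file bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .brainage import BrainAgeResult, ScreenParams, SVRConfig, apply_model, loocv_predict
from .entropy import FEATURE_SET_NAMES, PEParams, WindowParams, build_feature_matrix
from .preprocess import cv_table, preprocess_recording
from .stats import discriminate, group_difference_table, roc_auc, t_two_sample
from .synth import CohortConfig, generate_cohort, subjects_frame

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Full-pipeline configuration (serializable to/from JSON)."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    pe: PEParams = field(default_factory=PEParams)
    window: WindowParams = field(default_factory=WindowParams)
    screen: ScreenParams = field(default_factory=ScreenParams)
    svr: SVRConfig = field(default_factory=SVRConfig)
    cv_threshold: float = 0.075
    lowpass_cutoff: float = 0.2
    despike_z: float = 5.0
    feature_sets: tuple[str, ...] = FEATURE_SET_NAMES
    seed: int = 0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        kwargs = dict(raw)
        for key, sub in (
            ("cohort", CohortConfig),
            ("pe", PEParams),
            ("window", WindowParams),
            ("screen", ScreenParams),
            ("svr", SVRConfig),
        ):
            if key in kwargs:
                d = dict(kwargs[key])
                for f in dataclasses.fields(sub):
                    if f.name in d and isinstance(d[f.name], list):
                        d[f.name] = tuple(d[f.name])
                kwargs[key] = sub(**d)
        if "feature_sets" in kwargs:
            kwargs["feature_sets"] = tuple(kwargs["feature_sets"])
        return cls(**kwargs)


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """Execute every stage and write outputs + manifest to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = dataclasses.replace(config.cohort, seed=config.seed)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "stages": {},
    }
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(manifest["config"], sort_keys=True).encode()
    ).hexdigest()[:16]

    # -- synth ----------------------------------------------------------
    subjects, raws = generate_cohort(cohort)
    meta = subjects_frame(subjects)
    meta.to_csv(out / "subjects.csv", index=False)
    manifest["stages"]["synth"] = {"n_subjects": len(subjects)}

    # -- preprocess ------------------------------------------------------
    recs, qc_rows = [], []
    for raw in raws:
        rec = preprocess_recording(
            raw,
            cv_threshold=config.cv_threshold,
            lowpass_cutoff=config.lowpass_cutoff,
            despike_z=config.despike_z,
        )
        recs.append(rec)
        cvs = cv_table(raw)
        for c, lab in enumerate(raw.channel_labels):
            qc_rows.append(
                {
                    "subject_id": raw.subject_id,
                    "channel": lab,
                    "cv_w1": cvs[c, 0],
                    "cv_w2": cvs[c, 1],
                    "excluded": not rec.qc_mask[c],
                }
            )
    qc = pd.DataFrame(qc_rows)
    qc.to_csv(out / "qc_report.csv", index=False)
    manifest["stages"]["preprocess"] = {
        "n_excluded_channels": int(qc["excluded"].sum())
    }

    # -- entropy ---------------------------------------------------------
    fm = build_feature_matrix(recs, config.pe, config.window)
    fm.to_csv(out / "features.csv")
    (out / "feature_sets.json").write_text(json.dumps(fm.feature_sets, indent=2))
    manifest["stages"]["entropy"] = {
        "n_subjects": len(fm.subjects),
        "n_features": len(fm.feature_names),
        "dropped_channels": fm.dropped_channels,
    }

    # -- brainage --------------------------------------------------------
    ba_summary = []
    results: dict[str, tuple[BrainAgeResult, BrainAgeResult]] = {}
    for fs_name in config.feature_sets:
        hc_res = loocv_predict(
            fm, meta, svr=config.svr, screen=config.screen, feature_set=fs_name
        )
        mdd_res = apply_model(
            fm, meta, hc_res, svr=config.svr, screen=config.screen,
            feature_set=fs_name,
        )
        results[fs_name] = (hc_res, mdd_res)
        pd.concat([hc_res.table, mdd_res.table]).to_csv(
            out / f"brainage_{fs_name}.csv", index=False
        )
        t, dfree, p = t_two_sample(
            mdd_res.table["bag"], hc_res.table["bag"]
        )
        ba_summary.append(
            {
                "feature_set": fs_name,
                "hc_r": hc_res.r,
                "hc_rmse": hc_res.rmse,
                "hc_mean_bag": hc_res.mean_bag,
                "mdd_mean_bag": mdd_res.mean_bag,
                "bag_t": t,
                "bag_p": p,
                "modal_c": mdd_res.folds[0].selected_c,
            }
        )
    ba_df = pd.DataFrame(ba_summary)
    ba_df.to_csv(out / "brainage_summary.csv", index=False)
    (out / "model_report.json").write_text(
        json.dumps(
            {
                fs: {
                    "folds": [dataclasses.asdict(f) for f in res[0].folds],
                    "r": res[0].r,
                    "rmse": res[0].rmse,
                }
                for fs, res in results.items()
            },
            indent=2,
        )
    )
    manifest["stages"]["brainage"] = {"feature_sets": list(config.feature_sets)}

    # -- stats -----------------------------------------------------------
    labels = meta["group"].to_numpy()
    gstats = group_difference_table(
        fm.values, labels, age=meta["age"].to_numpy()
    )
    gstats.to_csv(out / "group_stats.csv")
    sig_cols = list(gstats.index[gstats["significant"]])
    single, combo = discriminate(
        fm.values, labels, columns=sig_cols or None, seed=config.seed
    )
    single.to_csv(out / "roc_table.csv")
    bag_auc = {
        fs: roc_auc(
            np.r_[res[0].table["bag"], res[1].table["bag"]],
            np.r_[res[0].table["group"], res[1].table["group"]],
            "MDD",
        ).auc
        for fs, res in results.items()
    }
    (out / "discrimination.json").write_text(
        json.dumps({"combination": combo, "bag_auc": bag_auc}, indent=2)
    )
    manifest["stages"]["stats"] = {
        "n_significant_features": len(sig_cols),
        "combo_auc_in_sample": combo["auc_in_sample"],
    }

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    logger.info("pipeline complete: %s", out)
    return out
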