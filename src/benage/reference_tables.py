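"""Published reference-cohort summary statistics used in worked examples.

These are the printed group summaries from the clinical study this package's
analysis pipeline follows (49 healthy controls, 35 patients with major
depressive disorder; the underlying recordings are not public). They are
INPUTS for the summary-statistic worked examples — recomputing the printed
test statistics from printed (mean, SD, n) values — not outputs of this
package, and they never stand in for computed results.
"""

from __future__ import annotations

from .stats import SummaryStats

#: Predicted-brain-age group summaries per feature set:
#: (HC SummaryStats, MDD SummaryStats, printed pooled-t value).
PREDICTED_AGE_SUMMARIES: dict[str, tuple[SummaryStats, SummaryStats, float]] = {
    "HbO_static": (SummaryStats(27.31, 0.80, 49), SummaryStats(33.05, 1.21, 35), -26.18),
    "HbR_static": (SummaryStats(27.27, 0.79, 49), SummaryStats(32.54, 1.67, 35), -19.31),
    "HbT_static": (SummaryStats(27.87, 0.89, 49), SummaryStats(32.80, 1.45, 35), -19.26),
    "HbO_dynamic": (SummaryStats(27.03, 0.55, 49), SummaryStats(32.95, 1.19, 35), -30.69),
    "HbR_dynamic": (SummaryStats(27.41, 0.74, 49), SummaryStats(32.96, 1.78, 35), -19.56),
    "HbT_dynamic": (SummaryStats(27.09, 0.64, 49), SummaryStats(32.93, 1.64, 35), -22.67),
    "Static_all": (SummaryStats(27.54, 0.73, 49), SummaryStats(32.77, 1.34, 35), -22.97),
    "Dynamic_all": (SummaryStats(27.15, 0.58, 49), SummaryStats(32.68, 1.62, 35), -22.08),
    "ALL": (SummaryStats(27.12, 0.55, 49), SummaryStats(32.56, 1.55, 35), -22.72),
}

#: Printed sex counts (male, female) per group and the printed chi-square.
#: The printed MDD counts sum to 37 despite the stated n = 35; the counts
#: are used exactly as printed.
SEX_TABLE = {"MDD": (14, 23), "HC": (21, 28), "chi2": 0.22}

#: Best-model brain-age-gap means (years) reported for the reference
#: cohorts; context values only — not reproducible without the recordings.
REPORTED_BAG_YEARS = {"HC_best_model": 2.50, "MDD_best_model": 8.23}
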