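"""Printed characteristics of the 37-participant stroke/TBI study cohort.

These are the published group counts and summary statistics (16 stroke,
21 TBI survivors with residual upper-limb hemiparesis) that the
group-comparison statistics in :mod:`armscore.cohort_stats` operate on.
Categorical tables are (group × category) counts with stroke as the
first row; continuous summaries are (mean, SD, n) per group.

``PRINTED_CHI2`` / ``PRINTED_T`` hold the statistic values as printed in
the source table (2 decimal places).  Note that the inpatient-setting
chi-square recomputes to 6.3450 from the printed counts, one unit in the
last printed digit away from the printed 6.35; and that the printed age,
chronicity, and discharge-FAS t values are *not* recoverable from the
printed summaries under either pooled or Welch conventions (they were
presumably computed from unrounded data), so they are kept here only for
reference.
"""

from __future__ import annotations

__all__ = [
    "CATEGORICAL_TABLES",
    "CONTINUOUS_SUMMARIES",
    "PRINTED_CHI2",
    "PRINTED_T",
    "REPRODUCIBLE_T_ROWS",
    "N_STROKE",
    "N_TBI",
]

N_STROKE = 16
N_TBI = 21

# rows: (stroke, TBI); columns: variable categories
CATEGORICAL_TABLES: dict[str, list[list[int]]] = {
    "sex_male": [[9, 7], [17, 4]],                 # male / female
    "ethnicity": [[13, 2, 1], [20, 0, 1]],         # Caucasian / Afr.Am. / other
    "hemiparesis_left": [[11, 5], [6, 15]],        # left / right
    "setting_inpatient": [[10, 6], [20, 1]],       # inpatient / outpatient
    "affected_dominant": [[6, 10], [13, 8]],       # dominant / non-dominant
}

# (mean, sd, n) per group, stroke first
CONTINUOUS_SUMMARIES: dict[str, tuple[tuple, tuple]] = {
    "age_years": ((53.87, 25.74, N_STROKE), (34.03, 16.86, N_TBI)),
    "chronicity_months": ((13.03, 20.41, N_STROKE), (4.99, 8.17, N_TBI)),
    "fma_baseline": ((36.44, 10.43, N_STROKE), (37.10, 9.70, N_TBI)),
    "fma_discharge": ((45.69, 12.92, N_STROKE), (51.67, 11.78, N_TBI)),
    "fas_baseline": ((2.98, 0.73, N_STROKE), (3.17, 0.73, N_TBI)),
    "fas_discharge": ((3.51, 0.82, N_STROKE), (3.90, 0.84, N_TBI)),
}

PRINTED_CHI2: dict[str, tuple[float, int]] = {
    "sex_male": (2.65, 1),
    "ethnicity": (2.86, 2),
    "hemiparesis_left": (5.90, 1),
    "setting_inpatient": (6.35, 1),
    "affected_dominant": (2.17, 1),
}

PRINTED_T: dict[str, tuple[float, int]] = {
    "age_years": (3.65, 35),
    "chronicity_months": (1.49, 35),
    "fma_baseline": (-0.20, 35),
    "fma_discharge": (-1.47, 35),
    "fas_baseline": (-0.78, 35),
    "fas_discharge": (-1.39, 35),
}

#: Continuous rows whose printed t statistic is recoverable from the
#: printed summaries (pooled variance, 2 d.p.).
REPRODUCIBLE_T_ROWS = ("fma_baseline", "fma_discharge", "fas_baseline")
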