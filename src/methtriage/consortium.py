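"""Published consortium scale: cohort summary inputs and derived constants.

The motivating consortium meta-analysed 19 pregnancy cohorts for the newborn
EWAS of continuous maternal BMI.  The cohort sample sizes and mean maternal
BMIs below (from the published characteristics table) are the inputs from
which the sample-size-weighted mean BMI is computed, and they anchor the
synthetic generator's defaults.  The probe-coverage counts are the published
post-filter tallies: 473,864 autosomal non-control CpGs measured in at least
one cohort, of which 218,350 were measured in all 19 cohorts and 393,986 in
at least 18.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "NEWBORN_COHORTS",
    "PROBES_TOTAL",
    "PROBES_ALL_COHORTS",
    "PROBES_18_PLUS",
    "weighted_mean_bmi",
    "coverage_percentages",
]

#: (cohort, N in the continuous-BMI model, mean maternal BMI kg/m^2)
NEWBORN_COHORTS = pd.DataFrame(
    [
        ("ALSPAC", 788, 22.8),
        ("CBC_Hispanic", 132, 24.2),
        ("CBC_White", 155, 23.3),
        ("CHAMACOS", 368, 26.9),
        ("EARLI", 211, 27.8),
        ("GECKO", 176, 24.2),
        ("GEN3G", 170, 24.8),
        ("GenerationR", 875, 24.5),
        ("GOYA", 545, 23.1),
        ("IOW_F2", 53, 27.7),
        ("MEDALL", 330, 24.1),
        ("MoBa1", 1034, 24.0),
        ("MoBa2", 647, 24.2),
        ("MoBa3", 231, 24.2),
        ("NEST", 384, 27.6),
        ("NFCS", 867, 23.5),
        ("NHBCS", 118, 24.4),
        ("RICHS", 96, 25.8),
        ("ProjectViva", 343, 24.3),
    ],
    columns=["cohort", "n", "mean_bmi"],
)

PROBES_TOTAL = 473_864
PROBES_ALL_COHORTS = 218_350
PROBES_18_PLUS = 393_986


def weighted_mean_bmi(table: pd.DataFrame | None = None) -> float:
    """Sample-size-weighted mean maternal BMI across cohorts (kg/m^2)."""
    t = NEWBORN_COHORTS if table is None else table
    return float((t["n"] * t["mean_bmi"]).sum() / t["n"].sum())


def coverage_percentages() -> tuple[float, float]:
    """Percent of meta-analysed probes measured in all cohorts / in >= 18."""
    return (
        100.0 * PROBES_ALL_COHORTS / PROBES_TOTAL,
        100.0 * PROBES_18_PLUS / PROBES_TOTAL,
    )
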