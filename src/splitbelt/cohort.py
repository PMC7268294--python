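"""Reference cohort: 12 chronic-stage stroke survivors from the flat/incline
split-belt study this pipeline re-implements.

The table holds the published per-participant protocol values: age, sex,
affected body side, lower-extremity Fugl-Meyer score, the slow/mid/fast belt
speeds (m/s), total adaptation and post-adaptation stride counts for the flat
and incline sessions, and the incline-session slope (degrees).  It is used for
protocol-arithmetic checks (the slow/fast speeds derive from the mid speed)
and to parameterize realistic synthetic cohorts.
"""

from __future__ import annotations

import pandas as pd

from .config import derive_belt_speeds

_COLUMNS = [
    "subject_id", "age", "sex", "affected_side", "fugl_meyer",
    "slow_speed", "mid_speed", "fast_speed",
    "adapt_strides_flat", "adapt_strides_incline",
    "post_strides_flat", "post_strides_incline",
    "incline_slope_deg",
]

_ROWS = [
    ("P1",  43, "F", "R", 33, 0.75, 1.13, 1.50, 907, 609, 605, 303, 8.5),
    ("P2",  55, "F", "R", 26, 0.54, 0.81, 1.08, 867, 301, 642, 300, 5.0),
    ("P3",  64, "F", "R", 29, 0.40, 0.60, 0.80, 617, 368, 307, 10,  5.0),
    ("P4",  58, "F", "R", 21, 0.30, 0.45, 0.60, 901, 406, 625, 10,  5.0),
    ("P5",  66, "M", "R", 30, 0.51, 0.77, 1.02, 606, 452, 599, 302, 5.0),
    ("P6",  60, "F", "R", 26, 0.60, 0.90, 1.20, 907, 597, 600, 300, 5.0),
    ("P7",  77, "M", "R", 30, 0.23, 0.35, 0.47, 589, 605, 598, 302, 5.0),
    ("P8",  59, "M", "R", 32, 0.47, 0.70, 0.93, 905, 608, 600, 306, 8.5),
    ("P9",  52, "M", "R", 32, 0.64, 0.96, 1.28, 903, 602, 603, 302, 5.0),
    ("P10", 66, "M", "L", 29, 0.51, 0.76, 1.01, 908, 519, 602, 299, 8.5),
    ("P11", 75, "M", "R", 32, 0.63, 0.94, 1.25, 913, 497, 552, 306, 5.0),
    ("P12", 49, "M", "R", 33, 0.47, 0.71, 0.95, 931, 450, 303, 300, 5.0),
]


def reference_cohort() -> pd.DataFrame:
    """The published participant table as a DataFrame (one row per subject)."""
    return pd.DataFrame(_ROWS, columns=_COLUMNS)


def age_summary() -> tuple[float, float]:
    """(mean, sample SD) of participant ages."""
    ages = reference_cohort()["age"]
    return float(ages.mean()), float(ages.std(ddof=1))


def speed_rule_report() -> pd.DataFrame:
    """Derived vs. published slow/fast speeds for every participant.

    Adds columns with the speeds derived from each printed mid speed and
    boolean exact-match flags.  The derivation reproduces the published values
    except where the printed mid speed itself was rounded (see methods note).
    """
    table = reference_cohort().copy()
    derived = table["mid_speed"].map(derive_belt_speeds)
    table["derived_slow"] = [s for s, _ in derived]
    table["derived_fast"] = [f for _, f in derived]
    table["slow_matches"] = table["derived_slow"] == table["slow_speed"]
    table["fast_matches"] = table["derived_fast"] == table["fast_speed"]
    return table
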