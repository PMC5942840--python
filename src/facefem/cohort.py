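"""Packaged reference cohort of eight Le Fort I maxillary advancement cases.

Ages, sex, imaging time intervals (days) and planned advancements (mm) for
the eight-subject cohort are shipped as a plain CSV fixture; the loader
never touches the network.  The synthetic pipeline uses the planned
advancements as per-subject surgical plans and the ids to define the
training/validation split.
"""

from __future__ import annotations

import math
from importlib import resources

import pandas as pd

#: Convenience aliases for the verbose fixture column names.
COLUMN_ALIASES = {
    "advancement": "planned_maxillary_advancement_mm",
    "planned_advancement": "planned_maxillary_advancement_mm",
    "surgery_to_postop": "surgery_to_postop_cbct_days",
    "preop_to_surgery": "preop_cbct_to_surgery_days",
    "preop_to_postop": "preop_cbct_to_postop_cbct_days",
}

_STATISTICS = ("mean", "sd")
_ROUNDINGS = ("none", "integer", "1dp")


def load_cohort_table() -> pd.DataFrame:
    """Load the packaged eight-subject cohort table."""
    with resources.files("facefem.data").joinpath("cohort.csv").open() as fh:
        table = pd.read_csv(fh)
    if len(table) != 8:
        raise ValueError("cohort fixture must contain exactly 8 records")
    return table


def _round_half_away(x: float) -> float:
    return math.copysign(math.floor(abs(x) + 0.5), x)


def summarize_column(
    table: pd.DataFrame,
    column: str,
    statistic: str = "mean",
    rounding: str = "none",
) -> float:
    """Summary statistic over all eight cohort values.

    ``statistic`` is ``"mean"`` or ``"sd"`` (sample SD, n-1 denominator);
    ``rounding`` is ``"none"``, ``"integer"`` (half away from zero) or
    ``"1dp"``.
    """
    column = COLUMN_ALIASES.get(column, column)
    if column not in table.columns:
        raise KeyError(f"unknown cohort column {column!r}")
    if statistic not in _STATISTICS:
        raise ValueError(f"statistic must be one of {_STATISTICS}")
    if rounding not in _ROUNDINGS:
        raise ValueError(f"rounding must be one of {_ROUNDINGS}")
    values = pd.to_numeric(table[column])
    out = float(values.mean()) if statistic == "mean" else float(values.std(ddof=1))
    if rounding == "integer":
        return _round_half_away(out)
    if rounding == "1dp":
        return _round_half_away(out * 10.0) / 10.0
    return out
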