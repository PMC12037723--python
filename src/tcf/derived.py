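"""Derived clinical indices computed from raw counts and vitals.

Five ratios routinely used as sepsis severity markers:

* NLR — neutrophil-to-lymphocyte ratio
* PLR — platelet-to-lymphocyte ratio
* LMR — lymphocyte-to-monocyte ratio
* PAR — platelet-to-albumin ratio
* SI  — shock index, heart rate / systolic blood pressure

Counts are in 10^9/L, albumin in g/L, heart rate in beats/min, systolic
pressure in mmHg; no unit conversion is performed.  A ratio whose numerator
or denominator is missing, or whose denominator is zero, is missing (NaN) —
never infinity, so downstream min-max scaling is not poisoned.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np


from tcf.cohort import CohortTable, ColumnSpec

#: ratio name -> (numerator input, denominator input)
RATIO_DEFINITIONS: dict[str, tuple[str, str]] = {
    "NLR": ("neutrophil_count", "lymphocyte_count"),
    "PLR": ("platelet_count", "lymphocyte_count"),
    "LMR": ("lymphocyte_count", "monocyte_count"),
    "PAR": ("platelet_count", "albumin"),
    "SI": ("heart_rate", "systolic_bp"),
}

INPUT_FIELDS = (
    "neutrophil_count",
    "lymphocyte_count",
    "platelet_count",
    "monocyte_count",
    "albumin",
    "heart_rate",
    "systolic_bp",
)

#: default cohort column name for each raw input
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "neutrophil_count": "NEUT",
    "lymphocyte_count": "LYM",
    "platelet_count": "PLT",
    "monocyte_count": "MONO",
    "albumin": "ALB",
    "heart_rate": "HR",
    "systolic_bp": "SBP",
}


def _checked(values: Mapping[str, float | None]) -> dict[str, float]:
    out = {}
    for name in INPUT_FIELDS:
        v = values.get(name)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            out[name] = np.nan
            continue
        v = float(v)
        if v < 0:
            raise ValueError(f"{name} must be nonnegative, got {v}")
        out[name] = v
    return out


def compute_ratios(inputs: Mapping[str, float | None]) -> dict[str, float]:
    """Compute the five derived indices for one patient.

    Parameters
    ----------
    inputs
        Mapping from input field names (see ``INPUT_FIELDS``) to values;
        absent or None/NaN entries are treated as missing.

    Returns
    -------
    dict mapping ``NLR, PLR, LMR, PAR, SI`` to a float or NaN.
    """
    v = _checked(inputs)
    out = {}
    for ratio, (num, den) in RATIO_DEFINITIONS.items():
        a, b = v[num], v[den]
        out[ratio] = np.nan if (np.isnan(a) or np.isnan(b) or b == 0) else a / b
    return out


def add_derived_features(
    table: CohortTable, column_map: Mapping[str, str] | None = None
) -> CohortTable:
    """Append the five ratio columns to a cohort (vectorised).

    ``column_map`` maps input field names to cohort column names; inputs whose
    column is absent from the cohort are treated as all-missing, so the
    ratios that need them come out missing rather than failing.
    """
    cmap = dict(DEFAULT_COLUMN_MAP if column_map is None else column_map)
    n = table.n_patients
    cols: dict[str, np.ndarray] = {}
    for field, col in cmap.items():
        if col in table.frame.columns:
            vals = table.frame[col].to_numpy(dtype=float)
            if np.nanmin(vals, initial=np.inf) < 0:
                raise ValueError(f"negative values in input column {col!r}")
            cols[field] = vals
        else:
            cols[field] = np.full(n, np.nan)
    out = table
    for ratio, (num, den) in RATIO_DEFINITIONS.items():
        a, b = cols[num], cols[den]
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where((b == 0) | np.isnan(a) | np.isnan(b), np.nan, a / b)
        out = out.append_feature(ColumnSpec(ratio, "continuous", "", "feature"), r)
    return out
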