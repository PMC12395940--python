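"""Schema and validation for the per-unit area table.

An area table is a pandas DataFrame with one row per areal unit:

    unit_id                              string, unique
    pop_F_lt65, pop_F_ge65,
    pop_M_lt65, pop_M_ge65               person-years by age-sex stratum
    y_inc_F_lt65, ..., y_inc_M_ge65      observed late-stage case counts
    y_mort_F_lt65, ..., y_mort_M_ge65    observed death counts
    x                                    exposure (screening rate, pct points)
    rurality, pcp_density,
    specialist_density, income,
    immigrants                           covariates
    u_true                               latent confounder (synthetic only)
"""

from __future__ import annotations

import numpy as np
import pandas as pd

STRATA: tuple[str, ...] = ("F_lt65", "F_ge65", "M_lt65", "M_ge65")
OUTCOMES: tuple[str, ...] = ("incidence", "mortality")
_PREFIX = {"incidence": "y_inc", "mortality": "y_mort"}

COVARIATES: tuple[str, ...] = (
    "rurality",
    "pcp_density",
    "specialist_density",
    "income",
    "immigrants",
)


def pop_cols(strata: tuple[str, ...] = STRATA) -> list[str]:
    return [f"pop_{s}" for s in strata]


def count_cols(outcome: str, strata: tuple[str, ...] = STRATA) -> list[str]:
    if outcome not in _PREFIX:
        raise ValueError(f"outcome must be one of {OUTCOMES}, got {outcome!r}")
    return [f"{_PREFIX[outcome]}_{s}" for s in strata]


def validate_area_table(
    areas: pd.DataFrame, strata: tuple[str, ...] = STRATA
) -> pd.DataFrame:
    """Check the schema invariants; returns the table unchanged.

    Raises ValueError on missing/duplicate ids, nonpositive populations,
    counts exceeding populations, or negative exposure.
    """
    if "unit_id" not in areas.columns:
        raise ValueError("area table must have a unit_id column")
    ids = areas["unit_id"]
    if ids.isna().any():
        raise ValueError("missing unit_id values")
    if ids.duplicated().any():
        dupes = ids[ids.duplicated()].tolist()
        raise ValueError(f"duplicate unit ids: {dupes}")
    for col in pop_cols(strata):
        if col not in areas.columns:
            raise ValueError(f"missing population column {col}")
        if (areas[col] <= 0).any():
            raise ValueError(f"nonpositive population in {col}")
    for outcome in OUTCOMES:
        for s in strata:
            ycol = f"{_PREFIX[outcome]}_{s}"
            if ycol not in areas.columns:
                continue
            y = areas[ycol]
            if (y < 0).any():
                raise ValueError(f"negative counts in {ycol}")
            if (y > areas[f"pop_{s}"]).any():
                raise ValueError(f"counts exceed population in {ycol}")
    if "x" in areas.columns and (np.asarray(areas["x"]) < 0).any():
        raise ValueError("exposure x must be nonnegative")
    return areas


def aggregate_counts(
    areas: pd.DataFrame, outcome: str, strata: tuple[str, ...] = STRATA
) -> np.ndarray:
    """Per-unit aggregate count y_i = sum over strata."""
    return areas[count_cols(outcome, strata)].to_numpy().sum(axis=1)
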