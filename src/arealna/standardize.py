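"""Indirect age-sex standardization: expected counts and standardized ratios.

Reference stratum rates are computed from the pooled analysis table itself
(internal standardization) by default, so expected counts conserve the
observed total: sum(E_i) = sum(O_i).  External reference rates may be
supplied instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .areas import STRATA, aggregate_counts, count_cols, pop_cols

__all__ = ["StratumRates", "national_rates", "expected_counts", "smr_table"]


@dataclass(frozen=True)
class StratumRates:
    """Events per person-year for each age-sex stratum, one outcome."""

    outcome: str
    rates: dict[str, float]

    def __post_init__(self) -> None:
        for s, r in self.rates.items():
            if r < 0:
                raise ValueError(f"negative rate for stratum {s}")

    def as_array(self, strata: tuple[str, ...] = STRATA) -> np.ndarray:
        return np.array([self.rates[s] for s in strata])


def national_rates(
    areas: pd.DataFrame, outcome: str, strata: tuple[str, ...] = STRATA
) -> StratumRates:
    """Pooled stratum-specific rates: total events / total person-years."""
    rates: dict[str, float] = {}
    for s, ycol, pcol in zip(strata, count_cols(outcome, strata), pop_cols(strata)):
        pop = float(areas[pcol].sum())
        if pop <= 0:
            raise ValueError(f"stratum {s} has zero total population")
        rates[s] = float(areas[ycol].sum()) / pop
    return StratumRates(outcome=outcome, rates=rates)


def expected_counts(
    areas: pd.DataFrame,
    rates: StratumRates,
    strata: tuple[str, ...] = STRATA,
) -> pd.DataFrame:
    """Per-unit observed counts O, expected counts E, and ratio O/E.

    E_i = sum_s pop[s]_i * r_s.  Units with E_i = 0 and O_i = 0 get an
    undefined (NaN) ratio and are flagged in the ``smr_defined`` column;
    E_i = 0 with O_i > 0 is an error.
    """
    r = rates.as_array(strata)
    P = areas[pop_cols(strata)].to_numpy(dtype=float)
    E = P @ r
    O = aggregate_counts(areas, rates.outcome, strata).astype(float)
    bad = (E == 0) & (O > 0)
    if bad.any():
        where = areas.loc[bad, "unit_id"].tolist()
        raise ValueError(f"zero expected count with observed cases in units {where}")
    undefined = E == 0
    if undefined.any():
        warnings.warn(
            f"{int(undefined.sum())} unit(s) have zero expected count; "
            "SMR undefined there",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        smr = np.where(undefined, np.nan, O / np.where(E == 0, np.nan, E))
    return pd.DataFrame(
        {
            "unit_id": areas["unit_id"].to_numpy(),
            "O": O,
            "E": E,
            "smr": smr,
            "smr_defined": ~undefined,
        }
    )


def smr_table(
    areas: pd.DataFrame,
    outcome: str,
    rates: StratumRates | None = None,
    strata: tuple[str, ...] = STRATA,
) -> pd.DataFrame:
    """Convenience wrapper: internal rates unless external ones are given."""
    if rates is None:
        rates = national_rates(areas, outcome, strata)
    elif rates.outcome != outcome:
        raise ValueError(
            f"rates are for {rates.outcome!r}, requested outcome {outcome!r}"
        )
    return expected_counts(areas, rates, strata)
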