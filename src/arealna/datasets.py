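"""Packaged reference data."""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_stage_counts"]


def load_stage_counts() -> pd.DataFrame:
    """National late-stage CRC counts by sex and age group, Norway 2016-2021.

    Long format: age_group in {total, lt65, ge65}, sex in {female, male},
    outcome in {mortality, incidence}, with the published count and rate
    per 10 000 population.
    """
    ref = resources.files("arealna").joinpath(
        "data/norway_crc_late_stage_2016_2021.csv"
    )
    with resources.as_file(ref) as path:
        return pd.read_csv(path)
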