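"""Years of potential life lost and present value of future lost productivity.

The model
---------

For a death at integer age ``a`` of sex ``s``, the years of potential life
lost (YPLL) are the remaining life expectancy ``e(s, a)`` from the life
table. Death-count tables are fractional after HPV attribution, so table
totals are ``sum over ages of count(a) * e(s, a)``.

The present value of future lost productivity (PVFLP) follows the
human-capital approach: every future year of expected life contributes the
market earnings and the non-market (household and caregiving) production the
decedent would have generated, discounted back to the reference year. With
``L = e(s, a)`` and discount rate ``r``, lost years are attained ages
``k = a + 1, ..., a + floor(L)`` (no productivity is counted in the year of
death itself), each discounted by ``(1 + r)^-(k - a)``:

* market: ``participation(s, k) * weekly_wage(s, k) * 52 * markup`` — the
  annualized wage times the fringe-benefit markup (default 1.464). The
  ``as_printed`` annualization drops the factor 52 and reproduces the
  weekly-scale arithmetic of the source worked example; ``weeks52`` is the
  pipeline default.
* non-market: the profile's annual non-market value at attained age ``k``,
  with no participation or markup multiplier (it is already a
  population-average annual amount).

Economic values are looked up at the attained age in each future year, so a
decedent's stream walks through successive age bins; attained ages past 100
use the terminal bin. A fractional final year can optionally be counted with
weight ``frac(L)`` (``final_year_handling="fractional"``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError
from .types import (
    BurdenResult,
    EconProfile,
    LifeTable,
    MortalityTable,
    RESULT_COLUMNS,
    TOTAL_LABEL,
)

ANNUALIZATIONS = ("weeks52", "as_printed")
FINAL_YEAR_MODES = ("truncate", "fractional")


@dataclass(frozen=True)
class PvflpSettings:
    """Knobs of the productivity-loss calculation.

    annualization
        ``weeks52`` multiplies the weekly wage by 52 (annual earnings; the
        pipeline default); ``as_printed`` leaves it on the weekly scale for
        verifying the source's literal worked-example arithmetic.
    discount_rate
        Annual discount rate converting future values to the reference year
        (default 0.03).
    markup
        Fringe-benefit markup converting wages to total compensation
        (default 1.464).
    first_lost_age_offset
        First lost year is at attained age ``age + offset`` (default 1: the
        year of death contributes nothing).
    final_year_handling
        ``truncate`` counts floor(L) whole years; ``fractional`` adds the
        final partial year weighted by frac(L).
    """

    annualization: str = "weeks52"
    discount_rate: float = 0.03
    markup: float = 1.464
    first_lost_age_offset: int = 1
    final_year_handling: str = "truncate"

    def __post_init__(self):
        if self.annualization not in ANNUALIZATIONS:
            raise DataError(f"annualization must be one of {ANNUALIZATIONS}")
        if self.final_year_handling not in FINAL_YEAR_MODES:
            raise DataError(f"final_year_handling must be one of {FINAL_YEAR_MODES}")
        if self.discount_rate < 0:
            raise DataError("discount_rate must be non-negative")
        if not (self.markup > 0):
            raise DataError("markup must be positive")
        if self.first_lost_age_offset < 0:
            raise DataError("first_lost_age_offset must be non-negative")

    @classmethod
    def from_profile(cls, econ: EconProfile, **overrides) -> "PvflpSettings":
        """Settings seeded with a profile's markup and discount rate."""
        base = {"markup": econ.markup, "discount_rate": econ.discount_rate}
        base.update(overrides)
        return cls(**base)


def ypll_for_death(age: int, sex: str, lt: LifeTable) -> float:
    """Remaining life expectancy at the age of death — the YPLL of one death."""
    return lt.expectancy(sex, age)


def total_ypll(attributed: MortalityTable, lt: LifeTable) -> dict[tuple[str, str], float]:
    """Per-(site, sex) YPLL: sum over ages of count(age) x e(sex, age)."""
    out: dict[tuple[str, str], float] = {}
    for row in attributed.data.itertuples(index=False):
        key = (row.site, row.sex)
        out[key] = out.get(key, 0.0) + row.deaths * lt.expectancy(row.sex, row.age)
    return out


def annual_market_value(
    age: int, sex: str, econ: EconProfile, settings: PvflpSettings
) -> float:
    """Expected annual market compensation lost at an attained age."""
    participation, weekly_wage, _ = econ.row_for(sex, age)
    weeks = 52.0 if settings.annualization == "weeks52" else 1.0
    return participation * weekly_wage * weeks * settings.markup


def annual_nonmarket_value(age: int, sex: str, econ: EconProfile) -> float:
    """Annual value of lost non-market work at an attained age (no markup)."""
    return econ.row_for(sex, age)[2]


def pvflp_for_death(
    age: int,
    sex: str,
    lt: LifeTable,
    econ: EconProfile,
    settings: PvflpSettings,
) -> tuple[float, float]:
    """Discounted (market, non-market) productivity lost by one death.

    Walks every lost year at its attained age, values it with the economic
    profile, and discounts by ``(1 + r)^-(k - age)``.
    """
    L = lt.expectancy(sex, age)
    r = settings.discount_rate
    n_full = math.floor(L)
    market = 0.0
    nonmarket = 0.0
    for k in range(age + settings.first_lost_age_offset, age + n_full + 1):
        disc = (1.0 + r) ** -(k - age)
        market += annual_market_value(k, sex, econ, settings) * disc
        nonmarket += annual_nonmarket_value(k, sex, econ) * disc
    if settings.final_year_handling == "fractional":
        frac = L - n_full
        if frac > 0:
            k = age + n_full + 1
            if k >= age + settings.first_lost_age_offset:
                disc = frac * (1.0 + r) ** -(k - age)
                market += annual_market_value(k, sex, econ, settings) * disc
                nonmarket += annual_nonmarket_value(k, sex, econ) * disc
    return market, nonmarket


def total_burden(
    attributed: MortalityTable,
    lt: LifeTable,
    econ: EconProfile,
    settings: PvflpSettings,
    hpv_group: str = "any",
) -> BurdenResult:
    """Aggregate deaths, YPLL, and PVFLP per (site, sex) stratum.

    Returns one row per stratum plus a grand-total row (site and sex
    ``"all"``) whose entries are the exact sums over strata. Per-death
    quotients are NaN for zero-death strata.
    """
    pv_cache: dict[tuple[str, int], tuple[float, float]] = {}
    rows = []
    df = attributed.data
    for (site, sex), grp in df.groupby(["site", "sex"], sort=False):
        deaths = ypll = market = nonmarket = 0.0
        for row in grp.itertuples(index=False):
            key = (row.sex, row.age)
            if key not in pv_cache:
                pv_cache[key] = pvflp_for_death(row.age, row.sex, lt, econ, settings)
            m, nm = pv_cache[key]
            deaths += row.deaths
            ypll += row.deaths * lt.expectancy(row.sex, row.age)
            market += row.deaths * m
            nonmarket += row.deaths * nm
        rows.append((site, sex, deaths, ypll, market, nonmarket))

    records = []
    tot = np.zeros(4)
    for site, sex, deaths, ypll, market, nonmarket in sorted(
        rows, key=lambda t: (t[1], t[0])
    ):
        tot += (deaths, ypll, market, nonmarket)
        records.append(_result_row(site, sex, hpv_group, deaths, ypll, market, nonmarket))
    records.append(_result_row(TOTAL_LABEL, TOTAL_LABEL, hpv_group, *tot))
    return BurdenResult(pd.DataFrame(records, columns=RESULT_COLUMNS))


def _result_row(site, sex, group, deaths, ypll, market, nonmarket):
    total = market + nonmarket
    ypll_pd = ypll / deaths if deaths > 0 else float("nan")
    pv_pd = total / deaths if deaths > 0 else float("nan")
    return (site, sex, group, deaths, ypll, market, nonmarket, total, ypll_pd, pv_pd)
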