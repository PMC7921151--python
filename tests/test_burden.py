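"""YPLL and discounted productivity-loss calculations."""

import math

import numpy as np
import pandas as pd
import pytest

import hpvburden as hb
from hpvburden.errors import CoverageError, DataError
from conftest import scalar_attribution
import _oracles


# ------------------------------------------------------------------------ YPLL

def test_ypll_anchor_and_scaling(life_table):
    """e(female, 25) = 57 years, so 5.46 deaths lose 311.22 years."""
    e = hb.ypll_for_death(25, "female", life_table)
    assert e == 57.0
    assert 5.46 * e == pytest.approx(311.22, abs=1e-9)


def test_ypll_age_outside_coverage_errors(life_table):
    with pytest.raises(CoverageError):
        hb.ypll_for_death(101, "female", life_table)


def test_total_ypll_matches_per_entry_loop(life_table):
    """Table-level YPLL equals an independent per-entry accumulation."""
    rng = np.random.default_rng(11)
    ages = rng.integers(15, 101, size=50)
    counts = rng.uniform(0, 40, size=50)
    records = [("anus", "male", int(a), float(c)) for a, c in zip(ages, counts)]
    table = hb.MortalityTable(
        pd.DataFrame(records, columns=["site", "sex", "age", "deaths"])
        .groupby(["site", "sex", "age"], as_index=False)["deaths"].sum()
    )
    edict = _oracles.life_expectancy_dict()
    expected = sum(c * edict[("male", int(a))] for a, c in zip(ages, counts))
    got = hb.total_ypll(table, life_table)[("anus", "male")]
    assert got == pytest.approx(expected, rel=1e-9)


def test_total_ypll_additive_across_strata(life_table):
    t1 = hb.MortalityTable.from_records([("cervix", "female", 40, 10.0)])
    t2 = hb.MortalityTable.from_records([("penis", "male", 60, 5.0)])
    both = hb.MortalityTable(pd.concat([t1.data, t2.data]))
    a = hb.total_ypll(both, life_table)
    assert a[("cervix", "female")] == hb.total_ypll(t1, life_table)[("cervix", "female")]
    assert a[("penis", "male")] == hb.total_ypll(t2, life_table)[("penis", "male")]


# --------------------------------------------------------------- annual values

AS_PRINTED = hb.PvflpSettings(annualization="as_printed")
WEEKS52 = hb.PvflpSettings()


@pytest.mark.parametrize(
    "age,sex,expected",
    [
        (27, "female", 809.79),  # 0.764 x 724 x 1.464
        (32, "female", 789.65),  # 0.745 x 724 x 1.464
    ],
)
def test_annual_market_value_as_printed(econ, age, sex, expected):
    got = hb.annual_market_value(age, sex, econ, AS_PRINTED)
    assert got == pytest.approx(expected, abs=0.005)


def test_annual_market_value_weeks52(econ):
    got = hb.annual_market_value(27, "female", econ, WEEKS52)
    assert got == pytest.approx(809.79 * 52, abs=0.5)


@pytest.mark.parametrize("sex", ["female", "male"])
def test_age_15_has_zero_productivity(econ, sex):
    assert hb.annual_market_value(15, sex, econ, WEEKS52) == 0.0
    assert hb.annual_nonmarket_value(15, sex, econ) == 0.0


@pytest.mark.parametrize(
    "age,sex,expected",
    [(27, "female", 33087.0), (80, "male", 11896.0), (105, "male", 11896.0)],
)
def test_annual_nonmarket_value(econ, age, sex, expected):
    """Non-market value is the bin's annual amount; ages past 100 use 75+."""
    assert hb.annual_nonmarket_value(age, sex, econ) == expected


# ----------------------------------------------------------- pvflp_for_death

def test_single_lost_year_discount_identities(flat_life_table, econ):
    """With e = 1 everywhere, one year is lost at age+1: undiscounted it is
    worth the annual value exactly; at rate r it is worth value / (1 + r)."""
    v_market = hb.annual_market_value(41, "male", econ, WEEKS52)
    v_nonmarket = hb.annual_nonmarket_value(41, "male", econ)
    m0, n0 = hb.pvflp_for_death(
        40, "male", flat_life_table, econ, hb.PvflpSettings(discount_rate=0.0)
    )
    assert (m0, n0) == (v_market, v_nonmarket)
    m3, n3 = hb.pvflp_for_death(40, "male", flat_life_table, econ, WEEKS52)
    assert m3 == pytest.approx(v_market / 1.03, rel=1e-12)
    assert n3 == pytest.approx(v_nonmarket / 1.03, rel=1e-12)


def test_pvflp_matches_independent_loop(life_table, econ):
    """Spot-check against the independently coded year-by-year loop."""
    edict = _oracles.life_expectancy_dict()
    for age, sex in [(25, "female"), (25, "male"), (60, "female"), (99, "male")]:
        got = hb.pvflp_for_death(age, sex, life_table, econ, WEEKS52)
        want = _oracles.pvflp_loop(age, sex, edict[(sex, age)], 0.03)
        assert got == pytest.approx(want, rel=1e-9)
        undisc = _oracles.pvflp_loop(age, sex, edict[(sex, age)], 0.0)
        assert sum(got) < sum(undisc)  # discounting strictly shrinks the stream


def test_final_year_handling_modes(econ):
    """Truncate and fractional agree on integer expectancies; a fractional
    expectancy adds the partial year's discounted value."""
    rows = [{"sex": s, "age": a, "e": 10.0 if a % 2 else 10.5}
            for s in ("female", "male") for a in range(15, 101)]
    lt = hb.LifeTable(pd.DataFrame(rows))
    trunc = hb.PvflpSettings(final_year_handling="truncate")
    frac = hb.PvflpSettings(final_year_handling="fractional")
    # integer L: identical
    assert hb.pvflp_for_death(41, "female", lt, econ, trunc) == hb.pvflp_for_death(
        41, "female", lt, econ, frac
    )
    # L = 10.5: fractional adds half the 11th year, discounted
    mt, nt = hb.pvflp_for_death(40, "female", lt, econ, trunc)
    mf, nf = hb.pvflp_for_death(40, "female", lt, econ, frac)
    extra_m = 0.5 * hb.annual_market_value(51, "female", econ, frac) / 1.03**11
    assert mf - mt == pytest.approx(extra_m, rel=1e-12)
    assert nf > nt


def test_discount_monotonicity(life_table, econ):
    rates = [0.0, 0.01, 0.03, 0.06, 0.10]
    vals = [
        sum(hb.pvflp_for_death(30, "female", life_table, econ,
                               hb.PvflpSettings(discount_rate=r)))
        for r in rates
    ]
    assert all(a > b for a, b in zip(vals, vals[1:]))


def test_settings_validation():
    with pytest.raises(DataError):
        hb.PvflpSettings(annualization="monthly")
    with pytest.raises(DataError):
        hb.PvflpSettings(discount_rate=-0.01)
    with pytest.raises(DataError):
        hb.PvflpSettings(final_year_handling="extrapolate")


# ---------------------------------------------------------------- total_burden

def test_total_burden_empty_table(life_table, econ):
    empty = hb.MortalityTable(pd.DataFrame(columns=["site", "sex", "age", "deaths"]))
    res = hb.total_burden(empty, life_table, econ, WEEKS52)
    totals = res.totals()
    assert len(res.strata()) == 0 and len(totals) == 1
    assert totals.loc[0, ["deaths", "ypll", "pvflp_total"]].tolist() == [0.0, 0.0, 0.0]
    assert math.isnan(totals.loc[0, "ypll_per_death"])


def test_total_burden_single_stratum_equals_totals(life_table, econ):
    table = hb.MortalityTable.from_records(
        [("cervix", "female", 25, 5.46), ("cervix", "female", 40, 2.0)]
    )
    res = hb.total_burden(table, life_table, econ, WEEKS52)
    stratum = res.strata().iloc[0]
    total = res.totals().iloc[0]
    for col in ("deaths", "ypll", "pvflp_market", "pvflp_nonmarket", "pvflp_total"):
        assert stratum[col] == total[col]
    assert stratum["ypll_per_death"] == pytest.approx(stratum["ypll"] / 7.46)
    res.validate()


def test_total_burden_conservation(synthetic_table, attribution, life_table, econ):
    """Grand totals equal the sums over strata and whole-table quantities."""
    attributed = hb.attribute_deaths(synthetic_table, attribution, "any")
    res = hb.total_burden(attributed, life_table, econ, WEEKS52, hpv_group="any")
    strata, totals = res.strata(), res.totals().iloc[0]
    for col in ("deaths", "ypll", "pvflp_market", "pvflp_nonmarket", "pvflp_total"):
        assert totals[col] == pytest.approx(strata[col].sum(), rel=1e-9)
    assert totals["deaths"] == pytest.approx(attributed.total_deaths(), rel=1e-12)
    assert totals["ypll"] == pytest.approx(
        sum(hb.total_ypll(attributed, life_table).values()), rel=1e-12
    )
    res.validate()


def test_total_burden_linear_in_counts(life_table, econ):
    base = hb.MortalityTable.from_records(
        [("anus", "female", 50, 10.0), ("anus", "male", 70, 4.0)]
    )
    doubled = hb.MortalityTable(base.data.assign(deaths=base.data["deaths"] * 2))
    r1 = hb.total_burden(base, life_table, econ, WEEKS52).totals().iloc[0]
    r2 = hb.total_burden(doubled, life_table, econ, WEEKS52).totals().iloc[0]
    for col in ("deaths", "ypll", "pvflp_total"):
        assert r2[col] == pytest.approx(2 * r1[col], rel=1e-15)
    for col in ("ypll_per_death", "pvflp_per_death"):
        assert r2[col] == pytest.approx(r1[col], rel=1e-12)


def test_attribution_commutes_with_burden(synthetic_table, life_table, econ):
    """Burden of the f-scaled table equals f times the burden of the raw table."""
    f = 0.37
    scaled = hb.attribute_deaths(synthetic_table, scalar_attribution(f), "any")
    r_scaled = hb.total_burden(scaled, life_table, econ, WEEKS52).totals().iloc[0]
    r_raw = hb.total_burden(synthetic_table, life_table, econ, WEEKS52).totals().iloc[0]
    for col in ("deaths", "ypll", "pvflp_market", "pvflp_nonmarket", "pvflp_total"):
        assert r_scaled[col] == pytest.approx(f * r_raw[col], rel=1e-12)
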