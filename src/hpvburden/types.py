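"""Domain containers for the mortality-burden pipeline.

Each container wraps a validated :class:`pandas.DataFrame` and is immutable
after construction. Conventions:

* cancer sites: ``cervix, vagina, vulva, penis, anus, oropharynx``;
  cervix/vagina/vulva are female-only and penis male-only.
* ages are integer single years of age in [15, 100]; a registry-style
  "100 and over" terminal bucket is mapped to age 100 at read time.
* fractions (attribution, labor-force participation) are stored on the
  0-1 scale in memory; files carry the 0-100 percentage scale.
* death counts are non-negative reals — attributable-death tables are
  fractional by design and are only rounded in reports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    CoverageError,
    DataError,
    MissingAttributionError,
    SchemaError,
    SexSiteError,
)

SITES = ("anus", "cervix", "oropharynx", "penis", "vagina", "vulva")
FEMALE_ONLY_SITES = frozenset({"cervix", "vagina", "vulva"})
MALE_ONLY_SITES = frozenset({"penis"})
DUAL_SEX_SITES = frozenset({"anus", "oropharynx"})
SEXES = ("female", "male")

AGE_MIN = 15
AGE_MAX = 100

#: HPV type groups the pipeline can apportion deaths to. ``9v`` is the union
#: of the 16/18 and 31/33/45/52/58 groups (the nonavalent-vaccine types);
#: ``all_deaths`` bypasses attribution (fraction 1).
HPV_GROUPS = ("any", "1618", "5types", "9v", "all_deaths")


def sexes_for_site(site: str) -> tuple[str, ...]:
    if site in FEMALE_ONLY_SITES:
        return ("female",)
    if site in MALE_ONLY_SITES:
        return ("male",)
    return SEXES


def _check_site_sex(site: str, sex: str) -> None:
    if site not in SITES:
        raise SchemaError(f"unknown cancer site {site!r}; expected one of {SITES}")
    if sex not in SEXES:
        raise SchemaError(f"unknown sex {sex!r}; expected one of {SEXES}")
    if sex not in sexes_for_site(site):
        raise SexSiteError(f"site {site!r} cannot carry deaths for sex {sex!r}")


@dataclass(frozen=True)
class MortalityTable:
    """Death counts keyed by (site, sex, single year of age).

    ``data`` columns: ``site, sex, age, deaths``; one row per key, sorted by
    (sex, site, age) with females first. Counts may be fractional.
    """

    data: pd.DataFrame

    def __post_init__(self):
        df = self.data
        required = ["site", "sex", "age", "deaths"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise SchemaError(f"mortality table missing columns {missing}")
        df = df.loc[:, required].copy()
        if len(df):
            ages = pd.to_numeric(df["age"], errors="raise")
            if not np.all(ages == ages.astype(int)):
                raise SchemaError("ages must be integer years")
            df["age"] = ages.astype(int)
            df["deaths"] = pd.to_numeric(df["deaths"], errors="raise").astype(float)
            bad_age = df[(df["age"] < AGE_MIN) | (df["age"] > AGE_MAX)]
            if len(bad_age):
                raise DataError(
                    f"ages outside [{AGE_MIN}, {AGE_MAX}]: "
                    f"{sorted(bad_age['age'].unique().tolist())}"
                )
            if (df["deaths"] < 0).any() or not np.isfinite(df["deaths"]).all():
                raise DataError("death counts must be finite and non-negative")
            for site, sex in df[["site", "sex"]].drop_duplicates().itertuples(index=False):
                _check_site_sex(site, sex)
            if df.duplicated(["site", "sex", "age"]).any():
                dups = df[df.duplicated(["site", "sex", "age"], keep=False)]
                raise DataError(
                    "duplicate (site, sex, age) entries: "
                    f"{dups[['site', 'sex', 'age']].to_dict('records')}"
                )
        else:
            df = df.astype({"site": str, "sex": str, "age": int, "deaths": float})
        df = df.sort_values(["sex", "site", "age"], kind="mergesort").reset_index(drop=True)
        object.__setattr__(self, "data", df)

    @classmethod
    def from_records(cls, records) -> "MortalityTable":
        """Build from an iterable of (site, sex, age, deaths) tuples."""
        return cls(pd.DataFrame(records, columns=["site", "sex", "age", "deaths"]))

    def total_deaths(self) -> float:
        return float(self.data["deaths"].sum())

    def strata(self) -> list[tuple[str, str]]:
        """Distinct (site, sex) pairs present, in output order."""
        return list(
            self.data[["site", "sex"]].drop_duplicates().itertuples(index=False, name=None)
        )

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


@dataclass(frozen=True)
class AttributionTable:
    """Fractions of cancers at each site attributable to HPV type groups.

    ``data`` columns: ``site, sex, f_any, f_1618, f_5types`` with fractions on
    the 0-1 scale; ``sex`` is ``None`` for single-sex sites (one row), and
    per-sex for anus and oropharynx.
    """

    data: pd.DataFrame

    def __post_init__(self):
        df = self.data.copy()
        required = ["site", "sex", "f_any", "f_1618", "f_5types"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise SchemaError(f"attribution table missing columns {missing}")
        df["sex"] = df["sex"].where(pd.notna(df["sex"]), None)
        for col in ("f_any", "f_1618", "f_5types"):
            df[col] = pd.to_numeric(df[col], errors="raise").astype(float)
            if ((df[col] < 0) | (df[col] > 1)).any():
                raise DataError(f"{col} must lie in [0, 1] (percent inputs are /100)")
        bad = df[df["f_1618"] + df["f_5types"] > df["f_any"] + 1e-12]
        if len(bad):
            raise DataError(
                "type-specific fractions exceed the any-HPV fraction for "
                f"{bad[['site', 'sex']].to_dict('records')}"
            )
        for row in df.itertuples(index=False):
            if row.site not in SITES:
                raise SchemaError(f"unknown cancer site {row.site!r}")
            if row.sex is not None:
                _check_site_sex(row.site, row.sex)
        if df.duplicated(["site", "sex"]).any():
            raise DataError("duplicate (site, sex) attribution rows")
        object.__setattr__(self, "data", df.reset_index(drop=True))
        lookup = {}
        for row in df.itertuples(index=False):
            lookup[(row.site, row.sex)] = (row.f_any, row.f_1618, row.f_5types)
        object.__setattr__(self, "_lookup", lookup)

    def fraction(self, site: str, sex: str, group: str) -> float:
        """Attributable fraction for one stratum and HPV type group."""
        if group not in HPV_GROUPS:
            raise SchemaError(f"unknown HPV group {group!r}; expected one of {HPV_GROUPS}")
        if group == "all_deaths":
            return 1.0
        row = self._lookup.get((site, sex)) or self._lookup.get((site, None))
        if row is None:
            raise MissingAttributionError(
                f"no attribution fractions for site={site!r}, sex={sex!r}"
            )
        f_any, f_1618, f_5types = row
        return {
            "any": f_any,
            "1618": f_1618,
            "5types": f_5types,
            "9v": f_1618 + f_5types,
        }[group]


@dataclass(frozen=True)
class LifeTable:
    """Sex-specific remaining life expectancy at integer ages 15-100.

    ``data`` columns: ``sex, age, e`` (years). Each sex present must cover
    every age in [15, 100].
    """

    data: pd.DataFrame

    def __post_init__(self):
        df = self.data.copy()
        required = ["sex", "age", "e"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise SchemaError(f"life table missing columns {missing}")
        df["age"] = pd.to_numeric(df["age"], errors="raise").astype(int)
        df["e"] = pd.to_numeric(df["e"], errors="raise").astype(float)
        full = set(range(AGE_MIN, AGE_MAX + 1))
        for sex, grp in df.groupby("sex"):
            if sex not in SEXES:
                raise SchemaError(f"unknown sex {sex!r} in life table")
            gaps = sorted(full - set(grp["age"]))
            if gaps:
                raise CoverageError(f"life table for {sex} missing ages {gaps}")
            if grp.duplicated("age").any():
                raise DataError(f"duplicate ages in life table for {sex}")
        if (df["e"] < 0).any():
            raise DataError("life expectancy must be non-negative")
        if ((df["age"] < AGE_MAX) & (df["e"] <= 0)).any():
            raise DataError("life expectancy must be strictly positive below age 100")
        if (df["e"] > 115 - df["age"]).any():
            raise DataError("life expectancy exceeds the 115-year sanity bound")
        df = df.sort_values(["sex", "age"]).reset_index(drop=True)
        object.__setattr__(self, "data", df)
        object.__setattr__(
            self, "_lookup", {(r.sex, r.age): r.e for r in df.itertuples(index=False)}
        )

    def expectancy(self, sex: str, age: int) -> float:
        try:
            return self._lookup[(sex, int(age))]
        except KeyError:
            raise CoverageError(f"no life expectancy for sex={sex!r}, age={age}") from None


@dataclass(frozen=True)
class EconProfile:
    """Age-bin x sex economic inputs for the human-capital model.

    ``bins`` columns: ``age_lo, age_hi, sex, participation (0-1),
    weekly_wage (USD/week), nonmarket_annual (USD/year)``. Bins must exactly
    partition [15, 100] for each sex. Attained ages past 100 (reached while
    discounting long survival streams) fall back to the terminal bin.
    """

    bins: pd.DataFrame
    markup: float = 1.464
    discount_rate: float = 0.03
    reference_year: int = 2017

    def __post_init__(self):
        df = self.bins.copy()
        required = ["age_lo", "age_hi", "sex", "participation", "weekly_wage", "nonmarket_annual"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise SchemaError(f"economic profile missing columns {missing}")
        df["age_lo"] = df["age_lo"].astype(int)
        df["age_hi"] = df["age_hi"].astype(int)
        for col in ("participation", "weekly_wage", "nonmarket_annual"):
            df[col] = pd.to_numeric(df[col], errors="raise").astype(float)
        if ((df["participation"] < 0) | (df["participation"] > 1)).any():
            raise DataError("participation must lie in [0, 1] (percent inputs are /100)")
        if (df[["weekly_wage", "nonmarket_annual"]] < 0).any().any():
            raise DataError("monetary values must be non-negative")
        for sex, grp in df.groupby("sex"):
            if sex not in SEXES:
                raise SchemaError(f"unknown sex {sex!r} in economic profile")
            grp = grp.sort_values("age_lo")
            if grp["age_lo"].iloc[0] != AGE_MIN or grp["age_hi"].iloc[-1] != AGE_MAX:
                raise CoverageError(f"bins for {sex} must span [{AGE_MIN}, {AGE_MAX}]")
            lo, hi = grp["age_lo"].to_numpy(), grp["age_hi"].to_numpy()
            if (hi < lo).any() or (lo[1:] != hi[:-1] + 1).any():
                raise CoverageError(f"bins for {sex} must partition [{AGE_MIN}, {AGE_MAX}]")
        if not (self.markup > 0):
            raise DataError("markup must be positive")
        if self.discount_rate < 0:
            raise DataError("discount rate must be non-negative")
        df = df.sort_values(["sex", "age_lo"]).reset_index(drop=True)
        object.__setattr__(self, "bins", df)
        lookup = {}
        for row in df.itertuples(index=False):
            for a in range(row.age_lo, row.age_hi + 1):
                lookup[(row.sex, a)] = (row.participation, row.weekly_wage, row.nonmarket_annual)
        object.__setattr__(self, "_lookup", lookup)

    def row_for(self, sex: str, age: int) -> tuple[float, float, float]:
        """(participation, weekly wage, annual non-market value) at an age.

        Ages above the table's terminal bin are clamped into it.
        """
        age = min(int(age), AGE_MAX)
        try:
            return self._lookup[(sex, age)]
        except KeyError:
            raise CoverageError(f"no economic bin for sex={sex!r}, age={age}") from None


RESULT_COLUMNS = [
    "site",
    "sex",
    "hpv_group",
    "deaths",
    "ypll",
    "pvflp_market",
    "pvflp_nonmarket",
    "pvflp_total",
    "ypll_per_death",
    "pvflp_per_death",
]

#: site/sex labels used for the per-group grand-total row of a BurdenResult
TOTAL_LABEL = "all"


@dataclass(frozen=True)
class BurdenResult:
    """Burden estimates per (site, sex, HPV group) stratum.

    One row per stratum plus, per HPV group, a grand-total row labelled
    ``site == sex == "all"``. Per-death quotients are NaN where a stratum has
    zero deaths (undefined). All quantities are linear in the attribution
    fraction, so the ``9v`` rows equal the sum of the ``1618`` and ``5types``
    rows whenever all three groups are present.
    """

    data: pd.DataFrame

    def __post_init__(self):
        df = self.data.loc[:, RESULT_COLUMNS].copy().reset_index(drop=True)
        object.__setattr__(self, "data", df)

    def strata(self) -> pd.DataFrame:
        """Rows for individual (site, sex) strata, excluding totals rows."""
        return self.data[self.data["site"] != TOTAL_LABEL].reset_index(drop=True)

    def totals(self) -> pd.DataFrame:
        """The per-group grand-total rows."""
        return self.data[self.data["site"] == TOTAL_LABEL].reset_index(drop=True)

    def validate(self, rtol: float = 1e-9) -> None:
        """Check internal consistency; raises :class:`DataError` on failure."""
        df = self.data
        for row in df.itertuples(index=False):
            for total, quot in (
                (row.ypll, row.ypll_per_death),
                (row.pvflp_total, row.pvflp_per_death),
            ):
                if row.deaths > 0:
                    if not math.isclose(quot, total / row.deaths, rel_tol=rtol):
                        raise DataError("per-death quotient inconsistent with totals")
                elif not math.isnan(quot):
                    raise DataError("per-death quotient must be NaN when deaths == 0")
            if not math.isclose(
                row.pvflp_total, row.pvflp_market + row.pvflp_nonmarket, rel_tol=rtol
            ):
                raise DataError("total PVFLP must equal market + non-market")
        groups = set(df["hpv_group"])
        if {"1618", "5types", "9v"} <= groups:
            key = ["site", "sex"]
            parts = (
                df[df["hpv_group"].isin(["1618", "5types"])]
                .groupby(key)[["deaths", "ypll", "pvflp_total"]]
                .sum()
            )
            nine = df[df["hpv_group"] == "9v"].set_index(key)[["deaths", "ypll", "pvflp_total"]]
            if not np.allclose(parts.sort_index(), nine.sort_index(), rtol=rtol, atol=1e-12):
                raise DataError("9v stratum does not equal 1618 + 5types")

    @classmethod
    def concat(cls, results: list["BurdenResult"]) -> "BurdenResult":
        return cls(pd.concat([r.data for r in results], ignore_index=True))
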