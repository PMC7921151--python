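"""Readers and writers for the pipeline's tabular formats.

Two mortality dialects are supported:

* ``csv`` — the package's own format, header ``site,sex,age,deaths``,
  ``#``-prefixed comment lines permitted.
* ``wonder`` — a CDC WONDER-style export: tab-delimited, optionally quoted
  fields, a leading ``Notes`` column, a ``Single-Year Ages Code`` column
  (``"100+"`` maps to age 100), a ``Gender`` column, a ``Deaths`` column,
  and an ICD-10 cause-of-death code column translated to a cancer site via a
  configurable code map. Everything from the first blank line, ``---`` rule,
  or ``Total``/notes row onward is provenance text and is discarded.
  Suppressed counts abort the read with an error naming the rows.

Percentage-scaled inputs (attribution fractions, labor-force participation)
are converted to the 0-1 scale here, at the I/O boundary, and nowhere else.
"""

from __future__ import annotations

import csv
import io as _io
import math
from importlib import resources
from pathlib import Path

import pandas as pd

from .errors import DataError, SchemaError, SuppressedCountError
from .types import (
    AttributionTable,
    BurdenResult,
    EconProfile,
    LifeTable,
    MortalityTable,
    TOTAL_LABEL,
)

#: Default ICD-10 three-character code -> cancer site translation. The
#: oropharyngeal group spans the whole lip/oral-cavity/pharynx chapter
#: C00-C14; pass a narrower map to restrict it (e.g. C01-02, C09-10, C14).
DEFAULT_ICD10_SITE_MAP = {
    "C53": "cervix",
    "C51": "vulva",
    "C52": "vagina",
    "C60": "penis",
    "C21": "anus",
    **{f"C{i:02d}": "oropharynx" for i in range(0, 15)},
    "C00-C14": "oropharynx",
}

_WONDER_CODE_COLUMNS = (
    "Cause of death Code",
    "ICD-10 113 Cause List Code",
    "ICD Sub-Chapter Code",
    "ICD-10 Codes Code",
)


def _as_text(source) -> str:
    if hasattr(source, "read"):
        return source.read()
    path = Path(source)
    return path.read_text()


def _read_simple_csv(source, required: list[str], what: str) -> pd.DataFrame:
    text = _as_text(source)
    try:
        df = pd.read_csv(_io.StringIO(text), comment="#", skip_blank_lines=True, dtype=str)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{what}: empty input, no header found") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: malformed header, missing columns {missing}")
    if df.empty:
        raise DataError(f"{what}: no records")
    return df


def read_mortality(source, dialect: str = "csv", code_map=None) -> MortalityTable:
    """Read a death-count table in either the ``csv`` or ``wonder`` dialect."""
    if dialect == "csv":
        df = _read_simple_csv(source, ["site", "sex", "age", "deaths"], "mortality table")
        supp = df[df["deaths"].str.strip().str.lower() == "suppressed"]
        if len(supp):
            raise SuppressedCountError(
                f"row {i + 2} ({r.site}/{r.sex}/age {r.age})"
                for i, r in zip(supp.index, supp.itertuples(index=False))
            )
        return MortalityTable(df)
    if dialect == "wonder":
        return _read_wonder(_as_text(source), code_map or DEFAULT_ICD10_SITE_MAP)
    raise SchemaError(f"unknown mortality dialect {dialect!r}")


def _site_for_code(code: str, code_map: dict) -> str:
    code = code.strip().strip('"')
    if code in code_map:
        return code_map[code]
    stem = code.split(".")[0]
    if stem in code_map:
        return code_map[stem]
    raise SchemaError(f"unknown site code {code!r}; not in the ICD-10 code map")


def _read_wonder(text: str, code_map: dict) -> MortalityTable:
    lines = text.splitlines()
    if not lines:
        raise SchemaError("wonder export: empty input")
    reader = csv.reader(lines, delimiter="\t")
    header = [h.strip().strip('"') for h in next(reader)]
    code_col = next((c for c in _WONDER_CODE_COLUMNS if c in header), None)
    needed = ["Single-Year Ages Code", "Gender", "Deaths"]
    missing = [c for c in needed if c not in header]
    if missing or code_col is None:
        raise SchemaError(
            f"wonder export: malformed header, missing {missing or ['an ICD-10 code column']}"
        )
    idx = {c: header.index(c) for c in needed}
    idx["code"] = header.index(code_col)

    records: list[tuple[str, str, int, float]] = []
    suppressed: list[str] = []
    for lineno, raw in enumerate(reader, start=2):
        row = [f.strip().strip('"') for f in raw]
        if not any(row):  # blank line ends the data section
            break
        if row[0].startswith("---") or row[0] == "Notes" or (header[0] == "Notes" and row[0]):
            break
        if "Total" in row[: idx["code"] + 1]:
            continue  # WONDER subtotal rows duplicate the stratified counts
        if len(row) < len(header):
            raise SchemaError(f"wonder export: short row at line {lineno}")
        age_code = row[idx["Single-Year Ages Code"]]
        sex_raw = row[idx["Gender"]].lower()
        deaths_raw = row[idx["Deaths"]]
        site = _site_for_code(row[idx["code"]], code_map)
        sex = {"female": "female", "f": "female", "male": "male", "m": "male"}.get(sex_raw)
        if sex is None:
            raise SchemaError(f"wonder export: unknown gender {sex_raw!r} at line {lineno}")
        age = 100 if age_code in ("100+", "100") else None
        if age is None:
            try:
                age = int(age_code)
            except ValueError:
                raise SchemaError(
                    f"wonder export: unparseable age code {age_code!r} at line {lineno}"
                ) from None
        if deaths_raw.lower() == "suppressed":
            suppressed.append(f"line {lineno} ({site}/{sex}/age {age_code})")
            continue
        records.append((site, sex, age, float(deaths_raw)))
    if suppressed:
        raise SuppressedCountError(suppressed)
    if not records:
        raise DataError("wonder export: no records")
    df = pd.DataFrame(records, columns=["site", "sex", "age", "deaths"])
    # several ICD codes (the C00-C14 chapter) fold into one site
    df = df.groupby(["site", "sex", "age"], as_index=False)["deaths"].sum()
    return MortalityTable(df)


def read_attribution(source) -> AttributionTable:
    """Read site/sex attribution percentages (0-100 on disk, 0-1 in memory)."""
    df = _read_simple_csv(
        source,
        ["site", "sex", "pct_any_hpv", "pct_hpv_16_18", "pct_hpv_31_33_45_52_58"],
        "attribution table",
    )
    out = pd.DataFrame(
        {
            "site": df["site"].str.strip(),
            "sex": df["sex"].where(df["sex"].notna() & (df["sex"].str.strip() != ""), None),
            "f_any": pd.to_numeric(df["pct_any_hpv"]) / 100.0,
            "f_1618": pd.to_numeric(df["pct_hpv_16_18"]) / 100.0,
            "f_5types": pd.to_numeric(df["pct_hpv_31_33_45_52_58"]) / 100.0,
        }
    )
    return AttributionTable(out)


def read_life_table(source) -> LifeTable:
    df = _read_simple_csv(source, ["sex", "age", "life_expectancy_years"], "life table")
    return LifeTable(
        pd.DataFrame(
            {
                "sex": df["sex"].str.strip(),
                "age": pd.to_numeric(df["age"]),
                "e": pd.to_numeric(df["life_expectancy_years"]),
            }
        )
    )


def read_econ_profile(
    source,
    markup: float = 1.464,
    discount_rate: float = 0.03,
    reference_year: int = 2017,
) -> EconProfile:
    """Read the age-bin economic table; scalar settings ride in as arguments."""
    df = _read_simple_csv(
        source,
        [
            "age_lo",
            "age_hi",
            "sex",
            "labor_force_participation_pct",
            "median_weekly_wage_usd",
            "nonmarket_annual_usd",
        ],
        "economic profile",
    )
    bins = pd.DataFrame(
        {
            "age_lo": pd.to_numeric(df["age_lo"]),
            "age_hi": pd.to_numeric(df["age_hi"]),
            "sex": df["sex"].str.strip(),
            "participation": pd.to_numeric(df["labor_force_participation_pct"]) / 100.0,
            "weekly_wage": pd.to_numeric(df["median_weekly_wage_usd"]),
            "nonmarket_annual": pd.to_numeric(df["nonmarket_annual_usd"]),
        }
    )
    return EconProfile(
        bins, markup=markup, discount_rate=discount_rate, reference_year=reference_year
    )


# ---------------------------------------------------------------------------
# packaged fixtures

def _data_path(name: str):
    return resources.files("hpvburden.data").joinpath(name)


def load_attribution() -> AttributionTable:
    """The packaged HPV type-attribution fractions."""
    return read_attribution(_io.StringIO(_data_path("attribution_table1.csv").read_text()))


def load_life_table() -> LifeTable:
    """The packaged synthetic 2016-scale US life table."""
    return read_life_table(
        _io.StringIO(_data_path("life_table_2016_synthetic.csv").read_text())
    )


def load_econ_profile(**kwargs) -> EconProfile:
    """The packaged 2017 labor-market and non-market productivity inputs."""
    return read_econ_profile(
        _io.StringIO(_data_path("econ_profile_2017.csv").read_text()), **kwargs
    )


# ---------------------------------------------------------------------------
# results

def round_half_up(x: float) -> int:
    """Round to nearest integer with exact halves going up (report rounding)."""
    return int(math.floor(x + 0.5))


DEATHS_YPLL_COLUMNS = [
    "site",
    "sex",
    "hpv_group",
    "deaths",
    "deaths_rounded",
    "ypll",
    "ypll_per_death",
]
PVFLP_COLUMNS = [
    "site",
    "sex",
    "hpv_group",
    "pvflp_market_usd",
    "pvflp_nonmarket_usd",
    "pvflp_total_usd",
    "pvflp_total_thousands",
    "pct_of_group_total",
    "pvflp_per_death_usd",
]


def _ordered(result: BurdenResult) -> pd.DataFrame:
    strata = result.strata().sort_values(
        ["hpv_group", "sex", "site"], kind="mergesort"
    )
    totals = result.totals().sort_values("hpv_group", kind="mergesort")
    return pd.concat([strata, totals], ignore_index=True)


def write_results(result: BurdenResult, destination) -> tuple[Path, Path]:
    """Write the deaths/YPLL and PVFLP report tables under ``destination``.

    Strata are ordered site-alphabetically within sex, females first, within
    each HPV group; grand-total rows come last. Monetary totals appear at
    full precision and rounded to thousands; the percent column gives each
    stratum's share of its group's total PVFLP.
    """
    destination = Path(destination)
    destination.mkdir(parents=True, exist_ok=True)
    df = _ordered(result)

    group_tot = (
        df[df["site"] != TOTAL_LABEL].groupby("hpv_group")["pvflp_total"].transform("sum")
    )
    dy = pd.DataFrame(
        {
            "site": df["site"],
            "sex": df["sex"],
            "hpv_group": df["hpv_group"],
            "deaths": df["deaths"],
            "deaths_rounded": [round_half_up(d) for d in df["deaths"]],
            "ypll": df["ypll"],
            "ypll_per_death": df["ypll_per_death"],
        }
    )
    pv = pd.DataFrame(
        {
            "site": df["site"],
            "sex": df["sex"],
            "hpv_group": df["hpv_group"],
            "pvflp_market_usd": df["pvflp_market"],
            "pvflp_nonmarket_usd": df["pvflp_nonmarket"],
            "pvflp_total_usd": df["pvflp_total"],
            "pvflp_total_thousands": [round_half_up(v / 1000.0) for v in df["pvflp_total"]],
            "pct_of_group_total": 100.0 * df["pvflp_total"] / group_tot,
            "pvflp_per_death_usd": df["pvflp_per_death"],
        }
    )
    # totals rows have no share-of-group entry
    pv.loc[df["site"] == TOTAL_LABEL, "pct_of_group_total"] = float("nan")
    if df.empty:
        dy = pd.DataFrame(columns=DEATHS_YPLL_COLUMNS)
        pv = pd.DataFrame(columns=PVFLP_COLUMNS)
    dy_path = destination / "deaths_ypll.csv"
    pv_path = destination / "pvflp.csv"
    dy[DEATHS_YPLL_COLUMNS].to_csv(dy_path, index=False)
    pv[PVFLP_COLUMNS].to_csv(pv_path, index=False)
    return dy_path, pv_path


def read_results(destination) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read back the two report tables written by :func:`write_results`."""
    destination = Path(destination)
    dy = pd.read_csv(destination / "deaths_ypll.csv", float_precision="round_trip")
    pv = pd.read_csv(destination / "pvflp.csv", float_precision="round_trip")
    return dy, pv
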