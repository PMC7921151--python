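"""Apportion raw cancer death counts to HPV type groups.

Attribution is age-invariant: one fraction per (site, sex) scales every age's
count, so attributable deaths are fractional and all downstream burden
quantities are linear in the fraction.
"""

from __future__ import annotations

from .errors import MissingAttributionError
from .types import AttributionTable, MortalityTable


def attribute_deaths(
    deaths: MortalityTable, attribution: AttributionTable, group: str
) -> MortalityTable:
    """Scale each stratum's counts by its attributable fraction for ``group``.

    ``group="all_deaths"`` applies fraction 1 and returns an equal table;
    ``group="9v"`` uses the 16/18 plus 31/33/45/52/58 fractions combined.
    Raises :class:`~hpvburden.errors.MissingAttributionError` if any observed
    (site, sex) lacks an attribution row.
    """
    df = deaths.data.copy()
    factors = {}
    missing = []
    for site, sex in deaths.strata():
        try:
            factors[(site, sex)] = attribution.fraction(site, sex, group)
        except MissingAttributionError:
            missing.append((site, sex))
    if missing:
        raise MissingAttributionError(
            f"no attribution fractions for observed strata: {sorted(missing)}"
        )
    if len(df):
        df["deaths"] = df["deaths"] * [
            factors[(s, x)] for s, x in zip(df["site"], df["sex"])
        ]
    return MortalityTable(df)


def site_totals(deaths: MortalityTable) -> dict[tuple[str, str], float]:
    """Exact per-(site, sex) death totals, summed over ages without rounding."""
    if deaths.data.empty:
        return {}
    sums = deaths.data.groupby(["site", "sex"])["deaths"].sum()
    return {key: float(v) for key, v in sums.items()}
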