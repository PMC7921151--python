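"""Exception hierarchy for input validation and lookups."""


class DataError(ValueError):
    """Base class for malformed or inconsistent input data."""


class SchemaError(DataError):
    """Missing/unknown columns, unparseable values, or unknown codes."""


class SuppressedCountError(DataError):
    """A mortality export contains suppressed (withheld) death counts."""

    def __init__(self, rows):
        self.rows = list(rows)
        detail = "; ".join(self.rows)
        super().__init__(
            f"{len(self.rows)} row(s) carry suppressed death counts and cannot "
            f"be used: {detail}"
        )


class CoverageError(DataError):
    """A life table does not cover every required single year of age."""


class SexSiteError(DataError):
    """A death count is recorded for an anatomically impossible sex-site pair."""


class MissingAttributionError(DataError):
    """No attribution fraction is available for an observed (site, sex)."""
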