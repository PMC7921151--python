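import pandas as pd
import pytest

import hpvburden as hb


@pytest.fixture(scope="session")
def attribution():
    return hb.load_attribution()


@pytest.fixture(scope="session")
def life_table():
    return hb.load_life_table()


@pytest.fixture(scope="session")
def econ():
    return hb.load_econ_profile()


@pytest.fixture(scope="session")
def synthetic_table():
    """A full six-site synthetic mortality table at the published totals."""
    return hb.generate_mortality(hb.default_published_profiles(), seed=20170101)


@pytest.fixture
def flat_life_table():
    """Constant remaining life expectancy (1 year) at every age — makes each
    death lose exactly one future year, so discounting is checkable by hand."""
    rows = [
        {"sex": sex, "age": age, "e": 1.0}
        for sex in ("female", "male")
        for age in range(15, 101)
    ]
    return hb.LifeTable(pd.DataFrame(rows))


def scalar_attribution(f_any, f_1618=0.0, f_5types=0.0):
    """One attribution fraction applied to every site and sex."""
    rows = []
    for site in ("cervix", "vagina", "vulva", "penis"):
        rows.append({"site": site, "sex": None, "f_any": f_any,
                     "f_1618": f_1618, "f_5types": f_5types})
    for site in ("anus", "oropharynx"):
        for sex in ("female", "male"):
            rows.append({"site": site, "sex": sex, "f_any": f_any,
                         "f_1618": f_1618, "f_5types": f_5types})
    return hb.AttributionTable(pd.DataFrame(rows))
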