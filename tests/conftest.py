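import warnings

import pytest

import gripref as g
from gripref import published as pub


@pytest.fixture(scope="session")
def default_cohort():
    """One seeded study-design cohort (n = 2,970), shared across tests."""
    return g.generate_cohort(g.default_spec(seed=1))


@pytest.fixture(scope="session")
def boys(default_cohort):
    return [r for r in default_cohort if r.sex == "boys"]


@pytest.fixture(scope="session")
def girls(default_cohort):
    return [r for r in default_cohort if r.sex == "girls"]


@pytest.fixture(scope="session")
def boys_model(boys):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return g.fit_lms(boys)


@pytest.fixture(scope="session")
def printed_tables():
    """Bundled printed reference tables (triples + printed cells), per sex."""
    return {sex: pub.reference_table(sex) for sex in pub.SEXES}


@pytest.fixture(scope="session")
def hbz_tables(printed_tables):
    return {sex: g.build_hbz_table(ref) for sex, ref in printed_tables.items()}
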