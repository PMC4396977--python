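import pytest

import parscreen as ps


@pytest.fixture(scope="session")
def table1():
    """The bundled 29-cohort rs13266634 case-control table."""
    return ps.load_bundled_cohorts()


@pytest.fixture(scope="session")
def completed(table1):
    return [ps.complete_cohort(r) for r in table1]


@pytest.fixture(scope="session")
def by_group(completed):
    out = {}
    for r in completed:
        out.setdefault(r.group, []).append(r)
    return out


@pytest.fixture(scope="session")
def risks(table1):
    """Per-subgroup exposure frequency, pooled OR, and attributable risk."""
    return ps.ethnicity_risks(table1)
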