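import math

import pytest

from rletox import ToxicityRecord, ToxicitySeries, load_table1_fixture


def series_on_line(a, b, times, species="Testis piscis", toxicant="testox", noise=None):
    """Series whose LC50 values sit exactly on c = a·ln(t) + b (plus optional offsets)."""
    recs = []
    for i, t in enumerate(times):
        c = a * math.log(t) + b
        if noise is not None:
            c += noise[i]
        recs.append(ToxicityRecord(time_days=t, lc50_ugL=c))
    return ToxicitySeries(species=species, toxicant=toxicant, records=recs)


@pytest.fixture(scope="session")
def table1():
    return load_table1_fixture()


@pytest.fixture(scope="session")
def table1_by_species(table1):
    by = {}
    for e in table1:
        by.setdefault(e.species, []).append(e)
    return by
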