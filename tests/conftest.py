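import datetime as dt
import math

import pandas as pd
import pytest
from hypothesis import settings

import rsvstab as rs

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")

D0 = dt.date(2020, 12, 14)


def make_pm(rows: dict[str, list[float | None]], start: dt.date = D0,
            **meta) -> rs.PullMatrix:
    """Build a PullMatrix from {unit: values}; None marks a missing cell."""
    n_days = len(next(iter(rows.values())))
    dates = [start + dt.timedelta(days=k) for k in range(n_days)]
    data = pd.DataFrame(
        [[math.nan if v is None else float(v) for v in vals]
         for vals in rows.values()],
        index=pd.Index(list(rows), name="unit"), columns=dates)
    meta.setdefault("query", "test query")
    meta.setdefault("geo_scope", "test")
    meta.setdefault("unit_level", "city")
    meta.setdefault("period_start", dt.date(2020, 2, 1))
    meta.setdefault("period_end", dt.date(2020, 12, 4))
    return rs.PullMatrix(data=data, **meta)


@pytest.fixture(scope="session")
def table2():
    return rs.load_fixture("table2")


@pytest.fixture(scope="session")
def table3():
    return rs.load_fixture("table3")


@pytest.fixture(scope="session")
def table4():
    return rs.load_fixture("table4")


@pytest.fixture(scope="session")
def table5():
    return rs.load_fixture("table5")
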