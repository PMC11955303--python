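import datetime as dt

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from catchassoc.catchdata import CatchRecord
from catchassoc.events import build_deployment_events


def rec(site="Pihaena", date="2014-11-03", setn=1, time=None, ind=None,
        sex="unknown", fl=None, rid=None):
    """Terse CatchRecord factory for hand-built fixtures."""
    t = None
    if time is not None:
        h, m = time.split(":")
        t = dt.time(int(h), int(m))
    rid = rid or f"{site}-{date}-{setn}-{ind}-{time}-{fl}"
    return CatchRecord(record_id=rid, site=site,
                       date=dt.date.fromisoformat(date), set_number=setn,
                       capture_time=t, individual_id=ind, sex=sex,
                       fork_length_mm=fl)


@pytest.fixture
def make_record():
    return rec


@pytest.fixture
def toy_events():
    """3 deployments, 4 tagged individuals, with one repeated dyad."""
    records = [
        rec(site="A", date="2021-10-01", ind="x", sex="male", fl=450, time="18:00"),
        rec(site="A", date="2021-10-01", ind="y", sex="female", fl=500, time="18:00"),
        rec(site="A", date="2021-10-15", ind="x", sex="male", fl=460, time="18:30"),
        rec(site="A", date="2021-10-15", ind="y", sex="female", fl=510, time="18:45"),
        rec(site="B", date="2021-11-02", ind="z", sex="male", fl=600, time="17:10"),
        rec(site="B", date="2021-11-02", ind="w", sex="female", fl=430, time="17:10"),
    ]
    return build_deployment_events(records)


@pytest.fixture(scope="session")
def small_solitary():
    from catchassoc.synthetic import scenario_config, simulate_dataset
    return simulate_dataset(
        scenario_config("solitary", seed=77, n_sites=3, years=(2021,)))
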