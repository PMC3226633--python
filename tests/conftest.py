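import dataclasses

import pytest
from hypothesis import HealthCheck, settings

import antbiogeo as ab
from antbiogeo.occurrence import EventTable, SamplingEvent

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_event(eid, species, island="I", site="s1", year=2005, week=20,
               method="pitfall", habitat="unknown"):
    return SamplingEvent(
        event_id=eid, island=island, site=site, year=year, week=week,
        method=method, habitat=habitat,
        counts={sp: 1 for sp in species} if not isinstance(species, dict) else species,
    )


def make_table(species_sets, **kw):
    """EventTable from a list of species iterables (one event each)."""
    return EventTable(
        [make_event(f"e{i}", sps, site=f"s{i}", **kw) for i, sps in enumerate(species_sets)]
    )


@pytest.fixture(scope="session")
def printed():
    return ab.load_printed_fixtures()


@pytest.fixture(scope="session")
def default_park():
    """One default synthetic park (the study conditions), seed 0."""
    return ab.simulate_park(ab.default_config())


@pytest.fixture(scope="session")
def small_park():
    """A reduced park for fast event-level checks."""
    cfg = dataclasses.replace(
        ab.default_config(),
        islands=ab.synthetic.DEFAULT_ISLANDS[:3],
        years=(2005, 2006),
        seed=11,
    )
    return ab.simulate_park(cfg)
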