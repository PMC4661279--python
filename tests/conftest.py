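import pytest

import ambicon as ac


@pytest.fixture(scope="session")
def gamble_set():
    return ac.generate_gamble_set(seed=0)


@pytest.fixture(scope="session")
def session4(gamble_set):
    """Full-size behavioural session: 4 runs, 128 gamble trials."""
    return ac.build_session(gamble_set, seed=0, n_runs=4, volumes_per_run=120)


@pytest.fixture(scope="session")
def session2(gamble_set):
    """Desk-scale imaging session: 2 runs x 120 volumes, zero slack."""
    return ac.build_session(gamble_set, seed=0, n_runs=2, volumes_per_run=120)


@pytest.fixture(scope="session")
def neutral():
    return ac.SubjectParameters()


@pytest.fixture(scope="session")
def by_level(gamble_set):
    def get(condition, level):
        return next(g for g in gamble_set.unique[condition] if g.level == level)

    return get


@pytest.fixture(scope="session")
def cohort():
    return ac.sample_population(ac.PopulationSpec(seed=1))
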