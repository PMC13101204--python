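import pytest

import aobci


@pytest.fixture(scope="session")
def paradigms():
    return aobci.make_paradigms()


@pytest.fixture(scope="session")
def rhtd(paradigms):
    return paradigms[0]


@pytest.fixture()
def gen_config():
    return aobci.GeneratorConfig()


@pytest.fixture()
def quiet_config():
    """Noise-free generator for analytic checks."""
    return aobci.GeneratorConfig(noise_scale=0.0)


@pytest.fixture(scope="session")
def tiny_plan():
    """One RHTD run with a single repeat per target (4 trials)."""
    return aobci.SessionPlan(
        runs=(("RHTD", "visual"),), trials_per_run=4, repeats_per_target=1
    )


@pytest.fixture(scope="session")
def rhtd_plan_4runs():
    return aobci.SessionPlan(runs=tuple(("RHTD", "visual") for _ in range(4)))


@pytest.fixture(scope="session")
def lhtd_plan_4runs():
    return aobci.SessionPlan(runs=tuple(("LHTD", "visual") for _ in range(4)))


@pytest.fixture(scope="session")
def rhtd_session(paradigms, rhtd_plan_4runs):
    """One default-condition RHTD session (4 runs x 20 trials), shared."""
    epochs, events = aobci.simulate_session(
        rhtd_plan_4runs, paradigms, aobci.GeneratorConfig(), 12345
    )
    return epochs, events
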