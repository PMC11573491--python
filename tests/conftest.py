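import pytest

from ddstates import runs as runs_mod
from ddstates.synth import SynthSpec, generate_spikes, run_coverage_session


@pytest.fixture(scope="session")
def coverage_session():
    """Scripted 8 s-delay session with three runs of each run type."""
    return run_coverage_session(n_blocks=3, delay_s=8.0, seed=5)


@pytest.fixture(scope="session")
def coverage_runs(coverage_session):
    return runs_mod.segment_runs(coverage_session)


@pytest.fixture(scope="session")
def ramping_spec():
    return SynthSpec(seed=7, template="ramping", n_neurons=40, effect_size_hz=3.0)


@pytest.fixture(scope="session")
def ramping_spikes(ramping_spec, coverage_session, coverage_runs):
    """Poisson ensemble with a ramping pre-choice template and a planted
    Change-trial pattern offset."""
    return generate_spikes(ramping_spec, coverage_session, coverage_runs)
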