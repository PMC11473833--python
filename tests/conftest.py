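import numpy as np
import pytest

from casplex import simulate as sim
from casplex.io import KineticTrace


@pytest.fixture(scope="session")
def default_params():
    return sim.SignalModelParams()


@pytest.fixture(scope="session")
def noiseless_params():
    import dataclasses
    return dataclasses.replace(sim.SignalModelParams(), noise_sd=0.0, batch_scale_sd=0.0)


@pytest.fixture(scope="session")
def small_cohort():
    """Moderate-noise cohort, 5 samples/genotype, used by several suites."""
    params = sim.SignalModelParams().with_noise_preset("moderate")
    return sim.generate_cohort(5, params, seed=11)


@pytest.fixture(scope="session")
def low_noise_cohort():
    params = sim.SignalModelParams().with_noise_preset("low")
    return sim.generate_cohort(8, params, seed=13)


@pytest.fixture(scope="session")
def template():
    return sim.generate_templates(300, seed=5)


def make_trace(rfus, times=None, channel="FAM", role="sample", **kw):
    rfus = np.asarray(rfus, dtype=float)
    if times is None:
        times = np.arange(rfus.size) * 5.0
    defaults = dict(well="A1", sample_id="s1", batch="batch0")
    defaults.update(kw)
    return KineticTrace(channel=channel, role=role, times=np.asarray(times, float),
                        rfus=rfus, **defaults)
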