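import numpy as np
import pytest

import spikefractal as sf


@pytest.fixture(scope="session")
def poisson_train() -> sf.SpikeTrain:
    return sf.generate_poisson(rate=20.0, duration=60.0, seed=11)


@pytest.fixture(scope="session")
def periodic_train() -> sf.SpikeTrain:
    return sf.generate_periodic(period=0.02, duration=60.0)


@pytest.fixture(scope="session")
def entrained_train() -> sf.SpikeTrain:
    return sf.generate_entrained_train(sf.EntrainmentConfig(seed=21))


@pytest.fixture(scope="session")
def fractal_train() -> sf.SpikeTrain:
    return sf.generate_fractal_isi_train(
        sf.FractalTrainConfig(target_H=0.8, n_spikes=4096, seed=31)
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
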