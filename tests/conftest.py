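import numpy as np
import pytest

from hrsnn.encoding import EncoderConfig
from hrsnn.experiments import PipelineConfig
from hrsnn.lif_core import LIFParameters
from hrsnn.synthetic_data import SyntheticTaskConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_lif(tau_m=10.0, r_m=1.0, a=0.0, v_threshold=1.0, v_reset=0.0,
             refractory=2.0, n=1):
    return LIFParameters(tau_m=np.full(n, tau_m), r_m=np.full(n, r_m),
                         a=np.full(n, a), v_threshold=np.full(n, v_threshold),
                         v_reset=np.full(n, v_reset),
                         refractory=np.full(n, refractory))


@pytest.fixture
def lif_params():
    return make_lif()


@pytest.fixture
def small_task():
    return SyntheticTaskConfig(n_classes=2, frames_per_clip=10,
                               frame_shape=(12, 12), clips_per_class=4,
                               pixel_noise_sd=0.0, object_kind="bar", seed=7)


@pytest.fixture
def small_dataset(small_task):
    return generate_dataset(small_task)


@pytest.fixture
def tiny_pipeline():
    return PipelineConfig(n_recurrent=60, n_output=10, epochs=1,
                          encoder=EncoderConfig(pool_size=2))
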