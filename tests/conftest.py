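import numpy as np
import pytest

from iscocta import QuantConfig, process_volume, quantify, reference_phantom


@pytest.fixture(scope="session")
def reference_run():
    """Reference phantom rendered and processed once for the whole session.

    Returns (volume, truth, mean_vol, contrast_vol, flow_vol, vad_result).
    """
    volume, truth = reference_phantom()
    mean_vol, contrast_vol, flow_vol = process_volume(volume)
    result = quantify(flow_vol, QuantConfig(), protocol=volume.protocol)
    return volume, truth, mean_vol, contrast_vol, flow_vol, result


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
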