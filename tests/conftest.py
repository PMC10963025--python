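import numpy as np
import pytest

from docksim import CONDITION_PARAMS, ModelParams, TrainProtocol


@pytest.fixture
def control_params() -> ModelParams:
    return CONDITION_PARAMS["control"]


@pytest.fixture
def fourap_params() -> ModelParams:
    return CONDITION_PARAMS["4ap"]


@pytest.fixture
def ptp_params() -> ModelParams:
    return CONDITION_PARAMS["ptp"]


def protocol(n_stim=8, freq_hz=100.0, n_trains=5000, seed=0) -> TrainProtocol:
    return TrainProtocol(n_stim=n_stim, freq_hz=freq_hz, n_trains=n_trains, seed=seed)


def mc_se(x: np.ndarray) -> np.ndarray:
    """Monte-Carlo standard error of the mean along axis 0."""
    x = np.asarray(x, dtype=float)
    return x.std(axis=0, ddof=1) / np.sqrt(x.shape[0])
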