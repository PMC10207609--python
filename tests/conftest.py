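import numpy as np
import pytest

from dcequant import AcquisitionParams, AIFParams, evaluate_aif, make_truth


@pytest.fixture(scope="session")
def params_short():
    """Dynamic protocol truncated to ~5 min for fast tests."""
    return AcquisitionParams(n_frames=160, frame_interval=2.0)


@pytest.fixture(scope="session")
def params_full():
    """The full-length dynamic protocol (610 frames, ~20 min)."""
    return AcquisitionParams()


@pytest.fixture(scope="session")
def aif_short(params_short):
    return evaluate_aif(AIFParams(), params_short.frame_times, params_short.hematocrit)


@pytest.fixture(scope="session")
def aif_full(params_full):
    return evaluate_aif(AIFParams(), params_full.frame_times, params_full.hematocrit)


@pytest.fixture(scope="session")
def truth32():
    return make_truth(grid_shape=(32, 32))


@pytest.fixture(scope="session")
def mono_exp_aif():
    """Mono-exponential plasma input with a closed-form Tofts solution."""
    times = np.arange(0.0, 1200.0, 2.0)
    D, m = 5.0, 0.01
    cp = D * np.exp(-m * times)
    from dcequant import AIFCurve

    return AIFCurve(times=times, cp=cp), D, m
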