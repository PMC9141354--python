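import numpy as np
import pytest

from t2biexp.signal_model import BiexpParams, EchoSeries, biexp_signal

ECHO_TIMES = np.arange(9.0, 73.0, 9.0)  # the 8-echo protocol, 9..72 ms


@pytest.fixture(scope="session")
def echo_times() -> np.ndarray:
    return ECHO_TIMES.copy()


def noiseless_series(t_s: float, t_l: float, a_s: float = 1200.0,
                     a_l: float = 1800.0, n: float = 0.0) -> EchoSeries:
    params = BiexpParams(a_s=a_s, a_l=a_l, t_s=t_s, t_l=t_l, n=n)
    return EchoSeries(ECHO_TIMES, biexp_signal(params, ECHO_TIMES))
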