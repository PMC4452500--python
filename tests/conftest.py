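import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


def rel_max_diff(a: np.ndarray, b: np.ndarray) -> float:
    """Largest elementwise relative deviation (floor 1e-12 on the scale)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    return float(np.max(np.abs(a - b) / np.maximum(np.abs(b), 1e-12)))
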