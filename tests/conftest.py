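import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def brute_force_inhibition(activity, sigmas, gain, rectify):
    """Naive double loop over all source/target unit pairs (oracle)."""
    rows, cols = activity.shape
    out = np.empty_like(activity, dtype=float)
    for x0 in range(rows):
        for y0 in range(cols):
            total = 0.0
            for x in range(rows):
                for y in range(cols):
                    if (x, y) == (x0, y0):
                        continue
                    r2 = (x - x0) ** 2 + (y - y0) ** 2
                    total += (
                        gain
                        * activity[x, y] ** 2
                        * np.exp(-r2 / (2.0 * sigmas[x, y] ** 2))
                    )
            val = activity[x0, y0] - total
            out[x0, y0] = max(val, 0.0) if rectify else val
    return out


def brute_force_feedforward(a_inh, weights):
    """Naive quadruple loop for the fully connected projection (oracle)."""
    rows, cols, orows, ocols = weights.shape
    out = np.zeros((orows, ocols))
    for i in range(orows):
        for j in range(ocols):
            for x in range(rows):
                for y in range(cols):
                    out[i, j] += a_inh[x, y] * weights[x, y, i, j]
    return out
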