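import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def naive_judgment(values):
    """Plain-Python transcription of the two-stage decision flow chart.

    Written independently of the package internals (explicit loops, manual
    variance) to serve as an equivalence oracle.  Returns
    (stage1_failed, batch_failed).
    """
    def mean(xs):
        return sum(xs) / len(xs)

    def sample_sd(xs):
        m = mean(xs)
        return math.sqrt(sum((x - m) ** 2 for x in xs) / (len(xs) - 1))

    def clamp(m):
        if m < 98.5:
            return 98.5
        if m > 101.5:
            return 101.5
        return m

    first = list(values[:10])
    m1 = mean(first)
    av1 = abs(clamp(m1) - m1) + 2.4 * sample_sd(first)
    if av1 <= 15.0:
        return False, False
    allv = list(values)
    m2 = mean(allv)
    M2 = clamp(m2)
    av2 = abs(M2 - m2) + 2.0 * sample_sd(allv)
    violated = False
    for x in allv:
        if x < 0.75 * M2 or x > 1.25 * M2:
            violated = True
    return True, (av2 > 15.0) or violated


@pytest.fixture
def rng():
    return np.random.default_rng(20230210)
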