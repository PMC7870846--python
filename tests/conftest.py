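import numpy as np
import pytest

from mfapkit.equilibria import TernaryAllosterySystem
from mfapkit.synthetic_data import NoiseModel


@pytest.fixture
def negative_allostery_system():
    """EF-hand-like sensor: analyte binding weakens chromophore affinity."""
    return TernaryAllosterySystem(
        kd_chromophore_apo=1.8, kd_chromophore_holo=11.0, kd_analyte_apo=60.0
    )


@pytest.fixture
def positive_allostery_system():
    """Kd- = 11, Kd+ = 1.8: analyte binding tightens chromophore binding."""
    return TernaryAllosterySystem(
        kd_chromophore_apo=11.0, kd_chromophore_holo=1.8, kd_analyte_apo=2300.0
    )


@pytest.fixture
def cv5_noise():
    return NoiseModel(cv=0.05)


def bisect(f, lo, hi, iters=200):
    """Plain bisection; independent of scipy root-finders for oracle use."""
    flo = f(lo)
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        fm = f(mid)
        if flo * fm <= 0:
            hi = mid
        else:
            lo, flo = mid, fm
    return 0.5 * (lo + hi)
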