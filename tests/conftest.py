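import numpy as np
import pytest


@pytest.fixture
def parallel_plate():
    """Straight wall y=0 with a parallel iris at depth 0.2 mm, spur at origin."""
    from acangle.geometry import BScanSection

    wall = np.column_stack([np.linspace(-3.0, 1.2, 85), np.zeros(85)])
    iris = np.column_stack([np.linspace(-2.5, 1.0, 71), np.full(71, 0.2)])
    return BScanSection(posterior_cornea=wall, anterior_iris=iris,
                        scleral_spur=np.array([0.0, 0.0]), side="right")


@pytest.fixture
def wedge():
    """Straight wall y=0, iris y = 0.15 - 0.1 x (recess peripheral), spur at 0."""
    from acangle.geometry import BScanSection

    wall = np.column_stack([np.linspace(-3.0, 1.2, 85), np.zeros(85)])
    x = np.linspace(-2.5, 1.0, 71)
    iris = np.column_stack([x, 0.15 - 0.1 * x])
    return BScanSection(posterior_cornea=wall, anterior_iris=iris,
                        scleral_spur=np.array([0.0, 0.0]), side="right")
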