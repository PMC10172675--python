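import numpy as np
import pytest

from normforge.grm import GRMParams, default_grid
from normforge.scales import ScaleSpec
from normforge.simulate import ItemBank


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture(scope="session")
def tiny_params():
    """Three small mixed-format items for exhaustive-enumeration oracles."""
    return GRMParams(
        ["i1", "i2", "i3"],
        np.array([1.2, 0.8, 1.5]),
        [np.array([-0.5, 0.7]), np.array([0.0]), np.array([-1.0, 0.2, 1.1])],
    )


@pytest.fixture(scope="session")
def bank10():
    """A 10-item 4-category bank with known truth, for recovery/diagnostics."""
    rng = np.random.default_rng(11)
    ids = [f"i{j}" for j in range(1, 11)]
    a = rng.uniform(1.2, 2.4, 10)
    b = [np.sort(rng.uniform(-1.8, 1.8, 3)) for _ in range(10)]
    b = [np.maximum.accumulate(bi) + np.array([0.0, 0.4, 0.8]) for bi in b]
    spec = ScaleSpec("SIM10", ids, [4] * 10)
    return ItemBank(spec, GRMParams(ids, a, b))


@pytest.fixture(scope="session")
def dif_bank():
    """Five strongly discriminating 5-category items, the DIF study fixture.

    Discriminations in the 2.4-3.3 range are typical of short clinical
    screeners; the effect-size gate's power depends directly on them.
    """
    ids = [f"i{j}" for j in range(1, 6)]
    a = np.array([2.7, 3.0, 2.4, 3.3, 2.85])
    b = [
        np.array([-1.2, -0.2, 0.8, 1.6]),
        np.array([-0.8, 0.2, 1.0, 1.9]),
        np.array([-1.5, -0.4, 0.6, 1.5]),
        np.array([-0.5, 0.4, 1.2, 2.0]),
        np.array([-1.0, 0.0, 0.9, 1.7]),
    ]
    spec = ScaleSpec("DIF5", ids, [5] * 5)
    return ItemBank(spec, GRMParams(ids, a, b))
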