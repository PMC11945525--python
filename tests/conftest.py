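import numpy as np
import pytest

from stripseg.synthetic import SyntheticConfig, generate_sample


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def straight_ribbon(width: int, canvas: int = 128, row: int = 50,
                    col_span: tuple[int, int] = (10, 118)) -> np.ndarray:
    """Axis-aligned horizontal ribbon mask of exact odd width centred on `row`."""
    assert width % 2 == 1, "use odd widths so the centre row is a pixel row"
    m = np.zeros((canvas, canvas), dtype=np.uint8)
    h = width // 2
    m[row - h : row + h + 1, col_span[0] : col_span[1]] = 1
    return m


@pytest.fixture(scope="session")
def default_sample():
    """One default-configuration synthetic sample, shared across tests."""
    return generate_sample(SyntheticConfig(seed=7))


@pytest.fixture(scope="session")
def small_samples():
    """Eight 96-px synthetic pairs for desk-scale training tests."""
    cfg = SyntheticConfig(canvas_size=96, seed=11)
    return [generate_sample(cfg, seed=1000 + i) for i in range(8)]
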