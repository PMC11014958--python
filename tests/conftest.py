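import numpy as np
import pytest

from polarcell import GridSpec, ModelParameters, PhaseField


def tanh_disc(grid: GridSpec, r: float, epsilon: float, center=None) -> PhaseField:
    """Tanh-profile disc of radius r (phi = +1 inside)."""
    X, Y = grid.meshgrid()
    if center is None:
        center = (0.5 * grid.lx, 0.5 * grid.ly)
    rr = np.hypot(X - center[0], Y - center[1])
    return PhaseField(np.tanh((r - rr) / (np.sqrt(2.0) * epsilon)), grid)


def tanh_slab(grid: GridSpec, half_width: float, epsilon: float) -> PhaseField:
    """Flat 1D tanh interface pair (slab |x - lx/2| < half_width)."""
    X, _ = grid.meshgrid()
    s = half_width - np.abs(X - 0.5 * grid.lx)
    return PhaseField(np.tanh(s / (np.sqrt(2.0) * epsilon)), grid)


def ellipse_polygon(a: float, b: float, n: int = 4096, center=(0.0, 0.0)) -> np.ndarray:
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return np.column_stack([center[0] + a * np.cos(t), center[1] + b * np.sin(t)])


@pytest.fixture
def unit_grid():
    return GridSpec(256, 256, 4.0, 4.0)


@pytest.fixture
def params_fine():
    return ModelParameters(epsilon=0.05, Ca=0.1, Be=1.0)
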