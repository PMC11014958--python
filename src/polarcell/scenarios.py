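"""Scenario presets, initial states, and synthetic fixtures.

The three computational regimes compare steady-state cell shape at t = 5
starting from the same elliptic cell with microtubules along the P/D (x)
axis:

* ``balanced``       Fa = −1,  Ca = 0.1 — protrusion and tension balance,
  the cell approximately keeps its shape;
* ``low_protrusion`` Fa = −10, Ca = 0.1 — weak protrusion, the cell
  shortens along P/D;
* ``low_tension``    Fa = −1,  Ca = 1 — weak tension, the cell elongates.

The synthetic fixtures (filament-texture images with known axial-angle
distributions, exponential-saturation ablation tracks) carry their
ground truth so the measurement procedures in :mod:`polarcell.quantify`
can be validated end to end without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.draw import line_aa

from .dynamics import SimulationState
from .fields import FlowState, OrientationField, PhaseField, indicator
from .grid import GridSpec
from .params import ModelParameters
from .quantify import ABLATION_DT, ABLATION_SPAN, AblationTrack, fold_axial_angle

__all__ = [
    "ScenarioConfig",
    "SyntheticFilamentSpec",
    "PRESETS",
    "regime_preset",
    "default_grid",
    "initial_cell_state",
    "synthetic_filament_image",
    "synthetic_ablation_track",
]

# Default regime geometry: aspect 1.5 ellipse, domain side 4x the
# major diameter, 128^2 nodes, interface eps = 2h.  The semi-axes are
# sized so the balanced preset sits near mechanical equilibrium
# (sigma*(kappa_tip - kappa_side) ~ 1/|Fa| with sigma = (2sqrt2/3)/Ca).
DEFAULT_A = 15.0
DEFAULT_B = 10.0
DEFAULT_N = 128
DEFAULT_SIDE = 4.0 * 2.0 * DEFAULT_A

_PRESET_TABLE = {
    "balanced": {"Fa": -1.0, "Ca": 0.1},
    "low_protrusion": {"Fa": -10.0, "Ca": 0.1},
    "low_tension": {"Fa": -1.0, "Ca": 1.0},
}
PRESETS = tuple(_PRESET_TABLE)


def default_grid(n: int = DEFAULT_N, side: float = DEFAULT_SIDE) -> GridSpec:
    return GridSpec(n, n, side, side)


def regime_preset(name: str, **overrides) -> ModelParameters:
    """Model parameters of one of the three computational regimes.

    All presets share the fixed bending number and the closure defaults;
    only (Fa, Ca) differ.  ``overrides`` may adjust closure constants
    (e.g. dt or epsilon for a non-default grid).
    """
    if name not in _PRESET_TABLE:
        raise ValueError(
            f"unknown preset {name!r}; valid presets: {', '.join(PRESETS)}"
        )
    kwargs = dict(_PRESET_TABLE[name])
    kwargs.update(overrides)
    return ModelParameters(**kwargs)


@dataclass(frozen=True)
class ScenarioConfig:
    """One simulation scenario: preset or explicit parameters + geometry."""

    preset: str | None = "balanced"
    params: ModelParameters | None = None
    grid: GridSpec = field(default_factory=default_grid)
    a: float = DEFAULT_A  # ellipse semi-major axis (P/D direction)
    b: float = DEFAULT_B  # ellipse semi-minor axis
    tilt: float = 0.0  # degrees, major-axis tilt from the x axis
    output_times: tuple[float, ...] = tuple(np.round(np.arange(0.0, 5.0 + 1e-9, 0.25), 10))
    seed: int | None = None  # fixtures only; the solver itself is seed-free

    def __post_init__(self):
        if not (self.a >= self.b > 0):
            raise ValueError("ellipse semi-axes must satisfy a >= b > 0")
        if self.preset is None and self.params is None:
            raise ValueError("either a preset name or explicit parameters required")

    def model_parameters(self) -> ModelParameters:
        if self.params is not None:
            return self.params
        return regime_preset(self.preset)


def initial_cell_state(config: ScenarioConfig, params: ModelParameters) -> SimulationState:
    """Elliptic cell with microtubules along the P/D (x) axis at t = 0.

    φ is a tanh profile of the (approximate) signed distance to the
    ellipse boundary, positive inside, so the φ = 0 level set is exactly
    the ellipse; P = (1, 0)·φ̃; the fluid starts at rest.
    """
    grid = config.grid
    params.check_resolution(grid.h)
    if 2.0 * config.a > 0.5 * min(grid.lx, grid.ly):
        raise ValueError(
            "cell too large for domain: major diameter must be at most half the side"
        )
    X, Y = grid.meshgrid()
    xc, yc = 0.5 * grid.lx, 0.5 * grid.ly
    dx, dy = X - xc, Y - yc
    if config.tilt:
        th = np.radians(config.tilt)
        dx, dy = np.cos(th) * dx + np.sin(th) * dy, -np.sin(th) * dx + np.cos(th) * dy
    a, b = config.a, config.b
    e = np.sqrt((dx / a) ** 2 + (dy / b) ** 2)
    # first-order signed distance: (1 - e)/|grad e|, positive inside
    grad_e = np.sqrt((dx / a**2) ** 2 + (dy / b**2) ** 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        sdist = np.where(grad_e > 0, (1.0 - e) * e / np.where(grad_e > 0, grad_e, 1.0), b)
    phi = np.tanh(sdist / (np.sqrt(2.0) * params.epsilon))
    phase = PhaseField(phi, grid)
    phit = indicator(phase)
    orient = OrientationField(phit.copy(), np.zeros(grid.shape), grid)
    return SimulationState(t=0.0, phase=phase, orient=orient, flow=FlowState.zeros(grid))


# ---------------------------------------------------------------------------
# synthetic fixtures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticFilamentSpec:
    """Ground-truthed filament-texture image specification.

    Axial segment angles are drawn from a von Mises distribution on the
    doubled angle (the standard axial-data model); κ_vm = 0 is uniform,
    large κ_vm concentrates all segments at the mean angle.
    """

    mean_angle: float = 0.0  # degrees, relative to the P/D (x) axis
    kappa_vm: float = 8.0  # concentration on the doubled-angle circle
    n_segments: int = 500
    image_size: int = 512  # pixels per side
    segment_length: float = 60.0  # pixels
    segment_blur: float = 1.0  # px Gaussian blur giving the filament width
    noise_sd: float = 0.05  # additive Gaussian noise (image max is ~1)
    seed: int = 0

    def __post_init__(self):
        if self.kappa_vm < 0:
            raise ValueError("kappa_vm must be non-negative")
        if self.n_segments < 1:
            raise ValueError("need at least one segment")
        if self.image_size < 8:
            raise ValueError("image too small")


def synthetic_filament_image(spec: SyntheticFilamentSpec) -> tuple[np.ndarray, pd.DataFrame]:
    """Render anti-aliased filament segments with known axial angles.

    Returns the float image (Cartesian row = y convention, values ≥ 0)
    and the ground-truth table of per-segment angles (degrees, folded to
    (−90, 90]).  Bit-identical under a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.kappa_vm >= 1e6:
        doubled = np.full(spec.n_segments, np.radians(2.0 * spec.mean_angle))
    else:
        doubled = rng.vonmises(
            np.radians(2.0 * spec.mean_angle), spec.kappa_vm, size=spec.n_segments
        )
    angles = fold_axial_angle(np.degrees(doubled) / 2.0)
    size = spec.image_size
    img = np.zeros((size, size))
    half = spec.segment_length / 2.0
    margin = int(np.ceil(half)) + 2
    cx = rng.uniform(margin, size - margin, spec.n_segments)
    cy = rng.uniform(margin, size - margin, spec.n_segments)
    for x0, y0, ang in zip(cx, cy, np.radians(angles)):
        ux, uy = np.cos(ang), np.sin(ang)
        r0, c0 = int(round(y0 - half * uy)), int(round(x0 - half * ux))
        r1, c1 = int(round(y0 + half * uy)), int(round(x0 + half * ux))
        rr, cc, val = line_aa(r0, c0, r1, c1)
        ok = (rr >= 0) & (rr < size) & (cc >= 0) & (cc < size)
        img[rr[ok], cc[ok]] += val[ok]
    if spec.segment_blur > 0:
        img = gaussian_filter(img, spec.segment_blur)
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, img.shape)
    truth = pd.DataFrame({"segment": np.arange(spec.n_segments), "angle_deg": angles})
    return img, truth


def synthetic_ablation_track(
    d0: float,
    A: float,
    tau: float,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[AblationTrack, float]:
    """Exponential-saturation vertex-separation track plus its ground truth.

    d(t) = d0 + A(1 − e^{−t/τ}) + noise on the 200 ms grid over 2 s.
    Returns the track and the noiseless initial recoil velocity
    A(1 − e^{−0.2/τ})/0.2, the quantity the measurement should recover.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    times = np.round(np.arange(0.0, ABLATION_SPAN + 1e-9, ABLATION_DT), 10)
    d = d0 + A * (1.0 - np.exp(-times / tau))
    if noise_sd > 0:
        d = d + np.random.default_rng(seed).normal(0.0, noise_sd, d.shape)
    d = np.clip(d, 0.0, None)
    truth = A * (1.0 - np.exp(-ABLATION_DT / tau)) / ABLATION_DT
    return AblationTrack(times=times, distances=d), truth
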