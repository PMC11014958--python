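"""Field containers: phase field, orientation field, Stokes flow state.

The cell is described by a scalar phase field φ (1 inside, −1 outside,
smooth across an interface of thickness ~ε), the mean microtubule
direction by a 2-vector orientation field P (unit length inside the cell,
vanishing outside), and the fluid by a velocity/pressure pair (u, p) of a
Stokes problem on the periodic domain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import GridSpec

__all__ = [
    "PhaseField",
    "OrientationField",
    "FlowState",
    "indicator",
    "PHI_BOUND_SLACK",
]

#: permitted overshoot of |φ| beyond 1 (and |P| beyond 1) during dynamics
PHI_BOUND_SLACK = 0.05


def _require_same_grid(*grids: GridSpec) -> None:
    first = grids[0]
    for g in grids[1:]:
        if g != first:
            raise ValueError("fields must share one grid")


@dataclass
class PhaseField:
    """Scalar phase field φ on a periodic grid (1 inside the cell, −1 outside)."""

    values: np.ndarray
    grid: GridSpec

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.grid.check_field(self.values, "phi")

    def mass(self) -> float:
        """Total mass ∫φ dx — conserved by the dynamics."""
        return self.grid.integrate(self.values)

    def within_bounds(self, slack: float = PHI_BOUND_SLACK) -> bool:
        return bool(np.all(np.abs(self.values) <= 1.0 + slack))

    def copy(self) -> "PhaseField":
        return PhaseField(self.values.copy(), self.grid)


@dataclass
class OrientationField:
    """Vector field P giving the average local microtubule direction."""

    px: np.ndarray
    py: np.ndarray
    grid: GridSpec

    def __post_init__(self) -> None:
        self.px = np.asarray(self.px, dtype=float)
        self.py = np.asarray(self.py, dtype=float)
        self.grid.check_field(self.px, "px")
        self.grid.check_field(self.py, "py")

    def norm(self) -> np.ndarray:
        return np.hypot(self.px, self.py)

    def copy(self) -> "OrientationField":
        return OrientationField(self.px.copy(), self.py.copy(), self.grid)


@dataclass
class FlowState:
    """Velocity (ux, uy) and pressure p of the periodic Stokes problem.

    Gauge: zero-mean velocity and pressure on the torus.
    """

    ux: np.ndarray
    uy: np.ndarray
    p: np.ndarray
    grid: GridSpec

    def __post_init__(self) -> None:
        self.ux = np.asarray(self.ux, dtype=float)
        self.uy = np.asarray(self.uy, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        for arr, name in ((self.ux, "ux"), (self.uy, "uy"), (self.p, "p")):
            self.grid.check_field(arr, name)

    @classmethod
    def zeros(cls, grid: GridSpec) -> "FlowState":
        z = np.zeros(grid.shape)
        return cls(z.copy(), z.copy(), z.copy(), grid)

    def speed(self) -> np.ndarray:
        return np.hypot(self.ux, self.uy)

    def copy(self) -> "FlowState":
        return FlowState(self.ux.copy(), self.uy.copy(), self.p.copy(), self.grid)


def indicator(phase: PhaseField | np.ndarray) -> np.ndarray:
    """Interior indicator φ̃ = (φ + 1)/2: 1 inside the cell, 0 outside."""
    values = phase.values if isinstance(phase, PhaseField) else np.asarray(phase)
    return 0.5 * (values + 1.0)
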