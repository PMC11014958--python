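"""Uniform periodic grids for the diffuse-interface model.

The continuum domain is a flat 2-torus discretized by a uniform node grid
with square cells.  All fields (phase field, orientation field, velocity,
pressure) live on the nodes; spectral differentiation assumes periodicity
in both directions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np

__all__ = ["GridSpec"]


@dataclass(frozen=True)
class GridSpec:
    """Uniform periodic grid with square cells.

    Parameters
    ----------
    nx, ny : int
        Node counts along x and y.  At least 32 each.
    lx, ly : float
        Domain side lengths in model units.  The spacing ``lx/nx`` must
        equal ``ly/ny`` (square cells).
    """

    nx: int
    ny: int
    lx: float
    ly: float

    def __post_init__(self) -> None:
        if self.nx < 32 or self.ny < 32:
            raise ValueError("grid must have at least 32 nodes per direction")
        hx = self.lx / self.nx
        hy = self.ly / self.ny
        if not np.isclose(hx, hy, rtol=1e-12):
            raise ValueError(f"grid cells must be square (hx={hx}, hy={hy})")

    @property
    def h(self) -> float:
        """Grid spacing (equal in both directions)."""
        return self.lx / self.nx

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nx, self.ny)

    @property
    def cell_area(self) -> float:
        return self.h * self.h

    @cached_property
    def x(self) -> np.ndarray:
        """Node x coordinates, shape (nx,)."""
        return np.arange(self.nx) * self.h

    @cached_property
    def y(self) -> np.ndarray:
        """Node y coordinates, shape (ny,)."""
        return np.arange(self.ny) * self.h

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray]:
        """Coordinate arrays X, Y of shape (nx, ny) (ij indexing)."""
        return np.meshgrid(self.x, self.y, indexing="ij")

    def integrate(self, values: np.ndarray) -> float:
        """Integral of a nodal field over the torus.

        The periodic trapezoid rule reduces to a plain sum times the cell
        area and is spectrally accurate for smooth periodic fields.
        """
        return float(np.sum(values) * self.cell_area)

    def check_field(self, values: np.ndarray, name: str = "field") -> None:
        if values.shape != self.shape:
            raise ValueError(
                f"{name} has shape {values.shape}, expected {self.shape}"
            )
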