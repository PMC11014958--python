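"""Free-energy functionals of the force-balance model.

The total free energy splits into

* kinetic energy of the fluid,          E_kin = ∫ ½|u|² dx
* Cahn–Hilliard surface energy,         E_surf = (1/Ca) ∫ (ε/2)|∇φ|² + W(φ)/ε dx
* diffuse-interface Helfrich bending,   E_bend = (1/Be) ∫ (1/(2ε)) (ε∇²φ − W′(φ)/ε)² dx
* microtubule-network energy,           E_P = ∫ (κ_P/2)|∇P|² + (1/(4δ_P)) (|P|² − φ̃²)² dx

with the quartic double well W(φ) = ¼(φ² − 1)² whose minima sit at the two
bulk phases φ = ±1.  The surface term integrates to a line tension of
σ = (2√2/3)/Ca per unit interface length; the bending term is the
Willmore (squared chemical-potential) approximation of the Helfrich
energy; E_P weakly enforces |P| = 1 inside the cell (where φ̃ = 1) and
P = 0 outside (φ̃ = 0), with |P| tracking φ̃ linearly across the
interface so the orientation field decays at least as fast as the
interior indicator.

All integrals use the periodic trapezoid rule and all gradients are
spectral, so each energy here is an exact discrete functional of the
nodal values — the variational derivatives in :mod:`polarcell.dynamics`
are its exact discrete gradients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fields import FlowState, OrientationField, PhaseField, indicator
from .params import ModelParameters
from .spectral import ops_for

__all__ = [
    "double_well",
    "double_well_prime",
    "double_well_second",
    "surface_energy",
    "bending_energy",
    "polar_energy",
    "kinetic_energy",
    "total_energy",
    "EnergyBreakdown",
    "LINE_TENSION_COEFF",
]

#: line-tension constant ∫√(2W) dφ = 2√2/3 of the quartic well
LINE_TENSION_COEFF = 2.0 * np.sqrt(2.0) / 3.0


def double_well(value):
    """Quartic double-well potential W(φ) = ¼(φ²−1)², minima at ±1."""
    v = np.asarray(value, dtype=float)
    w = 0.25 * (v * v - 1.0) ** 2
    return w if w.ndim else float(w)


def double_well_prime(value):
    """W′(φ) = φ³ − φ."""
    v = np.asarray(value, dtype=float)
    w = v**3 - v
    return w if w.ndim else float(w)


def double_well_second(value):
    """W″(φ) = 3φ² − 1."""
    v = np.asarray(value, dtype=float)
    w = 3.0 * v * v - 1.0
    return w if w.ndim else float(w)


def _check_resolution(phase: PhaseField, params: ModelParameters) -> None:
    params.check_resolution(phase.grid.h)


def surface_energy(phase: PhaseField, params: ModelParameters) -> float:
    """Cahn–Hilliard surface energy (1/Ca)∫ (ε/2)|∇φ|² + W(φ)/ε dx."""
    _check_resolution(phase, params)
    ops = ops_for(phase.grid)
    gx, gy = ops.grad(phase.values)
    density = 0.5 * params.epsilon * (gx * gx + gy * gy) + double_well(
        phase.values
    ) / params.epsilon
    return phase.grid.integrate(density) / params.Ca


def bending_energy(phase: PhaseField, params: ModelParameters) -> float:
    """Willmore-type bending energy (1/Be)∫ (1/(2ε)) (ε∇²φ − W′(φ)/ε)² dx.

    For a tanh profile around a circle of radius r ≫ ε this approaches
    (2√2/3)·π/(Be·r), the Helfrich energy of the circle times the
    diffuse-interface line-tension constant.
    """
    _check_resolution(phase, params)
    ops = ops_for(phase.grid)
    omega = params.epsilon * ops.laplacian(phase.values) - double_well_prime(
        phase.values
    ) / params.epsilon
    return phase.grid.integrate(omega * omega) / (2.0 * params.epsilon * params.Be)


def polar_energy(
    phase: PhaseField, orient: OrientationField, params: ModelParameters
) -> float:
    """Microtubule-network energy: distortion plus norm penalty.

    E_P = ∫ (κ_P/2)|∇P|² + (1/(4δ_P)) (|P|² − φ̃²)² dx.  Zero iff P is
    uniform with |P| = φ̃ everywhere: unit length inside the cell,
    vanishing outside.
    """
    if phase.grid != orient.grid:
        raise ValueError("phase and orientation fields must share one grid")
    ops = ops_for(phase.grid)
    gxx, gxy = ops.grad(orient.px)
    gyx, gyy = ops.grad(orient.py)
    distortion = 0.5 * params.kappa_P * (gxx**2 + gxy**2 + gyx**2 + gyy**2)
    mismatch = orient.px**2 + orient.py**2 - indicator(phase) ** 2
    penalty = mismatch * mismatch / (4.0 * params.delta_P)
    return phase.grid.integrate(distortion + penalty)


def kinetic_energy(flow: FlowState, params: ModelParameters | None = None) -> float:
    """E_kin = ∫ ½|u|² dx (unit fluid density inside and outside)."""
    return flow.grid.integrate(0.5 * (flow.ux**2 + flow.uy**2))


@dataclass(frozen=True)
class EnergyBreakdown:
    """Decomposition of the total free energy into its four contributions."""

    e_kin: float
    e_surf: float
    e_bend: float
    e_polar: float

    @property
    def e_total(self) -> float:
        return self.e_kin + self.e_surf + self.e_bend + self.e_polar

    @property
    def e_membrane(self) -> float:
        """Membrane energy E_S = surface + bending."""
        return self.e_surf + self.e_bend

    def as_dict(self) -> dict:
        return {
            "e_kin": self.e_kin,
            "e_surf": self.e_surf,
            "e_bend": self.e_bend,
            "e_polar": self.e_polar,
            "e_total": self.e_total,
        }


def total_energy(
    phase: PhaseField,
    orient: OrientationField,
    flow: FlowState,
    params: ModelParameters,
) -> EnergyBreakdown:
    """Evaluate all four energy components on one shared grid."""
    if not (phase.grid == orient.grid == flow.grid):
        raise ValueError("all fields must share one grid")
    return EnergyBreakdown(
        e_kin=kinetic_energy(flow, params),
        e_surf=surface_energy(phase, params),
        e_bend=bending_energy(phase, params),
        e_polar=polar_energy(phase, orient, params),
    )
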