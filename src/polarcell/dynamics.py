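"""Time evolution of the coupled phase-field / active-gel / Stokes system.

The fields evolve as an advected gradient flow of the free energy in
:mod:`polarcell.energy`:

* phase field (conserved Cahn–Hilliard flow):  ∂tφ + u·∇φ = γ_φ ∇²μ,
  with μ = δ(E_surf + E_bend + E_P)/δφ;
* orientation field:  ∂tP + (u·∇)P = γ_P h, with h = −δE_P/δP;
* fluid: quasi-static Stokes flow −η∇²u + ∇p = f, ∇·u = 0, forced by the
  passive (thermodynamically conjugate) coupling force and the divergence
  of the protrusive active stress σ_a = (1/Fa) φ̃ P⊗P.

Discretization: pseudospectral in space on the periodic grid, first-order
IMEX in time — the stiff linear parts (∇⁴/∇⁶ terms of the conserved flow,
the distortion Laplacian of P) are implicit in Fourier space, the
nonlinear and coupling terms explicit; the stiff norm-penalty relaxation
of P is applied as an exact pointwise logistic substep.  The k = 0 mode
of every φ update vanishes identically, so the total mass ∫φ dx is
conserved to round-off.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .energy import (
    EnergyBreakdown,
    double_well_prime,
    double_well_second,
    total_energy,
)
from .fields import (
    PHI_BOUND_SLACK,
    FlowState,
    OrientationField,
    PhaseField,
    indicator,
)
from .grid import GridSpec
from .params import ModelParameters
from .spectral import SpectralOps, ops_for

__all__ = [
    "SimulationState",
    "Trajectory",
    "StepDivergenceError",
    "chemical_potential",
    "molecular_field",
    "active_stress",
    "body_force",
    "stokes_solve",
    "advance_step",
    "run_simulation",
    "steady_state_reached",
]


class StepDivergenceError(RuntimeError):
    """Raised when a time step produces non-finite or out-of-bound fields."""

    def __init__(self, field_name: str, t: float, detail: str = ""):
        self.field_name = field_name
        self.t = t
        super().__init__(
            f"time step diverged at t={t:g} in field '{field_name}' {detail}".rstrip()
        )


# ---------------------------------------------------------------------------
# variational derivatives and forces
# ---------------------------------------------------------------------------

def chemical_potential(
    phase: PhaseField, orient: OrientationField, params: ModelParameters
) -> np.ndarray:
    """μ = δ(E_surf + E_bend + E_P)/δφ, the exact discrete first variation.

    Three contributions: the Cahn–Hilliard part (1/Ca)(W′(φ)/ε − ε∇²φ),
    the Willmore part (1/Be)(∇²ω − W″(φ)ω/ε²) with ω = ε∇²φ − W′(φ)/ε,
    and the penalty coupling −(1/(2δ_P))(|P|² − φ̃²)φ̃ from E_P through φ̃.
    """
    params.check_resolution(phase.grid.h)
    if phase.grid != orient.grid:
        raise ValueError("phase and orientation fields must share one grid")
    ops = ops_for(phase.grid)
    phi = phase.values
    eps = params.epsilon
    lap_phi = ops.laplacian(phi)
    wp = double_well_prime(phi)
    mu_surf = (wp / eps - eps * lap_phi) / params.Ca
    omega = eps * lap_phi - wp / eps
    mu_bend = (ops.laplacian(omega) - double_well_second(phi) * omega / eps**2) / params.Be
    phit = indicator(phase)
    mismatch = orient.px**2 + orient.py**2 - phit**2
    mu_polar = -mismatch * phit / (2.0 * params.delta_P)
    return mu_surf + mu_bend + mu_polar


def molecular_field(
    phase: PhaseField, orient: OrientationField, params: ModelParameters
) -> tuple[np.ndarray, np.ndarray]:
    """h = −δE_P/δP = κ_P∇²P − (1/δ_P)(|P|² − φ̃²)P.

    Relaxation of P along h decreases E_P; h vanishes at uniform P with
    |P| = φ̃.
    """
    if phase.grid != orient.grid:
        raise ValueError("phase and orientation fields must share one grid")
    ops = ops_for(orient.grid)
    mismatch = orient.px**2 + orient.py**2 - indicator(phase) ** 2
    coeff = mismatch / params.delta_P
    hx = params.kappa_P * ops.laplacian(orient.px) - coeff * orient.px
    hy = params.kappa_P * ops.laplacian(orient.py) - coeff * orient.py
    return hx, hy


def active_stress(
    phase: PhaseField, orient: OrientationField, params: ModelParameters
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Protrusive active stress σ_a = (1/Fa) φ̃ P⊗P.

    Returns the components (σ_xx, σ_xy, σ_yy).  With Fa < 0 the tensor is
    negative semi-definite, which makes its divergence push the interface
    outward along ±P — the mesoscopic protrusive force of the microtubule
    network.  Vanishes outside the cell where φ̃ = 0.
    """
    if params.Fa >= 0:
        raise ValueError("Fa must be negative")
    phit = indicator(phase)
    pref = phit / params.Fa
    sxx = pref * orient.px * orient.px
    sxy = pref * orient.px * orient.py
    syy = pref * orient.py * orient.py
    return sxx, sxy, syy


def body_force(
    phase: PhaseField,
    orient: OrientationField,
    params: ModelParameters,
    mu: np.ndarray | None = None,
    h: tuple[np.ndarray, np.ndarray] | None = None,
    include_active: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Force density on the fluid: passive coupling plus active stress.

    The passive part is the thermodynamically conjugate force
    f = μ∇φ + (∇P)ᵀ(δE_P/δP), chosen so that with the active stress off
    the discrete total energy is non-increasing: the power the force
    injects into the Stokes flow exactly equals the advective energy loss
    of the fields.  The active part is ∇·σ_a.
    """
    ops = ops_for(phase.grid)
    if mu is None:
        mu = chemical_potential(phase, orient, params)
    if h is None:
        h = molecular_field(phase, orient, params)
    hx, hy = h
    gpx, gpy = ops.grad(phase.values)
    fx = mu * gpx
    fy = mu * gpy
    # (∇P)ᵀ g with g = δE_P/δP = −h : f_i += g_j ∂_i P_j
    dpx_dx, dpx_dy = ops.grad(orient.px)
    dpy_dx, dpy_dy = ops.grad(orient.py)
    fx += -hx * dpx_dx - hy * dpy_dx
    fy += -hx * dpx_dy - hy * dpy_dy
    if include_active:
        sxx, sxy, syy = active_stress(phase, orient, params)
        sxx_h = ops.fft(sxx)
        sxy_h = ops.fft(sxy)
        syy_h = ops.fft(syy)
        fx += ops.ifft(1j * ops.kx * sxx_h + 1j * ops.ky * sxy_h)
        fy += ops.ifft(1j * ops.kx * sxy_h + 1j * ops.ky * syy_h)
    return fx, fy


def stokes_solve(
    fx: np.ndarray,
    fy: np.ndarray,
    params: ModelParameters,
    grid: GridSpec,
) -> FlowState:
    """Solve −η∇²u + ∇p = f, ∇·u = 0 on the torus (zero-mean gauge).

    Spectral solution: pressure from the divergence of f, velocity from
    the Leray projection of f divided by ηk².  The mean force (k = 0
    mode) is removed — the torus problem is solvable only for zero-mean
    forcing — and the returned velocity is divergence-free to round-off.
    """
    if params.eta <= 0:
        raise ValueError("viscosity must be positive")
    ops = ops_for(grid)
    fxh = ops.fft(fx)
    fyh = ops.fft(fy)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv_k2 = np.where(ops.k2 > 0, 1.0 / np.where(ops.k2 > 0, ops.k2, 1.0), 0.0)
    kf = 1j * (ops.kx * fxh + ops.ky * fyh)
    ph = -kf * inv_k2
    # subtracting ∇p (transform i k p̂) is the Leray projection of f
    proj_fx = fxh - 1j * ops.kx * ph
    proj_fy = fyh - 1j * ops.ky * ph
    uxh = proj_fx * inv_k2 / params.eta
    uyh = proj_fy * inv_k2 / params.eta
    uxh[0, 0] = 0.0
    uyh[0, 0] = 0.0
    ph[0, 0] = 0.0
    return FlowState(ops.ifft(uxh), ops.ifft(uyh), ops.ifft(ph), grid)


# ---------------------------------------------------------------------------
# state bundle and time stepping
# ---------------------------------------------------------------------------

@dataclass
class SimulationState:
    """Bundle of the model unknowns at one time."""

    t: float
    phase: PhaseField
    orient: OrientationField
    flow: FlowState

    def energy(self, params: ModelParameters) -> EnergyBreakdown:
        return total_energy(self.phase, self.orient, self.flow, params)

    def copy(self) -> "SimulationState":
        return SimulationState(
            self.t, self.phase.copy(), self.orient.copy(), self.flow.copy()
        )


def _implicit_phi_symbol(ops: SpectralOps, params: ModelParameters) -> np.ndarray:
    """Positive implicit symbol for the conserved phase-field flow.

    Includes the leading linear terms γε/Ca k⁴ and γε/Be k⁶ plus an
    Eyre-type k² stabilization of the explicitly treated −W′ part.
    """
    g = params.gamma_phi
    stab = 2.0 / (params.Ca * params.epsilon)
    return g * (
        params.epsilon / params.Ca * ops.k4
        + params.epsilon / params.Be * ops.k6
        + stab * ops.k2
    )


def _norm_relaxation(
    px: np.ndarray,
    py: np.ndarray,
    target: np.ndarray,
    rate_dt: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact substep of dm/dt = −2r(m − a)m for m = |P|², a = target ≥ 0.

    Logistic in m; the direction of P is untouched.  Unconditionally
    stable for any step size, which is what makes the small-δ_P penalty
    usable without tiny time steps.
    """
    m0 = px * px + py * py
    a = np.clip(target, 0.0, None)
    lam = 2.0 * rate_dt * a
    denom = m0 + (a - m0) * np.exp(-lam)
    pos = a > 1e-14
    m_new = np.where(
        pos,
        np.where(denom > 0, a * m0 / np.where(denom > 0, denom, 1.0), 0.0),
        m0 / (1.0 + 2.0 * rate_dt * m0),
    )
    scale = np.sqrt(np.where(m0 > 0, m_new / np.where(m0 > 0, m0, 1.0), 0.0))
    return px * scale, py * scale


def advance_step(
    state: SimulationState,
    params: ModelParameters,
    include_active: bool = True,
) -> SimulationState:
    """Advance the coupled system by one time step dt.

    Order of operations: (1) variational derivatives of the current
    fields, (2) body force and Stokes solve, (3) IMEX transport updates
    of φ and P with the fresh velocity, followed by the exact norm
    relaxation of P.  Raises :class:`StepDivergenceError` if the step
    leaves a field non-finite or outside its bound invariants.
    """
    grid = state.phase.grid
    ops = ops_for(grid)
    dt = params.dt

    mu = chemical_potential(state.phase, state.orient, params)
    h = molecular_field(state.phase, state.orient, params)
    fx, fy = body_force(
        state.phase, state.orient, params, mu=mu, h=h, include_active=include_active
    )
    flow = stokes_solve(fx, fy, params, grid)

    # --- phase field: IMEX conserved gradient flow + advection ---
    phi = state.phase.values
    phih = ops.fft(phi)
    gpx, gpy = ops.grad(phi)
    adv = ops.dealias(flow.ux * gpx + flow.uy * gpy)
    advh = ops.fft(adv)
    advh[0, 0] = 0.0  # ∫u·∇φ dx = 0 for div-free u: enforce mass conservation
    muh = ops.fft(mu)
    L = _implicit_phi_symbol(ops, params)
    rhs = phih + dt * (-advh - params.gamma_phi * ops.k2 * muh + L * phih)
    phih_new = rhs / (1.0 + dt * L)
    phi_new = ops.ifft(phih_new)

    # --- orientation field: advect, implicit distortion, exact norm relax ---
    adv_px = ops.dealias(flow.ux * ops.dx(state.orient.px) + flow.uy * ops.dy(state.orient.px))
    adv_py = ops.dealias(flow.ux * ops.dx(state.orient.py) + flow.uy * ops.dy(state.orient.py))
    denom_p = 1.0 + dt * params.gamma_P * params.kappa_P * ops.k2
    pxh = (ops.fft(state.orient.px - dt * adv_px)) / denom_p
    pyh = (ops.fft(state.orient.py - dt * adv_py)) / denom_p
    px_star = ops.ifft(pxh)
    py_star = ops.ifft(pyh)
    px_new, py_new = _norm_relaxation(
        px_star,
        py_star,
        indicator(phi_new) ** 2,
        params.gamma_P * dt / params.delta_P,
    )

    t_new = state.t + dt
    if not np.all(np.isfinite(phi_new)):
        raise StepDivergenceError("phi", t_new, "(non-finite values)")
    if np.max(np.abs(phi_new)) > 1.0 + PHI_BOUND_SLACK:
        raise StepDivergenceError(
            "phi", t_new, f"(|phi| max {np.max(np.abs(phi_new)):.3f} > 1.05)"
        )
    if not (np.all(np.isfinite(px_new)) and np.all(np.isfinite(py_new))):
        raise StepDivergenceError("P", t_new, "(non-finite values)")
    if not (np.all(np.isfinite(flow.ux)) and np.all(np.isfinite(flow.uy))):
        raise StepDivergenceError("u", t_new, "(non-finite values)")

    return SimulationState(
        t=t_new,
        phase=PhaseField(phi_new, grid),
        orient=OrientationField(px_new, py_new, grid),
        flow=flow,
    )


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Sampled output of one simulation run."""

    times: list[float] = field(default_factory=list)
    metrics: list = field(default_factory=list)  # ShapeMetrics rows
    energies: list[EnergyBreakdown] = field(default_factory=list)
    states: list[SimulationState] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def metrics_frame(self):
        """Time series of shape metrics and energies as a DataFrame."""
        import pandas as pd

        rows = []
        for t, m, e in zip(self.times, self.metrics, self.energies):
            row = {"t": t}
            row.update(m.as_dict())
            row.update(e.as_dict())
            rows.append(row)
        return pd.DataFrame(rows)


def run_simulation(
    initial: SimulationState,
    params: ModelParameters,
    output_times,
    include_active: bool = True,
    keep_fields: bool = False,
) -> Trajectory:
    """Run the solver to the last output time, sampling shape metrics.

    ``output_times`` must start at 0 and be strictly increasing; each is
    snapped to the nearest multiple of dt.  The run is fully
    deterministic — identical inputs give bit-identical trajectories.
    """
    from .quantify import extract_contour, shape_metrics

    output_times = [float(t) for t in output_times]
    if not output_times or output_times[0] != 0.0:
        raise ValueError("output times must start at t = 0")
    if any(b <= a for a, b in zip(output_times, output_times[1:])):
        raise ValueError("output times must be strictly increasing")

    dt = params.dt
    out_steps = [int(round(t / dt)) for t in output_times]
    traj = Trajectory(
        provenance={
            "params": params.to_dict(),
            "grid": {
                "nx": initial.phase.grid.nx,
                "ny": initial.phase.grid.ny,
                "lx": initial.phase.grid.lx,
                "ly": initial.phase.grid.ly,
            },
            "include_active": include_active,
        }
    )

    def sample(state: SimulationState) -> None:
        contour = extract_contour(state.phase)
        traj.times.append(state.t)
        traj.metrics.append(shape_metrics(contour.polygon))
        traj.energies.append(state.energy(params))
        if keep_fields:
            traj.states.append(state.copy())

    state = initial
    sample(state)
    next_idx = 1
    for step in range(1, out_steps[-1] + 1):
        state = advance_step(state, params, include_active=include_active)
        if next_idx < len(out_steps) and step == out_steps[next_idx]:
            state = SimulationState(
                t=output_times[next_idx], phase=state.phase,
                orient=state.orient, flow=state.flow,
            )
            sample(state)
            next_idx += 1
    return traj


def steady_state_reached(metrics_series, window: int = 10, tol: float = 1e-3) -> bool:
    """True iff feret_major and circularity are flat over the trailing window.

    Flat means the max relative change across the last ``window`` samples
    is at most ``tol`` for both series.
    """
    if len(metrics_series) < window:
        raise ValueError(f"need at least {window} samples, got {len(metrics_series)}")
    tail = metrics_series[-window:]
    for attr in ("feret_major", "circularity"):
        vals = np.array([getattr(m, attr) for m in tail], dtype=float)
        ref = np.max(np.abs(vals))
        if ref == 0:
            continue
        if (vals.max() - vals.min()) / ref > tol:
            return False
    return True
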