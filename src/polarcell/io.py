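"""Serialization: metrics CSV, HDF5 field snapshots, manifests, renders."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .dynamics import SimulationState, Trajectory
from .fields import FlowState, OrientationField, PhaseField
from .grid import GridSpec

__all__ = [
    "write_metrics_csv",
    "write_state_h5",
    "read_state_h5",
    "write_manifest",
    "render_phase_png",
]


def write_metrics_csv(traj: Trajectory, path) -> Path:
    """Write the (t, shape metrics, energies) time series as CSV."""
    path = Path(path)
    traj.metrics_frame().to_csv(path, index=False, float_format="%.12g")
    return path


def write_state_h5(state: SimulationState, path) -> Path:
    """Snapshot the fields (phi, px, py, ux, uy, p) with grid metadata."""
    path = Path(path)
    g = state.phase.grid
    with h5py.File(path, "w") as f:
        f.attrs["t"] = state.t
        f.attrs["nx"], f.attrs["ny"] = g.nx, g.ny
        f.attrs["lx"], f.attrs["ly"] = g.lx, g.ly
        f.create_dataset("phi", data=state.phase.values)
        f.create_dataset("px", data=state.orient.px)
        f.create_dataset("py", data=state.orient.py)
        f.create_dataset("ux", data=state.flow.ux)
        f.create_dataset("uy", data=state.flow.uy)
        f.create_dataset("p", data=state.flow.p)
    return path


def read_state_h5(path) -> SimulationState:
    with h5py.File(path, "r") as f:
        grid = GridSpec(int(f.attrs["nx"]), int(f.attrs["ny"]),
                        float(f.attrs["lx"]), float(f.attrs["ly"]))
        return SimulationState(
            t=float(f.attrs["t"]),
            phase=PhaseField(f["phi"][...], grid),
            orient=OrientationField(f["px"][...], f["py"][...], grid),
            flow=FlowState(f["ux"][...], f["uy"][...], f["p"][...], grid),
        )


def write_manifest(path, payload: dict) -> Path:
    """Write a JSON run manifest (parameters, grid, versions)."""
    from . import __version__

    path = Path(path)
    record = {"polarcell_version": __version__}
    record.update(payload)
    path.write_text(json.dumps(record, indent=2, sort_keys=True, default=str) + "\n")
    return path


def render_phase_png(state: SimulationState, path, quiver_stride: int = 8) -> Path:
    """Render φ with a P quiver overlay and the φ = 0 membrane line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    g = state.phase.grid
    fig, ax = plt.subplots(figsize=(5, 5))
    X, Y = g.meshgrid()
    ax.imshow(
        state.phase.values.T,
        origin="lower",
        extent=(0, g.lx, 0, g.ly),
        cmap="viridis",
        vmin=-1,
        vmax=1,
    )
    s = quiver_stride
    ax.quiver(
        X[::s, ::s], Y[::s, ::s],
        state.orient.px[::s, ::s], state.orient.py[::s, ::s],
        color="turquoise", scale=40,
    )
    ax.contour(X, Y, state.phase.values, levels=[0.0], colors="white")
    ax.set_title(f"t = {state.t:g}")
    ax.set_xlabel("x (P/D)")
    ax.set_ylabel("y (A/P)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
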