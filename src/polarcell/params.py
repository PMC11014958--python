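"""Model parameters of the actomyosin–microtubule force-balance model.

The physical control parameters are the interface thickness ``epsilon``,
the capillary number ``Ca`` (larger Ca = weaker surface tension, i.e.
weaker actomyosin), the bending number ``Be`` (Helfrich bending
resistance, kept fixed across regimes) and the active force number ``Fa``
(negative; larger |Fa| = weaker microtubule protrusion).  The remaining
scalars are closure constants of this implementation: fluid viscosity,
orientation-field distortion modulus and norm-penalty scale, the two
gradient-flow mobilities and the time step.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace

__all__ = ["ModelParameters"]


@dataclass(frozen=True)
class ModelParameters:
    """Dimensionless parameters of the coupled phase-field/active-gel model.

    Attributes
    ----------
    epsilon : float
        Interface-thickness parameter of the diffuse interface, > 0.
    Ca : float
        Capillary number scaling surface tension as 1/Ca, > 0.
    Be : float
        Bending-resistance number scaling the Helfrich term as 1/Be, > 0.
    Fa : float
        Active force number, strictly negative; the active stress is
        (1/Fa) φ̃ P⊗P, protrusive along P.
    eta : float
        Fluid viscosity of the Stokes problem (closure constant).
    kappa_P : float
        One-constant distortion modulus of the orientation field.
    delta_P : float
        Scale of the quartic penalty tying |P|² to the interior
        indicator φ̃ (small values enforce |P|=1 inside strongly).
    gamma_phi : float
        Mobility of the conserved (Cahn–Hilliard type) phase-field flow.
    gamma_P : float
        Relaxation rate of the orientation field along its molecular field.
    dt : float
        Time step of the semi-implicit scheme.
    t_end : float
        Final simulation time (the regimes are compared at t = 5).
    """

    epsilon: float = 1.875
    Ca: float = 0.1
    Be: float = 1.0
    Fa: float = -1.0
    eta: float = 1.0
    kappa_P: float = 0.01
    delta_P: float = 0.01
    gamma_phi: float = 1.0
    gamma_P: float = 1.0
    dt: float = 0.01
    t_end: float = 5.0

    def __post_init__(self) -> None:
        if self.Fa >= 0:
            raise ValueError("Fa must be strictly negative (protrusive active stress)")
        for name in ("epsilon", "Ca", "Be", "eta", "kappa_P", "delta_P",
                     "gamma_phi", "gamma_P", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    def check_resolution(self, h: float) -> None:
        """Require the interface to be resolved by the grid (ε ≥ 2h)."""
        if self.epsilon < 2.0 * h - 1e-12:
            raise ValueError(
                f"interface not resolved: epsilon={self.epsilon} < 2h={2 * h}"
            )

    def replace(self, **changes) -> "ModelParameters":
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return asdict(self)
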