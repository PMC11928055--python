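"""Model parameters for the membrane-skeleton network.

All lengths are in nm, forces in pN, energies in pN nm, times in s. The
defaults are the fitted parameter set of the generalized spring-and-cable
model of the actin-spectrin meshwork: Hookean spectrin springs with a
detachment force threshold, connector springs to focal adhesions, a
discrete dihedral bending energy with a global surface-area constraint,
and tension-only myosin cables with stochastic turnover.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass


@dataclass
class Params:
    """One validated record of every model parameter.

    Attributes
    ----------
    zeta : float
        Drag coefficient of the overdamped dynamics, pN s/nm.
    dt : float
        Forward-Euler time step, s.
    k_s_S, d0_S, F_th : float
        Spectrin spring constant (pN/nm), resting length (nm) and the
        expansive-force threshold for spectrin unbinding (pN).
    k_s_C : float
        Connector (focal-adhesion spring) constant, pN/nm.
    d0_C1 .. d0_C4 : float
        Connector resting lengths: isotropic compression, isotropic
        extension, shear, adhered cell (nm).
    dI_C1, dI_C3 : float
        Connector initial lengths for isotropic stress and shear (nm).
        The adhered-cell initial lengths follow from the geometry.
    k_b : float
        Membrane bending constant, pN nm (200 kT).
    theta0_deg : float
        Spontaneous dihedral angle between adjacent triangle normals,
        degrees (stored in degrees, used in radians).
    k_A : float
        Surface-area constraint force-scale coefficient.
    k_c_M : float
        Myosin cable constant, pN/nm (tension = k_c_M * length).
    phi_a, phi_r : float
        Stochastic myosin addition / removal rates, 1/s.
    d_min, d_max : float
        Myosin cable minimum (removal) and maximum (attachment) lengths, nm.
    volume_exclusion_fraction : float
        Fractional volume reduction of the excluded region (0.15 means
        actin nodes may not enter a region 15% smaller than the initial
        enclosed volume).
    seed : int
        Seed for the per-run random stream.
    """

    zeta: float = 1.25
    dt: float = 0.002

    k_s_S: float = 1.0
    d0_S: float = 180.0
    F_th: float = 0.05

    k_s_C: float = 1.0
    d0_C1: float = 450.0
    d0_C2: float = 270.0
    d0_C3: float = 270.0
    d0_C4: float = 75.0
    dI_C1: float = 360.1389
    dI_C3: float = 1138.4638

    k_b: float = 820.0
    theta0_deg: float = 0.0
    k_A: float = 0.0380

    k_c_M: float = 0.1071
    phi_a: float = 0.01
    phi_r: float = 0.0063
    d_min: float = 135.0
    d_max: float = 450.0

    volume_exclusion_fraction: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        validate_params(self)

    @property
    def theta0(self) -> float:
        """Spontaneous angle in radians."""
        import math

        return math.radians(self.theta0_deg)

    def replace(self, **kwargs) -> "Params":
        """Return a validated copy with the given fields overridden."""
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_POSITIVE = (
    "zeta", "dt", "k_s_S", "d0_S", "F_th", "k_s_C",
    "d0_C1", "d0_C2", "d0_C3", "d0_C4", "dI_C1", "dI_C3",
    "k_b", "k_A", "k_c_M", "d_min", "d_max",
)
_NONNEG = ("phi_a", "phi_r")


def validate_params(p: Params) -> Params:
    """Check all parameter invariants; return ``p`` unchanged if they hold.

    Raises
    ------
    ValueError
        On any non-positive length/rate/constant, ``d_min >= d_max``, or a
        volume-exclusion fraction outside [0, 1).
    """
    for name in _POSITIVE:
        v = getattr(p, name)
        if not (v > 0):
            raise ValueError(f"parameter {name} must be strictly positive, got {v!r}")
    for name in _NONNEG:
        v = getattr(p, name)
        if v < 0:
            raise ValueError(f"parameter {name} must be non-negative, got {v!r}")
    if not (p.d_min < p.d_max):
        raise ValueError(f"d_min ({p.d_min}) must be smaller than d_max ({p.d_max})")
    if not (0.0 <= p.volume_exclusion_fraction < 1.0):
        raise ValueError(
            f"volume_exclusion_fraction must lie in [0, 1), got {p.volume_exclusion_fraction!r}"
        )
    if int(p.seed) != p.seed:
        raise ValueError("seed must be an integer")
    return p
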