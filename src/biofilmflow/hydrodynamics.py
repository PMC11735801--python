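"""Flow-condition calculations for wide rectangular channels.

All quantities are SI internally.  :meth:`ChannelSpec.from_lab_units`
accepts the bench units commonly used for this kind of flow cell
(mm, mL/s, mPa·s) and converts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

#: density of water near 24-27 deg C, kg/m^3
WATER_DENSITY = 997.0

#: local shear amplification at the tip of a leaning-pillar microcolony,
#: taken from an external DNS of shear flow around a tilted cylinder.
TIP_SHEAR_AMPLIFICATION = 3.0


@dataclass(frozen=True)
class ChannelSpec:
    """Rectangular channel geometry and working-fluid properties (SI).

    Attributes
    ----------
    H : channel height, m
    w : channel width, m
    Q : volumetric flow rate, m^3/s
    mu : dynamic viscosity, Pa s
    rho : fluid density, kg/m^3
    """

    H: float
    w: float
    Q: float
    mu: float
    rho: float = WATER_DENSITY

    def __post_init__(self) -> None:
        for name in ("H", "w", "Q", "mu", "rho"):
            if getattr(self, name) < 0 or (name != "Q" and getattr(self, name) == 0):
                raise ValueError(f"{name} must be positive")
        if self.w / self.H < 10:
            warnings.warn(
                f"aspect ratio w/H = {self.w / self.H:.2f} < 10; "
                "the plane-Poiseuille wall-shear estimate degrades in narrow ducts",
                stacklevel=2,
            )

    @classmethod
    def from_lab_units(
        cls,
        H_mm: float,
        w_mm: float,
        Q_mL_s: float,
        mu_mPa_s: float,
        rho: float = WATER_DENSITY,
    ) -> "ChannelSpec":
        return cls(H=H_mm * 1e-3, w=w_mm * 1e-3, Q=Q_mL_s * 1e-6, mu=mu_mPa_s * 1e-3, rho=rho)


@dataclass(frozen=True)
class FlowConditions:
    """Derived flow quantities: wall shear stress, bulk velocity,
    hydraulic diameter and Reynolds number."""

    tau_w: float  # Pa
    U_b: float  # m/s
    D_H: float  # m
    Re: float  # dimensionless


@dataclass(frozen=True)
class StreamerStretch:
    """Observed stretching of one streamer filament.

    ``L0`` and ``L`` are the initial and final lengths (m), ``dt`` the
    elapsed time (s) and ``tau_s`` the local shear stress acting on the
    filament (Pa).
    """

    L0: float
    L: float
    dt: float
    tau_s: float

    def __post_init__(self) -> None:
        if self.L0 <= 0:
            raise ValueError("L0 must be positive")
        if self.L < self.L0:
            raise ValueError("final length must be >= initial length")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.tau_s < 0:
            raise ValueError("tau_s must be non-negative")


def wall_shear_stress(c: ChannelSpec) -> float:
    """Plane-Poiseuille wall shear stress, tau_w = 6 mu Q / (H^2 w), in Pa."""
    return 6.0 * c.mu * c.Q / (c.H**2 * c.w)


def hydraulic_diameter(H: float, w: float) -> float:
    """Hydraulic diameter of a rectangular duct, D_H = 2 H w / (H + w)."""
    if H <= 0 or w <= 0:
        raise ValueError("H and w must be positive")
    return 2.0 * H * w / (H + w)


def bulk_velocity(c: ChannelSpec) -> float:
    """Bulk (cross-section averaged) velocity U_b = Q / (H w), in m/s."""
    return c.Q / (c.H * c.w)


def reynolds(c: ChannelSpec) -> float:
    """Channel Reynolds number Re = U_b D_H rho / mu."""
    return bulk_velocity(c) * hydraulic_diameter(c.H, c.w) * c.rho / c.mu


def flow_conditions(c: ChannelSpec) -> FlowConditions:
    return FlowConditions(
        tau_w=wall_shear_stress(c),
        U_b=bulk_velocity(c),
        D_H=hydraulic_diameter(c.H, c.w),
        Re=reynolds(c),
    )


def tip_shear(tau_w: float, amplification: float = TIP_SHEAR_AMPLIFICATION) -> float:
    """Local shear stress near the tip of a microcolony.

    The amplification factor is an input constant (default 3, from an
    external simulation of flow past a tilted cylinder); no flow solver
    is run here.
    """
    if tau_w < 0:
        raise ValueError("tau_w must be non-negative")
    return amplification * tau_w


def streamer_viscosity(s: StreamerStretch) -> float:
    """Effective biofilm viscosity from fluidised stretching of a streamer.

    Inverts the viscous strain-rate balance
    ``(1/L0) dL/dt = tau_s / mu_b`` into
    ``mu_b = tau_s * dt * L0 / (L - L0)``, returned in Pa s.
    """
    dL = s.L - s.L0
    if dL == 0:
        raise ValueError("streamer did not elongate; viscosity is unbounded")
    return s.tau_s * s.dt * s.L0 / dL


# ---------------------------------------------------------------------------
# The six experimental channel configurations (bench units: mm, mL/s, mPa s),
# sorted by increasing wall shear stress, together with the values the
# source table prints for cross-checking.
#
# Note: the printed hydraulic diameters of cases 4 and 5 (2.64, 1.9 mm) are
# swapped relative to the printed heights (1, sqrt(2) mm); the height row is
# consistent with the wall-shear row and is trusted here.
# ---------------------------------------------------------------------------

_SQRT2 = math.sqrt(2.0)

CASE_PARAMETERS: dict[int, tuple[float, float, float, float]] = {
    # case: (H_mm, w_mm, Q_mL_s, mu_mPa_s)
    1: (2.0, 20.0, 1.0, 0.91),
    2: (_SQRT2, 20.0, 1.0, 0.91),
    3: (2.0, 20.0, 2.63, 0.85),
    4: (1.0, 20.0, 1.0, 0.91),
    5: (_SQRT2, 20.0, 2.63, 0.85),
    6: (1.0, 20.0, 2.63, 0.85),
}

CHANNEL_CASES: dict[int, ChannelSpec] = {
    k: ChannelSpec.from_lab_units(*v) for k, v in CASE_PARAMETERS.items()
}

#: wall shear stress per case as printed, Pa
PRINTED_TAU_W: dict[int, float] = {1: 0.068, 2: 0.14, 3: 0.17, 4: 0.27, 5: 0.34, 6: 0.67}
#: hydraulic diameter per case as printed, mm (cases 4/5 swapped in print)
PRINTED_D_H: dict[int, float] = {1: 3.63, 2: 2.64, 3: 3.63, 4: 2.64, 5: 1.9, 6: 1.9}
#: nominal Reynolds number per case as printed
PRINTED_RE: dict[int, float] = {1: 100, 2: 100, 3: 300, 4: 100, 5: 300, 6: 300}

TABLE_TAU_W = tuple(PRINTED_TAU_W[k] for k in sorted(PRINTED_TAU_W))
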