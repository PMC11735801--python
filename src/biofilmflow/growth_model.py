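"""Friction-limited growth model for a population of microcolonies.

The model works in a consistent unit system: lengths in micrometres,
times in hours, stresses in Pa.  Consequently the effective biofilm
viscosity ``mu_b`` is stored in Pa·h; use
:meth:`GrowthParams.with_si_viscosity` to supply it in Pa·s.

Each microcolony obeys a height balance ``dh/dt = g - e`` between a
constant biological growth rate ``g`` and a shear-driven erosion rate
``e = (C / mu_b) * h * tau_w``, which yields an equilibrium height
``h_max = g mu_b / (C tau_w)``.  Colonies appear at a constant rate
``beta``, so the population biovolume grows like ``K t / tau_w`` with
``K = beta A_fp g mu_b / C``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import curve_fit

#: conversion from Pa·s to Pa·h
PA_S_TO_PA_H = 1.0 / 3600.0


@dataclass(frozen=True)
class GrowthParams:
    """Parameters of the erosion-growth balance.

    Attributes
    ----------
    g : colony height growth rate, um/h
    C : dimensionless erosion coefficient
    mu_b : effective biofilm viscosity, Pa·h
    beta : colony appearance rate, 1/h
    A_fp : colony footprint area, um^2
    A : observed field area, um^2
    """

    g: float
    C: float
    mu_b: float
    beta: float
    A_fp: float
    A: float

    def __post_init__(self) -> None:
        for name in ("g", "C", "mu_b", "beta", "A_fp", "A"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def with_si_viscosity(
        cls, g: float, C: float, mu_b_pa_s: float, beta: float, A_fp: float, A: float
    ) -> "GrowthParams":
        """Construct with ``mu_b`` given in Pa·s instead of Pa·h."""
        return cls(g=g, C=C, mu_b=mu_b_pa_s * PA_S_TO_PA_H, beta=beta, A_fp=A_fp, A=A)


@dataclass(frozen=True)
class GrowthCurvePoint:
    """One observation of mean biofilm thickness."""

    t: float  # h
    tau_w: float  # Pa
    T_bar: float  # um

    def __post_init__(self) -> None:
        if self.t < 0 or self.tau_w <= 0 or self.T_bar < 0:
            raise ValueError("require t >= 0, tau_w > 0, T_bar >= 0")


@dataclass(frozen=True)
class PowerLawFit:
    """Result of fitting ``T_bar = a * t * tau_w**k``."""

    a: float
    k: float
    a_sd: float
    k_sd: float
    n_points: int


def erosion_rate(h_mc: float, tau_w: float, p: GrowthParams) -> float:
    """Erosion rate ``e = (C / mu_b) h_mc tau_w`` in um/h."""
    if h_mc < 0:
        raise ValueError("h_mc must be non-negative")
    return p.C / p.mu_b * h_mc * tau_w


def time_constant(p: GrowthParams, tau_w: float) -> float:
    """Relaxation time of the height balance, ``mu_b / (C tau_w)``, in hours."""
    if tau_w <= 0:
        raise ValueError("tau_w must be positive")
    return p.mu_b / (p.C * tau_w)


def equilibrium_height(p: GrowthParams, tau_w: float) -> float:
    """Maximum colony height ``h_max = g mu_b / (C tau_w)`` in um."""
    if tau_w <= 0:
        raise ValueError("tau_w must be positive (h_max is unbounded otherwise)")
    return p.g * p.mu_b / (p.C * tau_w)


def tip_velocity(p: GrowthParams, mu: float) -> float:
    """Fluid velocity at the equilibrium colony tip, in um/s.

    ``u_max = (g / C) (mu_b / mu)`` with ``mu`` the medium viscosity in
    Pa·s; independent of the wall shear stress.  Equals
    ``h_max * tau_w / mu`` exactly (with tau_w in Pa and mu in Pa·s).
    """
    if mu <= 0:
        raise ValueError("mu must be positive")
    return p.g * p.mu_b / (p.C * mu)


def closed_form_height(
    p: GrowthParams, tau_w: float, t, h0: float = 0.0
) -> np.ndarray | float:
    """Analytic solution of the height balance.

    ``h(t) = h_max + (h0 - h_max) exp(-t / t_c)`` with
    ``t_c = mu_b / (C tau_w)``.
    """
    h_max = equilibrium_height(p, tau_w)
    t_c = time_constant(p, tau_w)
    return h_max + (h0 - h_max) * np.exp(-np.asarray(t, dtype=float) / t_c)


def solve_height(
    p: GrowthParams, tau_w: float, t_grid: Sequence[float], h0: float = 0.0
) -> np.ndarray:
    """Numerically integrate ``dh/dt = g - (C/mu_b) h tau_w`` on ``t_grid``.

    Times are in hours and must be increasing; returns heights in um.
    Agrees with :func:`closed_form_height` to better than 1e-6 relative.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) == 0:
        raise ValueError("t_grid must be a non-empty 1D sequence")
    if np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    rate = p.C / p.mu_b * tau_w

    def rhs(_t, h):
        return p.g - rate * h

    h_scale = max(abs(h0), equilibrium_height(p, tau_w))
    t0 = min(0.0, t_grid[0])
    sol = solve_ivp(
        rhs,
        (t0, t_grid[-1]),
        [h0],
        t_eval=t_grid,
        method="LSODA",
        rtol=1e-10,
        atol=1e-12 * h_scale,
    )
    if not sol.success:  # pragma: no cover - LSODA is robust on a linear ODE
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return sol.y[0]


def biovolume_prefactor(p: GrowthParams) -> float:
    """``K = beta A_fp g mu_b / C`` such that ``V_b = K t / tau_w`` (um^3 Pa / h)."""
    return p.beta * p.A_fp * p.g * p.mu_b / p.C


def population_biovolume(
    p: GrowthParams, t: float, tau_w: float, mode: str = "equilibrium"
) -> tuple[float, float]:
    """Collective biovolume ``V_b`` (um^3) and mean thickness ``T_bar`` (um).

    ``mode="equilibrium"`` assumes every colony has reached ``h_max``:
    ``V_b = beta t A_fp h_max = K t / tau_w``.  ``mode="integrated"``
    accounts for the transient of each colony by integrating the analytic
    height over a continuous arrival density ``beta``; it converges to the
    equilibrium result for ``t >> t_c``.
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    h_max = equilibrium_height(p, tau_w)
    if mode == "equilibrium":
        v_b = p.beta * t * p.A_fp * h_max
    elif mode == "integrated":
        t_c = time_constant(p, tau_w)
        # beta A_fp int_0^t h(t - s) ds with h(a) = h_max (1 - exp(-a / t_c))
        v_b = p.beta * p.A_fp * h_max * (t - t_c * (1.0 - np.exp(-t / t_c)))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return v_b, v_b / p.A


def _as_arrays(
    points: Iterable[GrowthCurvePoint] | None,
    t,
    tau_w,
    T_bar,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if points is not None:
        pts = list(points)
        t = np.array([q.t for q in pts], dtype=float)
        tau_w = np.array([q.tau_w for q in pts], dtype=float)
        T_bar = np.array([q.T_bar for q in pts], dtype=float)
    else:
        t = np.asarray(t, dtype=float)
        tau_w = np.asarray(tau_w, dtype=float)
        T_bar = np.asarray(T_bar, dtype=float)
    if not (t.shape == tau_w.shape == T_bar.shape):
        raise ValueError("t, tau_w and T_bar must have matching shapes")
    return t, tau_w, T_bar


def fit_power_law(
    points: Iterable[GrowthCurvePoint] | None = None,
    *,
    t=None,
    tau_w=None,
    T_bar=None,
) -> PowerLawFit:
    """Nonlinear least-squares fit of ``T_bar = a * t * tau_w**k``.

    The fit minimises unweighted residuals on the original scale.  The
    initial guess comes from ordinary least squares of ``log(T_bar / t)``
    against ``log(tau_w)``; parameter standard deviations come from the
    curvature of the residual surface (the covariance returned by
    :func:`scipy.optimize.curve_fit`).

    Requires at least three usable points (``t > 0``, ``T_bar > 0``)
    spanning at least two distinct shear-stress values.
    """
    t, tau_w, T_bar = _as_arrays(points, t, tau_w, T_bar)
    if np.any(tau_w <= 0):
        raise ValueError("tau_w values must be positive")
    usable = (t > 0) & (T_bar > 0)
    if usable.sum() < 3:
        raise ValueError("need at least 3 points with t > 0 and T_bar > 0")
    if len(np.unique(tau_w[usable])) < 2:
        raise ValueError(
            "the exponent k is unidentifiable from a single shear-stress level; "
            "provide data at >= 2 distinct tau_w values"
        )
    # keep points with t > 0 in the fit; T_bar = 0 observations still carry
    # information on the original scale
    keep = t > 0
    tf, tauf, Tf = t[keep], tau_w[keep], T_bar[keep]

    x = np.log(tau_w[usable])
    y = np.log(T_bar[usable] / t[usable])
    k0, loga0 = np.polyfit(x, y, 1)

    def model(X, a, k):
        tt, tw = X
        return a * tt * tw**k

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-residual fits warn about pcov
        popt, pcov = curve_fit(
            model, (tf, tauf), Tf, p0=(np.exp(loga0), k0), maxfev=10000
        )
    perr = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
    return PowerLawFit(
        a=float(popt[0]),
        k=float(popt[1]),
        a_sd=float(perr[0]),
        k_sd=float(perr[1]),
        n_points=int(keep.sum()),
    )


def recover_from_pipeline(summaries) -> PowerLawFit:
    """Fit the thickness power law to measured scan summaries.

    ``summaries`` is an iterable of objects exposing ``time``, ``tau_w``
    and ``T_bar`` attributes (e.g. :class:`~biofilmflow.morphometrics.ScanSummary`),
    covering at least two shear-stress conditions.
    """
    summaries = list(summaries)
    if not summaries:
        raise ValueError("no summaries given")
    return fit_power_law(
        t=[s.time for s in summaries],
        tau_w=[s.tau_w for s in summaries],
        T_bar=[s.T_bar for s in summaries],
    )
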