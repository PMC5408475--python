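"""Closed-form steady-state, Hopf and Turing analysis of the oscillator.

Everything here is analytic desk-scale algebra on the two-variable model

    dx/dt = k1 - 2*k2*x*y**gamma
    dy/dt = k2*x*y**gamma - k3*y**m

Linearizing about the unique positive steady state gives a 2x2 Jacobian
whose trace sign decides oscillation (Hopf bifurcation at trace = 0, where
the determinant is always positive) and whose diffusion-augmented
eigenvalues decide spatial (Turing) instability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .params import DiffusionParams, InvalidRegimeError, KineticParams

__all__ = [
    "SteadyState",
    "StabilityReport",
    "TuringPrediction",
    "derivatives",
    "steady_state",
    "stability_report",
    "hopf_threshold",
    "period_estimate",
    "period_fold_change",
    "eta",
    "turing_prediction",
    "dispersion_relation",
    "dispersion_max",
]


@dataclass(frozen=True)
class SteadyState:
    """The unique positive fixed point of the well-mixed system."""

    x_star: float
    y_star: float


@dataclass(frozen=True)
class StabilityReport:
    """Jacobian, eigenvalues and Hopf data at the steady state.

    Attributes
    ----------
    a, b, c, d : float
        Jacobian elements d(x')/dx, d(x')/dy, d(y')/dx, d(y')/dy.
    trace, determinant : float
        a + d and a*d - b*c; the determinant is positive for every valid
        parameter set, so stability is decided by the trace alone.
    eigenvalues : tuple of complex
        Roots of lambda^2 - trace*lambda + determinant = 0.
    k3c : float or None
        Hopf threshold in k3 (None when gamma <= m: no oscillation possible).
    Tp : float or None
        Linear period estimate 2*pi/sqrt(det) at the Hopf point.
    eta : float or None
        The combination 4*k2/(k1*(gamma - m)) controlling the threshold.
    oscillatory : bool
        True iff trace > 0 (steady state unstable via a Hopf mode).
    """

    a: float
    b: float
    c: float
    d: float
    trace: float
    determinant: float
    eigenvalues: tuple[complex, complex]
    k3c: float | None
    Tp: float | None
    eta: float | None
    oscillatory: bool


@dataclass(frozen=True)
class TuringPrediction:
    """Critical wavenumber/wavelength of the diffusion-driven instability.

    ``kappa_T_exact`` comes from the full expression
    kappa^2 = (a*Dy + d*Dx)/(2*Dx*Dy); ``kappa_T_approx`` from the
    fast-inhibitor limit d/(2*Dy) valid when Dx >> Dy.  ``kappa_T`` and
    ``lambda_T`` report the exact branch.
    """

    kappa_T: float
    lambda_T: float
    kappa_T_exact: float
    kappa_T_approx: float

    @property
    def lambda_T_approx(self) -> float:
        return 2.0 * math.pi / self.kappa_T_approx


def _check_nonnegative(x: float, y: float) -> None:
    if x < 0 or y < 0:
        raise ValueError(f"concentrations must be non-negative, got x={x}, y={y}")


def _uptake(x, y, p: KineticParams):
    """Membrane-uptake flux k2*x*y^gamma (or its saturating Hill variant)."""
    yg = np.power(y, p.gamma)
    if p.saturating_uptake:
        return p.k2 * x * yg / (p.L + yg)
    return p.k2 * x * yg


def derivatives(x: float, y: float, p: KineticParams) -> tuple[float, float]:
    """Right-hand side (dx/dt, dy/dt) of the oscillator at state (x, y).

    The uptake consumes two monomers per dimer formed, hence the factor 2
    in dx/dt; with k1 = k3 = 0 the total x + 2y is conserved.
    """
    _check_nonnegative(x, y)
    up = _uptake(x, y, p)
    dxdt = p.k1 - 2.0 * up
    dydt = up - p.k3 * np.power(y, p.m)
    return (float(dxdt), float(dydt))


def steady_state(p: KineticParams) -> SteadyState:
    """Positive fixed point: y* = (k1/(2 k3))^(1/m), x* from the x-nullcline."""
    p.require_positive_rates()
    y_star = (p.k1 / (2.0 * p.k3)) ** (1.0 / p.m)
    x_star = p.k1 / (2.0 * p.k2 * y_star**p.gamma)
    if p.saturating_uptake:
        x_star *= 1.0 + p.L / y_star**p.gamma
    return SteadyState(x_star=x_star, y_star=y_star)


def eta(p: KineticParams) -> float:
    """The threshold combination eta = 4*k2 / (k1*(gamma - m)).

    eta^(m/(gamma+1)) sets the Hopf threshold and eta^((gamma-1)/(2(gamma+1)))
    the period prefactor, so schedules that shrink k2 and gamma - m in
    concert leave both nearly unchanged.
    """
    p.require_oscillatory_regime()
    if p.k1 <= 0:
        raise ValueError("eta requires k1 > 0")
    return 4.0 * p.k2 / (p.k1 * (p.gamma - p.m))


def hopf_threshold(p: KineticParams) -> float:
    """Critical degradation rate k3c; the steady state oscillates iff k3 > k3c."""
    p.require_oscillatory_regime()
    return 0.5 * p.k1 * eta(p) ** (p.m / (p.gamma + 1.0))


def period_estimate(p: KineticParams) -> float:
    """Linear (Hopf-point) period 2*pi/sqrt(det) evaluated at k3 = k3c.

    Tp = 2*pi/(m*k1*k2)^(1/2) * eta^((gamma-1)/(2*(gamma+1))).  Valid near
    the bifurcation; the dominant dependence is Tp ~ k2^(-1/2) when eta is
    held fixed, which is how an FGF8-driven drop in k2 slows the clock.
    """
    p.require_oscillatory_regime()
    expo = (p.gamma - 1.0) / (2.0 * (p.gamma + 1.0))
    return 2.0 * math.pi / math.sqrt(p.m * p.k1 * p.k2) * eta(p) ** expo


def period_fold_change(k2_start: float, k2_end: float) -> float:
    """Fold-change of the linear period when k2 drops with eta held constant.

    Under the slow-down protocol (m rising toward gamma so that
    eta = 4*k2/(k1*(gamma - m)) stays fixed), the period's eta-dependent
    factor is frozen and the front factor leaves Tp largely inversely
    proportional to sqrt(k2): a 25-fold drop in k2 slows the clock
    five-fold, a 100-fold drop ten-fold.  The residual front-factor drift
    from the rising cooperativity m (bounded by sqrt(gamma/m_start)) is
    neglected here, as it is in the closed-form protocol analysis.
    """
    if k2_start <= 0 or k2_end <= 0:
        raise ValueError("rate constants must be positive")
    return math.sqrt(k2_start / k2_end)


def _jacobian(p: KineticParams) -> tuple[float, float, float, float]:
    ss = steady_state(p)
    x, y = ss.x_star, ss.y_star
    a = -2.0 * p.k2 * y**p.gamma
    b = -2.0 * p.k2 * x * p.gamma * y ** (p.gamma - 1.0)
    c = p.k2 * y**p.gamma
    d = p.k2 * p.gamma * x * y ** (p.gamma - 1.0) - p.k3 * p.m * y ** (p.m - 1.0)
    return a, b, c, d


def stability_report(p: KineticParams) -> StabilityReport:
    """Full linear-stability summary at the steady state.

    The determinant reduces to the closed form
    k1*k2*m*(k1/(2*k3))^((gamma-1)/m) > 0, so the Hopf condition is
    simply trace > 0.
    """
    a, b, c, d = _jacobian(p)
    tr = a + d
    det = a * d - b * c
    disc = complex(tr * tr - 4.0 * det)
    sq = disc**0.5
    eigs = ((tr + sq) / 2.0, (tr - sq) / 2.0)
    if p.oscillator_capable:
        k3c = hopf_threshold(p)
        Tp = period_estimate(p)
        et = eta(p)
    else:
        k3c = Tp = et = None
    return StabilityReport(
        a=a, b=b, c=c, d=d,
        trace=tr, determinant=det,
        eigenvalues=eigs,
        k3c=k3c, Tp=Tp, eta=et,
        oscillatory=bool(tr > 0),
    )


def determinant_closed_form(p: KineticParams) -> float:
    """det = k1*k2*m*(k1/(2*k3))^((gamma-1)/m), the always-positive closed form."""
    return p.k1 * p.k2 * p.m * (p.k1 / (2.0 * p.k3)) ** ((p.gamma - 1.0) / p.m)


def turing_prediction(p: KineticParams, d: DiffusionParams) -> TuringPrediction:
    """Critical wavenumber kappa_T and wavelength lambda_T = 2*pi/kappa_T.

    Exact branch: kappa_T^2 = (a*Dy + d*Dx)/(2*Dx*Dy).  Fast-activator
    limit (Dx >> Dy): kappa_T^2 ~ d/(2*Dy) =
    (k1/(4*Dy))*(gamma - m)*(2*k3/k1)^(1/m), so lambda_T is proportional
    to sqrt(Dy) of the slow membrane-bound species.

    Raises
    ------
    ValueError
        If either squared wavenumber is non-positive (no finite-wavelength
        Turing mode for these parameters).
    """
    if d.Dx <= 0 or d.Dy <= 0:
        raise ValueError("turing_prediction requires Dx > 0 and Dy > 0")
    a, _, _, jd = _jacobian(p)
    k2_exact = (a * d.Dy + jd * d.Dx) / (2.0 * d.Dx * d.Dy)
    k2_approx = (p.k1 / (4.0 * d.Dy)) * (p.gamma - p.m) * (
        2.0 * p.k3 / p.k1
    ) ** (1.0 / p.m)
    if k2_exact <= 0 or k2_approx <= 0:
        raise ValueError(
            "no finite-wavelength Turing mode: squared critical wavenumber "
            f"is non-positive (exact {k2_exact:.4g}, approx {k2_approx:.4g})"
        )
    kT = math.sqrt(k2_exact)
    return TuringPrediction(
        kappa_T=kT,
        lambda_T=2.0 * math.pi / kT,
        kappa_T_exact=kT,
        kappa_T_approx=math.sqrt(k2_approx),
    )


def dispersion_relation(
    p: KineticParams, d: DiffusionParams, kappa: Sequence[float] | np.ndarray
) -> np.ndarray:
    """Largest real eigenvalue part of J - diag(Dx*k^2, Dy*k^2) per wavenumber."""
    kappa = np.asarray(kappa, dtype=float)
    a, b, c, jd = _jacobian(p)
    k2 = kappa**2
    aa = a - d.Dx * k2
    dd = jd - d.Dy * k2
    tr = aa + dd
    det = aa * dd - b * c
    disc = (tr * tr - 4.0 * det).astype(complex)
    lam1 = (tr + np.sqrt(disc)) / 2.0
    lam2 = (tr - np.sqrt(disc)) / 2.0
    return np.maximum(lam1.real, lam2.real)


def dispersion_max(
    p: KineticParams, d: DiffusionParams, kappa_grid: Sequence[float]
) -> tuple[float, float]:
    """Grid wavenumber with the fastest linear growth, and that growth rate.

    At kappa = 0 this reduces to the homogeneous eigenvalues of
    ``stability_report``; a positive maximum at kappa > 0 with a negative
    (or smaller) value at kappa = 0 signals a Turing band.
    """
    kappa = np.asarray(list(kappa_grid), dtype=float)
    if kappa.size == 0:
        raise ValueError("kappa_grid must be non-empty")
    if np.any(kappa < 0):
        raise ValueError("wavenumbers must be non-negative")
    growth = dispersion_relation(p, d, kappa)
    i = int(np.argmax(growth))
    return float(kappa[i]), float(growth[i])
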