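"""Parameter containers for the teneurin membrane-binding oscillator.

The model tracks the cytoplasmic monomer concentration ``x`` and the
membrane-bound dimer concentration ``y``:

    dx/dt = k1 - 2*k2*x*y**gamma
    dy/dt = k2*x*y**gamma - k3*y**m

``k1`` is the constant synthesis rate of the cytoplasmic form, ``k2`` the
cooperative membrane-uptake rate constant (the FGF8-controlled knob),
``k3`` the degradation rate constant of the membrane dimer, ``gamma`` the
Hill coefficient of uptake and ``m`` the Hill coefficient of degradation.
Sustained oscillation requires ``gamma > m``.

All quantities are dimensionless model units.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping


class InvalidRegimeError(ValueError):
    """Raised when an operation requires the oscillatory regime gamma > m."""


@dataclass(frozen=True)
class KineticParams:
    """Reaction constants of the membrane-binding oscillator.

    Parameters
    ----------
    k1 : float
        Synthesis rate of the cytoplasmic monomer (concentration/time).
    k2 : float
        Cooperative membrane-uptake rate constant.
    k3 : float
        Degradation rate constant of the membrane-bound dimer.
    gamma : float
        Hill coefficient of membrane uptake.
    m : float
        Hill coefficient of dimer degradation.
    L : float, optional
        Half-saturation constant of the full Hill uptake form
        ``x*y**gamma/(L + y**gamma)``.  The default model keeps only the
        numerator (``saturating_uptake=False``); L is exposed for
        robustness experiments only.
    saturating_uptake : bool
        If True, use the full saturating Hill uptake instead of the
        numerator-only form.  All closed-form stability results assume
        the numerator-only default.
    """

    k1: float = 1.0
    k2: float = 0.2
    k3: float = 0.475
    gamma: float = 2.4
    m: float = 1.6
    L: float = 1.0
    saturating_uptake: bool = False

    def __post_init__(self) -> None:
        # k1 = k3 = 0 is admitted so the conservation law d(x + 2y)/dt = 0
        # of the pure-uptake stoichiometry can be exercised; every
        # steady-state/threshold formula additionally requires k1, k3 > 0.
        for name in ("k2", "gamma", "m"):
            v = getattr(self, name)
            if not v > 0:
                raise ValueError(f"{name} must be > 0, got {v!r}")
        for name in ("k1", "k3"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v!r}")
        if self.L <= 0:
            raise ValueError(f"L must be > 0, got {self.L!r}")

    def require_positive_rates(self) -> None:
        """Guard for formulas that divide by k1 or k3."""
        if self.k1 <= 0 or self.k3 <= 0:
            raise ValueError(
                f"this operation requires k1 > 0 and k3 > 0, got k1={self.k1}, k3={self.k3}"
            )

    @property
    def oscillator_capable(self) -> bool:
        """True iff gamma > m, the necessary condition for a Hopf bifurcation."""
        return self.gamma > self.m

    def require_oscillatory_regime(self) -> None:
        if not self.oscillator_capable:
            raise InvalidRegimeError(
                f"oscillation requires gamma > m, got gamma={self.gamma}, m={self.m}"
            )

    def with_(self, **kwargs) -> "KineticParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    @classmethod
    def from_mapping(cls, d: Mapping) -> "KineticParams":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown kinetic parameter(s): {sorted(unknown)}")
        return cls(**dict(d))


@dataclass(frozen=True)
class DiffusionParams:
    """Diffusion coefficients (length^2/time).

    Dx is the fast cytoplasmic monomer; Dy the slow membrane-bound dimer.
    The Turing regime assumes Dx >> Dy.
    """

    Dx: float = 1.45
    Dy: float = 0.09

    def __post_init__(self) -> None:
        if self.Dx < 0 or self.Dy < 0:
            raise ValueError(f"diffusion coefficients must be >= 0, got {self}")

    @classmethod
    def from_mapping(cls, d: Mapping) -> "DiffusionParams":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown diffusion parameter(s): {sorted(unknown)}")
        return cls(**dict(d))
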