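"""Time integration of the well-mixed oscillator and the FGF8 slow-down protocol.

The protocol emulates a cell drifting down the posterior FGF8 gradient: the
uptake rate k2 falls by orders of magnitude while the degradation Hill
coefficient m rises toward gamma so that the threshold combination
eta = 4*k2/(k1*(gamma - m)) stays constant.  Because the linear period
scales as k2**-0.5 * eta**((gamma-1)/(2*(gamma+1))), a 100-fold drop in k2
with eta held fixed slows the clock ten-fold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.signal import find_peaks

from .params import InvalidRegimeError, KineticParams
from .stability import derivatives, eta, hopf_threshold, steady_state

__all__ = [
    "Trajectory",
    "ParameterSchedule",
    "PeriodProfile",
    "integrate",
    "measure_periods",
    "build_slowdown_schedule",
    "run_slowdown",
    "default_initial_condition",
]

#: Default solver tolerances: period measurement needs phase accuracy.
RTOL = 1e-8
ATOL = 1e-10

#: Seed used for the default 1% initial perturbation.
DEFAULT_SEED = 1729


class SolverError(RuntimeError):
    """ODE solver failed to converge; carries the failing time."""

    def __init__(self, message: str, t_fail: float):
        super().__init__(f"{message} (at t = {t_fail:.6g})")
        self.t_fail = t_fail


@dataclass(frozen=True)
class Trajectory:
    """Time series of cytoplasmic x and membrane-bound dimer y."""

    times: np.ndarray
    x_series: np.ndarray
    y_series: np.ndarray
    params_used: object

    def __post_init__(self):
        n = len(self.times)
        if len(self.x_series) != n or len(self.y_series) != n:
            raise ValueError("times, x_series, y_series must have equal length")


@dataclass(frozen=True)
class PeriodProfile:
    """Successive peak times of y and the peak-to-peak periods between them."""

    peak_times: np.ndarray
    periods: np.ndarray
    sustained: bool

    @property
    def no_sustained_oscillation(self) -> bool:
        return not self.sustained


@dataclass(frozen=True)
class ParameterSchedule:
    """Time-varying kinetics for the slow-down protocol.

    ``k2_of_t`` must be non-increasing and positive; ``m_of_t`` must stay
    below gamma at all times (otherwise the oscillator dies, which the
    constructor rejects); ``k3_of_t`` defaults to tracking a constant
    multiple of the instantaneous Hopf threshold so the clock stays mildly
    super-critical throughout.
    """

    base: KineticParams
    duration: float
    k2_of_t: Callable[[float], float]
    m_of_t: Callable[[float], float]
    k3_of_t: Callable[[float], float]
    eta_policy: str = "hold-eta-constant"

    def params_at(self, t: float) -> KineticParams:
        return self.base.with_(
            k2=float(self.k2_of_t(t)),
            m=float(self.m_of_t(t)),
            k3=float(self.k3_of_t(t)),
        )

    def validate(self, n_check: int = 201) -> None:
        ts = np.linspace(0.0, self.duration, n_check)
        k2s = np.array([self.k2_of_t(t) for t in ts])
        ms = np.array([self.m_of_t(t) for t in ts])
        if np.any(k2s <= 0):
            raise ValueError("schedule drives k2 <= 0")
        if np.any(ms >= self.base.gamma):
            raise ValueError(
                "schedule drives m >= gamma; the oscillator would stop"
            )


def _rhs_const(p: KineticParams):
    k1, k2, k3, g, m = p.k1, p.k2, p.k3, p.gamma, p.m

    def rhs(t, s):
        x, y = s
        yc = max(y, 0.0)
        up = k2 * x * yc**g
        return (k1 - 2.0 * up, up - k3 * yc**m)

    return rhs


def _rhs_schedule(sched: ParameterSchedule):
    k1, g = sched.base.k1, sched.base.gamma

    def rhs(t, s):
        x, y = s
        yc = max(y, 0.0)
        up = sched.k2_of_t(t) * x * yc**g
        return (k1 - 2.0 * up, up - sched.k3_of_t(t) * yc ** sched.m_of_t(t))

    return rhs


def default_initial_condition(
    p: KineticParams, rel_amplitude: float = 0.01, seed: int = DEFAULT_SEED
) -> tuple[float, float]:
    """Steady state with a seeded multiplicative perturbation (default 1%)."""
    rng = np.random.default_rng(seed)
    ss = steady_state(p)
    fx, fy = 1.0 + rel_amplitude * rng.uniform(-1, 1, size=2)
    return (ss.x_star * fx, ss.y_star * fy)


def integrate(
    p: KineticParams | ParameterSchedule,
    init: tuple[float, float] | None = None,
    t_span: tuple[float, float] = (0.0, 200.0),
    n_samples: int | None = None,
    method: str = "LSODA",
    rtol: float = RTOL,
    atol: float = ATOL,
) -> Trajectory:
    """Integrate the oscillator ODEs, with constant or scheduled parameters.

    Parameters
    ----------
    p : KineticParams or ParameterSchedule
        Constant kinetics, or a time-varying schedule.
    init : (x0, y0), optional
        Non-negative initial concentrations; defaults to the (initial)
        steady state plus a 1% seeded perturbation.
    t_span : (t0, t1)
        Integration window.
    n_samples : int, optional
        Number of equispaced output samples; default resolves the expected
        period with ~40 points.
    """
    if isinstance(p, ParameterSchedule):
        p.validate()
        p0 = p.params_at(t_span[0])
        rhs = _rhs_schedule(p)
        ref_period = _safe_period(p.params_at(p.duration)) or 50.0
    else:
        p0 = p
        rhs = _rhs_const(p)
        ref_period = _safe_period(p) or 50.0
    if init is None:
        init = default_initial_condition(p0)
    x0, y0 = init
    if x0 < 0 or y0 < 0:
        raise ValueError("initial concentrations must be non-negative")
    if not t_span[1] > t_span[0]:
        raise ValueError("t_span must have positive length")
    if n_samples is None:
        n_samples = max(200, int(40 * (t_span[1] - t_span[0]) / ref_period))
    t_eval = np.linspace(t_span[0], t_span[1], n_samples)
    sol = solve_ivp(
        rhs, t_span, [x0, y0], method=method, t_eval=t_eval, rtol=rtol, atol=atol
    )
    if not sol.success:
        raise SolverError(sol.message, float(sol.t[-1]) if sol.t.size else t_span[0])
    return Trajectory(
        times=sol.t, x_series=sol.y[0], y_series=sol.y[1], params_used=p
    )


def _safe_period(p: KineticParams) -> float | None:
    try:
        from .stability import period_estimate

        return period_estimate(p)
    except (InvalidRegimeError, ValueError, ZeroDivisionError):
        return None


def measure_periods(
    traj: Trajectory,
    rel_prominence: float = 0.05,
    abs_floor_frac: float = 0.01,
) -> PeriodProfile:
    """Locate maxima of y and report peak-to-peak periods.

    A maximum counts as a peak when its prominence exceeds both
    ``rel_prominence`` of the local peak-to-trough amplitude (robust to a
    drifting mean during schedules) and ``abs_floor_frac`` of the mean
    level of y (rejects numerically-resolved decaying wiggles of a stable
    focus).  Fewer than two surviving peaks flags "no sustained
    oscillation".
    """
    y = np.asarray(traj.y_series, dtype=float)
    t = np.asarray(traj.times, dtype=float)
    peaks, props = find_peaks(y, prominence=0.0)
    if peaks.size == 0:
        return PeriodProfile(np.array([]), np.array([]), sustained=False)
    floor = abs_floor_frac * float(np.mean(y))
    keep = []
    for i, pk in enumerate(peaks):
        lo, hi = int(props["left_bases"][i]), int(props["right_bases"][i])
        local_amp = float(y[lo : hi + 1].max() - y[lo : hi + 1].min())
        prom = float(props["prominences"][i])
        if prom >= max(rel_prominence * local_amp, floor):
            keep.append(pk)
    peaks = np.array(keep, dtype=int)
    if peaks.size < 2:
        return PeriodProfile(t[peaks], np.array([]), sustained=False)
    peak_times = t[peaks]
    periods = np.diff(peak_times)
    # Sustained: the oscillation still has full-size peaks in the final
    # quarter of the run (a decaying focus loses its late peaks to the
    # absolute floor instead).
    last_q = peak_times >= t[0] + 0.75 * (t[-1] - t[0])
    sustained = bool(np.any(last_q))
    return PeriodProfile(peak_times, periods, sustained=sustained)


def build_slowdown_schedule(
    k2_start: float,
    k2_end: float,
    m_start: float,
    p: KineticParams,
    duration: float,
    eta_policy: str = "hold-eta-constant",
    k2_interpolation: str = "exponential",
    k3_supercriticality: float = 1.05,
) -> ParameterSchedule:
    """Schedule emulating the FGF8-driven slow-down.

    k2 decays from ``k2_start`` to ``k2_end`` (exponential in time by
    default: FGF8 decay is exponential-like; linear available).  Under the
    default "hold-eta-constant" policy m rises as
    m(t) = gamma - 4*k2(t)/(k1*eta0) with eta0 the starting value, so eta
    is constant by construction.  k3 tracks ``k3_supercriticality`` times
    the instantaneous Hopf threshold, keeping the clock mildly
    super-critical throughout.
    """
    if not k2_end < k2_start:
        raise ValueError("slow-down requires k2_end < k2_start")
    if not m_start < p.gamma:
        raise ValueError("m_start must be below gamma")
    base = p.with_(k2=k2_start, m=m_start)
    eta0 = eta(base)

    if k2_interpolation == "exponential":
        rate = math.log(k2_end / k2_start) / duration

        def k2_of_t(t: float) -> float:
            return k2_start * math.exp(rate * min(max(t, 0.0), duration))

    elif k2_interpolation == "linear":

        def k2_of_t(t: float) -> float:
            f = min(max(t, 0.0), duration) / duration
            return k2_start + (k2_end - k2_start) * f

    else:
        raise ValueError(f"unknown k2_interpolation {k2_interpolation!r}")

    if eta_policy == "hold-eta-constant":

        def m_of_t(t: float) -> float:
            return p.gamma - 4.0 * k2_of_t(t) / (p.k1 * eta0)

    elif eta_policy == "free":

        def m_of_t(t: float) -> float:
            return m_start

    else:
        raise ValueError(f"unknown eta_policy {eta_policy!r}")

    def k3_of_t(t: float) -> float:
        pt = p.with_(k2=k2_of_t(t), m=m_of_t(t))
        return k3_supercriticality * hopf_threshold(pt)

    sched = ParameterSchedule(
        base=base,
        duration=duration,
        k2_of_t=k2_of_t,
        m_of_t=m_of_t,
        k3_of_t=k3_of_t,
        eta_policy=eta_policy,
    )
    sched.validate()
    return sched


def run_slowdown(
    schedule: ParameterSchedule,
    init: tuple[float, float] | None = None,
    n_samples: int | None = None,
    **solver_opts,
) -> tuple[Trajectory, PeriodProfile]:
    """Integrate a slow-down schedule and measure the growing period.

    The sampling density is chosen from the fastest (initial) period so
    early peaks are resolved even though late cycles are much slower.
    """
    p0 = schedule.params_at(0.0)
    if init is None:
        init = default_initial_condition(p0)
    T0 = _safe_period(p0) or 10.0
    if n_samples is None:
        n_samples = max(2000, int(40 * schedule.duration / T0))
    traj = integrate(
        schedule, init=init, t_span=(0.0, schedule.duration),
        n_samples=n_samples, **solver_opts,
    )
    return traj, measure_periods(traj)
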