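"""Oscillator-growth segmentation and the transition to Turing patterning.

A 1-D tissue elongates at rate ``v``: new cells (unit length) are appended
at the posterior end, each inheriting the current state of the posterior
clock.  As the tissue grows, a cell's distance from the posterior
increases, and the FGF8 proxy k2 falls along the gradient, slowing that
cell's oscillator.  When a cell crosses the determination front (or its
instantaneous period exceeds a threshold), its oscillator phase is latched
permanently — a documented stand-in for the bistable freezing switch, not
an explicit bistable model.  Segment boundaries are laid where the frozen
phase completes a cycle, so segment length ~ v * T_posterior
(clock-and-wavefront).

``run_transition`` then hands the frozen spatial pattern to the
reaction-diffusion system as an initial bias: if the inherited wavelength
lies inside the Turing-unstable band, the simultaneous (Turing) mechanism
regrows the *same* pattern; otherwise the pattern snaps to the intrinsic
Turing wavelength.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np

from .params import DiffusionParams, KineticParams
from .stability import (
    hopf_threshold,
    period_estimate,
    steady_state,
    turing_prediction,
)
from .dynamics import integrate, default_initial_condition
from .spatial import Field1D, Grid1D, classify_pattern, measure_wavelength, simulate_rd

__all__ = [
    "GrowthConfig",
    "SegmentMap",
    "TransitionResult",
    "exponential_k2_gradient",
    "run_growth",
    "run_transition",
]


def exponential_k2_gradient(
    k2_posterior: float, decay_length: float
) -> Callable[[float], float]:
    """k2 falling exponentially with distance from the posterior end.

    Mirrors the FGF8 mechanism: transcription confined to the growth zone
    plus first-order mRNA decay gives an exponential protein gradient.
    """

    def profile(dist: float) -> float:
        return k2_posterior * math.exp(-max(dist, 0.0) / decay_length)

    return profile


def flat_k2_gradient(k2: float) -> Callable[[float], float]:
    """No slow-down: every cell keeps the posterior kinetics."""
    return lambda dist: k2


@dataclass(frozen=True)
class GrowthConfig:
    """Configuration of the elongating-tissue simulation.

    Parameters
    ----------
    elongation_rate : float
        New tissue length per unit time (v); cells have unit length, so
        one cell is born every 1/v time units.
    psm_length : float
        Distance from the posterior end to the determination front; a cell
        beyond it is frozen under the "front-position" rule.
    gradient_profile : callable
        Distance-from-posterior -> k2 (non-increasing, positive).
    freeze_rule : "front-position" or "period-threshold"
    freeze_period_threshold : float
        Instantaneous linear period (from the cell's current kinetics)
        above which a cell freezes, for the "period-threshold" rule.
    total_time : float
    hold_eta : bool
        If True (default) m and k3 co-vary with the local k2 exactly as in
        the slow-down schedule (m = gamma - 4*k2/(k1*eta0),
        k3 = 1.05 * k3c), so each cell's clock stays mildly super-critical
        as it drifts down the gradient.
    """

    elongation_rate: float
    psm_length: float
    gradient_profile: Callable[[float], float]
    freeze_rule: Literal["front-position", "period-threshold"] = "front-position"
    freeze_period_threshold: float = math.inf
    total_time: float = 300.0
    hold_eta: bool = True

    def __post_init__(self):
        # v = 0 is admitted as a degenerate case (no cells are ever born,
        # so no segments form); negative rates are rejected.
        if self.elongation_rate < 0:
            raise ValueError("elongation_rate must be >= 0")
        if self.psm_length <= 0:
            raise ValueError("psm_length must be > 0")


@dataclass(frozen=True)
class SegmentMap:
    """Frozen-phase record along the anterior->posterior axis."""

    positions: np.ndarray      # cell-centre coordinates, anterior first
    frozen_phase: np.ndarray   # latched phase per frozen cell (radians)
    boundaries: np.ndarray     # positions of positive-going phase-zero crossings
    segment_lengths: np.ndarray

    def __post_init__(self):
        if np.any(np.diff(self.boundaries) <= 0):
            raise ValueError("boundaries must be strictly increasing")


@dataclass(frozen=True)
class TransitionResult:
    """Wavelengths before/after the switch to reaction-diffusion patterning."""

    pre_wavelength: float
    post_wavelength: float | None
    ratio: float | None
    verdict_label: str


def _local_params(p: KineticParams, k2_local: float, eta0: float, hold_eta: bool) -> KineticParams:
    if hold_eta:
        m_local = p.gamma - 4.0 * k2_local / (p.k1 * eta0)
        q = p.with_(k2=k2_local, m=m_local)
        return q.with_(k3=1.05 * hopf_threshold(q))
    return p.with_(k2=k2_local)


def _freeze_age(cfg: GrowthConfig, p: KineticParams, eta0: float | None) -> float:
    """Cell age at which the freeze rule fires (identical for every cell).

    Front-position: age = psm_length / v exactly.  Period-threshold: the
    local linear period grows monotonically with age as the cell slides
    down the gradient, so the firing age is found by bisection.
    """
    v = cfg.elongation_rate
    if v == 0:
        return math.inf
    if cfg.freeze_rule == "front-position":
        return cfg.psm_length / v
    if cfg.freeze_rule != "period-threshold":
        raise ValueError(f"unknown freeze_rule {cfg.freeze_rule!r}")

    def period_at(age: float) -> float:
        q = _local_params(p, cfg.gradient_profile(v * age), eta0, cfg.hold_eta)
        return period_estimate(q)

    if period_at(0.0) > cfg.freeze_period_threshold:
        return 0.0
    lo, hi = 0.0, cfg.psm_length / v
    while period_at(hi) < cfg.freeze_period_threshold:
        lo, hi = hi, 2.0 * hi
        if hi > 100.0 * cfg.total_time:
            raise ValueError("period never reaches freeze_period_threshold")
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if period_at(mid) < cfg.freeze_period_threshold:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def run_growth(
    cfg: GrowthConfig,
    p: KineticParams,
    seed: int = 1729,
    dt: float = 0.25,
) -> tuple[SegmentMap, Field1D]:
    """Simulate posterior elongation with per-cell oscillators and phase freezing.

    Cells are uncoupled compartments sharing only their posterior birth
    state (syncytial synchronization is the posterior clock's job); each
    runs its own oscillator with k2 set by its growing distance from the
    posterior until the freeze rule fires, whereupon its phase (angle of
    (x - x*, y - y*) at the local steady state) is latched.  Returns the
    segment map and a cell x time kymograph of y.

    Raises
    ------
    ValueError
        If the posterior kinetics are not oscillatory (k3 <= k3c there).
    """
    from scipy.integrate import solve_ivp

    from .stability import stability_report

    k2_post = cfg.gradient_profile(0.0)
    if k2_post <= 0:
        raise ValueError("gradient_profile must be positive at the posterior")
    eta0 = 4.0 * p.k2 / (p.k1 * (p.gamma - p.m)) if cfg.hold_eta else None
    p_post = _local_params(p, k2_post, eta0, cfg.hold_eta)
    if not stability_report(p_post).oscillatory:
        raise ValueError(
            "posterior must be oscillatory: k3 <= Hopf threshold at the growth zone"
        )

    v = cfg.elongation_rate
    tau_f = _freeze_age(cfg, p, eta0)
    n_cells = int(math.floor(v * cfg.total_time))  # unit cell length
    times = np.arange(0.0, cfg.total_time + dt / 2, dt)
    n_t = len(times)

    if n_cells == 0 or not math.isfinite(tau_f):
        # degenerate: nothing is born (v = 0) or nothing ever freezes
        empty = np.array([])
        seg_map = SegmentMap(empty, empty, empty, empty)
        grid = Grid1D(length=32.0, n_points=32)
        zeros = np.zeros((32, n_t))
        return seg_map, Field1D(grid=grid, times=times,
                                x_field=zeros, y_field=zeros.copy())

    # posterior clock, integrated once; cells branch off at their birth
    # time, and its unwrapped phase anchors every cell's cumulative phase.
    # A spin-up of ~15 periods puts the clock on its limit cycle before the
    # first cell is born, so every segment reflects the asymptotic period.
    x0, y0 = default_initial_condition(p_post, seed=seed)
    T_lin = period_estimate(p_post)
    spin = integrate(p_post, init=(x0, y0), t_span=(0.0, 15.0 * T_lin), n_samples=50)
    x0, y0 = float(spin.x_series[-1]), float(spin.y_series[-1])
    birth_times = np.arange(n_cells) / v
    ss_post = steady_state(p_post)
    post = integrate(
        p_post, init=(x0, y0), t_span=(0.0, cfg.total_time),
        n_samples=max(800, 8 * n_t),
    )
    theta_post = np.unwrap(
        np.arctan2(post.y_series - ss_post.y_star, post.x_series - ss_post.x_star)
    )
    birth_x = np.interp(birth_times, post.times, post.x_series)
    birth_y = np.interp(birth_times, post.times, post.y_series)
    birth_theta = np.interp(birth_times, post.times, theta_post)

    # shared age grid for every full-life cell (dense: the phase winding
    # must be unwrapped through the fast spike of the relaxation cycle)
    T_post = period_estimate(p_post)
    dt_age = min(dt, T_post / 80.0)
    n_age = max(3, int(math.ceil(tau_f / dt_age)) + 1)
    ages = np.linspace(0.0, tau_f, n_age)
    # local kinetics and steady states along the age grid (shared by all cells)
    qs = [
        _local_params(p, cfg.gradient_profile(v * a), eta0, cfg.hold_eta)
        for a in ages
    ]
    ss_x = np.array([steady_state(q).x_star for q in qs])
    ss_y = np.array([steady_state(q).y_star for q in qs])

    def cell_rhs(age, s):
        x, y = s
        yc = max(y, 0.0)
        q = _local_params(p, cfg.gradient_profile(v * age), eta0, cfg.hold_eta)
        up = q.k2 * x * yc**q.gamma
        return (q.k1 - 2.0 * up, up - q.k3 * yc**q.m)

    y_kym = np.zeros((n_cells, n_t))
    phase_unwrapped = np.full(n_cells, np.nan)  # cumulative phase at freeze
    frozen_wrapped = np.full(n_cells, np.nan)
    frozen_flag = np.zeros(n_cells, dtype=bool)

    for i in range(n_cells):
        t_birth = birth_times[i]
        life_end = min(tau_f, cfg.total_time - t_birth)
        if life_end <= 0:
            continue
        n_life = int(np.searchsorted(ages, life_end, side="right"))
        ages_i = ages[:n_life] if n_life >= 2 else np.array([0.0, life_end])
        sol = solve_ivp(
            cell_rhs, (0.0, float(ages_i[-1])), [birth_x[i], birth_y[i]],
            method="LSODA", t_eval=ages_i, rtol=1e-8, atol=1e-10,
        )
        if not sol.success:
            raise RuntimeError(f"cell {i} integration failed: {sol.message}")
        y_kym[i] = np.interp(
            times - t_birth, ages_i, sol.y[1], left=0.0, right=sol.y[1, -1]
        )
        if t_birth + tau_f <= cfg.total_time and n_life == n_age:
            # winding of (x - x*, y - y*) around the drifting local steady
            # state over the cell's life, added to the posterior phase at
            # birth: a continuous, monotone-in-birth-time cumulative phase
            theta = np.unwrap(
                np.arctan2(sol.y[1] - ss_y[:n_life], sol.y[0] - ss_x[:n_life])
            )
            frozen_flag[i] = True
            phase_unwrapped[i] = birth_theta[i] + (theta[-1] - theta[0])
            frozen_wrapped[i] = math.atan2(
                sol.y[1, -1] - ss_y[-1], sol.y[0, -1] - ss_x[-1]
            )

    frozen_idx = np.where(frozen_flag)[0]
    positions = frozen_idx.astype(float) + 0.5  # cell centres, anterior first
    boundaries = _phase_cycle_crossings(positions, phase_unwrapped[frozen_idx])
    seg_map = SegmentMap(
        positions=positions,
        frozen_phase=frozen_wrapped[frozen_idx],
        boundaries=boundaries,
        segment_lengths=np.diff(boundaries),
    )
    grid = Grid1D(length=float(max(n_cells, 32)), n_points=max(n_cells, 32))
    if n_cells < 32:  # pad the kymograph to the minimal grid
        y_kym = np.vstack([y_kym, np.zeros((32 - n_cells, n_t))])
    field = Field1D(grid=grid, times=times, x_field=np.zeros_like(y_kym), y_field=y_kym)
    return seg_map, field


def _phase_cycle_crossings(positions: np.ndarray, cum_phase: np.ndarray) -> np.ndarray:
    """Positions where the cumulative frozen phase crosses a multiple of 2*pi.

    ``cum_phase`` is the unwrapped (continuously wound) phase at freezing,
    a monotone function of position: posterior cells froze later, after
    more clock turns.  Each full turn lays one boundary (the positive-going
    zero crossing of the wrapped phase), located by linear interpolation.
    """
    if len(positions) < 2:
        return np.array([])
    phi = np.asarray(cum_phase, dtype=float)
    if phi[-1] < phi[0]:  # clockwise rotation: flip so phi increases
        phi = -phi
    lo = math.ceil(phi[0] / (2 * math.pi))
    hi = math.floor(phi[-1] / (2 * math.pi))
    bounds = []
    for n in range(lo, hi + 1):
        target = 2 * math.pi * n
        j = int(np.searchsorted(phi, target))
        if j == 0 or j >= len(positions):
            continue
        f = (target - phi[j - 1]) / (phi[j] - phi[j - 1])
        bounds.append(positions[j - 1] + f * (positions[j] - positions[j - 1]))
    return np.array(bounds)


def run_transition(
    cfg: GrowthConfig,
    p_pre: KineticParams,
    p_post: KineticParams,
    d: DiffusionParams,
    switch_time: float | None = None,
    seed: int = 1729,
    bias_amplitude: float = 0.03,
    t_rd: float = 600.0,
    points_per_cell: int = 4,
) -> TransitionResult:
    """Sequential-to-simultaneous transition: frozen segments seed a Turing run.

    Phase 1 runs the growth scenario with ``p_pre`` until ``switch_time``
    (default: cfg.total_time).  Phase 2 switches the mature region to
    ``p_post`` kinetics with diffusion ``d``: the frozen phase pattern,
    rescaled to a small bias (``bias_amplitude``) around the new
    homogeneous steady state, is the initial condition of the
    reaction-diffusion solver.  Reports the mean pre-transition segment
    length, the post-transition dominant wavelength, and their ratio
    (None when no stationary pattern forms).
    """
    seg_map, _ = run_growth(cfg, p_pre, seed=seed)
    if len(seg_map.segment_lengths) == 0:
        raise ValueError("no segments formed before the transition")
    pre_wl = float(np.mean(seg_map.segment_lengths))

    # mature-region initial bias: cos of the frozen phase, small amplitude
    length = float(seg_map.positions[-1] - seg_map.positions[0]) + 1.0
    n = max(32, int(round(length * points_per_cell)))
    grid = Grid1D(length=length, n_points=n, boundary="no-flux")
    z = grid.positions
    phase_on_grid = np.interp(
        z, seg_map.positions - seg_map.positions[0] + 0.5, seg_map.frozen_phase
    )
    ss = steady_state(p_post)
    rng = np.random.default_rng(seed)
    x0 = ss.x_star * (1.0 + 0.002 * rng.uniform(-1, 1, n))
    y0 = ss.y_star * (1.0 + bias_amplitude * np.cos(phase_on_grid)
                      + 0.002 * rng.uniform(-1, 1, n))
    field = simulate_rd(p_post, d, grid, init=(x0, y0), t_span=(0.0, t_rd), seed=seed)
    verdict = classify_pattern(field)
    if verdict.label == "stationary_pattern":
        post_wl = measure_wavelength(field)
        return TransitionResult(
            pre_wavelength=pre_wl,
            post_wavelength=post_wl,
            ratio=post_wl / pre_wl,
            verdict_label=verdict.label,
        )
    return TransitionResult(
        pre_wavelength=pre_wl,
        post_wavelength=None,
        ratio=None,
        verdict_label=verdict.label,
    )
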