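"""Closed-form model analysis: steady state, Hopf threshold, Turing modes."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tenmclock import (
    DiffusionParams,
    InvalidRegimeError,
    KineticParams,
    derivatives,
    dispersion_max,
    dispersion_relation,
    eta,
    hopf_threshold,
    period_estimate,
    period_fold_change,
    stability_report,
    steady_state,
    turing_prediction,
)
from tenmclock.stability import determinant_closed_form

from conftest import random_oscillator_params


# --- strategies: valid oscillator-capable parameter sets -------------------

@st.composite
def oscillator_params(draw):
    gamma = draw(st.floats(1.6, 3.2))
    m = draw(st.floats(0.8, gamma - 0.3))
    return KineticParams(
        k1=draw(st.floats(0.4, 2.5)),
        k2=draw(st.floats(0.05, 1.5)),
        k3=draw(st.floats(0.1, 1.5)),
        gamma=gamma,
        m=m,
    )


# --- derivatives ------------------------------------------------------------

@pytest.mark.parametrize(
    "x, y, kwargs, expected",
    [
        # steady state: k1 = 2*k3 forces y* = 1, x* = k1/(2*k2)
        (2.5, 1.0, dict(k1=1, k2=0.2, gamma=2.4, m=1.6, k3=0.5), (0.0, 0.0)),
        # uptake vanishes at x = 0
        (0.0, 1.0, dict(k1=1, k2=0.2, gamma=2.4, m=1.6, k3=0.5), (1.0, -0.5)),
        # generic hand evaluation
        (1.0, 1.0, dict(k1=1, k2=0.75, gamma=2, m=1.25, k3=0.49), (-0.5, 0.26)),
    ],
)
def test_derivatives_hand_values(x, y, kwargs, expected):
    p = KineticParams(**kwargs)
    dx, dy = derivatives(x, y, p)
    assert dx == pytest.approx(expected[0], abs=1e-12)
    assert dy == pytest.approx(expected[1], abs=1e-12)


def test_derivatives_reject_negative_concentrations(fig4_kinetics):
    with pytest.raises(ValueError):
        derivatives(-0.1, 1.0, fig4_kinetics)
    with pytest.raises(ValueError):
        derivatives(1.0, -1e-9, fig4_kinetics)


def test_conservation_without_synthesis_and_degradation():
    """With k1 = k3 = 0 the uptake stoichiometry conserves x + 2y exactly."""
    p = KineticParams(k1=0.0, k2=0.3, k3=0.0, gamma=2.0, m=1.5)
    for x, y in [(1.0, 2.0), (0.5, 0.1), (3.0, 0.0)]:
        dx, dy = derivatives(x, y, p)
        assert dx + 2.0 * dy == pytest.approx(0.0, abs=1e-15)


# --- steady state ------------------------------------------------------------

@pytest.mark.parametrize(
    "kwargs, expected",
    [
        (dict(k1=1, k2=0.2, gamma=2.4, m=1.6, k3=0.5), (2.5, 1.0)),
        (dict(k1=2, k2=1, gamma=2, m=2, k3=1), (1.0, 1.0)),
        # computed from y* = (k1/2k3)^(1/m) and the x-nullcline
        (dict(k1=1, k2=0.2, gamma=2.4, m=1.6, k3=0.475), (2.314864, 1.032578)),
    ],
)
def test_steady_state_values(kwargs, expected):
    p = KineticParams(**kwargs)
    ss = steady_state(p)
    assert ss.x_star == pytest.approx(expected[0], rel=1e-6)
    assert ss.y_star == pytest.approx(expected[1], rel=1e-6)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(oscillator_params())
def test_derivatives_vanish_at_steady_state(p):
    ss = steady_state(p)
    dx, dy = derivatives(ss.x_star, ss.y_star, p)
    scale = max(p.k1, p.k3)
    assert abs(dx) <= 1e-12 * scale
    assert abs(dy) <= 1e-12 * scale


# --- stability report ---------------------------------------------------------

def test_stability_report_at_hopf_point():
    """At k3 = k3c (0.50 for this set) the trace vanishes and det = 0.32."""
    p = KineticParams(k1=1, k2=0.2, gamma=2.4, m=1.6, k3=0.5)
    rep = stability_report(p)
    assert rep.determinant == pytest.approx(0.32, rel=1e-12)
    assert rep.trace == pytest.approx(0.0, abs=1e-12)
    # purely imaginary eigenvalues +/- i*sqrt(det)
    assert rep.eigenvalues[0].imag == pytest.approx(math.sqrt(0.32), rel=1e-10)


def test_subthreshold_set_is_not_oscillatory(fig4_kinetics):
    assert stability_report(fig4_kinetics).oscillatory is False


@settings(max_examples=300, deadline=None, derandomize=True)
@given(oscillator_params())
def test_determinant_positive_and_matches_closed_form(p):
    rep = stability_report(p)
    assert rep.determinant > 0
    closed = determinant_closed_form(p)
    assert rep.determinant == pytest.approx(closed, rel=1e-10)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(oscillator_params())
def test_trace_vanishes_at_hopf_threshold(p):
    k3c = hopf_threshold(p)
    rep = stability_report(p.with_(k3=k3c))
    scale = abs(rep.a) + abs(rep.d)
    assert abs(rep.trace) <= 1e-8 * scale


def test_determinant_positivity_random_sample():
    rng = np.random.default_rng(42)
    for _ in range(1000):
        p = random_oscillator_params(rng)
        rep = stability_report(p)
        assert rep.determinant > 0
        assert rep.determinant == pytest.approx(
            determinant_closed_form(p), rel=1e-10
        )


# --- Hopf threshold, eta, period -----------------------------------------------

def test_hopf_threshold_printed_value():
    """The Turing-regime kinetic set has k3c exactly 1/2 (eta = 1 there)."""
    p = KineticParams(k1=1, k2=0.2, gamma=2.4, m=1.6, k3=0.475)
    assert hopf_threshold(p) == pytest.approx(0.5, abs=1e-15)
    assert eta(p) == pytest.approx(1.0, abs=1e-15)


def test_hopf_threshold_generic_value():
    # independent evaluation: (1/2)*(4*0.75/0.75)^(1.25/3)
    p = KineticParams(k1=1, k2=0.75, gamma=2.0, m=1.25, k3=0.49)
    expected = 0.5 * 4.0 ** (1.25 / 3.0)
    assert hopf_threshold(p) == pytest.approx(expected, rel=1e-12)
    assert hopf_threshold(p) == pytest.approx(0.891, abs=5e-4)


def test_equal_hill_coefficients_are_invalid_regime():
    p = KineticParams(k1=1, k2=0.3, k3=0.4, gamma=2.0, m=2.0)
    with pytest.raises(InvalidRegimeError):
        hopf_threshold(p)
    with pytest.raises(InvalidRegimeError):
        period_estimate(p)
    with pytest.raises(InvalidRegimeError):
        eta(p)


def test_eta_values_and_invariance():
    assert eta(KineticParams(k1=1, k2=0.25, k3=0.4, gamma=2.0, m=1.0)) == 1.0
    p = KineticParams(k1=1, k2=0.2, k3=0.5, gamma=2.4, m=1.6)
    # scaling k2 and (gamma - m) together leaves eta unchanged
    for f in (0.1, 0.5, 3.0):
        q = p.with_(k2=f * p.k2, m=p.gamma - f * (p.gamma - p.m))
        assert eta(q) == pytest.approx(eta(p), rel=1e-12)


def test_period_estimate_equals_2pi_over_sqrt_det_at_threshold():
    rng = np.random.default_rng(7)
    for _ in range(50):
        p = random_oscillator_params(rng)
        p_c = p.with_(k3=hopf_threshold(p))
        det = determinant_closed_form(p_c)
        assert period_estimate(p) == pytest.approx(
            2.0 * math.pi / math.sqrt(det), rel=1e-10
        )


def test_period_estimate_fig4_value():
    p = KineticParams(k1=1, k2=0.2, gamma=2.4, m=1.6, k3=0.5)
    # eta = 1 so Tp = 2*pi/sqrt(0.32)
    assert period_estimate(p) == pytest.approx(2 * math.pi / math.sqrt(0.32), rel=1e-12)


def test_period_fold_change_front_factor_scaling():
    assert period_fold_change(0.5, 0.02) == pytest.approx(5.0, abs=1e-15)
    assert period_fold_change(0.75, 0.0075) == pytest.approx(10.0, rel=1e-15)
    with pytest.raises(ValueError):
        period_fold_change(0.0, 0.1)


# --- Turing prediction -----------------------------------------------------------

def test_turing_prediction_values(fig4_kinetics, fig4_diffusion):
    tp = turing_prediction(fig4_kinetics, fig4_diffusion)
    assert tp.kappa_T_approx == pytest.approx(1.467, abs=2e-3)
    assert tp.lambda_T_approx == pytest.approx(4.283, abs=5e-3)
    assert tp.lambda_T == pytest.approx(2 * math.pi / tp.kappa_T, rel=1e-14)


def test_turing_wavelength_scales_as_sqrt_Dy(fig4_kinetics, fig4_diffusion):
    tp1 = turing_prediction(fig4_kinetics, fig4_diffusion)
    d4 = DiffusionParams(Dx=fig4_diffusion.Dx, Dy=4 * fig4_diffusion.Dy)
    tp2 = turing_prediction(fig4_kinetics, d4)
    assert tp2.lambda_T_approx == pytest.approx(2 * tp1.lambda_T_approx, rel=1e-12)


def test_no_turing_mode_when_hill_coefficients_equal():
    p = KineticParams(k1=1, k2=0.2, k3=0.475, gamma=2.0, m=2.0)
    with pytest.raises(ValueError, match="no finite-wavelength"):
        turing_prediction(p, DiffusionParams(1.45, 0.09))


def test_approx_and_exact_wavenumbers_agree_for_large_diffusion_contrast():
    # kappa_approx/kappa_exact = (1 - r)^(-1/2) with r = |a|*Dy/(d*Dx), so
    # the 5% agreement holds when the stabilizing self-decay of x is
    # subdominant (r <= 0.09), which a large Dx/Dy contrast promotes but
    # does not by itself guarantee.
    rng = np.random.default_rng(11)
    checked = 0
    while checked < 40:
        p = random_oscillator_params(rng)
        Dy = rng.uniform(0.02, 0.3)
        d = DiffusionParams(Dx=rng.uniform(16, 60) * Dy, Dy=Dy)
        try:
            tp = turing_prediction(p, d)
        except ValueError:
            continue
        rep = stability_report(p)
        r = abs(rep.a) * d.Dy / (rep.d * d.Dx)
        if r > 0.09:
            continue
        assert abs(tp.kappa_T_approx - tp.kappa_T_exact) <= 0.05 * tp.kappa_T_exact
        checked += 1


# --- dispersion relation ------------------------------------------------------------

def test_dispersion_at_zero_reduces_to_homogeneous_eigenvalues(fig4_kinetics, fig4_diffusion):
    rep = stability_report(fig4_kinetics)
    kappa, growth = dispersion_max(fig4_kinetics, fig4_diffusion, [0.0])
    assert kappa == 0.0
    assert growth == pytest.approx(
        max(rep.eigenvalues[0].real, rep.eigenvalues[1].real), rel=1e-12
    )


def test_dispersion_max_near_critical_wavenumber(fig4_kinetics, fig4_diffusion):
    """The fastest-growing mode sits a little below the marginal kappa_T."""
    tp = turing_prediction(fig4_kinetics, fig4_diffusion)
    grid = np.linspace(0.01, 4.0, 2000)
    kappa, growth = dispersion_max(fig4_kinetics, fig4_diffusion, grid)
    assert growth > 0
    assert abs(kappa - tp.kappa_T_approx) <= 0.15 * tp.kappa_T_approx


def test_equal_diffusion_gives_no_turing_instability():
    # stable focus: trace < 0; equal diffusion shifts both eigenvalues down
    p = KineticParams(k1=1, k2=0.2, gamma=2.4, m=1.6, k3=0.475)
    d = DiffusionParams(0.5, 0.5)
    grid = np.linspace(0.0, 4.0, 500)
    kappa, growth = dispersion_max(p, d, grid)
    assert kappa == 0.0
    assert growth < 0


def test_dispersion_max_rejects_bad_grids(fig4_kinetics, fig4_diffusion):
    with pytest.raises(ValueError):
        dispersion_max(fig4_kinetics, fig4_diffusion, [])
    with pytest.raises(ValueError):
        dispersion_max(fig4_kinetics, fig4_diffusion, [-1.0, 1.0])
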