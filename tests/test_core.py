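"""Plasticity-rule enumeration, mean-field drift, fixed points, timescales."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from compsyn import (
    PlasticityParams,
    drift,
    integrate,
    neighbor_outcome_probs,
    relaxation_time,
    stable_fixed_point,
)
from compsyn.core import (
    STRONG,
    WEAK,
    drift_closed_form,
    drift_polynomial,
    relaxation_time_closed_form,
    stable_fixed_point_closed_form,
    transition_probs,
)
from compsyn.exceptions import (
    IntegrationInstabilityError,
    InvalidParameterError,
)

probs = st.floats(min_value=0.01, max_value=0.99)


@pytest.mark.parametrize("bad", [0.0, 1.0, -0.2, 1.3])
def test_params_rejects_boundary_values(bad):
    with pytest.raises(InvalidParameterError):
        PlasticityParams(bad, 0.5)
    with pytest.raises(InvalidParameterError):
        PlasticityParams(0.5, bad)


def test_outcome_probs_invalid_type_rejected():
    with pytest.raises(InvalidParameterError):
        neighbor_outcome_probs("medium", WEAK, PlasticityParams(0.5, 0.5))


@pytest.mark.parametrize(
    "left,right,alpha,beta,expected",
    [
        # same-type neighbours give zero/unpolarized outcomes only
        (STRONG, STRONG, 0.8, 0.2, (0.0, 0.0, 1.0)),
        (WEAK, WEAK, 0.8, 0.2, (0.0, 0.0, 1.0)),
        # mixed: pot = alpha(1-beta), dep = beta(1-alpha)
        (STRONG, WEAK, 0.8, 0.2, (0.64, 0.04, 0.32)),
        (WEAK, STRONG, 0.8, 0.2, (0.64, 0.04, 0.32)),
        # equal activation probabilities make pot and dep symmetric
        (STRONG, WEAK, 0.5, 0.5, (0.25, 0.25, 0.5)),
    ],
)
def test_outcome_prob_examples(left, right, alpha, beta, expected):
    out = neighbor_outcome_probs(left, right, PlasticityParams(alpha, beta))
    np.testing.assert_allclose(out.as_tuple(), expected, atol=1e-14)


@settings(derandomize=True, max_examples=200)
@given(alpha=probs, beta=probs)
def test_outcome_probs_sum_to_one(alpha, beta):
    params = PlasticityParams(alpha, beta)
    for lt in (STRONG, WEAK):
        for rt in (STRONG, WEAK):
            out = neighbor_outcome_probs(lt, rt, params)
            assert abs(sum(out.as_tuple()) - 1.0) <= 1e-12
            assert all(-1e-12 <= p <= 1.0 + 1e-12 for p in out.as_tuple())


def test_drift_vanishes_at_homogeneous_states():
    params = PlasticityParams(0.8, 0.2)
    assert drift(0.0, params) == 0.0
    assert drift(1.0, params) == 0.0


def test_drift_symmetric_params_stationary_at_half():
    assert drift(0.5, PlasticityParams(0.37, 0.37)) == pytest.approx(0.0, abs=1e-15)


def test_drift_sign_brackets_stable_point():
    params = PlasticityParams(0.8, 0.2)
    assert drift(0.5, params) > 0
    assert drift(0.99, params) < 0


def test_drift_rejects_x_outside_unit_interval():
    with pytest.raises(ValueError):
        drift(1.2, PlasticityParams(0.5, 0.5))


def test_transition_probs_weigh_mixed_configurations():
    # at x=1/2 all four neighbour configurations have weight 1/4;
    # mixed ones (total weight 1/2) alone contribute
    params = PlasticityParams(0.8, 0.2)
    w_up, w_down = transition_probs(0.5, params)
    assert w_up == pytest.approx(0.5 * 0.64)
    assert w_down == pytest.approx(0.5 * 0.04)


def test_closed_form_drift_matches_enumeration_polynomial(rng):
    xs = np.linspace(0.0, 1.0, 17)
    for _ in range(50):
        a, b = rng.uniform(0.05, 0.95, 2)
        params = PlasticityParams(a, b)
        poly = drift_polynomial(params)
        for x in xs:
            assert abs(poly(x) - drift_closed_form(x, params)) < 1e-14
            assert abs(poly(x) - drift(x, params)) < 1e-14


def test_relabeling_antisymmetry_of_drift(rng):
    # exchanging strong and weak labels maps x -> 1-x and flips the drift
    for _ in range(20):
        a, b = rng.uniform(0.05, 0.95, 2)
        params = PlasticityParams(a, b)
        for x in np.linspace(0.0, 1.0, 9):
            assert drift(x, params) == pytest.approx(
                -drift(1.0 - x, params.swapped()), abs=1e-14
            )


def test_stable_fixed_point_examples():
    assert stable_fixed_point(PlasticityParams(0.5, 0.5)) == pytest.approx(
        0.5, abs=1e-12
    )
    assert stable_fixed_point(PlasticityParams(0.8, 0.2)) == pytest.approx(
        0.64 / 0.68, abs=1e-12
    )


def test_stable_fixed_point_swap_symmetry(rng):
    for _ in range(20):
        a, b = rng.uniform(0.05, 0.95, 2)
        x1 = stable_fixed_point(PlasticityParams(a, b))
        x2 = stable_fixed_point(PlasticityParams(b, a))
        assert x1 == pytest.approx(1.0 - x2, abs=1e-12)


def test_stable_fixed_point_agrees_with_closed_form(rng):
    for _ in range(50):
        a, b = rng.uniform(0.05, 0.95, 2)
        params = PlasticityParams(a, b)
        assert stable_fixed_point(params) == pytest.approx(
            stable_fixed_point_closed_form(params), abs=1e-12
        )


def test_relaxation_time_symmetric_value():
    assert relaxation_time(PlasticityParams(0.5, 0.5)) == pytest.approx(
        4.0, rel=1e-12
    )


def test_relaxation_time_swap_symmetry(rng):
    for _ in range(20):
        a, b = rng.uniform(0.05, 0.95, 2)
        t1 = relaxation_time(PlasticityParams(a, b))
        t2 = relaxation_time(PlasticityParams(b, a))
        assert t1 == pytest.approx(t2, rel=1e-11)


def test_corner_parameters_give_long_retention():
    # widely separated activation probabilities -> long relaxation time
    assert relaxation_time(PlasticityParams(0.99, 0.01)) > 25 * relaxation_time(
        PlasticityParams(0.5, 0.5)
    )


def test_relaxation_time_matches_closed_form(rng):
    for _ in range(50):
        a, b = rng.uniform(0.05, 0.95, 2)
        params = PlasticityParams(a, b)
        np.testing.assert_allclose(
            relaxation_time(params),
            relaxation_time_closed_form(params),
            rtol=1e-12,
        )


def test_trajectory_rate_matches_relaxation_time(rng):
    # independent oracle: fit the exponential decay rate toward x* on an
    # integrated trajectory and compare with 1/tau
    for _ in range(5):
        a, b = rng.uniform(0.2, 0.8, 2)
        params = PlasticityParams(a, b)
        x_star = stable_fixed_point(params)
        tau = relaxation_time(params)
        traj = integrate(x_star + 0.01, params, duration=14 * tau, dt=0.005)
        dist = np.abs(traj.x - x_star)
        sel = (dist > 1e-5) & (dist < 1e-3)
        slope = np.polyfit(traj.t[sel], np.log(dist[sel]), 1)[0]
        assert -1.0 / slope == pytest.approx(tau, rel=0.01)


def test_boundary_repulsion(rng):
    eps = 1e-4
    for _ in range(20):
        a, b = rng.uniform(0.1, 0.9, 2)
        params = PlasticityParams(a, b)
        assert drift(eps, params) > 0
        assert drift(1 - eps, params) < 0


def test_integrate_fixed_point_is_constant():
    params = PlasticityParams(0.7, 0.3)
    x_star = stable_fixed_point(params)
    traj = integrate(x_star, params, duration=10.0, dt=0.01)
    np.testing.assert_allclose(traj.x, x_star, atol=1e-9)


def test_integrate_converges_to_fixed_point():
    params = PlasticityParams(0.8, 0.2)
    x_star = stable_fixed_point(params)
    traj = integrate(0.3, params, duration=400.0, dt=0.01)
    assert abs(traj.final_state.x - x_star) < 1e-6


def test_integrate_monotone_approach():
    params = PlasticityParams(0.8, 0.2)
    traj = integrate(0.3, params, duration=100.0, dt=0.01)
    assert np.all(np.diff(traj.x) >= 0)


def test_integrate_instability_error_for_large_dt():
    with pytest.raises(IntegrationInstabilityError):
        integrate(0.3, PlasticityParams(0.8, 0.2), duration=200.0, dt=60.0)


def test_adaptive_integrator_agrees_with_euler():
    params = PlasticityParams(0.7, 0.3)
    euler = integrate(0.2, params, duration=50.0, dt=0.001, record_every=1000)
    adaptive = integrate(
        0.2, params, duration=50.0, dt=0.001, method="adaptive",
        record_every=1000,
    )
    np.testing.assert_allclose(euler.x, adaptive.x, atol=5e-4)


def test_trajectory_iterates_mean_field_states():
    traj = integrate(0.4, PlasticityParams(0.5, 0.5), duration=1.0, dt=0.1)
    states = list(traj)
    assert states[0].t == 0.0 and states[0].x == 0.4
    assert len(states) == len(traj)
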