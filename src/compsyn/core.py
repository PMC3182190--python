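"""Plasticity rules and mean-field dynamics of the competing-synapse model.

A one-dimensional chain of binary synapses ("strong" / "weak") connects
threshold neurons. When a synapse is considered for an update, each flanking
neuron fires independently with a probability set by the type of its *other*
adjacent synapse: ``alpha`` if that synapse is strong, ``beta`` if weak. The
update has anti-Hebbian polarity: with mixed-type neighbours, the candidate
synapse is potentiated (set strong) when only the strong-adjacent neuron
fires and depressed (set weak) when only the weak-adjacent neuron fires; in
every other case, including same-type neighbours, nothing happens.

The mean-field (effective) description replaces the chain by the fraction
``x`` of strong synapses, uniform over the lattice and free of correlations.
Averaging the single-update rules over neighbour configurations drawn
independently with strong-probability ``x`` yields the deterministic drift

    dx/dt = (1 - x) * W_up(x) - x * W_down(x),

a cubic polynomial with unstable absorbing fixed points at 0 and 1 and a
stable interior fixed point ``x*`` to which the system relaxes exponentially
with time constant ``tau = -1 / drift'(x*)``. Time is measured in sweeps
(one expected update attempt per synapse).

Everything here is *built from the single-update enumeration*: the drift,
fixed point and relaxation time are obtained by enumerating the four joint
activation outcomes, and the closed forms (``*_closed_form``) are derived
expressions cross-checked against that enumeration in the test suite.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from numpy.polynomial import Polynomial
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from . import _kernels
from .exceptions import (
    DegenerateParametersError,
    IntegrationInstabilityError,
    InvalidParameterError,
    MarginalStabilityError,
)

__all__ = [
    "STRONG",
    "WEAK",
    "PlasticityParams",
    "OutcomeProbs",
    "MeanFieldState",
    "FixedPointSummary",
    "Trajectory",
    "neighbor_outcome_probs",
    "transition_probs",
    "drift",
    "drift_polynomial",
    "drift_closed_form",
    "stable_fixed_point",
    "stable_fixed_point_closed_form",
    "relaxation_time",
    "relaxation_time_closed_form",
    "fixed_point_summary",
    "integrate",
]

STRONG = "strong"
WEAK = "weak"
_SYNAPSE_TYPES = (STRONG, WEAK)

#: Exclusion margin for the open-interval parameter check. Boundary values
#: (0 or 1) freeze one synapse type and destroy the interior fixed point.
PARAM_EPS = 1e-9


@dataclass(frozen=True)
class PlasticityParams:
    """Neuron activation probabilities, one per adjacent-synapse type.

    alpha : activation probability of a neuron whose other adjacent synapse
        is strong; beta : likewise for a weak adjacent synapse. Both must lie
        strictly inside (0, 1).
    """

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        for name, value in (("alpha", self.alpha), ("beta", self.beta)):
            if not (PARAM_EPS < value < 1.0 - PARAM_EPS):
                raise InvalidParameterError(
                    f"{name} = {value!r} must lie strictly inside (0, 1)"
                )

    def swapped(self) -> "PlasticityParams":
        """Parameters under the strong<->weak relabeling."""
        return PlasticityParams(self.beta, self.alpha)

    def activation_prob(self, synapse_type: str) -> float:
        if synapse_type == STRONG:
            return self.alpha
        if synapse_type == WEAK:
            return self.beta
        raise InvalidParameterError(f"unknown synapse type {synapse_type!r}")


@dataclass(frozen=True)
class OutcomeProbs:
    """Per-update probabilities of potentiation / depression / no change."""

    p_potentiate: float
    p_depress: float
    p_none: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.p_potentiate, self.p_depress, self.p_none)


@dataclass(frozen=True)
class MeanFieldState:
    """Fraction of strong synapses at a given time (sweep units)."""

    x: float
    t: float


@dataclass(frozen=True)
class FixedPointSummary:
    """Stable interior fixed point with its relaxation timescale."""

    x_star: float
    tau: float

    @property
    def rate(self) -> float:
        return 1.0 / self.tau


class Trajectory:
    """A recorded mean-field trajectory (times and strong fractions)."""

    def __init__(self, t: np.ndarray, x: np.ndarray):
        t = np.asarray(t, dtype=float)
        x = np.asarray(x, dtype=float)
        if t.shape != x.shape:
            raise ValueError("t and x must have equal length")
        self.t = t
        self.x = x

    def __len__(self) -> int:
        return len(self.t)

    def __iter__(self):
        for ti, xi in zip(self.t, self.x):
            yield MeanFieldState(x=float(xi), t=float(ti))

    @property
    def final_state(self) -> MeanFieldState:
        return MeanFieldState(x=float(self.x[-1]), t=float(self.t[-1]))


def neighbor_outcome_probs(
    left_type: str, right_type: str, params: PlasticityParams
) -> OutcomeProbs:
    """Single-update outcome probabilities given the two neighbour types.

    Enumerates the 2x2 joint activation outcomes of the flanking neurons
    (each fires independently, probability set by the type of its other
    adjacent synapse) and classifies each by polarity: potentiation iff the
    neighbours are of mixed type and only the strong-adjacent neuron fires,
    depression iff mixed and only the weak-adjacent neuron fires, no change
    otherwise.
    """
    p_left = params.activation_prob(left_type)
    p_right = params.activation_prob(right_type)
    mixed = left_type != right_type
    p_pot = p_dep = p_none = 0.0
    for fires_left, fires_right in itertools.product((False, True), repeat=2):
        w = (p_left if fires_left else 1.0 - p_left) * (
            p_right if fires_right else 1.0 - p_right
        )
        if mixed and fires_left != fires_right:
            fired_type = left_type if fires_left else right_type
            if fired_type == STRONG:
                p_pot += w
            else:
                p_dep += w
        else:
            p_none += w
    return OutcomeProbs(p_pot, p_dep, p_none)


def transition_probs(x: float, params: PlasticityParams) -> tuple[float, float]:
    """Mean-field weak->strong and strong->weak transition probabilities.

    Averages the enumeration over neighbour configurations drawn
    independently with strong-probability x (mixed weight 2x(1-x)).
    """
    _check_fraction(x)
    w_up = w_down = 0.0
    for lt, rt in itertools.product(_SYNAPSE_TYPES, repeat=2):
        weight = (x if lt == STRONG else 1.0 - x) * (
            x if rt == STRONG else 1.0 - x
        )
        probs = neighbor_outcome_probs(lt, rt, params)
        w_up += weight * probs.p_potentiate
        w_down += weight * probs.p_depress
    return w_up, w_down


def drift(x: float, params: PlasticityParams) -> float:
    """Mean-field drift dx/dt = (1-x) W_up(x) - x W_down(x)."""
    _check_fraction(x)
    w_up, w_down = transition_probs(x, params)
    return (1.0 - x) * w_up - x * w_down


def drift_polynomial(params: PlasticityParams) -> Polynomial:
    """The drift as an exact cubic polynomial, built from the enumeration.

    The x-dependence enters only through the neighbour-configuration weights,
    which are quadratics in x; assembling them symbolically gives the drift's
    coefficients in closed form without transcribing any formula.
    """
    xp = Polynomial([0.0, 1.0])
    weights = {STRONG: xp, WEAK: 1.0 - xp}
    w_up = Polynomial([0.0])
    w_down = Polynomial([0.0])
    for lt, rt in itertools.product(_SYNAPSE_TYPES, repeat=2):
        weight = weights[lt] * weights[rt]
        probs = neighbor_outcome_probs(lt, rt, params)
        w_up = w_up + weight * probs.p_potentiate
        w_down = w_down + weight * probs.p_depress
    return (1.0 - xp) * w_up - xp * w_down


def drift_coefficients(params: PlasticityParams) -> np.ndarray:
    """Ascending cubic coefficients of the drift (padded to length 4)."""
    coef = drift_polynomial(params).coef
    out = np.zeros(4)
    out[: len(coef)] = coef
    return out


def _competition_rates(params: PlasticityParams) -> tuple[float, float]:
    """Per-mixed-pair potentiation and depression rates A, B.

    A = alpha (1 - beta) is the probability that, at a mixed neighbour pair,
    only the strong-adjacent neuron fires; B = beta (1 - alpha) likewise for
    the weak-adjacent neuron.
    """
    a, b = params.alpha, params.beta
    return a * (1.0 - b), b * (1.0 - a)


def drift_closed_form(x: float, params: PlasticityParams) -> float:
    """Derived closed form of the drift: 2 x (1-x) [(1-x) A - x B]."""
    A, B = _competition_rates(params)
    return 2.0 * x * (1.0 - x) * ((1.0 - x) * A - x * B)


def stable_fixed_point(params: PlasticityParams, *, eps: float = 1e-6) -> float:
    """Unique stable interior fixed point of the drift, by bracketed root.

    Uses Brent's method on (eps, 1-eps) at near machine precision and checks
    stability (drift'(x*) < 0).
    """
    poly = drift_polynomial(params)
    interior = poly // Polynomial([0.0, 1.0]) // Polynomial([1.0, -1.0])
    lo, hi = eps, 1.0 - eps
    f_lo, f_hi = interior(lo), interior(hi)
    if f_lo == 0.0:
        x_star = lo
    elif f_hi == 0.0:
        x_star = hi
    elif f_lo * f_hi > 0:
        raise DegenerateParametersError(
            f"no interior sign change of the drift in ({lo}, {hi}) for {params}"
        )
    else:
        x_star = brentq(interior, lo, hi, xtol=1e-15, rtol=8.9e-16)
    if poly.deriv()(x_star) >= 0:
        raise DegenerateParametersError(
            f"interior root {x_star} of the drift is not stable for {params}"
        )
    return float(x_star)


def stable_fixed_point_closed_form(params: PlasticityParams) -> float:
    """Derived closed form x* = A / (A + B)."""
    A, B = _competition_rates(params)
    return A / (A + B)


def relaxation_time(params: PlasticityParams) -> float:
    """Exponential relaxation time tau = -1 / drift'(x*).

    The derivative is evaluated analytically on the enumeration-built cubic.
    """
    x_star = stable_fixed_point(params)
    slope = drift_polynomial(params).deriv()(x_star)
    if abs(slope) < 1e-12:
        raise MarginalStabilityError(
            f"|drift'(x*)| = {abs(slope):.3e} < 1e-12 for {params}"
        )
    return float(-1.0 / slope)


def relaxation_time_closed_form(params: PlasticityParams) -> float:
    """Derived closed form tau = 1 / (2 x* (1 - x*) (A + B))."""
    A, B = _competition_rates(params)
    x_star = stable_fixed_point_closed_form(params)
    return 1.0 / (2.0 * x_star * (1.0 - x_star) * (A + B))


def fixed_point_summary(params: PlasticityParams) -> FixedPointSummary:
    """Stable fixed point and relaxation time in one record."""
    return FixedPointSummary(
        x_star=stable_fixed_point(params), tau=relaxation_time(params)
    )


def integrate(
    x0: float,
    params: PlasticityParams,
    duration: float,
    dt: float = 0.01,
    *,
    method: str = "euler",
    record_every: int = 1,
) -> Trajectory:
    """Deterministically integrate the mean-field drift from x0.

    method="euler" is the reference explicit scheme (time units = sweeps);
    method="adaptive" delegates to scipy's RK45 with dense sampling on the
    same grid. Raises IntegrationInstabilityError if a step leaves [0, 1].
    """
    _check_fraction(x0)
    if dt <= 0:
        raise ValueError("dt must be positive")
    if duration < 0:
        raise ValueError("duration must be non-negative")
    n_steps = int(round(duration / dt))
    if method == "euler":
        c0, c1, c2, c3 = drift_coefficients(params)
        out_x = np.empty(n_steps // record_every + 2)
        status, n_rec = _kernels.euler_path(
            c0, c1, c2, c3, float(x0), float(dt), n_steps, int(record_every),
            out_x,
        )
        if status == 2:
            raise IntegrationInstabilityError(
                f"Euler step left [0, 1] (dt={dt}); reduce dt"
            )
        steps = np.arange(0, n_steps + 1, record_every)
        if n_steps % record_every != 0:
            steps = np.append(steps, n_steps)
        return Trajectory(steps * dt, out_x[:n_rec])
    if method == "adaptive":
        poly = drift_polynomial(params)
        t_eval = np.arange(0, n_steps + 1, record_every) * dt
        sol = solve_ivp(
            lambda t, y: poly(y[0]),
            (0.0, n_steps * dt),
            [float(x0)],
            t_eval=t_eval,
            rtol=1e-10,
            atol=1e-12,
            vectorized=False,
        )
        x = np.clip(sol.y[0], 0.0, 1.0)
        return Trajectory(sol.t, x)
    raise ValueError(f"unknown method {method!r}")


def _check_fraction(x: float) -> None:
    if not (0.0 <= x <= 1.0):
        raise ValueError(f"x = {x!r} must lie in [0, 1]")
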