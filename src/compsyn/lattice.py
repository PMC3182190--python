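"""Stochastic simulation of the 1-D chain of competing binary synapses.

This is the microscopic model the mean-field description approximates: a
periodic chain of N binary synapses updated random-sequentially. One sweep
(N candidate updates, uniform site choice with replacement) equals one unit
of mean-field time. Each update draws fresh, independent activations for the
two flanking neurons and applies the anti-Hebbian polarity rule; the
homogeneous all-strong and all-weak states are absorbing, so the interior
fixed point of the mean-field dynamics is metastable at finite N.

The simulator doubles as the independent oracle for the mean-field level:
its stationary strong fraction is compared against the deterministic fixed
point in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import _kernels
from .core import STRONG, WEAK, PlasticityParams
from .exceptions import EstimationError

__all__ = [
    "LatticeState",
    "LatticeTrajectory",
    "init_lattice",
    "update_once",
    "run_sweeps",
    "stationary_fraction",
]

_MIN_SITES = 3


@dataclass(frozen=True)
class LatticeState:
    """Binary strong(1)/weak(0) state vector of the synapse chain."""

    states: np.ndarray
    boundary: str = "periodic"
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if self.boundary != "periodic":
            raise ValueError("only periodic boundaries are supported")
        states = np.ascontiguousarray(self.states, dtype=np.int8)
        if states.ndim != 1 or states.size < _MIN_SITES:
            raise ValueError(f"lattice needs at least {_MIN_SITES} sites")
        if not np.isin(states, (0, 1)).all():
            raise ValueError("states must be 0 (weak) or 1 (strong)")
        object.__setattr__(self, "states", states)

    @property
    def n(self) -> int:
        return int(self.states.size)

    @property
    def strong_fraction(self) -> float:
        return float(self.states.mean())

    def type_at(self, idx: int) -> str:
        return STRONG if self.states[idx] == 1 else WEAK


@dataclass(frozen=True)
class LatticeTrajectory:
    """Strong fraction recorded on a sweep schedule."""

    sweep_times: np.ndarray
    strong_fraction: np.ndarray
    absorbed: bool = False

    def __post_init__(self) -> None:
        if len(self.sweep_times) != len(self.strong_fraction):
            raise ValueError("sweep_times and strong_fraction lengths differ")


def init_lattice(n: int, x0: float, seed: int | None = None) -> LatticeState:
    """Random lattice with each site independently strong w.p. x0."""
    if n < _MIN_SITES:
        raise ValueError(f"n = {n} must be at least {_MIN_SITES}")
    if not (0.0 <= x0 <= 1.0):
        raise ValueError(f"x0 = {x0!r} must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    states = (rng.random(n) < x0).astype(np.int8)
    return LatticeState(states=states, rng_seed=seed)


def update_once(
    state: LatticeState,
    idx: int,
    params: PlasticityParams,
    rng: np.random.Generator,
) -> LatticeState:
    """One candidate-synapse update; returns the (possibly new) state.

    Draws the two flanking neurons' activations — two uniforms consumed from
    ``rng`` in left, right order — and applies the polarity rule:
    potentiation sets the candidate strong, depression sets it weak, zero
    polarity leaves it unchanged.
    """
    if not (0 <= idx < state.n):
        raise IndexError(f"site index {idx} out of range for n = {state.n}")
    states = state.states.copy()
    u = rng.random(2)
    _kernels.lattice_sweep_block(
        states,
        np.array([idx], dtype=np.int64),
        u[:1],
        u[1:],
        params.alpha,
        params.beta,
    )
    return replace(state, states=states)


def run_sweeps(
    state: LatticeState,
    params: PlasticityParams,
    n_sweeps: int,
    record_every: int = 1,
    seed: int | None = None,
) -> LatticeTrajectory:
    """Random-sequential dynamics for n_sweeps sweeps (N updates each).

    Records the strong fraction at t = 0 and then every ``record_every``
    sweeps. The generator is seeded from ``seed`` (falling back to the
    state's rng_seed), so repeated runs are bit-identical. If an absorbing
    state is hit, the remaining schedule is filled with the constant value
    and the trajectory is flagged.
    """
    if n_sweeps < 1:
        raise ValueError("n_sweeps must be at least 1")
    if record_every < 1:
        raise ValueError("record_every must be at least 1")
    if seed is None:
        seed = state.rng_seed
    rng = np.random.default_rng(seed)
    n = state.n
    states = state.states.copy()

    n_records = n_sweeps // record_every
    times = np.arange(0, n_records + 1, dtype=float) * record_every
    fractions = np.empty(n_records + 1)
    fractions[0] = states.mean()
    absorbed = _is_absorbed(states)

    for block in range(1, n_records + 1):
        if not absorbed:
            m = record_every * n
            idx = rng.integers(0, n, size=m)
            u = rng.random((2, m))
            _kernels.lattice_sweep_block(
                states, idx, u[0], u[1], params.alpha, params.beta
            )
            absorbed = _is_absorbed(states)
        fractions[block] = states.mean()
    return LatticeTrajectory(
        sweep_times=times, strong_fraction=fractions, absorbed=absorbed
    )


def stationary_fraction(
    traj: LatticeTrajectory,
    burn_in: float = 0.5,
    n_batches: int = 10,
) -> tuple[float, float]:
    """Stationary mean and batch-means standard error of the strong fraction.

    Discards the first ``burn_in`` fraction of the record, splits the rest
    into ``n_batches`` equal batches and reports the mean together with
    std(batch means)/sqrt(n_batches), which absorbs autocorrelation at the
    batch scale.
    """
    if not (0.0 <= burn_in < 1.0):
        raise ValueError("burn_in must lie in [0, 1)")
    if n_batches < 2:
        raise ValueError("need at least 2 batches")
    values = np.asarray(traj.strong_fraction)
    start = int(np.floor(burn_in * len(values)))
    window = values[start:]
    if len(window) < 2 * n_batches:
        raise EstimationError(
            f"post-burn-in window of {len(window)} points is too short "
            f"for {n_batches} batches"
        )
    batch_size = len(window) // n_batches
    trimmed = window[: batch_size * n_batches]
    batch_means = trimmed.reshape(n_batches, batch_size).mean(axis=1)
    mean = float(trimmed.mean())
    stderr = float(batch_means.std(ddof=1) / np.sqrt(n_batches))
    return mean, stderr


def _is_absorbed(states: np.ndarray) -> bool:
    s = int(states.sum())
    return s == 0 or s == states.size
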