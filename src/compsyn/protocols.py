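"""Saturation-based timescale measurement on the mean-field dynamics.

Each protocol starts at the fixed point of the default (unperturbed)
parameters. A phase applies its signal and the state evolves until it
"saturates" at the new fixed point: the change of the strong fraction per
unit time (one sweep) falls below a tolerance, |dx/dt| < tol. The elapsed
time from phase onset to saturation is the measured timescale of that phase.
Measured this way the times are independent of the integrator step to first
order, and exactly symmetric under the strong<->weak relabeling x -> 1 - x.

For the reversal (anterograde-interference) protocol the second timescale is
measured only from the moment the trajectory first returns to the default
fixed-point level, located by linear interpolation between recorded points,
until saturation at the reversed-signal fixed point: the system first
"forgets" the original signal and only then is timed "learning" its
opposite.

Each protocol also carries an analytic counterpart: relaxation toward a
fixed point is exponential with time constant tau evaluated at the *end
state* parameters of the phase, so the analytic timescale ratio is
tau(phase-2 end state) / tau(phase-1 end state).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels
from .core import (
    PlasticityParams,
    drift_coefficients,
    relaxation_time,
    stable_fixed_point,
)
from .exceptions import (
    DegenerateParametersError,
    IntegrationInstabilityError,
    NonConvergenceError,
    ZeroShiftError,
)
from .signals import FIXED_DURATION, SignalProtocol, apply_signal

logger = logging.getLogger(__name__)

__all__ = [
    "SaturationConfig",
    "SaturationResult",
    "PhaseRecord",
    "ProtocolResult",
    "evolve_until_saturation",
    "run_protocol",
    "analytic_timescale_ratio",
]

#: Integration proceeds in segments of this many time units so that record
#: buffers stay small while max_time can remain generous.
_SEGMENT_TIME = 2000.0
#: Trajectories are recorded every ~0.1 time units.
_RECORD_INTERVAL = 0.1


@dataclass(frozen=True)
class SaturationConfig:
    """Saturation tolerance and integrator settings.

    tol: threshold on the change of the strong fraction per unit time below
    which the state counts as saturated; dt: Euler step (sweeps); max_time:
    safety cap per phase.
    """

    tol: float = 1e-6
    dt: float = 0.01
    max_time: float = 1e5

    def __post_init__(self) -> None:
        if not (0.0 < self.tol < 1.0):
            raise ValueError("tol must lie in (0, 1)")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.max_time <= 0:
            raise ValueError("max_time must be positive")


@dataclass(frozen=True)
class SaturationResult:
    """Outcome of evolving one phase to saturation."""

    t_sat: float
    x_end: float
    t: np.ndarray
    x: np.ndarray
    degenerate: bool = False


@dataclass(frozen=True)
class PhaseRecord:
    """Recorded trajectory of one protocol phase (absolute times)."""

    label: str
    s: float
    params: PlasticityParams
    t: np.ndarray
    x: np.ndarray


@dataclass(frozen=True)
class ProtocolResult:
    """Measured and analytic timescales of a two-phase protocol."""

    protocol: SignalProtocol
    default_params: PlasticityParams
    t_learn: float
    t_second: float | None
    ratio: float | None
    analytic_ratio: float | None
    phases: tuple[PhaseRecord, ...] = field(repr=False)

    def to_frame(self) -> pd.DataFrame:
        """Full trajectory as a tidy (t, x, phase) table."""
        frames = [
            pd.DataFrame({"t": p.t, "x": p.x, "phase": p.label})
            for p in self.phases
        ]
        return pd.concat(frames, ignore_index=True)

    def summary_dict(self) -> dict:
        return {
            "protocol": self.protocol.kind,
            "signal": self.protocol.signal,
            "alpha": self.default_params.alpha,
            "beta": self.default_params.beta,
            "t_learn": self.t_learn,
            "t_second": self.t_second,
            "ratio": self.ratio,
            "analytic_ratio": self.analytic_ratio,
        }


def evolve_until_saturation(
    x0: float, params: PlasticityParams, cfg: SaturationConfig
) -> SaturationResult:
    """Integrate from x0 under fixed params until |dx/dt| < tol.

    Returns the elapsed time, final state and the recorded trajectory. If
    the initial state is already saturated the result carries t_sat = 0 and
    a degeneracy flag. Raises NonConvergenceError beyond cfg.max_time.
    """
    if not (0.0 <= x0 <= 1.0):
        raise ValueError(f"x0 = {x0!r} must lie in [0, 1]")
    c0, c1, c2, c3 = drift_coefficients(params)
    dt = cfg.dt
    stride = max(1, int(round(_RECORD_INTERVAL / dt)))
    seg_steps = max(stride, int(round(_SEGMENT_TIME / dt)))
    max_steps_total = int(np.ceil(cfg.max_time / dt))

    t_chunks: list[np.ndarray] = []
    x_chunks: list[np.ndarray] = []
    x = float(x0)
    steps_done = 0
    first = True
    while True:
        budget = min(seg_steps, max_steps_total - steps_done)
        out_step = np.empty(budget // stride + 3, dtype=np.int64)
        out_x = np.empty_like(out_step, dtype=float)
        status, n_steps, x, n_rec = _kernels.euler_saturate(
            c0, c1, c2, c3, x, dt, cfg.tol, budget, stride, out_step, out_x
        )
        skip = 0 if first else 1  # later segments repeat the previous endpoint
        t_chunks.append((steps_done + out_step[skip:n_rec]) * dt)
        x_chunks.append(out_x[skip:n_rec].copy())
        steps_done += n_steps
        if status == 2:
            raise IntegrationInstabilityError(
                f"Euler step left [0, 1] (dt={dt}); reduce dt"
            )
        if status == 0:
            degenerate = first and n_steps == 0
            t = np.concatenate(t_chunks)
            xs = np.concatenate(x_chunks)
            return SaturationResult(
                t_sat=steps_done * dt,
                x_end=float(x),
                t=t,
                x=xs,
                degenerate=degenerate,
            )
        if steps_done >= max_steps_total:
            raise NonConvergenceError(
                f"no saturation within max_time = {cfg.max_time} "
                f"(tol = {cfg.tol}, params = {params})"
            )
        first = False


def run_protocol(
    default_params: PlasticityParams,
    protocol: SignalProtocol,
    cfg: SaturationConfig | None = None,
) -> ProtocolResult:
    """Run a signal protocol from the default fixed point.

    Phase 1 measures the learning time to saturation under the shifted
    parameters. For de-adaptation and downscaling, phase 2 starts from the
    learned state and measures its own saturation time. For reversal, phase
    2 is timed from the first crossing of the default fixed-point level.
    """
    cfg = cfg or SaturationConfig()
    phase_params = [apply_signal(default_params, p.s) for p in protocol.phases]
    if protocol.phases[0].s == 0:
        raise ZeroShiftError("phase-1 signal is zero; learning time undefined")

    x_default = stable_fixed_point(default_params)
    records: list[PhaseRecord] = []

    res1 = _run_phase(x_default, phase_params[0], protocol.phases[0], cfg)
    if res1.degenerate:
        raise DegenerateParametersError(
            "perturbed fixed point coincides with the default state; "
            "learning time undefined"
        )
    t_learn = res1.t_sat
    records.append(
        PhaseRecord(
            label="phase1",
            s=protocol.phases[0].s,
            params=phase_params[0],
            t=res1.t,
            x=res1.x,
        )
    )
    logger.info(
        "phase 1 (s=%+.4g) saturated at t=%.4g, x=%.6g",
        protocol.phases[0].s, t_learn, res1.x_end,
    )

    if len(protocol.phases) == 1:
        return ProtocolResult(
            protocol=protocol,
            default_params=default_params,
            t_learn=t_learn,
            t_second=None,
            ratio=None,
            analytic_ratio=None,
            phases=tuple(records),
        )

    phase2 = protocol.phases[1]
    res2 = _run_phase(res1.x_end, phase_params[1], phase2, cfg)
    if res2.degenerate:
        raise DegenerateParametersError(
            "phase-2 fixed point coincides with the learned state; "
            "second timescale undefined"
        )
    records.append(
        PhaseRecord(
            label="phase2",
            s=phase2.s,
            params=phase_params[1],
            t=res2.t + t_learn,
            x=res2.x,
        )
    )
    logger.info(
        "phase 2 (s=%+.4g) saturated after t=%.4g, x=%.6g",
        phase2.s, res2.t_sat, res2.x_end,
    )

    if protocol.kind == "reversal":
        t_cross = _first_crossing(res2.t, res2.x, x_default)
        if t_cross is None:
            raise NonConvergenceError(
                "reversal trajectory never returned to the default "
                f"fixed-point level x* = {x_default:.6g}"
            )
        t_second = res2.t_sat - t_cross
    else:
        t_second = res2.t_sat

    analytic = analytic_timescale_ratio(default_params, protocol)
    return ProtocolResult(
        protocol=protocol,
        default_params=default_params,
        t_learn=t_learn,
        t_second=t_second,
        ratio=t_second / t_learn,
        analytic_ratio=analytic,
        phases=tuple(records),
    )


def analytic_timescale_ratio(
    default_params: PlasticityParams, protocol: SignalProtocol
) -> float | None:
    """Ratio of the analytic relaxation time constants of the two phases.

    Relaxation is exponential with time constant tau evaluated at the end
    state of each phase, so the ratio is tau(phase-2 params) / tau(phase-1
    params); for de-adaptation this is tau(default) / tau(signal-on).
    """
    if protocol.phases[0].s == 0:
        raise ZeroShiftError("phase-1 signal is zero; learning time undefined")
    phase_params = [apply_signal(default_params, p.s) for p in protocol.phases]
    if len(phase_params) == 1:
        return None
    return relaxation_time(phase_params[-1]) / relaxation_time(phase_params[0])


def _run_phase(x0, params, phase, cfg: SaturationConfig) -> SaturationResult:
    if phase.termination == FIXED_DURATION:
        from .core import integrate

        traj = integrate(x0, params, phase.duration, cfg.dt)
        return SaturationResult(
            t_sat=phase.duration,
            x_end=float(traj.x[-1]),
            t=traj.t,
            x=traj.x,
            degenerate=False,
        )
    return evolve_until_saturation(x0, params, cfg)


def _first_crossing(t: np.ndarray, x: np.ndarray, level: float) -> float | None:
    """Time of the first crossing of `level`, linearly interpolated."""
    d = x - level
    if d[0] == 0.0:
        return float(t[0])
    sign_change = d[:-1] * d[1:] <= 0.0
    idx = np.nonzero(sign_change)[0]
    if idx.size == 0:
        return None
    i = int(idx[0])
    if d[i + 1] == d[i]:
        return float(t[i])
    frac = d[i] / (d[i] - d[i + 1])
    return float(t[i] + frac * (t[i + 1] - t[i]))
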