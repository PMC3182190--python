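"""Signal perturbations of the plasticity parameters and protocol shapes.

A signal of strength ``s`` acts as a biasing field shifting the two
activation probabilities by equal and opposite amounts, ``(alpha, beta) ->
(alpha + s, beta - s)``. The sum alpha + beta is conserved, so perturbed
states move parallel to the alpha = 1 - beta diagonal — the line along which
the range of imposable signals is maximal. Three two-phase protocol shapes
mirror classic motor-adaptation paradigms: de-adaptation (signal, then no
signal), downscaling (signal, then half signal) and reversal / anterograde
interference (signal, then sign-reversed signal).
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import PlasticityParams
from .exceptions import InadmissibleSignalError, ZeroShiftError

__all__ = [
    "SignalPhase",
    "SignalProtocol",
    "PROTOCOL_KINDS",
    "apply_signal",
    "allowed_signal_range",
    "build_protocol",
]

PROTOCOL_KINDS = ("constant", "deadaptation", "downscaling", "reversal")

UNTIL_SATURATION = "until_saturation"
FIXED_DURATION = "fixed_duration"


@dataclass(frozen=True)
class SignalPhase:
    """One piecewise-constant signal phase.

    The phase either runs until the state saturates (the default, matching
    the measurement convention used throughout) or for a fixed duration.
    """

    s: float
    termination: str = UNTIL_SATURATION
    duration: float | None = None

    def __post_init__(self) -> None:
        if self.termination not in (UNTIL_SATURATION, FIXED_DURATION):
            raise ValueError(f"unknown termination {self.termination!r}")
        if self.termination == FIXED_DURATION:
            if self.duration is None or self.duration <= 0:
                raise ValueError("fixed_duration phases need duration > 0")
        elif self.duration is not None:
            raise ValueError("duration only applies to fixed_duration phases")


@dataclass(frozen=True)
class SignalProtocol:
    """An ordered list of signal phases of a named protocol kind."""

    kind: str
    phases: tuple[SignalPhase, ...]

    def __post_init__(self) -> None:
        if self.kind not in PROTOCOL_KINDS:
            raise ValueError(f"unknown protocol kind {self.kind!r}")
        if not self.phases:
            raise ValueError("protocol needs at least one phase")

    @property
    def signal(self) -> float:
        return self.phases[0].s


def apply_signal(params: PlasticityParams, s: float) -> PlasticityParams:
    """Shift the parameters by the signal: (alpha + s, beta - s).

    Raises InadmissibleSignalError, naming the violated bound, if either
    shifted probability leaves the open interval (0, 1).
    """
    alpha, beta = params.alpha + s, params.beta - s
    if not (0.0 < alpha < 1.0):
        raise InadmissibleSignalError(
            f"alpha + s = {alpha:.6g} falls outside (0, 1) for s = {s:.6g}"
        )
    if not (0.0 < beta < 1.0):
        raise InadmissibleSignalError(
            f"beta - s = {beta:.6g} falls outside (0, 1) for s = {s:.6g}"
        )
    try:
        return PlasticityParams(alpha, beta)
    except ValueError as exc:  # within epsilon of a boundary
        raise InadmissibleSignalError(str(exc)) from exc


def allowed_signal_range(params: PlasticityParams) -> tuple[float, float]:
    """Open interval of signal strengths s for which apply_signal succeeds.

    Intersecting 0 < alpha + s < 1 and 0 < beta - s < 1 gives
    (max(-alpha, beta - 1), min(1 - alpha, beta)); the interval length is
    maximal (equal to 1) exactly on the diagonal alpha + beta = 1.
    """
    lo = max(-params.alpha, params.beta - 1.0)
    hi = min(1.0 - params.alpha, params.beta)
    return (lo, hi)


def build_protocol(kind: str, s: float) -> SignalProtocol:
    """Build the phase list for a named protocol at signal strength s."""
    if kind not in PROTOCOL_KINDS:
        raise ValueError(f"unknown protocol kind {kind!r}")
    if kind != "constant" and s == 0:
        raise ZeroShiftError(
            "s = 0 gives a zero parameter shift; learning time undefined"
        )
    phase_values = {
        "constant": (s,),
        "deadaptation": (s, 0.0),
        "downscaling": (s, s / 2.0),
        "reversal": (s, -s),
    }[kind]
    return SignalProtocol(
        kind=kind, phases=tuple(SignalPhase(v) for v in phase_values)
    )
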