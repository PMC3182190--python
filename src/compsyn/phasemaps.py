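"""Two-dimensional timescale maps over default parameter and signal strength.

Confining the default system to the diagonal alpha + beta = 1 — where the
range of imposable signals is maximal — parametrizes it by a single value
``a`` (default params (a, 1 - a)). Sweeping ``a`` against the signal
strength ``s`` yields maps of the natural log of the protocol's
second-to-first timescale ratio, by the analytic route (pure time-constant
ratios) or the numeric route (measured saturation times). Cells where any
phase of the protocol is inadmissible, or where the measurement degenerates,
are masked.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .core import PlasticityParams, relaxation_time
from .exceptions import (
    ConfigurationError,
    DegenerateParametersError,
    InadmissibleSignalError,
    ZeroShiftError,
)
from .protocols import SaturationConfig, run_protocol, analytic_timescale_ratio
from .signals import build_protocol, apply_signal

__all__ = ["PhaseMap", "MapComparison", "rate_map", "ratio_map", "compare_maps"]


@dataclass(frozen=True)
class PhaseMap:
    """ln timescale-ratio over the (a, s) plane with an admissibility mask."""

    kind: str
    method: str
    a_grid: np.ndarray
    s_grid: np.ndarray
    log_ratio: np.ndarray
    admissible_mask: np.ndarray

    def __post_init__(self) -> None:
        for name, g in (("a_grid", self.a_grid), ("s_grid", self.s_grid)):
            if len(g) == 0 or np.any(np.diff(g) <= 0):
                raise ConfigurationError(f"{name} must be strictly increasing")
        if self.log_ratio.shape != (len(self.a_grid), len(self.s_grid)):
            raise ConfigurationError("log_ratio shape does not match grids")
        finite = np.isfinite(self.log_ratio)
        if not np.array_equal(finite, self.admissible_mask):
            raise ConfigurationError(
                "log_ratio must be finite exactly on the admissible mask"
            )

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (a, s, log_ratio, admissible)."""
        aa, ss = np.meshgrid(self.a_grid, self.s_grid, indexing="ij")
        return pd.DataFrame(
            {
                "a": aa.ravel(),
                "s": ss.ravel(),
                "log_ratio": self.log_ratio.ravel(),
                "admissible": self.admissible_mask.ravel(),
            }
        )

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, kind: str, method: str
    ) -> "PhaseMap":
        a_grid = np.unique(df["a"].to_numpy())
        s_grid = np.unique(df["s"].to_numpy())
        shape = (len(a_grid), len(s_grid))
        order = np.lexsort((df["s"].to_numpy(), df["a"].to_numpy()))
        return cls(
            kind=kind,
            method=method,
            a_grid=a_grid,
            s_grid=s_grid,
            log_ratio=df["log_ratio"].to_numpy()[order].reshape(shape),
            admissible_mask=df["admissible"].to_numpy()[order]
            .astype(bool)
            .reshape(shape),
        )


@dataclass(frozen=True)
class MapComparison:
    """Agreement summary between two maps on their joint admissible cells."""

    spearman: float
    max_abs_diff: float
    n_cells: int

    def to_dict(self) -> dict:
        return {
            "spearman": self.spearman,
            "max_abs_diff": self.max_abs_diff,
            "n_cells": self.n_cells,
        }


def rate_map(
    alpha_grid: np.ndarray, beta_grid: np.ndarray
) -> np.ndarray:
    """Relaxation rate 1/tau over the (alpha, beta) parameter plane.

    Entry [i, j] is the rate at (alpha_grid[i], beta_grid[j]); on a shared
    grid the map is symmetric under transposition (strong<->weak
    relabeling).
    """
    out = np.empty((len(alpha_grid), len(beta_grid)))
    for i, a in enumerate(alpha_grid):
        for j, b in enumerate(beta_grid):
            out[i, j] = 1.0 / relaxation_time(PlasticityParams(a, b))
    return out


def ratio_map(
    kind: str,
    a_grid: np.ndarray,
    s_grid: np.ndarray,
    method: str = "analytic",
    cfg: SaturationConfig | None = None,
) -> PhaseMap:
    """ln timescale-ratio map of a protocol over the (a, s) plane.

    method="analytic" uses the pure time-constant ratio; method="numeric"
    runs the full saturation measurement per cell. Inadmissible or
    degenerate cells are NaN and masked.
    """
    if method not in ("analytic", "numeric"):
        raise ConfigurationError(f"unknown method {method!r}")
    a_grid = np.asarray(a_grid, dtype=float)
    s_grid = np.asarray(s_grid, dtype=float)
    cfg = cfg or SaturationConfig()
    log_ratio = np.full((len(a_grid), len(s_grid)), np.nan)
    for i, a in enumerate(a_grid):
        default = PlasticityParams(a, 1.0 - a)
        for j, s in enumerate(s_grid):
            try:
                protocol = build_protocol(kind, s)
                for phase in protocol.phases:
                    apply_signal(default, phase.s)  # admissibility check
                if method == "analytic":
                    ratio = analytic_timescale_ratio(default, protocol)
                else:
                    ratio = run_protocol(default, protocol, cfg).ratio
            except (
                InadmissibleSignalError,
                ZeroShiftError,
                DegenerateParametersError,
            ):
                continue
            if ratio is not None and ratio > 0:
                log_ratio[i, j] = np.log(ratio)
    mask = np.isfinite(log_ratio)
    if not mask.any():
        raise ConfigurationError("empty admissible region for this grid")
    return PhaseMap(
        kind=kind,
        method=method,
        a_grid=a_grid,
        s_grid=s_grid,
        log_ratio=log_ratio,
        admissible_mask=mask,
    )


def compare_maps(map_a: PhaseMap, map_b: PhaseMap) -> MapComparison:
    """Rank correlation and max abs difference over jointly admissible cells."""
    if (
        not np.array_equal(map_a.a_grid, map_b.a_grid)
        or not np.array_equal(map_a.s_grid, map_b.s_grid)
        or map_a.kind != map_b.kind
    ):
        raise ValueError("maps must share grids and protocol kind")
    joint = map_a.admissible_mask & map_b.admissible_mask
    if joint.sum() < 2:
        raise ValueError("fewer than 2 jointly admissible cells")
    va, vb = map_a.log_ratio[joint], map_b.log_ratio[joint]
    rho = spearmanr(va, vb).statistic
    return MapComparison(
        spearman=float(rho),
        max_abs_diff=float(np.max(np.abs(va - vb))),
        n_cells=int(joint.sum()),
    )
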