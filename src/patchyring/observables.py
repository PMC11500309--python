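"""Observables: order parameter R, entropy production S, first-passage
times, and bond-event statistics.

R is the fraction of target bonds currently formed, quantized in multiples
of 1/n_target_bonds; R = 1 defines the assembled state.  S is the
trajectory entropy production in units of k_B, accumulated per accepted MC
move as the log-ratio of forward and reverse acceptance probabilities.  At
equilibrium its long-run rate vanishes; under the drive it grows on
average, quantifying the dissipation that buys the faster assembly.

First-passage metrics follow the censoring convention of the source
protocol: a run that never reaches the monitored event contributes its
simulation cap to the median.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import Configuration, TargetStructure
from .potentials import InteractionParams, SquareWaveDrive

__all__ = [
    "ObservableSeries",
    "BondEvent",
    "AssemblyMetrics",
    "CensoredTime",
    "order_parameter",
    "entropy_increment",
    "first_assembly_time",
    "stability_time",
    "enhancement_factor",
    "bond_phase_statistics",
    "censored_median",
]


@dataclass(frozen=True)
class BondEvent:
    """One bond formation or breakage along a trajectory."""

    time: float
    kind: str  # "formation" | "breakage"
    pair: tuple[int, int, int, int]  # (i, a, j, b), i < j
    phase: str = "none"  # drive phase at the event: high | low | none

    def __post_init__(self) -> None:
        if self.kind not in ("formation", "breakage"):
            raise ValueError(f"unknown bond event kind {self.kind!r}")


@dataclass
class ObservableSeries:
    """Time series of R, S, U plus bond events along one realization."""

    time: np.ndarray
    R: np.ndarray
    S: np.ndarray
    U: np.ndarray
    time_unit: str = "steps"  # "steps" (MC) or "ps" (MD)
    cap: float = 0.0
    first_assembly_step: int = -1  # exact event time, -1 if never
    first_break_step: int = -1
    bond_events: list[BondEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.time) and np.any(np.diff(self.time) < 0):
            raise ValueError("time axis must be non-decreasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.time, "R": self.R, "S": self.S, "U": self.U}
        )


@dataclass(frozen=True)
class CensoredTime:
    """A first-passage time with its censoring flag."""

    value: float
    censored: bool


@dataclass
class AssemblyMetrics:
    """Per-condition summary: medians of T_fas / T_stable with censoring."""

    times: list[CensoredTime]

    @property
    def median(self) -> float:
        return censored_median(self.times)

    @property
    def n_censored(self) -> int:
        return sum(t.censored for t in self.times)


def order_parameter(
    config: Configuration,
    target: TargetStructure,
    params: InteractionParams,
    adjacency: str = "state-compatible",
) -> float:
    """Fraction of target bonds formed: R in {0, 1/n, ..., 1}.

    ``state-compatible`` counts every bond present (all bonds involve
    attractive state pairs by construction, and patch saturation caps the
    count at n); ``labeled`` counts only the exact target quadruples.
    """
    from .mc import bond_indicator, current_bonds  # runtime import: no cycle

    if target.n_bonds < 1:
        raise ValueError("target must have at least one bond")
    if adjacency == "labeled":
        formed = sum(
            bond_indicator(config, i, a, j, b, params)
            for (i, a, j, b) in target.adjacency
        )
    else:
        formed = len(current_bonds(config, params))
    return min(formed, target.n_bonds) / target.n_bonds


def entropy_increment(
    case: str,
    dU: float,
    eps_drive: float,
    accepted: bool,
    temperature: float,
) -> float:
    """Entropy production of one MC move, in k_B units.

    For an accepted move, dS = ln[a(x->x')/a(x'->x)], the log-ratio of the
    (possibly drive-modified) acceptance probabilities of the move and its
    exact reverse; with symmetric proposals this is -(dU - bias)/kT, where
    bias = +eps_drive for a forming move and -eps_drive for a breaking one.
    Rejected moves contribute nothing.
    """
    if not accepted:
        return 0.0
    from .potentials import KB

    if case == "forming":
        bias = eps_drive
    elif case == "breaking":
        bias = -eps_drive
    elif case in ("persisting", "neutral"):
        bias = 0.0
    else:
        raise ValueError(f"unknown drive case {case!r}")
    return -(dU - bias) / (KB * temperature)


def first_assembly_time(series: ObservableSeries, cap: float | None = None) -> CensoredTime:
    """T_fas: earliest time with R = 1, censored at the cap if never reached."""
    if cap is None:
        cap = series.cap
    if series.first_assembly_step >= 0:
        return CensoredTime(float(series.first_assembly_step), False)
    hits = np.nonzero(series.R >= 1.0)[0]
    if len(hits):
        return CensoredTime(float(series.time[hits[0]]), False)
    return CensoredTime(float(cap), True)


def stability_time(series: ObservableSeries, cap: float | None = None) -> CensoredTime:
    """T_stable: earliest time with R < 1 for a target-initialized run."""
    if len(series.R) == 0 or series.R[0] < 1.0:
        raise ValueError("stability protocol requires a run starting at R = 1")
    if cap is None:
        cap = series.cap
    if series.first_break_step >= 0:
        return CensoredTime(float(series.first_break_step), False)
    drops = np.nonzero(series.R < 1.0)[0]
    if len(drops):
        return CensoredTime(float(series.time[drops[0]]), False)
    return CensoredTime(float(cap), True)


def censored_median(times: list[CensoredTime]) -> float:
    """Median with censored runs entered at their cap value.

    This reproduces the plateau-at-simulation-length behaviour of ensembles
    where most realizations never assemble.
    """
    if not times:
        raise ValueError("no realizations")
    return float(np.median([t.value for t in times]))


def enhancement_factor(median_eq: float, median_driven: float) -> float:
    """T_enhance = median T_fas(equilibrium) / median T_fas(driven).

    Values > 1 mean the drive accelerates assembly (fold-improvement
    convention).
    """
    if median_driven <= 0:
        raise ZeroDivisionError("driven median must be positive")
    if median_eq <= 0:
        raise ValueError("equilibrium median must be positive")
    return median_eq / median_driven


def bond_phase_statistics(
    events: list[BondEvent], drive: SquareWaveDrive | None = None
) -> dict:
    """Per-drive-phase event counts and bond lifetime statistics.

    Lifetimes pair each formation with the next breakage of the same bond;
    bonds still formed at the end of the run contribute no lifetime.
    """
    counts = {
        ("formation", "high"): 0, ("formation", "low"): 0, ("formation", "none"): 0,
        ("breakage", "high"): 0, ("breakage", "low"): 0, ("breakage", "none"): 0,
    }
    open_since: dict[tuple, float] = {}
    lifetimes: list[float] = []
    last_kind: dict[tuple, str] = {}
    for ev in sorted(events, key=lambda e: e.time):
        prev = last_kind.get(ev.pair)
        if prev == ev.kind:
            raise ValueError(
                f"events for pair {ev.pair} must alternate formation/breakage"
            )
        last_kind[ev.pair] = ev.kind
        counts[(ev.kind, ev.phase)] += 1
        if ev.kind == "formation":
            open_since[ev.pair] = ev.time
        else:
            t0 = open_since.pop(ev.pair, None)
            if t0 is not None:
                lifetimes.append(ev.time - t0)
    return {
        "counts": counts,
        "lifetimes": np.asarray(lifetimes, dtype=float),
        "mean_lifetime": float(np.mean(lifetimes)) if lifetimes else math.nan,
    }
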