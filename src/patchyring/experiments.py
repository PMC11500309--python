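"""Sweep orchestration over (eps_patch, drive) grids and region labelling.

A sweep runs seeded replicate ensembles over a grid of interaction
strengths and drive values, collecting per-realization first-passage times
into a tidy table (one row per condition x replicate, never
pre-aggregated).  The interaction-strength axis is then segmented into the
characteristic regimes:

* Region I   -- too weak to assemble: median T_fas pinned at the cap;
* Region II  -- the optimal window: T_fas drops to a plateau;
* Region III -- kinetic trapping: T_fas rises again at strong coupling.

(For target-initialized stability sweeps the analogous split is Region A,
unstable, vs Region B, stable.)
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import (
    SimulationBox,
    make_ring_target,
    random_configuration,
)
from .mc import DriveSpec, MCParams, run_mc
from .observables import first_assembly_time, stability_time
from .potentials import InteractionParams

__all__ = [
    "SweepSpec",
    "RegionLabels",
    "run_sweep",
    "segment_regions",
    "DEFAULT_BOX_EDGES",
]

#: published cubic cell edges per system size (A)
DEFAULT_BOX_EDGES = {8: 8.0, 10: 9.0, 13: 15.0, 100: 30.0}


@dataclass(frozen=True)
class SweepSpec:
    """One sweep: engine x grid x replicates, fully seeded.

    Replicate ``k`` of any condition uses seed ``base_seed + k``, so the
    whole results table is a pure function of the spec.
    """

    engine: str = "mc"
    n: int = 8
    init: str = "random"  # "random" -> T_fas, "target" -> T_stable
    eps_patch_grid: tuple[float, ...] = (10.0,)
    drive_grid: tuple[float, ...] = (0.0,)
    replicates: int = 20
    base_seed: int = 0
    cap: float = 10_000_000  # steps (MC) or ps (MD)
    temperature: float = 65.0
    box_edge: float | None = None
    boundary: str = "reflective"
    stride: int = 10_000
    adjacency: str = "state-compatible"

    def __post_init__(self) -> None:
        if self.engine not in ("mc", "md"):
            raise ValueError(f"unknown engine {self.engine!r}")
        if self.init not in ("random", "target"):
            raise ValueError(f"unknown init {self.init!r}")
        if self.replicates < 1 or not self.eps_patch_grid or not self.drive_grid:
            raise ValueError("need >= 1 replicate and non-empty grids")

    @property
    def edge(self) -> float:
        if self.box_edge is not None:
            return self.box_edge
        return DEFAULT_BOX_EDGES[self.n]


@dataclass
class RegionLabels:
    """Contiguous interaction-strength regimes and the Region II plateau."""

    eps_values: np.ndarray
    labels: list[str]  # per eps value: "I" | "II" | "III"
    plateau: float  # mean of Region II medians (nan if Region II empty)

    def label_of(self, eps: float) -> str:
        idx = int(np.argmin(np.abs(self.eps_values - eps)))
        return self.labels[idx]


def _one_realization(spec: SweepSpec, eps_patch: float, drive_val: float,
                     seed: int) -> dict:
    n_states = 1 if spec.n == 100 else (3 if spec.n % 2 else 2)
    interactions = InteractionParams().with_depth(eps_patch, n_states)
    box = SimulationBox.cubic(spec.edge, spec.boundary)
    if spec.n not in (8, 10, 13):
        raise ValueError(
            "sweeps cover the ring systems n in {8, 10, 13}; drive larger "
            "systems through run_mc/run_md directly"
        )
    _, target = make_ring_target(spec.n, box)
    if spec.init == "target":
        config = target.reference.copy()
    else:
        config = random_configuration(
            spec.n, box, min_separation=interactions.sigma_bead, seed=seed
        )

    if spec.engine == "mc":
        params = MCParams(
            temperature=spec.temperature, n_steps=int(spec.cap),
            stride=spec.stride, seed=seed,
        )
        drive = DriveSpec(drive_val, spec.adjacency)
        series, state = run_mc(
            config, target, params, interactions, drive,
            stop_at_assembly=spec.init == "random",
            stop_at_break=spec.init == "target",
        )
        srate = series.S[-1] / series.time[-1] if series.time[-1] > 0 else 0.0
    else:
        from .md import MDParams, run_md
        from .potentials import SquareWaveDrive

        params = MDParams(duration=float(spec.cap), seed=seed,
                          temperature=spec.temperature)
        sw = SquareWaveDrive(drive_val) if drive_val else None
        series, _, _ = run_md(
            config, target, params, interactions, sw,
            stop_at_assembly=spec.init == "random",
            stop_at_break=spec.init == "target",
        )
        srate = 0.0

    if spec.init == "random":
        t = first_assembly_time(series, spec.cap)
    else:
        t = stability_time(series, spec.cap)
    return {
        "eps_patch": eps_patch,
        "drive": drive_val,
        "seed": seed,
        "time": t.value,
        "censored": t.censored,
        "final_R": float(series.R[-1]),
        "mean_S_rate": float(srate),
    }


def run_sweep(spec: SweepSpec, resume_path: str | Path | None = None) -> pd.DataFrame:
    """Run all (eps_patch, drive, replicate) cells; tidy table out.

    With ``resume_path`` the table is checkpointed to CSV after every row
    and previously completed rows are skipped on restart, yielding a table
    identical to an uninterrupted run.
    """
    done: pd.DataFrame | None = None
    if resume_path is not None and Path(resume_path).exists():
        done = pd.read_csv(resume_path)
    rows: list[dict] = []
    for eps in spec.eps_patch_grid:
        for dv in spec.drive_grid:
            for k in range(spec.replicates):
                seed = spec.base_seed + k
                if done is not None:
                    hit = done[
                        (done.eps_patch == eps) & (done.drive == dv)
                        & (done.seed == seed)
                    ]
                    if len(hit):
                        rows.append(hit.iloc[0].to_dict())
                        continue
                rows.append(_one_realization(spec, eps, dv, seed))
                if resume_path is not None:
                    pd.DataFrame(rows).to_csv(resume_path, index=False)
    table = pd.DataFrame(rows)
    table["censored"] = table["censored"].astype(bool)
    return table


def condition_medians(table: pd.DataFrame) -> pd.DataFrame:
    """Median time per (eps_patch, drive) with censor counts."""
    out = (
        table.groupby(["eps_patch", "drive"])
        .agg(median_time=("time", "median"), n_censored=("censored", "sum"),
             n=("time", "size"))
        .reset_index()
    )
    return out


def segment_regions(
    eps_values: Sequence[float],
    medians: Sequence[float],
    cap: float,
    plateau_rise: float = 1.5,
    censor_frac: float = 0.95,
) -> RegionLabels:
    """Segment the eps_patch axis into Regions I / II / III.

    Region I: leading values whose median sits at the cap (>= censor_frac
    * cap).  Region III: trailing values, after the global minimum, whose
    median rises above ``plateau_rise`` times the provisional plateau (or
    returns to the cap).  Region II: everything between; its mean median is
    the reported plateau.  Labels are contiguous by construction.
    """
    eps = np.asarray(eps_values, dtype=float)
    med = np.asarray(medians, dtype=float)
    if len(eps) < 3:
        raise ValueError("region segmentation needs >= 3 grid points")
    if np.any(np.diff(eps) <= 0):
        raise ValueError("eps grid must be strictly increasing")
    m = len(eps)
    labels = ["II"] * m
    at_cap = med >= censor_frac * cap
    if at_cap.all():
        return RegionLabels(eps, ["I"] * m, float("nan"))
    # Region I: leading contiguous censored block
    i1 = 0
    while i1 < m and at_cap[i1]:
        labels[i1] = "I"
        i1 += 1
    imin = i1 + int(np.argmin(med[i1:]))
    provisional = med[imin]
    # Region III: first index after the minimum exceeding the rise threshold
    i3 = m
    for k in range(imin + 1, m):
        if med[k] > plateau_rise * provisional or at_cap[k]:
            i3 = k
            break
    for k in range(i3, m):
        labels[k] = "III"
    sel = [k for k in range(m) if labels[k] == "II"]
    plateau = float(np.mean(med[sel])) if sel else float("nan")
    return RegionLabels(eps, labels, plateau)


def region_plateau(table: pd.DataFrame, cap: float) -> tuple[RegionLabels, float]:
    """Convenience: medians -> region labels -> Region II plateau."""
    med = condition_medians(table)
    med = med[med.drive == med.drive.min()].sort_values("eps_patch")
    rl = segment_regions(med.eps_patch.values, med.median_time.values, cap)
    return rl, rl.plateau
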