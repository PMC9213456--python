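"""Virtual-cell-population orchestration.

Expands species-value x parameter-value sweeps into per-cell runs with
deterministic seeds, executes them (optionally on a local process pool —
results are independent of worker count by construction), classifies each
cell's fate (S-phase entry via the summed-cyclin rule, death via the
cleaved-PARP rule) and aggregates per-condition fractions with binomial
standard errors:

    s.e.m. = sqrt(pct * (100 - pct) / n_cells)

Dead cells are excluded from the S-phase count (a dead cell is not in
S-phase).
"""

from __future__ import annotations

import itertools
import math
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .assembly import CompiledModel
from .engine import SimulationConfig, Trajectory, apply_ligands, simulate_cell
from .errors import CellTabError

__all__ = [
    "SweepSpec",
    "RunSpec",
    "FateSummary",
    "PopulationResult",
    "expand_sweep",
    "run_population",
    "classify_sphase",
    "sem_binomial",
]


@dataclass(frozen=True)
class SweepSpec:
    """Cartesian sweep: every combination of the species-value and
    parameter-value lists, each simulated for ``num_cells`` cells."""

    base_config: SimulationConfig
    species_values: tuple[tuple[str, tuple[float, ...]], ...] = ()
    ratelaw_values: tuple[tuple[str, tuple[float, ...]], ...] = ()
    num_cells: int = 1
    base_seed: int = 0

    def __post_init__(self):
        if self.num_cells < 1:
            raise CellTabError("num_cells must be >= 1")


@dataclass(frozen=True)
class RunSpec:
    condition_index: int
    cell_index: int
    seed: int
    species_overrides: tuple[tuple[str, float], ...]
    parameter_overrides: tuple[tuple[str, float], ...]
    config: SimulationConfig


def _cell_seed(base_seed: int, condition: int, cell: int) -> int:
    """Deterministic, collision-free-in-practice per-cell seed derived by
    keying a seed sequence on (condition, cell)."""
    ss = np.random.SeedSequence(base_seed, spawn_key=(condition, cell))
    return int(ss.generate_state(1, np.uint32)[0]) % (2 ** 31)


def expand_sweep(s: SweepSpec) -> list[RunSpec]:
    """All (condition, cell) runs: Cartesian product of the value lists,
    replicated ``num_cells`` times with distinct deterministic seeds.  The
    count is ``prod(len(values)) * num_cells``; empty sweep lists yield
    ``num_cells`` runs of the base condition."""
    axes: list[list[tuple[str, str, float]]] = []
    for name, values in s.species_values:
        axes.append([("species", name, float(v)) for v in values])
    for name, values in s.ratelaw_values:
        axes.append([("parameter", name, float(v)) for v in values])
    combos = list(itertools.product(*axes)) if axes else [()]
    runs: list[RunSpec] = []
    for ci, combo in enumerate(combos):
        species = tuple((n, v) for kind, n, v in combo if kind == "species")
        params = tuple((n, v) for kind, n, v in combo if kind == "parameter")
        for cell in range(s.num_cells):
            seed = _cell_seed(s.base_seed, ci, cell)
            cfg = replace(s.base_config, seed=seed)
            runs.append(RunSpec(
                condition_index=ci, cell_index=cell, seed=seed,
                species_overrides=species, parameter_overrides=params,
                config=cfg))
    return runs


def sem_binomial(percentage: float, n_cells: int) -> float:
    """Binomial-proportion standard error of the mean, in percent."""
    if not (0.0 <= percentage <= 100.0):
        raise CellTabError(f"percentage {percentage} outside [0, 100]")
    if n_cells < 1:
        raise CellTabError("n_cells must be >= 1")
    return math.sqrt(percentage * (100.0 - percentage) / n_cells)


def classify_sphase(
    traj: Trajectory,
    cyclin_roles: Sequence[str],
    t_eval_h: float,
    threshold_nM: float = 20.0,
    any_time: bool = False,
) -> bool:
    """True iff the summed cyclin concentration strictly exceeds the
    threshold at ``t_eval_h`` (or at any recorded time up to it when
    ``any_time``)."""
    t_eval_s = t_eval_h * 3600.0
    if t_eval_s > traj.time_s[-1] + 1e-9 and traj.died_at_s is None:
        raise CellTabError(
            f"evaluation time {t_eval_h} h beyond trajectory end "
            f"{traj.time_s[-1] / 3600.0:.2f} h")
    cols = [traj.species_order.index(c) for c in cyclin_roles]
    total = traj.species[:, cols].sum(axis=1)
    if any_time:
        mask = traj.time_s <= t_eval_s + 1e-9
        return bool(np.any(total[mask] > threshold_nM))
    idx = int(np.argmin(np.abs(traj.time_s - t_eval_s)))
    return bool(total[idx] > threshold_nM)


@dataclass
class FateSummary:
    condition_index: int
    n_cells: int
    n_failed: int
    fraction_sphase_pct: float | None
    fraction_dead_pct: float
    sem_sphase_pct: float | None
    sem_dead_pct: float
    species_overrides: tuple[tuple[str, float], ...] = ()
    parameter_overrides: tuple[tuple[str, float], ...] = ()


@dataclass
class PopulationResult:
    summaries: list[FateSummary]
    fates: list[tuple[int, int, bool, bool]]  # (condition, cell, dead, sphase)
    trajectories: list[Trajectory] | None = None


def _run_one(args) -> tuple[int, int, bool, bool, Trajectory]:
    model, run, t_eval_h, keep = args
    m = model
    if run.parameter_overrides:
        m = m.with_parameters(dict(run.parameter_overrides))
    if run.species_overrides:
        m = m.with_initial_state(
            apply_ligands(m.initial_state, m, run.species_overrides))
    traj = simulate_cell(m, run.config)
    dead = traj.died_at_s is not None
    cyclins = model.roles.get("cyclins")
    sphase = False
    if cyclins is not None and not dead:
        sphase = classify_sphase(traj, cyclins, t_eval_h)
    return (run.condition_index, run.cell_index, dead, sphase,
            traj if keep else None)


def run_population(
    model: CompiledModel,
    sweep: SweepSpec,
    workers: int = 1,
    t_eval_h: float | None = None,
    keep_trajectories: bool = True,
) -> PopulationResult:
    """Execute every run of the sweep and aggregate per-condition fates.

    ``t_eval_h`` defaults to the configured duration (S-phase evaluated at
    the end of the run).  Individual run failures are recorded and the
    condition summary counts its missing cells.
    """
    runs = expand_sweep(sweep)
    if t_eval_h is None:
        t_eval_h = sweep.base_config.duration_h
    jobs = [(model, r, t_eval_h, keep_trajectories) for r in runs]
    results = []
    failures: dict[int, int] = {}
    if workers <= 1:
        for job in jobs:
            try:
                results.append(_run_one(job))
            except CellTabError:
                failures[job[1].condition_index] = \
                    failures.get(job[1].condition_index, 0) + 1
    else:
        with ProcessPoolExecutor(max_workers=workers) as pool:
            for job, res in zip(jobs, pool.map(_run_one, jobs, chunksize=4)):
                results.append(res)
    results.sort(key=lambda r: (r[0], r[1]))

    has_cyclins = model.roles.get("cyclins") is not None
    fates = [(ci, cell, dead, sphase) for ci, cell, dead, sphase, _ in results]
    trajectories = [t for *_, t in results] if keep_trajectories else None

    summaries: list[FateSummary] = []
    by_condition: dict[int, list[tuple[bool, bool]]] = {}
    for ci, _, dead, sphase in fates:
        by_condition.setdefault(ci, []).append((dead, sphase))
    cond_meta = {r.condition_index: (r.species_overrides, r.parameter_overrides)
                 for r in runs}
    for ci in sorted(by_condition):
        cells = by_condition[ci]
        n = len(cells)
        pct_dead = 100.0 * sum(d for d, _ in cells) / n
        if has_cyclins:
            pct_s = 100.0 * sum(s for _, s in cells) / n
            sem_s = sem_binomial(pct_s, n)
        else:
            pct_s = sem_s = None
        summaries.append(FateSummary(
            condition_index=ci, n_cells=n, n_failed=failures.get(ci, 0),
            fraction_sphase_pct=pct_s, fraction_dead_pct=pct_dead,
            sem_sphase_pct=sem_s, sem_dead_pct=sem_binomial(pct_dead, n),
            species_overrides=cond_meta[ci][0],
            parameter_overrides=cond_meta[ci][1]))
    return PopulationResult(summaries=summaries, fates=fates,
                            trajectories=trajectories)
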