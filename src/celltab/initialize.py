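"""Model initialization: omics-target derivation, translation-rate
calibration, starved-cell phenotype checks, parameter scans and
coordinate-wise trajectory fitting.

The central operation is :func:`calibrate_translation`: given a target
total protein concentration per gene, the model is simulated (without
ligands, deterministically) to its unstimulated steady state, the
volume-corrected total over all species carrying each gene is measured,
and each gene's translation rate constant is multiplied by
``target/current``.  For linear production-decay chains one update is
exact (steady state ``P* = k_TL m* / k_deg``); complexes converge
geometrically.  The updated rate constants and the steady-state species
concentrations together define the initialized model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .assembly import CompiledModel, observable_values
from .engine import SimulationConfig, Trajectory, simulate_cell
from .errors import CellTabError
from .genes import mpc_to_nM
from .model_io import GeneRecord

__all__ = [
    "CalibrationTargets",
    "CalibrationResult",
    "PhenotypeCriteria",
    "PhenotypeReport",
    "derive_targets",
    "calibrate_translation",
    "phenotype_check",
    "scan_parameter",
    "coordinate_fit",
    "simulate_to_steady_state",
    "gene_species_members",
    "gene_total",
    "translation_parameter_map",
]


@dataclass
class CalibrationTargets:
    """Per-gene target total protein (nM, volume-corrected to the reference
    compartment) with provenance ('measured' or 'imputed')."""

    targets_nM: dict[str, float]
    source: dict[str, str]


def derive_targets(
    genes: Sequence[GeneRecord],
    ratios: Mapping[str, float],
    volume_L: float,
) -> CalibrationTargets:
    """Targets from proteomics where measured, otherwise imputed as
    ``mrna_mpc * protein/mRNA ratio`` converted to nM."""
    targets: dict[str, float] = {}
    source: dict[str, str] = {}
    missing = []
    for g in genes:
        if g.protein_mpc is not None:
            targets[g.name] = float(mpc_to_nM(g.protein_mpc, volume_L))
            source[g.name] = "measured"
        elif g.name in ratios:
            targets[g.name] = float(mpc_to_nM(g.mrna_mpc * ratios[g.name], volume_L))
            source[g.name] = "imputed"
        else:
            missing.append(g.name)
    if missing:
        raise CellTabError(
            "genes with neither protein abundance nor an mRNA/protein ratio: "
            + ", ".join(missing))
    return CalibrationTargets(targets_nM=targets, source=source)


# ---------------------------------------------------------------------------
# steady state
# ---------------------------------------------------------------------------

def simulate_to_steady_state(
    model: CompiledModel,
    max_hours: float = 1000.0,
    exchange_interval_s: float = 300.0,
    check_hours: float = 1.0,
    rel_tol: float = 1e-8,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> np.ndarray:
    """Deterministic, unstimulated long run until stationary.

    Runs in blocks of ``check_hours`` and stops once the largest relative
    state change per hour drops below ``rel_tol`` (or at ``max_hours``).
    The default 1000-hour cap bounds the equilibration run; the
    stationarity check ends it much earlier for any relaxing model.
    """
    current = model
    state = model.initial_state.copy()
    hours_done = 0.0
    while hours_done < max_hours:
        block = min(check_hours, max_hours - hours_done)
        cfg = SimulationConfig(
            duration_h=block, deterministic=True,
            exchange_interval_s=exchange_interval_s, rtol=rtol, atol=atol)
        traj = simulate_cell(current.with_initial_state(state), cfg)
        new = traj.species[-1]
        scale = np.maximum(np.abs(new), atol * 1e3)
        delta = float(np.max(np.abs(new - state) / scale)) / block
        state = new
        hours_done += block
        if delta < rel_tol:
            break
    return state


# ---------------------------------------------------------------------------
# gene <-> species/parameter wiring
# ---------------------------------------------------------------------------

def gene_species_members(model: CompiledModel, gene: str) -> list[int]:
    """Species indices carrying ``gene`` (shared ENSEMBL identifier with the
    gene's transcript), excluding the transcript itself."""
    bundle = model.gene_bundle
    names = [g.name for g in bundle.genes]
    if gene not in names:
        raise CellTabError(f"unknown gene {gene!r}")
    g = names.index(gene)
    ti = bundle.transcript_index[g]
    if ti < 0:
        raise CellTabError(f"gene {gene!r} has no transcript species")
    ids = set(model.species_gene_ids[ti])
    if not ids:
        raise CellTabError(
            f"transcript of {gene!r} carries no ENSEMBL identifiers")
    members = [i for i in range(model.n_species)
               if i != ti and ids & set(model.species_gene_ids[i])]
    if not members:
        raise CellTabError(f"no protein species found for gene {gene!r}")
    return members


def gene_total(model: CompiledModel, state: Sequence[float], gene: str,
               reference_compartment: str = "Cytoplasm") -> float:
    """Volume-corrected total concentration over all species of a gene."""
    v_ref = model.compartment_volumes[reference_compartment]
    total = 0.0
    for i in gene_species_members(model, gene):
        v = model.compartment_volumes[model.species_compartment[i]]
        total += float(state[i]) * v / v_ref
    return total


def translation_parameter_map(model: CompiledModel) -> dict[str, str]:
    """Auto-detected gene -> global translation parameter mapping.

    The translation reaction of a gene is the (unique) reaction whose rate
    expression contains the gene's transcript symbol; its single global
    parameter is the translation rate constant.  Raises when ambiguous.
    """
    import sympy as sp

    bundle = model.gene_bundle
    params = set(model.parameter_names)
    out: dict[str, str] = {}
    for g, gene in enumerate(bundle.genes):
        ti = bundle.transcript_index[g]
        if ti < 0:
            continue
        tsym = sp.Symbol(model.species_order[ti])
        hits = []
        for j, expr in enumerate(model.rate_exprs):
            if tsym in expr.free_symbols:
                ps = [str(s) for s in expr.free_symbols if str(s) in params]
                hits.append((j, ps))
        if len(hits) != 1 or len(hits[0][1]) != 1:
            raise CellTabError(
                f"cannot auto-detect the translation parameter of gene "
                f"{gene.name!r}; pass gene_param_map explicitly")
        out[gene.name] = hits[0][1][0]
    return out


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

@dataclass
class CalibrationResult:
    model: CompiledModel
    converged: bool
    iterations: int
    totals_nM: dict[str, float]
    history: list[dict[str, float]] = field(default_factory=list)
    not_converged: list[str] = field(default_factory=list)


def calibrate_translation(
    model: CompiledModel,
    targets: CalibrationTargets,
    gene_param_map: Mapping[str, str] | None = None,
    excluded_observables: Sequence[str] = (),
    tol: float = 0.01,
    max_iter: int = 25,
    reference_compartment: str = "Cytoplasm",
    steady_state_kwargs: Mapping | None = None,
) -> CalibrationResult:
    """Iterative proportional fitting of translation rate constants.

    Genes listed (by their total observable name or gene name) in
    ``excluded_observables`` are reported but not updated.  The returned
    model carries the fitted constants and the steady-state reached as its
    new initial state.
    """
    sskw = dict(steady_state_kwargs or {})
    if gene_param_map is None:
        gene_param_map = translation_parameter_map(model)
    gene_names = [g.name for g in model.gene_bundle.genes]
    excluded = set(excluded_observables)

    def is_excluded(gene: str) -> bool:
        return gene in excluded or f"tot_{gene}" in excluded

    current = model
    history: list[dict[str, float]] = []
    totals: dict[str, float] = {}
    for it in range(1, max_iter + 1):
        ss = simulate_to_steady_state(current, **sskw)
        totals = {g: gene_total(current, ss, g, reference_compartment)
                  for g in gene_names if g in gene_param_map}
        history.append(dict(totals))
        off = {}
        for g, total in totals.items():
            target = targets.targets_nM.get(g)
            if target is None or is_excluded(g):
                continue
            if target == 0:
                continue  # handled by direct zeroing below
            if total == 0:
                raise CellTabError(
                    f"gene {g!r}: zero simulated total with nonzero target "
                    f"{target} nM; translation path is disconnected")
            if abs(total - target) > tol * target:
                off[g] = target / total
        zero_updates = {
            gene_param_map[g]: 0.0 for g in totals
            if targets.targets_nM.get(g) == 0 and not is_excluded(g)
            and current.parameter_value(gene_param_map[g]) != 0.0
        }
        if not off and not zero_updates:
            return CalibrationResult(
                model=current.with_initial_state(ss), converged=True,
                iterations=it, totals_nM=totals, history=history)
        updates = {gene_param_map[g]: current.parameter_value(gene_param_map[g]) * f
                   for g, f in off.items()}
        updates.update(zero_updates)
        # restart the next equilibration from the state just reached
        current = current.with_parameters(updates).with_initial_state(ss)
    ss = simulate_to_steady_state(current, **sskw)
    totals = {g: gene_total(current, ss, g, reference_compartment)
              for g in gene_names if g in gene_param_map}
    bad = [g for g, t in totals.items()
           if not is_excluded(g) and g in targets.targets_nM
           and targets.targets_nM[g] > 0
           and abs(t - targets.targets_nM[g]) > tol * targets.targets_nM[g]]
    return CalibrationResult(
        model=current.with_initial_state(ss), converged=not bad,
        iterations=max_iter, totals_nM=totals, history=history,
        not_converged=bad)


# ---------------------------------------------------------------------------
# phenotype checks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhenotypeCriteria:
    """Starved-cell behavior required of an initialized model over the
    horizon: no apoptosis, no S-phase entry (48 h by default)."""

    horizon_h: float = 48.0
    forbid_death: bool = True
    forbid_sphase: bool = True
    sphase_threshold_nM: float = 20.0


@dataclass
class PhenotypeReport:
    passed: bool
    died_at_s: float | None
    sphase_at_s: float | None
    notices: list[str] = field(default_factory=list)


def phenotype_check(model: CompiledModel, criteria: PhenotypeCriteria,
                    cfg: SimulationConfig | None = None) -> PhenotypeReport:
    """Deterministic unstimulated run over the horizon; flags death
    (cleaved-PARP rule) and S-phase entry (summed-cyclin rule)."""
    if cfg is None:
        cfg = SimulationConfig(duration_h=criteria.horizon_h, deterministic=True)
    traj = simulate_cell(model, cfg)
    notices: list[str] = []
    died = traj.died_at_s
    if "parp" not in model.roles:
        notices.append("death roles not configured; apoptosis check disabled")
    sphase_at = None
    cyclins = model.roles.get("cyclins")
    if cyclins is None:
        notices.append("cyclin roles not configured; S-phase check disabled")
    else:
        cols = [traj.species_order.index(c) for c in cyclins]
        total = traj.species[:, cols].sum(axis=1)
        above = np.nonzero(total > criteria.sphase_threshold_nM)[0]
        if above.size:
            sphase_at = float(traj.time_s[above[0]])
    passed = True
    if criteria.forbid_death and died is not None:
        passed = False
    if criteria.forbid_sphase and sphase_at is not None:
        passed = False
    return PhenotypeReport(passed=passed, died_at_s=died,
                           sphase_at_s=sphase_at, notices=notices)


# ---------------------------------------------------------------------------
# scans and coordinate-wise fitting
# ---------------------------------------------------------------------------

def scan_parameter(
    model: CompiledModel,
    name: str,
    low: float,
    high: float,
    n_points: int,
    criterion: Callable[[Trajectory], bool],
    cfg: SimulationConfig | None = None,
) -> tuple[float | None, list[tuple[float, bool]]]:
    """Evaluate ``criterion`` on deterministic runs over a log-uniform grid
    in ``[low, high]``; returns the smallest passing value (or None) and
    the full (value, result) table."""
    if n_points < 1:
        raise CellTabError("n_points must be >= 1")
    if n_points == 1:
        grid = np.array([low])
    else:
        if not (0 < low < high):
            raise CellTabError("scan needs 0 < low < high")
        grid = np.logspace(math.log10(low), math.log10(high), n_points)
    if cfg is None:
        cfg = SimulationConfig(duration_h=24.0, deterministic=True)
    table = []
    for v in grid:
        traj = simulate_cell(model.with_parameters({name: float(v)}), cfg)
        table.append((float(v), bool(criterion(traj))))
    passing = [v for v, ok in table if ok]
    return (min(passing) if passing else None), table


def _observable_series(model: CompiledModel, traj: Trajectory,
                       observable: str) -> np.ndarray:
    if observable in list(model.observables.columns):
        return np.array([
            observable_values(model, traj.species[i])[observable]
            for i in range(traj.n_time)
        ])
    if observable in traj.species_order:
        return traj.series(observable)
    raise CellTabError(f"unknown observable or species {observable!r}")


@dataclass
class FitResult:
    values: dict[str, float]
    sse: float
    history: list[tuple[str, float, float]]  # (parameter, chosen value, sse)


def coordinate_fit(
    model: CompiledModel,
    param_names: Sequence[str],
    reference: tuple[np.ndarray, np.ndarray],
    observable: str,
    cfg: SimulationConfig | None = None,
    log10_halfwidth: float = 2.0,
    n_grid: int = 25,
) -> FitResult:
    """Coordinate-wise grid search minimizing the trajectory SSE.

    Each parameter in order is varied over ``n_grid`` log-spaced points in
    ``[v * 10^-h, v * 10^+h]`` around its current value (the center point
    is the current value itself, so the SSE never increases); the best
    value is retained before moving on.  ``reference`` is ``(times_s,
    values)`` for the named observable or species.
    """
    ref_t, ref_v = np.asarray(reference[0], float), np.asarray(reference[1], float)
    if cfg is None:
        horizon = float(ref_t.max()) / 3600.0
        cfg = SimulationConfig(duration_h=max(horizon, 1e-3), deterministic=True)

    def sse_of(m: CompiledModel) -> float:
        traj = simulate_cell(m, cfg)
        series = _observable_series(m, traj, observable)
        sim = np.interp(ref_t, traj.time_s, series)
        return float(np.sum((sim - ref_v) ** 2))

    current = model
    values = {p: current.parameter_value(p) for p in param_names}
    best_sse = sse_of(current)
    history: list[tuple[str, float, float]] = []
    for p in param_names:
        center = current.parameter_value(p)
        offsets = np.linspace(-log10_halfwidth, log10_halfwidth, n_grid)
        grid = center * 10.0 ** offsets
        best_v = center
        for v in grid:
            trial = current.with_parameters({p: float(v)})
            s = sse_of(trial)
            if s < best_sse:
                best_sse, best_v = s, float(v)
        current = current.with_parameters({p: best_v})
        values[p] = best_v
        history.append((p, best_v, best_sse))
    return FitResult(values=values, sse=best_sse, history=history)
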