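"""Single-cell simulation loop: stiff ODE integration interleaved with the
gene-expression module at a fixed exchange interval (30 s by default).

In hybrid mode (``deterministic=False``) the stochastic module samples gene
switching and mRNA birth/death each window and the transcript species in
the ODE state are overwritten with the new copy numbers (converted to nM in
each transcript's home compartment).  In deterministic mode the transcripts
follow the expected-value window update instead and the run is
seed-independent; it corresponds to an average cell.

A cell dies when the cleaved-PARP role species strictly exceeds the PARP
role species; the simulation then stops at the end of the offending window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .assembly import CompiledModel
from .errors import SimulationError
from . import genes as ge

__all__ = [
    "DoseEvent",
    "SimulationConfig",
    "Trajectory",
    "simulate_cell",
    "apply_ligands",
    "check_death",
]


@dataclass(frozen=True)
class DoseEvent:
    """Set the listed species to the given nM at ``time_h`` (snapped to the
    nearest exchange-window boundary)."""

    time_h: float
    ligands: tuple[tuple[str, float], ...]


@dataclass(frozen=True)
class SimulationConfig:
    duration_h: float
    deterministic: bool = False
    ligands: tuple[tuple[str, float], ...] = ()
    doses: tuple[DoseEvent, ...] = ()
    exchange_interval_s: float = 30.0
    seed: int | None = None
    record_stride: int = 1
    rtol: float = 1e-6
    atol: float = 1e-9
    negative_clamp: float = 1e-6  # clamp values in (-clamp, 0); abort below
    max_step_failures: str = "raise"
    label: str = ""

    def __post_init__(self):
        if self.duration_h <= 0:
            raise SimulationError("duration_h must be > 0")
        if self.exchange_interval_s <= 0:
            raise SimulationError("exchange_interval_s must be > 0")
        if self.record_stride < 1:
            raise SimulationError("record_stride must be >= 1")


@dataclass
class Trajectory:
    """The three output matrices of one run: time points in seconds, species
    concentrations (nM) per time point, and gene activation states per
    window; plus the death time if the cell died."""

    time_s: np.ndarray
    species: np.ndarray      # n_time x n_species
    gene_states: np.ndarray  # n_time x n_genes (active copies)
    species_order: list[str]
    gene_order: list[str]
    died_at_s: float | None = None

    @property
    def n_time(self) -> int:
        return len(self.time_s)

    def series(self, species_name: str) -> np.ndarray:
        return self.species[:, self.species_order.index(species_name)]

    def at_time(self, t_s: float) -> np.ndarray:
        """State at the recorded point nearest ``t_s`` (must be within one
        exchange interval)."""
        idx = int(np.argmin(np.abs(self.time_s - t_s)))
        return self.species[idx]


def apply_ligands(state: np.ndarray, model: CompiledModel,
                  ligands: Sequence[tuple[str, float]]) -> np.ndarray:
    """Return a copy of ``state`` with the listed species set to the given
    nM values; all other entries untouched."""
    out = np.asarray(state, float).copy()
    index = model.species_index
    for name, conc in ligands:
        if name not in index:
            raise SimulationError(f"unknown ligand species {name!r}")
        out[index[name]] = float(conc)
    return out


def check_death(state: Sequence[float], model: CompiledModel) -> bool:
    """True iff cleaved-PARP strictly exceeds PARP; False (check disabled)
    when the role species are not configured on the model."""
    parp = model.roles.get("parp")
    cparp = model.roles.get("cleaved_parp")
    if parp is None or cparp is None:
        return False
    index = model.species_index
    return float(state[index[cparp]]) > float(state[index[parp]])


def _integrate_window(model: CompiledModel, state: np.ndarray, dt: float,
                      t0: float, cfg: SimulationConfig) -> np.ndarray:
    rhs = lambda t, y: model.evaluate_rhs(y)
    sol = solve_ivp(rhs, (0.0, dt), state, method="LSODA",
                    rtol=cfg.rtol, atol=cfg.atol, t_eval=(dt,))
    if not sol.success:
        raise SimulationError(
            f"integrator failure at t = {t0:.1f} s: {sol.message}")
    out = sol.y[:, -1]
    neg = out < 0
    if neg.any():
        worst = float(out.min())
        if worst < -cfg.negative_clamp:
            raise SimulationError(
                f"negative concentration {worst:.3e} nM beyond tolerance at "
                f"t = {t0 + dt:.1f} s")
        out = np.where(neg, 0.0, out)
    return out


def simulate_cell(model: CompiledModel, cfg: SimulationConfig,
                  rng: np.random.Generator | None = None) -> Trajectory:
    """Run one cell and return its :class:`Trajectory`.

    Ligands in ``cfg.ligands`` overwrite the initial state at t = 0;
    additional :class:`DoseEvent`s fire at later window boundaries
    (two-phase protocols such as pre-conditioning followed by treatment).
    """
    bundle = model.gene_bundle
    interval = cfg.exchange_interval_s
    n_windows = int(round(cfg.duration_h * 3600.0 / interval))
    if n_windows < 1:
        raise SimulationError("duration shorter than one exchange interval")

    if rng is None:
        rng = np.random.default_rng(cfg.seed)

    state = apply_ligands(model.initial_state, model, cfg.ligands)
    dose_at: dict[int, tuple[tuple[str, float], ...]] = {}
    for dose in cfg.doses:
        w = int(round(dose.time_h * 3600.0 / interval))
        dose_at.setdefault(w, ())
        dose_at[w] = dose_at[w] + tuple(dose.ligands)

    # transcript bookkeeping
    t_idx = np.asarray(bundle.transcript_index, dtype=int)
    has_t = t_idx >= 0
    t_vol = np.ones(bundle.n_genes)
    for g in range(bundle.n_genes):
        if has_t[g]:
            comp = model.species_compartment[t_idx[g]]
            t_vol[g] = model.compartment_volumes[comp]

    gstate = ge.initial_gene_state(bundle, rng=rng,
                                   deterministic=cfg.deterministic)
    mrna_real = gstate.mrna.astype(float)  # deterministic-mode state
    f_active = np.array([
        g.k_activation / (g.k_activation + g.k_inactivation)
        if (g.k_activation + g.k_inactivation) > 0 else 0.0
        for g in bundle.genes
    ])
    copy_numbers = np.array([g.copy_number for g in bundle.genes], float)

    def write_transcripts(st: np.ndarray) -> None:
        counts = mrna_real if cfg.deterministic else gstate.mrna
        for g in range(bundle.n_genes):
            if has_t[g]:
                st[t_idx[g]] = ge.mpc_to_nM(counts[g], t_vol[g])

    if bundle.n_genes:
        write_transcripts(state)

    def gene_snapshot() -> np.ndarray:
        if cfg.deterministic:
            return copy_numbers * f_active
        return gstate.active.astype(float)

    n_rec = n_windows // cfg.record_stride + 1
    times = np.empty(n_rec)
    species_mat = np.empty((n_rec, model.n_species))
    gene_mat = np.empty((n_rec, bundle.n_genes))
    times[0] = 0.0
    species_mat[0] = state
    gene_mat[0] = gene_snapshot()
    rec = 1

    died_at = None
    for w in range(n_windows):
        t0 = w * interval
        if w in dose_at:
            state = apply_ligands(state, model, dose_at[w])
        state = _integrate_window(model, state, interval, t0, cfg)

        if bundle.n_genes:
            rates = ge.effective_transcription_rates(bundle, state)
            if cfg.deterministic:
                mrna_real = ge.expected_window_update(
                    mrna_real, bundle, rates, interval)
            else:
                gstate = ge.step_gene_states(gstate, bundle, interval, rng)
                gstate = ge.step_mrna_counts(gstate, bundle, rates, interval, rng)
            write_transcripts(state)

        if (w + 1) % cfg.record_stride == 0:
            times[rec] = t0 + interval
            species_mat[rec] = state
            gene_mat[rec] = gene_snapshot()
            rec += 1

        if check_death(state, model):
            died_at = t0 + interval
            break

    times = times[:rec]
    species_mat = species_mat[:rec]
    gene_mat = gene_mat[:rec]
    return Trajectory(
        time_s=times,
        species=species_mat,
        gene_states=gene_mat,
        species_order=list(model.species_order),
        gene_order=[g.name for g in bundle.genes],
        died_at_s=died_at,
    )


def save_trajectory(traj: Trajectory, prefix: str | "os.PathLike") -> list[str]:
    """Write a trajectory as TSV (``<prefix>_species.tsv``,
    ``<prefix>_genes.tsv``) plus a compact ``.npz`` archive."""
    import pandas as pd
    from pathlib import Path

    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = []
    df = pd.DataFrame(traj.species, columns=traj.species_order)
    df.insert(0, "time_s", traj.time_s)
    p = prefix.with_name(prefix.name + "_species.tsv")
    df.to_csv(p, sep="\t", index=False)
    paths.append(str(p))
    if traj.gene_order:
        dg = pd.DataFrame(traj.gene_states, columns=traj.gene_order)
        dg.insert(0, "time_s", traj.time_s)
        p = prefix.with_name(prefix.name + "_genes.tsv")
        dg.to_csv(p, sep="\t", index=False)
        paths.append(str(p))
    p = prefix.with_name(prefix.name + ".npz")
    np.savez(p, time_s=traj.time_s, species=traj.species,
             gene_states=traj.gene_states,
             died_at_s=np.array(np.nan if traj.died_at_s is None else traj.died_at_s))
    paths.append(str(p))
    return paths
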