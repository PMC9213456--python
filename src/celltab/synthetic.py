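"""Toy-model fixture generator.

Emits complete, valid model-definition sets in the TSV dialects with
analytically known behavior, so the compiler, the stochastic module, the
hybrid loop, calibration and the population layer can all be exercised
without any external model files.

The default toy mirrors the four-compartment layout of a mammalian cell
(Cytoplasm, Mitochondria, Nucleus, Extracellular with realistic volume
orders of magnitude) and contains, per gene, a telegraph gene with a
transcript species ``m_<G>``, a translated protein ``p_<G>`` (formula-type
translation law, so both compiler branches are covered) and first-order
protein decay (mass-action).  Optional blocks add a cross-compartment
ligand/receptor binding step (exercising the V_c/V_e correction), a
Michaelis-Menten complex-clearance law, Hill regulation edges, a
PARP/cleaved-PARP death pair driven by a tunable cleavage reaction, and a
cyclin triple driven by tunable zeroth-order induction.

Default rates describe a slow-switching mammalian gene: 2 gene copies,
symmetric switching at 5e-3 /s, constitutive transcription 0.01 mpc/s per
active copy, mRNA half-life ~2 h (1e-4 /s), translation 1e-3 /s and
protein half-life ~19 h (1e-5 /s), giving a stationary mean of 100 mRNA
molecules and ~10^4 protein copies per cell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import CellTabError
from .genes import N_AVOGADRO, mpc_to_nM
from .model_io import (
    CompartmentRecord,
    GeneRecord,
    ModelInputSet,
    ReactionRecord,
    RegulationEntry,
    SpeciesRecord,
    write_input_set,
)

__all__ = ["ToySpec", "RegEdge", "make_toy_model", "analytic_reference",
           "random_toy_spec"]

_COMPARTMENTS = (
    CompartmentRecord("Cytoplasm", 5.25e-12, "GO:0005737"),
    CompartmentRecord("Mitochondria", 3.675e-13, "GO:0005739"),
    CompartmentRecord("Nucleus", 1.755e-12, "GO:0005634"),
    CompartmentRecord("Extracellular", 5.0e-5, "GO:0005576"),
)


@dataclass(frozen=True)
class RegEdge:
    """Hill regulation of ``gene`` transcription by species ``regulator``;
    positive ``hill`` activates, negative represses."""

    gene: str
    regulator: str
    hill: float
    half_max_nM: float


@dataclass(frozen=True)
class ToySpec:
    n_genes: int = 3
    include_ligand_receptor: bool = True
    include_death_pair: bool = True
    include_cyclin_triple: bool = True
    regulation_edges: tuple[RegEdge, ...] = ()
    # telegraph / expression rates (scalars, or one value per gene)
    gene_copy_number: int | tuple[int, ...] = 2
    k_activation: float | tuple[float, ...] = 5e-3
    k_inactivation: float | tuple[float, ...] = 5e-3
    k_transcription_const: float | tuple[float, ...] = 1e-2
    k_transcription_max: float | tuple[float, ...] = 2e-2
    k_mrna_degradation: float | tuple[float, ...] = 1e-4
    k_translation: float | tuple[float, ...] = 1e-3
    k_protein_degradation: float | tuple[float, ...] = 1e-5
    # signaling block
    ligand_nM: float = 10.0
    receptor_nM: float = 50.0
    k_bind: float = 1e-3      # 1/(nM s), extracellular reaction
    k_unbind: float = 1e-3    # 1/s
    k_cat: float = 0.1        # MM clearance of the complex, nM/s
    k_M: float = 50.0         # nM
    # death pair
    parp_nM: float = 100.0
    k_cleave: float = 0.0     # 1/s; 0 = cell never dies
    # cyclin triple
    k_cyclin_production: float = 4e-4  # nM/s, zeroth order
    k_cyclin_degradation: float = 1e-4

    def per_gene(self, name: str) -> tuple:
        v = getattr(self, name)
        if isinstance(v, (int, float)):
            return tuple([v] * self.n_genes)
        if len(v) != self.n_genes:
            raise CellTabError(
                f"{name}: expected {self.n_genes} per-gene values, got {len(v)}")
        return tuple(v)


def _gene_names(spec: ToySpec) -> list[str]:
    return [f"G{i + 1}" for i in range(spec.n_genes)]


def analytic_reference(spec: ToySpec) -> dict:
    """Closed-form stationary moments for the linear production-decay motifs.

    Returns per-gene mean mRNA (mpc and nM) and steady protein (nM), plus
    cyclin steady states when present.  Regulated genes are flagged
    unsupported (their occupancy depends on simulated protein levels; only
    the x = B half-occupancy identity is analytic).
    """
    names = _gene_names(spec)
    regulated = {e.gene for e in spec.regulation_edges}
    v_cyt = _COMPARTMENTS[0].volume_L
    out: dict = {"genes": {}, "formulas": {
        "mean_mrna_mpc": "n_copies * k_act/(k_act+k_inact) * k_tc / k_deg",
        "steady_protein_nM": "k_translation * mrna_nM / k_protein_degradation",
    }}
    copies = spec.per_gene("gene_copy_number")
    k_on = spec.per_gene("k_activation")
    k_off = spec.per_gene("k_inactivation")
    k_tc = spec.per_gene("k_transcription_const")
    k_dm = spec.per_gene("k_mrna_degradation")
    k_tl = spec.per_gene("k_translation")
    k_dp = spec.per_gene("k_protein_degradation")
    for g, name in enumerate(names):
        if name in regulated:
            out["genes"][name] = {"supported": False,
                                  "reason": "transcription is regulated"}
            continue
        f = k_on[g] / (k_on[g] + k_off[g]) if (k_on[g] + k_off[g]) > 0 else 0.0
        mean_mpc = copies[g] * f * k_tc[g] / k_dm[g] if k_dm[g] > 0 else math.inf
        mean_nM = float(mpc_to_nM(mean_mpc, v_cyt))
        protein = k_tl[g] * mean_nM / k_dp[g] if k_dp[g] > 0 else math.inf
        out["genes"][name] = {
            "supported": True,
            "active_fraction": f,
            "mean_mrna_mpc": mean_mpc,
            "mean_mrna_nM": mean_nM,
            "steady_protein_nM": protein,
        }
    if spec.include_cyclin_triple:
        steady = spec.k_cyclin_production / spec.k_cyclin_degradation
        out["cyclin_steady_nM"] = steady
        out["cyclin_sum_nM"] = 3 * steady
    return out


def make_toy_model(spec: ToySpec, directory: str | Path | None = None) -> ModelInputSet:
    """Build the toy :class:`ModelInputSet`; also writes the TSV files when
    ``directory`` is given.  Initial conditions are placed at the analytic
    steady state of each motif, so unstimulated deterministic trajectories
    start flat and hybrid runs start at stationarity."""
    names = _gene_names(spec)
    v_cyt = _COMPARTMENTS[0].volume_L
    copies = spec.per_gene("gene_copy_number")
    k_on = spec.per_gene("k_activation")
    k_off = spec.per_gene("k_inactivation")
    k_tc = spec.per_gene("k_transcription_const")
    k_tm = spec.per_gene("k_transcription_max")
    k_dm = spec.per_gene("k_mrna_degradation")
    k_tl = spec.per_gene("k_translation")
    k_dp = spec.per_gene("k_protein_degradation")

    genes: list[GeneRecord] = []
    species: list[SpeciesRecord] = []
    reactions: list[ReactionRecord] = []
    stoich: dict[str, dict[str, int]] = {}

    def add_reaction(rec: ReactionRecord, changes: dict[str, int]) -> None:
        reactions.append(rec)
        stoich[rec.name] = changes

    for g, name in enumerate(names):
        f = k_on[g] / (k_on[g] + k_off[g]) if (k_on[g] + k_off[g]) > 0 else 0.0
        mean_mpc = copies[g] * f * k_tc[g] / k_dm[g] if k_dm[g] > 0 else 0.0
        mrna_nM = float(mpc_to_nM(mean_mpc, v_cyt))
        protein_nM = k_tl[g] * mrna_nM / k_dp[g] if k_dp[g] > 0 else 0.0
        protein_mpc = protein_nM * (N_AVOGADRO * v_cyt) / 1e9
        ens = f"ENSG_{name}"
        genes.append(GeneRecord(
            name=name, copy_number=copies[g], mrna_mpc=mean_mpc,
            k_inactivation=k_off[g], k_activation=k_on[g],
            k_transcription_const=k_tc[g], k_transcription_max=k_tm[g],
            k_mrna_degradation=k_dm[g], protein_mpc=protein_mpc,
            protein_half_life=(math.log(2) / k_dp[g] if k_dp[g] > 0 else None),
            k_translation=k_tl[g],
        ))
        species.append(SpeciesRecord(f"m_{name}", "Cytoplasm", mrna_nM, (ens,)))
        species.append(SpeciesRecord(f"p_{name}", "Cytoplasm", protein_nM, (ens,)))
        add_reaction(
            ReactionRecord(name=f"vTL{g + 1}", compartment="Cytoplasm",
                           formula=f"kTL * m_{name}",
                           local_parameters=(("kTL", k_tl[g]),)),
            {f"p_{name}": 1},
        )
        add_reaction(
            ReactionRecord(name=f"vDP{g + 1}", compartment="Cytoplasm",
                           rate_constant=k_dp[g]),
            {f"p_{name}": -1},
        )

    if spec.include_ligand_receptor:
        species.append(SpeciesRecord("L", "Extracellular", spec.ligand_nM, ()))
        species.append(SpeciesRecord("R", "Cytoplasm", spec.receptor_nM, ()))
        species.append(SpeciesRecord("C", "Cytoplasm", 0.0, ()))
        add_reaction(
            ReactionRecord(name="vBind", compartment="Extracellular",
                           rate_constant=spec.k_bind),
            {"L": -1, "R": -1, "C": 1},
        )
        add_reaction(
            ReactionRecord(name="vUnbind", compartment="Cytoplasm",
                           rate_constant=spec.k_unbind),
            {"C": -1, "L": 1, "R": 1},
        )
        add_reaction(
            ReactionRecord(name="vClear", compartment="Cytoplasm",
                           formula="kcat * C / (kM + C)",
                           local_parameters=(("kcat", spec.k_cat),
                                             ("kM", spec.k_M))),
            {"C": -1},
        )

    if spec.include_death_pair:
        species.append(SpeciesRecord("PARP", "Cytoplasm", spec.parp_nM, ()))
        species.append(SpeciesRecord("cPARP", "Cytoplasm", 0.0, ()))
        add_reaction(
            ReactionRecord(name="vCleave", compartment="Cytoplasm",
                           rate_constant=spec.k_cleave),
            {"PARP": -1, "cPARP": 1},
        )

    if spec.include_cyclin_triple:
        steady = spec.k_cyclin_production / spec.k_cyclin_degradation
        for cyc in ("CycE", "CycA", "CycB"):
            species.append(SpeciesRecord(cyc, "Cytoplasm", steady, ()))
            add_reaction(
                ReactionRecord(name=f"vProd{cyc}", compartment="Cytoplasm",
                               rate_constant=spec.k_cyclin_production),
                {cyc: 1},
            )
            add_reaction(
                ReactionRecord(name=f"vDeg{cyc}", compartment="Cytoplasm",
                               rate_constant=spec.k_cyclin_degradation),
                {cyc: -1},
            )

    species_names = [s.name for s in species]
    for e in spec.regulation_edges:
        if e.gene not in names:
            raise CellTabError(f"regulation edge references unknown gene {e.gene!r}")
        if e.regulator not in species_names:
            raise CellTabError(
                f"regulation edge references unknown species {e.regulator!r}")

    reaction_names = [r.name for r in reactions]
    smat = pd.DataFrame(0, index=species_names, columns=reaction_names, dtype=int)
    for rname, changes in stoich.items():
        for sname, coeff in changes.items():
            smat.loc[sname, rname] = coeff

    regulators = sorted({e.regulator for e in spec.regulation_edges}) or ["p_G1"]
    regulation = [
        RegulationEntry(gene=e.gene, regulator=e.regulator, hill=e.hill,
                        half_max_nM=e.half_max_nM)
        for e in spec.regulation_edges
    ]

    obs_cols: dict[str, list[int]] = {}
    for g, name in enumerate(names):
        obs_cols[f"tot_{name}"] = [1 if s.name == f"p_{name}" else 0 for s in species]
    if spec.include_cyclin_triple:
        obs_cols["total_cyclin"] = [
            1 if s.name in ("CycE", "CycA", "CycB") else 0 for s in species]
    observables = pd.DataFrame(obs_cols, index=species_names, dtype=int)

    m = ModelInputSet(
        genes=genes,
        species=species,
        reactions=reactions,
        stoichiometry=smat,
        regulation=regulation,
        regulator_columns=regulators,
        compartments=list(_COMPARTMENTS),
        observables=observables,
        initializer=None,
        regulation_gene_order=[g.name for g in genes],
    )
    if directory is not None:
        write_input_set(m, directory)
    return m


def random_toy_spec(seed: int) -> ToySpec:
    """A randomized toy specification with per-gene rates sampled
    log-uniformly from realistic ranges; used for property tests."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(1, 5))

    def logu(lo: float, hi: float, size: int) -> tuple[float, ...]:
        return tuple(float(x) for x in
                     np.exp(rng.uniform(np.log(lo), np.log(hi), size)))

    edges: tuple[RegEdge, ...] = ()
    if n >= 2 and rng.random() < 0.5:
        hill = float(rng.choice([-2.0, -1.0, 1.0, 2.0]))
        edges = (RegEdge(gene=f"G{n}", regulator="p_G1", hill=hill,
                         half_max_nM=float(np.exp(rng.uniform(0, 3)))),)
    return ToySpec(
        n_genes=n,
        include_ligand_receptor=bool(rng.random() < 0.8),
        include_death_pair=bool(rng.random() < 0.7),
        include_cyclin_triple=bool(rng.random() < 0.7),
        regulation_edges=edges,
        gene_copy_number=tuple(int(c) for c in rng.integers(1, 5, n)),
        k_activation=logu(1e-3, 1e-2, n),
        k_inactivation=logu(1e-3, 1e-2, n),
        k_transcription_const=logu(5e-3, 5e-2, n),
        k_transcription_max=logu(1e-2, 1e-1, n),
        k_mrna_degradation=logu(5e-5, 1e-3, n),
        k_translation=logu(1e-4, 1e-2, n),
        k_protein_degradation=logu(5e-6, 1e-4, n),
        ligand_nM=float(np.exp(rng.uniform(0, 3))),
        receptor_nM=float(np.exp(rng.uniform(2, 5))),
        k_bind=float(np.exp(rng.uniform(np.log(1e-4), np.log(1e-2)))),
        k_unbind=float(np.exp(rng.uniform(np.log(1e-4), np.log(1e-2)))),
        k_cleave=0.0,
    )
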