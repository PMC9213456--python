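"""Compile a validated model-definition set into an executable reaction network.

The compiler turns a :class:`~celltab.model_io.ModelInputSet` into a
:class:`CompiledModel`: ordered species with initial concentrations, an
integer stoichiometric matrix, one symbolic rate expression per reaction,
a globally renamed parameter table, and the gene-expression rate bundle
used by the stochastic module.

Units and the compartment-correction rule
-----------------------------------------
All concentrations are nM relative to each species' *home* compartment and
time is in seconds.  A rate law is evaluated in its reaction's home
compartment: a mass-action law for reaction *j* with rate constant *k* is

    v_j = k * prod_reactants (c_i * V_home(i) / V_rxn(j)) ** |S_ij|

so reactant concentrations are volume-corrected into the reaction
compartment (for a cytoplasmic receptor consumed by an extracellular
binding reaction this is the factor V_c/V_e).  Formula laws are taken
verbatim; any cross-compartment correction inside a formula is the model
author's responsibility.  Species derivatives are scaled back into each
species' home compartment:

    dc_i/dt = sum_j S_ij * v_j * V_rxn(j) / V_home(i)

Parameter renaming
------------------
Local rate-law parameters are renamed to global names in ascending
rate-law order: reaction *j* (1-based) contributes ``k<j>`` for a
mass-action constant or ``k<j>_<i>`` for the *i*-th formula parameter
(order of first appearance).  The mapping is a bijection from
(reaction, local name) pairs to global names and is exported as the
ParamsAll report.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import sympy as sp

from .errors import CompileError
from .model_io import (
    GeneRecord,
    ModelInputSet,
    RegulationEntry,
    validate_input_set,
)

__all__ = [
    "CompiledModel",
    "GeneBundle",
    "compile_model",
    "export_model_text",
    "export_parameter_report",
    "export_sbml",
    "import_sbml",
    "observable_values",
]

_IDENT = re.compile(r"[A-Za-z_][A-Za-z0-9_]*")


@dataclass(frozen=True)
class GeneBundle:
    """OmicsData-derived rates plus regulation wiring for the stochastic module.

    ``regulation[g]`` lists ``(species_index, hill, half_max_nM)`` for gene
    ``g`` (signed Hill coefficient: positive activates, negative represses);
    ``transcript_index[g]`` is the species index of gene ``g``'s transcript,
    or -1 when the model has no matching transcript species.
    """

    genes: tuple[GeneRecord, ...]
    regulation: tuple[tuple[tuple[int, float, float], ...], ...]
    transcript_index: tuple[int, ...]

    @property
    def n_genes(self) -> int:
        return len(self.genes)


@dataclass
class CompiledModel:
    species_order: list[str]
    initial_state: np.ndarray
    stoichiometry: np.ndarray  # species x reactions, int
    reaction_names: list[str]
    rate_exprs: list[sp.Expr]
    parameter_table: pd.DataFrame  # global_name, reaction, local_name, value
    param_values: np.ndarray
    compartment_volumes: dict[str, float]
    compartment_go: dict[str, str]
    species_compartment: list[str]
    species_gene_ids: list[tuple[str, ...]]
    reaction_compartment: list[str]
    gene_bundle: GeneBundle
    observables: pd.DataFrame
    roles: dict[str, object] = field(default_factory=dict)
    _rate_fn: Callable | None = field(default=None, repr=False, compare=False)
    _scale: np.ndarray | None = field(default=None, repr=False, compare=False)

    # -- pickling: the lambdified function is rebuilt on demand -------------
    def __getstate__(self):
        state = self.__dict__.copy()
        state["_rate_fn"] = None
        return state

    @property
    def n_species(self) -> int:
        return len(self.species_order)

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_names)

    @property
    def species_index(self) -> dict[str, int]:
        return {n: i for i, n in enumerate(self.species_order)}

    @property
    def parameter_names(self) -> list[str]:
        return list(self.parameter_table["global_name"])

    def parameter_value(self, name: str) -> float:
        idx = self.parameter_names.index(name)
        return float(self.param_values[idx])

    def with_parameters(self, updates: Mapping[str, float]) -> "CompiledModel":
        """Copy of the model with the named global parameters replaced."""
        names = self.parameter_names
        vals = self.param_values.copy()
        for k, v in updates.items():
            if k not in names:
                raise CompileError(f"unknown global parameter {k!r}")
            vals[names.index(k)] = float(v)
        table = self.parameter_table.copy()
        table["value"] = vals
        out = replace(self, param_values=vals, parameter_table=table)
        out._rate_fn = self._rate_fn  # expressions unchanged, reuse compiled fn
        return out

    def with_initial_state(self, state: np.ndarray) -> "CompiledModel":
        out = replace(self, initial_state=np.asarray(state, float).copy())
        out._rate_fn = self._rate_fn
        return out

    # -- numerics -----------------------------------------------------------
    def _build_rate_fn(self) -> Callable:
        s_syms = [sp.Symbol(n) for n in self.species_order]
        p_syms = [sp.Symbol(n) for n in self.parameter_names]
        return sp.lambdify((s_syms, p_syms), self.rate_exprs, modules="numpy")

    @property
    def rate_fn(self) -> Callable:
        if self._rate_fn is None:
            self._rate_fn = self._build_rate_fn()
        return self._rate_fn

    @property
    def _deriv_scale(self) -> np.ndarray:
        """S_ij * V_rxn(j) / V_home(i), precomputed."""
        if self._scale is None:
            v_rxn = np.array([self.compartment_volumes[c]
                              for c in self.reaction_compartment])
            v_home = np.array([self.compartment_volumes[c]
                               for c in self.species_compartment])
            self._scale = self.stoichiometry * (v_rxn[None, :] / v_home[:, None])
        return self._scale

    def evaluate_rates(self, state: Sequence[float]) -> np.ndarray:
        state = np.asarray(state, float)
        return np.asarray(self.rate_fn(state, self.param_values), float)

    def evaluate_rhs(self, state: Sequence[float], t: float = 0.0) -> np.ndarray:
        """d(state)/dt in home-compartment nM/s; autonomous in ``t``."""
        state = np.asarray(state, float)
        if state.shape != (self.n_species,):
            raise CompileError(
                f"state length {state.shape} != species count {self.n_species}")
        if not np.all(np.isfinite(state)):
            raise CompileError("non-finite entry in state vector")
        return self._deriv_scale @ self.evaluate_rates(state)


# ---------------------------------------------------------------------------
# compilation
# ---------------------------------------------------------------------------

def _sympify(formula: str, allowed: dict[str, sp.Symbol]) -> sp.Expr:
    for tok in set(_IDENT.findall(formula)):
        if tok not in allowed:
            raise CompileError(f"formula references unknown symbol {tok!r}")
    try:
        expr = sp.sympify(formula, locals=dict(allowed), evaluate=True)
    except (sp.SympifyError, SyntaxError) as exc:
        raise CompileError(f"cannot parse formula {formula!r}: {exc}") from None
    return expr


def _build_gene_bundle(m: ModelInputSet, species_index: dict[str, int]) -> GeneBundle:
    transcripts = m.transcript_species()
    reg_by_gene: dict[str, list[tuple[int, float, float]]] = {g.name: [] for g in m.genes}
    for e in m.regulation:
        reg_by_gene[e.gene].append((species_index[e.regulator], e.hill, e.half_max_nM))
    return GeneBundle(
        genes=tuple(m.genes),
        regulation=tuple(tuple(reg_by_gene[g.name]) for g in m.genes),
        transcript_index=tuple(
            species_index.get(transcripts.get(g.name, ""), -1) for g in m.genes
        ),
    )


def _default_roles(species_names: Iterable[str]) -> dict[str, object]:
    names = set(species_names)
    roles: dict[str, object] = {}
    if {"PARP", "cPARP"} <= names:
        roles["parp"] = "PARP"
        roles["cleaved_parp"] = "cPARP"
    cyclins = [n for n in ("CycE", "CycA", "CycB") if n in names]
    if len(cyclins) == 3:
        roles["cyclins"] = tuple(cyclins)
    return roles


def compile_model(m: ModelInputSet, check: bool = True) -> CompiledModel:
    """Compile a model-definition set; validates first unless ``check=False``."""
    if check:
        validate_input_set(m, strict=True)

    species_names = m.species_names
    species_index = {n: i for i, n in enumerate(species_names)}
    volumes = m.compartment_volumes
    s_syms = {n: sp.Symbol(n) for n in species_names}
    stoich = m.stoichiometry.to_numpy(dtype=int)

    exprs: list[sp.Expr] = []
    rows = []  # parameter table rows
    values: list[float] = []
    for j, r in enumerate(m.reactions):
        v_rxn = volumes[r.compartment]
        if r.is_mass_action:
            k = r.rate_constant
            if k < 0:
                raise CompileError(
                    f"reaction {r.name!r}: negative mass-action constant {k}")
            gname = f"k{j + 1}"
            rows.append((gname, r.name, "k", float(k)))
            values.append(float(k))
            expr: sp.Expr = sp.Symbol(gname)
            for i in np.nonzero(stoich[:, j] < 0)[0]:
                ratio = volumes[m.species[i].compartment] / v_rxn
                term = s_syms[species_names[i]] * sp.Float(ratio) \
                    if ratio != 1.0 else s_syms[species_names[i]]
                expr = expr * term ** int(-stoich[i, j])
            exprs.append(expr)
        else:
            allowed = dict(s_syms)
            sub = {}
            for i, (local, val) in enumerate(r.local_parameters):
                gname = f"k{j + 1}_{i + 1}"
                rows.append((gname, r.name, local, float(val)))
                values.append(float(val))
                allowed[local] = sp.Symbol(local)
                sub[sp.Symbol(local)] = sp.Symbol(gname)
            expr = _sympify(r.formula, allowed).xreplace(sub)
            exprs.append(expr)

    table = pd.DataFrame(rows, columns=["global_name", "reaction", "local_name", "value"])

    model = CompiledModel(
        species_order=species_names,
        initial_state=np.array([s.initial_nM for s in m.species], float),
        stoichiometry=stoich,
        reaction_names=m.reaction_names,
        rate_exprs=exprs,
        parameter_table=table,
        param_values=np.array(values, float),
        compartment_volumes=dict(volumes),
        compartment_go={c.name: c.go_term for c in m.compartments},
        species_compartment=[s.compartment for s in m.species],
        species_gene_ids=[s.gene_ids for s in m.species],
        reaction_compartment=[r.compartment for r in m.reactions],
        gene_bundle=_build_gene_bundle(m, species_index),
        observables=m.observables.copy(),
        roles=_default_roles(species_names),
    )
    return model


# ---------------------------------------------------------------------------
# observables
# ---------------------------------------------------------------------------

def observable_values(
    c: CompiledModel,
    state: Sequence[float],
    reference_compartment: str = "Cytoplasm",
) -> pd.Series:
    """Volume-corrected observable totals at ``state``.

    Observable *j* is ``sum_i O_ij * c_i * V_home(i) / V_ref`` with the
    cytoplasm as the default reference compartment.
    """
    state = np.asarray(state, float)
    v_ref = c.compartment_volumes[reference_compartment]
    v_home = np.array([c.compartment_volumes[x] for x in c.species_compartment])
    weighted = state * v_home / v_ref
    membership = c.observables.to_numpy(dtype=float)
    return pd.Series(membership.T @ weighted, index=list(c.observables.columns))


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------

def export_model_text(c: CompiledModel) -> str:
    """Human-readable listing of every model element, in stable order."""
    lines = ["# compartments (name, volume_L)"]
    for name, vol in c.compartment_volumes.items():
        go = c.compartment_go.get(name, "")
        lines.append(f"compartment {name} = {vol!r}" + (f"  # {go}" if go else ""))
    lines.append("")
    lines.append("# species (name, compartment, initial_nM)")
    for i, name in enumerate(c.species_order):
        lines.append(
            f"species {name} in {c.species_compartment[i]} = "
            f"{float(c.initial_state[i])!r}")
    lines.append("")
    lines.append("# reactions (name, compartment, rate law)")
    for j, name in enumerate(c.reaction_names):
        lines.append(
            f"reaction {name} in {c.reaction_compartment[j]}: "
            f"v = {sp.sstr(c.rate_exprs[j])}")
    lines.append("")
    lines.append("# parameters (global name, value)")
    for _, row in c.parameter_table.iterrows():
        lines.append(f"parameter {row.global_name} = {float(row.value)!r}"
                     f"  # {row.reaction}:{row.local_name}")
    return "\n".join(lines) + "\n"


def export_parameter_report(c: CompiledModel, path: str | Path | None = None) -> pd.DataFrame:
    """The ParamsAll table: every global parameter with its source reaction,
    original local name, and value.  Written as TSV when ``path`` is given."""
    table = c.parameter_table.copy()
    if path is not None:
        table.to_csv(path, sep="\t", index=False)
    return table


# -- SBML -------------------------------------------------------------------

def _sanitize_id(name: str) -> str:
    out = re.sub(r"[^A-Za-z0-9_]", "_", name)
    if not re.match(r"[A-Za-z_]", out):
        out = "_" + out
    return out


def sanitize_ids(names: Sequence[str]) -> dict[str, str]:
    """Deterministic SBML-safe identifier mapping; collisions get suffixes."""
    mapping: dict[str, str] = {}
    used: set[str] = set()
    for n in names:
        s = _sanitize_id(n)
        base, k = s, 2
        while s in used:
            s = f"{base}__{k}"
            k += 1
        mapping[n] = s
        used.add(s)
    return mapping


def export_sbml(c: CompiledModel, path: str | Path | None = None) -> str:
    """Export as an annotated SBML Level 3 Version 2 document.

    The kinetic-law math of reaction *j* is ``v_j * V_rxn(j)`` (the rate
    expression times the reaction compartment size symbol), so an SBML
    interpreter using concentration units reproduces
    ``dc_i/dt = S_ij v_j V_rxn / V_home(i)`` exactly.  Compartments carry GO
    annotations and species their ENSEMBL gene identifiers.  Returns the
    document as a string; also written to ``path`` when given.
    """
    import libsbml

    ids = sanitize_ids(list(c.compartment_volumes) + c.species_order
                       + c.reaction_names + c.parameter_names)

    doc = libsbml.SBMLDocument(3, 2)
    model = doc.createModel()
    model.setId("celltab_model")
    model.setTimeUnits("second")

    for name, vol in c.compartment_volumes.items():
        comp = model.createCompartment()
        comp.setId(ids[name])
        comp.setName(name)
        comp.setSize(vol)
        comp.setConstant(True)
        comp.setSpatialDimensions(3)
        go = c.compartment_go.get(name, "")
        if go:
            comp.setMetaId("meta_" + ids[name])
            cv = libsbml.CVTerm(libsbml.BIOLOGICAL_QUALIFIER)
            cv.setBiologicalQualifierType(libsbml.BQB_IS)
            cv.addResource("https://identifiers.org/" + go)
            comp.addCVTerm(cv)

    for i, name in enumerate(c.species_order):
        s = model.createSpecies()
        s.setId(ids[name])
        s.setName(name)
        s.setCompartment(ids[c.species_compartment[i]])
        s.setInitialConcentration(float(c.initial_state[i]))
        s.setHasOnlySubstanceUnits(False)
        s.setBoundaryCondition(False)
        s.setConstant(False)
        if c.species_gene_ids[i]:
            s.setMetaId("meta_" + ids[name])
            cv = libsbml.CVTerm(libsbml.BIOLOGICAL_QUALIFIER)
            cv.setBiologicalQualifierType(libsbml.BQB_IS_ENCODED_BY)
            for gid in c.species_gene_ids[i]:
                cv.addResource("https://identifiers.org/ensembl/" + gid)
            s.addCVTerm(cv)

    for gname, rxn, local, value in c.parameter_table.itertuples(index=False):
        p = model.createParameter()
        p.setId(ids[gname])
        p.setName(f"{rxn}:{local}")
        p.setValue(float(value))
        p.setConstant(True)

    rename = {sp.Symbol(n): sp.Symbol(ids[n])
              for n in c.species_order + c.parameter_names
              if ids[n] != n}
    for j, rname in enumerate(c.reaction_names):
        r = model.createReaction()
        r.setId(ids[rname])
        r.setName(rname)
        r.setReversible(False)
        stoich_col = c.stoichiometry[:, j]
        in_stoich: set[str] = set()
        for i in np.nonzero(stoich_col)[0]:
            coeff = int(stoich_col[i])
            ref = r.createReactant() if coeff < 0 else r.createProduct()
            ref.setSpecies(ids[c.species_order[i]])
            ref.setStoichiometry(abs(coeff))
            ref.setConstant(True)
            in_stoich.add(c.species_order[i])
        expr = c.rate_exprs[j]
        for sym in expr.free_symbols:
            n = str(sym)
            if n in in_stoich or n not in set(c.species_order):
                continue
            mod = r.createModifier()
            mod.setSpecies(ids[n])
        math_expr = expr.xreplace(rename) * sp.Symbol(ids[c.reaction_compartment[j]])
        formula = sp.sstr(math_expr)
        ast = libsbml.parseL3Formula(formula.replace("**", "^"))
        if ast is None:
            raise CompileError(f"cannot encode kinetic law for {rname!r}: {formula}")
        kl = r.createKineticLaw()
        kl.setMath(ast)

    sbml = libsbml.writeSBMLToString(doc)
    if path is not None:
        Path(path).write_text(sbml)
    return sbml


def import_sbml(source: str | Path) -> CompiledModel:
    """Re-import an SBML document produced by :func:`export_sbml`.

    Recovers species order, compartments, the parameter table (original
    reaction/local names from the parameter ``name`` attribute), the
    stoichiometric matrix, and the rate expressions (kinetic law divided by
    the reaction-compartment size).  The gene-expression bundle is not part
    of SBML and comes back empty.
    """
    import libsbml

    text = str(source)
    if "\n" not in text and Path(text).exists():
        text = Path(text).read_text()
    doc = libsbml.readSBMLFromString(text)
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR):
        raise CompileError("SBML document has read errors: "
                           + doc.getErrorLog().toString())
    model = doc.getModel()

    comp_vol: dict[str, float] = {}
    comp_go: dict[str, str] = {}
    id2comp: dict[str, str] = {}
    for comp in (model.getCompartment(i) for i in range(model.getNumCompartments())):
        name = comp.getName() or comp.getId()
        id2comp[comp.getId()] = name
        comp_vol[name] = comp.getSize()
        go = ""
        for t in range(comp.getNumCVTerms()):
            cv = comp.getCVTerm(t)
            for ri in range(cv.getNumResources()):
                res = cv.getResourceURI(ri)
                if "/GO:" in res or res.startswith("https://identifiers.org/GO"):
                    go = res.rsplit("/", 1)[-1]
        comp_go[name] = go

    species_order: list[str] = []
    initial: list[float] = []
    sp_comp: list[str] = []
    gene_ids: list[tuple[str, ...]] = []
    id2name: dict[str, str] = {}
    for s in (model.getSpecies(i) for i in range(model.getNumSpecies())):
        name = s.getName() or s.getId()
        id2name[s.getId()] = name
        species_order.append(name)
        initial.append(s.getInitialConcentration())
        sp_comp.append(id2comp[s.getCompartment()])
        ids = []
        for t in range(s.getNumCVTerms()):
            cv = s.getCVTerm(t)
            for ri in range(cv.getNumResources()):
                res = cv.getResourceURI(ri)
                if "/ensembl/" in res:
                    ids.append(res.rsplit("/", 1)[-1])
        gene_ids.append(tuple(ids))

    rows = []
    values = []
    param_ids = []
    for p in (model.getParameter(i) for i in range(model.getNumParameters())):
        label = p.getName() or ":"
        rxn, _, local = label.partition(":")
        rows.append((p.getId(), rxn, local, p.getValue()))
        values.append(p.getValue())
        param_ids.append(p.getId())

    sp_index = {s: i for i, s in enumerate(species_order)}
    n_rxn = model.getNumReactions()
    stoich = np.zeros((len(species_order), n_rxn), dtype=int)
    rxn_names: list[str] = []
    rxn_comp: list[str] = []
    exprs: list[sp.Expr] = []
    back = {sid: sp.Symbol(name) for sid, name in id2name.items()}
    for pid, row in zip(param_ids, rows):
        back[pid] = sp.Symbol(pid)
    for j in range(n_rxn):
        r = model.getReaction(j)
        rxn_names.append(r.getName() or r.getId())
        for ref in (r.getReactant(i) for i in range(r.getNumReactants())):
            stoich[sp_index[id2name[ref.getSpecies()]], j] -= int(ref.getStoichiometry())
        for ref in (r.getProduct(i) for i in range(r.getNumProducts())):
            stoich[sp_index[id2name[ref.getSpecies()]], j] += int(ref.getStoichiometry())
        formula = libsbml.formulaToL3String(r.getKineticLaw().getMath())
        allowed = {sid: sp.Symbol(sid) for sid in id2comp}
        allowed.update({sid: sp.Symbol(sid) for sid in id2name})
        allowed.update({pid: sp.Symbol(pid) for pid in param_ids})
        expr_full = sp.sympify(formula.replace("^", "**"), locals=allowed)
        comp_id = None
        for cid in id2comp:
            if sp.Symbol(cid) in expr_full.free_symbols:
                comp_id = cid
        # the trailing compartment factor is the reaction compartment
        candidates = [cid for cid in id2comp if sp.Symbol(cid) in expr_full.free_symbols]
        if len(candidates) == 1:
            comp_id = candidates[0]
        elif not candidates:
            raise CompileError(f"kinetic law of {rxn_names[-1]!r} lacks a "
                               "compartment factor")
        rxn_comp.append(id2comp[comp_id])
        expr = sp.cancel(expr_full / sp.Symbol(comp_id))
        # map sanitized ids back to original names
        remap = {sp.Symbol(sid): sp.Symbol(name) for sid, name in id2name.items()
                 if sid != name}
        exprs.append(expr.xreplace(remap))

    table = pd.DataFrame(rows, columns=["global_name", "reaction", "local_name", "value"])
    observables = pd.DataFrame(index=species_order)
    return CompiledModel(
        species_order=species_order,
        initial_state=np.asarray(initial, float),
        stoichiometry=stoich,
        reaction_names=rxn_names,
        rate_exprs=exprs,
        parameter_table=table,
        param_values=np.asarray(values, float),
        compartment_volumes=comp_vol,
        compartment_go=comp_go,
        species_compartment=sp_comp,
        species_gene_ids=gene_ids,
        reaction_compartment=rxn_comp,
        gene_bundle=GeneBundle(genes=(), regulation=(), transcript_index=()),
        observables=observables,
        roles=_default_roles(species_order),
    )
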