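"""Read, validate and write the tab-separated model-definition dialects.

A model is defined by eight TSV files, each with one header row:

``OmicsData``
    One row per gene: HGNC name, gene copy number, mRNA copies per cell
    (mpc), gene inactivation rate (1/s), gene activation rate (1/s),
    constitutive transcription rate (molecules/s per active copy), maximal
    transcription rate (molecules/s per active copy), mRNA degradation rate
    (1/s), protein mpc (may be empty), protein half-life in seconds (may be
    empty), translation rate constant (1/s).
``Species``
    One row per species: unique name, home compartment, initial
    concentration in nM (relative to the home compartment), comma-separated
    ENSEMBL gene identifiers (may be empty).  Transcripts are ordinary
    species; by convention a species named ``m_<GENE>`` is the transcript of
    OmicsData gene ``<GENE>`` (the prefix is configurable).
``Ratelaws``
    One row per reaction: unique name, home compartment, then either a
    single nonnegative number (mass-action rate constant, nM/s units implied
    by the stoichiometry) or a formula string followed by one value per
    local parameter.  Local parameter names start with ``k`` and are unique
    within the formula; their values follow in order of first appearance.
``StoichiometricMatrix``
    Species x reactions grid of integer coefficients; row order matches the
    Species file, column order matches the Ratelaws file.
``GeneReg``
    Genes x regulator-species grid; rows follow OmicsData order.  A cell is
    either ``0`` (no effect) or ``A; B`` where ``A`` is a signed Hill
    coefficient (positive = activation, negative = repression) and ``B`` the
    half-maximal concentration in nM.
``Compartments``
    One row per compartment: name, volume in liters, GO term.
``Observables``
    Species x observables 0/1 membership grid; an observable is the
    volume-corrected total over all species containing a protein.
``Initializer`` (optional)
    Ragged 11-column file driving the calibration procedure: species
    override (cols 1-2: species, nM), mRNA adjustment (cols 3-4: gene, mpc),
    parameter override (cols 5-6: parameter, value; col 7 reserved),
    excluded observable (col 8), single-parameter scan (cols 9-11: name,
    low, high).
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ModelIOError

__all__ = [
    "GeneRecord",
    "SpeciesRecord",
    "ReactionRecord",
    "RegulationEntry",
    "CompartmentRecord",
    "InitializerSpec",
    "ModelInputSet",
    "ValidationReport",
    "DEFAULT_FILENAMES",
    "read_input_set",
    "write_input_set",
    "validate_input_set",
    "parse_regulation_cell",
]

DEFAULT_FILENAMES: dict[str, str] = {
    "omics": "OmicsData.txt",
    "species": "Species.txt",
    "ratelaws": "Ratelaws.txt",
    "stoichiometry": "StoichiometricMatrix.txt",
    "regulation": "GeneReg.txt",
    "compartments": "Compartments.txt",
    "observables": "Observables.txt",
    "initializer": "Initializer.txt",
}

_MANDATORY = (
    "omics",
    "species",
    "ratelaws",
    "stoichiometry",
    "regulation",
    "compartments",
    "observables",
)

_IDENT = re.compile(r"[A-Za-z_][A-Za-z0-9_]*")


@dataclass(frozen=True)
class GeneRecord:
    """One OmicsData row: telegraph-model rates and omics abundances."""

    name: str
    copy_number: int
    mrna_mpc: float
    k_inactivation: float
    k_activation: float
    k_transcription_const: float
    k_transcription_max: float
    k_mrna_degradation: float
    protein_mpc: float | None
    protein_half_life: float | None
    k_translation: float


@dataclass(frozen=True)
class SpeciesRecord:
    name: str
    compartment: str
    initial_nM: float
    gene_ids: tuple[str, ...] = ()


@dataclass(frozen=True)
class ReactionRecord:
    """One Ratelaws row.

    Exactly one of ``rate_constant`` (mass-action) and ``formula`` is set.
    ``local_parameters`` is the ordered (name, value) list for formula laws.
    """

    name: str
    compartment: str
    rate_constant: float | None = None
    formula: str | None = None
    local_parameters: tuple[tuple[str, float], ...] = ()

    @property
    def is_mass_action(self) -> bool:
        return self.rate_constant is not None


@dataclass(frozen=True)
class RegulationEntry:
    """Regulator ``species`` acting on ``gene`` transcription.

    ``hill`` keeps the sign convention of the input grid: positive values
    denote activation, negative repression.
    """

    gene: str
    regulator: str
    hill: float
    half_max_nM: float

    @property
    def is_activator(self) -> bool:
        return self.hill > 0


@dataclass(frozen=True)
class CompartmentRecord:
    name: str
    volume_L: float
    go_term: str = ""


@dataclass(frozen=True)
class InitializerSpec:
    species_overrides: tuple[tuple[str, float], ...] = ()
    mrna_adjustments: tuple[tuple[str, float], ...] = ()
    parameter_overrides: tuple[tuple[str, float], ...] = ()
    observables_excluded: tuple[str, ...] = ()
    scan: tuple[str, float, float] | None = None


@dataclass
class ModelInputSet:
    """Parsed contents of one model-definition directory.

    ``stoichiometry`` is a species x reactions integer DataFrame whose index
    follows Species-file order and whose columns follow Ratelaws order;
    ``observables`` is a species x observables 0/1 DataFrame.
    """

    genes: list[GeneRecord]
    species: list[SpeciesRecord]
    reactions: list[ReactionRecord]
    stoichiometry: pd.DataFrame
    regulation: list[RegulationEntry]
    regulator_columns: list[str]
    compartments: list[CompartmentRecord]
    observables: pd.DataFrame
    initializer: InitializerSpec | None = None
    transcript_prefix: str = "m_"
    regulation_gene_order: list[str] = field(default_factory=list)

    # -- convenience lookups -------------------------------------------------
    @property
    def species_names(self) -> list[str]:
        return [s.name for s in self.species]

    @property
    def reaction_names(self) -> list[str]:
        return [r.name for r in self.reactions]

    @property
    def gene_names(self) -> list[str]:
        return [g.name for g in self.genes]

    @property
    def compartment_volumes(self) -> dict[str, float]:
        return {c.name: c.volume_L for c in self.compartments}

    def transcript_species(self) -> dict[str, str]:
        """Map gene name -> transcript species name (``m_<GENE>`` convention)."""
        names = set(self.species_names)
        out = {}
        for g in self.genes:
            cand = self.transcript_prefix + g.name
            if cand in names:
                out[g.name] = cand
        return out

    def __eq__(self, other: object) -> bool:  # DataFrames need .equals
        if not isinstance(other, ModelInputSet):
            return NotImplemented
        return (
            self.genes == other.genes
            and self.species == other.species
            and self.reactions == other.reactions
            and self.stoichiometry.equals(other.stoichiometry)
            and self.regulation == other.regulation
            and self.regulator_columns == other.regulator_columns
            and self.compartments == other.compartments
            and self.observables.equals(other.observables)
            and self.initializer == other.initializer
            and self.transcript_prefix == other.transcript_prefix
        )


@dataclass
class ValidationReport:
    findings: list[tuple[str, str]] = field(default_factory=list)  # (check, message)
    checks_run: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.findings

    def add(self, check: str, message: str) -> None:
        self.findings.append((check, message))

    def __str__(self) -> str:
        if self.passed:
            return f"OK ({len(self.checks_run)} checks passed)"
        lines = [f"FAILED ({len(self.findings)} findings)"]
        lines += [f"  [{c}] {m}" for c, m in self.findings]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# parsing helpers
# ---------------------------------------------------------------------------

def _read_rows(path: Path) -> list[list[str]]:
    with open(path, newline="") as fh:
        rows = [row for row in csv.reader(fh, delimiter="\t")]
    return [r for r in rows if any(cell.strip() for cell in r)]


def _num(cell: str, path: Path, row: int, col: int) -> float:
    try:
        return float(cell)
    except ValueError:
        raise ModelIOError(
            f"{path.name}: malformed numeric cell {cell!r} at row {row}, column {col}"
        ) from None


def _opt_num(cell: str, path: Path, row: int, col: int) -> float | None:
    if cell.strip() == "":
        return None
    return _num(cell, path, row, col)


def _int(cell: str, path: Path, row: int, col: int) -> int:
    v = _num(cell, path, row, col)
    if v != int(v):
        raise ModelIOError(
            f"{path.name}: expected integer, got {cell!r} at row {row}, column {col}"
        )
    return int(v)


def parse_regulation_cell(cell: str) -> tuple[float, float] | None:
    """Parse one GeneReg grid cell.

    Returns ``None`` for "0" (no effect), otherwise ``(hill, half_max)``
    where a positive Hill coefficient denotes activation and a negative one
    repression.  Raises :class:`ModelIOError` on malformed cells or a
    non-positive half-max.
    """
    text = cell.strip()
    if text in ("", "0", "0.0"):
        return None
    parts = text.split(";")
    if len(parts) != 2:
        raise ModelIOError(f"regulation cell {cell!r} is not of the form 'A; B'")
    try:
        a = float(parts[0])
        b = float(parts[1])
    except ValueError:
        raise ModelIOError(f"regulation cell {cell!r} has non-numeric A or B") from None
    if a == 0:
        return None
    if b <= 0:
        raise ModelIOError(f"regulation cell {cell!r}: half-max B must be > 0")
    return a, b


def _parse_omics(path: Path) -> list[GeneRecord]:
    rows = _read_rows(path)
    genes = []
    for i, row in enumerate(rows[1:], start=2):
        row = row + [""] * (11 - len(row))
        genes.append(
            GeneRecord(
                name=row[0].strip(),
                copy_number=_int(row[1], path, i, 2),
                mrna_mpc=_num(row[2], path, i, 3),
                k_inactivation=_num(row[3], path, i, 4),
                k_activation=_num(row[4], path, i, 5),
                k_transcription_const=_num(row[5], path, i, 6),
                k_transcription_max=_num(row[6], path, i, 7),
                k_mrna_degradation=_num(row[7], path, i, 8),
                protein_mpc=_opt_num(row[8], path, i, 9),
                protein_half_life=_opt_num(row[9], path, i, 10),
                k_translation=_num(row[10], path, i, 11),
            )
        )
    return genes


def _parse_species(path: Path) -> list[SpeciesRecord]:
    rows = _read_rows(path)
    out = []
    for i, row in enumerate(rows[1:], start=2):
        row = row + [""] * (4 - len(row))
        ids = tuple(t.strip() for t in row[3].split(",") if t.strip())
        out.append(
            SpeciesRecord(
                name=row[0].strip(),
                compartment=row[1].strip(),
                initial_nM=_num(row[2], path, i, 3),
                gene_ids=ids,
            )
        )
    return out


def _is_number(text: str) -> bool:
    try:
        float(text)
        return True
    except ValueError:
        return False


def _formula_parameters(formula: str, species_names: set[str]) -> list[str]:
    """Ordered local parameter names: identifiers starting with 'k' that are
    not species names, in order of first appearance."""
    seen: list[str] = []
    for tok in _IDENT.findall(formula):
        if tok in species_names or tok in seen:
            continue
        if tok.startswith("k"):
            seen.append(tok)
    return seen


def _parse_ratelaws(path: Path, species_names: set[str]) -> list[ReactionRecord]:
    rows = _read_rows(path)
    out = []
    for i, row in enumerate(rows[1:], start=2):
        if len(row) < 3:
            raise ModelIOError(f"{path.name}: row {i} has fewer than 3 columns")
        name, comp, law = row[0].strip(), row[1].strip(), row[2].strip()
        if _is_number(law):
            out.append(
                ReactionRecord(name=name, compartment=comp,
                               rate_constant=_num(law, path, i, 3))
            )
            continue
        params = _formula_parameters(law, species_names)
        values = [c for c in row[3:] if c.strip() != ""]
        if len(values) != len(params):
            raise ModelIOError(
                f"{path.name}: row {i} ({name}): formula declares "
                f"{len(params)} parameters {params} but {len(values)} values given"
            )
        pairs = tuple(
            (p, _num(v, path, i, 4 + j)) for j, (p, v) in enumerate(zip(params, values))
        )
        dupes = {p for p in params if params.count(p) > 1}
        if dupes:
            raise ModelIOError(
                f"{path.name}: row {i} ({name}): duplicate parameter names {sorted(dupes)}"
            )
        out.append(
            ReactionRecord(name=name, compartment=comp, formula=law,
                           local_parameters=pairs)
        )
    return out


def _parse_grid(path: Path, kind: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = [str(c) for c in df.columns]
    try:
        as_float = df.astype(float)
    except ValueError as exc:
        raise ModelIOError(f"{path.name}: malformed numeric cell in {kind} grid: {exc}")
    as_int = as_float.round().astype(int)
    if not (as_float.values == as_int.values).all():
        raise ModelIOError(f"{path.name}: non-integer entry in {kind} grid")
    return as_int


def _parse_regulation(path: Path) -> tuple[list[RegulationEntry], list[str], list[str]]:
    rows = _read_rows(path)
    header = rows[0]
    regulators = [c.strip() for c in header[1:]]
    entries: list[RegulationEntry] = []
    gene_order: list[str] = []
    for i, row in enumerate(rows[1:], start=2):
        gene = row[0].strip()
        gene_order.append(gene)
        for j, cell in enumerate(row[1:]):
            if j >= len(regulators):
                raise ModelIOError(f"{path.name}: row {i} has more cells than header columns")
            try:
                parsed = parse_regulation_cell(cell)
            except ModelIOError as exc:
                raise ModelIOError(f"{path.name}: row {i}, column {j + 2}: {exc}")
            if parsed is not None:
                entries.append(
                    RegulationEntry(gene=gene, regulator=regulators[j],
                                    hill=parsed[0], half_max_nM=parsed[1])
                )
    return entries, regulators, gene_order


def _parse_compartments(path: Path) -> list[CompartmentRecord]:
    rows = _read_rows(path)
    out = []
    for i, row in enumerate(rows[1:], start=2):
        row = row + [""] * (3 - len(row))
        out.append(
            CompartmentRecord(name=row[0].strip(),
                              volume_L=_num(row[1], path, i, 2),
                              go_term=row[2].strip())
        )
    return out


def _parse_initializer(path: Path) -> InitializerSpec:
    rows = _read_rows(path)
    species_overrides: list[tuple[str, float]] = []
    mrna_adjustments: list[tuple[str, float]] = []
    parameter_overrides: list[tuple[str, float]] = []
    excluded: list[str] = []
    scan: tuple[str, float, float] | None = None
    for i, row in enumerate(rows[1:], start=2):
        row = row + [""] * (11 - len(row))
        if row[0].strip():
            species_overrides.append((row[0].strip(), _num(row[1], path, i, 2)))
        if row[2].strip():
            mrna_adjustments.append((row[2].strip(), _num(row[3], path, i, 4)))
        if row[4].strip():
            parameter_overrides.append((row[4].strip(), _num(row[5], path, i, 6)))
        if row[7].strip():
            excluded.append(row[7].strip())
        if row[8].strip() and scan is None:
            scan = (row[8].strip(), _num(row[9], path, i, 10), _num(row[10], path, i, 11))
    return InitializerSpec(
        species_overrides=tuple(species_overrides),
        mrna_adjustments=tuple(mrna_adjustments),
        parameter_overrides=tuple(parameter_overrides),
        observables_excluded=tuple(excluded),
        scan=scan,
    )


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def read_input_set(
    directory: str | Path,
    filename_map: Mapping[str, str] | None = None,
    transcript_prefix: str = "m_",
) -> ModelInputSet:
    """Parse one model-definition directory into a :class:`ModelInputSet`.

    ``filename_map`` overrides the default file names per role (keys of
    :data:`DEFAULT_FILENAMES`).  The Initializer file is optional; all other
    files are mandatory.
    """
    directory = Path(directory)
    names = dict(DEFAULT_FILENAMES)
    if filename_map:
        names.update(filename_map)
    paths = {k: directory / v for k, v in names.items()}
    for key in _MANDATORY:
        if not paths[key].exists():
            raise ModelIOError(f"missing mandatory model file: {paths[key]}")

    genes = _parse_omics(paths["omics"])
    species = _parse_species(paths["species"])
    species_names = {s.name for s in species}
    reactions = _parse_ratelaws(paths["ratelaws"], species_names)
    stoich = _parse_grid(paths["stoichiometry"], "stoichiometric")
    regulation, regulators, reg_gene_order = _parse_regulation(paths["regulation"])
    compartments = _parse_compartments(paths["compartments"])
    observables = _parse_grid(paths["observables"], "observable membership")
    comp_names = {c.name for c in compartments}
    for s in species:
        if s.compartment not in comp_names:
            raise ModelIOError(
                f"species {s.name!r} references unknown compartment {s.compartment!r}"
            )
    for r in reactions:
        if r.compartment not in comp_names:
            raise ModelIOError(
                f"reaction {r.name!r} references unknown compartment {r.compartment!r}"
            )
    initializer = None
    if paths["initializer"].exists():
        initializer = _parse_initializer(paths["initializer"])
    return ModelInputSet(
        genes=genes,
        species=species,
        reactions=reactions,
        stoichiometry=stoich,
        regulation=regulation,
        regulator_columns=regulators,
        compartments=compartments,
        observables=observables,
        initializer=initializer,
        transcript_prefix=transcript_prefix,
        regulation_gene_order=reg_gene_order,
    )


def _fmt(value: float) -> str:
    """Full-precision numeric formatting that round-trips through float()."""
    return repr(float(value))


def write_input_set(
    m: ModelInputSet,
    directory: str | Path,
    filename_map: Mapping[str, str] | None = None,
) -> dict[str, Path]:
    """Write ``m`` back to disk in the TSV dialects; returns the paths written."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    names = dict(DEFAULT_FILENAMES)
    if filename_map:
        names.update(filename_map)
    paths = {k: directory / v for k, v in names.items()}

    def w(path: Path, rows: Iterable[Sequence[str]]) -> None:
        with open(path, "w", newline="") as fh:
            csv.writer(fh, delimiter="\t", lineterminator="\n").writerows(rows)

    rows = [["gene", "copy_number", "mrna_mpc", "k_gene_inactivation",
             "k_gene_activation", "k_transcription_const", "k_transcription_max",
             "k_mrna_degradation", "protein_mpc", "protein_half_life",
             "k_translation"]]
    for g in m.genes:
        rows.append([
            g.name, str(g.copy_number), _fmt(g.mrna_mpc), _fmt(g.k_inactivation),
            _fmt(g.k_activation), _fmt(g.k_transcription_const),
            _fmt(g.k_transcription_max), _fmt(g.k_mrna_degradation),
            "" if g.protein_mpc is None else _fmt(g.protein_mpc),
            "" if g.protein_half_life is None else _fmt(g.protein_half_life),
            _fmt(g.k_translation),
        ])
    w(paths["omics"], rows)

    rows = [["species", "compartment", "initial_nM", "ensembl_ids"]]
    for s in m.species:
        rows.append([s.name, s.compartment, _fmt(s.initial_nM), ",".join(s.gene_ids)])
    w(paths["species"], rows)

    rows = [["reaction", "compartment", "ratelaw", "parameter_values"]]
    for r in m.reactions:
        if r.is_mass_action:
            rows.append([r.name, r.compartment, _fmt(r.rate_constant)])
        else:
            rows.append([r.name, r.compartment, r.formula]
                        + [_fmt(v) for _, v in r.local_parameters])
    w(paths["ratelaws"], rows)

    m.stoichiometry.to_csv(paths["stoichiometry"], sep="\t", index_label="species")

    reg_lookup = {(e.gene, e.regulator): e for e in m.regulation}
    rows = [["gene"] + list(m.regulator_columns)]
    for g in m.genes:
        row = [g.name]
        for reg in m.regulator_columns:
            e = reg_lookup.get((g.name, reg))
            row.append("0" if e is None else f"{_fmt(e.hill)}; {_fmt(e.half_max_nM)}")
        rows.append(row)
    w(paths["regulation"], rows)

    rows = [["compartment", "volume_L", "go_term"]]
    for c in m.compartments:
        rows.append([c.name, _fmt(c.volume_L), c.go_term])
    w(paths["compartments"], rows)

    m.observables.to_csv(paths["observables"], sep="\t", index_label="species")

    written = {k: paths[k] for k in _MANDATORY}
    if m.initializer is not None:
        ini = m.initializer
        n = max(len(ini.species_overrides), len(ini.mrna_adjustments),
                len(ini.parameter_overrides), len(ini.observables_excluded),
                1 if ini.scan else 0)
        rows = [["species", "nM", "gene", "mpc", "parameter", "value",
                 "reserved", "excluded_observable", "scan_parameter",
                 "scan_low", "scan_high"]]
        for i in range(n):
            row = [""] * 11
            if i < len(ini.species_overrides):
                row[0], row[1] = ini.species_overrides[i][0], _fmt(ini.species_overrides[i][1])
            if i < len(ini.mrna_adjustments):
                row[2], row[3] = ini.mrna_adjustments[i][0], _fmt(ini.mrna_adjustments[i][1])
            if i < len(ini.parameter_overrides):
                row[4], row[5] = ini.parameter_overrides[i][0], _fmt(ini.parameter_overrides[i][1])
            if i < len(ini.observables_excluded):
                row[7] = ini.observables_excluded[i]
            if i == 0 and ini.scan is not None:
                row[8], row[9], row[10] = ini.scan[0], _fmt(ini.scan[1]), _fmt(ini.scan[2])
            rows.append(row)
        w(paths["initializer"], rows)
        written["initializer"] = paths["initializer"]
    return written


def validate_input_set(m: ModelInputSet, strict: bool = False) -> ValidationReport:
    """Cross-check the mutual consistency of the parsed files.

    Order-sensitive checks: the stoichiometric-matrix rows must equal the
    Species file names in the same order, its columns the Ratelaws names in
    the same order, Observables rows the Species order, and GeneReg rows the
    OmicsData gene order.  With ``strict=True`` any finding raises.
    """
    rep = ValidationReport()

    def check(name: str, ok: bool, message: str) -> None:
        rep.checks_run.append(name)
        if not ok:
            rep.add(name, message)

    sp_names = m.species_names
    check("species-stoich-rows", list(m.stoichiometry.index) == sp_names,
          f"stoichiometric-matrix rows ({len(m.stoichiometry.index)}) do not match "
          f"Species rows ({len(sp_names)}) in order")
    check("ratelaws-stoich-cols", list(m.stoichiometry.columns) == m.reaction_names,
          f"stoichiometric-matrix columns ({len(m.stoichiometry.columns)}) do not "
          f"match Ratelaws rows ({len(m.reaction_names)}) in order")
    check("observables-rows", list(m.observables.index) == sp_names,
          "Observables rows do not match Species rows in order")
    ok_entries = m.observables.isin([0, 1]).all().all() if m.observables.size else True
    check("observables-binary", bool(ok_entries), "Observables entries must be 0 or 1")

    comp_names = {c.name for c in m.compartments}
    dupes = {c.name for c in m.compartments
             if sum(1 for x in m.compartments if x.name == c.name) > 1}
    check("compartments-unique", not dupes, f"duplicate compartment names: {sorted(dupes)}")
    for c in m.compartments:
        check("compartment-volume", c.volume_L > 0,
              f"compartment {c.name!r} has non-positive volume {c.volume_L}")

    seen = set()
    for s in m.species:
        check("species-unique", s.name not in seen, f"duplicate species name {s.name!r}")
        seen.add(s.name)
        check("species-compartment", s.compartment in comp_names,
              f"species {s.name!r} in unknown compartment {s.compartment!r}")
        check("species-initial", s.initial_nM >= 0,
              f"species {s.name!r} has negative initial concentration")

    sp_set = set(sp_names)
    for r in m.reactions:
        check("reaction-compartment", r.compartment in comp_names,
              f"reaction {r.name!r} in unknown compartment {r.compartment!r}")
        if r.formula is not None:
            local = {p for p, _ in r.local_parameters}
            for tok in set(_IDENT.findall(r.formula)):
                check("formula-symbols", tok in sp_set or tok in local,
                      f"reaction {r.name!r}: formula references undeclared "
                      f"symbol {tok!r}")

    gene_set = set(m.gene_names)
    seen_g = set()
    for g in m.genes:
        check("genes-unique", g.name not in seen_g, f"duplicate gene name {g.name!r}")
        seen_g.add(g.name)
        for attr in ("k_inactivation", "k_activation", "k_transcription_const",
                     "k_transcription_max", "k_mrna_degradation", "k_translation"):
            check("gene-rates", getattr(g, attr) >= 0,
                  f"gene {g.name!r}: {attr} is negative")
        check("gene-copies", g.copy_number >= 0,
              f"gene {g.name!r}: negative copy number")
    if m.regulation_gene_order:
        check("regulation-gene-order", m.regulation_gene_order == m.gene_names,
              "GeneReg rows do not follow OmicsData gene order")
    for e in m.regulation:
        check("regulation-gene", e.gene in gene_set,
              f"regulation row gene {e.gene!r} not in OmicsData")
        check("regulation-species", e.regulator in sp_set,
              f"regulator species {e.regulator!r} not in Species")
    for reg in m.regulator_columns:
        check("regulator-columns", reg in sp_set,
              f"GeneReg column species {reg!r} not in Species")

    if strict and not rep.passed:
        raise ModelIOError(str(rep))
    return rep
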