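import dataclasses

import numpy as np
import pytest

from celltab import (
    ToySpec,
    compile_model,
    export_model_text,
    export_parameter_report,
    export_sbml,
    import_sbml,
    make_toy_model,
    observable_values,
)
from celltab.errors import CompileError
from celltab.model_io import ReactionRecord
from celltab.synthetic import random_toy_spec

from oracles import oracle_rates, oracle_rhs


def random_states(model, n, seed=0):
    rng = np.random.default_rng(seed)
    return rng.uniform(0.0, 100.0, size=(n, model.n_species))


@pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
def test_rhs_matches_hand_assembled_oracle(seed):
    """The compiled RHS agrees with a brute-force per-reaction summation
    built directly from the input files (no sympy) at random states."""
    m = make_toy_model(random_toy_spec(seed))
    model = compile_model(m)
    for state in random_states(model, 25, seed):
        ours = model.evaluate_rhs(state)
        ref = oracle_rhs(m, state)
        denom = np.maximum(np.abs(ref), 1e-30)
        mask = ref != 0
        assert np.max(np.abs(ours - ref)[mask] / denom[mask]) < 1e-12
        assert np.allclose(ours[~mask], 0.0, atol=1e-20)


def test_cross_compartment_concentration_is_volume_corrected(toy_set):
    """A cytoplasmic reactant in an extracellular reaction enters the law
    multiplied by V_c/V_e."""
    model = compile_model(toy_set)
    j = model.reaction_names.index("vBind")
    state = model.initial_state.copy()
    idx = model.species_index
    state[idx["L"]] = 2.0
    state[idx["R"]] = 30.0
    vc = model.compartment_volumes["Cytoplasm"]
    ve = model.compartment_volumes["Extracellular"]
    k = model.parameter_value("k7")
    expected = k * 2.0 * (30.0 * vc / ve)
    assert model.evaluate_rates(state)[j] == pytest.approx(expected, rel=1e-14)


def test_extracellular_volume_scaling_rescales_binding_flux(default_spec):
    """Rescaling V_e by lambda rescales the cross-compartment binding flux
    by exactly 1/lambda."""
    lam = 3.7
    m1 = make_toy_model(default_spec)
    m2 = make_toy_model(default_spec)
    m2.compartments = [
        dataclasses.replace(c, volume_L=c.volume_L * lam)
        if c.name == "Extracellular" else c
        for c in m2.compartments
    ]
    mod1, mod2 = compile_model(m1), compile_model(m2)
    j = mod1.reaction_names.index("vBind")
    state = mod1.initial_state
    v1 = mod1.evaluate_rates(state)[j]
    v2 = mod2.evaluate_rates(state)[j]
    assert v2 * lam == pytest.approx(v1, rel=1e-12)


def test_zero_mass_action_constant_gives_zero_flux(toy_set):
    model = compile_model(toy_set)  # vCleave has k = 0 by default
    j = model.reaction_names.index("vCleave")
    for state in random_states(model, 5):
        assert model.evaluate_rates(state)[j] == 0.0
        assert oracle_rates(toy_set, state)[j] == 0.0


def test_closed_binding_system_conserves_mass(toy_set):
    """For A + B <-> C (unit stoichiometry, single effective moiety) the
    conserved combinations have zero derivative."""
    model = compile_model(toy_set)
    idx = model.species_index
    vols = {n: model.compartment_volumes[c]
            for n, c in zip(model.species_order, model.species_compartment)}
    for state in random_states(model, 20, seed=3):
        rhs = model.evaluate_rhs(state)
        # receptor moiety: R + C in amount units (both cytoplasmic)
        amount_rate = rhs[idx["R"]] * vols["R"] + rhs[idx["C"]] * vols["C"]
        # vClear consumes C; subtract its contribution to isolate binding
        j = model.reaction_names.index("vClear")
        clear = model.evaluate_rates(state)[j] * vols["C"]
        assert amount_rate + clear == pytest.approx(0.0, abs=1e-12 * max(abs(clear), 1.0))
        # PARP moiety is fully closed: PARP + cPARP amounts constant
        parp_rate = rhs[idx["PARP"]] * vols["PARP"] + rhs[idx["cPARP"]] * vols["cPARP"]
        assert parp_rate == pytest.approx(0.0, abs=1e-18)


def test_zero_state_without_zeroth_order_reactions(linear_model):
    state = np.zeros(linear_model.n_species)
    assert np.all(linear_model.evaluate_rhs(state) == 0.0)


def test_rhs_rejects_nonfinite_state(toy_model):
    state = toy_model.initial_state.copy()
    state[0] = np.nan
    with pytest.raises(CompileError):
        toy_model.evaluate_rhs(state)


def test_negative_mass_action_constant_is_fatal(toy_set):
    broken = dataclasses.replace(toy_set)
    broken.reactions = list(toy_set.reactions)
    j = [i for i, r in enumerate(broken.reactions) if r.is_mass_action][0]
    broken.reactions[j] = dataclasses.replace(broken.reactions[j], rate_constant=-1.0)
    with pytest.raises(CompileError):
        compile_model(broken, check=False)


def test_parameter_renaming_is_bijective_and_stable(toy_set):
    model = compile_model(toy_set)
    table = model.parameter_table
    assert table["global_name"].is_unique
    pairs = list(zip(table["reaction"], table["local_name"]))
    assert len(set(pairs)) == len(pairs)
    again = compile_model(toy_set)
    assert list(again.parameter_table["global_name"]) == list(table["global_name"])
    # distinct local names in one formula map to distinct globals
    clear = table[table["reaction"] == "vClear"]
    assert set(clear["local_name"]) == {"kcat", "kM"}
    assert clear["global_name"].is_unique


def test_parameter_report_row_count(toy_set, tmp_path):
    """One row per mass-action constant plus one per formula parameter."""
    model = compile_model(toy_set)
    n_mass = sum(1 for r in toy_set.reactions if r.is_mass_action)
    n_formula = sum(len(r.local_parameters) for r in toy_set.reactions)
    report = export_parameter_report(model, tmp_path / "params.tsv")
    assert len(report) == n_mass + n_formula
    import pandas as pd

    on_disk = pd.read_csv(tmp_path / "params.tsv", sep="\t")
    assert list(on_disk["global_name"]) == list(report["global_name"])
    assert np.allclose(on_disk["value"], report["value"])


def test_model_text_lists_every_element(toy_model):
    text = export_model_text(toy_model)
    for name in toy_model.species_order:
        assert f"species {name} " in text
    for name in toy_model.reaction_names:
        assert f"reaction {name} " in text
    # values printed at full precision: parse back and compare
    for _, row in toy_model.parameter_table.iterrows():
        line = [l for l in text.splitlines()
                if l.startswith(f"parameter {row.global_name} ")][0]
        assert float(line.split("=")[1].split("#")[0]) == row.value


@pytest.mark.parametrize("seed", [11, 12, 13])
def test_sbml_round_trip(tmp_path, seed):
    """export -> import preserves species order, parameter table, and RHS
    values at random states; a second export is a fixpoint."""
    m = make_toy_model(random_toy_spec(seed))
    model = compile_model(m)
    path = tmp_path / "model.xml"
    export_sbml(model, path)
    back = import_sbml(path)
    assert back.species_order == model.species_order
    assert list(back.parameter_table["global_name"]) == model.parameter_names
    # the SBML writer serializes doubles at 15 significant digits
    assert np.allclose(back.param_values, model.param_values, rtol=1e-14, atol=0)
    assert np.array_equal(back.stoichiometry, model.stoichiometry)
    for state in random_states(model, 20, seed):
        a, b = model.evaluate_rhs(state), back.evaluate_rhs(state)
        assert np.allclose(a, b, rtol=1e-12, atol=1e-18)
    second = export_sbml(back)
    assert import_sbml(second).species_order == back.species_order
    assert export_sbml(import_sbml(second)) == second


def test_sbml_is_schema_valid(toy_model, tmp_path):
    import libsbml

    export_sbml(toy_model, tmp_path / "m.xml")
    doc = libsbml.readSBMLFromFile(str(tmp_path / "m.xml"))
    doc.checkConsistency()
    errors = [doc.getError(i) for i in range(doc.getNumErrors())]
    assert not [e for e in errors if e.getSeverity() >= libsbml.LIBSBML_SEV_ERROR]


def test_sbml_carries_annotations(toy_set, tmp_path):
    """Species keep their ENSEMBL identifiers and compartments their GO
    terms through SBML."""
    model = compile_model(toy_set)
    export_sbml(model, tmp_path / "m.xml")
    back = import_sbml(tmp_path / "m.xml")
    assert back.species_gene_ids[model.species_index["m_G1"]] == ("ENSG_G1",)
    assert back.compartment_go["Cytoplasm"] == "GO:0005737"


def test_species_with_two_gene_ids_keeps_both(toy_set, tmp_path):
    m = dataclasses.replace(toy_set)
    m.species = list(toy_set.species)
    m.species[1] = dataclasses.replace(m.species[1],
                                       gene_ids=("ENSG_G1", "ENSG_ALT"))
    model = compile_model(m)
    export_sbml(model, tmp_path / "m.xml")
    back = import_sbml(tmp_path / "m.xml")
    assert set(back.species_gene_ids[1]) == {"ENSG_G1", "ENSG_ALT"}


def test_observable_values(toy_model):
    state = toy_model.initial_state.copy()
    idx = toy_model.species_index
    obs = observable_values(toy_model, state)
    # single member in the reference compartment: equals its concentration
    assert obs["tot_G1"] == pytest.approx(state[idx["p_G1"]])
    # all-zero state -> all observables zero
    assert np.all(observable_values(toy_model, np.zeros(toy_model.n_species)) == 0)


def test_observable_volume_correction(toy_set):
    """A member in the nucleus contributes V_n/V_c of its nM value."""
    m = dataclasses.replace(toy_set)
    m.species = list(toy_set.species)
    i = [k for k, s in enumerate(m.species) if s.name == "p_G1"][0]
    m.species[i] = dataclasses.replace(m.species[i], compartment="Nucleus")
    model = compile_model(m)
    state = np.zeros(model.n_species)
    state[model.species_index["p_G1"]] = 10.0
    vn = model.compartment_volumes["Nucleus"]
    vc = model.compartment_volumes["Cytoplasm"]
    assert observable_values(model, state)["tot_G1"] == pytest.approx(10.0 * vn / vc)


def test_formula_with_unknown_symbol_fails_compile(toy_set):
    broken = dataclasses.replace(toy_set)
    broken.reactions = list(toy_set.reactions)
    broken.reactions[0] = ReactionRecord(
        name="vTL1", compartment="Cytoplasm",
        formula="kTL * nothere", local_parameters=(("kTL", 1.0),))
    with pytest.raises(CompileError):
        compile_model(broken, check=False)
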