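import dataclasses

import numpy as np
import pytest

from celltab import (
    CalibrationTargets,
    PhenotypeCriteria,
    SimulationConfig,
    ToySpec,
    calibrate_translation,
    compile_model,
    coordinate_fit,
    derive_targets,
    make_toy_model,
    phenotype_check,
    scan_parameter,
    simulate_cell,
)
from celltab.errors import CellTabError
from celltab.genes import mpc_to_nM
from celltab.initialize import gene_total, translation_parameter_map
from celltab.model_io import GeneRecord


SS_KW = dict(max_hours=200.0)


def make_gene(name="G1", mrna=100.0, protein=None, half_life=None):
    return GeneRecord(name=name, copy_number=2, mrna_mpc=mrna,
                      k_inactivation=5e-3, k_activation=5e-3,
                      k_transcription_const=1e-2, k_transcription_max=0.0,
                      k_mrna_degradation=1e-4, protein_mpc=protein,
                      protein_half_life=half_life, k_translation=1e-3)


class TestDeriveTargets:
    V = 5.25e-12

    def test_measured_gene_uses_proteomics(self):
        t = derive_targets([make_gene(protein=10_000.0)], {}, self.V)
        assert t.source["G1"] == "measured"
        assert t.targets_nM["G1"] == pytest.approx(float(mpc_to_nM(10_000, self.V)))

    def test_imputed_gene_uses_mrna_ratio(self):
        t = derive_targets([make_gene(mrna=10.0)], {"G1": 1000.0}, self.V)
        assert t.source["G1"] == "imputed"
        assert t.targets_nM["G1"] == pytest.approx(float(mpc_to_nM(10_000, self.V)))

    def test_zero_mrna_imputes_zero(self):
        t = derive_targets([make_gene(mrna=0.0)], {"G1": 1000.0}, self.V)
        assert t.targets_nM["G1"] == 0.0

    def test_gene_without_data_is_fatal(self):
        with pytest.raises(CellTabError, match="G1"):
            derive_targets([make_gene()], {}, self.V)

    def test_imputation_is_linear_in_mrna(self):
        a = derive_targets([make_gene(mrna=5.0)], {"G1": 100.0}, self.V)
        b = derive_targets([make_gene(mrna=15.0)], {"G1": 100.0}, self.V)
        assert b.targets_nM["G1"] == pytest.approx(3 * a.targets_nM["G1"])


@pytest.fixture(scope="module")
def calib_model():
    spec = ToySpec(n_genes=1, include_ligand_receptor=False,
                   include_death_pair=False, include_cyclin_triple=False,
                   k_protein_degradation=1e-4)
    return compile_model(make_toy_model(spec))


class TestCalibration:
    def test_recovers_closed_form_rate(self, calib_model):
        """With fixed mRNA m* and decay k_deg, the fitted translation rate
        is k_deg * P_target / m*."""
        mstar = calib_model.initial_state[calib_model.species_index["m_G1"]]
        target = 100.0
        expected = 1e-4 * target / mstar
        targets = CalibrationTargets({"G1": target}, {"G1": "measured"})
        res = calibrate_translation(calib_model, targets,
                                    steady_state_kwargs=SS_KW)
        assert res.converged
        fitted = res.model.parameter_value(
            translation_parameter_map(calib_model)["G1"])
        assert fitted == pytest.approx(expected, rel=0.01)
        # reached steady state matches the target total
        assert res.totals_nM["G1"] == pytest.approx(target, rel=0.01)

    def test_recalibration_is_a_fixpoint(self, calib_model):
        targets = CalibrationTargets({"G1": 100.0}, {"G1": "measured"})
        res = calibrate_translation(calib_model, targets,
                                    steady_state_kwargs=SS_KW)
        pname = translation_parameter_map(calib_model)["G1"]
        res2 = calibrate_translation(res.model, targets,
                                     steady_state_kwargs=SS_KW)
        k1 = res.model.parameter_value(pname)
        k2 = res2.model.parameter_value(pname)
        assert abs(k2 - k1) <= 0.01 * k1

    def test_target_equal_to_current_changes_nothing(self, calib_model):
        pname = translation_parameter_map(calib_model)["G1"]
        current_total = gene_total(
            calib_model,
            simulate_cell(calib_model, SimulationConfig(
                duration_h=1.0, deterministic=True)).species[-1],
            "G1")
        targets = CalibrationTargets({"G1": current_total}, {"G1": "measured"})
        res = calibrate_translation(calib_model, targets,
                                    steady_state_kwargs=SS_KW)
        assert res.model.parameter_value(pname) == \
            calib_model.parameter_value(pname)

    def test_zero_translation_rate_gives_zero_total(self, calib_model):
        """Loss-of-function context: zeroing the translation rate drives the
        steady-state protein total to zero."""
        pname = translation_parameter_map(calib_model)["G1"]
        knocked = calib_model.with_parameters({pname: 0.0})
        from celltab.initialize import simulate_to_steady_state

        ss = simulate_to_steady_state(knocked, **SS_KW)
        assert gene_total(knocked, ss, "G1") == pytest.approx(0.0, abs=1e-9)

    def test_excluded_gene_is_reported_but_not_updated(self, calib_model):
        pname = translation_parameter_map(calib_model)["G1"]
        targets = CalibrationTargets({"G1": 100.0}, {"G1": "measured"})
        res = calibrate_translation(calib_model, targets,
                                    excluded_observables=("tot_G1",),
                                    steady_state_kwargs=SS_KW)
        assert res.model.parameter_value(pname) == \
            calib_model.parameter_value(pname)
        assert "G1" in res.totals_nM

    def test_geometric_convergence_on_linear_chain(self, calib_model):
        """Proportional fitting contracts gene totals onto the target
        (here: exactly, within two iterations)."""
        targets = CalibrationTargets({"G1": 42.0}, {"G1": "measured"})
        res = calibrate_translation(calib_model, targets,
                                    steady_state_kwargs=SS_KW)
        assert res.converged and res.iterations <= 3
        errs = [abs(h["G1"] - 42.0) / 42.0 for h in res.history]
        assert errs[-1] < 0.01


class TestPhenotypeCheck:
    def test_unconfigured_roles_pass_vacuously(self, linear_model):
        report = phenotype_check(linear_model, PhenotypeCriteria(horizon_h=0.1))
        assert report.passed
        assert len(report.notices) == 2

    def test_cyclin_threshold_violation_reported_with_time(self, toy_model):
        # raise cyclin induction after compilation so the summed-cyclin
        # trajectory starts at 12 nM and crosses 20 nM mid-run
        prod = [g for g, r in zip(toy_model.parameter_names,
                                  toy_model.parameter_table["reaction"])
                if r.startswith("vProdCyc")]
        boosted = toy_model.with_parameters({p: 4e-3 for p in prod})
        report = phenotype_check(boosted, PhenotypeCriteria(horizon_h=4.0))
        assert not report.passed
        assert report.sphase_at_s is not None and report.sphase_at_s > 0

    def test_quiet_model_passes(self, toy_model):
        report = phenotype_check(
            toy_model, PhenotypeCriteria(horizon_h=1.0))
        assert report.passed
        assert report.died_at_s is None and report.sphase_at_s is None


class TestScanParameter:
    def test_monotone_criterion_brackets_threshold(self, default_spec):
        """Smallest passing cleavage rate brackets the true death threshold
        within one grid step (bisection oracle on the same model)."""
        model = compile_model(make_toy_model(default_spec))
        cfg = SimulationConfig(duration_h=1.0, deterministic=True)

        def dies(traj):
            return traj.died_at_s is not None

        low, high, n = 1e-4, 1e-2, 9
        chosen, table = scan_parameter(model, "k10", low, high, n,
                                       dies, cfg=cfg)
        assert chosen is not None
        # independent bisection for the true threshold
        lo, hi = low, high
        for _ in range(30):
            mid = np.sqrt(lo * hi)
            traj = simulate_cell(model.with_parameters({"k10": mid}), cfg)
            if dies(traj):
                hi = mid
            else:
                lo = mid
        step = (np.log10(high) - np.log10(low)) / (n - 1)
        assert abs(np.log10(chosen) - np.log10(hi)) <= step + 1e-9

    def test_always_true_selects_lowest_value(self, toy_model):
        chosen, table = scan_parameter(
            toy_model, "k7", 1e-5, 1e-3, 5, lambda t: True,
            cfg=SimulationConfig(duration_h=0.05, deterministic=True))
        assert chosen == pytest.approx(1e-5)
        assert len(table) == 5

    def test_single_point_evaluates_at_low(self, toy_model):
        chosen, table = scan_parameter(
            toy_model, "k7", 2e-4, 1e-3, 1, lambda t: False,
            cfg=SimulationConfig(duration_h=0.05, deterministic=True))
        assert chosen is None
        assert table == [(2e-4, False)]


@pytest.fixture(scope="module")
def fit_setup():
    model = compile_model(make_toy_model(ToySpec()))
    cfg = SimulationConfig(duration_h=1.0, deterministic=True)
    traj = simulate_cell(model, cfg)
    ref = (traj.time_s[::4], traj.series("C")[::4])
    return model, cfg, ref


class TestCoordinateFit:

    def test_reference_at_current_parameters_changes_nothing(self, fit_setup):
        model, cfg, ref = fit_setup
        fit = coordinate_fit(model, ["k7"], ref, "C", cfg=cfg, n_grid=9)
        assert fit.values["k7"] == model.parameter_value("k7")
        assert fit.sse == pytest.approx(0.0, abs=1e-12)

    def test_recovers_perturbed_parameter_within_one_grid_step(self, fit_setup):
        model, cfg, ref = fit_setup
        true = model.parameter_value("k8")
        perturbed = model.with_parameters({"k8": true * 10 ** 0.7})
        fit = coordinate_fit(perturbed, ["k8"], ref, "C", cfg=cfg)
        step = 4.0 / 24.0
        assert abs(np.log10(fit.values["k8"] / true)) <= step + 1e-9

    def test_sse_never_increases_across_steps(self, fit_setup):
        model, cfg, ref = fit_setup
        perturbed = model.with_parameters({
            "k7": model.parameter_value("k7") * 3.0,
            "k8": model.parameter_value("k8") / 3.0,
        })
        fit = coordinate_fit(perturbed, ["k7", "k8"], ref, "C",
                             cfg=cfg, n_grid=9)
        sses = [s for _, _, s in fit.history]
        assert all(b <= a + 1e-12 for a, b in zip(sses, sses[1:]))

    def test_single_parameter_order_is_irrelevant(self, fit_setup):
        model, cfg, ref = fit_setup
        perturbed = model.with_parameters({"k7": model.parameter_value("k7") * 2})
        f1 = coordinate_fit(perturbed, ["k7"], ref, "C", cfg=cfg, n_grid=9)
        f2 = coordinate_fit(perturbed, ["k7"], ref, "C", cfg=cfg, n_grid=9)
        assert f1.values == f2.values and f1.sse == f2.sse
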