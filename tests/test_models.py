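import json

import numpy as np
import pytest

from vpapk.data import Covariates, DoseEvent, ObservationEvent, SubjectRecord
from vpapk.models import (
    MODEL_IDS,
    MODELS,
    FormulationError,
    export_registry,
    get_model,
    individual_predictions,
    population_predictions,
    residual_apply,
    sample_individual,
    typical_parameters,
)
from vpapk.structural import conc_1cmt_ss


def _cov(**kwargs):
    base = dict(sex="male", age=4.92, weight=19.0, albumin=42.2,
                daily_dose=23.44 * 19.0, formulation="syrup")
    base.update(kwargs)
    return Covariates(**base)


class TestTypicalValues:
    """Hand-computed typical parameters at a cohort-median-like child."""

    def test_serrano2019(self, reference_covariates):
        p = typical_parameters("serrano2019", reference_covariates)
        assert p.cl == pytest.approx(0.012 * 19 ** 0.715 * 23.44 ** 0.306,
                                     rel=1e-12)
        assert p.cl == pytest.approx(0.2586, abs=5e-4)
        assert p.v == pytest.approx(4.56, abs=1e-3)
        assert p.ka == pytest.approx(1.9)

    def test_serrano2019_carbamazepine_multiplier(self, reference_covariates):
        base = typical_parameters("serrano2019", reference_covariates)
        with_cbz = typical_parameters("serrano2019", _cov(cbz=True))
        assert with_cbz.cl / base.cl == pytest.approx(1.359, rel=1e-12)

    def test_jiang_typical_clearance(self):
        p = typical_parameters("jiang", _cov())
        assert p.cl == pytest.approx(0.106 + 0.0157 * 4.92, rel=1e-12)
        assert round(p.cl, 2) == 0.18

    def test_jiang_literal_printed_form_differs(self):
        lit = typical_parameters("jiang", _cov(), jiang_literal_printed_form=True)
        # with no co-medication 0.106^0 = 1, an implausible base clearance
        assert lit.cl == pytest.approx(1.0 + 0.0157 * 4.92, rel=1e-12)

    def test_rodrigues_reference_adult_scale(self):
        p = typical_parameters("rodrigues", _cov(weight=70.0, age=15.0,
                                                 daily_dose=70 * 23.44))
        assert p.cl == pytest.approx(0.624, rel=1e-12)
        assert p.v == pytest.approx(13.0, rel=1e-12)

    def test_serrano2022_reference_adult_scale(self):
        p = typical_parameters("serrano2022", _cov(weight=70.0, age=15.0,
                                                   daily_dose=70 * 23.44))
        assert p.cl == pytest.approx(0.646, rel=1e-12)
        assert p.v == pytest.approx(14.0, rel=1e-12)
        assert p.ka == pytest.approx(2.64)

    def test_ogungbenro_two_compartment(self):
        p = typical_parameters("ogungbenro", _cov(), allow_ka_fallback=True)
        assert p.is_two_compartment
        assert p.cl == pytest.approx(0.854 * (19 / 70) ** 0.75, rel=1e-12)
        assert p.vc == pytest.approx(10.3 * (19 / 70) * (4.92 / 8.5) ** -0.267,
                                     rel=1e-12)
        assert p.vp == pytest.approx(4.08 * 19 / 70, rel=1e-12)

    def test_gu_large_apparent_volume_for_total_drug(self):
        # unbound-drug volume scales to 1680 L/70 kg; the observation
        # function maps unbound to total
        p = typical_parameters("gu", _cov())
        assert p.v == pytest.approx(1680.1 * 19 / 70, rel=1e-12)
        spec = get_model("gu")
        assert spec.obs_strategy == "linear_ns"

    def test_ding_age_dependent_allometric_exponent(self):
        # by age ~5 the maturation term saturates: exponent ~ 0.695
        young = typical_parameters("ding", _cov(age=0.3, weight=6.0,
                                                daily_dose=6 * 23.44))
        old = typical_parameters("ding", _cov())
        exp_young = np.log(young.cl / (0.3 * (1.0 + 2.8 * 23.44 ** 1.68 /
                                              (37.4 ** 1.68 + 23.44 ** 1.68)))
                           ) / np.log(6.0 / 70.0)
        exp_old = np.log(old.cl / (0.3 * (1.0 + 2.8 * 23.44 ** 1.68 /
                                          (37.4 ** 1.68 + 23.44 ** 1.68)))
                         ) / np.log(19.0 / 70.0)
        assert exp_young == pytest.approx(0.791, abs=5e-3)
        assert exp_old == pytest.approx(0.695, abs=5e-3)

    @pytest.mark.parametrize("model_id", MODEL_IDS)
    def test_positive_parameters_over_cohort_range(self, model_id):
        rng = np.random.default_rng(7)
        for _ in range(50):
            age = float(rng.uniform(0.5, 15.0))
            wt = float(np.clip(2 * age + 9 + rng.normal(0, 3), 4.0, 70.0))
            cov = _cov(age=age, weight=wt,
                       daily_dose=wt * float(rng.uniform(8.0, 60.0)),
                       sex=str(rng.choice(["male", "female"])),
                       cbz=bool(rng.random() < 0.2))
            p = typical_parameters(model_id, cov, allow_ka_fallback=True)
            assert p.cl > 0 and p.v > 0 and p.ka > 0


class TestAbsorptionRules:
    def test_jiang_sustained_release_slows_absorption(self):
        slow = typical_parameters("jiang", _cov(formulation="sustained_release"))
        fast = typical_parameters("jiang", _cov(formulation="syrup"))
        assert slow.ka == pytest.approx(0.251)
        assert fast.ka == pytest.approx(2.491)

    def test_unpublished_formulation_raises_without_fallback(self):
        cov = _cov(formulation="enteric_coated")
        with pytest.raises(FormulationError):
            typical_parameters("ding", cov)
        p = typical_parameters("ding", cov, allow_ka_fallback=True)
        assert p.ka == pytest.approx(1.57)

    def test_nakashima_absorption_lag(self):
        p = typical_parameters("nakashima", _cov())
        assert p.tlag == pytest.approx(3.0)


class TestRandomEffects:
    def test_sampled_clearance_cv_matches_omega(self, reference_covariates):
        draws = [sample_individual("serrano2019", reference_covariates, seed)
                 for seed in range(2000)]
        log_cl = np.log([d.params.cl for d in draws])
        assert np.std(log_cl) == pytest.approx(0.214, abs=0.02)
        typ = typical_parameters("serrano2019", reference_covariates)
        assert np.median(np.exp(log_cl)) == pytest.approx(typ.cl, rel=0.05)

    def test_eta_free_parameters_unperturbed(self, reference_covariates):
        # serrano2019 has BSV on CL only: V and ka stay at typical values
        d = sample_individual("serrano2019", reference_covariates, 3)
        typ = typical_parameters("serrano2019", reference_covariates)
        assert d.params.v == typ.v and d.params.ka == typ.ka
        assert set(d.eta) == {"cl"}

    def test_correlated_etas_reproduce_covariance(self):
        cov = _cov()
        rng = np.random.default_rng(99)
        draws = [sample_individual("ogungbenro", cov, rng,
                                   allow_ka_fallback=True)
                 for _ in range(4000)]
        etas = np.array([[d.eta[n] for n in ("cl", "vc", "vp")]
                         for d in draws])
        emp = np.cov(etas.T)
        spec = get_model("ogungbenro")
        assert np.allclose(emp, spec.omega_matrix(), atol=0.05)

    def test_omega_matrices_positive_definite(self):
        for spec in MODELS.values():
            if spec.omega:
                vals = np.linalg.eigvalsh(spec.omega_matrix())
                assert np.all(vals > 0)


class TestResidual:
    def test_additive_noise_scale(self, rng):
        out = residual_apply("serrano2019", np.full(20000, 60.0), rng)
        assert np.std(out) == pytest.approx(15.6, rel=0.05)

    def test_proportional_noise_scales_with_concentration(self, rng):
        lo = residual_apply("rodrigues", np.full(20000, 20.0), rng)
        hi = residual_apply("rodrigues", np.full(20000, 80.0), rng)
        assert np.std(lo) == pytest.approx(0.154 * 20, rel=0.05)
        assert np.std(hi) == pytest.approx(0.154 * 80, rel=0.05)

    def test_floor_at_zero_and_domain(self, rng):
        out = residual_apply("serrano2019", np.full(5000, 1.0), rng)
        assert np.all(out >= 0)
        with pytest.raises(ValueError):
            residual_apply("serrano2019", -1.0, rng)


class TestPredictions:
    def test_population_prediction_matches_structural_closed_form(
            self, steady_state_subject):
        preds = population_predictions("serrano2019", steady_state_subject)
        p = typical_parameters("serrano2019", steady_state_subject.covariates)
        for (t, c) in preds:
            assert c == pytest.approx(conc_1cmt_ss(p, 240.0, 12.0, t), rel=1e-10)

    def test_gu_observation_is_total_exceeding_unbound(self, steady_state_subject):
        preds = population_predictions("gu", steady_state_subject)
        p = typical_parameters("gu", steady_state_subject.covariates)
        for (t, c_total) in preds:
            cu = conc_1cmt_ss(p, 240.0, 12.0, t)
            assert c_total > cu > 0

    def test_individual_prediction_at_zero_eta_equals_population(
            self, steady_state_subject):
        pop = [c for _, c in population_predictions("jiang", steady_state_subject)]
        ind = individual_predictions("jiang", steady_state_subject,
                                     {"cl": 0.0, "v": 0.0, "ka": 0.0})
        assert np.allclose(ind, pop, rtol=1e-12)

    def test_vectorised_eta_gives_replicate_matrix(self, steady_state_subject):
        eta = {"cl": np.array([0.0, 0.2, -0.2])}
        out = individual_predictions("serrano2019", steady_state_subject, eta)
        assert out.shape == (3, 2)
        # higher clearance -> lower trough
        assert np.all(out[1] < out[0]) and np.all(out[2] > out[0])

    def test_non_steady_state_superposition(self):
        cov = _cov()
        doses = tuple(DoseEvent(time=12.0 * i, amount=240.0) for i in range(4))
        obs = (ObservationEvent(time=47.0, concentration=50.0,
                                time_after_dose=11.0),)
        s = SubjectRecord(id="n", covariates=cov, doses=doses, observations=obs)
        (t, c), = population_predictions("serrano2019", s)
        p = typical_parameters("serrano2019", cov)
        from vpapk.structural import conc_superposition
        expected = conc_superposition(p, [(d.time, d.amount) for d in doses], 47.0)
        assert c == pytest.approx(expected, rel=1e-10)


class TestRegistry:
    def test_ten_models_exported_and_json_ready(self):
        reg = export_registry()
        assert len(reg) == 10
        json.dumps(reg)  # must be serialisable as plain data
        for entry in reg.values():
            assert entry["residual"]["kind"] in ("additive", "proportional")
            assert entry["structural"] in ("1CMT", "2CMT")

    def test_unknown_model_id_lists_valid_ids(self):
        with pytest.raises(KeyError, match="serrano2019"):
            get_model("nope")
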