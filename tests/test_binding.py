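import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vpapk.binding import (
    LINEAR_NS_DEFAULTS,
    VARIANTS,
    BindingParams,
    bound_concentration,
    fit_population,
    nonlinear_clearance,
    population_ofv,
    total_from_unbound,
    unbound_from_total,
)
from vpapk.cohort import CohortConfig, generate_cohort


class TestObservationFunctions:
    def test_langmuir_half_saturation_and_capacity(self):
        # at Cu = Kd the bound concentration is half of Bm
        assert bound_concentration("langmuir", 7.8) == pytest.approx(65.0)
        assert bound_concentration("langmuir", 1e7) == pytest.approx(130.0,
                                                                     rel=1e-5)

    def test_linear_ns_worked_value(self):
        # Bm/2 at Cu = Kd plus the non-saturable slope
        cb = bound_concentration("linear_ns", 2.12)
        assert cb == pytest.approx(67.3 / 2 + 2.25 * 2.12, rel=1e-12)

    def test_one_site_molar_bookkeeping(self):
        # saturation capacity = N * [albumin] in molar units
        cap = bound_concentration("one_site", 1e7, alb=42.0)
        assert cap == pytest.approx(1.98 * 42.0 / 66500.0 * 1000 * 144.21,
                                    rel=1e-4)

    def test_unbound_fraction_in_therapeutic_range(self):
        # VPA is ~90-95% protein-bound around 50 mg/L total
        cu = unbound_from_total("one_site", 50.0, alb=42.0)
        fu = cu / 50.0
        assert 0.03 < fu < 0.2

    def test_saturation_raises_unbound_fraction(self):
        fu = [unbound_from_total("one_site", ct) / ct for ct in (30.0, 75.0, 150.0)]
        assert fu[0] < fu[1] < fu[2]

    def test_total_strictly_increasing_and_inversion_roundtrip(self):
        cu = np.linspace(0.0, 40.0, 50)
        for strategy in ("one_site", "langmuir", "linear_ns"):
            ct = total_from_unbound(strategy, cu)
            assert np.all(np.diff(ct) > 0)
            back = unbound_from_total(strategy, ct)
            assert np.allclose(back, cu, atol=1e-9)

    def test_inversion_reference_value(self):
        ct = total_from_unbound("langmuir", 7.8)
        assert ct == pytest.approx(72.8)
        assert unbound_from_total("langmuir", 72.8) == pytest.approx(7.8,
                                                                     abs=1e-9)

    @settings(max_examples=60, deadline=None)
    @given(st.sampled_from(["one_site", "langmuir", "linear_ns"]),
           st.floats(min_value=1e-3, max_value=500.0))
    def test_roundtrip_property_any_total(self, strategy, ct):
        cu = unbound_from_total(strategy, ct)
        assert 0.0 <= cu <= ct
        assert total_from_unbound(strategy, cu) == pytest.approx(ct, abs=1e-8)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            bound_concentration("langmuir", -1.0)
        with pytest.raises(ValueError):
            bound_concentration("unknown", 1.0)
        with pytest.raises(ValueError):
            BindingParams(gamma=0.0)
        with pytest.raises(ValueError):
            BindingParams(bm=-1.0)


class TestClearanceStrategies:
    def test_dde_at_half_maximal_dose(self):
        # at DDW = DD50 the induction term is Emax/2 -> CL = 2.4 clp
        assert nonlinear_clearance("dde", 0.31, 37.4) == pytest.approx(
            0.31 * 2.4, rel=1e-12)

    def test_exponent_identity_at_reference_dose(self):
        p = BindingParams(k_exp=0.3)
        assert nonlinear_clearance("exponent", 0.31, 25.0, p) == pytest.approx(0.31)
        # positive exponent: clearance rises with dose (autoinduction-like)
        assert nonlinear_clearance("exponent", 0.31, 50.0, p) > 0.31

    def test_vectorised_and_monotone(self):
        ddw = np.linspace(5.0, 60.0, 30)
        cl = nonlinear_clearance("dde", 0.31, ddw)
        assert cl.shape == ddw.shape
        assert np.all(np.diff(cl) > 0)


def _binding_cohort(variant, n=80, seed=2024, **truth_params):
    cfg = CohortConfig(n_subjects=n, seed=seed, truth_model=variant,
                       truth_params=truth_params or None)
    ds, sidecar = generate_cohort(cfg)
    return ds, sidecar


class TestPopulationFit:
    def test_exponent_variant_recovers_truth(self):
        ds, sidecar = _binding_cohort("model_V")
        fit = fit_population("model_V", ds, seed=11, n_starts=3)
        assert fit.converged
        est = fit.estimates
        assert est["clp"] == pytest.approx(0.31, rel=0.25)
        assert est["k_exp"] == pytest.approx(0.30, abs=0.15)
        assert est["omega_cl"] == pytest.approx(0.30, rel=0.5)

    def test_langmuir_variant_recovers_unbound_clearance(self):
        ds, _ = _binding_cohort("model_II")
        fit = fit_population("model_II", ds, seed=5, n_starts=3)
        assert fit.converged
        est = fit.estimates
        assert est["clp"] == pytest.approx(3.0, rel=0.3)
        # the fitted optimum is at least as good as the generating truth
        truth = {"clp": 3.0, "v": 400.0, "omega_cl": 0.3, "sigma_prop": 0.1}
        assert fit.ofv <= population_ofv("model_II", ds, truth) + 1e-6

    def test_ofv_prefers_truth_over_biased_parameters(self):
        ds, _ = _binding_cohort("model_II", n=60, seed=7)
        truth = {"clp": 3.0, "v": 400.0, "omega_cl": 0.3, "sigma_prop": 0.1}
        biased = dict(truth, clp=3.0 * 1.3)
        assert population_ofv("model_II", ds, truth) < population_ofv(
            "model_II", ds, biased)

    def test_unknown_variant_rejected(self):
        ds, _ = _binding_cohort("model_V", n=5, seed=1)
        with pytest.raises(ValueError, match="variant"):
            fit_population("model_X", ds)
        assert set(VARIANTS) == {"model_I", "model_II", "model_III",
                                 "model_IV", "model_V"}

    def test_linear_ns_defaults_are_distinct_constants(self):
        assert LINEAR_NS_DEFAULTS.kd == pytest.approx(2.12)
        assert LINEAR_NS_DEFAULTS.bm == pytest.approx(67.3)
        assert BindingParams().kd == pytest.approx(7.8)
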