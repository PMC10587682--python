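"""Virtual pediatric TDM cohort generation.

Every pipeline stage in this package is exercised on synthetic cohorts
whose covariate structure emulates a routine valproic-acid monitoring
population: 202 children, 255 steady-state trough samples, median age
4.92 y (0.17-15.00), median weight 19 kg (4.00-70.00), median daily dose
23.44 mg/kg/day (8.70-57.69), albumin 42.2 +/- 3.65 g/L, syrup vs
sustained-release formulations roughly 76/24, and mostly newer-generation
co-medications.  Observations are simulated from any library model (or a
binding-strategy truth) with the truth etas stored alongside, so
parameter-recovery audits are exact.

The age and dose distributions are lognormal with the target medians and
the spread implied by the reported mean/median ratio; weight follows a
coarse pediatric growth rule (weight ~ 2*age + 9 kg plus noise).  These
choices are deliberately simple emulations, not physiologic growth
models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .binding import (
    BindingParams,
    CLEARANCE_STRATEGIES,
    FIT_KA,
    LINEAR_NS_DEFAULTS,
    VARIANTS,
    bound_concentration,
    nonlinear_clearance,
)
from .data import Covariates, DoseEvent, ObservationEvent, PKDataset, SubjectRecord
from .models import MODEL_IDS, get_model, individual_predictions, sample_individual
from .structural import _conc_1cmt_ss_arr

__all__ = [
    "CohortConfig",
    "generate_covariates",
    "generate_regimens",
    "build_design",
    "simulate_observations",
    "generate_cohort",
]

#: Floor applied to simulated concentrations so records stay valid;
#: well below the assay's limit of quantification.
_CONC_FLOOR = 0.05


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions of the emulated TDM cohort.

    Defaults reproduce the reference evaluation cohort's summary
    statistics; distributional spreads are derived from the reported
    mean/median pairs (lognormal sigma = sqrt(2 ln(mean/median))).
    """

    n_subjects: int = 202
    seed: int = 0
    # age: lognormal, median 4.92 y, mean 5.74 y, truncated
    age_median: float = 4.92
    age_sigma: float = math.sqrt(2.0 * math.log(5.74 / 4.92))
    age_bounds: tuple = (0.17, 15.0)
    # weight: growth rule 2*age + 9 kg with gaussian noise, truncated
    weight_noise_sd: float = 3.0
    weight_bounds: tuple = (4.0, 70.0)
    # daily dose per kg: lognormal, median 23.44, mean 24.50, truncated
    ddw_median: float = 23.44
    ddw_sigma: float = math.sqrt(2.0 * math.log(24.50 / 23.44))
    ddw_bounds: tuple = (8.70, 57.69)
    dose_rounding: float = 10.0  # mg, practical strength granularity
    # formulation mix (per sample: 194 syrup / 61 sustained release)
    p_syrup: float = 194.0 / 255.0
    p_male: float = 139.0 / 202.0
    albumin_mean: float = 42.21  # g/L
    albumin_sd: float = 3.65
    albumin_bounds: tuple = (29.7, 70.5)
    # co-medication prevalence per sample; only CBZ/PB/PHT/LTG/CLB are
    # consumed by the model library, the rest populate other_comed
    p_cbz: float = 3.0 / 255.0
    p_ltg: float = 10.0 / 255.0
    p_pb: float = 0.0
    p_pht: float = 0.0
    p_clb: float = 0.0
    p_other_comed: float = 82.0 / 255.0  # levetiracetam/oxcarbazepine/...
    p_uncontrolled: float = 0.2
    # dosing: 1-3 administrations per day
    daily_frequency_probs: tuple = (0.2, 0.6, 0.2)  # for 1, 2, 3 times/day
    # sampling: fraction of subjects contributing a second trough
    p_second_sample: float = 53.0 / 202.0
    truth_model: str = "serrano2019"
    truth_params: dict | None = None  # overrides for binding-variant truths
    #: multiplies every simulated subject's true clearance; values != 1
    #: create a deliberately misspecified cohort for power studies
    truth_cl_scale: float = 1.0
    loq: float = 1.0  # mg/L


def _truncated(draw, lo: float, hi: float, rng, max_tries: int = 1000):
    """Resample ``draw(rng)`` until it lands inside [lo, hi]."""
    for _ in range(max_tries):
        x = draw(rng)
        if lo <= x <= hi:
            return x
    return min(max(x, lo), hi)


def generate_covariates(cfg: CohortConfig) -> list[Covariates]:
    """Draw one covariate record per subject, reproducible by seed.

    Weight is positively linked to age through the growth rule, so the
    cohort shows the strong age-weight rank correlation real pediatric
    data have.
    """
    if cfg.n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    mu_age = math.log(cfg.age_median)
    mu_ddw = math.log(cfg.ddw_median)
    out = []
    for _ in range(cfg.n_subjects):
        age = _truncated(lambda r: math.exp(mu_age + cfg.age_sigma * r.standard_normal()),
                         *cfg.age_bounds, rng)
        weight = _truncated(lambda r: 2.0 * age + 9.0
                            + cfg.weight_noise_sd * r.standard_normal(),
                            *cfg.weight_bounds, rng)
        ddw = _truncated(lambda r: math.exp(mu_ddw + cfg.ddw_sigma * r.standard_normal()),
                         *cfg.ddw_bounds, rng)
        dd = max(cfg.dose_rounding,
                 round(ddw * weight / cfg.dose_rounding) * cfg.dose_rounding)
        albumin = _truncated(lambda r: cfg.albumin_mean
                             + cfg.albumin_sd * r.standard_normal(),
                             *cfg.albumin_bounds, rng)
        out.append(Covariates(
            sex="male" if rng.random() < cfg.p_male else "female",
            age=age, weight=weight, albumin=albumin, daily_dose=dd,
            formulation="syrup" if rng.random() < cfg.p_syrup
            else "sustained_release",
            cbz=bool(rng.random() < cfg.p_cbz),
            pb=bool(rng.random() < cfg.p_pb),
            pht=bool(rng.random() < cfg.p_pht),
            ltg=bool(rng.random() < cfg.p_ltg),
            clb=bool(rng.random() < cfg.p_clb),
            other_comed=bool(rng.random() < cfg.p_other_comed),
            uncontrolled_epilepsy=bool(rng.random() < cfg.p_uncontrolled),
        ))
    return out


def generate_regimens(covariates, cfg: CohortConfig) -> list[tuple[DoseEvent, ...]]:
    """Steady-state oral regimens: the daily dose split into 1-3 equal
    administrations (interval 24, 12 or 8 h), encoded as a single
    steady-state dose event per subject."""
    rng = np.random.default_rng(cfg.seed + 1)
    probs = np.asarray(cfg.daily_frequency_probs, dtype=float)
    probs = probs / probs.sum()
    regimens = []
    for cov in covariates:
        n_daily = int(rng.choice((1, 2, 3), p=probs))
        tau = 24.0 / n_daily
        amount = cov.daily_dose / n_daily
        regimens.append((DoseEvent(time=0.0, amount=amount,
                                   interdose_interval=tau, steady_state=True),))
    return regimens


def build_design(cfg: CohortConfig) -> PKDataset:
    """Assemble the sampling design: covariates, regimens, and trough
    observation slots (DV holds the LOQ as a placeholder until
    :func:`simulate_observations` fills it)."""
    covariates = generate_covariates(cfg)
    regimens = generate_regimens(covariates, cfg)
    rng = np.random.default_rng(cfg.seed + 2)
    subjects = []
    for i, (cov, doses) in enumerate(zip(covariates, regimens)):
        tau = doses[0].interdose_interval
        times = [tau]
        if rng.random() < cfg.p_second_sample:
            times.append(2.0 * tau)
        obs = tuple(ObservationEvent(time=t, concentration=cfg.loq,
                                     time_after_dose=tau) for t in times)
        subjects.append(SubjectRecord(id=f"S{i + 1:04d}", covariates=cov,
                                      doses=doses, observations=obs))
    return PKDataset(subjects=tuple(subjects),
                     provenance=f"synthetic design (seed={cfg.seed}, "
                                f"n={cfg.n_subjects})")


#: Truth parameters used when simulating from a binding-strategy variant.
_BINDING_TRUTH_DEFAULTS = {
    "clp": 0.31, "v": 15.0, "omega_cl": 0.3, "sigma_prop": 0.1,
    "k_exp": 0.30, "dd50": 37.4,
    # unbound-kinetics variants run at larger apparent unbound CL/V
    "clp_unbound": 3.0, "v_unbound": 400.0,
}


def simulate_observations(design: PKDataset, truth: str, seed: int = 0,
                          truth_params: dict | None = None,
                          loq: float = 1.0, cl_scale: float = 1.0,
                          **kwargs) -> tuple[PKDataset, dict]:
    """Fill the design's observation slots from a ground-truth model.

    ``truth`` is a library model id or a binding variant (``model_I`` ..
    ``model_V``).  Per subject the etas are drawn once, per observation a
    residual error is applied; concentrations below ``loq`` are flagged,
    never dropped.  Returns ``(dataset, sidecar)`` where the sidecar maps
    subject id -> truth etas (and holds the truth parameters), enabling
    exact recovery audits.
    """
    rng = np.random.default_rng(seed)
    if truth in MODEL_IDS:
        return _simulate_from_library(design, truth, rng, loq,
                                      cl_scale=cl_scale, **kwargs)
    if truth in VARIANTS:
        params = dict(_BINDING_TRUTH_DEFAULTS)
        if truth_params:
            params.update(truth_params)
        return _simulate_from_binding(design, truth, params, rng, loq)
    raise KeyError(f"unknown truth model {truth!r}; valid: "
                   f"{', '.join(MODEL_IDS + tuple(VARIANTS))}")


def _fill(subject: SubjectRecord, values, loq: float) -> SubjectRecord:
    obs = tuple(
        ObservationEvent(time=o.time,
                         concentration=max(float(v), _CONC_FLOOR),
                         time_after_dose=o.time_after_dose,
                         below_loq=bool(v < loq))
        for o, v in zip(subject.observations, values))
    return replace(subject, observations=obs)


def _simulate_from_library(design, truth, rng, loq, cl_scale=1.0, **kwargs):
    spec = get_model(truth)
    subjects, sidecar = [], {"truth": truth, "etas": {},
                             "cl_scale": cl_scale}
    shift = math.log(cl_scale)
    for s in design.subjects:
        ind = sample_individual(truth, s.covariates, rng, **kwargs)
        eta = dict(ind.eta)
        if shift != 0.0:
            eta["cl"] = eta.get("cl", 0.0) + shift
        conc = np.atleast_1d(
            individual_predictions(truth, s, eta, **kwargs))
        kind, sigma = spec.residual
        eps = rng.standard_normal(conc.shape) * sigma
        dv = conc + eps if kind == "additive" else conc * (1.0 + eps)
        subjects.append(_fill(s, dv, loq))
        sidecar["etas"][s.id] = dict(ind.eta)
    ds = PKDataset(subjects=tuple(subjects),
                   provenance=design.provenance + f"; simulated from {truth}")
    return ds, sidecar


def _simulate_from_binding(design, variant, params, rng, loq):
    strategy = VARIANTS[variant]
    if strategy in CLEARANCE_STRATEGIES:
        clp, v = params["clp"], params["v"]
    else:
        clp, v = params["clp_unbound"], params["v_unbound"]
    bp = LINEAR_NS_DEFAULTS if strategy == "linear_ns" else BindingParams()
    bp = replace(bp, dd50=params["dd50"], k_exp=params["k_exp"])
    omega, sigma = params["omega_cl"], params["sigma_prop"]
    subjects, sidecar = [], {"truth": variant, "etas": {},
                             "params": dict(params)}
    for s in design.subjects:
        cov = s.covariates
        ka = FIT_KA.get(cov.formulation)
        if ka is None:
            raise ValueError(f"subject {s.id}: no fixed ka for formulation "
                             f"{cov.formulation!r} in binding simulation")
        eta = float(rng.standard_normal() * omega)
        d = s.doses[0]
        tads = np.array([o.time_after_dose for o in s.observations])
        if strategy in CLEARANCE_STRATEGIES:
            cl = nonlinear_clearance(strategy, clp, cov.daily_dose_per_kg, bp)
            conc = _conc_1cmt_ss_arr(d.amount, d.interdose_interval, tads,
                                     cl * math.exp(eta), v, ka)
        else:
            cu = _conc_1cmt_ss_arr(d.amount, d.interdose_interval, tads,
                                   clp * math.exp(eta), v, ka)
            conc = cu + np.asarray(
                bound_concentration(strategy, cu, cov.albumin, bp))
        dv = conc * (1.0 + rng.standard_normal(conc.shape) * sigma)
        subjects.append(_fill(s, dv, loq))
        sidecar["etas"][s.id] = {"cl": eta}
    ds = PKDataset(subjects=tuple(subjects),
                   provenance=design.provenance + f"; simulated from {variant}")
    return ds, sidecar


def generate_cohort(cfg: CohortConfig, **kwargs) -> tuple[PKDataset, dict]:
    """Design + simulation in one call (the usual entry point)."""
    design = build_design(cfg)
    return simulate_observations(design, cfg.truth_model, seed=cfg.seed + 3,
                                 truth_params=cfg.truth_params, loq=cfg.loq,
                                 cl_scale=cfg.truth_cl_scale, **kwargs)
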