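"""Library of published pediatric valproic-acid population-PK models.

Ten literature models are encoded behind one interface: covariate
equations for the typical parameters, between-subject variability (BSV)
as lognormal random effects, residual-error models (additive in mg/L or
proportional), and formulation-specific absorption rules.  Model ids:

========== ============================================================
id          source model
========== ============================================================
serrano2019 Serrano et al. 2019 (Spain): allometric WT + daily-dose
            exponent on CL, carbamazepine multiplier
eldesoky    El-Desoky et al. (Egypt): additive covariate model on CL
jiang       Jiang et al. (China): co-medication + age on CL
silva       Silva et al. (Mexico): additive WT/daily-dose, phenobarbital
ogungbenro  Ogungbenro & Aarons (US): the only two-compartment model,
            correlated random effects on CL/Vc/Vp
nakashima   Nakashima et al. (Japan): daily-dose power model, multiple
            co-medication multipliers, absorption lag 3 h
ding        Ding et al. (China): age-dependent allometric exponent and a
            dose-dependent maximum-effect (DDE) clearance term
rodrigues   Rodrigues et al. (France): pure allometry
gu          Gu et al. (China): unbound-drug kinetics with postmenstrual-age
            maturation; observations are total concentrations through the
            linear non-saturable binding equation (hence V/F = 1680 L)
serrano2022 Serrano et al. 2022 (Spain): allometry + age + co-medications
========== ============================================================

All thetas are fixed literature constants; nothing here is re-estimated.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .binding import LINEAR_NS_DEFAULTS, bound_concentration
from .data import Covariates, SubjectRecord
from .structural import (
    PKParameters,
    _conc_1cmt_single_arr,
    _conc_1cmt_ss_arr,
    _conc_2cmt_single_arr,
    _conc_2cmt_ss_arr,
)

__all__ = [
    "MODEL_IDS",
    "ModelSpec",
    "IndividualParameters",
    "get_model",
    "typical_parameters",
    "sample_individual",
    "residual_apply",
    "population_predictions",
    "individual_predictions",
    "export_registry",
]


class MissingCovariateError(KeyError):
    """A model needs a covariate the subject record does not carry."""


class FormulationError(ValueError):
    """A model has no absorption rule for the subject's formulation."""


@dataclass(frozen=True)
class ModelSpec:
    """One published popPK model (immutable registry entry)."""

    id: str
    label: str
    structural: str  # "1CMT" | "2CMT"
    #: parameters carrying a lognormal random effect -> omega (SD of eta)
    omega: dict
    #: optional covariance entries between etas, keyed by frozenset pairs
    omega_cov: dict
    residual: tuple  # ("additive", mg/L) | ("proportional", fraction)
    #: formulation -> (ka 1/h, tlag h); "*" is an any-formulation rule
    ka_rule: dict
    #: documented fallback for formulations outside the published rule
    ka_fallback: dict
    required_covariates: tuple
    #: observation strategy mapping unbound -> total, or None
    obs_strategy: str | None = None
    notes: str = ""

    @property
    def eta_names(self) -> tuple:
        return tuple(sorted(self.omega))

    def omega_matrix(self) -> np.ndarray:
        """Full covariance matrix of the eta vector (order: eta_names)."""
        names = self.eta_names
        m = np.diag([self.omega[n] ** 2 for n in names])
        for pair, covv in self.omega_cov.items():
            a, b = sorted(pair)
            i, j = names.index(a), names.index(b)
            m[i, j] = m[j, i] = covv
        return m


@dataclass(frozen=True)
class IndividualParameters:
    """Individual PK parameters: typical values perturbed by exp(eta)."""

    params: PKParameters
    eta: dict
    model_id: str


# ---------------------------------------------------------------------------
# covariate equations (typical values)
# ---------------------------------------------------------------------------

_EL_DESOKY_CL_FLOOR = 1e-6  # additive covariate models can cross zero


def _cl_serrano2019(c: Covariates) -> float:
    cl = 0.012 * c.weight ** 0.715 * c.daily_dose_per_kg ** 0.306
    return cl * (1.359 if c.cbz else 1.0)


def _cl_eldesoky(c: Covariates) -> float:
    cl = (0.105 + 0.000248 * c.daily_dose + 0.0968 * c.age / 20.0
          + (0.151 if c.cbz else 0.0)
          + (0.0803 if c.uncontrolled_epilepsy else 0.0))
    if cl < _EL_DESOKY_CL_FLOOR:
        warnings.warn("eldesoky: additive covariate model produced CL <= 0; "
                      f"floored at {_EL_DESOKY_CL_FLOOR} L/h")
        cl = _EL_DESOKY_CL_FLOOR
    return cl


def _cl_jiang(c: Covariates, literal: bool = False) -> float:
    """Jiang clearance.  The printed form 0.106^(0.98 CO) + 0.0157 AGE is
    internally inconsistent with the model's reported typical CL of
    0.18 L/h; the default multiplicative reading 0.106*0.98^CO reproduces
    it.  ``literal=True`` evaluates the printed exponent form."""
    co = 1.0 if c.comedication else 0.0
    if literal:
        return 0.106 ** (0.98 * co) + 0.0157 * c.age
    return 0.106 * 0.98 ** co + 0.0157 * c.age


def _cl_silva(c: Covariates) -> float:
    cl = 0.0466 + 0.00363 * c.weight + 0.000282 * c.daily_dose
    return cl * (1.236 if c.pb else 1.0)


def _cl_ogungbenro(c: Covariates) -> float:
    return 0.854 * (c.weight / 70.0) ** 0.75


def _cl_nakashima(c: Covariates) -> float:
    cl = 0.559 * (c.daily_dose / 1000.0) ** 0.596
    if c.sex == "female":
        cl *= 0.917
    if c.cbz:
        cl *= 1.19
    if c.pb:
        cl *= 1.12
    if c.pht:
        cl *= 1.43
    if c.clb:
        cl *= 0.906
    return cl


_DING_AGE50 = 0.802  # years; midpoint of the age effect on the WT exponent


def _cl_ding(c: Covariates) -> float:
    age_term = c.age ** 8.63 / (_DING_AGE50 ** 8.63 + c.age ** 8.63)
    wt_exp = 0.791 - 0.096 * age_term
    dde = 1.0 + 2.8 * c.daily_dose_per_kg ** 1.68 / (
        37.4 ** 1.68 + c.daily_dose_per_kg ** 1.68)
    cl = 0.3 * (c.weight / 70.0) ** wt_exp * dde
    return cl * (1.43 if c.cbz else 1.0)


def _cl_rodrigues(c: Covariates) -> float:
    return 0.624 * (c.weight / 70.0) ** 0.75


def _cl_gu(c: Covariates) -> float:
    mat = c.pma ** 4.17 / (33.7 ** 4.17 + c.pma ** 4.17)
    cl = 10.4 * (c.weight / 70.0) ** 0.75 * mat
    return cl * (1.25 if c.ltg else 1.0)


def _cl_serrano2022(c: Covariates) -> float:
    cl = 0.646 * (c.weight / 70.0) ** 0.75 * (c.age / 15.0) ** -0.0154
    if c.pht:
        cl *= 1.640
    if c.pb:
        cl *= 1.386
    if c.cbz:
        cl *= 1.521
    return cl


_TYPICAL_FNS = {
    "serrano2019": lambda c, **kw: {"cl": _cl_serrano2019(c), "v": 0.24 * c.weight},
    "eldesoky": lambda c, **kw: {"cl": _cl_eldesoky(c), "v": 11.5},
    "jiang": lambda c, literal=False, **kw: {
        "cl": _cl_jiang(c, literal), "v": 2.88 + 0.157 * c.weight},
    "silva": lambda c, **kw: {"cl": _cl_silva(c), "v": 0.24 * c.weight},
    "ogungbenro": lambda c, **kw: {
        "cl": _cl_ogungbenro(c),
        "vc": 10.3 * (c.weight / 70.0) * (c.age / 8.5) ** -0.267,
        "vp": 4.08 * (c.weight / 70.0),
        "q": 5.34 * (c.weight / 70.0) ** 0.75},
    "nakashima": lambda c, **kw: {
        "cl": _cl_nakashima(c), "v": 21.4 * (c.daily_dose / 1000.0) ** 1.52},
    "ding": lambda c, **kw: {"cl": _cl_ding(c), "v": 22.2 * (c.weight / 70.0)},
    "rodrigues": lambda c, **kw: {"cl": _cl_rodrigues(c), "v": 13.0 * (c.weight / 70.0)},
    "gu": lambda c, **kw: {"cl": _cl_gu(c), "v": 1680.1 * (c.weight / 70.0)},
    "serrano2022": lambda c, **kw: {"cl": _cl_serrano2022(c), "v": 14.0 * (c.weight / 70.0)},
}


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

def _cv(percent: float) -> float:
    """Printed CV% -> lognormal eta SD (standard pharmacometric reading)."""
    return percent / 100.0


_GU_DING_KA = {"syrup": (2.64, 0.0), "conventional_tablet": (1.57, 0.0),
               "sustained_release": (0.46, 0.0)}

MODELS: dict[str, ModelSpec] = {
    "serrano2019": ModelSpec(
        id="serrano2019", label="Serrano et al. 2019", structural="1CMT",
        omega={"cl": _cv(21.4)}, omega_cov={},
        residual=("additive", 15.6),
        ka_rule={"*": (1.9, 0.0)}, ka_fallback={},
        required_covariates=("weight", "daily_dose_per_kg", "cbz")),
    "eldesoky": ModelSpec(
        id="eldesoky", label="El-Desoky et al.", structural="1CMT",
        omega={"cl": _cv(23.6)}, omega_cov={},
        residual=("additive", 5.24),
        ka_rule={"syrup": (4.0, 0.0), "enteric_coated": (1.0, 0.0)},
        ka_fallback={"sustained_release": (1.0, 0.0),
                     "conventional_tablet": (1.0, 0.0),
                     "capsule": (1.0, 0.0), "sprinkle": (1.0, 0.0)},
        required_covariates=("daily_dose", "age", "cbz", "uncontrolled_epilepsy")),
    "jiang": ModelSpec(
        id="jiang", label="Jiang et al.", structural="1CMT",
        omega={"cl": _cv(25.1), "v": _cv(49.1), "ka": _cv(11.0)}, omega_cov={},
        residual=("additive", 13.2),
        # ka = 0.251 + 2.24 (1 - HS); HS = 1 for sustained release
        ka_rule={"sustained_release": (0.251, 0.0), "*": (2.491, 0.0)},
        ka_fallback={},
        required_covariates=("age", "weight")),
    "silva": ModelSpec(
        id="silva", label="Silva et al.", structural="1CMT",
        omega={"cl": _cv(14.1)}, omega_cov={},
        residual=("additive", 17.3),
        ka_rule={"*": (1.2, 0.0)}, ka_fallback={},
        required_covariates=("weight", "daily_dose", "pb")),
    "ogungbenro": ModelSpec(
        id="ogungbenro", label="Ogungbenro & Aarons", structural="2CMT",
        omega={"cl": _cv(35.9), "vc": _cv(19.6), "vp": _cv(101.5)},
        # reported joint-variability entries, read as covariances of the etas
        omega_cov={frozenset(("cl", "vc")): 0.0397,
                   frozenset(("cl", "vp")): 0.0777,
                   frozenset(("vc", "vp")): 0.144},
        residual=("proportional", 0.348),
        ka_rule={"capsule": (2.0, 0.0), "sprinkle": (1.2, 1.0),
                 "conventional_tablet": (4.1, 2.0)},
        ka_fallback={"syrup": (2.0, 0.0), "sustained_release": (1.2, 1.0),
                     "enteric_coated": (4.1, 2.0)},
        required_covariates=("weight", "age")),
    "nakashima": ModelSpec(
        id="nakashima", label="Nakashima et al.", structural="1CMT",
        # V and ka variability entries are printed as variances of the etas
        omega={"cl": _cv(24.2), "v": math.sqrt(0.043), "ka": math.sqrt(0.088)},
        omega_cov={},
        residual=("proportional", 0.248),
        ka_rule={"*": (0.109, 3.00)}, ka_fallback={},
        required_covariates=("daily_dose", "sex", "cbz", "pb", "pht", "clb")),
    "ding": ModelSpec(
        id="ding", label="Ding et al.", structural="1CMT",
        omega={"cl": _cv(19.5)}, omega_cov={},
        residual=("additive", 13.3),
        ka_rule=_GU_DING_KA,
        ka_fallback={"enteric_coated": (1.57, 0.0), "capsule": (1.57, 0.0),
                     "sprinkle": (2.64, 0.0)},
        required_covariates=("weight", "age", "daily_dose_per_kg", "cbz")),
    "rodrigues": ModelSpec(
        id="rodrigues", label="Rodrigues et al.", structural="1CMT",
        omega={"cl": _cv(33.9)}, omega_cov={},
        residual=("proportional", 0.154),
        ka_rule={"*": (0.274, 0.0)}, ka_fallback={},
        required_covariates=("weight",)),
    "gu": ModelSpec(
        id="gu", label="Gu et al.", structural="1CMT",
        omega={"cl": _cv(43.0), "v": _cv(92.8)}, omega_cov={},
        residual=("proportional", 0.025),
        ka_rule=_GU_DING_KA,
        ka_fallback={"enteric_coated": (1.57, 0.0), "capsule": (1.57, 0.0),
                     "sprinkle": (2.64, 0.0)},
        required_covariates=("weight", "pma", "ltg"),
        obs_strategy="linear_ns",
        notes="structural parameters describe unbound drug; observations "
              "are total concentrations via the linear non-saturable "
              "binding equation"),
    "serrano2022": ModelSpec(
        id="serrano2022", label="Serrano et al. 2022", structural="1CMT",
        omega={"cl": _cv(26.8)}, omega_cov={},
        residual=("proportional", 0.577),
        ka_rule={"syrup": (2.64, 0.0), "enteric_coated": (0.78, 0.0),
                 "sustained_release": (0.38, 0.0)},
        ka_fallback={"conventional_tablet": (0.78, 0.0), "capsule": (2.64, 0.0),
                     "sprinkle": (2.64, 0.0)},
        required_covariates=("weight", "age", "pht", "pb", "cbz")),
}

MODEL_IDS = tuple(MODELS)


def get_model(model_id: str) -> ModelSpec:
    try:
        return MODELS[model_id]
    except KeyError:
        raise KeyError(f"unknown model id {model_id!r}; valid ids: "
                       f"{', '.join(MODEL_IDS)}") from None


def _resolve_ka(spec: ModelSpec, formulation: str,
                allow_fallback: bool) -> tuple[float, float]:
    if formulation in spec.ka_rule:
        return spec.ka_rule[formulation]
    if "*" in spec.ka_rule:
        return spec.ka_rule["*"]
    if allow_fallback and formulation in spec.ka_fallback:
        return spec.ka_fallback[formulation]
    raise FormulationError(
        f"model {spec.id!r} has no absorption rule for formulation "
        f"{formulation!r} (published rules: {sorted(spec.ka_rule)})")


def typical_parameters(model_id: str, cov: Covariates, *,
                       allow_ka_fallback: bool = False,
                       jiang_literal_printed_form: bool = False) -> PKParameters:
    """Evaluate a model's covariate equations at one subject's covariates.

    Returns the population-typical :class:`PKParameters` (all random
    effects at zero).  ``allow_ka_fallback`` extends the published
    formulation rules with the documented fallback mapping so all ten
    models can be evaluated on a syrup/sustained-release TDM cohort.
    """
    spec = get_model(model_id)
    for name in spec.required_covariates:
        if getattr(cov, name, None) is None:
            raise MissingCovariateError(
                f"model {model_id!r} requires covariate {name!r}")
    ka, tlag = _resolve_ka(spec, cov.formulation, allow_ka_fallback)
    vals = _TYPICAL_FNS[model_id](cov, literal=jiang_literal_printed_form)
    if spec.structural == "2CMT":
        return PKParameters(cl=vals["cl"], v=vals["vc"], ka=ka, tlag=tlag,
                            vc=vals["vc"], vp=vals["vp"], q=vals["q"])
    return PKParameters(cl=vals["cl"], v=vals["v"], ka=ka, tlag=tlag)


def sample_individual(model_id: str, cov: Covariates, rng_seed,
                      **kwargs) -> IndividualParameters:
    """Draw one individual's parameters: typical values times exp(eta),
    eta ~ N(0, Omega) with the model's covariance structure.

    ``rng_seed`` may be an integer seed or a ``numpy.random.Generator``.
    """
    spec = get_model(model_id)
    rng = np.random.default_rng(rng_seed) if not isinstance(
        rng_seed, np.random.Generator) else rng_seed
    names = spec.eta_names
    omega = spec.omega_matrix()
    if names and np.any(np.diag(omega) > 0):
        try:
            chol = np.linalg.cholesky(omega + 1e-14 * np.eye(len(names)))
        except np.linalg.LinAlgError:
            raise ValueError(f"model {model_id!r}: omega matrix not "
                             "positive definite") from None
        eta_vec = chol @ rng.standard_normal(len(names))
    else:
        eta_vec = np.zeros(len(names))
    eta = dict(zip(names, eta_vec))
    params = _apply_eta(typical_parameters(model_id, cov, **kwargs), eta)
    return IndividualParameters(params=params, eta=eta, model_id=model_id)


def _apply_eta(p: PKParameters, eta: dict) -> PKParameters:
    updates = {}
    for name, value in eta.items():
        current = getattr(p, name)
        updates[name] = current * math.exp(value)
    if "vc" in updates:
        updates["v"] = updates["vc"]
    fields = {f: getattr(p, f) for f in ("cl", "v", "ka", "tlag", "vc", "vp", "q")}
    fields.update(updates)
    return PKParameters(**fields)


def residual_apply(model_id: str, conc, rng_seed):
    """Perturb concentrations with the model's residual-error model.

    Additive models add N(0, sigma^2) noise in mg/L; proportional models
    multiply by (1 + eps), eps ~ N(0, sigma^2).  Results are floored at
    zero (a concentration cannot be negative); scalar in, scalar out.
    """
    spec = get_model(model_id)
    rng = np.random.default_rng(rng_seed) if not isinstance(
        rng_seed, np.random.Generator) else rng_seed
    conc_arr = np.asarray(conc, dtype=float)
    if np.any(conc_arr < 0):
        raise ValueError("concentration must be >= 0")
    kind, sigma = spec.residual
    eps = rng.standard_normal(conc_arr.shape) * sigma
    out = conc_arr + eps if kind == "additive" else conc_arr * (1.0 + eps)
    out = np.maximum(out, 0.0)
    return out if out.ndim else out.item()


# ---------------------------------------------------------------------------
# predictions
# ---------------------------------------------------------------------------

def _conc_subject(spec: ModelSpec, p_arrays: dict, subject: SubjectRecord,
                  times=None) -> np.ndarray:
    """Concentration at each observation time for (possibly vectorised)
    parameter arrays; returns shape broadcast(params) x n_times."""
    if times is None:
        times = [o.time for o in subject.observations]
    two = spec.structural == "2CMT"
    cols = []
    for t in times:
        total = 0.0
        for d in subject.doses:
            if d.steady_state:
                args = (d.amount, d.interdose_interval, t - d.time)
                if two:
                    c = _conc_2cmt_ss_arr(*args, p_arrays["cl"], p_arrays["vc"],
                                          p_arrays["vp"], p_arrays["q"],
                                          p_arrays["ka"], p_arrays["tlag"])
                else:
                    c = _conc_1cmt_ss_arr(*args, p_arrays["cl"], p_arrays["v"],
                                          p_arrays["ka"], p_arrays["tlag"])
            else:
                if d.time > t:
                    continue
                args = (d.amount, t - d.time)
                if two:
                    c = _conc_2cmt_single_arr(*args, p_arrays["cl"], p_arrays["vc"],
                                              p_arrays["vp"], p_arrays["q"],
                                              p_arrays["ka"], p_arrays["tlag"])
                else:
                    c = _conc_1cmt_single_arr(*args, p_arrays["cl"], p_arrays["v"],
                                              p_arrays["ka"], p_arrays["tlag"])
            total = total + c
        cols.append(np.atleast_1d(total))
    out = np.stack(np.broadcast_arrays(*cols), axis=-1) if cols else np.zeros((1, 0))
    if spec.obs_strategy is not None:
        out = out + bound_concentration(spec.obs_strategy, out,
                                        subject.covariates.albumin,
                                        LINEAR_NS_DEFAULTS)
    return out


def _params_to_arrays(p: PKParameters, eta: dict | None = None) -> dict:
    """Parameter dict of broadcastable arrays, optionally scaled by exp(eta)
    (eta values may themselves be arrays, enabling replicate simulation)."""
    arrays = {"cl": np.asarray(p.cl, float), "v": np.asarray(p.v, float),
              "ka": np.asarray(p.ka, float), "tlag": np.asarray(p.tlag, float)}
    if p.is_two_compartment:
        arrays.update(vc=np.asarray(p.vc, float), vp=np.asarray(p.vp, float),
                      q=np.asarray(p.q, float))
    if eta:
        for name, value in eta.items():
            arrays[name] = arrays[name] * np.exp(np.asarray(value, float))
        if "vc" in eta:
            arrays["v"] = arrays["vc"]
    return arrays


def population_predictions(model_id: str, subject: SubjectRecord,
                           **kwargs) -> list[tuple[float, float]]:
    """PRED (all random effects at zero) at each observation time.

    For the Gu model the unbound structural prediction is mapped to a
    total concentration through its binding observation function.
    Returns ``[(time, pred_mg_per_L), ...]``, one entry per observation.
    """
    spec = get_model(model_id)
    p = typical_parameters(model_id, subject.covariates, **kwargs)
    preds = _conc_subject(spec, _params_to_arrays(p), subject)[0]
    return [(o.time, float(c)) for o, c in zip(subject.observations, preds)]


def individual_predictions(model_id: str, subject: SubjectRecord,
                           eta: dict, times=None, **kwargs) -> np.ndarray:
    """IPRED at observation times (or ``times``) for a given eta vector.

    ``eta`` maps parameter name -> value; values may be arrays (e.g. one
    draw per simulation replicate), in which case the result has shape
    ``eta_shape x n_times``.
    """
    spec = get_model(model_id)
    p = typical_parameters(model_id, subject.covariates, **kwargs)
    out = _conc_subject(spec, _params_to_arrays(p, eta), subject, times=times)
    return out if out.shape[0] > 1 else out[0]


def export_registry() -> dict:
    """Registry as plain data (YAML/JSON-ready) so every constant is
    auditable without reading code."""
    reg = {}
    for mid, spec in MODELS.items():
        reg[mid] = {
            "label": spec.label,
            "structural": spec.structural,
            "bsv_omega": dict(spec.omega),
            "bsv_covariances": {"~".join(sorted(k)): v
                                for k, v in spec.omega_cov.items()},
            "residual": {"kind": spec.residual[0], "sigma": spec.residual[1]},
            "ka_rule": {k: {"ka": v[0], "tlag": v[1]}
                        for k, v in spec.ka_rule.items()},
            "ka_fallback": {k: {"ka": v[0], "tlag": v[1]}
                            for k, v in spec.ka_fallback.items()},
            "required_covariates": list(spec.required_covariates),
            "observation_strategy": spec.obs_strategy,
        }
    return reg
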