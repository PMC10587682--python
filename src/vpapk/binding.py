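"""Protein-binding non-linearity strategies for valproic acid.

VPA is 90-95% bound to plasma albumin and the binding saturates over the
therapeutic range, so total concentration rises less than proportionally
with dose.  Five modelling strategies capture this:

* ``one_site``   - single-class binding-site model: Cb = N*K*Cu*ALB/(1+K*Cu),
  evaluated in molar units (N = sites per albumin, K in 1/mM).
* ``langmuir``   - Langmuir isotherm: Cb = Bm*Cu/(Kd+Cu).
* ``linear_ns``  - Langmuir plus a linear non-saturable component:
  Cb = Bm*Cu/(Kd+Cu) + NS*Cu.
* ``dde``        - dose-dependent maximum-effect clearance:
  CL = CLp*(1 + Emax*DDW^g/(DD50^g+DDW^g)).
* ``exponent``   - simple exponent clearance: CL = CLp*(DDW/25)^k.

The first three are observation functions (the structural compartment
tracks unbound drug; measurements are total), the last two act on
apparent clearance directly.  ``fit_population`` estimates the free
parameters of each strategy on a trough dataset by a Laplace-approximate
marginal likelihood with a lognormal between-subject effect on clearance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize

from .structural import _conc_1cmt_ss_arr

__all__ = [
    "BindingParams",
    "BindingFitResult",
    "OBSERVATION_STRATEGIES",
    "CLEARANCE_STRATEGIES",
    "VARIANTS",
    "bound_concentration",
    "total_from_unbound",
    "unbound_from_total",
    "nonlinear_clearance",
    "fit_population",
    "population_ofv",
]

VPA_MOLAR_MASS = 144.21  # g/mol
ALBUMIN_MOLAR_MASS = 66_500.0  # g/mol

OBSERVATION_STRATEGIES = ("one_site", "langmuir", "linear_ns")
CLEARANCE_STRATEGIES = ("dde", "exponent")

#: Mapping of population-fit variant -> binding strategy.  Variants I, II
#: and IV track unbound drug with a total-concentration observation
#: function; III and V put the non-linearity on clearance.
VARIANTS = {
    "model_I": "one_site",
    "model_II": "langmuir",
    "model_III": "dde",
    "model_IV": "linear_ns",
    "model_V": "exponent",
}


@dataclass(frozen=True)
class BindingParams:
    """Binding and non-linearity constants.

    Defaults are the literature values the strategies are anchored to:
    one-site N=1.98 sites, K=15.5 /mM; Langmuir Kd=7.8, Bm=130 mg/L;
    linear non-saturable Kd=2.12, Bm=67.3 mg/L, NS=2.25; DDE Emax=2.8,
    gamma=1.68 with DD50 estimable; exponent k estimable around a
    reference daily dose of 25 mg/kg/day.
    """

    n_sites: float = 1.98  # binding sites per albumin molecule
    k_assoc: float = 15.5  # 1/mM
    kd: float = 7.8  # mg/L (Langmuir); use 2.12 for linear_ns
    bm: float = 130.0  # mg/L (Langmuir); use 67.3 for linear_ns
    ns: float = 2.25  # dimensionless slope of non-saturable binding
    emax: float = 2.8
    gamma: float = 1.68
    dd50: float = 37.4  # mg/kg/day, estimable
    k_exp: float = 0.0  # exponent of daily dose, estimable
    clp: float = 0.31  # L/h, estimable plasma clearance
    dd_ref: float = 25.0  # mg/kg/day normalisation of the exponent model

    def __post_init__(self) -> None:
        for name in ("n_sites", "k_assoc", "kd", "bm", "ns", "emax", "dd50", "clp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.gamma <= 0:
            raise ValueError(f"gamma must be > 0, got {self.gamma}")


#: Constants as used for the linear non-saturable strategy.
LINEAR_NS_DEFAULTS = BindingParams(kd=2.12, bm=67.3, ns=2.25)


def _params_for(strategy: str, p: BindingParams | None) -> BindingParams:
    if p is not None:
        return p
    return LINEAR_NS_DEFAULTS if strategy == "linear_ns" else BindingParams()


def bound_concentration(strategy: str, cu, alb: float = 42.0,
                        p: BindingParams | None = None):
    """Bound VPA concentration (mg/L) as a function of unbound ``cu`` (mg/L).

    ``alb`` (g/L) is consumed only by the ``one_site`` strategy.  Accepts
    scalars or arrays; monotone non-decreasing in ``cu``.
    """
    p = _params_for(strategy, p)
    cu = np.asarray(cu, dtype=float)
    if np.any(cu < 0):
        raise ValueError("unbound concentration must be >= 0")
    if strategy == "one_site":
        cu_mm = cu / VPA_MOLAR_MASS  # mg/L over g/mol -> mmol/L = mM
        alb_mm = alb / (ALBUMIN_MOLAR_MASS / 1000.0)
        cb_mm = p.n_sites * p.k_assoc * cu_mm * alb_mm / (1.0 + p.k_assoc * cu_mm)
        cb = cb_mm * VPA_MOLAR_MASS
    elif strategy == "langmuir":
        cb = p.bm * cu / (p.kd + cu)
    elif strategy == "linear_ns":
        cb = p.bm * cu / (p.kd + cu) + p.ns * cu
    else:
        raise ValueError(f"unknown observation strategy {strategy!r}; "
                         f"expected one of {OBSERVATION_STRATEGIES}")
    return cb if cb.ndim else cb.item()


def total_from_unbound(strategy: str, cu, alb: float = 42.0,
                       p: BindingParams | None = None):
    """Total concentration Ct = Cu + Cb(Cu); strictly increasing in Cu."""
    cb = bound_concentration(strategy, cu, alb, p)
    out = np.asarray(cu, dtype=float) + cb
    return out if np.ndim(cu) else out.item()


def unbound_from_total(strategy: str, ct, alb: float = 42.0,
                       p: BindingParams | None = None):
    """Invert the total-concentration observation function.

    Unique because Ct(Cu) is strictly increasing; solved by bracketed
    Brent root-finding on [0, Ct] to an absolute tolerance of 1e-12 mg/L.
    """
    p = _params_for(strategy, p)

    def invert_one(ct_i: float) -> float:
        if ct_i < 0:
            raise ValueError("total concentration must be >= 0")
        if ct_i == 0.0:
            return 0.0
        f = lambda cu: total_from_unbound(strategy, cu, alb, p) - ct_i
        return optimize.brentq(f, 0.0, ct_i, xtol=1e-12, rtol=1e-14, maxiter=200)

    if np.ndim(ct):
        return np.array([invert_one(float(c)) for c in np.asarray(ct).ravel()]
                        ).reshape(np.shape(ct))
    return invert_one(float(ct))


def nonlinear_clearance(strategy: str, clp, ddw, p: BindingParams | None = None):
    """Apparent clearance (L/h) under a dose-driven non-linearity.

    ``dde``:      CL = clp * (1 + Emax * DDW^g / (DD50^g + DDW^g))
    ``exponent``: CL = clp * (DDW / 25)^k
    with DDW the daily dose in mg/kg/day.
    """
    p = p if p is not None else BindingParams()
    clp = np.asarray(clp, dtype=float)
    ddw = np.asarray(ddw, dtype=float)
    if np.any(ddw < 0):
        raise ValueError("daily dose must be >= 0")
    if strategy == "dde":
        frac = ddw ** p.gamma / (p.dd50 ** p.gamma + ddw ** p.gamma)
        out = clp * (1.0 + p.emax * frac)
    elif strategy == "exponent":
        out = clp * (ddw / p.dd_ref) ** p.k_exp
    else:
        raise ValueError(f"unknown clearance strategy {strategy!r}; "
                         f"expected one of {CLEARANCE_STRATEGIES}")
    return out if out.ndim else out.item()


# ---------------------------------------------------------------------------
# population fitting (Laplace-approximate marginal likelihood)
# ---------------------------------------------------------------------------

#: Fixed absorption rate constants by formulation during binding fits;
#: trough-only data cannot identify absorption, so ka is never estimated.
FIT_KA = {"syrup": 2.64, "conventional_tablet": 1.57, "sustained_release": 0.46}


@dataclass(frozen=True)
class BindingFitResult:
    """Estimates and objective of one population binding fit."""

    variant: str
    estimates: dict  # clp, v, omega_cl, sigma_prop (+ dd50 or k_exp)
    ofv: float  # -2 log approximate marginal likelihood
    converged: bool
    n_subjects: int
    n_obs: int
    seed: int
    n_starts: int = 5
    start_ofvs: tuple = field(default_factory=tuple)


class _FitData:
    """Per-observation flat arrays extracted from a PKDataset."""

    def __init__(self, ds) -> None:
        sid, dose, tau, tad, y, ddw, alb, ka = [], [], [], [], [], [], [], []
        for i, s in enumerate(ds.subjects):
            d = s.doses[0]
            if not d.steady_state:
                raise ValueError(
                    f"subject {s.id}: binding fits expect steady-state regimens")
            ka_i = FIT_KA.get(s.covariates.formulation)
            if ka_i is None:
                raise ValueError(
                    f"subject {s.id}: no fixed ka for formulation "
                    f"{s.covariates.formulation!r}")
            for o in s.observations:
                sid.append(i)
                dose.append(d.amount)
                tau.append(d.interdose_interval)
                tad.append(o.time_after_dose)
                y.append(o.concentration)
                ddw.append(s.covariates.daily_dose_per_kg)
                alb.append(s.covariates.albumin)
                ka.append(ka_i)
        self.subject_index = np.asarray(sid)
        self.dose = np.asarray(dose, dtype=float)
        self.tau = np.asarray(tau, dtype=float)
        self.tad = np.asarray(tad, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.ddw = np.asarray(ddw, dtype=float)
        self.alb = np.asarray(alb, dtype=float)
        self.ka = np.asarray(ka, dtype=float)
        self.n_subjects = len(ds.subjects)
        self.n_obs = len(self.y)


def _predict_obs(variant: str, data: _FitData, clp: float, v: float,
                 eta_per_obs: np.ndarray, p: BindingParams) -> np.ndarray:
    """Predicted total concentration per observation given per-obs eta on CL."""
    strategy = VARIANTS[variant]
    if strategy in CLEARANCE_STRATEGIES:
        cl = nonlinear_clearance(strategy, clp, data.ddw, p) * np.exp(eta_per_obs)
        return _conc_1cmt_ss_arr(data.dose, data.tau, data.tad, cl, v, data.ka)
    # unbound kinetics; observation is total
    cl_u = clp * np.exp(eta_per_obs)
    cu = _conc_1cmt_ss_arr(data.dose, data.tau, data.tad, cl_u, v, data.ka)
    if strategy == "one_site":
        return cu + _one_site_vec(cu, data.alb, p)
    return cu + bound_concentration(strategy, cu, p=p)


def _one_site_vec(cu: np.ndarray, alb: np.ndarray, p: BindingParams) -> np.ndarray:
    cu_mm = cu / VPA_MOLAR_MASS
    alb_mm = alb / (ALBUMIN_MOLAR_MASS / 1000.0)
    return p.n_sites * p.k_assoc * cu_mm * alb_mm / (1.0 + p.k_assoc * cu_mm) \
        * VPA_MOLAR_MASS


_LOG2PI = math.log(2.0 * math.pi)


def _joint_m2ll(variant, data, clp, v, omega, sigma, eta_subj, p):
    """-2 log joint density, per subject (vector of length n_subjects)."""
    eta_obs = eta_subj[data.subject_index]
    f = _predict_obs(variant, data, clp, v, eta_obs, p)
    f = np.maximum(f, 1e-9)  # proportional error variance needs f > 0
    var = (sigma * f) ** 2
    per_obs = _LOG2PI + np.log(var) + (data.y - f) ** 2 / var
    per_subj = np.bincount(data.subject_index, weights=per_obs,
                           minlength=data.n_subjects)
    prior = _LOG2PI + 2.0 * np.log(omega) + (eta_subj / omega) ** 2
    return per_subj + prior


def _inner_map(variant, data, clp, v, omega, sigma, p,
               eta0=None, max_iter=60):
    """Vectorised damped-Newton MAP of the per-subject eta (scalar each).

    Returns (eta_hat, j(eta_hat), h) with h the second derivative of the
    -2 log joint at the optimum (central finite differences)."""
    n = data.n_subjects
    eta = np.zeros(n) if eta0 is None else eta0.copy()
    j = _joint_m2ll(variant, data, clp, v, omega, sigma, eta, p)
    step = 1e-4
    for _ in range(max_iter):
        jp = _joint_m2ll(variant, data, clp, v, omega, sigma, eta + step, p)
        jm = _joint_m2ll(variant, data, clp, v, omega, sigma, eta - step, p)
        g = (jp - jm) / (2.0 * step)
        h = (jp - 2.0 * j + jm) / step ** 2
        h_safe = np.where(h > 1e-8, h, 2.0 / omega ** 2)  # prior curvature fallback
        delta = -g / h_safe
        delta = np.clip(delta, -1.0, 1.0)
        # backtracking (vectorised): halve steps that do not decrease j
        for _bt in range(20):
            trial = _joint_m2ll(variant, data, clp, v, omega, sigma, eta + delta, p)
            worse = trial > j + 1e-12
            if not np.any(worse):
                break
            delta = np.where(worse, 0.5 * delta, delta)
            if np.max(np.abs(delta)) < 1e-14:
                break
        eta = eta + np.where(trial <= j, delta, 0.0)
        j_new = np.minimum(trial, j)
        if np.max(np.abs(g)) < 1e-7 or np.max(np.abs(j - j_new)) < 1e-12:
            j = j_new
            break
        j = j_new
    # curvature at the optimum
    jp = _joint_m2ll(variant, data, clp, v, omega, sigma, eta + step, p)
    jm = _joint_m2ll(variant, data, clp, v, omega, sigma, eta - step, p)
    h = (jp - 2.0 * j + jm) / step ** 2
    h = np.where(h > 1e-8, h, 2.0 / omega ** 2)
    return eta, j, h


def _laplace_ofv(variant, data, clp, v, omega, sigma, p, extra=None):
    """-2 log Laplace-approximate marginal likelihood of the dataset."""
    eta, j, h = _inner_map(variant, data, clp, v, omega, sigma, p)
    # integral ~ joint(eta_hat) * sqrt(2 pi / (j''/2));   j = -2 log joint
    return float(np.sum(j - _LOG2PI + np.log(0.5 * h)))


def _unpack(variant: str, x: np.ndarray, base: BindingParams):
    clp, v, omega, sigma = np.exp(x[:4])
    p = base
    if variant == "model_III":
        p = replace(base, dd50=float(np.exp(x[4])))
    elif variant == "model_V":
        p = replace(base, k_exp=float(x[4]))
    return float(clp), float(v), float(omega), float(sigma), p


def _n_free(variant: str) -> int:
    return 5 if variant in ("model_III", "model_V") else 4


_DEFAULT_INIT = {"clp": 0.31, "v": 15.0, "omega_cl": 0.3, "sigma_prop": 0.15,
                 "dd50": 30.0, "k_exp": 0.3}
# Unbound-kinetics variants (I, II, IV) have much larger apparent unbound
# clearance/volume; start them in that regime.
_UNBOUND_INIT = {"clp": 3.0, "v": 400.0, "omega_cl": 0.3, "sigma_prop": 0.15}


def population_ofv(variant: str, ds, params: dict,
                   base: BindingParams | None = None) -> float:
    """OFV (-2 log approximate marginal likelihood) at given parameters.

    ``params`` holds clp, v, omega_cl, sigma_prop and, depending on the
    variant, dd50 (model III) or k_exp (model V).
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    base = _fit_base(variant, base)
    data = _FitData(ds)
    p = base
    if variant == "model_III":
        p = replace(p, dd50=float(params["dd50"]))
    elif variant == "model_V":
        p = replace(p, k_exp=float(params["k_exp"]))
    return _laplace_ofv(variant, data, params["clp"], params["v"],
                        params["omega_cl"], params["sigma_prop"], p)


def _fit_base(variant: str, base: BindingParams | None) -> BindingParams:
    if base is not None:
        return base
    return LINEAR_NS_DEFAULTS if variant == "model_IV" else BindingParams()


def fit_population(variant: str, ds, init: dict | None = None,
                   seed: int = 0, n_starts: int = 5,
                   base: BindingParams | None = None) -> BindingFitResult:
    """Fit one binding-strategy population model to a trough dataset.

    The structural base is a one-compartment first-order-absorption model
    at steady state with ka fixed by formulation; free parameters are the
    plasma (or unbound) clearance ``clp``, volume ``v``, the lognormal
    between-subject SD on clearance ``omega_cl`` and the proportional
    residual SD ``sigma_prop``, plus ``dd50`` (model III) or ``k_exp``
    (model V).  Binding constants stay fixed at their literature values.

    Optimisation is bounded quasi-Newton (L-BFGS-B) on log-transformed
    parameters with ``n_starts`` multi-starts jittered deterministically
    from ``seed``; the marginal likelihood uses a per-subject Laplace
    approximation with finite-difference curvature.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of "
                         f"{sorted(VARIANTS)}")
    base = _fit_base(variant, base)
    data = _FitData(ds)
    strategy = VARIANTS[variant]
    defaults = dict(_DEFAULT_INIT if strategy in CLEARANCE_STRATEGIES
                    else {**_DEFAULT_INIT, **_UNBOUND_INIT})
    if init:
        defaults.update(init)

    x0 = np.array([math.log(defaults["clp"]), math.log(defaults["v"]),
                   math.log(defaults["omega_cl"]), math.log(defaults["sigma_prop"])])
    if variant == "model_III":
        x0 = np.append(x0, math.log(defaults["dd50"]))
    elif variant == "model_V":
        x0 = np.append(x0, defaults["k_exp"])

    lo = np.array([math.log(1e-4), math.log(0.1), math.log(0.01), math.log(0.005)])
    hi = np.array([math.log(1e3), math.log(1e5), math.log(3.0), math.log(2.0)])
    if variant == "model_III":
        lo, hi = np.append(lo, math.log(1.0)), np.append(hi, math.log(500.0))
    elif variant == "model_V":
        lo, hi = np.append(lo, -3.0), np.append(hi, 3.0)
    bounds = list(zip(lo, hi))

    def objective(x: np.ndarray) -> float:
        clp, v, omega, sigma, p = _unpack(variant, x, base)
        try:
            val = _laplace_ofv(variant, data, clp, v, omega, sigma, p)
        except FloatingPointError:
            return 1e12
        return val if np.isfinite(val) else 1e12

    rng = np.random.default_rng(seed)
    best = None
    start_ofvs = []
    for start in range(max(1, n_starts)):
        xs = x0 if start == 0 else np.clip(
            x0 + rng.normal(0.0, 0.3, size=x0.size), lo, hi)
        res = optimize.minimize(objective, xs, method="L-BFGS-B", bounds=bounds,
                                options={"maxiter": 300, "ftol": 1e-10})
        start_ofvs.append(float(res.fun))
        if best is None or res.fun < best.fun:
            best = res

    clp, v, omega, sigma, p = _unpack(variant, best.x, base)
    estimates = {"clp": clp, "v": v, "omega_cl": omega, "sigma_prop": sigma}
    if variant == "model_III":
        estimates["dd50"] = p.dd50
    elif variant == "model_V":
        estimates["k_exp"] = p.k_exp
    return BindingFitResult(
        variant=variant, estimates=estimates, ofv=float(best.fun),
        converged=bool(best.success and np.isfinite(best.fun)),
        n_subjects=data.n_subjects, n_obs=data.n_obs, seed=seed,
        n_starts=max(1, n_starts), start_ofvs=tuple(start_ofvs))
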