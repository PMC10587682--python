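"""Closed-form concentration predictions for oral first-order-absorption models.

One- and two-compartment disposition, single dose, arbitrary dose
histories by superposition, and multiple-dose steady state.  All
parameters are apparent oral parameters (CL/F, V/F, ...): bioavailability
is absorbed into them, as the published pediatric VPA models
parameterise.  Every function broadcasts over numpy arrays so the
simulation diagnostics can evaluate thousands of replicate parameter
sets in one call.

Units: time h, amounts mg, volumes L, clearances L/h, concentrations mg/L.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PKParameters",
    "conc_1cmt_single",
    "conc_1cmt_ss",
    "conc_2cmt_single",
    "conc_2cmt_ss",
    "conc_superposition",
]

# Relative ka-vs-ke gap below which the absorption/elimination closed form
# switches to its analytic confluent limit (avoids catastrophic cancellation).
_KA_KE_TOL = 1e-8


@dataclass(frozen=True)
class PKParameters:
    """Apparent PK parameters of one individual (or the population typical).

    ``cl``/``v``/``ka`` suffice for one-compartment kinetics; ``vc``,
    ``vp`` and ``q`` switch on the two-compartment disposition (``v`` is
    then ignored and ``vc`` is the central volume the concentration
    refers to).
    """

    cl: float  # L/h
    v: float  # L
    ka: float  # 1/h
    tlag: float = 0.0  # h
    vc: float | None = None
    vp: float | None = None
    q: float | None = None

    def __post_init__(self) -> None:
        for name in ("cl", "v", "ka"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.tlag < 0:
            raise ValueError(f"tlag must be >= 0, got {self.tlag}")
        if self.is_two_compartment:
            if self.vc is None or self.vp is None or self.q is None:
                raise ValueError("two-compartment model needs vc, vp and q together")
            if self.vc <= 0 or self.vp <= 0 or self.q <= 0:
                raise ValueError("vc, vp, q must all be > 0")

    @property
    def is_two_compartment(self) -> bool:
        return self.q is not None or self.vp is not None or self.vc is not None


# ---------------------------------------------------------------------------
# one compartment
# ---------------------------------------------------------------------------

def _conc_1cmt_single_arr(dose, t, cl, v, ka, tlag=0.0):
    dose, t, cl, v, ka, tlag = np.broadcast_arrays(
        *np.atleast_1d(dose, t, cl, v, ka, tlag))
    ke = cl / v
    tp = np.maximum(t - tlag, 0.0)
    degenerate = np.abs(ka - ke) < _KA_KE_TOL * ke
    ka_safe = np.where(degenerate, ke * 2.0, ka)  # dummy; branch masked out
    with np.errstate(over="ignore", invalid="ignore"):
        regular = (dose * ka_safe / (v * (ka_safe - ke))) * (
            np.exp(-ke * tp) - np.exp(-ka_safe * tp))
    limit = dose * ke * tp * np.exp(-ke * tp) / v
    out = np.where(degenerate, limit, regular)
    return np.where(t < tlag, 0.0, out)


def conc_1cmt_single(p: PKParameters, dose: float, t):
    """Concentration after a single oral dose at t=0 (1CMT, first order)."""
    _check_positive_dose_time(dose, t)
    out = _conc_1cmt_single_arr(dose, t, p.cl, p.v, p.ka, p.tlag)
    return out.item() if np.isscalar(t) else out


def _conc_1cmt_ss_arr(dose, tau, t, cl, v, ka, tlag=0.0):
    """Vectorised steady-state 1CMT profile; ``t`` taken modulo ``tau``
    after subtracting ``tlag`` (times before tlag wrap to the previous
    interval's tail)."""
    dose, tau, t, cl, v, ka, tlag = np.broadcast_arrays(
        *np.atleast_1d(dose, tau, t, cl, v, ka, tlag))
    ke = cl / v
    tp = np.mod(t - tlag, tau)
    eke = np.exp(-ke * tau)
    degenerate = np.abs(ka - ke) < _KA_KE_TOL * ke
    ka_safe = np.where(degenerate, ke * 2.0, ka)
    with np.errstate(over="ignore", invalid="ignore"):
        eka = np.exp(-ka_safe * tau)
        regular = (dose * ka_safe / (v * (ka_safe - ke))) * (
            np.exp(-ke * tp) / (1.0 - eke) - np.exp(-ka_safe * tp) / (1.0 - eka))
    # confluent limit ka -> ke of the accumulation form
    limit = (dose * ke / v) * (
        tp * np.exp(-ke * tp) / (1.0 - eke)
        + tau * np.exp(-ke * (tp + tau)) / (1.0 - eke) ** 2)
    return np.where(degenerate, limit, regular)


def conc_1cmt_ss(p: PKParameters, dose: float, tau: float, t):
    """Steady-state concentration under a repeated oral regimen.

    Parameters
    ----------
    p : PKParameters
        One-compartment parameters (cl, v, ka; optional tlag).
    dose : mg per administration.
    tau : dosing interval, h.
    t : time within (or beyond) an interval, h; evaluated modulo ``tau``
        after subtracting ``tlag``, so ``t = tau`` is the trough.

    Notes
    -----
    Continuous in all parameters; the ka -> ke degeneracy evaluates the
    analytic ``t e^{-kt}`` limit.
    """
    _check_positive_dose_time(dose, t)
    if tau <= 0:
        raise ValueError(f"tau must be > 0, got {tau}")
    out = _conc_1cmt_ss_arr(dose, tau, t, p.cl, p.v, p.ka, p.tlag)
    return out.item() if np.isscalar(t) else out


def _check_positive_dose_time(dose, t) -> None:
    if np.any(np.asarray(dose) < 0):
        raise ValueError("dose must be >= 0")
    if np.any(np.asarray(t) < 0):
        raise ValueError("t must be >= 0")


# ---------------------------------------------------------------------------
# two compartments
# ---------------------------------------------------------------------------

def _macro_constants(cl, vc, vp, q):
    """Hybrid rate constants (alpha, beta) and micro-constant k21."""
    ke = cl / vc
    k12 = q / vc
    k21 = q / vp
    s = ke + k12 + k21
    disc = np.sqrt(np.maximum(s * s - 4.0 * ke * k21, 0.0))
    alpha = 0.5 * (s + disc)
    beta = 0.5 * (s - disc)
    return alpha, beta, k21


def _sep(ka, lam):
    """Nudge ka off an exact eigenvalue collision (measure-zero degeneracy)."""
    return np.where(np.abs(ka - lam) < 1e-9 * lam, ka * (1.0 + 1e-7), ka)


def _conc_2cmt_terms(dose, cl, vc, vp, q, ka):
    alpha, beta, k21 = _macro_constants(cl, vc, vp, q)
    ka = _sep(_sep(ka, alpha), beta)
    pref = ka * dose / vc
    ca = pref * (k21 - alpha) / ((ka - alpha) * (beta - alpha))
    cb = pref * (k21 - beta) / ((ka - beta) * (alpha - beta))
    cc = pref * (k21 - ka) / ((alpha - ka) * (beta - ka))
    return (ca, alpha), (cb, beta), (cc, ka)


def _conc_2cmt_single_arr(dose, t, cl, vc, vp, q, ka, tlag=0.0):
    dose, t, cl, vc, vp, q, ka, tlag = np.broadcast_arrays(
        *np.atleast_1d(dose, t, cl, vc, vp, q, ka, tlag))
    tp = np.maximum(t - tlag, 0.0)
    out = np.zeros_like(tp, dtype=float)
    for coef, lam in _conc_2cmt_terms(dose, cl, vc, vp, q, ka):
        out = out + coef * np.exp(-lam * tp)
    return np.where(t < tlag, 0.0, out)


def conc_2cmt_single(p: PKParameters, dose: float, t):
    """Concentration after a single oral dose, two-compartment disposition."""
    _check_positive_dose_time(dose, t)
    out = _conc_2cmt_single_arr(dose, t, p.cl, p.vc, p.vp, p.q, p.ka, p.tlag)
    return out.item() if np.isscalar(t) else out


def _conc_2cmt_ss_arr(dose, tau, t, cl, vc, vp, q, ka, tlag=0.0):
    dose, tau, t, cl, vc, vp, q, ka, tlag = np.broadcast_arrays(
        *np.atleast_1d(dose, tau, t, cl, vc, vp, q, ka, tlag))
    tp = np.mod(t - tlag, tau)
    out = np.zeros_like(tp, dtype=float)
    for coef, lam in _conc_2cmt_terms(dose, cl, vc, vp, q, ka):
        out = out + coef * np.exp(-lam * tp) / (1.0 - np.exp(-lam * tau))
    return out


def conc_2cmt_ss(p: PKParameters, dose: float, tau: float, t):
    """Steady-state two-compartment concentration (bi-exponential
    disposition with first-order absorption, accumulation by the usual
    1/(1-e^{-lambda tau}) factor per exponential)."""
    _check_positive_dose_time(dose, t)
    if tau <= 0:
        raise ValueError(f"tau must be > 0, got {tau}")
    out = _conc_2cmt_ss_arr(dose, tau, t, p.cl, p.vc, p.vp, p.q, p.ka, p.tlag)
    return out.item() if np.isscalar(t) else out


# ---------------------------------------------------------------------------
# superposition (oracle for the steady-state forms; exact for linear kinetics)
# ---------------------------------------------------------------------------

def conc_superposition(p: PKParameters, doses, t: float) -> float:
    """Sum of single-dose profiles over an explicit dose history.

    ``doses`` is an iterable of objects with ``time`` and ``amount``
    attributes (or (time, amount) pairs).  Exact for linear kinetics;
    serves as the brute-force oracle that the closed steady-state forms
    are verified against.
    """
    doses = list(doses)
    if not doses:
        raise ValueError("doses must be non-empty")
    single = conc_2cmt_single if p.is_two_compartment else conc_1cmt_single
    total = 0.0
    for d in doses:
        time, amount = (d.time, d.amount) if hasattr(d, "time") else (d[0], d[1])
        if time <= t:
            total += single(p, amount, t - time)
    return total
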