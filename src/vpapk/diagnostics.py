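"""Simulation-based diagnostics: replicate simulation, NPDE, pcVPC.

A candidate model is stress-tested by simulating the evaluation dataset
K times (default 2000) under its fixed published parameters, then asking
whether the observations look like one more replicate:

* NPDE - per subject, observed and simulated vectors are decorrelated
  with the lower-triangular factor of the empirical simulated
  covariance; the rank of each decorrelated observation within its
  simulated distribution, mapped through the standard-normal quantile,
  should be N(0,1) under a correct model.  A three-test battery
  (Wilcoxon signed-rank for the mean, a two-sided variance test against
  1, Shapiro-Wilk for normality) with a Bonferroni global decision
  formalises the check.
* pcVPC - observations and simulations are prediction-corrected
  (scaled by the ratio of the bin-median population prediction to each
  point's own prediction) and their percentiles compared per
  time-after-dose bin, with simulated 95% confidence bands.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data import PKDataset
from .models import get_model, individual_predictions, population_predictions

__all__ = [
    "SimulationEnsemble",
    "NpdeResult",
    "PcvpcResult",
    "simulate_replicates",
    "compute_npde",
    "npde_tests",
    "pcvpc",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimulationEnsemble:
    """K replicate simulations of a dataset's observation vector."""

    k: int
    sims: np.ndarray  # (k, n_obs) simulated concentrations, mg/L
    pred: np.ndarray  # (n_obs,) population predictions
    obs: np.ndarray  # (n_obs,) the actual observations
    subject_index: np.ndarray  # (n_obs,) subject of each column
    tad: np.ndarray  # (n_obs,) time after dose, h
    seed: int
    model_id: str = ""

    def __post_init__(self) -> None:
        if self.sims.shape != (self.k, self.pred.size):
            raise ValueError("sims must be k x n_obs")
        if not np.all(np.isfinite(self.sims)):
            raise ValueError("simulated concentrations must be finite")


@dataclass(frozen=True)
class NpdeResult:
    """NPDE values and the three-test battery outcome."""

    npde: np.ndarray
    p_mean: float | None = None  # Wilcoxon signed-rank vs 0
    p_var: float | None = None  # two-sided variance test vs 1
    p_norm: float | None = None  # Shapiro-Wilk
    p_global: float | None = None  # Bonferroni-adjusted min p
    reject_global: bool | None = None
    alpha: float | None = None


@dataclass(frozen=True)
class PcvpcResult:
    """Prediction-corrected VPC tables (no rendering; tidy arrays)."""

    bin_edges: np.ndarray  # (n_bins + 1,) on time after dose
    bin_n: np.ndarray  # observations per bin
    observed: np.ndarray  # (n_bins, 3): 2.5/50/97.5 percentiles of pc-obs
    sim_band_lo: np.ndarray  # (n_bins, 3): lower 95% band per percentile
    sim_band_hi: np.ndarray  # (n_bins, 3): upper 95% band per percentile
    percentiles: tuple = (2.5, 50.0, 97.5)


def simulate_replicates(model_id: str, ds: PKDataset, k: int = 2000,
                        seed: int = 0, **kwargs) -> SimulationEnsemble:
    """Simulate the dataset ``k`` times under the model's published
    parameters.

    The design (doses, sampling times, covariates) is held fixed; each
    replicate redraws every subject's etas from Omega and every
    observation's residual error from the model's error model.
    Reproducible: the same seed yields the same ensemble.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    spec = get_model(model_id)
    rng = np.random.default_rng(seed)
    names = spec.eta_names
    omega = spec.omega_matrix()
    chol = np.linalg.cholesky(omega + 1e-14 * np.eye(len(names))) if names else None

    sims_cols, pred_cols, obs_cols, sub_idx, tads = [], [], [], [], []
    for i, subject in enumerate(ds.subjects):
        n_i = len(subject.observations)
        if n_i == 0:
            continue
        if names:
            eta_draws = rng.standard_normal((k, len(names))) @ chol.T
            eta = {n: eta_draws[:, j] for j, n in enumerate(names)}
        else:
            eta = {}
        conc = np.atleast_2d(
            individual_predictions(model_id, subject, eta, **kwargs))
        if conc.shape != (k, n_i):  # no-eta models broadcast to one row
            conc = np.broadcast_to(conc, (k, n_i)).copy()
        kind, sigma = spec.residual
        eps = rng.standard_normal((k, n_i)) * sigma
        sim = conc + eps if kind == "additive" else conc * (1.0 + eps)
        sims_cols.append(sim)
        pred_cols.extend(p for _, p in population_predictions(
            model_id, subject, **kwargs))
        obs_cols.extend(o.concentration for o in subject.observations)
        sub_idx.extend([i] * n_i)
        tads.extend(o.time_after_dose for o in subject.observations)

    return SimulationEnsemble(
        k=k, sims=np.concatenate(sims_cols, axis=1),
        pred=np.asarray(pred_cols), obs=np.asarray(obs_cols),
        subject_index=np.asarray(sub_idx), tad=np.asarray(tads),
        seed=seed, model_id=model_id)


def compute_npde(ensemble: SimulationEnsemble, obs=None,
                 ridge: float = 1e-10) -> NpdeResult:
    """Normalised prediction distribution errors.

    Per subject: decorrelate the observed vector and each simulated
    vector with the lower-triangular Cholesky factor of the empirical
    simulated covariance; the prediction discrepancy ``pde`` is the
    fraction of decorrelated simulations below the decorrelated
    observation, clamped to [1/(2k), 1 - 1/(2k)], and npde is its
    standard-normal quantile.
    """
    y_all = ensemble.obs if obs is None else np.asarray(obs, dtype=float)
    k = ensemble.k
    npde = np.empty(y_all.size)
    for i in np.unique(ensemble.subject_index):
        cols = np.flatnonzero(ensemble.subject_index == i)
        sims = ensemble.sims[:, cols]
        y = y_all[cols]
        mu = sims.mean(axis=0)
        cov = np.atleast_2d(np.cov(sims, rowvar=False, ddof=1))
        try:
            chol = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            lam = ridge * max(float(np.trace(cov)) / cov.shape[0], 1.0)
            log.warning("singular simulated covariance for subject index %s; "
                        "ridge-regularised with %.2e", i, lam)
            chol = np.linalg.cholesky(cov + lam * np.eye(cov.shape[0]))
        y_star = _tri_solve(chol, y - mu)
        sims_star = _tri_solve(chol, (sims - mu).T).T
        pde = (sims_star < y_star).mean(axis=0)
        pde = np.clip(pde, 1.0 / (2 * k), 1.0 - 1.0 / (2 * k))
        npde[cols] = stats.norm.ppf(pde)
    return NpdeResult(npde=npde)


def _tri_solve(chol: np.ndarray, b: np.ndarray) -> np.ndarray:
    from scipy.linalg import solve_triangular
    return solve_triangular(chol, b, lower=True)


def npde_tests(result: NpdeResult, alpha: float = 0.05) -> NpdeResult:
    """Three-test battery on the npde sample with a Bonferroni global rule.

    * mean: Wilcoxon signed-rank against a zero median;
    * variance: two-sided chi-square test of the sample variance against 1
      (the construction the reference NPDE implementation uses for its
      'Fisher' variance test);
    * normality: Shapiro-Wilk.

    The global decision rejects when the smallest p-value is below
    ``alpha / 3``; ``p_global = min(1, 3 * min p)``.
    """
    x = np.asarray(result.npde, dtype=float)
    n = x.size
    if n < 10:
        raise ValueError(f"need >= 10 npde values for the test battery, got {n}")
    p_mean = float(stats.wilcoxon(x, zero_method="wilcox",
                                  alternative="two-sided").pvalue)
    s2 = float(np.var(x, ddof=1))
    chi2 = (n - 1) * s2  # reference variance 1
    p_var = float(2.0 * min(stats.chi2.cdf(chi2, n - 1),
                            stats.chi2.sf(chi2, n - 1)))
    p_var = min(p_var, 1.0)
    p_norm = float(stats.shapiro(x).pvalue)
    p_min = min(p_mean, p_var, p_norm)
    return NpdeResult(npde=x, p_mean=p_mean, p_var=p_var, p_norm=p_norm,
                      p_global=min(1.0, 3.0 * p_min),
                      reject_global=bool(p_min < alpha / 3.0), alpha=alpha)


def _auto_bins(tad: np.ndarray, n_bins: int) -> np.ndarray:
    """Quantile-based automatic binning on time after dose; duplicate
    edges (ties: trough-only data) collapse into fewer bins."""
    qs = np.linspace(0.0, 1.0, n_bins + 1)
    edges = np.unique(np.quantile(tad, qs))
    if edges.size < 2:  # all observations share one time
        edges = np.array([edges[0] - 0.5, edges[0] + 0.5])
    if edges.size - 1 < n_bins:
        log.info("automatic binning collapsed to %d bin(s) "
                 "(ties on time after dose)", edges.size - 1)
    return edges


def pcvpc(ensemble: SimulationEnsemble, obs=None, n_bins: int = 4,
          percentiles=(2.5, 50.0, 97.5), band: float = 95.0) -> PcvpcResult:
    """Prediction-corrected visual predictive check tables.

    Each observed and simulated value is corrected by
    ``pcY = Y * median(PRED in bin) / PRED``; per bin the observed
    percentiles are compared against the ``band``% interval of the same
    percentiles across replicates.  Empty bins are merged by the
    duplicate-dropping automatic binning.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    y = ensemble.obs if obs is None else np.asarray(obs, dtype=float)
    edges = _auto_bins(ensemble.tad, n_bins)
    idx = np.clip(np.searchsorted(edges, ensemble.tad, side="right") - 1,
                  0, edges.size - 2)
    nb = edges.size - 1
    obs_pct = np.full((nb, len(percentiles)), np.nan)
    lo = np.full((nb, len(percentiles)), np.nan)
    hi = np.full((nb, len(percentiles)), np.nan)
    bin_n = np.zeros(nb, dtype=int)
    a = (100.0 - band) / 2.0
    for b in range(nb):
        cols = np.flatnonzero(idx == b)
        bin_n[b] = cols.size
        if cols.size == 0:
            continue
        pred = ensemble.pred[cols]
        factor = np.median(pred) / pred
        pc_obs = y[cols] * factor
        pc_sims = ensemble.sims[:, cols] * factor
        obs_pct[b] = np.percentile(pc_obs, percentiles)
        rep_pct = np.percentile(pc_sims, percentiles, axis=1).T  # (k, 3)
        lo[b] = np.percentile(rep_pct, a, axis=0)
        hi[b] = np.percentile(rep_pct, 100.0 - a, axis=0)
    return PcvpcResult(bin_edges=edges, bin_n=bin_n, observed=obs_pct,
                       sim_band_lo=lo, sim_band_hi=hi,
                       percentiles=tuple(percentiles))
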