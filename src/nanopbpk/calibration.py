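"""Hierarchical Bayesian calibration of monitored PBPK parameters.

Three-stage model.  Stage 1 (likelihood): observations are lognormally
distributed around the model prediction, ``log y_ij ~ N(log f(D_i; t_ij;
theta_i), sigma^2)``.  Stage 2 (population): the log-parameter vector of each
study group is multivariate normal, ``theta_tr_i ~ MVN(mu, Sigma)`` with
``theta_i = exp(theta_tr_i)``.  Stage 3 (hyperpriors): ``mu ~ MVN(M, S^2)``;
``Sigma = diag(s) C diag(s)`` with half-normal priors on the scale vector
``s`` and the residual SD ``sigma`` and an LKJ(a) prior on the correlation
matrix ``C``.

Sampling uses a blocked Metropolis-within-Gibbs scheme: the population mean
``mu`` has a conjugate multivariate-normal full conditional and is drawn
exactly; the per-group log parameters (the only block touching the ODE
forward model), ``sigma``, and the ``(s, C)`` block are updated by adaptive
random-walk Metropolis.  The correlation matrix is parameterized by canonical
partial correlations, under which the LKJ prior factorizes into independent
shifted-Beta terms.  Convergence is assessed with the split Gelman-Rubin
potential scale reduction factor (R-hat <= 1.2 taken as converged).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Dict, Hashable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_solve, cholesky, solve_triangular

from .pbpk import (
    ExposureScenario,
    NanoKineticParams,
    PhysiologyRat,
    Route,
    dose_metrics,
    make_scenario,
    simulate,
)

logger = logging.getLogger("nanopbpk")

#: the nine monitored parameters: PC maximum uptake rates and release rates
#: in liver, spleen, kidney and lung, plus the urinary elimination constant
MONITORED_DEFAULT: tuple[str, ...] = (
    "k_max_liver",
    "k_max_spleen",
    "k_max_kidney",
    "k_max_lung",
    "k_release_liver",
    "k_release_spleen",
    "k_release_kidney",
    "k_release_lung",
    "k_urine",
)

_LOG_2PI = math.log(2.0 * math.pi)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ObservationRecord:
    """One tissue measurement from one study group."""

    study: Hashable
    route: Route
    tissue: str
    time_h: float
    dose_ug: float
    value: float
    unit: str = "pct_id"
    size_nm: float = float("nan")
    sd: float | None = None
    n: int | None = None


def records_from_frame(df: pd.DataFrame) -> list[ObservationRecord]:
    """Convert a tidy observation table to records, one study per
    (route, size) group.  Non-positive observations are excluded with a
    logged count (they cannot enter a lognormal likelihood)."""
    from .datasets import canonical_tissue

    n_dropped = int((df["value"] <= 0).sum())
    if n_dropped:
        logger.info("dropping %d non-positive observations", n_dropped)
    df = df[df["value"] > 0]
    records = []
    for (route, size), grp in df.groupby(["route", "size_nm"], sort=True):
        study = f"{route}:{size}"
        for row in grp.itertuples(index=False):
            records.append(
                ObservationRecord(
                    study=study,
                    route=Route.parse(route),
                    tissue=canonical_tissue(row.tissue),
                    time_h=float(row.time_h),
                    dose_ug=float(row.dose_ug),
                    value=float(row.value),
                    unit=str(row.unit),
                    size_nm=float(size),
                )
            )
    return records


@dataclass
class HierarchicalPriors:
    """Hyperprior specification for the three-stage model."""

    monitored_names: tuple[str, ...]
    hyper_mean: np.ndarray  # M, log scale (p,)
    hyper_sd: np.ndarray  # sqrt(diag S^2), log scale (p,)
    halfnormal_scale_s: np.ndarray | float = 1.0
    halfnormal_scale_sigma: float = 1.0
    lkj_shape: float = 2.0

    def __post_init__(self) -> None:
        self.monitored_names = tuple(self.monitored_names)
        p = len(self.monitored_names)
        self.hyper_mean = np.broadcast_to(np.asarray(self.hyper_mean, float), (p,)).copy()
        self.hyper_sd = np.broadcast_to(np.asarray(self.hyper_sd, float), (p,)).copy()
        self.halfnormal_scale_s = np.broadcast_to(
            np.asarray(self.halfnormal_scale_s, float), (p,)
        ).copy()
        if np.any(self.hyper_sd <= 0) or np.any(self.halfnormal_scale_s <= 0):
            raise ValueError("prior scales must be > 0")
        if self.halfnormal_scale_sigma <= 0 or self.lkj_shape <= 0:
            raise ValueError("prior scales must be > 0")

    @property
    def p(self) -> int:
        return len(self.monitored_names)

    @classmethod
    def from_params(
        cls,
        params: NanoKineticParams,
        monitored: Sequence[str] = MONITORED_DEFAULT,
        hyper_sd: float = 1.0,
        **kwargs,
    ) -> "HierarchicalPriors":
        """Center the hyperprior mean at a point-parameter set (log scale)."""
        m = np.log([params.get(name) for name in monitored])
        return cls(tuple(monitored), m, np.full(len(m), hyper_sd), **kwargs)


@dataclass
class MCMCConfig:
    """Sampler configuration.  R-hat needs >= 2 chains; default 4."""

    n_chains: int = 4
    n_warmup: int = 500
    n_samples: int = 1000
    seed: int = 0
    inner_cov_steps: int = 5  # inner MH iterations for the (s, C) block
    target_accept: float = 0.3
    laplace_init: bool = True  # MAP pre-fit + Laplace proposal shape per group
    fix_sigma: float | None = None  # fix residual SD (testing / profiling)
    fix_s: float | np.ndarray | None = None  # fix population scales

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ValueError("R-hat requires at least 2 chains")
        if self.n_warmup < 0 or self.n_samples < 1:
            raise ValueError("invalid iteration counts")


# ---------------------------------------------------------------------------
# density components (stage-wise log densities)
# ---------------------------------------------------------------------------


def _group_records(
    obs: Sequence[ObservationRecord],
) -> list[tuple[Hashable, list[ObservationRecord]]]:
    order: list[Hashable] = []
    groups: Dict[Hashable, list[ObservationRecord]] = {}
    for rec in obs:
        if rec.study not in groups:
            groups[rec.study] = []
            order.append(rec.study)
        groups[rec.study].append(rec)
    return [(k, groups[k]) for k in order]


def log_likelihood(
    obs: Sequence[ObservationRecord],
    theta_by_study: Mapping[Hashable, np.ndarray],
    sigma: float,
    forward: Callable,
) -> float:
    """Stage-1 lognormal log likelihood.

    ``forward(theta_i, study, records)`` must return positive predictions
    aligned with ``records``; a non-positive prediction at an observation is
    an error naming the record.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    total = 0.0
    for study, records in _group_records(obs):
        theta = np.asarray(theta_by_study[study], float)
        preds = np.asarray(forward(theta, study, records), float)
        bad = np.nonzero(~(preds > 0))[0]
        if bad.size:
            rec = records[bad[0]]
            raise ValueError(
                f"non-positive model prediction at {rec.tissue} t={rec.time_h} h "
                f"(study {rec.study!r})"
            )
        resid = np.log([r.value for r in records]) - np.log(preds)
        total += float(
            -0.5 * resid.size * (_LOG_2PI + 2.0 * math.log(sigma))
            - 0.5 * np.sum(resid**2) / sigma**2
        )
    return total


def log_population(theta_tr: np.ndarray, mu: np.ndarray, sigma2: np.ndarray) -> float:
    """Stage-2 multivariate-normal log density of the group log parameters."""
    theta_tr = np.atleast_2d(np.asarray(theta_tr, float))
    mu = np.asarray(mu, float)
    sigma2 = np.asarray(sigma2, float)
    if not np.allclose(sigma2, sigma2.T):
        raise ValueError("population covariance must be symmetric")
    try:
        chol = cholesky(sigma2, lower=True)
    except np.linalg.LinAlgError as exc:
        raise ValueError("population covariance must be positive definite") from exc
    z = solve_triangular(chol, (theta_tr - mu).T, lower=True)
    logdet = 2.0 * float(np.sum(np.log(np.diag(chol))))
    n, p = theta_tr.shape
    return float(-0.5 * np.sum(z**2) - 0.5 * n * (p * _LOG_2PI + logdet))


def _halfnormal_logpdf(x: np.ndarray, scale: np.ndarray) -> float:
    x = np.asarray(x, float)
    if np.any(x < 0):
        return -math.inf
    return float(
        np.sum(0.5 * math.log(2.0 / math.pi) - np.log(scale) - 0.5 * (x / scale) ** 2)
    )


def lkj_logpdf(C: np.ndarray, shape: float) -> float:
    """Unnormalized LKJ log density, ``(shape - 1) * log det C``."""
    C = np.asarray(C, float)
    if not np.allclose(np.diag(C), 1.0, atol=1e-10):
        raise ValueError("correlation matrix must have unit diagonal")
    sign, logdet = np.linalg.slogdet(C)
    if sign <= 0:
        raise ValueError("correlation matrix must be positive definite")
    return float((shape - 1.0) * logdet)


def log_hyperprior(
    mu: np.ndarray,
    s: np.ndarray,
    C: np.ndarray,
    sigma: float,
    priors: HierarchicalPriors,
) -> float:
    """Stage-3 log density: MVN(M, S^2) on mu, half-normal on s and sigma,
    LKJ(a) on C (unnormalized, consistent across evaluations)."""
    mu = np.asarray(mu, float)
    s = np.asarray(s, float)
    if np.any(s <= 0) or sigma <= 0:
        return -math.inf
    z = (mu - priors.hyper_mean) / priors.hyper_sd
    lp = float(
        -0.5 * np.sum(z**2) - np.sum(np.log(priors.hyper_sd)) - 0.5 * priors.p * _LOG_2PI
    )
    lp += _halfnormal_logpdf(s, priors.halfnormal_scale_s)
    lp += _halfnormal_logpdf(
        np.array([sigma]), np.array([priors.halfnormal_scale_sigma])
    )
    lp += lkj_logpdf(C, priors.lkj_shape)
    return lp


def joint_log_density(
    obs: Sequence[ObservationRecord],
    theta_tr_by_study: Mapping[Hashable, np.ndarray],
    mu: np.ndarray,
    s: np.ndarray,
    C: np.ndarray,
    sigma: float,
    priors: HierarchicalPriors,
    forward: Callable,
) -> float:
    """Full joint log density = likelihood + population + hyperprior."""
    s = np.asarray(s, float)
    sigma2 = np.diag(s) @ np.asarray(C, float) @ np.diag(s)
    theta_tr = np.array([theta_tr_by_study[k] for k, _ in _group_records(obs)])
    theta_nat = {k: np.exp(np.asarray(v, float)) for k, v in theta_tr_by_study.items()}
    return (
        log_likelihood(obs, theta_nat, sigma, forward)
        + log_population(theta_tr, mu, sigma2)
        + log_hyperprior(mu, s, C, sigma, priors)
    )


# ---------------------------------------------------------------------------
# convergence diagnostics and posterior summaries
# ---------------------------------------------------------------------------


def rhat(chains: np.ndarray, split: bool = True) -> float:
    """Gelman-Rubin potential scale reduction factor for one parameter.

    ``chains`` has shape (n_chains, n_iterations).  With ``split=True`` each
    chain is halved first (the stricter, modern default).
    """
    chains = np.atleast_2d(np.asarray(chains, float))
    if chains.shape[0] < 2:
        raise ValueError("R-hat requires at least 2 chains")
    if chains.shape[1] < 4:
        raise ValueError("R-hat requires chains of length >= 4")
    if split:
        half = chains.shape[1] // 2
        chains = np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)
    m, n = chains.shape
    within = chains.var(axis=1, ddof=1)
    w = within.mean()
    if w == 0:
        raise ValueError("zero within-chain variance in all chains")
    b = n * chains.mean(axis=1).var(ddof=1)
    var_plus = (n - 1) / n * w + b / n
    return float(math.sqrt(var_plus / w))


def summarize_posterior(draws: np.ndarray) -> dict:
    """Geometric mean/GSD and percentiles of natural-scale posterior draws."""
    draws = np.asarray(draws, float).ravel()
    if draws.size < 100:
        raise ValueError("need at least 100 draws to summarize")
    if np.any(draws <= 0):
        raise ValueError("draws must be positive on the natural scale")
    logs = np.log(draws)
    return {
        "geo_mean": float(np.exp(logs.mean())),
        "gsd": float(np.exp(logs.std(ddof=1))),
        "q2.5": float(np.percentile(draws, 2.5)),
        "q50": float(np.percentile(draws, 50)),
        "q97.5": float(np.percentile(draws, 97.5)),
    }


# ---------------------------------------------------------------------------
# correlation-matrix transform (canonical partial correlations)
# ---------------------------------------------------------------------------


def _cpc_positions(p: int) -> list[tuple[int, int]]:
    return [(r, c) for r in range(1, p) for c in range(r)]


def chol_from_cpc(z: np.ndarray, p: int) -> np.ndarray:
    """Lower-Cholesky factor of the correlation matrix built from canonical
    partial correlations ``z`` in (-1, 1), row-wise order."""
    L = np.zeros((p, p))
    L[0, 0] = 1.0
    idx = 0
    for r in range(1, p):
        rem = 1.0
        for c in range(r):
            L[r, c] = z[idx] * math.sqrt(rem)
            rem -= L[r, c] ** 2
            idx += 1
        L[r, r] = math.sqrt(max(rem, 0.0))
    return L


def _cpc_log_prior(z: np.ndarray, p: int, shape: float) -> float:
    """LKJ(shape) expressed on canonical partial correlations, plus the
    tanh-reparameterization Jacobian: each unconstrained coordinate y with
    z = tanh(y) contributes ``alpha_c * log(1 - z^2)`` where
    ``alpha_c = shape + (p - 2 - c) / 2`` depends on the column index."""
    lp = 0.0
    for z_k, (_, c) in zip(z, _cpc_positions(p)):
        alpha = shape + (p - 2 - c) / 2.0
        lp += alpha * math.log1p(-z_k**2)
    return lp


# ---------------------------------------------------------------------------
# forward model wrapper for PBPK calibration
# ---------------------------------------------------------------------------


class PBPKForward:
    """Evaluate the PBPK model for calibration, with per-theta caching.

    Each study key maps to a fixed (physiology, base parameter set, exposure
    scenario); a call overrides the monitored parameters with ``theta``
    (natural scale, ordered like ``monitored_names``), simulates once per
    distinct theta and serves every observation of that study from the
    cached %ID / %IPLD table.
    """

    def __init__(
        self,
        phys: PhysiologyRat,
        base_params: Mapping[Hashable, NanoKineticParams],
        scenarios: Mapping[Hashable, ExposureScenario],
        monitored_names: Sequence[str] = MONITORED_DEFAULT,
        rtol: float = 1e-5,
        atol: float = 1e-9,
        max_cache: int = 1024,
    ) -> None:
        self.phys = phys
        self.base_params = dict(base_params)
        self.scenarios = dict(scenarios)
        self.monitored_names = tuple(monitored_names)
        self.rtol = rtol
        self.atol = atol
        self.max_cache = max_cache
        self._cache: Dict[tuple, dict] = {}
        self.n_solves = 0

    def params_for(self, study: Hashable, theta: np.ndarray) -> NanoKineticParams:
        params = self.base_params[study].copy()
        for name, value in zip(self.monitored_names, theta):
            params = params.with_value(name, float(value))
        return params

    def _tables(self, study: Hashable, theta: np.ndarray) -> dict:
        key = (study, np.asarray(theta, float).tobytes())
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        scenario = self.scenarios[study]
        traj = simulate(
            self.phys,
            self.params_for(study, theta),
            scenario,
            rtol=self.rtol,
            atol=self.atol,
        )
        self.n_solves += 1
        metrics = dose_metrics(traj, scenario, windows=())
        tables = {"pct_id": metrics.pct_id, "pct_ipld": metrics.pct_ipld}
        if len(self._cache) >= self.max_cache:
            self._cache.pop(next(iter(self._cache)))
        self._cache[key] = tables
        return tables

    def __call__(
        self, theta: np.ndarray, study: Hashable, records: Sequence[ObservationRecord]
    ) -> np.ndarray:
        tables = self._tables(study, theta)
        out = np.empty(len(records))
        for i, rec in enumerate(records):
            table = tables[rec.unit] if rec.unit in tables and tables[rec.unit] else tables["pct_id"]
            out[i] = table[(rec.tissue, rec.time_h)]
        return out


def forward_from_frame(
    df: pd.DataFrame,
    phys: PhysiologyRat,
    base_params: Mapping[tuple[Route, float], NanoKineticParams] | None = None,
    monitored_names: Sequence[str] = MONITORED_DEFAULT,
    **kwargs,
) -> tuple[list[ObservationRecord], PBPKForward]:
    """Build (records, forward model) from a tidy observation table.

    Each (route, size) pair becomes one study group; base parameter sets
    default to the packaged reference set for that route and size.
    """
    from .datasets import default_params

    records = records_from_frame(df)
    bases: Dict[Hashable, NanoKineticParams] = {}
    scenarios: Dict[Hashable, ExposureScenario] = {}
    for study, recs in _group_records(records):
        rec0 = recs[0]
        times = sorted({r.time_h for r in recs})
        scenarios[study] = make_scenario(rec0.route, rec0.dose_ug, times)
        if base_params is not None and (rec0.route, rec0.size_nm) in base_params:
            bases[study] = base_params[(rec0.route, rec0.size_nm)].copy()
        else:
            bases[study] = default_params(rec0.size_nm, rec0.route)
    return records, PBPKForward(phys, bases, scenarios, monitored_names, **kwargs)


# ---------------------------------------------------------------------------
# the sampler
# ---------------------------------------------------------------------------


@dataclass
class MCMCResult:
    """Posterior draws (post-warmup) and derived summaries."""

    monitored_names: tuple[str, ...]
    studies: tuple[Hashable, ...]
    draws: Dict[str, np.ndarray]  # mu/s: (chains, samples, p); sigma: (chains, samples)
    accept_rates: Dict[str, float]

    def rhat_per_parameter(self) -> pd.Series:
        mu = self.draws["mu"]
        vals = [rhat(mu[:, :, k]) for k in range(mu.shape[2])]
        return pd.Series(vals, index=list(self.monitored_names), name="rhat")

    @property
    def max_rhat(self) -> float:
        return float(self.rhat_per_parameter().max())

    def summary(self) -> pd.DataFrame:
        """Per-parameter population geometric mean, population GSD, credible
        interval (on the population geometric mean) and split R-hat."""
        mu = self.draws["mu"]
        s = self.draws["s"]
        rows = []
        rh = self.rhat_per_parameter()
        for k, name in enumerate(self.monitored_names):
            gm_draws = np.exp(mu[:, :, k].ravel())
            stats = summarize_posterior(gm_draws)
            rows.append(
                {
                    "parameter": name,
                    "geo_mean": stats["geo_mean"],
                    "gsd": float(np.exp(np.mean(s[:, :, k]))),
                    "q2.5": stats["q2.5"],
                    "q50": stats["q50"],
                    "q97.5": stats["q97.5"],
                    "rhat": float(rh[name]),
                }
            )
        return pd.DataFrame(rows)


class _ChainState:
    __slots__ = (
        "mu", "theta_tr", "log_s", "y_z", "log_sigma",
        "loglik", "theta_scale", "pcn_beta", "trans_scale", "sz_scale", "sigma_scale",
    )


def run_mcmc(
    obs: Sequence[ObservationRecord],
    priors: HierarchicalPriors,
    config: MCMCConfig,
    forward: Callable,
) -> MCMCResult:
    """Sample the three-stage hierarchical posterior.

    ``forward(theta_natural, study, records)`` returns predictions for one
    study group; any callable with that contract works (the PBPK model via
    :class:`PBPKForward`, or e.g. an identity map in analytic checks).
    """
    p = priors.p
    groups = _group_records(obs)
    studies = tuple(k for k, _ in groups)
    n_g = len(groups)
    y_log = [np.log([r.value for r in recs]) for _, recs in groups]
    n_obs = sum(len(v) for v in y_log)
    positions = _cpc_positions(p)
    nz = len(positions)
    sample_z = p > 1
    fix_sigma = config.fix_sigma
    fix_s = None if config.fix_s is None else np.broadcast_to(
        np.asarray(config.fix_s, float), (p,)
    ).copy()

    n_keep = config.n_samples
    out_mu = np.empty((config.n_chains, n_keep, p))
    out_s = np.empty((config.n_chains, n_keep, p))
    out_sigma = np.empty((config.n_chains, n_keep))
    out_theta = np.empty((config.n_chains, n_keep, n_g, p))
    acc_counts = {"theta": 0, "translate": 0, "sigma": 0, "sz": 0}
    prop_counts = {"theta": 0, "translate": 0, "sigma": 0, "sz": 0}

    def group_loglik(gi: int, theta_tr_i: np.ndarray, sigma: float) -> float:
        study, recs = groups[gi]
        theta = np.exp(theta_tr_i)
        try:
            preds = np.asarray(forward(theta, study, recs), float)
        except Exception:
            return -math.inf
        if not np.all(np.isfinite(preds)) or np.any(preds <= 0):
            return -math.inf
        resid = y_log[gi] - np.log(preds)
        return float(
            -0.5 * resid.size * (_LOG_2PI + 2.0 * math.log(sigma))
            - 0.5 * np.sum(resid**2) / sigma**2
        )

    def sigma_chol(log_s: np.ndarray, y_z: np.ndarray) -> np.ndarray:
        s = np.exp(log_s)
        if sample_z:
            L = chol_from_cpc(np.tanh(y_z), p)
        else:
            L = np.eye(p)
        return s[:, None] * L  # chol of diag(s) C diag(s)

    def mvn_quad(chol_l: np.ndarray, x: np.ndarray) -> float:
        z = solve_triangular(chol_l, x, lower=True)
        return float(np.sum(z**2))

    def population_logpdf(chol_l: np.ndarray, theta_tr: np.ndarray, mu: np.ndarray) -> float:
        logdet = 2.0 * float(np.sum(np.log(np.diag(chol_l))))
        quad = sum(mvn_quad(chol_l, theta_tr[i] - mu) for i in range(n_g))
        return -0.5 * quad - 0.5 * n_g * (p * _LOG_2PI + logdet)

    def sz_log_target(log_s: np.ndarray, y_z: np.ndarray, theta_tr, mu) -> float:
        s = np.exp(log_s)
        chol_l = sigma_chol(log_s, y_z)
        if np.any(np.diag(chol_l) <= 0):
            return -math.inf
        lp = population_logpdf(chol_l, theta_tr, mu)
        if fix_s is None:
            # half-normal prior on s plus log-jacobian of s = exp(log_s)
            lp += _halfnormal_logpdf(s, priors.halfnormal_scale_s) + float(np.sum(log_s))
        if sample_z:
            lp += _cpc_log_prior(np.tanh(y_z), p, priors.lkj_shape)
        return lp

    # -- MAP pre-fit and Laplace proposal shapes (shared across chains).
    # For each group, maximize likelihood x MVN(M, S^2) over theta_tr, take
    # the inverse curvature as the random-walk proposal covariance, and start
    # the chains jittered around the mode.  The prior curvature bounds the
    # Hessian away from singularity in weakly identified directions.
    map_theta = np.tile(priors.hyper_mean, (n_g, 1))
    laplace_chol: list[np.ndarray | None] = [None] * n_g
    if config.laplace_init:
        from scipy.optimize import minimize

        sigma_map = 0.25
        prior_prec0 = 1.0 / priors.hyper_sd**2
        for gi in range(n_g):
            def neg_log_post(th: np.ndarray) -> float:
                ll = group_loglik(gi, th, sigma_map)
                lp = -0.5 * float(np.sum(prior_prec0 * (th - priors.hyper_mean) ** 2))
                return -(ll + lp)

            opt = minimize(
                neg_log_post,
                priors.hyper_mean,
                method="Nelder-Mead",
                options={"maxiter": 400, "xatol": 1e-3, "fatol": 1e-3},
            )
            map_theta[gi] = opt.x
            h = 0.05
            hess = np.empty((p, p))
            f0 = neg_log_post(opt.x)
            fp = np.array([neg_log_post(opt.x + h * np.eye(p)[j]) for j in range(p)])
            fm = np.array([neg_log_post(opt.x - h * np.eye(p)[j]) for j in range(p)])
            for j in range(p):
                hess[j, j] = (fp[j] - 2 * f0 + fm[j]) / h**2
                for k in range(j + 1, p):
                    fpp = neg_log_post(opt.x + h * (np.eye(p)[j] + np.eye(p)[k]))
                    hess[j, k] = hess[k, j] = (
                        fpp - fp[j] - fp[k] + f0
                    ) / h**2
            hess = 0.5 * (hess + hess.T)
            w, v = np.linalg.eigh(hess)
            w = np.clip(w, 0.5 * prior_prec0.min(), None)
            cov = (v / w) @ v.T
            laplace_chol[gi] = cholesky(cov, lower=True)

    seed_seq = np.random.SeedSequence(config.seed)
    chain_seeds = seed_seq.spawn(config.n_chains)

    for chain in range(config.n_chains):
        rng = np.random.default_rng(chain_seeds[chain])
        st = _ChainState()
        st.mu = priors.hyper_mean + 0.1 * rng.standard_normal(p)
        st.theta_tr = map_theta + 0.1 * rng.standard_normal((n_g, p))
        if config.laplace_init:
            st.mu = map_theta.mean(axis=0) + 0.1 * rng.standard_normal(p)
        st.log_s = (
            np.log(fix_s) if fix_s is not None
            else np.log(0.3 * np.ones(p)) + 0.1 * rng.standard_normal(p)
        )
        st.y_z = np.zeros(nz)
        st.log_sigma = (
            math.log(fix_sigma) if fix_sigma is not None
            else math.log(0.3) + 0.1 * rng.standard_normal()
        )
        st.theta_scale = np.full(n_g, 2.38 / math.sqrt(p) if config.laplace_init else 0.25)
        st.sz_scale = 0.15
        st.sigma_scale = 0.3
        st.loglik = np.array(
            [group_loglik(i, st.theta_tr[i], math.exp(st.log_sigma)) for i in range(n_g)]
        )
        st.pcn_beta = np.full(n_g, 0.3)
        st.trans_scale = np.full(p, 0.5)

        total_iters = config.n_warmup + n_keep
        for it in range(total_iters):
            warm = it < config.n_warmup
            sigma = math.exp(st.log_sigma)
            chol_l = sigma_chol(st.log_s, st.y_z)

            # -- conjugate draw of the population mean
            prior_prec = 1.0 / priors.hyper_sd**2
            eye = np.eye(p)
            sig_inv = cho_solve((chol_l, True), eye)
            lam = np.diag(prior_prec) + n_g * sig_inv
            b = prior_prec * priors.hyper_mean + sig_inv @ st.theta_tr.sum(axis=0)
            lam_chol = cholesky(lam, lower=True)
            mean = cho_solve((lam_chol, True), b)
            st.mu = mean + solve_triangular(lam_chol.T, rng.standard_normal(p), lower=False)

            # -- per-group log parameters (MH; the only ODE-solving block).
            # Even iterations: random walk shaped by the current population
            # covariance.  Odd iterations: preconditioned Crank-Nicolson step,
            # which leaves MVN(mu, Sigma) invariant so the acceptance ratio is
            # a pure likelihood ratio -- this keeps weakly identified
            # directions mixing at the population scale.
            use_pcn = it % 2 == 1
            for gi in range(n_g):
                prop_counts["theta"] += 1
                if use_pcn:
                    beta = min(st.pcn_beta[gi], 1.0)
                    prop = (
                        st.mu
                        + math.sqrt(1.0 - beta**2) * (st.theta_tr[gi] - st.mu)
                        + beta * (chol_l @ rng.standard_normal(p))
                    )
                    new_ll = group_loglik(gi, prop, sigma)
                    log_ratio = new_ll - st.loglik[gi]
                else:
                    shape_l = laplace_chol[gi] if laplace_chol[gi] is not None else chol_l
                    prop = st.theta_tr[gi] + st.theta_scale[gi] * (
                        shape_l @ rng.standard_normal(p)
                    )
                    cur_pop = -0.5 * mvn_quad(chol_l, st.theta_tr[gi] - st.mu)
                    new_pop = -0.5 * mvn_quad(chol_l, prop - st.mu)
                    new_ll = group_loglik(gi, prop, sigma)
                    log_ratio = (new_ll + new_pop) - (st.loglik[gi] + cur_pop)
                accepted = math.log(rng.random()) < log_ratio
                if accepted:
                    st.theta_tr[gi] = prop
                    st.loglik[gi] = new_ll
                    acc_counts["theta"] += 1
                if warm:
                    step = 0.05 * ((1 - config.target_accept) if accepted else -config.target_accept)
                    if use_pcn:
                        st.pcn_beta[gi] = min(st.pcn_beta[gi] * math.exp(step), 0.99)
                    else:
                        st.theta_scale[gi] *= math.exp(step)

            # -- joint translation move: shift one coordinate of mu and of
            # every group's theta_tr by the same delta.  The population term
            # is invariant (theta - mu unchanged), so acceptance depends on
            # the likelihood and the mu hyperprior only; this breaks the
            # mu/theta lockstep for weakly identified coordinates.
            for k_tr in rng.choice(p, size=min(3, p), replace=False):
                delta = st.trans_scale[k_tr] * rng.standard_normal()
                prop_theta = st.theta_tr.copy()
                prop_theta[:, k_tr] += delta
                new_mu_k = st.mu[k_tr] + delta
                new_lls = np.array(
                    [group_loglik(gi, prop_theta[gi], sigma) for gi in range(n_g)]
                )
                log_ratio = float(new_lls.sum() - st.loglik.sum()) + (
                    -0.5 * ((new_mu_k - priors.hyper_mean[k_tr]) / priors.hyper_sd[k_tr]) ** 2
                    + 0.5 * ((st.mu[k_tr] - priors.hyper_mean[k_tr]) / priors.hyper_sd[k_tr]) ** 2
                )
                prop_counts["translate"] += 1
                accepted = math.log(rng.random()) < log_ratio
                if accepted:
                    st.theta_tr = prop_theta
                    st.mu[k_tr] = new_mu_k
                    st.loglik = new_lls
                    acc_counts["translate"] += 1
                if warm:
                    step = 0.1 * ((1 - config.target_accept) if accepted else -config.target_accept)
                    st.trans_scale[k_tr] *= math.exp(step)

            # -- residual SD
            if fix_sigma is None:
                ssr = 0.0
                for gi in range(n_g):
                    # recover SSR from the cached per-group log likelihood
                    ssr += (
                        -st.loglik[gi]
                        - 0.5 * y_log[gi].size * (_LOG_2PI + 2.0 * st.log_sigma)
                    ) * 2.0 * sigma**2
                prop_ls = st.log_sigma + st.sigma_scale * rng.standard_normal()
                prop_sig = math.exp(prop_ls)

                def sigma_target(sg: float, ls: float) -> float:
                    return (
                        -n_obs * ls
                        - 0.5 * ssr / sg**2
                        + _halfnormal_logpdf(np.array([sg]), np.array([priors.halfnormal_scale_sigma]))
                        + ls  # jacobian of sigma = exp(log_sigma)
                    )

                prop_counts["sigma"] += 1
                if math.log(rng.random()) < sigma_target(prop_sig, prop_ls) - sigma_target(
                    sigma, st.log_sigma
                ):
                    # rescale cached log likelihoods to the new sigma
                    for gi in range(n_g):
                        n_i = y_log[gi].size
                        ssr_i = (
                            -st.loglik[gi] - 0.5 * n_i * (_LOG_2PI + 2.0 * st.log_sigma)
                        ) * 2.0 * sigma**2
                        st.loglik[gi] = (
                            -0.5 * n_i * (_LOG_2PI + 2.0 * prop_ls)
                            - 0.5 * ssr_i / prop_sig**2
                        )
                    st.log_sigma = prop_ls
                    acc_counts["sigma"] += 1
                    if warm:
                        st.sigma_scale *= math.exp(0.05 * (1 - config.target_accept))
                elif warm:
                    st.sigma_scale *= math.exp(-0.05 * config.target_accept)

            # -- population scale / correlation blocks (cheap; no ODE solves)
            cur = sz_log_target(st.log_s, st.y_z, st.theta_tr, st.mu)
            if fix_s is None:
                for _ in range(config.inner_cov_steps):
                    new_log_s = st.log_s + st.sz_scale * rng.standard_normal(p)
                    cand = sz_log_target(new_log_s, st.y_z, st.theta_tr, st.mu)
                    prop_counts["sz"] += 1
                    if math.log(rng.random()) < cand - cur:
                        st.log_s, cur = new_log_s, cand
                        acc_counts["sz"] += 1
                        if warm:
                            st.sz_scale *= math.exp(0.02 * (1 - config.target_accept))
                    elif warm:
                        st.sz_scale *= math.exp(-0.02 * config.target_accept)
            if sample_z:
                for k in range(config.inner_cov_steps):
                    if k % 2 == 0:
                        # independence proposal from the LKJ prior itself (in
                        # CPC space); prior and proposal terms cancel, so the
                        # acceptance ratio is the population-MVN ratio alone
                        z_prop = np.empty(nz)
                        for j, (_, c) in enumerate(positions):
                            alpha = priors.lkj_shape + (p - 2 - c) / 2.0
                            z_prop[j] = 2.0 * rng.beta(alpha, alpha) - 1.0
                        new_y_z = np.arctanh(np.clip(z_prop, -1 + 1e-12, 1 - 1e-12))
                        chol_cur = sigma_chol(st.log_s, st.y_z)
                        chol_new = sigma_chol(st.log_s, new_y_z)
                        log_ratio = population_logpdf(
                            chol_new, st.theta_tr, st.mu
                        ) - population_logpdf(chol_cur, st.theta_tr, st.mu)
                    else:
                        new_y_z = st.y_z + st.sz_scale * rng.standard_normal(nz)
                        cand = sz_log_target(st.log_s, new_y_z, st.theta_tr, st.mu)
                        log_ratio = cand - cur
                    prop_counts["sz"] += 1
                    if math.log(rng.random()) < log_ratio:
                        st.y_z = new_y_z
                        cur = sz_log_target(st.log_s, st.y_z, st.theta_tr, st.mu)
                        acc_counts["sz"] += 1

            if not warm:
                j = it - config.n_warmup
                out_mu[chain, j] = st.mu
                out_s[chain, j] = np.exp(st.log_s)
                out_sigma[chain, j] = math.exp(st.log_sigma)
                out_theta[chain, j] = st.theta_tr

    accept_rates = {
        k: (acc_counts[k] / prop_counts[k] if prop_counts[k] else float("nan"))
        for k in acc_counts
    }
    logger.info("MCMC acceptance rates: %s", accept_rates)
    return MCMCResult(
        monitored_names=priors.monitored_names,
        studies=studies,
        draws={"mu": out_mu, "s": out_s, "sigma": out_sigma, "theta_tr": out_theta},
        accept_rates=accept_rates,
    )
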