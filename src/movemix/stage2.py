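"""Second-stage hierarchical sampler (proposal-recursive MCMC).

The full hierarchical model couples every individual's movement parameters
through treatment-level means and (co)variances. Rather than tuning
proposals for hundreds of individual-level parameters, the second stage
recycles each parameter's first-stage draws as its Metropolis-Hastings
proposal pool. The generalized acceptance ratio for a scalar parameter is

    [data | proposal] [proposal | group] [kde(current)]
    -------------------------------------------------- ,
    [data | current ] [current  | group] [kde(proposal)]

where the proposal density is approximated by a kernel density estimate of
the first-stage pool. Because the first stage used support-matching priors
(beta/wrapped-Cauchy/inverse-gamma) while the hierarchy places normal
distributions on transformed scales, the group ("process") density carries
a change-of-variables Jacobian. Coefficients of the correlated ``beta``
vector are updated one at a time against their conditional normal given
the components already updated this iteration. Treatment-level parameters
then get conjugate Gibbs updates (normal-normal means, inverse-gamma
variances, inverse-Wishart coefficient covariance).

The data likelihood here is the state-integrated mixture, so no latent
states are carried in the second stage. Encamped-only individuals have a
likelihood that is flat in (gamma, theta, sigma1_sq); only their
``beta`` update sees data, through the probability of never moving.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import gaussian_filter1d
from scipy.special import logit, logsumexp, ndtr

from .landscape import CategoricalRaster, design_matrix
from .model import (
    HyperPriorConfig,
    IndividualParams,
    ModelConstants,
    Trajectory,
    TreatmentParams,
    state_log_densities,
)
from .stage1 import Stage1Results

__all__ = [
    "silverman_bandwidth",
    "kde_logpdf",
    "KDECache",
    "ProposalPool",
    "propose_from_stage1",
    "process_log_density",
    "conditional_beta_logpdf",
    "mh_update_scalar",
    "mh_update_beta",
    "gibbs_update_treatment",
    "HierarchicalModel",
    "HierarchicalResults",
    "fit_hierarchical",
]

_LOG_2PI = float(np.log(2.0 * np.pi))
_SCALARS = ("gamma", "theta", "sigma1_sq")


def _norm_logpdf(x, mu, var):
    return -0.5 * (_LOG_2PI + np.log(var) + (x - mu) ** 2 / var)


def silverman_bandwidth(pool: np.ndarray) -> float:
    """Normal-reference (Silverman) plug-in bandwidth with a floor of
    1e-6 times the pool range; degenerate pools are rejected."""
    pool = np.asarray(pool, dtype=float)
    n = len(pool)
    if n < 2:
        raise ValueError("pool must contain at least 2 draws")
    rng_ = float(np.ptp(pool))
    if rng_ == 0.0:
        raise ValueError(
            "degenerate proposal pool (all draws identical); "
            "apply a bandwidth floor or check the first-stage fit"
        )
    sd = float(np.std(pool, ddof=1))
    iqr = float(np.subtract(*np.percentile(pool, [75, 25])))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    h = 0.9 * spread * n ** (-0.2)
    return max(h, 1e-6 * rng_)


def kde_logpdf(pool: np.ndarray, x, bandwidth: float | None = None):
    """Exact Gaussian-kernel log density of the pool, evaluated at ``x``.

    Equal-weight normal mixture centred on the pool draws; strictly
    positive everywhere. Vectorized over ``x``.
    """
    pool = np.asarray(pool, dtype=float)
    h = silverman_bandwidth(pool) if bandwidth is None else float(bandwidth)
    x_arr = np.atleast_1d(np.asarray(x, dtype=float))
    zs = (x_arr[:, None] - pool[None, :]) / h
    log_kernels = -0.5 * zs**2 - 0.5 * _LOG_2PI - np.log(h)
    out = logsumexp(log_kernels, axis=1) - np.log(len(pool))
    return float(out[0]) if np.isscalar(x) or np.asarray(x).ndim == 0 else out


class KDECache:
    """Binned kernel density estimate with fast interpolated evaluation.

    The pool is histogrammed onto a fine grid and convolved with the
    Gaussian kernel (the standard binned KDE used by kernel-density
    software), then log-density queries interpolate linearly. Evaluation
    error is negligible against the Monte Carlo noise of the sampler while
    making pool-sized (10^5) un-thinned proposals affordable.
    """

    def __init__(self, pool: np.ndarray, n_grid: int = 4096):
        pool = np.asarray(pool, dtype=float)
        self.bandwidth = silverman_bandwidth(pool)
        lo = pool.min() - 5.0 * self.bandwidth
        hi = pool.max() + 5.0 * self.bandwidth
        counts, edges = np.histogram(pool, bins=n_grid, range=(lo, hi))
        dx = edges[1] - edges[0]
        dens = gaussian_filter1d(
            counts / (len(pool) * dx), sigma=self.bandwidth / dx, mode="constant"
        )
        self.grid = 0.5 * (edges[:-1] + edges[1:])
        self.log_density = np.log(np.clip(dens, 1e-300, None))

    def __call__(self, x: float) -> float:
        return float(
            np.interp(x, self.grid, self.log_density, left=-690.0, right=-690.0)
        )

    def quadrature_mass(self) -> float:
        dx = self.grid[1] - self.grid[0]
        return float(np.sum(np.exp(self.log_density)) * dx)


@dataclass
class ProposalPool:
    """One individual's stage-1 draws, per scalar parameter, with KDE
    evaluation caches. Beta components are pooled per coefficient."""

    draws: dict[str, np.ndarray]
    kdes: dict[str, KDECache] = field(default_factory=dict)

    @classmethod
    def from_stage1(cls, res: Stage1Results, burn_in: int = 0) -> "ProposalPool":
        sl = slice(burn_in, None)
        draws = {
            "gamma": res.gamma[sl],
            "theta": res.theta[sl],
            "sigma1_sq": res.sigma1_sq[sl],
        }
        for i in range(res.beta.shape[1]):
            draws[f"beta_{i}"] = res.beta[sl, i]
        if any(len(v) == 0 for v in draws.values()):
            raise ValueError("empty proposal pool after burn-in")
        pool = cls(draws=draws)
        for name, vals in draws.items():
            pool.kdes[name] = KDECache(vals)
        return pool


def propose_from_stage1(pool: np.ndarray, rng: np.random.Generator) -> float:
    """Uniformly draw one stored first-stage sample as the MH proposal."""
    pool = np.asarray(pool)
    if len(pool) == 0:
        raise ValueError("proposal pool is empty")
    return float(pool[rng.integers(len(pool))])


def process_log_density(param_name: str, value: float, treatment: TreatmentParams) -> float:
    """Individual-level ("process") log density on the natural scale.

    The hierarchy is normal on transformed scales, so natural-scale
    evaluation carries the change-of-variables Jacobian: logit for gamma
    (Jacobian 1/(g(1-g))), log of the standard deviation for sigma1_sq
    (Jacobian 1/(2 s2)), and no transform for theta. Out-of-support values
    return -inf rather than raising, so the MH step simply rejects them.
    """
    if param_name == "gamma":
        if not (0.0 < value < 1.0):
            return -np.inf
        return float(
            _norm_logpdf(logit(value), treatment.mu_logit_gamma, treatment.var_logit_gamma)
            - np.log(value * (1.0 - value))
        )
    if param_name == "sigma1_sq":
        if not (value > 0.0):
            return -np.inf
        return float(
            _norm_logpdf(0.5 * np.log(value), treatment.mu_log_sigma1, treatment.var_log_sigma1)
            - np.log(2.0 * value)
        )
    if param_name == "theta":
        return float(_norm_logpdf(value, treatment.mu_theta, treatment.var_theta))
    raise ValueError(f"unknown scalar parameter {param_name!r}")


def conditional_beta_logpdf(
    beta: np.ndarray,
    component: int,
    mu_beta: np.ndarray,
    Sigma_beta: np.ndarray,
) -> float:
    """Log density of one beta coefficient conditional on the others.

    Standard multivariate-normal conditioning: with o the other components
    at their current values, the conditional is univariate normal with
    mean ``mu_l + S_lo S_oo^-1 (beta_o - mu_o)`` and variance
    ``S_ll - S_lo S_oo^-1 S_ol``.
    """
    beta = np.asarray(beta, dtype=float)
    mu_beta = np.asarray(mu_beta, dtype=float)
    Sigma_beta = np.asarray(Sigma_beta, dtype=float)
    k = len(beta)
    others = [i for i in range(k) if i != component]
    S_oo = Sigma_beta[np.ix_(others, others)]
    S_lo = Sigma_beta[component, others]
    try:
        chol = np.linalg.cholesky(S_oo)
    except np.linalg.LinAlgError as exc:
        raise ValueError("Sigma_beta must be positive definite") from exc
    w = np.linalg.solve(chol.T, np.linalg.solve(chol, beta[others] - mu_beta[others]))
    wS = np.linalg.solve(chol.T, np.linalg.solve(chol, S_lo))
    cond_mean = mu_beta[component] + S_lo @ w
    cond_var = Sigma_beta[component, component] - S_lo @ wS
    if cond_var <= 0:
        raise ValueError("Sigma_beta must be positive definite")
    return float(_norm_logpdf(beta[component], cond_mean, cond_var))


# ---------------------------------------------------------------------------
# Per-individual likelihood context


class _IndividualContext:
    """Data and cached likelihood pieces for one individual."""

    def __init__(
        self,
        trajectory: Trajectory,
        design: np.ndarray,
        constants: ModelConstants,
        encamped_only: bool,
    ):
        disp = trajectory.displacements()
        self.individual_id = trajectory.individual_id
        self.treatment = trajectory.treatment
        self.delta_t = disp.delta_t
        self.delta_prev = disp.delta_prev
        self.design = np.asarray(design, dtype=float)
        self.constants = constants
        self.encamped_only = encamped_only
        self.m = disp.n_eligible
        if self.m:
            ss0 = np.einsum("ij,ij->i", self.delta_t, self.delta_t)
            var0 = constants.sigma0**2
            self.logf0 = -_LOG_2PI - np.log(var0) - ss0 / (2.0 * var0)
        else:
            self.logf0 = np.zeros(0)

    def movement_logf1(self, gamma: float, theta: float, sigma1_sq: float) -> np.ndarray:
        if self.m == 0:
            return np.zeros(0)
        _, logf1 = state_log_densities(
            self.delta_t, self.delta_prev, gamma, theta, sigma1_sq, self.constants
        )
        return logf1

    def loglik(self, beta: np.ndarray, logf1: np.ndarray) -> float:
        """Mixture log-likelihood; for encamped-only individuals the states
        are pinned encamped, so only the never-move probability sees beta."""
        if self.m == 0:
            return 0.0
        eta = self.design @ beta
        if self.encamped_only:
            return float(np.sum(np.log(np.clip(1.0 - ndtr(eta), 1e-300, None)))
                         + np.sum(self.logf0))
        p = ndtr(eta)
        with np.errstate(divide="ignore"):
            return float(
                np.sum(
                    np.logaddexp(np.log(p) + logf1, np.log1p(-p) + self.logf0)
                )
            )


def mh_update_scalar(
    param_name: str,
    current: float,
    current_loglik: float,
    current_logf1: np.ndarray,
    params: IndividualParams,
    ctx: _IndividualContext,
    pool: ProposalPool,
    treatment: TreatmentParams,
    rng: np.random.Generator,
) -> tuple[float, float, np.ndarray, bool]:
    """One recursive MH update of gamma, theta or sigma1_sq.

    Returns (value, loglik, logf1, accepted). The acceptance ratio is
    likelihood ratio x process-density ratio x reversed KDE ratio.
    """
    proposal = propose_from_stage1(pool.draws[param_name], rng)
    kde = pool.kdes[param_name]

    if ctx.encamped_only:
        prop_loglik, prop_logf1 = current_loglik, current_logf1
    else:
        trial = {
            "gamma": params.gamma,
            "theta": params.theta,
            "sigma1_sq": params.sigma1_sq,
        }
        trial[param_name] = proposal
        prop_logf1 = ctx.movement_logf1(trial["gamma"], trial["theta"], trial["sigma1_sq"])
        prop_loglik = ctx.loglik(params.beta, prop_logf1)

    log_ratio = (
        (prop_loglik - current_loglik)
        + (process_log_density(param_name, proposal, treatment)
           - process_log_density(param_name, current, treatment))
        + (kde(current) - kde(proposal))
    )
    if np.log(rng.random()) < log_ratio:
        return proposal, prop_loglik, prop_logf1, True
    return current, current_loglik, current_logf1, False


def mh_update_beta(
    params: IndividualParams,
    current_loglik: float,
    current_logf1: np.ndarray,
    ctx: _IndividualContext,
    pool: ProposalPool,
    treatment: TreatmentParams,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float, list[bool]]:
    """Component-at-a-time recursive MH update of the beta vector.

    Each coefficient is proposed from its own first-stage pool and judged
    against the data product over eligible steps, its conditional normal
    given the other current-iteration components, and the KDE correction.
    Assumes gamma, theta, sigma1_sq were already updated this iteration
    (their movement densities enter through ``current_logf1``).
    """
    beta = params.beta.copy()
    accepted = []
    for l in range(len(beta)):
        name = f"beta_{l}"
        proposal = propose_from_stage1(pool.draws[name], rng)
        kde = pool.kdes[name]
        cand = beta.copy()
        cand[l] = proposal
        prop_loglik = ctx.loglik(cand, current_logf1)
        log_ratio = (
            (prop_loglik - current_loglik)
            + (conditional_beta_logpdf(cand, l, treatment.mu_beta, treatment.Sigma_beta)
               - conditional_beta_logpdf(beta, l, treatment.mu_beta, treatment.Sigma_beta))
            + (kde(beta[l]) - kde(proposal))
        )
        if np.log(rng.random()) < log_ratio:
            beta = cand
            current_loglik = prop_loglik
            accepted.append(True)
        else:
            accepted.append(False)
    return beta, current_loglik, accepted


def gibbs_update_treatment(
    individuals: list[IndividualParams],
    hyper: HyperPriorConfig,
    current: TreatmentParams,
    rng: np.random.Generator,
) -> TreatmentParams:
    """Conjugate Gibbs draw of one treatment group's parameters.

    Means get normal-normal updates given the current (co)variances;
    variances get inverse-gamma updates given the new means; the beta
    covariance gets an inverse-Wishart update (or, under the diagonal
    model, independent inverse-gamma variances).
    """
    if not individuals:
        raise ValueError("group must contain at least one individual")
    n = len(individuals)
    B = np.array([ind.beta for ind in individuals])
    k = B.shape[1]
    lg = np.array([logit(ind.gamma) for ind in individuals])
    th = np.array([ind.theta for ind in individuals])
    ls = np.array([0.5 * np.log(ind.sigma1_sq) for ind in individuals])

    # mu_beta | betas, Sigma_beta
    Sinv = np.linalg.inv(current.Sigma_beta)
    P0inv = np.linalg.inv(hyper.Sigma_beta_pop)
    post_prec = n * Sinv + P0inv
    post_cov = np.linalg.inv(post_prec)
    post_mean = post_cov @ (Sinv @ B.sum(axis=0) + P0inv @ hyper.mu_beta_pop)
    chol = np.linalg.cholesky(post_cov)
    mu_beta = post_mean + chol @ rng.standard_normal(k)

    # Sigma_beta | betas, mu_beta
    centered = B - mu_beta
    if hyper.beta_cov_model == "wishart":
        scale = hyper.wishart_S * hyper.wishart_nu + centered.T @ centered
        Sigma_beta = stats.invwishart.rvs(
            df=hyper.wishart_nu + n, scale=scale, random_state=rng
        )
    else:
        diag = np.array(
            [
                (hyper.ig_scale(hyper.r_beta) + np.sum(centered[:, c] ** 2) / 2.0)
                / rng.gamma(hyper.q_beta + n / 2.0, 1.0)
                for c in range(k)
            ]
        )
        Sigma_beta = np.diag(diag)

    def scalar_updates(vals, mu_pop, var_pop, q, r, cur_var):
        post_var = 1.0 / (n / cur_var + 1.0 / var_pop)
        post_mu = post_var * (vals.sum() / cur_var + mu_pop / var_pop)
        mu = float(rng.normal(post_mu, np.sqrt(post_var)))
        var = float(
            (hyper.ig_scale(r) + np.sum((vals - mu) ** 2) / 2.0)
            / rng.gamma(q + n / 2.0, 1.0)
        )
        return mu, var

    mu_lg, var_lg = scalar_updates(
        lg, hyper.mu_logit_gamma_pop, hyper.var_logit_gamma_pop,
        hyper.q_logit_gamma, hyper.r_logit_gamma, current.var_logit_gamma,
    )
    mu_th, var_th = scalar_updates(
        th, hyper.mu_theta_pop, hyper.var_theta_pop,
        hyper.q_theta, hyper.r_theta, current.var_theta,
    )
    mu_ls, var_ls = scalar_updates(
        ls, hyper.mu_log_sigma1_pop, hyper.var_log_sigma1_pop,
        hyper.q_log_sigma1, hyper.r_log_sigma1, current.var_log_sigma1,
    )
    return TreatmentParams(
        mu_beta=mu_beta,
        Sigma_beta=Sigma_beta,
        mu_logit_gamma=mu_lg,
        var_logit_gamma=var_lg,
        mu_theta=mu_th,
        var_theta=var_th,
        mu_log_sigma1=mu_ls,
        var_log_sigma1=var_ls,
    )


_TREATMENT_SCALARS = (
    "mu_logit_gamma",
    "var_logit_gamma",
    "mu_theta",
    "var_theta",
    "mu_log_sigma1",
    "var_log_sigma1",
)


@dataclass
class HierarchicalResults:
    """Draws from the second-stage hierarchical fit.

    ``burn_in`` iterations (10% by default) are dropped by every accessor
    and summary; the raw arrays keep all iterations.
    """

    individual_ids: list[str]
    treatments_by_id: dict[str, str]
    groups: list[str]
    gamma: np.ndarray       # (n_iter, n_ind)
    theta: np.ndarray
    sigma1_sq: np.ndarray
    beta: np.ndarray        # (n_iter, n_ind, k)
    treatment_mu_beta: dict[str, np.ndarray]       # group -> (n_iter, k)
    treatment_Sigma_beta: dict[str, np.ndarray]    # group -> (n_iter, k, k)
    treatment_scalars: dict[str, dict[str, np.ndarray]]
    n_iter: int
    burn_in: int
    seed: int | None
    acceptance_rates: dict[str, float]

    @property
    def kept(self) -> slice:
        return slice(self.burn_in, None)

    def individual_draws(self, param: str) -> pd.DataFrame:
        """Post-burn-in draws, one column per individual."""
        if param.startswith("beta_"):
            arr = self.beta[self.kept, :, int(param.split("_")[1])]
        else:
            arr = getattr(self, param)[self.kept]
        return pd.DataFrame(arr, columns=self.individual_ids)

    def treatment_params_at(self, group: str, iteration: int) -> TreatmentParams:
        sc = self.treatment_scalars[group]
        return TreatmentParams(
            mu_beta=self.treatment_mu_beta[group][iteration],
            Sigma_beta=self.treatment_Sigma_beta[group][iteration],
            **{name: float(sc[name][iteration]) for name in _TREATMENT_SCALARS},
        )

    def treatment_draws(self, group: str, param: str) -> np.ndarray:
        """Post-burn-in treatment-level draws of one parameter."""
        if param == "mu_beta":
            return self.treatment_mu_beta[group][self.kept]
        if param.startswith("mu_beta_"):
            return self.treatment_mu_beta[group][self.kept, int(param.split("_")[-1])]
        if param == "Sigma_beta":
            return self.treatment_Sigma_beta[group][self.kept]
        return self.treatment_scalars[group][param][self.kept]

    def summary(self) -> pd.DataFrame:
        """Posterior mean/sd/95% interval of treatment-level parameters."""
        rows = []
        for group in self.groups:
            cols = {
                f"mu_beta_{i}": self.treatment_mu_beta[group][self.kept, i]
                for i in range(self.treatment_mu_beta[group].shape[1])
            }
            for name in _TREATMENT_SCALARS:
                cols[name] = self.treatment_scalars[group][name][self.kept]
            for name, draws in cols.items():
                rows.append(
                    {
                        "group": group,
                        "parameter": name,
                        "mean": np.mean(draws),
                        "sd": np.std(draws, ddof=1),
                        "q2.5": np.quantile(draws, 0.025),
                        "q97.5": np.quantile(draws, 0.975),
                    }
                )
        return pd.DataFrame(rows).set_index(["group", "parameter"])


class HierarchicalModel:
    """Full hierarchical movement model fit by recursive proposals.

    Parameters
    ----------
    trajectories
        All individuals' trajectories (any treatment mix).
    stage1_results
        Mapping individual_id -> :class:`Stage1Results`; every trajectory
        must have one.
    designs / raster
        Either precomputed design matrices per individual or a raster to
        extract them from.
    hyperpriors
        :class:`HyperPriorConfig`; defaults to the model's standard
        semi-informative settings.
    """

    def __init__(
        self,
        trajectories: list[Trajectory],
        stage1_results: dict[str, Stage1Results],
        designs: dict[str, np.ndarray] | None = None,
        raster: CategoricalRaster | None = None,
        hyperpriors: HyperPriorConfig | None = None,
        constants: ModelConstants | None = None,
        stage1_burn_in: int = 0,
    ):
        self.hyper = hyperpriors if hyperpriors is not None else HyperPriorConfig()
        self.constants = constants if constants is not None else ModelConstants()
        missing = [t.individual_id for t in trajectories if t.individual_id not in stage1_results]
        if missing:
            raise ValueError(
                f"no first-stage samples for individual(s): {', '.join(missing)}"
            )
        self.contexts: list[_IndividualContext] = []
        self.pools: list[ProposalPool] = []
        self.stage1 = stage1_results
        for traj in trajectories:
            if designs is not None:
                X = designs[traj.individual_id]
            elif raster is not None:
                X = design_matrix(raster, traj)
            else:
                raise ValueError("either designs or raster must be supplied")
            res = stage1_results[traj.individual_id]
            self.contexts.append(
                _IndividualContext(traj, X, self.constants, res.encamped_only)
            )
            self.pools.append(ProposalPool.from_stage1(res, burn_in=stage1_burn_in))
        self.groups = sorted({c.treatment for c in self.contexts})

    def fit(
        self,
        n_iter: int = 50_000,
        seed: int | None = None,
        burn_in_frac: float = 0.1,
    ) -> HierarchicalResults:
        """Run the second-stage sampler.

        Each iteration updates, per individual, gamma, theta and
        sigma1_sq (recursive scalar MH) then the beta coefficients
        (conditional recursive MH), followed by conjugate Gibbs draws of
        every treatment group's parameters. The first ``burn_in_frac`` of
        iterations is flagged as burn-in for downstream summaries.
        """
        rng = np.random.default_rng(seed)
        n_ind = len(self.contexts)
        k = self.contexts[0].design.shape[1] if n_ind else 4

        # Initialize individuals at their stage-1 posterior means and
        # groups at the sample moments of those means.
        params = [self.stage1[c.individual_id].posterior_mean_params() for c in self.contexts]
        group_params: dict[str, TreatmentParams] = {}
        for g in self.groups:
            members = [p for p, c in zip(params, self.contexts) if c.treatment == g]
            lg = np.array([logit(p.gamma) for p in members])
            th = np.array([p.theta for p in members])
            ls = np.array([0.5 * np.log(p.sigma1_sq) for p in members])
            B = np.array([p.beta for p in members])
            group_params[g] = TreatmentParams(
                mu_beta=B.mean(axis=0),
                Sigma_beta=np.cov(B.T) + 0.1 * np.eye(k) if len(members) > 1 else np.eye(k),
                mu_logit_gamma=float(lg.mean()),
                var_logit_gamma=max(float(lg.var(ddof=1)) if len(members) > 1 else 0.5, 0.1),
                mu_theta=float(th.mean()),
                var_theta=max(float(th.var(ddof=1)) if len(members) > 1 else 0.5, 0.1),
                mu_log_sigma1=float(ls.mean()),
                var_log_sigma1=max(float(ls.var(ddof=1)) if len(members) > 1 else 0.5, 0.1),
            )

        logf1 = [
            ctx.movement_logf1(p.gamma, p.theta, p.sigma1_sq)
            for ctx, p in zip(self.contexts, params)
        ]
        loglik = [
            ctx.loglik(p.beta, lf) for ctx, p, lf in zip(self.contexts, params, logf1)
        ]

        out = HierarchicalResults(
            individual_ids=[c.individual_id for c in self.contexts],
            treatments_by_id={c.individual_id: c.treatment for c in self.contexts},
            groups=self.groups,
            gamma=np.empty((n_iter, n_ind)),
            theta=np.empty((n_iter, n_ind)),
            sigma1_sq=np.empty((n_iter, n_ind)),
            beta=np.empty((n_iter, n_ind, k)),
            treatment_mu_beta={g: np.empty((n_iter, k)) for g in self.groups},
            treatment_Sigma_beta={g: np.empty((n_iter, k, k)) for g in self.groups},
            treatment_scalars={
                g: {name: np.empty(n_iter) for name in _TREATMENT_SCALARS}
                for g in self.groups
            },
            n_iter=n_iter,
            burn_in=int(round(burn_in_frac * n_iter)),
            seed=seed,
            acceptance_rates={},
        )
        accepts = {name: 0 for name in _SCALARS}
        accepts.update({f"beta_{i}": 0 for i in range(k)})

        for it in range(n_iter):
            for i, ctx in enumerate(self.contexts):
                p = params[i]
                tp = group_params[ctx.treatment]
                pool = self.pools[i]
                for name in _SCALARS:
                    cur = getattr(p, name)
                    val, loglik[i], logf1[i], acc = mh_update_scalar(
                        name, cur, loglik[i], logf1[i], p, ctx, pool, tp, rng
                    )
                    setattr(p, name, val)
                    accepts[name] += acc
                p.beta, loglik[i], acc_beta = mh_update_beta(
                    p, loglik[i], logf1[i], ctx, pool, tp, rng
                )
                for l, a in enumerate(acc_beta):
                    accepts[f"beta_{l}"] += a
                out.gamma[it, i] = p.gamma
                out.theta[it, i] = p.theta
                out.sigma1_sq[it, i] = p.sigma1_sq
                out.beta[it, i] = p.beta
            for g in self.groups:
                members = [p for p, c in zip(params, self.contexts) if c.treatment == g]
                group_params[g] = gibbs_update_treatment(
                    members, self.hyper, group_params[g], rng
                )
                out.treatment_mu_beta[g][it] = group_params[g].mu_beta
                out.treatment_Sigma_beta[g][it] = group_params[g].Sigma_beta
                for name in _TREATMENT_SCALARS:
                    out.treatment_scalars[g][name][it] = getattr(group_params[g], name)

        denom = n_iter * max(n_ind, 1)
        out.acceptance_rates = {name: cnt / denom for name, cnt in accepts.items()}
        return out


def fit_hierarchical(
    stage1_results: dict[str, Stage1Results],
    trajectories: list[Trajectory],
    designs: dict[str, np.ndarray] | None = None,
    raster: CategoricalRaster | None = None,
    hyperpriors: HyperPriorConfig | None = None,
    n_iter: int = 50_000,
    seed: int | None = None,
    burn_in_frac: float = 0.1,
    constants: ModelConstants | None = None,
) -> HierarchicalResults:
    """Convenience wrapper: build a :class:`HierarchicalModel` and fit it."""
    model = HierarchicalModel(
        trajectories,
        stage1_results,
        designs=designs,
        raster=raster,
        hyperpriors=hyperpriors,
        constants=constants,
    )
    return model.fit(n_iter=n_iter, seed=seed, burn_in_frac=burn_in_frac)
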