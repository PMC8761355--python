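"""First-stage per-individual MCMC.

Each animal's trajectory is fit independently under temporary priors whose
supports match the parameters, so that every update is either conjugate or
prior-as-proposal Metropolis-Hastings and the sampler needs no tuning:

* latent states ``z`` and probit auxiliaries ``v`` — data augmentation
  (Albert-Chib), making the coefficient update conjugate;
* ``beta`` — Gibbs from the normal full conditional given ``v``;
* ``gamma`` and ``theta`` — Metropolis-Hastings with the prior as the
  proposal (Beta and wrapped-Cauchy), so the acceptance ratio is a pure
  likelihood ratio over the movement-state steps;
* ``sigma1_sq`` — Gibbs from the inverse-gamma full conditional.

Trajectories with no step longer than the encamped threshold cannot
identify the movement state; for those, every step is pinned to the
encamped state and the movement parameters sample their priors.

All draws are stored; burn-in and thinning are deferred to second-stage
usage and downstream summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, ndtr, ndtri

from .landscape import CategoricalRaster, design_matrix
from .model import (
    DisplacementSeries,
    IndividualParams,
    LatentStates,
    ModelConstants,
    Stage1Priors,
    Trajectory,
    propagation_matrix,
    state_log_densities,
)

__all__ = [
    "detect_encamped_only",
    "update_latent_states",
    "update_beta_gibbs",
    "update_sigma1_gibbs",
    "update_gamma_theta_mh",
    "sample_wrapped_cauchy",
    "Stage1Model",
    "Stage1Results",
    "fit_individual",
]

_EPS = 1e-16


def _invgamma_rvs(shape: float, scale: float, rng: np.random.Generator) -> float:
    """Inverse-gamma draw (shape-scale convention) via a gamma reciprocal."""
    return scale / float(rng.gamma(shape, 1.0))


def detect_encamped_only(disp: DisplacementSeries, constants: ModelConstants) -> bool:
    """True when no displacement exceeds the encamped threshold.

    Such trajectories cannot separate the two states (the movement variance
    would be driven below the encamped variance), so the sampler fixes all
    steps to the encamped state.
    """
    if len(disp.deltas) < 2:
        raise ValueError("trajectory must have at least 3 relocations")
    lengths = np.linalg.norm(disp.deltas, axis=1)
    return bool(np.all(lengths <= constants.encamped_threshold))


def _sample_truncnorm(mu: np.ndarray, z: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw v ~ N(mu, 1) truncated to (0, inf) where z == 1, (-inf, 0] else.

    Inverse-CDF sampling; stable for the moderate |mu| values a proper
    probit prior produces.
    """
    u = rng.random(mu.shape)
    pos = ndtr(mu)        # P(v > 0)
    neg = ndtr(-mu)       # P(v <= 0)
    arg = np.where(z == 1, neg + u * pos, u * neg)
    return mu + ndtri(np.clip(arg, _EPS, 1.0 - _EPS))


def update_latent_states(
    delta_t: np.ndarray,
    delta_prev: np.ndarray,
    design: np.ndarray,
    params: IndividualParams,
    constants: ModelConstants,
    rng: np.random.Generator,
) -> LatentStates:
    """Joint draw of (z, v) from their full conditional.

    ``z_t`` is Bernoulli with probability
    ``p_t f1 / (p_t f1 + (1 - p_t) f0)`` where f1/f0 are the state
    densities of the observed displacement; ``v_t`` is then truncated
    normal around the probit linear predictor, positive iff ``z_t = 1``.
    """
    mu = design @ params.beta
    p = ndtr(mu)
    logf0, logf1 = state_log_densities(
        delta_t, delta_prev, params.gamma, params.theta, params.sigma1_sq, constants
    )
    with np.errstate(divide="ignore"):
        logit_pz = np.log(p) + logf1 - np.log1p(-p) - logf0
    pz1 = expit(logit_pz)
    z = (rng.random(len(p)) < pz1).astype(int)
    v = _sample_truncnorm(mu, z, rng)
    return LatentStates(z=z, v=v)


def update_beta_gibbs(
    v: np.ndarray,
    design: np.ndarray,
    prior_mu: np.ndarray,
    prior_var: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Conjugate normal draw of beta given the probit auxiliaries.

    Posterior covariance ``(X'X + I/prior_var)^-1`` and mean
    ``cov (X'v + prior_mu/prior_var)``; with zero data rows this is exactly
    the prior.
    """
    k = len(prior_mu)
    design = np.asarray(design, dtype=float).reshape(-1, k)
    precision = design.T @ design + np.eye(k) / prior_var
    cov = np.linalg.inv(precision)
    mean = cov @ (design.T @ np.asarray(v, dtype=float) + np.asarray(prior_mu) / prior_var)
    chol = np.linalg.cholesky(cov)
    return mean + chol @ rng.standard_normal(k)


def update_sigma1_gibbs(
    residuals: np.ndarray,
    q: float,
    r: float,
    rng: np.random.Generator,
) -> float:
    """Inverse-gamma Gibbs draw of the movement-state variance.

    ``residuals`` are the (m, 2) movement-step residual vectors
    ``delta_t - gamma M(theta) delta_{t-1}``; the full conditional is
    IG(q + m, r + SSR/2) in the shape-scale convention (each movement step
    contributes two scalar residual components). Zero movement steps give
    a draw from the prior.
    """
    residuals = np.asarray(residuals, dtype=float).reshape(-1, 2)
    m_components = residuals.size  # 2 per movement step
    ssr = float(np.sum(residuals**2))
    shape = q + m_components / 2.0
    scale = r + ssr / 2.0
    return _invgamma_rvs(shape, scale, rng)


def sample_wrapped_cauchy(
    mu: float, rho: float, rng: np.random.Generator, size=None
) -> np.ndarray | float:
    """Inverse-CDF draw from the wrapped Cauchy distribution on [0, 2pi).

    A Cauchy(mu, scale) variate wrapped to the circle is wrapped Cauchy
    with concentration rho = exp(-scale); inverting through the Cauchy
    quantile gives theta = mu + 2 atan(((1-rho)/(1+rho)) tan(pi(u-1/2))).
    """
    u = rng.random(size)
    draws = mu + 2.0 * np.arctan(
        (1.0 - rho) / (1.0 + rho) * np.tan(np.pi * (u - 0.5))
    )
    return np.mod(draws, 2.0 * np.pi)


def _movement_loglik(
    gamma: float,
    theta: float,
    sigma1_sq: float,
    delta_t: np.ndarray,
    delta_prev: np.ndarray,
    z: np.ndarray,
    constants: ModelConstants,
) -> float:
    """Log-likelihood terms that depend on (gamma, theta): the
    movement-state displacement densities only."""
    if not np.any(z == 1):
        return 0.0
    idx = z == 1
    _, logf1 = state_log_densities(
        delta_t[idx], delta_prev[idx], gamma, theta, sigma1_sq, constants
    )
    return float(np.sum(logf1))


def update_gamma_theta_mh(
    gamma: float,
    theta: float,
    delta_t: np.ndarray,
    delta_prev: np.ndarray,
    z: np.ndarray,
    sigma1_sq: float,
    priors: Stage1Priors,
    constants: ModelConstants,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Prior-as-proposal Metropolis-Hastings updates of gamma then theta.

    Proposals are independent prior draws, so prior and proposal densities
    cancel and the acceptance probability is min(1, likelihood ratio) over
    the movement-state steps. With no movement steps every proposal is
    accepted and the chain samples the prior.
    """
    cur_ll = _movement_loglik(gamma, theta, sigma1_sq, delta_t, delta_prev, z, constants)

    prop_gamma = float(rng.beta(priors.gamma_a, priors.gamma_b))
    prop_ll = _movement_loglik(prop_gamma, theta, sigma1_sq, delta_t, delta_prev, z, constants)
    if np.log(rng.random()) < prop_ll - cur_ll:
        gamma, cur_ll = prop_gamma, prop_ll

    prop_theta = float(sample_wrapped_cauchy(priors.theta_mu, priors.theta_rho, rng))
    prop_ll = _movement_loglik(gamma, prop_theta, sigma1_sq, delta_t, delta_prev, z, constants)
    if np.log(rng.random()) < prop_ll - cur_ll:
        theta = prop_theta
    return gamma, theta


@dataclass
class Stage1Results:
    """Posterior draws from one individual's first-stage fit."""

    individual_id: str
    treatment: str
    beta: np.ndarray          # (n_iter, 4)
    gamma: np.ndarray         # (n_iter,)
    theta: np.ndarray         # (n_iter,)
    sigma1_sq: np.ndarray     # (n_iter,)
    z: np.ndarray             # (n_iter, n_eligible) uint8
    encamped_only: bool
    n_iter: int
    seed: int | None

    def posterior_mean_params(self) -> IndividualParams:
        gamma = float(np.clip(np.mean(self.gamma), 1e-6, 1 - 1e-6))
        return IndividualParams(
            beta=self.beta.mean(axis=0),
            gamma=gamma,
            theta=float(np.mean(self.theta)),
            sigma1_sq=float(np.mean(self.sigma1_sq)),
        )

    def summary(self) -> pd.DataFrame:
        """Posterior mean, sd and central 95% interval per parameter."""
        rows = {}
        cols = {f"beta_{i}": self.beta[:, i] for i in range(self.beta.shape[1])}
        cols.update(gamma=self.gamma, theta=self.theta, sigma1_sq=self.sigma1_sq)
        for name, draws in cols.items():
            rows[name] = {
                "mean": np.mean(draws),
                "sd": np.std(draws, ddof=1),
                "q2.5": np.quantile(draws, 0.025),
                "q97.5": np.quantile(draws, 0.975),
            }
        return pd.DataFrame(rows).T

    def to_frame(self) -> pd.DataFrame:
        """Long-format draw table (parameter, iteration, value)."""
        n = self.n_iter
        frames = []
        cols = {f"beta_{i}": self.beta[:, i] for i in range(self.beta.shape[1])}
        cols.update(gamma=self.gamma, theta=self.theta, sigma1_sq=self.sigma1_sq)
        for name, draws in cols.items():
            frames.append(
                pd.DataFrame(
                    {
                        "parameter": name,
                        "iteration": np.arange(1, n + 1),
                        "value": draws,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


class Stage1Model:
    """Per-individual first-stage model, statsmodels style.

    Construct from a trajectory plus either a precomputed design matrix
    (one one-hot row per likelihood-eligible step) or a raster to extract
    it from, then call :meth:`fit`.
    """

    def __init__(
        self,
        trajectory: Trajectory,
        design: np.ndarray | None = None,
        raster: CategoricalRaster | None = None,
        priors: Stage1Priors | None = None,
        constants: ModelConstants | None = None,
    ):
        if len(trajectory) < 3:
            raise ValueError(
                f"trajectory {trajectory.individual_id!r} has fewer than 3 relocations"
            )
        self.trajectory = trajectory
        self.priors = priors if priors is not None else Stage1Priors()
        self.constants = constants if constants is not None else ModelConstants()
        self.disp = trajectory.displacements()
        if design is None:
            if raster is None:
                raise ValueError("either design or raster must be supplied")
            design = design_matrix(raster, trajectory)
        design = np.asarray(design, dtype=float)
        if design.shape[0] != self.disp.n_eligible:
            raise ValueError(
                f"design has {design.shape[0]} rows but trajectory has "
                f"{self.disp.n_eligible} likelihood-eligible steps"
            )
        self.design = design
        self.encamped_only = detect_encamped_only(self.disp, self.constants)

    def _initial_params(self) -> IndividualParams:
        # Moment-matching start: long steps flag the movement state.
        lengths = np.linalg.norm(self.disp.delta_t, axis=1)
        z0 = (lengths > self.constants.encamped_threshold).astype(int)
        floor = 2.0 * self.constants.sigma0**2
        if z0.sum() >= 2:
            comps = self.disp.delta_t[z0 == 1].ravel()
            s2 = max(float(np.var(comps, ddof=1)), floor)
        else:
            s2 = floor
        return IndividualParams(
            beta=np.zeros(self.design.shape[1]), gamma=0.5, theta=np.pi, sigma1_sq=s2
        )

    def fit(
        self,
        n_iter: int = 100_000,
        seed: int | None = None,
        rng: np.random.Generator | None = None,
        store_states: bool = True,
    ) -> Stage1Results:
        """Run the systematic-scan sampler: (z, v) -> beta -> gamma ->
        theta -> sigma1_sq each iteration. Deterministic given the seed."""
        if n_iter < 1:
            raise ValueError("n_iter must be at least 1")
        if rng is None:
            rng = np.random.default_rng(seed)
        pri, cst = self.priors, self.constants
        dts, dps, X = self.disp.delta_t, self.disp.delta_prev, self.design
        m = self.disp.n_eligible
        k = X.shape[1]

        params = self._initial_params()
        z = np.zeros(m, dtype=int)
        if not self.encamped_only:
            z = (np.linalg.norm(dts, axis=1) > cst.encamped_threshold).astype(int)
        v = _sample_truncnorm(X @ params.beta, z, rng) if m else np.zeros(0)

        out_beta = np.empty((n_iter, k))
        out_gamma = np.empty(n_iter)
        out_theta = np.empty(n_iter)
        out_sigma = np.empty(n_iter)
        out_z = np.zeros((n_iter, m), dtype=np.uint8) if store_states else None

        for it in range(n_iter):
            if self.encamped_only:
                # States pinned encamped; movement parameters sample priors.
                z = np.zeros(m, dtype=int)
                v = _sample_truncnorm(X @ params.beta, z, rng) if m else v
                params.beta = update_beta_gibbs(v, X, pri.mu_beta, pri.var_beta, rng)
                params.gamma = float(rng.beta(pri.gamma_a, pri.gamma_b))
                params.theta = float(
                    sample_wrapped_cauchy(pri.theta_mu, pri.theta_rho, rng)
                )
                params.sigma1_sq = _invgamma_rvs(pri.sigma_q, pri.sigma_r, rng)
            else:
                states = update_latent_states(dts, dps, X, params, cst, rng)
                z, v = states.z, states.v
                params.beta = update_beta_gibbs(v, X, pri.mu_beta, pri.var_beta, rng)
                params.gamma, params.theta = update_gamma_theta_mh(
                    params.gamma, params.theta, dts, dps, z,
                    params.sigma1_sq, pri, cst, rng,
                )
                M = propagation_matrix(params.theta)
                resid = dts[z == 1] - params.gamma * dps[z == 1] @ M.T
                params.sigma1_sq = update_sigma1_gibbs(resid, pri.sigma_q, pri.sigma_r, rng)

            out_beta[it] = params.beta
            out_gamma[it] = params.gamma
            out_theta[it] = params.theta
            out_sigma[it] = params.sigma1_sq
            if store_states:
                out_z[it] = z

        return Stage1Results(
            individual_id=self.trajectory.individual_id,
            treatment=self.trajectory.treatment,
            beta=out_beta,
            gamma=out_gamma,
            theta=out_theta,
            sigma1_sq=out_sigma,
            z=out_z if store_states else np.zeros((0, m), dtype=np.uint8),
            encamped_only=self.encamped_only,
            n_iter=n_iter,
            seed=seed,
        )


def fit_individual(
    trajectory: Trajectory,
    design: np.ndarray,
    priors: Stage1Priors | None = None,
    n_iter: int = 100_000,
    seed: int | None = None,
    constants: ModelConstants | None = None,
) -> Stage1Results:
    """Convenience wrapper: build a :class:`Stage1Model` and fit it."""
    model = Stage1Model(trajectory, design=design, priors=priors, constants=constants)
    return model.fit(n_iter=n_iter, seed=seed)
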