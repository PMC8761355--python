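"""Independent oracle samplers and closed forms used only by the tests.

The single-stage hierarchical sampler below fits the same two-state
mixture hierarchy as the package but with a completely different MCMC
scheme — random-walk Metropolis on transformed scales for individual
parameters plus textbook conjugate group updates — so its posterior can
serve as an independent check of the two-stage proposal-recursive fit.
It deliberately shares no sampling code with the package.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit, logit, ndtr

LOG2PI = np.log(2 * np.pi)


def mixture_loglik(delta_t, delta_prev, X, beta, gamma, theta, sigma1_sq, sigma0=5.0):
    """State-integrated log-likelihood, written directly from the mixture."""
    c, s = np.cos(theta), np.sin(theta)
    mx = gamma * (c * delta_prev[:, 0] - s * delta_prev[:, 1])
    my = gamma * (s * delta_prev[:, 0] + c * delta_prev[:, 1])
    r2_1 = (delta_t[:, 0] - mx) ** 2 + (delta_t[:, 1] - my) ** 2
    r2_0 = delta_t[:, 0] ** 2 + delta_t[:, 1] ** 2
    f1 = np.exp(-LOG2PI - np.log(sigma1_sq) - r2_1 / (2 * sigma1_sq))
    f0 = np.exp(-LOG2PI - np.log(sigma0**2) - r2_0 / (2 * sigma0**2))
    p = ndtr(X @ beta)
    return float(np.sum(np.log(p * f1 + (1 - p) * f0)))


def single_stage_fit(
    data,
    groups,
    hyper,
    n_iter,
    seed,
    rw_scales=(0.35, 0.35, 0.25, 0.45),
):
    """Single-stage random-walk MCMC for the full hierarchy.

    Parameters
    ----------
    data
        list of dicts with keys delta_t, delta_prev, X, group.
    groups
        ordered group labels.
    hyper
        mapping with keys mirroring the package hyperpriors:
        mu_lg_pop, var_lg_pop, mu_th_pop, var_th_pop, mu_ls_pop,
        var_ls_pop, Sigma_b_pop (k x k), q/r pairs (gamma-precision
        convention: precision ~ Gamma(q, scale r)), wishart_S, wishart_nu.

    Returns dict of treatment-level draw arrays per group.
    """
    rng = np.random.default_rng(seed)
    n = len(data)
    k = data[0]["X"].shape[1]
    s_lg, s_th, s_ls, s_b = rw_scales

    # individual state on transformed scales
    lg = np.zeros(n)
    th = np.full(n, np.pi)
    ls = np.full(n, np.log(20.0))
    B = np.zeros((n, k))
    ll = np.array(
        [
            mixture_loglik(
                d["delta_t"], d["delta_prev"], d["X"], B[i], expit(lg[i]), th[i],
                np.exp(2 * ls[i]),
            )
            for i, d in enumerate(data)
        ]
    )
    # group state
    g_idx = {g: [i for i, d in enumerate(data) if d["group"] == g] for g in groups}
    state = {
        g: dict(
            mu_lg=hyper["mu_lg_pop"], var_lg=0.5,
            mu_th=hyper["mu_th_pop"], var_th=0.5,
            mu_ls=hyper["mu_ls_pop"], var_ls=0.5,
            mu_b=np.zeros(k), Sigma_b=np.eye(k),
        )
        for g in groups
    }
    out = {
        g: {name: np.empty(n_iter) for name in ("mu_lg", "mu_th", "mu_ls")}
        for g in groups
    }

    def norm_lp(x, m, v):
        return -0.5 * (LOG2PI + np.log(v) + (x - m) ** 2 / v)

    for it in range(n_iter):
        for i, d in enumerate(data):
            gs = state[d["group"]]
            # logit(gamma) random walk
            prop = lg[i] + s_lg * rng.standard_normal()
            ll_p = mixture_loglik(
                d["delta_t"], d["delta_prev"], d["X"], B[i], expit(prop), th[i],
                np.exp(2 * ls[i]),
            )
            lr = (ll_p - ll[i]) + norm_lp(prop, gs["mu_lg"], gs["var_lg"]) - norm_lp(
                lg[i], gs["mu_lg"], gs["var_lg"]
            )
            if np.log(rng.random()) < lr:
                lg[i], ll[i] = prop, ll_p
            # theta random walk
            prop = th[i] + s_th * rng.standard_normal()
            ll_p = mixture_loglik(
                d["delta_t"], d["delta_prev"], d["X"], B[i], expit(lg[i]), prop,
                np.exp(2 * ls[i]),
            )
            lr = (ll_p - ll[i]) + norm_lp(prop, gs["mu_th"], gs["var_th"]) - norm_lp(
                th[i], gs["mu_th"], gs["var_th"]
            )
            if np.log(rng.random()) < lr:
                th[i], ll[i] = prop, ll_p
            # log(sigma1) random walk
            prop = ls[i] + s_ls * rng.standard_normal()
            ll_p = mixture_loglik(
                d["delta_t"], d["delta_prev"], d["X"], B[i], expit(lg[i]), th[i],
                np.exp(2 * prop),
            )
            lr = (ll_p - ll[i]) + norm_lp(prop, gs["mu_ls"], gs["var_ls"]) - norm_lp(
                ls[i], gs["mu_ls"], gs["var_ls"]
            )
            if np.log(rng.random()) < lr:
                ls[i], ll[i] = prop, ll_p
            # beta joint random walk with MVN process prior
            prop_b = B[i] + s_b * rng.standard_normal(k)
            ll_p = mixture_loglik(
                d["delta_t"], d["delta_prev"], d["X"], prop_b, expit(lg[i]), th[i],
                np.exp(2 * ls[i]),
            )
            Sinv = np.linalg.inv(gs["Sigma_b"])
            dp_ = prop_b - gs["mu_b"]
            dc_ = B[i] - gs["mu_b"]
            lr = (ll_p - ll[i]) - 0.5 * (dp_ @ Sinv @ dp_ - dc_ @ Sinv @ dc_)
            if np.log(rng.random()) < lr:
                B[i], ll[i] = prop_b, ll_p

        for g in groups:
            idx = g_idx[g]
            m = len(idx)
            gs = state[g]
            for key, vals, mu_pop, var_pop, q, r in (
                ("lg", lg[idx], hyper["mu_lg_pop"], hyper["var_lg_pop"],
                 hyper["q_lg"], hyper["r_lg"]),
                ("th", th[idx], hyper["mu_th_pop"], hyper["var_th_pop"],
                 hyper["q_th"], hyper["r_th"]),
                ("ls", ls[idx], hyper["mu_ls_pop"], hyper["var_ls_pop"],
                 hyper["q_ls"], hyper["r_ls"]),
            ):
                v = gs[f"var_{key}"]
                pv = 1.0 / (m / v + 1.0 / var_pop)
                pm = pv * (np.sum(vals) / v + mu_pop / var_pop)
                mu_new = rng.normal(pm, np.sqrt(pv))
                # precision ~ Gamma(q, scale r) prior
                shape = q + m / 2.0
                rate = 1.0 / r + np.sum((vals - mu_new) ** 2) / 2.0
                var_new = 1.0 / rng.gamma(shape, 1.0 / rate)
                gs[f"mu_{key}"], gs[f"var_{key}"] = mu_new, var_new
            # mu_b, Sigma_b conjugate updates
            Sinv = np.linalg.inv(gs["Sigma_b"])
            P0inv = np.linalg.inv(hyper["Sigma_b_pop"])
            cov = np.linalg.inv(m * Sinv + P0inv)
            mean = cov @ (Sinv @ B[idx].sum(axis=0))
            gs["mu_b"] = rng.multivariate_normal(mean, cov)
            centered = B[idx] - gs["mu_b"]
            scale = hyper["wishart_S"] * hyper["wishart_nu"] + centered.T @ centered
            df = hyper["wishart_nu"] + m
            # inverse-Wishart draw via the inverse of a Wishart draw
            L = np.linalg.cholesky(np.linalg.inv(scale))
            A = np.zeros((k, k))
            for a in range(k):
                A[a, a] = np.sqrt(rng.chisquare(df - a))
                for b in range(a):
                    A[a, b] = rng.standard_normal()
            W = L @ A @ A.T @ L.T
            gs["Sigma_b"] = np.linalg.inv(W)

            out[g]["mu_lg"][it] = gs["mu_lg"]
            out[g]["mu_th"][it] = gs["mu_th"]
            out[g]["mu_ls"][it] = gs["mu_ls"]
    return out


def default_oracle_hyper(k=4):
    """The package's standard hyperpriors, restated independently."""
    return dict(
        mu_lg_pop=float(logit(0.7)), var_lg_pop=1.5,
        mu_th_pop=float(np.pi), var_th_pop=float(np.pi**2 / 4),
        mu_ls_pop=float(np.log(20.0)), var_ls_pop=100.0,
        q_lg=0.001, r_lg=1000.0,
        q_th=2.5, r_th=0.5,
        q_ls=0.001, r_ls=1000.0,
        Sigma_b_pop=np.eye(k),
        wishart_S=np.eye(k),
        wishart_nu=6.0,
    )
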