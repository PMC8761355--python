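"""Derived quantities, hypothesis tests and posterior diagnostics.

Treatment-level parameters live on transformed scales (logit, log,
probit). Natural-scale group means — mean autocorrelation, mean movement
scale in metres, mean movement probability per landscape feature — are
obtained per MCMC iteration by Monte Carlo integration over the group's
individual-level distributions. Hypothesis tests compare treatment groups
through the posterior distribution of pairwise differences and the
posterior probability that one group's parameter exceeds another's.
Individual heterogeneity within a group is the per-iteration sample
variance of the individual-level values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, ndtr

from .landscape import CATEGORIES
from .model import TreatmentParams

__all__ = [
    "back_transform_treatment",
    "back_transform_results",
    "posterior_probability_greater",
    "difference_summary",
    "DifferenceSummary",
    "individual_heterogeneity",
    "summarize",
    "trace_diagnostics",
    "save_trace_plots",
]


def back_transform_treatment(
    tp: TreatmentParams,
    n_mc: int = 1000,
    rng: np.random.Generator | None = None,
    integrate: bool = True,
) -> dict[str, float]:
    """Natural-scale group means for one treatment-level draw.

    With ``integrate`` (default), draws ``n_mc`` pseudo-individuals from
    the group's distributions and averages the inverse transforms — the
    group mean accounts for individual heterogeneity. With
    ``integrate=False`` the plug-in inverse transforms of the means are
    returned instead. Group variances of zero make the two identical.
    """
    if n_mc < 1:
        raise ValueError("n_mc must be at least 1")
    out: dict[str, float] = {}
    if not integrate or (
        tp.var_logit_gamma == 0
        and tp.var_log_sigma1 == 0
        and not np.any(tp.Sigma_beta)
    ):
        out["mu_gamma"] = float(expit(tp.mu_logit_gamma))
        out["mu_sigma1"] = float(np.exp(tp.mu_log_sigma1))
        out["mu_theta"] = float(tp.mu_theta)
        for c, cat in enumerate(CATEGORIES[: len(tp.mu_beta)]):
            out[f"mu_p_{cat}"] = float(ndtr(tp.mu_beta[c]))
        return out
    if rng is None:
        rng = np.random.default_rng()
    lg = rng.normal(tp.mu_logit_gamma, np.sqrt(tp.var_logit_gamma), size=n_mc)
    ls = rng.normal(tp.mu_log_sigma1, np.sqrt(tp.var_log_sigma1), size=n_mc)
    betas = rng.multivariate_normal(tp.mu_beta, tp.Sigma_beta, size=n_mc)
    out["mu_gamma"] = float(np.mean(expit(lg)))
    out["mu_sigma1"] = float(np.mean(np.exp(ls)))
    out["mu_theta"] = float(tp.mu_theta)
    for c, cat in enumerate(CATEGORIES[: len(tp.mu_beta)]):
        out[f"mu_p_{cat}"] = float(np.mean(ndtr(betas[:, c])))
    return out


def back_transform_results(
    results,
    n_mc: int = 1000,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    integrate: bool = True,
) -> dict[str, pd.DataFrame]:
    """Iteration-indexed natural-scale draws per treatment group.

    Applies :func:`back_transform_treatment` to every post-burn-in
    second-stage draw; returns group -> DataFrame with one column per
    derived quantity.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    out: dict[str, pd.DataFrame] = {}
    for group in results.groups:
        rows = []
        for it in range(results.burn_in, results.n_iter):
            tp = results.treatment_params_at(group, it)
            rows.append(back_transform_treatment(tp, n_mc=n_mc, rng=rng, integrate=integrate))
        out[group] = pd.DataFrame(rows)
    return out


def posterior_probability_greater(draws_a: np.ndarray, draws_b: np.ndarray) -> float:
    """Fraction of iterations with a > b; exact ties count half.

    This is the posterior probability that group a's parameter exceeds
    group b's, the standard MCMC hypothesis-testing statistic.
    """
    a = np.asarray(draws_a, dtype=float)
    b = np.asarray(draws_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("draw vectors must be aligned and equal length")
    return float((np.sum(a > b) + 0.5 * np.sum(a == b)) / len(a))


@dataclass
class DifferenceSummary:
    mean_difference: float
    ci_lower: float
    ci_upper: float
    probability_greater: float


def difference_summary(
    draws_a: np.ndarray, draws_b: np.ndarray, ci_level: float = 0.95
) -> DifferenceSummary:
    """Posterior summary of the derived quantity a - b."""
    a = np.asarray(draws_a, dtype=float)
    b = np.asarray(draws_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("draw vectors must be aligned and equal length")
    diff = a - b
    alpha = (1.0 - ci_level) / 2.0
    return DifferenceSummary(
        mean_difference=float(np.mean(diff)),
        ci_lower=float(np.quantile(diff, alpha)),
        ci_upper=float(np.quantile(diff, 1.0 - alpha)),
        probability_greater=posterior_probability_greater(a, b),
    )


def individual_heterogeneity(draws: np.ndarray) -> np.ndarray:
    """Per-iteration sample variance across a group's individuals.

    ``draws`` has shape (n_iterations, n_individuals); the variance uses
    the n-1 denominator. At least two individuals are required.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.ndim != 2 or draws.shape[1] < 2:
        raise ValueError("heterogeneity needs draws for at least 2 individuals")
    return np.var(draws, axis=1, ddof=1)


def summarize(draws: np.ndarray, ci_level: float = 0.95) -> tuple[float, float, float]:
    """Posterior mean and equal-tailed credible interval."""
    draws = np.asarray(draws, dtype=float)
    if draws.size == 0:
        raise ValueError("cannot summarize an empty draw vector")
    alpha = (1.0 - ci_level) / 2.0
    return (
        float(np.mean(draws)),
        float(np.quantile(draws, alpha)),
        float(np.quantile(draws, 1.0 - alpha)),
    )


def trace_diagnostics(draws: dict[str, np.ndarray] | pd.DataFrame) -> pd.DataFrame:
    """Effective sample size and split-chain R-hat per parameter.

    An automated stand-in for visual trace inspection: each chain is split
    in half and the rank-normalized split-R-hat computed (flagged when
    above 1.1), alongside the bulk effective sample size.
    """
    import arviz as az

    if isinstance(draws, pd.DataFrame):
        draws = {c: draws[c].to_numpy() for c in draws.columns}
    rows = []
    for name, chain in draws.items():
        chain = np.asarray(chain, dtype=float)
        if len(chain) < 100:
            raise ValueError(f"parameter {name!r}: need at least 100 draws for diagnostics")
        # the autocorrelation estimator can nominally exceed n; cap at n
        ess = min(float(az.ess(az.convert_to_dataset(chain[None, :]))["x"]), len(chain))
        half = chain[: 2 * (len(chain) // 2)].reshape(2, -1)  # split-chain R-hat
        rhat = float(az.rhat(az.convert_to_dataset(half))["x"])
        rows.append(
            {"parameter": name, "ess": ess, "rhat": rhat, "flagged": bool(rhat > 1.1)}
        )
    return pd.DataFrame(rows).set_index("parameter")


def save_trace_plots(
    draws: dict[str, np.ndarray] | pd.DataFrame, path, max_params: int = 12
) -> None:
    """Write a simple trace-plot panel to ``path`` (PNG) for manual review."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if isinstance(draws, pd.DataFrame):
        draws = {c: draws[c].to_numpy() for c in draws.columns}
    names = list(draws)[:max_params]
    n = len(names)
    fig, axes = plt.subplots(n, 1, figsize=(8, 1.6 * n), squeeze=False)
    for ax, name in zip(axes[:, 0], names):
        ax.plot(np.asarray(draws[name]), lw=0.4)
        ax.set_ylabel(name, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
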