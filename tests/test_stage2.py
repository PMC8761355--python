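"""Second-stage recursive sampler: KDE proposal densities, change-of-
variables process densities, generalized MH ratios and treatment-level
conjugate updates."""

import numpy as np
import pytest
from scipy import stats
from scipy.special import expit, logit, ndtr

from movemix import (
    HyperPriorConfig,
    IndividualParams,
    ModelConstants,
    Trajectory,
    TreatmentParams,
)
from movemix.stage2 import (
    HierarchicalModel,
    KDECache,
    ProposalPool,
    _IndividualContext,
    conditional_beta_logpdf,
    gibbs_update_treatment,
    kde_logpdf,
    mh_update_beta,
    mh_update_scalar,
    process_log_density,
    propose_from_stage1,
    silverman_bandwidth,
)


class TestKdeLogpdf:
    def test_symmetric_pool_gives_symmetric_density(self):
        pool = np.array([-1.3, 1.3])
        for x in [0.2, 0.7, 2.0]:
            assert kde_logpdf(pool, x) == pytest.approx(kde_logpdf(pool, -x), abs=1e-12)

    def test_quadrature_mass_is_one(self):
        rng = np.random.default_rng(0)
        pool = rng.normal(2.0, 0.5, 400)
        h = silverman_bandwidth(pool)
        grid = np.linspace(pool.min() - 10 * h, pool.max() + 10 * h, 20_001)
        mass = np.trapezoid(np.exp(kde_logpdf(pool, grid)), grid)
        assert mass == pytest.approx(1.0, abs=1e-3)

    def test_matches_direct_mixture_formula(self):
        rng = np.random.default_rng(1)
        pool = rng.normal(0, 1, 250)
        h = silverman_bandwidth(pool)
        xs = rng.uniform(-3, 3, 100)
        for x in xs:
            direct = np.log(
                np.mean(stats.norm.pdf(x, loc=pool, scale=h))
            )
            assert kde_logpdf(pool, float(x)) == pytest.approx(direct, abs=1e-10)

    def test_degenerate_pool_rejected(self):
        with pytest.raises(ValueError, match="bandwidth|degenerate"):
            kde_logpdf(np.ones(50), 1.0)

    def test_binned_cache_agrees_with_exact(self):
        rng = np.random.default_rng(2)
        pool = rng.normal(0.5, 0.2, 2000)
        cache = KDECache(pool)
        assert cache.quadrature_mass() == pytest.approx(1.0, abs=1e-3)
        for x in [0.1, 0.5, 0.9]:
            assert cache(x) == pytest.approx(kde_logpdf(pool, x), abs=5e-3)


class TestProposeFromStage1:
    def test_membership_and_determinism(self):
        pool = np.array([1.0, 2.0, 3.0])
        a = [propose_from_stage1(pool, np.random.default_rng(3)) for _ in range(5)]
        b = [propose_from_stage1(pool, np.random.default_rng(3)) for _ in range(5)]
        assert a == b
        assert all(x in pool for x in a)

    def test_uniform_frequencies(self):
        pool = np.array([1.0, 2.0, 3.0])
        rng = np.random.default_rng(4)
        draws = [propose_from_stage1(pool, rng) for _ in range(30_000)]
        counts = [draws.count(v) for v in pool]
        chi2 = stats.chisquare(counts)
        assert chi2.pvalue > 0.001

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            propose_from_stage1(np.array([]), np.random.default_rng(0))


def _tp():
    return TreatmentParams(
        mu_beta=np.array([0.1, -0.2, 0.0, 0.3]),
        Sigma_beta=np.array(
            [
                [0.3, 0.1, 0.0, 0.0],
                [0.1, 0.4, 0.05, 0.0],
                [0.0, 0.05, 0.2, 0.02],
                [0.0, 0.0, 0.02, 0.25],
            ]
        ),
        mu_logit_gamma=0.0,
        var_logit_gamma=1.0,
        mu_theta=np.pi,
        var_theta=0.5,
        mu_log_sigma1=np.log(25.0),
        var_log_sigma1=0.3,
    )


class TestProcessLogDensity:
    def test_gamma_jacobian_at_half(self):
        tp = _tp()
        expected = stats.norm.logpdf(0.0, 0.0, 1.0) + np.log(4.0)
        assert process_log_density("gamma", 0.5, tp) == pytest.approx(expected, abs=1e-12)

    def test_gamma_density_integrates_to_one(self):
        tp = _tp()
        g = np.linspace(1e-6, 1 - 1e-6, 200_001)
        vals = np.array([process_log_density("gamma", x, tp) for x in g[:: 100]])
        # finer integration with vectorized formula
        dens = np.exp(
            stats.norm.logpdf(logit(g), tp.mu_logit_gamma, np.sqrt(tp.var_logit_gamma))
            - np.log(g * (1 - g))
        )
        assert np.trapezoid(dens, g) == pytest.approx(1.0, abs=1e-4)
        assert np.allclose(
            vals,
            np.log(dens[::100]),
            atol=1e-9,
        )

    def test_sigma_density_integrates_to_one(self):
        tp = _tp()
        s2 = np.geomspace(1e-2, 1e7, 400_001)
        dens = np.exp([process_log_density("sigma1_sq", x, tp) for x in s2[::200]])
        full = np.exp(
            stats.norm.logpdf(0.5 * np.log(s2), tp.mu_log_sigma1, np.sqrt(tp.var_log_sigma1))
            - np.log(2 * s2)
        )
        assert np.trapezoid(full, s2) == pytest.approx(1.0, abs=1e-3)
        assert np.allclose(np.log(full[::200]), np.log(dens), atol=1e-9)

    def test_theta_is_plain_normal(self):
        tp = _tp()
        for x in [-1.0, 2.0, 7.0]:
            assert process_log_density("theta", x, tp) == pytest.approx(
                stats.norm.logpdf(x, tp.mu_theta, np.sqrt(tp.var_theta)), abs=1e-12
            )

    def test_out_of_support_is_minus_inf(self):
        tp = _tp()
        assert process_log_density("gamma", 1.2, tp) == -np.inf
        assert process_log_density("sigma1_sq", -3.0, tp) == -np.inf


class TestConditionalBetaLogpdf:
    def test_diagonal_covariance_reduces_to_marginal(self):
        mu = np.array([0.1, -0.2, 0.3, 0.0])
        Sigma = np.diag([0.3, 0.5, 0.2, 0.4])
        beta = np.array([0.5, 0.1, -0.3, 0.2])
        for l in range(4):
            expected = stats.norm.logpdf(beta[l], mu[l], np.sqrt(Sigma[l, l]))
            assert conditional_beta_logpdf(beta, l, mu, Sigma) == pytest.approx(
                expected, abs=1e-12
            )

    def test_bivariate_matches_joint_over_marginal(self):
        rho = 0.6
        s1, s2 = 0.7, 1.2
        mu = np.array([0.2, -0.5])
        Sigma = np.array([[s1**2, rho * s1 * s2], [rho * s1 * s2, s2**2]])
        beta = np.array([0.9, 0.4])
        got = conditional_beta_logpdf(beta, 0, mu, Sigma)
        # direct: conditional mean/variance formulas
        cm = mu[0] + rho * (s1 / s2) * (beta[1] - mu[1])
        cv = s1**2 * (1 - rho**2)
        assert got == pytest.approx(stats.norm.logpdf(beta[0], cm, np.sqrt(cv)), abs=1e-12)
        # and: log joint minus log marginal
        ratio = stats.multivariate_normal(mu, Sigma).logpdf(beta) - stats.norm.logpdf(
            beta[1], mu[1], s2
        )
        assert got == pytest.approx(ratio, abs=1e-12)

    def test_conditioning_never_inflates_variance(self):
        rng = np.random.default_rng(5)
        A = rng.normal(0, 1, (4, 4))
        Sigma = A @ A.T + 0.5 * np.eye(4)
        mu = np.zeros(4)
        for l in range(4):
            others = [i for i in range(4) if i != l]
            S_oo = Sigma[np.ix_(others, others)]
            S_lo = Sigma[l, others]
            cv = Sigma[l, l] - S_lo @ np.linalg.solve(S_oo, S_lo)
            assert cv <= Sigma[l, l]

    def test_non_pd_rejected(self):
        Sigma = np.ones((3, 3))  # singular
        with pytest.raises((ValueError, np.linalg.LinAlgError)):
            conditional_beta_logpdf(np.zeros(3), 0, np.zeros(3), Sigma)


def _toy_setup(T=12, seed=6):
    """Small individual context + synthetic proposal pools."""
    rng = np.random.default_rng(seed)
    positions = np.cumsum(rng.normal(0, 15, (T, 2)), axis=0) + 500
    traj = Trajectory(
        individual_id="toy", treatment="resident",
        days=np.arange(1, T + 1), positions=positions,
    )
    m = traj.displacements().n_eligible
    X = np.eye(4)[rng.integers(0, 4, m)]
    ctx = _IndividualContext(traj, X, ModelConstants(), encamped_only=False)
    draws = {
        "gamma": np.clip(rng.beta(3, 3, 600), 1e-4, 1 - 1e-4),
        "theta": rng.uniform(0, 2 * np.pi, 600),
        "sigma1_sq": rng.gamma(5.0, 60.0, 600),
    }
    for i in range(4):
        draws[f"beta_{i}"] = rng.normal(0, 0.8, 600)
    pool = ProposalPool(draws=draws)
    # exact KDEs so the oracle comparison is at machine precision
    for name, vals in draws.items():
        h = silverman_bandwidth(vals)
        pool.kdes[name] = lambda x, vals=vals, h=h: float(kde_logpdf(vals, x, h))
    return ctx, pool


class TestMhUpdateScalar:
    def test_matches_independent_ratio_computation(self):
        """Replay the update with an identical RNG and recompute every
        factor of the generalized ratio independently."""
        from _oracles import mixture_loglik

        ctx, pool = _toy_setup()
        tp = _tp()
        params = IndividualParams(
            beta=np.array([0.2, -0.1, 0.0, 0.1]), gamma=0.55, theta=3.0, sigma1_sq=380.0
        )
        logf1 = ctx.movement_logf1(params.gamma, params.theta, params.sigma1_sq)
        ll = ctx.loglik(params.beta, logf1)
        for trial in range(100):
            rng_a = np.random.default_rng(100 + trial)
            rng_b = np.random.default_rng(100 + trial)
            name = ("gamma", "theta", "sigma1_sq")[trial % 3]
            cur = getattr(params, name)
            got, got_ll, _, accepted = mh_update_scalar(
                name, cur, ll, logf1, params, ctx, pool, tp, rng_a
            )
            # independent replay
            pool_vals = pool.draws[name]
            prop = float(pool_vals[rng_b.integers(len(pool_vals))])
            trial_p = dict(
                gamma=params.gamma, theta=params.theta, sigma1_sq=params.sigma1_sq
            )
            cur_vals = dict(trial_p)
            trial_p[name] = prop
            ll_prop = mixture_loglik(
                ctx.delta_t, ctx.delta_prev, ctx.design, params.beta,
                trial_p["gamma"], trial_p["theta"], trial_p["sigma1_sq"],
            )
            ll_cur = mixture_loglik(
                ctx.delta_t, ctx.delta_prev, ctx.design, params.beta,
                cur_vals["gamma"], cur_vals["theta"], cur_vals["sigma1_sq"],
            )
            h = silverman_bandwidth(pool_vals)

            def proc(v):
                if name == "gamma":
                    if not 0 < v < 1:
                        return -np.inf
                    return stats.norm.logpdf(
                        logit(v), tp.mu_logit_gamma, np.sqrt(tp.var_logit_gamma)
                    ) - np.log(v * (1 - v))
                if name == "sigma1_sq":
                    return stats.norm.logpdf(
                        0.5 * np.log(v), tp.mu_log_sigma1, np.sqrt(tp.var_log_sigma1)
                    ) - np.log(2 * v)
                return stats.norm.logpdf(v, tp.mu_theta, np.sqrt(tp.var_theta))

            log_ratio = (
                (ll_prop - ll_cur)
                + (proc(prop) - proc(cur))
                + (
                    np.log(np.mean(stats.norm.pdf(cur, pool_vals, h)))
                    - np.log(np.mean(stats.norm.pdf(prop, pool_vals, h)))
                )
            )
            expect_accept = np.log(rng_b.random()) < log_ratio
            assert accepted == expect_accept
            assert got == (prop if expect_accept else cur)
            if accepted:
                assert got_ll == pytest.approx(ll_prop, abs=1e-8)
            setattr(params, name, got)
            logf1 = ctx.movement_logf1(params.gamma, params.theta, params.sigma1_sq)
            ll = ctx.loglik(params.beta, logf1)

    def test_flat_likelihood_reduces_to_process_times_kde(self):
        # encamped-only context: gamma updates never touch the data
        ctx, pool = _toy_setup(seed=7)
        ctx.encamped_only = True
        tp = _tp()
        params = IndividualParams(
            beta=np.zeros(4), gamma=0.5, theta=np.pi, sigma1_sq=400.0
        )
        rng = np.random.default_rng(8)
        accepted = 0
        n = 3000
        val = params.gamma
        for _ in range(n):
            val, _, _, acc = mh_update_scalar(
                "gamma", val, 0.0, np.zeros(0), params, ctx, pool, tp, rng
            )
            params.gamma = val
            accepted += acc
        assert 0 < accepted < n  # acceptance strictly inside (0, 1)


class TestMhUpdateBeta:
    def test_data_factor_count_bookkeeping(self):
        rng = np.random.default_rng(9)
        T = 5
        positions = np.cumsum(rng.normal(0, 15, (T, 2)), axis=0)
        traj = Trajectory(
            individual_id="t5", treatment="resident",
            days=np.arange(1, T + 1), positions=positions,
        )
        m = traj.displacements().n_eligible
        assert m == T - 2  # likelihood terms run t = 3..T
        ctx = _IndividualContext(
            traj, np.eye(4)[:m], ModelConstants(), encamped_only=False
        )
        assert ctx.m == 3

    def test_matches_independent_ratio_computation(self):
        from _oracles import mixture_loglik

        ctx, pool = _toy_setup(seed=10)
        tp = _tp()
        params = IndividualParams(
            beta=np.array([0.2, -0.1, 0.0, 0.1]), gamma=0.55, theta=3.0, sigma1_sq=380.0
        )
        logf1 = ctx.movement_logf1(params.gamma, params.theta, params.sigma1_sq)
        ll = ctx.loglik(params.beta, logf1)
        rng_a = np.random.default_rng(11)
        rng_b = np.random.default_rng(11)
        new_beta, new_ll, accepted = mh_update_beta(
            params, ll, logf1, ctx, pool, tp, rng_a
        )
        # replay component-at-a-time
        beta = params.beta.copy()
        cur_ll = ll
        for l in range(4):
            vals = pool.draws[f"beta_{l}"]
            prop = float(vals[rng_b.integers(len(vals))])
            cand = beta.copy()
            cand[l] = prop
            ll_prop = mixture_loglik(
                ctx.delta_t, ctx.delta_prev, ctx.design, cand,
                params.gamma, params.theta, params.sigma1_sq,
            )
            h = silverman_bandwidth(vals)

            def cond(bvec):
                others = [i for i in range(4) if i != l]
                S_oo = tp.Sigma_beta[np.ix_(others, others)]
                S_lo = tp.Sigma_beta[l, others]
                cm = tp.mu_beta[l] + S_lo @ np.linalg.solve(
                    S_oo, bvec[others] - tp.mu_beta[others]
                )
                cv = tp.Sigma_beta[l, l] - S_lo @ np.linalg.solve(S_oo, S_lo)
                return stats.norm.logpdf(bvec[l], cm, np.sqrt(cv))

            log_ratio = (
                (ll_prop - cur_ll)
                + (cond(cand) - cond(beta))
                + (
                    np.log(np.mean(stats.norm.pdf(beta[l], vals, h)))
                    - np.log(np.mean(stats.norm.pdf(prop, vals, h)))
                )
            )
            if np.log(rng_b.random()) < log_ratio:
                beta, cur_ll = cand, ll_prop
                assert accepted[l]
            else:
                assert not accepted[l]
        assert np.allclose(new_beta, beta)
        assert new_ll == pytest.approx(cur_ll, abs=1e-8)


class TestGibbsUpdateTreatment:
    def _inds(self, n, seed=12):
        rng = np.random.default_rng(seed)
        return [
            IndividualParams(
                beta=rng.normal(0, 0.5, 4),
                gamma=float(expit(rng.normal(0.5, 0.4))),
                theta=float(np.mod(rng.normal(np.pi, 0.3), 2 * np.pi)),
                sigma1_sq=float(np.exp(rng.normal(np.log(25), 0.3)) ** 2),
            )
            for _ in range(n)
        ]

    def test_normal_normal_closed_form(self):
        """Empirical moments of the mu draws match the textbook posterior."""
        inds = self._inds(6)
        hyper = HyperPriorConfig()
        current = _tp()
        rng = np.random.default_rng(13)
        draws = np.array(
            [
                gibbs_update_treatment(inds, hyper, current, rng).mu_logit_gamma
                for _ in range(20_000)
            ]
        )
        vals = np.array([logit(p.gamma) for p in inds])
        n = len(vals)
        pv = 1.0 / (n / current.var_logit_gamma + 1.0 / hyper.var_logit_gamma_pop)
        pm = pv * (
            vals.sum() / current.var_logit_gamma
            + hyper.mu_logit_gamma_pop / hyper.var_logit_gamma_pop
        )
        assert draws.mean() == pytest.approx(pm, abs=4 * np.sqrt(pv / len(draws)))
        assert draws.var(ddof=1) == pytest.approx(pv, rel=0.05)

    def test_single_individual_near_flat_prior_centers_on_it(self):
        ind = self._inds(1, seed=14)
        hyper = HyperPriorConfig(var_logit_gamma_pop=1e4)
        current = _tp()
        current.var_logit_gamma = 1e-4  # group variance tiny -> data dominate
        rng = np.random.default_rng(15)
        draws = np.array(
            [
                gibbs_update_treatment(ind, hyper, current, rng).mu_logit_gamma
                for _ in range(10_000)
            ]
        )
        assert abs(draws.mean() - logit(ind[0].gamma)) < 0.05

    def test_sigma_beta_draws_positive_definite(self):
        inds = self._inds(5)
        hyper = HyperPriorConfig()
        rng = np.random.default_rng(16)
        current = _tp()
        for _ in range(50):
            tp = gibbs_update_treatment(inds, hyper, current, rng)
            assert np.all(np.linalg.eigvalsh(tp.Sigma_beta) > 0)
            current = tp

    def test_diagonal_covariance_model(self):
        inds = self._inds(5)
        hyper = HyperPriorConfig(beta_cov_model="diagonal")
        rng = np.random.default_rng(17)
        tp = gibbs_update_treatment(inds, hyper, _tp(), rng)
        off = tp.Sigma_beta - np.diag(np.diag(tp.Sigma_beta))
        assert np.all(off == 0)
        assert np.all(np.diag(tp.Sigma_beta) > 0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            gibbs_update_treatment([], HyperPriorConfig(), _tp(), np.random.default_rng(0))


class TestDetailedBalanceSmoke:
    """On a single-parameter reduction with a small discrete pool and a
    flat likelihood, the chain's empirical stationary frequencies must
    match the analytic invariant law (process density reweighted by the
    uniform-proposal / KDE mismatch) within Monte Carlo error."""

    def test_stationary_frequencies(self):
        support = np.array([0.3, 0.5, 0.7])
        pool_vals = np.repeat(support, 200)
        h = silverman_bandwidth(pool_vals)
        tp = _tp()

        def proc(v):
            return float(
                stats.norm.logpdf(logit(v), tp.mu_logit_gamma, np.sqrt(tp.var_logit_gamma))
                - np.log(v * (1 - v))
            )

        kde_at = {v: np.log(np.mean(stats.norm.pdf(v, pool_vals, h))) for v in support}
        # invariant law of the approximate-proposal chain
        weights = np.array([np.exp(proc(v) - kde_at[v]) for v in support])
        target = weights / weights.sum()

        rng = np.random.default_rng(18)
        cur = 0.5
        counts = {v: 0 for v in support}
        n = 60_000
        for _ in range(n):
            prop = float(pool_vals[rng.integers(len(pool_vals))])
            lr = (proc(prop) - proc(cur)) + (kde_at[cur] - kde_at[prop])
            if np.log(rng.random()) < lr:
                cur = prop
            counts[cur] += 1
        freqs = np.array([counts[v] / n for v in support])
        # generous 3-sigma-ish band accounting for autocorrelation
        assert np.all(np.abs(freqs - target) < 0.02)


class TestHierarchicalModelPlumbing:
    def _mini_fit(self, n_iter=300, seed=19):
        from movemix import StudyConfig, default_treatment_truth, simulate_study
        from movemix.landscape import design_matrix, generate_synthetic_raster
        from movemix.stage1 import Stage1Model

        raster = generate_synthetic_raster(40, 40, cell_size=3.0, seed=20)
        truth = {k: default_treatment_truth()[k] for k in ("resident", "forest_to_urban")}
        ds = simulate_study(
            StudyConfig(
                treatments=truth, n_individuals=2, length_range=(25, 30),
                raster=raster, seed=21,
            )
        )
        designs = {
            t.individual_id: design_matrix(raster, t) for t in ds.trajectories
        }
        s1 = {
            t.individual_id: Stage1Model(t, design=designs[t.individual_id]).fit(
                800, seed=22
            )
            for t in ds.trajectories
        }
        model = HierarchicalModel(ds.trajectories, s1, designs=designs)
        return model.fit(n_iter=n_iter, seed=seed), ds

    def test_burn_in_convention_and_acceptance_logging(self):
        res, _ = self._mini_fit()
        assert res.burn_in == 30  # 10% of 300
        assert res.n_iter - res.burn_in == 270
        for name, rate in res.acceptance_rates.items():
            assert 0.0 < rate < 1.0, name

    def test_missing_stage1_named(self):
        from movemix import StudyConfig, simulate_study
        from movemix.landscape import generate_synthetic_raster

        raster = generate_synthetic_raster(40, 40, cell_size=3.0, seed=23)
        ds = simulate_study(
            StudyConfig(n_individuals=1, length_range=(10, 12), raster=raster, seed=24)
        )
        with pytest.raises(ValueError, match=ds.trajectories[0].individual_id):
            HierarchicalModel(ds.trajectories, {}, raster=raster)

    def test_seed_determinism(self):
        a, _ = self._mini_fit(n_iter=100, seed=25)
        b, _ = self._mini_fit(n_iter=100, seed=25)
        assert np.array_equal(a.gamma, b.gamma)
        assert np.array_equal(
            a.treatment_mu_beta["resident"], b.treatment_mu_beta["resident"]
        )
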