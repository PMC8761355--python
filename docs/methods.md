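# Methods

## Model

The data model is a two-component mixture of isotropic bivariate normals
on daily displacement vectors. The encamped component has mean zero and
fixed standard deviation `sigma0 = 5` m per coordinate — chosen as a
typical refuge (tree-canopy) diameter plus positional error, and reported
through the convention that twice the state standard deviation is the
radius of the "95% movement kernel" (so the encamped kernel is 10 m).
`kernel_radius` implements exactly that `2*sigma` convention; note that
for an isotropic bivariate normal the 2-sigma circle actually contains
about 86.5% of the mass (1.96-sigma covers 95% per coordinate), but the
reporting convention is kept as is because it is how these kernels are
quoted in the field.

The movement component is a damped rotation of the previous
displacement: mean `gamma * M(theta) @ delta_prev` with variance
`sigma1_sq` per coordinate. `gamma -> 1` with `theta = pi/2` produces
rigid 90-degree zig-zags; `gamma -> 0` is an uncorrelated walk; `theta`
near `pi` encodes course reversals (commuting between refuges).

The mixture probability is probit-linked to the landscape:
`p_t = Phi(x' beta)` with `x` the one-hot (cell-means) indicator of the
category at the step's **starting** position `s_{t-1}`. Cell-means coding
(no intercept) was chosen so each coefficient maps directly to a
per-category movement probability, `Phi(beta_c)`, which is how results
are naturally reported.

### Likelihood indexing and day gaps

The first displacement of a trajectory is an initial condition: it is
conditioned on but never modelled (the autoregression needs a
predecessor), so likelihood terms run from the third relocation. A term
enters the likelihood only if the three relocations it involves fall on
consecutive days: a displacement spanning a multi-day gap is not a
nightly displacement, and rather than imputing we exclude. The
`DisplacementSeries` type tracks the surviving terms and the count lost
to gaps.

### Hierarchy

Individual parameters arise from group-level normals on transformed
scales: `beta_i ~ N(mu_beta_j, Sigma_beta_j)`, `logit(gamma_i)`,
`theta_i`, `log(sigma_{1,i})` each univariate normal. The internal
parameter is the variance `sigma1_sq`; the hierarchy applies to
`log(sigma_1) = 0.5 * log(sigma1_sq)`. `theta` is treated on its natural
scale in `[0, 2pi)` with a plain normal group density whose default
hyperprior (mean `pi`, variance `pi^2/4`) keeps essentially all mass on
the circle — the normal mixes better than the wrapped Cauchy here, and
with turning angles concentrated away from the 0/2pi seam the wrapping
discontinuity is immaterial.

Hyperpriors: normal priors on group means
(`mu_logit_gamma ~ N(logit(0.7), 1.5)` regularizes the movement state
away from zero autocorrelation and thereby away from label switching;
`mu_log_sigma1 ~ N(log 20, 100)` centres the movement kernel on the
40 m nightly scale typical of the study species), inverse-gamma priors
on group variances, and an inverse-Wishart prior on `Sigma_beta_j`
(default `S = I`, `nu = 6`, i.e. dimension + 2, the smallest integer df
giving a finite mean). A config switch (`beta_cov_model="diagonal"`)
replaces the inverse-Wishart with independent diagonal variances under
IG(0.01, 10) priors; the full covariance is the default because the
component-at-a-time coefficient updates explicitly use its off-diagonal
structure.

**Inverse-gamma convention.** A printed variance prior "IG(q, r)" with
pairs like (0.001, 1000) is read, by default, as Gamma(shape q, scale r)
on the *precision* — the classic diffuse variance prior (precision rate
0.001). Read instead as an inverse-gamma scale parameter, r = 1000 would
concentrate group variances near 1000 and decouple the group means from
the data, the opposite of a diffuse prior's role. Users whose convention
differs can flip `HyperPriorConfig.ig_parameterization` to
`"shape-scale"`. The stage-1 prior IG(q1=1, r1=0.1) for `sigma1_sq` is
kept in the literal shape-scale convention (density
`x^-(q+1) exp(-r/x)`, a heavy-tailed `x^-2` prior); at that stage the
likelihood dominates and the choice is immaterial.

## Stage 1: per-individual sampler

A systematic scan per iteration: `(z, v) -> beta -> gamma -> theta ->
sigma1_sq`.

* Latent states `z_t` are Bernoulli with full-conditional probability
  `p f1 / (p f1 + (1-p) f0)`; the probit auxiliaries `v_t ~ N(x'beta, 1)`
  are truncated to the sign dictated by `z_t` (inverse-CDF sampling,
  stable for the moderate linear predictors a proper N(0,1) coefficient
  prior produces).
* `beta` is conjugate multivariate normal given `v` (Albert–Chib).
* `gamma` and `theta` use their priors — Beta(1,1) and wrapped
  Cauchy(0, 0.1), near-uniform — as independence proposals, so the
  acceptance probability is a pure likelihood ratio over movement-state
  steps. Wrapped-Cauchy draws use the inverse CDF
  `mu + 2 atan(((1-rho)/(1+rho)) tan(pi(u-1/2)))`.
* `sigma1_sq` is conjugate inverse-gamma: shape `q1 + m`, scale
  `r1 + SSR/2`, with `m` movement steps contributing two residual
  components each.

Initialization is cheap moment matching: `z` set by a 10 m step-length
threshold, `beta = 0`, `gamma = 0.5`, `theta = pi`, `sigma1_sq` the
sample variance of long-step components floored at `2 sigma0^2`.

**Encamped-only rule.** If no displacement exceeds 10 m the two states
are not separable (the movement variance would collapse below the
encamped variance); all steps are pinned to the encamped state, `beta`
continues its conjugate update against all-encamped states, and
`gamma`, `theta`, `sigma1_sq` sample their priors. We implement only
the stated 10 m rule, with ties (`== 10 m`) counted encamped.

All stage-1 draws are stored unthinned with no burn-in removal; the
second stage consumes complete pools (a `stage1_burn_in_frac` knob
exists, default 0).

The scan's joint correctness is tested with a Geweke-style
successive-conditional simulation (alternating data simulation and
sampler transitions must preserve prior moments), alongside closed-form
oracles for each conjugate update.

## Stage 2: proposal-recursive hierarchical sampler

Each iteration updates every individual's `gamma`, `theta`, `sigma1_sq`
(one at a time) and then the four `beta` coefficients (one at a time),
followed by conjugate Gibbs updates of each group's parameters.

The scalar acceptance ratio is

```
  [data | proposal]    [proposal | group]    kde(current)
  ----------------- x ------------------- x --------------
  [data | current ]    [current  | group]    kde(proposal)
```

with the proposal drawn uniformly from that parameter's stage-1 pool.
The data term is the state-integrated mixture likelihood (no latent
states are carried in stage 2). The group ("process") term is evaluated
on the natural scale with the change-of-variables Jacobian: logit for
`gamma` (`1/(g(1-g))`), log-standard-deviation for `sigma1_sq`
(`1/(2 s2)`), none for `theta`. Out-of-support proposals get a process
density of zero (rejected) rather than an exception. `beta` components
use the univariate normal conditional given the other components'
current-iteration values, per the standard multivariate-normal
partition.

For encamped-only individuals the stage-2 data likelihood is flat in
`(gamma, theta, sigma1_sq)` — their updates reduce to process-density
times KDE corrections, so their posteriors follow the group-level
process model — while `beta` still sees the probability of never
moving.

**KDE proposal density.** Each scalar pool gets a Gaussian KDE with the
normal-reference (Silverman) bandwidth
`0.9 min(sd, IQR/1.34) n^{-1/5}`, floored at `1e-6` of the pool range;
an all-identical pool is an error. The sampler evaluates the KDE through
a binned cache: the pool is histogrammed onto a 4096-point grid,
convolved with the Gaussian kernel, and log-density queries interpolate
linearly — the standard binned KDE used by kernel-density software,
making unthinned 10^5-draw pools affordable. The exact mixture form
(`kde_logpdf`) is retained and tested against the cache; cache error is
orders of magnitude below the sampler's Monte Carlo noise.

Pools are used unthinned: the generalized acceptance ratio is designed
for autocorrelated pools and no independence correction is applied.

Treatment-level updates are fully conjugate: normal–normal for the four
means (given current variances), inverse-gamma for the three scalar
variances (given the new means), inverse-Wishart
(`df = nu + n_j`, scale `S nu + sum of outer products`) for
`Sigma_beta_j`. Individuals are initialized at their stage-1 posterior
means and groups at the sample moments of those means (variances floored
at 0.1 to avoid a degenerate first scan). The first 10% of stage-2
iterations are discarded as burn-in by every accessor and summary;
per-parameter acceptance rates are logged on the results object.

The two-stage machinery is validated end to end against an independently
coded single-stage random-walk sampler for the same hierarchy (shared
nothing but the model definition): posterior means of group-level
parameters agree within combined Monte Carlo error on a small study.

## Derived quantities and hypothesis testing

Group means on natural scales are computed per MCMC iteration by Monte
Carlo integration: `n_mc` pseudo-individuals (default 1,000, exposed in
config) are drawn from the group's distributions and their inverse
transforms averaged — `mu_gamma` (inverse logit), `mu_sigma1` (exp,
metres), and `mu_p` per landscape category (`Phi` of coefficient draws
from `N(mu_beta, Sigma_beta)`, so individual heterogeneity in
coefficients is integrated over; a plug-in `Phi(mu_beta)` option
exists). Pairwise group comparisons report the posterior mean
difference, an equal-tailed 95% interval, and the posterior probability
that one group exceeds the other (fraction of iterations, ties counted
half — ties have measure zero for continuous chains). Individual
heterogeneity within a group is the per-iteration sample variance
(n−1 denominator) across that group's individual-level values.

Convergence checking replaces visual trace inspection with split-chain
rank-normalized R-hat (flagging > 1.1) and bulk effective sample size
(capped at the draw count), via ArviZ; trace-plot panels are still
written for manual review.

## Synthetic data generator

The generator is the exact generative counterpart of the fitted model,
emulating the motivating study's conditions: three treatment groups
(resident, forest-to-urban, urban-to-urban), 28 individuals per group by
default (the study had 29/32/23), trajectory lengths uniform on 5–77
daily relocations, encamped scale 5 m, group-mean movement scales of
23/31/34 m, turning-angle means at `pi`, movement probabilities per
landscape feature in the 0.25–0.5 band, and a 1.5-logit-unit separation
between the resident and forest-to-urban groups' mean autocorrelation —
a built-in positive for ordered-difference hypothesis tests. Group-level
variances are moderate (0.09–0.25 on transformed scales): individuals
differ visibly but less than groups do.

The landscape generator partitions a grid into nearest-seed patches with
category quotas proportional to requested cover fractions — contiguous
blocky mosaics, as in classified urban imagery, rather than
cell-by-cell noise. The default synthetic landscape is 2 km x 2 km at
10 m resolution: coarse relative to the 0.7 m classified imagery the
model was built for (cell size is configurable), but large enough that a
movement-state walk essentially never reaches the boundary. Where it
does, displacements reflect at the edge so every position keeps
covariate support — a deliberate deviation from the field reality that
animals can leave a study site, needed because a simulator must keep its
covariates defined. The first displacement of each trajectory is drawn
from the encamped kernel (the modal state) as its initial condition.

What the generator does **not** emulate: positional/triangulation error,
capture and tagging processes, seasonal effects, missing days (days are
consecutive by construction; the likelihood's gap handling is tested
separately through constructed tables), and fine-grained (sub-10 m)
landscape texture. Passing recovery tests therefore demonstrate
correctness of the inference machinery under the model, not robustness
to these real-data complications.

## Problem sizes and numerical choices

Default iteration counts mirror a full-scale analysis (100,000 stage-1
iterations per individual, 50,000 stage-2, 10% stage-2 burn-in). The
test suite and recovery studies run scaled-down versions chosen to keep
the whole suite in the minutes range while leaving comfortable
statistical margins: one individual at T = 300 with 10,000 stage-1
iterations for individual-level recovery; 3 groups x 8 individuals x 80
relocations with 10,000/5,000 iterations for hierarchical recovery
(95% CI coverage of the 21 group-level location parameters and detection
of the built-in autocorrelation difference); 2 groups x 2 individuals x
30 relocations for the single-stage cross-check.

Numerical details worth knowing: probit probabilities use `ndtr` /
`ndtri` (no overflow for the moderate linear predictors the N(0,1)
coefficient scale implies); mixture log-likelihoods combine components
with `logaddexp`; truncated normals are inverse-CDF sampled with CDF
arguments clipped to `[1e-16, 1-1e-16]`; inverse-gamma draws are gamma
reciprocals; per-individual RNG streams derive from the master seed by
SHA-256 of `"{seed}:{label}"`, so parallel or reordered stage-1
execution cannot change results. Draw tables round-trip CSV at full
float precision (`float_precision="round_trip"` on read, shortest-repr
on write), which the byte-identity determinism tests rely on.

## Known limitations

* Positional error is not modelled; relocations are treated as exact.
* The wrapped-vs-linear treatment of `theta` assumes turning angles stay
  away from the 0/2pi seam; pathological individuals whose posterior
  straddles the seam would mix poorly.
* The binned KDE cache trades a ~1e-3 log-density approximation for
  speed; with very small pools (< ~100 draws) the exact mixture should
  be preferred (pools that small do not arise at default settings).
* Acceptance rates of recursive updates depend on how much the
  hierarchy shrinks individuals away from their stage-1 posteriors;
  severely shrunken individuals (tiny trajectories in tight groups) can
  see low acceptance, visible in the logged rates.
* GeoTIFF rasters are not read; landscape import/export is ESRI ASCII
  grid with integer category codes.
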