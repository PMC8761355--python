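# movemix

Bayesian hierarchical two-state movement models for daily animal
relocation data, fit by two-stage proposal-recursive MCMC.

`movemix` is aimed at movement ecologists analysing telemetry studies in
which animals alternate between an **encamped** state (short, directionless
steps around a refuge) and a **movement** state (long, directionally
autocorrelated steps), and in which the propensity to move depends on the
habitat the animal currently occupies. The motivating setting is an
experimental translocation study of an invasive nocturnal snake in an
urban landscape mosaic, but nothing in the package is specific to that
system: any study with daily fixes, a categorical habitat raster and a
grouped (treatment / population / site) design fits.

## The model

Daily relocations $s_t$ are differenced into displacements
$\delta_t = s_t - s_{t-1}$. For each individual $i$ in group $j$, for
$t = 3, \dots, T_i$:

$$
\delta_{it} \sim
\begin{cases}
\mathrm{N}\!\left(\gamma_i \, M(\theta_i)\,\delta_{it-1},\; \sigma^2_{1,i} I\right) & \text{with probability } p_{it}\\[2pt]
\mathrm{N}\!\left(0,\; \sigma^2_0 I\right) & \text{with probability } 1 - p_{it}
\end{cases}
\qquad
p_{it} = \Phi\!\left(x_{it-1}' \beta_i\right)
$$

where $M(\theta)$ is the rotation ("propagation") matrix that turns the
previous displacement by $\theta_i$ radians, $\gamma_i \in (0,1)$ damps
adherence to it, $\sigma^2_{1,i}$ is the individual movement-state
variance, $\sigma_0 = 5$ m is a fixed encamped scale (a "95% movement
kernel" of $2\sigma_0 = 10$ m), and $x_{it-1}$ one-hot encodes the
landscape category (tree, pavement, grass, building) at the step's
starting position. Individual parameters arise from group-level normal
distributions on transformed scales ($\beta_i$, $\mathrm{logit}\,\gamma_i$,
$\theta_i$, $\log \sigma_{1,i}$), with conjugate hyperpriors
(normal means, inverse-gamma variances, inverse-Wishart coefficient
covariance).

Fitting is **proposal-recursive**: each individual is first fit alone
with support-matching temporary priors (probit data augmentation gives
conjugate $\beta$ and $\sigma^2_1$ updates; prior-as-proposal MH handles
$\gamma$ and $\theta$ — no tuning anywhere). The second stage then fits
the full hierarchy by recycling each parameter's first-stage draws as
Metropolis–Hastings proposals, with a kernel-density estimate of the
pool standing in for the proposal density and change-of-variables
corrections reconciling the two stages' parameterizations. Individuals
whose every step is $\le$ 10 m are pinned to the encamped state for
identifiability. Group comparisons are made through posterior
distributions of pairwise differences of back-transformed group means,
and individual heterogeneity via the per-iteration sample variance of
individual-level estimates.

## Worked example

Simulate a small three-group study with known truth, fit both stages and
test a group difference (a full-scale analysis would use the default
100,000 / 50,000 iterations; this runs in about two minutes):

```python
import movemix as mm
from movemix.landscape import design_matrix, generate_synthetic_raster
from movemix.stage1 import Stage1Model
from movemix.stage2 import HierarchicalModel
from movemix.summaries import back_transform_results, difference_summary

raster = generate_synthetic_raster(150, 150, cell_size=10.0, seed=7)
study = mm.StudyConfig(n_individuals=6, length_range=(40, 77), raster=raster, seed=7)
dataset = mm.simulate_study(study)

designs = {t.individual_id: design_matrix(raster, t) for t in dataset.trajectories}
stage1 = {
    t.individual_id: Stage1Model(t, design=designs[t.individual_id]).fit(5_000, seed=1)
    for t in dataset.trajectories
}
results = HierarchicalModel(dataset.trajectories, stage1, designs=designs).fit(
    n_iter=3_000, seed=2
)

derived = back_transform_results(results, n_mc=500, seed=3)
for g in results.groups:
    print(g, "mu_gamma=%.2f mu_sigma1=%.1f m mu_p_pavement=%.2f" % (
        derived[g]["mu_gamma"].mean(),
        derived[g]["mu_sigma1"].mean(),
        derived[g]["mu_p_pavement"].mean(),
    ))
ds = difference_summary(
    derived["forest_to_urban"]["mu_gamma"].to_numpy(),
    derived["resident"]["mu_gamma"].to_numpy(),
)
print("Delta mu_gamma (forest_to_urban - resident): %.3f  [%.3f, %.3f]  P=%.2f"
      % (ds.mean_difference, ds.ci_lower, ds.ci_upper, ds.probability_greater))
```

Output:

```
forest_to_urban mu_gamma=0.75 mu_sigma1=41.9 m mu_p_pavement=0.56
resident mu_gamma=0.60 mu_sigma1=20.2 m mu_p_pavement=0.51
urban_to_urban mu_gamma=0.64 mu_sigma1=32.8 m mu_p_pavement=0.38
Delta mu_gamma (forest_to_urban - resident): 0.150  [-0.148, 0.415]  P=0.82
```

`mu_gamma` is the group-mean directional autocorrelation, `mu_sigma1`
the group-mean movement-state step scale in metres (double it for the
95% movement kernel), and `mu_p_pavement` the group-mean nightly
movement probability when starting from pavement — all Monte Carlo
averages over each group's individual-level distributions, per MCMC
iteration. The last line is a hypothesis test: the forest-to-urban group's
mean autocorrelation exceeds the residents' by 0.15 with posterior
probability 0.82 (this toy study is deliberately small; the generating
truth does separate the groups).

The same pipeline is available from the shell:

```bash
movemix all --config config.yaml          # simulate -> stage1 -> stage2 -> summarize
```

which writes trajectory/raster/truth files, per-individual and
hierarchical draw tables, derived-quantity summaries, pairwise-difference
tables with posterior probabilities, heterogeneity summaries, and
R-hat/ESS diagnostics with trace plots.

## Layout

| module | contents |
| --- | --- |
| `movemix.model` | domain types and probability kernels of the two-state model |
| `movemix.landscape` | categorical rasters, synthetic landscape generator, design rows |
| `movemix.simulate` | generative model: parameter draws, trajectories, whole studies |
| `movemix.stage1` | per-individual sampler (`Stage1Model` / `Stage1Results`) |
| `movemix.stage2` | recursive hierarchical sampler (`HierarchicalModel` / `HierarchicalResults`) |
| `movemix.summaries` | back-transformed group means, hypothesis tests, diagnostics |
| `movemix.io` | CSV/ASCII-grid/YAML formats, seed derivation |
| `movemix.cli` | `movemix` command-line pipeline |

See `docs/methods.md` for the modeling and numerical details.
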