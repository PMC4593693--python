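# assocnet

Edge-weight inference with uncertainty for animal social networks.

Field studies of animal sociality typically record, for each pair of
individuals (dyad), a sequence of binary observations: together (1) or apart
(0) in each sampling period, or co-membership in observed groups
(gambit-of-the-group data). The quantity of interest is each dyad's
**association rate** θ — the probability the pair is together in a sampling
unit — which defines the weighted social network. With the small samples
typical of field data, a point estimate of θ is not enough: the uncertainty
around every edge, and its propagation into node-level network metrics,
determines whether conclusions about social structure are trustworthy.

`assocnet` is for behavioural ecologists and network scientists who want
that uncertainty quantified. It provides:

- **Empirical-Bayes edge inference.** Each edge weight gets a beta prior
  Beta(a, b) shared across dyads, updated by conjugacy with the dyad's
  counts (d co-occurrences out of s sampled units):

  P(θ | d, s) ∝ θ^(d+a−1) (1−θ)^((s−d)+b−1),   i.e. θ | d, s ~ Beta(a+d, b+s−d).

  The prior parameters are fitted from all observed data by type-II maximum
  likelihood, maximizing the marginal beta-binomial log likelihood
  Σ [ln B(a+d, b+s−d) − ln B(a, b)]. Point estimate: posterior mode.
  Uncertainty: equal-tailed 95% credible interval. Replicate networks drawn
  from the posteriors propagate uncertainty to weighted degree, eigenvector
  centrality and betweenness.
- **Frequentist comparators.** The simple ratio index SRI = d/s with
  percentile bootstrap intervals over resampled sampling units (b-SRI), and
  exact Clopper–Pearson binomial intervals.
- **A ground-truth simulator** (Poisson-distributed gregariousness, optional
  clique structure, Bernoulli sampling of each dyad at its true weight) and
  an **evaluation framework** measuring absolute error, rank accuracy and
  interval calibration (false-positive/false-negative rates) of all methods.
- **Reliability curves** for empirical data: re-estimate the network from
  growing subsets of the observations and check whether edge estimates and
  mean weighted degree have stabilized by the time all data are used.

## Worked example

```python
import numpy as np
from assocnet import (
    GeneratorConfig, generate_true_network, sample_observations,
    counts_from_periods, fit_empirical_prior, posterior_update,
    credible_interval, interval_coverage, mean_absolute_error,
)

net = generate_true_network(GeneratorConfig(n_nodes=15, cliques=True, seed=1))
obs = sample_observations(net, n_periods=20, seed=2)
counts = counts_from_periods(obs)

prior = fit_empirical_prior(counts)
print(f"fitted prior: a={prior.a:.3f}, b={prior.b:.3f}")

est = credible_interval(posterior_update(counts, prior), level=0.95)
print(f"mean |error| vs truth: {mean_absolute_error(est.point, net.weights):.4f}")
fp, fn = interval_coverage(est, net.weights)
print(f"false positives: {fp:.3%}, false negatives: {fn:.3%}")
```

Output:

```
fitted prior: a=0.446, b=4.340
mean |error| vs truth: 0.0360
false positives: 0.952%, false negatives: 0.000%
```

The fitted prior (a < 1, b ≈ 4) says most dyads associate rarely — exactly
what the clique-structured generator produces. After 20 sampling periods the
posterior-mode network is within 0.036 of the truth on average, and of the
105 true edge weights, about 1% fall below their 95% credible interval and
none above it.

The same analysis runs from the shell:

```bash
assocnet simulate --n-nodes 15 --n-periods 20 --seed 1 --out-dir sim/
assocnet estimate --input sim/periods.csv --method bayes --out-dir est/
assocnet reliability --input sim/periods.csv --method bayes --grid-step 5 --out-dir rel/
```

A single observation of two individuals together gives SRI = 1 with a
bootstrap interval of width zero — the bootstrap's known degenerate limit —
while the Bayesian posterior Beta(a+1, b) correctly reports that almost any
association rate is still plausible. That contrast is the package's reason
to exist.

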