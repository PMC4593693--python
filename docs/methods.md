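# Methods

## Estimand and data model

The estimand is the per-dyad association rate θ ∈ (0, 1): the probability
that an unordered pair of individuals is recorded together in one sampling
unit. Observations of a dyad are modelled as independent Bernoulli(θ) draws,
so the sufficient statistics are the co-occurrence count d and the sampling
count s (units in which at least one member of the dyad was observed). For
complete sampling-period data s equals the number of periods for every
dyad; for group-by-individual (GBI) data, d counts groups containing both
individuals and s counts groups containing either. Dyads with s = 0 carry
no likelihood; they are reported with an explicit "unsampled" mask (SRI
convention: weight 0 plus mask) so that "never seen together" and "never
sampled" stay distinguishable downstream.

Independence across dyads and across sampling units is assumed throughout.
Real association data violate both (shared group membership induces
dependence between dyads within a period; sociality varies in time); the
bootstrap comparator partially respects within-period dependence because it
resamples whole sampling units.

## Bayesian edge model

Each edge has prior θ ~ Beta(a, b) with (a, b) shared across all dyads of a
network, and posterior Beta(a + d, b + s − d) by conjugacy.

**Prior fitting (empirical Bayes / type-II ML).** (a, b) maximize the
summed log marginal likelihood of all sampled dyads,
Σ [ln B(a+d, b+s−d) − ln B(a, b)], with the binomial coefficients dropped
as constants in (a, b). The optimizer is a Nelder–Mead simplex in
(ln a, ln b) from a method-of-moments start, box-bounded to
a, b ∈ [1e-3, 1e3], with objective tolerance 1e-8. The log parameterization
keeps positivity without constraints and makes the geometry near the
optimum benign. Data with no overdispersion (all dyads the same frequency)
or fully degenerate data (all d = 0 or all d = s) push the maximum to a
bound; the fit is clamped there and a RuntimeWarning is emitted. Fitting
the prior from the data being analysed is not strictly Bayesian; a hold-out
variant (`split_periods`: fit the prior on an initial fraction of the
periods, update only with the remainder) is provided but off by default,
since with field-scale sample sizes the lost data usually costs more than
the double use of data.

**Point estimate.** The posterior mode: (α−1)/(α+β−2) for an interior peak
(α, β > 1); 0 when α ≤ 1 < β; 1 when β ≤ 1 < α; and the posterior mean as a
documented fallback when both α ≤ 1 and β ≤ 1 (bathtub density with no
single peak — in practice only the bare prior on unsampled dyads), with a
warning.

**Interval.** Equal-tailed: the (1−level)/2 and (1+level)/2 beta quantiles,
default level 0.95. Equal-tailed rather than highest-posterior-density
because it is deterministic, cheap, invariant to the quantile solver, and
conservative for skewed betas; the choice is recorded in output metadata.
For well-sampled dyads the two coincide to practical precision.

**Uncertainty propagation.** Replicate networks are drawn by sampling every
dyad independently from its posterior and symmetrizing; node metrics
evaluated over the ensemble give percentile intervals. Independent per-dyad
draws ignore posterior dependence between edges — the main caveat for
metrics, like betweenness, that are sensitive to joint structure.

## Frequentist comparators

**b-SRI.** 100 bootstrap replicates (configurable) resample the S sampling
units uniformly with replacement to size S and recompute the full SRI
network; per-dyad intervals are percentile quantiles over replicates with
linear interpolation between order statistics (the rule matters at the
margin with 100 replicates and is recorded in metadata). Whole units are
resampled, never individual dyad records. The point estimate is the SRI of
the original data, exactly. With S = 1 every replicate equals the
observation and all intervals have width zero.

**Clopper–Pearson.** The exact binomial interval per dyad:
lower = BetaQuantile(0.025; d, s−d+1) (0 at d=0),
upper = BetaQuantile(0.975; d+1, s−d) (1 at d=s). Known to be conservative,
increasingly so at small s.

## Node metrics

Weighted degree (strength) is the row sum of the weight matrix. Eigenvector
centrality is the leading eigenvector (symmetric eigendecomposition),
rescaled to maximum 1; on disconnected networks it is computed on the
largest component with zeros elsewhere and a warning — posterior-draw
networks are almost surely connected, bootstrap ones need not be.
Betweenness uses shortest paths on edge lengths 1/weight (strong
associations are short), with zero-weight edges absent, tie multiplicities
split fractionally, and raw unordered-pair counts (no normalization — only
rankings are ever compared, so a constant factor cancels).

## Ground-truth simulator

The generator emulates the structure of passerine flock association data:
per-node gregariousness scores Poisson(λ=3) plus an offset 0.05 (so no node
is a true isolate), normalized by the maximum score into a probability;
optional allocation of nodes to 5 cliques independently with equal
probability (empty cliques permitted); edge weight = product of the two
gregariousness probabilities times 0.9 (same clique), 0.1 (different
cliques), or 0.5 (no clique structure). Sampling draws each dyad
independently per period as Bernoulli(true weight). Draw order is fixed
(node scores, then clique labels; dyads in row-major upper-triangle order,
periods within dyad) so a seed fully determines the output.

What the simulator does **not** emulate: observation error and missed
identifications, unequal detectability between individuals, temporal
autocorrelation of associations, and dependence between dyads within a
period (each dyad is sampled independently even within one "period").
Passing tests therefore demonstrate correctness of the inference machinery
and calibration under the stated generative model, not robustness to these
real-data features.

## Evaluation framework

Error = mean |estimate − truth| over dyads; relative accuracy = Spearman
rank correlation (average ranks on ties; NaN with a warning for constant
inputs); interval reliability = false-positive rate (truth strictly below
the interval) and false-negative rate (truth strictly above), each nominally
2.5% for calibrated 95% intervals. Edge-level rates are pooled over the
dyads of a replicate network, then averaged or quantiled across replicates;
study summaries report the median and the 2.5/97.5 percentiles across the
(default 100) replicate networks. Within a replicate, the maximum sampling
effort is simulated once and smaller efforts use prefixes — valid because
periods are i.i.d., and it keeps the full factorial study fast enough to
re-run casually (about 10 s for 100 networks × 3 efforts × 3 methods on one
core).

**Calibration behaviour worth knowing.** Under clique-structured truth the
distribution of true edge weights is bimodal, and a single fitted beta
prior cannot match both modes. The practical consequence, measured by the
study runner: false-negative rates sit near the nominal 2.5% across
sampling efforts, while false-positive rates run low (≈1–1.7%) — for the
many near-zero edges the fitted small-a prior puts the lower credible bound
astronomically close to zero, so true weights almost never fall below it.
With unstructured (no-clique) truth the imbalance reverses (FP ≈ 3–6%).
Both regimes still beat the bootstrap comparator by an order of magnitude
on false negatives at sparse sampling. A hierarchical or
mixture/covariate-informed prior would be the principled fix; it is out of
scope here.

## Reliability (subsampling) curves

For observed data without ground truth, `subsample_stability` re-estimates
edges and mean weighted degree from growing subsets of the sampling units:
cumulative prefixes in observation order by default (mirroring how data
accumulate in the field), or seeded random subsets without replacement.
Grid spacing defaults to 20 units, with the final point always at the full
dataset. The stabilization diagnostic — final two grid points' mean-degree
intervals overlap and the point estimates differ by <5% relative — is a
labelled reporting heuristic, not a hypothesis test.

## Numerical and design choices

- Quantiles: beta quantiles via scipy's incomplete-beta inversion;
  empirical quantiles via linear interpolation.
- `metric_uncertainty` takes an optional `point_network`; when omitted the
  elementwise mean of the replicates is used for the point metric.
- Dyad order, 0-based internal indexing, string IDs in files; all writers
  emit a JSON run-metadata sidecar (seed, method, level, quantile rule,
  versions).
- Problem sizes in the test suite and the acceptance script (50–100
  replicate networks of 15 nodes, sampling efforts 10–50, 10⁴-dyad
  coverage simulations) were chosen as the smallest giving Monte-Carlo
  error comfortably below the effect sizes under test.

## Known limitations

- No observation-error or detectability model: a single observed
  co-occurrence forces the posterior probability of θ = 0 to zero.
- Per-dyad independence in both fitting and posterior draws (see above).
- Empirical-Bayes coverage is exactly nominal only when the prior family
  matches the true edge-weight distribution; see the calibration note.
- The generator's networks are fully connected with poorly differentiated
  relationships, which makes betweenness an unstable target; rank
  correlations for betweenness are accordingly low for every method.
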