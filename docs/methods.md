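# Methods

## The model

`mrfprio` treats disease-gene identification as a Bayesian labelling
problem: binary labels `x_i ∈ {0, 1}` over a fixed gene universe, one
disease class at a time, with the known genes of that class clamped to
1. The joint distribution over labels is an Ising-type Markov random
field whose neighbourhood system is the union of `K` undirected
networks:

    P(x | θ) = Z(θ)^{-1} exp( Σ_i α_i x_i + Σ_k [ β_k N10_k + γ_k N11_k + κ N00_k ] )

with `κ ≡ 1` (one of the three edge weights is redundant — multiplying
all edge terms of a network by a constant shifts the energy uniformly).
Only first- and second-order clique potentials are modelled; the
assumptions are therefore (i) gene-level prior effects enter through a
per-gene field, (ii) network evidence enters only through pairwise edge
category counts, and (iii) networks contribute independently given the
labels. Edges are unweighted: input edge weights are ignored, and
duplicate edges and self-loops are removed on reading.

The single-site conditional is `P(x_i = 1 | x_−i) = σ(T(i))` with local
field

    T(i) = α_i + Σ_k [ (β_k − 1) M0_k(i) + (γ_k − β_k) M1_k(i) ].

`T(i)` is exactly the energy difference between the two labellings of
gene *i*; a property test checks this identity against two independent
energy evaluations to 1e−10, and the sampler's conditionals are checked
against full enumeration of the Gibbs measure on graphs of up to 15
free genes.

## Parameter estimation

`θ` is estimated by pseudo-likelihood: a binary logistic regression of
the current labels on the design `(M0_1, M1_1, …, M0_K, M1_K)`, one row
per gene. The fitted coefficients `(α̂, b_1, c_1, …)` map to the edge
weights as `β_k = b_k + 1`, `γ_k = c_k + β_k`.

Numerical choices:

* The fit is a Newton/IRLS iteration with a ridge penalty `λ = 1e−6`
  on the slope coefficients (the intercept is unpenalized), step
  halving on objective increase, gradient tolerance 1e−10 and at most
  100 iterations. On well-posed designs it agrees with an unpenalized
  maximum-likelihood fit to better than 1e−6. Under complete
  separation — routine in early sweeps, when few genes are labelled 1 —
  the iteration stops at the budget and returns large-but-finite
  coefficients; an all-zero column (e.g. no labelled neighbour
  anywhere) simply keeps its coefficient at 0.
* A design in which *all* labels are equal is not identifiable and
  raises an estimation error naming the offending sweep rather than
  returning an arbitrary fit.

Two conventions are available for the field term, selected by
`alpha_mode`:

* `global` (default): the regression intercept `α̂` is used for every
  gene in `T(i)`; the per-gene complex priors act only through the
  initialization. This matches a three-coefficient-per-network
  regression (constant, `M0`, `M1`) and makes the fitted constant
  directly interpretable.
* `offset`: the per-gene prior log-odds `logit(π̂_i)` enter the
  regression as a fixed offset, a free constant is still fitted, and
  `T(i) = logit(π̂_i) + α̂ + Σ_k(…)`. This honours a fully gene-specific
  field at the cost of trusting the prior scale.

The mode is recorded in every result object.

## Sampling schedule

One sweep updates all unclamped genes sequentially (by gene index by
default; a shuffled-per-sweep order is available for sensitivity
checks), each update using the labels as they are at that moment. The
drivers are:

* **imrf1** — per sweep: re-estimate `θ` from the full current
  labelling, then sweep once. Re-estimation happens every sweep, so
  parameters and labels relax together. After `burn_in` sweeps
  (default 100) every `thin`-th sweep (default 10) of the remaining
  `total − burn_in` (default 900) is recorded — 90 snapshots under the
  defaults. The posterior is the mean of the recorded per-sweep
  conditional probabilities `σ(T(i))` rather than of the binary labels:
  the conditional is the quantity the chain-variation diagnostic `Q(t)
  = Σ_i (P_i(t) − P_i(t−1))²` is defined on, and averaging it
  (Rao-Blackwellization) has strictly smaller Monte-Carlo variance.
  `Q(t)` is reported as a diagnostic only; the sweep budget is fixed
  rather than adaptive, so runs are reproducible and comparable.
* **imrf2** — after the imrf1 pass, `θ` is frozen at its snapshot
  average, unknown labels are re-initialized by Bernoulli draws from
  the lag-period posterior, and `prediction_steps` (default 100)
  further sweeps are run without re-estimation; their averaged
  conditionals are the final posterior. Freezing removes the residual
  parameter noise that re-estimation injects into every sweep.
* **deng** — the one-shot baseline: `θ` is estimated once, from known
  genes only (class genes as 1-rows, known genes of other classes as
  0-rows, neighbour counts restricted to known-labelled genes), then
  held fixed. It requires at least `2K + 2` known-labelled rows. With
  dozens of known genes against thousands of candidates this estimate
  ignores almost the entire network and routinely produces wildly
  overconfident posteriors — which is precisely the behaviour the
  interleaved modes correct, and which the evaluation reproduces.

Unknown labels are initialized by Bernoulli draws from the prior
probabilities — the only principled source of an initial configuration —
and the fixed-θ helpers in `mrfprio.synthetic` follow the same policy.
Known genes of *other* disease classes are deliberately left unclamped
during a run: they double as leave-one-out negative controls, and
clamping them to 0 would leak the evaluation design into the model.
All randomness flows from a single integer seed through one NumPy
generator; identical seed, inputs and configuration give byte-identical
results.

## Priors, decision scores, validation

Complex-derived priors: for each complex containing the gene and
containing at least one known disease gene of any class, the candidate
value is `A/B` (class genes over all known disease genes in the
complex); the prior is the maximum candidate. Genes in no such complex
get the genome-wide rate `C/D`. Priors are clipped to
`[1e−6, 1 − 1e−6]` so their log-odds stay finite when `A = 0` or
`A = B`; complexes with `B = 0` contribute no candidate because `A/B`
is undefined there.

Posteriors are converted to decision scores by fractional rank over the
unclamped genes (average rank for ties), mapping onto `(0, 1]`. The
score is invariant to monotone transforms of the posterior and makes a
single threshold meaningful across disease classes with very different
numbers of known genes.

Leave-one-out validation masks each known class gene that has at least
one interaction partner, rebuilds its prior *with the gene removed from
every disease-gene set* (no leakage), re-runs the chosen mode and
records the held-out gene's decision score as a positive. Known genes
of other classes are scored as negatives from the base run — they are
never clamped, so that run already treats them as unknowns. ROC curves
group tied scores at one threshold; the trapezoidal AUC equals the
normalized Mann–Whitney U statistic, an identity the tests check to
1e−12.

## Synthetic data

The generator exists so that every stage is testable without database
downloads. Two scenario families:

* **Model-faithful** (`make_benchmark`): `K` Erdős–Rényi networks, a
  ground truth drawn from the MRF itself by long fixed-θ Gibbs runs, a
  fraction of the 1-genes revealed as known (default 0.5), negative
  controls drawn from the true 0-genes, and complexes sampled with
  1-genes over-weighted 3:1 so the priors carry signal. Default scale:
  2000 genes, `K = 2`, edge probabilities (0.004, 0.006), 20 complexes
  of size 8, truth sampled by 500 sweeps. Defaults for the generating
  parameters are `θ = (−2, 1.5, 3)`.
  A caveat that follows from Ising phase behaviour: with `β > κ = 1`
  every neighbour, whatever its label, raises the propensity to be
  labelled 1, and once the mean degree exceeds roughly
  `−2α/( β − 1 )` the model is supercritical — the sampled truth
  collapses to an almost-all-ones configuration, leaving no negative
  class and a non-identifiable estimation design. The default
  parameters above sit in that regime at the default density (mean
  degree ≈ 20), so scenarios built from them are flagged `degenerate`
  and are useful for studying the collapse itself, not for ranking
  experiments. Subcritical settings (e.g. `β ≤ 1`, stronger negative
  `α`) produce sparse, clustered positive classes but only a handful
  of positives at this scale.
* **Planted module** (`make_planted_benchmark`): a deliberately
  misspecified variant — `module_size` genes (default 60) are labelled
  1 and wired densely (within-module edge probability 0.15 per
  network) on top of the background graphs. This emulates the
  guilt-by-association structure of real disease classes (a sparse
  positive class whose members interact) without assuming the fitted
  model generated the data, and is the scenario used in the worked
  example and the acceptance script.

What the generator does **not** emulate: scale-free degree
distributions, correlated edges across networks, noisy or biased
complex annotations, and class overlap. Passing benchmarks therefore
demonstrates correctness of the machinery and the qualitative
superiority of interleaved estimation over the one-shot baseline — not
performance on real curated databases.

## Problem sizes

The test suite and the acceptance script are sized for a single CPU:
exact-oracle comparisons enumerate graphs of ≤ 12–15 genes and run
chains of 2×10⁵ sweeps; estimator checks use 2000-gene designs;
benchmark runs use 2000 genes, two networks and the default 1000+100
sweep schedule. The acceptance script completes in under a minute; its
enumeration check draws couplings near the neutral value 1, where
single-site Gibbs mixes well within the budget — strongly frustrated
couplings can trap a single chain for longer than any fixed budget, a
standard limitation of single-site samplers that the test suite
demonstrates explicitly (and distinguishes from bias by multi-chain
averaging).

## Known limitations

* Single-site Gibbs mixes slowly near phase boundaries and in
  frustrated regimes; no tempering or block updates are provided.
* The pseudo-likelihood fit is re-run every sweep; for very large
  universes this dominates runtime (the sweep kernel itself is
  compiled).
* Gene identifiers are matched as case-sensitive strings; aliasing and
  ID mapping are out of scope.
* Higher-order clique potentials, weighted or signed edges, and
  temperature ≠ 1 are not modelled.
* Genes appearing in associations but in no network are dropped with a
  warning; genes isolated in every network are never excluded from a
  run but are untestable in leave-one-out validation.
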