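# mrfprio

Disease-gene prioritization by Gibbs sampling of an Ising-type Markov
random field (MRF) over multiple biological networks.

Most human genetic diseases involve several genes, and genes associated
with similar disorders tend to be functionally related — they interact,
share pathways and complexes, and co-express ("guilt by association").
`mrfprio` integrates any number of gene–gene networks (protein–protein
interaction, pathway co-existence, co-expression, …) with known
gene–disease associations and protein-complex membership, and returns a
posterior probability that each candidate gene belongs to a given
disease class. It is aimed at computational biologists who have edge
lists and a gene–disease table and want a principled, reproducible
ranking rather than a nearest-neighbour heuristic: the MRF conditions on
the whole configuration of labels, not just on edges touching known
disease genes.

## Model

Let `x = (x_1, …, x_N)` be binary disease labels over the gene universe
and `H^1 … H^K` be `K` undirected networks on those genes. Under a
labelling, the edges of network `k` split into three classes with counts
`N11_k` (both ends 1), `N10_k` (mixed) and `N00_k` (both ends 0). The
joint label distribution is the Gibbs distribution `P(x) ∝ exp(−U(x))`
with Ising energy

    U(x) = − Σ_i α_i x_i − Σ_k ( β_k N10_k + γ_k N11_k + κ N00_k ),  κ ≡ 1.

The single-site conditional is logistic in the local field

    T(i) = α_i + Σ_k [ (β_k − 1) M0_k(i) + (γ_k − β_k) M1_k(i) ],
    P(x_i = 1 | x_−i) = 1 / (1 + e^−T(i)),

where `M0_k(i)`/`M1_k(i)` count gene *i*'s 0- and 1-labelled neighbours
in network `k`. Parameters are estimated by pseudo-likelihood: a binary
logistic regression of the current labels on the neighbour counts,
interleaved with the Gibbs sweeps:

* **imrf1** — every sweep re-estimates `θ = (α, β_1, γ_1, …, β_K, γ_K)`
  from *all* currently labelled genes (known + sampled), then performs
  one sequential Gibbs sweep; posteriors average the per-sweep
  conditional probabilities over a thinned post-burn-in window
  (defaults: 1000 sweeps, burn-in 100, every 10th recorded → 90
  snapshots).
* **imrf2** — additionally freezes `θ` at its lag-period average and
  runs a 100-sweep prediction period whose averaged conditionals are the
  final posterior (the most stable mode, and the default).
* **deng** — the classical baseline: `θ` estimated once from the known
  genes only (positives of the class, negatives from other classes) and
  held fixed. With few known genes this estimate is unreliable and the
  baseline floods the ranking with high posteriors.

Priors come from protein complexes: for a gene in a complex,
`π̂_i = A/B`, the fraction of the complex's known disease genes that
belong to the class of interest (maximum over the gene's complexes);
genes in no complex get the genome-wide class rate `C/D`. Rankings are
reported as rank-percentile *decision scores* so one threshold is
comparable across disease classes of different sizes, and validation is
leave-one-out: each known gene with at least one interaction partner is
masked, its prior rebuilt without its own label, and its re-scored rank
compared against known genes of other classes (ROC/AUC).

## Worked example

Everything below is synthetic and generated on the fly — no downloads.
The planted-module benchmark hides a 60-gene disease module in two
background networks of 2000 genes, reveals half of it as "known", and
asks the sampler to find the rest:

```python
import numpy as np
import pandas as pd
from mrfprio import DiseaseGeneMRF, SamplerConfig
from mrfprio.evaluation import roc_auc
from mrfprio.synthetic import make_planted_benchmark

scenario = make_planted_benchmark(n_genes=2000, K=2, module_size=60, seed=1)
model = DiseaseGeneMRF.from_scenario(scenario)
result = model.fit(mode="imrf2", config=SamplerConfig(seed=1))
print(result.summary())
```

```
Gibbs MRF sampling result
=========================
mode:            imrf2
alpha mode:      global
genes:           2000 (30 known, 1970 candidates)
sweeps:          1000 (burn-in 100, thin 10, prediction 100)
alpha:           -69.2828
network 1:       beta = +1.0738, gamma = +26.9316
network 2:       beta = +1.2020, gamma = +1.7413
final Q(t):      0
```

The fitted `γ_1 ≫ β_1 > κ = 1` says network 1's 1–1 edges are strongly
over-represented — the sampler has locked onto the planted module (the
large magnitudes reflect the ridge-bounded fit under complete
separation: the module is perfectly distinguishable here). `Q(t)`, the
summed squared change of the per-gene posteriors between adjacent
sweeps, has reached 0: the chain is stationary. Ranking the candidates
and scoring hidden module members against negative-control genes:

```python
frame = result.to_frame(scenario.collection.universe)
print(frame[frame.known_flag == 0]
      .sort_values("decision_score", ascending=False).head())

hp, ng = scenario.hidden_positives, scenario.negative_controls
s = result.decision_scores()
table = pd.DataFrame({
    "label": np.r_[np.ones(len(hp), int), np.zeros(len(ng), int)],
    "score": np.r_[s[hp], s[ng]]})
print(f"hidden-positive vs negative-control AUC: {roc_auc(table).auc:.3f}")
```

```
 gene  known_flag    prior  posterior  decision_score
G0041           0 0.015000        1.0         0.99264
G0458           0 0.015000        1.0         0.99264
G1726           0 0.015000        1.0         0.99264
G1642           0 0.999999        1.0         0.99264
G1044           0 0.015000        1.0         0.99264

hidden-positive vs negative-control AUC: 1.000
```

All top-ranked candidates are hidden module members; the one with prior
≈ 1 sits in a simulated complex rich in known genes, the others are
found through their edges alone. Running the same model with
`mode="deng"` drops the AUC to ≈ 0.5 and pushes essentially every
candidate above posterior 0.9 — the instability the interleaved
re-estimation was designed to fix.

The same pipeline is scriptable from the shell:

```sh
mrfprio simulate --planted --n-genes 2000 --module-size 60 --seed 1 --out scen/
mrfprio rank --networks scen/network_er1.tsv --networks scen/network_er2.tsv \
    --associations scen/associations.tsv --class class1 \
    --complexes scen/complexes.gmt --mode imrf2 --seed 1 --out ranking.tsv
mrfprio evaluate --networks scen/network_er1.tsv --networks scen/network_er2.tsv \
    --associations scen/associations.tsv --class class1 \
    --mode imrf1 --seed 1 --out eval/
```

`build-net` additionally constructs co-expression (Pearson correlation
> 0.5), pathway co-existence and merged ("mixed") networks from raw
expression tables and gene sets.

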