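"""Synthetic instances and benchmarks.

Provides random multi-network instances, an exact small-graph reference
distribution (full enumeration of the Gibbs measure, usable as an oracle
for the sampler), and model-faithful benchmark scenarios in which a
hidden ground-truth labelling is drawn from the MRF itself, a fraction
of the 1-genes is revealed as "known", and protein complexes are
simulated with 1-genes over-represented so the complex priors carry
signal.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np

from ._gibbs import pack_adjacency, run_sweeps
from .core import LabelConfig, MRFParams, PriorVector, _field_vector
from .data import BioNetwork, ComplexSet, GeneUniverse, NetworkCollection
from .errors import CapabilityError, ConfigurationError, MrfPrioError

log = logging.getLogger(__name__)

ENUM_LIMIT = 15  # largest universe enumerated exactly (2^N configurations)


def generate_networks(
    n_genes: int,
    K: int,
    edge_prob,
    seed: int,
    universe: GeneUniverse | None = None,
) -> NetworkCollection:
    """K independent Erdos-Renyi graphs over a shared synthetic universe."""
    if n_genes < 2:
        raise ConfigurationError("need at least two genes")
    edge_prob = np.broadcast_to(np.asarray(edge_prob, dtype=float), (K,))
    if not ((edge_prob > 0) & (edge_prob < 1)).all():
        raise ConfigurationError("edge probabilities must lie in (0, 1)")
    if universe is None:
        width = len(str(n_genes - 1))
        universe = GeneUniverse(f"G{i:0{width}d}" for i in range(n_genes))
    ss = np.random.SeedSequence(seed)
    nets = []
    for k, child in enumerate(ss.spawn(K)):
        g = nx.fast_gnp_random_graph(
            n_genes, float(edge_prob[k]),
            seed=int(child.generate_state(1)[0] % (2**31)),
        )
        nets.append(BioNetwork(f"er{k + 1}", g.edges(), n_genes))
    return NetworkCollection(universe, nets)


class ExactGibbs:
    """Exactly enumerated Gibbs distribution on a small universe.

    Enumerates every configuration consistent with the clamped genes
    (clamped positions fixed at 1) and normalizes explicitly; exposes the
    partition function, marginals, conditionals and exact sampling.
    """

    def __init__(
        self,
        collection: NetworkCollection,
        params: MRFParams,
        alpha_field,
        clamped: np.ndarray | None = None,
    ):
        n = collection.n_genes
        if clamped is None:
            clamped = np.zeros(n, dtype=bool)
        clamped = np.asarray(clamped, dtype=bool)
        free = np.where(~clamped)[0]
        if len(free) > ENUM_LIMIT:
            raise CapabilityError(
                f"{len(free)} free genes exceed the {ENUM_LIMIT}-gene enumeration "
                "limit; use the Gibbs sampler instead"
            )
        alpha = _field_vector(alpha_field, n)
        m = len(free)
        bits = ((np.arange(2**m)[:, None] >> np.arange(m)) & 1).astype(np.int8)
        configs = np.ones((2**m, n), dtype=np.int8)
        configs[:, free] = bits
        # energy of every configuration, vectorized over edges
        neg_u = configs.astype(float) @ alpha
        for k, net in enumerate(collection):
            i, j = net.edge_arrays()
            xi = configs[:, i].astype(float)
            xj = configs[:, j].astype(float)
            n11 = (xi * xj).sum(axis=1)
            n10 = (xi * (1 - xj) + (1 - xi) * xj).sum(axis=1)
            n00 = ((1 - xi) * (1 - xj)).sum(axis=1)
            neg_u += (params.beta[k] * n10 + params.gamma[k] * n11
                      + params.kappa * n00)
        self.configs = configs
        self.clamped = clamped
        self.log_weights = neg_u  # log of unnormalized probability, -U
        shift = neg_u.max()
        w = np.exp(neg_u - shift)
        self.Z = float(w.sum() * np.exp(shift)) if shift < 700 else np.inf
        self.probs = w / w.sum()

    def marginals(self) -> np.ndarray:
        """Exact P(x_i = 1) per gene (1 for clamped genes)."""
        return self.probs @ self.configs

    def conditional(self, gene: int, rest: np.ndarray) -> float:
        """Exact P(x_gene = 1 | rest) from the enumerated table."""
        rest = np.asarray(rest, dtype=np.int8)
        others = np.arange(self.configs.shape[1]) != gene
        match = (self.configs[:, others] == rest[others]).all(axis=1)
        sub = self.probs[match]
        ones = self.configs[match, gene] == 1
        return float(sub[ones].sum() / sub.sum())

    def sample(self, rng: np.random.Generator, size: int | None = None) -> np.ndarray:
        idx = rng.choice(len(self.probs), size=size, p=self.probs)
        return self.configs[idx]


def sample_configuration_exact(
    collection: NetworkCollection,
    params: MRFParams,
    priors: PriorVector | np.ndarray | float,
    rng: np.random.Generator,
    clamped: np.ndarray | None = None,
) -> LabelConfig:
    """Draw one configuration from the exactly normalized Gibbs measure
    (universes of up to 15 free genes)."""
    dist = ExactGibbs(collection, params, priors, clamped=clamped)
    labels = dist.sample(rng)
    return LabelConfig(labels, dist.clamped.copy())


def sample_configuration_gibbs(
    collection: NetworkCollection,
    params: MRFParams,
    priors: PriorVector | np.ndarray | float,
    sweeps: int,
    seed: int,
    clamped: np.ndarray | None = None,
    init: np.ndarray | None = None,
) -> LabelConfig:
    """Long-run fixed-theta Gibbs draw, for truths too large to enumerate."""
    if sweeps < 1:
        raise ConfigurationError("sweeps must be >= 1")
    n = collection.n_genes
    if clamped is None:
        clamped = np.zeros(n, dtype=bool)
    rng = np.random.default_rng(seed)
    alpha = _field_vector(priors, n)
    if init is None:
        # initialize from the field's implied prior, as the run drivers do
        from .core import sigmoid

        labels = (rng.random(n) < sigmoid(alpha)).astype(np.int8)
    else:
        labels = np.asarray(init, dtype=np.int8).copy()
    labels[clamped] = 1
    state = LabelConfig(labels, clamped)
    indptr, indices = pack_adjacency(collection.adjacencies())
    free = np.where(~clamped)[0].astype(np.int64)
    chunk = 2000
    done = 0
    while done < sweeps:
        s = min(chunk, sweeps - done)
        order = np.broadcast_to(free, (s, len(free)))
        uniforms = rng.random((s, len(free)))
        probs = np.empty((s, n))
        run_sweeps(state.labels, indptr, indices, alpha, params.beta,
                   params.gamma, np.ascontiguousarray(order), uniforms, probs)
        done += s
    return state


def gibbs_marginals(
    collection: NetworkCollection,
    params: MRFParams,
    priors: PriorVector | np.ndarray | float,
    sweeps: int,
    burn_in: int,
    seed: int,
    clamped: np.ndarray | None = None,
    rao_blackwell: bool = True,
) -> np.ndarray:
    """Empirical fixed-theta marginals P(x_i = 1) from a long Gibbs run.

    Averages the per-sweep conditional probabilities after ``burn_in``
    (Rao-Blackwellized estimate; set ``rao_blackwell=False`` to average
    the binary labels instead). Clamped genes report 1.
    """
    if not (0 <= burn_in < sweeps):
        raise ConfigurationError("need 0 <= burn_in < sweeps")
    n = collection.n_genes
    if clamped is None:
        clamped = np.zeros(n, dtype=bool)
    rng = np.random.default_rng(seed)
    alpha = _field_vector(priors, n)
    from .core import sigmoid

    labels = (rng.random(n) < sigmoid(alpha)).astype(np.int8)
    labels[clamped] = 1
    indptr, indices = pack_adjacency(collection.adjacencies())
    free = np.where(~clamped)[0].astype(np.int64)
    acc = np.zeros(n)
    n_acc = 0
    done = 0
    chunk = 5000
    while done < sweeps:
        s = min(chunk, sweeps - done)
        order = np.ascontiguousarray(np.broadcast_to(free, (s, len(free))))
        uniforms = rng.random((s, len(free)))
        probs = np.ones((s, n))
        run_sweeps(labels, indptr, indices, alpha, params.beta, params.gamma,
                   order, uniforms, probs)
        lo = max(burn_in - done, 0)
        if lo < s:
            if rao_blackwell:
                acc += probs[lo:].sum(axis=0)
            else:
                # the label drawn for gene free[t] in sweep s is exactly
                # uniforms[s, t] < probs[s, free[t]]
                drawn = uniforms[lo:] < probs[lo:][:, free]
                acc[free] += drawn.sum(axis=0)
                acc[clamped] += s - lo
            n_acc += s - lo
        done += s
    marg = acc / max(n_acc, 1)
    marg[clamped] = 1.0
    return marg


@dataclass
class BenchmarkScenario:
    """A fully synthetic, reproducible prioritization problem.

    ``truth`` is a configuration drawn from the MRF with ``theta_true``;
    ``known`` reveals a fraction of its 1-genes, ``negative_controls``
    plays the role of known disease genes of other classes (drawn from
    the true 0-genes), and ``complexes`` are gene sets enriched for
    1-genes so the complex prior is informative.
    """

    collection: NetworkCollection
    truth: np.ndarray
    known: np.ndarray
    negative_controls: np.ndarray
    complexes: ComplexSet
    theta_true: MRFParams
    known_fraction: float
    seed: int

    @property
    def hidden_positives(self) -> np.ndarray:
        known = set(self.known.tolist())
        return np.array(
            [i for i in np.where(self.truth == 1)[0] if i not in known],
            dtype=np.int64,
        )

    @property
    def degenerate(self) -> bool:
        """True when evaluation is impossible: no hidden positives or no
        true 0-genes to serve as negatives."""
        return len(self.hidden_positives) == 0 or (self.truth == 0).sum() == 0


def make_benchmark(
    n_genes: int = 2000,
    K: int = 2,
    edge_prob=(0.004, 0.006),
    theta_true: MRFParams | None = None,
    known_fraction: float = 0.5,
    n_complexes: int = 20,
    complex_size: int = 8,
    seed: int = 0,
    truth_sweeps: int = 500,
    enrichment: float = 3.0,
    n_negative_controls: int | None = None,
) -> BenchmarkScenario:
    """Generate a benchmark scenario with a model-faithful hidden truth.

    The ground truth is sampled by ``truth_sweeps`` fixed-theta Gibbs
    sweeps from an all-zero start with the constant field alpha of
    ``theta_true``. Complexes draw ``complex_size`` genes with 1-genes
    over-weighted ``enrichment``:1. A scenario whose truth contains no
    1-gene is regenerated with a fresh sub-seed (at most 10 attempts).
    """
    if not (0 < known_fraction <= 1):
        raise ConfigurationError("known_fraction must be in (0, 1]")
    if theta_true is None:
        theta_true = MRFParams(
            alpha=-2.0, beta=np.full(K, 1.5), gamma=np.full(K, 3.0)
        )
    for attempt in range(10):
        sub = np.random.SeedSequence([seed, attempt])
        s_net, s_truth, s_rest = (
            int(x.generate_state(1)[0] % (2**31)) for x in sub.spawn(3)
        )
        collection = generate_networks(n_genes, K, edge_prob, s_net)
        truth_state = sample_configuration_gibbs(
            collection, theta_true, theta_true.alpha, truth_sweeps, s_truth,
            init=np.zeros(n_genes, dtype=np.int8),
        )
        truth = truth_state.labels.copy()
        if truth.sum() > 0:
            break
        log.warning("benchmark truth had no 1-genes; regenerating (attempt %d)",
                    attempt + 1)
    else:
        raise MrfPrioError("could not generate a truth with at least one 1-gene")
    rng = np.random.default_rng(s_rest)
    ones = np.where(truth == 1)[0]
    zeros = np.where(truth == 0)[0]
    n_known = max(1, int(round(known_fraction * len(ones))))
    known = np.sort(rng.choice(ones, size=n_known, replace=False))
    if n_negative_controls is None:
        n_negative_controls = n_known
    negatives = np.sort(
        rng.choice(zeros, size=min(n_negative_controls, len(zeros)), replace=False)
    ) if len(zeros) else np.empty(0, dtype=np.int64)
    # complexes enriched for 1-genes
    weights = np.where(truth == 1, enrichment, 1.0).astype(float)
    weights /= weights.sum()
    members_list = []
    for c in range(n_complexes):
        members = rng.choice(n_genes, size=complex_size, replace=False, p=weights)
        members_list.append((f"cpx{c + 1}", frozenset(int(m) for m in members)))
    scenario = BenchmarkScenario(
        collection=collection,
        truth=truth,
        known=known,
        negative_controls=negatives,
        complexes=ComplexSet(members_list),
        theta_true=theta_true,
        known_fraction=known_fraction,
        seed=seed,
    )
    if scenario.degenerate:
        log.warning(
            "benchmark scenario is degenerate for evaluation: "
            "%d hidden positives, %d true 0-genes",
            len(scenario.hidden_positives), int((truth == 0).sum()),
        )
    return scenario


def make_planted_benchmark(
    n_genes: int = 2000,
    K: int = 2,
    edge_prob=(0.004, 0.006),
    module_size: int = 60,
    module_edge_prob: float = 0.15,
    known_fraction: float = 0.5,
    n_complexes: int = 20,
    complex_size: int = 8,
    seed: int = 0,
    enrichment: float = 3.0,
    n_negative_controls: int | None = None,
) -> BenchmarkScenario:
    """Misspecified benchmark variant: a planted dense disease module.

    Instead of drawing the truth from the MRF itself, ``module_size``
    genes are labelled 1 and wired densely (edge probability
    ``module_edge_prob`` within the module, per network) on top of the
    Erdos-Renyi background. This emulates the guilt-by-association
    structure of real disease classes — a sparse positive class whose
    members interact — without assuming the fitted model is the
    generating one. ``theta_true`` on the returned scenario is the
    module's nominal field/coupling and is not used to generate labels.
    """
    if not (2 <= module_size < n_genes):
        raise ConfigurationError("module_size must be in [2, n_genes)")
    ss = np.random.SeedSequence([seed, 12345])
    s_net, s_rest = (int(x.generate_state(1)[0] % (2**31)) for x in ss.spawn(2))
    collection = generate_networks(n_genes, K, edge_prob, s_net)
    rng = np.random.default_rng(s_rest)
    module = np.sort(rng.choice(n_genes, size=module_size, replace=False))
    nets = []
    for net in collection:
        extra = [
            (int(module[a]), int(module[b]))
            for a in range(module_size)
            for b in range(a + 1, module_size)
            if rng.random() < module_edge_prob
        ]
        nets.append(BioNetwork(net.name, set(net.edges) | set(extra), n_genes))
    collection = NetworkCollection(collection.universe, nets)
    truth = np.zeros(n_genes, dtype=np.int8)
    truth[module] = 1
    n_known = max(1, int(round(known_fraction * module_size)))
    known = np.sort(rng.choice(module, size=n_known, replace=False))
    zeros = np.where(truth == 0)[0]
    if n_negative_controls is None:
        n_negative_controls = n_known
    negatives = np.sort(
        rng.choice(zeros, size=min(n_negative_controls, len(zeros)),
                   replace=False)
    )
    weights = np.where(truth == 1, enrichment, 1.0).astype(float)
    weights /= weights.sum()
    members_list = []
    for c in range(n_complexes):
        members = rng.choice(n_genes, size=complex_size, replace=False, p=weights)
        members_list.append((f"cpx{c + 1}", frozenset(int(m) for m in members)))
    return BenchmarkScenario(
        collection=collection,
        truth=truth,
        known=known,
        negative_controls=negatives,
        complexes=ComplexSet(members_list),
        theta_true=MRFParams(alpha=-4.0, beta=np.full(K, 1.0),
                             gamma=np.full(K, 2.0)),
        known_fraction=known_fraction,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# scenario directories (text-only, for the CLI round trip)
# ---------------------------------------------------------------------------

def write_scenario(scenario: BenchmarkScenario, outdir: str | Path) -> None:
    from .io import write_edge_list, write_gene_sets

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    uni = scenario.collection.universe
    for net in scenario.collection:
        write_edge_list(net, uni, outdir / f"network_{net.name}.tsv")
    write_gene_sets(
        ((name, [uni[i] for i in sorted(members)])
         for name, members in scenario.complexes),
        outdir / "complexes.gmt",
    )
    with open(outdir / "associations.tsv", "w") as fh:
        for i in scenario.known:
            fh.write(f"{uni[int(i)]}\tclass1\n")
        for i in scenario.negative_controls:
            fh.write(f"{uni[int(i)]}\tother\n")
    with open(outdir / "truth.tsv", "w") as fh:
        fh.write("gene\ttrue_label\tknown\n")
        known = set(scenario.known.tolist())
        for i, g in enumerate(uni):
            fh.write(f"{g}\t{int(scenario.truth[i])}\t{int(i in known)}\n")
    manifest = {
        "seed": scenario.seed,
        "known_fraction": scenario.known_fraction,
        "theta_true": {
            "alpha": scenario.theta_true.alpha,
            "beta": scenario.theta_true.beta.tolist(),
            "gamma": scenario.theta_true.gamma.tolist(),
        },
        "networks": [net.name for net in scenario.collection],
        "n_genes": scenario.collection.n_genes,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
        fh.write("\n")
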