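"""The Ising-type MRF over multiple networks: energy, local field, priors.

Model
-----
For binary labels ``x`` over ``N`` genes and ``K`` undirected networks,
the joint distribution is the Gibbs distribution ``P(x) = exp(-U(x)) / Z``
with energy

    U(x) = - sum_i alpha_i x_i
           - sum_k ( beta_k N10_k + gamma_k N11_k + kappa N00_k ),

where ``N11_k / N10_k / N00_k`` count the edges of network ``k`` joining
two 1-genes, a 1-gene and a 0-gene, and two 0-genes, and ``kappa`` is
fixed at 1 (one of the three edge weights is redundant). The conditional
distribution of one label given all the others depends only on the local
field

    T(i) = alpha_i + sum_k [ (beta_k - 1) M0_k(i) + (gamma_k - beta_k) M1_k(i) ],

with ``M0_k(i)/M1_k(i)`` the 0- and 1-labelled neighbors of gene ``i``
in network ``k``, via ``P(x_i = 1 | rest) = sigmoid(T(i))``. T(i) is
exactly the energy difference ``U(x_i=0, rest) - U(x_i=1, rest)``.

Priors come from protein complexes: within a complex, the fraction of its
known disease genes that belong to the class of interest; genes in no
complex fall back to the genome-wide rate of the class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import BioNetwork, ComplexSet, NetworkCollection
from .errors import ConsistencyError, DimensionError, MrfPrioError

#: Probabilities are clipped to [PRIOR_EPS, 1 - PRIOR_EPS] so log-odds stay finite.
PRIOR_EPS = 1e-6


@dataclass
class MRFParams:
    """Parameters theta = (alpha, beta_1, gamma_1, ..., beta_K, gamma_K).

    ``alpha`` is the global field coefficient (the regression constant);
    ``beta[k]`` weighs mixed (1-0) edges and ``gamma[k]`` weighs 1-1 edges
    of network ``k``. The 0-0 edge weight ``kappa`` is identically 1.
    """

    alpha: float
    beta: np.ndarray
    gamma: np.ndarray

    def __post_init__(self) -> None:
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        self.gamma = np.atleast_1d(np.asarray(self.gamma, dtype=float))
        if self.beta.shape != self.gamma.shape:
            raise DimensionError("beta and gamma must have one entry per network")
        if not (np.isfinite(self.alpha) and np.isfinite(self.beta).all()
                and np.isfinite(self.gamma).all()):
            raise MrfPrioError("MRF parameters must be finite")

    @property
    def kappa(self) -> float:
        return 1.0

    @property
    def K(self) -> int:
        return len(self.beta)

    def as_vector(self) -> np.ndarray:
        """(alpha, beta_1..K, gamma_1..K) as a flat array."""
        return np.concatenate([[self.alpha], self.beta, self.gamma])

    @classmethod
    def from_vector(cls, v: np.ndarray) -> "MRFParams":
        v = np.asarray(v, dtype=float)
        K = (len(v) - 1) // 2
        return cls(alpha=float(v[0]), beta=v[1:1 + K], gamma=v[1 + K:])


class LabelConfig:
    """Binary label configuration with clamped (known-positive) genes.

    Clamped positions always carry label 1; attempts to construct a state
    violating that invariant raise :class:`ConsistencyError`.
    """

    def __init__(self, labels: np.ndarray, clamped: np.ndarray | None = None):
        labels = np.asarray(labels, dtype=np.int8)
        if not np.isin(labels, (0, 1)).all():
            raise ConsistencyError("labels must be binary")
        n = len(labels)
        if clamped is None:
            clamped = np.zeros(n, dtype=bool)
        clamped = np.asarray(clamped, dtype=bool)
        if clamped.shape != labels.shape:
            raise DimensionError("labels and clamped mask must have equal length")
        if not (labels[clamped] == 1).all():
            raise ConsistencyError("clamped genes must carry label 1")
        self.labels = labels
        self.clamped = clamped

    @classmethod
    def from_known(cls, n: int, known: np.ndarray | list[int]) -> "LabelConfig":
        """All-zero configuration with ``known`` genes clamped at 1."""
        labels = np.zeros(n, dtype=np.int8)
        clamped = np.zeros(n, dtype=bool)
        known = np.asarray(list(known), dtype=np.int64)
        labels[known] = 1
        clamped[known] = True
        return cls(labels, clamped)

    @property
    def n(self) -> int:
        return len(self.labels)

    def copy(self) -> "LabelConfig":
        return LabelConfig(self.labels.copy(), self.clamped.copy())

    def with_labels(self, labels: np.ndarray) -> "LabelConfig":
        return LabelConfig(labels, self.clamped.copy())


class PriorVector:
    """Per-gene prior probabilities pi_i with their log-odds alpha_i.

    Probabilities are clipped to ``[PRIOR_EPS, 1 - PRIOR_EPS]`` so that
    ``alpha_i = logit(pi_i)`` is always finite.
    """

    def __init__(self, pi: np.ndarray):
        pi = np.asarray(pi, dtype=float)
        if np.isnan(pi).any():
            raise DimensionError("priors contain NaN")
        self.pi = np.clip(pi, PRIOR_EPS, 1.0 - PRIOR_EPS)

    @property
    def alpha(self) -> np.ndarray:
        return logit(self.pi)

    def __len__(self) -> int:
        return len(self.pi)


@dataclass
class NeighborCounts:
    """Per-network 0- and 1-labelled neighbor counts of one gene."""

    m0: np.ndarray
    m1: np.ndarray


@dataclass
class EdgeCategoryCounts:
    """Edge counts of one network under one labelling: 1-1, 1-0, 0-0."""

    n11: int
    n10: int
    n00: int

    @property
    def total(self) -> int:
        return self.n11 + self.n10 + self.n00


def sigmoid(t: np.ndarray | float) -> np.ndarray | float:
    """Overflow-safe logistic function 1 / (1 + e^(-t))."""
    t = np.asarray(t, dtype=float)
    out = np.empty_like(t)
    pos = t >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-t[pos]))
    et = np.exp(t[~pos])
    out[~pos] = et / (1.0 + et)
    return out if out.ndim else float(out)


def logit(p: np.ndarray | float) -> np.ndarray | float:
    """log(p / (1-p)); domain error outside the open unit interval."""
    p = np.asarray(p, dtype=float)
    if ((p <= 0) | (p >= 1)).any():
        raise MrfPrioError("logit requires p in the open interval (0, 1)")
    out = np.log(p) - np.log1p(-p)
    return out if out.ndim else float(out)


def conditional_probability(t_value: float) -> float:
    """P(x_i = 1 | rest) = e^T / (e^T + 1), computed overflow-safely."""
    return float(sigmoid(float(t_value)))


def edge_category_counts(network: BioNetwork, labels: LabelConfig | np.ndarray) -> EdgeCategoryCounts:
    """Classify the edges of one network under a labelling into 1-1 / 1-0 / 0-0."""
    x = labels.labels if isinstance(labels, LabelConfig) else np.asarray(labels, np.int8)
    if len(x) != network.n_genes:
        raise DimensionError("labelling does not cover the network's universe")
    i, j = network.edge_arrays()
    xi, xj = x[i], x[j]
    n11 = int(np.sum(xi * xj))
    n10 = int(np.sum(xi * (1 - xj) + (1 - xi) * xj))
    n00 = int(np.sum((1 - xi) * (1 - xj)))
    return EdgeCategoryCounts(n11=n11, n10=n10, n00=n00)


def neighbor_counts(
    gene: int, collection: NetworkCollection, labels: LabelConfig | np.ndarray
) -> NeighborCounts:
    """M0_k and M1_k of one gene across all K networks."""
    x = labels.labels if isinstance(labels, LabelConfig) else np.asarray(labels, np.int8)
    K = collection.K
    m0 = np.zeros(K, dtype=np.int64)
    m1 = np.zeros(K, dtype=np.int64)
    for k, a in enumerate(collection.adjacencies()):
        nb = a.indices[a.indptr[gene]:a.indptr[gene + 1]]
        m1[k] = int(x[nb].sum())
        m0[k] = len(nb) - m1[k]
    return NeighborCounts(m0=m0, m1=m1)


def neighbor_count_matrix(
    collection: NetworkCollection, labels: LabelConfig | np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized neighbor counts for all genes: (M0, M1), each (K, n)."""
    x = labels.labels if isinstance(labels, LabelConfig) else np.asarray(labels, np.int8)
    xf = x.astype(np.float64)
    m1 = np.stack([a @ xf for a in collection.adjacencies()])
    deg = collection.degrees().astype(np.float64)
    return deg - m1, m1


def _field_vector(alpha, n: int) -> np.ndarray:
    """Normalize a field specification (PriorVector, scalar or array) to (n,)."""
    if isinstance(alpha, PriorVector):
        vec = alpha.alpha
    else:
        vec = np.asarray(alpha, dtype=float)
        if vec.ndim == 0:
            vec = np.full(n, float(vec))
    if vec.shape != (n,):
        raise DimensionError(f"field vector has shape {vec.shape}, expected ({n},)")
    return vec


def energy(
    collection: NetworkCollection,
    labels: LabelConfig | np.ndarray,
    params: MRFParams,
    alpha_field,
) -> float:
    """Energy U(x | theta) of a configuration.

    ``alpha_field`` is the per-gene field: a :class:`PriorVector` (whose
    log-odds are used), a scalar (broadcast, the global-alpha mode) or an
    (n,) array.
    """
    x = labels.labels if isinstance(labels, LabelConfig) else np.asarray(labels, np.int8)
    n = collection.n_genes
    if len(x) != n:
        raise DimensionError("labelling does not cover the universe")
    if params.K != collection.K:
        raise DimensionError("params have wrong number of networks")
    alpha = _field_vector(alpha_field, n)
    u = -float(alpha @ x)
    for k, net in enumerate(collection):
        c = edge_category_counts(net, x)
        u -= params.beta[k] * c.n10 + params.gamma[k] * c.n11 + params.kappa * c.n00
    return u


def local_field(
    gene: int,
    collection: NetworkCollection,
    labels: LabelConfig | np.ndarray,
    params: MRFParams,
    alpha_field,
) -> float:
    """Local field T(i); equals U(x_i=0, rest) - U(x_i=1, rest)."""
    alpha = _field_vector(alpha_field, collection.n_genes)
    nc = neighbor_counts(gene, collection, labels)
    t = float(alpha[gene])
    t += float(((params.beta - params.kappa) * nc.m0).sum())
    t += float(((params.gamma - params.beta) * nc.m1).sum())
    return t


def complex_prior(
    gene: int,
    complexes: ComplexSet,
    disease_genes: frozenset[int] | set[int],
    all_disease_genes: frozenset[int] | set[int],
    universe_size: int,
) -> float:
    """Complex-derived prior probability of one gene.

    For each complex containing the gene with at least one known disease
    gene (of any class), the candidate value is A / B where A counts the
    complex's genes known for the class of interest and B counts all its
    known disease genes; the prior is the maximum candidate. Genes in no
    complex — or only in complexes without known disease genes — fall back
    to C / D, the class size over the universe size. The result is clipped
    away from {0, 1} so its log-odds stay finite.
    """
    disease_genes = frozenset(disease_genes)
    all_disease_genes = frozenset(all_disease_genes)
    if not disease_genes <= all_disease_genes:
        raise ConsistencyError(
            "class disease genes must be a subset of all known disease genes"
        )
    if universe_size <= 0:
        raise DimensionError("universe_size must be positive")
    candidates = []
    for members in complexes.membership(gene):
        b = len(members & all_disease_genes)
        if b > 0:
            a = len(members & disease_genes)
            candidates.append(a / b)
    if candidates:
        p = max(candidates)
    else:
        p = len(disease_genes) / universe_size
    return float(np.clip(p, PRIOR_EPS, 1.0 - PRIOR_EPS))


def build_priors(
    universe_size: int,
    complexes: ComplexSet | None,
    disease_genes: frozenset[int] | set[int],
    all_disease_genes: frozenset[int] | set[int] | None = None,
) -> PriorVector:
    """Complex priors for every gene in the universe.

    With no complexes, every gene gets the genome-wide class rate C / D.
    """
    if all_disease_genes is None:
        all_disease_genes = frozenset(disease_genes)
    if complexes is None:
        complexes = ComplexSet([])
    pi = np.empty(universe_size, dtype=float)
    # genes covered by some complex are few; precompute complex -> B once
    fallback = float(np.clip(len(frozenset(disease_genes)) / universe_size,
                             PRIOR_EPS, 1.0 - PRIOR_EPS))
    in_any = set()
    for _, members in complexes:
        in_any |= members
    pi[:] = fallback
    for g in in_any:
        if 0 <= g < universe_size:
            pi[g] = complex_prior(g, complexes, disease_genes,
                                  all_disease_genes, universe_size)
    return PriorVector(pi)
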