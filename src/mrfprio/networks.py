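"""Derived-network construction and universe filtering.

Co-expression networks link genes whose expression profiles have a
Pearson correlation strictly above a threshold (default 0.5). Pathway
co-existence networks link any two genes that share a pathway (a union
of cliques). The frequency filter keeps genes that have at least one
edge in a minimum number of the input networks; protein complexes are
deliberately never turned into a network — they only inform the prior.
"""

from __future__ import annotations

import numpy as np

from .data import BioNetwork, ExpressionMatrix, GeneUniverse, NetworkCollection
from .errors import ConfigurationError, DimensionError


def coexpression_network(
    expr: ExpressionMatrix,
    universe: GeneUniverse,
    threshold: float = 0.5,
    name: str = "coexpression",
) -> BioNetwork:
    """Network with an edge where pairwise Pearson correlation > ``threshold``.

    Rows with zero variance have undefined correlation and contribute no
    edges. Expression rows whose gene is absent from the universe are
    ignored.
    """
    if expr.n_samples < 2:
        raise DimensionError("need >= 2 samples to compute correlations")
    if not (-1.0 < threshold < 1.0):
        raise ConfigurationError(f"threshold must be in (-1, 1), got {threshold}")
    keep = [k for k, g in enumerate(expr.genes) if g in universe]
    idx = np.array([universe.index(expr.genes[k]) for k in keep], dtype=np.int64)
    values = expr.values[keep]
    edges: list[tuple[int, int]] = []
    if len(keep) >= 2:
        sd = values.std(axis=1)
        nonconst = sd > 0
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(values)
        r, c = np.where(np.triu(corr > threshold, k=1))
        for a, b in zip(r, c):
            if nonconst[a] and nonconst[b]:
                edges.append((int(idx[a]), int(idx[b])))
    return BioNetwork(name, edges, len(universe))


def pathway_coexistence_network(
    sets: list[tuple[str, list[str]]],
    universe: GeneUniverse,
    name: str = "pathway",
) -> BioNetwork:
    """Union-of-cliques network: an edge joins two genes that co-occur in
    any pathway gene set. Members absent from the universe are ignored."""
    if not sets:
        raise ConfigurationError("need at least one gene set")
    edges: list[tuple[int, int]] = []
    for _, members in sets:
        idx = sorted({universe.index(m) for m in members if m in universe})
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                edges.append((idx[a], idx[b]))
    return BioNetwork(name, edges, len(universe))


def filter_by_network_frequency(
    collection: NetworkCollection, min_count: int
) -> tuple[NetworkCollection, GeneUniverse]:
    """Restrict the universe to genes that appear (degree >= 1) in at least
    ``min_count`` of the networks, re-indexing all networks.

    Edges with a removed endpoint are dropped. Raising ``min_count`` never
    adds genes (monotone filter).
    """
    if min_count < 1:
        raise ConfigurationError("min_count must be >= 1")
    degs = collection.degrees()  # (K, n)
    appears = (degs >= 1).sum(axis=0)
    keep = np.where(appears >= min_count)[0]
    if len(keep) == 0:
        raise ConfigurationError(
            f"no gene appears in >= {min_count} of {collection.K} networks"
        )
    old_universe = collection.universe
    new_universe = GeneUniverse(old_universe[int(i)] for i in keep)
    remap = -np.ones(len(old_universe), dtype=np.int64)
    remap[keep] = np.arange(len(keep))
    new_nets = []
    for net in collection:
        edges = [
            (int(remap[i]), int(remap[j]))
            for i, j in net.edges
            if remap[i] >= 0 and remap[j] >= 0
        ]
        new_nets.append(BioNetwork(net.name, edges, len(new_universe)))
    return NetworkCollection(new_universe, new_nets), new_universe


def merge_networks(collection: NetworkCollection, name: str = "merged") -> BioNetwork:
    """Unweighted union of all edge sets (the 'mixed network' used by
    single-network integration baselines)."""
    edges: set[tuple[int, int]] = set()
    for net in collection:
        edges |= net.edges
    return BioNetwork(name, edges, collection.n_genes)
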