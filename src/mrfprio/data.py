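"""Core domain containers: gene universe, networks, associations, complexes.

The gene universe fixes a 0-based integer index for every gene symbol;
all other objects store integer indices against one shared universe.
Gene identifiers are case-sensitive strings and no symbol aliasing is
attempted — identifier curation is a task upstream of this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import scipy.sparse as sp

from .errors import DimensionError, ResolutionError


class GeneUniverse:
    """Ordered, indexed set of gene symbols.

    Parameters
    ----------
    genes
        Iterable of unique, non-empty gene symbols. Order is preserved and
        defines the integer index of each gene.
    """

    def __init__(self, genes: Iterable[str] = ()):
        self._genes: list[str] = []
        self._index: dict[str, int] = {}
        for g in genes:
            self.add(g)

    def add(self, symbol: str) -> int:
        """Add ``symbol`` if absent; return its index."""
        if not symbol:
            raise ResolutionError("empty gene symbol")
        i = self._index.get(symbol)
        if i is None:
            i = len(self._genes)
            self._genes.append(symbol)
            self._index[symbol] = i
        return i

    @property
    def genes(self) -> list[str]:
        return list(self._genes)

    def index(self, symbol: str) -> int:
        try:
            return self._index[symbol]
        except KeyError:
            raise ResolutionError(f"unknown gene symbol: {symbol!r}") from None

    def indices(self, symbols: Iterable[str]) -> list[int]:
        return [self.index(s) for s in symbols]

    def __len__(self) -> int:
        return len(self._genes)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._index

    def __getitem__(self, i: int) -> str:
        return self._genes[i]

    def __iter__(self) -> Iterator[str]:
        return iter(self._genes)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, GeneUniverse) and self._genes == other._genes

    def __repr__(self) -> str:
        return f"GeneUniverse({len(self)} genes)"


def _canonical_edges(edges: Iterable[tuple[int, int]], n: int) -> frozenset[tuple[int, int]]:
    out = set()
    for i, j in edges:
        if not (0 <= i < n and 0 <= j < n):
            raise DimensionError(f"edge ({i},{j}) outside universe of size {n}")
        if i == j:
            continue  # self-loops are dropped
        out.add((i, j) if i < j else (j, i))
    return frozenset(out)


class BioNetwork:
    """Simple undirected graph over a gene universe.

    Edges are stored canonically as sorted index pairs; self-loops and
    duplicate edges are silently removed on construction.
    """

    def __init__(self, name: str, edges: Iterable[tuple[int, int]], n_genes: int):
        self.name = name
        self.n_genes = int(n_genes)
        self.edges = _canonical_edges(edges, self.n_genes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Endpoint index arrays (i, j) with i < j, in sorted order."""
        if not self.edges:
            return (np.empty(0, dtype=np.int64),) * 2
        e = np.array(sorted(self.edges), dtype=np.int64)
        return e[:, 0], e[:, 1]

    def adjacency(self) -> sp.csr_matrix:
        """Symmetric 0/1 adjacency as CSR."""
        i, j = self.edge_arrays()
        data = np.ones(2 * len(i), dtype=np.float64)
        a = sp.coo_matrix(
            (data, (np.concatenate([i, j]), np.concatenate([j, i]))),
            shape=(self.n_genes, self.n_genes),
        )
        return a.tocsr()

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_genes, dtype=np.int64)
        i, j = self.edge_arrays()
        np.add.at(deg, i, 1)
        np.add.at(deg, j, 1)
        return deg

    def neighbors(self, gene: int) -> np.ndarray:
        a = self.adjacency()
        return a.indices[a.indptr[gene]:a.indptr[gene + 1]]

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, BioNetwork)
            and self.n_genes == other.n_genes
            and self.edges == other.edges
        )

    def __repr__(self) -> str:
        return f"BioNetwork({self.name!r}, {self.n_genes} genes, {self.n_edges} edges)"


class NetworkCollection:
    """Ordered list of :class:`BioNetwork` sharing one :class:`GeneUniverse`."""

    def __init__(self, universe: GeneUniverse, networks: Sequence[BioNetwork]):
        if len(networks) < 1:
            raise DimensionError("a NetworkCollection needs at least one network")
        n = len(universe)
        for net in networks:
            if net.n_genes != n:
                raise DimensionError(
                    f"network {net.name!r} is over {net.n_genes} genes, universe has {n}"
                )
        self.universe = universe
        self.networks = list(networks)
        self._adj: list[sp.csr_matrix] | None = None

    @property
    def K(self) -> int:
        return len(self.networks)

    @property
    def n_genes(self) -> int:
        return len(self.universe)

    def adjacencies(self) -> list[sp.csr_matrix]:
        if self._adj is None:
            self._adj = [net.adjacency() for net in self.networks]
        return self._adj

    def degrees(self) -> np.ndarray:
        """(K, n) per-network degree matrix."""
        return np.stack([net.degrees() for net in self.networks])

    def __len__(self) -> int:
        return len(self.networks)

    def __iter__(self) -> Iterator[BioNetwork]:
        return iter(self.networks)

    def __getitem__(self, k: int) -> BioNetwork:
        return self.networks[k]

    def __repr__(self) -> str:
        return f"NetworkCollection(K={self.K}, n={self.n_genes})"


@dataclass
class DiseaseAssociationTable:
    """Map disease-class name -> set of gene indices (classes may overlap)."""

    classes: dict[str, frozenset[int]] = field(default_factory=dict)
    n_dropped: int = 0  # associations whose gene was outside the universe

    def all_disease_genes(self) -> frozenset[int]:
        out: set[int] = set()
        for genes in self.classes.values():
            out |= genes
        return frozenset(out)

    def __getitem__(self, name: str) -> frozenset[int]:
        return self.classes[name]


@dataclass
class ComplexSet:
    """Named protein complexes as gene-index sets (each of size >= 2)."""

    complexes: list[tuple[str, frozenset[int]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.complexes = [
            (name, frozenset(members)) for name, members in self.complexes
        ]
        for name, members in self.complexes:
            if len(members) < 2:
                raise DimensionError(
                    f"complex {name!r} has {len(members)} member(s); need >= 2"
                )

    def membership(self, gene: int) -> list[frozenset[int]]:
        return [m for _, m in self.complexes if gene in m]

    def __len__(self) -> int:
        return len(self.complexes)

    def __iter__(self):
        return iter(self.complexes)


@dataclass
class ExpressionMatrix:
    """genes x samples expression values; ``genes`` names the rows."""

    genes: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.genes):
            raise DimensionError("expression matrix shape does not match gene list")
        if np.isnan(self.values).any():
            raise DimensionError("expression matrix contains missing values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]
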