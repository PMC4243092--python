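"""Readers and writers for the plain-text interchange formats.

Edge lists are two-column (or more; extra columns ignored) whitespace- or
tab-delimited text, one edge per line. Gene sets use the GMT dialect
(name, description, members, tab-separated). Associations are two-column
TSV ``gene<TAB>class``. Expression is TSV with the gene symbol in the
first column and one column per sample.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .data import (
    BioNetwork,
    DiseaseAssociationTable,
    ExpressionMatrix,
    GeneUniverse,
)
from .errors import ParseError, ResolutionError

log = logging.getLogger(__name__)


def read_edge_list(
    path: str | Path,
    universe: GeneUniverse,
    universe_policy: str = "grow",
    name: str | None = None,
) -> BioNetwork:
    """Read an edge list into a :class:`BioNetwork` over ``universe``.

    ``universe_policy='grow'`` extends the universe with unseen symbols
    (in place); ``'strict'`` raises :class:`ResolutionError` for them.
    Self-loops are dropped and duplicate undirected edges collapsed.
    """
    if universe_policy not in ("grow", "strict"):
        raise ValueError(f"unknown universe_policy: {universe_policy!r}")
    edges: list[tuple[int, int]] = []
    path = Path(path)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ParseError(f"expected >= 2 columns, got {len(fields)}", lineno)
            a, b = fields[0], fields[1]
            if universe_policy == "strict":
                if a not in universe:
                    raise ResolutionError(f"line {lineno}: unknown gene symbol {a!r}")
                if b not in universe:
                    raise ResolutionError(f"line {lineno}: unknown gene symbol {b!r}")
                ia, ib = universe.index(a), universe.index(b)
            else:
                ia, ib = universe.add(a), universe.add(b)
            edges.append((ia, ib))
    return BioNetwork(name or path.stem, edges, len(universe))


def write_edge_list(network: BioNetwork, universe: GeneUniverse, path: str | Path) -> None:
    """Write the canonical (deduplicated, loop-free) edge set as 2-column TSV."""
    with open(path, "w") as fh:
        for i, j in sorted(network.edges):
            fh.write(f"{universe[i]}\t{universe[j]}\n")


def read_gene_sets(path: str | Path) -> list[tuple[str, list[str]]]:
    """Read a GMT file as a list of (name, members); member lists deduplicated
    preserving first occurrence, file order preserved for names."""
    out: list[tuple[str, list[str]]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"GMT line needs name, description and >= 1 member "
                    f"({len(fields)} field(s) found)",
                    lineno,
                )
            name = fields[0]
            members = list(dict.fromkeys(m for m in fields[2:] if m))
            out.append((name, members))
    return out


def write_gene_sets(sets: Iterable[tuple[str, Iterable[str]]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in sets:
            fh.write("\t".join([name, "na", *members]) + "\n")


def read_associations(path: str | Path, universe: GeneUniverse) -> DiseaseAssociationTable:
    """Read a 2-column TSV of (gene, disease class).

    Genes absent from the universe are dropped; the number of dropped rows
    is logged and recorded on the returned table.
    """
    classes: dict[str, set[int]] = {}
    dropped = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 2:
                raise ParseError(f"expected 2 columns, got {len(fields)}", lineno)
            gene, klass = fields[0], fields[1]
            if not klass:
                raise ParseError("empty disease-class name", lineno)
            if gene not in universe:
                dropped += 1
                continue
            classes.setdefault(klass, set()).add(universe.index(gene))
    if dropped:
        log.warning("read_associations: dropped %d association(s) to genes "
                    "outside the universe", dropped)
    return DiseaseAssociationTable(
        classes={k: frozenset(v) for k, v in classes.items()}, n_dropped=dropped
    )


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a genes x samples TSV (first column = gene symbol).

    Rows containing missing values are rejected (dropped with a logged count).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    n_bad = int(df.isna().any(axis=1).sum())
    if n_bad:
        log.warning("read_expression: dropping %d row(s) with missing values", n_bad)
        df = df.dropna(axis=0)
    return ExpressionMatrix(genes=[str(g) for g in df.index], values=df.to_numpy(float))


def write_ranking(result, universe: GeneUniverse, path: str | Path) -> None:
    """Write a ranking TSV: gene, known_flag, prior, posterior, decision_score.

    Rows are sorted by decision score descending with a deterministic
    lexicographic tie-break on the gene symbol. Known (clamped) genes carry
    posterior 1 and decision score 1.
    """
    frame = result.to_frame(universe)
    frame = frame.sort_values(
        ["decision_score", "gene"], ascending=[False, True], kind="mergesort"
    )
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")
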