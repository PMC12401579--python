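"""Hallmark gene sets, interaction networks, and normalized graph operators.

Ten cancer hallmarks are each represented by a gene set (GMT file) and by the
subgraph of a curated functional-interaction network restricted to that set.
All hallmark networks share one node universe -- the genes that belong to at
least one hallmark set *and* have expression values -- so their adjacency
matrices have identical dimension and can be stacked into a tensor.

The message-passing operator for a hallmark is the residual-augmented
symmetric normalization

    A_bar = I + D^(-1/2) A D^(-1/2)

where ``A`` is the binary undirected adjacency and ``D`` the degree matrix.
Genes with no within-hallmark neighbors get ``D^(-1/2) = 0`` by convention,
so their operator row is the identity row and their embedded feature is their
own expression value (the residual connection).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)

MAX_HALLMARKS_DEFAULT = None  # no hard cap; the canonical analysis uses 10


def _canon(symbol: str) -> str:
    """Canonicalize a gene symbol: trim whitespace, upper-case.

    Exact case-insensitive matching only; no alias resolution.
    """
    return symbol.strip().upper()


@dataclass(frozen=True)
class GeneUniverse:
    """Ordered shared gene index for every matrix in the pipeline."""

    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("GeneUniverse contains duplicate gene symbols")

    def __len__(self) -> int:
        return len(self.genes)

    def index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}


@dataclass(frozen=True)
class HallmarkGeneSets:
    """Mapping hallmark id (0..H-1) -> gene-symbol set, plus hallmark names."""

    names: tuple[str, ...]
    sets: tuple[frozenset[str], ...]

    @property
    def n_hallmarks(self) -> int:
        return len(self.sets)

    def union(self) -> frozenset[str]:
        out: set[str] = set()
        for s in self.sets:
            out |= s
        return frozenset(out)


@dataclass(frozen=True)
class HallmarkNetwork:
    """Undirected binary gene-gene graph for one hallmark, over the full universe."""

    hallmark_id: int
    universe: GeneUniverse
    adjacency: sp.csr_matrix  # symmetric, zero diagonal, binary
    degrees: np.ndarray

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.nnz // 2)


@dataclass(frozen=True)
class NormalizedAdjacency:
    """The operator I + D^(-1/2) A D^(-1/2) for one hallmark network."""

    hallmark_id: int
    universe: GeneUniverse
    matrix: sp.csr_matrix

    def dense(self) -> np.ndarray:
        return np.asarray(self.matrix.todense())


def load_gene_sets(path: str | Path) -> HallmarkGeneSets:
    """Parse a GMT file (name, description, member genes per tab-separated line).

    Raises ``ValueError`` on an empty file, duplicate set names, or a line with
    zero genes, naming the offending line.
    """
    path = Path(path)
    names: list[str] = []
    sets: list[frozenset[str]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line has no member genes "
                    f"(need name, description, >=1 gene)"
                )
            name = fields[0].strip()
            genes = frozenset(_canon(g) for g in fields[2:] if g.strip())
            if not genes:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} is empty")
            if name in names:
                raise ValueError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            names.append(name)
            sets.append(genes)
    if not names:
        raise ValueError(f"{path}: GMT file contains no gene sets")
    return HallmarkGeneSets(names=tuple(names), sets=tuple(sets))


def load_edge_list(path: str | Path) -> list[tuple[str, str]]:
    """Read a 2-column TSV of directed gene-gene interactions.

    An optional header line (detected when the first row repeats on neither
    side as a gene pair elsewhere is fragile, so detection is simply: a first
    line whose lower-cased fields look like column names) is skipped.  A third
    column (interaction type) is ignored.  Duplicate pairs after
    canonicalization and self-edges are removed; direction is kept as read.
    """
    path = Path(path)
    header_tokens = {"source", "target", "gene1", "gene2", "from", "to", "genea", "geneb"}
    edges: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    n_self = 0
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected >= 2 tab-separated columns")
            a, b = _canon(fields[0]), _canon(fields[1])
            if lineno == 1 and (a.lower() in header_tokens or b.lower() in header_tokens):
                continue
            if a == b:
                n_self += 1
                continue
            if (a, b) in seen:
                continue
            seen.add((a, b))
            edges.append((a, b))
    if n_self:
        logger.info("dropped %d self-edges from %s", n_self, path)
    return edges


def build_universe(
    sets: HallmarkGeneSets, expression_genes: Sequence[str]
) -> GeneUniverse:
    """Intersect the union of hallmark sets with the expression-matrix genes.

    Order follows first appearance in the expression matrix, so every
    downstream matrix row index matches the expression rows.
    """
    if sets.n_hallmarks == 0 or len(expression_genes) == 0:
        raise ValueError("gene sets and expression genes must be non-empty")
    union = sets.union()
    seen: set[str] = set()
    ordered: list[str] = []
    for g in expression_genes:
        cg = _canon(g)
        if cg in union and cg not in seen:
            seen.add(cg)
            ordered.append(cg)
    if not ordered:
        raise ValueError(
            "no overlap between hallmark gene sets and expression genes"
        )
    return GeneUniverse(genes=tuple(ordered))


def build_hallmark_network(
    universe: GeneUniverse,
    sets: HallmarkGeneSets,
    edges: Iterable[tuple[str, str]],
    hallmark_id: int,
    *,
    restrict_to_set: bool = True,
) -> HallmarkNetwork:
    """Project the directed edge list onto one hallmark's undirected subgraph.

    An undirected edge {i, j} exists iff (i, j) or (j, i) appears in the edge
    list, both genes are in the universe, and (when ``restrict_to_set``, the
    default) both belong to the hallmark's gene set.  Genes outside the set
    remain isolated nodes so all hallmark networks share the same dimension.
    Edge endpoints absent from the universe are dropped and counted in a log
    summary.
    """
    if not 0 <= hallmark_id < sets.n_hallmarks:
        raise ValueError(f"hallmark_id {hallmark_id} out of range 0..{sets.n_hallmarks - 1}")
    idx = universe.index()
    members = sets.sets[hallmark_id] if restrict_to_set else frozenset(universe.genes)
    rows: list[int] = []
    cols: list[int] = []
    n_dropped = 0
    pair_seen: set[tuple[int, int]] = set()
    for a, b in edges:
        a, b = _canon(a), _canon(b)
        if a not in idx or b not in idx:
            n_dropped += 1
            continue
        if a not in members or b not in members:
            continue
        i, j = idx[a], idx[b]
        if i == j:
            continue
        key = (min(i, j), max(i, j))
        if key in pair_seen:
            continue
        pair_seen.add(key)
        rows.extend((key[0], key[1]))
        cols.extend((key[1], key[0]))
    if n_dropped:
        logger.info(
            "hallmark %d: dropped %d edges with endpoints outside the universe",
            hallmark_id,
            n_dropped,
        )
    n = len(universe)
    data = np.ones(len(rows), dtype=np.float64)
    adjacency = sp.csr_matrix((data, (rows, cols)), shape=(n, n))
    degrees = np.asarray(adjacency.sum(axis=1)).ravel()
    return HallmarkNetwork(
        hallmark_id=hallmark_id, universe=universe, adjacency=adjacency, degrees=degrees
    )


def normalize_adjacency(net: HallmarkNetwork) -> NormalizedAdjacency:
    """Compute A_bar = I + D^(-1/2) A D^(-1/2) with the degree-0 convention.

    Degree-0 genes take ``D^(-1/2) = 0`` so their row is exactly the identity
    row: an isolated gene's embedded feature is its own expression value.
    """
    n = len(net.universe)
    with np.errstate(divide="ignore"):
        d_inv_sqrt = np.where(net.degrees > 0, 1.0 / np.sqrt(net.degrees), 0.0)
    dmat = sp.diags(d_inv_sqrt)
    norm = dmat @ net.adjacency @ dmat
    matrix = sp.identity(n, format="csr") + norm.tocsr()
    return NormalizedAdjacency(
        hallmark_id=net.hallmark_id, universe=net.universe, matrix=matrix
    )


def export_sif(net: HallmarkNetwork, path: str | Path, relation: str = "interacts") -> None:
    """Write the hallmark network as a SIF file (gene relation gene per edge)."""
    genes = net.universe.genes
    coo = sp.triu(net.adjacency, k=1).tocoo()
    with Path(path).open("w") as fh:
        for i, j in zip(coo.row, coo.col):
            fh.write(f"{genes[i]}\t{relation}\t{genes[j]}\n")


def export_edge_tsv(net: HallmarkNetwork, path: str | Path) -> None:
    """Write the hallmark network as a 2-column TSV edge list with header."""
    genes = net.universe.genes
    coo = sp.triu(net.adjacency, k=1).tocoo()
    with Path(path).open("w") as fh:
        fh.write("gene_a\tgene_b\n")
        for i, j in zip(coo.row, coo.col):
            fh.write(f"{genes[i]}\t{genes[j]}\n")


def build_all_networks(
    universe: GeneUniverse,
    sets: HallmarkGeneSets,
    edges: Iterable[tuple[str, str]],
    *,
    restrict_to_set: bool = True,
) -> list[HallmarkNetwork]:
    """Build one hallmark network per gene set over the shared universe."""
    edges = list(edges)
    return [
        build_hallmark_network(universe, sets, edges, h, restrict_to_set=restrict_to_set)
        for h in range(sets.n_hallmarks)
    ]
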