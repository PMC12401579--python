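"""Graph-convolutional embedding of expression into a gene x hallmark x sample tensor.

For each hallmark network the embedding applies

    f(H, A_bar) = sigma(A_bar @ H @ W)

where ``A_bar = I + D^(-1/2) A D^(-1/2)`` is the residual-augmented
normalized adjacency, ``H`` the genes x samples input (initially the
log2(TPM+1) expression matrix), ``W`` a weight matrix and ``sigma`` an
activation.  The canonical configuration uses one aggregation layer, an
identity ``W`` (each gene's feature is its own expression plus the
degree-normalized sum of its neighbors' expression) and ReLU -- which on
non-negative expression input is the identity, so the default embedding is
exactly ``A_bar @ X`` per hallmark.

Stacking the H per-hallmark matrices yields the 3-D tensor consumed by the
classifiers; the flattening order into the dense head is gene-major,
hallmark-minor (feature index = gene_index * H + hallmark_index).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from hallmarkgraph.knowledge_graph import GeneUniverse, NormalizedAdjacency


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x samples matrix on the log2(TPM+1) scale, rows in universe order."""

    values: np.ndarray
    genes: tuple[str, ...]
    sample_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.genes), len(self.sample_ids)):
            raise ValueError(
                f"expression shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.sample_ids)} samples"
            )
        if np.isnan(self.values).any():
            raise ValueError("expression matrix contains missing values")

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return ExpressionMatrix(
            values=self.values[:, idx],
            genes=self.genes,
            sample_ids=tuple(sample_ids),
        )

    def restrict_genes(self, universe: GeneUniverse) -> "ExpressionMatrix":
        pos = {g: i for i, g in enumerate(self.genes)}
        idx = [pos[g] for g in universe.genes]
        return ExpressionMatrix(
            values=self.values[idx, :],
            genes=universe.genes,
            sample_ids=self.sample_ids,
        )


def load_expression(path: str | Path) -> ExpressionMatrix:
    """Read a genes x samples TSV/CSV with gene symbols in the first column
    and sample ids in the header."""
    import pandas as pd

    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    return ExpressionMatrix(
        values=df.to_numpy(dtype=np.float64),
        genes=tuple(str(g).strip().upper() for g in df.index),
        sample_ids=tuple(str(s) for s in df.columns),
    )


@dataclass(frozen=True)
class EmbeddingSpec:
    """Configuration of the graph aggregation.

    weight_mode:
        "identity" (default) -- W is the identity; the feature is the plain
        degree-normalized neighbor-expression sum with residual.
        "scalar" -- W = scalar * I with the given ``scalar_weight``.
        "dense"  -- a fixed square matrix ``dense_weight`` applied on the
        sample/feature axis.
    """

    n_layers: int = 1
    weight_mode: str = "identity"
    activation: str = "relu"
    scalar_weight: float = 1.0
    dense_weight: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        if self.weight_mode not in ("identity", "scalar", "dense"):
            raise ValueError(f"unknown weight_mode {self.weight_mode!r}")
        if self.activation not in ("relu", "none"):
            raise ValueError(f"unknown activation {self.activation!r}")
        if self.weight_mode == "dense" and self.dense_weight is None:
            raise ValueError("dense weight_mode requires dense_weight")


def _apply_weight(h: np.ndarray, spec: EmbeddingSpec) -> np.ndarray:
    if spec.weight_mode == "identity":
        return h
    if spec.weight_mode == "scalar":
        return h * spec.scalar_weight
    return h @ spec.dense_weight


def _activate(h: np.ndarray, spec: EmbeddingSpec) -> np.ndarray:
    if spec.activation == "relu":
        return np.maximum(h, 0.0)
    return h


def embed(
    X: ExpressionMatrix,
    adjacencies: Sequence[NormalizedAdjacency],
    spec: EmbeddingSpec = EmbeddingSpec(),
) -> np.ndarray:
    """Compute the gene x hallmark x sample embedding tensor.

    Each hallmark slice is ``sigma(A_bar_h @ H @ W)`` applied ``n_layers``
    times starting from the expression matrix.  Raises on a dimension
    mismatch between the adjacency operators and the expression rows.
    """
    n_genes, n_samples = X.values.shape
    for adj in adjacencies:
        if adj.matrix.shape != (n_genes, n_genes):
            raise ValueError(
                f"adjacency for hallmark {adj.hallmark_id} has shape "
                f"{adj.matrix.shape}, expected ({n_genes}, {n_genes})"
            )
        if adj.universe.genes != X.genes:
            raise ValueError(
                f"adjacency universe for hallmark {adj.hallmark_id} does not "
                "match the expression gene order"
            )
    tensor = np.empty((n_genes, len(adjacencies), n_samples), dtype=np.float64)
    for h, adj in enumerate(adjacencies):
        cur = X.values
        for _ in range(spec.n_layers):
            cur = _activate(adj.matrix @ _apply_weight(cur, spec), spec)
        tensor[:, h, :] = cur
    return tensor


def flatten_tensor(tensor: np.ndarray) -> np.ndarray:
    """Flatten a gene x hallmark x sample tensor to samples x features.

    Feature order is gene-major, hallmark-minor: feature ``g * H + h`` is
    gene ``g`` in hallmark slice ``h``.  This order is fixed so attributions
    map back to (gene, hallmark) pairs unambiguously.
    """
    n_genes, n_hallmarks, n_samples = tensor.shape
    return tensor.transpose(2, 0, 1).reshape(n_samples, n_genes * n_hallmarks)


def feature_index(gene_index: int, hallmark_index: int, n_hallmarks: int) -> int:
    """Flattened feature index of (gene, hallmark) under the fixed layout."""
    return gene_index * n_hallmarks + hallmark_index
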