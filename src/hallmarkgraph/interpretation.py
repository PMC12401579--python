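"""Shapley-value attribution of classifier decisions to genes and hallmarks.

The explainer is a model-agnostic permutation-sampling estimator of Shapley
values: for each sample to explain, features are inserted one by one in a
random order into a background reference, and each feature's marginal change
of the class probability is its contribution for that permutation.  Averaged
over permutations (with backgrounds resampled per permutation) the estimate
converges to the exact Shapley value; for a linear model a single
permutation is already exact per background draw, so the estimator can be
verified against the closed form  phi_i = w_i (x_i - E[x_i]).

Attribution scores are organized per (gene, hallmark) feature of the
embedding tensor, summarized as the mean absolute value over explained
samples and output classes.  Gene-level scores (summed over hallmark
copies) are normalized to total 1 per classifier before ranking; hallmark
contributions divide the summed per-hallmark attribution by the hallmark's
gene count and are then min-max normalized across hallmarks.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from hallmarkgraph.embedding import ExpressionMatrix
from hallmarkgraph.knowledge_graph import GeneUniverse, HallmarkGeneSets


def sampling_shapley(
    predict_fn: Callable[[np.ndarray], np.ndarray],
    background: np.ndarray,
    X: np.ndarray,
    *,
    n_permutations: int = 10,
    rng: np.random.Generator,
) -> np.ndarray:
    """Permutation-sampling Shapley values.

    ``predict_fn`` maps an (n, F) matrix to (n, C) outputs.  Returns an
    (n_explain, F, C) array of estimated Shapley values of each feature for
    each output, relative to the background distribution.  Cost is
    ``n_explain * n_permutations`` batched forward passes of F+1 rows each.
    """
    if len(background) == 0:
        raise ValueError("background set is empty")
    X = np.atleast_2d(X)
    n_explain, F = X.shape
    probe = predict_fn(X[:1])
    C = probe.shape[1]
    phi = np.zeros((n_explain, F, C))
    for s in range(n_explain):
        x = X[s]
        for _ in range(n_permutations):
            b = background[rng.integers(len(background))]
            order = rng.permutation(F)
            pos = np.empty(F, dtype=int)
            pos[order] = np.arange(F)
            # row i activates the first i features of the permutation
            on = pos[None, :] < np.arange(F + 1)[:, None]
            Z = np.where(on, x[None, :], b[None, :])
            out = predict_fn(Z)
            contrib = out[1:] - out[:-1]  # (F, C), row i -> feature order[i]
            phi[s, order] += contrib
    phi /= n_permutations
    return phi


def linear_shapley(
    weights: np.ndarray, background: np.ndarray, X: np.ndarray
) -> np.ndarray:
    """Closed-form Shapley values for a linear model f(x) = x @ w + b:
    phi_i = w_i * (x_i - mean_background_i).  Shapes: (F, C) weights,
    (n, F) inputs -> (n, F, C)."""
    delta = X - background.mean(axis=0)
    return delta[:, :, None] * weights[None, :, :]


@dataclass(frozen=True)
class AttributionMatrix:
    """Mean absolute Shapley value per (gene, hallmark) feature of one classifier."""

    values: np.ndarray  # (n_genes, n_hallmarks), >= 0
    genes: tuple[str, ...]
    n_background: int
    n_explained: int

    def __post_init__(self) -> None:
        if (self.values < 0).any():
            raise ValueError("attribution magnitudes must be non-negative")

    @property
    def n_hallmarks(self) -> int:
        return self.values.shape[1]

    def gene_scores(self, *, normalized: bool = True) -> dict[str, float]:
        """Per-gene score: sum over the gene's hallmark copies; normalized
        scores total 1 across genes (the classifier's attribution budget)."""
        raw = self.values.sum(axis=1)
        if normalized:
            total = raw.sum()
            if total > 0:
                raw = raw / total
        return dict(zip(self.genes, raw.tolist()))


def attribute(
    predict_fn: Callable[[np.ndarray], np.ndarray],
    background: np.ndarray,
    explain: np.ndarray,
    *,
    genes: Sequence[str],
    n_hallmarks: int,
    n_permutations: int = 10,
    max_background: int = 100,
    rng: np.random.Generator | None = None,
) -> AttributionMatrix:
    """Mean absolute Shapley value per (gene, hallmark) feature.

    ``background`` and ``explain`` are samples x features matrices in the
    fixed gene-major, hallmark-minor layout.  The background is subsampled
    to ``max_background`` rows; attributions are averaged over explained
    samples and output classes.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    if len(background) == 0:
        raise ValueError("background set is empty")
    if len(background) > max_background:
        keep = rng.choice(len(background), size=max_background, replace=False)
        background = background[keep]
    phi = sampling_shapley(
        predict_fn, background, explain, n_permutations=n_permutations, rng=rng
    )
    mean_abs = np.abs(phi).mean(axis=(0, 2))  # (F,)
    values = mean_abs.reshape(len(genes), n_hallmarks)
    return AttributionMatrix(
        values=values,
        genes=tuple(genes),
        n_background=len(background),
        n_explained=len(explain),
    )


@dataclass(frozen=True)
class GeneRanking:
    """Genes ordered by descending attribution score; ties alphabetical."""

    genes: tuple[str, ...]
    scores: tuple[float, ...]

    def top(self, k: int) -> tuple[str, ...]:
        return self.genes[:k]


def rank_genes(attr: AttributionMatrix) -> GeneRanking:
    """Rank genes by normalized gene-level attribution (sum over hallmark
    copies, scaled to total 1); ties break alphabetically by symbol."""
    scores = attr.gene_scores(normalized=True)
    ordered = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    return GeneRanking(
        genes=tuple(g for g, _ in ordered),
        scores=tuple(s for _, s in ordered),
    )


@dataclass(frozen=True)
class HallmarkContribution:
    """Per-hallmark attribution rollup: raw mean and min-max normalized score."""

    raw: tuple[float, ...]
    normalized: tuple[float, ...]


def hallmark_contribution(
    attr: AttributionMatrix, sets: HallmarkGeneSets, universe: GeneUniverse | None = None
) -> HallmarkContribution:
    """Summed per-hallmark attribution divided by the hallmark's gene count,
    then min-max normalized across hallmarks.

    The gene count is the hallmark set intersected with the analysis
    universe (only those genes carry features).  When all raw values are
    equal the normalized scores are all 0 by convention.
    """
    if sets.n_hallmarks != attr.n_hallmarks:
        raise ValueError("gene-set count does not match attribution hallmark count")
    gene_pool = set(universe.genes) if universe is not None else set(attr.genes)
    raw = []
    for h in range(sets.n_hallmarks):
        count = len(sets.sets[h] & gene_pool)
        if count == 0:
            raise ValueError(f"hallmark {h} has no genes in the universe")
        raw.append(float(attr.values[:, h].sum()) / count)
    raw_arr = np.asarray(raw)
    lo, hi = raw_arr.min(), raw_arr.max()
    if hi > lo:
        norm = (raw_arr - lo) / (hi - lo)
    else:
        norm = np.zeros_like(raw_arr)
    return HallmarkContribution(raw=tuple(raw_arr.tolist()), normalized=tuple(norm.tolist()))


def top_gene_overlap(
    rankings: Sequence[GeneRanking], k: int = 2000
) -> np.ndarray:
    """Pairwise fraction of shared genes among the top-k of each ranking.

    ``overlap[i, j] = |top_k(i) & top_k(j)| / k``; symmetric with unit
    diagonal.
    """
    for r in rankings:
        if k > len(r.genes):
            raise ValueError(f"k={k} exceeds ranking size {len(r.genes)}")
    tops = [set(r.top(k)) for r in rankings]
    n = len(tops)
    out = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = len(tops[i] & tops[j]) / k
    return out


def gene_correlation(X: ExpressionMatrix, genes: Sequence[str]) -> np.ndarray:
    """Pearson correlation of the given genes' expression across samples.

    Zero-variance genes produce NaN rows/columns (correlation undefined).
    Requires at least 3 samples.
    """
    pos = {g: i for i, g in enumerate(X.genes)}
    missing = [g for g in genes if g not in pos]
    if missing:
        raise ValueError(f"genes {missing} not in the expression universe")
    if len(X.sample_ids) < 3:
        raise ValueError("need at least 3 samples for correlation")
    sub = X.values[[pos[g] for g in genes], :]
    sd = sub.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(sub)
    corr = np.atleast_2d(corr)
    corr[sd == 0, :] = np.nan
    corr[:, sd == 0] = np.nan
    np.fill_diagonal(corr, np.where(sd > 0, 1.0, np.nan))
    return corr


def write_attribution_tsv(attr: AttributionMatrix, path: str | Path) -> None:
    """Export per-(gene, hallmark) scores as a TSV (gene, hallmark, score)."""
    with Path(path).open("w") as fh:
        fh.write("gene\thallmark\tscore\n")
        for gi, gene in enumerate(attr.genes):
            for h in range(attr.n_hallmarks):
                fh.write(f"{gene}\t{h}\t{attr.values[gi, h]:.10g}\n")
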