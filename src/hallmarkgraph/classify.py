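"""Per-tier classifiers: architectures, splits, training protocol, cross-validation.

Three architectures share one dense softmax head:

* ``hallmarkgraph`` -- the flattened gene x hallmark embedding tensor feeds
  the head directly (the graph aggregation has no learned weights);
* ``mlp_baseline``  -- the raw genes x samples expression feeds the head;
* ``cnn_baseline``  -- ten 1x1 convolution kernels (one per hallmark, 'same'
  padding) over the flattened tensor, then the head.

The head depth is 3 (512 -> 256 -> C), 2 (256 -> C) or 1 (C), where C is
the label count of the tier.  Training follows a fixed protocol: Adam with
learning rate 1e-3, batch size 200, at most 200 epochs, early stopping after
5 consecutive epochs without decline of the training loss, categorical
cross-entropy.  Model selection across stratified k-fold cross-validation
repeats uses balanced accuracy.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split

from hallmarkgraph import nn
from hallmarkgraph.embedding import EmbeddingSpec, ExpressionMatrix, embed, flatten_tensor
from hallmarkgraph.evaluation import compute_metrics
from hallmarkgraph.knowledge_graph import NormalizedAdjacency
from hallmarkgraph.label_hierarchy import LevelDataset

ARCHITECTURES = ("hallmarkgraph", "mlp_baseline", "cnn_baseline")

_HIDDEN_BY_DEPTH = {3: (512, 256), 2: (256,), 1: ()}


@dataclass(frozen=True)
class ClassifierConfig:
    architecture: str = "hallmarkgraph"
    mlp_depth: int = 3
    hidden_sizes: tuple[int, ...] | None = None
    n_labels: int = 2
    conv_kernels: int = 10

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.mlp_depth not in _HIDDEN_BY_DEPTH:
            raise ValueError(f"mlp_depth must be 1, 2 or 3, got {self.mlp_depth}")
        if self.n_labels < 2:
            raise ValueError("need at least 2 labels")
        if self.hidden_sizes is not None and len(self.hidden_sizes) != self.mlp_depth - 1:
            raise ValueError(
                f"hidden_sizes {self.hidden_sizes} inconsistent with "
                f"mlp_depth {self.mlp_depth}"
            )

    @property
    def hidden(self) -> tuple[int, ...]:
        return self.hidden_sizes if self.hidden_sizes is not None else _HIDDEN_BY_DEPTH[self.mlp_depth]

    @property
    def layer_sizes(self) -> tuple[int, ...]:
        return self.hidden + (self.n_labels,)


@dataclass(frozen=True)
class TrainingConfig:
    learning_rate: float = 1e-3
    batch_size: int = 200
    max_epochs: int = 200
    patience: int = 5
    min_delta: float = 1e-4
    train_fraction: float = 0.6
    test_fraction: float = 0.4
    cv_folds: int = 5
    repeats: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.train_fraction + self.test_fraction - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")


def build_classifier(cfg: ClassifierConfig, input_dim: int, seed: int = 0) -> nn.Network:
    """Construct an untrained network for the given architecture.

    ``input_dim`` is the flattened feature count (genes x hallmarks for the
    tensor-consuming architectures, genes for the raw-expression baseline).
    """
    rng = np.random.default_rng(seed)
    layers: list = []
    dense_in = input_dim
    if cfg.architecture == "cnn_baseline":
        layers.append(nn.Conv1x1(cfg.conv_kernels, rng))
        layers.append(nn.ReLU())
        dense_in = input_dim * cfg.conv_kernels
    for size in cfg.hidden:
        layers.append(nn.Dense(dense_in, size, rng))
        layers.append(nn.ReLU())
        dense_in = size
    layers.append(nn.Dense(dense_in, cfg.n_labels, rng))
    return nn.Network(layers)


def features_for(
    architecture: str,
    X: ExpressionMatrix,
    adjacencies: Sequence[NormalizedAdjacency],
    spec: EmbeddingSpec = EmbeddingSpec(),
) -> np.ndarray:
    """Samples x features design matrix for an architecture."""
    if architecture == "mlp_baseline":
        return X.values.T.copy()
    return flatten_tensor(embed(X, adjacencies, spec))


def stratified_split(
    dataset: LevelDataset,
    fractions: tuple[float, float] = (0.6, 0.4),
    seed: int = 0,
) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """Stratified train/test split of a level dataset by its tier labels.

    Per-label proportions in each part are within one sample of the target
    fraction; the split is disjoint, exhaustive, and deterministic given the
    seed.  A label with a single sample is an upstream cleaning defect.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    labels = np.asarray(dataset.labels)
    values, counts = np.unique(labels, return_counts=True)
    singletons = values[counts < 2]
    if len(singletons):
        raise ValueError(
            f"labels {list(singletons)} have a single sample; run filter_cohort "
            "(singleton demotion) before splitting"
        )
    idx = np.arange(len(dataset))
    train_idx, test_idx = train_test_split(
        idx,
        train_size=fractions[0],
        stratify=labels,
        random_state=seed,
        shuffle=True,
    )
    ids = np.asarray(dataset.sample_ids)
    return tuple(ids[np.sort(train_idx)]), tuple(ids[np.sort(test_idx)])


@dataclass
class TrainedClassifier:
    """A fitted per-tier softmax classifier plus its training provenance."""

    level: int
    architecture: str
    net: nn.Network
    vocabulary: tuple[str, ...]
    genes: tuple[str, ...]
    embedding_spec: EmbeddingSpec
    history: list[float] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)
    scaler_mean: np.ndarray | None = None
    scaler_sd: np.ndarray | None = None

    @property
    def n_labels(self) -> int:
        return len(self.vocabulary)

    def transform(self, features: np.ndarray) -> np.ndarray:
        """Apply the per-feature standardization fitted on the training split."""
        if self.scaler_mean is None:
            return features
        return (features - self.scaler_mean) / self.scaler_sd

    def predict_proba_features(self, features: np.ndarray) -> np.ndarray:
        return self.net.predict_proba(self.transform(features))

    def predict_features(self, features: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Probabilities and argmax label indices for a feature matrix.

        Ties resolve to the lowest vocabulary index (numpy argmax semantics).
        """
        probs = self.predict_proba_features(features)
        return probs, probs.argmax(axis=1)


def train(
    cfg: ClassifierConfig,
    features: np.ndarray,
    labels: Sequence[str],
    training: TrainingConfig = TrainingConfig(),
    *,
    level: int = 1,
    genes: tuple[str, ...] = (),
    embedding_spec: EmbeddingSpec = EmbeddingSpec(),
    vocabulary: tuple[str, ...] | None = None,
    seed: int | None = None,
) -> TrainedClassifier:
    """Fit one classifier on a samples x features matrix and string labels."""
    if len(features) == 0:
        raise ValueError("empty training data")
    vocab = vocabulary if vocabulary is not None else tuple(sorted(set(labels)))
    label_to_idx = {lab: i for i, lab in enumerate(vocab)}
    y = np.asarray([label_to_idx[lab] for lab in labels])
    seed = training.seed if seed is None else seed
    cfg = ClassifierConfig(
        architecture=cfg.architecture,
        mlp_depth=cfg.mlp_depth,
        hidden_sizes=cfg.hidden_sizes,
        n_labels=len(vocab),
        conv_kernels=cfg.conv_kernels,
    )
    # standardize per feature on the training split; conditions the loss
    # surface so the fixed learning rate is stable across input scales
    mu = features.mean(axis=0)
    sd = features.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    net = build_classifier(cfg, features.shape[1], seed=seed)
    rng = np.random.default_rng(seed + 1)
    result = nn.fit(
        net,
        (features - mu) / sd,
        y,
        n_classes=len(vocab),
        lr=training.learning_rate,
        batch_size=training.batch_size,
        max_epochs=training.max_epochs,
        patience=training.patience,
        min_delta=training.min_delta,
        rng=rng,
    )
    return TrainedClassifier(
        level=level,
        architecture=cfg.architecture,
        net=net,
        vocabulary=vocab,
        genes=genes,
        embedding_spec=embedding_spec,
        history=result.history,
        provenance={
            "seed": seed,
            "n_epochs": result.n_epochs,
            "stopped_early": result.stopped_early,
            "n_train": int(len(features)),
        },
        scaler_mean=mu,
        scaler_sd=sd,
    )


def predict(
    classifier: TrainedClassifier,
    X: ExpressionMatrix,
    adjacencies: Sequence[NormalizedAdjacency],
) -> tuple[np.ndarray, list[str]]:
    """Per-sample label probabilities and argmax labels for new expression.

    The expression gene order must equal the classifier's training universe;
    no silent reindexing is performed.
    """
    if classifier.genes and X.genes != classifier.genes:
        raise ValueError(
            "expression gene order differs from the classifier's universe; "
            "restrict/reorder genes explicitly before predicting"
        )
    features = features_for(
        classifier.architecture, X, adjacencies, classifier.embedding_spec
    )
    probs, idx = classifier.predict_features(features)
    return probs, [classifier.vocabulary[i] for i in idx]


@dataclass
class CrossValidationResult:
    fold_metrics: list[dict]
    summary: dict[str, tuple[float, float]]
    best: TrainedClassifier
    best_fold: dict


def cross_validate(
    cfg: ClassifierConfig,
    features: np.ndarray,
    labels: Sequence[str],
    training: TrainingConfig = TrainingConfig(),
    *,
    level: int = 1,
    genes: tuple[str, ...] = (),
    embedding_spec: EmbeddingSpec = EmbeddingSpec(),
) -> CrossValidationResult:
    """Repeated stratified k-fold cross-validation with balanced-accuracy
    model selection.

    Each repeat reshuffles the folds with a derived seed; per-fold test
    metrics are aggregated to mean +/- SD and the fold model with the highest
    balanced accuracy is returned as the best model.
    """
    if training.cv_folds < 2:
        raise ValueError("need at least 2 folds")
    labels = np.asarray(labels)
    vocab = tuple(sorted(set(labels)))
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < training.cv_folds:
        warnings.warn(
            "some label has fewer samples than folds; folds may miss classes",
            stacklevel=2,
        )
    fold_metrics: list[dict] = []
    best: TrainedClassifier | None = None
    best_fold: dict = {}
    best_balacc = -np.inf
    for repeat in range(training.repeats):
        seed = training.seed + 1000 * repeat
        skf = StratifiedKFold(
            n_splits=training.cv_folds, shuffle=True, random_state=seed
        )
        for fold, (train_idx, test_idx) in enumerate(skf.split(features, labels)):
            clf = train(
                cfg,
                features[train_idx],
                labels[train_idx],
                training,
                level=level,
                genes=genes,
                embedding_spec=embedding_spec,
                vocabulary=vocab,
                seed=seed + fold,
            )
            probs, idx = clf.predict_features(features[test_idx])
            pred = np.asarray([vocab[i] for i in idx])
            report = compute_metrics(labels[test_idx], pred, probs, vocabulary=vocab)
            record = {"repeat": repeat, "fold": fold, **report.as_dict()}
            fold_metrics.append(record)
            if report.balanced_accuracy > best_balacc:
                best_balacc = report.balanced_accuracy
                best = clf
                best_fold = record
    metric_names = [k for k in fold_metrics[0] if k not in ("repeat", "fold")]
    summary = {}
    for name in metric_names:
        vals = np.asarray([m[name] for m in fold_metrics], dtype=float)
        vals = vals[~np.isnan(vals)]
        summary[name] = (float(vals.mean()), float(vals.std(ddof=1) if len(vals) > 1 else 0.0))
    assert best is not None
    return CrossValidationResult(
        fold_metrics=fold_metrics, summary=summary, best=best, best_fold=best_fold
    )


# ---------------------------------------------------------------------------
# Checkpointing


def save_classifier(clf: TrainedClassifier, path: str | Path) -> None:
    """Serialize weights to ``<path>.npz`` and config to a JSON sidecar."""
    path = Path(path)
    weights = clf.net.get_weights()
    arrays = {f"w{i:03d}": w for i, w in enumerate(weights)}
    if clf.scaler_mean is not None:
        arrays["scaler_mean"] = clf.scaler_mean
        arrays["scaler_sd"] = clf.scaler_sd
    np.savez(path.with_suffix(".npz"), **arrays)
    sidecar = {
        "level": clf.level,
        "architecture": clf.architecture,
        "vocabulary": list(clf.vocabulary),
        "genes": list(clf.genes),
        "history": clf.history,
        "provenance": clf.provenance,
        "embedding": {
            "n_layers": clf.embedding_spec.n_layers,
            "weight_mode": clf.embedding_spec.weight_mode,
            "activation": clf.embedding_spec.activation,
        },
        "n_weights": len(weights),
        "layer_shapes": [list(w.shape) for w in weights],
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_classifier(path: str | Path) -> TrainedClassifier:
    """Rebuild a classifier from ``save_classifier`` output."""
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    with np.load(path.with_suffix(".npz")) as data:
        weights = [data[k] for k in sorted(data.files) if k.startswith("w")]
        scaler_mean = data["scaler_mean"] if "scaler_mean" in data.files else None
        scaler_sd = data["scaler_sd"] if "scaler_sd" in data.files else None
    net = _net_from_weights(sidecar["architecture"], weights)
    spec = EmbeddingSpec(
        n_layers=sidecar["embedding"]["n_layers"],
        weight_mode=sidecar["embedding"]["weight_mode"],
        activation=sidecar["embedding"]["activation"],
    )
    return TrainedClassifier(
        level=sidecar["level"],
        architecture=sidecar["architecture"],
        net=net,
        vocabulary=tuple(sidecar["vocabulary"]),
        genes=tuple(sidecar["genes"]),
        embedding_spec=spec,
        history=sidecar["history"],
        provenance=sidecar["provenance"],
        scaler_mean=scaler_mean,
        scaler_sd=scaler_sd,
    )


def _net_from_weights(architecture: str, weights: list[np.ndarray]) -> nn.Network:
    rng = np.random.default_rng(0)
    layers: list = []
    i = 0
    if architecture == "cnn_baseline":
        layers.append(nn.Conv1x1(len(weights[0]), rng))
        layers.append(nn.ReLU())
        i = 2
    dense_pairs = [(weights[j], weights[j + 1]) for j in range(i, len(weights), 2)]
    for j, (W, b) in enumerate(dense_pairs):
        layer = nn.Dense(W.shape[0], W.shape[1], rng)
        layers.append(layer)
        if j < len(dense_pairs) - 1:
            layers.append(nn.ReLU())
    net = nn.Network(layers)
    net.set_weights(weights)
    return net
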