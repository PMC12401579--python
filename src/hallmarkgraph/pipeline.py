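"""End-to-end orchestration: prepare inputs, train per-tier classifiers,
validate hierarchically, explain.

``run_prepare`` loads the four inputs (GMT gene sets, interaction edge list,
expression matrix, sample table plus diagnosis token map), cleans the cohort
(grouping, FALSE correction, filtering), builds the per-hallmark normalized
adjacency operators, and writes a provenance log.  ``run_all`` then trains
one classifier per requested tier level on the TRUE group, reports
cross-validation metrics, validates the best models hierarchically on the
FALSE group, and optionally computes Shapley attributions.

Every output directory gets a ``run_meta.json`` sidecar with the config hash
and seed; two runs with equal config hashes produce equal reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from hallmarkgraph import classify, evaluation, interpretation, knowledge_graph as kg
from hallmarkgraph.embedding import EmbeddingSpec, ExpressionMatrix, load_expression
from hallmarkgraph import label_hierarchy as lh

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    gmt: str
    edges: str
    expression: str
    samples: str
    token_map: str
    corrections: str | None = None
    out: str | None = None
    levels: tuple[int, ...] | None = None  # None -> every level with samples
    min_group_size: int = 3
    architecture: str = "hallmarkgraph"
    mlp_depth: int = 3
    embedding_layers: int = 1
    learning_rate: float = 1e-3
    batch_size: int = 200
    max_epochs: int = 200
    patience: int = 5
    cv_folds: int = 5
    repeats: int = 5
    seed: int = 0
    explain: bool = False
    explain_background: int = 50
    explain_samples: int = 20
    shap_permutations: int = 5

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "levels" in raw and raw["levels"] is not None:
            raw["levels"] = tuple(raw["levels"])
        return cls(**raw)

    def training(self) -> classify.TrainingConfig:
        return classify.TrainingConfig(
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            max_epochs=self.max_epochs,
            patience=self.patience,
            cv_folds=self.cv_folds,
            repeats=self.repeats,
            seed=self.seed,
        )

    def classifier(self, n_labels: int = 2) -> classify.ClassifierConfig:
        return classify.ClassifierConfig(
            architecture=self.architecture,
            mlp_depth=self.mlp_depth,
            n_labels=n_labels,
        )

    def embedding(self) -> EmbeddingSpec:
        return EmbeddingSpec(n_layers=self.embedding_layers)


def config_hash(cfg: RunConfig) -> str:
    payload = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class Prepared:
    cohort: lh.CohortTable
    universe: kg.GeneUniverse
    gene_sets: kg.HallmarkGeneSets
    networks: list[kg.HallmarkNetwork]
    adjacencies: list[kg.NormalizedAdjacency]
    expression: ExpressionMatrix  # restricted to the universe
    token_map: dict[str, lh.TokenRule]


def run_prepare(cfg: RunConfig) -> Prepared:
    """Load, clean, and assemble everything training needs; write artifacts
    when an output directory is configured."""
    for name in ("gmt", "edges", "expression", "samples", "token_map"):
        path = getattr(cfg, name)
        if not Path(path).exists():
            raise FileNotFoundError(f"{name} input not found: {path}")

    gene_sets = kg.load_gene_sets(cfg.gmt)
    edges = kg.load_edge_list(cfg.edges)
    expression_full = load_expression(cfg.expression)
    universe = kg.build_universe(gene_sets, expression_full.genes)
    expression = expression_full.restrict_genes(universe)
    networks = kg.build_all_networks(universe, gene_sets, edges)
    adjacencies = [kg.normalize_adjacency(net) for net in networks]

    cohort = lh.load_sample_table(cfg.samples)
    token_map = lh.load_token_map(cfg.token_map)
    corrections = lh.load_corrections(cfg.corrections) if cfg.corrections else None
    lh.clean_cohort(
        cohort, token_map, corrections=corrections, min_group_size=cfg.min_group_size
    )

    if cfg.out:
        outdir = Path(cfg.out)
        outdir.mkdir(parents=True, exist_ok=True)
        _write_prepared(cfg, outdir, cohort, universe, networks)
    return Prepared(
        cohort=cohort,
        universe=universe,
        gene_sets=gene_sets,
        networks=networks,
        adjacencies=adjacencies,
        expression=expression,
        token_map=token_map,
    )


def _write_prepared(cfg, outdir: Path, cohort, universe, networks) -> None:
    (outdir / "universe.txt").write_text("\n".join(universe.genes) + "\n")
    with (outdir / "cleaned_samples.tsv").open("w") as fh:
        fh.write("sample_id\tdiagnosis\tgroup\tlabel\n")
        for rec in cohort.records:
            lab = "|".join(rec.labels[0].tiers) if rec.labels else ""
            fh.write(f"{rec.sample_id}\t{rec.diagnosis}\t{rec.group}\t{lab}\n")
    for net in networks:
        kg.export_edge_tsv(net, outdir / f"network_h{net.hallmark_id:02d}.tsv")
    cohort.write_provenance(outdir / "provenance.jsonl")
    _write_meta(cfg, outdir)


def _write_meta(cfg: RunConfig, outdir: Path) -> None:
    (outdir / "run_meta.json").write_text(
        json.dumps({"config_hash": config_hash(cfg), "seed": cfg.seed}, indent=2)
    )


def run_all(cfg: RunConfig) -> dict:
    """Train/evaluate every requested level, validate on the FALSE group.

    Returns ``{"levels": {k: {...cv summary...}}, "validation": {...},
    "attributions": {...}}``; the same content is written as JSON when an
    output directory is configured.
    """
    prep = run_prepare(cfg)
    outdir = Path(cfg.out) if cfg.out else None
    embedding_spec = cfg.embedding()
    training = cfg.training()

    max_depth = max((r.depth for r in prep.cohort.true_records()), default=0)
    levels = cfg.levels if cfg.levels is not None else tuple(range(1, max_depth + 1))

    sample_pos = {s: i for i, s in enumerate(prep.expression.sample_ids)}
    feature_cache: np.ndarray | None = None

    def features_of(sample_ids) -> np.ndarray:
        nonlocal feature_cache
        if feature_cache is None:
            feature_cache = classify.features_for(
                cfg.architecture, prep.expression, prep.adjacencies, embedding_spec
            )
        idx = [sample_pos[s] for s in sample_ids]
        return feature_cache[idx]

    level_reports: dict[int, dict] = {}
    best_models: dict[int, classify.TrainedClassifier] = {}
    for level in levels:
        try:
            dataset = lh.extract_level_dataset(prep.cohort, level)
        except ValueError as exc:
            warnings.warn(f"level {level} skipped: {exc}", stacklevel=2)
            continue
        feats = features_of(dataset.sample_ids)
        result = classify.cross_validate(
            cfg.classifier(len(dataset.vocabulary)),
            feats,
            list(dataset.labels),
            training,
            level=level,
            genes=prep.universe.genes,
            embedding_spec=embedding_spec,
        )
        best_models[level] = result.best
        level_reports[level] = {
            "n_samples": len(dataset),
            "n_labels": len(dataset.vocabulary),
            "vocabulary": list(dataset.vocabulary),
            "cv_summary": {k: {"mean": m, "sd": s} for k, (m, s) in result.summary.items()},
            "best_fold": result.best_fold,
        }
        if outdir:
            outdir.mkdir(parents=True, exist_ok=True)
            classify.save_classifier(result.best, outdir / f"level{level}_model")

    validation = _validate_false_group(prep, best_models, features_of)

    attributions = {}
    if cfg.explain and best_models:
        attributions = _explain(cfg, prep, best_models, features_of)

    report = {
        "levels": {str(k): v for k, v in level_reports.items()},
        "validation": validation,
        "attributions": attributions,
    }
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        _write_meta(cfg, outdir)
    return report


def _validate_false_group(prep: Prepared, best_models, features_of) -> dict:
    """Hierarchical validation of the best per-level models on FALSE samples.

    The tier-1 reference is the corrected, diagnosis-derived label; deeper
    tiers come from the sample's original (pre-correction) label path.
    Samples whose labels were deleted keep only the diagnosis-derived tier 1.
    """
    false_records = [
        r for r in prep.cohort.false_records()
        if r.sample_id in set(prep.expression.sample_ids)
    ]
    if not false_records or not best_models:
        return {}
    truth: dict[str, tuple[str, ...]] = {}
    for rec in false_records:
        if rec.labels:
            tier1 = rec.labels[0].tier(1)
        else:
            tier1 = prep.token_map[rec.diagnosis].primary_label
        deeper: tuple[str, ...] = ()
        if rec.labels and rec.original_labels and len(rec.original_labels) == 1:
            deeper = rec.original_labels[0].tiers[1:]
        truth[rec.sample_id] = (tier1,) + deeper
    ids = [r.sample_id for r in false_records]
    feats = features_of(ids)
    predictions: dict[int, dict[str, str]] = {}
    for level, clf in best_models.items():
        _, idx = clf.predict_features(feats)
        predictions[level] = {
            sid: clf.vocabulary[i] for sid, i in zip(ids, idx)
        }
    report = evaluation.validate_hierarchy(predictions, truth)
    return report.as_dict()


def _explain(cfg: RunConfig, prep: Prepared, best_models, features_of) -> dict:
    rng = np.random.default_rng(cfg.seed + 777)
    out: dict = {}
    for level, clf in best_models.items():
        dataset = lh.extract_level_dataset(prep.cohort, level)
        feats = features_of(dataset.sample_ids)
        n = len(feats)
        bg_idx = rng.choice(n, size=min(cfg.explain_background, n), replace=False)
        ex_idx = rng.choice(n, size=min(cfg.explain_samples, n), replace=False)
        attr = interpretation.attribute(
            clf.predict_proba_features,
            feats[bg_idx],
            feats[ex_idx],
            genes=prep.universe.genes,
            n_hallmarks=prep.gene_sets.n_hallmarks,
            n_permutations=cfg.shap_permutations,
            rng=rng,
        )
        ranking = interpretation.rank_genes(attr)
        contrib = interpretation.hallmark_contribution(
            attr, prep.gene_sets, prep.universe
        )
        out[str(level)] = {
            "top_genes": list(ranking.top(min(20, len(ranking.genes)))),
            "hallmark_raw": list(contrib.raw),
            "hallmark_normalized": list(contrib.normalized),
        }
        if cfg.out:
            interpretation.write_attribution_tsv(
                attr, Path(cfg.out) / f"level{level}_attributions.tsv"
            )
    return out
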