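"""Synthetic cohorts with planted class structure for end-to-end testing.

The generator emulates the four pipeline inputs -- hallmark gene sets (GMT),
a directed interaction edge list, a log2(TPM+1)-scaled expression matrix,
and a sample table with hierarchical labels plus clinical diagnoses --
together with a ground-truth manifest recording what was planted.

Design of the planted structure:

* the gene universe is partitioned into H hallmark base sets, each then
  extended with a configurable fraction of genes from other hallmarks, so
  sets overlap and their union is the whole universe;
* interactions are an Erdos-Renyi graph over the universe with random edge
  orientation, plus a block of expression-only genes that belong to no
  hallmark (exercising the universe intersection);
* samples sit at the leaves of a label tree (branching per tier, depth <= 8)
  whose tier strings follow the field's labeling style ("T001 AAA",
  "T001 AAA SAAA0", ...); each leaf class has a disjoint block of
  informative genes whose mean expression is shifted by the effect size;
* a configurable fraction of samples get deliberately discordant labels
  (the diagnosis-specific token is replaced by another class's token), so
  TRUE/FALSE grouping must flag exactly those;
* expression = per-gene lognormal baseline + class shift + Gaussian noise,
  rectified at zero to stay on the non-negative log2(TPM+1) scale.

Everything is deterministic given the seed; regenerating with the same spec
produces byte-identical files.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from hallmarkgraph.embedding import ExpressionMatrix
from hallmarkgraph.knowledge_graph import GeneUniverse, HallmarkGeneSets
from hallmarkgraph.label_hierarchy import TokenRule


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for one synthetic cohort.

    Defaults give the reference fixture: 3 primary classes at a single tier,
    100 samples per class (300 total), 10 hallmarks over 200 genes, effect
    size 2 on 20 informative genes per class, noise SD 1, 10% discordant
    samples, seed 7.
    """

    n_genes: int = 200
    n_extra_genes: int = 20
    n_hallmarks: int = 10
    overlap_fraction: float = 0.25
    edge_density: float = 0.05
    branching: tuple[int, ...] = (3,)
    n_samples_per_leaf: int = 100
    n_informative: int = 20
    effect_size: float = 2.0
    noise_sd: float = 1.0
    baseline_log_mean: float = 1.0
    baseline_log_sd: float = 0.5
    fraction_false: float = 0.1
    plant_singleton: bool = False
    seed: int = 7

    def __post_init__(self) -> None:
        if len(self.branching) > 8:
            raise ValueError("label tree depth cannot exceed 8 tiers")
        if any(b < 1 for b in self.branching):
            raise ValueError("branching factors must be positive")
        if not 0 <= self.overlap_fraction <= 1:
            raise ValueError("overlap_fraction must be in [0, 1]")
        n_leaves = int(np.prod(self.branching))
        if n_leaves * self.n_informative > self.n_genes:
            raise ValueError(
                f"{n_leaves} leaf classes x {self.n_informative} informative "
                f"genes exceed {self.n_genes} genes"
            )
        if self.n_hallmarks > self.n_genes:
            raise ValueError("more hallmarks than genes")
        if self.fraction_false > 0 and self.branching[0] < 2:
            raise ValueError(
                "discordant samples need at least 2 primary classes to borrow "
                "a mismatched token from"
            )

    @property
    def depth(self) -> int:
        return len(self.branching)

    @property
    def n_leaves(self) -> int:
        return int(np.prod(self.branching))

    @property
    def n_samples(self) -> int:
        return self.n_leaves * self.n_samples_per_leaf


@dataclass
class SyntheticCohort:
    """In-memory synthetic cohort plus its ground-truth manifest."""

    spec: FixtureSpec
    universe: GeneUniverse
    gene_sets: HallmarkGeneSets
    edges: list[tuple[str, str]]
    expression: ExpressionMatrix  # universe genes + extra genes, planted order
    sample_ids: list[str]
    diagnoses: list[str]
    label_strings: list[str]  # pipe-joined tier paths
    token_map: dict[str, TokenRule]
    manifest: dict


def _site_code(i: int) -> str:
    """Three-letter site code per primary class: AAA, BBB, ..., then AAB etc."""
    letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    if i < 26:
        return letters[i] * 3
    a, b = divmod(i - 26, 26)
    return letters[a] + letters[a] + letters[b]


def simulate(spec: FixtureSpec = FixtureSpec()) -> SyntheticCohort:
    """Generate a cohort in memory; deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)

    # --- gene universe and hallmark sets -----------------------------------
    genes = [f"G{i:05d}" for i in range(spec.n_genes)]
    extra = [f"X{i:05d}" for i in range(spec.n_extra_genes)]
    perm = rng.permutation(spec.n_genes)
    base: list[list[str]] = [[] for _ in range(spec.n_hallmarks)]
    for pos, gi in enumerate(perm):
        base[pos % spec.n_hallmarks].append(genes[gi])
    sets: list[frozenset[str]] = []
    for h in range(spec.n_hallmarks):
        members = set(base[h])
        outside = sorted(set(genes) - members)
        n_extra_members = int(spec.overlap_fraction * len(members))
        if n_extra_members and outside:
            picks = rng.choice(len(outside), size=min(n_extra_members, len(outside)),
                               replace=False)
            members |= {outside[i] for i in picks}
        sets.append(frozenset(members))
    gene_sets = HallmarkGeneSets(
        names=tuple(f"HALLMARK_{h:02d}" for h in range(spec.n_hallmarks)),
        sets=tuple(sets),
    )

    # --- interaction edge list ---------------------------------------------
    iu, ju = np.triu_indices(spec.n_genes, k=1)
    mask = rng.random(len(iu)) < spec.edge_density
    flip = rng.random(len(iu)) < 0.5
    edges: list[tuple[str, str]] = []
    for a, b, f in zip(iu[mask], ju[mask], flip[mask]):
        edges.append((genes[b], genes[a]) if f else (genes[a], genes[b]))

    # per-hallmark ground-truth edge counts (undirected pairs within set)
    pair_set = {frozenset((a, b)) for a, b in edges}
    hallmark_edge_counts = [
        sum(1 for p in pair_set if p <= s) for s in sets
    ]

    # --- label tree ---------------------------------------------------------
    leaf_paths = list(itertools.product(*(range(b) for b in spec.branching)))
    sites = [_site_code(i) for i in range(spec.branching[0])]
    diagnoses_by_primary = [f"{s}C" for s in sites]
    subtype_tokens = [f"S{s}" for s in sites]

    def tier_labels(path: tuple[int, ...], primary: int) -> list[str]:
        tiers = [f"T{primary:03d} {sites[primary]}"]
        for depth_idx, branch in enumerate(path[1:], start=2):
            suffix = f"{subtype_tokens[primary]}{branch}" if depth_idx == 2 else f"U{branch}"
            tiers.append(f"{tiers[-1]} {suffix}")
        return tiers

    token_map = {
        diagnoses_by_primary[i]: TokenRule(
            diagnosis=diagnoses_by_primary[i],
            primary_token=sites[i],
            subtype_token=subtype_tokens[i],
            primary_label=f"T{i:03d} {sites[i]}",
        )
        for i in range(spec.branching[0])
    }

    # --- samples ------------------------------------------------------------
    sample_ids: list[str] = []
    diagnoses: list[str] = []
    label_strings: list[str] = []
    leaf_of_sample: list[int] = []
    n_false = int(round(spec.fraction_false * spec.n_samples))
    false_flat_idx = set(
        rng.choice(spec.n_samples, size=n_false, replace=False).tolist()
    )
    flat = 0
    false_ids: list[str] = []
    for leaf_idx, path in enumerate(leaf_paths):
        primary = path[0]
        tiers_true = tier_labels(path, primary)
        for s in range(spec.n_samples_per_leaf):
            sid = f"S{flat:05d}"
            sample_ids.append(sid)
            diagnoses.append(diagnoses_by_primary[primary])
            leaf_of_sample.append(leaf_idx)
            if flat in false_flat_idx:
                false_ids.append(sid)
                other = (primary + 1) % spec.branching[0]
                if spec.depth >= 2:
                    # corrupt the subtype token from tier 2 downward
                    bad = [tiers_true[0]]
                    for depth_idx, branch in enumerate(path[1:], start=2):
                        suffix = (
                            f"{subtype_tokens[other]}{branch}"
                            if depth_idx == 2
                            else f"U{branch}"
                        )
                        bad.append(f"{bad[-1]} {suffix}")
                    label_strings.append("|".join(bad))
                else:
                    # discordant primary label
                    label_strings.append(f"T{other:03d} {sites[other]}")
            else:
                label_strings.append("|".join(tiers_true))
            flat += 1

    if spec.plant_singleton and spec.depth >= 2:
        sid = f"S{flat:05d}"
        primary = 0
        tiers = tier_labels(leaf_paths[0], primary)
        tiers[-1] = tiers[-1] + "ZSING"  # unique leaf label, concordant tokens
        sample_ids.append(sid)
        diagnoses.append(diagnoses_by_primary[primary])
        label_strings.append("|".join(tiers))
        leaf_of_sample.append(0)

    # --- expression ---------------------------------------------------------
    all_genes = genes + extra
    n_total_samples = len(sample_ids)
    baseline = rng.lognormal(
        spec.baseline_log_mean, spec.baseline_log_sd, size=len(all_genes)
    )
    informative: dict[int, list[str]] = {}
    gene_pool = rng.permutation(spec.n_genes)
    for leaf_idx in range(spec.n_leaves):
        chosen = gene_pool[
            leaf_idx * spec.n_informative : (leaf_idx + 1) * spec.n_informative
        ]
        informative[leaf_idx] = [genes[i] for i in chosen]
    gene_index = {g: i for i, g in enumerate(all_genes)}
    values = baseline[:, None] + rng.normal(
        0.0, spec.noise_sd, size=(len(all_genes), n_total_samples)
    )
    for s, leaf_idx in enumerate(leaf_of_sample):
        for g in informative[leaf_idx]:
            values[gene_index[g], s] += spec.effect_size
    values = np.maximum(values, 0.0)
    expression = ExpressionMatrix(
        values=values, genes=tuple(all_genes), sample_ids=tuple(sample_ids)
    )

    # --- manifest -----------------------------------------------------------
    group = {
        sid: ("FALSE" if sid in set(false_ids) else "TRUE") for sid in sample_ids
    }
    demoted: list[str] = []
    if spec.plant_singleton and spec.depth >= 2:
        singleton_sid = sample_ids[spec.n_samples]
        group[singleton_sid] = "FALSE"
        demoted.append(singleton_sid)
    n_true = sum(1 for g in group.values() if g == "TRUE")
    # all planted samples have full depth, so every level keeps all TRUE samples
    level_counts = {k: n_true for k in range(1, spec.depth + 1)}
    manifest = {
        "spec": {**asdict(spec), "branching": list(spec.branching)},
        "universe_size": spec.n_genes,
        "hallmark_sizes": [len(s) for s in sets],
        "hallmark_edge_counts": hallmark_edge_counts,
        "n_samples": n_total_samples,
        "n_false": len(false_ids) + len(demoted),
        "false_ids": sorted(set(false_ids) | set(demoted)),
        "demoted_singletons": demoted,
        "group": group,
        "level_counts": {str(k): v for k, v in level_counts.items()},
        "informative_genes": {str(k): v for k, v in informative.items()},
        "leaf_of_sample": dict(zip(sample_ids, leaf_of_sample)),
        "leaf_labels": {
            str(i): "|".join(tier_labels(path, path[0]))
            for i, path in enumerate(leaf_paths)
        },
    }

    return SyntheticCohort(
        spec=spec,
        universe=GeneUniverse(genes=tuple(genes)),
        gene_sets=gene_sets,
        edges=edges,
        expression=expression,
        sample_ids=sample_ids,
        diagnoses=diagnoses,
        label_strings=label_strings,
        token_map=token_map,
        manifest=manifest,
    )


def generate_cohort(spec: FixtureSpec, outdir: str | Path) -> dict:
    """Write the four input files plus token map and manifest; returns the
    manifest.  Files: fixture.gmt, edges.tsv, expression.tsv, samples.tsv,
    token_map.tsv, manifest.json."""
    cohort = simulate(spec)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    with (outdir / "fixture.gmt").open("w") as fh:
        for name, members in zip(cohort.gene_sets.names, cohort.gene_sets.sets):
            fh.write("\t".join([name, "synthetic hallmark set"] + sorted(members)) + "\n")

    with (outdir / "edges.tsv").open("w") as fh:
        fh.write("source\ttarget\n")
        for a, b in cohort.edges:
            fh.write(f"{a}\t{b}\n")

    with (outdir / "expression.tsv").open("w") as fh:
        fh.write("gene\t" + "\t".join(cohort.expression.sample_ids) + "\n")
        for gi, gene in enumerate(cohort.expression.genes):
            row = "\t".join(f"{v:.6f}" for v in cohort.expression.values[gi])
            fh.write(f"{gene}\t{row}\n")

    with (outdir / "samples.tsv").open("w") as fh:
        fh.write("sample_id\tdiagnosis\tlabel\n")
        for sid, diag, lab in zip(
            cohort.sample_ids, cohort.diagnoses, cohort.label_strings
        ):
            fh.write(f"{sid}\t{diag}\t{lab}\n")

    with (outdir / "token_map.tsv").open("w") as fh:
        fh.write("diagnosis\tprimary_token\tsubtype_token\tprimary_label\n")
        for rule in cohort.token_map.values():
            fh.write(
                f"{rule.diagnosis}\t{rule.primary_token}\t{rule.subtype_token}"
                f"\t{rule.primary_label}\n"
            )

    (outdir / "manifest.json").write_text(json.dumps(cohort.manifest, indent=2, sort_keys=True))
    return cohort.manifest


def planted_signal_check(cohort: SyntheticCohort) -> bool:
    """Verify the planted effect: for each leaf class the mean expression of
    its informative genes differs between in-class and out-of-class samples
    by approximately the effect size (within 3 standard errors).

    With effect size 0 the check passes when the difference stays within
    3 SE of zero.
    """
    spec = cohort.spec
    X = cohort.expression.values
    gene_index = {g: i for i, g in enumerate(cohort.expression.genes)}
    leaf_of = cohort.manifest["leaf_of_sample"]
    sample_leaf = np.asarray([leaf_of[s] for s in cohort.sample_ids])
    ok = True
    for leaf_str, genes in cohort.manifest["informative_genes"].items():
        leaf = int(leaf_str)
        rows = [gene_index[g] for g in genes]
        in_mask = sample_leaf == leaf
        if in_mask.all() or not in_mask.any():
            continue
        x_in = X[np.ix_(rows, np.where(in_mask)[0])].ravel()
        x_out = X[np.ix_(rows, np.where(~in_mask)[0])].ravel()
        diff = x_in.mean() - x_out.mean()
        se = np.sqrt(x_in.var(ddof=1) / len(x_in) + x_out.var(ddof=1) / len(x_out))
        if abs(diff - spec.effect_size) > 3 * se + 0.1 * spec.noise_sd:
            # small slack term absorbs the rectification bias at zero
            ok = False
    return ok
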