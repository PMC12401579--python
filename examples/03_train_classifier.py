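"""Train and cross-validate a tier-1 classifier on the reference fixture.

Embeds expression through the ten hallmark operators, flattens the
gene x hallmark tensor, and runs stratified 5-fold cross-validation of the
dense softmax head (512 -> 256 -> C, Adam, early stopping).  With the
planted effect size of 2 the three primary classes are fully recoverable.
"""

from hallmarkgraph import classify, knowledge_graph as kg, label_hierarchy as lh
from hallmarkgraph.synthetic import FixtureSpec, simulate

data = simulate(FixtureSpec(seed=7))  # 3 classes, 300 samples, effect size 2
records = [
    lh.SampleRecord(sample_id=s, diagnosis=d,
                    labels=(lh.parse_label(l, sample_id=s),),
                    original_labels=(lh.parse_label(l, sample_id=s),))
    for s, d, l in zip(data.sample_ids, data.diagnoses, data.label_strings)
]
cohort = lh.CohortTable(records=records)
lh.clean_cohort(cohort, data.token_map)

nets = kg.build_all_networks(data.universe, data.gene_sets, data.edges)
adjs = [kg.normalize_adjacency(n) for n in nets]
expr = data.expression.restrict_genes(data.universe)
dataset = lh.extract_level_dataset(cohort, 1)

features = classify.features_for("hallmarkgraph", expr, adjs)
pos = {s: i for i, s in enumerate(expr.sample_ids)}
F = features[[pos[s] for s in dataset.sample_ids]]

result = classify.cross_validate(
    classify.ClassifierConfig(n_labels=len(dataset.vocabulary)),
    F, list(dataset.labels),
    classify.TrainingConfig(cv_folds=5, repeats=1, seed=7),
)

print(f"tier-1 dataset: {len(dataset)} TRUE samples, labels {dataset.vocabulary}")
mean, sd = result.summary["balanced_accuracy"]
print(f"5-fold CV balanced accuracy: {mean:.3f} +/- {sd:.3f}")
mean, sd = result.summary["macro_auroc"]
print(f"5-fold CV macro AUROC:       {mean:.3f} +/- {sd:.3f}")
print("(balanced accuracy is the model-selection criterion; 1.0 means every")
print(" class is recovered perfectly on every held-out fold)")
print(f"best fold stopped after {result.best.provenance['n_epochs']} epochs "
      f"(early stop patience 5 on the training loss)")
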