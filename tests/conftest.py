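"""Shared fixtures: small synthetic cohorts and their prepared pipelines."""

from __future__ import annotations

import numpy as np
import pytest

from hallmarkgraph import knowledge_graph as kg
from hallmarkgraph import label_hierarchy as lh
from hallmarkgraph.synthetic import FixtureSpec, SyntheticCohort, simulate


@pytest.fixture(scope="session")
def default_cohort() -> SyntheticCohort:
    """The reference fixture: 3 primary classes, 300 samples, effect size 2."""
    return simulate(FixtureSpec())


@pytest.fixture(scope="session")
def deep_cohort() -> SyntheticCohort:
    """A depth-3 cohort (3 x 2 x 2 leaves) for hierarchical metrics."""
    return simulate(
        FixtureSpec(branching=(3, 2, 2), n_samples_per_leaf=12, n_informative=10,
                    n_genes=240, seed=11)
    )


def cohort_table_of(cohort: SyntheticCohort) -> lh.CohortTable:
    """Build a CohortTable from the in-memory synthetic sample records."""
    records = [
        lh.SampleRecord(
            sample_id=sid,
            diagnosis=diag,
            labels=(lh.parse_label(lab, sample_id=sid),),
            original_labels=(lh.parse_label(lab, sample_id=sid),),
        )
        for sid, diag, lab in zip(
            cohort.sample_ids, cohort.diagnoses, cohort.label_strings
        )
    ]
    return lh.CohortTable(records=records)


@pytest.fixture(scope="session")
def default_prepared(default_cohort):
    """Cleaned cohort + normalized adjacencies + universe-restricted expression."""
    cohort = cohort_table_of(default_cohort)
    lh.clean_cohort(cohort, default_cohort.token_map)
    nets = kg.build_all_networks(
        default_cohort.universe, default_cohort.gene_sets, default_cohort.edges
    )
    adjs = [kg.normalize_adjacency(n) for n in nets]
    expr = default_cohort.expression.restrict_genes(default_cohort.universe)
    return cohort, nets, adjs, expr


def random_graph(n_nodes: int, density: float, rng: np.random.Generator):
    """A random undirected binary adjacency over n_nodes (dense numpy)."""
    a = (rng.random((n_nodes, n_nodes)) < density).astype(float)
    a = np.triu(a, k=1)
    return a + a.T


def network_from_dense(adjacency: np.ndarray) -> kg.HallmarkNetwork:
    """Wrap a dense symmetric 0/1 matrix as a HallmarkNetwork on fake genes."""
    import scipy.sparse as sp

    n = len(adjacency)
    universe = kg.GeneUniverse(genes=tuple(f"N{i}" for i in range(n)))
    mat = sp.csr_matrix(adjacency)
    return kg.HallmarkNetwork(
        hallmark_id=0,
        universe=universe,
        adjacency=mat,
        degrees=adjacency.sum(axis=1),
    )


def dense_normalized_oracle(adjacency: np.ndarray) -> np.ndarray:
    """Naive dense computation of I + D^(-1/2) A D^(-1/2) (degree-0 rows
    become identity rows); the independent reference for the sparse path."""
    n = len(adjacency)
    deg = adjacency.sum(axis=1)
    d_inv_sqrt = np.zeros(n)
    nz = deg > 0
    d_inv_sqrt[nz] = 1.0 / np.sqrt(deg[nz])
    return np.eye(n) + np.diag(d_inv_sqrt) @ adjacency @ np.diag(d_inv_sqrt)
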