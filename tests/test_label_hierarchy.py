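"""Label parsing, diagnosis concordance grouping, and cohort cleaning rules."""

import pytest

from hallmarkgraph import label_hierarchy as lh
from conftest import cohort_table_of


def make_record(sample_id, diagnosis, label, original=None):
    labels = tuple(lh.parse_label(p, sample_id=sample_id) for p in label.split(";")) if label else ()
    originals = (
        tuple(lh.parse_label(p, sample_id=sample_id) for p in original.split(";"))
        if original
        else labels
    )
    return lh.SampleRecord(
        sample_id=sample_id, diagnosis=diagnosis, labels=labels, original_labels=originals
    )


# The melanoma worked example: a cutaneous-melanoma (SKCM) sample is TRUE when
# its primary label is the melanoma code and every deeper tier carries SKCM.
SKCM_RULES = {
    "SKCM": lh.TokenRule(
        diagnosis="SKCM",
        primary_token="MELA",
        subtype_token="SKCM",
        primary_label="T013 MELA",
    )
}


class TestParseLabel:
    def test_two_tier_label_splits_on_pipe(self):
        label = lh.parse_label("T013 MELA|T013 MELA SKCM")
        assert label.tiers == ("T013 MELA", "T013 MELA SKCM")
        assert label.depth == 2

    def test_single_tier(self):
        assert lh.parse_label("T000 CNS").depth == 1

    def test_more_than_eight_tiers_rejected(self):
        with pytest.raises(ValueError, match="9 tiers"):
            lh.parse_label("|".join(f"T{i}" for i in range(9)))

    def test_empty_tier_rejected(self):
        with pytest.raises(ValueError, match="empty tier"):
            lh.parse_label("A||B")


class TestMatchTokens:
    @pytest.mark.parametrize(
        "tokens, tier, expected",
        [
            ("SKCM", "T013 MELA SKCM", True),
            ("SKCM", "T013 MELA UVM", False),
            ("skcm", "T013 MELA SKCM", True),  # case-insensitive
            ([], "anything", True),  # vacuous truth
            (["MELA", "SKCM"], "T013 MELA SKCM", True),
            (["MELA", "UVM"], "T013 MELA SKCM", False),
        ],
    )
    def test_substring_containment(self, tokens, tier, expected):
        assert lh.match_tokens(tokens, tier) is expected


class TestAssignGroup:
    def test_concordant_skcm_sample_is_true(self):
        rec = make_record(
            "s1", "SKCM",
            "T013 MELA|T013 MELA SKCM|T013 MELA SKCM A|T013 MELA SKCM A B",
        )
        assert lh.assign_group(rec, SKCM_RULES).group == lh.TRUE

    def test_one_discordant_tier_makes_false(self):
        rec = make_record(
            "s1", "SKCM",
            "T013 MELA|T013 MELA SKCM|T013 MELA UVM X|T013 MELA SKCM A B",
        )
        assert lh.assign_group(rec, SKCM_RULES).group == lh.FALSE

    def test_single_tier_concordant_sample_is_true(self):
        rec = make_record("s1", "SKCM", "T013 MELA")
        assert lh.assign_group(rec, SKCM_RULES).group == lh.TRUE

    def test_unknown_diagnosis_raises(self):
        rec = make_record("s1", "UVM", "T013 MELA")
        with pytest.raises(KeyError, match="UVM"):
            lh.assign_group(rec, SKCM_RULES)

    def test_grouping_idempotent_and_never_flips_true_samples(self):
        cohort = lh.CohortTable(records=[
            make_record("t", "SKCM", "T013 MELA|T013 MELA SKCM"),
            make_record("f", "SKCM", "T013 MELA|T013 MELA UVM"),
        ])
        lh.group_cohort(cohort, SKCM_RULES)
        assert [r.group for r in cohort.records] == ["TRUE", "FALSE"]
        lh.group_cohort(cohort, SKCM_RULES)  # idempotent
        assert [r.group for r in cohort.records] == ["TRUE", "FALSE"]
        lh.correct_false_samples(cohort, SKCM_RULES)
        lh.group_cohort(cohort, SKCM_RULES)
        assert cohort.records[0].group == lh.TRUE  # TRUE samples never flip


class TestCorrectFalseSamples:
    def test_false_sample_truncated_to_diagnosis_primary(self):
        cohort = lh.CohortTable(records=[
            make_record("f", "SKCM", "T099 WRONG|T099 WRONG X|T099 WRONG X Y|T099 WRONG X Y Z")
        ])
        lh.group_cohort(cohort, SKCM_RULES)
        lh.correct_false_samples(cohort, SKCM_RULES)
        rec = cohort.records[0]
        assert rec.labels[0].tiers == ("T013 MELA",)
        assert rec.original_labels[0].depth == 4  # original retained for validation

    def test_conflicting_tier1_labels_deleted_entirely(self):
        cohort = lh.CohortTable(records=[
            make_record("f", "SKCM", "T099 WRONG;T098 OTHER")
        ])
        lh.group_cohort(cohort, SKCM_RULES)
        lh.correct_false_samples(cohort, SKCM_RULES)
        assert cohort.records[0].labels == ()
        assert cohort.records[0].diagnosis == "SKCM"
        assert any(e["event"] == "labels_deleted" for e in cohort.provenance)

    def test_true_samples_untouched(self):
        cohort = lh.CohortTable(records=[
            make_record("t", "SKCM", "T013 MELA|T013 MELA SKCM")
        ])
        lh.group_cohort(cohort, SKCM_RULES)
        lh.correct_false_samples(cohort, SKCM_RULES)
        assert cohort.records[0].labels[0].depth == 2

    def test_no_false_sample_deeper_than_one_tier_post_correction(self):
        cohort = lh.CohortTable(records=[
            make_record(f"s{i}", "SKCM", "T013 MELA|T013 MELA UVM|T013 MELA UVM X")
            for i in range(4)
        ])
        lh.group_cohort(cohort, SKCM_RULES)
        lh.correct_false_samples(cohort, SKCM_RULES)
        assert all(r.depth <= 1 for r in cohort.false_records())


class TestFilterCohort:
    def test_small_diagnosis_groups_removed_and_boundary_kept(self):
        records = [make_record(f"a{i}", "SKCM", "T013 MELA") for i in range(3)]
        records += [make_record(f"b{i}", "UVM", "T014 MELA UVM") for i in range(2)]
        cohort = lh.CohortTable(records=records)
        lh.filter_cohort(cohort, min_group_size=3)
        kept = {r.sample_id for r in cohort.records}
        assert kept == {"a0", "a1", "a2"}

    def test_singleton_leaf_label_demotes_sample_to_false(self):
        records = [
            make_record(f"s{i}", "SKCM", "T013 MELA|T013 MELA SKCM") for i in range(3)
        ]
        records.append(make_record("solo", "SKCM", "T013 MELA|T013 MELA SKCM|T013 MELA SKCM RARE"))
        cohort = lh.CohortTable(records=records)
        lh.group_cohort(cohort, SKCM_RULES)
        lh.filter_cohort(cohort)
        solo = next(r for r in cohort.records if r.sample_id == "solo")
        assert solo.group == lh.FALSE
        assert solo.labels[0].tiers == ("T013 MELA",)


class TestLevelDatasets:
    @staticmethod
    def _cohort_with_depths():
        records = [
            make_record("d1", "SKCM", "T013 MELA"),
            make_record("d2a", "SKCM", "T013 MELA|T013 MELA SKCM"),
            make_record("d2b", "SKCM", "T013 MELA|T013 MELA SKCM"),
            make_record("d3", "SKCM", "T013 MELA|T013 MELA SKCM|T013 MELA SKCM X"),
        ]
        cohort = lh.CohortTable(records=records)
        lh.group_cohort(cohort, SKCM_RULES)
        return cohort

    def test_depth_filter_counts(self):
        cohort = self._cohort_with_depths()
        assert len(lh.extract_level_dataset(cohort, 2)) == 3
        assert len(lh.extract_level_dataset(cohort, 1)) == 4

    def test_level_beyond_max_depth_raises(self):
        with pytest.raises(ValueError, match="depth 4"):
            lh.extract_level_dataset(self._cohort_with_depths(), 4)

    def test_levels_nested_and_counts_sum_to_size(self, deep_cohort):
        cohort = cohort_table_of(deep_cohort)
        lh.clean_cohort(cohort, deep_cohort.token_map)
        previous = None
        for level in (3, 2, 1):
            ds = lh.extract_level_dataset(cohort, level)
            ids = set(ds.sample_ids)
            if previous is not None:
                assert previous <= ids
            previous = ids
            from collections import Counter

            assert sum(Counter(ds.labels).values()) == len(ds)
            assert set(ds.labels) == set(ds.vocabulary)

    def test_fixture_level_counts_match_manifest(self, deep_cohort):
        cohort = cohort_table_of(deep_cohort)
        lh.clean_cohort(cohort, deep_cohort.token_map)
        for level, expected in deep_cohort.manifest["level_counts"].items():
            assert len(lh.extract_level_dataset(cohort, int(level))) == expected


class TestGroupingRecoversManifest:
    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_pipeline_matches_generator_truth(self, seed):
        from hallmarkgraph.synthetic import FixtureSpec, simulate

        cohort_data = simulate(
            FixtureSpec(branching=(3, 2), n_samples_per_leaf=10, n_informative=5,
                        n_genes=120, seed=seed, plant_singleton=True)
        )
        cohort = cohort_table_of(cohort_data)
        lh.clean_cohort(cohort, cohort_data.token_map)
        got = {r.sample_id: r.group for r in cohort.records}
        assert got == cohort_data.manifest["group"]
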