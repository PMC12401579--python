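"""Hierarchical subtype labels, TRUE/FALSE grouping, and cohort cleaning.

Samples carry a hierarchical subtype label of up to eight tiers (tier 1 is
the primary cancer type, e.g. ``"T013 MELA"``; deeper tiers refine it, e.g.
``"T013 MELA SKCM"``) plus an independent clinical diagnosis string.  A
sample is TRUE when its label path is concordant with the diagnosis -- the
diagnosis-specific tokens appear in every tier -- and FALSE otherwise.  TRUE
samples train the classifiers; FALSE samples are held out for hierarchical
validation.

Cleaning rules, applied in order:

1. manual corrections file (sample id -> replacement label),
2. TRUE/FALSE grouping by token concordance,
3. FALSE correction: the primary label is replaced by the diagnosis-derived
   one and deeper tiers are dropped; a FALSE sample carrying more than one
   distinct tier-1 label has all labels deleted,
4. removal of diagnosis groups with fewer than ``min_group_size`` samples,
5. demotion of any tier-level label carried by exactly one sample: that
   sample moves to the FALSE group (singletons cannot train a classifier).

Every correction and filter decision is appended to a provenance log.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

MAX_TIERS = 8

TRUE = "TRUE"
FALSE = "FALSE"
UNASSIGNED = "UNASSIGNED"


@dataclass(frozen=True)
class HierarchicalLabel:
    """An ordered path of tier labels, tier 1 first; depth <= 8."""

    tiers: tuple[str, ...]

    @property
    def depth(self) -> int:
        return len(self.tiers)

    def tier(self, k: int) -> str:
        """1-based tier accessor."""
        return self.tiers[k - 1]


@dataclass(frozen=True)
class TokenRule:
    """Concordance tokens for one clinical diagnosis.

    ``primary_token`` must appear in the tier-1 label, ``subtype_token`` in
    every deeper tier, for the sample to be TRUE.  ``primary_label`` is the
    replacement tier-1 label used when correcting FALSE samples.
    """

    diagnosis: str
    primary_token: str
    subtype_token: str
    primary_label: str


@dataclass
class SampleRecord:
    sample_id: str
    diagnosis: str
    labels: tuple[HierarchicalLabel, ...] = ()
    group: str = UNASSIGNED
    original_labels: tuple[HierarchicalLabel, ...] = ()

    @property
    def label(self) -> HierarchicalLabel | None:
        return self.labels[0] if self.labels else None

    @property
    def depth(self) -> int:
        return self.labels[0].depth if self.labels else 0


@dataclass
class CohortTable:
    records: list[SampleRecord]
    provenance: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.sample_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids in cohort")

    def log(self, **event) -> None:
        self.provenance.append(event)

    def true_records(self) -> list[SampleRecord]:
        return [r for r in self.records if r.group == TRUE]

    def false_records(self) -> list[SampleRecord]:
        return [r for r in self.records if r.group == FALSE]

    def write_provenance(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            for event in self.provenance:
                fh.write(json.dumps(event) + "\n")


@dataclass(frozen=True)
class LevelDataset:
    """Training material for one tier level: TRUE samples of depth >= k."""

    level: int
    sample_ids: tuple[str, ...]
    labels: tuple[str, ...]
    vocabulary: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.sample_ids)


def parse_label(
    raw: str, *, tier_delimiter: str = "|", sample_id: str = "?"
) -> HierarchicalLabel:
    """Split a serialized label path into tiers; at most 8 non-empty tiers."""
    if not raw or not raw.strip():
        raise ValueError(f"sample {sample_id}: empty label string")
    tiers = [t.strip() for t in raw.split(tier_delimiter)]
    if any(not t for t in tiers):
        raise ValueError(f"sample {sample_id}: label {raw!r} has an empty tier")
    if len(tiers) > MAX_TIERS:
        raise ValueError(
            f"sample {sample_id}: label has {len(tiers)} tiers (maximum {MAX_TIERS})"
        )
    return HierarchicalLabel(tiers=tuple(tiers))


def match_tokens(tokens: Sequence[str] | str, tier: str) -> bool:
    """True iff every token appears as a case-insensitive substring of the tier."""
    if isinstance(tokens, str):
        tokens = [tokens]
    tier_lower = tier.lower()
    return all(tok.lower() in tier_lower for tok in tokens)


def assign_group(record: SampleRecord, token_map: Mapping[str, TokenRule]) -> SampleRecord:
    """Classify one sample as TRUE or FALSE by diagnosis-token concordance.

    TRUE requires a single unambiguous label whose tier 1 contains the
    diagnosis's primary token and whose every deeper tier contains the
    subtype token.  A record carrying more than one label path is discordant
    by construction and is FALSE.
    """
    if not record.labels:
        raise ValueError(f"sample {record.sample_id}: cannot group a sample without a label")
    if record.diagnosis not in token_map:
        raise KeyError(
            f"sample {record.sample_id}: diagnosis {record.diagnosis!r} absent from token map"
        )
    rule = token_map[record.diagnosis]
    if len(record.labels) > 1:
        return replace(record, group=FALSE)
    label = record.labels[0]
    ok = match_tokens(rule.primary_token, label.tier(1)) and all(
        match_tokens(rule.subtype_token, label.tier(k)) for k in range(2, label.depth + 1)
    )
    return replace(record, group=TRUE if ok else FALSE)


def group_cohort(cohort: CohortTable, token_map: Mapping[str, TokenRule]) -> CohortTable:
    """Assign TRUE/FALSE to every record; idempotent."""
    cohort.records = [assign_group(r, token_map) for r in cohort.records]
    return cohort


def correct_false_samples(
    cohort: CohortTable, token_map: Mapping[str, TokenRule]
) -> CohortTable:
    """Rewrite FALSE samples' labels so only the diagnosis-derived tier 1 remains.

    A FALSE sample with more than one distinct tier-1 label in its original
    record is considered unreliable: all labels are deleted and only the
    diagnosis is retained.
    """
    for i, rec in enumerate(cohort.records):
        if rec.group != FALSE:
            continue
        originals = rec.original_labels or rec.labels
        tier1s = {lab.tier(1) for lab in rec.labels}
        if len(tier1s) > 1:
            cohort.records[i] = replace(
                rec, labels=(), original_labels=originals
            )
            cohort.log(
                event="labels_deleted",
                sample_id=rec.sample_id,
                reason="multiple tier-1 labels",
                original=[list(lab.tiers) for lab in originals],
            )
            continue
        rule = token_map[rec.diagnosis]
        corrected = HierarchicalLabel(tiers=(rule.primary_label,))
        if rec.labels != (corrected,):
            cohort.log(
                event="false_corrected",
                sample_id=rec.sample_id,
                original=[list(lab.tiers) for lab in originals],
                corrected=list(corrected.tiers),
            )
        cohort.records[i] = replace(
            rec, labels=(corrected,), original_labels=originals
        )
    return cohort


def filter_cohort(cohort: CohortTable, min_group_size: int = 3) -> CohortTable:
    """Drop small diagnosis groups and demote singleton labels to FALSE.

    Diagnosis groups with fewer than ``min_group_size`` samples are removed
    entirely.  Then any (level, label) pair represented by exactly one TRUE
    sample demotes that sample to FALSE with its label truncated to tier 1
    (the tier-1 label of a formerly TRUE sample already matches its
    diagnosis).  Demotion repeats until no singleton remains.
    """
    counts: dict[str, int] = {}
    for rec in cohort.records:
        counts[rec.diagnosis] = counts.get(rec.diagnosis, 0) + 1
    kept = []
    for rec in cohort.records:
        if counts[rec.diagnosis] < min_group_size:
            cohort.log(
                event="diagnosis_group_removed",
                sample_id=rec.sample_id,
                diagnosis=rec.diagnosis,
                group_size=counts[rec.diagnosis],
            )
        else:
            kept.append(rec)
    cohort.records = kept

    changed = True
    while changed:
        changed = False
        label_counts: dict[tuple[int, str], int] = {}
        for rec in cohort.records:
            if rec.group != TRUE:
                continue
            for k in range(1, rec.depth + 1):
                key = (k, rec.labels[0].tier(k))
                label_counts[key] = label_counts.get(key, 0) + 1
        for i, rec in enumerate(cohort.records):
            if rec.group != TRUE:
                continue
            singleton_at = [
                k
                for k in range(1, rec.depth + 1)
                if label_counts[(k, rec.labels[0].tier(k))] == 1
            ]
            if singleton_at:
                truncated = HierarchicalLabel(tiers=(rec.labels[0].tier(1),))
                cohort.log(
                    event="singleton_demoted",
                    sample_id=rec.sample_id,
                    levels=singleton_at,
                    original=list(rec.labels[0].tiers),
                )
                cohort.records[i] = replace(
                    rec,
                    group=FALSE,
                    labels=(truncated,),
                    original_labels=rec.original_labels or rec.labels,
                )
                changed = True
                break
    return cohort


def extract_level_dataset(cohort: CohortTable, level: int) -> LevelDataset:
    """Materialize the tier-``level`` training set from TRUE samples."""
    if not 1 <= level <= MAX_TIERS:
        raise ValueError(f"level must be in 1..{MAX_TIERS}, got {level}")
    ids: list[str] = []
    labels: list[str] = []
    for rec in cohort.true_records():
        if rec.depth >= level:
            ids.append(rec.sample_id)
            labels.append(rec.labels[0].tier(level))
    if not ids:
        raise ValueError(f"no TRUE sample reaches tier depth {level}")
    vocabulary = tuple(sorted(set(labels)))
    return LevelDataset(
        level=level,
        sample_ids=tuple(ids),
        labels=tuple(labels),
        vocabulary=vocabulary,
    )


# ---------------------------------------------------------------------------
# File interfaces


def load_sample_table(
    path: str | Path,
    *,
    tier_delimiter: str = "|",
    label_delimiter: str = ";",
) -> CohortTable:
    """Read the sample TSV: sample_id, diagnosis, and either a single
    ``label`` column (tiers joined by ``tier_delimiter``, alternative label
    paths joined by ``label_delimiter``) or eight columns ``tier1..tier8``.
    The encoding is auto-detected from the header.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"sample_id", "diagnosis"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: sample table needs columns {sorted(required)}")
    tier_cols = [f"tier{k}" for k in range(1, MAX_TIERS + 1) if f"tier{k}" in df.columns]
    records: list[SampleRecord] = []
    for row in df.itertuples(index=False):
        row_d = row._asdict()
        sid = row_d["sample_id"]
        labels: tuple[HierarchicalLabel, ...]
        if "label" in df.columns and row_d.get("label", ""):
            labels = tuple(
                parse_label(part, tier_delimiter=tier_delimiter, sample_id=sid)
                for part in row_d["label"].split(label_delimiter)
                if part.strip()
            )
        elif tier_cols:
            tiers = []
            for col in tier_cols:
                val = row_d[col].strip()
                if not val:
                    break
                tiers.append(val)
            labels = (HierarchicalLabel(tiers=tuple(tiers)),) if tiers else ()
        else:
            labels = ()
        records.append(
            SampleRecord(
                sample_id=sid,
                diagnosis=row_d["diagnosis"],
                labels=labels,
                original_labels=labels,
            )
        )
    return CohortTable(records=records)


def load_token_map(path: str | Path) -> dict[str, TokenRule]:
    """Read the diagnosis->token config TSV with columns
    diagnosis, primary_token, subtype_token, primary_label."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    needed = {"diagnosis", "primary_token", "subtype_token", "primary_label"}
    if not needed <= set(df.columns):
        raise ValueError(f"{path}: token map needs columns {sorted(needed)}")
    out: dict[str, TokenRule] = {}
    for row in df.itertuples(index=False):
        out[row.diagnosis] = TokenRule(
            diagnosis=row.diagnosis,
            primary_token=row.primary_token,
            subtype_token=row.subtype_token,
            primary_label=row.primary_label,
        )
    return out


def apply_corrections(
    cohort: CohortTable, corrections: Mapping[str, str], *, tier_delimiter: str = "|"
) -> CohortTable:
    """Apply a manual corrections file (sample id -> replacement label path)
    before grouping; mirrors hand-fixing typos in the source annotations."""
    for i, rec in enumerate(cohort.records):
        if rec.sample_id in corrections:
            new = parse_label(
                corrections[rec.sample_id],
                tier_delimiter=tier_delimiter,
                sample_id=rec.sample_id,
            )
            cohort.log(
                event="manual_correction",
                sample_id=rec.sample_id,
                original=[list(lab.tiers) for lab in rec.labels],
                corrected=list(new.tiers),
            )
            cohort.records[i] = replace(rec, labels=(new,), original_labels=(new,))
    return cohort


def load_corrections(path: str | Path) -> dict[str, str]:
    """Read a corrections TSV with columns sample_id, label."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if not {"sample_id", "label"} <= set(df.columns):
        raise ValueError(f"{path}: corrections file needs sample_id and label columns")
    return dict(zip(df["sample_id"], df["label"]))


def clean_cohort(
    cohort: CohortTable,
    token_map: Mapping[str, TokenRule],
    *,
    corrections: Mapping[str, str] | None = None,
    min_group_size: int = 3,
) -> CohortTable:
    """Run the full cleaning pipeline in the canonical order."""
    if corrections:
        apply_corrections(cohort, corrections)
    group_cohort(cohort, token_map)
    correct_false_samples(cohort, token_map)
    filter_cohort(cohort, min_group_size=min_group_size)
    return cohort
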