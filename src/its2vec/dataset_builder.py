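"""Reference-set construction: taxonomy filtering, per-SH capping, and the
partition into m-regular subsets with per-subset cross-validation folds.

The construction mirrors how UNITE-style reference sets are prepared for
species-level classification:

1. discard sequences without clear genus/species information
   (``g__unidentified``, ``s__uncultured``, or an empty rank);
2. drop SHs represented by a single sequence (a class needs at least two
   members to be both trained and validated);
3. cap over-represented SHs at 10 randomly selected sequences;
4. partition the result by representation count: ITSset_m holds the species
   represented by exactly m sequences (m = 2..10), each with dense 0-based
   integer class labels assigned in sorted-SH order.

Each ITSset_m is evaluated by m-fold cross-validation in which every fold
contains exactly one sequence of every SH; the largest subset (ITSset_10) is
first subsampled to 5 sequences per SH and evaluated with 5-fold CV.

Capping cannot create singletons and singleton-dropping cannot push an SH
over the cap, so steps 2 and 3 commute; the order above is fixed for
determinism and the whole pipeline is idempotent.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ._seeds import derive_seed
from .errors import ConsistencyError
from .seqio import SequenceRecord

logger = logging.getLogger(__name__)

MIN_SUBSET_M = 2
MAX_PER_SH = 10
EVAL_SUBSAMPLE_TARGET = 5

#: removal reasons logged by filter_unidentified, checked in this order
REASON_EMPTY_RANK = "empty-genus-or-species"
REASON_UNIDENTIFIED = "unidentified"
REASON_UNCULTURED = "uncultured"


@dataclass
class ITSSubset:
    """All records of species represented by exactly m sequences.

    ``sh_index`` maps each SH code to a dense 0-based class label, assigned
    in sorted-SH order for run-to-run stability.
    """

    m: int
    records: list[SequenceRecord]
    sh_index: dict[str, int]

    @property
    def n_classes(self) -> int:
        return len(self.sh_index)

    def labels(self) -> np.ndarray:
        return np.array([self.sh_index[r.sh_code] for r in self.records],
                        dtype=np.int64)

    def validate(self) -> None:
        counts = Counter(r.sh_code for r in self.records)
        bad = {sh: c for sh, c in counts.items() if c != self.m}
        if bad:
            raise ConsistencyError(
                f"ITSset_{self.m}: SH counts deviate from m: {bad}")
        if sorted(self.sh_index.values()) != list(range(len(self.sh_index))):
            raise ConsistencyError(
                f"ITSset_{self.m}: class labels are not dense 0-based integers")


@dataclass
class CVFoldPlan:
    """Assignment of each record index to a fold (one record per SH per fold)."""

    n_folds: int
    assignment: dict[int, int]
    seed: int

    def fold_indices(self, fold: int) -> list[int]:
        return sorted(i for i, f in self.assignment.items() if f == fold)


def _rank_removed(value: str, keyword: str) -> bool:
    return keyword in value.lower()


def filter_unidentified(
    records: Sequence[SequenceRecord],
) -> tuple[list[SequenceRecord], Counter]:
    """Drop records without clear genus/species taxonomy.

    A record is removed when its genus or species rank is empty, or contains
    "unidentified" or "uncultured" (case-insensitive substring match, so
    variants like "uncultured_fungus" are caught). Returns the survivors (in
    order) and a per-reason removal count; a record is counted under the
    first reason that applies.
    """
    survivors: list[SequenceRecord] = []
    removals: Counter = Counter()
    for record in records:
        genus, species = record.lineage.genus, record.lineage.species
        if not genus or not species:
            removals[REASON_EMPTY_RANK] += 1
        elif _rank_removed(genus, "unidentified") or _rank_removed(species, "unidentified"):
            removals[REASON_UNIDENTIFIED] += 1
        elif _rank_removed(genus, "uncultured") or _rank_removed(species, "uncultured"):
            removals[REASON_UNCULTURED] += 1
        else:
            survivors.append(record)
    for reason, count in sorted(removals.items()):
        logger.info("filter_unidentified: removed %d record(s): %s", count, reason)
    return survivors, removals


def _group_by_sh(records: Sequence[SequenceRecord]) -> dict[str, list[int]]:
    groups: dict[str, list[int]] = defaultdict(list)
    for i, record in enumerate(records):
        groups[record.sh_code].append(i)
    return groups


def _by_accession(records: Sequence[SequenceRecord], indices: list[int]) -> list[int]:
    # stable key so seeded per-SH draws are independent of record order
    return sorted(indices, key=lambda i: records[i].accession)


def cap_per_sh(
    records: Sequence[SequenceRecord],
    max_per_sh: int = MAX_PER_SH,
    seed: int = 0,
) -> list[SequenceRecord]:
    """Randomly down-sample over-represented SHs to ``max_per_sh`` sequences.

    The selection is uniform without replacement, driven by a per-SH stream
    derived from (seed, sh_code), so it is reproducible and independent of
    record order. Survivors keep their original relative order.
    """
    if max_per_sh < 1:
        raise ValueError("max_per_sh must be >= 1")
    keep: set[int] = set()
    for sh_code, indices in _group_by_sh(records).items():
        if len(indices) <= max_per_sh:
            keep.update(indices)
        else:
            ordered = _by_accession(records, indices)
            rng = np.random.default_rng(derive_seed(seed, "cap", sh_code))
            chosen = rng.choice(len(ordered), size=max_per_sh, replace=False)
            keep.update(ordered[int(i)] for i in chosen)
    return [r for i, r in enumerate(records) if i in keep]


def drop_singletons(records: Sequence[SequenceRecord]) -> list[SequenceRecord]:
    """Remove records whose SH has exactly one sequence."""
    counts = Counter(r.sh_code for r in records)
    return [r for r in records if counts[r.sh_code] >= 2]


def partition_subsets(
    records: Sequence[SequenceRecord],
    min_m: int = MIN_SUBSET_M,
    max_m: int = MAX_PER_SH,
) -> dict[int, ITSSubset]:
    """Partition filtered/capped records into ITSset_m by SH representation.

    Every SH must have between ``min_m`` and ``max_m`` records (the upstream
    pipeline guarantees this); a count outside that range raises
    ConsistencyError. Subsets are keyed by m and carry dense labels in
    sorted-SH order. Only non-empty subsets are returned.
    """
    counts = Counter(r.sh_code for r in records)
    bad = {sh: c for sh, c in counts.items() if not (min_m <= c <= max_m)}
    if bad:
        raise ConsistencyError(
            f"SH counts outside {min_m}..{max_m} after preprocessing: {bad}")
    by_m: dict[int, list[SequenceRecord]] = defaultdict(list)
    for record in records:
        by_m[counts[record.sh_code]].append(record)
    subsets: dict[int, ITSSubset] = {}
    for m in sorted(by_m):
        members = by_m[m]
        sh_codes = sorted({r.sh_code for r in members})
        subset = ITSSubset(
            m=m, records=members,
            sh_index={sh: i for i, sh in enumerate(sh_codes)},
        )
        subset.validate()
        subsets[m] = subset
    return subsets


def subsample_for_eval(
    subset: ITSSubset, target_per_sh: int = EVAL_SUBSAMPLE_TARGET, seed: int = 0
) -> ITSSubset:
    """Randomly reduce a subset to ``target_per_sh`` sequences per SH.

    Applied to ITSset_10 before cross-validation so the largest subset is
    evaluated on 5 sequences per SH with 5-fold CV. Class labels are
    preserved.
    """
    if target_per_sh > subset.m:
        raise ValueError(
            f"target_per_sh={target_per_sh} exceeds subset regularity m={subset.m}")
    if target_per_sh == subset.m:
        return subset
    keep: set[int] = set()
    for sh_code, indices in _group_by_sh(subset.records).items():
        ordered = _by_accession(subset.records, indices)
        rng = np.random.default_rng(derive_seed(seed, "subsample", sh_code))
        chosen = rng.choice(len(ordered), size=target_per_sh, replace=False)
        keep.update(ordered[int(i)] for i in chosen)
    records = [r for i, r in enumerate(subset.records) if i in keep]
    out = ITSSubset(m=target_per_sh, records=records, sh_index=dict(subset.sh_index))
    out.validate()
    return out


def make_cv_folds(subset: ITSSubset, n_folds: int, seed: int = 0) -> CVFoldPlan:
    """Assign each record to a fold so every fold has one record per SH.

    Requires ``n_folds`` equal to the subset's records-per-SH; within each SH
    a seeded permutation spreads the m records over the m folds, so every
    class appears exactly once per fold and in every training split.
    """
    if n_folds != subset.m:
        raise ValueError(
            f"n_folds={n_folds} must equal records-per-SH m={subset.m}")
    assignment: dict[int, int] = {}
    for sh_code, indices in _group_by_sh(subset.records).items():
        ordered = _by_accession(subset.records, indices)
        rng = np.random.default_rng(derive_seed(seed, "folds", sh_code))
        perm = rng.permutation(n_folds)
        for pos, record_idx in enumerate(ordered):
            assignment[record_idx] = int(perm[pos])
    return CVFoldPlan(n_folds=n_folds, assignment=assignment, seed=seed)


@dataclass
class BuildReport:
    """Stage-by-stage record/SH counts plus the filter's removal reasons."""

    stages: list[tuple[str, int, int]]  # (stage, n_sequences, n_SHs)
    removals: Counter = field(default_factory=Counter)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages, columns=["stage", "sequences", "SHs"])


def build_dataset(
    records: Sequence[SequenceRecord],
    max_per_sh: int = MAX_PER_SH,
    seed: int = 0,
) -> tuple[dict[int, ITSSubset], BuildReport]:
    """Full construction pipeline: filter -> drop singletons -> cap -> partition."""

    def n_sh(recs):
        return len({r.sh_code for r in recs})

    stages = [("input", len(records), n_sh(records))]
    filtered, removals = filter_unidentified(records)
    stages.append(("filtered", len(filtered), n_sh(filtered)))
    no_singletons = drop_singletons(filtered)
    stages.append(("singletons-dropped", len(no_singletons), n_sh(no_singletons)))
    capped = cap_per_sh(no_singletons, max_per_sh=max_per_sh,
                        seed=derive_seed(seed, "cap-stage"))
    stages.append(("capped", len(capped), n_sh(capped)))
    subsets = partition_subsets(capped, max_m=max_per_sh)
    report = BuildReport(stages=stages, removals=removals)
    for stage, n_seq, n in stages:
        logger.info("build_dataset: %-18s %6d sequences, %5d SHs", stage, n_seq, n)
    return subsets, report
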