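"""Differential protein-list set algebra across conditions and replicates.

This is the analytical core of the pipeline:

1. *Background subtraction* — per biological replicate, proteins detected in
   the corresponding non-transgenic sample are removed from each
   TurboID-positive list, leaving proteins attributable to ligase-catalysed
   labelling.
2. *Venn partitioning* — the per-replicate revised lists are unioned within
   condition, and the trained vs control unions are partitioned into
   trained-unique (the *learning proteome*), control-unique, and shared
   proteins.  A protein appearing in trained lists of >=1 replicate and in
   control lists of >=1 (possibly different) replicate counts as shared.
3. *Replicate-occurrence counting and classification* — each candidate is
   counted across replicates and classified *strong* when detected in at
   least ``strong_min`` (default 3) of them, *weak* otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Set, Tuple

from .hits import HitSet
from .records import GROUPS, TIERS, ContractError

Sample = Tuple[str, int]


@dataclass(frozen=True)
class ConditionLists:
    """Per-replicate background-subtracted protein lists per condition."""

    trained: Mapping[int, FrozenSet[str]]
    control: Mapping[int, FrozenSet[str]]
    tier: str = "assigned_only"

    @property
    def replicates(self) -> List[int]:
        return sorted(self.trained)


@dataclass(frozen=True)
class VennPartition:
    """Disjoint partition of trained vs control protein unions.

    ``trained_unique`` is the learning proteome: proteins detected (after
    non-transgenic subtraction) only in trained samples, in any replicate.
    """

    trained_unique: FrozenSet[str]
    control_unique: FrozenSet[str]
    shared: FrozenSet[str]

    @property
    def trained_total(self) -> int:
        """All trained-detected proteins: unique + shared."""
        return len(self.trained_unique) + len(self.shared)

    @property
    def control_total(self) -> int:
        return len(self.control_unique) + len(self.shared)

    def summary(self) -> Dict[str, int]:
        return {
            "trained_unique": len(self.trained_unique),
            "control_unique": len(self.control_unique),
            "shared": len(self.shared),
            "trained_total": self.trained_total,
            "control_total": self.control_total,
        }


def venn_totals(trained_unique: int, control_unique: int, shared: int) -> Dict[str, int]:
    """The arithmetic identity behind any Venn summary, on bare counts."""
    return {
        "trained_unique": trained_unique,
        "control_unique": control_unique,
        "shared": shared,
        "trained_total": trained_unique + shared,
        "control_total": control_unique + shared,
    }


@dataclass(frozen=True)
class CandidateRecord:
    """Occurrence counts and strength call for one learning-proteome protein."""

    accession: str
    gene: Optional[str]
    n_trained_assigned: int
    n_control_assigned: int
    n_trained_all: int
    strength: str  # "strong" | "weak"


def subtract_background(target: Set[str], background: Set[str]) -> Set[str]:
    """Set difference ``target \\ background`` (non-transgenic subtraction)."""
    return set(target) - set(background)


def derive_condition_lists(
    hits: Mapping[Sample, HitSet], tier: str = "assigned_only"
) -> ConditionLists:
    """Background-subtract each TurboID sample against its non-Tg counterpart.

    The subtraction is strictly per replicate: TurboID-trained replicate *r*
    minus non-Tg-trained replicate *r*, and likewise for the control arm.
    All four groups must be present for every replicate used.
    """
    if tier not in TIERS:
        raise ContractError(f"unknown tier {tier!r}; expected one of {TIERS}")
    replicates = sorted({rep for (_, rep) in hits})
    if not replicates:
        raise ContractError("no samples provided")
    for rep in replicates:
        for group in GROUPS:
            if (group, rep) not in hits:
                raise ContractError(f"missing sample ({group!r}, replicate {rep})")
    trained = {}
    control = {}
    for rep in replicates:
        trained[rep] = frozenset(subtract_background(
            hits[("turbo_trained", rep)].combined(tier),
            hits[("nonTg_trained", rep)].combined(tier),
        ))
        control[rep] = frozenset(subtract_background(
            hits[("turbo_control", rep)].combined(tier),
            hits[("nonTg_control", rep)].combined(tier),
        ))
    return ConditionLists(trained=trained, control=control, tier=tier)


def build_venn(lists: ConditionLists) -> VennPartition:
    """Union within condition across replicates, then partition."""
    if not lists.trained and not lists.control:
        raise ContractError("empty condition lists")
    t: Set[str] = set().union(*lists.trained.values()) if lists.trained else set()
    c: Set[str] = set().union(*lists.control.values()) if lists.control else set()
    return VennPartition(
        trained_unique=frozenset(t - c),
        control_unique=frozenset(c - t),
        shared=frozenset(t & c),
    )


def count_occurrences(accession: str, lists: ConditionLists) -> Tuple[int, int]:
    """(n trained replicates, n control replicates) containing ``accession``."""
    n_trained = sum(1 for members in lists.trained.values() if accession in members)
    n_control = sum(1 for members in lists.control.values() if accession in members)
    return n_trained, n_control


def classify_candidate(n_trained_all: int, strong_min: int = 3) -> str:
    """Strong iff detected in >= ``strong_min`` replicates (inclusive)."""
    if n_trained_all < 0:
        raise ContractError("replicate count cannot be negative")
    return "strong" if n_trained_all >= strong_min else "weak"


def build_candidate_table(
    accessions: Iterable[str],
    assigned_lists: ConditionLists,
    all_lists: ConditionLists,
    strong_min: int = 3,
    gene_of=None,
) -> List[CandidateRecord]:
    """Occurrence counts at both hit tiers plus a strength call per protein.

    ``assigned_lists`` must be derived at the assigned-only tier and
    ``all_lists`` at the assigned+unassigned tier; the strength call uses
    the latter, which is the more sensitive detection record.
    """
    out = []
    for acc in sorted(set(accessions)):
        n_tr_assigned, n_ct_assigned = count_occurrences(acc, assigned_lists)
        n_tr_all, _ = count_occurrences(acc, all_lists)
        out.append(CandidateRecord(
            accession=acc,
            gene=gene_of(acc) if gene_of else None,
            n_trained_assigned=n_tr_assigned,
            n_control_assigned=n_ct_assigned,
            n_trained_all=n_tr_all,
            strength=classify_candidate(n_tr_all, strong_min=strong_min),
        ))
    return out


def write_candidate_table(records: Iterable[CandidateRecord], path) -> None:
    import csv
    from pathlib import Path

    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow([
            "accession", "gene", "n_trained_assigned",
            "n_control_assigned", "n_trained_all", "strength",
        ])
        for rec in records:
            writer.writerow([
                rec.accession, rec.gene or "", rec.n_trained_assigned,
                rec.n_control_assigned, rec.n_trained_all, rec.strength,
            ])
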