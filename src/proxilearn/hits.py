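"""Protein hit calling for one sample: assigned hits and peptide rescue.

A protein is an *assigned hit* in a sample when the search engine reported at
least one peptide unique to it — no score threshold is applied at this stage,
which keeps sensitivity for low-abundance neuronal proteins.

Peptides the engine could not attribute to a protein ("unassigned") are
*rescued* by searching the proteome for exact substring occurrences, the
offline equivalent of a 100%-identity short-peptide database search.  A match
is accepted only when the peptide's score is >= ``score_min`` (inclusive) and
its expect value under an iid residue-composition model is below
``evalue_max``.

Expect model
------------
With per-residue background frequencies ``f`` estimated from the database
(add-one smoothed over the 20-residue alphabet) and a peptide ``p`` of length
``L``, the expected number of chance occurrences of ``p`` among the database's
length-``L`` windows is::

    E = S(L) * prod_i f(p_i),   S(L) = max(1, total_residues - n_proteins*(L-1))

``S(L)`` counts the length-``L`` windows in the database.  ``E`` decreases
strictly when a residue is appended (every ``f < 1`` and ``S`` is
non-increasing in ``L``), so longer exact matches are always more significant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from .records import (
    AMINO_ACIDS,
    ContractError,
    ProteomeDb,
    PsmRecord,
    TIERS,
)


@dataclass(frozen=True)
class RescueParams:
    """Thresholds for rescuing unassigned peptides.

    ``score_min`` is inclusive (a peptide scoring exactly at the threshold is
    considered); ``evalue_max`` is exclusive (the expect value must be
    strictly below it).  ``min_peptide_len`` guards against spurious very
    short matches that a sequence-similarity search would never report.
    """

    score_min: float = 15.0
    evalue_max: float = 0.05
    min_peptide_len: int = 6

    def __post_init__(self) -> None:
        if self.score_min < 0:
            raise ContractError("score_min must be >= 0")
        if not (0 <= self.evalue_max <= 1):
            raise ContractError("evalue_max must be in [0, 1]")
        if self.min_peptide_len < 1:
            raise ContractError("min_peptide_len must be >= 1")


@dataclass(frozen=True)
class RescueRow:
    """Audit-trail row for one considered unassigned peptide."""

    peptide: str
    score: float
    accessions: Tuple[str, ...]
    expect: Optional[float]
    accepted: bool

    @property
    def n_matches(self) -> int:
        return len(self.accessions)

    @property
    def ambiguous(self) -> bool:
        return len(self.accessions) > 1


@dataclass
class HitSet:
    """Assigned and rescued protein hits for one (group, replicate) sample."""

    sample: Tuple[str, int]
    assigned: Set[str]
    rescued: Set[str] = field(default_factory=set)
    rescue_report: List[RescueRow] = field(default_factory=list)

    def combined(self, tier: str = "assigned_plus_unassigned") -> Set[str]:
        if tier not in TIERS:
            raise ContractError(f"unknown tier {tier!r}; expected one of {TIERS}")
        if tier == "assigned_only":
            return set(self.assigned)
        return set(self.assigned) | set(self.rescued)


def _check_single_sample(psms: Sequence[PsmRecord]) -> Optional[Tuple[str, int]]:
    samples = {rec.sample for rec in psms}
    if len(samples) > 1:
        raise ContractError(
            f"records from multiple samples passed: {sorted(samples)}"
        )
    return next(iter(samples)) if samples else None


def call_assigned_hits(psms: Sequence[PsmRecord]) -> Set[str]:
    """Accessions with >=1 unique peptide in this sample (no score cutoff)."""
    _check_single_sample(psms)
    return {rec.accession for rec in psms if rec.accession and rec.is_unique}


def residue_frequencies(db: ProteomeDb) -> Dict[str, float]:
    """Add-one-smoothed residue frequencies over the 20-letter alphabet."""
    counts = dict.fromkeys(AMINO_ACIDS, 0)
    for _, seq in db.records.values():
        for ch in seq:
            counts[ch] += 1
    denom = db.total_residues + len(AMINO_ACIDS)
    return {aa: (counts[aa] + 1) / denom for aa in AMINO_ACIDS}


def n_windows(db: ProteomeDb, length: int) -> int:
    """Number of length-``length`` windows in the database, floored at 1."""
    return max(1, db.total_residues - db.n_proteins * (length - 1))


def peptide_expect(
    peptide: str, db: ProteomeDb, freqs: Optional[Dict[str, float]] = None
) -> float:
    """Expected chance occurrences of ``peptide`` among database windows.

    For peptides longer than every database sequence the window count
    degenerates; the value is still defined (computed with S=1) so callers
    can report rather than crash on pathological input.
    """
    if not peptide:
        raise ContractError("peptide must be non-empty")
    if freqs is None:
        freqs = residue_frequencies(db)
    log_p = sum(math.log(freqs[ch]) for ch in peptide)
    return n_windows(db, len(peptide)) * math.exp(log_p)


def rescue_unassigned(
    psms: Sequence[PsmRecord], db: ProteomeDb, params: RescueParams = RescueParams()
) -> Tuple[Set[str], List[RescueRow]]:
    """Rescue protein identities from unassigned peptides.

    Only unassigned records with ``score >= score_min`` and length
    >= ``min_peptide_len`` are considered.  A peptide is accepted iff it is
    an exact substring of at least one database sequence and its expect
    value is strictly below ``evalue_max``; every matching accession is
    rescued (ambiguous matches are flagged in the report, not dropped).
    Returns ``(rescued accessions, report)`` with one report row per
    considered peptide.
    """
    _check_single_sample(psms)
    freqs = residue_frequencies(db)
    rescued: Set[str] = set()
    report: List[RescueRow] = []
    seen: Set[str] = set()  # one report row per distinct considered peptide
    for rec in psms:
        if rec.accession is not None:
            continue
        if rec.score < params.score_min:
            continue
        if len(rec.peptide) < params.min_peptide_len:
            continue
        if rec.peptide in seen:
            continue
        seen.add(rec.peptide)
        matches = tuple(
            acc for acc, (_, seq) in db.records.items() if rec.peptide in seq
        )
        expect = peptide_expect(rec.peptide, db, freqs) if matches else None
        accepted = bool(matches) and expect is not None and expect < params.evalue_max
        if accepted:
            rescued.update(matches)
        report.append(RescueRow(
            peptide=rec.peptide,
            score=rec.score,
            accessions=matches,
            expect=expect,
            accepted=accepted,
        ))
    return rescued, report


def call_hits(
    psms: Sequence[PsmRecord],
    db: Optional[ProteomeDb] = None,
    params: RescueParams = RescueParams(),
    sample: Optional[Tuple[str, int]] = None,
) -> HitSet:
    """Full hit calling for one sample: assigned hits plus rescue.

    When no database is given only assigned hits are called (the rescued
    set stays empty).  ``sample`` identifies the (group, replicate) when the
    record list may legitimately be empty.
    """
    observed = _check_single_sample(psms)
    if observed is not None and sample is not None and observed != sample:
        raise ContractError(f"records are from {observed}, not {sample}")
    sample = observed or sample
    if sample is None:
        raise ContractError("cannot call hits on an empty, unlabelled record list")
    assigned = call_assigned_hits(psms)
    if db is None:
        return HitSet(sample=sample, assigned=assigned)
    rescued, report = rescue_unassigned(psms, db, params)
    return HitSet(sample=sample, assigned=assigned, rescued=rescued,
                  rescue_report=report)


def write_rescue_report(report: Iterable[RescueRow], path) -> None:
    """Write the rescue audit trail as TSV."""
    import csv
    from pathlib import Path

    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["peptide", "score", "n_matches", "accessions", "expect", "accepted"]
        )
        for row in report:
            writer.writerow([
                row.peptide,
                row.score,
                row.n_matches,
                ";".join(row.accessions),
                "" if row.expect is None else f"{row.expect:.6g}",
                int(row.accepted),
            ])
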