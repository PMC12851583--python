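"""Core in-memory containers shared across the pipeline.

The pipeline operates on four kinds of records:

* :class:`PsmRecord` — one peptide observation from a search-engine export,
  belonging to one experimental sample (group x biological replicate).
* :class:`ProteomeDb` — the protein search database (accession -> sequence,
  with an optional gene symbol per accession) used for peptide rescue.
* :class:`ExpressionMatrix` — a neuron-class x gene expression matrix with a
  detection threshold, the substrate for neuron-class representation analyses.
* :class:`PlateCount` — worm counts per scoring zone of one chemotaxis plate
  (one technical replicate).

All containers validate on construction and raise :class:`FormatError` /
:class:`ContractError` rather than repairing bad input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

#: The 20 canonical amino-acid one-letter codes.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

#: The four experimental groups of the labelling design: non-transgenic
#: animals (no biotin ligase) and TurboID-expressing animals, each either
#: conditioned with high salt ("control") or with no salt + food ("trained").
GROUPS = ("nonTg_control", "nonTg_trained", "turbo_control", "turbo_trained")

#: Hit tiers used when building per-replicate protein lists.
TIERS = ("assigned_only", "assigned_plus_unassigned")


class ProxilearnError(Exception):
    """Base class for all package errors."""


class FormatError(ProxilearnError, ValueError):
    """Malformed on-disk input (missing column, bad residue, ragged row...)."""


class ConfigError(ProxilearnError, ValueError):
    """Invalid configuration value; the message names the offending field."""


class ContractError(ProxilearnError, ValueError):
    """An operation was called outside its contract (e.g. mixed samples)."""


def _check_peptide(peptide: str) -> None:
    if not peptide:
        raise FormatError("peptide must be a non-empty amino-acid string")
    bad = set(peptide) - _AA_SET
    if bad:
        raise FormatError(
            f"peptide {peptide!r} contains invalid residue(s): "
            + ",".join(sorted(bad))
        )


@dataclass(frozen=True)
class PsmRecord:
    """One peptide-spectrum match in one sample.

    ``accession is None`` marks an *unassigned* peptide: the search engine
    produced a sequence and score but could not attribute the peptide to a
    protein.  Such rows are candidates for rescue (see
    :mod:`proxilearn.hits`).  Unassigned rows can never be flagged unique.
    """

    group: str
    replicate: int
    accession: Optional[str]
    gene: Optional[str]
    peptide: str
    score: float
    is_unique: bool

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise FormatError(
                f"unknown group {self.group!r}; expected one of {GROUPS}"
            )
        if self.replicate < 1:
            raise FormatError("replicate must be a positive integer")
        _check_peptide(self.peptide)
        if self.score < 0:
            raise FormatError(f"score must be >= 0, got {self.score}")
        if self.accession is None and self.is_unique:
            raise FormatError("an unassigned peptide cannot be flagged unique")

    @property
    def sample(self) -> Tuple[str, int]:
        return (self.group, self.replicate)


@dataclass(frozen=True)
class ProteomeDb:
    """Accession -> (gene, amino-acid sequence) mapping.

    Stands in for the reference-protein search database: peptide rescue
    looks for exact substring matches against these sequences, and the
    expect-value model is parameterised by their residue composition.
    """

    records: Mapping[str, Tuple[Optional[str], str]]

    def __post_init__(self) -> None:
        if not self.records:
            raise FormatError("proteome database is empty")
        for acc, (gene, seq) in self.records.items():
            if not seq:
                raise FormatError(f"empty sequence for accession {acc!r}")
            bad = set(seq) - _AA_SET
            if bad:
                raise FormatError(
                    f"sequence for {acc!r} contains invalid residue(s): "
                    + ",".join(sorted(bad))
                )

    @property
    def n_proteins(self) -> int:
        return len(self.records)

    @property
    def total_residues(self) -> int:
        return sum(len(seq) for _, seq in self.records.values())

    @property
    def max_length(self) -> int:
        return max(len(seq) for _, seq in self.records.values())

    def sequence(self, accession: str) -> str:
        return self.records[accession][1]

    def gene(self, accession: str) -> Optional[str]:
        return self.records[accession][0]

    def genes_for(self, accessions) -> list:
        """Gene symbols for a set of accessions (falling back to the
        accession itself where no gene is recorded), sorted, deduplicated."""
        out = {self.gene(a) or a for a in accessions}
        return sorted(out)


@dataclass(frozen=True)
class ExpressionMatrix:
    """Neuron-class x gene expression values with a detection threshold.

    A gene is *called expressed* in a class when its value is >= ``threshold``
    (inclusive cutoff).  Mirrors the bulk-query behaviour of neuron-resolved
    expression resources, where the threshold is a stringency level for a
    detection call.
    """

    values: pd.DataFrame  # index = neuron classes, columns = genes
    threshold: float

    def __post_init__(self) -> None:
        df = self.values
        if df.index.has_duplicates:
            raise FormatError("duplicate neuron-class names in matrix")
        if df.columns.has_duplicates:
            raise FormatError("duplicate gene names in matrix")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError("expression matrix contains non-numeric cells")
        if np.isnan(arr).any():
            raise FormatError("expression matrix contains missing values")
        if (arr < 0).any():
            raise FormatError("expression values must be non-negative")
        if self.threshold < 0:
            raise FormatError("threshold must be non-negative")

    @property
    def classes(self) -> Sequence[str]:
        return list(self.values.index)

    @property
    def genes(self) -> Sequence[str]:
        return list(self.values.columns)


#: Group labels for the appetitive (salt-associative) paradigm ...
ASSAY_GROUPS_ASSOCIATIVE = ("naive", "high_salt_control", "trained")
#: ... and for the aversive paradigm (conditioned = salt + starvation).
ASSAY_GROUPS_AVERSIVE = ("naive", "mock_conditioned", "conditioned")


@dataclass(frozen=True)
class PlateCount:
    """Worm counts for one chemotaxis plate (one technical replicate).

    ``n_high``/``n_low`` are animals immobilised in the high-/low-salt
    scoring zones, ``n_origin`` those remaining at the origin, ``n_total``
    the whole plated population (which may exceed the sum of the three
    zones when animals wander off-zone).
    """

    genotype: str
    group: str
    bio_rep: int
    tech_rep: int
    n_high: int
    n_low: int
    n_origin: int
    n_total: int

    def __post_init__(self) -> None:
        for name in ("n_high", "n_low", "n_origin", "n_total"):
            if getattr(self, name) < 0:
                raise FormatError(f"{name} must be >= 0")
        if self.bio_rep < 1 or self.tech_rep < 1:
            raise FormatError("replicate indices must be positive")
        if self.n_high + self.n_low + self.n_origin > self.n_total:
            raise FormatError(
                "zone counts exceed total population: "
                f"{self.n_high}+{self.n_low}+{self.n_origin} > {self.n_total}"
            )
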