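"""Gene-list analyses against a neuron-class expression matrix.

Two summaries are computed from a thresholded neuron-class x gene matrix:

* *Percent neuronal* — the fraction of a gene list expressed (value >=
  threshold) in at least one neuron class; a sanity check that a proteome
  captured from the nervous system is, in fact, neuronal.
* *Neuron-class representation ranking* — per-class counts of genes from the
  trained-unique and control-unique lists, with the trained counts divided
  by the list-size ratio ``f = |trained| / |control|`` so that equal
  per-class densities give fold change 1, then classes ranked by descending
  fold change.  Only classes represented in **both** lists are ranked
  (fold change is undefined otherwise); the rest are reported as excluded.

The ranking is descriptive: no significance is attached to ranks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .records import ContractError, ExpressionMatrix


@dataclass(frozen=True)
class NeuronalSummary:
    """Percent-neuronal result; the unrounded percentage is retained."""

    n_genes: int
    n_expressed: int
    missing_genes: Tuple[str, ...]  # genes absent from the matrix

    @property
    def percent(self) -> float:
        return 100.0 * self.n_expressed / self.n_genes

    @property
    def percent_rounded(self) -> int:
        return int(round(self.percent))


@dataclass(frozen=True)
class RankRow:
    neuron_class: str
    n_trained: int
    n_control: int
    n_trained_norm: float
    fold_change: float
    rank: int


@dataclass(frozen=True)
class RankingResult:
    norm_factor: float
    rows: Tuple[RankRow, ...]
    excluded_classes: Tuple[str, ...]

    def rank_of(self, neuron_class: str) -> Optional[int]:
        for row in self.rows:
            if row.neuron_class == neuron_class:
                return row.rank
        return None


def expressed_classes(gene: str, matrix: ExpressionMatrix) -> Set[str]:
    """Neuron classes where ``gene`` is called expressed (value >= threshold).

    A gene absent from the matrix yields the empty set (callers that need to
    distinguish absence use :func:`percent_neuronal`'s ``missing_genes``).
    """
    if gene not in matrix.values.columns:
        return set()
    col = matrix.values[gene]
    return set(col.index[col >= matrix.threshold])


def percent_neuronal(genes: Sequence[str], matrix: ExpressionMatrix) -> NeuronalSummary:
    """Share of ``genes`` expressed in >=1 neuron class at the threshold."""
    genes = list(dict.fromkeys(genes))  # dedupe, order-preserving
    if not genes:
        raise ContractError("percent_neuronal requires a non-empty gene list")
    missing = tuple(g for g in genes if g not in matrix.values.columns)
    present = [g for g in genes if g not in set(missing)]
    if present:
        sub = matrix.values[present].to_numpy()
        n_expressed = int(((sub >= matrix.threshold).any(axis=0)).sum())
    else:
        n_expressed = 0
    return NeuronalSummary(
        n_genes=len(genes), n_expressed=n_expressed, missing_genes=missing
    )


def class_counts(
    genes: Sequence[str], matrix: ExpressionMatrix
) -> Tuple[Dict[str, int], Tuple[str, ...]]:
    """Per-class count of list genes expressed in that class.

    Returns ``(counts, missing_genes)``; genes absent from the matrix
    contribute nothing and are reported rather than silently dropped.
    """
    genes = list(dict.fromkeys(genes))
    missing = tuple(g for g in genes if g not in matrix.values.columns)
    present = [g for g in genes if g not in set(missing)]
    counts = dict.fromkeys(matrix.classes, 0)
    if present:
        calls = matrix.values[present].to_numpy() >= matrix.threshold
        for cls, n in zip(matrix.classes, calls.sum(axis=1)):
            counts[cls] = int(n)
    return counts, missing


def normalisation_factor(n_trained: int, n_control: int) -> float:
    """List-size ratio ``f = |trained| / |control|`` used to normalise counts."""
    if n_control <= 0:
        raise ContractError("control gene list must be non-empty")
    if n_trained <= 0:
        raise ContractError("trained gene list must be non-empty")
    return n_trained / n_control


def rank_neuron_classes(
    trained_genes: Sequence[str],
    control_genes: Sequence[str],
    matrix: ExpressionMatrix,
) -> RankingResult:
    """Rank neuron classes by normalised trained/control representation.

    Per class: ``fold_change = (n_trained / f) / n_control`` with
    ``f = |trained_genes| / |control_genes|``.  Classes lacking genes from
    either list are excluded.  Ties are broken by class name (ascending) for
    determinism; ranks are contiguous from 1.
    """
    f = normalisation_factor(
        len(dict.fromkeys(trained_genes)), len(dict.fromkeys(control_genes))
    )
    trained_counts, _ = class_counts(trained_genes, matrix)
    control_counts, _ = class_counts(control_genes, matrix)
    scored: List[Tuple[str, int, int, float, float]] = []
    excluded: List[str] = []
    for cls in matrix.classes:
        n_t, n_c = trained_counts[cls], control_counts[cls]
        if n_t >= 1 and n_c >= 1:
            n_t_norm = n_t / f
            scored.append((cls, n_t, n_c, n_t_norm, n_t_norm / n_c))
        else:
            excluded.append(cls)
    scored.sort(key=lambda item: (-item[4], item[0]))
    rows = tuple(
        RankRow(
            neuron_class=cls, n_trained=n_t, n_control=n_c,
            n_trained_norm=n_t_norm, fold_change=fc, rank=i,
        )
        for i, (cls, n_t, n_c, n_t_norm, fc) in enumerate(scored, start=1)
    )
    return RankingResult(
        norm_factor=f, rows=rows, excluded_classes=tuple(sorted(excluded))
    )


def write_ranking(result: RankingResult, path) -> None:
    """Ranking as TSV with a leading summary block (comment lines)."""
    import csv
    from pathlib import Path

    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        fh.write(f"# norm_factor\t{result.norm_factor:.6g}\n")
        fh.write(f"# n_ranked_classes\t{len(result.rows)}\n")
        fh.write(f"# n_excluded_classes\t{len(result.excluded_classes)}\n")
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow([
            "class", "n_trained", "n_control", "n_trained_norm",
            "fold_change", "rank",
        ])
        for row in result.rows:
            writer.writerow([
                row.neuron_class, row.n_trained, row.n_control,
                f"{row.n_trained_norm:.6g}", f"{row.fold_change:.6g}", row.rank,
            ])
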