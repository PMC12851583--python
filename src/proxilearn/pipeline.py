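"""End-to-end analysis: hit calling -> condition lists -> Venn -> candidates
-> percent neuronal -> neuron-class ranking, with every stage written as TSV
plus a run manifest.

The pipeline consumes a bundle directory (as written by
:func:`proxilearn.synth.write_bundle`, or assembled from real exports in the
same layout) and writes its outputs to a separate directory.  All outputs
are deterministic functions of the inputs.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

from . import io as pio
from .enrich import percent_neuronal, rank_neuron_classes, write_ranking
from .hits import HitSet, RescueParams, call_hits, write_rescue_report
from .records import ContractError, GROUPS
from .sets import (
    build_candidate_table,
    build_venn,
    derive_condition_lists,
    write_candidate_table,
)
from .synth import read_bundle_psm_tables


@dataclass
class PipelineConfig:
    """Paths and parameters for one pipeline run."""

    bundle_dir: Path
    out_dir: Path
    rescue: RescueParams = field(default_factory=RescueParams)
    strong_min: int = 3
    venn_tier: str = "assigned_only"
    expression_threshold: float = 2.0


@dataclass
class PipelineReport:
    venn_summary: Dict[str, int]
    n_candidates: int
    n_strong: int
    percent_neuronal_trained: float
    norm_factor: float
    top_classes: List[str]
    learning_proteome: List[str]


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    bundle_dir = Path(config.bundle_dir)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    proteome = pio.read_fasta(bundle_dir / "proteome.fasta")
    expression = pio.read_expression_matrix(
        bundle_dir / "expression_matrix.tsv", threshold=config.expression_threshold
    )
    tables = read_bundle_psm_tables(bundle_dir)
    if not tables:
        raise ContractError(f"no PSM tables found in {bundle_dir}")
    replicates = sorted({rep for (_, rep) in tables})

    # stage 1: per-sample hit calling (assigned + rescued)
    hits: Dict[Tuple[str, int], HitSet] = {}
    for group in GROUPS:
        for rep in replicates:
            key = (group, rep)
            if key not in tables:
                raise ContractError(f"missing sample {key} in {bundle_dir}")
            hits[key] = call_hits(
                tables[key], db=proteome, params=config.rescue, sample=key
            )
    all_report = [row for hs in hits.values() for row in hs.rescue_report]
    write_rescue_report(all_report, out_dir / "rescue_report.tsv")

    # stage 2: per-replicate background subtraction at both tiers
    assigned_lists = derive_condition_lists(hits, tier="assigned_only")
    all_lists = derive_condition_lists(hits, tier="assigned_plus_unassigned")
    for rep in replicates:
        pio.write_accession_list(
            assigned_lists.trained[rep], out_dir / f"trained_rep{rep}_revised.tsv"
        )
        pio.write_accession_list(
            assigned_lists.control[rep], out_dir / f"control_rep{rep}_revised.tsv"
        )

    # stage 3: Venn partition (learning proteome) on the configured tier
    venn_lists = assigned_lists if config.venn_tier == "assigned_only" else all_lists
    venn = build_venn(venn_lists)
    pio.write_accession_list(venn.trained_unique, out_dir / "venn_trained_unique.tsv")
    pio.write_accession_list(venn.control_unique, out_dir / "venn_control_unique.tsv")
    pio.write_accession_list(venn.shared, out_dir / "venn_shared.tsv")
    with (out_dir / "venn_summary.tsv").open("w", encoding="utf-8") as fh:
        for key, value in venn.summary().items():
            fh.write(f"{key}\t{value}\n")

    # stage 4: occurrence counting + strong/weak classification
    candidates = build_candidate_table(
        venn.trained_unique, assigned_lists, all_lists,
        strong_min=config.strong_min,
        gene_of=lambda acc: proteome.gene(acc) if acc in proteome.records else None,
    )
    write_candidate_table(candidates, out_dir / "candidate_table.tsv")

    # stage 5: percent neuronal + neuron-class ranking on gene lists
    trained_genes = proteome.genes_for(venn.trained_unique)
    control_genes = proteome.genes_for(venn.control_unique)
    pct = percent_neuronal(trained_genes, expression) if trained_genes else None
    if trained_genes and control_genes:
        ranking = rank_neuron_classes(trained_genes, control_genes, expression)
        write_ranking(ranking, out_dir / "neuron_class_ranking.tsv")
        norm_factor = ranking.norm_factor
        top = [row.neuron_class for row in ranking.rows[:20]]
    else:
        ranking, norm_factor, top = None, float("nan"), []

    report = PipelineReport(
        venn_summary=venn.summary(),
        n_candidates=len(candidates),
        n_strong=sum(1 for c in candidates if c.strength == "strong"),
        percent_neuronal_trained=pct.percent if pct else float("nan"),
        norm_factor=norm_factor,
        top_classes=top,
        learning_proteome=sorted(venn.trained_unique),
    )
    _write_manifest(config, bundle_dir, out_dir, report)
    return report


def _write_manifest(
    config: PipelineConfig, bundle_dir: Path, out_dir: Path, report: PipelineReport
) -> None:
    lines = [
        f"bundle_dir\t{bundle_dir}",
        f"venn_tier\t{config.venn_tier}",
        f"strong_min\t{config.strong_min}",
        f"score_min\t{config.rescue.score_min}",
        f"evalue_max\t{config.rescue.evalue_max}",
        f"min_peptide_len\t{config.rescue.min_peptide_len}",
        f"expression_threshold\t{config.expression_threshold}",
    ]
    for name in ("proteome.fasta", "expression_matrix.tsv"):
        path = bundle_dir / name
        if path.exists():
            lines.append(f"sha256[{name}]\t{_checksum(path)}")
    for key, value in report.venn_summary.items():
        lines.append(f"venn[{key}]\t{value}")
    lines.append(f"n_candidates\t{report.n_candidates}")
    lines.append(f"n_strong\t{report.n_strong}")
    lines.append(f"percent_neuronal_trained\t{report.percent_neuronal_trained:.4f}")
    lines.append(f"norm_factor\t{report.norm_factor:.6g}")
    (out_dir / "run_manifest.txt").write_text("\n".join(lines) + "\n", encoding="utf-8")
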