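"""Seeded generator for a complete synthetic labelling experiment.

The generator emulates the statistical structure of a whole-nervous-system
proximity-labelling study of salt associative learning: four experimental
groups (non-transgenic control / trained, TurboID control / trained) x five
biological replicates of search-engine-style peptide tables, a toy proteome,
a thresholded neuron-class x gene expression matrix, chemotaxis plate
counts, and the ground truth needed to score downstream recovery.

Planted structure
-----------------
* *trained-specific* proteins appear (stochastically, with
  ``detect_prob_signal`` per replicate) only in TurboID-trained samples —
  the ground-truth learning proteome;
* *control-specific* proteins likewise only in TurboID-control samples;
* *shared background* proteins (ribosomal/mitochondrial-like contaminants)
  appear in any TurboID sample with ``detect_prob_background`` per
  replicate, never in non-transgenic samples;
* *endogenously biotinylated* proteins (carboxylase-like, highly abundant)
  appear in **every** sample of every group, so per-replicate
  non-transgenic subtraction removes them exactly.

Every emitted peptide is an exact substring of its source protein; a
fraction ``unassigned_frac`` of peptide rows is emitted without an
accession to exercise the rescue stage.  Assigned peptide scores are drawn
from a "confident" normal distribution and unassigned ones from an even
mixture of confident and marginal distributions, so the score threshold of
the rescue stage separates them imperfectly, as in real exports.

Determinism: one seed per bundle; every sub-stream (proteome, expression,
plates, each group x replicate table) is derived from it with a fixed
spawn key, with groups ordered alphabetically and replicates ascending, so
identical configurations yield byte-identical bundles.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import io as pio
from .records import (
    AMINO_ACIDS,
    ASSAY_GROUPS_ASSOCIATIVE,
    ConfigError,
    ExpressionMatrix,
    GROUPS,
    PlateCount,
    ProteomeDb,
    PsmRecord,
)

# Mildly non-uniform residue weights (loosely mimicking natural proteome
# composition) so the expect model sees non-trivial frequencies.
_RESIDUE_WEIGHTS = np.array([
    8.3, 1.4, 5.4, 6.2, 3.9, 7.3, 2.3, 5.3, 5.8, 9.7,
    2.4, 4.3, 4.9, 4.0, 5.3, 6.9, 5.5, 6.9, 1.1, 3.3,
])
_RESIDUE_P = _RESIDUE_WEIGHTS / _RESIDUE_WEIGHTS.sum()

# Fixed spawn keys for named sub-streams; PSM tables use an offset keyed by
# (alphabetical group index, replicate) so adding streams never perturbs
# existing ones.
_STREAM_PROTEOME = 0
_STREAM_EXPRESSION = 1
_STREAM_PLATES = 2
_STREAM_PSM_BASE = 10


@dataclass(frozen=True)
class ScoreModel:
    """Peptide-score distributions (normal, clipped at 0)."""

    confident_loc: float = 40.0
    confident_scale: float = 8.0
    marginal_loc: float = 12.0
    marginal_scale: float = 4.0


def _default_ci_means() -> Dict[Tuple[str, str], float]:
    # Naive and high-salt-control animals strongly prefer high salt
    # (CI ~0.8); trained animals shift to a neutral response (CI ~0).
    return {
        ("WT", "naive"): 0.8,
        ("WT", "high_salt_control"): 0.8,
        ("WT", "trained"): 0.0,
    }


@dataclass(frozen=True)
class SynthConfig:
    """Configuration for one synthetic experiment.

    Defaults describe a desk-scale version of the study design: 4 groups x
    5 replicates, ~10% of proteins planted as trained-specific, high
    per-replicate detection of planted signal (0.9) over sparse background
    (0.05), and ~90% of genes neuronal.
    """

    n_proteins: int = 300
    n_neuron_classes: int = 128
    frac_neuronal: float = 0.9
    n_trained_specific: int = 30
    n_control_specific: int = 16
    n_shared_background: int = 20
    n_endogenous_biotin: int = 10
    n_replicates: int = 5
    detect_prob_signal: float = 0.9
    detect_prob_background: float = 0.05
    peptides_per_protein: int = 3
    peptide_len_range: Tuple[int, int] = (8, 20)
    scores: ScoreModel = field(default_factory=ScoreModel)
    unassigned_frac: float = 0.1
    expression_threshold: float = 2.0
    plate_n_worms: int = 100
    n_bio_reps: int = 5
    n_tech_reps: int = 3
    ci_means: Mapping[Tuple[str, str], float] = field(
        default_factory=_default_ci_means
    )
    ci_noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_proteins", "n_neuron_classes", "n_trained_specific",
            "n_control_specific", "n_shared_background", "n_endogenous_biotin",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name in ("n_replicates", "peptides_per_protein", "plate_n_worms",
                     "n_bio_reps", "n_tech_reps"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        for name in ("frac_neuronal", "detect_prob_signal",
                     "detect_prob_background", "unassigned_frac"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1]")
        planted = (self.n_trained_specific + self.n_control_specific
                   + self.n_shared_background + self.n_endogenous_biotin)
        if planted > self.n_proteins:
            raise ConfigError(
                "n_proteins too small: planted sets total "
                f"{planted} > n_proteins={self.n_proteins}"
            )
        lo, hi = self.peptide_len_range
        if not (1 <= lo <= hi):
            raise ConfigError("peptide_len_range must satisfy 1 <= lo <= hi")
        if self.ci_noise_sd < 0:
            raise ConfigError("ci_noise_sd must be >= 0")
        for key, mean in self.ci_means.items():
            if not (-1.0 <= mean <= 1.0):
                raise ConfigError(f"ci_means[{key}] must be in [-1, 1]")
        if self.expression_threshold < 0:
            raise ConfigError("expression_threshold must be >= 0")


@dataclass(frozen=True)
class TruthTable:
    trained_specific: FrozenSet[str]
    control_specific: FrozenSet[str]
    shared_background: FrozenSet[str]
    endogenous_biotin: FrozenSet[str]
    neuronal_genes: FrozenSet[str]

    def __post_init__(self) -> None:
        sets = [self.trained_specific, self.control_specific,
                self.shared_background, self.endogenous_biotin]
        total = sum(len(s) for s in sets)
        if len(frozenset().union(*sets)) != total:
            raise ConfigError("truth accession sets must be pairwise disjoint")


@dataclass(frozen=True)
class SynthBundle:
    config: SynthConfig
    psm_tables: Mapping[Tuple[str, int], Tuple[PsmRecord, ...]]
    proteome: ProteomeDb
    expression: ExpressionMatrix
    plate_counts: Tuple[PlateCount, ...]
    truth: TruthTable


def _rng(config: SynthConfig, key: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(key,))
    )


def _accession(i: int) -> str:
    return f"ACC{i:04d}"


def _gene(i: int) -> str:
    return f"g{i:04d}"


def _make_proteome(config: SynthConfig) -> ProteomeDb:
    rng = _rng(config, _STREAM_PROTEOME)
    records = {}
    alphabet = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)
    for i in range(config.n_proteins):
        length = int(rng.integers(120, 400))
        seq = alphabet[rng.choice(20, size=length, p=_RESIDUE_P)].tobytes().decode()
        records[_accession(i)] = (_gene(i), seq)
    return ProteomeDb(records=records)


def _make_truth(config: SynthConfig, neuronal_genes: FrozenSet[str]) -> TruthTable:
    idx = 0

    def take(n: int) -> FrozenSet[str]:
        nonlocal idx
        out = frozenset(_accession(i) for i in range(idx, idx + n))
        idx += n
        return out

    return TruthTable(
        trained_specific=take(config.n_trained_specific),
        control_specific=take(config.n_control_specific),
        shared_background=take(config.n_shared_background),
        endogenous_biotin=take(config.n_endogenous_biotin),
        neuronal_genes=neuronal_genes,
    )


def _make_expression(config: SynthConfig) -> Tuple[ExpressionMatrix, FrozenSet[str]]:
    rng = _rng(config, _STREAM_EXPRESSION)
    thr = config.expression_threshold
    classes = [f"N{i:03d}" for i in range(config.n_neuron_classes)]
    genes = [_gene(i) for i in range(config.n_proteins)]
    values = np.empty((len(classes), len(genes)))
    neuronal: List[str] = []
    for j, gene in enumerate(genes):
        is_neuronal = rng.random() < config.frac_neuronal
        # sub-threshold noise everywhere first
        values[:, j] = rng.uniform(0.0, max(thr, 1e-9) * 0.95, size=len(classes))
        if is_neuronal:
            neuronal.append(gene)
            expressed = rng.random(len(classes)) < 0.15
            if not expressed.any():
                expressed[int(rng.integers(len(classes)))] = True
            k = int(expressed.sum())
            values[expressed, j] = thr + rng.exponential(scale=3.0, size=k)
    df = pd.DataFrame(values, index=classes, columns=genes)
    return ExpressionMatrix(values=df, threshold=thr), frozenset(neuronal)


def _detected_accessions(
    config: SynthConfig, truth: TruthTable, group: str,
    rng: np.random.Generator,
) -> List[str]:
    """Which proteins are detected in one sample, in sorted order."""
    detected: List[str] = []
    # endogenously biotinylated proteins: every sample, every group
    detected.extend(sorted(truth.endogenous_biotin))
    if group.startswith("turbo"):
        for acc in sorted(truth.shared_background):
            if rng.random() < config.detect_prob_background:
                detected.append(acc)
    if group == "turbo_trained":
        for acc in sorted(truth.trained_specific):
            if rng.random() < config.detect_prob_signal:
                detected.append(acc)
    if group == "turbo_control":
        for acc in sorted(truth.control_specific):
            if rng.random() < config.detect_prob_signal:
                detected.append(acc)
    return detected


def _emit_peptides(
    config: SynthConfig, proteome: ProteomeDb, group: str, replicate: int,
    accession: str, rng: np.random.Generator,
) -> List[PsmRecord]:
    seq = proteome.sequence(accession)
    gene = proteome.gene(accession)
    lo, hi = config.peptide_len_range
    sm = config.scores
    out: List[PsmRecord] = []
    for k in range(config.peptides_per_protein):
        length = int(rng.integers(lo, hi + 1))
        length = min(length, len(seq))
        start = int(rng.integers(0, len(seq) - length + 1))
        peptide = seq[start:start + length]
        unassigned = rng.random() < config.unassigned_frac
        if unassigned:
            if rng.random() < 0.5:
                score = rng.normal(sm.confident_loc, sm.confident_scale)
            else:
                score = rng.normal(sm.marginal_loc, sm.marginal_scale)
            rec = PsmRecord(
                group=group, replicate=replicate, accession=None, gene=None,
                peptide=peptide, score=max(0.0, float(score)), is_unique=False,
            )
        else:
            # the first assigned peptide of a protein is always unique,
            # later ones only usually, mimicking shared tryptic peptides
            is_unique = k == 0 or rng.random() < 0.7
            score = rng.normal(sm.confident_loc, sm.confident_scale)
            rec = PsmRecord(
                group=group, replicate=replicate, accession=accession,
                gene=gene, peptide=peptide, score=max(0.0, float(score)),
                is_unique=is_unique,
            )
        out.append(rec)
    return out


def generate_psm_tables(
    config: SynthConfig, proteome: ProteomeDb, truth: TruthTable,
) -> Dict[Tuple[str, int], Tuple[PsmRecord, ...]]:
    tables: Dict[Tuple[str, int], Tuple[PsmRecord, ...]] = {}
    for gi, group in enumerate(sorted(GROUPS)):
        for replicate in range(1, config.n_replicates + 1):
            key = _STREAM_PSM_BASE + gi * 1000 + replicate
            rng = _rng(config, key)
            records: List[PsmRecord] = []
            for acc in _detected_accessions(config, truth, group, rng):
                records.extend(
                    _emit_peptides(config, proteome, group, replicate, acc, rng)
                )
            tables[(group, replicate)] = tuple(records)
    return tables


def _counts_from_ci(ci: float, n_total: int, n_origin: int) -> Tuple[int, int]:
    """Split the scoring-zone population to realise ``ci`` after rounding.

    Rounding is half-up, so a CI of exactly 0 with an odd scoring
    population breaks the tie toward the high-salt zone.
    """
    scoring = n_total - n_origin
    n_high = int(np.floor(scoring * (1.0 + ci) / 2.0 + 0.5))
    n_high = min(max(n_high, 0), scoring)
    return n_high, scoring - n_high


def generate_plate_counts(
    config: SynthConfig,
    pairs: Optional[Sequence[Tuple[str, str]]] = None,
) -> List[PlateCount]:
    """Plate counts for each (genotype, group) x bio rep x tech rep.

    ``pairs`` defaults to the keys of ``config.ci_means``; requesting a pair
    without a configured mean CI is a configuration error.  Noise is applied
    on the CI scale (normal, sd ``ci_noise_sd``, clamped to [-1, 1]) and
    converted to integer zone counts by rounding; 5% of each plate's
    population stays at the origin.
    """
    rng = _rng(config, _STREAM_PLATES)
    if pairs is None:
        pairs = sorted(config.ci_means.keys())
    out: List[PlateCount] = []
    for genotype, group in pairs:
        if (genotype, group) not in config.ci_means:
            raise ConfigError(f"ci_means missing key ({genotype!r}, {group!r})")
        mean = config.ci_means[(genotype, group)]
        for bio_rep in range(1, config.n_bio_reps + 1):
            for tech_rep in range(1, config.n_tech_reps + 1):
                ci = float(np.clip(rng.normal(mean, config.ci_noise_sd), -1, 1))
                n_total = config.plate_n_worms
                n_origin = int(round(0.05 * n_total))
                n_high, n_low = _counts_from_ci(ci, n_total, n_origin)
                out.append(PlateCount(
                    genotype=genotype, group=group, bio_rep=bio_rep,
                    tech_rep=tech_rep, n_high=n_high, n_low=n_low,
                    n_origin=n_origin, n_total=n_total,
                ))
    return out


def generate_experiment(config: SynthConfig) -> SynthBundle:
    """Generate the full synthetic bundle for ``config`` (deterministic)."""
    proteome = _make_proteome(config)
    expression, neuronal = _make_expression(config)
    truth = _make_truth(config, neuronal)
    tables = generate_psm_tables(config, proteome, truth)
    plates = tuple(generate_plate_counts(config))
    return SynthBundle(
        config=config, psm_tables=tables, proteome=proteome,
        expression=expression, plate_counts=plates, truth=truth,
    )


# ---------------------------------------------------------------------------
# On-disk bundle layout


def write_bundle(bundle: SynthBundle, outdir) -> Path:
    """Write all bundle artefacts to ``outdir`` (created if needed)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for (group, rep), records in sorted(bundle.psm_tables.items()):
        pio.write_psm_table(records, outdir / f"{group}_rep{rep}.tsv")
    pio.write_fasta(bundle.proteome, outdir / "proteome.fasta")
    pio.write_expression_matrix(bundle.expression, outdir / "expression_matrix.tsv")
    pio.write_plate_counts(bundle.plate_counts, outdir / "plate_counts.csv")
    truth = bundle.truth
    for name in ("trained_specific", "control_specific",
                 "shared_background", "endogenous_biotin"):
        pio.write_accession_list(getattr(truth, name), outdir / f"truth_{name}.tsv")
    with (outdir / "truth_neuronal_genes.tsv").open("w", encoding="utf-8") as fh:
        fh.write("gene\n")
        for g in sorted(truth.neuronal_genes):
            fh.write(g + "\n")
    _write_manifest(bundle.config, outdir / "manifest.txt")
    return outdir


def _write_manifest(config: SynthConfig, path: Path) -> None:
    with path.open("w", encoding="utf-8") as fh:
        for key, value in sorted(asdict(config).items()):
            if key == "ci_means":
                value = {f"{g}/{grp}": v for (g, grp), v in value.items()}
            fh.write(f"{key}\t{value!r}\n")


def read_bundle_psm_tables(directory) -> Dict[Tuple[str, int], List[PsmRecord]]:
    """Load every ``<group>_rep<k>.tsv`` PSM table from a bundle directory."""
    directory = Path(directory)
    tables: Dict[Tuple[str, int], List[PsmRecord]] = {}
    for path in sorted(directory.glob("*_rep*.tsv")):
        stem = path.stem
        group, _, rep = stem.rpartition("_rep")
        if group in GROUPS and rep.isdigit():
            tables[(group, int(rep))] = pio.read_psm_table(path)
    return tables
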