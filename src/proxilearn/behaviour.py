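"""Chemotaxis-index computation and learning-assay group comparison.

The chemotaxis index (CI) of one plate is::

    CI = (n_high - n_low) / (n_total - n_origin)

and lies in [-1, +1]: +1 is complete preference for the high-salt zone, -1
for the low-salt zone.  Plates with fewer than 20 animals, or with every
animal at the origin, are excluded from analysis rather than scored.

Technical replicates are averaged into one CI per biological replicate,
which is the unit of analysis.  Learning comparisons across genotypes use a
two-way ANOVA (genotype x conditioning group) on biological-replicate CIs
followed by Tukey-adjusted pairwise contrasts; per-cell Shapiro-Wilk
normality checks are reported as warnings only.

A mutant's learning phenotype is called from the Tukey contrast of
mutant-trained against wild-type-trained: a significantly *higher* trained
CI means the mutant failed to shift its salt preference (learning
defective); significantly *lower* means an exaggerated shift (enhanced
learning); otherwise the mutant is wild-type-like.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .records import ContractError, PlateCount

#: Minimum animals per technical replicate for inclusion.
MIN_POPULATION = 20

LEARNING_DEFECTIVE = "learning_defective"
ENHANCED_LEARNING = "enhanced_learning"
WILD_TYPE_LIKE = "wild_type_like"


@dataclass(frozen=True)
class ChemotaxisResult:
    plate: PlateCount
    ci: Optional[float]
    excluded: bool = False
    exclusion_reason: Optional[str] = None


@dataclass(frozen=True)
class LearningComparison:
    per_bio_rep_ci: pd.DataFrame  # columns: genotype, group, bio_rep, ci
    anova_table: pd.DataFrame
    pairwise: pd.DataFrame
    phenotype_calls: Dict[str, str]
    normality_warnings: Tuple[str, ...] = ()


def chemotaxis_index(plate: PlateCount) -> ChemotaxisResult:
    """Score one plate; degenerate plates are excluded, never raised."""
    if plate.n_total < MIN_POPULATION:
        return ChemotaxisResult(
            plate=plate, ci=None, excluded=True,
            exclusion_reason="below minimum population",
        )
    denom = plate.n_total - plate.n_origin
    if denom <= 0:
        return ChemotaxisResult(
            plate=plate, ci=None, excluded=True,
            exclusion_reason="no animals outside origin",
        )
    return ChemotaxisResult(plate=plate, ci=(plate.n_high - plate.n_low) / denom)


def aggregate_biological_replicates(
    results: Sequence[ChemotaxisResult],
) -> pd.DataFrame:
    """Mean CI over included technical replicates per (genotype, group, bio_rep).

    Cells whose technical replicates were all excluded are dropped with a
    warning (they cannot contribute a biological-replicate value).
    """
    rows = []
    dropped: Dict[Tuple[str, str, int], int] = {}
    by_cell: Dict[Tuple[str, str, int], List[float]] = {}
    for res in results:
        key = (res.plate.genotype, res.plate.group, res.plate.bio_rep)
        if res.excluded:
            dropped[key] = dropped.get(key, 0) + 1
            continue
        by_cell.setdefault(key, []).append(res.ci)
    for key in dropped:
        if key not in by_cell:
            warnings.warn(
                f"all technical replicates excluded for {key}; "
                "biological replicate dropped",
                stacklevel=2,
            )
    for (genotype, group, bio_rep), cis in sorted(by_cell.items()):
        rows.append({
            "genotype": genotype, "group": group, "bio_rep": bio_rep,
            "ci": float(np.mean(cis)), "n_tech": len(cis),
        })
    return pd.DataFrame(rows, columns=["genotype", "group", "bio_rep", "ci", "n_tech"])


def _normality_checks(data: pd.DataFrame) -> Tuple[str, ...]:
    notes = []
    for (genotype, group), sub in data.groupby(["genotype", "group"], sort=True):
        vals = sub["ci"].to_numpy()
        if len(vals) < 3 or np.ptp(vals) == 0:
            continue
        stat, p = stats.shapiro(vals)
        if p < 0.05:
            notes.append(
                f"Shapiro-Wilk failed for ({genotype}, {group}): "
                f"W={stat:.3f}, p={p:.3g}"
            )
    return tuple(notes)


def compare_learning(
    data: pd.DataFrame,
    wild_type_label: str = "WT",
    trained_label: str = "trained",
    alpha: float = 0.05,
) -> LearningComparison:
    """Two-way ANOVA + Tukey contrasts on per-bio-rep CIs, with phenotype calls.

    ``data`` needs columns ``genotype, group, bio_rep, ci`` with >=2
    genotypes (including ``wild_type_label``), >=2 groups, and >=2
    biological replicates per (genotype, group) cell.
    """
    required = {"genotype", "group", "bio_rep", "ci"}
    if not required.issubset(data.columns):
        raise ContractError(f"data must have columns {sorted(required)}")
    genotypes = sorted(data["genotype"].unique())
    groups = sorted(data["group"].unique())
    if wild_type_label not in genotypes:
        raise ContractError(f"wild-type genotype {wild_type_label!r} absent")
    if trained_label not in groups:
        raise ContractError(f"trained group {trained_label!r} absent")
    if len(genotypes) < 2 or len(groups) < 2:
        raise ContractError("need >=2 genotypes and >=2 groups")
    for gt in genotypes:
        for gr in groups:
            n = ((data["genotype"] == gt) & (data["group"] == gr)).sum()
            if n < 2:
                raise ContractError(
                    f"cell ({gt!r}, {gr!r}) has {n} biological replicate(s); "
                    "need >=2"
                )

    notes = _normality_checks(data)
    for note in notes:
        warnings.warn(note, stacklevel=2)

    df = data.copy()
    model = smf.ols("ci ~ C(genotype) * C(group)", data=df).fit()
    anova = sm.stats.anova_lm(model, typ=2)

    cell = df["genotype"] + "|" + df["group"]
    tukey = pairwise_tukeyhsd(df["ci"].to_numpy(), cell.to_numpy(), alpha=alpha)
    pairwise = pd.DataFrame(
        tukey.summary().data[1:], columns=tukey.summary().data[0]
    )

    calls: Dict[str, str] = {}
    wt_cell = f"{wild_type_label}|{trained_label}"
    for gt in genotypes:
        if gt == wild_type_label:
            continue
        mut_cell = f"{gt}|{trained_label}"
        row = pairwise[
            ((pairwise["group1"] == wt_cell) & (pairwise["group2"] == mut_cell))
            | ((pairwise["group1"] == mut_cell) & (pairwise["group2"] == wt_cell))
        ]
        if row.empty:
            raise ContractError(f"no Tukey contrast for {mut_cell} vs {wt_cell}")
        row = row.iloc[0]
        # meandiff is group2 - group1; orient as mutant - wild type
        diff = float(row["meandiff"])
        if row["group2"] == wt_cell:
            diff = -diff
        if not bool(row["reject"]):
            calls[gt] = WILD_TYPE_LIKE
        elif diff > 0:
            calls[gt] = LEARNING_DEFECTIVE
        else:
            calls[gt] = ENHANCED_LEARNING

    return LearningComparison(
        per_bio_rep_ci=df.reset_index(drop=True),
        anova_table=anova,
        pairwise=pairwise,
        phenotype_calls=calls,
        normality_warnings=notes,
    )
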