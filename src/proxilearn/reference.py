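"""Published summary tables from the salt-learning proximity-labelling study.

These are *inputs* for arithmetic consistency checks, not results computed
by this package:

* ``FIG_VENN`` — the published Venn counts of assigned-hit proteins after
  non-transgenic subtraction: trained-unique (the learning proteome),
  control-unique, and shared.
* :func:`candidate_panel` — the 26 candidates assayed behaviourally, with
  the number of biological replicates (of 5) in which each was detected at
  the assigned and assigned+unassigned tiers, and the reported strong/weak
  class.
* :func:`neuronal_percentages` — the per-replicate percent-neuronal values
  reported for the six mass-spectrometry runs (replicate 3 was run on both
  instruments).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: Published Venn counts (assigned-hit tier, after non-Tg subtraction).
FIG_VENN = {"trained_unique": 706, "control_unique": 388, "shared": 304}


def _load(name: str) -> pd.DataFrame:
    ref = resources.files("proxilearn.data").joinpath(name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def candidate_panel() -> pd.DataFrame:
    """The 26-candidate behavioural panel with replicate detection counts."""
    return _load("candidate_panel.tsv")


def neuronal_percentages() -> pd.DataFrame:
    """Per-run percent-neuronal values (assigned and all-hit tiers)."""
    return _load("neuronal_percentages.tsv").astype(
        {"pct_neuronal_assigned": float, "pct_neuronal_all": float}
    )
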