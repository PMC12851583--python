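# proxilearn

Analysis pipeline for **proximity-labelling proteomics of learning** in
*C. elegans*.  In the underlying experimental design, the promiscuous
biotin ligase TurboID is expressed throughout the worm nervous system and
biotin is supplied only during the conditioning step of a salt
associative-learning assay, so that proteins present in neurons *during
learning* are tagged, enriched, and identified by mass spectrometry.
`proxilearn` turns the resulting per-sample peptide tables into a
condition-specific **learning proteome** and supporting analyses:

* **Hit calling** — assigned hits (≥ 1 unique peptide per protein, no score
  cutoff) plus *rescue* of unassigned peptides by exact-substring search of
  the proteome with an iid expect-value model (score ≥ 15, E < 0.05).
* **Set algebra** — per-replicate subtraction of non-transgenic background,
  then a cross-replicate Venn partition into trained-unique (the learning
  proteome), control-unique, and shared proteins.
* **Candidate classification** — replicate-occurrence counting and the
  strong (≥ 3 of 5 replicates) / weak (< 3) rule.
* **Neuron-class analyses** — percent-neuronal of a gene list against a
  thresholded neuron-class × gene expression matrix, and fold-change
  ranking of classes with trained counts normalised by the list-size ratio
  *f* = |trained| / |control|.
* **Behaviour** — chemotaxis index CI = (n_high − n_low) / (n_total −
  n_origin), technical→biological replicate aggregation, two-way ANOVA +
  Tukey contrasts, and learning-phenotype calls (a mutant whose trained CI
  is significantly *higher* than wild type failed to learn).
* **Synthetic data** — a seeded generator producing a full experiment
  (4 groups × 5 replicates of PSM tables, toy proteome FASTA, expression
  matrix, plate counts) with planted ground truth, so the whole chain is
  testable without any download.

See `docs/methods.md` for the models, defaults, and their rationale.

## Worked example

```python
import proxilearn as pl
from proxilearn.synth import write_bundle
from proxilearn.pipeline import PipelineConfig, run_pipeline

cfg = pl.SynthConfig(seed=7)          # 300 proteins, 30 planted trained-specific
bundle = pl.generate_experiment(cfg)
write_bundle(bundle, "demo/bundle")
report = run_pipeline(PipelineConfig(bundle_dir="demo/bundle", out_dir="demo/out"))
```

prints (via the fields of `report`):

```
venn: {'trained_unique': 31, 'control_unique': 21, 'shared': 1,
       'trained_total': 32, 'control_total': 22}
candidates: 31 strong: 30
percent neuronal (trained-unique): 96.8
norm factor: 1.476
recovered 30/30 planted proteins
```

All 30 planted trained-specific proteins are recovered in the 31-protein
learning proteome (the one extra is a sparse background contaminant that,
by chance, was never seen in a control replicate — exactly the kind of
false positive the strong/weak classification downweights).  One shared
protein was detected in both arms and correctly lands in the Venn overlap
rather than the learning proteome.  `demo/out/` contains the per-replicate
revised lists, Venn partition, candidate table, rescue audit report, and
the neuron-class ranking, e.g.:

```
class   n_trained  n_control  n_trained_norm  fold_change  rank
N073    9          1          6.09677         6.09677      1
```

The same run is available from the shell:

```
proxilearn simulate --out demo/bundle --seed 7
proxilearn run-all  --bundle demo/bundle --out demo/out
proxilearn behaviour --plates demo/bundle/plate_counts.csv --out demo/behaviour
```

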