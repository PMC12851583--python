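# Methods

`proxilearn` re-implements, as a tested and reusable pipeline, the data
analysis of a whole-nervous-system proximity-labelling experiment in
*C. elegans* salt associative learning: TurboID-expressing and
non-transgenic animals are conditioned either with high salt ("control")
or with no salt + food ("trained"), biotinylated proteins are identified
per biological replicate by mass spectrometry, and the *learning proteome*
is the set of proteins detected only in trained TurboID animals after
background subtraction.

## Hit calling

A protein is an **assigned hit** in a sample when the search-engine export
contains at least one peptide flagged unique to it.  No peptide or protein
score threshold is applied at this stage; the design deliberately trades
specificity for sensitivity to low-abundance neuronal proteins, and the
downstream per-replicate subtraction and replicate-occurrence counting are
the controls for that choice.

**Unassigned** peptides (sequence + score but no protein attribution) are
rescued offline.  A 100%-identity match of a short peptide against a
protein database is exactly an exact-substring occurrence, so rescue scans
the FASTA for substring matches and attaches a significance via an iid
residue-composition model: with add-one-smoothed database frequencies
*f(a)* and a peptide *p* of length *L*,

```
E = S(L) · Π_i f(p_i),   S(L) = max(1, N − k·(L−1))
```

where *N* is the total residue count and *k* the number of sequences, so
*S(L)* is the number of length-*L* windows the match could have landed in.
*E* is the expected number of chance occurrences; it strictly decreases as
the peptide is extended.  A peptide is accepted when its score is ≥ 15
(inclusive, matching the printed threshold), its length is ≥ 6, it occurs
in ≥ 1 sequence, and *E* < 0.05.  Ambiguous peptides rescue **all** of
their matches, flagged in the audit report — the criteria do not resolve
ties, and a conservative superset keeps downstream sets auditable.  The
length floor (not part of the published criteria) exists because 1–3-mer
"matches" are uninformative; it is configurable.  Two sub-threshold
peptides never jointly rescue a protein: a single qualifying peptide is
required.

## Set algebra

Per biological replicate *r* and tier (assigned only, or assigned +
rescued), the revised lists are

```
trained[r] = hits(TurboID trained, r) \ hits(non-Tg trained, r)
control[r] = hits(TurboID control, r) \ hits(non-Tg control, r)
```

— subtraction is strictly within-replicate.  Lists are then unioned across
replicates within condition and partitioned: trained-unique (the learning
proteome), control-unique, and shared.  A protein in trained lists of ≥ 1
replicate and control lists of ≥ 1 (possibly different) replicate is
*shared*; this union-then-partition reading is the only one consistent
with the published overlap semantics.  The Venn partition defaults to the
assigned tier; occurrence counting and the strong/weak call use both
tiers.  Candidates are **strong** when detected in ≥ 3 of the 5 replicates
(inclusive) at the assigned+unassigned tier, **weak** otherwise.

## Neuron-class analyses

Expression calls are inclusive: a gene is expressed in a class when its
matrix value is ≥ the threshold (default 2; in the real resource the
threshold is a categorical stringency level, modelled here as a numeric
cutoff).  *Percent neuronal* is the share of a gene list expressed in ≥ 1
class (unrounded value retained; integer rounding only for reporting).
For class ranking, trained counts are **divided** by the list-size ratio
*f* = |trained| / |control| (≈ 1.8 for the published list sizes 706/388);
dividing — rather than multiplying — is the only direction under which
the correction removes the list-size bias, giving fold change 1 for equal
per-class densities.  Fold change = (n_trained / f) / n_control, computed
only for classes with ≥ 1 gene from *both* lists (others are reported as
excluded, avoiding division by zero); ranks are descending by fold change
with ties broken by class name for determinism.  No significance is
attached to ranks — the analysis is descriptive by design.

## Behaviour

CI = (n_high − n_low) / (n_total − n_origin) ∈ [−1, 1].  Technical
replicates with fewer than 20 animals, or with all animals at the origin,
are excluded (not errors).  The analysis unit is the biological-replicate
mean CI over included technical replicates.  Group comparison is a two-way
ANOVA (genotype × conditioning group, type-II) on those means, followed by
Tukey-adjusted pairwise contrasts at α = 0.05; per-cell Shapiro–Wilk
checks raise warnings only (no automatic non-parametric fallback).  The
phenotype call uses exactly the mutant-trained vs wild-type-trained
contrast: significantly higher trained CI → learning defective (the
expected preference shift failed), significantly lower → enhanced
learning, otherwise wild-type-like.  The same machinery serves the
aversive paradigm via group labels (naive / mock_conditioned /
conditioned).

## Synthetic-data generator

The generator emulates the study design — 4 groups × 5 biological
replicates — with planted ground truth:

| parameter | default | meaning |
|---|---|---|
| n_proteins | 300 | toy proteome size (sequences 120–400 aa, iid residues with mildly non-uniform composition so expect values are non-degenerate) |
| n_trained_specific | 30 | planted learning-proteome proteins, emitted only in TurboID-trained samples |
| n_control_specific | 16 | planted control-arm proteins (the 30/16 ratio mirrors the ≈1.8 trained/control list-size ratio) |
| n_shared_background | 20 | ribosomal/mitochondrial-like contaminants, any TurboID sample |
| n_endogenous_biotin | 10 | carboxylase-like proteins, every sample of every group |
| detect_prob_signal | 0.9 | per-replicate detection probability of planted proteins |
| detect_prob_background | 0.05 | per-replicate probability for shared background |
| peptides_per_protein / peptide_len_range | 3 / (8, 20) | emitted peptides are exact substrings of their protein |
| unassigned_frac | 0.1 | fraction of rows emitted without an accession, to exercise rescue |
| scores | N(40, 8) / N(12, 4), clipped at 0 | confident vs marginal distributions; unassigned rows draw from an even mixture so the ≥15 threshold separates imperfectly |
| frac_neuronal / n_neuron_classes | 0.9 / 128 | ≈90% of genes expressed in ≥1 of 128 classes, matching the reported neuronal representation and class count |
| ci_means / ci_noise_sd | naive 0.8, control 0.8, trained 0.0 / 0.05 | CI noise applied on the CI scale, clamped to [−1, 1], converted to counts by half-up rounding (ties toward the high zone); 5% of each plate's 100 animals stay at the origin, none off-zone |

Endogenously biotinylated proteins are emitted deterministically in every
sample: they are the most abundant background in real experiments, and
deterministic presence makes per-replicate non-transgenic subtraction
remove them exactly, so that with background and unassigned rates at zero
the pipeline provably recovers the planted truth verbatim.  The first
assigned peptide of every detected protein is unique-flagged; later
peptides are unique with probability 0.7, mimicking shared tryptic
peptides.

Randomness: one seed per bundle; each artefact (proteome, expression,
plates, every group × replicate table) uses a sub-stream derived from it
with a fixed spawn key, groups ordered alphabetically and replicates
ascending, so configurations are byte-reproducible and adding streams
cannot perturb existing ones.

What the generator does **not** emulate: spectra, retention times,
ionisation efficiency, missed cleavages, protein abundance (presence /
absence only), isoform structure, correlated detection across replicates,
or worm locomotion.  Passing recovery benchmarks therefore demonstrates
the correctness of the list algebra and thresholds under the stated
detection model — not instrument-level performance on real data.

## Problem sizes and numerical choices

The bundled benchmarks use a 300-protein proteome, 5 replicates, 20 seeded
bundles for recovery, and 200 Monte-Carlo repeats per effect direction for
the phenotype-power check; these sizes give stable estimates (recovery and
call-accuracy margins are wide) at desk scale.  The expect product is
computed in log space; float round-trips in TSVs use `%.17g` and pandas'
round-trip parser.  Readers reject rather than repair malformed input.
Degenerate plates are excluded with a recorded reason rather than raised.

## Known limitations

* The expect model is iid composition-based, not an alignment-statistics
  model; it is calibrated for exact matches of short peptides only.
* Accessions are taken as given — no isoform or accession-version
  deduplication before set operations.
* Published headline counts (706/388/304, per-replicate percentages)
  derive from deposited raw data and are reproduced here only as
  arithmetic identities on the printed values, not recomputed from
  spectra.
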