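"""The synthetic experiment generator: determinism, planted structure, noise."""

import filecmp

import numpy as np
import pytest

from proxilearn import (
    ConfigError,
    SynthConfig,
    chemotaxis_index,
    generate_experiment,
    generate_plate_counts,
)
from proxilearn.synth import write_bundle


class TestConfigValidation:
    def test_invalid_probability_names_field(self):
        with pytest.raises(ConfigError, match="detect_prob_signal"):
            SynthConfig(detect_prob_signal=1.5)

    def test_planted_sets_cannot_exceed_proteome(self):
        with pytest.raises(ConfigError, match="n_proteins"):
            SynthConfig(n_proteins=10, n_trained_specific=8, n_shared_background=8)

    def test_bad_peptide_length_range(self):
        with pytest.raises(ConfigError, match="peptide_len_range"):
            SynthConfig(peptide_len_range=(10, 5))


class TestDeterminism:
    def test_same_seed_gives_identical_bundles(self):
        a = generate_experiment(SynthConfig(seed=42))
        b = generate_experiment(SynthConfig(seed=42))
        assert a.psm_tables == b.psm_tables
        assert a.proteome.records == b.proteome.records
        assert (a.expression.values == b.expression.values).all().all()
        assert a.plate_counts == b.plate_counts
        assert a.truth == b.truth

    def test_written_bundles_are_byte_identical(self, tmp_path):
        bundle = generate_experiment(SynthConfig(seed=42))
        d1 = write_bundle(bundle, tmp_path / "one")
        d2 = write_bundle(generate_experiment(SynthConfig(seed=42)), tmp_path / "two")
        names = sorted(p.name for p in d1.iterdir())
        assert names == sorted(p.name for p in d2.iterdir())
        match, mismatch, errors = filecmp.cmpfiles(d1, d2, names, shallow=False)
        assert mismatch == [] and errors == []

    def test_different_seeds_differ(self):
        a = generate_experiment(SynthConfig(seed=1))
        b = generate_experiment(SynthConfig(seed=2))
        assert a.psm_tables != b.psm_tables


class TestPlantedStructure:
    def test_bundle_shape(self, bundle7):
        assert len(bundle7.psm_tables) == 4 * bundle7.config.n_replicates
        accessions = {
            rec.accession
            for recs in bundle7.psm_tables.values() for rec in recs
            if rec.accession is not None
        }
        assert accessions <= set(bundle7.proteome.records)

    def test_truth_sets_are_disjoint(self, bundle7):
        t = bundle7.truth
        sets = [t.trained_specific, t.control_specific,
                t.shared_background, t.endogenous_biotin]
        assert sum(map(len, sets)) == len(frozenset().union(*sets))

    def test_trained_specific_only_in_turbo_trained(self, bundle7):
        planted = bundle7.truth.trained_specific
        for (group, _), recs in bundle7.psm_tables.items():
            seen = {r.accession for r in recs} & planted
            if group != "turbo_trained":
                assert seen == set()

    def test_endogenous_biotin_in_every_sample(self, bundle7):
        endo = bundle7.truth.endogenous_biotin
        for recs in bundle7.psm_tables.values():
            assert endo <= {r.accession for r in recs}

    def test_empty_plant_case(self):
        bundle = generate_experiment(SynthConfig(seed=3, n_trained_specific=0))
        assert bundle.truth.trained_specific == frozenset()
        planted_only_trained = set()
        for (group, _), recs in bundle.psm_tables.items():
            if group == "turbo_trained":
                planted_only_trained |= {r.accession for r in recs if r.accession}
        # everything in trained tables is background/endogenous, by truth
        background = (bundle.truth.shared_background
                      | bundle.truth.endogenous_biotin)
        assert planted_only_trained <= background

    def test_every_peptide_is_substring_of_its_protein(self, bundle7):
        sequences = [seq for _, seq in bundle7.proteome.records.values()]
        for recs in bundle7.psm_tables.values():
            for rec in recs:
                if rec.accession is not None:
                    assert rec.peptide in bundle7.proteome.sequence(rec.accession)
                else:
                    assert any(rec.peptide in seq for seq in sequences)

    def test_unassigned_fraction_close_to_configured(self, bundle7):
        rows = [r for recs in bundle7.psm_tables.values() for r in recs]
        frac = sum(r.accession is None for r in rows) / len(rows)
        assert abs(frac - bundle7.config.unassigned_frac) < 0.05

    def test_neuronal_fraction_and_matrix_coverage(self, bundle7):
        m = bundle7.expression
        calls = (m.values.to_numpy() >= m.threshold).any(axis=0)
        frac = calls.mean()
        assert abs(frac - bundle7.config.frac_neuronal) < 0.07
        # every planted protein's gene is a matrix column
        genes = set(m.genes)
        for acc in bundle7.truth.trained_specific:
            assert bundle7.proteome.gene(acc) in genes


class TestPlateGeneration:
    def test_ci_one_no_noise_puts_all_scoring_worms_high(self):
        config = SynthConfig(seed=1, ci_noise_sd=0.0,
                             ci_means={("WT", "trained"): 1.0})
        for plate in generate_plate_counts(config):
            assert plate.n_low == 0
            assert plate.n_high == plate.n_total - plate.n_origin

    def test_ci_zero_no_noise_splits_evenly_tie_to_high(self):
        config = SynthConfig(seed=1, ci_noise_sd=0.0, plate_n_worms=101,
                             ci_means={("WT", "trained"): 0.0})
        for plate in generate_plate_counts(config):
            assert 0 <= plate.n_high - plate.n_low <= 1

    def test_missing_ci_mean_is_config_error(self):
        config = SynthConfig(seed=1)
        with pytest.raises(ConfigError, match="ci_means"):
            generate_plate_counts(config, pairs=[("mutantX", "trained")])

    def test_monte_carlo_mean_matches_target(self):
        # 1000 plates at CI 0.8, sd 0.05: the implied mean CI stays within
        # 0.02 of the target despite rounding to integer counts
        config = SynthConfig(
            seed=3, plate_n_worms=100, ci_noise_sd=0.05,
            ci_means={("WT", "trained"): 0.8},
            n_bio_reps=334, n_tech_reps=3,
        )
        plates = generate_plate_counts(config)[:1000]
        cis = [chemotaxis_index(p).ci for p in plates]
        assert abs(float(np.mean(cis)) - 0.8) < 0.02


class TestReplayOracle:
    def test_downstream_recovery_matches_table_replay(self):
        """An independent scan of the emitted tables predicts the learning
        proteome; the pipeline must recover >=80% of planted proteins."""
        from proxilearn.hits import call_hits
        from proxilearn.sets import build_venn, derive_condition_lists

        config = SynthConfig(seed=7, n_proteins=200, n_trained_specific=20,
                             detect_prob_signal=0.9)
        bundle = generate_experiment(config)

        # oracle: replay detection directly from the emitted rows
        def assigned(group, rep):
            return {
                r.accession for r in bundle.psm_tables[(group, rep)]
                if r.accession and r.is_unique
            }

        trained_union, control_union = set(), set()
        for rep in range(1, config.n_replicates + 1):
            trained_union |= assigned("turbo_trained", rep) - assigned("nonTg_trained", rep)
            control_union |= assigned("turbo_control", rep) - assigned("nonTg_control", rep)
        oracle_proteome = trained_union - control_union

        hits = {
            key: call_hits(recs, db=bundle.proteome, sample=key)
            for key, recs in bundle.psm_tables.items()
        }
        venn = build_venn(derive_condition_lists(hits, "assigned_only"))
        assert venn.trained_unique == oracle_proteome

        truth = bundle.truth.trained_specific
        recovery = len(venn.trained_unique & truth) / len(truth)
        assert recovery >= 0.8
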