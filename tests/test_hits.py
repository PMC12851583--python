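"""Hit calling: the unique-peptide rule, the expect model, and peptide rescue."""

import math
import random

import pytest

from proxilearn import (
    ContractError,
    ProteomeDb,
    PsmRecord,
    RescueParams,
    call_assigned_hits,
    peptide_expect,
    rescue_unassigned,
    residue_frequencies,
)
from proxilearn.records import AMINO_ACIDS


def _rec(accession, unique, peptide="ACDEFGHIK", score=30.0, group="turbo_trained"):
    return PsmRecord(group, 1, accession, None, peptide, score,
                     unique and accession is not None)


class TestAssignedHits:
    def test_unique_peptide_rule(self):
        psms = [_rec("P1", True), _rec("P2", False)]
        assert call_assigned_hits(psms) == {"P1"}

    def test_empty_input_gives_empty_set(self):
        assert call_assigned_hits([]) == set()

    def test_no_score_threshold_applied(self):
        assert call_assigned_hits([_rec("P1", True, score=0.0)]) == {"P1"}

    def test_mixed_samples_rejected(self):
        psms = [_rec("P1", True), _rec("P2", True, group="turbo_control")]
        with pytest.raises(ContractError, match="multiple samples"):
            call_assigned_hits(psms)

    def test_matches_brute_force_and_is_order_invariant(self):
        rng = random.Random(11)
        psms = [
            _rec(f"P{rng.randrange(20)}", rng.random() < 0.4)
            for _ in range(100)
        ]
        by_acc = {}
        for rec in psms:
            by_acc.setdefault(rec.accession, []).append(rec.is_unique)
        expected = {acc for acc, flags in by_acc.items() if any(flags)}
        assert call_assigned_hits(psms) == expected
        shuffled = psms[:]
        rng.shuffle(shuffled)
        assert call_assigned_hits(shuffled) == expected
        assert call_assigned_hits(psms + psms) == expected  # idempotent


class TestResidueFrequencies:
    def test_add_one_smoothing_closed_form(self):
        db = ProteomeDb(records={"P1": (None, "AAAA")})
        freqs = residue_frequencies(db)
        assert freqs["A"] == pytest.approx(5 / 24)
        for aa in AMINO_ACIDS.replace("A", ""):
            assert freqs[aa] == pytest.approx(1 / 24)

    def test_frequencies_sum_to_one(self, bundle7):
        freqs = residue_frequencies(bundle7.proteome)
        assert abs(sum(freqs.values()) - 1.0) < 1e-12

    def test_matches_direct_counting(self, tiny_db):
        counts = {aa: 0 for aa in AMINO_ACIDS}
        for _, seq in tiny_db.records.values():
            for ch in seq:
                counts[ch] += 1
        total = sum(counts.values())
        freqs = residue_frequencies(tiny_db)
        for aa in AMINO_ACIDS:
            assert freqs[aa] == pytest.approx((counts[aa] + 1) / (total + 20))


class TestPeptideExpect:
    def test_single_residue_direct_formula(self):
        # 10 sequences, 100 residues total, exactly 5 A's -> f(A) = 6/120 = 0.05
        records = {"Q0": (None, "AAAAA" + "C" * 5)}
        for i in range(1, 10):
            records[f"Q{i}"] = (None, "C" * 10)
        db = ProteomeDb(records=records)
        freqs = residue_frequencies(db)
        assert freqs["A"] == pytest.approx(0.05)
        assert peptide_expect("A", db, freqs) == pytest.approx(100 * 0.05)

    def test_appending_a_residue_never_increases_expect(self, bundle7):
        db = bundle7.proteome
        freqs = residue_frequencies(db)
        rng = random.Random(5)
        for _ in range(50):
            pep = "".join(rng.choice(AMINO_ACIDS) for _ in range(rng.randrange(1, 15)))
            e = peptide_expect(pep, db, freqs)
            for aa in "AWLC":
                assert peptide_expect(pep + aa, db, freqs) < e

    def test_agrees_with_independent_reimplementation(self, bundle7):
        db = bundle7.proteome
        freqs = residue_frequencies(db)
        rng = random.Random(17)
        for _ in range(100):
            pep = "".join(rng.choice(AMINO_ACIDS) for _ in range(8))
            windows = max(1, db.total_residues - db.n_proteins * (len(pep) - 1))
            expected = windows
            for ch in pep:
                expected *= freqs[ch]
            got = peptide_expect(pep, db, freqs)
            assert got == pytest.approx(expected, rel=1e-12)

    def test_longer_than_every_sequence_still_defined(self):
        db = ProteomeDb(records={"P1": (None, "ACDEF")})
        e = peptide_expect("ACDEFACDEF", db)
        assert 0 < e < 1  # S floored at 1, tiny composition product


def _unassigned(peptide, score):
    return PsmRecord("turbo_trained", 1, None, None, peptide, score, False)


class TestRescue:
    def test_score_threshold_is_inclusive(self, tiny_db):
        pep = tiny_db.sequence("P1")[:10]
        below, _ = rescue_unassigned([_unassigned(pep, 14.9)], tiny_db)
        at, _ = rescue_unassigned([_unassigned(pep, 15.0)], tiny_db)
        assert below == set()
        assert at == {"P1"}

    def test_exact_substring_with_small_expect_is_rescued(self, tiny_db):
        pep = tiny_db.sequence("P1")[2:14]
        rescued, report = rescue_unassigned([_unassigned(pep, 40.0)], tiny_db)
        assert rescued == {"P1"}
        (row,) = report
        assert row.accepted and row.expect < 0.05 and not row.ambiguous

    def test_no_match_reports_rejected_row(self, tiny_db):
        rescued, report = rescue_unassigned([_unassigned("WAWAWAWAWA", 40.0)], tiny_db)
        assert rescued == set()
        (row,) = report
        assert not row.accepted and row.n_matches == 0

    def test_ambiguous_peptide_rescues_all_matches_flagged(self):
        db = ProteomeDb(records={
            "A": (None, "MMMMACDEFGHIKMMMM"),
            "B": (None, "WWWWACDEFGHIKWWWW"),
        })
        rescued, report = rescue_unassigned([_unassigned("ACDEFGHIK", 30.0)], db)
        assert rescued == {"A", "B"}
        assert report[0].ambiguous

    def test_short_peptides_not_considered(self, tiny_db):
        pep = tiny_db.sequence("P1")[:4]  # below min_peptide_len
        rescued, report = rescue_unassigned([_unassigned(pep, 40.0)], tiny_db)
        assert rescued == set() and report == []

    def test_degenerate_thresholds_give_empty_rescue(self, tiny_db):
        pep = tiny_db.sequence("P1")[:10]
        psms = [_unassigned(pep, 40.0)]
        rescued, _ = rescue_unassigned(psms, tiny_db, RescueParams(evalue_max=0.0))
        assert rescued == set()
        rescued, _ = rescue_unassigned(
            psms, tiny_db, RescueParams(score_min=math.inf)
        )
        assert rescued == set()

    def test_tightening_thresholds_never_enlarges_rescue(self, bundle7):
        db = bundle7.proteome
        psms = [
            rec for recs in bundle7.psm_tables.values() for rec in recs
            if rec.accession is None and rec.sample == ("turbo_trained", 1)
        ]
        base, _ = rescue_unassigned(psms, db, RescueParams())
        stricter_score, _ = rescue_unassigned(psms, db, RescueParams(score_min=30))
        stricter_e, _ = rescue_unassigned(psms, db, RescueParams(evalue_max=1e-6))
        assert stricter_score <= base
        assert stricter_e <= base

    def test_matches_nested_loop_substring_oracle(self, tiny_db):
        rng = random.Random(23)
        params = RescueParams()
        psms = []
        for _ in range(80):
            if rng.random() < 0.5:
                acc = rng.choice(list(tiny_db.records))
                seq = tiny_db.sequence(acc)
                length = rng.randrange(6, 13)
                start = rng.randrange(0, len(seq) - length + 1)
                pep = seq[start:start + length]
            else:
                pep = "".join(rng.choice(AMINO_ACIDS) for _ in range(rng.randrange(6, 13)))
            psms.append(_unassigned(pep, rng.uniform(5, 45)))
        rescued, _ = rescue_unassigned(psms, tiny_db, params)

        expected = set()
        for rec in psms:
            if rec.score < params.score_min or len(rec.peptide) < params.min_peptide_len:
                continue
            matches = []
            for acc, (_, seq) in tiny_db.records.items():
                found = any(
                    seq[i:i + len(rec.peptide)] == rec.peptide
                    for i in range(len(seq) - len(rec.peptide) + 1)
                )
                if found:
                    matches.append(acc)
            if matches and peptide_expect(rec.peptide, tiny_db) < params.evalue_max:
                expected.update(matches)
        assert rescued == expected
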