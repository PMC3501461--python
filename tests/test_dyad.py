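"""Global alignment correctness and dyad conservation classification."""

import numpy as np
import pytest
from Bio import Align
from Bio.Align import substitution_matrices

from mcsurvey.dyad import (
    DyadReference,
    classify_dyad,
    global_align,
    substitution_profile,
)
from mcsurvey.errors import ValidationError

from oracles import brute_force_align_score

_B62 = substitution_matrices.load("BLOSUM62")
_AA = "ACDEFGHIKLMNPQRSTVWY"


def random_seq(rng, max_len=8, min_len=1):
    n = int(rng.integers(min_len, max_len + 1))
    return "".join(rng.choice(list(_AA), size=n))


class TestGlobalAlign:
    def test_self_alignment_is_identity(self):
        aln = global_align("ACH", "ACH")
        assert aln.aligned_a == aln.aligned_b == "ACH"
        assert aln.score == sum(_B62[c, c] for c in "ACH")

    def test_single_gap_inserted(self):
        aln = global_align("ACGH", "ACH")
        assert aln.score == brute_force_align_score("ACGH", "ACH")
        assert aln.aligned_b.count("-") == 1

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_bruteforce_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        a, b = random_seq(rng, 6), random_seq(rng, 6)
        assert global_align(a, b).score == brute_force_align_score(a, b)

    def test_matches_biopython_optimum(self):
        # independent dynamic-programming implementation as a second oracle
        aligner = Align.PairwiseAligner()
        aligner.substitution_matrix = _B62
        aligner.open_gap_score = -8
        aligner.extend_gap_score = -8
        aligner.mode = "global"
        rng = np.random.default_rng(123)
        for _ in range(30):
            a, b = random_seq(rng, 30, 5), random_seq(rng, 30, 5)
            assert global_align(a, b).score == aligner.score(a, b)

    def test_score_symmetric(self):
        rng = np.random.default_rng(77)
        for _ in range(20):
            a, b = random_seq(rng, 12), random_seq(rng, 12)
            assert global_align(a, b).score == global_align(b, a).score

    def test_invalid_character_rejected(self):
        with pytest.raises(ValidationError):
            global_align("AC-", "ACH")

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValidationError):
            global_align("", "ACH")


class TestClassifyDyad:
    def test_reference_against_itself_positive(self, reference):
        result = classify_dyad(reference.reference_sequence, reference, "p1")
        assert result.status == "Positive"
        assert result.residue_at_cys == "C"
        assert result.residue_at_his == "H"

    def test_cys_to_ser_substitution_negative(self, reference):
        seq = list(reference.reference_sequence)
        seq[reference.cys_pos - 1] = "S"
        result = classify_dyad("".join(seq), reference)
        assert result.status == "Negative"
        assert result.residue_at_cys == "S"
        assert result.residue_at_his == "H"

    def test_his_to_tyr_substitution_negative(self, reference):
        seq = list(reference.reference_sequence)
        seq[reference.his_pos - 1] = "Y"
        result = classify_dyad("".join(seq), reference)
        assert result.status == "Negative"
        assert result.residue_at_his == "Y"

    def test_deletion_counts_as_substitution(self, reference):
        # drop a window around the catalytic cysteine
        seq = (
            reference.reference_sequence[: reference.cys_pos - 5]
            + reference.reference_sequence[reference.cys_pos + 5 :]
        )
        result = classify_dyad(seq, reference)
        assert result.status == "Negative"
        assert result.residue_at_cys == "-"
        assert not result.low_confidence

    def test_terminal_fragment_is_low_confidence(self, reference):
        # fragment far N-terminal of both catalytic residues
        seq = reference.reference_sequence[:40]
        result = classify_dyad(seq, reference)
        assert result.status == "Negative"
        assert result.residue_at_cys == "-" and result.residue_at_his == "-"
        assert result.low_confidence

    def test_reference_invariants_enforced(self):
        with pytest.raises(ValidationError):
            DyadReference("AAAA", cys_pos=1, his_pos=2)  # position 1 is not C


class TestSubstitutionProfile:
    def _result(self, pid, status, at_cys="C", at_his="H"):
        from mcsurvey.dyad import DyadResult

        return DyadResult(pid, status, at_cys, at_his)

    def test_all_positive_group(self):
        results = [self._result(f"p{i}", "Positive") for i in range(5)]
        prof = substitution_profile(results, {f"p{i}": "Cyanobacteria" for i in range(5)})
        assert prof["per_group"].iloc[0]["fraction_positive"] == 1.0

    def test_planted_75_percent_group(self):
        results = [self._result(f"p{i}", "Positive") for i in range(3)]
        results.append(self._result("p3", "Negative", at_cys="S"))
        prof = substitution_profile(
            results, {f"p{i}": "Alphaproteobacteria" for i in range(4)}
        )
        row = prof["per_group"].iloc[0]
        assert row["fraction_positive"] == 0.75

    def test_planted_substitution_fractions_exact(self):
        # 43% of cysteine substitutions are serine: 3 of 7
        results = []
        groups = {}
        for i, res in enumerate(["S", "S", "S", "A", "G", "T", "V"]):
            results.append(self._result(f"n{i}", "Negative", at_cys=res))
            groups[f"n{i}"] = "g"
        prof = substitution_profile(results, groups)
        count, fraction = prof["cys_substitutions"]["S"]
        assert count == 3
        assert fraction == pytest.approx(3 / 7)

    def test_group_fractions_average_to_overall(self):
        rng = np.random.default_rng(5)
        results, groups = [], {}
        for i in range(200):
            status = "Positive" if rng.random() < 0.8 else "Negative"
            at_cys = "C" if status == "Positive" else "S"
            results.append(self._result(f"p{i}", status, at_cys=at_cys))
            groups[f"p{i}"] = f"grp{i % 5}"
        prof = substitution_profile(results, groups)
        tbl = prof["per_group"]
        weighted = (tbl["fraction_positive"] * tbl["n"]).sum() / tbl["n"].sum()
        overall = sum(r.status == "Positive" for r in results) / len(results)
        assert weighted == pytest.approx(overall)
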