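"""Envelope extraction, dyad filtering and greedy identity clustering."""

import numpy as np
import pytest

from mcsurvey.curation import (
    CurationConfig,
    Envelope,
    cluster_representatives,
    curation_report,
    dyad_filter,
    extract_envelopes,
    sequence_identity,
)
from mcsurvey.errors import ValidationError
from mcsurvey.io_formats import ProteinRecord

from conftest import make_hit


class TestExtractEnvelopes:
    def test_slice_semantics(self):
        protein = ProteinRecord("p1", "g1", "MAAACHWWW")
        hit = make_hit(env_from=4, env_to=6, model_length=3, hmm_to=3)
        (env,) = extract_envelopes([hit], [protein])
        assert env == Envelope("p1", "ACH")

    def test_envelope_beyond_sequence_rejected(self):
        protein = ProteinRecord("p1", "g1", "MACH")
        hit = make_hit(env_from=2, env_to=10, model_length=9, hmm_to=9)
        with pytest.raises(ValidationError, match="p1"):
            extract_envelopes([hit], [protein])

    def test_missing_protein_rejected(self):
        hit = make_hit(protein_id="absent", env_from=1, env_to=4, model_length=4, hmm_to=4)
        with pytest.raises(ValidationError, match="absent"):
            extract_envelopes([hit], [])

    def test_planted_segments_recovered(self, small_survey):
        from mcsurvey.io_formats import read_domain_hits, read_sequences
        from mcsurvey.architecture import METACASPASE_DOMAIN

        files, truth = small_survey
        proteins = {p.protein_id: p for p in read_sequences(files.proteins)}
        mc_hits = [
            h
            for h in read_domain_hits(files.hits)
            if h.domain_name == METACASPASE_DOMAIN
            and h.protein_id in truth.metacaspase_ids
        ]
        envelopes = extract_envelopes(mc_hits, proteins)
        for hit, env in zip(mc_hits, envelopes):
            assert len(env.sequence) == hit.env_to - hit.env_from + 1


class TestDyadFilter:
    def test_reference_itself_retained(self, reference):
        envs = [Envelope("p1", reference.reference_sequence)]
        assert dyad_filter(envs, reference) == envs

    def test_his_to_tyr_discarded(self, reference):
        seq = list(reference.reference_sequence)
        seq[reference.his_pos - 1] = "Y"
        assert dyad_filter([Envelope("p1", "".join(seq))], reference) == []

    def test_mixed_planted_set_exact_count(self, reference):
        rng = np.random.default_rng(4)
        envelopes = []
        for i in range(40):
            seq = list(reference.reference_sequence)
            if i >= 25:  # plant 15 negatives
                if rng.random() < 0.5:
                    seq[reference.cys_pos - 1] = "S"
                else:
                    seq[reference.his_pos - 1] = "Y"
            envelopes.append(Envelope(f"p{i}", "".join(seq)))
        retained = dyad_filter(envelopes, reference)
        assert len(retained) == 25
        assert {e.protein_id for e in retained} == {f"p{i}" for i in range(25)}

    def test_idempotent(self, reference):
        envs = [Envelope("p1", reference.reference_sequence)]
        once = dyad_filter(envs, reference)
        assert dyad_filter(once, reference) == once


class TestClustering:
    def test_identical_sequences_one_cluster(self):
        envs = [Envelope("a", "WYKWYKWYKW"), Envelope("b", "WYKWYKWYKW")]
        reps, assignment = cluster_representatives(envs)
        assert len(reps) == 1
        assert assignment == {"a": reps[0].protein_id, "b": reps[0].protein_id}

    def test_ninety_percent_identity_joins_at_threshold(self):
        envs = [Envelope("a", "AAAAAAAAAA"), Envelope("b", "AAAAAAAAAC")]
        assert sequence_identity(envs[0].sequence, envs[1].sequence) == pytest.approx(0.9)
        reps, _ = cluster_representatives(envs, CurationConfig(identity_threshold=0.90))
        assert len(reps) == 1

    def test_below_threshold_founds_new_cluster(self):
        envs = [Envelope("a", "AAAAAAAAAA"), Envelope("b", "AAAAAAAACC")]
        reps, _ = cluster_representatives(envs, CurationConfig(identity_threshold=0.90))
        assert len(reps) == 2

    def test_representative_is_longest_member(self):
        envs = [Envelope("short", "WYKWYKWY"), Envelope("long", "WYKWYKWYKW")]
        reps, assignment = cluster_representatives(envs)
        assert reps[0].protein_id == "long"
        assert assignment["short"] == "long"

    def _random_envelopes(self, rng, n=8):
        base = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=30))
        envs = []
        for i in range(n):
            seq = list(base[: int(rng.integers(20, 31))])
            for _ in range(int(rng.integers(0, 8))):
                pos = int(rng.integers(len(seq)))
                seq[pos] = rng.choice(list("ACDEFGHIKLMNPQRSTVWY"))
            envs.append(Envelope(f"p{i}", "".join(seq)))
        return envs

    @pytest.mark.parametrize("seed", range(10))
    def test_membership_rule_holds_posthoc(self, seed):
        # every non-representative is >= threshold-identical to its representative,
        # and no member fits an earlier-founded cluster than the one it joined
        rng = np.random.default_rng(seed)
        envs = self._random_envelopes(rng)
        cfg = CurationConfig(identity_threshold=0.90)
        reps, assignment = cluster_representatives(envs, cfg)
        rep_by_id = {r.protein_id: r for r in reps}
        founding_order = [r.protein_id for r in reps]
        for env in envs:
            rep = rep_by_id[assignment[env.protein_id]]
            if env.protein_id != rep.protein_id:
                assert sequence_identity(env.sequence, rep.sequence) >= cfg.identity_threshold
            for earlier in founding_order[: founding_order.index(rep.protein_id)]:
                if len(rep_by_id[earlier].sequence) >= len(env.sequence) and earlier != env.protein_id:
                    assert (
                        sequence_identity(env.sequence, rep_by_id[earlier].sequence)
                        < cfg.identity_threshold
                    )

    def test_cluster_count_monotone_in_threshold(self):
        rng = np.random.default_rng(3)
        envs = self._random_envelopes(rng, 10)
        counts = [
            len(cluster_representatives(envs, CurationConfig(identity_threshold=t))[0])
            for t in (0.5, 0.7, 0.9, 1.0)
        ]
        assert counts == sorted(counts)

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            cluster_representatives([])


class TestCurationReport:
    def test_full_length_envelopes_fully_occupy(self, reference):
        envs = [Envelope("p1", reference.reference_sequence)]
        report = curation_report(envs, reference)
        assert all(c == 1.0 for c in report["column_occupancy"])
        assert report["per_sequence"].iloc[0]["terminal_gap_fraction"] == 0.0

    def test_terminal_truncation_reported(self, reference):
        half = reference.reference_sequence[: len(reference.reference_sequence) // 2]
        report = curation_report([Envelope("p1", half)], reference)
        frac = report["per_sequence"].iloc[0]["terminal_gap_fraction"]
        assert 0.4 < frac < 0.6
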