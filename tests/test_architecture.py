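"""Conflict resolution, topology integration, repeat grouping and the census."""

import itertools

import numpy as np
import pytest

from mcsurvey.architecture import (
    METACASPASE_DOMAIN,
    ArchitectureElement,
    architecture_census,
    assemble_protein,
    build_architecture,
    domain_prevalence,
    hits_conflict,
    integrate_topology,
    resolve_domain_conflicts,
)
from mcsurvey.errors import ValidationError
from mcsurvey.io_formats import GenomeRecord, TopologySegment

from conftest import make_hit
from oracles import dominant_elimination


def random_hit_set(rng, n):
    hits = []
    for i in range(n):
        start = int(rng.integers(1, 200))
        length = int(rng.integers(10, 120))
        hits.append(
            make_hit(
                protein_id="p1",
                domain_name=f"D{rng.integers(6)}",
                model_length=length,
                hmm_from=1,
                hmm_to=length,
                env_from=start,
                env_to=start + length - 1,
                i_evalue=float(10.0 ** rng.uniform(-30, -3)),
            )
        )
    return hits


class TestConflictResolution:
    def test_disjoint_domains_both_survive(self):
        a = make_hit(domain_name="A", env_from=1, env_to=100, model_length=100, hmm_to=100)
        b = make_hit(domain_name="B", env_from=150, env_to=200, model_length=51, hmm_to=51)
        assert len(resolve_domain_conflicts([a, b])) == 2

    def test_overlap_beyond_quarter_of_either_conflicts(self):
        # overlap 20 residues = 20% of A (no conflict for A) but 50% of B
        a = make_hit(domain_name="A", env_from=1, env_to=100, model_length=100,
                     hmm_to=100, i_evalue=1e-5)
        b = make_hit(domain_name="B", env_from=81, env_to=120, model_length=40,
                     hmm_to=40, i_evalue=1e-3)
        assert hits_conflict(a, b)
        survivors = resolve_domain_conflicts([a, b])
        assert [h.domain_name for h in survivors] == ["A"]

    def test_quarter_overlap_exactly_is_tolerated(self):
        # overlap 10 = exactly 25% of both 40-residue envelopes: not a conflict
        a = make_hit(domain_name="A", env_from=1, env_to=40, model_length=40,
                     hmm_to=40, i_evalue=1e-5)
        b = make_hit(domain_name="B", env_from=31, env_to=70, model_length=40,
                     hmm_to=40, i_evalue=1e-3)
        assert not hits_conflict(a, b)
        assert len(resolve_domain_conflicts([a, b])) == 2

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_pairwise_elimination_oracle(self, seed):
        rng = np.random.default_rng(seed)
        hits = random_hit_set(rng, int(rng.integers(2, 9)))
        assert resolve_domain_conflicts(hits) == dominant_elimination(hits)

    def test_order_independent(self):
        rng = np.random.default_rng(5)
        hits = random_hit_set(rng, 6)
        baseline = resolve_domain_conflicts(hits)
        for perm in itertools.permutations(hits):
            assert resolve_domain_conflicts(list(perm)) == baseline

    def test_no_surviving_pair_conflicts(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            survivors = resolve_domain_conflicts(random_hit_set(rng, 8))
            for a, b in itertools.combinations(survivors, 2):
                assert not hits_conflict(a, b)

    def test_mixed_proteins_rejected(self):
        with pytest.raises(ValidationError):
            resolve_domain_conflicts([make_hit(protein_id="p1"), make_hit(protein_id="p2")])


class TestTopologyIntegration:
    def test_helix_inside_domain_dropped(self):
        dom = make_hit(env_from=1, env_to=100, model_length=100, hmm_to=100)
        segs = [
            TopologySegment("p1", "inside", 1, 10),
            TopologySegment("p1", "helix", 11, 33),
            TopologySegment("p1", "outside", 34, 120),
        ]
        elements = integrate_topology([dom], segs)
        assert [e.kind for e in elements] == ["pfam"]

    def test_lone_nterminal_helix_is_signal_peptide(self):
        dom = make_hit(env_from=40, env_to=300, model_length=252, hmm_to=252)
        segs = [
            TopologySegment("p1", "inside", 1, 4),
            TopologySegment("p1", "helix", 5, 27),
            TopologySegment("p1", "outside", 28, 320),
        ]
        elements = integrate_topology([dom], segs)
        tmh = [e for e in elements if e.kind == "tmh"]
        assert len(tmh) == 1
        assert tmh[0].signal_peptide_flag
        assert tmh[0].orientation == "iTMHo"

    def test_reverse_flanks_give_oTMHi(self):
        segs = [
            TopologySegment("p1", "outside", 1, 40),
            TopologySegment("p1", "helix", 41, 63),
            TopologySegment("p1", "inside", 64, 100),
        ]
        elements = integrate_topology([], segs, protein_id="p1")
        assert elements[0].orientation == "oTMHi"
        assert not elements[0].signal_peptide_flag  # start > 30

    def test_foreign_segment_rejected(self):
        dom = make_hit(env_from=1, env_to=50, model_length=50, hmm_to=50)
        with pytest.raises(ValidationError):
            integrate_topology([dom], [TopologySegment("other", "helix", 60, 80)])


class TestBuildArchitecture:
    def test_repeat_grouping(self):
        els = [
            ArchitectureElement("WD40", "pfam", s, s + 39) for s in (1, 50, 100)
        ]
        arch = build_architecture(els, protein_id="p1")
        assert len(arch.elements) == 1
        assert arch.elements[0].repeat_count == 3
        assert arch.canonical == "WD40"
        assert not arch.is_metacaspase

    def test_metacaspase_with_partner_domain(self):
        els = [
            ArchitectureElement(METACASPASE_DOMAIN, "pfam", 1, 252),
            ArchitectureElement("FGE-sulfatase", "pfam", 300, 560),
        ]
        arch = build_architecture(els, protein_id="p1")
        assert arch.canonical == "Bac_PepC14|FGE-sulfatase"
        assert arch.is_metacaspase

    def test_metacaspase_lost_in_conflict_excludes_protein(self):
        # a stronger fully-overlapping domain displaces the metacaspase hit
        mc = make_hit(domain_name=METACASPASE_DOMAIN, env_from=10, env_to=260,
                      i_evalue=1e-5, model_length=252, hmm_to=252)
        stronger = make_hit(domain_name="TPR_1", env_from=5, env_to=270,
                            i_evalue=1e-20, model_length=266, hmm_to=266)
        arch = assemble_protein([mc, stronger], [], protein_id="p1")
        assert arch.canonical == "TPR_1"
        assert not arch.is_metacaspase

    def test_empty_elements(self):
        arch = build_architecture([], protein_id="p1")
        assert arch.canonical == "" and not arch.is_metacaspase

    def test_repeat_collapse_idempotent_and_count_invariant(self):
        els = [
            ArchitectureElement("WD40", "pfam", 1, 40),
            ArchitectureElement("WD40", "pfam", 50, 90, repeat_count=2),
            ArchitectureElement("NACHT", "pfam", 200, 360),
        ]
        arch = build_architecture(els)
        again = build_architecture(arch.elements)
        assert again.elements == arch.elements
        assert again.canonical == arch.canonical == "WD40|NACHT"

    def test_orientation_aware_canonical_is_optional(self):
        segs = [
            TopologySegment("p1", "inside", 1, 4),
            TopologySegment("p1", "helix", 5, 27),
            TopologySegment("p1", "outside", 28, 100),
        ]
        els = integrate_topology([], segs, protein_id="p1")
        plain = build_architecture(els, protein_id="p1")
        oriented = build_architecture(els, protein_id="p1", include_orientation=True)
        assert plain.canonical == "TMH"
        assert oriented.canonical == "iTMHo"

    def test_elements_trace_back_to_inputs(self):
        rng = np.random.default_rng(21)
        hits = random_hit_set(rng, 6)
        segs = [
            TopologySegment("p1", "inside", 1, 300),
            TopologySegment("p1", "helix", 301, 323),
            TopologySegment("p1", "outside", 324, 400),
        ]
        arch = assemble_protein(hits, segs, protein_id="p1")
        hit_spans = {(h.env_from, h.env_to) for h in hits}
        for el in arch.elements:
            if el.kind == "pfam" and el.repeat_count == 1:
                assert (el.start, el.end) in hit_spans
            elif el.kind == "tmh":
                assert (el.start, el.end) == (301, 323)


class TestCensus:
    GENOMES = [
        GenomeRecord("g1", "o1", "Cyanobacteria", "Bacteria", 3000),
        GenomeRecord("g2", "o2", "Alphaproteobacteria", "Bacteria", 4000),
    ]

    def _arch(self, pid, gid, labels):
        els = []
        pos = 1
        for lab in labels:
            els.append(ArchitectureElement(lab, "pfam", pos, pos + 30))
            pos += 50
        return build_architecture(els, protein_id=pid, genome_id=gid)

    def test_counts_and_group_uniqueness(self):
        archs = [
            self._arch("p1", "g1", [METACASPASE_DOMAIN, "WD40"]),
            self._arch("p2", "g1", [METACASPASE_DOMAIN, "WD40"]),
            self._arch("p3", "g1", [METACASPASE_DOMAIN, "WD40"]),
            self._arch("p4", "g2", [METACASPASE_DOMAIN, "WD40"]),
            self._arch("p5", "g2", [METACASPASE_DOMAIN]),
        ]
        census = architecture_census(archs, self.GENOMES)
        row = census[census["canonical"] == "Bac_PepC14|WD40"].iloc[0]
        assert row["n_sequences"] == 4
        assert row["n_groups"] == 2
        assert not row["group_unique"]
        solo = census[census["canonical"] == "Bac_PepC14"].iloc[0]
        assert solo["group_unique"]

    def test_non_metacaspases_excluded(self):
        archs = [self._arch("p1", "g1", ["WD40"])]
        assert len(architecture_census(archs, self.GENOMES)) == 0

    def test_planted_palette_census_matches_manifest(self, small_survey):
        from mcsurvey.io_formats import read_genome_table

        files, truth = small_survey
        genomes = read_genome_table(files.genomes)
        group_of = truth.groups
        archs = []
        for pid, key in truth.canonical.items():
            gid = pid.split("_")[0]
            els = []
            pos = 1
            for lab in key.split("|"):
                kind = "tmh" if lab == "TMH" else "pfam"
                els.append(ArchitectureElement(lab, kind, pos, pos + 20))
                pos += 40
            archs.append(build_architecture(els, protein_id=pid, genome_id=gid))
        census = architecture_census(archs, genomes)
        planted_incidence = {}
        for pid, key in truth.canonical.items():
            planted_incidence.setdefault(key, set()).add(group_of[pid.split("_")[0]])
        assert set(census["canonical"]) == set(planted_incidence)
        for _, row in census.iterrows():
            assert set(row["groups"].split(";")) == planted_incidence[row["canonical"]]

    def test_domain_prevalence_percentage(self):
        # 73 of 671 sequences carrying WD40 reads out as 10.9%
        archs = []
        for i in range(671):
            labels = [METACASPASE_DOMAIN] + (["WD40"] if i < 73 else [])
            archs.append(self._arch(f"p{i}", "g1", labels))
        prev = domain_prevalence(archs)
        wd40 = prev[prev["domain"] == "WD40"].iloc[0]
        assert wd40["n_sequences"] == 73
        assert wd40["percent"] == 10.9
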