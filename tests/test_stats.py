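"""Abundance normalization, group summaries and percentage formatting."""

import numpy as np
import pytest

from mcsurvey.architecture import (
    METACASPASE_DOMAIN,
    ArchitectureElement,
    build_architecture,
)
from mcsurvey.errors import ValidationError
from mcsurvey.io_formats import GenomeRecord
from mcsurvey.stats import (
    AbundanceRecord,
    carrier_split,
    genome_abundance,
    group_summary,
    survey_percentages,
)


def mc_arch(pid, gid):
    el = ArchitectureElement(METACASPASE_DOMAIN, "pfam", 1, 252)
    return build_architecture([el], protein_id=pid, genome_id=gid)


def genome(gid, group="Cyanobacteria", count=4000, sk="Bacteria"):
    return GenomeRecord(gid, f"org {gid}", group, sk, count)


class TestGenomeAbundance:
    def test_zero_metacaspases(self):
        (rec,) = genome_abundance([], [genome("g1")])
        assert rec.metacaspase_count == 0
        assert rec.abundance == 0.0

    def test_haliscomenobacter_style_normalization(self):
        # 28 metacaspase genes on a 6747-protein proteome: 4.15 per 1000
        archs = [mc_arch(f"p{i}", "g1") for i in range(28)]
        (rec,) = genome_abundance(archs, [genome("g1", count=6747)])
        assert rec.metacaspase_count == 28
        assert round(rec.abundance, 2) == 4.15

    def test_unknown_genome_rejected(self):
        with pytest.raises(ValidationError, match="g9"):
            genome_abundance([mc_arch("p1", "g9")], [genome("g1")])

    def test_planted_counts_match_manifest(self, small_survey):
        from mcsurvey.io_formats import read_genome_table

        files, truth = small_survey
        genomes = read_genome_table(files.genomes)
        archs = [mc_arch(pid, pid.split("_")[0]) for pid in truth.metacaspase_ids]
        records = genome_abundance(archs, genomes)
        expected = truth.expected_abundance()
        assert len(records) == len(expected)
        for rec in records:
            count, abundance = expected[rec.genome_id]
            assert rec.metacaspase_count == count
            assert rec.abundance == pytest.approx(abundance, abs=1e-9)


class TestGroupSummary:
    def test_unweighted_mean(self):
        genomes = [genome("g1"), genome("g2")]
        records = [
            AbundanceRecord("g1", 0, 0.0),
            AbundanceRecord("g2", 8, 2.0),
        ]
        table = group_summary(records, genomes)
        assert table.iloc[0]["mean_abundance"] == pytest.approx(1.0)

    def test_ordering_by_descending_mean(self):
        genomes = [
            genome("g1", group="A"),
            genome("g2", group="B"),
            genome("g3", group="B"),
        ]
        records = [
            AbundanceRecord("g1", 2, 0.5),
            AbundanceRecord("g2", 8, 2.0),
            AbundanceRecord("g3", 4, 1.0),
        ]
        table = group_summary(records, genomes)
        assert list(table["group"]) == ["B", "A"]

    def test_sparse_empty_groups_fold_into_other(self):
        genomes = [genome(f"g{i}", group="Rare") for i in range(3)]
        genomes += [genome("g9", group="Cyanobacteria")]
        records = [AbundanceRecord(f"g{i}", 0, 0.0) for i in range(3)]
        records += [AbundanceRecord("g9", 2, 0.5)]
        table = group_summary(records, genomes)
        assert set(table["group"]) == {"Cyanobacteria", "Other"}
        other = table[table["group"] == "Other"].iloc[0]
        assert other["n_genomes"] == 3

    def test_group_with_metacaspases_never_folds(self):
        genomes = [genome("g1", group="Tiny")]
        records = [AbundanceRecord("g1", 1, 0.25)]
        table = group_summary(records, genomes)
        assert list(table["group"]) == ["Tiny"]

    def test_bin_counts_partition_genomes(self):
        rng = np.random.default_rng(8)
        genomes = [genome(f"g{i}") for i in range(40)]
        records = [
            AbundanceRecord(f"g{i}", int(c), float(a))
            for i, (c, a) in enumerate(
                zip(rng.integers(0, 10, 40), rng.uniform(0, 3, 40))
            )
        ]
        records = [
            AbundanceRecord(r.genome_id, r.metacaspase_count, 0.0 if r.metacaspase_count == 0 else r.abundance)
            for r in records
        ]
        table = group_summary(records, genomes)
        bin_cols = [c for c in table.columns if c.startswith(("0", "(", ">"))]
        assert table[bin_cols].to_numpy().sum() == 40

    def test_pooled_mode(self):
        genomes = [genome("g1", count=1000), genome("g2", count=3000)]
        records = [AbundanceRecord("g1", 1, 1.0), AbundanceRecord("g2", 1, 1 / 3)]
        table = group_summary(records, genomes, pooled=True)
        assert table.iloc[0]["mean_abundance"] == pytest.approx(1000 * 2 / 4000)


class TestSurveyPercentages:
    @pytest.mark.parametrize(
        "num, den, decimals, expected",
        [
            (267, 1463, 0, 18),
            (73, 671, 1, 10.9),
            (47, 671, 1, 7.0),
            (40, 671, 1, 6.0),
            (39, 671, 1, 5.8),
            (33, 671, 1, 4.9),
            (5, 114, 0, 4),
            (0, 10, 1, 0.0),
        ],
    )
    def test_printed_style_percentages(self, num, den, decimals, expected):
        assert survey_percentages(num, den, decimals) == expected

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValidationError):
            survey_percentages(1, 0)

    def test_half_rounds_away_from_zero(self):
        assert survey_percentages(5, 1000, 1) == 0.5
        assert survey_percentages(1, 8, 0) == 13  # 12.5 -> 13

    def test_complement_sums_to_hundred_within_rounding(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            den = int(rng.integers(1, 2000))
            num = int(rng.integers(0, den + 1))
            s = survey_percentages(num, den, 1) + survey_percentages(den - num, den, 1)
            assert s in (99.9, 100.0, 100.1)


class TestCarrierSplit:
    def test_single_vs_multi(self):
        records = [
            AbundanceRecord("g1", 1, 0.1),
            AbundanceRecord("g2", 3, 0.9),
            AbundanceRecord("g3", 1, 0.2),
        ]
        assert carrier_split(records) == {
            "carriers": 3,
            "single_copy": 2,
            "multi_copy": 1,
        }
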