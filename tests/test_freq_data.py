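"""Frequency-table reading, validation, founder subsampling, monomorphism."""

import numpy as np
import pandas as pd
import pytest

from gwaspower.exceptions import (
    InsufficientSampleError,
    PanelMappingError,
    ParseError,
    ValidationError,
)
from gwaspower.freq_data import (
    FrequencyTable,
    annotate_monomorphic,
    filter_polymorphic_any,
    read_frequency_table,
    subsample_founders,
    write_frequency_table,
)

from conftest import make_table

VCF_TEXT = """\
##fileformat=VCFv4.2
##contig=<ID=1,length=1000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3\ts4
1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\t0/1
1\t200\trs2\tC\tT\t.\tPASS\t.\tGT\t0/0\t./.\t0/1\t1/1
1\t300\trs3\tG\tA,C\t.\tPASS\t.\tGT\t0/0\t0/1\t0/2\t1/2
"""


class TestTsvRoundTrip:
    def test_written_table_reads_back_identically(self, toy_table, tmp_path):
        path = tmp_path / "freq.tsv"
        write_frequency_table(toy_table, path)
        back = read_frequency_table(path)
        assert back.panels == toy_table.panels
        assert back.source == toy_table.source
        pd.testing.assert_frame_equal(
            back.frame[["CEU", "YRI"]], toy_table.frame[["CEU", "YRI"]]
        )
        assert list(back.snp_ids) == list(toy_table.snp_ids)

    def test_metadata_round_trip(self, toy_table, tmp_path):
        toy_table.chromosomes = {"CEU": 100, "YRI": 100}
        toy_table.source = "estimated"
        path = tmp_path / "freq.tsv"
        write_frequency_table(toy_table, path)
        back = read_frequency_table(path)
        assert back.chromosomes == {"CEU": 100, "YRI": 100}
        assert back.source == "estimated"

    def test_three_row_two_panel_file(self, tmp_path):
        path = tmp_path / "f.tsv"
        path.write_text(
            "snp_id\tchrom\tpos\tallele_a\tallele_b\tCEU\tYRI\n"
            "rs1\t1\t10\tA\tG\t0.1\t0.4\n"
            "rs2\t1\t20\tC\tT\t0.2\t0.5\n"
            "rs3\t2\t30\tG\tA\t0.3\t0.6\n"
        )
        table = read_frequency_table(path)
        assert len(table) == 3
        assert table.panels == ["CEU", "YRI"]

    def test_out_of_range_frequency_rejected(self, tmp_path):
        path = tmp_path / "f.tsv"
        path.write_text(
            "snp_id\tchrom\tpos\tallele_a\tallele_b\tCEU\n"
            "rs1\t1\t10\tA\tG\t1.2\n"
        )
        with pytest.raises(ValidationError, match="outside"):
            read_frequency_table(path)

    def test_malformed_row_names_line(self, tmp_path):
        path = tmp_path / "f.tsv"
        path.write_text(
            "snp_id\tchrom\tpos\tallele_a\tallele_b\tCEU\n"
            "rs1\t1\t10\tA\tG\t0.1\n"
            "rs2\t1\t20\tC\tT\toops\n"
        )
        with pytest.raises(ParseError, match="line 3"):
            read_frequency_table(path)

    def test_missing_marker_allowed(self, tmp_path):
        path = tmp_path / "f.tsv"
        path.write_text(
            "snp_id\tchrom\tpos\tallele_a\tallele_b\tCEU\n"
            "rs1\t1\t10\tA\tG\tNA\n"
        )
        table = read_frequency_table(path)
        assert np.isnan(table.freqs("CEU")[0])


class TestValidation:
    def test_duplicate_snp_id_rejected(self):
        with pytest.raises(ValidationError, match="duplicate"):
            table = make_table({"CEU": [0.1, 0.2]})
            table.frame.loc[1, "snp_id"] = "s1"
            table.validate()

    def test_identical_alleles_rejected(self):
        with pytest.raises(ValidationError, match="allele"):
            make_table({"CEU": [0.1]}, alleles=("A", "A"))


class TestVcfInput:
    def test_per_panel_allele_counts(self, tmp_path):
        path = tmp_path / "toy.vcf"
        path.write_text(VCF_TEXT)
        panel_map = {"s1": "P1", "s2": "P1", "s3": "P2", "s4": "P2"}
        with pytest.warns(UserWarning, match="multi-allelic"):
            table = read_frequency_table(path, format="vcf", panel_map=panel_map)
        # rs1 REF=A: P1 has 0/0,0/1 -> 3/4; P2 has 1/1,0/1 -> 1/4
        assert table.freqs("P1")[0] == pytest.approx(0.75)
        assert table.freqs("P2")[0] == pytest.approx(0.25)
        # rs2: missing call drops 2 chromosomes from P1's denominator
        assert table.freqs("P1")[1] == pytest.approx(1.0)  # only s1 called: 2/2 REF
        assert table.freqs("P2")[1] == pytest.approx(0.25)
        # the multi-allelic rs3 is rejected
        assert len(table) == 2
        assert table.chromosomes == {"P1": 4, "P2": 4}

    def test_unmapped_sample_raises(self, tmp_path):
        path = tmp_path / "toy.vcf"
        path.write_text(VCF_TEXT)
        with pytest.raises(PanelMappingError, match="s4"):
            with pytest.warns(UserWarning):
                read_frequency_table(
                    path, format="vcf", panel_map={"s1": "P1", "s2": "P1", "s3": "P2"}
                )

    def test_vcf_requires_panel_map(self, tmp_path):
        path = tmp_path / "toy.vcf"
        path.write_text(VCF_TEXT)
        with pytest.raises(PanelMappingError):
            read_frequency_table(path, format="vcf")


class TestSubsampleFounders:
    def test_full_panel_selection_reproduces_panel_frequency(
        self, toy_genotypes, panel_map_20
    ):
        table = subsample_founders(toy_genotypes, panel_map_20, n_founders=10, seed=0)
        for panel, cols in (("P1", range(10)), ("P2", range(10, 20))):
            expect = toy_genotypes.dosage[:, list(cols)].sum(axis=1) / 20.0
            np.testing.assert_allclose(table.freqs(panel), expect)

    def test_chromosome_metadata(self, toy_genotypes, panel_map_20):
        table = subsample_founders(toy_genotypes, panel_map_20, n_founders=5, seed=0)
        assert table.chromosomes == {"P1": 10, "P2": 10}

    def test_same_seed_byte_identical(self, toy_genotypes, panel_map_20, tmp_path):
        paths = []
        for run in (1, 2):
            t = subsample_founders(toy_genotypes, panel_map_20, n_founders=6, seed=42)
            p = tmp_path / f"run{run}.tsv"
            write_frequency_table(t, p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_insufficient_samples_names_panel(self, toy_genotypes, panel_map_20):
        with pytest.raises(InsufficientSampleError, match="P1"):
            subsample_founders(toy_genotypes, panel_map_20, n_founders=11, seed=0)

    def test_frequencies_are_chromosome_multiples(self, toy_genotypes, panel_map_20):
        for seed in range(5):
            t = subsample_founders(toy_genotypes, panel_map_20, n_founders=7, seed=seed)
            for panel in t.panels:
                f = t.freqs(panel) * 14  # 2 * n_founders chromosomes
                np.testing.assert_allclose(f, np.round(f), atol=1e-9)

    def test_mean_over_seeds_converges_to_panel_frequency(
        self, toy_genotypes, panel_map_20
    ):
        full = toy_genotypes.dosage[:, :10].sum(axis=1) / 20.0  # P1
        draws = np.array(
            [
                subsample_founders(toy_genotypes, panel_map_20, 6, seed=s).freqs("P1")
                for s in range(1000)
            ]
        )
        mean = draws.mean(axis=0)
        se = draws.std(axis=0, ddof=1) / np.sqrt(len(draws))
        assert np.all(np.abs(mean - full) <= 3 * se)


class TestMonomorphic:
    def test_flags_and_counts(self):
        table = make_table(
            {
                "CEU": [0.05, 0.20, 0.30, 0.40, 0.02, 0.10],
                "B": [0.30, 0.00, 0.20, 1.00, 0.10, 0.50],
            }
        )
        flags, counts = annotate_monomorphic(table, reference_panel="CEU")
        assert flags["B"].sum() == 2
        assert flags["CEU"].sum() == 0
        assert counts.loc["B"].sum() == 2  # stratified counts total the flags

    def test_zero_and_one_are_monomorphic_interior_is_not(self):
        table = make_table({"P": [0.0, 1.0, 0.01, 0.5]})
        flags, _ = annotate_monomorphic(table)
        assert list(flags["P"]) == [True, True, False, False]


class TestFilterPolymorphic:
    def test_enumerated_fixture(self):
        freqs = [0.0, 0.5, 0.0, 1.0, 0.2, 0.0, 0.9, 1.0, 0.3, 0.7]
        other = [0.0, 0.5, 0.1, 1.0, 0.2, 0.0, 0.9, 0.4, 0.3, 0.7]
        table = make_table({"A": freqs, "B": other})
        out = filter_polymorphic_any(table)
        assert len(out) == 7  # 3 records fixed in every panel drop out

    def test_kept_if_polymorphic_anywhere(self):
        table = make_table({"A": [0.5, 0.0], "B": [0.0, 0.0]})
        out = filter_polymorphic_any(table)
        assert list(out.snp_ids) == ["s1"]

    def test_idempotent(self, toy_table):
        once = filter_polymorphic_any(toy_table)
        twice = filter_polymorphic_any(once)
        pd.testing.assert_frame_equal(once.frame, twice.frame)
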