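"""I/O layer: VCF reading, population maps, writers, panel invariants."""

import numpy as np
import pandas as pd
import pytest

from sweepscan.haplo_io import (
    PanelError,
    Region,
    ScanResult,
    SiteInfo,
    attach_populations,
    read_phased_vcf,
    read_pop_map,
    subset_by_population,
    write_phased_vcf,
    write_regions_bed,
    write_scan_table,
)
from sweepscan.synthetic_data import SweepSpec, simulate_wf_sweep

from conftest import make_panel

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "##contig=<ID=1,length=100000>\n"
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\n"
)


def write_vcf(tmp_path, body):
    path = tmp_path / "in.vcf"
    path.write_text(VCF_HEADER + body)
    return str(path)


class TestReadPhasedVcf:
    def test_phased_record_transcribed_directly(self, tmp_path):
        path = write_vcf(tmp_path, "1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0|1\t1|1\n")
        panel, skip = read_phased_vcf(path)
        assert panel.alleles[:, 0].tolist() == [0, 1, 1, 1]
        assert sum(skip.values()) == 0

    def test_unphased_and_missing_records_skipped(self, tmp_path):
        body = (
            "1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0|1\t1|1\n"
            "1\t200\trs2\tA\tG\t.\tPASS\t.\tGT\t0/1\t1|1\n"
            "1\t300\trs3\tA\tG\t.\tPASS\t.\tGT\t.|.\t1|1\n"
        )
        panel, skip = read_phased_vcf(write_vcf(tmp_path, body))
        assert panel.n_sites == 1
        assert skip["unphased"] == 2

    def test_multiallelic_and_indel_skipped(self, tmp_path):
        body = (
            "1\t100\trs1\tA\tT,G\t.\tPASS\t.\tGT\t0|1\t1|1\n"
            "1\t200\trs2\tAT\tG\t.\tPASS\t.\tGT\t0|1\t1|1\n"
            "1\t300\trs3\tA\tG\t.\tPASS\t.\tGT\t0|1\t1|1\n"
        )
        panel, skip = read_phased_vcf(write_vcf(tmp_path, body))
        assert panel.n_sites == 1
        assert skip["multiallelic"] == 1
        assert skip["non_snp"] == 1

    def test_duplicate_position_keeps_first(self, tmp_path):
        body = (
            "1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0|1\t1|1\n"
            "1\t100\trs2\tC\tT\t.\tPASS\t.\tGT\t0|0\t1|1\n"
        )
        panel, skip = read_phased_vcf(write_vcf(tmp_path, body))
        assert panel.n_sites == 1
        assert panel.sites[0].site_id == "rs1"
        assert skip["duplicate_pos"] == 1

    def test_no_parsable_records_raises(self, tmp_path):
        path = write_vcf(tmp_path, "1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0/1\t1/1\n")
        with pytest.raises(PanelError, match="no parsable"):
            read_phased_vcf(path)

    def test_roundtrip_reproduces_allele_matrix(self, tmp_path):
        spec = SweepSpec(
            n_haplotypes=[12], chrom_length_bp=500_000, n_sites=40,
            n_anc_diploid=15, generations=3, seed=7,
        )
        panel, _ = simulate_wf_sweep(spec)
        out = tmp_path / "rt.vcf"
        write_phased_vcf(panel, str(out))
        back, skip = read_phased_vcf(str(out))
        assert np.array_equal(panel.alleles, back.alleles)
        assert [s.pos for s in back.sites] == [s.pos for s in panel.sites]
        assert sum(skip.values()) == 0


class TestPopMap:
    def test_basic_map_and_small_pop_warning(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("s1\tPopA\ns2\tPopB\n")
        mapping, warnings = read_pop_map(str(p))
        assert mapping == {"s1": "PopA", "s2": "PopB"}
        assert len(warnings) == 2  # both pops have a single sample

    def test_consistent_duplicate_deduplicated(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("s1\tPopA\ns1\tPopA\n")
        mapping, warnings = read_pop_map(str(p))
        assert mapping == {"s1": "PopA"}
        assert any("duplicate" in w for w in warnings)

    def test_conflicting_duplicate_raises(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("s1\tPopA\ns1\tPopB\n")
        with pytest.raises(PanelError, match="assigned to both"):
            read_pop_map(str(p))

    def test_header_row_recognised(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("sample_id\tpopulation\ns1\tPopA\ns2\tPopA\n")
        mapping, _ = read_pop_map(str(p))
        assert mapping == {"s1": "PopA", "s2": "PopA"}


class TestSubsetByPopulation:
    def _panel(self):
        alleles = np.arange(20).reshape(10, 2) % 2
        pops = {f"s{i}": ("A" if i < 3 else "B") for i in range(5)}
        return make_panel(alleles, pops=pops)

    def test_subset_keeps_exactly_that_populations_haplotypes(self):
        sub = subset_by_population(self._panel(), "A")
        assert sub.n_haplotypes == 6
        assert set(sub.sample_pop.values()) == {"A"}
        assert sub.n_sites == 2

    def test_subset_is_idempotent(self):
        once = subset_by_population(self._panel(), "B")
        twice = subset_by_population(once, "B")
        assert np.array_equal(once.alleles, twice.alleles)
        assert once.samples == twice.samples

    def test_unknown_population_raises(self):
        with pytest.raises(PanelError, match="unknown population"):
            subset_by_population(self._panel(), "Z")


class TestGenotypeMatrix:
    def test_dosage_equals_haplotype_pair_sums(self):
        rng = np.random.default_rng(3)
        panel = make_panel(rng.integers(0, 2, size=(16, 25)))
        gm = panel.to_genotype_matrix()
        expected = panel.alleles[0::2].astype(float) + panel.alleles[1::2]
        assert np.array_equal(gm.dosage, expected)

    def test_sites_must_strictly_increase(self):
        with pytest.raises(PanelError, match="strictly increasing"):
            make_panel(np.zeros((2, 2)), positions=[500, 500])


class TestWriters:
    def _result(self):
        df = pd.DataFrame(
            {
                "chrom": ["1", "1", "1"],
                "pos": [100, 200, 300],
                "site_id": ["a", "b", "c"],
                "raw": [0.5, np.nan, -0.2],
                "standardized": [1.1, np.nan, -0.4],
                "neglog10_p": [0.9, np.nan, 0.2],
                "valid": [True, False, True],
                "reason": ["", "maf", ""],
            }
        )
        return ScanResult(test="iHS", population="A", table=df)

    def test_scan_table_layout(self, tmp_path):
        out = tmp_path / "scan.tsv"
        write_scan_table(self._result(), str(out))
        lines = out.read_text().splitlines()
        assert len(lines) == 4
        assert lines[0].split("\t") == [
            "chrom", "pos", "site_id", "raw", "standardized", "neglog10_p", "valid", "reason",
        ]
        invalid_row = lines[2].split("\t")
        assert invalid_row[3:6] == ["", "", ""]  # scores blanked
        assert invalid_row[7] == "maf"

    def test_empty_scan_table_has_header_only(self, tmp_path):
        res = self._result()
        res.table = res.table.iloc[0:0]
        out = tmp_path / "scan.tsv"
        write_scan_table(res, str(out))
        assert len(out.read_text().splitlines()) == 1

    def _region(self, start, end, **kw):
        args = dict(
            population="A", test="iHS", chrom="1", start=start, end=end,
            n_sig_snps=4, peak_score=3.86, peak_neglog10p=3.95,
            size_kb=round((end - start) / 1000, 1),
        )
        args.update(kw)
        return Region(**args)

    def test_bed_coordinates_are_zero_based_half_open(self, tmp_path):
        out = tmp_path / "r.bed"
        write_regions_bed([self._region(35662318, 35684677)], str(out))
        chrom, start, end, name, score = out.read_text().split()
        assert (start, end) == ("35662317", "35684677")
        assert name == "A|iHS|4|22.4"
        assert score == "395"

    def test_bed_roundtrip_recovers_one_based_coordinates(self, tmp_path):
        regions = [self._region(100, 100), self._region(500, 900)]
        out = tmp_path / "r.bed"
        write_regions_bed(regions, str(out))
        for line, reg in zip(out.read_text().splitlines(), regions):
            _, b_start, b_end, *_ = line.split("\t")
            assert int(b_start) + 1 == reg.start
            assert int(b_end) == reg.end

    def test_empty_region_list_gives_empty_file(self, tmp_path):
        out = tmp_path / "r.bed"
        write_regions_bed([], str(out))
        assert out.read_text() == ""

    def test_unsorted_regions_raise(self, tmp_path):
        regions = [self._region(500, 900), self._region(100, 200)]
        with pytest.raises(PanelError, match="sorted"):
            write_regions_bed(regions, str(tmp_path / "r.bed"))


def test_attach_populations_requires_every_sample():
    panel = make_panel(np.zeros((4, 3)))
    with pytest.raises(PanelError, match="misses samples"):
        attach_populations(panel, {"s0": "A"})
    out = attach_populations(panel, {"s0": "X", "s1": "Y"})
    assert out.sample_pop == {"s0": "X", "s1": "Y"}


def test_site_position_must_be_positive():
    with pytest.raises(PanelError):
        SiteInfo(chrom="1", pos=0, site_id="bad")
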