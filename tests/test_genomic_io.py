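"""genomic_io: format parsing, coordinate conventions, interval index."""

import gzip

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from refaudit import genomic_io as gio
from refaudit.genomic_io import (
    FormatError,
    GenomeCoordinate,
    Interval,
    ProbeRecord,
    ValidationError,
    build_interval_index,
    normalize_chrom,
    query_point,
    query_window,
    read_bed,
    read_gwas_catalog,
    read_probe_manifest,
    read_report_tsv,
    read_vcf,
    write_report_tsv,
    write_vcf,
)

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n"
)


def write_vcf_text(path, body, samples="s1"):
    path.write_text(VCF_HEADER.format(samples=samples) + body)
    return path


class TestVcf:
    def test_single_record_direct_transcription(self, tmp_path):
        p = write_vcf_text(tmp_path / "a.vcf", "1\t100\t.\tA\tC\t.\tPASS\t.\tGT\t0/1\n")
        samples, sites = read_vcf(p)
        assert samples == ["s1"]
        assert len(sites) == 1
        site = sites[0]
        assert (site.coord.chrom, site.coord.pos, site.ref, site.alts) == ("1", 100, "A", ["C"])
        assert site.genotypes == [(0, 1)]

    def test_multiallelic_alt_kept_as_one_site(self, tmp_path):
        p = write_vcf_text(tmp_path / "a.vcf", "1\t100\t.\tA\tC,T\t.\tPASS\t.\tGT\t1/2\n")
        _, sites = read_vcf(p)
        assert sites[0].alts == ["C", "T"]
        assert sites[0].genotypes == [(1, 2)]

    def test_non_integer_pos_is_format_error_with_line(self, tmp_path):
        p = write_vcf_text(tmp_path / "a.vcf", "1\tabc\t.\tA\tC\t.\tPASS\t.\tGT\t0/1\n")
        with pytest.raises(FormatError, match="line 3"):
            read_vcf(p)

    def test_gt_index_out_of_range_is_format_error(self, tmp_path):
        p = write_vcf_text(tmp_path / "a.vcf", "1\t100\t.\tA\tC\t.\tPASS\t.\tGT\t0/2\n")
        with pytest.raises(FormatError):
            read_vcf(p)

    def test_missing_and_half_calls_are_missing(self, tmp_path):
        body = (
            "1\t100\t.\tA\tC\t.\tPASS\t.\tGT\t./.\t0/.\t.\t0|1\n"
        )
        p = write_vcf_text(tmp_path / "a.vcf", body, samples="s1\ts2\ts3\ts4")
        _, sites = read_vcf(p)
        assert sites[0].genotypes == [None, None, None, (0, 1)]

    def test_phased_and_unphased_equivalent(self, tmp_path):
        pa = write_vcf_text(tmp_path / "a.vcf", "1\t5\t.\tG\tT\t.\tPASS\t.\tGT\t1|0\n")
        pb = write_vcf_text(tmp_path / "b.vcf", "1\t5\t.\tG\tT\t.\tPASS\t.\tGT\t1/0\n")
        assert read_vcf(pa)[1][0].genotypes == read_vcf(pb)[1][0].genotypes

    def test_gzip_input(self, tmp_path):
        text = VCF_HEADER.format(samples="s1") + "1\t7\t.\tA\tC\t.\tPASS\t.\tGT\t1/1\n"
        p = tmp_path / "a.vcf.gz"
        with gzip.open(p, "wt") as fh:
            fh.write(text)
        _, sites = read_vcf(p)
        assert sites[0].genotypes == [(1, 1)]

    def test_output_sorted_by_position(self, tmp_path):
        body = "1\t200\t.\tA\tC\t.\tPASS\t.\tGT\t0/0\n1\t100\t.\tA\tC\t.\tPASS\t.\tGT\t0/0\n"
        p = write_vcf_text(tmp_path / "a.vcf", body)
        _, sites = read_vcf(p)
        assert [s.coord.pos for s in sites] == [100, 200]

    def test_round_trip_idempotent(self, tmp_path, small_cohort):
        matrix, _ = small_cohort
        sites = matrix.to_sites()
        p1, p2 = tmp_path / "r1.vcf", tmp_path / "r2.vcf"
        write_vcf(matrix.samples, sites, p1)
        samples, back = read_vcf(p1)
        write_vcf(samples, back, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_agrees_with_cyvcf2_oracle(self, tmp_path, small_cohort):
        cyvcf2 = pytest.importorskip("cyvcf2")
        matrix, _ = small_cohort
        p = tmp_path / "c.vcf"
        write_vcf(matrix.samples, matrix.to_sites(), p)
        _, ours = read_vcf(p)
        theirs = list(cyvcf2.VCF(str(p)))
        assert len(theirs) == len(ours)
        for site, rec in zip(ours, theirs):
            assert (site.coord.pos, site.ref, site.alts) == (rec.POS, rec.REF, rec.ALT)
            for gt, cy in zip(site.genotypes, rec.genotypes):
                assert gt == tuple(sorted(cy[:2]))


class TestCoordinates:
    @pytest.mark.parametrize(
        "raw,expected",
        [("chr1", "1"), ("1", "1"), ("chrX", "X"), ("x", "X"), ("chrM", "MT"), ("MT", "MT")],
    )
    def test_chrom_normalization(self, raw, expected):
        assert normalize_chrom(raw) == expected

    def test_coordinate_invariants(self):
        with pytest.raises(ValidationError):
            GenomeCoordinate("1", 0)
        with pytest.raises(ValidationError):
            Interval("1", 5, 5)
        assert GenomeCoordinate("chr2", 10) == GenomeCoordinate("2", 10)

    def test_interval_point_membership_half_open(self):
        iv = Interval("1", 10, 20)
        assert iv.contains_pos(11)   # 1-based 11 -> 0-based 10
        assert iv.contains_pos(20)   # 0-based 19, last inside
        assert not iv.contains_pos(21)  # 0-based 20, half-open end


class TestProbeManifest:
    HEADER = "probe_id\tplatform\tchrom\tpos\tallele_a\tallele_b\tfp_start\tfp_end\n"

    def test_basic_row(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text(self.HEADER + "p1\tOmni1M\t1\t500\tA\tG\t\t\n")
        probes = read_probe_manifest(p)
        assert probes[0].target == GenomeCoordinate("1", 500)
        assert probes[0].designed_alleles == {"A", "G"}
        assert probes[0].footprint is None

    def test_footprint_one_based_to_half_open(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text(self.HEADER + "p1\tOmni1M\t1\t500\tA\tG\t489\t539\n")
        fp = read_probe_manifest(p)[0].footprint
        assert (fp.start, fp.end) == (488, 539)

    def test_identical_alleles_rejected(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text(self.HEADER + "p2\tOmni1M\t1\t500\tA\tA\t\t\n")
        with pytest.raises(ValidationError):
            read_probe_manifest(p)

    def test_target_outside_footprint_rejected(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text(self.HEADER + "p3\tOmni1M\t1\t600\tA\tG\t489\t539\n")
        with pytest.raises(ValidationError):
            read_probe_manifest(p)

    def test_round_trip(self, tmp_path):
        probes = [
            ProbeRecord("p1", "X1", GenomeCoordinate("1", 500),
                        frozenset({"A", "G"}), Interval("1", 488, 539)),
            ProbeRecord("p2", "X1", GenomeCoordinate("2", 77), frozenset({"C", "T"})),
        ]
        p = tmp_path / "m.tsv"
        gio.write_probe_manifest(probes, p)
        assert read_probe_manifest(p) == probes


class TestBedAndCatalog:
    def test_bed_basic_and_error(self, tmp_path):
        good = tmp_path / "g.bed"
        good.write_text("1\t1000\t2000\n")
        assert read_bed(good) == [Interval("1", 1000, 2000)]
        bad = tmp_path / "b.bed"
        bad.write_text("1\t1000\t2000\n1\t5\t5\n")
        with pytest.raises(ValidationError, match="row 2"):
            read_bed(bad)

    def test_catalog_row(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("study_id\ttrait\tsnp_id\tchrom\tpos\ns1\theight\trs42\t1\t777\n")
        rows = read_gwas_catalog(p)
        assert rows[0].study_id == "s1"
        assert rows[0].coord == GenomeCoordinate("1", 777)

    def test_gene_models_round_trip(self, tmp_path):
        from refaudit.genomic_io import GeneModel, read_gene_models, write_gene_models

        genes = [
            GeneModel("g1", "+", (Interval("1", 10, 20), Interval("1", 30, 40)),
                      (Interval("1", 12, 18),)),
        ]
        p = tmp_path / "genes.tsv"
        write_gene_models(genes, p)
        assert read_gene_models(p) == genes


class TestIntervalIndex:
    def test_point_hit_and_half_open_boundary(self):
        index = build_interval_index([Interval("1", 10, 20)])
        assert query_point(index, GenomeCoordinate("1", 15)) == [Interval("1", 10, 20)]
        assert query_point(index, GenomeCoordinate("1", 21)) == []  # 0-based 20

    def test_unknown_chromosome_is_empty(self):
        index = build_interval_index([Interval("1", 10, 20)])
        assert query_point(index, GenomeCoordinate("9", 15)) == []

    def test_matches_linear_scan(self, rng):
        intervals = []
        for _ in range(200):
            chrom = str(rng.integers(1, 4))
            start = int(rng.integers(0, 5000))
            intervals.append(Interval(chrom, start, start + int(rng.integers(1, 300))))
        index = build_interval_index(intervals)
        for _ in range(500):
            coord = GenomeCoordinate(str(rng.integers(1, 4)), int(rng.integers(1, 5300)))
            brute = sorted(
                iv for iv in intervals
                if iv.chrom == coord.chrom and iv.contains_pos(coord.pos)
            )
            assert query_point(index, coord) == brute
        for _ in range(100):
            chrom = str(rng.integers(1, 4))
            start = int(rng.integers(0, 5000))
            win = Interval(chrom, start, start + int(rng.integers(1, 500)))
            brute = sorted(
                iv for iv in intervals
                if iv.chrom == chrom and iv.start < win.end and win.start < iv.end
            )
            assert query_window(index, win) == brute


class TestReportTsv:
    def test_empty_rows_header_only(self, tmp_path):
        p = tmp_path / "r.tsv"
        write_report_tsv([], p, columns=["a", "b"])
        assert p.read_text() == "a\tb\n"

    def test_three_rows_four_lines(self, tmp_path):
        p = tmp_path / "r.tsv"
        write_report_tsv([{"a": i} for i in range(3)], p)
        assert len(p.read_text().splitlines()) == 4

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(
            st.fixed_dictionaries(
                {
                    "x": st.text(
                        st.characters(blacklist_categories=("Cs", "Cc")),
                        max_size=12,
                    ).filter(lambda s: "\t" not in s and "\n" not in s and "\r" not in s),
                    "y": st.integers(-1000, 1000),
                }
            ),
            max_size=20,
        )
    )
    def test_round_trip_fuzzed(self, rows):
        import tempfile
        from pathlib import Path

        with tempfile.TemporaryDirectory() as d:
            p = Path(d) / "fuzz.tsv"
            write_report_tsv(rows, p, columns=["x", "y"])
            back = read_report_tsv(p)
        assert [{"x": r["x"], "y": str(r["y"])} for r in rows] == back
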