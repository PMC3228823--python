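"""I/O round trips, schema validation and probe-to-gene resolution."""

import pytest

from ripchip.array_io import (
    Blacklist,
    GeneAnnotation,
    PlatformSpec,
    SpotRecord,
    map_probes_to_genes,
    read_blacklist,
    read_callset,
    read_spot_table,
    resolve_dye_swap,
    write_blacklist,
    write_callset,
    write_spot_table,
)
from ripchip.errors import FormatError
from ripchip.target_calling import CallSet

from conftest import make_scan, make_spot

HEADER = "probe_id\tip_signal\tref_signal\tip_frac_above_bg\tref_frac_above_bg\tflag\n"


def write_table(path, rows):
    path.write_text(HEADER + "".join(rows))


class TestReadSpotTable:
    def test_well_formed_table_preserves_row_order(self, tmp_path):
        f = tmp_path / "scan.tsv"
        write_table(
            f,
            [
                "pA\t100\t50\t0.9\t0.8\t0\n",
                "pB\t10\t5\t0.5\t0.4\t0\n",
                "pA\t200\t100\t0.95\t0.85\t-50\n",
            ],
        )
        scan = read_spot_table(f, experiment_id="e1", bait_gene="g1")
        assert [s.probe_id for s in scan.spots] == ["pA", "pB", "pA"]
        assert scan.spots[0].ip_signal == 100.0
        assert scan.spots[2].flag == -50
        assert scan.experiment_id == "e1" and not scan.dye_swapped

    def test_missing_column_is_named(self, tmp_path):
        f = tmp_path / "scan.tsv"
        f.write_text(
            "probe_id\tip_signal\tref_signal\tref_frac_above_bg\tflag\n"
            "pA\t1\t1\t0.5\t0\n"
        )
        with pytest.raises(FormatError, match="ip_frac_above_bg"):
            read_spot_table(f, experiment_id="e", bait_gene="g")

    def test_header_only_file_is_an_empty_table_error(self, tmp_path):
        f = tmp_path / "scan.tsv"
        f.write_text(HEADER)
        with pytest.raises(FormatError, match="empty table"):
            read_spot_table(f, experiment_id="e", bait_gene="g")

    def test_non_numeric_value_reports_line_number(self, tmp_path):
        f = tmp_path / "scan.tsv"
        write_table(f, ["pA\t1\t1\t0.5\t0.5\t0\n", "pB\toops\t1\t0.5\t0.5\t0\n"])
        with pytest.raises(FormatError, match=r"line 3"):
            read_spot_table(f, experiment_id="e", bait_gene="g")

    def test_round_trip_is_stable(self, tmp_path):
        scan = make_scan([make_spot("p1", 123.456, 7.89), make_spot("p2", 1.0, 2.0)])
        f1, f2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_spot_table(scan, f1)
        back = read_spot_table(f1, experiment_id="exp1", bait_gene="geneB")
        write_spot_table(back, f2)
        assert f1.read_bytes() == f2.read_bytes()


class TestSpotRecordValidation:
    @pytest.mark.parametrize("field,value", [
        ("ip_frac_above_bg", 1.2),
        ("ref_frac_above_bg", -0.1),
        ("ip_signal", -5.0),
    ])
    def test_invalid_fields_rejected(self, field, value):
        kwargs = dict(probe_id="p", ip_signal=1.0, ref_signal=1.0,
                      ip_frac_above_bg=0.5, ref_frac_above_bg=0.5)
        kwargs[field] = value
        with pytest.raises(FormatError):
            SpotRecord(**kwargs)

    def test_platform_rescue_threshold_must_dominate(self):
        with pytest.raises(FormatError):
            PlatformSpec("bad", min_frac_ip=0.9, min_frac_ref=0.9, min_frac_ip_alone=0.5)


class TestProbeMapping:
    def test_noncoding_and_unmapped_probes_excluded_and_counted(self, simple_annotation):
        scan = make_scan([
            make_spot("geneA.p1"), make_spot("geneA.p2"),
            make_spot("ncX.p1"), make_spot("unknown.p1"),
        ])
        mapping = map_probes_to_genes(scan, simple_annotation)
        assert set(mapping.spots_by_gene) == {"geneA"}
        assert len(mapping.spots_by_gene["geneA"]) == 2
        assert mapping.n_noncoding == 1 and mapping.n_unmapped == 1

    def test_all_noncoding_yields_empty_mapping(self, simple_annotation):
        scan = make_scan([make_spot("ncX.p1")])
        mapping = map_probes_to_genes(scan, simple_annotation)
        assert mapping.spots_by_gene == {} and mapping.n_noncoding == 1

    def test_probe_mapped_to_two_genes_is_an_error(self):
        anns = [GeneAnnotation("p1", "geneA", True), GeneAnnotation("p1", "geneB", True)]
        with pytest.raises(FormatError, match="two genes"):
            map_probes_to_genes(make_scan([make_spot("p1")]), anns)


class TestDyeSwap:
    def test_channels_and_fracs_exchange(self):
        scan = make_scan(
            [SpotRecord("p1", 10.0, 20.0, 0.3, 0.7)], dye_swapped=True
        )
        resolved = resolve_dye_swap(scan)
        s = resolved.spots[0]
        assert (s.ip_signal, s.ref_signal) == (20.0, 10.0)
        assert (s.ip_frac_above_bg, s.ref_frac_above_bg) == (0.7, 0.3)
        assert not resolved.dye_swapped
        # unswapped scans pass through untouched
        assert resolve_dye_swap(resolved) is resolved


class TestBlacklistIO:
    def test_comments_ignored_and_duplicates_collapse(self, tmp_path):
        f = tmp_path / "bl.txt"
        f.write_text("# common contaminants\ngeneX\ngeneY\ngeneZ\ngeneX\n")
        bl = read_blacklist(f)
        assert len(bl) == 3 and "geneX" in bl

    def test_write_read_round_trip(self, tmp_path):
        bl = Blacklist(frozenset({"a", "b"}))
        f = tmp_path / "bl.txt"
        write_blacklist(bl, f)
        assert read_blacklist(f) == bl

    def test_unreadable_path_raises(self, tmp_path):
        with pytest.raises(FormatError):
            read_blacklist(tmp_path / "missing.txt")


class TestCallSetIO:
    def test_round_trip_preserves_content(self, tmp_path):
        cs = CallSet(
            bait_gene="geneB",
            replicate_sets=None,
            consensus=frozenset({"geneB", "geneA"}),
            support={"geneB": (3, 3), "geneA": (3, 3)},
            mean_s={"geneB": 6.25, "geneA": 3.5},
            category="targets",
            k=3,
            fp_expected=0.05 ** 3,
        )
        f = tmp_path / "callset.tsv"
        write_callset(cs, f)
        back = read_callset(f)
        assert back.bait_gene == cs.bait_gene
        assert back.consensus == cs.consensus
        assert back.support == cs.support
        assert back.mean_s == pytest.approx(cs.mean_s)
        assert back.category == cs.category
        assert back.k == cs.k
        assert back.fp_expected == pytest.approx(cs.fp_expected)
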