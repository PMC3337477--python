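"""Annotation parsing and window geometry, including the strand-mirror law."""

import numpy as np
import pytest

from readthrough.annotation import GeneModel, GeneSet, read_annotation
from readthrough.windows import (
    build_windows,
    downstream_window,
    primirna_window,
    target_end_windows,
)

GFF_HEADER = "##gff-version 3\n##sequence-region chr1 1 50000\n"


def write_gff(tmp_path, body):
    p = tmp_path / "genes.gff3"
    p.write_text(GFF_HEADER + body)
    return p


class TestReadAnnotation:
    def test_single_gene_parse(self, tmp_path):
        p = write_gff(tmp_path, "chr1\tsrc\tgene\t101\t600\t.\t+\t.\tID=g1\n")
        gs = read_annotation(p)
        assert len(gs) == 1
        g = gs["g1"]
        assert (g.start, g.end, g.strand, g.chrom) == (101, 600, "+", "chr1")
        assert gs.chrom_lengths == {"chr1": 50000}

    def test_missing_strand_skipped_with_warning(self, tmp_path, caplog):
        p = write_gff(
            tmp_path,
            "chr1\tsrc\tgene\t101\t600\t.\t.\t.\tID=g1\n"
            "chr1\tsrc\tgene\t700\t900\t.\t+\t.\tID=g2\n",
        )
        with caplog.at_level("WARNING"):
            gs = read_annotation(p)
        assert [g.id for g in gs] == ["g2"]
        assert "no strand" in caplog.text

    def test_mir_id_list_marks_exactly_one(self, tmp_path):
        body = "".join(
            f"chr1\tsrc\tgene\t{i * 1000 + 1}\t{i * 1000 + 500}\t.\t+\t.\tID=g{i}\n" for i in range(3)
        )
        gs = read_annotation(write_gff(tmp_path, body), mir_ids=["g1"])
        assert sum(g.kind == "mir" for g in gs) == 1
        assert gs["g1"].kind == "mir"

    def test_mirna_featuretype_and_target_list(self, tmp_path):
        body = (
            "chr1\tsrc\tmiRNA_primary_transcript\t100\t400\t.\t-\t.\tID=MIR1\n"
            "chr1\tsrc\tgene\t1000\t2000\t.\t+\t.\tID=g1\n"
        )
        gs = read_annotation(write_gff(tmp_path, body), target_ids=["g1"])
        assert gs["MIR1"].kind == "mir"
        assert gs["g1"].is_mirna_target

    def test_duplicate_id_raises(self, tmp_path):
        body = (
            "chr1\tsrc\tgene\t100\t400\t.\t+\t.\tID=g1\n"
            "chr1\tsrc\tgene\t1000\t2000\t.\t+\t.\tID=g1\n"
        )
        with pytest.raises(ValueError, match="duplicate"):
            read_annotation(write_gff(tmp_path, body))


class TestGeneModel:
    def test_invalid_strand_and_span_rejected(self):
        with pytest.raises(ValueError):
            GeneModel("x", "chr1", ".", 1, 10)
        with pytest.raises(ValueError):
            GeneModel("x", "chr1", "+", 10, 5)

    def test_gene_beyond_chromosome_rejected(self):
        with pytest.raises(ValueError):
            GeneSet([GeneModel("x", "chr1", "+", 1, 200)], {"chr1": 100})


class TestDownstreamWindow:
    def test_plus_strand(self):
        w = downstream_window(GeneModel("g", "chr1", "+", 1, 1000), 500, 5000)
        # 1-based bases 1001..1500
        assert (w.begin, w.end, w.strand, w.truncated) == (1000, 1500, "+", False)

    def test_minus_strand(self):
        w = downstream_window(GeneModel("g", "chr1", "-", 2001, 3000), 500, 5000)
        # 1-based bases 1501..2000
        assert (w.begin, w.end, w.strand) == (1500, 2000, "-")

    def test_truncated_at_chromosome_end(self):
        w = downstream_window(GeneModel("g", "chr1", "+", 1, 920), 500, 1000)
        assert (w.length, w.truncated) == (80, True)

    def test_zero_length_flagged_untestable(self):
        w = downstream_window(GeneModel("g", "chr1", "+", 1, 1000), 500, 1000)
        assert not w.is_testable

    def test_never_overlaps_own_gene_when_untruncated(self, rng):
        for _ in range(50):
            start = int(rng.integers(1000, 5000))
            end = start + int(rng.integers(100, 2000))
            strand = "+" if rng.random() < 0.5 else "-"
            g = GeneModel("g", "chr1", strand, start, end)
            w = downstream_window(g, 500, 100000)
            assert not w.truncated
            assert not w.overlaps(g.begin0, g.end0)


class TestPrimirnaWindow:
    def test_plus_strand_pad(self):
        g = GeneModel("m", "chr1", "+", 1000, 1300, kind="mir")
        w = primirna_window(g, 500, 5000)
        assert (w.begin, w.end) == (999, 1800)  # 1-based 1000..1800

    def test_minus_strand_pad(self):
        g = GeneModel("m", "chr1", "-", 1000, 1300, kind="mir")
        w = primirna_window(g, 500, 5000)
        assert (w.begin, w.end) == (499, 1300)  # 1-based 500..1300

    def test_zero_pad_equals_gene_span(self):
        g = GeneModel("m", "chr1", "+", 1000, 1300, kind="mir")
        w = primirna_window(g, 0, 5000)
        assert (w.begin, w.end) == (g.begin0, g.end0)

    def test_rejects_non_mir(self):
        with pytest.raises(ValueError):
            primirna_window(GeneModel("g", "chr1", "+", 1000, 1300), 500, 5000)


class TestTargetEndWindows:
    def test_plus_strand(self):
        g = GeneModel("t", "chr1", "+", 101, 600, is_mirna_target=True)
        head, tail = target_end_windows(g, 200)
        assert (head.begin, head.end) == (100, 300)  # 1-based 101..300
        assert (tail.begin, tail.end) == (400, 600)  # 1-based 401..600

    def test_minus_strand_mirror(self):
        g = GeneModel("t", "chr1", "-", 101, 600, is_mirna_target=True)
        head, tail = target_end_windows(g, 200)
        assert (head.begin, head.end) == (400, 600)
        assert (tail.begin, tail.end) == (100, 300)

    def test_short_gene_truncates_to_span(self):
        g = GeneModel("t", "chr1", "+", 101, 250, is_mirna_target=True)
        head, tail = target_end_windows(g, 200)
        assert head.truncated and tail.truncated
        assert (head.begin, head.end) == (tail.begin, tail.end) == (100, 250)

    def test_head_before_tail_for_long_plus_genes(self):
        g = GeneModel("t", "chr1", "+", 1, 1000)
        head, tail = target_end_windows(g, 200)
        assert head.end <= tail.begin


def _mirror_gene(g, L):
    return GeneModel(g.id, g.chrom, "-" if g.strand == "+" else "+", L - g.end + 1, L - g.start + 1,
                     kind=g.kind, is_mirna_target=g.is_mirna_target)


def test_strand_mirror_property(rng):
    """Reflecting coordinates through the chromosome midpoint and flipping
    strands maps every window family onto the reflected window exactly."""
    L = 100000
    for _ in range(40):
        start = int(rng.integers(2000, L - 5000))
        end = start + int(rng.integers(300, 3000))
        strand = "+" if rng.random() < 0.5 else "-"
        g = GeneModel("g", "chr1", strand, start, end, kind="mir", is_mirna_target=True)
        m = _mirror_gene(g, L)
        for fn in (
            lambda x: downstream_window(x, 500, L),
            lambda x: primirna_window(x, 500, L),
            lambda x: target_end_windows(x, 200)[0],
            lambda x: target_end_windows(x, 200)[1],
        ):
            w, wm = fn(g), fn(m)
            assert (wm.begin, wm.end) == (L - w.end, L - w.begin)
            assert wm.strand != w.strand


def test_build_windows_roles(small_genes):
    windows = build_windows(small_genes)
    roles = {}
    for w in windows:
        roles.setdefault(w.gene_id, []).append(w.role)
    assert roles["gA"] == ["downstream500"]
    assert sorted(roles["mir1"]) == ["downstream500", "primirna_ext"]
    assert sorted(roles["tgt1"]) == ["downstream500", "target_head200", "target_tail200"]
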