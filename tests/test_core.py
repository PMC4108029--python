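"""Coordinate primitives: intron chains, splice-site typing, segmentation,
genome↔transcript projection, and GFF3 round-tripping."""

import numpy as np
import pytest

from splicescape.core import (
    AnnotationSet,
    GeneModel,
    GenomeSequence,
    Interval,
    TranscriptModel,
    classify_splice_site,
    genome_pos_to_transcript,
    intron_chain,
    map_genome_to_transcript,
    map_transcript_to_genome,
    segment_transcript_regions,
)
from splicescape.io import read_gff3, write_gff3


class TestInterval:
    def test_rejects_empty_and_inverted(self):
        with pytest.raises(ValueError):
            Interval("chr1", 10, 10)
        with pytest.raises(ValueError):
            Interval("", 0, 5)

    def test_overlap_arithmetic(self):
        a = Interval("chr1", 0, 100)
        assert a.overlap_len(Interval("chr1", 50, 150)) == 50
        assert a.overlap_len(Interval("chr2", 50, 150)) == 0


class TestTranscriptModel:
    def test_sorts_exons_on_load(self, make_tx):
        t = make_tx("t1", [(300, 400), (100, 200)])
        assert [e.start for e in t.exons] == [100, 300]

    def test_rejects_overlapping_exons(self, make_tx):
        with pytest.raises(ValueError, match="overlapping"):
            make_tx("t1", [(100, 250), (200, 300)])

    def test_rejects_cds_outside_exons(self, make_tx):
        with pytest.raises(ValueError, match="CDS"):
            make_tx("t1", [(100, 200)], cds=[(150, 250)])


@pytest.mark.parametrize(
    "exons,expected",
    [
        ([(100, 200), (300, 400)], [(200, 300)]),
        ([(0, 50)], []),
        ([(0, 10), (20, 30), (40, 50)], [(10, 20), (30, 40)]),
    ],
)
def test_intron_chain(make_tx, exons, expected):
    t = make_tx("t1", exons)
    assert [(i.start, i.end) for i in intron_chain(t)] == expected


def test_intron_count_matches_exon_count(make_tx):
    rng = np.random.default_rng(7)
    for _ in range(50):
        n = int(rng.integers(1, 8))
        cuts = np.sort(rng.choice(np.arange(0, 2000, 3), size=2 * n, replace=False))
        exons = [(int(cuts[2 * i]), int(cuts[2 * i + 1])) for i in range(n)]
        t = make_tx("t", exons)
        assert len(intron_chain(t)) == len(t.exons) - 1


class TestSpliceSiteTyping:
    def test_plus_strand_canonical(self, toy_genome):
        donor, acceptor, klass = classify_splice_site(
            Interval("chr1", 200, 300, "+"), toy_genome
        )
        assert (donor, acceptor, klass) == ("GT", "AG", "canonical_GT_AG")

    def test_gc_ag(self, toy_genome):
        assert classify_splice_site(Interval("chr1", 500, 600, "+"), toy_genome)[2] == "GC_AG"

    def test_minus_strand_reads_reverse_complement(self, toy_genome):
        # forward CT...AC becomes GT...AG in transcript orientation
        donor, acceptor, klass = classify_splice_site(
            Interval("chr1", 700, 800, "-"), toy_genome
        )
        assert (donor, acceptor, klass) == ("GT", "AG", "canonical_GT_AG")

    def test_n_gives_other(self):
        g = GenomeSequence({"chr1": "GN" + "A" * 96 + "AG"})
        assert classify_splice_site(Interval("chr1", 0, 100, "+"), g)[2] == "other"

    def test_out_of_bounds_errors(self, toy_genome):
        with pytest.raises(IndexError):
            classify_splice_site(Interval("chr1", 990, 1100, "+"), toy_genome)


class TestSegmentation:
    def test_plus_strand(self, make_tx):
        t = make_tx("t1", [(0, 300)], cds=[(100, 250)])
        assert segment_transcript_regions(t) == {
            "5UTR": (0, 100),
            "CDS": (100, 250),
            "3UTR": (250, 300),
        }

    def test_minus_strand_flips_utrs(self, make_tx):
        t = make_tx("t1", [(0, 300)], strand="-", cds=[(100, 250)])
        seg = segment_transcript_regions(t)
        # transcript coordinates run 5'→3': the genomic tail is the 5' UTR
        assert seg["5UTR"] == (0, 50)
        assert seg["CDS"] == (50, 200)
        assert seg["3UTR"] == (200, 300)

    def test_cds_spanning_whole_transcript(self, make_tx):
        t = make_tx("t1", [(0, 300)], cds=[(0, 300)])
        seg = segment_transcript_regions(t)
        assert seg["5UTR"] == (0, 0) and seg["3UTR"] == (300, 300)

    def test_no_cds_errors(self, make_tx):
        with pytest.raises(ValueError, match="no CDS"):
            segment_transcript_regions(make_tx("t1", [(0, 300)]))


class TestCoordinateProjection:
    def test_within_single_exon(self, make_tx):
        t = make_tx("t1", [(100, 200), (300, 400)])
        assert map_genome_to_transcript(t, Interval("chr1", 110, 130)) == (10, 30)

    def test_interval_touching_intron_is_absent(self, make_tx):
        t = make_tx("t1", [(100, 200), (300, 400)])
        assert map_genome_to_transcript(t, Interval("chr1", 190, 210)) is None

    def test_interval_containing_intronic_bases_is_absent(self, make_tx):
        # a genomic interval across the intron includes non-exonic bases;
        # junction-spanning footprints are mapped piecewise (see mirna)
        t = make_tx("t1", [(100, 200), (300, 400)])
        assert map_genome_to_transcript(t, Interval("chr1", 190, 310)) is None

    def test_piecewise_footprint_spans_junction_contiguously(self, make_tx):
        t = make_tx("t1", [(100, 200), (300, 400)])
        left = map_genome_to_transcript(t, Interval("chr1", 190, 200))
        right = map_genome_to_transcript(t, Interval("chr1", 300, 310))
        assert left == (90, 100) and right == (100, 110)

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_exhaustive_per_base_oracle(self, make_tx, strand):
        """Projection agrees with per-base lookup on a 3-exon toy transcript."""
        t = make_tx("t1", [(10, 40), (60, 90), (120, 150)], strand=strand)
        for start in range(0, 160):
            for length in range(1, 31):
                iv = Interval("chr1", start, start + length, strand)
                got = map_genome_to_transcript(t, iv)
                # oracle: per-base transcript coordinates must be defined,
                # consecutive, and length-preserving
                coords = [genome_pos_to_transcript(t, p) for p in range(start, start + length)]
                if any(c is None for c in coords):
                    expect = None
                else:
                    coords = sorted(coords)
                    contiguous = coords == list(range(coords[0], coords[0] + length))
                    expect = (coords[0], coords[0] + length) if contiguous else None
                assert got == expect, (strand, start, length)

    def test_round_trip_through_genome(self, make_tx):
        t = make_tx("t1", [(10, 40), (60, 90)], strand="-")
        pieces = map_transcript_to_genome(t, 5, 45)
        assert sum(len(p) for p in pieces) == 40
        back = [map_genome_to_transcript(t, p) for p in pieces]
        assert all(b is not None for b in back)


class TestGFF3RoundTrip:
    def _ann(self, make_tx):
        t1 = make_tx("t1.1", [(99, 200), (300, 400)], cds=[(150, 200), (300, 350)], gene="g1")
        t2 = make_tx("t1.2", [(99, 400)], gene="g1")
        t3 = make_tx("t2.1", [(600, 800)], strand="-", gene="g2")
        return AnnotationSet([GeneModel("g1", [t1, t2]), GeneModel("g2", [t3])], version="v2")

    def test_round_trip_exact(self, make_tx, tmp_path):
        ann = self._ann(make_tx)
        path = tmp_path / "out.gff3"
        write_gff3(ann, path)
        back = read_gff3(path)
        assert sorted(back.genes) == sorted(ann.genes)
        for g in ann:
            for t in g.transcripts:
                bt = back[g.id].transcript(t.id)
                assert [(e.start, e.end) for e in bt.exons] == [(e.start, e.end) for e in t.exons]
                assert bt.strand == t.strand and bt.gene_id == t.gene_id
                if t.cds:
                    assert [(c.start, c.end) for c in bt.cds] == [(c.start, c.end) for c in t.cds]

    def test_on_disk_coordinates_are_one_based_inclusive(self, make_tx, tmp_path):
        ann = self._ann(make_tx)
        path = tmp_path / "out.gff3"
        write_gff3(ann, path)
        exon_lines = [
            l.split("\t") for l in path.read_text().splitlines()
            if not l.startswith("#") and l.split("\t")[2] == "exon"
        ]
        lengths = sorted(int(f[4]) - int(f[3]) + 1 for f in exon_lines)
        expected = sorted(
            len(e) for g in ann for t in g.transcripts for e in t.exons
        )
        assert lengths == expected
        # the first exon of g1 starts at internal 99 → 100 on disk
        assert min(int(f[3]) for f in exon_lines) == 100


def test_annotation_index_returns_exact_overlaps(make_tx):
    g1 = GeneModel("g1", [make_tx("g1.1", [(100, 200)], gene="g1")])
    g2 = GeneModel("g2", [make_tx("g2.1", [(500, 700)], gene="g2")])
    ann = AnnotationSet([g1, g2])
    assert [g.id for g in ann.overlapping(Interval("chr1", 150, 160))] == ["g1"]
    assert [g.id for g in ann.overlapping(Interval("chr1", 200, 500))] == []
    assert ann.nearest_distance(Interval("chr1", 300, 310)) == 100


from hypothesis import given, settings, strategies as st


@settings(derandomize=True, max_examples=150, deadline=None)
@given(data=st.data())
def test_transcript_to_genome_footprints_preserve_length(data):
    """Any transcript-coordinate range lifts to exonic pieces whose lengths
    sum to the range length, each piece inside one exon."""
    n_ex = data.draw(st.integers(1, 5))
    bounds = data.draw(
        st.lists(st.integers(0, 400), min_size=2 * n_ex, max_size=2 * n_ex,
                 unique=True).map(sorted)
    )
    exons = [(bounds[2 * i], bounds[2 * i + 1]) for i in range(n_ex)]
    strand = data.draw(st.sampled_from(["+", "-"]))
    t = TranscriptModel(
        "t", "g", [Interval("chr1", s, e, strand) for s, e in exons]
    )
    start = data.draw(st.integers(0, t.length - 1))
    end = data.draw(st.integers(start + 1, t.length))
    pieces = map_transcript_to_genome(t, start, end)
    assert sum(len(p) for p in pieces) == end - start
    for p in pieces:
        assert any(e.start <= p.start and p.end <= e.end for e in t.exons)
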