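"""Annotation-version comparison: fusion/split groups, evidence support,
global CDS alignment scoring, and new-gene filtering."""

import numpy as np
import pytest

from splicescape.core import (
    AnnotationSet,
    GeneModel,
    GenomeSequence,
    Interval,
    PipelineThresholds,
)
from splicescape.compare import (
    BestHitTable,
    adjudicate_group,
    detect_fusion_split,
    evaluate_alternative_cds,
    filter_new_genes,
    global_protein_alignment,
    intron_evidence_support,
    translate_cds,
)

from oracles import oracle_global_alignment_score


def gene(make_tx, gid, exons, strand="+"):
    return GeneModel(gid, [make_tx(f"{gid}.1", exons, strand=strand, gene=gid)])


class TestFusionSplit:
    def _ab(self, make_tx):
        A = AnnotationSet(
            [
                gene(make_tx, "A1", [(100, 300)]),
                gene(make_tx, "A2", [(500, 700)]),
                gene(make_tx, "A3", [(5000, 5400)]),
            ],
            version="v1",
        )
        B = AnnotationSet(
            [
                gene(make_tx, "B1", [(100, 300), (500, 700)]),  # fuses A1+A2
                gene(make_tx, "B2", [(5000, 5400)]),  # 1:1 with A3
            ],
            version="v2",
        )
        return A, B

    def test_fusion_detected_with_two_partners(self, make_tx):
        A, B = self._ab(make_tx)
        groups = detect_fusion_split(A, B)
        assert len(groups) == 1
        (grp,) = groups
        assert grp.focal == "B1" and grp.partners == ["A1", "A2"]
        assert grp.direction == "fusion_in_B"

    def test_one_to_one_overlaps_give_nothing(self, make_tx):
        A = AnnotationSet([gene(make_tx, "A1", [(0, 200)])])
        B = AnnotationSet([gene(make_tx, "B1", [(50, 250)])])
        assert detect_fusion_split(A, B) == []

    def test_direction_swap_under_argument_exchange(self, make_tx):
        A, B = self._ab(make_tx)
        fwd = detect_fusion_split(A, B)
        rev = detect_fusion_split(B, A)
        assert [(g.focal, tuple(g.partners)) for g in fwd] == [
            (g.focal, tuple(g.partners)) for g in rev
        ]
        assert {g.direction for g in fwd} == {"fusion_in_B"}
        assert {g.direction for g in rev} == {"split_in_B"}

    def test_opposite_strand_overlap_ignored(self, make_tx):
        A = AnnotationSet(
            [gene(make_tx, "A1", [(0, 200)]), gene(make_tx, "A2", [(300, 500)])]
        )
        B = AnnotationSet([gene(make_tx, "B1", [(0, 500)], strand="-")])
        assert detect_fusion_split(A, B) == []


class TestAdjudication:
    def grp(self, make_tx):
        A, _ = (None, None)
        from splicescape.compare import FusionSplitGroup

        return FusionSplitGroup("B1", ["A1", "A2"], "fusion_in_B")

    def test_shared_hit_vindicates_merged_gene(self, make_tx):
        hits = BestHitTable(
            {"B1": ("AT1G00010", 500, 0.9), "A1": ("AT1G00010", 300, 0.9),
             "A2": ("AT1G00010", 250, 0.8)}
        )
        assert adjudicate_group(self.grp(make_tx), hits) == "B_better"

    def test_distinct_hits_favor_split_genes(self, make_tx):
        hits = BestHitTable(
            {"B1": ("AT1G00010", 500, 0.9), "A1": ("AT1G00010", 300, 0.9),
             "A2": ("AT2G00020", 250, 0.8)}
        )
        assert adjudicate_group(self.grp(make_tx), hits) == "A_better"

    def test_missing_hit_is_ambiguous(self, make_tx):
        hits = BestHitTable({"B1": ("AT1G00010", 500, 0.9), "A1": ("AT1G00010", 300, 0.9)})
        assert adjudicate_group(self.grp(make_tx), hits) == "ambiguous"

    def test_split_direction_mirrors_verdict(self, make_tx):
        from splicescape.compare import FusionSplitGroup

        grp = FusionSplitGroup("A1", ["B1", "B2"], "split_in_B")
        hits = BestHitTable(
            {"A1": ("AT1G00010", 500, 0.9), "B1": ("AT1G00010", 300, 0.9),
             "B2": ("AT2G00020", 250, 0.8)}
        )
        # the split genes hit two subjects → the splitting annotation wins
        assert adjudicate_group(grp, hits) == "B_better"


class TestEvidenceSupport:
    def test_tiers(self):
        introns = [
            Interval("chr1", 100, 200, "+"),
            Interval("chr1", 300, 400, "+"),
            Interval("chr1", 500, 600, "+"),
        ]
        protein = {("chr1", 100, 200, "+")}
        est = {("chr1", 100, 200, "+"), ("chr1", 300, 400, "+")}
        rnaseq = {("chr1", 100, 200, "+")}
        supports, tiers = intron_evidence_support(introns, protein, est, rnaseq)
        assert supports[0].supported_by == {"protein", "EST", "RNAseq"}
        assert supports[1].supported_by == {"EST"}
        assert supports[2].supported_by == set()
        assert tiers == {"ge1": 2, "ge2": 1, "eq3": 1}

    def test_matching_is_exact_coordinate(self):
        introns = [Interval("chr1", 100, 200, "+")]
        est = {("chr1", 101, 200, "+")}  # off by one
        _, tiers = intron_evidence_support(introns, set(), est, set())
        assert tiers["ge1"] == 0


class TestGlobalAlignment:
    def test_self_alignment_is_maximal(self):
        rng = np.random.default_rng(3)
        aas = "ARNDCQEGHILKMFPSTWYV"
        x = "".join(rng.choice(list(aas), size=20))
        self_score, ident = global_protein_alignment(x, x)
        assert ident == 1.0
        for _ in range(10):
            y = "".join(rng.choice(list(aas), size=20))
            assert global_protein_alignment(x, y)[0] <= self_score

    def test_matches_quadratic_dp_oracle(self):
        """Affine-gap NW scores equal an independent Gotoh DP."""
        rng = np.random.default_rng(42)
        aas = "ARNDCQEGHILKMFPSTWYV"
        for _ in range(50):
            n, m = int(rng.integers(5, 31)), int(rng.integers(5, 31))
            x = "".join(rng.choice(list(aas), size=n))
            y = "".join(rng.choice(list(aas), size=m))
            score, _ = global_protein_alignment(x, y)
            assert score == pytest.approx(oracle_global_alignment_score(x, y))

    def test_quarter_identity_pair(self):
        # gapless optimum: M matches, W/W/W mismatch → identity exactly 25%
        score, ident = global_protein_alignment("MMMM", "MWWW")
        assert ident == 0.25


def _cds_gene(gid, peptide, chrom, offset, genome_parts):
    """Build a single-exon gene whose CDS encodes ``peptide``."""
    codon = {
        "M": "ATG", "K": "AAA", "L": "CTG", "V": "GTG", "A": "GCT",
        "W": "TGG", "R": "CGT", "S": "TCT", "G": "GGT", "E": "GAA",
    }
    nt = "".join(codon[a] for a in peptide) + "TAA"
    genome_parts.append((offset, nt))
    exon = Interval(chrom, offset, offset + len(nt), "+")
    t = {"id": f"{gid}.1", "gene": gid, "exon": exon}
    from splicescape.core import TranscriptModel

    tx = TranscriptModel(f"{gid}.1", gid, [exon], cds=[exon])
    return GeneModel(gid, [tx])


class TestAlternativeCds:
    def _setup(self):
        parts = []
        ref = "MKLVAWRSGE" * 3
        a = _cds_gene("A", ref, "chr1", 100, parts)  # exact copy of ref
        b = _cds_gene("B", ref[:15], "chr1", 400, parts)  # truncated copy
        seq = list("A" * 1000)
        for off, nt in parts:
            seq[off : off + len(nt)] = nt
        genome = GenomeSequence({"chr1": "".join(seq)})
        return a, b, ref, genome

    def test_exact_copy_beats_truncation(self):
        a, b, ref, genome = self._setup()
        rec = evaluate_alternative_cds(a, b, ref, genome)
        assert rec["verdict"] == "A_better"
        assert rec["identity_a"] == 1.0

    def test_low_identity_discarded(self):
        # both products are near-0% identical to the homolog → discarded
        a, b, _, genome = self._setup()
        rec = evaluate_alternative_cds(a, b, "W" * 30, genome)
        assert rec["identity_a"] < 0.3 and rec["verdict"] == "discarded"

    def test_untranslatable_cds_flagged(self, make_tx):
        a, b, ref, genome = self._setup()
        # CDS length not divisible by three
        t = make_tx("X.1", [(0, 10)], cds=[(0, 10)], gene="X")
        with pytest.raises(ValueError):
            translate_cds(t, genome)
        g = GeneModel("X", [t])
        rec = evaluate_alternative_cds(g, b, ref, genome)
        assert rec["flagged"] and rec["score_a"] is None
        assert rec["verdict"] == "B_better"


class TestNewGeneFilter:
    def test_domain_alone_rescues(self, th):
        ev = {"g1": {"domain": True, "coverage": 0.1}}
        assert filter_new_genes(["g1"], ev, th) == ["g1"]

    def test_coverage_just_below_half_rejected(self, th):
        ev = {"g1": {"coverage": 0.49}, "g2": {"coverage": 0.50}}
        assert filter_new_genes(["g1", "g2"], ev, th) == ["g2"]

    def test_noncoding_exclusion_precedes_rescue(self, th):
        ev = {"g1": {"noncoding": True, "domain": True, "coverage": 1.0}}
        assert filter_new_genes(["g1"], ev, th) == []

    def test_mirna_similarity_excludes(self, th):
        ev = {"g1": {"mirna_similar": True, "homolog": True}}
        assert filter_new_genes(["g1"], ev, th) == []

    def test_monotone_in_evidence(self, th):
        base = {"g1": {"coverage": 0.2}}
        more = {"g1": {"coverage": 0.2, "homolog": True}}
        assert set(filter_new_genes(["g1"], base, th)) <= set(
            filter_new_genes(["g1"], more, th)
        )

    def test_coverage_out_of_range_errors(self, th):
        with pytest.raises(ValueError):
            filter_new_genes(["g1"], {"g1": {"coverage": 1.5}}, th)
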