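"""Domain types and structural primitives shared by every analysis stage.

Coordinate convention: all intervals are 0-based, half-open, on a named
chromosome.  GFF3/GTF files on disk are 1-based inclusive; the conversion
happens only in :mod:`splicescape.io`.

The central object is the :class:`TranscriptModel` — a strand-aware exon
chain with an optional CDS — grouped into :class:`GeneModel` and indexed in
an :class:`AnnotationSet`.  Structural operations (intron chains, splice-site
dinucleotide typing, UTR/CDS segmentation, genome↔transcript coordinate
projection) live here because every downstream module needs them.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

from intervaltree import IntervalTree

__all__ = [
    "Interval",
    "TranscriptModel",
    "GeneModel",
    "AnnotationSet",
    "GenomeSequence",
    "PipelineThresholds",
    "intron_chain",
    "classify_splice_site",
    "segment_transcript_regions",
    "map_genome_to_transcript",
    "map_transcript_to_genome",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse-complement a nucleotide string (case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class Interval:
    """A genomic interval, 0-based half-open, with optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("Interval.chrom must be non-empty")
        if not self.start < self.end:
            raise ValueError(
                f"Interval requires start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end

    def overlap_len(self, other: "Interval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass
class TranscriptModel:
    """An isoform: ordered, disjoint exons on one chromosome and strand.

    ``cds`` (if given) is the coding span as a list of intervals that must be
    a sub-union of the exons.  ``source`` labels the producing program or
    annotation version (``cufflinks``, ``v1``, ...).
    """

    id: str
    gene_id: str
    exons: list[Interval]
    cds: list[Interval] | None = None
    source: str = ""

    def __post_init__(self):
        if not self.exons:
            raise ValueError(f"transcript {self.id}: no exons")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        chrom = self.exons[0].chrom
        strand = self.exons[0].strand
        for e in self.exons:
            if e.chrom != chrom or e.strand != strand:
                raise ValueError(f"transcript {self.id}: exons on mixed chrom/strand")
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(f"transcript {self.id}: overlapping exons")
        if self.cds is not None:
            self.cds = sorted(self.cds, key=lambda c: c.start)
            for c in self.cds:
                if not any(e.start <= c.start and c.end <= e.end for e in self.exons):
                    raise ValueError(
                        f"transcript {self.id}: CDS segment {c.start}-{c.end} "
                        "not contained in an exon"
                    )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def span(self) -> Interval:
        return Interval(self.chrom, self.start, self.end, self.strand)

    @property
    def length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def cds_span(self) -> Interval | None:
        if not self.cds:
            return None
        return Interval(self.chrom, self.cds[0].start, self.cds[-1].end, self.strand)

    def is_exonic(self, pos: int) -> bool:
        """True if genomic position ``pos`` falls inside an exon."""
        i = bisect.bisect_right([e.start for e in self.exons], pos) - 1
        return i >= 0 and pos < self.exons[i].end


@dataclass
class GeneModel:
    """A gene: one or more isoforms sharing a gene id, chrom and strand."""

    id: str
    transcripts: list[TranscriptModel]

    def __post_init__(self):
        if not self.transcripts:
            raise ValueError(f"gene {self.id}: no transcripts")
        chrom = self.transcripts[0].chrom
        strand = self.transcripts[0].strand
        for t in self.transcripts:
            if t.chrom != chrom or t.strand != strand:
                raise ValueError(f"gene {self.id}: transcripts on mixed chrom/strand")

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    @property
    def span(self) -> Interval:
        return Interval(
            self.chrom,
            min(t.start for t in self.transcripts),
            max(t.end for t in self.transcripts),
            self.strand,
        )

    def transcript(self, tid: str) -> TranscriptModel:
        for t in self.transcripts:
            if t.id == tid:
                return t
        raise KeyError(tid)


class AnnotationSet:
    """Genes indexed by id plus a per-chromosome interval index on gene spans."""

    def __init__(self, genes: list[GeneModel], version: str = ""):
        self.version = version
        self.genes: dict[str, GeneModel] = {}
        for g in genes:
            if g.id in self.genes:
                raise ValueError(f"duplicate gene id {g.id}")
            self.genes[g.id] = g
        self._trees: dict[str, IntervalTree] = {}
        for g in genes:
            s = g.span
            self._trees.setdefault(s.chrom, IntervalTree()).addi(s.start, s.end, g.id)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes.values())

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.genes

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self.genes[gene_id]

    def transcripts(self):
        for g in self:
            yield from g.transcripts

    def overlapping(self, iv: Interval) -> list[GeneModel]:
        """Genes whose span overlaps ``iv`` (strand-blind)."""
        tree = self._trees.get(iv.chrom)
        if tree is None:
            return []
        hits = sorted(tree.overlap(iv.start, iv.end), key=lambda h: (h.begin, h.data))
        return [self.genes[h.data] for h in hits]

    def nearest_distance(self, iv: Interval) -> int | None:
        """Span-to-span distance from ``iv`` to the nearest gene, 0 if overlapping.

        Returns None when the annotation has no gene on that chromosome.
        """
        tree = self._trees.get(iv.chrom)
        if tree is None or len(tree) == 0:
            return None
        if tree.overlap(iv.start, iv.end):
            return 0
        best = None
        for h in tree:
            if h.end <= iv.start:
                d = iv.start - h.end
            elif h.begin >= iv.end:
                d = h.begin - iv.end
            else:
                d = 0
            best = d if best is None else min(best, d)
        return best


class GenomeSequence:
    """chrom → nucleotide string over {A,C,G,T,N}; access is case-insensitive."""

    def __init__(self, sequences: dict[str, str]):
        self.sequences = {k: v.upper() for k, v in sequences.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def __getitem__(self, chrom: str) -> str:
        return self.sequences[chrom]

    def fetch(self, iv: Interval) -> str:
        """Forward-strand sequence of ``iv`` (no strand flipping)."""
        seq = self.sequences[iv.chrom]
        if iv.start < 0 or iv.end > len(seq):
            raise IndexError(
                f"{iv.chrom}:{iv.start}-{iv.end} outside sequence of length {len(seq)}"
            )
        return seq[iv.start : iv.end]

    def fetch_stranded(self, iv: Interval) -> str:
        """Sequence of ``iv`` read 5'→3' on its strand."""
        s = self.fetch(iv)
        return revcomp(s) if iv.strand == "-" else s


@dataclass
class PipelineThresholds:
    """Single home for every tunable cutoff of the pipeline.

    Defaults reproduce the published grape-reannotation workflow: spliced-read
    anchors of 15 nt and 40 nt total alignment; junction coverage 4 (both
    replicates) or 10 (single replicate); 2-of-3 assembler consensus with a
    150 nt length floor; the lncRNA cascade (200 nt, 1 kb intergenic
    isolation, 100 nt/30% intronic context, 30% antisense exon overlap);
    1 FPKM detection in both replicates; 50% coverage for new-gene rescue;
    30% identity floor for coding-sequence comparison; FDR 0.05.
    """

    min_anchor: int = 15
    min_aligned: int = 40
    min_cov_both_reps: int = 4
    min_cov_single_rep: int = 10
    min_programs: int = 2
    min_transcript_len: int = 150
    min_lnc_len: int = 200
    intergenic_min_dist: int = 1000
    intronic_min_exon_dist: int = 100
    intronic_max_intron_frac: float = 0.30
    antisense_min_exon_overlap_frac: float = 0.30
    detection_fpkm: float = 1.0
    new_gene_min_coverage_frac: float = 0.50
    min_cds_identity: float = 0.30
    fdr_alpha: float = 0.05
    min_orf_codons: int = 100
    mono_exon_overlap_frac: float = 0.50

    def __post_init__(self):
        for name in (
            "min_anchor",
            "min_aligned",
            "min_cov_both_reps",
            "min_cov_single_rep",
            "min_programs",
            "min_transcript_len",
            "min_lnc_len",
            "intergenic_min_dist",
            "intronic_min_exon_dist",
            "detection_fpkm",
            "min_orf_codons",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in (
            "intronic_max_intron_frac",
            "antisense_min_exon_overlap_frac",
            "new_gene_min_coverage_frac",
            "min_cds_identity",
            "fdr_alpha",
            "mono_exon_overlap_frac",
        ):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must lie in (0, 1]")


# ---------------------------------------------------------------------------
# structural operations


def intron_chain(t: TranscriptModel) -> list[Interval]:
    """Gaps between consecutive exons, in genomic order; [] for monoexonic."""
    return [
        Interval(t.chrom, a.end, b.start, t.strand)
        for a, b in zip(t.exons, t.exons[1:])
    ]


def classify_splice_site(
    intron: Interval, genome: GenomeSequence
) -> tuple[str, str, str]:
    """Type an intron's boundary dinucleotides.

    Returns ``(donor, acceptor, klass)`` with the donor being the first two
    intronic bases read 5'→3' in transcript orientation and the acceptor the
    last two.  Minus-strand introns are reverse-complemented before reading.
    Classes: ``canonical_GT_AG``, ``GC_AG``, ``other`` (any N → ``other``).
    """
    if len(intron) < 4:
        raise ValueError(f"intron of length {len(intron)} has no distinct dinucleotides")
    seq = genome.fetch_stranded(intron)
    donor, acceptor = seq[:2], seq[-2:]
    if donor == "GT" and acceptor == "AG":
        klass = "canonical_GT_AG"
    elif donor == "GC" and acceptor == "AG":
        klass = "GC_AG"
    else:
        klass = "other"
    return donor, acceptor, klass


def _transcript_cds_range(t: TranscriptModel) -> tuple[int, int]:
    """CDS extent in transcript coordinates (5'→3'), half-open."""
    if not t.cds:
        raise ValueError(f"transcript {t.id} has no CDS; UTR segmentation undefined")
    span = t.cds_span
    lo = map_genome_to_transcript(t, Interval(t.chrom, span.start, span.start + 1, t.strand))
    hi = map_genome_to_transcript(t, Interval(t.chrom, span.end - 1, span.end, t.strand))
    if lo is None or hi is None:
        raise ValueError(f"transcript {t.id}: CDS ends not exonic")
    a = min(lo[0], hi[0])
    b = max(lo[1], hi[1])
    return a, b


def segment_transcript_regions(t: TranscriptModel) -> dict[str, tuple[int, int]]:
    """Partition transcript coordinates into 5'UTR / CDS / 3'UTR.

    Returns half-open transcript-coordinate ranges (5'→3'); empty UTRs come
    back as zero-length ranges.  Raises if the transcript has no CDS.
    """
    a, b = _transcript_cds_range(t)
    n = t.length
    return {"5UTR": (0, a), "CDS": (a, b), "3UTR": (b, n)}


def label_transcript_position(t: TranscriptModel, pos: int) -> str:
    """Region label (5UTR/CDS/3UTR) of one transcript coordinate."""
    regions = segment_transcript_regions(t)
    for name, (a, b) in regions.items():
        if a <= pos < b:
            return name
    raise IndexError(f"position {pos} outside transcript of length {t.length}")


def _exon_offsets(t: TranscriptModel) -> list[int]:
    """Cumulative mature-transcript offset of each exon (genomic order)."""
    offsets, acc = [], 0
    for e in t.exons:
        offsets.append(acc)
        acc += len(e)
    return offsets


def genome_pos_to_transcript(t: TranscriptModel, pos: int) -> int | None:
    """Transcript coordinate (5'→3') of genomic position ``pos``, or None."""
    offsets = _exon_offsets(t)
    for e, off in zip(t.exons, offsets):
        if e.start <= pos < e.end:
            fwd = off + (pos - e.start)
            return fwd if t.strand != "-" else t.length - 1 - fwd
    return None


def map_genome_to_transcript(
    t: TranscriptModel, iv: Interval
) -> tuple[int, int] | None:
    """Project a genomic interval into mature-transcript coordinates.

    Succeeds iff every base of ``iv`` is exonic in ``t`` and the covered bases
    are consecutive in the mature transcript (the interval may legally span a
    splice junction whose flanking exons are adjacent in ``t``).  Returns the
    half-open transcript range, or None.
    """
    if iv.chrom != t.chrom:
        return None
    # walk exon by exon; gaps between covered exon fragments are only
    # allowed when the fragments abut in the mature RNA
    positions = []  # (covered lo, covered hi, exon index)
    for i, e in enumerate(t.exons):
        lo, hi = max(iv.start, e.start), min(iv.end, e.end)
        if lo < hi:
            positions.append((lo, hi, i))
    covered = sum(hi - lo for lo, hi, _ in positions)
    if covered != len(iv):
        return None  # some base non-exonic
    # contiguity in the mature transcript: each fragment must reach its
    # exon's edge facing the next covered fragment, on adjacent exons
    for (lo1, hi1, i1), (lo2, hi2, i2) in zip(positions, positions[1:]):
        if hi1 != t.exons[i1].end or lo2 != t.exons[i2].start or i2 != i1 + 1:
            return None
    offsets = _exon_offsets(t)
    first_lo, _, first_i = positions[0]
    fwd_start = offsets[first_i] + (first_lo - t.exons[first_i].start)
    fwd_end = fwd_start + len(iv)
    if t.strand == "-":
        return t.length - fwd_end, t.length - fwd_start
    return fwd_start, fwd_end


def map_transcript_to_genome(t: TranscriptModel, start: int, end: int) -> list[Interval]:
    """Genomic footprint of a transcript-coordinate range (possibly split)."""
    if not (0 <= start < end <= t.length):
        raise IndexError(f"range [{start},{end}) outside transcript length {t.length}")
    if t.strand == "-":
        start, end = t.length - end, t.length - start
    pieces = []
    off = 0
    for e in t.exons:
        lo = max(start, off)
        hi = min(end, off + len(e))
        if lo < hi:
            pieces.append(Interval(t.chrom, e.start + (lo - off), e.start + (hi - off), t.strand))
        off += len(e)
    return pieces
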