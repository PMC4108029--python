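"""Spliced-read and junction acceptance filters.

Candidate introns come from spliced read alignments (SAM or a 6-column
junction table).  A read survives iff every aligned block is at least
``min_anchor`` (15 nt) long and the blocks total at least ``min_aligned``
(40 nt).  A junction is accepted iff it is confirmed by both biological
replicates with a summed coverage of at least 4 reads, or — when only one
replicate saw it — by at least 10 reads from that replicate.
"""

from __future__ import annotations

from dataclasses import dataclass

import pysam

from .core import Interval, PipelineThresholds

__all__ = [
    "SplicedReadAlignment",
    "JunctionEvidence",
    "FilterDecision",
    "filter_spliced_read",
    "accept_junction",
    "collect_junctions",
    "read_sam_spliced",
    "read_junction_table",
    "write_junction_table",
]


@dataclass
class SplicedReadAlignment:
    """One spliced alignment: ≥2 aligned blocks separated by skipped regions."""

    read_id: str
    chrom: str
    strand: str
    blocks: list[Interval]
    replicate: int

    def __post_init__(self):
        if self.replicate not in (1, 2):
            raise ValueError(f"read {self.read_id}: replicate must be 1 or 2")
        self.blocks = sorted(self.blocks, key=lambda b: b.start)
        for a, b in zip(self.blocks, self.blocks[1:]):
            if b.start <= a.end:
                raise ValueError(f"read {self.read_id}: blocks not separated by a gap")

    @property
    def gaps(self) -> list[Interval]:
        return [
            Interval(self.chrom, a.end, b.start, self.strand)
            for a, b in zip(self.blocks, self.blocks[1:])
        ]


@dataclass
class JunctionEvidence:
    """A candidate intron and its per-replicate read support."""

    intron: Interval
    count_rep1: int = 0
    count_rep2: int = 0
    min_anchor: int | None = None
    total_aligned: int = 0
    accepted: bool = False

    @property
    def counts(self) -> tuple[int, int]:
        return self.count_rep1, self.count_rep2


@dataclass(frozen=True)
class FilterDecision:
    keep: bool
    reason: str = ""  # 'anchor' or 'total' when rejected


def filter_spliced_read(
    r: SplicedReadAlignment, th: PipelineThresholds
) -> FilterDecision:
    """Per-read filter: all anchors ≥ min_anchor, total alignment ≥ min_aligned."""
    if len(r.blocks) < 2:
        raise ValueError(f"read {r.read_id}: not a spliced read (<2 blocks)")
    if min(len(b) for b in r.blocks) < th.min_anchor:
        return FilterDecision(False, "anchor")
    if sum(len(b) for b in r.blocks) < th.min_aligned:
        return FilterDecision(False, "total")
    return FilterDecision(True)


def accept_junction(counts: tuple[int, int], th: PipelineThresholds) -> bool:
    """Replicate-aware junction acceptance.

    Accept iff both replicates confirm it and they total ≥ 4 reads, or a
    single replicate confirms it with ≥ 10 reads.
    """
    c1, c2 = counts
    if c1 < 0 or c2 < 0:
        raise ValueError("negative read counts")
    if c1 >= 1 and c2 >= 1:
        return c1 + c2 >= th.min_cov_both_reps
    single = max(c1, c2)
    return single >= th.min_cov_single_rep


def collect_junctions(
    reads: list[SplicedReadAlignment], th: PipelineThresholds
) -> list[JunctionEvidence]:
    """Aggregate kept reads into per-intron evidence and apply acceptance.

    Reads spanning several introns contribute each gap independently; the two
    blocks flanking a given gap must both satisfy the anchor rule for that
    gap to count (the read-level total-alignment rule applies once).
    """
    table: dict[Interval, JunctionEvidence] = {}
    for r in reads:
        if sum(len(b) for b in r.blocks) < th.min_aligned:
            continue
        for left, gap, right in zip(r.blocks, r.gaps, r.blocks[1:]):
            if len(left) < th.min_anchor or len(right) < th.min_anchor:
                continue
            ev = table.setdefault(gap, JunctionEvidence(intron=gap))
            if r.replicate == 1:
                ev.count_rep1 += 1
            else:
                ev.count_rep2 += 1
            anchor = min(len(left), len(right))
            ev.min_anchor = anchor if ev.min_anchor is None else min(ev.min_anchor, anchor)
            ev.total_aligned += sum(len(b) for b in r.blocks)
    out = sorted(
        table.values(), key=lambda ev: (ev.intron.chrom, ev.intron.start, ev.intron.end)
    )
    for ev in out:
        ev.accepted = accept_junction(ev.counts, th)
    return out


def read_sam_spliced(path, replicate_of=None) -> list[SplicedReadAlignment]:
    """Read spliced alignments from a (text) SAM file.

    The replicate of a read is looked up from its RG tag via ``replicate_of``
    (mapping read-group → 1|2); with no mapping, RG '1'/'2' are used directly
    and untagged reads default to replicate 1.  Only reads whose CIGAR
    contains an N (skipped region) are returned; M/=/X and D advance the
    current block, N closes it.
    """
    out = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam.fetch(until_eof=True):
            if aln.is_unmapped or aln.cigartuples is None:
                continue
            if not any(op == 3 for op, _ in aln.cigartuples):
                continue
            blocks, pos, block_start = [], aln.reference_start, aln.reference_start
            for op, length in aln.cigartuples:
                if op in (0, 7, 8, 2):  # M, =, X, D consume reference
                    pos += length
                elif op == 3:  # N closes the current block
                    if pos > block_start:
                        blocks.append((block_start, pos))
                    pos += length
                    block_start = pos
                # I, S, H, P consume no reference
            if pos > block_start:
                blocks.append((block_start, pos))
            if len(blocks) < 2:
                continue
            strand = "-" if aln.is_reverse else "+"
            rg = aln.get_tag("RG") if aln.has_tag("RG") else "1"
            if replicate_of is not None:
                rep = int(replicate_of[rg])
            else:
                rep = int(rg) if rg in ("1", "2") else 1
            chrom = aln.reference_name
            out.append(
                SplicedReadAlignment(
                    read_id=aln.query_name,
                    chrom=chrom,
                    strand=strand,
                    blocks=[Interval(chrom, s, e, strand) for s, e in blocks],
                    replicate=rep,
                )
            )
    return out


def read_junction_table(path, th: PipelineThresholds) -> list[JunctionEvidence]:
    """Read pre-aggregated junctions: chrom, start, end, strand, rep1, rep2.

    Coordinates are 0-based half-open intron coordinates.  Acceptance is
    applied on load.
    """
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("chrom\t"):
                continue
            chrom, start, end, strand, c1, c2 = line.split("\t")[:6]
            ev = JunctionEvidence(
                intron=Interval(chrom, int(start), int(end), strand),
                count_rep1=int(c1),
                count_rep2=int(c2),
            )
            ev.accepted = accept_junction(ev.counts, th)
            out.append(ev)
    return out


def write_junction_table(evidence: list[JunctionEvidence], path) -> None:
    """BED-like output of junctions with support columns."""
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tstrand\trep1_count\trep2_count\taccepted\n")
        for ev in sorted(
            evidence, key=lambda e: (e.intron.chrom, e.intron.start, e.intron.end)
        ):
            i = ev.intron
            fh.write(
                f"{i.chrom}\t{i.start}\t{i.end}\t{i.strand}\t"
                f"{ev.count_rep1}\t{ev.count_rep2}\t{int(ev.accepted)}\n"
            )
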