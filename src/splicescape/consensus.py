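"""Multi-assembler transcript consensus.

Transcript models reconstructed by independent programs (e.g. Cufflinks,
IsoLasso, Scripture) are grouped by genomic structure; a structure is kept
when at least two distinct programs predicted it and the representative is
at least 150 nt long.

Structural identity means identical ordered intron chains on the same
chromosome and strand; terminal exon ends may differ.  Monoexonic models —
for which intron chains carry no information — match by reciprocal overlap
of at least 50% of each, grouped by single linkage.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import Interval, PipelineThresholds, TranscriptModel, intron_chain

__all__ = ["AssemblySet", "structures_match", "build_consensus"]


@dataclass
class AssemblySet:
    """All transcript models produced by one program."""

    program: str
    transcripts: list[TranscriptModel]

    def __post_init__(self):
        ids = [t.id for t in self.transcripts]
        if len(ids) != len(set(ids)):
            raise ValueError(f"assembly {self.program}: duplicate transcript ids")


def _chain_key(t: TranscriptModel) -> tuple:
    return (t.chrom, t.strand, tuple((i.start, i.end) for i in intron_chain(t)))


def _reciprocal_overlap(a: TranscriptModel, b: TranscriptModel, frac: float) -> bool:
    ov = a.exons[0].overlap_len(b.exons[0])
    return ov >= frac * len(a.exons[0]) and ov >= frac * len(b.exons[0])


def structures_match(
    a: TranscriptModel,
    b: TranscriptModel,
    th: PipelineThresholds | None = None,
) -> bool:
    """Same genomic structure, in the intron-chain sense.

    Multiexonic: identical intron chains (chrom+strand).  Monoexonic:
    reciprocal overlap ≥ ``mono_exon_overlap_frac`` of each model.
    A monoexonic model never matches a multiexonic one.
    """
    th = th or PipelineThresholds()
    if a.chrom != b.chrom or a.strand != b.strand:
        return False
    mono_a, mono_b = len(a.exons) == 1, len(b.exons) == 1
    if mono_a != mono_b:
        return False
    if mono_a:
        return _reciprocal_overlap(a, b, th.mono_exon_overlap_frac)
    return _chain_key(a) == _chain_key(b)


def _representative(group: list[tuple[str, TranscriptModel]]) -> TranscriptModel:
    """One transcript per group: structure from the lexicographically first
    program, terminal exon ends extended to the group's extremes."""
    group = sorted(group, key=lambda pt: (pt[0], pt[1].id))
    program, base = group[0]
    lo = min(t.start for _, t in group)
    hi = max(t.end for _, t in group)
    exons = list(base.exons)
    first = exons[0]
    exons[0] = Interval(first.chrom, min(lo, first.start), first.end, first.strand)
    last = exons[-1]
    exons[-1] = Interval(last.chrom, last.start, max(hi, last.end), last.strand)
    if len(exons) == 1:
        exons = [Interval(first.chrom, min(lo, first.start), max(hi, first.end), first.strand)]
    programs = sorted({p for p, _ in group})
    rep = TranscriptModel(
        id=base.id,
        gene_id=base.gene_id,
        exons=exons,
        cds=None,
        source=program,
    )
    rep.support_programs = programs  # annotation for GFF3 output
    return rep


def build_consensus(
    sets: list[AssemblySet], th: PipelineThresholds | None = None
) -> list[TranscriptModel]:
    """Consensus models supported by ≥ min_programs with length ≥ 150 nt."""
    th = th or PipelineThresholds()
    if len(sets) < 2:
        raise ValueError("consensus requires at least two assembly sets")

    # multiexonic: exact grouping on the intron-chain key
    multi: dict[tuple, list[tuple[str, TranscriptModel]]] = {}
    mono: list[tuple[str, TranscriptModel]] = []
    for s in sets:
        for t in s.transcripts:
            if len(t.exons) == 1:
                mono.append((s.program, t))
            else:
                multi.setdefault(_chain_key(t), []).append((s.program, t))

    groups = list(multi.values())

    # monoexonic: single-linkage on reciprocal overlap, per chrom/strand
    by_loc: dict[tuple[str, str], list[tuple[str, TranscriptModel]]] = {}
    for p, t in mono:
        by_loc.setdefault((t.chrom, t.strand), []).append((p, t))
    for items in by_loc.values():
        items = sorted(items, key=lambda pt: pt[1].start)
        parent = list(range(len(items)))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(items)):
            for j in range(i + 1, len(items)):
                if items[j][1].start >= items[i][1].end:
                    break
                if structures_match(items[i][1], items[j][1], th):
                    parent[find(i)] = find(j)
        comp: dict[int, list[tuple[str, TranscriptModel]]] = {}
        for i, item in enumerate(items):
            comp.setdefault(find(i), []).append(item)
        groups.extend(comp.values())

    out = []
    for group in groups:
        programs = {p for p, _ in group}
        if len(programs) < th.min_programs:
            continue
        rep = _representative(group)
        if rep.length < th.min_transcript_len:
            continue
        out.append(rep)
    out.sort(key=lambda t: (t.chrom, t.start, t.id))
    return out
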