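"""Stringent long non-coding RNA candidate filtering.

Candidate transcripts (typically assembler output that matched no reference
model) are first placed relative to the reference annotation — intergenic
('u'), intronic ('i') or antisense-exonic ('x'); any same-strand exon
overlap disqualifies — then pushed through an ordered filter cascade:

1. length ≥ 200 nt;
2. class code ∈ {u, i, x};
3. no coding potential (an ORF-based heuristic by default; external
   coding-potential calls plug in through the evidence tables);
4. no annotated protein domain;
5. no repeat overlap;
6. genomic-context filter per class — intergenic candidates must sit more
   than 1 kb from the nearest gene (discarding stray UTR fragments),
   intronic candidates must keep ≥ 100 nt from both flanking exons and
   stay under 30% of the host intron (discarding immature/IR fragments),
   antisense candidates must cover ≥ 30% of the overlapped exon;
7. detection at ≥ 1 FPKM in both replicates of at least one sample.

Every candidate carries an audit trail naming the first failing filter, so
the whole funnel is reconstructible from one table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core import (
    AnnotationSet,
    GenomeSequence,
    Interval,
    PipelineThresholds,
    TranscriptModel,
    intron_chain,
)

__all__ = [
    "LncRNACandidate",
    "FILTER_ORDER",
    "assign_class_code",
    "orf_coding_potential",
    "run_lncrna_pipeline",
]

FILTER_ORDER = (
    "length",
    "class_code",
    "coding_potential",
    "domain",
    "repeat",
    "context",
    "expression",
)

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class ClassContext:
    """Where a candidate sits relative to the reference annotation."""

    code: str  # 'u' | 'i' | 'x' | 'other'
    nearest_gene_distance: int | None = None  # for 'u'
    host_intron: Interval | None = None  # for 'i'
    exon_dist_left: int | None = None
    exon_dist_right: int | None = None
    overlapped_exon: Interval | None = None  # for 'x'
    exon_overlap_frac: float = 0.0


@dataclass
class LncRNACandidate:
    transcript: TranscriptModel
    context: ClassContext | None = None
    audit: list[tuple[str, bool, object]] = field(default_factory=list)
    status: str = "pending"  # 'accepted' | 'rejected'
    failed_filter: str = ""

    @property
    def class_code(self) -> str:
        return self.context.code if self.context else "other"


def assign_class_code(t: TranscriptModel, ref: AnnotationSet) -> ClassContext:
    """Class-code a candidate against the reference annotation.

    'u' — no overlap with any reference gene span (nearest distance kept);
    'i' — contained in an intron of a reference transcript, no exon overlap
    (host intron and flanking-exon distances kept); 'x' — overlaps a
    reference exon on the opposite strand (best overlap fraction of the exon
    kept); any same-strand exon overlap, or span overlap fitting no class,
    is 'other'.  Unstranded candidates can only be 'u' or 'i'.
    """
    span = t.span
    genes = ref.overlapping(span)
    if not genes:
        return ClassContext("u", nearest_gene_distance=ref.nearest_distance(span))

    same_strand_exon = False
    best_x: tuple[float, Interval] | None = None
    host: tuple[Interval, int, int] | None = None
    for g in genes:
        for rt in g.transcripts:
            for e in rt.exons:
                ov = span.overlap_len(Interval(e.chrom, e.start, e.end))
                if ov <= 0:
                    continue
                if t.strand != "." and e.strand != t.strand:
                    frac = ov / len(e)
                    if best_x is None or frac > best_x[0]:
                        best_x = (frac, e)
                else:
                    same_strand_exon = True
            for i in intron_chain(rt):
                if i.start <= span.start and span.end <= i.end:
                    left = span.start - i.start
                    right = i.end - span.end
                    if host is None or len(i) < len(host[0]):
                        host = (i, left, right)
    if same_strand_exon:
        return ClassContext("other")
    if best_x is not None:
        return ClassContext("x", overlapped_exon=best_x[1], exon_overlap_frac=best_x[0])
    if host is not None:
        return ClassContext(
            "i", host_intron=host[0], exon_dist_left=host[1], exon_dist_right=host[2]
        )
    return ClassContext("other")


def orf_coding_potential(
    seq: str, min_codons: int = 100
) -> tuple[str, int]:
    """ORF-length heuristic for coding potential.

    Scans the three forward frames of the oriented transcript sequence for
    ATG→stop ORFs; the transcript is called coding when the longest complete
    ORF reaches ``min_codons`` codons (stop included).  Returns
    ``(call, longest_orf_codons)`` with call 'coding' or 'noncoding'.
    """
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    longest = 0
    for frame in range(3):
        start = None
        for p in range(frame, len(seq) - 2, 3):
            codon = seq[p : p + 3]
            if start is None:
                if codon == "ATG":
                    start = p
            elif codon in _STOPS:
                longest = max(longest, (p + 3 - start) // 3)
                start = None
    call = "coding" if longest >= min_codons else "noncoding"
    return call, longest


def _transcript_sequence(t: TranscriptModel, genome: GenomeSequence) -> str:
    parts = [genome.fetch(e) for e in t.exons]
    seq = "".join(parts)
    if t.strand == "-":
        from .core import revcomp

        seq = revcomp(seq)
    return seq


def _context_filter(c: LncRNACandidate, th: PipelineThresholds) -> tuple[bool, object]:
    ctx = c.context
    if ctx.code == "u":
        d = ctx.nearest_gene_distance
        if d is None:  # no gene on the chromosome at all
            return True, None
        return d > th.intergenic_min_dist, d
    if ctx.code == "i":
        dist_ok = (
            ctx.exon_dist_left >= th.intronic_min_exon_dist
            and ctx.exon_dist_right >= th.intronic_min_exon_dist
        )
        frac = c.transcript.length / len(ctx.host_intron)
        return dist_ok and frac <= th.intronic_max_intron_frac, {
            "exon_dist": (ctx.exon_dist_left, ctx.exon_dist_right),
            "intron_frac": round(frac, 4),
        }
    if ctx.code == "x":
        return (
            ctx.exon_overlap_frac >= th.antisense_min_exon_overlap_frac,
            round(ctx.exon_overlap_frac, 4),
        )
    return False, ctx.code


def run_lncrna_pipeline(
    candidates: list[TranscriptModel],
    ref: AnnotationSet,
    genome: GenomeSequence,
    evidence: dict | None = None,
    expression: dict[str, dict[str, tuple[float, float]]] | None = None,
    th: PipelineThresholds | None = None,
    skip_filters: set[str] = frozenset(),
) -> list[LncRNACandidate]:
    """Run the full lncRNA filter cascade with per-candidate audit trails.

    ``evidence`` may carry ``domain_flags`` (set of candidate ids),
    ``repeat_intervals`` (list of Interval) and ``coding_flags`` (dict id →
    'coding'|'noncoding', overriding the ORF heuristic, e.g. from an
    external coding-potential tool).  ``expression`` maps candidate id →
    {sample → (fpkm_rep1, fpkm_rep2)}; a candidate with no expression entry
    fails the expression filter.  Filters named in ``skip_filters`` are
    recorded as skipped and never fail.
    """
    th = th or PipelineThresholds()
    evidence = evidence or {}
    domain_flags = set(evidence.get("domain_flags", ()))
    repeat_intervals = list(evidence.get("repeat_intervals", ()))
    coding_flags = dict(evidence.get("coding_flags", {}))
    expression = expression or {}

    out = []
    for t in candidates:
        if t.chrom not in genome or t.end > len(genome[t.chrom]):
            raise ValueError(f"candidate {t.id} outside genome bounds")
        cand = LncRNACandidate(transcript=t, context=assign_class_code(t, ref))
        seq = _transcript_sequence(t, genome)

        def check(name) -> tuple[bool, object]:
            if name == "length":
                return t.length >= th.min_lnc_len, t.length
            if name == "class_code":
                return cand.context.code in ("u", "i", "x"), cand.context.code
            if name == "coding_potential":
                if t.id in coding_flags:
                    return coding_flags[t.id] == "noncoding", coding_flags[t.id]
                call, orf = orf_coding_potential(seq, th.min_orf_codons)
                return call == "noncoding", orf
            if name == "domain":
                return t.id not in domain_flags, t.id in domain_flags
            if name == "repeat":
                hit = any(t.span.overlap_len(r) > 0 for r in repeat_intervals)
                return not hit, hit
            if name == "context":
                return _context_filter(cand, th)
            if name == "expression":
                samples = expression.get(t.id, {})
                detected = any(
                    r1 >= th.detection_fpkm and r2 >= th.detection_fpkm
                    for r1, r2 in samples.values()
                )
                return detected, {s: v for s, v in sorted(samples.items())}
            raise KeyError(name)

        for name in FILTER_ORDER:
            if name in skip_filters:
                cand.audit.append((name, True, "skipped"))
                continue
            ok, value = check(name)
            cand.audit.append((name, ok, value))
            if not ok:
                cand.status = "rejected"
                cand.failed_filter = name
                break
        else:
            cand.status = "accepted"
        out.append(cand)
    return out
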