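"""Detection, classification and summarisation of alternative-splicing events.

Events are found by pairwise comparison of the isoforms of a gene, in the
style of splicing-graph bubble callers: within the genomic overlap of the two
isoforms, maximal stretches where the exon/intron structures disagree are
delimited by splice sites shared by both isoforms (or by the overlap edges)
and classified by the pattern of splice sites each isoform places inside the
variable region:

* intron retention (IR) — one isoform splices exactly one intron across the
  region, the other runs through it as uninterrupted exon;
* exon skipping (ES) — one isoform holds one or more complete exons inside a
  region the other spans with a single intron, flanking sites shared;
* Alt5 / Alt3 — the two isoforms disagree only on the donor (5') or the
  acceptor (3') coordinate of one intron, read in transcript orientation;
* complex — any coupled combination of differences.

Differences confined to transcript start/end positions (outside the mutual
overlap) are differential initiation/termination, not splicing, and produce
no event.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core import (
    AnnotationSet,
    GeneModel,
    GenomeSequence,
    Interval,
    TranscriptModel,
    classify_splice_site,
    intron_chain,
    map_genome_to_transcript,
    segment_transcript_regions,
)

__all__ = [
    "SpliceEvent",
    "IntronClassSets",
    "enumerate_pairwise_events",
    "classify_event",
    "localize_event",
    "gene_events",
    "deduplicated_gene_events",
    "classify_intron_sets",
    "summarize_as_landscape",
]

EVENT_TYPES = ("IR", "ES", "Alt5", "Alt3", "complex")


@dataclass
class SpliceEvent:
    """A variable region between two isoform structure groups of one gene."""

    gene_id: str
    chrom: str
    strand: str
    region: tuple[int, int]  # hull of the differing bases, half-open
    flank_left: int  # nearest shared splice site / overlap edge on the left
    flank_right: int
    group_a: list[str]  # isoform ids sharing structure A inside the region
    group_b: list[str]
    sig_a: tuple  # ordered (type, pos) splice sites of structure A in (flanks)
    sig_b: tuple
    event_type: str = ""
    region_label: str = ""
    retained_intron: tuple[int, int] | None = None

    @property
    def region_interval(self) -> Interval:
        return Interval(self.chrom, self.region[0], self.region[1], self.strand)

    @property
    def key(self) -> tuple:
        """Dedup key: same flanks and same pair of structures (unordered)."""
        sigs = tuple(sorted((self.sig_a, self.sig_b)))
        return (self.flank_left, self.flank_right, sigs)


@dataclass
class IntronClassSets:
    """Intron partitions of one gene: ALL ⊇ ASI ⊇ IR, IC = ALL − ASI."""

    ALL: set[tuple[int, int]] = field(default_factory=set)
    ASI: set[tuple[int, int]] = field(default_factory=set)
    IR: set[tuple[int, int]] = field(default_factory=set)

    @property
    def IC(self) -> set[tuple[int, int]]:
        return self.ALL - self.ASI

    @property
    def AS_minus_IR(self) -> set[tuple[int, int]]:
        return self.ASI - self.IR


def _sites_in(t: TranscriptModel, lo: int, hi: int) -> list[tuple[str, int]]:
    """Typed splice sites of ``t`` strictly inside (lo, hi), genomic order.

    'D' = exon→intron transition (genomic left-to-right), 'A' = intron→exon.
    """
    sites = []
    for e in t.exons:
        if lo < e.start < hi:
            sites.append(("A", e.start))
        if lo < e.end < hi:
            sites.append(("D", e.end))
    sites.sort(key=lambda s: s[1])
    return sites


def _exonic_runs(t: TranscriptModel, lo: int, hi: int) -> list[tuple[int, int]]:
    runs = []
    for e in t.exons:
        s, eo = max(e.start, lo), min(e.end, hi)
        if s < eo:
            runs.append((s, eo))
    return runs


def _diff_runs(a: TranscriptModel, b: TranscriptModel, lo: int, hi: int):
    """Maximal intervals inside [lo,hi) where exonic status differs."""
    bounds = {lo, hi}
    for t in (a, b):
        for e in t.exons:
            for p in (e.start, e.end):
                if lo < p < hi:
                    bounds.add(p)
    bounds = sorted(bounds)
    runs = []
    for s, e in zip(bounds, bounds[1:]):
        if a.is_exonic(s) != b.is_exonic(s):
            if runs and runs[-1][1] == s:
                runs[-1][1] = e
            else:
                runs.append([s, e])
    return [(s, e) for s, e in runs]


def enumerate_pairwise_events(
    a: TranscriptModel, b: TranscriptModel
) -> list[SpliceEvent]:
    """Variable regions between two isoforms, restricted to their overlap."""
    if a.chrom != b.chrom or a.strand != b.strand:
        raise ValueError("isoforms must share chrom and strand")
    lo, hi = max(a.start, b.start), min(a.end, b.end)
    if lo >= hi:
        return []
    runs = _diff_runs(a, b, lo, hi)
    if not runs:
        return []

    sites_a = _sites_in(a, lo, hi)
    sites_b = _sites_in(b, lo, hi)
    common = sorted({s for s in sites_a} & {s for s in sites_b}, key=lambda s: s[1])
    common_pos = [p for _, p in common]

    # group diff runs: a shared splice site between two runs separates events
    groups: list[list[tuple[int, int]]] = [[runs[0]]]
    for prev, cur in zip(runs, runs[1:]):
        if any(prev[1] <= p <= cur[0] for p in common_pos):
            groups.append([cur])
        else:
            groups[-1].append(cur)

    events = []
    for grp in groups:
        s, e = grp[0][0], grp[-1][1]
        fl = max((p for p in common_pos if p <= s), default=lo)
        fr = min((p for p in common_pos if p >= e), default=hi)
        ev = SpliceEvent(
            gene_id=a.gene_id,
            chrom=a.chrom,
            strand=a.strand,
            region=(s, e),
            flank_left=fl,
            flank_right=fr,
            group_a=[a.id],
            group_b=[b.id],
            sig_a=tuple(_sites_in(a, fl, fr)),
            sig_b=tuple(_sites_in(b, fl, fr)),
        )
        ev.event_type = classify_event(ev, a, b)
        events.append(ev)
    return events


def _is_retention(sig: tuple, region: tuple[int, int]) -> bool:
    """One spliced intron exactly covering the region: sites = D@s, A@e."""
    return (
        len(sig) == 2
        and sig[0] == ("D", region[0])
        and sig[1] == ("A", region[1])
    )


def _is_cassette(sig: tuple) -> bool:
    """≥1 complete exon inside the region: alternating A,D,...,A,D."""
    if len(sig) < 2 or len(sig) % 2 != 0:
        return False
    return all(t == ("AD"[i % 2]) for i, (t, _) in enumerate(sig))


def classify_event(e: SpliceEvent, a: TranscriptModel, b: TranscriptModel) -> str:
    """Assign IR / ES / Alt5 / Alt3 / complex from the event signatures."""
    sig_a, sig_b = e.sig_a, e.sig_b
    if bool(sig_a) != bool(sig_b):
        full, empty_tx = (sig_a, b) if sig_a else (sig_b, a)
        if _is_retention(full, e.region) and empty_tx.is_exonic(e.region[0]):
            e.retained_intron = e.region
            return "IR"
        if _is_cassette(full) and not empty_tx.is_exonic(e.region[0]):
            return "ES"
        return "complex"
    if len(sig_a) == 1 and len(sig_b) == 1 and sig_a[0][0] == sig_b[0][0]:
        site_type = sig_a[0][0]
        # genomic 'D' (exon end) is the intron's 5' donor on +, acceptor on −
        if site_type == "D":
            return "Alt5" if e.strand != "-" else "Alt3"
        return "Alt3" if e.strand != "-" else "Alt5"
    return "complex"


def _region_labels(ref: TranscriptModel, region: tuple[int, int]) -> set[str]:
    """Segmentation labels touched by ref's exonic bases inside the region."""
    seg = segment_transcript_regions(ref)
    labels = set()
    for s, e in _exonic_runs(ref, region[0], region[1]):
        mapped = map_genome_to_transcript(ref, Interval(ref.chrom, s, e, ref.strand))
        if mapped is None:  # exonic run within one exon always maps
            continue
        for name, (a0, b0) in seg.items():
            if a0 < b0 and mapped[0] < b0 and a0 < mapped[1]:
                labels.add(name)
    return labels


def localize_event(e: SpliceEvent, ref: TranscriptModel) -> str:
    """Label an event 5UTR / CDS / 3UTR / CDS_UTR_spanning on a CDS-bearing
    reference isoform.

    When the reference has no exonic base inside the variable region (the
    region is one of its introns, as for IR seen from the splicing isoform),
    the labels of the nearest exonic bases on either side are used instead.
    """
    if not ref.cds:
        raise ValueError(f"reference isoform {ref.id} has no CDS")
    labels = _region_labels(ref, e.region)
    if not labels:
        s, r = e.region
        # take the label adjacent to the region on each side
        near = set()
        for side, rng in (("L", (ref.start, s)), ("R", (r, ref.end))):
            runs = _exonic_runs(ref, rng[0], rng[1])
            if not runs:
                continue
            pos = runs[-1][1] - 1 if side == "L" else runs[0][0]
            near |= _region_labels(ref, (pos, pos + 1))
        labels = near
    if not labels:
        return "CDS_UTR_spanning"
    if labels == {"CDS"}:
        return "CDS"
    if labels == {"5UTR"}:
        return "5UTR"
    if labels == {"3UTR"}:
        return "3UTR"
    return "CDS_UTR_spanning"


def gene_events(g: GeneModel) -> list[SpliceEvent]:
    """All pairwise events among a gene's isoforms (not deduplicated)."""
    out = []
    txs = sorted(g.transcripts, key=lambda t: t.id)
    for i in range(len(txs)):
        for j in range(i + 1, len(txs)):
            out.extend(enumerate_pairwise_events(txs[i], txs[j]))
    return out


def deduplicated_gene_events(g: GeneModel) -> list[SpliceEvent]:
    """Pairwise events merged on (flanks, structure pair): each distinct
    variable region counts once per gene, isoform groups pooled."""
    merged: dict[tuple, SpliceEvent] = {}
    for ev in gene_events(g):
        if ev.key in merged:
            kept = merged[ev.key]
            for iso, sig in ((ev.group_a[0], ev.sig_a), (ev.group_b[0], ev.sig_b)):
                side = kept.group_a if sig == kept.sig_a else kept.group_b
                if iso not in side:
                    side.append(iso)
        else:
            merged[ev.key] = ev
    return sorted(merged.values(), key=lambda e: (e.region, e.event_type))


def classify_intron_sets(
    g: GeneModel, events: list[SpliceEvent] | None = None
) -> IntronClassSets:
    """Partition a gene's introns into constitutive / AS / retained classes."""
    if events is None:
        events = deduplicated_gene_events(g)
    sets = IntronClassSets()
    for t in g.transcripts:
        for i in intron_chain(t):
            sets.ALL.add((i.start, i.end))
    for ev in events:
        s, e = ev.region
        for i in sets.ALL:
            if i[0] < e and s < i[1]:
                sets.ASI.add(i)
        if ev.event_type == "IR" and ev.retained_intron:
            sets.IR.add(ev.retained_intron)
    sets.IR &= sets.ALL
    sets.ASI |= sets.IR
    return sets


def _localization_reference(g: GeneModel, ev: SpliceEvent) -> TranscriptModel | None:
    """CDS-bearing participant with the longest CDS."""
    participants = set(ev.group_a) | set(ev.group_b)
    best, best_len = None, -1
    for t in g.transcripts:
        if t.id in participants and t.cds:
            clen = sum(len(c) for c in t.cds)
            if clen > best_len or (clen == best_len and t.id < best.id):
                best, best_len = t, clen
    return best


def _cds_endpoints(t: TranscriptModel) -> tuple[int, int] | None:
    """Genomic positions of the start codon and stop codon (5'-anchored)."""
    if not t.cds:
        return None
    span = t.cds_span
    if t.strand == "-":
        return span.end, span.start
    return span.start, span.end


def summarize_as_landscape(
    ann: AnnotationSet, genome: GenomeSequence | None = None
) -> dict:
    """Gene-level alternative-splicing census of an annotation.

    Reports multiexonic and AS gene fractions, the isoforms-per-gene
    histogram, deduplicated event counts per class, donor/acceptor
    dinucleotide class fractions (when a genome is given), event region
    fractions, and — among multi-isoform CDS-bearing genes — the fractions
    with alternative start codons / stop codons and, separately, with
    alternative transcript start/end positions.
    """
    n_genes = len(ann)
    multiexonic = 0
    as_genes = 0
    iso_hist: dict[int, int] = {}
    event_counts = {k: 0 for k in EVENT_TYPES}
    region_counts = {"5UTR": 0, "CDS": 0, "3UTR": 0, "CDS_UTR_spanning": 0}
    site_counts = {"canonical_GT_AG": 0, "GC_AG": 0, "other": 0}
    all_events = []
    n_multi_iso_cds = 0
    alt_start_codon = alt_stop_codon = 0
    n_multi_iso = 0
    alt_tss = alt_tes = 0
    seen_introns = set()

    for g in ann:
        n_iso = len(g.transcripts)
        iso_hist[n_iso] = iso_hist.get(n_iso, 0) + 1
        if any(len(t.exons) > 1 for t in g.transcripts):
            multiexonic += 1
        events = deduplicated_gene_events(g)
        if events:
            as_genes += 1
        for ev in events:
            event_counts[ev.event_type] += 1
            ref = _localization_reference(g, ev)
            if ref is not None:
                ev.region_label = localize_event(ev, ref)
                region_counts[ev.region_label] += 1
            all_events.append(ev)
        if genome is not None:
            for t in g.transcripts:
                for i in intron_chain(t):
                    key = (i.chrom, i.start, i.end, i.strand)
                    if key in seen_introns or len(i) < 4:
                        continue
                    seen_introns.add(key)
                    site_counts[classify_splice_site(i, genome)[2]] += 1
        if n_iso >= 2:
            n_multi_iso += 1
            if len({t.start for t in g.transcripts}) > 1:
                alt_tss += 1
            if len({t.end for t in g.transcripts}) > 1:
                alt_tes += 1
            ends = [_cds_endpoints(t) for t in g.transcripts if t.cds]
            if len(ends) >= 2:
                n_multi_iso_cds += 1
                if len({e[0] for e in ends}) > 1:
                    alt_start_codon += 1
                if len({e[1] for e in ends}) > 1:
                    alt_stop_codon += 1

    n_events = sum(event_counts.values())
    n_sites = sum(site_counts.values())
    n_regions = sum(region_counts.values())

    def frac(x, n):
        return x / n if n else 0.0

    return {
        "n_genes": n_genes,
        "frac_multiexonic": frac(multiexonic, n_genes),
        "n_as_genes": as_genes,
        "frac_as_of_multiexonic": frac(as_genes, multiexonic),
        "isoforms_per_gene_hist": dict(sorted(iso_hist.items())),
        "event_counts": event_counts,
        "n_events": n_events,
        "event_fractions": {k: frac(v, n_events) for k, v in event_counts.items()},
        "splice_site_counts": site_counts,
        "splice_site_fractions": {k: frac(v, n_sites) for k, v in site_counts.items()},
        "region_counts": region_counts,
        "region_fractions": {k: frac(v, n_regions) for k, v in region_counts.items()},
        "frac_alt_start_codon": frac(alt_start_codon, n_multi_iso_cds),
        "frac_alt_stop_codon": frac(alt_stop_codon, n_multi_iso_cds),
        "frac_alt_tss": frac(alt_tss, n_multi_iso),
        "frac_alt_tes": frac(alt_tes, n_multi_iso),
    }
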