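"""Synthetic genomes, annotations, junction evidence, expression designs,
lncRNA candidates and miRNA sites with complete planted ground truth.

The generator emulates the study conditions of a plant reannotation
project: multi-isoform gene models carrying each alternative-splicing class
(retained introns drawn from a shorter length distribution than other AS
introns, medians 123 vs 702 nt), splice sites written explicitly at intron
boundaries with a 97.5 / 1 / 1.5 % GT-AG / GC-AG / other mix, junction
evidence with two biological replicates straddling the acceptance
boundaries, a tissue × genotype × condition expression design with two
replicates per sample in which tissue explains more isoform-ratio variance
than genotype, and lncRNA candidates of classes u/i/x together with one
decoy family per pipeline filter, each placed one unit beyond its
threshold.

Everything is driven by :func:`numpy.random.default_rng`, so a fixed seed
reproduces every file byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    AnnotationSet,
    GeneModel,
    GenomeSequence,
    Interval,
    TranscriptModel,
    classify_splice_site,
    genome_pos_to_transcript,
    intron_chain,
    map_transcript_to_genome,
    revcomp,
)

__all__ = [
    "SyntheticTruth",
    "simulate_annotated_genome",
    "simulate_junction_evidence",
    "simulate_expression_design",
    "simulate_lncrna_candidates",
    "simulate_mirna_sites",
    "random_gene",
]

# stop codons in all three frames of the oriented sequence, every ~250 nt,
# cap any open reading frame well under the 100-codon coding cutoff
_STOP_CASSETTE = "TAAATGAATAG"

_EVENT_CLASSES = ("IR", "ES", "Alt5", "Alt3", "complex")

_SITE_DINUCS = {
    "canonical_GT_AG": ("GT", "AG"),
    "GC_AG": ("GC", "AG"),
    "other": ("AT", "AC"),
}


@dataclass
class SyntheticTruth:
    """Ground-truth record accompanying every synthetic dataset."""

    seed: int
    params: dict = field(default_factory=dict)
    events: list[dict] = field(default_factory=list)  # gene, type, region, ...
    intron_classes: dict[str, dict] = field(default_factory=dict)
    splice_site_counts: dict[str, int] = field(default_factory=dict)
    junctions: list[dict] = field(default_factory=list)
    expression: dict = field(default_factory=dict)
    lncrna: list[dict] = field(default_factory=list)
    mirna_sites: list[dict] = field(default_factory=list)


class _MutableGenome:
    def __init__(self, rng: np.random.Generator, n_chroms: int, chrom_len: int):
        alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
        self.seqs = {
            f"chr{i + 1}": alphabet[rng.integers(0, 4, size=chrom_len)].copy()
            for i in range(n_chroms)
        }

    def write(self, chrom: str, pos: int, s: str) -> None:
        arr = self.seqs[chrom]
        if pos < 0 or pos + len(s) > len(arr):
            raise IndexError(f"write outside {chrom}")
        arr[pos : pos + len(s)] = np.frombuffer(s.encode(), dtype=np.uint8)

    def freeze(self) -> GenomeSequence:
        return GenomeSequence(
            {c: arr.tobytes().decode() for c, arr in self.seqs.items()}
        )


def _lognormal_length(
    rng, median: float, sigma: float, minimum: int, maximum: int | None = None
) -> int:
    n = max(minimum, int(round(median * float(np.exp(rng.normal(0.0, sigma))))))
    return n if maximum is None else min(n, maximum)


def _build_exons(starts_lens: list[tuple[int, int]], chrom: str, strand: str):
    return [Interval(chrom, s, s + ln, strand) for s, ln in starts_lens]


def _default_cds(t: TranscriptModel, utr: int = 150) -> list[Interval] | None:
    n = t.length
    if n < 3 * utr:
        utr = n // 4
    lo, hi = utr, n - utr
    if hi - lo < 30:
        return None
    return map_transcript_to_genome(t, lo, hi)


def simulate_annotated_genome(
    n_genes: int = 200,
    event_counts: dict[str, int] | None = None,
    n_truncated: int = 15,
    n_chroms: int = 20,
    chrom_len: int = 100_000,
    splice_site_composition: tuple[float, float, float] = (0.975, 0.01, 0.015),
    ir_intron_median: float = 123.0,
    as_intron_median: float = 702.0,
    constitutive_intron_median: float = 300.0,
    intron_sigma: float = 0.35,
    seed: int = 0,
) -> tuple[GenomeSequence, AnnotationSet, SyntheticTruth]:
    """Genome + annotation with one planted AS event per designated gene.

    ``event_counts`` maps event class → number of genes carrying exactly one
    such event (default {IR: 20, ES: 8, Alt5: 8, Alt3: 8, complex: 4});
    ``n_truncated`` genes get a 5'-truncated second isoform with an
    identical intron chain (differential initiation, not splicing).  The
    remaining genes are single-isoform.  Every intron boundary dinucleotide
    is written into the genome; the truth records the per-class site counts
    read back from the final sequence.
    """
    if event_counts is None:
        event_counts = {"IR": 20, "ES": 8, "Alt5": 8, "Alt3": 8, "complex": 4}
    for k in event_counts:
        if k not in _EVENT_CLASSES:
            raise ValueError(f"unknown event class {k!r}")
    n_event_genes = sum(event_counts.values())
    if n_event_genes + n_truncated > n_genes:
        raise ValueError(
            f"{n_event_genes} event genes + {n_truncated} truncated genes "
            f"exceed n_genes={n_genes}"
        )

    rng = np.random.default_rng(seed)
    genome = _MutableGenome(rng, n_chroms, chrom_len)
    truth = SyntheticTruth(
        seed=seed,
        params={
            "n_genes": n_genes,
            "event_counts": dict(event_counts),
            "n_truncated": n_truncated,
            "splice_site_composition": list(splice_site_composition),
            "ir_intron_median": ir_intron_median,
            "as_intron_median": as_intron_median,
        },
    )
    if n_genes == 0:
        return genome.freeze(), AnnotationSet([], version="synthetic"), truth

    roles = [(cls, None) for cls in _EVENT_CLASSES for _ in range(event_counts.get(cls, 0))]
    roles += [("truncated", None)] * n_truncated
    roles += [("plain", None)] * (n_genes - len(roles))
    rng.shuffle(roles)

    genes_per_chrom = -(-n_genes // n_chroms)  # ceil
    slot = (chrom_len - 4000) // genes_per_chrom
    genes: list[GeneModel] = []
    all_introns: set[Interval] = set()

    for gi, (role, _) in enumerate(roles):
        chrom = f"chr{gi // genes_per_chrom + 1}"
        origin = 2000 + (gi % genes_per_chrom) * slot
        strand = "+" if rng.random() < 0.5 else "-"
        gid = f"G{gi + 1:04d}"

        n_exons = int(rng.integers(4, 7))
        exon_lens = [int(rng.integers(140, 260)) for _ in range(n_exons)]
        intron_lens = [
            _lognormal_length(rng, constitutive_intron_median, intron_sigma, 80, 600)
            for _ in range(n_exons - 1)
        ]
        # the last intron is a large host intron usable by intronic lncRNAs
        intron_lens[-1] = int(rng.integers(2500, 3000))
        ev_idx = 1  # internal intron / exon used by the planted event
        if role == "IR":
            intron_lens[ev_idx] = _lognormal_length(rng, ir_intron_median, intron_sigma, 24, 400)
        elif role in ("Alt5", "Alt3", "complex"):
            intron_lens[ev_idx] = _lognormal_length(rng, as_intron_median, intron_sigma, 150, 1800)

        starts, pos = [], origin
        for i in range(n_exons):
            starts.append(pos)
            pos += exon_lens[i]
            if i < n_exons - 1:
                pos += intron_lens[i]
        if pos > chrom_len - 2000:
            raise ValueError("chromosome too short for requested gene density")
        exons_a = _build_exons(list(zip(starts, exon_lens)), chrom, strand)
        iso_a = TranscriptModel(f"{gid}.1", gid, exons_a, source="synthetic")
        isoforms = [iso_a]

        ev_record = None
        if role == "IR":
            i0 = exons_a[ev_idx]
            i1 = exons_a[ev_idx + 1]
            merged = Interval(chrom, i0.start, i1.end, strand)
            exons_b = [e for k, e in enumerate(exons_a) if k not in (ev_idx, ev_idx + 1)]
            exons_b.append(merged)
            intron = (i0.end, i1.start)
            ev_record = {"type": "IR", "region": intron, "retained_intron": intron}
            isoforms.append(TranscriptModel(f"{gid}.2", gid, exons_b, source="synthetic"))
        elif role == "ES":
            k = ev_idx + 1  # internal exon
            cassette = exons_a[k]
            exons_b = [e for i2, e in enumerate(exons_a) if i2 != k]
            ev_record = {"type": "ES", "region": (cassette.start, cassette.end)}
            isoforms.append(TranscriptModel(f"{gid}.2", gid, exons_b, source="synthetic"))
        elif role in ("Alt5", "Alt3", "complex"):
            d = int(rng.integers(12, 60))
            left = exons_a[ev_idx]
            right = exons_a[ev_idx + 1]
            s_i, e_i = left.end, right.start  # the variant intron of isoform A
            exons_b = list(exons_a)
            # the variant boundary moves inward (isoform B's exon grows into
            # the intron); the donor is the intron's genomic start on '+'
            # and its genomic end on '−', the acceptor the opposite end
            shift_start = role == "complex" or (role == "Alt5") == (strand == "+")
            shift_end = role == "complex" or (role == "Alt3") == (strand == "+")
            if shift_start:
                exons_b[ev_idx] = Interval(chrom, left.start, left.end + d, strand)
            if shift_end:
                exons_b[ev_idx + 1] = Interval(chrom, right.start - d, right.end, strand)
            if role == "complex":
                region = (s_i, e_i)
            elif shift_start:
                region = (s_i, s_i + d)
            else:
                region = (e_i - d, e_i)
            ev_record = {"type": role, "region": region}
            isoforms.append(TranscriptModel(f"{gid}.2", gid, exons_b, source="synthetic"))
        elif role == "truncated":
            # second isoform starting inside exon 2: identical intron chain
            # within the overlap — differential initiation, no AS event
            e1 = exons_a[1]
            cut = e1.start + len(e1) // 2
            exons_b = [Interval(chrom, cut, e1.end, strand)] + exons_a[2:]
            isoforms.append(TranscriptModel(f"{gid}.2", gid, exons_b, source="synthetic"))

        isoforms = [
            TranscriptModel(t.id, gid, t.exons, cds=_default_cds(t), source="synthetic")
            for t in isoforms
        ]
        gene = GeneModel(gid, isoforms)
        genes.append(gene)

        for t in gene.transcripts:
            all_introns.update(intron_chain(t))

        if ev_record is not None:
            ev_record.update({"gene": gid, "chrom": chrom, "strand": strand})
            truth.events.append(ev_record)

        # planted intron-class sets (coordinates only)
        classes = {"ALL": set(), "ASI": set(), "IR": set()}
        for t in gene.transcripts:
            classes["ALL"].update((i.start, i.end) for i in intron_chain(t))
        if ev_record is not None:
            lo, hi = ev_record["region"]
            classes["ASI"] = {i for i in classes["ALL"] if i[0] < hi and lo < i[1]}
            if role == "IR":
                classes["IR"] = {ev_record["retained_intron"]}
                classes["ASI"] |= classes["IR"]
        truth.intron_classes[gid] = {k: sorted(v) for k, v in classes.items()}

    # write splice-site dinucleotides for every distinct intron
    p = np.asarray(splice_site_composition, dtype=float)
    p = p / p.sum()
    klasses = list(_SITE_DINUCS)
    for intron in sorted(all_introns, key=lambda i: (i.chrom, i.start, i.end, i.strand)):
        k = klasses[int(rng.choice(3, p=p))]
        donor, acceptor = _SITE_DINUCS[k]
        if intron.strand == "-":
            genome.write(intron.chrom, intron.end - 2, revcomp(donor))
            genome.write(intron.chrom, intron.start, revcomp(acceptor))
        else:
            genome.write(intron.chrom, intron.start, donor)
            genome.write(intron.chrom, intron.end - 2, acceptor)

    frozen = genome.freeze()
    counts = {"canonical_GT_AG": 0, "GC_AG": 0, "other": 0}
    for intron in all_introns:
        counts[classify_splice_site(intron, frozen)[2]] += 1
    truth.splice_site_counts = counts

    ann = AnnotationSet(genes, version="synthetic")
    return frozen, ann, truth


# ---------------------------------------------------------------------------
# junction evidence


def simulate_junction_evidence(
    ann: AnnotationSet,
    mean_coverage: float = 8.0,
    n_decoys_per_mode: int = 3,
    anchor: int = 25,
    seed: int = 0,
) -> tuple[list[tuple], SyntheticTruth]:
    """Junction table rows (chrom, start, end, strand, rep1, rep2) + truth.

    True introns receive Poisson coverage split over both replicates with a
    floor that guarantees acceptance; decoy junctions (shifted copies of
    real introns) are planted at coverages straddling every acceptance
    boundary: (3,0), (9,0), (2,1) rejected; (10,0), (2,2), (3,1) accepted.
    """
    rng = np.random.default_rng(seed)
    truth = SyntheticTruth(seed=seed, params={"mean_coverage": mean_coverage})
    introns = sorted(
        {
            (i.chrom, i.start, i.end, i.strand)
            for t in ann.transcripts()
            for i in intron_chain(t)
        }
    )
    rows = []
    for chrom, s, e, strand in introns:
        c1 = 2 + int(rng.poisson(mean_coverage / 2))
        c2 = 2 + int(rng.poisson(mean_coverage / 2))
        rows.append((chrom, s, e, strand, c1, c2))
        truth.junctions.append(
            {"intron": (chrom, s, e, strand), "counts": (c1, c2),
             "kind": "true", "expected_accept": True}
        )
    decoy_modes = [
        ((3, 0), False),
        ((9, 0), False),
        ((2, 1), False),
        ((1, 2), False),
        ((10, 0), True),
        ((2, 2), True),
        ((3, 1), True),
    ]
    if introns:
        real = set(introns)
        used = set(real)
        for m, (counts, expect) in enumerate(decoy_modes):
            for k in range(n_decoys_per_mode):
                chrom, s, e, strand = introns[(m * n_decoys_per_mode + k) % len(introns)]
                shift = 7 + 13 * m + k
                while (chrom, s + shift, e + shift, strand) in used:
                    shift += 1
                ds, de = s + shift, e + shift
                used.add((chrom, ds, de, strand))
                rows.append((chrom, ds, de, strand, counts[0], counts[1]))
                truth.junctions.append(
                    {"intron": (chrom, ds, de, strand), "counts": counts,
                     "kind": "decoy", "expected_accept": expect}
                )
    rows.sort()
    truth.params["anchor"] = anchor
    return rows, truth


# ---------------------------------------------------------------------------
# expression design


def simulate_expression_design(
    ann: AnnotationSet | None = None,
    n_genes: int = 200,
    tissues: tuple[str, ...] = ("leaf", "root", "berry"),
    genotypes: tuple[str, ...] = ("101.14", "M4"),
    conditions: tuple[str, ...] = ("ctrl", "stress"),
    switching_fraction: float = 0.30,
    base_log2_ratio: float = 3.3,
    tissue_ratio_amplitude: float = 1.5,
    genotype_ratio_amplitude: float = 0.6,
    tissue_expr_sd: float = 1.0,
    noise_sd: float = 0.15,
    base_log2_fpkm: float = 6.5,
    seed: int = 0,
):
    """Two-isoform FPKM design with tissue ≫ genotype isoform-ratio structure.

    Each gene's two isoforms share a baseline log2 ratio of ±3.3 (a ~10:1
    major isoform); tissue perturbs the ratio by up to ±1.5 log2 units and
    genotype by ±0.6, so the ratio's sign — hence the major isoform — never
    flips from those effects alone.  A ``switching_fraction`` of genes
    additionally reverses the ratio in one randomly chosen tissue (a genuine
    major-isoform switch).  Gene totals vary by tissue but not genotype.
    Returns (ExpressionTable, SyntheticTruth); genes come from ``ann`` (its
    two-isoform genes) or are synthesised when ``ann`` is None.
    """
    from .expression import ExpressionTable
    import pandas as pd

    rng = np.random.default_rng(seed)
    if ann is not None:
        pairs = [
            (g.id, sorted(t.id for t in g.transcripts)[:2])
            for g in ann
            if len(g.transcripts) >= 2
        ]
    else:
        pairs = [(f"G{i + 1:04d}", [f"G{i + 1:04d}.1", f"G{i + 1:04d}.2"]) for i in range(n_genes)]
    if len(pairs) < 2:
        raise ValueError("need at least two multi-isoform genes")

    samples = [
        (f"{t}_{g}_{c}", t, g, c) for t in tissues for g in genotypes for c in conditions
    ]
    meta = pd.DataFrame(
        [{"sample": s, "tissue": t, "genotype": g, "condition": c} for s, t, g, c in samples]
    ).set_index("sample")

    truth = SyntheticTruth(
        seed=seed,
        params={
            "switching_fraction": switching_fraction,
            "tissue_ratio_amplitude": tissue_ratio_amplitude,
            "genotype_ratio_amplitude": genotype_ratio_amplitude,
            "n_genes": len(pairs),
        },
    )
    records = []
    switch_flags = rng.random(len(pairs)) < switching_fraction
    truth.expression = {"major": {}, "switching_genes": [], "samples": [s for s, *_ in samples]}

    for gi, (gid, (iso1, iso2)) in enumerate(pairs):
        sign = 1.0 if rng.random() < 0.5 else -1.0
        r0 = sign * base_log2_ratio
        u = {t: float(rng.uniform(-1, 1)) * tissue_ratio_amplitude for t in tissues}
        w = float(rng.uniform(0.5, 1.0)) * genotype_ratio_amplitude
        texpr = {t: float(rng.normal(0.0, tissue_expr_sd)) for t in tissues}
        base = float(rng.normal(base_log2_fpkm, 0.8))
        switch_tissue = None
        if switch_flags[gi]:
            switch_tissue = tissues[int(rng.integers(0, len(tissues)))]
            truth.expression["switching_genes"].append(gid)

        for sample, tissue, genotype, cond in samples:
            r = r0 + u[tissue] + w * (1.0 if genotype == genotypes[0] else -1.0)
            if tissue == switch_tissue:
                r = -r
            total = 2.0 ** (base + texpr[tissue] + float(rng.normal(0, noise_sd)))
            v2 = total / (1.0 + 2.0 ** r)
            v1 = total - v2
            major = iso1 if v1 >= v2 else iso2
            truth.expression["major"][f"{gid}|{sample}"] = major
            for iso, v in ((iso1, v1), (iso2, v2)):
                for rep in (1, 2):
                    noisy = v * 2.0 ** float(rng.normal(0, noise_sd))
                    records.append(
                        {"isoform": iso, "gene": gid, "sample": sample,
                         "replicate": rep, "fpkm": round(noisy, 4)}
                    )

    frame = pd.DataFrame.from_records(records)
    return ExpressionTable(frame, meta), truth


# ---------------------------------------------------------------------------
# lncRNA candidates


def _stop_cassette_seq(rng: np.random.Generator, n: int) -> str:
    """Random sequence with stops in all frames every ~250 nt (no long ORF)."""
    alphabet = "ACGT"
    out = []
    produced = 0
    while produced < n:
        chunk = "".join(alphabet[i] for i in rng.integers(0, 4, size=240))
        out.append(chunk + _STOP_CASSETTE)
        produced += 240 + len(_STOP_CASSETTE)
    return "".join(out)[:n]


def _orf_seq(rng: np.random.Generator, n: int, orf_codons: int = 101) -> str:
    """Stop-free ORF of ``orf_codons`` codons embedded in cassette sequence."""
    safe_codons = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
                   if a + b + c not in ("TAA", "TAG", "TGA", "ATG")]
    body = "".join(
        safe_codons[int(i)] for i in rng.integers(0, len(safe_codons), size=orf_codons - 2)
    )
    orf = "ATG" + body + "TAA"
    pad = n - len(orf)
    left = _stop_cassette_seq(rng, pad // 2)
    right = _stop_cassette_seq(rng, pad - pad // 2)
    # keep the reading frame of the ORF intact regardless of pad length
    return (left + orf + right)[:n]


def _gaps(ann: AnnotationSet, genome: GenomeSequence, min_gap: int):
    """Gaps (chrom, lo, hi) strictly between consecutive gene spans.

    Chromosome-end gaps are excluded so that every gap is bounded by real
    genes on both sides, making nearest-gene distances well defined.
    """
    spans: dict[str, list[tuple[int, int]]] = {c: [] for c in genome.sequences}
    for g in ann:
        s = g.span
        spans[s.chrom].append((s.start, s.end))
    gaps = []
    for chrom, items in sorted(spans.items()):
        items.sort()
        for (s1, e1), (s2, e2) in zip(items, items[1:]):
            if s2 - e1 >= min_gap:
                gaps.append((chrom, e1, s2))
    return gaps


def simulate_lncrna_candidates(
    genome: GenomeSequence,
    ann: AnnotationSet,
    n_per_class: int = 6,
    n_decoys_per_mode: int = 2,
    seed: int = 0,
) -> tuple[list[TranscriptModel], dict, dict, SyntheticTruth]:
    """Plant clean u/i/x lncRNAs plus one decoy family per pipeline filter.

    Decoys sit one unit beyond their threshold: 199 nt candidates, intergenic
    fragments 999 nt from a gene, intronic fragments 99 nt from an exon or
    filling 31% of their host intron, antisense overlaps of 29% of an exon,
    101-codon-ORF candidates, repeat-overlapping and domain-flagged
    candidates, and candidates quantified at (1.2, 0.8) FPKM.  Candidate
    sequence is written into the genome (stop-rich, so the ORF heuristic
    calls clean candidates non-coding by construction).

    Returns (candidates, evidence, expression, truth); ``genome`` is
    modified in place.
    """
    rng = np.random.default_rng(seed)
    arrs = {c: bytearray(s.encode()) for c, s in genome.sequences.items()}

    def write(chrom, pos, s):
        arrs[chrom][pos : pos + len(s)] = s.encode()

    candidates: list[TranscriptModel] = []
    evidence = {"domain_flags": set(), "repeat_intervals": [], "coding_flags": {}}
    expression: dict[str, dict[str, tuple[float, float]]] = {}
    truth = SyntheticTruth(seed=seed, params={"n_per_class": n_per_class})

    gaps = _gaps(ann, genome, min_gap=2600)
    # large host introns planted by the genome simulator (last intron of
    # each gene, ~3 kb); take one transcript per gene
    hosts = []
    for g in sorted(ann, key=lambda g: g.id):
        t = g.transcripts[0]
        chain = intron_chain(t)
        if chain and len(chain[-1]) >= 2400:
            hosts.append((g.id, chain[-1]))
    # exons usable for antisense overlaps: terminal exons of single-isoform
    # genes, overlap extending beyond the gene span
    x_exons = []
    for g in sorted(ann, key=lambda g: g.id):
        if len(g.transcripts) != 1:
            continue
        t = g.transcripts[0]
        x_exons.append((g.id, t.exons[-1], t.strand, "right"))

    counter = [0]

    def new_id(prefix):
        counter[0] += 1
        return f"LNC{counter[0]:03d}_{prefix}"

    def add(cid, chrom, start, end, strand, seq_oriented, *, klass, status,
            fail="", fpkm=(2.0, 2.5), domain=False, repeat=False):
        g = seq_oriented if strand != "-" else revcomp(seq_oriented)
        write(chrom, start, g)
        t = TranscriptModel(cid, cid, [Interval(chrom, start, end, strand)], source="cuff")
        candidates.append(t)
        expression[cid] = {"leaf_101.14_ctrl": fpkm, "root_101.14_ctrl": (1.8, 2.2)}
        if fail == "expression":
            expression[cid] = {s: fpkm for s in expression[cid]}
        if domain:
            evidence["domain_flags"].add(cid)
        if repeat:
            evidence["repeat_intervals"].append(
                Interval(chrom, start + 10, start + 60, ".")
            )
        truth.lncrna.append(
            {"id": cid, "class": klass, "status": status, "first_fail": fail}
        )

    gap_i = [0]

    def take_gap(needed):
        while gap_i[0] < len(gaps):
            chrom, lo, hi = gaps[gap_i[0]]
            gap_i[0] += 1
            if hi - lo >= needed:
                return chrom, lo, hi
        raise ValueError("genome too small to place requested lncRNA candidates")

    # -- clean intergenic (u): 1.2 kb from both neighbours
    for k in range(n_per_class):
        L = 500
        chrom, lo, hi = take_gap(2 * 1201 + L)
        start = lo + 1201
        strand = "+" if k % 2 == 0 else "-"
        add(new_id("u"), chrom, start, start + L, strand,
            _stop_cassette_seq(rng, L), klass="u", status="accepted")

    # -- clean intronic (i): centred in a large host intron
    for k in range(n_per_class):
        if not hosts:
            raise ValueError("no host introns available")
        gid, intron = hosts.pop(0)
        L = min(400, int(0.3 * len(intron)) - 1)
        start = intron.start + (len(intron) - L) // 2
        strand = intron.strand
        add(new_id("i"), intron.chrom, start, start + L, strand,
            _stop_cassette_seq(rng, L), klass="i", status="accepted")

    # -- clean antisense (x): cover 60% of a terminal exon, extend outwards
    for k in range(n_per_class):
        if not x_exons:
            raise ValueError("no exons available for antisense candidates")
        gid, exon, gstrand, side = x_exons.pop(0)
        ov = max(200, int(0.6 * len(exon)))
        ov = min(ov, len(exon))
        L = max(300, ov + 100)
        start = exon.end - ov
        strand = "-" if gstrand == "+" else "+"
        add(new_id("x"), exon.chrom, start, start + L, strand,
            _stop_cassette_seq(rng, L), klass="x", status="accepted")

    # -- decoy families, one per filter, each one unit beyond its threshold
    for k in range(n_decoys_per_mode):
        # length: 199 nt (floor is 200)
        chrom, lo, hi = take_gap(2 * 1201 + 199)
        add(new_id("short"), chrom, lo + 1201, lo + 1400, "+",
            _stop_cassette_seq(rng, 199), klass="u", status="rejected", fail="length")

        # class code: same-strand exon overlap ('other')
        gid, exon, gstrand, side = x_exons.pop(0)
        ov = min(300, len(exon))
        L = ov + 200
        add(new_id("samestrand"), exon.chrom, exon.end - ov, exon.end - ov + L,
            gstrand, _stop_cassette_seq(rng, L), klass="other",
            status="rejected", fail="class_code")

        # coding potential: embedded 101-codon ORF
        chrom, lo, hi = take_gap(2 * 1201 + 600)
        add(new_id("orf"), chrom, lo + 1201, lo + 1801, "+",
            _orf_seq(rng, 600), klass="u", status="rejected", fail="coding_potential")

        # domain flag
        chrom, lo, hi = take_gap(2 * 1201 + 500)
        add(new_id("domain"), chrom, lo + 1201, lo + 1701, "+",
            _stop_cassette_seq(rng, 500), klass="u", status="rejected",
            fail="domain", domain=True)

        # repeat overlap
        chrom, lo, hi = take_gap(2 * 1201 + 500)
        add(new_id("repeat"), chrom, lo + 1201, lo + 1701, "+",
            _stop_cassette_seq(rng, 500), klass="u", status="rejected",
            fail="repeat", repeat=True)

        # context/u: 999 nt from the nearest gene (missing-UTR mimic)
        chrom, lo, hi = take_gap(999 + 400 + 1201)
        add(new_id("near"), chrom, lo + 999, lo + 999 + 400, "+",
            _stop_cassette_seq(rng, 400), klass="u", status="rejected", fail="context")

        # context/i: 99 nt from the flanking exon
        gid, intron = hosts.pop(0)
        L = 300
        start = intron.start + 99
        add(new_id("nearexon"), intron.chrom, start, start + L, intron.strand,
            _stop_cassette_seq(rng, L), klass="i", status="rejected", fail="context")

        # context/i: 31% of the host intron
        gid, intron = hosts.pop(0)
        L = int(0.31 * len(intron)) + 1
        start = intron.start + (len(intron) - L) // 2
        add(new_id("bigfrac"), intron.chrom, start, start + L, intron.strand,
            _stop_cassette_seq(rng, L), klass="i", status="rejected", fail="context")

        # context/x: 29% overlap of the exon
        gid, exon, gstrand, side = x_exons.pop(0)
        ov = max(2, int(0.29 * len(exon)))
        L = max(250, ov + 150)
        add(new_id("shallow"), exon.chrom, exon.end - ov, exon.end - ov + L,
            "-" if gstrand == "+" else "+", _stop_cassette_seq(rng, L),
            klass="x", status="rejected", fail="context")

        # expression: (1.2, 0.8) in every sample
        chrom, lo, hi = take_gap(2 * 1201 + 500)
        add(new_id("lowexp"), chrom, lo + 1201, lo + 1701, "+",
            _stop_cassette_seq(rng, 500), klass="u", status="rejected",
            fail="expression", fpkm=(1.2, 0.8))

    genome.sequences = {c: bytes(a).decode() for c, a in arrs.items()}
    return candidates, evidence, expression, truth


# ---------------------------------------------------------------------------
# miRNA target sites


def simulate_mirna_sites(
    ann: AnnotationSet,
    truth_events: list[dict],
    site_len: int = 21,
    seed: int = 0,
) -> tuple[list, SyntheticTruth]:
    """Plant target sites whose isoform-level fate is known by construction.

    Per planted IR event gene: a junction-spanning site on the splicing
    isoform, interrupted by the retained intron (loss: splicing, IR).  Per
    ES gene: a site inside the cassette exon (loss: splicing, no IR).  Per
    truncated-isoform gene: a site in exon 1 of the long isoform (loss:
    initiation/termination).  Single-isoform genes contribute nothing; a
    constitutive-exon control site is placed on every used gene.
    """
    from .mirna import TargetSite

    truth = SyntheticTruth(seed=seed)
    sites: list[TargetSite] = []
    idx = 0
    events_by_gene = {ev["gene"]: ev for ev in truth_events}

    from .core import map_genome_to_transcript

    for g in sorted(ann, key=lambda g: g.id):
        if len(g.transcripts) < 2:
            continue
        ev = events_by_gene.get(g.id)
        half = site_len // 2
        made = None
        if ev is not None and ev["type"] == "IR":
            carrier = g.transcripts[0]  # splicing isoform keeps the junction
            js, je = ev["retained_intron"]
            # transcript coordinate of the junction between the two exons
            jt = min(
                genome_pos_to_transcript(carrier, js - 1),
                genome_pos_to_transcript(carrier, je),
            )
            start = jt - half + 1  # spans the junction on both sides
            made = ("splicing", True, carrier, start)
        elif ev is not None and ev["type"] == "ES":
            carrier = g.transcripts[0]
            lo, hi = ev["region"]
            mid = (lo + hi) // 2
            iv = Interval(carrier.chrom, mid - half, mid - half + site_len, carrier.strand)
            rng_t = map_genome_to_transcript(carrier, iv)
            made = ("splicing", False, carrier, rng_t[0])
        elif ev is None:
            # truncated-isoform gene: site in the genomic first exon, which
            # the short isoform lacks regardless of strand
            carrier = g.transcripts[0]
            e0 = carrier.exons[0]
            iv = Interval(carrier.chrom, e0.start + 30, e0.start + 30 + site_len, carrier.strand)
            rng_t = map_genome_to_transcript(carrier, iv)
            made = ("initiation_or_termination", False, carrier, rng_t[0])
        if made is None:
            continue
        cause, ir_flag, carrier, start = made
        idx += 1
        site = TargetSite(f"miR{idx:03d}", carrier.id, start, start + site_len)
        sites.append(site)
        truth.mirna_sites.append(
            {"mirna": site.mirna, "gene": g.id, "carrier": carrier.id,
             "expected_cause": cause, "expected_ir": ir_flag}
        )
        # constitutive control site in the genomic last exon (shared by all
        # isoform constructions used here)
        last = carrier.exons[-1]
        mid = (last.start + last.end) // 2
        iv = Interval(carrier.chrom, mid - half, mid - half + site_len, carrier.strand)
        rng_t = map_genome_to_transcript(carrier, iv)
        idx += 1
        ctrl = TargetSite(f"miR{idx:03d}", carrier.id, rng_t[0], rng_t[0] + site_len)
        sites.append(ctrl)
        truth.mirna_sites.append(
            {"mirna": ctrl.mirna, "gene": g.id, "carrier": carrier.id,
             "expected_cause": "present_everywhere", "expected_ir": False}
        )
    return sites, truth


# ---------------------------------------------------------------------------
# random structures for oracle-equivalence suites


def random_gene(
    rng: np.random.Generator,
    gene_id: str = "G1",
    chrom: str = "chr1",
    max_isoforms: int = 4,
    max_exons: int = 6,
    span: int = 600,
) -> GeneModel:
    """A random multi-isoform gene for brute-force comparison suites.

    Each isoform draws a sorted set of distinct boundaries inside the span;
    consecutive boundary pairs become exons.  Structures are unconstrained
    (any mixture of shared and private splice sites), which is exactly what
    an event-caller stress test needs.
    """
    strand = "+" if rng.random() < 0.5 else "-"
    n_iso = int(rng.integers(2, max_isoforms + 1))
    isoforms = []
    for k in range(n_iso):
        n_ex = int(rng.integers(1, max_exons + 1))
        while True:
            cuts = np.sort(rng.choice(np.arange(0, span, 5), size=2 * n_ex, replace=False))
            lens = np.diff(cuts)
            if np.all(lens[::2] >= 5):  # exon pieces non-trivial
                break
        exons = [
            Interval(chrom, int(cuts[2 * i]), int(cuts[2 * i + 1]), strand)
            for i in range(n_ex)
        ]
        isoforms.append(TranscriptModel(f"{gene_id}.{k + 1}", gene_id, exons))
    return GeneModel(gene_id, isoforms)
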