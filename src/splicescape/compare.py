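"""Comparison of two annotation versions of the same genome.

Covers four evaluation tasks performed when a reannotation (B, "v2-like")
replaces an older gene set (A, "v1-like"):

* fusion/split detection — genes of one set overlapping ≥2 genes of the
  other — with best-hit adjudication against a reference proteome (a merged
  gene is vindicated when it shares one best hit with all its parts; the
  split genes win when they hit ≥2 distinct subjects; a missing hit makes
  the group ambiguous);
* intron evidence support: confirmation of introns by protein, EST and
  RNA-seq junction evidence, with ≥1/≥2/=3 source tier counts;
* alternative-CDS scoring: protein-level Needleman–Wunsch global alignment
  of both versions' products against the shared homolog, discarding pairs
  under 30% identity and keeping the higher-scoring version;
* new-gene acceptance filtering (miRNA-similarity and coding-potential
  exclusions, then homolog / domain / ≥50% RNA-seq coverage rescue).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .core import (
    AnnotationSet,
    GeneModel,
    Interval,
    PipelineThresholds,
    TranscriptModel,
)

__all__ = [
    "FusionSplitGroup",
    "EvidenceSupport",
    "BestHitTable",
    "detect_fusion_split",
    "adjudicate_group",
    "intron_evidence_support",
    "translate_cds",
    "global_protein_alignment",
    "evaluate_alternative_cds",
    "filter_new_genes",
]


@dataclass
class FusionSplitGroup:
    """One merged gene and the ≥2 genes it overlaps in the other annotation."""

    focal: str  # merged gene id
    partners: list[str]  # split gene ids in the other annotation
    direction: str  # 'fusion_in_B' (focal ∈ B) or 'split_in_B' (focal ∈ A)
    verdict: str = ""  # 'A_better' | 'B_better' | 'ambiguous'


@dataclass
class EvidenceSupport:
    intron: Interval
    supported_by: set[str] = field(default_factory=set)

    def __post_init__(self):
        bad = self.supported_by - {"protein", "EST", "RNAseq"}
        if bad:
            raise ValueError(f"unknown evidence sources: {bad}")


class BestHitTable:
    """query id → (subject id, score, identity); at most one hit per query."""

    def __init__(self, hits: dict[str, tuple[str, float, float]] | None = None):
        self.hits = dict(hits or {})

    def subject(self, query: str) -> str | None:
        entry = self.hits.get(query)
        return entry[0] if entry else None

    @classmethod
    def from_tsv(cls, path) -> "BestHitTable":
        hits = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#") or line.startswith("query\t"):
                    continue
                q, s, score, ident = line.split("\t")[:4]
                if q in hits:
                    raise ValueError(f"duplicate best-hit entry for {q}")
                hits[q] = (s, float(score), float(ident))
        return cls(hits)


def _exonic_tree(ann: AnnotationSet):
    """(chrom, strand) → sorted exon intervals with owning gene ids."""
    idx: dict[tuple[str, str], list[tuple[int, int, str]]] = {}
    for g in ann:
        for t in g.transcripts:
            for e in t.exons:
                idx.setdefault((e.chrom, e.strand), []).append((e.start, e.end, g.id))
    for v in idx.values():
        v.sort()
    return idx


def _overlapping_genes(gene: GeneModel, idx) -> set[str]:
    """Genes of the other annotation with same-strand exonic overlap ≥ 1 bp."""
    partners = set()
    items = idx.get((gene.chrom, gene.strand), [])
    for t in gene.transcripts:
        for e in t.exons:
            for s, eo, gid in items:
                if s >= e.end:
                    break
                if eo > e.start:
                    partners.add(gid)
    return partners


def detect_fusion_split(A: AnnotationSet, B: AnnotationSet) -> list[FusionSplitGroup]:
    """Genes of one annotation with exonic overlap to ≥2 genes of the other.

    A gene of B overlapping ≥2 genes of A is a fusion in B; a gene of A
    overlapping ≥2 genes of B means B split it.  Overlap is same-strand
    exonic overlap of at least 1 bp.
    """
    idx_a, idx_b = _exonic_tree(A), _exonic_tree(B)
    groups = []
    for g in sorted(B, key=lambda g: g.id):
        partners = _overlapping_genes(g, idx_a)
        if len(partners) >= 2:
            groups.append(
                FusionSplitGroup(g.id, sorted(partners), direction="fusion_in_B")
            )
    for g in sorted(A, key=lambda g: g.id):
        partners = _overlapping_genes(g, idx_b)
        if len(partners) >= 2:
            groups.append(
                FusionSplitGroup(g.id, sorted(partners), direction="split_in_B")
            )
    return groups


def adjudicate_group(grp: FusionSplitGroup, hits: BestHitTable) -> str:
    """Best-hit adjudication of a fusion/split group.

    The merged gene wins when it and all split parts share one best-hit
    subject; the split side wins when the parts hit ≥2 distinct subjects;
    any queried gene without a hit makes the group ambiguous.  The verdict
    names the annotation (A or B) judged better.
    """
    merged_hit = hits.subject(grp.focal)
    part_hits = [hits.subject(p) for p in grp.partners]
    merged_side = "B" if grp.direction == "fusion_in_B" else "A"
    split_side = "A" if merged_side == "B" else "B"
    if merged_hit is None or any(h is None for h in part_hits):
        verdict = "ambiguous"
    elif len(set(part_hits)) >= 2:
        verdict = f"{split_side}_better"
    elif set(part_hits) == {merged_hit}:
        verdict = f"{merged_side}_better"
    else:
        verdict = "ambiguous"
    grp.verdict = verdict
    return verdict


def intron_evidence_support(
    introns: list[Interval],
    protein: set | list,
    est: set | list,
    rnaseq: set | list,
) -> tuple[list[EvidenceSupport], dict[str, int]]:
    """Per-intron evidence support plus ≥1 / ≥2 / =3 source tier counts.

    Evidence sets contain confirmed introns; matching is exact on
    (chrom, start, end, strand).
    """

    def keyset(items):
        out = set()
        for i in items:
            out.add((i.chrom, i.start, i.end, i.strand) if isinstance(i, Interval) else tuple(i))
        return out

    sources = {"protein": keyset(protein), "EST": keyset(est), "RNAseq": keyset(rnaseq)}
    supports = []
    tiers = {"ge1": 0, "ge2": 0, "eq3": 0}
    for i in introns:
        key = (i.chrom, i.start, i.end, i.strand)
        by = {name for name, s in sources.items() if key in s}
        supports.append(EvidenceSupport(i, by))
        n = len(by)
        if n >= 1:
            tiers["ge1"] += 1
        if n >= 2:
            tiers["ge2"] += 1
        if n == 3:
            tiers["eq3"] += 1
    return supports, tiers


# ---------------------------------------------------------------------------
# alternative-CDS evaluation


def translate_cds(t: TranscriptModel, genome) -> str:
    """Protein product of a transcript's CDS.

    Raises ValueError when the CDS length is not a multiple of three or the
    product carries an internal stop (such models are flagged and excluded
    by the caller).
    """
    if not t.cds:
        raise ValueError(f"transcript {t.id} has no CDS")
    parts = [genome.fetch(c) for c in t.cds]
    nt = "".join(parts)
    if t.strand == "-":
        from .core import revcomp

        nt = revcomp(nt)
    if len(nt) % 3 != 0:
        raise ValueError(f"transcript {t.id}: CDS length {len(nt)} not divisible by 3")
    aa = str(Seq(nt).translate())
    if aa.endswith("*"):
        aa = aa[:-1]
    if "*" in aa:
        raise ValueError(f"transcript {t.id}: internal stop codon")
    return aa


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


def global_protein_alignment(x: str, y: str) -> tuple[float, float]:
    """Needleman–Wunsch global alignment score and percent identity.

    BLOSUM62 with affine gaps (open 10, extend 0.5, end gaps penalised);
    identity = matched positions / alignment length.
    """
    aligner = _aligner()
    aln = aligner.align(x, y)[0]
    counts = aln.counts()
    length = aln.length
    identity = counts.identities / length if length else 0.0
    return float(aln.score), identity


def evaluate_alternative_cds(
    model_a: GeneModel,
    model_b: GeneModel,
    ref_protein: str,
    genome,
    th: PipelineThresholds | None = None,
) -> dict:
    """Score two gene models' products against their shared homolog.

    For each model every translatable isoform is aligned and the best score
    kept; pairs whose best identities both fall below the identity floor are
    discarded.  Returns a record with per-model best scores, identities,
    flagged (untranslatable) isoforms and the verdict
    ('A_better' | 'B_better' | 'tie' | 'discarded').
    """
    th = th or PipelineThresholds()

    def best(model: GeneModel):
        best_score, best_ident, flagged = None, None, []
        for t in model.transcripts:
            if not t.cds:
                continue
            try:
                aa = translate_cds(t, genome)
            except ValueError as exc:
                flagged.append((t.id, str(exc)))
                continue
            score, ident = global_protein_alignment(aa, ref_protein)
            if best_score is None or score > best_score:
                best_score, best_ident = score, ident
        return best_score, best_ident, flagged

    score_a, ident_a, flagged_a = best(model_a)
    score_b, ident_b, flagged_b = best(model_b)
    record = {
        "gene_a": model_a.id,
        "gene_b": model_b.id,
        "score_a": score_a,
        "score_b": score_b,
        "identity_a": ident_a,
        "identity_b": ident_b,
        "flagged": flagged_a + flagged_b,
    }
    ok_a = score_a is not None and ident_a >= th.min_cds_identity
    ok_b = score_b is not None and ident_b >= th.min_cds_identity
    if not ok_a and not ok_b:
        record["verdict"] = "discarded"
    elif ok_a and not ok_b:
        record["verdict"] = "A_better"
    elif ok_b and not ok_a:
        record["verdict"] = "B_better"
    elif score_a > score_b:
        record["verdict"] = "A_better"
    elif score_b > score_a:
        record["verdict"] = "B_better"
    else:
        record["verdict"] = "tie"
    return record


def filter_new_genes(
    candidates: list[str],
    evidence: dict[str, dict],
    th: PipelineThresholds | None = None,
) -> list[str]:
    """Acceptance filter for newly predicted genes.

    ``evidence`` maps gene id → {mirna_similar, noncoding, homolog, domain:
    bool; coverage: float in [0,1]}; a missing gene or key counts as
    negative evidence.  A candidate is accepted iff it is neither
    miRNA-similar nor flagged non-coding, and has a homolog, a predicted
    domain, or RNA-seq coverage of at least half the gene model.
    """
    th = th or PipelineThresholds()
    accepted = []
    for gid in candidates:
        ev = evidence.get(gid, {})
        cov = float(ev.get("coverage", 0.0))
        if not (0.0 <= cov <= 1.0):
            raise ValueError(f"{gid}: coverage {cov} outside [0, 1]")
        if ev.get("mirna_similar", False) or ev.get("noncoding", False):
            continue
        if (
            ev.get("homolog", False)
            or ev.get("domain", False)
            or cov >= th.new_gene_min_coverage_frac
        ):
            accepted.append(gid)
    return accepted
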