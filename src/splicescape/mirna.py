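"""Projection of miRNA target sites across a gene's isoforms.

Target-site predictions arrive in transcript coordinates on a named carrier
isoform.  Each site is lifted to its genomic footprint (possibly split over
a splice junction) and tested on every other isoform of the gene: the site
survives only where all footprint bases are exonic and consecutive in the
mature transcript.  Sites lost from an isoform are classified by cause —
differential initiation/termination when the footprint falls outside the
isoform's genomic span, splicing otherwise — with the region of the site on
the carrier and an intron-retention involvement flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core import (
    GeneModel,
    Interval,
    TranscriptModel,
    label_transcript_position,
    map_genome_to_transcript,
    map_transcript_to_genome,
)
from .events import SpliceEvent

__all__ = ["TargetSite", "project_site", "classify_site_loss", "read_sites_tsv"]


@dataclass
class TargetSite:
    mirna: str
    carrier_id: str
    start: int  # transcript coordinates on the carrier, half-open
    end: int
    footprint: list[Interval] = field(default_factory=list)
    region_label: str = ""

    def resolve(self, carrier: TranscriptModel) -> None:
        self.footprint = map_transcript_to_genome(carrier, self.start, self.end)
        if carrier.cds:
            self.region_label = label_transcript_position(carrier, self.start)


def _carrier(site: TargetSite, gene: GeneModel) -> TranscriptModel:
    for t in gene.transcripts:
        if t.id == site.carrier_id:
            return t
    raise ValueError(f"carrier {site.carrier_id} not an isoform of gene {gene.id}")


def project_site(site: TargetSite, gene: GeneModel) -> dict[str, bool]:
    """Presence of a site in each isoform of the carrier's gene.

    Present iff every genomic footprint base is exonic in the isoform and
    the bases are contiguous in its mature sequence (junction-spanning
    sites require the two flanks to be adjacent exons).
    """
    carrier = _carrier(site, gene)
    if not site.footprint:
        site.resolve(carrier)
    presence = {}
    for t in gene.transcripts:
        if t.id == carrier.id:
            presence[t.id] = True
            continue
        ok = True
        mapped = []
        for piece in site.footprint:
            rng = map_genome_to_transcript(t, piece)
            if rng is None:
                ok = False
                break
            mapped.append(rng)
        if ok and len(mapped) > 1:
            # the pieces themselves must be consecutive in t's mature RNA
            order = sorted(mapped)
            ok = all(a[1] == b[0] for a, b in zip(order, order[1:]))
        # a retained intron *inside* the hull also breaks contiguity even
        # when every piece maps — the pieces then map non-adjacently, which
        # the check above catches; single-piece sites map contiguously by
        # construction of map_genome_to_transcript
        presence[t.id] = ok
    return presence


def classify_site_loss(
    site: TargetSite,
    gene: GeneModel,
    events: list[SpliceEvent],
    presence: dict[str, bool] | None = None,
) -> list[dict]:
    """Why a site is absent from particular isoforms.

    One record per absent isoform: cause 'initiation_or_termination' when
    the genomic footprint is not fully inside the isoform's span (takes
    precedence), else 'splicing'; region from the carrier; IR_involved when
    a retained intron of an IR event overlaps the footprint hull.
    """
    carrier = _carrier(site, gene)
    if not site.footprint:
        site.resolve(carrier)
    if presence is None:
        presence = project_site(site, gene)
    absent = [tid for tid, ok in sorted(presence.items()) if not ok]
    if not absent:
        raise ValueError(
            f"site {site.mirna}@{site.carrier_id}: present in all isoforms"
        )
    hull_start = site.footprint[0].start
    hull_end = site.footprint[-1].end
    ir_hit = any(
        ev.event_type == "IR"
        and ev.retained_intron
        and ev.retained_intron[0] < hull_end
        and hull_start < ev.retained_intron[1]
        for ev in events
    )
    records = []
    for tid in absent:
        t = gene.transcript(tid)
        outside = hull_start < t.start or hull_end > t.end
        cause = "initiation_or_termination" if outside else "splicing"
        records.append(
            {
                "gene": gene.id,
                "mirna": site.mirna,
                "isoform": tid,
                "cause": cause,
                "region": site.region_label,
                "IR_involved": bool(ir_hit) if cause == "splicing" else False,
            }
        )
    return records


def read_sites_tsv(path) -> list[TargetSite]:
    """Sites TSV: mirna, transcript, start, end (transcript coordinates)."""
    sites = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("mirna\t"):
                continue
            mirna, tid, start, end = line.split("\t")[:4]
            sites.append(TargetSite(mirna, tid, int(start), int(end)))
    return sites
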