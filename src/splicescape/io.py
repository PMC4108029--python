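"""Annotation and sequence I/O.

GFF3 and GTF are 1-based inclusive on disk; everything in memory is 0-based
half-open.  The conversion happens here and nowhere else: for any feature,
``gff_end - gff_start + 1`` equals the in-memory interval length.

GFF3 is read and written (gene/mRNA/exon/CDS features, ID/Parent links);
GTF is read-only (transcript_id/gene_id attributes).  FASTA goes through
Biopython.
"""

from __future__ import annotations

import urllib.parse
from collections import OrderedDict

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import AnnotationSet, GeneModel, GenomeSequence, Interval, TranscriptModel

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "read_gtf",
    "read_tsv",
    "write_tsv",
]


def read_fasta(path) -> GenomeSequence:
    return GenomeSequence(
        {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    )


def write_fasta(genome: GenomeSequence, path, width: int = 80) -> None:
    records = [
        SeqRecord(Seq(seq), id=chrom, description="")
        for chrom, seq in genome.sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def _iter_features(path):
    """Yield (chrom, source, type, start0, end, strand, attrs) via gffutils."""
    # gffutils sniffs the GFF3/GTF dialect from the first lines
    for f in gffutils.iterators.DataIterator(str(path)):
        attrs = {k: ",".join(v) for k, v in f.attributes.items()}
        yield (f.seqid, f.source, f.featuretype, f.start - 1, f.end, f.strand, attrs)


def _assemble(features, transcript_types, version: str) -> AnnotationSet:
    """Build an AnnotationSet from (tid → gene/exons/cds/source) groups."""
    tx_meta: dict[str, dict] = OrderedDict()

    def meta(tid):
        return tx_meta.setdefault(
            tid, {"gene": None, "exons": [], "cds": [], "source": ""}
        )

    for chrom, source, ftype, start, end, strand, attrs in features:
        if ftype in transcript_types:
            tid = attrs.get("ID") or attrs.get("transcript_id")
            if tid is None:
                raise ValueError(f"{ftype} feature without ID/transcript_id")
            m = meta(tid)
            m["gene"] = attrs.get("Parent") or attrs.get("gene_id") or tid
            m["source"] = source
        elif ftype in ("exon", "CDS"):
            parents = attrs.get("Parent") or attrs.get("transcript_id")
            if parents is None:
                raise ValueError(f"{ftype} feature without Parent/transcript_id")
            for tid in parents.split(","):
                m = meta(tid)
                iv = Interval(chrom, start, end, strand)
                (m["exons"] if ftype == "exon" else m["cds"]).append(iv)
                if not m["source"]:
                    m["source"] = source
                if m["gene"] is None and "gene_id" in attrs:
                    m["gene"] = attrs["gene_id"]
        # gene and UTR features carry no information we do not rebuild

    genes: dict[str, list[TranscriptModel]] = OrderedDict()
    for tid, m in tx_meta.items():
        if not m["exons"]:
            continue
        gid = m["gene"] or tid
        t = TranscriptModel(
            id=tid,
            gene_id=gid,
            exons=m["exons"],
            cds=m["cds"] or None,
            source=m["source"],
        )
        genes.setdefault(gid, []).append(t)
    return AnnotationSet(
        [GeneModel(gid, txs) for gid, txs in genes.items()], version=version
    )


_GFF3_TX_TYPES = {"mRNA", "transcript", "lnc_RNA", "ncRNA"}


def read_gff3(path, version: str = "") -> AnnotationSet:
    return _assemble(_iter_features(path), _GFF3_TX_TYPES, version)


def read_gtf(path, version: str = "") -> AnnotationSet:
    return _assemble(_iter_features(path), {"transcript"}, version)


def _fmt_attrs(**kv) -> str:
    return ";".join(f"{k}={urllib.parse.quote(str(v), safe=' ,:')}" for k, v in kv.items() if v != "")


def write_gff3(ann: AnnotationSet, path, extra_transcript_attrs=None) -> None:
    """Write gene/mRNA/exon/CDS features, 1-based inclusive, diff-stable order.

    ``extra_transcript_attrs`` maps transcript id → dict of extra attributes
    (used e.g. for consensus support and lncRNA class annotations).
    """
    extra_transcript_attrs = extra_transcript_attrs or {}
    lines = ["##gff-version 3"]
    genes = sorted(ann, key=lambda g: (g.chrom, g.span.start, g.id))
    for g in genes:
        s = g.span
        src = g.transcripts[0].source or "splicescape"
        lines.append(
            "\t".join(
                [s.chrom, src, "gene", str(s.start + 1), str(s.end), ".", g.strand, ".",
                 _fmt_attrs(ID=g.id)]
            )
        )
        for t in sorted(g.transcripts, key=lambda t: t.id):
            attrs = {"ID": t.id, "Parent": g.id}
            attrs.update(extra_transcript_attrs.get(t.id, {}))
            lines.append(
                "\t".join(
                    [t.chrom, t.source or "splicescape", "mRNA",
                     str(t.start + 1), str(t.end), ".", t.strand, ".",
                     _fmt_attrs(**attrs)]
                )
            )
            for e in t.exons:
                lines.append(
                    "\t".join(
                        [e.chrom, t.source or "splicescape", "exon",
                         str(e.start + 1), str(e.end), ".", e.strand, ".",
                         _fmt_attrs(Parent=t.id)]
                    )
                )
            for c in t.cds or []:
                lines.append(
                    "\t".join(
                        [c.chrom, t.source or "splicescape", "CDS",
                         str(c.start + 1), str(c.end), ".", c.strand, "0",
                         _fmt_attrs(Parent=t.id)]
                    )
                )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_tsv(path) -> tuple[list[str], list[list[str]]]:
    """Read a header + rows TSV, skipping '#' comment lines."""
    header, rows = None, []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
            else:
                rows.append(fields)
    if header is None:
        raise ValueError(f"{path}: empty table")
    return header, rows


def write_tsv(path, header: list[str], rows) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
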