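# Methods

This note records the models, conventions, defaults and design choices
behind `splicescape`, and what the synthetic-data generator does and does
not emulate.

## Coordinates and containers

All in-memory intervals are 0-based half-open; GFF3/GTF on disk are 1-based
inclusive, converted only in `splicescape.io`. Exons arriving unsorted are
sorted on load; overlapping exons within one transcript are an input error,
never silently merged. Genome access is case-insensitive and soft-masking
is ignored (repeats enter as a separate evidence table). Strand "." is
tolerated only for lncRNA candidates before classification; all AS analysis
requires an explicit strand.

`map_genome_to_transcript` projects a genomic interval into mature-RNA
coordinates iff every base is exonic and the bases are consecutive in the
mature transcript; an interval containing intronic bases has no image.
Junction-spanning features (miRNA sites) are therefore carried as
piecewise footprints — a list of per-exon genomic intervals — and mapped
piece by piece with an adjacency check, which is exactly how presence of a
site across isoforms is decided.

## Junction filters

The per-read rule (all anchors ≥ `min_anchor` = 15 nt, total alignment ≥
`min_aligned` = 40 nt) and the replicate rule (both replicates, sum ≥ 4; or
one replicate, ≥ 10) are implemented literally. Two points the source
material leaves open were fixed as follows: read counts are tallied *after*
the per-read filter, and for reads spanning more than two exons each gap is
supported only when *both* flanking anchors reach 15 nt — a symmetric,
slightly stricter reading of "overlap length on one exon". Junction strand
comes from the read's strand flag (directional libraries).

## Consensus

Structural identity for multiexonic models is intron-chain equality — an
equivalence relation, so groups are well defined. Monoexonic models have no
intron chain; reciprocal overlap ≥ 50% of each model was chosen, with
single-linkage grouping (the relation is not transitive; the audit is in
the group membership). The representative takes the structure of the
lexicographically first program and extends its terminal exons to the
group's extremes, maximising UTR capture. The length rule keeps models of
exactly 150 nt (the cutoff is "shorter than 150 is removed").

## Alternative-splicing events

Events are defined pairwise between isoforms, restricted to their genomic
overlap: differences confined to transcript start/end positions are
differential initiation/termination, not splicing, and yield no event.
Within the overlap, maximal runs of exon/intron disagreement are merged
into one event unless a splice site shared by both isoforms (same
coordinate, same orientation) separates them; the variable region is the
hull of the merged runs, flanked by the nearest shared sites or overlap
edges. Classification reads the splice sites each isoform places between
the flanks:

| pattern (one isoform / other) | class |
|---|---|
| `D,A` exactly spanning the region / none (exonic across) | IR |
| alternating `A,D,…` complete exon(s) / none (intronic across) | ES |
| one `D` each at different coordinates | Alt5 (+) / Alt3 (−) |
| one `A` each at different coordinates | Alt3 (+) / Alt5 (−) |
| anything else | complex |

Donor/acceptor are read in transcript orientation, so the same forward-
coordinate difference flips Alt5↔Alt3 on the minus strand. Multi-intron
retentions and coupled donor+acceptor shifts are complex by construction.
The same semantics are enforced in the test suite by an independent
per-base brute-force oracle on randomized isoform structures.

Gene-level event counts deduplicate on (flanking coordinates, unordered
structure pair), so a variable region shared by several isoform pairs
counts once per gene; pairwise counts remain available. Event localization
uses the participating CDS-bearing isoform with the longest CDS; when that
isoform has no exonic base inside the region (IR seen from the splicing
isoform), the labels of the nearest exonic bases on both sides are used.
"Alternative start/stop" is reported both on CDS start/stop codon positions
and on transcript start/end positions, labelled separately, because the two
readings differ and both are in circulation.

## lncRNA cascade

Filter order is fixed: length → class code → coding potential → domain →
repeat → genomic context → expression. The audit records every filter up to
and including the first failure, so funnel counts are reconstructible and
disabling the failing filter provably admits the candidate to the next one.
Conventions where the source prose is ambiguous: the 1-kb intergenic rule
is measured span-to-span and strand-ignorant; intronic distances are to the
flanking exons of the host transcript whose intron contains the candidate
(smallest containing intron); the antisense overlap fraction is relative to
the overlapped exon's length (the candidate-length alternative is one
config switch away); unstranded candidates can be u or i but never x. The
built-in coding-potential call is deliberately simple — longest forward-
frame ATG→stop ORF, coding iff ≥ 100 codons (stop included) — and is
overridden per candidate by external coding flags when a dedicated tool's
output is available. Expression requires ≥ 1 FPKM in both replicates of at
least one sample.

## Isoform expression

Detection demands both replicates ≥ 1 FPKM (FPKM below ~1 is where
quantification noise dominates); the working value is the replicate mean,
and gene expression is the sum of detected isoform values. Major-isoform
ties break lexicographically. The switching matrix designates per gene the
two isoforms detected in the most samples (ties: higher summed FPKM, then
id, and the first-designated isoform is the ratio's numerator); undetected
partners are floored at the detection threshold before the log2 ratio so
the matrix is complete — the floor value is the detection limit itself,
which bounds rather than invents a ratio. PCA is centered but not scaled
(log-ratio units are comparable across genes) with an SVD whose component
signs are fixed deterministically. Differential testing uses Welch's
t-test (no equal-variance assumption) and Benjamini–Hochberg adjustment at
q ≤ 0.05; features with zero variance in both groups get p = 1 and a flag.

## Annotation comparison

Fusion/split overlap means same-strand exonic overlap ≥ 1 bp (configurable).
Adjudication favours the merged gene when it and all parts share one
best-hit subject, the split genes when the parts hit ≥ 2 subjects, and
returns "ambiguous" whenever a queried gene has no hit; top-1 best hits are
compared. Protein comparison is global Needleman–Wunsch via BLOSUM62 with
affine gaps (open 10, extend 0.5, end gaps penalised); identity is matches
over alignment length, and an alignment under 30% identity is discarded —
when only one side survives the floor, that side wins. CDSs that do not
translate (length not divisible by three, internal stop) are flagged and
excluded rather than guessed at.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *study conditions* the pipeline was built for:

* a 20-chromosome, 100-kb-per-chromosome genome carrying ~200 genes of 4–6
  exons, every intron boundary written explicitly with a 97.5 / 1 / 1.5 %
  GT-AG / GC-AG / other splice-site mix;
* exactly one planted AS event per designated gene, constructed so the
  event caller's recovery can be checked coordinate-exactly: IR genes draw
  the retained intron from a short distribution (median 123 nt) and other
  AS genes from a long one (median 702 nt), mirroring the empirical
  contrast between retained and non-retained AS introns; some genes carry a
  5′-truncated second isoform (differential initiation, no event);
* junction tables with Poisson coverage over two replicates plus decoys at
  coverages (3,0), (9,0), (2,1), (1,2), (10,0), (2,2), (3,1) straddling
  every acceptance boundary;
* a 3-tissue × 2-genotype × 2-condition design with two replicates per
  sample: each gene has a ±3.3 log2 baseline isoform ratio (a ~10:1 major
  isoform), tissue perturbs the ratio by up to ±1.5 log2 units, genotype by
  up to ±0.6, and a planted fraction of genes (default 30%) genuinely
  switches its major isoform in one tissue — so tissue spans two principal
  components, genotype the third, and gene totals vary by tissue only;
* lncRNA candidates of all three classes plus one decoy family per filter,
  each placed one unit beyond its threshold (199 nt; 999 nt from a gene;
  99 nt from an exon; 31% of the host intron; 29% exon overlap; a
  101-codon ORF; repeat-overlapping; domain-flagged; FPKM (1.2, 0.8)),
  with candidate sequence written stop-rich so clean candidates are
  non-coding *by construction*;
* miRNA sites whose isoform-level fate is known: junction-spanning sites
  broken by retained introns, cassette-exon sites lost by skipping,
  5′-exon sites lost by truncation, and constitutive controls.

It does **not** emulate read-level sequence (no FASTQ, no error model, no
colorspace), expression-dependent assembly artefacts, overlapping gene
loci, trans-splicing, or genome-scale repeat structure. Default gene
structures are compact (exons 140–260 nt, constitutive introns capped at
600 nt, one ~2.5–3 kb host intron per gene) so that genes, their decoys
and the intergenic placements all fit 100-kb chromosomes; planted events
sit inside the CDS by default. Passing tests therefore demonstrate
correctness of the *decision rules* under controlled conditions, not
robustness to alignment noise or assembler idiosyncrasies — on real data
the junction and consensus stages inherit whatever errors the upstream
aligner and assemblers make.

All randomness flows through `numpy.random.default_rng(seed)`; a fixed
seed reproduces every output byte for byte, and problem sizes throughout
the suite (≤ 200 genes, 500 random oracle genes, 500-gene expression
designs, 1000-feature null panels) keep a full run in the tens of seconds
on one CPU.

## Known limitations

* The event taxonomy is pairwise-derived; genes with many isoforms can in
  principle contain nested variable regions that a full splicing-graph
  bubble decomposition would subdivide differently — deduplication on
  (flanks, structure pair) keeps counts stable but is one of several
  defensible granularities.
* The ORF heuristic is a stand-in for dedicated coding-potential tools and
  ignores codon usage, conservation and peptide features; its 100-codon
  cutoff is conventional.
* `evaluate_alternative_cds` compares best isoforms only; it does not
  attempt codon-aware alignment or frame recovery for broken models.
* Monoexonic consensus grouping by single-linkage can chain distant models
  through intermediates; with the 50% reciprocal rule this is rare but not
  impossible.
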