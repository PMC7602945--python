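# Methods

## Problem setting

Conifer genomes are tens of gigabases, mostly TE-derived, with highly
diverged repeat families, scaffolds truncated at repeat loci, and
extensive N-masking. Under those conditions full-length TE matching
undercounts insertions; short TE-derived repeats — direct-repeat
fragments, chiefly LTR candidates — are more robust queries. The package
implements the resulting analysis chain: build the repeat query library,
extract gene-anchored regions, search, test distance-binned enrichment,
group genes into TE-associated networks with GO statistics, type intron
insertion patterns, and sanity-check element structure.

## Synthetic data: what it emulates, and what it does not

The simulator is first-class, tested code; every downstream stage is
validated against genomes it generates because the planted truth is exact.

Emulated features:

* gene models with 2–4 exons, configurable exon (default 150–400 bp) and
  intron (default 800–3,000 bp) length ranges, both strands, one
  transcript per gene (spliced exon chain);
* intergenic background at 38% GC (the gymnosperm genome-wide average)
  and GC-richer transcripts (default 44%), generated with exact base
  composition so even short segments track their target;
* LTR retrotransposons with two identical LTR copies starting TG and
  ending CA, a polypurine tract (AAGAGGGAG) immediately 5′ of the 3′
  LTR, and optional IUPAC motifs placed in LTR or internal regions;
* MITEs/DNA transposons with exact terminal inverted repeats;
* insertion mechanics: target-site duplication of configurable length,
  strand choice, and degradation classes — full length, solo LTR (one
  LTR copy, no internal sequence), internal-only, and random 30–70%
  truncation;
* substitution divergence (0–30%), contiguous-run N-masking, and nested
  insertion of one element into another's internal region.

Insertions are planted sequentially; coordinates of features already on
the scaffold shift rightward and the truth table stores final
coordinates, so truth is directly comparable to pipeline output.
Divergence is substitution-only by default to keep truth coordinates
exact; indel polymorphism, known to be abundant in real conifer TEs, is
therefore *not* emulated, and passing tests say nothing about gapped
alignment sensitivity. Nor does the simulator attempt realistic repeat
landscapes at Gbp scale, nesting depth beyond one level, or transposition
dynamics; positions within a target region are uniform with a safety
margin, avoiding previously planted loci.

## Repeat library

Direct-repeat pairs are found by self-alignment of each entry (plus
strand, off-diagonal), keeping maximal same-orientation pairs with
non-overlapping copies, each ≥ 100 bp at ≥ 80% pair identity; the 5′ copy
is the emitted sequence. Entries with no internal direct repeat (MITEs)
are kept whole so short elements stay searchable. Tandem-like pairs whose
copies overlap are excluded.

Clustering is greedy and length-sorted (ties lexicographic by id): each
sequence joins the first representative at ≥ 80% global identity, else
founds a cluster. Identity is matches / alignment columns of a global
alignment of the shorter sequence onto the longer (computed with edlib's
infix mode), the CD-Hit-like definition. The final 0.1–2 kb length band
uses inclusive bounds; the reduction report carries counts and the
percent reduction to one decimal.

## Similarity search

The built-in engine indexes subject k-mers (default k = 11, N-free),
collects seeded diagonals, and reports every maximal positive-scoring
ungapped segment (Ruzzo–Tompa decomposition) with score ≥ 16 under
match +1 / mismatch −2; N never counts as a match. Identity is computed
per HSP; query coverage per HSP uses the full query length as
denominator. E-values follow the Karlin–Altschul formula with the
published ungapped nucleotide constants for +1/−2 (λ = 1.33, K = 0.621),
both configurable. Because the simulator is substitution-only, ungapped
segments are the exact local alignments for synthetic data; tests verify
best-hit identity within one percentage point of a full Smith–Waterman
oracle and ≥ 99% recovery of planted insertions at ≤ 10% divergence.

Raw-hit filters are inclusive (≥) — identity 80, length 100 bp, qcov 90
(the `pila` species profile lowers qcov to 80) — while the high-quality
rule for network formation is strict (>): length > 1 kb and identity
> 80, MITE queries > 200 bp, e-value < 0.01. Both boundary conventions
are deliberate and tested.

External hit tables in 12/13-column BLAST tabular format can replace the
built-in engine; minus-strand rows (descending coordinates) are
normalised to ascending intervals, and a missing qcovhsp column is
recomputed from the query-length table.

## Gene regions

GFF3 (1-based inclusive) is converted to 0-based half-open coordinates at
the boundary; single-exon genes are dropped for the intron analyses.
Flanks are oriented by gene strand (5′ = upstream of the transcription
start) — biologically meaningful and symmetric under
genome reverse-complementation. Each 5-kb flank is cut into five 1-kb
bins indexed by distance (bin 0 adjacent to the gene); bins clipped by a
scaffold end keep their shorter remainder with a truncated flag. No
exclusivity rule is applied when flank bins overlap neighbouring genes.

Coordinate verification re-places each annotated transcript on the
genome: exons are placed individually (full exon coverage at ≥ 98%
identity) and chained colinearly on one scaffold; the chain must cover
100% of the transcript. Identical placements collapse; of repeated
partial structures the most complete chain is kept; genes spanning
> 20 kb are flagged, not removed. This exon-chaining placement is the
package's design for spliced placement with a local aligner.

The TE-like gene screen removes a gene iff hits to a single library entry
at identity strictly > 80% cover strictly > 50% of the transcript; hits
shorter than 100 bp are ignored as coverage evidence (they are below the
pipeline's own minimum alignment length and would otherwise let chance
micro-matches tip a gene over the boundary).

## Enrichment statistic

Per repeat query, unique gene hits (HSP multiplicity collapsed) are
counted in each of the ten bins. The default proximal/distal grouping is
{5′ bin 0, 3′ bin 0} versus the remaining eight bins, giving
df = 2 + 8 − 2 = 8, consistent with the printed critical values
(t > 5.04 at p = 0.001, t > 2.31 at p = 0.05, both two-tailed); the
"literal" 0–1 kb versus 2–5 kb grouping (df = 6) is available by
configuration, since the stated df and the stated bin comparison cannot
both hold for a two-sample equal-variance test. Counts enter the test by
default; ratio normalisation by extracted-region counts is optional, as
is a Bonferroni correction across queries (off by default). Degenerate
pooled variance yields t = 0 when means agree and a signed-infinity
sentinel when they differ. Calibration at the defaults: false-positive
rate ≤ 7% at the nominal 5% level over 100 null replicates, and ≥ 90%
power at the strong level for a 5× proximal bias over ≥ 50 genes.

## Networks and GO

Network membership keys are (family, location class) with location
classes 5′ flank 0–2 kb, 3′ flank 0–2 kb, and intron; "0–2 kb" is
resolved at bin granularity (bins 0 and 1). A gene joins once per network
regardless of supporting-hit multiplicity. Unannotated genes remain
members but are excluded from GO testing; the background is all annotated
genes. The per-term p-value is the exact hypergeometric upper tail
P(X ≥ k), computed by integer summation (verified against exhaustive
enumeration for N ≤ 12 and scipy's survival function elsewhere).
Bonferroni m defaults to the number of terms tested in the given network,
matching the propagate-then-test behaviour of the classic GO tools; m =
all annotated terms is selectable. Annotations are propagated to all
ancestors along is_a/part_of edges before testing (obonet/networkx).
Exports are GraphML, SIF, and TSV edge lists with deterministic node
order — a text replacement for interactive network visualisation.

## Patterns, node genes, GC

Intron signatures are presence/absence sets over two alphabets kept
separate — short TE-derived repeats and long (>1 kb) hits — ignoring
copy number and intron position; the signature string is canonical
(sorted) so input order never matters. Pattern classes are exact
signature-equality groups labelled by lexicographic rank (published
letter labels are arbitrary and unreproducible). Node genes carry
strictly more than `min_distinct` (default 8) distinct repeats, counting
the union of both alphabets — the union choice is this package's
decision where the original counting rule was unstated. GC percentages
exclude N from numerator and denominator (masked TE parts would
otherwise bias intron GC), returning a None sentinel for all-N input.

## Structural QC

`split_ltr_internal` uses the entry's terminal direct-repeat pair;
`solo_ratio` counts LTR-query versus internal-query hits at an identity
preset (0.80 or 0.90): a purely full-length population gives exactly 2.0
(two LTR copies, one internal region per element), and excess LTR hits
indicate solo-LTR formation. Hits, not loci, are counted. Locus
classification requires an LTR–internal–LTR same-strand chain within
1.5× the family length for a FULL_LENGTH call (the adjacency span is
this package's choice); an isolated LTR is SOLO_LTR, internal-only
evidence INTERNAL_ONLY, anything else TRUNCATED — a fully masked
internal region can therefore never produce a FULL_LENGTH call. TIR
detection maximises an alignment score (+1/−2) over lengths with ≥ 90%
prefix/revcomp-suffix identity so exact TIRs report their exact length;
TSD detection takes the longest exact flanking duplication within
2–40 bp (no mismatch tolerance, matching how direct repeats are
reported). The IUPAC motif scanner reports all occurrences on both
strands and replaces web-based promoter/TFBS tools within this package's
scope.

## Pipeline

Stages run in a fixed order (library → regions → search → enrichment →
networks/GO → patterns/nodes → structure QC) in a single process; every
run logs the package version, seed, and resolved configuration, and
writes per-stage counts to `summary.json`. Stages always recompute —
at the problem sizes this package targets (fixture: 24 genes across two
scaffolds, three TE families, ~28 planted insertions) a full run takes
seconds, and recomputation is the simplest byte-reproducibility
guarantee. The species profiles differ only in the qcov-per-HSP
threshold (90 vs 80).

## Numerical and degenerate-input conventions

* All intervals are 0-based half-open internally; GFF3 I/O is 1-based
  inclusive; BED output is 0-based half-open.
* Empty inputs return empty results rather than errors wherever the
  operation has a natural empty answer (empty library statistics return
  a None sentinel; an empty annotated network membership yields an empty
  GO table; a zero-hit row scores t = 0, not significant).
* Ties are broken deterministically everywhere: clustering order is
  (length desc, id), pattern labels are lexicographic, network exports
  sort nodes, node-gene ranks break ties by gene id.
* Seeds: one `numpy` Generator drives each simulation; identical seeds
  give byte-identical FASTA/GFF3/truth outputs and pipeline tables.

## Known limitations

* The aligner is ungapped; on real (indel-rich) conifer data an external
  gapped engine via the tabular reader is the appropriate configuration,
  and the sensitivity contract shown on synthetic data does not transfer
  to gapped divergence.
* One transcript per gene; isoforms are out of scope.
* The greedy clustering is O(n²) in the worst case and intended for
  libraries up to a few thousand repeats, not the full multi-million
  entry scale of real repeat databases.
* GO testing assumes the annotation's term universe; no semantic
  collapsing of related terms is attempted.
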