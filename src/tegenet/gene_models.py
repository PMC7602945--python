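"""Gene-region ingestion and extraction.

Reads a genome FASTA and a gene annotation GFF3, verifies and cleans gene
coordinates, and extracts the region datasets the downstream searches run
against: introns, gene bodies, and the ten 1-kb flank-bin datasets (five
bins upstream and five downstream of each gene, within a 5-kb window).

Coordinates are 0-based half-open internally; GFF3 I/O converts from the
1-based inclusive convention at the boundary.  Flanks are oriented by gene
strand, so the 5' flank is always upstream of the transcription start.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils

from .seqs import read_fasta, revcomp
from .similarity import AlignParams, seeded_align

FLANK_SIDES = ("FLANK5", "FLANK3")


@dataclass(frozen=True)
class GeneModel:
    """One gene with a single transcript (the spliced exon chain)."""

    gene_id: str
    scaffold: str
    strand: str
    exons: tuple[tuple[int, int], ...]  # sorted by genomic coordinate
    transcript: str  # spliced, gene-strand orientation

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def span(self) -> int:
        return self.end - self.start

    def intron_intervals(self) -> list[tuple[int, int]]:
        """Genomic intron intervals ordered 5'->3' on the gene strand."""
        gaps = [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]
        return gaps[::-1] if self.strand == "-" else gaps

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1


@dataclass(frozen=True)
class Region:
    """One extracted subject region (flank bin, intron, or gene body)."""

    region_id: str
    gene_id: str
    kind: str  # FLANK5 | FLANK3 | INTRON | GENE
    index: int  # bin 0..4 for flanks, 1-based for introns, 0 for GENE
    scaffold: str
    start: int
    end: int
    sequence: str  # forward genomic strand
    truncated: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class RegionSet:
    """Region collection plus the id -> (gene, kind, index) resolver map."""

    regions: list[Region]

    def region_map(self) -> dict[str, tuple[str, str, int]]:
        return {r.region_id: (r.gene_id, r.kind, r.index) for r in self.regions}

    def subjects(self) -> dict[str, str]:
        return {r.region_id: r.sequence for r in self.regions}

    def by_kind(self, kind: str) -> list[Region]:
        return [r for r in self.regions if r.kind == kind]

    def bin_counts(self) -> dict[tuple[str, int], int]:
        """Extracted-region count per (side, bin) — the denominator of the
        per-bin hit ratio."""
        counts: dict[tuple[str, int], int] = {}
        for r in self.regions:
            if r.kind in FLANK_SIDES:
                counts[(r.kind, r.index)] = counts.get((r.kind, r.index), 0) + 1
        return counts


# ---------------------------------------------------------------------------
# annotation ingestion
# ---------------------------------------------------------------------------

def read_annotation(
    genome: str | Path | Mapping[str, str],
    gff3: str | Path,
    require_introns: bool = True,
) -> tuple[list[GeneModel], list[tuple[str, str]]]:
    """Load gene models from a genome FASTA (or scaffold dict) and a GFF3.

    Returns (genes, rejections); rejections are (gene_id, reason) pairs.
    Genes whose exons fall outside scaffold bounds are rejected; with
    ``require_introns`` single-exon genes are dropped (the analyses run on
    intron-containing genes).
    """
    scaffolds = (
        dict(genome) if isinstance(genome, Mapping) else dict(read_fasta(genome))
    )
    db = gffutils.create_db(
        str(gff3),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    rejections: list[tuple[str, str]] = []
    for g in db.features_of_type("gene", order_by=("seqid", "start")):
        gene_id = g.id
        if g.seqid not in scaffolds:
            rejections.append((gene_id, f"UNKNOWN_SCAFFOLD:{g.seqid}"))
            continue
        seq = scaffolds[g.seqid]
        exons = sorted(
            (f.start - 1, f.end)  # GFF3 1-based inclusive -> half-open
            for f in db.children(g, featuretype="exon")
        )
        if not exons:
            rejections.append((gene_id, "NO_EXONS"))
            continue
        if exons[0][0] < 0 or exons[-1][1] > len(seq):
            rejections.append((gene_id, "EXON_OUTSIDE_SCAFFOLD"))
            continue
        if any(exons[i][1] > exons[i + 1][0] for i in range(len(exons) - 1)):
            rejections.append((gene_id, "OVERLAPPING_EXONS"))
            continue
        if require_introns and len(exons) < 2:
            rejections.append((gene_id, "NO_INTRONS"))
            continue
        transcript = "".join(seq[s:e] for s, e in exons)
        if g.strand == "-":
            transcript = revcomp(transcript)
        genes.append(
            GeneModel(
                gene_id=gene_id,
                scaffold=g.seqid,
                strand=g.strand if g.strand in "+-" else "+",
                exons=tuple(exons),
                transcript=transcript,
            )
        )
    return genes, rejections


# ---------------------------------------------------------------------------
# coordinate verification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Placement:
    scaffold: str
    start: int
    end: int
    strand: str
    identity: float  # weighted mean over chained exon HSPs
    coverage: float  # covered transcript fraction
    n_exons_placed: int


@dataclass
class VerificationResult:
    verified: list[GeneModel]
    placements: dict[str, Placement]
    flagged_long: list[str]  # genomic span above the manual-check threshold
    rejections: list[tuple[str, str]]


def verify_gene_coordinates(
    genes: Sequence[GeneModel],
    genome: Mapping[str, str],
    min_id: float = 0.98,
    min_qcov: float = 1.00,
    max_gene_len_flag: int = 20000,
    params: AlignParams | None = None,
) -> VerificationResult:
    """Re-place each transcript on the genome and keep verifiable genes.

    Each exon is placed independently with the built-in aligner (an exon
    placement must cover the exon fully at >= min_id identity); colinear
    same-scaffold placements are chained and the chain must cover
    >= min_qcov of the transcript.  Identical (scaffold, span) placements
    collapse to one; of repeated partial structures on one scaffold only
    the most complete chain is kept.  Genes spanning more than
    ``max_gene_len_flag`` are flagged, not removed.
    """
    params = params or AlignParams()
    verified: list[GeneModel] = []
    placements: dict[str, Placement] = {}
    flagged: list[str] = []
    rejections: list[tuple[str, str]] = []
    for gene in genes:
        exon_seqs = _exon_seqs(gene, genome)
        candidates: list[Placement] = []
        for scaffold_id, scaffold_seq in genome.items():
            chain = _chain_exons(
                gene, exon_seqs, scaffold_id, scaffold_seq, min_id, params
            )
            if chain is not None:
                candidates.append(chain)
        candidates = [c for c in candidates if c.coverage >= min_qcov - 1e-9]
        # collapse identical (scaffold, coordinates) placements
        seen: set[tuple[str, int, int]] = set()
        unique: list[Placement] = []
        for c in sorted(
            candidates, key=lambda c: (-c.n_exons_placed, -c.coverage, c.scaffold)
        ):
            key = (c.scaffold, c.start, c.end)
            if key not in seen:
                seen.add(key)
                unique.append(c)
        if not unique:
            rejections.append((gene.gene_id, "NO_PLACEMENT"))
            continue
        best = unique[0]  # the conventional structure with most exons present
        placements[gene.gene_id] = best
        verified.append(gene)
        if gene.span > max_gene_len_flag:
            flagged.append(gene.gene_id)
    return VerificationResult(verified, placements, flagged, rejections)


def _exon_seqs(gene: GeneModel, genome: Mapping[str, str]) -> list[str]:
    """Exon query pieces cut from the *annotated transcript* (the claim
    being verified), in genomic order on the forward strand."""
    forward = revcomp(gene.transcript) if gene.strand == "-" else gene.transcript
    pieces, pos = [], 0
    for s, e in gene.exons:
        pieces.append(forward[pos : pos + (e - s)])
        pos += e - s
    return pieces


def _chain_exons(
    gene: GeneModel,
    exon_seqs: list[str],
    scaffold_id: str,
    scaffold_seq: str,
    min_id: float,
    params: AlignParams,
) -> Placement | None:
    """Greedy colinear chain of per-exon placements on one scaffold."""
    placed: list[tuple[int, int, float, int]] = []  # (sstart, send, pident, exon_len)
    prev_end = -1
    n_placed = 0
    for exon_seq in exon_seqs:
        hits = [
            h
            for h in seeded_align("exon", exon_seq, scaffold_id, scaffold_seq, params)
            if h.qcov_hsp >= 100.0 - 1e-9
            and h.pident >= 100.0 * min_id
            and h.strand == "+"
            and h.sstart >= prev_end
        ]
        if not hits:
            continue
        best = max(hits, key=lambda h: (h.pident, -h.sstart))
        placed.append((best.sstart, best.send, best.pident, len(exon_seq)))
        prev_end = best.send
        n_placed += 1
    if not placed:
        return None
    total = sum(len(s) for s in exon_seqs)
    covered = sum(L for *_x, L in placed)
    wident = sum(p * L for _s, _e, p, L in placed) / covered / 100.0
    return Placement(
        scaffold=scaffold_id,
        start=placed[0][0],
        end=placed[-1][1],
        strand=gene.strand,
        identity=wident,
        coverage=covered / total,
        n_exons_placed=n_placed,
    )


# ---------------------------------------------------------------------------
# TE-like gene filter
# ---------------------------------------------------------------------------

def filter_te_like_genes(
    genes: Sequence[GeneModel],
    te_library: Mapping[str, str],
    min_cov: float = 0.50,
    min_id: float = 0.80,
    min_hit_len: int = 100,
    params: AlignParams | None = None,
) -> tuple[list[GeneModel], list[tuple[str, str]]]:
    """Drop genes whose transcripts look like TEs.

    A gene is removed iff hits to some single library entry at identity
    strictly above ``min_id`` cover strictly more than ``min_cov`` of its
    transcript; hits shorter than ``min_hit_len`` are too weak to count
    toward coverage.  Returns (kept, removed) with the matching entry id.
    """
    if not te_library:
        raise ValueError("TE library must be non-empty")
    params = params or AlignParams()
    kept: list[GeneModel] = []
    removed: list[tuple[str, str]] = []
    for gene in genes:
        culprit = None
        for te_id, te_seq in te_library.items():
            hits = seeded_align(gene.gene_id, gene.transcript, te_id, te_seq, params)
            intervals = [
                (h.qstart, h.qend)
                for h in hits
                if h.pident > 100.0 * min_id and h.aln_len >= min_hit_len
            ]
            if not intervals:
                continue
            cov = _union_len(intervals) / len(gene.transcript)
            if cov > min_cov:
                culprit = te_id
                break
        if culprit is None:
            kept.append(gene)
        else:
            removed.append((gene.gene_id, culprit))
    return kept, removed


def _union_len(intervals: list[tuple[int, int]]) -> int:
    total, cur_s, cur_e = 0, None, None
    for s, e in sorted(intervals):
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s
    return total


# ---------------------------------------------------------------------------
# region extraction
# ---------------------------------------------------------------------------

def extract_flanks(
    genes: Sequence[GeneModel],
    genome: Mapping[str, str],
    window: int = 5000,
    bin_width: int = 1000,
) -> RegionSet:
    """Cut the 5' and 3' gene flanks into distance-indexed bins.

    Bin 0 is adjacent to the gene; with the 5-kb window and 1-kb bins this
    yields ten datasets (five per side).  Bins clipped by a scaffold end
    are retained with their shorter remainder and flagged truncated;
    fully-absent bins are omitted.  Overlap with neighbouring genes is
    allowed — there is no exclusivity rule.
    """
    if window % bin_width != 0:
        raise ValueError("window must be divisible by bin_width")
    n_bins = window // bin_width
    regions: list[Region] = []
    for gene in genes:
        scaffold = genome[gene.scaffold]
        for side in FLANK_SIDES:
            upstream = (side == "FLANK5") == (gene.strand == "+")
            for b in range(n_bins):
                if upstream:
                    lo = gene.start - (b + 1) * bin_width
                    hi = gene.start - b * bin_width
                else:
                    lo = gene.end + b * bin_width
                    hi = gene.end + (b + 1) * bin_width
                clipped_lo = max(lo, 0)
                clipped_hi = min(hi, len(scaffold))
                if clipped_hi <= clipped_lo:
                    continue
                regions.append(
                    Region(
                        region_id=f"{gene.gene_id}|{side}|{b}",
                        gene_id=gene.gene_id,
                        kind=side,
                        index=b,
                        scaffold=gene.scaffold,
                        start=clipped_lo,
                        end=clipped_hi,
                        sequence=scaffold[clipped_lo:clipped_hi],
                        truncated=(clipped_hi - clipped_lo) < bin_width,
                    )
                )
    return RegionSet(regions)


def extract_introns(
    genes: Sequence[GeneModel], genome: Mapping[str, str]
) -> RegionSet:
    """Intron regions, indexed 1-based 5'->3' on the gene strand."""
    regions: list[Region] = []
    for gene in genes:
        scaffold = genome[gene.scaffold]
        for i, (s, e) in enumerate(gene.intron_intervals(), start=1):
            if e <= s:
                continue
            regions.append(
                Region(
                    region_id=f"{gene.gene_id}|INTRON|{i}",
                    gene_id=gene.gene_id,
                    kind="INTRON",
                    index=i,
                    scaffold=gene.scaffold,
                    start=s,
                    end=e,
                    sequence=scaffold[s:e],
                )
            )
    return RegionSet(regions)


def extract_gene_genomic(
    genes: Sequence[GeneModel], genome: Mapping[str, str]
) -> dict[str, str]:
    """Genomic gene sequences from transcription start to termination site,
    reverse-complemented to gene orientation for minus-strand genes."""
    out: dict[str, str] = {}
    for gene in genes:
        seq = genome[gene.scaffold][gene.start : gene.end]
        out[gene.gene_id] = revcomp(seq) if gene.strand == "-" else seq
    return out


def write_regions_bed(path: str | Path, regions: Iterable[Region]) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(
                f"{r.scaffold}\t{r.start}\t{r.end}\t{r.region_id}\t0\t+\n"
            )
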