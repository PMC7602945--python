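"""Intron insertion-pattern typing, node genes, and GC profiling.

Genes are typed by which TE families hit their introns: a signature keeps
two separate presence/absence alphabets — short TE-derived repeats and
long (>1 kb) high-quality hits — without regard to which intron or how
many copies.  Identical signatures group into pattern classes.  "Node
genes" carry many distinct repeats in their introns (strictly more than
the threshold, default eight) and rank by that count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .seqs import gc_fraction as _gc_raw
from .similarity import Hit


@dataclass(frozen=True)
class PatternSignature:
    gene_id: str
    short_families: tuple[str, ...]  # sorted
    long_families: tuple[str, ...]  # sorted

    @property
    def text(self) -> str:
        return ",".join(self.short_families) + "|" + ",".join(self.long_families)

    @property
    def n_distinct(self) -> int:
        return len(set(self.short_families) | set(self.long_families))


@dataclass(frozen=True)
class PatternClass:
    label: str  # deterministic lexicographic rank: P001, P002, ...
    signature: str
    members: tuple[str, ...]


@dataclass(frozen=True)
class NodeGeneReport:
    gene_id: str
    distinct_repeats: int
    rank: int


@dataclass(frozen=True)
class GCProfile:
    gene_id: str
    transcript_gc: float | None
    intron_gc: float | None
    te_gc: float | None  # GC over TE-occupied intron intervals


def intron_signature(
    gene_id: str,
    short_hits: Iterable[Hit],
    long_hits: Iterable[Hit],
    family_of_query: Mapping[str, str] | None = None,
) -> PatternSignature:
    """Presence/absence signature over the two hit alphabets.

    Hits must already be restricted to the gene's introns; copy number
    and intron position are ignored.
    """

    def fam(h: Hit) -> str:
        if family_of_query:
            return family_of_query.get(h.query_id, h.query_id)
        return h.query_id

    return PatternSignature(
        gene_id=gene_id,
        short_families=tuple(sorted({fam(h) for h in short_hits})),
        long_families=tuple(sorted({fam(h) for h in long_hits})),
    )


def group_patterns(signatures: Sequence[PatternSignature]) -> list[PatternClass]:
    """Group identical signatures; labels follow lexicographic signature
    order (the letter labels used in publications are arbitrary)."""
    by_sig: dict[str, list[str]] = {}
    for s in signatures:
        by_sig.setdefault(s.text, []).append(s.gene_id)
    classes = []
    for rank, sig in enumerate(sorted(by_sig), start=1):
        classes.append(
            PatternClass(
                label=f"P{rank:03d}",
                signature=sig,
                members=tuple(sorted(by_sig[sig])),
            )
        )
    return classes


def node_genes(
    signatures: Sequence[PatternSignature], min_distinct: int = 8
) -> list[NodeGeneReport]:
    """Genes with strictly more than ``min_distinct`` distinct repeats in
    their introns (union of both alphabets), sorted by count descending,
    ties by gene id."""
    if min_distinct < 1:
        raise ValueError("min_distinct must be >= 1")
    qualifying = [
        (s.gene_id, s.n_distinct) for s in signatures if s.n_distinct > min_distinct
    ]
    qualifying.sort(key=lambda kv: (-kv[1], kv[0]))
    return [
        NodeGeneReport(gene_id=g, distinct_repeats=c, rank=i + 1)
        for i, (g, c) in enumerate(qualifying)
    ]


def gc_fraction(seq: str) -> float | None:
    """GC percent with N excluded from numerator and denominator; None
    for sequences with no unambiguous bases."""
    try:
        return _gc_raw(seq)
    except ValueError:
        return None


def gc_profile(
    gene_id: str,
    transcript: str,
    intron_seqs: Sequence[str],
    te_intervals_by_intron: Mapping[int, Sequence[tuple[int, int]]] | None = None,
) -> GCProfile:
    """GC of the transcript, the concatenated introns, and the
    TE-occupied intron intervals (intervals are intron-local,
    0-based half-open, keyed by intron list index)."""
    intron_cat = "".join(intron_seqs)
    te_parts: list[str] = []
    if te_intervals_by_intron:
        for idx, intervals in sorted(te_intervals_by_intron.items()):
            seq = intron_seqs[idx]
            for s, e in intervals:
                if not (0 <= s <= e <= len(seq)):
                    raise ValueError(
                        f"TE interval ({s}, {e}) outside intron {idx} of {gene_id}"
                    )
                te_parts.append(seq[s:e])
    return GCProfile(
        gene_id=gene_id,
        transcript_gc=gc_fraction(transcript) if transcript else None,
        intron_gc=gc_fraction(intron_cat) if intron_cat else None,
        te_gc=gc_fraction("".join(te_parts)) if te_parts else None,
    )


def write_patterns_tsv(path, classes: Sequence[PatternClass]) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tsignature\tclass\n")
        for c in classes:
            for g in c.members:
                fh.write(f"{g}\t{c.signature}\t{c.label}\n")


def write_node_genes_tsv(path, reports: Sequence[NodeGeneReport]) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tdistinct_repeats\trank\n")
        for r in reports:
            fh.write(f"{r.gene_id}\t{r.distinct_repeats}\t{r.rank}\n")


def write_gc_tsv(path, profiles: Sequence[GCProfile]) -> None:
    def fmt(x: float | None) -> str:
        return "NA" if x is None else f"{x:.2f}"

    with open(path, "w") as fh:
        fh.write("gene_id\ttranscript_gc\tintron_gc\tte_gc\n")
        for p in profiles:
            fh.write(
                f"{p.gene_id}\t{fmt(p.transcript_gc)}\t{fmt(p.intron_gc)}\t"
                f"{fmt(p.te_gc)}\n"
            )
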