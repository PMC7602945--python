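"""Structural QC of TE loci.

Checks that matter for assembly-quality assessment: splitting an RLX into
its LTR and internal parts, the LTR:internal hit ratio (2.0 when every
element is full-length — each element carries two LTR copies and one
internal region), locus classification into full-length / solo-LTR /
internal-only / truncated, detection of terminal inverted repeats (TIRs)
and target-site duplications (TSDs), and an IUPAC motif scanner that
stands in for web-based promoter/TFBS tools.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .repeat_library import TEEntry, extract_direct_repeats
from .seqs import iupac_regex, revcomp
from .similarity import Hit
from .synthetic_data import StructureError


@dataclass(frozen=True)
class StructureCall:
    start: int
    end: int
    call: str  # FULL_LENGTH | SOLO_LTR | INTERNAL_ONLY | TRUNCATED
    ltr_intervals: tuple[tuple[int, int], ...]
    termini_ok: bool
    tsd: str | None = None


@dataclass(frozen=True)
class RatioReport:
    family_id: str
    identity_level: float
    n_ltr_hits: int
    n_internal_hits: int

    @property
    def ratio(self) -> float | None:
        """LTR:internal hit ratio; None when no internal hits exist."""
        if self.n_internal_hits == 0:
            return None
        return self.n_ltr_hits / self.n_internal_hits


@dataclass(frozen=True)
class MotifHit:
    name: str
    pattern: str
    position: int
    strand: str


# ---------------------------------------------------------------------------
# RLX partitioning and the solo-LTR ratio
# ---------------------------------------------------------------------------

def split_ltr_internal(
    entry: TEEntry, min_ltr: int = 50, min_id: float = 0.8
) -> tuple[str, str]:
    """Split a full-length RLX entry into (ltr, internal) using its
    terminal direct-repeat pair; the 5' copy is the LTR representative.

    Raises StructureError when the entry has no terminal repeat pair
    (e.g. a MITE)."""
    repeats = extract_direct_repeats(entry, min_len=min_ltr, min_id=min_id)
    n = len(entry.sequence)
    terminal = [
        r
        for r in repeats
        if r.copy1[0] <= 10 and r.copy2[1] >= n - 10
    ]
    if not terminal:
        raise StructureError(
            f"{entry.entry_id}: no terminal direct-repeat pair found"
        )
    best = max(terminal, key=lambda r: r.length)
    ltr = best.sequence
    internal = entry.sequence[best.copy1[1] : best.copy2[0]]
    return ltr, internal


def solo_ratio(
    family_id: str,
    ltr_hits: Sequence[Hit],
    internal_hits: Sequence[Hit],
    identity_level: float = 0.9,
) -> RatioReport:
    """LTR:internal hit-count ratio at one identity level.

    Hits below the level are discarded; full-length elements contribute
    two LTR hits and one internal hit, so an all-full-length region set
    gives a ratio of 2.0, while excess LTR hits flag solo LTRs.
    """
    lvl = 100.0 * identity_level
    n_ltr = sum(1 for h in ltr_hits if h.pident >= lvl)
    n_int = sum(1 for h in internal_hits if h.pident >= lvl)
    return RatioReport(
        family_id=family_id,
        identity_level=identity_level,
        n_ltr_hits=n_ltr,
        n_internal_hits=n_int,
    )


def classify_locus(
    hits: Sequence[Hit],
    family_total_len: int,
    locus_seq: str | None = None,
    max_span_factor: float = 1.5,
) -> StructureCall:
    """Classify clustered hits near one genomic position.

    ``hits`` are LTR-query and internal-query hits around the locus (the
    query_id must end in ``:ltr`` or ``:internal``).  FULL_LENGTH needs a
    same-strand LTR-internal-LTR chain within ``max_span_factor`` times
    the family length; an isolated LTR is SOLO_LTR; internal evidence
    without an LTR is INTERNAL_ONLY; anything else is TRUNCATED.
    ``termini_ok`` is set when the locus sequence starts TG and ends CA.
    """
    if not hits:
        raise ValueError("no hits to classify")
    hits = sorted(hits, key=lambda h: h.sstart)
    ltrs = [h for h in hits if h.query_id.endswith(":ltr")]
    internals = [h for h in hits if h.query_id.endswith(":internal")]
    start = min(h.sstart for h in hits)
    end = max(h.send for h in hits)
    termini_ok = bool(
        locus_seq and locus_seq.startswith("TG") and locus_seq.endswith("CA")
    )
    max_span = max_span_factor * family_total_len

    call = "TRUNCATED"
    ltr_ivals = tuple((h.sstart, h.send) for h in ltrs)
    if len(ltrs) >= 2 and internals:
        for i, a in enumerate(ltrs):
            for b in ltrs[i + 1 :]:
                if a.strand != b.strand:
                    continue
                if b.send - a.sstart > max_span:
                    continue
                between = [
                    h
                    for h in internals
                    if h.strand == a.strand
                    and h.sstart >= a.send
                    and h.send <= b.sstart
                ]
                if between:
                    call = "FULL_LENGTH"
                    ltr_ivals = ((a.sstart, a.send), (b.sstart, b.send))
                    break
            if call == "FULL_LENGTH":
                break
    if call != "FULL_LENGTH":
        if ltrs and not internals:
            call = "SOLO_LTR"
        elif internals and not ltrs:
            call = "INTERNAL_ONLY"
        elif len(ltrs) == 1 and internals:
            call = "TRUNCATED"
        elif len(ltrs) >= 2 and not internals:
            # two LTR hits may be two neighbouring solo LTRs; without
            # internal evidence the locus is not FULL
            call = "SOLO_LTR"
    return StructureCall(
        start=start,
        end=end,
        call=call,
        ltr_intervals=ltr_ivals,
        termini_ok=termini_ok,
    )


# ---------------------------------------------------------------------------
# TIR and TSD detection
# ---------------------------------------------------------------------------

def detect_tir(
    seq: str, min_len: int = 10, max_len: int = 60, min_id: float = 0.9
) -> tuple[int, float] | None:
    """Best terminal inverted repeat: prefix vs revcomp(suffix).

    Among lengths whose identity is >= min_id, the length maximising the
    alignment score (match +1 / mismatch -2; ties to the longer) is
    returned, so exact TIRs are reported at their exact boundary rather
    than padded with tolerated mismatches.  Returns (tir_len, identity)
    or None when no length qualifies.
    """
    n = len(seq)
    if n < 2 * min_len:
        return None
    best: tuple[int, float] | None = None
    best_score = None
    hi = min(max_len, n // 2)
    for L in range(min_len, hi + 1):
        prefix = seq[:L]
        suffix_rc = revcomp(seq[n - L :])
        m = sum(1 for x, y in zip(prefix, suffix_rc) if x == y and x != "N")
        ident = m / L
        score = m - 2 * (L - m)
        if ident >= min_id and (best_score is None or score >= best_score):
            best = (L, ident)
            best_score = score
    return best


def detect_tsd(
    genome_seq: str,
    locus_start: int,
    locus_end: int,
    min_len: int = 2,
    max_len: int = 40,
) -> str | None:
    """Longest exact direct duplication immediately flanking a locus.

    The left TSD copy is the ``L`` bases before locus_start, the right
    copy the ``L`` bases after locus_end; loci too close to a scaffold
    edge return None.
    """
    if locus_start < max_len or locus_end + max_len > len(genome_seq):
        return None
    for L in range(max_len, min_len - 1, -1):
        left = genome_seq[locus_start - L : locus_start]
        right = genome_seq[locus_end : locus_end + L]
        if left == right and "N" not in left:
            return left
    return None


# ---------------------------------------------------------------------------
# IUPAC motif scanning
# ---------------------------------------------------------------------------

def scan_motifs(
    seq: str, motifs: Iterable[tuple[str, str]]
) -> list[MotifHit]:
    """All occurrences of each IUPAC motif on both strands.

    Positions are forward-strand 0-based starts of the match; minus-strand
    hits report the forward-strand interval start of the reverse-
    complemented occurrence.  Invalid IUPAC codes raise ValueError.
    """
    out: list[MotifHit] = []
    for name, pattern in motifs:
        rx = iupac_regex(pattern)
        for m in rx.finditer(seq):
            out.append(MotifHit(name, pattern, m.start(), "+"))
        rc = revcomp(seq)
        n = len(seq)
        for m in rx.finditer(rc):
            start = n - m.end()
            out.append(MotifHit(name, pattern, start, "-"))
    out.sort(key=lambda h: (h.position, h.name, h.strand))
    return out


def write_structure_tsv(path, calls: Sequence[StructureCall]) -> None:
    with open(path, "w") as fh:
        fh.write("start\tend\tcall\ttermini_ok\tn_ltr_hits\ttsd\n")
        for c in calls:
            fh.write(
                f"{c.start}\t{c.end}\t{c.call}\t{int(c.termini_ok)}\t"
                f"{len(c.ltr_intervals)}\t{c.tsd or 'NA'}\n"
            )


def write_ratio_tsv(path, reports: Sequence[RatioReport]) -> None:
    with open(path, "w") as fh:
        fh.write("family_id\tidentity_level\tn_ltr_hits\tn_internal_hits\tratio\n")
        for r in reports:
            ratio = "NA" if r.ratio is None else f"{r.ratio:.3f}"
            fh.write(
                f"{r.family_id}\t{r.identity_level:g}\t{r.n_ltr_hits}\t"
                f"{r.n_internal_hits}\t{ratio}\n"
            )
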