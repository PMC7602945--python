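"""Similarity search between repeat queries and region subjects.

The built-in engine is an ungapped seed-based local aligner: exact k-mer
seeds identify candidate diagonals, and every maximal positive-scoring
segment on a seeded diagonal (Ruzzo–Tompa decomposition) above the score
cutoff is reported as an HSP.  Scoring is match +1 / mismatch -2, the
classic BLASTN nucleotide scheme; N never counts as a match.  E-values use
the Karlin–Altschul formula with the published ungapped constants for that
scheme (lambda = 1.33, K = 0.621); both are configurable.

External search engines remain pluggable through the 12/13-column
BLAST-tabular reader, so precomputed hit tables can be filtered and fed to
the downstream stages unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .seqs import encode, revcomp

# Karlin-Altschul ungapped constants for match +1 / mismatch -2
KA_LAMBDA = 1.33
KA_K = 0.621


@dataclass(frozen=True)
class Hit:
    """One high-scoring segment pair (HSP).

    Intervals are 0-based half-open on the forward strand of both query
    and subject; ``strand`` is the strand of the query relative to the
    subject.  ``pident`` is matches / alignment length x 100 and
    ``qcov_hsp`` is the HSP's query span / full query length x 100.
    """

    query_id: str
    subject_id: str
    pident: float
    aln_len: int
    qcov_hsp: float
    qstart: int
    qend: int
    sstart: int
    send: int
    strand: str
    evalue: float
    score: float

    def __post_init__(self):
        if not (0.0 <= self.pident <= 100.0):
            raise ValueError(f"pident out of range: {self.pident}")
        if self.aln_len < 1:
            raise ValueError("aln_len must be >= 1")
        if self.qcov_hsp > 100.0 + 1e-9:
            raise ValueError(f"qcov_hsp above 100: {self.qcov_hsp}")


@dataclass(frozen=True)
class HitFilter:
    """Keep thresholds for raw similarity hits (all inclusive, >=)."""

    min_pident: float = 80.0
    min_len: int = 100
    min_qcov: float = 90.0
    max_evalue: float | None = None

    def keeps(self, h: Hit) -> bool:
        if h.pident < self.min_pident or h.aln_len < self.min_len:
            return False
        if h.qcov_hsp < self.min_qcov:
            return False
        if self.max_evalue is not None and h.evalue > self.max_evalue:
            return False
        return True


#: Species profiles: the sugar-pine analyses relax qcov-per-HSP to 80.
PROFILES = {
    "pita": HitFilter(min_pident=80.0, min_len=100, min_qcov=90.0),
    "pila": HitFilter(min_pident=80.0, min_len=100, min_qcov=80.0),
}


@dataclass(frozen=True)
class HQHitRule:
    """High-quality hit rule for network formation (strict comparisons):
    long hits need aln_len > 1000 bp and pident > 80; MITE queries need
    aln_len > 200 bp; all need e-value < 0.01."""

    min_long_len: int = 1000
    min_long_pident: float = 80.0
    min_mite_len: int = 200
    max_evalue: float = 0.01


@dataclass
class AlignParams:
    seed_len: int = 11
    match: int = 1
    mismatch: int = -2
    min_score: int = 16
    ka_lambda: float = KA_LAMBDA
    ka_k: float = KA_K


# ---------------------------------------------------------------------------
# seeded ungapped aligner
# ---------------------------------------------------------------------------

def _kmer_index(enc: np.ndarray, k: int) -> dict[bytes, list[int]]:
    index: dict[bytes, list[int]] = {}
    n = len(enc)
    buf = enc.tobytes()
    for i in range(n - k + 1):
        word = buf[i : i + k]
        if b"\x04" in word:  # skip seeds containing N
            continue
        index.setdefault(word, []).append(i)
    return index


def _maximal_segments(score: np.ndarray, min_score: int) -> list[tuple[int, int, int]]:
    """Ruzzo–Tompa decomposition of a +/- score vector into all maximal
    positive-scoring disjoint segments with total >= min_score.

    Returns (start, end, total) triples, end exclusive.
    """
    # stack of candidate segments as (Lcum, Rcum, start, end); cum = prefix sums
    out: list[tuple[int, int, int]] = []
    stack: list[list[int]] = []  # [Lcum, Rcum, start, end]
    cum = 0
    for i, s in enumerate(score):
        if s <= 0:
            cum += int(s)
            continue
        seg = [cum, cum + int(s), i, i + 1]
        cum += int(s)
        while True:
            # find rightmost stacked segment j with Lcum_j < seg Lcum
            j = len(stack) - 1
            while j >= 0 and stack[j][0] >= seg[0]:
                j -= 1
            if j >= 0 and stack[j][1] < seg[1]:
                # merge stack[j..] into seg
                seg = [stack[j][0], seg[1], stack[j][2], seg[3]]
                del stack[j:]
                continue
            break
        stack.append(seg)
    for lcum, rcum, start, end in stack:
        total = rcum - lcum
        if total >= min_score:
            # trim leading/trailing non-positive positions (defensive)
            out.append((start, end, total))
    return out


def _hsps_on_strand(
    q_enc: np.ndarray,
    s_enc: np.ndarray,
    params: AlignParams,
    s_index: dict[bytes, list[int]],
) -> list[tuple[int, int, int, int, int]]:
    """Yield (qstart, qend, sstart, matches, score) HSPs for one query
    orientation against an indexed subject."""
    k = params.seed_len
    nq, ns = len(q_enc), len(s_enc)
    if nq < k or ns < k:
        return []
    qbuf = q_enc.tobytes()
    diagonals: set[int] = set()
    for i in range(nq - k + 1):
        word = qbuf[i : i + k]
        if b"\x04" in word:
            continue
        for j in s_index.get(word, ()):
            diagonals.add(j - i)

    hsps: list[tuple[int, int, int, int, int]] = []
    for d in sorted(diagonals):
        i0 = max(0, -d)
        i1 = min(nq, ns - d)
        if i1 - i0 < k:
            continue
        qs = q_enc[i0:i1]
        ss = s_enc[i0 + d : i1 + d]
        match = (qs == ss) & (qs != 4) & (ss != 4)
        score = np.where(match, params.match, params.mismatch)
        for start, end, total in _maximal_segments(score, params.min_score):
            m = int(match[start:end].sum())
            hsps.append((i0 + start, i0 + end, i0 + start + d, m, total))
    return hsps


def _evalue(score: float, m: int, n: int, params: AlignParams) -> float:
    return params.ka_k * m * n * math.exp(-params.ka_lambda * score)


def seeded_align(
    query_id: str,
    query: str,
    subject_id: str,
    subject: str,
    params: AlignParams | None = None,
) -> list[Hit]:
    """All local ungapped alignments of query against subject, both strands.

    Coordinates in the returned hits are forward-strand and ascending on
    both sequences; minus-strand hits carry strand "-" with the query
    interval given on the forward query strand.
    """
    params = params or AlignParams()
    if not query or not subject:
        return []
    q_enc = encode(query)
    s_enc = encode(subject)
    s_index = _kmer_index(s_enc, params.seed_len)
    nq = len(query)

    hits: list[Hit] = []
    for strand, qe in (("+", q_enc), ("-", encode(revcomp(query)))):
        for qstart, qend, sstart, matches, score in _hsps_on_strand(
            qe, s_enc, params, s_index
        ):
            aln_len = qend - qstart
            if strand == "-":
                qstart, qend = nq - qend, nq - qstart
            hits.append(
                Hit(
                    query_id=query_id,
                    subject_id=subject_id,
                    pident=100.0 * matches / aln_len,
                    aln_len=aln_len,
                    qcov_hsp=100.0 * aln_len / nq,
                    qstart=qstart,
                    qend=qend,
                    sstart=sstart,
                    send=sstart + aln_len,
                    strand=strand,
                    evalue=_evalue(score, nq, len(subject), params),
                    score=float(score),
                )
            )
    hits.sort(key=lambda h: (-h.score, h.sstart, h.qstart, h.strand))
    return hits


def search_many(
    queries: Mapping[str, str],
    subjects: Mapping[str, str],
    params: AlignParams | None = None,
) -> list[Hit]:
    """Align every query against every subject (deterministic order)."""
    params = params or AlignParams()
    out: list[Hit] = []
    subject_items = [(sid, encode(s), len(s)) for sid, s in subjects.items()]
    indexed = [
        (sid, s_enc, slen, _kmer_index(s_enc, params.seed_len))
        for sid, s_enc, slen in subject_items
    ]
    for qid, qseq in queries.items():
        if not qseq:
            continue
        nq = len(qseq)
        q_fwd = encode(qseq)
        q_rev = encode(revcomp(qseq))
        for sid, s_enc, slen, s_index in indexed:
            for strand, qe in (("+", q_fwd), ("-", q_rev)):
                for qstart, qend, sstart, matches, score in _hsps_on_strand(
                    qe, s_enc, params, s_index
                ):
                    aln_len = qend - qstart
                    if strand == "-":
                        qstart, qend = nq - qend, nq - qstart
                    out.append(
                        Hit(
                            query_id=qid,
                            subject_id=sid,
                            pident=100.0 * matches / aln_len,
                            aln_len=aln_len,
                            qcov_hsp=100.0 * aln_len / nq,
                            qstart=qstart,
                            qend=qend,
                            sstart=sstart,
                            send=sstart + aln_len,
                            strand=strand,
                            evalue=_evalue(score, nq, slen, params),
                            score=float(score),
                        )
                    )
    return out


# ---------------------------------------------------------------------------
# tabular I/O
# ---------------------------------------------------------------------------

_TAB_COLS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()


def read_hits_tsv(path, query_lengths: Mapping[str, int] | None = None) -> list[Hit]:
    """Read BLAST-tabular (outfmt 6) hits, optional 13th qcovhsp column.

    When qcovhsp is absent it is computed from qstart/qend and a query
    length table; rows are 1-based inclusive in the dialect and converted
    to 0-based half-open.  Malformed rows raise with the line number.
    """
    hits: list[Hit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) not in (12, 13):
                raise ValueError(
                    f"{path}:{lineno}: expected 12 or 13 columns, got {len(fields)}"
                )
            try:
                qseqid, sseqid = fields[0], fields[1]
                pident = float(fields[2])
                length = int(fields[3])
                qstart, qend = int(fields[6]), int(fields[7])
                sstart, send = int(fields[8]), int(fields[9])
                evalue = float(fields[10])
                bitscore = float(fields[11])
                qcov = float(fields[12]) if len(fields) == 13 else None
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed row: {exc}") from None
            strand = "+"
            if qstart > qend:
                qstart, qend = qend, qstart
                strand = "-"
            if sstart > send:
                sstart, send = send, sstart
                strand = "-"
            qstart, sstart = qstart - 1, sstart - 1  # to 0-based half-open
            if qcov is None:
                if query_lengths is None or qseqid not in query_lengths:
                    raise ValueError(
                        f"{path}:{lineno}: no qcovhsp column and no query "
                        f"length known for {qseqid!r}"
                    )
                qcov = 100.0 * (qend - qstart) / query_lengths[qseqid]
            hits.append(
                Hit(
                    query_id=qseqid,
                    subject_id=sseqid,
                    pident=pident,
                    aln_len=length,
                    qcov_hsp=min(qcov, 100.0),
                    qstart=qstart,
                    qend=qend,
                    sstart=sstart,
                    send=send,
                    strand=strand,
                    evalue=evalue,
                    score=bitscore,
                )
            )
    return hits


def write_hits_tsv(path, hits: Iterable[Hit]) -> None:
    """Write hits in the 13-column tabular dialect (1-based inclusive)."""
    with open(path, "w") as fh:
        for h in hits:
            qs, qe = h.qstart + 1, h.qend
            ss, se = h.sstart + 1, h.send
            if h.strand == "-":
                ss, se = se, ss
            fh.write(
                "\t".join(
                    [
                        h.query_id,
                        h.subject_id,
                        f"{h.pident:.2f}",
                        str(h.aln_len),
                        str(round(h.aln_len * (1 - h.pident / 100.0))),
                        "0",
                        str(qs),
                        str(qe),
                        str(ss),
                        str(se),
                        f"{h.evalue:.2e}",
                        f"{h.score:.1f}",
                        f"{h.qcov_hsp:.2f}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# filtering and aggregation
# ---------------------------------------------------------------------------

def filter_hits(hits: Iterable[Hit], f: HitFilter) -> list[Hit]:
    return [h for h in hits if f.keeps(h)]


def unique_gene_hits(
    hits: Iterable[Hit],
    region_map: Mapping[str, tuple[str, str, int]],
) -> dict[tuple[str, str, int], set[str]]:
    """Collapse HSP multiplicity: one (query, gene, location class, index)
    combination counts once.

    ``region_map`` resolves a subject region id to (gene_id, kind, index)
    where kind is FLANK5/FLANK3/INTRON.  Returns a mapping
    (query_id, kind, index) -> set of gene ids hit.
    """
    out: dict[tuple[str, str, int], set[str]] = {}
    for h in hits:
        if h.subject_id not in region_map:
            raise KeyError(f"unresolvable region id {h.subject_id!r}")
        gene_id, kind, index = region_map[h.subject_id]
        out.setdefault((h.query_id, kind, index), set()).add(gene_id)
    return out


def classify_hq(
    hits: Iterable[Hit],
    rule: HQHitRule | None = None,
    mite_families: frozenset[str] | set[str] = frozenset(),
) -> list[Hit]:
    """Select high-quality hits for network formation.

    Non-MITE queries: aln_len > 1 kb AND pident > 80 (strict).  Queries in
    ``mite_families`` use the short-element rule aln_len > 200 bp.  All
    hits additionally require e-value < 0.01 (strict).
    """
    rule = rule or HQHitRule()
    kept = []
    for h in hits:
        if h.evalue >= rule.max_evalue:
            continue
        if h.query_id in mite_families:
            if h.aln_len > rule.min_mite_len:
                kept.append(h)
        elif h.aln_len > rule.min_long_len and h.pident > rule.min_long_pident:
            kept.append(h)
    return kept
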