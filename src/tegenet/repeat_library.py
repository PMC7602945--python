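"""Build the TE-derived repeat query library.

Full-length TE entries (typically LTR retrotransposons) carry direct
repeats — the LTRs — that make compact, sensitive search queries even when
genome assemblies truncate or mask the element bodies.  This module
extracts those direct-repeat pairs, greedily clusters them at a global
identity threshold (CD-Hit style: longest first, first representative
above threshold wins), and applies the 0.1–2 kb length band used for the
final query database.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import edlib

from .similarity import AlignParams, seeded_align


@dataclass(frozen=True)
class TEEntry:
    entry_id: str
    sequence: str
    te_class: str | None = None

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"entry {self.entry_id} has an empty sequence")
        bad = set(self.sequence.upper()) - set("ACGTN")
        if bad:
            raise ValueError(f"entry {self.entry_id}: bad characters {sorted(bad)}")


@dataclass(frozen=True)
class DerivedRepeat:
    """A direct-repeat pair extracted from one entry; ``sequence`` is the
    5' copy.  Copy intervals are 0-based half-open and non-overlapping."""

    repeat_id: str
    parent_id: str
    copy1: tuple[int, int]
    copy2: tuple[int, int]
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class RepeatLibrary:
    repeats: list[DerivedRepeat]
    provenance: list[tuple[str, int]] = field(default_factory=list)

    def log(self, step: str) -> None:
        self.provenance.append((step, len(self.repeats)))

    def __len__(self) -> int:
        return len(self.repeats)


# ---------------------------------------------------------------------------
# direct-repeat extraction
# ---------------------------------------------------------------------------

def extract_direct_repeats(
    entry: TEEntry, min_len: int = 100, min_id: float = 0.8
) -> list[DerivedRepeat]:
    """Find maximal same-orientation repeat pairs within one entry.

    Self-alignment of the entry (plus strand, off-diagonal HSPs only)
    yields candidate pairs; each surviving pair has two non-overlapping
    copies, each >= min_len, with copy-to-copy identity >= min_id.
    Entries shorter than 2*min_len return an empty list.
    """
    if min_len < 50:
        raise ValueError("min_len must be >= 50")
    if not 0.7 <= min_id <= 1.0:
        raise ValueError("min_id must be in [0.7, 1.0]")
    seq = entry.sequence.upper()
    if len(seq) < 2 * min_len:
        return []
    # tolerant score cutoff so diverged copies still seed
    params = AlignParams(min_score=min(30, min_len // 2))
    hits = seeded_align(entry.entry_id, seq, entry.entry_id, seq, params)
    pairs: list[tuple[tuple[int, int], tuple[int, int]]] = []
    for h in hits:
        if h.strand != "+":
            continue
        if h.qstart == h.sstart:  # trivial self-diagonal
            continue
        if h.qstart > h.sstart:  # symmetric duplicate; keep 5'-first form
            continue
        c1, c2 = (h.qstart, h.qend), (h.sstart, h.send)
        if c1[1] - c1[0] < min_len:
            continue
        if c2[0] < c1[1]:  # overlapping copies (tandem-ish); skip
            continue
        if h.pident < 100.0 * min_id:
            continue
        pairs.append((c1, c2))
    # drop pairs contained within a longer pair (maximality)
    pairs.sort(key=lambda p: (-(p[0][1] - p[0][0]), p[0][0], p[1][0]))
    kept: list[tuple[tuple[int, int], tuple[int, int]]] = []
    for c1, c2 in pairs:
        contained = any(
            k1[0] <= c1[0] and c1[1] <= k1[1] and k2[0] <= c2[0] and c2[1] <= k2[1]
            for k1, k2 in kept
        )
        if not contained:
            kept.append((c1, c2))
    kept.sort(key=lambda p: p[0][0])
    return [
        DerivedRepeat(
            repeat_id=f"{entry.entry_id}:dr{i + 1}",
            parent_id=entry.entry_id,
            copy1=c1,
            copy2=c2,
            sequence=seq[c1[0] : c1[1]],
        )
        for i, (c1, c2) in enumerate(kept)
    ]


def extract_library(
    entries: Iterable[TEEntry],
    min_len: int = 100,
    min_id: float = 0.8,
    keep_entry_without_repeats: bool = True,
) -> RepeatLibrary:
    """Extract direct repeats from every entry.

    Entries with no internal direct repeat (e.g. MITEs) are retained as
    whole-entry repeats when ``keep_entry_without_repeats`` is set, so
    short elements stay searchable.
    """
    repeats: list[DerivedRepeat] = []
    for entry in entries:
        found = extract_direct_repeats(entry, min_len=min_len, min_id=min_id)
        if not found and keep_entry_without_repeats:
            n = len(entry.sequence)
            found = [
                DerivedRepeat(
                    repeat_id=f"{entry.entry_id}:full",
                    parent_id=entry.entry_id,
                    copy1=(0, n),
                    copy2=(0, n),
                    sequence=entry.sequence.upper(),
                )
            ]
        repeats.extend(found)
    lib = RepeatLibrary(repeats)
    lib.log("extracted")
    return lib


# ---------------------------------------------------------------------------
# greedy clustering
# ---------------------------------------------------------------------------

def global_identity(a: str, b: str) -> float:
    """Identity of a global alignment of the shorter onto the longer
    sequence (matches / alignment columns), the CD-Hit-like definition."""
    if not a or not b:
        return 0.0
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    res = edlib.align(short, long_, mode="HW", task="path")
    aln = edlib.getNiceAlignment(res, short, long_)
    matched = aln["matched_aligned"]
    if not matched:
        return 0.0
    return matched.count("|") / len(matched)


def greedy_cluster(
    seqs: Sequence[tuple[str, str]], threshold: float = 0.8
) -> list[tuple[str, list[str]]]:
    """Greedy length-sorted clustering at a global identity threshold.

    ``seqs`` is (id, sequence) pairs.  Sequences are processed longest
    first (ties lexicographic by id); each joins the first representative
    with identity >= threshold, otherwise founds a new cluster.  Returns
    (representative_id, member_ids) in creation order; the representative
    is included among its members.
    """
    if not 0.5 < threshold <= 1.0:
        raise ValueError("threshold must be in (0.5, 1.0]")
    order = sorted(seqs, key=lambda kv: (-len(kv[1]), kv[0]))
    reps: list[tuple[str, str, list[str]]] = []  # (rep_id, rep_seq, members)
    for sid, seq in order:
        for rep_id, rep_seq, members in reps:
            if global_identity(seq, rep_seq) >= threshold:
                members.append(sid)
                break
        else:
            reps.append((sid, seq, [sid]))
    return [(rep_id, members) for rep_id, _seq, members in reps]


def cluster_library(lib: RepeatLibrary, threshold: float = 0.8) -> RepeatLibrary:
    """Reduce the library to cluster representatives."""
    pairs = [(r.repeat_id, r.sequence) for r in lib.repeats]
    by_id = {r.repeat_id: r for r in lib.repeats}
    clusters = greedy_cluster(pairs, threshold=threshold)
    out = RepeatLibrary(
        [by_id[rep_id] for rep_id, _members in clusters],
        provenance=list(lib.provenance),
    )
    out.log(f"clustered@{threshold:g}")
    return out


# ---------------------------------------------------------------------------
# length filter and summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReductionReport:
    n_before: int
    n_after: int

    @property
    def percent_reduction(self) -> float:
        if self.n_before == 0:
            return 0.0
        return round(100.0 * (self.n_before - self.n_after) / self.n_before, 1)


def length_filter(
    lib: RepeatLibrary, min_len: int = 100, max_len: int = 2000
) -> tuple[RepeatLibrary, ReductionReport]:
    """Keep repeats with min_len <= length <= max_len (inclusive bounds)."""
    if min_len >= max_len:
        raise ValueError("min_len must be < max_len")
    kept = [r for r in lib.repeats if min_len <= r.length <= max_len]
    report = ReductionReport(n_before=len(lib.repeats), n_after=len(kept))
    out = RepeatLibrary(kept, provenance=list(lib.provenance))
    out.log(f"length_filter[{min_len},{max_len}]")
    return out, report


@dataclass(frozen=True)
class LibraryStats:
    count: int
    mean_length: float
    median_length: float
    min_length: int
    max_length: int


def library_stats(lib: RepeatLibrary) -> LibraryStats | None:
    """Summary statistics; None for an empty library."""
    if not lib.repeats:
        return None
    import numpy as np

    lengths = np.array([r.length for r in lib.repeats])
    return LibraryStats(
        count=len(lengths),
        mean_length=float(round(lengths.mean(), 1)),
        median_length=float(np.median(lengths)),
        min_length=int(lengths.min()),
        max_length=int(lengths.max()),
    )
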