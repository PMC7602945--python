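"""Small sequence primitives shared across the pipeline.

Sequences are plain upper-case strings over the ACGTN alphabet; genomic
intervals are 0-based half-open throughout the package (GFF3 I/O converts
at the boundary).
"""

from __future__ import annotations

import re
from typing import Iterable, Iterator

import numpy as np

DNA = "ACGT"
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# IUPAC nucleotide codes -> the set of bases they stand for
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

# uint8 encoding used by the aligner: A=0 C=1 G=2 T=3 N=4
_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 (A=0 C=1 G=2 T=3, anything else=N=4)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    """GC percent over unambiguous bases; positions with N are excluded
    from both numerator and denominator.  Raises ValueError on sequences
    that are empty after N-exclusion (the caller decides the sentinel)."""
    g = seq.count("G") + seq.count("g")
    c = seq.count("C") + seq.count("c")
    a = seq.count("A") + seq.count("a")
    t = seq.count("T") + seq.count("t")
    denom = a + c + g + t
    if denom == 0:
        raise ValueError("sequence has no unambiguous bases")
    return 100.0 * (g + c) / denom


def random_seq(length: int, gc: float, rng: np.random.Generator) -> str:
    """Random sequence with *exact* GC composition (rounded count), so short
    segments stay within tight tolerance of the target."""
    n_gc = int(round(length * gc))
    n_at = length - n_gc
    half_gc, half_at = n_gc // 2, n_at // 2
    bases = (
        ["G"] * half_gc + ["C"] * (n_gc - half_gc)
        + ["A"] * half_at + ["T"] * (n_at - half_at)
    )
    arr = np.array(bases, dtype="U1")
    rng.shuffle(arr)
    return "".join(arr)


def iupac_regex(pattern: str) -> re.Pattern:
    """Compile an IUPAC motif into a regex; invalid codes raise ValueError."""
    parts = []
    for ch in pattern.upper():
        if ch not in IUPAC:
            raise ValueError(f"invalid IUPAC code {ch!r} in motif {pattern!r}")
        opts = IUPAC[ch]
        parts.append(opts if len(opts) == 1 else f"[{opts}]")
    return re.compile("".join(parts))


def sample_iupac(pattern: str, rng: np.random.Generator) -> str:
    """Draw one concrete sequence compatible with an IUPAC motif."""
    out = []
    for ch in pattern.upper():
        if ch not in IUPAC:
            raise ValueError(f"invalid IUPAC code {ch!r} in motif {pattern!r}")
        opts = IUPAC[ch]
        out.append(opts[int(rng.integers(len(opts)))] if len(opts) > 1 else opts)
    return "".join(out)


def write_fasta(path, records: Iterable[tuple[str, str]], width: int = 60) -> None:
    """Write (name, sequence) records as wrapped FASTA (default 60 col)."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    seq_records = (
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    )
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


def read_fasta(path) -> Iterator[tuple[str, str]]:
    """Yield (name, upper-case sequence) pairs from a FASTA file."""
    from Bio import SeqIO

    for record in SeqIO.parse(str(path), "fasta"):
        yield record.id, str(record.seq).upper()


def identity_over(a: str, b: str) -> float:
    """Ungapped identity between equal-length strings; N never matches."""
    if len(a) != len(b):
        raise ValueError("identity_over requires equal lengths")
    if not a:
        return 0.0
    m = sum(1 for x, y in zip(a, b) if x == y and x != "N")
    return m / len(a)
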