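"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from tegenet import GenomeSpec, InsertionPlan, TEFamilySpec, synth_genome


def sw_local_align(query: str, subject: str, match=1, mismatch=-2,
                   gap=-5) -> tuple[int, int, int]:
    """Brute-force Smith-Waterman oracle: (best score, matches, aln_len)
    of the best local alignment.  Independent of the package aligner."""
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    s = np.frombuffer(subject.encode(), dtype=np.uint8)
    nq, ns = len(q), len(s)
    H = np.zeros((nq + 1, ns + 1), dtype=np.int32)
    for i in range(1, nq + 1):
        sub = np.where((s == q[i - 1]) & (s != ord("N")), match, mismatch)
        for j in range(1, ns + 1):
            H[i, j] = max(
                0,
                H[i - 1, j - 1] + sub[j - 1],
                H[i - 1, j] + gap,
                H[i, j - 1] + gap,
            )
    best = int(H.max())
    i, j = np.unravel_index(int(H.argmax()), H.shape)
    # traceback to count matches and columns
    matches = cols = 0
    while i > 0 and j > 0 and H[i, j] > 0:
        sub = match if (q[i - 1] == s[j - 1] and q[i - 1] != ord("N")) else mismatch
        if H[i, j] == H[i - 1, j - 1] + sub:
            matches += int(q[i - 1] == s[j - 1] and q[i - 1] != ord("N"))
            cols += 1
            i, j = i - 1, j - 1
        elif H[i, j] == H[i - 1, j] + gap:
            cols += 1
            i -= 1
        else:
            cols += 1
            j -= 1
    return best, matches, cols


def brute_direct_repeats(seq: str, min_len: int) -> list[tuple[int, int, int]]:
    """Exhaustive exact direct-repeat scan: (start1, start2, length)
    triples of maximal exact repeats >= min_len, non-overlapping copies."""
    n = len(seq)
    found = []
    for i in range(n - 2 * min_len + 1):
        for j in range(i + min_len, n - min_len + 1):
            L = 0
            while j + L < n and seq[i + L] == seq[j + L] and i + L < j:
                L += 1
            if L >= min_len:
                # maximality: not extendable leftwards
                if i > 0 and j > 0 and seq[i - 1] == seq[j - 1]:
                    continue
                found.append((i, j, L))
    return found


@pytest.fixture(scope="session")
def rlx_spec() -> TEFamilySpec:
    return TEFamilySpec(
        family_id="RLX1", te_class="LTR_RLX",
        ltr_len=300, internal_len=1400, total_len=2000,
        tsd_len=5, gc_target=0.30,
    )


@pytest.fixture(scope="session")
def mite_spec() -> TEFamilySpec:
    return TEFamilySpec(
        family_id="MITE1", te_class="MITE",
        total_len=259, tir_len=24, tsd_len=9, gc_target=0.35,
    )


@pytest.fixture(scope="session")
def small_genome(rlx_spec, mite_spec):
    """A compact genome with known planted insertions for truth-recovery
    tests: full RLXs and solo LTRs in introns, MITEs in near flank bins."""
    plans = []
    k = 0

    def add(**kw):
        nonlocal k
        k += 1
        plans.append(InsertionPlan(plan_id=f"p{k:02d}", **kw))

    for g in (1, 2, 3, 4):
        add(family_id="RLX1", gene_id=f"G{g:04d}", region="INTRON", index=1)
    for g in (5, 6):
        add(family_id="RLX1", gene_id=f"G{g:04d}", region="INTRON", index=1,
            completeness="SOLO_LTR")
    for g in (1, 2, 3, 4, 5, 6, 7, 8):
        add(family_id="MITE1", gene_id=f"G{g:04d}",
            region="FLANK5" if g % 2 else "FLANK3", index=0)
    gspec = GenomeSpec(
        n_scaffolds=2, n_genes=12, intron_len_dist=(2500, 4000),
        intergenic_len=12000, rng_seed=7,
    )
    return synth_genome(gspec, [rlx_spec, mite_spec], plans)
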