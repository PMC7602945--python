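"""Structural QC: RLX splitting, solo-LTR ratios, locus classification,
TIR/TSD detection, and IUPAC motif scanning."""

import numpy as np
import pytest

from tegenet import (
    GenomeSpec,
    Hit,
    InsertionPlan,
    StructureError,
    TEEntry,
    TEFamilySpec,
    classify_locus,
    detect_tir,
    detect_tsd,
    scan_motifs,
    search_many,
    solo_ratio,
    split_ltr_internal,
    synth_genome,
    synth_te_family,
)
from tegenet.seqs import random_seq, revcomp
from tegenet.synthetic_data import PPT_MOTIF, apply_divergence, mask_regions


def _hit(query: str, sstart: int, send: int, pident=95.0, strand="+") -> Hit:
    return Hit(query_id=query, subject_id="locus", pident=pident,
               aln_len=send - sstart, qcov_hsp=95.0, qstart=0,
               qend=send - sstart, sstart=sstart, send=send, strand=strand,
               evalue=1e-20, score=float(send - sstart))


class TestSplitLtrInternal:
    def test_simulated_rlx_parts(self):
        spec = TEFamilySpec("R", "LTR_RLX", ltr_len=150, internal_len=400,
                            total_len=700)
        seq, _ = synth_te_family(spec, np.random.default_rng(0))
        ltr, internal = split_ltr_internal(TEEntry("R", seq))
        assert len(ltr) == 150
        assert len(internal) == 400
        assert ltr == seq[:150]

    def test_mite_has_no_direct_terminal_repeats(self, mite_spec):
        seq, _ = synth_te_family(mite_spec, np.random.default_rng(1))
        with pytest.raises(StructureError):
            split_ltr_internal(TEEntry("M", seq))

    def test_diverged_copies_boundaries_close(self):
        spec = TEFamilySpec("R", "LTR_RLX", ltr_len=200, internal_len=600,
                            total_len=1000)
        rng = np.random.default_rng(2)
        seq, _ = synth_te_family(spec, rng)
        seq = apply_divergence(seq, 0.05, rng)
        ltr, internal = split_ltr_internal(TEEntry("R", seq))
        assert abs(len(ltr) - 200) <= 5
        assert abs(len(internal) - 600) <= 10


class TestSoloRatio:
    def test_all_full_genome_ratio_exactly_two(self, rlx_spec):
        """Every planted element is full-length, so LTR queries hit twice
        per element and internal queries once: ratio 2.0 exactly."""
        plans = [
            InsertionPlan(f"p{g}", "RLX1", f"G{g:04d}", "INTRON", 1)
            for g in range(1, 7)
        ]
        sim = synth_genome(
            GenomeSpec(n_genes=8, intron_len_dist=(3000, 4500), rng_seed=21),
            [rlx_spec], plans,
        )
        consensus = sim.families["RLX1"][0]
        ltr, internal = split_ltr_internal(TEEntry("RLX1", consensus))
        intron_subjects = {}
        for g in sim.genes:
            seq = sim.scaffolds[g.scaffold]
            for i, (s, e) in enumerate(
                (g.exons[j][1], g.exons[j + 1][0])
                for j in range(len(g.exons) - 1)
            ):
                intron_subjects[f"{g.gene_id}|I{i}"] = seq[s:e]
        hits = search_many(
            {"RLX1:ltr": ltr, "RLX1:internal": internal}, intron_subjects
        )
        good = [h for h in hits if h.qcov_hsp >= 90.0]
        report = solo_ratio(
            "RLX1",
            [h for h in good if h.query_id.endswith(":ltr")],
            [h for h in good if h.query_id.endswith(":internal")],
            identity_level=0.9,
        )
        assert report.n_internal_hits == 6
        assert report.n_ltr_hits == 12
        assert report.ratio == pytest.approx(2.0)

    def test_printed_count_regime(self):
        ltr_hits = [_hit("F:ltr", i * 100, i * 100 + 90) for i in range(13)]
        internal_hits = [_hit("F:internal", 0, 400)]
        report = solo_ratio("F", ltr_hits, internal_hits, 0.9)
        assert report.ratio == pytest.approx(13.0)

    def test_no_internal_hits_sentinel(self):
        report = solo_ratio("F", [_hit("F:ltr", 0, 90)], [], 0.9)
        assert report.ratio is None
        assert report.n_ltr_hits == 1

    def test_identity_level_excludes_weak_hits(self):
        ltr_hits = [_hit("F:ltr", 0, 90, pident=85.0)]
        report = solo_ratio("F", ltr_hits, [], identity_level=0.9)
        assert report.n_ltr_hits == 0


class TestClassifyLocus:
    def test_full_chain(self):
        hits = [
            _hit("F:ltr", 1000, 1300),
            _hit("F:internal", 1350, 2700),
            _hit("F:ltr", 2750, 3050),
        ]
        call = classify_locus(hits, family_total_len=2000,
                              locus_seq="TG" + "A" * 2046 + "CA")
        assert call.call == "FULL_LENGTH"
        assert call.termini_ok

    def test_isolated_ltr_is_solo(self):
        call = classify_locus([_hit("F:ltr", 500, 800)], 2000)
        assert call.call == "SOLO_LTR"

    def test_internal_without_ltr(self):
        call = classify_locus([_hit("F:internal", 0, 1200)], 2000)
        assert call.call == "INTERNAL_ONLY"

    def test_chain_beyond_span_not_full(self):
        hits = [
            _hit("F:ltr", 0, 300),
            _hit("F:internal", 400, 1700),
            _hit("F:ltr", 9000, 9300),  # far beyond 1.5x family length
        ]
        call = classify_locus(hits, family_total_len=2000)
        assert call.call != "FULL_LENGTH"

    def test_masked_internal_never_full(self):
        # only LTR evidence survives a fully masked internal region
        hits = [_hit("F:ltr", 0, 300), _hit("F:ltr", 1700, 2000)]
        call = classify_locus(hits, family_total_len=2000)
        assert call.call in ("SOLO_LTR", "TRUNCATED")

    def test_never_full_for_simulated_solo_ltr_loci(self, small_genome):
        """Solo-LTR truth loci must never classify as FULL_LENGTH."""
        consensus = small_genome.families["RLX1"][0]
        ltr, internal = split_ltr_internal(TEEntry("RLX1", consensus))
        for t in small_genome.truth:
            if t.completeness != "SOLO_LTR":
                continue
            window = small_genome.scaffolds[t.scaffold][
                max(0, t.start - 3000) : t.end + 3000
            ]
            hits = search_many(
                {"RLX1:ltr": ltr, "RLX1:internal": internal},
                {"locus": window},
            )
            good = [h for h in hits if h.qcov_hsp >= 90 and h.pident >= 90]
            assert good, "solo LTR not even detected"
            call = classify_locus(good, family_total_len=2000)
            assert call.call != "FULL_LENGTH"


class TestDetectTir:
    def test_exact_24bp_tir(self, mite_spec):
        seq, _ = synth_te_family(mite_spec, np.random.default_rng(3))
        found = detect_tir(seq)
        assert found is not None
        assert found[0] == 24

    def test_one_mismatch_in_24_detected(self):
        rng = np.random.default_rng(4)
        tir = random_seq(24, 0.4, rng)
        stem = random_seq(150, 0.4, rng)
        suffix = list(revcomp(tir))
        suffix[10] = {"A": "C", "C": "A", "G": "T", "T": "G"}[suffix[10]]
        seq = tir + stem + "".join(suffix)
        found = detect_tir(seq)
        assert found is not None
        assert found[0] >= 20  # 23/24 = 95.8% over the full TIR

    def test_random_sequence_none(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            assert detect_tir(random_seq(300, 0.4, rng)) is None

    def test_agrees_with_bruteforce_scan(self):
        rng = np.random.default_rng(6)
        cases = [random_seq(200, 0.4, rng) for _ in range(10)]
        tir = random_seq(18, 0.4, rng)
        cases.append(tir + random_seq(100, 0.4, rng) + revcomp(tir))
        for seq in cases:
            got = detect_tir(seq, min_len=10, max_len=60)
            # oracle: direct score maximisation over all lengths
            best, best_score = None, None
            for L in range(10, min(60, len(seq) // 2) + 1):
                a, b = seq[:L], revcomp(seq[-L:])
                m = sum(x == y and x != "N" for x, y in zip(a, b))
                if m / L >= 0.9:
                    score = m - 2 * (L - m)
                    if best_score is None or score >= best_score:
                        best, best_score = L, score
            assert (got[0] if got else None) == best


class TestDetectTsd:
    def test_planted_tsds_recovered(self, small_genome):
        for t in small_genome.truth:
            got = detect_tsd(
                small_genome.scaffolds[t.scaffold], t.start, t.end
            )
            assert got is not None
            assert got == t.tsd or len(got) > len(t.tsd)

    def test_forty_bp_duplication_recovered(self):
        rng = np.random.default_rng(7)
        tsd = random_seq(40, 0.4, rng)
        genome = (
            random_seq(100, 0.4, rng) + tsd + random_seq(500, 0.3, rng)
            + tsd + random_seq(100, 0.4, rng)
        )
        got = detect_tsd(genome, 140, 640)
        assert got == tsd

    def test_no_duplication_none(self):
        rng = np.random.default_rng(8)
        genome = random_seq(1000, 0.4, rng)
        assert detect_tsd(genome, 400, 600) is None

    def test_scaffold_edge_returns_none(self):
        assert detect_tsd("ACGT" * 100, 10, 200) is None

    def test_agrees_with_bruteforce_on_short_fixtures(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            tsd_len = int(rng.integers(2, 12))
            tsd = random_seq(tsd_len, 0.5, rng)
            left = random_seq(50, 0.4, rng)
            right = random_seq(50, 0.4, rng)
            elem = random_seq(120, 0.3, rng)
            genome = left + tsd + elem + tsd + right
            s, e = len(left) + tsd_len, len(left) + tsd_len + len(elem)
            got = detect_tsd(genome, s, e)
            # oracle: longest L with exact flank equality
            expect = None
            for L in range(40, 1, -1):
                if s - L < 0 or e + L > len(genome):
                    continue
                if genome[s - L : s] == genome[e : e + L]:
                    expect = genome[s - L : s]
                    break
            assert got == expect


class TestScanMotifs:
    def test_ppt_found_at_planted_position(self, rlx_spec):
        seq, feats = synth_te_family(rlx_spec, np.random.default_rng(10))
        ppt_start = [f for f in feats if f[0] == "PPT"][0][1]
        hits = scan_motifs(seq, [("PPT", PPT_MOTIF)])
        plus = [h for h in hits if h.strand == "+"]
        assert [h.position for h in plus] == [ppt_start]

    def test_iupac_expansion(self):
        hits = scan_motifs("TATAAAA", [("TATA", "TATAWAW")])
        assert len([h for h in hits if h.strand == "+"]) == 1

    def test_minus_strand_occurrence(self):
        seq = "GGGG" + revcomp("TATAAAA") + "GGGG"
        hits = scan_motifs(seq, [("TATA", "TATAWAW")])
        minus = [h for h in hits if h.strand == "-"]
        assert len(minus) == 1
        assert minus[0].position == 4

    def test_empty_motif_list(self):
        assert scan_motifs("ACGTACGT", []) == []

    def test_invalid_iupac_code(self):
        with pytest.raises(ValueError):
            scan_motifs("ACGT", [("bad", "AXGT")])
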