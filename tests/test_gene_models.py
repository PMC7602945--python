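"""Annotation ingestion, coordinate verification, and region extraction."""

import numpy as np
import pytest

from tegenet import (
    GenomeSpec,
    InsertionPlan,
    TEFamilySpec,
    extract_flanks,
    extract_gene_genomic,
    extract_introns,
    filter_te_like_genes,
    read_annotation,
    synth_genome,
    synth_te_family,
    verify_gene_coordinates,
)
from tegenet.gene_models import GeneModel
from tegenet.seqs import random_seq, revcomp


def _gff(lines) -> str:
    return "##gff-version 3\n" + "\n".join(lines) + "\n"


def _write_inputs(tmp_path, genome: dict, gff_text: str):
    gff = tmp_path / "a.gff3"
    gff.write_text(gff_text)
    return genome, gff


@pytest.fixture()
def toy(tmp_path):
    """Two genes on one 30-kb scaffold: a 3-exon plus-strand gene and a
    2-exon minus-strand gene."""
    rng = np.random.default_rng(0)
    seq = random_seq(30000, 0.4, rng)
    lines = [
        "chr1\tt\tgene\t10001\t13000\t.\t+\t.\tID=gplus",
        "chr1\tt\tmRNA\t10001\t13000\t.\t+\t.\tID=gplus.t1;Parent=gplus",
        "chr1\tt\texon\t10001\t10300\t.\t+\t.\tID=e1;Parent=gplus.t1",
        "chr1\tt\texon\t11001\t11400\t.\t+\t.\tID=e2;Parent=gplus.t1",
        "chr1\tt\texon\t12501\t13000\t.\t+\t.\tID=e3;Parent=gplus.t1",
        "chr1\tt\tgene\t20001\t22000\t.\t-\t.\tID=gminus",
        "chr1\tt\tmRNA\t20001\t22000\t.\t-\t.\tID=gminus.t1;Parent=gminus",
        "chr1\tt\texon\t20001\t20400\t.\t-\t.\tID=e4;Parent=gminus.t1",
        "chr1\tt\texon\t21501\t22000\t.\t-\t.\tID=e5;Parent=gminus.t1",
    ]
    return _write_inputs(tmp_path, {"chr1": seq}, _gff(lines))


class TestReadAnnotation:
    def test_exon_and_intron_counts(self, toy):
        genome, gff = toy
        genes, rejections = read_annotation(genome, gff)
        assert rejections == []
        by_id = {g.gene_id: g for g in genes}
        assert by_id["gplus"].n_introns == 2
        assert by_id["gminus"].n_introns == 1

    def test_minus_strand_intron_order_and_transcript(self, toy):
        genome, gff = toy
        genes, _ = read_annotation(genome, gff)
        g = next(x for x in genes if x.gene_id == "gminus")
        # intron 1 (5'->3' on gene strand) is the gap nearest the 3'-most
        # genomic coordinate
        assert g.intron_intervals()[0] == (20400, 21500)
        expect = revcomp(genome["chr1"][21500:22000]) + revcomp(
            genome["chr1"][20000:20400]
        )
        assert g.transcript == expect

    def test_exon_outside_scaffold_rejected(self, tmp_path):
        rng = np.random.default_rng(1)
        genome = {"chr1": random_seq(1000, 0.4, rng)}
        lines = [
            "chr1\tt\tgene\t500\t5000\t.\t+\t.\tID=bad",
            "chr1\tt\tmRNA\t500\t5000\t.\t+\t.\tID=bad.t1;Parent=bad",
            "chr1\tt\texon\t500\t600\t.\t+\t.\tID=x1;Parent=bad.t1",
            "chr1\tt\texon\t4000\t5000\t.\t+\t.\tID=x2;Parent=bad.t1",
        ]
        _genome, gff = _write_inputs(tmp_path, genome, _gff(lines))
        genes, rejections = read_annotation(genome, gff)
        assert genes == []
        assert rejections == [("bad", "EXON_OUTSIDE_SCAFFOLD")]

    def test_single_exon_gene_dropped_when_introns_required(self, tmp_path):
        rng = np.random.default_rng(2)
        genome = {"chr1": random_seq(2000, 0.4, rng)}
        lines = [
            "chr1\tt\tgene\t101\t400\t.\t+\t.\tID=mono",
            "chr1\tt\tmRNA\t101\t400\t.\t+\t.\tID=mono.t1;Parent=mono",
            "chr1\tt\texon\t101\t400\t.\t+\t.\tID=m1;Parent=mono.t1",
        ]
        _genome, gff = _write_inputs(tmp_path, genome, _gff(lines))
        genes, rejections = read_annotation(genome, gff)
        assert genes == []
        assert rejections == [("mono", "NO_INTRONS")]
        genes2, _ = read_annotation(genome, gff, require_introns=False)
        assert [g.gene_id for g in genes2] == ["mono"]

    def test_simulator_truth_insertions_inside_extracted_introns(
        self, small_genome
    ):
        paths_genes = small_genome.genes
        gff = None  # build models directly from simulator coordinates
        genes = [
            GeneModel(
                g.gene_id, g.scaffold, g.strand,
                tuple(tuple(e) for e in g.exons),
                transcript="",
            )
            for g in paths_genes
        ]
        regions = extract_introns(genes, small_genome.scaffolds)
        for t in small_genome.truth:
            if not t.location.startswith("INTRON"):
                continue
            containing = [
                r for r in regions.regions
                if r.gene_id == t.gene_id and r.start <= t.start and t.end <= r.end
            ]
            assert len(containing) == 1
            assert containing[0].index == int(t.location.split(":")[1])


class TestRoundTripThroughSimulator:
    def test_gff_round_trip(self, tmp_path, small_genome):
        paths = small_genome.write(tmp_path)
        genes, rejections = read_annotation(paths["genome"], paths["gff"])
        assert rejections == []
        sim = {g.gene_id: g for g in small_genome.genes}
        assert set(sim) == {g.gene_id for g in genes}
        for g in genes:
            assert tuple(tuple(e) for e in sim[g.gene_id].exons) == g.exons
            assert sim[g.gene_id].strand == g.strand


class TestVerifyGeneCoordinates:
    def test_simulator_genes_fully_verified(self, small_genome):
        genes = _models(small_genome)
        result = verify_gene_coordinates(genes, small_genome.scaffolds)
        assert len(result.verified) == len(genes)
        assert result.rejections == []
        for g in genes:
            p = result.placements[g.gene_id]
            assert p.scaffold == g.scaffold
            assert (p.start, p.end) == (g.start, g.end)
            assert p.coverage == pytest.approx(1.0)

    def test_below_identity_placement_rejected(self):
        from tegenet.synthetic_data import apply_divergence

        rng = np.random.default_rng(3)
        scaffold = random_seq(6000, 0.4, rng)
        # the annotated transcript is only ~97% identical to its claimed
        # genomic exons, below the 98% verification threshold
        transcript = apply_divergence(
            scaffold[1000:1400] + scaffold[2000:2400], 0.03, rng
        )
        ghost = GeneModel(
            "ghost", "chr1", "+", ((1000, 1400), (2000, 2400)), transcript
        )
        result = verify_gene_coordinates([ghost], {"chr1": scaffold}, min_id=0.98)
        assert result.rejections and result.rejections[0][1] == "NO_PLACEMENT"

    def test_long_gene_flagged_not_removed(self, small_genome):
        genes = _models(small_genome)
        result = verify_gene_coordinates(
            genes, small_genome.scaffolds, max_gene_len_flag=5000
        )
        long_genes = [g.gene_id for g in genes if g.span > 5000]
        assert set(result.flagged_long) == set(long_genes)
        assert len(result.verified) == len(genes)


class TestTeLikeGeneFilter:
    def test_te_built_gene_removed_small_fragment_kept(self, rlx_spec):
        rng = np.random.default_rng(6)
        te_seq, _ = synth_te_family(rlx_spec, rng)
        false_gene = GeneModel(
            "false", "c", "+", ((0, 1200),),
            te_seq[:1200],  # 60% of the RLX
        )
        honest = GeneModel(
            "honest", "c", "+", ((0, 2000),),
            random_seq(1800, 0.44, rng) + te_seq[:200],  # 10% coverage
        )
        kept, removed = filter_te_like_genes(
            [false_gene, honest], {"RLX1": te_seq}
        )
        assert [g.gene_id for g in kept] == ["honest"]
        assert removed == [("false", "RLX1")]

    def test_exact_half_coverage_kept(self, rlx_spec):
        rng = np.random.default_rng(7)
        te_seq, _ = synth_te_family(rlx_spec, rng)
        # transcript of 2000 bp with exactly 1000 TE-derived bases; the
        # other half is the base-wise complement of the TE tail, so the
        # hit cannot extend a single base past the junction
        complement_tail = te_seq[1000:2000].translate(
            str.maketrans("ACGT", "TGCA")
        )
        transcript = te_seq[:1000] + complement_tail
        gene = GeneModel("edge", "c", "+", ((0, 2000),), transcript)
        kept, removed = filter_te_like_genes([gene], {"RLX1": te_seq})
        assert removed == []  # strictly-greater rule


class TestRegionExtraction:
    def test_ten_bin_datasets(self, small_genome):
        genes = _models(small_genome)
        flanks = extract_flanks(genes, small_genome.scaffolds)
        datasets = {(r.kind, r.index) for r in flanks.regions}
        assert len(datasets) == 10

    def test_bins_partition_flank_and_are_disjoint(self, small_genome):
        genes = _models(small_genome)
        flanks = extract_flanks(genes, small_genome.scaffolds)
        for gene in genes:
            for side in ("FLANK5", "FLANK3"):
                bins = sorted(
                    (r for r in flanks.regions
                     if r.gene_id == gene.gene_id and r.kind == side),
                    key=lambda r: r.start,
                )
                for a, b in zip(bins, bins[1:]):
                    assert a.end == b.start  # contiguous, disjoint
                total = sum(r.length for r in bins)
                assert total <= 5000

    def test_scaffold_start_truncates_bins(self):
        rng = np.random.default_rng(8)
        scaffold = random_seq(9000, 0.4, rng)
        gene = GeneModel("g", "c", "+", ((2500, 2800), (3600, 3900)), "")
        flanks = extract_flanks([gene], {"c": scaffold})
        five = sorted(
            (r for r in flanks.regions if r.kind == "FLANK5"),
            key=lambda r: r.index,
        )
        assert [r.length for r in five] == [1000, 1000, 500]
        assert [r.index for r in five] == [0, 1, 2]
        assert five[-1].truncated

    def test_neighbor_overlap_allowed(self):
        rng = np.random.default_rng(9)
        scaffold = random_seq(20000, 0.4, rng)
        g1 = GeneModel("g1", "c", "+", ((6000, 6200), (7000, 7200)), "")
        g2 = GeneModel("g2", "c", "+", ((8700, 8900), (9500, 9700)), "")
        flanks = extract_flanks([g1, g2], {"c": scaffold})
        # g2's 5' bins reach into g1's 3' bins; both are emitted
        assert len([r for r in flanks.regions if r.gene_id == "g1"]) == 10
        assert len([r for r in flanks.regions if r.gene_id == "g2"]) == 10

    def test_round_trip_region_sequences(self, small_genome):
        genes = _models(small_genome)
        for rs in (extract_flanks(genes, small_genome.scaffolds),
                   extract_introns(genes, small_genome.scaffolds)):
            for r in rs.regions:
                assert (
                    small_genome.scaffolds[r.scaffold][r.start : r.end]
                    == r.sequence
                )

    def test_gene_genomic_orientation_and_length(self, small_genome):
        genes = _models(small_genome)
        bodies = extract_gene_genomic(genes, small_genome.scaffolds)
        for g in genes:
            body = bodies[g.gene_id]
            assert len(body) == g.span
            raw = small_genome.scaffolds[g.scaffold][g.start : g.end]
            assert body == (revcomp(raw) if g.strand == "-" else raw)


def _models(sim) -> list[GeneModel]:
    genes = []
    for g in sim.genes:
        seq = sim.scaffolds[g.scaffold]
        transcript = "".join(seq[s:e] for s, e in g.exons)
        if g.strand == "-":
            transcript = revcomp(transcript)
        genes.append(
            GeneModel(g.gene_id, g.scaffold, g.strand,
                      tuple(tuple(e) for e in g.exons), transcript)
        )
    return genes
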