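"""End-to-end pipeline orchestration.

Stages run in a fixed order — repeat library, region extraction,
similarity search, enrichment, networks/GO, patterns/node genes,
structural QC — against either user-supplied inputs or the bundled
synthetic fixture.  A run directory collects every stage's tables plus a
``summary.json`` with per-stage counts; reruns with the same config and
seed are byte-identical.  Stages always recompute (runs at fixture scale
take seconds, so recomputation is the simplest determinism guarantee).
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import yaml

from . import __version__
from .enrichment import (
    GROUPINGS,
    count_by_bin,
    enrich_scan,
    write_enrichment_tsv,
)
from .gene_models import (
    RegionSet,
    extract_flanks,
    extract_gene_genomic,
    extract_introns,
    filter_te_like_genes,
    read_annotation,
    write_regions_bed,
)
from .networks_go import (
    build_networks,
    export_network,
    go_overrepresentation,
    load_annotation,
    write_go_tsv,
)
from .patterns_nodes import (
    gc_profile,
    group_patterns,
    intron_signature,
    node_genes,
    write_gc_tsv,
    write_node_genes_tsv,
    write_patterns_tsv,
)
from .repeat_library import (
    TEEntry,
    cluster_library,
    extract_library,
    length_filter,
    library_stats,
)
from .seqs import read_fasta, write_fasta
from .similarity import (
    PROFILES,
    AlignParams,
    HQHitRule,
    classify_hq,
    filter_hits,
    search_many,
    unique_gene_hits,
    write_hits_tsv,
)
from .synthetic_data import (
    GenomeSpec,
    InsertionPlan,
    Motif,
    TEFamilySpec,
    synth_genome,
    synth_go_annotation,
    write_go_annotation,
    write_synthetic_obo,
)
from .te_structure import solo_ratio, split_ltr_internal, write_ratio_tsv

log = logging.getLogger("tegenet")


@dataclass
class PipelineConfig:
    """Resolved configuration of one pipeline run."""

    genome_fasta: str | None = None
    gff3: str | None = None
    te_fasta: str | None = None
    go_annotation: str | None = None
    go_obo: str | None = None
    simulate: bool = False
    profile: str = "pita"  # pita: qcov >= 90 | pila: qcov >= 80
    cluster_threshold: float = 0.8
    lib_min_len: int = 100
    lib_max_len: int = 2000
    flank_window: int = 5000
    bin_width: int = 1000
    grouping: str = "default"
    node_min_distinct: int = 8
    solo_identity_level: float = 0.9
    seed: int = 0
    outdir: str = "tegenet_run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        if self.profile not in PROFILES:
            raise ValueError(f"unknown profile {self.profile!r}")
        if self.grouping not in GROUPINGS:
            raise ValueError(f"unknown grouping {self.grouping!r}")
        if not self.simulate:
            for name in ("genome_fasta", "gff3", "te_fasta"):
                value = getattr(self, name)
                if value is None:
                    raise FileNotFoundError(f"config field {name} is required")
                if not Path(value).exists():
                    raise FileNotFoundError(f"{name}: {value} does not exist")


# ---------------------------------------------------------------------------
# the bundled synthetic fixture
# ---------------------------------------------------------------------------

def demo_families() -> list[TEFamilySpec]:
    """The fixture's three family archetypes: a Daugava-style RLX with a
    PPT and TG..CA termini, a Plater-style MITE with 24-bp TIRs and long
    TSDs, and an Irbe-style DNA transposon."""
    return [
        TEFamilySpec(
            family_id="RLX1",
            te_class="LTR_RLX",
            ltr_len=300,
            internal_len=1400,
            total_len=2000,
            tsd_len=5,
            gc_target=0.30,
        ),
        TEFamilySpec(
            family_id="MITE1",
            te_class="MITE",
            total_len=259,
            tir_len=24,
            tsd_len=9,
            gc_target=0.35,
            motifs=(Motif("TATA", "TATAWAW", "STEM"),),
        ),
        TEFamilySpec(
            family_id="DNA1",
            te_class="TIR_DNA",
            total_len=820,
            tir_len=15,
            tsd_len=8,
            gc_target=0.40,
        ),
    ]


def demo_plans(n_genes: int, rng: np.random.Generator) -> list[InsertionPlan]:
    """Insertion plans exercising every analysis: a proximally-biased
    MITE, intron RLX/DNA insertions, and solo-LTR products."""
    plans: list[InsertionPlan] = []
    k = 0

    def add(**kw):
        nonlocal k
        k += 1
        plans.append(InsertionPlan(plan_id=f"plan{k:03d}", **kw))

    # MITE enriched in the nearest flank bins
    for g in range(1, min(13, n_genes + 1)):
        side = "FLANK5" if g % 2 else "FLANK3"
        add(family_id="MITE1", gene_id=f"G{g:04d}", region=side, index=0)
    # background MITE spread over distal bins
    add(family_id="MITE1", gene_id=f"G{14:04d}", region="FLANK5", index=3)
    # full-length RLX in introns (solo-ratio and network material)
    for g in range(15, min(21, n_genes + 1)):
        add(family_id="RLX1", gene_id=f"G{g:04d}", region="INTRON", index=1)
    # solo LTRs
    for g in range(21, min(24, n_genes + 1)):
        add(
            family_id="RLX1",
            gene_id=f"G{g:04d}",
            region="INTRON",
            index=1,
            completeness="SOLO_LTR",
        )
    # DNA TE shares introns with the RLX in a few genes (pattern classes)
    for g in range(15, min(19, n_genes + 1)):
        add(family_id="DNA1", gene_id=f"G{g:04d}", region="INTRON", index=1)
    return plans


def simulate_fixture(seed: int, outdir: Path) -> dict[str, Path]:
    """Generate the bundled fixture into ``outdir`` and return paths."""
    gspec = GenomeSpec(
        n_scaffolds=2,
        n_genes=24,
        exon_len_dist=(150, 400),
        intron_len_dist=(2500, 4000),
        intergenic_len=12000,
        background_gc=0.38,
        rng_seed=seed,
    )
    rng = np.random.default_rng(seed + 1)
    plans = demo_plans(gspec.n_genes, rng)
    genome = synth_genome(gspec, demo_families(), plans)
    paths = genome.write(outdir)
    gene_ids = [g.gene_id for g in genome.genes]
    annot = synth_go_annotation(gene_ids, rng)
    paths["go_annotation"] = outdir / "go_annotation.tsv"
    paths["go_obo"] = outdir / "go.obo"
    write_go_annotation(paths["go_annotation"], annot)
    write_synthetic_obo(paths["go_obo"])
    return paths


# ---------------------------------------------------------------------------
# the run
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute all stages; returns the summary dict (also written to
    ``summary.json`` in the run directory)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir)
    log.info("tegenet %s | seed=%d profile=%s", __version__, config.seed, config.profile)
    summary: dict[str, Any] = {
        "version": __version__,
        "config": asdict(config),
        "stages": {},
    }

    if config.simulate:
        fixture_dir = outdir / "fixture"
        paths = simulate_fixture(config.seed, fixture_dir)
        config.genome_fasta = str(paths["genome"])
        config.gff3 = str(paths["gff"])
        config.te_fasta = str(paths["te_fasta"])
        config.go_annotation = str(paths["go_annotation"])
        config.go_obo = str(paths["go_obo"])
        summary["stages"]["simulate"] = {"outdir": str(fixture_dir)}

    # stage 1: repeat library -------------------------------------------
    entries = [TEEntry(name, seq) for name, seq in read_fasta(config.te_fasta)]
    lib = extract_library(entries)
    lib = cluster_library(lib, threshold=config.cluster_threshold)
    lib, reduction = length_filter(lib, config.lib_min_len, config.lib_max_len)
    stats = library_stats(lib)
    write_fasta(outdir / "repeat_library.fa",
                [(r.repeat_id, r.sequence) for r in lib.repeats])
    _write_provenance(outdir / "library_provenance.tsv", lib.provenance)
    summary["stages"]["library"] = {
        "n_entries": len(entries),
        "n_repeats": len(lib),
        "percent_reduction": reduction.percent_reduction,
        "mean_length": stats.mean_length if stats else 0,
        "median_length": stats.median_length if stats else 0,
    }

    # stage 2: regions ---------------------------------------------------
    genome = dict(read_fasta(config.genome_fasta))
    genes, rejections = read_annotation(genome, config.gff3)
    te_seqs = {e.entry_id: e.sequence for e in entries}
    genes, removed = filter_te_like_genes(genes, te_seqs)
    flanks = extract_flanks(genes, genome, config.flank_window, config.bin_width)
    introns = extract_introns(genes, genome)
    gene_bodies = extract_gene_genomic(genes, genome)
    all_regions = RegionSet(flanks.regions + introns.regions)
    write_regions_bed(outdir / "regions.bed", all_regions.regions)
    n_bin_datasets = len({(r.kind, r.index) for r in flanks.regions})
    summary["stages"]["regions"] = {
        "n_genes": len(genes),
        "n_rejected": len(rejections),
        "n_te_like_removed": len(removed),
        "n_flank_bin_datasets": n_bin_datasets,
        "n_flank_regions": len(flanks.regions),
        "n_introns": len(introns.regions),
        "n_gene_bodies": len(gene_bodies),
    }

    # stage 3: similarity search ----------------------------------------
    queries = {r.repeat_id: r.sequence for r in lib.repeats}
    raw_hits = search_many(queries, all_regions.subjects(), AlignParams())
    hit_filter = PROFILES[config.profile]
    kept_hits = filter_hits(raw_hits, hit_filter)
    write_hits_tsv(outdir / "hits.tsv", kept_hits)
    summary["stages"]["search"] = {
        "n_raw_hits": len(raw_hits),
        "n_filtered_hits": len(kept_hits),
    }

    # stage 4: enrichment ------------------------------------------------
    region_map = all_regions.region_map()
    uniq = unique_gene_hits(kept_hits, region_map)
    matrix = count_by_bin(uniq, flanks.bin_counts())
    results = enrich_scan(matrix, GROUPINGS[config.grouping])
    write_enrichment_tsv(outdir / "enrichment.tsv", matrix, results)
    summary["stages"]["enrich"] = {
        "n_queries_scanned": len(results),
        "n_p001": sum(1 for r in results if r.significance == "P001"),
        "n_p05": sum(1 for r in results if r.significance == "P05"),
    }

    # stage 5: networks / GO --------------------------------------------
    mite_like = {
        r.repeat_id for r in lib.repeats if len(r.sequence) <= 500
    }
    family_of_query = {r.repeat_id: r.parent_id for r in lib.repeats}
    hq = classify_hq(raw_hits, HQHitRule(), mite_like)
    networks = build_networks(hq, region_map, family_of_query)
    export_network(networks, outdir / "networks.graphml", "graphml")
    export_network(networks, outdir / "networks.sif", "sif")
    go_rows_total = 0
    if config.go_annotation:
        annotation = load_annotation(config.go_annotation, config.go_obo)
        for key in sorted(networks, key=lambda k: (k.family_id, k.location)):
            rows = go_overrepresentation(networks[key], annotation)
            go_rows_total += len(rows)
            write_go_tsv(
                outdir / f"go_{key.family_id}_{key.location}.tsv", rows
            )
    summary["stages"]["networks"] = {
        "n_hq_hits": len(hq),
        "n_networks": len(networks),
        "network_sizes": {
            f"{k.family_id}@{k.location}": len(networks[k])
            for k in sorted(networks, key=lambda k: (k.family_id, k.location))
        },
        "n_go_rows": go_rows_total,
    }

    # stage 6: patterns / node genes / GC -------------------------------
    intron_map = {
        rid: info for rid, info in region_map.items() if info[1] == "INTRON"
    }
    short_by_gene: dict[str, list] = {}
    long_by_gene: dict[str, list] = {}
    for h in kept_hits:
        if h.subject_id not in intron_map:
            continue
        gene_id = intron_map[h.subject_id][0]
        short_by_gene.setdefault(gene_id, []).append(h)
    for h in hq:
        if h.subject_id not in intron_map:
            continue
        gene_id = intron_map[h.subject_id][0]
        if h.aln_len > 1000:
            long_by_gene.setdefault(gene_id, []).append(h)
    signatures = [
        intron_signature(
            g,
            short_by_gene.get(g, []),
            long_by_gene.get(g, []),
            family_of_query,
        )
        for g in sorted(set(short_by_gene) | set(long_by_gene))
    ]
    classes = group_patterns(signatures)
    nodes = node_genes(signatures, config.node_min_distinct)
    write_patterns_tsv(outdir / "patterns.tsv", classes)
    write_node_genes_tsv(outdir / "node_genes.tsv", nodes)
    gene_by_id = {g.gene_id: g for g in genes}
    profiles = []
    intron_seqs_by_gene: dict[str, list[str]] = {}
    for r in introns.regions:
        intron_seqs_by_gene.setdefault(r.gene_id, []).append(r.sequence)
    for gid in sorted(intron_seqs_by_gene):
        profiles.append(
            gc_profile(gid, gene_by_id[gid].transcript, intron_seqs_by_gene[gid])
        )
    write_gc_tsv(outdir / "gc_profiles.tsv", profiles)
    summary["stages"]["patterns"] = {
        "n_signatures": len(signatures),
        "n_pattern_classes": len(classes),
        "n_node_genes": len(nodes),
    }

    # stage 7: structural QC --------------------------------------------
    ratios = []
    for entry in entries:
        try:
            ltr, internal = split_ltr_internal(entry)
        except Exception:
            continue
        part_queries = {
            f"{entry.entry_id}:ltr": ltr,
            f"{entry.entry_id}:internal": internal,
        }
        part_hits = search_many(
            part_queries, {r.region_id: r.sequence for r in introns.regions}
        )
        good = [h for h in part_hits if h.qcov_hsp >= 90.0]
        report = solo_ratio(
            entry.entry_id,
            [h for h in good if h.query_id.endswith(":ltr")],
            [h for h in good if h.query_id.endswith(":internal")],
            config.solo_identity_level,
        )
        ratios.append(report)
    write_ratio_tsv(outdir / "solo_ratios.tsv", ratios)
    summary["stages"]["structure_qc"] = {
        "ratios": {
            r.family_id: (None if r.ratio is None else round(r.ratio, 3))
            for r in ratios
        }
    }

    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
    log.info("pipeline complete: %s", outdir / "summary.json")
    return summary


def _write_provenance(path: Path, provenance: Sequence[tuple[str, int]]) -> None:
    with open(path, "w") as fh:
        fh.write("step\tcount\n")
        for step, count in provenance:
            fh.write(f"{step}\t{count}\n")


def _setup_logging(outdir: Path) -> None:
    if not log.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
        log.addHandler(handler)
        log.setLevel(logging.INFO)
        log.propagate = False
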