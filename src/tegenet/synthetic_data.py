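"""Synthetic genomes with planted transposable-element insertions.

Every downstream stage of the pipeline is exercised against genomes built
here, where the ground truth of each planted insertion is known exactly.
The simulator emulates the features the analyses depend on:

* gene models with exons and introns on both strands, GC-rich transcripts
  against an AT-rich intergenic background (gymnosperm genomes average
  roughly 38% GC);
* LTR retrotransposons (RLX) with two identical LTR copies starting TG and
  ending CA, a polypurine tract (PPT) immediately 5' of the 3' LTR, and
  optional promoter-like IUPAC motifs;
* MITEs / DNA transposons with terminal inverted repeats (TIRs);
* insertion degradation classes: full-length elements, solo LTRs left by
  intra-element recombination, internal-only fragments, and truncations;
* target-site duplications (TSDs), substitution divergence, N-masking and
  nested insertions.

Insertions are planted sequentially; coordinates of features already on
the scaffold are shifted rightward, and the emitted truth table stores
final coordinates so it is directly comparable to pipeline output.
Divergence is substitution-only so truth coordinates stay exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .seqs import random_seq, revcomp, sample_iupac, write_fasta

LOCATION_KINDS = ("FLANK5", "FLANK3", "INTRON")
COMPLETENESS = ("FULL", "SOLO_LTR", "INTERNAL_ONLY", "TRUNCATED")

#: canonical PPT motif observed in pine RLX elements
PPT_MOTIF = "AAGAGGGAG"


class SpecificationError(ValueError):
    """An invalid family/genome/plan specification."""


class StructureError(ValueError):
    """A sequence does not have the structural layout an operation needs."""


@dataclass(frozen=True)
class Motif:
    name: str
    iupac: str
    where: str = "ANYWHERE"  # PPT | LTR | INTERNAL | STEM | ANYWHERE


@dataclass(frozen=True)
class TEFamilySpec:
    """Blueprint of one TE family consensus."""

    family_id: str
    te_class: str  # LTR_RLX | TIR_DNA | MITE
    total_len: int
    ltr_len: int = 0
    internal_len: int = 0
    tir_len: int = 0
    tsd_len: int = 5
    gc_target: float = 0.38
    motifs: tuple[Motif, ...] = ()

    def validate(self) -> None:
        if self.te_class not in ("LTR_RLX", "TIR_DNA", "MITE"):
            raise SpecificationError(f"unknown te_class {self.te_class!r}")
        if self.tsd_len < 0:
            raise SpecificationError("tsd_len must be >= 0")
        if not 0.0 < self.gc_target < 1.0:
            raise SpecificationError("gc_target must be in (0, 1)")
        if self.te_class == "LTR_RLX":
            if self.ltr_len < 10 or self.internal_len < 20:
                raise SpecificationError(
                    "LTR_RLX needs ltr_len >= 10 and internal_len >= 20"
                )
            if self.total_len != 2 * self.ltr_len + self.internal_len:
                raise SpecificationError(
                    "LTR_RLX total_len must equal 2*ltr_len + internal_len"
                )
        else:
            if self.tir_len < 1:
                raise SpecificationError(f"{self.te_class} needs tir_len >= 1")
            if 2 * self.tir_len > self.total_len:
                raise SpecificationError("2*tir_len must not exceed total_len")


@dataclass(frozen=True)
class GenomeSpec:
    n_scaffolds: int = 2
    n_genes: int = 30
    exon_len_dist: tuple[int, int] = (150, 400)
    intron_len_dist: tuple[int, int] = (800, 3000)
    intergenic_len: int = 12000
    background_gc: float = 0.38
    gene_gc: float = 0.44
    rng_seed: int = 0

    def validate(self) -> None:
        for lo, hi in (self.exon_len_dist, self.intron_len_dist):
            if lo <= 0 or hi < lo:
                raise SpecificationError("length distributions need 0 < min <= max")
        if self.intergenic_len <= 0 or self.n_scaffolds < 1 or self.n_genes < 1:
            raise SpecificationError("all counts/lengths must be positive")
        if not 0.0 < self.background_gc < 1.0:
            raise SpecificationError("background_gc must be in (0, 1)")


@dataclass(frozen=True)
class InsertionPlan:
    plan_id: str
    family_id: str
    gene_id: str
    region: str  # FLANK5 | FLANK3 | INTRON
    index: int  # flank bin 0..4, or 1-based intron index
    completeness: str = "FULL"
    divergence: float = 0.0
    strand: str = "+"
    nested_into: str | None = None
    mask_fraction: float = 0.0

    def validate(self) -> None:
        if self.region not in LOCATION_KINDS:
            raise SpecificationError(f"bad region {self.region!r}")
        if self.region != "INTRON" and not 0 <= self.index <= 4:
            raise SpecificationError("flank bin index must be in 0..4")
        if self.region == "INTRON" and self.index < 1:
            raise SpecificationError("intron index is 1-based")
        if self.completeness not in COMPLETENESS:
            raise SpecificationError(f"bad completeness {self.completeness!r}")
        if not 0.0 <= self.divergence <= 0.3:
            raise SpecificationError("divergence must be in [0, 0.3]")
        if not 0.0 <= self.mask_fraction <= 1.0:
            raise SpecificationError("mask_fraction must be in [0, 1]")
        if self.strand not in "+-":
            raise SpecificationError("strand must be + or -")


@dataclass
class TruthRecord:
    """Final coordinates and provenance of one planted insertion."""

    scaffold: str
    start: int
    end: int  # 0-based half-open
    family_id: str
    location: str  # e.g. "FLANK5:0" or "INTRON:2"
    completeness: str
    divergence: float
    strand: str
    tsd: str
    gene_id: str
    plan_id: str


@dataclass
class SimGene:
    gene_id: str
    scaffold: str
    strand: str
    exons: list[list[int]]  # absolute [start, end), sorted by coordinate

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def introns(self) -> list[tuple[int, int]]:
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]


@dataclass
class SyntheticGenome:
    scaffolds: dict[str, str]
    genes: list[SimGene]
    truth: list[TruthRecord]
    families: dict[str, tuple[str, list[tuple[str, int, int]]]]
    spec: GenomeSpec

    # -- writers ----------------------------------------------------------
    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fa",
            "gff": outdir / "genes.gff3",
            "truth_tsv": outdir / "truth.tsv",
            "truth_bed": outdir / "truth.bed",
            "te_fasta": outdir / "te_families.fa",
        }
        write_fasta(paths["genome"], sorted(self.scaffolds.items()))
        self.write_gff3(paths["gff"])
        self.write_truth(paths["truth_tsv"], paths["truth_bed"])
        write_fasta(
            paths["te_fasta"],
            [(fid, seq) for fid, (seq, _f) in sorted(self.families.items())],
        )
        return paths

    def write_gff3(self, path: str | Path) -> None:
        lines = ["##gff-version 3"]
        for g in sorted(self.genes, key=lambda g: (g.scaffold, g.start)):
            s1, e1 = g.start + 1, g.end  # 1-based inclusive
            lines.append(
                f"{g.scaffold}\ttegenet\tgene\t{s1}\t{e1}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}"
            )
            mrna = f"{g.gene_id}.t1"
            lines.append(
                f"{g.scaffold}\ttegenet\tmRNA\t{s1}\t{e1}\t.\t{g.strand}\t.\t"
                f"ID={mrna};Parent={g.gene_id}"
            )
            for i, (es, ee) in enumerate(g.exons, start=1):
                lines.append(
                    f"{g.scaffold}\ttegenet\texon\t{es + 1}\t{ee}\t.\t{g.strand}\t.\t"
                    f"ID={mrna}.exon{i};Parent={mrna}"
                )
        Path(path).write_text("\n".join(lines) + "\n")

    def write_truth(self, tsv_path: str | Path, bed_path: str | Path | None = None) -> None:
        header = (
            "scaffold\tstart\tend\tfamily_id\tlocation\tcompleteness\t"
            "divergence\tstrand\ttsd\tgene_id\tplan_id\n"
        )
        with open(tsv_path, "w") as fh:
            fh.write(header)
            for t in self.truth:
                fh.write(
                    f"{t.scaffold}\t{t.start}\t{t.end}\t{t.family_id}\t"
                    f"{t.location}\t{t.completeness}\t{t.divergence:g}\t"
                    f"{t.strand}\t{t.tsd}\t{t.gene_id}\t{t.plan_id}\n"
                )
        if bed_path is not None:
            with open(bed_path, "w") as fh:
                for t in self.truth:
                    name = f"{t.family_id}|{t.location}|{t.gene_id}"
                    fh.write(
                        f"{t.scaffold}\t{t.start}\t{t.end}\t{name}\t0\t{t.strand}\n"
                    )


# ---------------------------------------------------------------------------
# family synthesis
# ---------------------------------------------------------------------------

def synth_te_family(
    spec: TEFamilySpec, rng: np.random.Generator, max_tries: int = 50
) -> tuple[str, list[tuple[str, int, int]]]:
    """Build one family consensus and its feature table.

    LTR_RLX layout: LTR5 | internal (..PPT at its 3' end) | LTR3, both LTR
    copies identical, each starting TG and ending CA.  MITE/TIR_DNA layout:
    TIR | stem | revcomp(TIR).  Each motif's concrete sequence is planted
    once and the draw is retried if it occurs anywhere else by chance.
    """
    spec.validate()
    for _ in range(max_tries):
        seq, features, planted = _assemble_family(spec, rng)
        if all(seq.count(m) == 1 for m in planted):
            return seq, features
    raise RuntimeError(
        f"could not place motifs uniquely for family {spec.family_id}"
    )


def _assemble_family(spec, rng):
    features: list[tuple[str, int, int]] = []
    planted: list[str] = []
    if spec.te_class == "LTR_RLX":
        ltr = list("TG" + random_seq(spec.ltr_len - 4, spec.gc_target, rng) + "CA")
        internal = list(random_seq(spec.internal_len, spec.gc_target, rng))
        # PPT sits immediately 5' of the 3' LTR, i.e. at the internal 3' end
        ppt = PPT_MOTIF
        internal[-len(ppt):] = ppt
        planted.append(ppt)
        for m in spec.motifs:
            concrete = sample_iupac(m.iupac, rng)
            if m.where == "PPT":
                internal[-len(concrete):] = concrete
                planted[-1] = concrete  # replaces the default PPT
            elif m.where == "LTR":
                off = int(rng.integers(2, spec.ltr_len - 2 - len(concrete)))
                ltr[off : off + len(concrete)] = concrete
                planted.append(concrete)
            else:  # INTERNAL / ANYWHERE
                off = int(rng.integers(0, spec.internal_len - len(ppt) - len(concrete)))
                internal[off : off + len(concrete)] = concrete
                planted.append(concrete)
        ltr_s = "".join(ltr)
        internal_s = "".join(internal)
        seq = ltr_s + internal_s + ltr_s
        L, I = spec.ltr_len, spec.internal_len
        features = [
            ("LTR5", 0, L),
            ("internal", L, L + I),
            ("PPT", L + I - len(ppt), L + I),
            ("LTR3", L + I, 2 * L + I),
        ]
        # motifs inside the LTR occur twice (one per copy) by construction,
        # so only non-LTR motifs enter the uniqueness check
        uniq = [p for p in planted if p not in ltr_s]
        return seq, features, uniq
    else:  # MITE / TIR_DNA: TIR | stem | revcomp(TIR)
        t = spec.tir_len
        tir = random_seq(t, spec.gc_target, rng)
        stem = list(random_seq(spec.total_len - 2 * t, spec.gc_target, rng))
        # keep the TIR at exactly tir_len: the stem edges must not form a
        # chance extension of the inverted repeat
        comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
        if stem and stem[0] == comp[stem[-1]]:
            choices = [b for b in "ACGT" if b != stem[0]]
            stem[0] = choices[int(rng.integers(3))]
        for m in spec.motifs:
            concrete = sample_iupac(m.iupac, rng)
            off = int(rng.integers(0, max(1, len(stem) - len(concrete))))
            stem[off : off + len(concrete)] = concrete
            planted.append(concrete)
        seq = tir + "".join(stem) + revcomp(tir)
        features = [
            ("TIR5", 0, t),
            ("stem", t, spec.total_len - t),
            ("TIR3", spec.total_len - t, spec.total_len),
        ]
        return seq, features, planted


# ---------------------------------------------------------------------------
# sequence degradation operators
# ---------------------------------------------------------------------------

def apply_divergence(seq: str, d: float, rng: np.random.Generator) -> str:
    """Substitute a fraction ``d`` of positions (never inside N runs)."""
    if not 0.0 <= d <= 0.3:
        raise SpecificationError("divergence must be in [0, 0.3]")
    if d == 0.0 or not seq:
        return seq
    arr = np.array(list(seq), dtype="U1")
    eligible = arr != "N"
    hit = (rng.random(len(arr)) < d) & eligible
    for i in np.nonzero(hit)[0]:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[int(rng.integers(3))]
    return "".join(arr)


def recombine_solo_ltr(locus: str, min_ltr: int = 50, min_id: float = 0.8) -> str:
    """Model intra-element recombination of a full-length RLX locus:
    collapse LTR-internal-LTR into a single LTR.

    The terminal direct-repeat pair is located by scanning prefix/suffix
    lengths and taking the identity-maximising length (ties to the longer);
    the 5' copy is returned.  Inputs without such a layout raise
    StructureError — applying the operation twice therefore fails.
    """
    n = len(locus)
    best_len, best_id = 0, 0.0
    for L in range(min_ltr, (n - 1) // 2 + 1):
        a, b = locus[:L], locus[n - L :]
        m = sum(1 for x, y in zip(a, b) if x == y and x != "N")
        ident = m / L
        if ident >= min_id and ident >= best_id:
            best_len, best_id = L, ident
    if best_len == 0:
        raise StructureError("input is not a FULL LTR-internal-LTR layout")
    return locus[:best_len]


def mask_regions(
    seq: str, fraction: float, rng: np.random.Generator, run_len: int = 50
) -> str:
    """Replace ~fraction of positions with N in contiguous runs."""
    if not 0.0 <= fraction <= 1.0:
        raise SpecificationError("mask fraction must be in [0, 1]")
    n = len(seq)
    target = int(round(fraction * n))
    if target == 0:
        return seq
    if target >= n:
        return "N" * n
    arr = np.array(list(seq), dtype="U1")
    masked = int((arr == "N").sum())
    tries = 0
    while masked < target and tries < 10 * n:
        tries += 1
        need = target - masked
        run = min(run_len, need)
        start = int(rng.integers(0, n - run + 1))
        window = arr[start : start + run]
        fresh = int((window != "N").sum())
        if fresh == 0:
            continue
        if fresh > need:
            run = need  # shrink the run so we land on the target
            window = arr[start : start + run]
        window[:] = "N"
        masked = int((arr == "N").sum())
    return "".join(arr)


# ---------------------------------------------------------------------------
# genome assembly and insertion planting
# ---------------------------------------------------------------------------

def synth_genome(
    gspec: GenomeSpec,
    families: Sequence[TEFamilySpec],
    plans: Sequence[InsertionPlan] = (),
) -> SyntheticGenome:
    """Build a genome with gene models, then plant the planned insertions.

    Same seed => byte-identical FASTA/GFF3/truth outputs.
    """
    gspec.validate()
    for f in families:
        f.validate()
    for p in plans:
        p.validate()
    rng = np.random.default_rng(gspec.rng_seed)

    fam_specs = {f.family_id: f for f in families}
    fam_seqs: dict[str, tuple[str, list[tuple[str, int, int]]]] = {}
    for f in families:  # fixed order => deterministic
        fam_seqs[f.family_id] = synth_te_family(f, rng)

    scaffolds, genes = _build_gene_space(gspec, rng)
    genome = SyntheticGenome(
        scaffolds=scaffolds, genes=genes, truth=[], families=fam_seqs, spec=gspec
    )

    gene_by_id = {g.gene_id: g for g in genes}
    plan_by_id = {p.plan_id: p for p in plans}
    children: dict[str, list[InsertionPlan]] = {}
    top_level: list[InsertionPlan] = []
    for p in plans:
        if p.nested_into is not None:
            if p.nested_into not in plan_by_id:
                raise SpecificationError(
                    f"plan {p.plan_id} nests into unknown plan {p.nested_into}"
                )
            children.setdefault(p.nested_into, []).append(p)
        else:
            top_level.append(p)

    for plan in top_level:
        if plan.family_id not in fam_seqs:
            raise SpecificationError(f"plan references unknown family {plan.family_id}")
        if plan.gene_id not in gene_by_id:
            raise SpecificationError(f"plan references unknown gene {plan.gene_id}")
        _plant(genome, plan, children.get(plan.plan_id, ()), fam_specs, fam_seqs,
               gene_by_id[plan.gene_id], rng)
    genome.truth.sort(key=lambda t: (t.scaffold, t.start))
    return genome


def _build_gene_space(gspec: GenomeSpec, rng: np.random.Generator):
    scaffolds: dict[str, str] = {}
    genes: list[SimGene] = []
    per_scaffold = [[] for _ in range(gspec.n_scaffolds)]
    for i in range(gspec.n_genes):
        per_scaffold[i % gspec.n_scaffolds].append(i)
    for s_idx in range(gspec.n_scaffolds):
        name = f"scf{s_idx + 1}"
        parts: list[str] = []
        pos = 0
        for g_idx in per_scaffold[s_idx]:
            inter = random_seq(gspec.intergenic_len, gspec.background_gc, rng)
            parts.append(inter)
            pos += len(inter)
            n_exons = int(rng.integers(2, 5))
            exons: list[list[int]] = []
            strand = "+" if rng.random() < 0.5 else "-"
            for e in range(n_exons):
                if e > 0:
                    ilen = int(rng.integers(gspec.intron_len_dist[0],
                                            gspec.intron_len_dist[1] + 1))
                    parts.append(random_seq(ilen, gspec.background_gc, rng))
                    pos += ilen
                elen = int(rng.integers(gspec.exon_len_dist[0],
                                        gspec.exon_len_dist[1] + 1))
                parts.append(random_seq(elen, gspec.gene_gc, rng))
                exons.append([pos, pos + elen])
                pos += elen
            genes.append(SimGene(f"G{g_idx + 1:04d}", name, strand, exons))
        parts.append(random_seq(gspec.intergenic_len, gspec.background_gc, rng))
        pos += gspec.intergenic_len
        scaffolds[name] = "".join(parts)
    return scaffolds, genes


def _element_sequence(
    plan: InsertionPlan,
    child_plans: Sequence[InsertionPlan],
    fam_specs: dict[str, TEFamilySpec],
    fam_seqs: dict,
    rng: np.random.Generator,
) -> tuple[str, list[tuple[InsertionPlan, int, int, str]]]:
    """Assemble the sequence to plant and relative child intervals."""
    fspec = fam_specs[plan.family_id]
    consensus = fam_seqs[plan.family_id][0]
    if plan.completeness == "FULL":
        seq = consensus
    elif plan.completeness == "SOLO_LTR":
        if fspec.te_class != "LTR_RLX":
            raise SpecificationError("SOLO_LTR requires an LTR_RLX family")
        seq = consensus[: fspec.ltr_len]
    elif plan.completeness == "INTERNAL_ONLY":
        if fspec.te_class != "LTR_RLX":
            raise SpecificationError("INTERNAL_ONLY requires an LTR_RLX family")
        seq = consensus[fspec.ltr_len : fspec.ltr_len + fspec.internal_len]
    else:  # TRUNCATED: keep a contiguous 30-70% slice
        frac = float(rng.uniform(0.3, 0.7))
        keep = max(1, int(len(consensus) * frac))
        start = int(rng.integers(0, len(consensus) - keep + 1))
        seq = consensus[start : start + keep]

    child_records: list[tuple[InsertionPlan, int, int, str]] = []
    for cp in child_plans:
        if plan.completeness != "FULL":
            raise SpecificationError("nesting requires a FULL outer element")
        inner_seq, _ = _element_sequence(cp, (), fam_specs, fam_seqs, rng)
        if cp.divergence:
            inner_seq = apply_divergence(inner_seq, cp.divergence, rng)
        if cp.strand == "-":
            inner_seq = revcomp(inner_seq)
        lo = fspec.ltr_len if fspec.te_class == "LTR_RLX" else fspec.tir_len
        hi = len(seq) - lo
        cspec = fam_specs[cp.family_id]
        p = int(rng.integers(lo, max(lo + 1, hi)))
        tsd = seq[p : p + cspec.tsd_len]
        seq = seq[: p + cspec.tsd_len] + inner_seq + seq[p:]
        # shift previously placed children that sit downstream
        shift = cspec.tsd_len + len(inner_seq)
        child_records = [
            (q, s + shift if s >= p else s, e + shift if s >= p else e, t)
            for q, s, e, t in child_records
        ]
        child_records.append((cp, p + cspec.tsd_len, p + cspec.tsd_len + len(inner_seq), tsd))
    return seq, child_records


def _plant(genome, plan, child_plans, fam_specs, fam_seqs, gene, rng) -> None:
    seq, child_records = _element_sequence(plan, child_plans, fam_specs, fam_seqs, rng)
    if plan.divergence:
        seq = apply_divergence(seq, plan.divergence, rng)
    if plan.strand == "-":
        n = len(seq)
        seq = revcomp(seq)
        child_records = [(cp, n - e, n - s, t) for cp, s, e, t in child_records]
    if plan.mask_fraction:
        seq = mask_regions(seq, plan.mask_fraction, rng)

    fspec = fam_specs[plan.family_id]
    pos = _pick_position(genome, plan, gene, margin=fspec.tsd_len + 45, rng=rng)
    scaffold = gene.scaffold
    host = genome.scaffolds[scaffold]
    tsd = host[pos : pos + fspec.tsd_len]
    genome.scaffolds[scaffold] = host[: pos + fspec.tsd_len] + seq + host[pos:]
    shift = fspec.tsd_len + len(seq)

    for g in genome.genes:
        if g.scaffold != scaffold:
            continue
        for ex in g.exons:
            if ex[0] >= pos:
                ex[0] += shift
                ex[1] += shift
    for t in genome.truth:
        if t.scaffold == scaffold and t.start >= pos:
            t.start += shift
            t.end += shift

    location = f"{plan.region}:{plan.index}"
    elem_start = pos + fspec.tsd_len
    genome.truth.append(
        TruthRecord(scaffold, elem_start, elem_start + len(seq), plan.family_id,
                    location, plan.completeness, plan.divergence, plan.strand,
                    tsd, gene.gene_id, plan.plan_id)
    )
    for cp, cs, ce, ctsd in child_records:
        genome.truth.append(
            TruthRecord(scaffold, elem_start + cs, elem_start + ce, cp.family_id,
                        location, cp.completeness, cp.divergence, cp.strand,
                        ctsd, gene.gene_id, cp.plan_id)
        )


def _pick_position(genome, plan, gene, margin, rng) -> int:
    scaffold_len = len(genome.scaffolds[gene.scaffold])
    if plan.region == "INTRON":
        introns = gene.introns()
        if gene.strand == "-":
            introns = introns[::-1]
        if plan.index > len(introns):
            raise SpecificationError(
                f"plan {plan.plan_id}: gene {gene.gene_id} has no intron "
                f"{plan.index} (only {len(introns)})"
            )
        lo, hi = introns[plan.index - 1]
    else:
        b = plan.index
        upstream = (plan.region == "FLANK5") == (gene.strand == "+")
        if upstream:
            lo, hi = gene.start - (b + 1) * 1000, gene.start - b * 1000
        else:
            lo, hi = gene.end + b * 1000, gene.end + (b + 1) * 1000
    lo = max(lo + margin, margin)
    hi = min(hi - margin, scaffold_len - margin)
    if hi <= lo:
        raise SpecificationError(
            f"plan {plan.plan_id}: no room in {plan.region}:{plan.index} "
            f"of {gene.gene_id}"
        )
    occupied = [
        (t.start, t.end) for t in genome.truth if t.scaffold == gene.scaffold
    ]
    for _ in range(200):
        p = int(rng.integers(lo, hi))
        if all(p < s - margin or p >= e + margin for s, e in occupied):
            return p
    raise SpecificationError(
        f"plan {plan.plan_id}: could not find a free position in "
        f"{plan.region}:{plan.index} of {gene.gene_id}"
    )


# ---------------------------------------------------------------------------
# synthetic GO annotation (for the networks stage)
# ---------------------------------------------------------------------------

def synth_go_annotation(
    gene_ids: Sequence[str],
    rng: np.random.Generator,
    n_terms: int = 20,
    terms_per_gene: tuple[int, int] = (1, 4),
    annotated_fraction: float = 0.8,
) -> dict[str, set[str]]:
    """Random gene -> GO-term map over a small synthetic term set."""
    terms = [f"GO:{7000000 + i:07d}" for i in range(n_terms)]
    annot: dict[str, set[str]] = {}
    for gid in gene_ids:
        if rng.random() >= annotated_fraction:
            continue
        k = int(rng.integers(terms_per_gene[0], terms_per_gene[1] + 1))
        picks = rng.choice(n_terms, size=min(k, n_terms), replace=False)
        annot[gid] = {terms[int(i)] for i in picks}
    return annot


def write_go_annotation(path: str | Path, annot: dict[str, set[str]]) -> None:
    with open(path, "w") as fh:
        for gid in sorted(annot):
            for term in sorted(annot[gid]):
                fh.write(f"{gid}\t{term}\n")


def write_synthetic_obo(path: str | Path, n_terms: int = 20) -> None:
    """Tiny synthetic ontology: a root plus flat is_a children, matching the
    term ids produced by synth_go_annotation."""
    lines = ["format-version: 1.2", "ontology: go-synthetic", ""]
    root = "GO:0008150"
    lines += ["[Term]", f"id: {root}", "name: biological_process", ""]
    for i in range(n_terms):
        tid = f"GO:{7000000 + i:07d}"
        lines += ["[Term]", f"id: {tid}", f"name: synthetic process {i}",
                  f"is_a: {root} ! biological_process", ""]
    Path(path).write_text("\n".join(lines))
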