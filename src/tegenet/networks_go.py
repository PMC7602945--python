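"""TE-gene network formation and GO-term overrepresentation.

Genes sharing high-quality hits to the same TE family in the same
location class — the 0-2 kb 5' flank, the 0-2 kb 3' flank, or introns —
form a network.  Each network's annotated members are tested for GO-term
overrepresentation against the full annotated gene background with an
exact hypergeometric upper-tail test and Bonferroni correction (the
number of terms actually tested in that network is the default
correction factor, mirroring BINGO).  Annotations are propagated to all
ancestor terms along is_a/part_of edges before testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import obonet

from .similarity import Hit

#: network location classes
LOCATION_CLASSES = ("FLANK5_0_2KB", "FLANK3_0_2KB", "INTRON")

#: flank bins within 0-2 kb of the gene (bin resolution)
_NEAR_BINS = (0, 1)


@dataclass(frozen=True)
class NetworkKey:
    family_id: str
    location: str

    def __post_init__(self):
        if self.location not in LOCATION_CLASSES:
            raise ValueError(f"bad location class {self.location!r}")


@dataclass
class GeneNetwork:
    key: NetworkKey
    members: set[str]
    supporting_hits: dict[str, list[Hit]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class GOEnrichmentRow:
    term: str
    k: int  # network genes with the term
    n: int  # annotated network genes
    K: int  # background genes with the term
    N: int  # background size
    p_hyper: float
    p_bonf: float


# ---------------------------------------------------------------------------
# network formation
# ---------------------------------------------------------------------------

def build_networks(
    hq_hits: Iterable[Hit],
    region_map: Mapping[str, tuple[str, str, int]],
    family_of_query: Mapping[str, str] | None = None,
) -> dict[NetworkKey, GeneNetwork]:
    """Group genes by (family, location class) from high-quality hits.

    ``region_map`` resolves subject region ids to (gene, kind, index);
    flank hits count only when the bin lies within 0-2 kb.
    ``family_of_query`` maps query ids to family ids (identity by default,
    so each repeat query is its own family).  A gene appears once per
    network however many HSPs support it.
    """
    networks: dict[NetworkKey, GeneNetwork] = {}
    for h in hq_hits:
        if h.subject_id not in region_map:
            raise KeyError(f"unresolvable region id {h.subject_id!r}")
        gene_id, kind, index = region_map[h.subject_id]
        if kind == "INTRON":
            location = "INTRON"
        elif kind in ("FLANK5", "FLANK3"):
            if index not in _NEAR_BINS:
                continue
            location = f"{kind}_0_2KB"
        else:
            continue
        family = (
            family_of_query.get(h.query_id, h.query_id)
            if family_of_query
            else h.query_id
        )
        key = NetworkKey(family_id=family, location=location)
        net = networks.setdefault(key, GeneNetwork(key=key, members=set()))
        net.members.add(gene_id)
        net.supporting_hits.setdefault(gene_id, []).append(h)
    return networks


def location_overlap(
    networks: Sequence[GeneNetwork],
) -> dict[tuple[str, str], set[str]]:
    """Genes shared between location classes of one family's networks.

    Returns {(location_a, location_b): shared genes} for every class pair;
    an empty intersection means the family inserts into one location class
    or the other per gene, never both.
    """
    if len(networks) < 2:
        raise ValueError("need at least two networks of one family")
    families = {n.key.family_id for n in networks}
    if len(families) > 1:
        raise ValueError(f"networks span multiple families: {sorted(families)}")
    out: dict[tuple[str, str], set[str]] = {}
    for i in range(len(networks)):
        for j in range(i + 1, len(networks)):
            a, b = networks[i], networks[j]
            pair = tuple(sorted((a.key.location, b.key.location)))
            out[pair] = a.members & b.members
    return out


# ---------------------------------------------------------------------------
# GO annotation handling
# ---------------------------------------------------------------------------

@dataclass
class GOAnnotation:
    """Gene -> term mapping propagated up the ontology DAG."""

    gene_terms: dict[str, set[str]]

    @property
    def background(self) -> set[str]:
        return set(self.gene_terms)

    def genes_with_term(self, term: str) -> set[str]:
        return {g for g, ts in self.gene_terms.items() if term in ts}


def load_annotation(
    annot_tsv: str | Path,
    obo: str | Path | None = None,
    propagate: bool = True,
) -> GOAnnotation:
    """Read a 2-column gene->term TSV and propagate along the ontology."""
    gene_terms: dict[str, set[str]] = {}
    with open(annot_tsv) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{annot_tsv}:{lineno}: expected 2 columns")
            gene_terms.setdefault(parts[0], set()).add(parts[1])
    if obo is not None and propagate:
        ancestors = _ancestor_map(obo)
        for gene, terms in gene_terms.items():
            expanded = set(terms)
            for t in terms:
                expanded |= ancestors.get(t, set())
            gene_terms[gene] = expanded
    return GOAnnotation(gene_terms=gene_terms)


def _ancestor_map(obo_path: str | Path) -> dict[str, set[str]]:
    graph = obonet.read_obo(str(obo_path))
    rel = nx.MultiDiGraph()
    rel.add_nodes_from(graph.nodes)
    for child, parent, key in graph.edges(keys=True):
        if key in ("is_a", "part_of"):
            rel.add_edge(child, parent)
    return {node: nx.descendants(rel, node) for node in rel.nodes}


# ---------------------------------------------------------------------------
# hypergeometric overrepresentation
# ---------------------------------------------------------------------------

def hypergeom_upper(N: int, K: int, n: int, k: int) -> float:
    """Exact upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    N: background size, K: background genes with the term, n: sample
    size, k: sample genes with the term.  Computed by exact integer
    summation of the tail.
    """
    if not (0 <= k <= n <= N and 0 <= K <= N):
        raise ValueError(f"inconsistent arguments N={N} K={K} n={n} k={k}")
    if k == 0:
        return 1.0
    if k > K:
        return 0.0
    total = math.comb(N, n)
    tail = sum(
        math.comb(K, i) * math.comb(N - K, n - i)
        for i in range(k, min(K, n) + 1)
    )
    return tail / total


def go_overrepresentation(
    network: GeneNetwork,
    annotation: GOAnnotation,
    bonferroni_all_terms: bool = False,
) -> list[GOEnrichmentRow]:
    """Per-term overrepresentation of one network against the background.

    Unannotated members are excluded from testing; the background is all
    annotated genes.  One row per term present in the network (k >= 1);
    Bonferroni m defaults to the number of tested terms for this network
    (``bonferroni_all_terms`` switches m to all ontology terms seen in
    the annotation).  Rows sort by corrected p, then term id.
    """
    annotated_members = network.members & annotation.background
    if not annotated_members:
        return []
    N = len(annotation.background)
    n = len(annotated_members)
    terms_in_network: dict[str, int] = {}
    for g in annotated_members:
        for t in annotation.gene_terms[g]:
            terms_in_network[t] = terms_in_network.get(t, 0) + 1
    all_terms = {t for ts in annotation.gene_terms.values() for t in ts}
    m = len(all_terms) if bonferroni_all_terms else len(terms_in_network)
    rows = []
    for term, k in terms_in_network.items():
        K = len(annotation.genes_with_term(term))
        p = hypergeom_upper(N, K, n, k)
        rows.append(
            GOEnrichmentRow(
                term=term, k=k, n=n, K=K, N=N,
                p_hyper=p, p_bonf=min(1.0, m * p),
            )
        )
    rows.sort(key=lambda r: (r.p_bonf, r.term))
    return rows


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def export_network(
    networks: Mapping[NetworkKey, GeneNetwork] | Sequence[GeneNetwork],
    path: str | Path,
    fmt: str = "graphml",
) -> Path:
    """Write networks as GraphML, SIF, or a TSV edge list.

    Each network contributes a key node ``family@location`` linked to its
    member genes; node order is deterministic.
    """
    if isinstance(networks, Mapping):
        nets = [networks[k] for k in sorted(networks, key=lambda k: (k.family_id, k.location))]
    else:
        nets = sorted(networks, key=lambda n: (n.key.family_id, n.key.location))
    path = Path(path)
    edges: list[tuple[str, str]] = []
    for net in nets:
        hub = f"{net.key.family_id}@{net.key.location}"
        for gene in sorted(net.members):
            edges.append((hub, gene))
    if fmt == "graphml":
        g = nx.Graph()
        for net in nets:
            hub = f"{net.key.family_id}@{net.key.location}"
            g.add_node(hub, kind="te_location")
            for gene in sorted(net.members):
                g.add_node(gene, kind="gene")
        g.add_edges_from(edges)
        nx.write_graphml(g, path)
    elif fmt == "sif":
        with open(path, "w") as fh:
            for hub, gene in edges:
                fh.write(f"{hub}\tcontains\t{gene}\n")
    elif fmt == "tsv":
        with open(path, "w") as fh:
            fh.write("source\ttarget\n")
            for hub, gene in edges:
                fh.write(f"{hub}\t{gene}\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path


def write_go_tsv(path: str | Path, rows: Iterable[GOEnrichmentRow]) -> None:
    with open(path, "w") as fh:
        fh.write("term\tk\tn\tK\tN\tp_hyper\tp_bonf\n")
        for r in rows:
            fh.write(
                f"{r.term}\t{r.k}\t{r.n}\t{r.K}\t{r.N}\t"
                f"{r.p_hyper:.6g}\t{r.p_bonf:.6g}\n"
            )
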