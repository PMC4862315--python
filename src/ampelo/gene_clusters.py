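"""Ambiguity graph, gene clusters and the measurable-transcript list.

When probes cross-hybridize, several genes share probes and become
indistinguishable: their expression can only be assessed jointly.  Rather
than discarding shared probes, the compendium keeps them as measurements of
a *gene cluster*.  Clusters are the connected components, restricted to
components with at least two genes, of the bipartite probe–gene graph whose
edges are the surviving tiered alignments of non-unmapped probes.

Each cluster is classified by its edge structure:

* ``perfect_ambiguity`` — every probe aligns without mismatch to every
  member gene; the genes are interchangeable for the platform;
* ``weak_link`` — the genes are held together only through relaxed-tier
  (cross-hybridization) edges; without them the cluster falls apart;
* ``partial`` — the generic mixed case.

The *measurable transcripts* — rows of the final expression matrix — are
the singleton genes plus one entry per cluster; together they partition the
gene universe.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from ampelo.probe_alignment import AlignmentHit, MappingDecision

PROBE_PREFIX = "probe::"
GENE_PREFIX = "gene::"


@dataclass
class AmbiguityGraph:
    """Bipartite probe–gene graph of surviving tiered hits.

    Wraps a :class:`networkx.Graph` whose probe nodes are prefixed with
    ``probe::`` and gene nodes with ``gene::``; every edge carries ``tier``
    ('strong' or 'weak') and ``mismatches`` attributes.
    """

    graph: nx.Graph

    @property
    def probe_ids(self) -> set[str]:
        return {
            n[len(PROBE_PREFIX):]
            for n, d in self.graph.nodes(data=True)
            if d["kind"] == "probe"
        }

    @property
    def gene_ids(self) -> set[str]:
        return {
            n[len(GENE_PREFIX):]
            for n, d in self.graph.nodes(data=True)
            if d["kind"] == "gene"
        }

    def edges(self) -> list[tuple[str, str, str, int]]:
        """(probe_id, gene_id, tier, mismatches) for every edge."""
        out = []
        for u, v, d in self.graph.edges(data=True):
            probe, gene = (u, v) if u.startswith(PROBE_PREFIX) else (v, u)
            out.append(
                (
                    probe[len(PROBE_PREFIX):],
                    gene[len(GENE_PREFIX):],
                    d["tier"],
                    d["mismatches"],
                )
            )
        return sorted(out)


@dataclass(frozen=True)
class GeneCluster:
    cluster_id: str
    gene_ids: frozenset[str]
    probe_ids: frozenset[str]
    classification: str  # perfect_ambiguity | partial | weak_link

    def __post_init__(self) -> None:
        if len(self.gene_ids) < 2:
            raise ValueError(f"cluster {self.cluster_id}: needs >= 2 genes")


@dataclass(frozen=True)
class MeasurableTranscript:
    """A row of the expression matrix: one gene, or one whole cluster."""

    measurable_id: str
    member_gene_ids: frozenset[str]

    @property
    def is_cluster(self) -> bool:
        return len(self.member_gene_ids) > 1


def build_ambiguity_graph(
    decisions: Iterable[MappingDecision],
    tiered: Mapping[str, tuple[list[AlignmentHit], list[AlignmentHit]]],
    include_weak: bool = True,
) -> AmbiguityGraph:
    """Assemble the bipartite graph from mapping decisions and tiered hits.

    Only probes that mapped (unique or ambiguous) contribute nodes and
    edges; the edges are exactly their surviving strong and weak hits.
    Weak (cross-hybridization) edges contribute to connectivity by default,
    since cross-hybridization is precisely what makes genes jointly
    measurable; pass ``include_weak=False`` for strong-only clustering.
    """
    g = nx.Graph()
    for d in decisions:
        if d.status == "unmapped":
            continue
        strong_hits, weak_hits = tiered.get(d.probe_id, ([], []))
        pnode = PROBE_PREFIX + d.probe_id
        g.add_node(pnode, kind="probe")
        tiers = (("strong", strong_hits), ("weak", weak_hits))
        if not include_weak:
            tiers = (("strong", strong_hits),)
        for tier, hits in tiers:
            for h in hits:
                gnode = GENE_PREFIX + h.gene_id
                g.add_node(gnode, kind="gene")
                g.add_edge(pnode, gnode, tier=tier, mismatches=h.mismatches)
    return AmbiguityGraph(g)


def find_gene_clusters(graph: AmbiguityGraph) -> list[GeneCluster]:
    """Connected components with ≥ 2 genes, as classified clusters.

    Cluster ids are assigned deterministically (``cluster_0001``, ...) by
    sorting components on their smallest member gene id.
    """
    components = []
    for comp in nx.connected_components(graph.graph):
        genes = sorted(
            n[len(GENE_PREFIX):] for n in comp if n.startswith(GENE_PREFIX)
        )
        probes = sorted(
            n[len(PROBE_PREFIX):] for n in comp if n.startswith(PROBE_PREFIX)
        )
        if len(genes) >= 2:
            components.append((genes, probes))
    components.sort(key=lambda gp: gp[0][0])

    clusters = []
    for i, (genes, probes) in enumerate(components, start=1):
        cluster = GeneCluster(
            cluster_id=f"cluster_{i:04d}",
            gene_ids=frozenset(genes),
            probe_ids=frozenset(probes),
            classification="partial",
        )
        clusters.append(
            GeneCluster(
                cluster.cluster_id,
                cluster.gene_ids,
                cluster.probe_ids,
                classify_cluster(cluster, graph),
            )
        )
    return clusters


def classify_cluster(cluster: GeneCluster, graph: AmbiguityGraph) -> str:
    """Classify a cluster by the mismatch/tier structure of its edges."""
    g = graph.graph
    # perfect ambiguity: each probe has a 0-mismatch edge to each gene
    perfect = True
    for p in cluster.probe_ids:
        pnode = PROBE_PREFIX + p
        for gene in cluster.gene_ids:
            gnode = GENE_PREFIX + gene
            edge = g.get_edge_data(pnode, gnode)
            if edge is None or edge["mismatches"] != 0:
                perfect = False
                break
        if not perfect:
            break
    if perfect:
        return "perfect_ambiguity"

    strong_only = nx.Graph()
    strong_only.add_nodes_from(
        GENE_PREFIX + gene for gene in cluster.gene_ids
    )
    for p in cluster.probe_ids:
        pnode = PROBE_PREFIX + p
        for gnode in g.neighbors(pnode):
            if (
                gnode[len(GENE_PREFIX):] in cluster.gene_ids
                and g.edges[pnode, gnode]["tier"] == "strong"
            ):
                strong_only.add_edge(pnode, gnode)
    gene_nodes = [GENE_PREFIX + gene for gene in cluster.gene_ids]
    first = gene_nodes[0]
    reachable = nx.node_connected_component(strong_only, first)
    if not all(gn in reachable for gn in gene_nodes):
        return "weak_link"
    return "partial"


def define_measurables(
    all_gene_ids: Iterable[str],
    clusters: Sequence[GeneCluster],
) -> list[MeasurableTranscript]:
    """Partition the gene universe into measurable transcripts.

    Singleton genes come first (sorted by gene id), then clusters (sorted by
    cluster id).  Raises on clusters that overlap each other or reference
    genes outside the universe.
    """
    universe = set(all_gene_ids)
    seen: dict[str, str] = {}
    for c in clusters:
        for gene in c.gene_ids:
            if gene in seen:
                raise ValueError(
                    f"gene {gene} appears in clusters {seen[gene]} and "
                    f"{c.cluster_id}"
                )
            if gene not in universe:
                raise ValueError(
                    f"cluster {c.cluster_id} references unknown gene {gene}"
                )
            seen[gene] = c.cluster_id

    singletons = sorted(universe - seen.keys())
    measurables = [
        MeasurableTranscript(gene, frozenset([gene])) for gene in singletons
    ]
    for c in sorted(clusters, key=lambda c: c.cluster_id):
        measurables.append(MeasurableTranscript(c.cluster_id, c.gene_ids))
    return measurables


def cluster_size_table(
    clusters: Iterable[GeneCluster],
) -> dict[tuple[int, int], int]:
    """Tabulate clusters by (number of genes, number of probes)."""
    return dict(
        Counter((len(c.gene_ids), len(c.probe_ids)) for c in clusters)
    )


def probe_consistency_matrix(
    cluster: GeneCluster,
    probe_values: Mapping[str, Sequence[float]],
    min_overlap: int = 10,
) -> pd.DataFrame:
    """Uncentered-Pearson correlation matrix over a cluster's probes.

    ``probe_values`` maps each probe to its vector of contrast-level values
    (NaN for missing).  Entries with fewer than ``min_overlap`` shared
    defined positions, or an all-zero overlap, are NaN.  The diagnostic
    mirrors the probe-level expression check used to vet clusters: probes
    that truly measure the same transcript pool correlate near 1.
    """
    from ampelo.module_query import uncentered_pearson

    probes = sorted(cluster.probe_ids & set(probe_values))
    mat = pd.DataFrame(
        np.nan, index=probes, columns=probes, dtype=float
    )
    for i, p in enumerate(probes):
        x = np.asarray(probe_values[p], dtype=float)
        for q in probes[i:]:
            y = np.asarray(probe_values[q], dtype=float)
            score = uncentered_pearson(x, y, min_overlap=min_overlap)
            if score.value is not None:
                mat.loc[p, q] = score.value
                mat.loc[q, p] = score.value
    return mat


def mean_offdiagonal_consistency(matrix: pd.DataFrame) -> float:
    """Mean of the defined off-diagonal entries (NaN if none)."""
    arr = matrix.to_numpy(dtype=float, copy=True)
    np.fill_diagonal(arr, np.nan)
    if np.all(np.isnan(arr)):
        return float("nan")
    return float(np.nanmean(arr))


def filter_clusters_by_consistency(
    clusters: Sequence[GeneCluster],
    probe_values: Mapping[str, Sequence[float]],
    min_mean_consistency: float,
    min_overlap: int = 10,
) -> list[GeneCluster]:
    """Optional expression-based vetting of clusters.

    Drops (demotes back to singletons) clusters whose mean off-diagonal
    probe consistency is defined and falls below ``min_mean_consistency``,
    emulating a curator's inspection of probe-level expression coherence.
    Off by default in the pipeline.
    """
    kept = []
    for c in clusters:
        m = probe_consistency_matrix(c, probe_values, min_overlap=min_overlap)
        mean = mean_offdiagonal_consistency(m)
        if np.isnan(mean) or mean >= min_mean_consistency:
            kept.append(c)
    return kept


def write_clusters_tsv(clusters: Iterable[GeneCluster]) -> str:
    lines = ["cluster_id\tgene_ids\tprobe_ids\tclassification"]
    for c in sorted(clusters, key=lambda c: c.cluster_id):
        lines.append(
            "\t".join(
                [
                    c.cluster_id,
                    ";".join(sorted(c.gene_ids)),
                    ";".join(sorted(c.probe_ids)),
                    c.classification,
                ]
            )
        )
    return "\n".join(lines) + "\n"


def write_edge_list(graph: AmbiguityGraph) -> str:
    """Plain edge-list export (probe, gene, tier, mismatches) for viewers."""
    lines = ["probe_id\tgene_id\ttier\tmismatches"]
    for probe, gene, tier, mm in graph.edges():
        lines.append(f"{probe}\t{gene}\t{tier}\t{mm}")
    return "\n".join(lines) + "\n"
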