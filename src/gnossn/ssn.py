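"""Sequence similarity network construction and clustering.

An SSN has one node per protein and an edge wherever the pairwise alignment
score (−log10 E-value) meets the threshold.  Clusters are the connected
components — the "isofunctional cluster" semantics of EFI-EST, with no
community detection — numbered 1..C by decreasing size, ties broken by the
lexicographically smallest member ID.  Isolated nodes are retained (they
sort after all multi-node clusters) so that downstream presence/absence
analyses see every hub protein, connected or not.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .alignment import PairwiseHit
from .formats import ProteinRecord


class SSNError(ValueError):
    pass


@dataclass
class SSNGraph:
    """A thresholded similarity network with cluster numbering."""

    graph: nx.Graph
    threshold: float
    clusters: dict[str, int] | None = None
    singletons: set[str] = field(default_factory=set)

    @property
    def n_clusters(self) -> int:
        if self.clusters is None:
            raise SSNError("graph not clustered yet")
        return max(self.clusters.values(), default=0)

    def members(self, cluster: int) -> list[str]:
        return sorted(n for n, c in self.clusters.items() if c == cluster)

    def cluster_sizes(self) -> dict[int, int]:
        sizes: dict[int, int] = {}
        for c in self.clusters.values():
            sizes[c] = sizes.get(c, 0) + 1
        return sizes

    def partition(self) -> frozenset[frozenset[str]]:
        """Clusters as a set of node sets (for refinement checks)."""
        groups: dict[int, set[str]] = {}
        for n, c in self.clusters.items():
            groups.setdefault(c, set()).add(n)
        return frozenset(frozenset(g) for g in groups.values())


def _node_attrs(record: ProteinRecord) -> dict:
    attrs = {"description": record.description}
    if record.genome_id is not None:
        attrs["genome_id"] = record.genome_id
    return attrs


def build_ssn(
    hits: Iterable[PairwiseHit],
    node_set: Sequence[ProteinRecord] | Iterable[str],
    threshold: float,
) -> SSNGraph:
    """Threshold pairwise hits into a network over the given nodes.

    Pairs absent from ``hits`` are treated as below threshold.  All nodes are
    retained; isolated nodes are allowed.
    """
    if threshold <= 0:
        raise SSNError(f"threshold must be > 0, got {threshold}")
    g = nx.Graph()
    for item in node_set:
        if isinstance(item, ProteinRecord):
            g.add_node(item.protein_id, **_node_attrs(item))
        else:
            g.add_node(str(item))
    for hit in hits:
        if hit.alignment_score >= threshold:
            if hit.query_id in g and hit.subject_id in g and hit.query_id != hit.subject_id:
                g.add_edge(
                    hit.query_id,
                    hit.subject_id,
                    alignment_score=float(hit.alignment_score),
                    pct_identity=float(hit.pct_identity),
                )
    return SSNGraph(graph=g, threshold=threshold)


def cluster_ssn(ssn: SSNGraph) -> SSNGraph:
    """Number connected components 1..C: decreasing size, ties by smallest
    member ID; flag singletons."""
    comps = [sorted(c) for c in nx.connected_components(ssn.graph)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    clusters: dict[str, int] = {}
    singletons: set[str] = set()
    for number, comp in enumerate(comps, start=1):
        for node in comp:
            clusters[node] = number
        if len(comp) == 1:
            singletons.add(comp[0])
    ssn.clusters = clusters
    ssn.singletons = singletons
    return ssn


def threshold_sweep(
    hits: Sequence[PairwiseHit],
    node_set: Sequence[ProteinRecord] | Iterable[str],
    thresholds: Sequence[float],
) -> list[SSNGraph]:
    """Cluster the same hit set at each threshold (ascending).

    Because the edge set at a higher threshold is a subset of the edge set at
    any lower one, each higher-threshold partition refines the lower one.
    """
    if list(thresholds) != sorted(thresholds):
        raise SSNError("thresholds must be ascending")
    node_set = list(node_set)
    return [cluster_ssn(build_ssn(hits, node_set, t)) for t in thresholds]


def taxonomy_purity(
    ssn: SSNGraph, labels: Mapping[str, str]
) -> tuple[dict[int, float], float]:
    """Per-cluster purity (max taxon fraction) and the size-weighted mean
    purity over non-singleton clusters.

    Nodes missing from ``labels`` count as taxon "unknown".
    """
    if ssn.clusters is None:
        raise SSNError("cluster the graph first")
    by_cluster: dict[int, list[str]] = {}
    for node, c in ssn.clusters.items():
        by_cluster.setdefault(c, []).append(node)
    purity: dict[int, float] = {}
    weighted = 0.0
    weight_total = 0
    for c, nodes in by_cluster.items():
        taxa: dict[str, int] = {}
        for n in nodes:
            t = labels.get(n, "unknown")
            taxa[t] = taxa.get(t, 0) + 1
        p = max(taxa.values()) / len(nodes)
        purity[c] = p
        if len(nodes) > 1:
            weighted += p * len(nodes)
            weight_total += len(nodes)
    mean = weighted / weight_total if weight_total else float("nan")
    return purity, mean
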