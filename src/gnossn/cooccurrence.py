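"""SSN-of-neighbours (SSNN) clustering and hub co-occurrence analysis.

The neighbour proteins pooled from all hub windows are clustered into an SSN
at their own (lower) threshold; selected neighbour clusters are then mapped
back onto each hub as a binary presence matrix — a hub is "positive" for a
cluster iff at least one gene in its ±N window belongs to that cluster —
from which pairwise co-occurrence statistics and Venn region counts follow.

Presence is binary by design (it mirrors node colouring semantics); raw
neighbour counts are additionally exposed in the TSV output for
transparency.  "Exclusive" pairs require both sets nonempty, so empty
columns never raise vacuous flags.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .alignment import PairwiseHit
from .formats import ProteinRecord
from .neighborhoods import NeighborhoodWindow
from .ssn import SSNGraph, build_ssn, cluster_ssn

logger = logging.getLogger("gnossn")


class CooccurrenceError(ValueError):
    pass


@dataclass
class PresenceMatrix:
    """Binary hub × tracked-cluster matrix.

    ``data`` is a pandas DataFrame indexed by hub protein ID with one 0/1
    column per tracked cluster (column order = tracked order); ``counts``
    holds the underlying neighbour counts per cell.
    """

    data: pd.DataFrame
    counts: pd.DataFrame
    cluster_numbers: dict[str, int]

    @property
    def hubs(self) -> list[str]:
        return list(self.data.index)

    @property
    def cluster_names(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class VennSummary:
    """Region counts and co-occurrence flags for ≤ 3 tracked clusters.

    ``regions`` maps a region key — "&"-joined member names, "none" for the
    all-absent region — to its hub count; region counts sum to the number of
    hubs.  ``exclusive`` flags pairs with empty intersection and both sets
    nonempty; ``implications`` maps "X->Y" to the exception count |X \\ Y|
    (the implication holds exactly when the count is 0).
    """

    set_names: list[str]
    regions: dict[str, int]
    exclusive: dict[str, bool]
    implications: dict[str, int]
    n_hubs: int


def build_ssnn(
    neighbors: Sequence[ProteinRecord],
    hits: Iterable[PairwiseHit],
    threshold: float,
) -> SSNGraph:
    """SSN over the deduplicated neighbour set, clustered and numbered."""
    if not neighbors:
        import networkx as nx

        return SSNGraph(graph=nx.Graph(), threshold=threshold, clusters={}, singletons=set())
    return cluster_ssn(build_ssn(hits, neighbors, threshold))


def annotate_clusters(
    ssnn: SSNGraph,
    records: Mapping[str, ProteinRecord],
    labels: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-cluster annotation: majority functional label, its fraction,
    size, and the median member length (length separates otherwise similar
    isomerase families, e.g. ~275 aa vs ~325 aa proteins)."""
    if ssnn.clusters is None:
        raise CooccurrenceError("cluster the SSNN first")
    rows = []
    by_cluster: dict[int, list[str]] = {}
    for node, c in ssnn.clusters.items():
        by_cluster.setdefault(c, []).append(node)
    for c in sorted(by_cluster):
        nodes = sorted(by_cluster[c])
        lab_counts: dict[str, int] = {}
        lengths = []
        for n in nodes:
            label = (labels or {}).get(n) or records[n].description or "unknown"
            lab_counts[label] = lab_counts.get(label, 0) + 1
            lengths.append(len(records[n].sequence))
        majority = max(lab_counts.items(), key=lambda kv: (kv[1], kv[0]))[0]
        rows.append(
            {
                "cluster": c,
                "size": len(nodes),
                "majority_label": majority,
                "majority_fraction": lab_counts[majority] / len(nodes),
                "median_length": float(np.median(lengths)),
            }
        )
    return pd.DataFrame(rows)


def resolve_tracked_clusters(
    annotation: pd.DataFrame, tracked_labels: Sequence[str]
) -> dict[str, int]:
    """Map requested functional labels to SSNN cluster numbers.

    Each label resolves to the largest cluster whose majority label matches;
    labels matching no cluster are an error.
    """
    mapping: dict[str, int] = {}
    missing = []
    for label in tracked_labels:
        rows = annotation[annotation["majority_label"] == label]
        if rows.empty:
            missing.append(label)
            continue
        best = rows.sort_values(["size", "cluster"], ascending=[False, True]).iloc[0]
        mapping[label] = int(best["cluster"])
    if missing:
        raise CooccurrenceError(
            f"no SSNN cluster matches label(s) {missing}; "
            f"known labels: {sorted(annotation['majority_label'].unique())}"
        )
    return mapping


def presence_matrix(
    windows: Sequence[NeighborhoodWindow],
    ssnn: SSNGraph,
    tracked_clusters: Mapping[str, int] | Sequence[int],
) -> PresenceMatrix:
    """Binary matrix: hub × tracked cluster, 1 iff ≥ 1 window member belongs
    to the cluster.  Rows are ordered by hub ID, columns by tracked order."""
    if ssnn.clusters is None:
        raise CooccurrenceError("cluster the SSNN first")
    if isinstance(tracked_clusters, Mapping):
        tracked = dict(tracked_clusters)
    else:
        tracked = {f"cluster_{c}": int(c) for c in tracked_clusters}
    valid = set(ssnn.clusters.values())
    unknown = {name: c for name, c in tracked.items() if c not in valid}
    if unknown:
        raise CooccurrenceError(
            f"tracked cluster(s) not in SSNN: {unknown}; valid numbers 1..{ssnn.n_clusters}"
        )
    hub_ids = sorted(w.hub_id for w in windows)
    names = list(tracked)
    counts = pd.DataFrame(0, index=hub_ids, columns=names, dtype=int)
    for w in windows:
        for pid in w.neighbor_ids:
            c = ssnn.clusters.get(pid)
            if c is None:
                continue
            for name, num in tracked.items():
                if c == num:
                    counts.loc[w.hub_id, name] += 1
    data = (counts > 0).astype(int)
    return PresenceMatrix(data=data, counts=counts, cluster_numbers=tracked)


def venn(presence: PresenceMatrix, sets: Sequence[str]) -> VennSummary:
    """All 2^k region counts plus exclusivity and implication flags for up to
    three tracked clusters."""
    if len(sets) > 3:
        raise CooccurrenceError(
            "venn supports at most 3 sets; use cooccurrence_stats for pairwise analysis"
        )
    for s in sets:
        if s not in presence.data.columns:
            raise CooccurrenceError(f"{s!r} is not a presence matrix column")
    df = presence.data[list(sets)]
    n = len(df)
    regions: dict[str, int] = {}
    for include in itertools.product([0, 1], repeat=len(sets)):
        mask = np.ones(n, dtype=bool)
        members = []
        for s, inc in zip(sets, include):
            col = df[s].to_numpy().astype(bool)
            mask &= col if inc else ~col
            if inc:
                members.append(s)
        key = "&".join(members) if members else "none"
        regions[key] = int(mask.sum())
    exclusive: dict[str, bool] = {}
    implications: dict[str, int] = {}
    for a, b in itertools.combinations(sets, 2):
        xa = df[a].to_numpy().astype(bool)
        xb = df[b].to_numpy().astype(bool)
        both_nonempty = xa.any() and xb.any()
        exclusive[f"{a}|{b}"] = bool(both_nonempty and not (xa & xb).any())
    for a, b in itertools.permutations(sets, 2):
        xa = df[a].to_numpy().astype(bool)
        xb = df[b].to_numpy().astype(bool)
        implications[f"{a}->{b}"] = int((xa & ~xb).sum())
    return VennSummary(
        set_names=list(sets),
        regions=regions,
        exclusive=exclusive,
        implications=implications,
        n_hubs=n,
    )


def cooccurrence_stats(presence: PresenceMatrix) -> pd.DataFrame:
    """Pairwise |X|, |Y|, |X∩Y|, Jaccard, plus exclusivity/nesting marks for
    every pair of tracked clusters.  Row order of the matrix is irrelevant."""
    cols = presence.cluster_names
    if len(cols) < 2:
        raise CooccurrenceError("need at least 2 tracked clusters")
    rows = []
    for a, b in itertools.combinations(cols, 2):
        xa = presence.data[a].to_numpy().astype(bool)
        xb = presence.data[b].to_numpy().astype(bool)
        inter = int((xa & xb).sum())
        union = int((xa | xb).sum())
        na, nb = int(xa.sum()), int(xb.sum())
        rows.append(
            {
                "set_a": a,
                "set_b": b,
                "n_a": na,
                "n_b": nb,
                "intersection": inter,
                "jaccard": inter / union if union else 1.0,
                "mutually_exclusive": bool(na and nb and inter == 0),
                "nested": bool(na and nb and (inter == na or inter == nb)),
            }
        )
    return pd.DataFrame(rows)


def color_hub_ssn(hub_ssn: SSNGraph, presence: PresenceMatrix) -> SSNGraph:
    """Write one boolean attribute per tracked cluster onto hub SSN nodes
    (``presence_<name>``), for GraphML export and viewer colouring."""
    known = set(presence.data.index)
    for node in hub_ssn.graph.nodes:
        if node not in known:
            logger.warning("hub %s missing from presence matrix; flags set false", node)
        for name in presence.cluster_names:
            value = bool(presence.data.loc[node, name]) if node in known else False
            hub_ssn.graph.nodes[node][f"presence_{name}"] = value
    return hub_ssn
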