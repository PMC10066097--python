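"""Genome neighbourhood (±N ORF) extraction around hub genes.

ORF counting is strand-agnostic and contiguous in gene rank on the hub's
contig, not in base pairs; windows are clipped at contig ends and flagged as
truncated rather than wrapped.  Only CDS features count towards ranks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .formats import ProteinRecord

logger = logging.getLogger("gnossn")


class NeighborhoodError(ValueError):
    pass


@dataclass(frozen=True)
class NeighborhoodWindow:
    """The ordered ±N ORFs around one hub gene.

    ``neighbors`` holds (protein_id, signed rank offset, strand) sorted by
    offset; the hub itself is excluded.  Truncation flags mark windows
    clipped by a contig edge.
    """

    hub_id: str
    genome_id: str | None
    contig_id: str
    neighbors: tuple[tuple[str, int, str | None], ...]
    truncated_left: bool
    truncated_right: bool

    @property
    def neighbor_ids(self) -> tuple[str, ...]:
        return tuple(n[0] for n in self.neighbors)


def extract_window(
    genome: Sequence[ProteinRecord], hub_id: str, n_orfs: int
) -> NeighborhoodWindow:
    """Genes with order_index in [h−N, h+N] on the hub's contig (hub at h).

    ``truncated_left`` iff h − N < 0; ``truncated_right`` iff h + N exceeds
    the last rank on the contig.
    """
    if n_orfs < 1:
        raise NeighborhoodError("window half-width must be >= 1")
    hub = next((r for r in genome if r.protein_id == hub_id), None)
    if hub is None:
        raise NeighborhoodError(f"hub {hub_id!r} not found in genome")
    if hub.contig_id is None or hub.order_index is None:
        raise NeighborhoodError(f"hub {hub_id!r} lacks contig/order information")
    contig = [r for r in genome if r.contig_id == hub.contig_id]
    h = hub.order_index
    last = max(r.order_index for r in contig)
    neighbors = sorted(
        (
            (r.protein_id, r.order_index - h, r.strand)
            for r in contig
            if r.protein_id != hub.protein_id and abs(r.order_index - h) <= n_orfs
        ),
        key=lambda t: t[1],
    )
    return NeighborhoodWindow(
        hub_id=hub.protein_id,
        genome_id=hub.genome_id,
        contig_id=hub.contig_id,
        neighbors=tuple(neighbors),
        truncated_left=h - n_orfs < 0,
        truncated_right=h + n_orfs > last,
    )


def extract_windows(
    genomes: Mapping[str, Sequence[ProteinRecord]],
    hub_ids: Iterable[str],
    n_orfs: int,
) -> list[NeighborhoodWindow]:
    """Windows for many hubs; hubs without coordinates are skipped with a
    logged warning so sequence-only databases still flow through."""
    by_protein: dict[str, str] = {}
    for gid, records in genomes.items():
        for r in records:
            by_protein[r.protein_id] = gid
    windows = []
    for hub_id in hub_ids:
        gid = by_protein.get(hub_id)
        if gid is None:
            logger.warning("hub %s has no genome context; skipped", hub_id)
            continue
        try:
            windows.append(extract_window(genomes[gid], hub_id, n_orfs))
        except NeighborhoodError as exc:
            logger.warning("hub %s skipped: %s", hub_id, exc)
    return windows


def collect_neighbors(
    windows: Sequence[NeighborhoodWindow],
    proteins: Mapping[str, ProteinRecord],
) -> tuple[list[ProteinRecord], dict[str, list[str]], dict]:
    """Pool window members into a deduplicated neighbour set.

    Returns (unique neighbour records sorted by ID, provenance map
    neighbour → hub IDs, report with total occurrences and unique count).
    """
    if not windows:
        raise NeighborhoodError("no windows to collect from")
    provenance: dict[str, list[str]] = {}
    total = 0
    for w in windows:
        for pid in w.neighbor_ids:
            if pid not in proteins:
                raise NeighborhoodError(f"window references unknown protein {pid!r}")
            provenance.setdefault(pid, []).append(w.hub_id)
            total += 1
    unique = sorted(provenance)
    records = [proteins[pid] for pid in unique]
    report = {"total_occurrences": total, "unique_neighbors": len(unique)}
    return records, {k: sorted(v) for k, v in provenance.items()}, report
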