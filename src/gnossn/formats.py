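"""Readers/writers for the standard files the pipeline touches.

Everything downstream consumes only the domain types defined here:
:class:`ProteinRecord` (a protein sequence plus its genomic address) and
:class:`PipelineConfig` (every tunable threshold of the analysis).

Coordinates are 1-based inclusive (GFF3 convention).  Gene order on a contig
is by ascending start coordinate, strand-agnostic, with ties broken by
ascending end and then lexicographic protein ID so runs are reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd
import yaml
from Bio import SeqIO

logger = logging.getLogger("gnossn")

#: The 20 canonical amino acids, alphabetical one-letter codes.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Residues accepted in input sequences ('X' = unknown residue).
ALLOWED_RESIDUES = frozenset(AMINO_ACIDS) | {"X"}

HIT_TSV_COLUMNS = [
    "query",
    "subject",
    "raw_score",
    "evalue_log10",
    "alignment_score",
    "pct_identity",
    "aln_length",
]


class FormatError(ValueError):
    """Raised for malformed or inconsistent input files."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence plus (optionally) its genomic address.

    ``order_index`` is the 0-based rank of the gene on its contig by start
    coordinate; it is present iff ``contig_id`` is present.
    """

    protein_id: str
    sequence: str
    description: str = ""
    genome_id: str | None = None
    contig_id: str | None = None
    start: int | None = None
    end: int | None = None
    strand: str | None = None
    order_index: int | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise FormatError(f"empty sequence for {self.protein_id!r}")
        if self.start is not None and self.end is not None and self.end < self.start:
            raise FormatError(
                f"{self.protein_id!r}: end {self.end} < start {self.start}"
            )
        if (self.order_index is None) != (self.contig_id is None):
            raise FormatError(
                f"{self.protein_id!r}: order_index present iff contig_id present"
            )
        if self.strand is not None and self.strand not in ("+", "-"):
            raise FormatError(f"{self.protein_id!r}: bad strand {self.strand!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class PipelineConfig:
    """Run configuration; defaults are the published analysis parameters.

    * ``evalue_stage1`` / ``evalue_stage2`` — E-value cutoffs for the pairwise
      query scan and the profile re-search (1e-130, 1e-200).
    * ``ssn_threshold_primary`` / ``ssn_threshold_fine`` — minimum alignment
      score (−log10 E) for SSN edges (120 and 170).
    * ``ssnn_threshold`` — edge threshold for the SSN-of-neighbours (50).
    * ``window_orfs`` — neighbourhood half-width N in ORF ranks (10).
    * ``gap_open``/``gap_extend`` — affine gap costs: a gap of length k costs
      gap_open + k·gap_extend (BLAST convention, 11/1).
    * ``lambda_ka``/``k_ka`` — Karlin–Altschul parameters for gapped BLOSUM62.
    * ``n_shuffles`` — null sequences for empirical profile calibration.
    """

    evalue_stage1: float = 1e-130
    evalue_stage2: float = 1e-200
    ssn_threshold_primary: float = 120.0
    ssn_threshold_fine: float = 170.0
    ssnn_threshold: float = 50.0
    window_orfs: int = 10
    gap_open: int = 11
    gap_extend: int = 1
    lambda_ka: float = 0.267
    k_ka: float = 0.041
    n_shuffles: int = 200
    rng_seed: int = 0
    # Optional compute shortcut: skip pairs whose length ratio is below this
    # (they cannot form family edges); None disables the skip.
    length_ratio_min: float | None = None

    def __post_init__(self) -> None:
        for name in (
            "evalue_stage1",
            "evalue_stage2",
            "ssn_threshold_primary",
            "ssn_threshold_fine",
            "ssnn_threshold",
        ):
            if getattr(self, name) <= 0:
                raise FormatError(f"config: {name} must be > 0")
        if self.evalue_stage2 > self.evalue_stage1:
            raise FormatError("config: evalue_stage2 must be <= evalue_stage1")
        if self.window_orfs < 1:
            raise FormatError("config: window_orfs must be >= 1")
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise FormatError("config: gap penalties must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"config: unknown keys {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA into :class:`ProteinRecord` objects.

    IDs are the first whitespace-delimited header token; sequences are
    upper-cased; a single terminal ``*`` (stop) is stripped.  Duplicate IDs,
    empty files and residues outside the 20-letter alphabet plus 'X' are
    errors.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        pid = entry.id
        if pid in seen:
            raise FormatError(f"{path}: duplicate FASTA ID {pid!r}")
        seen.add(pid)
        seq = str(entry.seq).upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        bad = set(seq) - ALLOWED_RESIDUES
        if bad:
            raise FormatError(
                f"{path}: illegal residue(s) {sorted(bad)} in {pid!r}"
            )
        desc = entry.description.split(None, 1)
        records.append(
            ProteinRecord(
                protein_id=pid,
                sequence=seq,
                description=desc[1] if len(desc) > 1 else "",
            )
        )
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records as FASTA (ID + description header, 60-column wrap)."""
    with open(path, "w") as fh:
        for rec in records:
            header = rec.protein_id
            if rec.description:
                header += f" {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_genome(
    gff_path: str | Path,
    fasta_path: str | Path,
    genome_id: str | None = None,
) -> list[ProteinRecord]:
    """Read one genome: CDS features from GFF3 joined to a protein FASTA.

    Every CDS must name a protein present in the FASTA (attribute
    ``protein_id`` or, failing that, ``ID``).  Records carry genome, contig,
    1-based inclusive coordinates, strand and a per-contig ``order_index``
    assigned by ascending start, ties by ascending end then protein ID.
    """
    import gffutils

    gff_path = Path(gff_path)
    genome_id = genome_id or gff_path.stem
    proteins = {r.protein_id: r for r in read_fasta(fasta_path)}

    db = gffutils.create_db(
        str(gff_path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    raw: list[tuple[str, int, int, str, str]] = []
    seen_coords: set[tuple[str, int, int, str]] = set()
    missing: list[str] = []
    for feat in db.features_of_type("CDS"):
        attrs = feat.attributes
        pid = (attrs.get("protein_id") or attrs.get("ID") or [None])[0]
        if pid is None:
            raise FormatError(f"{gff_path}: CDS without protein_id/ID attribute")
        if pid not in proteins:
            missing.append(pid)
            continue
        key = (feat.seqid, feat.start, feat.end, pid)
        if key in seen_coords:
            raise FormatError(
                f"{gff_path}: duplicate CDS {pid!r} at {feat.seqid}:{feat.start}-{feat.end}"
            )
        seen_coords.add(key)
        raw.append((feat.seqid, feat.start, feat.end, feat.strand, pid))
    if missing:
        raise FormatError(
            f"{gff_path}: CDS protein IDs missing from FASTA: {sorted(set(missing))}"
        )
    if not raw:
        raise FormatError(f"{gff_path}: no CDS features")

    records: list[ProteinRecord] = []
    by_contig: dict[str, list[tuple[str, int, int, str, str]]] = {}
    for row in raw:
        by_contig.setdefault(row[0], []).append(row)
    for contig, rows in by_contig.items():
        rows.sort(key=lambda r: (r[1], r[2], r[4]))
        for idx, (ctg, start, end, strand, pid) in enumerate(rows):
            base = proteins[pid]
            records.append(
                ProteinRecord(
                    protein_id=pid,
                    sequence=base.sequence,
                    description=base.description,
                    genome_id=genome_id,
                    contig_id=ctg,
                    start=start,
                    end=end,
                    strand=strand if strand in ("+", "-") else None,
                    order_index=idx,
                )
            )
    return records


def write_gff3(records: Sequence[ProteinRecord], path: str | Path) -> None:
    """Write CDS features for records that carry coordinates."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        rows = [r for r in records if r.contig_id is not None]
        rows = sorted(rows, key=lambda r: (r.contig_id, r.start, r.end, r.protein_id))
        for r in rows:
            fh.write(
                "\t".join(
                    [
                        r.contig_id,
                        "gnossn",
                        "CDS",
                        str(r.start),
                        str(r.end),
                        ".",
                        r.strand or ".",
                        "0",
                        f"ID={r.protein_id};protein_id={r.protein_id};product={r.description}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# GraphML
# ---------------------------------------------------------------------------

def write_graphml(graph, path: str | Path) -> None:
    """Export a clustered SSN as Cytoscape-loadable GraphML.

    Node attributes: cluster number, singleton flag, description, taxonomy
    and any presence flags set on the graph; edge attributes: alignment
    score and percent identity.  Nodes and edges are written in sorted order
    so identical graphs produce byte-identical files.
    """
    if getattr(graph, "clusters", None) is None:
        raise FormatError("write_graphml: graph has no cluster numbering")
    g = nx.Graph()
    src = graph.graph
    for node in sorted(src.nodes):
        attrs = {
            k: v
            for k, v in sorted(src.nodes[node].items())
            if v is not None
        }
        attrs["cluster"] = int(graph.clusters[node])
        attrs["singleton"] = bool(node in graph.singletons)
        g.add_node(node, **attrs)
    for u, v in sorted(tuple(sorted(e)) for e in src.edges):
        data = src.edges[u, v]
        g.add_edge(
            u,
            v,
            alignment_score=float(data["alignment_score"]),
            pct_identity=float(data["pct_identity"]),
        )
    nx.write_graphml(g, str(path))


def read_graphml(path: str | Path) -> nx.Graph:
    """Re-read an exported GraphML (attribute types preserved)."""
    return nx.read_graphml(str(path))


# ---------------------------------------------------------------------------
# Hit / table I/O
# ---------------------------------------------------------------------------

def write_hits_tsv(hits, path: str | Path) -> None:
    """Stream pairwise hits to a BLAST-tabular-like TSV."""
    rows = [
        {
            "query": h.query_id,
            "subject": h.subject_id,
            "raw_score": h.raw_score,
            "evalue_log10": h.evalue_log10,
            "alignment_score": h.alignment_score,
            "pct_identity": h.pct_identity,
            "aln_length": h.aln_length,
        }
        for h in hits
    ]
    df = pd.DataFrame(rows, columns=HIT_TSV_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_hits_tsv(path: str | Path):
    """Read a hit TSV back into :class:`~gnossn.alignment.PairwiseHit`."""
    from .alignment import PairwiseHit

    df = pd.read_csv(path, sep="\t")
    hits = []
    for row in df.itertuples(index=False):
        hits.append(
            PairwiseHit(
                query_id=row.query,
                subject_id=row.subject,
                raw_score=float(row.raw_score),
                alignment_score=float(row.alignment_score),
                pct_identity=float(row.pct_identity),
                aln_length=int(row.aln_length),
                n_identities=int(round(row.pct_identity * row.aln_length / 100.0)),
            )
        )
    return hits


def write_json(obj: Mapping, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    import numpy as np

    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")
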