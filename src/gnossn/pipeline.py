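"""End-to-end orchestration: search → SSN → neighbourhoods → SSNN → co-occurrence.

A run is described by a ``run.yaml`` next to the data (as written by
:func:`gnossn.synthetic.emit_scenario`, or hand-written for real data):

.. code-block:: yaml

    config: config.yaml          # PipelineConfig fields
    genomes_dir: genomes         # <stem>.faa + <stem>.gff3 per genome
    query_fasta: query.faa       # single-record query
    taxonomy: taxonomy.tsv       # optional: genome_id -> taxon
    tracked_labels:              # SSNN clusters to track, by majority label
      lgdB1: 3-keto-levoglucosan beta-eliminase
    venn_sets: [lgdB1]           # <= 3 tracked names for the Venn summary

Every stage writes its artifact under the output directory, so stages are
independently re-runnable from files; the JSON run report echoes the
configuration, seeds, stage counts and a checksummed output manifest.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import cooccurrence as co
from .alignment import all_vs_all
from .formats import (
    PipelineConfig,
    ProteinRecord,
    read_fasta,
    read_genome,
    write_graphml,
    write_hits_tsv,
    write_json,
)
from .neighborhoods import collect_neighbors, extract_windows
from .search import two_stage_search
from .ssn import threshold_sweep, taxonomy_purity
from .synthetic import SyntheticLedger

logger = logging.getLogger("gnossn")


class PipelineError(RuntimeError):
    pass


@dataclass
class RunReport:
    """Provenance for one pipeline run: config echo, per-stage counts,
    seeds, timestamps, and a checksummed manifest of every output file."""

    config: dict
    stage_counts: dict
    rng_seed: int
    started: str
    finished: str = ""
    version: str = ""
    manifest: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        sc = self.stage_counts
        if sc.get("unique_neighbors", 0) > sc.get("neighbor_occurrences", 0):
            raise PipelineError("report inconsistent: unique > total neighbours")

    def to_json(self, path: str | Path) -> None:
        self.validate()
        write_json(dataclasses.asdict(self), path)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def load_run_spec(run_dir: str | Path) -> dict:
    run_dir = Path(run_dir)
    with open(run_dir / "run.yaml") as fh:
        spec = yaml.safe_load(fh)
    spec["_dir"] = run_dir
    return spec


def _load_genomes(genomes_dir: Path) -> dict[str, list[ProteinRecord]]:
    genomes: dict[str, list[ProteinRecord]] = {}
    for faa in sorted(genomes_dir.glob("*.faa")):
        gff = faa.with_suffix(".gff3")
        if not gff.exists():
            raise PipelineError(f"no GFF3 next to {faa}")
        genomes[faa.stem] = read_genome(gff, faa, genome_id=faa.stem)
    if not genomes:
        raise PipelineError(f"no genomes under {genomes_dir}")
    return genomes


def _load_taxonomy(path: Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["genome_id"], df["taxon"]))


def run_all(
    run_dir: str | Path,
    out_dir: str | Path,
    seed: int | None = None,
) -> RunReport:
    """Execute every stage in order, writing all intermediate artifacts.

    Idempotent for fixed inputs and seed: FASTA/GFF3/TSV/GraphML outputs are
    byte-identical across reruns (the JSON report differs in timestamps
    only).
    """
    started = datetime.datetime.now(datetime.timezone.utc).isoformat()
    run_dir = Path(run_dir)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    spec = load_run_spec(run_dir)
    config = PipelineConfig.from_yaml(run_dir / spec["config"])
    if seed is not None:
        config.rng_seed = seed
    stage = "load"
    try:
        genomes = _load_genomes(run_dir / spec["genomes_dir"])
        proteins = {r.protein_id: r for g in genomes.values() for r in g}
        db = [r for g in genomes.values() for r in g]
        query = read_fasta(run_dir / spec["query_fasta"])[0]
        taxonomy = (
            _load_taxonomy(run_dir / spec["taxonomy"]) if spec.get("taxonomy") else {}
        )

        stage = "search"
        logger.info("two-stage homolog search: %d proteins", len(db))
        homologs, search_report = two_stage_search(query, db, config)
        if len(homologs) < 2:
            raise PipelineError("fewer than 2 homologs retrieved; nothing to network")

        stage = "ssn"
        logger.info("hub SSN over %d homologs", len(homologs))
        hub_hits = all_vs_all(
            homologs, config, score_floor=config.ssn_threshold_primary
        )
        write_hits_tsv(hub_hits, out_dir / "hub_hits.tsv")
        thresholds = [config.ssn_threshold_primary, config.ssn_threshold_fine]
        ssn_primary, ssn_fine = threshold_sweep(hub_hits, homologs, thresholds)
        node_taxon = {
            h.protein_id: taxonomy.get(h.genome_id, "unknown") for h in homologs
        }
        for g in (ssn_primary, ssn_fine):
            for node, taxon in node_taxon.items():
                g.graph.nodes[node]["taxonomy"] = taxon
        purity_fine, mean_purity = taxonomy_purity(ssn_fine, node_taxon)

        stage = "neighborhood"
        hub_ids = sorted(h.protein_id for h in homologs)
        windows = extract_windows(genomes, hub_ids, config.window_orfs)
        neighbors, provenance, nb_report = collect_neighbors(windows, proteins)
        _write_windows_tsv(windows, out_dir / "windows.tsv")

        stage = "ssnn"
        logger.info("SSNN over %d unique neighbours", len(neighbors))
        ssnn_hits = all_vs_all(neighbors, config, score_floor=config.ssnn_threshold)
        write_hits_tsv(ssnn_hits, out_dir / "ssnn_hits.tsv")
        ssnn = co.build_ssnn(neighbors, ssnn_hits, config.ssnn_threshold)
        annotation = co.annotate_clusters(ssnn, proteins)
        annotation.to_csv(out_dir / "ssnn_clusters.tsv", sep="\t", index=False)

        stage = "cooccur"
        tracked_labels: Mapping[str, str] = spec["tracked_labels"]
        label_to_cluster = co.resolve_tracked_clusters(
            annotation, list(tracked_labels.values())
        )
        tracked = {
            name: label_to_cluster[label] for name, label in tracked_labels.items()
        }
        presence = co.presence_matrix(windows, ssnn, tracked)
        presence.data.to_csv(out_dir / "presence.tsv", sep="\t", index_label="hub_id")
        presence.counts.to_csv(
            out_dir / "presence_counts.tsv", sep="\t", index_label="hub_id"
        )
        venn_summary = co.venn(presence, spec["venn_sets"])
        write_json(dataclasses.asdict(venn_summary), out_dir / "venn.json")
        if len(presence.cluster_names) >= 2:
            co.cooccurrence_stats(presence).to_csv(
                out_dir / "cooccurrence.tsv", sep="\t", index=False
            )
        co.color_hub_ssn(ssn_fine, presence)
        co.color_hub_ssn(ssn_primary, presence)

        stage = "export"
        write_graphml(ssn_primary, out_dir / "ssn_primary.graphml")
        write_graphml(ssn_fine, out_dir / "ssn_fine.graphml")
        write_graphml(ssnn, out_dir / "ssnn.graphml")
    except Exception as exc:
        raise PipelineError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    stage_counts = {
        **{k: v for k, v in search_report.items() if isinstance(v, (int, float))},
        "homologs": len(homologs),
        "ssn_clusters_primary": ssn_primary.n_clusters,
        "ssn_clusters_fine": ssn_fine.n_clusters,
        "ssn_mean_taxonomy_purity_fine": mean_purity,
        "windows": len(windows),
        "neighbor_occurrences": nb_report["total_occurrences"],
        "unique_neighbors": nb_report["unique_neighbors"],
        "ssnn_clusters": ssnn.n_clusters,
        "venn_regions": venn_summary.regions,
        "venn_exclusive": venn_summary.exclusive,
        "venn_implications": venn_summary.implications,
        "tracked_clusters": tracked,
    }
    try:
        from importlib.metadata import version as _dist_version

        pkg_version = _dist_version("gnossn")
    except Exception:
        pkg_version = "unknown"
    report = RunReport(
        config=config.to_dict(),
        stage_counts=stage_counts,
        rng_seed=config.rng_seed,
        started=started,
        finished=datetime.datetime.now(datetime.timezone.utc).isoformat(),
        version=pkg_version,
    )
    for path in sorted(out_dir.rglob("*")):
        if path.is_file() and path.name != "report.json":
            report.manifest[str(path.relative_to(out_dir))] = _sha256(path)
    report.to_json(out_dir / "report.json")
    return report


def _write_windows_tsv(windows, path: Path) -> None:
    rows = []
    for w in sorted(windows, key=lambda w: w.hub_id):
        for pid, offset, strand in w.neighbors:
            rows.append(
                {
                    "hub_id": w.hub_id,
                    "neighbor": pid,
                    "offset": offset,
                    "strand": strand or ".",
                    "truncated_left": w.truncated_left,
                    "truncated_right": w.truncated_right,
                }
            )
    pd.DataFrame(
        rows,
        columns=[
            "hub_id",
            "neighbor",
            "offset",
            "strand",
            "truncated_left",
            "truncated_right",
        ],
    ).to_csv(path, sep="\t", index=False)


def report_compare(out_dir: str | Path, ledger: SyntheticLedger | str | Path) -> dict:
    """Cell-by-cell comparison of a pipeline run against a ground-truth ledger.

    Compares the presence matrix (via hub → genome mapping) and the Venn
    region counts, and reports per-family precision/recall.  Planted rule
    exceptions are part of the realised ledger, so they are expected matches,
    not mismatches.
    """
    out_dir = Path(out_dir)
    if not isinstance(ledger, SyntheticLedger):
        ledger = SyntheticLedger.from_json(ledger)
    presence = pd.read_csv(out_dir / "presence.tsv", sep="\t", index_col="hub_id")
    hub_to_genome = {info["hub_id"]: gid for gid, info in ledger.genomes.items()}
    unknown = [h for h in presence.index if h not in hub_to_genome]
    if unknown or len(presence) != len(hub_to_genome):
        raise PipelineError(
            f"hub set mismatch: {len(presence)} pipeline hubs vs "
            f"{len(hub_to_genome)} ledger genomes (unmapped: {unknown[:5]})"
        )
    families = [c for c in presence.columns if c in next(iter(ledger.presence.values()))]
    mismatches = 0
    cells = 0
    per_family: dict[str, dict] = {}
    for fam in families:
        tp = fp = fn = tn = 0
        for hub, row in presence.iterrows():
            truth = ledger.presence[hub_to_genome[hub]][fam]
            pred = int(row[fam])
            cells += 1
            if pred != truth:
                mismatches += 1
            tp += pred and truth
            fp += pred and not truth
            fn += truth and not pred
            tn += (not pred) and (not truth)
        per_family[fam] = {
            "precision": tp / (tp + fp) if tp + fp else 1.0,
            "recall": tp / (tp + fn) if tp + fn else 1.0,
            "mismatches": fp + fn,
        }
    import json

    with open(out_dir / "venn.json") as fh:
        venn_pipeline = json.load(fh)["regions"]
    venn_match = venn_pipeline == ledger.venn_regions
    return {
        "cells": cells,
        "cell_mismatches": mismatches,
        "presence_match": mismatches == 0,
        "venn_pipeline": venn_pipeline,
        "venn_ledger": ledger.venn_regions,
        "venn_match": venn_match,
        "per_family": per_family,
        "all_match": mismatches == 0 and venn_match,
    }
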