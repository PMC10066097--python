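"""Synthetic pangenome generator with ground-truth ledger.

Generates protein families with controlled within/between-family percent
identity, multi-contig genomes in which a hub gene is surrounded by
neighbour genes planted under explicit co-occurrence rules (implication,
exclusion, marginal presence), and a two-level taxonomy labelling — the
statistical structure the neighbourhood/SSN analysis assumes — so every
pipeline stage is testable without downloading any real database.

Model choices:

* Mutation is uniform substitution (each position independently replaced
  with probability 1 − target identity, by one of the 19 other residues),
  which keeps realised identity analytically predictable (binomial).  No
  indels: family members share their family's length.
* Family seed sequences are independent uniform-random sequences, so
  cross-family identity sits at the ~5–10 % background; divergence is
  additionally *enforced* by rejection sampling rather than assumed.
* Genome neighbourhood filler ("decoy") genes are drawn from a finite pool
  of perfectly conserved decoy sequences, emulating conserved housekeeping
  genes shared across strains; planted family members are freshly mutated
  per genome.
* Subfamily structure (the taxonomy level) is realised by mutating
  subfamily seeds derived from the family seed, so within-subfamily
  identity exceeds between-subfamily identity by construction.

The ledger records what was *realised*, not what was targeted: presence
tables and Venn regions are derivable from the planted layout by the window
definition, and this self-consistency is checked at emit time.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .alignment import align_local
from .formats import (
    AMINO_ACIDS,
    PipelineConfig,
    ProteinRecord,
    write_fasta,
    write_gff3,
)

_AA = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)


class SyntheticError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubfamilySpec:
    """One subfamily: its share of members, internal identity, taxon label."""

    weight: float
    within_identity: float
    taxon: str


@dataclass(frozen=True)
class FamilySpec:
    """A protein family: seed length, size, identity targets, annotation."""

    name: str
    seed_length: int
    n_members: int
    within_identity: float
    label: str
    subfamilies: tuple[SubfamilySpec, ...] = ()

    def __post_init__(self) -> None:
        if self.seed_length < 30:
            raise SyntheticError(f"{self.name}: seed_length must be >= 30")
        if not 0 < self.within_identity <= 1:
            raise SyntheticError(f"{self.name}: within_identity must be in (0, 1]")
        for sub in self.subfamilies:
            if sub.within_identity < self.within_identity:
                raise SyntheticError(
                    f"{self.name}: subfamily identity must be >= family identity"
                )


@dataclass(frozen=True)
class CooccurrenceRule:
    """Presence rule for one neighbour family.

    ``marginal_presence`` is the probability the family is planted when its
    constraints are satisfied; ``requires``/``excludes`` name other families;
    ``exception_rate`` is the probability that a constraint violation is
    planted anyway.
    """

    family: str
    marginal_presence: float
    requires: str | None = None
    excludes: str | None = None
    exception_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.marginal_presence <= 1:
            raise SyntheticError(f"{self.family}: marginal_presence not in [0, 1]")
        if not 0 <= self.exception_rate <= 1:
            raise SyntheticError(f"{self.family}: exception_rate not in [0, 1]")
        if self.requires is not None and self.requires == self.excludes:
            raise SyntheticError(f"{self.family}: requires == excludes")


# ---------------------------------------------------------------------------
# Sequence-level operations
# ---------------------------------------------------------------------------

def random_sequence(length: int, rng: np.random.Generator) -> str:
    """Uniform random sequence over the 20 canonical residues."""
    return _AA[rng.integers(0, 20, size=length)].tobytes().decode()


def mutate_sequence(seed: str, target_identity: float, rng: np.random.Generator) -> str:
    """Substitute each position independently with probability
    1 − target_identity; replacements are uniform over the 19 other residues.
    Length is preserved."""
    if not 0 < target_identity <= 1:
        raise SyntheticError("target_identity must be in (0, 1]")
    arr = np.frombuffer(seed.encode(), dtype=np.uint8).copy()
    idx = np.searchsorted(_AA, arr)
    mutate = rng.random(arr.size) < (1.0 - target_identity)
    n_mut = int(mutate.sum())
    if n_mut:
        draw = rng.integers(0, 19, size=n_mut)
        cur = idx[mutate]
        new = draw + (draw >= cur)  # uniform over the 19 non-current residues
        arr[mutate] = _AA[new]
    return arr.tobytes().decode()


def fractional_identity(a: str, b: str) -> float:
    """Position-wise identity of two equal-length sequences."""
    if len(a) != len(b):
        raise SyntheticError("sequences differ in length")
    xa = np.frombuffer(a.encode(), dtype=np.uint8)
    xb = np.frombuffer(b.encode(), dtype=np.uint8)
    return float((xa == xb).mean())


def cross_identity(a: str, b: str) -> float:
    """Identities in the optimal local alignment over min(len) — a
    length-normalised divergence measure that is not inflated by short,
    high-identity local hits between unrelated sequences."""
    ra = ProteinRecord(protein_id="a", sequence=a)
    rb = ProteinRecord(protein_id="b", sequence=b)
    hit = align_local(ra, rb)
    return hit.n_identities / min(len(a), len(b))


# ---------------------------------------------------------------------------
# Family generation
# ---------------------------------------------------------------------------

@dataclass
class Family:
    """A realised family: its seeds plus a factory for fresh members."""

    spec: FamilySpec
    seed: str
    subfamily_seeds: tuple[str, ...] = ()

    def draw_member(
        self, rng: np.random.Generator, subfamily: int | None = None
    ) -> tuple[str, int | None]:
        """A fresh member sequence (and its subfamily index, if any)."""
        if self.spec.subfamilies:
            if subfamily is None:
                weights = np.array([s.weight for s in self.spec.subfamilies], float)
                subfamily = int(rng.choice(len(weights), p=weights / weights.sum()))
            seq = mutate_sequence(
                self.subfamily_seeds[subfamily],
                self.spec.subfamilies[subfamily].within_identity,
                rng,
            )
            return seq, subfamily
        return mutate_sequence(self.seed, self.spec.within_identity, rng), None


def make_family(
    spec: FamilySpec, rng: np.random.Generator
) -> tuple[list[ProteinRecord], dict]:
    """Generate ``spec.n_members`` records plus a ground-truth fragment.

    With subfamilies, members are split by subfamily weight (largest
    remainder) and each subfamily's members are mutated from a subfamily
    seed that is itself a mutation of the family seed at the family's
    within-identity.
    """
    fam = realize_family(spec, rng)
    records: list[ProteinRecord] = []
    member_subfamily: dict[str, int | None] = {}
    if spec.subfamilies:
        weights = np.array([s.weight for s in spec.subfamilies], float)
        shares = weights / weights.sum() * spec.n_members
        sizes = np.floor(shares).astype(int)
        for _ in range(spec.n_members - int(sizes.sum())):
            sizes[int(np.argmax(shares - sizes))] += 1
        assignment = [k for k, n in enumerate(sizes) for _ in range(n)]
    else:
        assignment = [None] * spec.n_members
    for i, sub in enumerate(assignment):
        seq, sub_idx = fam.draw_member(rng, subfamily=sub)
        pid = f"{spec.name}_m{i:03d}"
        records.append(
            ProteinRecord(protein_id=pid, sequence=seq, description=spec.label)
        )
        member_subfamily[pid] = sub_idx
    identities = [fractional_identity(r.sequence, fam.seed) for r in records]
    fragment = {
        "name": spec.name,
        "label": spec.label,
        "seed_length": spec.seed_length,
        "within_identity": spec.within_identity,
        "member_subfamily": {
            pid: (None if s is None else spec.subfamilies[s].taxon)
            for pid, s in member_subfamily.items()
        },
        "identity_to_seed": {
            "min": min(identities),
            "mean": float(np.mean(identities)),
            "max": max(identities),
        },
    }
    return records, fragment


def realize_family(spec: FamilySpec, rng: np.random.Generator) -> Family:
    seed = random_sequence(spec.seed_length, rng)
    sub_seeds = tuple(
        mutate_sequence(seed, spec.within_identity, rng) for _ in spec.subfamilies
    )
    return Family(spec=spec, seed=seed, subfamily_seeds=sub_seeds)


def realize_families(
    specs: Sequence[FamilySpec],
    rng: np.random.Generator,
    max_cross_identity: float = 0.30,
    max_attempts: int = 50,
) -> dict[str, Family]:
    """Realise family seeds, enforcing cross-family divergence by rejection:
    a new seed is redrawn until its cross-identity to every accepted seed is
    ≤ the bound."""
    families: dict[str, Family] = {}
    for spec in specs:
        for attempt in range(max_attempts):
            fam = realize_family(spec, rng)
            if all(
                cross_identity(fam.seed, other.seed) <= max_cross_identity
                for other in families.values()
            ):
                families[spec.name] = fam
                break
        else:
            raise SyntheticError(
                f"could not realise {spec.name} below cross-identity "
                f"{max_cross_identity} in {max_attempts} attempts"
            )
    return families


# ---------------------------------------------------------------------------
# Pangenome generation
# ---------------------------------------------------------------------------

@dataclass
class SyntheticLedger:
    """Ground truth emitted by the generator.

    ``presence`` is the realised genome × family table (1 iff the family was
    planted in the hub window); ``venn_regions`` are the region counts it
    implies for the tracked sets.  Both are *realised*, not targeted.
    """

    rng_seed: int
    families: dict
    genomes: dict
    presence: dict[str, dict[str, int]]
    protein_family: dict[str, str]
    taxonomy: dict[str, str]
    tracked_sets: list[str]
    venn_regions: dict[str, int]
    cutoffs: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticLedger":
        with open(path) as fh:
            return cls(**json.load(fh))


def _sample_presence(
    rules: Sequence[CooccurrenceRule],
    n_genomes: int,
    rng: np.random.Generator,
    forced_exceptions: Mapping[str, int] | None = None,
) -> list[dict[str, bool]]:
    """Sample per-genome presence under the rules (rule order respected).

    Constraint violations occur at each rule's exception_rate; on top of
    that, ``forced_exceptions[family] = k`` deterministically converts k
    eligible genomes into violations of that family's ``requires``
    constraint (used to plant an exact number of exceptions).
    """
    presence: list[dict[str, bool]] = []
    for _ in range(n_genomes):
        state: dict[str, bool] = {}
        for rule in rules:
            want = rng.random() < rule.marginal_presence
            ok = True
            if rule.requires is not None and not state.get(rule.requires, False):
                ok = False
            if rule.excludes is not None and state.get(rule.excludes, False):
                ok = False
            if want and not ok:
                want = rng.random() < rule.exception_rate
            state[rule.family] = want
        presence.append(state)
    for fam, k in (forced_exceptions or {}).items():
        rule = next(r for r in rules if r.family == fam)
        if rule.requires is None:
            raise SyntheticError(f"forced exception for {fam} needs a requires rule")
        eligible = [
            i
            for i, st in enumerate(presence)
            if not st.get(rule.requires, False) and not st[fam]
        ]
        if len(eligible) < k:
            raise SyntheticError(
                f"cannot place {k} forced exception(s) for {fam}: "
                f"only {len(eligible)} eligible genomes"
            )
        for i in rng.choice(eligible, size=k, replace=False):
            presence[int(i)][fam] = True
    return presence


def make_pangenome(
    families: Mapping[str, Family],
    rules: Sequence[CooccurrenceRule],
    n_genomes: int,
    genes_per_contig: tuple[int, int],
    rng: np.random.Generator,
    hub_family: str,
    window_orfs: int = 10,
    decoy_pool_size: int = 100,
    decoy_length_range: tuple[int, int] = (150, 450),
    forced_exceptions: Mapping[str, int] | None = None,
    rng_seed: int = 0,
    out_dir: str | Path | None = None,
) -> tuple[dict[str, list[ProteinRecord]], SyntheticLedger]:
    """Generate genomes (FASTA + GFF3 if ``out_dir`` given) plus the ledger.

    Per genome: one contig of decoy genes with the hub gene at a drawn
    position and one fresh member of each present neighbour family planted
    at a distinct ORF offset within ±``window_orfs`` (and within the
    contig, so the ledger presence table is exactly what any correct window
    extraction will see).
    """
    if hub_family not in families:
        raise SyntheticError(f"hub family {hub_family!r} not realised")
    for rule in rules:
        for ref in (rule.family, rule.requires, rule.excludes):
            if ref is not None and ref not in families:
                raise SyntheticError(f"rule references unknown family {ref!r}")
    neighbour_rules = [r for r in rules if r.family != hub_family]
    presence_states = _sample_presence(
        neighbour_rules, n_genomes, rng, forced_exceptions
    )
    decoy_pool = [
        random_sequence(int(rng.integers(*decoy_length_range)), rng)
        for _ in range(decoy_pool_size)
    ]

    genomes: dict[str, list[ProteinRecord]] = {}
    ledger_genomes: dict[str, dict] = {}
    presence_table: dict[str, dict[str, int]] = {}
    protein_family: dict[str, str] = {}
    taxonomy: dict[str, str] = {}
    hub_spec = families[hub_family].spec

    for g, state in enumerate(presence_states):
        gid = f"g{g:04d}"
        n_genes = int(rng.integers(genes_per_contig[0], genes_per_contig[1] + 1))
        hub_pos = int(rng.integers(0, n_genes))
        planted = sorted(f for f, present in state.items() if present)
        offsets = [
            d
            for d in range(-window_orfs, window_orfs + 1)
            if d != 0 and 0 <= hub_pos + d < n_genes
        ]
        if len(planted) > len(offsets):
            raise SyntheticError(
                f"{gid}: {len(planted)} planted neighbours exceed "
                f"{len(offsets)} available window slots"
            )
        chosen = rng.choice(len(offsets), size=len(planted), replace=False)
        slot_of = {fam: offsets[int(i)] for fam, i in zip(planted, chosen)}

        hub_seq, sub_idx = families[hub_family].draw_member(rng)
        if sub_idx is not None:
            taxonomy[gid] = hub_spec.subfamilies[sub_idx].taxon
        else:
            taxonomy[gid] = "unknown"

        records: list[ProteinRecord] = []
        planted_detail: dict[str, dict] = {}
        position_payload: dict[int, tuple[str, str, str]] = {
            hub_pos: (f"{gid}_hub", hub_seq, hub_spec.label)
        }
        protein_family[f"{gid}_hub"] = hub_family
        for fam_name in planted:
            pos = hub_pos + slot_of[fam_name]
            seq, _ = families[fam_name].draw_member(rng)
            pid = f"{gid}_{fam_name}"
            position_payload[pos] = (pid, seq, families[fam_name].spec.label)
            protein_family[pid] = fam_name
            planted_detail[fam_name] = {"protein_id": pid, "offset": slot_of[fam_name]}
        for pos in range(n_genes):
            if pos in position_payload:
                continue
            pool_idx = int(rng.integers(0, decoy_pool_size))
            pid = f"{gid}_d{pos:03d}"
            position_payload[pos] = (pid, decoy_pool[pool_idx], "hypothetical protein")
            protein_family[pid] = "decoy"
        start = 1
        for pos in range(n_genes):
            pid, seq, label = position_payload[pos]
            end = start + 3 * len(seq) + 2
            records.append(
                ProteinRecord(
                    protein_id=pid,
                    sequence=seq,
                    description=label,
                    genome_id=gid,
                    contig_id=f"{gid}_c0",
                    start=start,
                    end=end,
                    strand="+" if rng.random() < 0.5 else "-",
                    order_index=pos,
                )
            )
            start = end + int(rng.integers(50, 300))
        genomes[gid] = records
        presence_table[gid] = {f: int(state[f]) for f in sorted(state)}
        ledger_genomes[gid] = {
            "hub_id": f"{gid}_hub",
            "n_genes": n_genes,
            "hub_position": hub_pos,
            "planted": planted_detail,
            "taxon": taxonomy[gid],
            "truncated_left": hub_pos - window_orfs < 0,
            "truncated_right": hub_pos + window_orfs > n_genes - 1,
        }

    tracked = sorted({r.family for r in neighbour_rules})
    ledger = SyntheticLedger(
        rng_seed=rng_seed,
        families={
            name: {
                "label": fam.spec.label,
                "seed_length": fam.spec.seed_length,
                "within_identity": fam.spec.within_identity,
                "subfamilies": [dataclasses.asdict(s) for s in fam.spec.subfamilies],
            }
            for name, fam in sorted(families.items())
        },
        genomes=ledger_genomes,
        presence=presence_table,
        protein_family=protein_family,
        taxonomy=taxonomy,
        tracked_sets=tracked,
        venn_regions={},
    )
    _check_ledger_consistency(genomes, ledger, window_orfs)
    if out_dir is not None:
        out_dir = Path(out_dir)
        (out_dir / "genomes").mkdir(parents=True, exist_ok=True)
        for gid in sorted(genomes):
            write_fasta(genomes[gid], out_dir / "genomes" / f"{gid}.faa")
            write_gff3(genomes[gid], out_dir / "genomes" / f"{gid}.gff3")
    return genomes, ledger


def venn_regions_from_presence(
    presence: Mapping[str, Mapping[str, int]], sets: Sequence[str]
) -> dict[str, int]:
    """Region counts implied by a presence table (independent of the
    pipeline's own Venn computation)."""
    import itertools

    regions: dict[str, int] = {}
    for include in itertools.product([0, 1], repeat=len(sets)):
        members = [s for s, inc in zip(sets, include) if inc]
        key = "&".join(members) if members else "none"
        regions[key] = 0
    for state in presence.values():
        members = [s for s in sets if state.get(s, 0)]
        key = "&".join(members) if members else "none"
        regions[key] += 1
    return regions


def _check_ledger_consistency(
    genomes: Mapping[str, Sequence[ProteinRecord]],
    ledger: SyntheticLedger,
    window_orfs: int,
) -> None:
    """Self-consistency at emit time: a brute-force window scan over the
    generated genomes must reproduce the ledger's presence table exactly."""
    from .neighborhoods import extract_window

    for gid, info in ledger.genomes.items():
        window = extract_window(genomes[gid], info["hub_id"], window_orfs)
        seen = {
            ledger.protein_family[pid]
            for pid in window.neighbor_ids
            if ledger.protein_family.get(pid, "decoy") != "decoy"
        }
        expected = {f for f, v in ledger.presence[gid].items() if v}
        if seen != expected:
            raise SyntheticError(
                f"ledger inconsistency in {gid}: window sees {sorted(seen)}, "
                f"ledger says {sorted(expected)}"
            )
        if (
            window.truncated_left != info["truncated_left"]
            or window.truncated_right != info["truncated_right"]
        ):
            raise SyntheticError(f"ledger inconsistency in {gid}: truncation flags")


# ---------------------------------------------------------------------------
# Built-in scenarios
# ---------------------------------------------------------------------------

def _paper_like_params() -> dict:
    """Qualitative structure of the published study at desk scale: one hub
    family with taxonomy-correlated subfamilies, neighbour families with the
    published co-occurrence pattern (B1 nearly ubiquitous; B2 requires B1 and
    excludes B3; B3 requires B1 with exactly one planted exception; B4 rare;
    C in about half the genomes), plus transporter/regulator neighbour
    clusters and conserved filler genes."""
    hub = FamilySpec(
        name="lgdA",
        seed_length=350,
        n_members=0,
        within_identity=0.85,
        label="levoglucosan dehydrogenase",
        subfamilies=(
            SubfamilySpec(0.45, 0.95, "Firmicutes"),
            SubfamilySpec(0.35, 0.95, "Actinobacteria"),
            SubfamilySpec(0.20, 0.95, "Proteobacteria"),
        ),
    )
    neighbours = [
        FamilySpec("lgdB1", 275, 0, 0.85, "3-keto-levoglucosan beta-eliminase"),
        FamilySpec("lgdB2", 325, 0, 0.85, "3-ketoglucose dehydratase"),
        FamilySpec("lgdB3", 280, 0, 0.85, "sugar phosphate isomerase, inosose dehydratase-like"),
        FamilySpec("lgdB4", 270, 0, 0.85, "sugar phosphate isomerase/epimerase"),
        FamilySpec("lgdC", 360, 0, 0.85, "glucose 3-dehydrogenase"),
        FamilySpec("abc_perm", 300, 0, 0.85, "ABC transporter permease"),
        FamilySpec("laci_reg", 220, 0, 0.85, "LacI family transcriptional regulator"),
    ]
    rules = [
        CooccurrenceRule("lgdB1", 0.95),
        CooccurrenceRule("lgdB3", 0.28, requires="lgdB1"),
        CooccurrenceRule("lgdB2", 0.30, requires="lgdB1", excludes="lgdB3"),
        CooccurrenceRule("lgdB4", 0.02, requires="lgdB1"),
        CooccurrenceRule("lgdC", 0.57),
        CooccurrenceRule("abc_perm", 0.40),
        CooccurrenceRule("laci_reg", 0.30),
    ]
    return {
        "families": [hub] + neighbours,
        "rules": rules,
        "hub_family": "lgdA",
        "n_genomes": 200,
        "genes_per_contig": (24, 30),
        "decoy_pool_size": 100,
        "forced_exceptions": {"lgdB3": 1},
        "tracked_labels": {
            "lgdB1": "3-keto-levoglucosan beta-eliminase",
            "lgdB2": "3-ketoglucose dehydratase",
            "lgdB3": "sugar phosphate isomerase, inosose dehydratase-like",
            "lgdC": "glucose 3-dehydrogenase",
        },
        "venn_sets": ["lgdB1", "lgdB2", "lgdB3"],
        "config": {},
    }


def _hierarchy_params() -> dict:
    """A hub family that splits into three taxonomy-aligned subfamilies at
    the fine SSN threshold; one common neighbour family."""
    hub = FamilySpec(
        name="lgdA",
        seed_length=350,
        n_members=0,
        within_identity=0.85,
        label="levoglucosan dehydrogenase",
        subfamilies=(
            SubfamilySpec(1.0, 0.95, "taxon_A"),
            SubfamilySpec(1.0, 0.95, "taxon_B"),
            SubfamilySpec(1.0, 0.95, "taxon_C"),
        ),
    )
    b1 = FamilySpec("lgdB1", 275, 0, 0.85, "3-keto-levoglucosan beta-eliminase")
    return {
        "families": [hub, b1],
        "rules": [CooccurrenceRule("lgdB1", 0.9)],
        "hub_family": "lgdA",
        "n_genomes": 36,
        "genes_per_contig": (12, 16),
        "decoy_pool_size": 30,
        "forced_exceptions": None,
        "tracked_labels": {"lgdB1": "3-keto-levoglucosan beta-eliminase"},
        "venn_sets": ["lgdB1"],
        "config": {},
    }


def _minimal_params() -> dict:
    """Two families, ten small genomes: an end-to-end smoke scenario."""
    hub = FamilySpec("lgdA", 150, 0, 0.90, "levoglucosan dehydrogenase")
    b1 = FamilySpec("lgdB1", 200, 0, 0.85, "3-keto-levoglucosan beta-eliminase")
    return {
        "families": [hub, b1],
        "rules": [CooccurrenceRule("lgdB1", 0.9)],
        "hub_family": "lgdA",
        "n_genomes": 10,
        "genes_per_contig": (6, 9),
        "decoy_pool_size": 15,
        "forced_exceptions": None,
        "tracked_labels": {"lgdB1": "3-keto-levoglucosan beta-eliminase"},
        "venn_sets": ["lgdB1"],
        # Small proteins score lower; scale the SSN thresholds with them.
        "config": {"ssn_threshold_primary": 40.0, "ssn_threshold_fine": 60.0},
    }


SCENARIOS = {
    "paper-like": _paper_like_params,
    "hierarchy": _hierarchy_params,
    "minimal": _minimal_params,
}


def place_cutoffs(
    query: ProteinRecord,
    genomes: Mapping[str, Sequence[ProteinRecord]],
    ledger: SyntheticLedger,
    hub_family: str,
    config: PipelineConfig,
) -> tuple[float, float]:
    """Place the two E-value cutoffs in the gap between the hub family and
    everything else, using the realised sequences.

    Stage 1 uses pairwise log10 E-values of the query against every distinct
    sequence; stage 2 builds and calibrates the profile exactly as the
    pipeline will and reads off the profile E-value gap.  Cutoffs are the
    log-space midpoints of the gaps (recorded in the ledger), so planted-
    family recovery is exact whenever the families are separable at all.
    """
    import math as _math

    from .search import build_profile, calibrate_profile, search_pairwise, search_profile

    db: list[ProteinRecord] = [r for recs in genomes.values() for r in recs]
    in_ids = {
        pid for pid, fam in ledger.protein_family.items() if fam == hub_family
    }

    def gap_midpoint(in_scores, out_scores, label):
        worst_in = max(in_scores)
        best_out = min(out_scores)
        if worst_in >= best_out:
            raise SyntheticError(
                f"{label}: no E-value gap between hub family and background "
                f"({worst_in:.1f} vs {best_out:.1f})"
            )
        return max((worst_in + best_out) / 2.0, -300.0)

    stage1_all = search_pairwise(query, db, 1e9, config)
    log_e = {h.subject_id: h.evalue_log10 for h in stage1_all}
    mid1 = gap_midpoint(
        [log_e[p] for p in in_ids],
        [v for p, v in log_e.items() if p not in in_ids],
        "stage 1",
    )
    evalue_stage1 = 10.0 ** mid1

    stage1_hits = [h for h in stage1_all if h.evalue_log10 <= mid1]
    profile = build_profile(query, stage1_hits)
    lengths = sorted(len(r.sequence) for r in db)
    calibrate_profile(
        profile,
        int(lengths[len(lengths) // 2]),
        n_shuffles=config.n_shuffles,
        rng_seed=config.rng_seed,
        gap_open=config.gap_open,
        gap_extend=config.gap_extend,
    )
    stage2_all = search_profile(profile, db, 1e9, config.gap_open, config.gap_extend)
    log_e2 = {h.subject_id: h.evalue_log10 for h in stage2_all}
    mid2 = gap_midpoint(
        [log_e2[p] for p in in_ids],
        [v for p, v in log_e2.items() if p not in in_ids],
        "stage 2",
    )
    evalue_stage2 = min(10.0 ** mid2, evalue_stage1)
    return evalue_stage1, evalue_stage2


def emit_scenario(
    name: str,
    out_dir: str | Path,
    seed: int = 0,
) -> tuple[Path, SyntheticLedger]:
    """Write a complete, self-describing scenario to ``out_dir``.

    Files: ``genomes/*.faa`` + ``genomes/*.gff3``, ``query.faa``,
    ``taxonomy.tsv``, ``config.yaml`` (pipeline configuration with the
    ledger-placed E-value cutoffs), ``run.yaml`` (what to analyse) and
    ``ledger.json`` (ground truth).  Byte-identical for identical seeds.
    """
    if name not in SCENARIOS:
        raise SyntheticError(
            f"unknown scenario {name!r}; options: {sorted(SCENARIOS)}"
        )
    params = SCENARIOS[name]()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    config = PipelineConfig(rng_seed=seed, **params["config"])
    families = realize_families(params["families"], rng)
    genomes, ledger = make_pangenome(
        families,
        params["rules"],
        params["n_genomes"],
        params["genes_per_contig"],
        rng,
        hub_family=params["hub_family"],
        window_orfs=config.window_orfs,
        decoy_pool_size=params["decoy_pool_size"],
        forced_exceptions=params["forced_exceptions"],
        rng_seed=seed,
        out_dir=out_dir,
    )
    ledger.tracked_sets = params["venn_sets"]
    ledger.venn_regions = venn_regions_from_presence(
        ledger.presence, params["venn_sets"]
    )

    first_gid = sorted(genomes)[0]
    hub_rec = next(
        r for r in genomes[first_gid] if r.protein_id == f"{first_gid}_hub"
    )
    query = ProteinRecord(
        protein_id="query",
        sequence=hub_rec.sequence,
        description=families[params["hub_family"]].spec.label,
    )
    write_fasta([query], out_dir / "query.faa")

    e1, e2 = place_cutoffs(query, genomes, ledger, params["hub_family"], config)
    config.evalue_stage1 = e1
    config.evalue_stage2 = e2
    ledger.cutoffs = {
        "evalue_stage1_log10": math.log10(e1),
        "evalue_stage2_log10": math.log10(e2),
    }
    config.to_yaml(out_dir / "config.yaml")

    with open(out_dir / "taxonomy.tsv", "w") as fh:
        fh.write("genome_id\ttaxon\n")
        for gid in sorted(ledger.taxonomy):
            fh.write(f"{gid}\t{ledger.taxonomy[gid]}\n")

    run_spec = {
        "scenario": name,
        "config": "config.yaml",
        "genomes_dir": "genomes",
        "query_fasta": "query.faa",
        "taxonomy": "taxonomy.tsv",
        "tracked_labels": params["tracked_labels"],
        "venn_sets": params["venn_sets"],
    }
    with open(out_dir / "run.yaml", "w") as fh:
        yaml.safe_dump(run_spec, fh, sort_keys=True)

    ledger.to_json(out_dir / "ledger.json")
    return out_dir, ledger
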