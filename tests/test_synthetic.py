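import json
import math

import numpy as np
import pytest

from gnossn import (
    CooccurrenceRule,
    FamilySpec,
    SubfamilySpec,
    emit_scenario,
    make_family,
    make_pangenome,
    mutate_sequence,
    realize_families,
)
from gnossn.formats import read_fasta, read_genome
from gnossn.neighborhoods import extract_window
from gnossn.synthetic import (
    SyntheticError,
    cross_identity,
    fractional_identity,
    random_sequence,
    venn_regions_from_presence,
)


class TestMutateSequence:
    def test_identity_one_is_noop(self, rng):
        seq = random_sequence(100, rng)
        assert mutate_sequence(seq, 1.0, rng) == seq

    def test_realised_identity_within_binomial_bounds(self, rng):
        """Target 0.8 over 500 positions: 3 sd of Binomial(500, 0.8)/500 is
        ~0.054."""
        seq = random_sequence(500, rng)
        for _ in range(5):
            mutant = mutate_sequence(seq, 0.8, rng)
            assert fractional_identity(seq, mutant) == pytest.approx(0.8, abs=0.054)

    def test_deterministic_under_seeded_rng(self):
        seq = random_sequence(200, np.random.default_rng(1))
        m1 = mutate_sequence(seq, 0.7, np.random.default_rng(9))
        m2 = mutate_sequence(seq, 0.7, np.random.default_rng(9))
        assert m1 == m2

    def test_length_preserved_and_alphabet_legal(self, rng):
        seq = random_sequence(80, rng)
        mutant = mutate_sequence(seq, 0.3, rng)
        assert len(mutant) == 80
        assert set(mutant) <= set("ACDEFGHIKLMNPQRSTVWY")

    def test_bad_identity_rejected(self, rng):
        with pytest.raises(SyntheticError):
            mutate_sequence("MKVLW" * 10, 0.0, rng)


class TestMakeFamily:
    def test_member_count_and_label(self, rng):
        spec = FamilySpec("fam", 120, 20, 0.85, "eliminase")
        records, fragment = make_family(spec, rng)
        assert len(records) == 20
        assert all(r.description == "eliminase" for r in records)
        assert fragment["identity_to_seed"]["mean"] == pytest.approx(0.85, abs=0.06)

    def test_pairwise_identity_floor(self, rng):
        """Members at 0.85 to the seed diverge pairwise to ~0.72; the
        worst-case two-sided bound is well above 0.65."""
        spec = FamilySpec("fam", 300, 20, 0.85, "x")
        records, _ = make_family(spec, rng)
        worst = min(
            fractional_identity(a.sequence, b.sequence)
            for i, a in enumerate(records)
            for b in records[i + 1 :]
        )
        assert worst >= 0.65

    def test_subfamily_structure(self, rng):
        spec = FamilySpec(
            "fam", 250, 20, 0.85, "x",
            subfamilies=(
                SubfamilySpec(1.0, 0.95, "tA"),
                SubfamilySpec(1.0, 0.95, "tB"),
            ),
        )
        records, fragment = make_family(spec, rng)
        taxa = fragment["member_subfamily"]
        groups = {}
        for r in records:
            groups.setdefault(taxa[r.protein_id], []).append(r.sequence)
        assert sorted(len(g) for g in groups.values()) == [10, 10]
        within = min(
            fractional_identity(a, b)
            for g in groups.values()
            for i, a in enumerate(g)
            for b in g[i + 1 :]
        )
        (ga, gb) = groups.values()
        between = max(fractional_identity(a, b) for a in ga for b in gb)
        assert within > between

    def test_subfamily_identity_below_family_rejected(self):
        with pytest.raises(SyntheticError, match="subfamily"):
            FamilySpec(
                "fam", 100, 5, 0.9, "x", subfamilies=(SubfamilySpec(1, 0.5, "t"),)
            )


class TestRealizeFamilies:
    def test_cross_family_divergence_enforced(self, rng):
        specs = [FamilySpec(f"f{i}", 220, 5, 0.85, "x") for i in range(4)]
        families = realize_families(specs, rng, max_cross_identity=0.30)
        seeds = [f.seed for f in families.values()]
        for i, a in enumerate(seeds):
            for b in seeds[i + 1 :]:
                assert cross_identity(a, b) <= 0.30


def two_family_setup(rng, rules, n_genomes=30, forced=None, genes=(8, 12)):
    specs = [
        FamilySpec("hub", 150, 0, 0.9, "hub protein"),
        FamilySpec("famB", 160, 0, 0.85, "B protein"),
    ]
    families = realize_families(specs, rng)
    return make_pangenome(
        families,
        rules,
        n_genomes,
        genes,
        rng,
        hub_family="hub",
        decoy_pool_size=10,
        forced_exceptions=forced,
    )


class TestMakePangenome:
    def test_marginal_one_gives_all_ones_column(self, rng):
        genomes, ledger = two_family_setup(rng, [CooccurrenceRule("famB", 1.0)])
        assert all(p["famB"] == 1 for p in ledger.presence.values())

    def test_truncation_flags_recorded(self, rng):
        genomes, ledger = two_family_setup(
            rng, [CooccurrenceRule("famB", 0.5)], n_genomes=50
        )
        # small contigs with window 10: every hub is near an edge
        assert any(g["truncated_left"] for g in ledger.genomes.values())
        for gid, info in ledger.genomes.items():
            assert info["truncated_left"] == (info["hub_position"] - 10 < 0)

    def test_window_scan_reproduces_presence_table(self, rng):
        genomes, ledger = two_family_setup(rng, [CooccurrenceRule("famB", 0.6)])
        for gid, records in genomes.items():
            w = extract_window(records, ledger.genomes[gid]["hub_id"], 10)
            seen = {
                ledger.protein_family[p]
                for p in w.neighbor_ids
                if ledger.protein_family[p] != "decoy"
            }
            assert ("famB" in seen) == bool(ledger.presence[gid]["famB"])

    def test_forced_exception_count_is_exact(self, rng):
        rules = [
            CooccurrenceRule("famB", 0.8),
            CooccurrenceRule("famC", 0.3, requires="famB"),
        ]
        specs = [
            FamilySpec("hub", 150, 0, 0.9, "hub protein"),
            FamilySpec("famB", 160, 0, 0.85, "B protein"),
            FamilySpec("famC", 170, 0, 0.85, "C protein"),
        ]
        families = realize_families(specs, rng)
        _, ledger = make_pangenome(
            families, rules, 60, (8, 12), rng,
            hub_family="hub", decoy_pool_size=10,
            forced_exceptions={"famC": 1},
        )
        exceptions = sum(
            1
            for p in ledger.presence.values()
            if p["famC"] and not p["famB"]
        )
        assert exceptions == 1

    def test_region_counts_near_multinomial_expectation(self, rng):
        """famB at marginal 0.7 over 200 genomes: realised count within 4
        binomial standard deviations."""
        _, ledger = two_family_setup(
            rng, [CooccurrenceRule("famB", 0.7)], n_genomes=200, genes=(10, 14)
        )
        count = sum(p["famB"] for p in ledger.presence.values())
        sd = math.sqrt(200 * 0.7 * 0.3)
        assert abs(count - 140) <= 4 * sd

    def test_implication_holds_without_exceptions(self, rng):
        rules = [
            CooccurrenceRule("famB", 0.6),
            CooccurrenceRule("famC", 0.5, requires="famB"),
        ]
        specs = [
            FamilySpec("hub", 150, 0, 0.9, "hub"),
            FamilySpec("famB", 160, 0, 0.85, "B"),
            FamilySpec("famC", 170, 0, 0.85, "C"),
        ]
        families = realize_families(specs, rng)
        _, ledger = make_pangenome(
            families, rules, 80, (8, 12), rng, hub_family="hub", decoy_pool_size=10
        )
        assert all(p["famB"] >= p["famC"] for p in ledger.presence.values())


class TestVennFromPresence:
    def test_regions_sum_and_keys(self):
        presence = {
            "g1": {"A": 1, "B": 0},
            "g2": {"A": 1, "B": 1},
            "g3": {"A": 0, "B": 0},
        }
        regions = venn_regions_from_presence(presence, ["A", "B"])
        assert regions == {"A": 1, "A&B": 1, "B": 0, "none": 1}


class TestEmitScenario:
    def test_minimal_files_and_ledger(self, minimal_scenario):
        path, ledger = minimal_scenario
        assert (path / "query.faa").exists()
        assert (path / "config.yaml").exists()
        faa = sorted((path / "genomes").glob("*.faa"))
        assert len(faa) == 10
        genome = read_genome(faa[0].with_suffix(".gff3"), faa[0])
        assert any(r.protein_id.endswith("_hub") for r in genome)
        regions = venn_regions_from_presence(ledger.presence, ledger.tracked_sets)
        assert regions == ledger.venn_regions

    def test_unknown_scenario_lists_options(self, tmp_path):
        with pytest.raises(SyntheticError, match="minimal"):
            emit_scenario("nope", tmp_path)

    def test_same_seed_byte_identical(self, tmp_path):
        emit_scenario("minimal", tmp_path / "a", seed=2)
        emit_scenario("minimal", tmp_path / "b", seed=2)
        files_a = sorted((tmp_path / "a").rglob("*.*"))
        files_b = sorted((tmp_path / "b").rglob("*.*"))
        assert [f.name for f in files_a] == [f.name for f in files_b]
        for fa, fb in zip(files_a, files_b):
            assert fa.read_bytes() == fb.read_bytes(), fa.name
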