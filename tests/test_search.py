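import math

import numpy as np
import pytest
from scipy import stats

from gnossn import (
    ProteinRecord,
    build_profile,
    calibrate_profile,
    search_pairwise,
    search_profile,
    two_stage_search,
)
from gnossn.formats import AMINO_ACIDS, PipelineConfig
from gnossn.search import (
    SearchError,
    fit_gumbel,
    gumbel_log10_sf,
    score_profile,
)
from gnossn.synthetic import mutate_sequence, random_sequence


def rec(pid, seq):
    return ProteinRecord(protein_id=pid, sequence=seq)


def family_db(rng, seed_len, n, identity, prefix):
    seed = random_sequence(seed_len, rng)
    return seed, [
        rec(f"{prefix}{i}", mutate_sequence(seed, identity, rng)) for i in range(n)
    ]


class TestSearchPairwise:
    def test_self_match_ranks_first(self, rng):
        _, db = family_db(rng, 150, 10, 0.8, "f")
        query = rec("q", db[3].sequence)
        hits = search_pairwise(query, db, evalue_cutoff=1e9)
        assert hits[0].subject_id == "f3"

    def test_unreachable_cutoff_gives_empty(self, rng):
        _, db = family_db(rng, 80, 5, 0.9, "f")
        assert search_pairwise(rec("q", db[0].sequence), db, 1e-300) == []

    def test_empty_db_rejected(self, rng):
        with pytest.raises(SearchError):
            search_pairwise(rec("q", "MKVLW"), [], 1.0)

    def test_planted_family_recovered_exactly(self, rng):
        """50 hub-family members plus 50 unrelated decoys: with the cutoff
        placed in the realised E-value gap, retrieval is exact."""
        seed, family = family_db(rng, 200, 50, 0.85, "fam")
        decoys = [rec(f"dec{i}", random_sequence(200, rng)) for i in range(50)]
        query = rec("q", seed)
        all_hits = search_pairwise(query, family + decoys, 1e9)
        log_e = {h.subject_id: h.evalue_log10 for h in all_hits}
        worst_in = max(log_e[r.protein_id] for r in family)
        best_out = min(log_e[r.protein_id] for r in decoys)
        assert worst_in < best_out, "no separation: generator regime violated"
        cutoff = 10 ** ((worst_in + best_out) / 2)
        got = {h.subject_id for h in search_pairwise(query, family + decoys, cutoff)}
        assert got == {r.protein_id for r in family}


class TestBuildProfile:
    def test_self_hit_profile_argmax_is_query(self, rng):
        query = rec("q", random_sequence(60, rng))
        hits = search_pairwise(query, [rec("s", query.sequence)], 1e9)
        profile = build_profile(query, hits)
        argmax = [AMINO_ACIDS[i] for i in profile.scores.argmax(axis=1)]
        assert "".join(argmax) == query.sequence

    def test_huge_pseudocount_flattens_to_background(self, rng):
        query = rec("q", random_sequence(40, rng))
        hits = search_pairwise(query, [rec("s", query.sequence)], 1e9)
        profile = build_profile(query, hits, pseudocount_weight=1e9)
        assert np.abs(profile.scores).max() < 1e-6

    def test_conserved_column_dominates(self, rng):
        """20 aligned members with an invariant column: that column's score
        for the conserved residue beats every alternative."""
        seed = random_sequence(100, rng)
        query = rec("q", seed)
        members = []
        for i in range(20):
            seq = mutate_sequence(seed, 0.7, rng)
            seq = seq[:50] + seed[50] + seq[51:]  # re-plant the invariant column
            members.append(rec(f"m{i}", seq))
        hits = search_pairwise(query, members, 1e9)
        profile = build_profile(query, hits)
        conserved = profile.scores[50]
        assert conserved.argmax() == AMINO_ACIDS.index(seed[50])

    def test_no_hits_instructs_fallback(self, rng):
        with pytest.raises(SearchError, match="pairwise-only"):
            build_profile(rec("q", "MKVLW"), [])


@pytest.fixture(scope="module")
def calibrated_profile():
    rng = np.random.default_rng(7)
    seed = random_sequence(120, rng)
    query = rec("q", seed)
    db = [rec(f"m{i}", mutate_sequence(seed, 0.85, rng)) for i in range(15)]
    hits = search_pairwise(query, db, 1e9)
    profile = build_profile(query, hits)
    return calibrate_profile(profile, db_length_model=150, n_shuffles=200, rng_seed=1)


class TestCalibrateProfile:
    def test_same_seed_same_fit(self, calibrated_profile):
        p2 = calibrate_profile(
            Profile_copy(calibrated_profile), 150, n_shuffles=200, rng_seed=1
        )
        assert p2.calibration == calibrated_profile.calibration

    def test_exceedance_at_mu_is_gumbel_like(self, calibrated_profile):
        """At the fitted location, P(score > mu) should be 1 - e^-1."""
        mu, beta = calibrated_profile.calibration
        rng = np.random.default_rng(2)
        cdf = np.cumsum(calibrated_profile.background)
        exceed = 0
        n = 200
        for i in range(n):
            u = rng.random(150)
            idx = np.clip(np.searchsorted(cdf, u), 0, 19)
            s = score_profile_idx(calibrated_profile, idx)
            exceed += s > mu
        assert exceed / n == pytest.approx(1 - math.exp(-1), abs=0.07)

    def test_too_few_shuffles_rejected(self, calibrated_profile):
        with pytest.raises(SearchError):
            calibrate_profile(calibrated_profile, 150, n_shuffles=10, rng_seed=0)


def Profile_copy(profile):
    from gnossn.search import Profile

    return Profile(
        query_id=profile.query_id,
        length=profile.length,
        scores=profile.scores.copy(),
        background=profile.background.copy(),
        pseudocount_weight=profile.pseudocount_weight,
    )


def score_profile_idx(profile, idx):
    from gnossn.search import _pssm_sw_score

    return _pssm_sw_score(profile.scores, idx.astype(np.int64), 12.0, 1.0)


class TestGumbelFit:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(0)
        draws = stats.gumbel_r.rvs(loc=10, scale=2, size=500, random_state=rng)
        mu, beta = fit_gumbel(draws)
        assert mu == pytest.approx(10, abs=0.5)
        assert beta == pytest.approx(2, abs=0.4)

    def test_log10_sf_deep_tail(self):
        # At z = 460 the survival function is ~1e-200: representable only in log.
        val = gumbel_log10_sf(10 + 2 * 460, mu=10, beta=2)
        assert val == pytest.approx(-460 / math.log(10), rel=1e-6)

    def test_log10_sf_matches_scipy_in_overlap(self):
        for x in [8, 10, 14, 20, 40]:
            assert gumbel_log10_sf(x, 10, 2) == pytest.approx(
                stats.gumbel_r.logsf(x, 10, 2) / math.log(10), rel=1e-9
            )


class TestSearchProfile:
    def test_uncalibrated_rejected(self, rng):
        query = rec("q", random_sequence(50, rng))
        hits = search_pairwise(query, [rec("s", query.sequence)], 1e9)
        profile = build_profile(query, hits)
        with pytest.raises(SearchError, match="calibrat"):
            search_profile(profile, [query], 1.0)

    def test_generous_cutoff_returns_everything(self, calibrated_profile, rng):
        db = [rec(f"x{i}", random_sequence(150, rng)) for i in range(8)]
        hits = search_profile(calibrated_profile, db, 1e9)
        assert {h.subject_id for h in hits} == {r.protein_id for r in db}

    def test_family_separation(self, rng):
        """Profile built from family A keeps A and rejects unrelated family B
        at a cutoff placed in the realised gap."""
        seed_a, fam_a = family_db(rng, 180, 20, 0.85, "A")
        _, fam_b = family_db(rng, 180, 20, 0.85, "B")
        query = rec("q", seed_a)
        db = fam_a + fam_b
        stage1 = search_pairwise(query, fam_a, 1e9)
        profile = build_profile(query, stage1)
        calibrate_profile(profile, 180, n_shuffles=200, rng_seed=3)
        all_hits = search_profile(profile, db, 1e9)
        log_e = {h.subject_id: h.evalue_log10 for h in all_hits}
        worst_a = max(log_e[r.protein_id] for r in fam_a)
        best_b = min(log_e[r.protein_id] for r in fam_b)
        assert worst_a < best_b
        cutoff = 10 ** max((worst_a + best_b) / 2, -300.0)
        got = {h.subject_id for h in search_profile(profile, db, cutoff)}
        assert got == {r.protein_id for r in fam_a}


class TestTwoStage:
    def test_family_only_db_returns_everything(self, rng):
        seed, fam = family_db(rng, 150, 12, 0.9, "f")
        config = PipelineConfig(evalue_stage1=1e-5, evalue_stage2=1e-6, rng_seed=1)
        homologs, report = two_stage_search(rec("q", seed), fam, config)
        assert {h.protein_id for h in homologs} == {r.protein_id for r in fam}
        assert report["stage2_final"] == report["stage2_retrieved"] == len(fam)

    def test_identity_tiers_split_by_cutoff(self, rng):
        """Three identity tiers; the stage-2 cutoff placed between tiers 2
        and 3 keeps exactly tiers 1 and 2."""
        seed = random_sequence(250, rng)
        tier1 = [rec(f"t1_{i}", mutate_sequence(seed, 0.95, rng)) for i in range(8)]
        tier2 = [rec(f"t2_{i}", mutate_sequence(seed, 0.70, rng)) for i in range(8)]
        tier3 = [rec(f"t3_{i}", random_sequence(250, rng)) for i in range(8)]
        db = tier1 + tier2 + tier3
        query = rec("q", seed)
        config = PipelineConfig(evalue_stage1=1e-3, evalue_stage2=1e-3, rng_seed=5)
        stage1 = search_pairwise(query, db, config.evalue_stage1, config)
        profile = build_profile(query, stage1)
        calibrate_profile(profile, 250, n_shuffles=200, rng_seed=5)
        probe = search_profile(profile, db, 1e9)
        log_e = {h.subject_id: h.evalue_log10 for h in probe}
        worst_in = max(v for k, v in log_e.items() if not k.startswith("t3"))
        best_out = min(v for k, v in log_e.items() if k.startswith("t3"))
        assert worst_in < best_out
        config = PipelineConfig(
            evalue_stage1=1e-3,
            evalue_stage2=10 ** max((worst_in + best_out) / 2, -300.0),
            rng_seed=5,
        )
        homologs, report = two_stage_search(query, db, config)
        assert {h.protein_id for h in homologs} == {
            r.protein_id for r in tier1 + tier2
        }
        assert report["stage2_final"] <= report["stage2_retrieved"]

    def test_report_counts_match_outputs(self, rng):
        seed, fam = family_db(rng, 120, 6, 0.9, "f")
        config = PipelineConfig(evalue_stage1=1e-4, evalue_stage2=1e-5, rng_seed=2)
        homologs, report = two_stage_search(rec("q", seed), fam, config)
        assert report["stage2_final"] == len(homologs)
        assert report["stage1_hits"] <= report["db_size"]
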