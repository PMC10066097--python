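"""Two-stage homolog retrieval.

Stage 1 scans the database with the query by pairwise Smith–Waterman and
keeps hits at the first E-value cutoff.  The hits are stacked into a
position-specific scoring matrix (PSSM) anchored on the query (a star
alignment: subject insertions relative to the query are discarded).  The
PSSM is calibrated empirically — its optimal local scores against shuffled
null sequences follow an extreme value (Gumbel) distribution, fitted by
maximum likelihood — and then re-searched against the database, keeping hits
at the second, stricter cutoff.

This PSSM-with-EVD-calibration is a deliberate simplification of a full
profile HMM: the procedure needs "a profile built from first-pass hits,
re-searched with an E-value threshold", and a calibrated PSSM has the same
selectivity behaviour at desk scale.

All E-value comparisons happen in log10 space: the stage-2 cutoff (1e-200 by
default) underflows double precision as a probability but not as a log.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from numba import njit
from scipy import stats

from .alignment import LN10, PairwiseHit, align_local
from .formats import AMINO_ACIDS, PipelineConfig, ProteinRecord


class SearchError(ValueError):
    pass


#: Robinson & Robinson amino-acid background frequencies (BLAST defaults),
#: in the order of :data:`~gnossn.formats.AMINO_ACIDS`.
_ROBINSON = {
    "A": 0.07805, "R": 0.05129, "N": 0.04487, "D": 0.05364, "C": 0.01925,
    "Q": 0.04264, "E": 0.06295, "G": 0.07377, "H": 0.02199, "I": 0.05142,
    "L": 0.09019, "K": 0.05744, "M": 0.02243, "F": 0.03856, "P": 0.05203,
    "S": 0.07120, "T": 0.05841, "W": 0.01330, "Y": 0.03216, "V": 0.06441,
}
BACKGROUND = np.array([_ROBINSON[a] for a in AMINO_ACIDS])
BACKGROUND = BACKGROUND / BACKGROUND.sum()

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


def encode_sequence(seq: str) -> np.ndarray:
    """Residues to 0..19 indices; unknown residues ('X') become −1."""
    return np.array([_AA_INDEX.get(c, -1) for c in seq], dtype=np.int64)


@dataclass
class Profile:
    """Position-specific scoring matrix with optional EVD calibration.

    ``scores`` is (query length × 20) in half-bit units (2·log2 odds);
    ``calibration`` is the fitted Gumbel (location mu, scale beta) of optimal
    local null scores, or None before :func:`calibrate_profile`.
    """

    query_id: str
    length: int
    scores: np.ndarray
    background: np.ndarray
    pseudocount_weight: float
    calibration: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.scores.shape != (self.length, 20):
            raise SearchError("profile scores must be (length, 20)")
        if abs(self.background.sum() - 1.0) > 1e-9:
            raise SearchError("background must sum to 1")
        if self.calibration is not None and self.calibration[1] <= 0:
            raise SearchError("calibration beta must be > 0")


# ---------------------------------------------------------------------------
# PSSM Smith–Waterman (numba kernel; no installed library scores a
# position-specific matrix with affine gaps)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _pssm_sw_score(scores, seq_idx, gap_first, gap_extend):  # pragma: no cover
    L = scores.shape[0]
    n = seq_idx.size
    NEG = -1.0e30
    h_prev = np.zeros(n + 1)
    f_prev = np.full(n + 1, NEG)
    best = 0.0
    for i in range(1, L + 1):
        h_cur = np.zeros(n + 1)
        f_cur = np.empty(n + 1)
        f_cur[0] = NEG
        e = NEG
        for j in range(1, n + 1):
            aa = seq_idx[j - 1]
            s = scores[i - 1, aa] if aa >= 0 else 0.0
            e = max(h_cur[j - 1] - gap_first, e - gap_extend)
            f_cur[j] = max(h_prev[j] - gap_first, f_prev[j] - gap_extend)
            h = h_prev[j - 1] + s
            if e > h:
                h = e
            if f_cur[j] > h:
                h = f_cur[j]
            if h < 0.0:
                h = 0.0
            h_cur[j] = h
            if h > best:
                best = h
        h_prev = h_cur
        f_prev = f_cur
    return best


def score_profile(
    profile: Profile, sequence: str, gap_open: int = 11, gap_extend: int = 1
) -> float:
    """Optimal local alignment score of a sequence against the PSSM."""
    idx = encode_sequence(sequence)
    return float(
        _pssm_sw_score(
            profile.scores, idx, float(gap_open + gap_extend), float(gap_extend)
        )
    )


# ---------------------------------------------------------------------------
# Gumbel tail, safe in log space
# ---------------------------------------------------------------------------

def gumbel_log10_sf(x: float, mu: float, beta: float) -> float:
    """log10 of the Gumbel survival function, accurate arbitrarily deep in
    the tail (where sf ≈ exp(−z) and the float sf would underflow)."""
    z = (x - mu) / beta
    if z > 35.0:
        return -z / LN10
    t = math.exp(-z)
    sf = -math.expm1(-t)
    if sf >= 1.0:
        return 0.0
    return math.log10(sf)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def search_pairwise(
    query: ProteinRecord,
    db: Sequence[ProteinRecord],
    evalue_cutoff: float,
    config: PipelineConfig | None = None,
) -> list[PairwiseHit]:
    """Stage 1: pairwise query scan, keeping hits with E ≤ cutoff.

    Hits are sorted by ascending E-value (compared as log10), ties by
    subject ID.  Identical database sequences are aligned once.
    """
    config = config or PipelineConfig()
    if not db:
        raise SearchError("empty database")
    if evalue_cutoff <= 0:
        raise SearchError("cutoff must be > 0")
    log_cut = math.log10(evalue_cutoff)
    cache: dict[str, PairwiseHit] = {}
    hits: list[PairwiseHit] = []
    for rec in db:
        template = cache.get(rec.sequence)
        if template is None:
            template = align_local(
                query, rec, config.gap_open, config.gap_extend,
                config.lambda_ka, config.k_ka,
            )
            cache[rec.sequence] = template
        if template.evalue_log10 <= log_cut:
            hits.append(replace(template, subject_id=rec.protein_id))
    hits.sort(key=lambda h: (h.evalue_log10, h.subject_id))
    return hits


def build_profile(
    query: ProteinRecord,
    hits: Sequence[PairwiseHit],
    pseudocount_weight: float = 1.0,
) -> Profile:
    """Stack stage-1 hit alignments into a query-anchored PSSM.

    Each hit's aligned subject residues are placed onto the query positions
    they align to (star alignment; subject insertions are discarded).
    Per-position residue counts are mixed with the background via the
    pseudocount weight; scores are half-bit log-odds.
    """
    if not hits:
        raise SearchError(
            "no hits to build a profile from; fall back to pairwise-only search"
        )
    L = len(query.sequence)
    counts = np.zeros((L, 20))
    for hit in hits:
        if hit.query_cols is None:
            raise SearchError(
                f"hit {hit.query_id}/{hit.subject_id} lacks alignment columns"
            )
        for pos, residue in enumerate(hit.query_cols):
            idx = _AA_INDEX.get(residue)
            if idx is not None:
                counts[pos, idx] += 1.0
    n_obs = counts.sum(axis=1, keepdims=True)
    w = float(pseudocount_weight)
    probs = (counts + w * BACKGROUND) / (n_obs + w)
    scores = 2.0 * np.log2(probs / BACKGROUND)
    return Profile(
        query_id=query.protein_id,
        length=L,
        scores=scores,
        background=BACKGROUND.copy(),
        pseudocount_weight=w,
    )


def calibrate_profile(
    profile: Profile,
    db_length_model: int,
    n_shuffles: int = 200,
    rng_seed: int = 0,
    gap_open: int = 11,
    gap_extend: int = 1,
) -> Profile:
    """Empirical EVD calibration of a profile.

    Scores the PSSM against ``n_shuffles`` null sequences of the modelled
    length (residues drawn i.i.d. from the background) and fits a Gumbel to
    the optimal local scores by maximum likelihood.  Deterministic for a
    given seed.
    """
    if n_shuffles < 50:
        raise SearchError("need at least 50 null sequences to calibrate")
    if db_length_model < 1:
        raise SearchError("length model must be >= 1")
    rng = np.random.default_rng(rng_seed)
    # Background-weighted draw: invert the CDF over the 20 residues.
    cdf = np.cumsum(profile.background)
    u = rng.random(size=(n_shuffles, db_length_model))
    null_idx = np.searchsorted(cdf, u).astype(np.int64)
    null_idx = np.clip(null_idx, 0, 19)
    scores = np.empty(n_shuffles)
    gap_first = float(gap_open + gap_extend)
    for i in range(n_shuffles):
        scores[i] = _pssm_sw_score(
            profile.scores, null_idx[i], gap_first, float(gap_extend)
        )
    if np.ptp(scores) == 0:
        raise SearchError("degenerate null score distribution (all equal)")
    mu, beta = fit_gumbel(scores)
    profile.calibration = (float(mu), float(beta))
    return profile


def fit_gumbel(samples: np.ndarray) -> tuple[float, float]:
    """Maximum-likelihood Gumbel (location, scale) fit."""
    loc, scale = stats.gumbel_r.fit(samples)
    return float(loc), float(scale)


def search_profile(
    profile: Profile,
    db: Sequence[ProteinRecord],
    evalue_cutoff: float,
    gap_open: int = 11,
    gap_extend: int = 1,
) -> list[PairwiseHit]:
    """Stage 2: PSSM search of the database with calibrated E-values.

    Per-sequence P-values come from the fitted Gumbel tail and are multiplied
    by the database size (Bonferroni-style correction, noted in the run
    report); hits with E ≤ cutoff are returned sorted by ascending E.
    """
    if profile.calibration is None:
        raise SearchError("profile is not calibrated; run calibrate_profile first")
    if not db:
        raise SearchError("empty database")
    mu, beta = profile.calibration
    log_cut = math.log10(evalue_cutoff)
    log_n = math.log10(len(db))
    cache: dict[str, float] = {}
    hits: list[PairwiseHit] = []
    for rec in db:
        s = cache.get(rec.sequence)
        if s is None:
            s = score_profile(profile, rec.sequence, gap_open, gap_extend)
            cache[rec.sequence] = s
        log10_e = log_n + gumbel_log10_sf(s, mu, beta)
        if log10_e <= log_cut:
            hits.append(
                PairwiseHit(
                    query_id=profile.query_id,
                    subject_id=rec.protein_id,
                    raw_score=s,
                    alignment_score=-log10_e,
                    pct_identity=0.0,
                    aln_length=0,
                    n_identities=0,
                )
            )
    hits.sort(key=lambda h: (h.evalue_log10, h.subject_id))
    return hits


def two_stage_search(
    query: ProteinRecord,
    db: Sequence[ProteinRecord],
    config: PipelineConfig | None = None,
    pseudocount_weight: float = 1.0,
) -> tuple[list[ProteinRecord], dict]:
    """The full retrieval chain: pairwise scan → profile → calibrate →
    profile re-search → final E-value filter.

    The profile re-search runs at the stage-1 cutoff and the retrieved set is
    then filtered to the stage-2 cutoff, mirroring the retrieve-then-filter
    structure of the original analysis (the profile pass may legitimately
    retrieve more sequences than the pairwise pass).  Returns the final
    homolog records plus a provenance report.
    """
    config = config or PipelineConfig()
    stage1 = search_pairwise(query, db, config.evalue_stage1, config)
    if not stage1:
        raise SearchError("stage 1 retrieved no hits at the configured cutoff")
    profile = build_profile(query, stage1, pseudocount_weight)
    lengths = sorted(len(r.sequence) for r in db)
    length_model = int(lengths[len(lengths) // 2])
    calibrate_profile(
        profile,
        length_model,
        n_shuffles=config.n_shuffles,
        rng_seed=config.rng_seed,
        gap_open=config.gap_open,
        gap_extend=config.gap_extend,
    )
    retrieved = search_profile(
        profile, db, config.evalue_stage1, config.gap_open, config.gap_extend
    )
    log_cut2 = math.log10(config.evalue_stage2)
    final = [h for h in retrieved if h.evalue_log10 <= log_cut2]
    by_id = {r.protein_id: r for r in db}
    homologs = [by_id[h.subject_id] for h in final]
    report = {
        "query_id": query.protein_id,
        "db_size": len(db),
        "stage1_hits": len(stage1),
        "stage2_retrieved": len(retrieved),
        "stage2_final": len(final),
        "evalue_stage1": config.evalue_stage1,
        "evalue_stage2": config.evalue_stage2,
        "evalue_correction": "per-sequence Gumbel P-value x database size",
        "calibration_mu": profile.calibration[0],
        "calibration_beta": profile.calibration[1],
        "length_model": length_model,
        "n_shuffles": config.n_shuffles,
        "rng_seed": config.rng_seed,
    }
    return homologs, report
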