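"""Pairwise local alignment and the EFI-style "alignment score" edge metric.

The edge metric used throughout is the alignment score −log10(E), with the
E-value from Karlin–Altschul statistics  E = K·m·n·exp(−λS)  evaluated in
log space so scores corresponding to E-values far below the double-precision
floor (e.g. 1e-200 and beyond) remain representable.

Smith–Waterman with affine gaps over BLOSUM62 is delegated to
``Bio.Align.PairwiseAligner``.  Gap convention: a gap of length k costs
``gap_open + k * gap_extend`` (BLAST-style 11/1 by default).

Percent identity uses the full alignment length, counting gap columns, in
the denominator — conventions differ between tools, so this is fixed here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .formats import PipelineConfig, ProteinRecord

LN10 = math.log(10.0)

#: Karlin–Altschul parameters for gapped BLOSUM62 (standard BLAST values).
DEFAULT_LAMBDA = 0.267
DEFAULT_K = 0.041


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class PairwiseHit:
    """One scored pairwise comparison.

    ``alignment_score`` is −log10 of the Karlin–Altschul E-value;
    ``raw_score`` is in substitution-matrix units (half-bits for BLOSUM62).
    ``query_cols`` (optional) maps each query position to the aligned subject
    residue, or '' where the query column is unaligned/gapped — used to stack
    hits into a profile.
    """

    query_id: str
    subject_id: str
    raw_score: float
    alignment_score: float
    pct_identity: float
    aln_length: int
    n_identities: int
    query_cols: tuple | None = field(default=None, compare=False, repr=False)

    @property
    def evalue_log10(self) -> float:
        return -self.alignment_score

    @property
    def evalue(self) -> float:
        """E-value as a float; underflows to 0.0 below ~1e-308."""
        try:
            return 10.0 ** (-self.alignment_score)
        except OverflowError:
            return math.inf


@lru_cache(maxsize=8)
def _make_aligner(gap_open: int, gap_extend: int) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    # Biopython charges open_gap_score for the first gap residue; shift so a
    # length-k gap costs gap_open + k*gap_extend.
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def karlin_altschul_evalue(
    raw_score: float,
    m: int,
    n: int,
    lambda_ka: float = DEFAULT_LAMBDA,
    k_ka: float = DEFAULT_K,
) -> tuple[float, float]:
    """Karlin–Altschul E-value for a local score S in an m × n search space.

    Returns ``(evalue, alignment_score)`` where ``alignment_score`` is
    −log10(E) = (λS − ln(K·m·n)) / ln 10, computed in log space.  The float
    ``evalue`` underflows to 0.0 for very large scores; use the alignment
    score for comparisons.
    """
    if m < 1 or n < 1:
        raise AlignmentError(f"sequence lengths must be >= 1, got m={m}, n={n}")
    alignment_score = (lambda_ka * raw_score - math.log(k_ka * m * n)) / LN10
    try:
        evalue = 10.0 ** (-alignment_score)
    except OverflowError:
        evalue = math.inf
    return evalue, alignment_score


def _alignment_stats(alignment) -> tuple[int, int, list[tuple[int, int, int]]]:
    """(n_identities, aln_length, aligned blocks) for a biopython alignment."""
    counts = alignment.counts()
    n_ident = counts.identities
    aln_length = alignment.length  # columns, including gap columns
    blocks = []
    tgt, qry = alignment.aligned
    for (ts, te), (qs, qe) in zip(tgt, qry):
        blocks.append((ts, te, qs))
    return n_ident, aln_length, blocks


def align_local(
    a: ProteinRecord,
    b: ProteinRecord,
    gap_open: int = 11,
    gap_extend: int = 1,
    lambda_ka: float = DEFAULT_LAMBDA,
    k_ka: float = DEFAULT_K,
    with_alignment: bool = True,
) -> PairwiseHit:
    """Smith–Waterman local alignment of two protein records.

    Symmetric by construction: the pair is aligned in a canonical order, so
    raw score, alignment length and percent identity are identical for
    (a, b) and (b, a).  If the optimal local score is 0 (no positive-scoring
    pair of residues) the hit has an empty alignment.
    """
    if not a.sequence or not b.sequence:
        raise AlignmentError("empty sequence")
    aligner = _make_aligner(gap_open, gap_extend)

    # Canonical orientation keeps traceback tie-breaking symmetric.
    swapped = (a.protein_id, a.sequence) > (b.protein_id, b.sequence)
    first, second = (b, a) if swapped else (a, b)

    raw = float(aligner.score(first.sequence, second.sequence))
    m, n = len(a.sequence), len(b.sequence)
    _, aln_score = karlin_altschul_evalue(raw, m, n, lambda_ka, k_ka)

    n_ident, aln_len, query_cols = 0, 0, None
    if with_alignment and raw > 0:
        alignment = aligner.align(first.sequence, second.sequence)[0]
        n_ident, aln_len, blocks = _alignment_stats(alignment)
        # Map subject residues onto the positions of `a` (the caller's query).
        cols = [""] * len(a.sequence)
        for ts, te, qs in blocks:
            if swapped:
                # `a` was the biopython query: invert block orientation.
                for k in range(te - ts):
                    cols[qs + k] = first.sequence[ts + k]
            else:
                for k in range(te - ts):
                    cols[ts + k] = second.sequence[qs + k]
        query_cols = tuple(cols)

    pct = 100.0 * n_ident / aln_len if aln_len else 0.0
    return PairwiseHit(
        query_id=a.protein_id,
        subject_id=b.protein_id,
        raw_score=raw,
        alignment_score=aln_score,
        pct_identity=pct,
        aln_length=aln_len,
        n_identities=n_ident,
        query_cols=query_cols,
    )


def all_vs_all(
    records: Sequence[ProteinRecord],
    config: PipelineConfig | None = None,
    score_floor: float | None = None,
) -> list[PairwiseHit]:
    """All-vs-all pairwise hits: exactly one per unordered pair (i < j by ID).

    Identical sequences are deduplicated internally, so datasets with many
    repeated proteins (conserved genes across genomes) are aligned once per
    distinct sequence pair.  With ``score_floor`` set, pairs whose alignment
    score falls below the floor are omitted (downstream graph construction
    treats missing pairs as below threshold); tracebacks (identity counts)
    are then only computed for retained pairs.
    """
    config = config or PipelineConfig()
    if len(records) < 2:
        raise AlignmentError("all_vs_all needs at least 2 records")
    ids = [r.protein_id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise AlignmentError(f"duplicate protein IDs: {dupes}")

    ordered = sorted(records, key=lambda r: r.protein_id)
    aligner = _make_aligner(config.gap_open, config.gap_extend)
    ratio_min = config.length_ratio_min

    # Group identical sequences; align one representative pair per sequence
    # pair and share the result.
    seq_groups: dict[str, list[ProteinRecord]] = {}
    for rec in ordered:
        seq_groups.setdefault(rec.sequence, []).append(rec)
    uniq_seqs = sorted(seq_groups)

    hits: list[PairwiseHit] = []

    def emit(rec_a: ProteinRecord, rec_b: ProteinRecord, template: PairwiseHit):
        qa, qb = sorted((rec_a, rec_b), key=lambda r: r.protein_id)
        hits.append(
            PairwiseHit(
                query_id=qa.protein_id,
                subject_id=qb.protein_id,
                raw_score=template.raw_score,
                alignment_score=template.alignment_score,
                pct_identity=template.pct_identity,
                aln_length=template.aln_length,
                n_identities=template.n_identities,
            )
        )

    def pair_hit(seq_a: str, seq_b: str) -> PairwiseHit | None:
        if ratio_min is not None:
            la, lb = len(seq_a), len(seq_b)
            if min(la, lb) / max(la, lb) < ratio_min:
                return None
        ra = seq_groups[seq_a][0]
        rb = seq_groups[seq_b][0]
        if score_floor is not None:
            # Cheap score-only pass first; traceback only if above the floor.
            raw = float(aligner.score(seq_a, seq_b))
            _, aln_score = karlin_altschul_evalue(
                raw, len(seq_a), len(seq_b), config.lambda_ka, config.k_ka
            )
            if aln_score < score_floor:
                return None
        return align_local(
            ra, rb, config.gap_open, config.gap_extend,
            config.lambda_ka, config.k_ka,
        )

    # Within-group (identical-sequence) pairs: one self-alignment each.
    for seq in uniq_seqs:
        group = seq_groups[seq]
        if len(group) < 2:
            continue
        template = align_local(
            group[0], group[0], config.gap_open, config.gap_extend,
            config.lambda_ka, config.k_ka,
        )
        if score_floor is not None and template.alignment_score < score_floor:
            continue
        for i in range(len(group)):
            for j in range(i + 1, len(group)):
                emit(group[i], group[j], template)

    for i in range(len(uniq_seqs)):
        for j in range(i + 1, len(uniq_seqs)):
            template = pair_hit(uniq_seqs[i], uniq_seqs[j])
            if template is None:
                continue
            for ra in seq_groups[uniq_seqs[i]]:
                for rb in seq_groups[uniq_seqs[j]]:
                    emit(ra, rb, template)

    hits.sort(key=lambda h: (h.query_id, h.subject_id))
    return hits
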