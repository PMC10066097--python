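"""Independent reference implementations used as test oracles.

Deliberately naive and separate from the package's code paths: a pure-Python
Gotoh dynamic program for local alignment scores, a transitive-closure
component finder, and a brute-force window scan.
"""

from __future__ import annotations

import math

from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def sw_score_reference(a: str, b: str, gap_open: int = 11, gap_extend: int = 1) -> float:
    """Smith–Waterman optimal local score, affine gaps, BLOSUM62.

    Gap of length k costs gap_open + k*gap_extend.  O(mn) with explicit
    H/E/F matrices; no traceback.
    """
    m, n = len(a), len(b)
    neg = -math.inf
    first = gap_open + gap_extend
    h_prev = [0.0] * (n + 1)
    f_prev = [neg] * (n + 1)
    best = 0.0
    for i in range(1, m + 1):
        h_cur = [0.0] * (n + 1)
        f_cur = [neg] * (n + 1)
        e = neg
        for j in range(1, n + 1):
            e = max(h_cur[j - 1] - first, e - gap_extend)
            f_cur[j] = max(h_prev[j] - first, f_prev[j] - gap_extend)
            h = max(
                0.0,
                h_prev[j - 1] + _BLOSUM62[a[i - 1], b[j - 1]],
                e,
                f_cur[j],
            )
            h_cur[j] = h
            if h > best:
                best = h
        h_prev, f_prev = h_cur, f_cur
    return best


def components_reference(nodes, edges) -> frozenset[frozenset]:
    """Connected components via boolean transitive closure (Floyd–Warshall)."""
    nodes = sorted(nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    k = len(nodes)
    reach = [[i == j for j in range(k)] for i in range(k)]
    for u, v in edges:
        reach[idx[u]][idx[v]] = True
        reach[idx[v]][idx[u]] = True
    for mid in range(k):
        for i in range(k):
            if reach[i][mid]:
                row_mid = reach[mid]
                row_i = reach[i]
                for j in range(k):
                    if row_mid[j]:
                        row_i[j] = True
    comps = []
    seen = set()
    for i, n in enumerate(nodes):
        if n in seen:
            continue
        comp = {nodes[j] for j in range(k) if reach[i][j]}
        seen |= comp
        comps.append(frozenset(comp))
    return frozenset(comps)


def window_reference(genome, hub_id: str, n_orfs: int):
    """Brute-force scan: every gene on the hub's contig within rank distance
    N, plus the truncation flags."""
    hub = next(r for r in genome if r.protein_id == hub_id)
    members = sorted(
        (
            (r.order_index - hub.order_index, r.protein_id)
            for r in genome
            if r.contig_id == hub.contig_id
            and r.protein_id != hub_id
            and abs(r.order_index - hub.order_index) <= n_orfs
        )
    )
    last = max(r.order_index for r in genome if r.contig_id == hub.contig_id)
    return (
        [pid for _, pid in members],
        hub.order_index - n_orfs < 0,
        hub.order_index + n_orfs > last,
    )
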