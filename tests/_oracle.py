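"""Independent oracles used by the test suite.

The alignment oracle enumerates *all* local alignments of a barcode in a
read window by exhaustive depth-first search over alignment paths (start
anywhere, first and last column must be aligned pairs, interior gaps
allowed), with branch-and-bound pruning that never discards a co-optimal
path.  It shares no code with the package's DP/backtrack implementation.
"""

from __future__ import annotations

from dataclasses import dataclass


def _is_match(a: str, b: str) -> bool:
    return a == b and a in "ACGT"


def brute_force_optimal(w: str, b: str, match=1, mismatch=-1, gap=-2):
    """All optimal local alignments of b in w by exhaustive path search.

    Returns (best_score, set of (read_start, read_end, bc_start, bc_end,
    matches, cols)).  best_score <= 0 means no positive-scoring alignment.
    """
    W, L = len(w), len(b)
    best = [0]
    results: set[tuple] = set()

    def dfs(i, j, i0, j0, score, matches, cols, ended_on_diag):
        # candidate end (local alignments end on an aligned pair)
        if ended_on_diag:
            if score > best[0]:
                best[0] = score
                results.clear()
            if score == best[0] and score > 0:
                results.add((i0, i, j0, j, matches, cols))
        # bound: even matching everything remaining cannot reach best
        if score + match * min(W - i, L - j) < best[0]:
            return
        if i < W and j < L:
            m = _is_match(w[i], b[j])
            dfs(i + 1, j + 1, i0, j0, score + (match if m else mismatch),
                matches + (1 if m else 0), cols + 1, True)
        if i < W and j < L:  # gaps only interior: must be able to end on diag later
            dfs(i + 1, j, i0, j0, score + gap, matches, cols + 1, False)
            dfs(i, j + 1, i0, j0, score + gap, matches, cols + 1, False)

    for i0 in range(W):
        for j0 in range(L):
            dfs(i0, j0, i0, j0, 0, 0, 0, False)
    return best[0], results


def oracle_match_aligned(
    seq: str,
    pool: list[tuple[str, str]],
    anchor: int,
    min_align_len: int = 10,
    min_identity: float = 0.90,
    max_start_offset: int = 2,
    max_end_gap: int = 5,
):
    """Reference implementation of the constrained fallback matcher.

    pool is a list of (strain_id, barcode).  Returns one of
    ("none", None, None), ("ambiguous", None, None) or
    ("assigned", strain_id, identity_fraction).
    """
    w0 = max(0, anchor - max_start_offset)
    window = seq[w0:]
    best_key = None  # (matches, cols)
    best_strain = None
    tie = False
    for strain_id, bc in pool:
        score, alns = brute_force_optimal(window, bc)
        if score <= 0:
            continue
        cand = None
        for (ri, re, bi, be, m, cols) in sorted(alns):
            if cols < min_align_len:
                continue
            if m + 1e-9 < min_identity * cols:
                continue
            if abs((w0 + ri) - anchor) > max_start_offset:
                continue
            if len(bc) - be > max_end_gap:
                continue
            # compare identity by cross-multiplication, then length
            if cand is None:
                cand = (m, cols)
            else:
                lhs, rhs = m * cand[1], cand[0] * cols
                if lhs > rhs or (lhs == rhs and cols > cand[1]):
                    cand = (m, cols)
        if cand is None:
            continue
        if best_key is None:
            best_key, best_strain, tie = cand, strain_id, False
        else:
            lhs, rhs = cand[0] * best_key[1], best_key[0] * cand[1]
            if lhs > rhs or (lhs == rhs and cand[1] > best_key[1]):
                best_key, best_strain, tie = cand, strain_id, False
            elif lhs == rhs and cand[1] == best_key[1] and strain_id != best_strain:
                tie = True
    if best_key is None:
        return ("none", None, None)
    if tie:
        return ("ambiguous", None, None)
    return ("assigned", best_strain, best_key[0] / best_key[1])
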