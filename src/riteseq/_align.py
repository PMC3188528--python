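"""Local-alignment engine for the barcode fallback matcher.

Scoring is +1 match, -1 mismatch, -2 per gap column (linear); N never
matches anything, including another N.  Two layers:

* a numba-compiled kernel that scores one read window against every
  catalog barcode at once (used to shortlist candidates cheaply), and
* an exact enumerator of *all* co-optimal local alignments for a single
  (window, barcode) pair, needed because co-optimal alignments can differ
  in identity and end position right at the admissibility boundaries.

Alignment summaries are (read_start, read_end, bc_start, bc_end, matches,
columns) with 0-based half-open coordinates; ``columns`` counts aligned
pairs plus gap columns.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def wrap(fn):
            return fn

        return wrap if not (args and callable(args[0])) else args[0]


#: base -> code; anything outside ACGT (incl. N) maps to 4 and never matches
BASE_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    BASE_CODE[_b] = _i
for _i, _b in enumerate(b"acgt"):
    BASE_CODE[_b] = _i

_LETTERS = np.frombuffer(b"ACGT", dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string to uint8 codes (A=0..T=3, other=4)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return BASE_CODE[raw]


def pack_barcodes(seqs: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Pack barcode strings into a (n, max_len) code matrix + length vector."""
    n = len(seqs)
    lens = np.array([len(s) for s in seqs], dtype=np.int64)
    mat = np.full((n, int(lens.max(initial=1))), 4, dtype=np.uint8)
    for i, s in enumerate(seqs):
        mat[i, : len(s)] = encode(s)
    return mat, lens


@njit(cache=True)
def _score_all(window, bc_mat, bc_lens, match, mismatch, gap):  # pragma: no cover
    n = bc_mat.shape[0]
    w = window.shape[0]
    out = np.zeros(n, dtype=np.int32)
    for k in range(n):
        L = bc_lens[k]
        best = 0
        row = np.zeros(L + 1, dtype=np.int32)
        for i in range(1, w + 1):
            a = window[i - 1]
            diag = 0
            left = 0
            for j in range(1, L + 1):
                b = bc_mat[k, j - 1]
                s = match if (a == b and a < 4) else mismatch
                v = diag + s
                t = row[j] + gap
                if t > v:
                    v = t
                t = left + gap
                if t > v:
                    v = t
                if v < 0:
                    v = 0
                diag = row[j]
                row[j] = v
                left = v
                if v > best:
                    best = v
        out[k] = best
    return out


def _score_all_py(window, bc_mat, bc_lens, match, mismatch, gap):
    """Pure-python twin of :func:`_score_all` (fallback / testing)."""
    n = bc_mat.shape[0]
    w = window.shape[0]
    out = np.zeros(n, dtype=np.int32)
    for k in range(n):
        L = int(bc_lens[k])
        best = 0
        row = [0] * (L + 1)
        for i in range(1, w + 1):
            a = window[i - 1]
            diag = 0
            left = 0
            for j in range(1, L + 1):
                b = bc_mat[k, j - 1]
                s = match if (a == b and a < 4) else mismatch
                v = max(diag + s, row[j] + gap, left + gap, 0)
                diag = row[j]
                row[j] = v
                left = v
                if v > best:
                    best = v
        out[k] = best
    return out


def score_candidates(
    window: np.ndarray,
    bc_mat: np.ndarray,
    bc_lens: np.ndarray,
    match: int = 1,
    mismatch: int = -1,
    gap: int = -2,
) -> np.ndarray:
    """Optimal local-alignment score of ``window`` against every barcode."""
    fn = _score_all if _HAVE_NUMBA else _score_all_py
    return fn(
        window,
        bc_mat,
        bc_lens,
        np.int32(match),
        np.int32(mismatch),
        np.int32(gap),
    )


@njit(cache=True)
def _fill_H(window, bc, match, mismatch, gap):  # pragma: no cover
    W = window.shape[0]
    L = bc.shape[0]
    H = np.zeros((W + 1, L + 1), dtype=np.int32)
    for i in range(1, W + 1):
        a = window[i - 1]
        for j in range(1, L + 1):
            b = bc[j - 1]
            s = match if (a == b and a < 4) else mismatch
            v = H[i - 1, j - 1] + s
            t = H[i - 1, j] + gap
            if t > v:
                v = t
            t = H[i, j - 1] + gap
            if t > v:
                v = t
            H[i, j] = v if v > 0 else 0
    return H


def _fill_H_py(window, bc, match, mismatch, gap):
    W, L = len(window), len(bc)
    H = np.zeros((W + 1, L + 1), dtype=np.int32)
    for i in range(1, W + 1):
        a = window[i - 1]
        for j in range(1, L + 1):
            b = bc[j - 1]
            s = match if (a == b and a < 4) else mismatch
            v = max(H[i - 1, j - 1] + s, H[i - 1, j] + gap, H[i, j - 1] + gap, 0)
            H[i, j] = v
    return H


def fill_H(window: np.ndarray, bc: np.ndarray, match: int, mismatch: int, gap: int):
    """Local-alignment score matrix (Smith-Waterman, linear gaps)."""
    fn = _fill_H if _HAVE_NUMBA else _fill_H_py
    return fn(window, bc, np.int32(match), np.int32(mismatch), np.int32(gap))


class Alignment(NamedTuple):
    read_start: int
    read_end: int
    bc_start: int
    bc_end: int
    matches: int
    columns: int

    @property
    def identity(self) -> float:
        return self.matches / self.columns


def optimal_alignments(
    window: str,
    barcode: str,
    match: int = 1,
    mismatch: int = -1,
    gap: int = -2,
    cap: int = 4096,
) -> tuple[int, list[Alignment]]:
    """Enumerate all optimal-score local alignments of barcode in window.

    Returns ``(best_score, alignments)``; ``best_score <= 0`` means no
    non-empty alignment scores positively and the list is empty.  The
    enumeration is exhaustive up to ``cap`` distinct alignment summaries
    (duplicates from alternative traceback paths with identical summaries
    are merged).
    """
    w = encode(window)
    b = encode(barcode)
    if len(w) == 0 or len(b) == 0:
        return 0, []
    H = fill_H(w, b, match, mismatch, gap)
    best = int(H.max())
    if best <= 0:
        return best, []
    return best, enumerate_optimal(H, w, b, match, mismatch, gap, cap)


def enumerate_optimal(
    H: np.ndarray,
    w: np.ndarray,
    b: np.ndarray,
    match: int = 1,
    mismatch: int = -1,
    gap: int = -2,
    cap: int = 4096,
) -> list[Alignment]:
    """All optimal-score local alignments from a filled score matrix."""
    best = int(H.max())
    if best <= 0:
        return []
    Hl = H.tolist()
    w = w.tolist() if hasattr(w, "tolist") else list(w)
    b = b.tolist() if hasattr(b, "tolist") else list(b)
    results: set[Alignment] = set()

    def backtrack(i: int, j: int, end_i: int, end_j: int, matches: int, cols: int):
        if len(results) >= cap:
            return
        h = Hl[i][j]
        if h == 0:
            results.add(Alignment(i, end_i, j, end_j, matches, cols))
            return
        if i > 0 and j > 0:
            is_match = w[i - 1] == b[j - 1] and w[i - 1] < 4
            s = match if is_match else mismatch
            if h == Hl[i - 1][j - 1] + s:
                backtrack(i - 1, j - 1, end_i, end_j, matches + (1 if is_match else 0), cols + 1)
        if i > 0 and h == Hl[i - 1][j] + gap:
            backtrack(i - 1, j, end_i, end_j, matches, cols + 1)
        if j > 0 and h == Hl[i][j - 1] + gap:
            backtrack(i, j - 1, end_i, end_j, matches, cols + 1)

    for i, j in zip(*np.nonzero(H == best)):
        backtrack(int(i), int(j), int(i), int(j), 0, 0)
    return sorted(results)


def min_admissible_score(min_align_len: int, min_identity: float) -> int:
    """Lower bound on the local score of any admissible alignment.

    With score = cols - 2x - 3g and x + g <= (1 - min_identity) * cols, an
    admissible alignment satisfies score >= cols * (3 * min_identity - 2),
    so for min_identity >= 2/3 the bound is min_align_len*(3*min_id - 2).
    Used only to shortlist candidates; never rejects a valid one.
    """
    bound = min_align_len * (3.0 * min_identity - 2.0)
    return max(1, int(np.floor(bound + 1e-9)))
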