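"""Per-read assignment: index demultiplexing, tag classification, anchored
exact barcode matching and the constrained alignment fallback.

A read is assigned in four stages:

1. ``demultiplex`` — the first 4 bases must match a sample index exactly
   (optionally also the next two bases must match the start of U1 or D1).
2. ``classify_tag`` — the read is an UpTag or DownTag amplicon depending on
   which common primer (U1/D1) it carries, by Hamming distance.
3. ``match_exact`` — the barcode is looked up by its seed prefix (11 nt,
   zero mismatches) at the expected anchor, trying start offsets 0, +1, -1.
4. ``match_aligned`` — reads the exact path misses are re-examined by
   optimal local alignment against every same-tag barcode, admitting only
   alignments of length >= 10, identity >= 90%, starting within 2 bases of
   the anchor and ending no more than 5 bases before the barcode's 3' end.

Ties at any stage become explicit AMBIGUOUS outcomes, never an arbitrary
pick: a falsely assigned read is exactly the failure mode the decoy
barcodes are there to measure.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import numpy as np

from . import _align
from .catalog import (
    BarcodeEntry,
    Catalog,
    PrimerSet,
    ReadLayout,
    SampleSheet,
    TagKind,
)

__all__ = [
    "Outcome",
    "Method",
    "MatchParams",
    "Assignment",
    "Read",
    "CatalogIndex",
    "demultiplex",
    "classify_tag",
    "match_exact",
    "match_aligned",
    "assign_read",
]


class Outcome(str, enum.Enum):
    ASSIGNED = "ASSIGNED"
    NO_INDEX = "NO_INDEX"
    TAG_AMBIGUOUS = "TAG_AMBIGUOUS"
    TOO_SHORT = "TOO_SHORT"
    NO_BARCODE = "NO_BARCODE"
    BARCODE_AMBIGUOUS = "BARCODE_AMBIGUOUS"

    def __str__(self) -> str:  # pragma: no cover
        return self.value


class Method(str, enum.Enum):
    EXACT = "EXACT"
    ALIGNED = "ALIGNED"

    def __str__(self) -> str:  # pragma: no cover
        return self.value


class Read(NamedTuple):
    """A sequencing read; quality is carried but never consulted."""

    read_id: str
    sequence: str
    quality: Optional[str] = None


@dataclass(frozen=True)
class MatchParams:
    """Tunable thresholds of the assignment algorithm.

    The seed length (11), alignment length (10), identity (0.90), start
    offset (2) and end gap (5) are the published constraints; the primer
    mismatch budget and the local-alignment scoring are pinned choices.
    """

    seed_len: int = 11
    anchor_jitter: tuple[int, ...] = (0, 1, -1)
    min_align_len: int = 10
    min_identity: float = 0.90
    max_start_offset: int = 2
    max_end_gap: int = 5
    primer_max_mismatch: int = 2
    match_score: int = 1
    mismatch_score: int = -1
    gap_score: int = -2
    strict_index: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.min_identity <= 1:
            raise ValueError("min_identity must be in (0, 1]")
        if self.min_align_len < 1 or self.min_align_len > 20:
            raise ValueError("min_align_len must be in 1..20")
        if self.seed_len < 1:
            raise ValueError("seed_len must be >= 1")
        if self.max_start_offset < 0 or self.max_end_gap < 0:
            raise ValueError("offsets must be >= 0")
        if 0 not in self.anchor_jitter:
            raise ValueError("anchor_jitter must contain 0")


@dataclass(frozen=True)
class Assignment:
    read_id: str
    outcome: Outcome
    sample_id: Optional[str] = None
    tag_kind: Optional[TagKind] = None
    strain_id: Optional[str] = None
    method: Optional[Method] = None
    identity: Optional[float] = None
    start_offset: Optional[int] = None

    def __post_init__(self) -> None:
        if self.outcome is Outcome.ASSIGNED:
            # sample_id may be absent for stage-level (pre-demultiplex) calls;
            # the full pipeline always sets it
            if None in (self.tag_kind, self.strain_id, self.method):
                raise ValueError("ASSIGNED requires tag, strain and method")
            if self.method is Method.EXACT and self.identity != 1.0:
                raise ValueError("EXACT assignments have identity 1.0")


class CatalogIndex:
    """Pre-computed lookup structures for one (catalog, primers, params).

    Holds, per tag kind: the entry list, seed-prefix hash maps grouped by
    prefix length (barcodes shorter than the seed use their full length),
    and the packed barcode matrix for the alignment kernel.
    """

    def __init__(
        self,
        catalog: Catalog,
        primers: PrimerSet,
        params: MatchParams | None = None,
    ):
        self.catalog = catalog
        self.primers = primers
        self.params = params or MatchParams()
        self.layout: ReadLayout = primers.layout(self.params.anchor_jitter)
        self.entries: dict[TagKind, list[BarcodeEntry]] = {}
        self.prefix_maps: dict[TagKind, list[tuple[int, dict[str, list[int]]]]] = {}
        self.bc_mat: dict[TagKind, np.ndarray] = {}
        self.bc_lens: dict[TagKind, np.ndarray] = {}
        for tag in TagKind:
            pool = catalog.by_tag(tag)
            self.entries[tag] = pool
            by_len: dict[int, dict[str, list[int]]] = {}
            for i, e in enumerate(pool):
                plen = min(self.params.seed_len, len(e.sequence))
                by_len.setdefault(plen, {}).setdefault(e.sequence[:plen], []).append(i)
            self.prefix_maps[tag] = sorted(by_len.items(), reverse=True)
            seqs = [e.sequence for e in pool] or ["A"]
            mat, lens = _align.pack_barcodes(seqs)
            if not pool:
                lens = np.zeros(0, dtype=np.int64)
                mat = mat[:0]
            self.bc_mat[tag] = mat
            self.bc_lens[tag] = lens
        self.min_score = _align.min_admissible_score(
            self.params.min_align_len, self.params.min_identity
        )


def demultiplex(
    read: Read | str,
    sheet: SampleSheet,
    primers: PrimerSet | None = None,
    strict: bool = False,
) -> Optional[str]:
    """Exact-match the read's leading index against the sample sheet.

    Returns the sample_id, or None for NO_INDEX.  In strict mode the two
    bases following the index must additionally equal the first two bases
    of U1 or D1 (the published index window spans positions 1-6).
    """
    seq = read.sequence if isinstance(read, Read) else read
    n = sheet.index_len
    sample_id = sheet.index_map.get(seq[:n]) if len(seq) >= n else None
    if sample_id is None:
        return None
    if strict:
        if primers is None:
            raise ValueError("strict demultiplexing requires primers")
        nxt = seq[n : n + 2]
        if len(nxt) < 2 or (nxt != primers.u1[:2] and nxt != primers.d1[:2]):
            return None
    return sample_id


def _hamming(a: str, b: str) -> int:
    """Mismatch count of a against b over len(b); missing bases and N count
    as mismatches."""
    d = 0
    for i, c in enumerate(b):
        if i >= len(a) or a[i] != c or a[i] == "N":
            d += 1
    return d


def classify_tag(
    read: Read | str, primers: PrimerSet, params: MatchParams | None = None
) -> Optional[TagKind]:
    """Decide UpTag vs DownTag from the common primer region.

    Returns the tag kind with the strictly smaller Hamming distance if it is
    within the mismatch budget; None (ambiguous) on ties or when both
    distances exceed the budget.
    """
    params = params or MatchParams()
    seq = read.sequence if isinstance(read, Read) else read
    n = primers.index_len
    du = _hamming(seq[n : n + len(primers.u1)], primers.u1)
    dd = _hamming(seq[n : n + len(primers.d1)], primers.d1)
    if du < dd and du <= params.primer_max_mismatch:
        return TagKind.UP
    if dd < du and dd <= params.primer_max_mismatch:
        return TagKind.DOWN
    return None


def _exact_hits(seq, index: CatalogIndex, tag: TagKind, start: int) -> list[int]:
    hits: list[int] = []
    for plen, pmap in index.prefix_maps[tag]:
        seg = seq[start : start + plen]
        if len(seg) == plen:
            found = pmap.get(seg)
            if found:
                hits.extend(found)
    return hits


def match_exact(
    read: Read | str,
    index: CatalogIndex,
    tag_kind: TagKind,
    sample_id: Optional[str] = None,
) -> Optional[Assignment]:
    """Zero-mismatch seed lookup at the anchor, trying jitter offsets in
    order (first offset with any hit wins; >1 hit there is ambiguous).

    Returns None when no offset yields a hit (caller falls back to
    alignment)."""
    seq = read.sequence if isinstance(read, Read) else read
    rid = read.read_id if isinstance(read, Read) else ""
    anchor = index.layout.anchor(tag_kind)
    for j in index.params.anchor_jitter:
        if anchor + j < 0:
            continue
        hits = _exact_hits(seq, index, tag_kind, anchor + j)
        if hits:
            if len(hits) > 1:
                return Assignment(
                    rid, Outcome.BARCODE_AMBIGUOUS, sample_id=sample_id, tag_kind=tag_kind
                )
            e = index.entries[tag_kind][hits[0]]
            return Assignment(
                rid,
                Outcome.ASSIGNED,
                sample_id=sample_id,
                tag_kind=tag_kind,
                strain_id=e.strain_id,
                method=Method.EXACT,
                identity=1.0,
                start_offset=j,
            )
    return None


def _identity_ok(matches: int, cols: int, min_identity: float) -> bool:
    return matches + 1e-9 >= min_identity * cols


def _better(m1: int, c1: int, m2: int, c2: int) -> int:
    """Compare (identity, length) keys by cross-multiplication.

    Returns +1 if (m1/c1, c1) beats (m2/c2, c2), -1 if worse, 0 if equal.
    """
    lhs = m1 * c2
    rhs = m2 * c1
    if lhs != rhs:
        return 1 if lhs > rhs else -1
    if c1 != c2:
        return 1 if c1 > c2 else -1
    return 0


def match_aligned(
    read: Read | str,
    index: CatalogIndex,
    tag_kind: TagKind,
    sample_id: Optional[str] = None,
) -> Optional[Assignment]:
    """Constrained local-alignment fallback over all same-tag barcodes.

    A candidate barcode is admissible iff one of its optimal-score local
    alignments (within the window starting max_start_offset bases before
    the anchor) has length >= min_align_len, identity >= min_identity,
    read start within max_start_offset of the anchor, and ends no more than
    max_end_gap bases before the barcode's 3' end.  The admissible
    candidate with the highest identity wins; ties go to the longer
    alignment; remaining ties between different strains are ambiguous.
    Returns None when no candidate is admissible (NO_BARCODE upstream).
    """
    p = index.params
    seq = read.sequence if isinstance(read, Read) else read
    rid = read.read_id if isinstance(read, Read) else ""
    anchor = index.layout.anchor(tag_kind)
    w0 = max(0, anchor - p.max_start_offset)
    window = seq[w0:]
    pool = index.entries[tag_kind]
    if len(window) < p.min_align_len or not pool:
        return None
    wcodes = _align.encode(window)
    scores = _align.score_candidates(
        wcodes,
        index.bc_mat[tag_kind],
        index.bc_lens[tag_kind],
        p.match_score,
        p.mismatch_score,
        p.gap_score,
    )
    best_entry: Optional[BarcodeEntry] = None
    best_m = best_c = 0
    best_start = 0
    tie = False
    shortlist = [int(k) for k in np.flatnonzero(scores >= index.min_score)]
    shortlist.sort(key=lambda k: -int(scores[k]))
    for k in shortlist:
        s = int(scores[k])
        if best_c:
            # an alignment tying or beating (best_m/best_c, best_c) needs a
            # local score of at least min_align_len*(3*identity - 2); prune
            # candidates whose optimum falls below that (cross-multiplied)
            if s * best_c < (3 * best_m - 2 * best_c) * p.min_align_len:
                break
        entry = pool[k]
        bcodes = index.bc_mat[tag_kind][k, : int(index.bc_lens[tag_kind][k])]
        H = _align.fill_H(
            wcodes, bcodes, p.match_score, p.mismatch_score, p.gap_score
        )
        alns = _align.enumerate_optimal(
            H, wcodes, bcodes, p.match_score, p.mismatch_score, p.gap_score
        )
        cand_m = cand_c = 0
        cand_start = 0
        for al in alns:
            abs_start = w0 + al.read_start
            if abs(abs_start - anchor) > p.max_start_offset:
                continue
            if len(entry.sequence) - al.bc_end > p.max_end_gap:
                continue
            if al.columns < p.min_align_len:
                continue
            if not _identity_ok(al.matches, al.columns, p.min_identity):
                continue
            if cand_c == 0 or _better(al.matches, al.columns, cand_m, cand_c) > 0:
                cand_m, cand_c = al.matches, al.columns
                cand_start = abs_start
        if cand_c == 0:
            continue
        if best_entry is None:
            best_entry, best_m, best_c, best_start = entry, cand_m, cand_c, cand_start
            tie = False
        else:
            cmp = _better(cand_m, cand_c, best_m, best_c)
            if cmp > 0:
                best_entry, best_m, best_c, best_start = (
                    entry,
                    cand_m,
                    cand_c,
                    cand_start,
                )
                tie = False
            elif cmp == 0 and entry.strain_id != best_entry.strain_id:
                tie = True
    if best_entry is None:
        return None
    if tie:
        return Assignment(
            rid, Outcome.BARCODE_AMBIGUOUS, sample_id=sample_id, tag_kind=tag_kind
        )
    return Assignment(
        rid,
        Outcome.ASSIGNED,
        sample_id=sample_id,
        tag_kind=tag_kind,
        strain_id=best_entry.strain_id,
        method=Method.ALIGNED,
        identity=best_m / best_c,
        start_offset=best_start - anchor,
    )


def assign_read(
    read: Read | str,
    index: CatalogIndex,
    sheet: SampleSheet,
) -> Assignment:
    """Full per-read chain: demultiplex, classify tag, exact, then aligned."""
    p = index.params
    seq = read.sequence if isinstance(read, Read) else read
    rid = read.read_id if isinstance(read, Read) else ""
    sample_id = demultiplex(seq, sheet, index.primers, strict=p.strict_index)
    if sample_id is None:
        return Assignment(rid, Outcome.NO_INDEX)
    primers = index.primers
    if len(seq) < primers.index_len + min(len(primers.u1), len(primers.d1)):
        return Assignment(rid, Outcome.TOO_SHORT, sample_id=sample_id)
    tag = classify_tag(seq, primers, p)
    if tag is None:
        return Assignment(rid, Outcome.TAG_AMBIGUOUS, sample_id=sample_id)
    if len(seq) < index.layout.anchor(tag) + p.min_align_len:
        return Assignment(rid, Outcome.TOO_SHORT, sample_id=sample_id, tag_kind=tag)
    asn = match_exact(read if isinstance(read, Read) else seq, index, tag, sample_id)
    if asn is not None:
        return asn
    asn = match_aligned(read if isinstance(read, Read) else seq, index, tag, sample_id)
    if asn is not None:
        return asn
    return Assignment(rid, Outcome.NO_BARCODE, sample_id=sample_id, tag_kind=tag)
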