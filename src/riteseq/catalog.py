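"""Barcode catalog, primer set, sample sheet and read-layout geometry.

Every strain in a pooled deletion-collection screen is identified by two
short DNA barcodes (an UpTag and a DownTag, up to 20 nt) amplified with the
common primers U1 (18 nt) and D1 (17 nt).  Amplicons are multiplexed with a
4-nt sample index, so every read is expected to look like::

    [4 nt index][U1 or D1 primer][barcode][downstream context ...]

which places the barcode at 0-based offset 22 (UpTag) or 21 (DownTag).
This module loads and validates the tables that define that geometry; the
matching and quantification stages build on the types defined here.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "TagKind",
    "EntryStatus",
    "Antibody",
    "BarcodeEntry",
    "Catalog",
    "CatalogError",
    "FormatError",
    "PrimerSet",
    "ReadLayout",
    "Sample",
    "SampleSheet",
    "load_catalog",
    "write_catalog",
    "load_sample_sheet",
    "write_sample_sheet",
    "load_primers",
    "write_primers",
    "prefix_collision_report",
]

_DNA = frozenset("ACGT")

MAX_BARCODE_LEN = 20
DEFAULT_SEED_LEN = 11

#: Common primer sequences of the yeast deletion-collection amplicons.
DEFAULT_U1 = "GATGTCCACGAGGTCTCT"
DEFAULT_D1 = "CGGTGTCGGTCTCGTAG"


class CatalogError(ValueError):
    """A catalog, sample sheet or primer table failed validation."""


class FormatError(CatalogError):
    """An input file is structurally malformed (missing columns, empty)."""


class TagKind(str, enum.Enum):
    UP = "UP"
    DOWN = "DOWN"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class EntryStatus(str, enum.Enum):
    ACTIVE = "ACTIVE"
    DECOY = "DECOY"
    CONTROL_HA = "CONTROL_HA"
    CONTROL_T7 = "CONTROL_T7"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Antibody(str, enum.Enum):
    HA = "HA"
    T7 = "T7"
    INPUT = "INPUT"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def _check_dna(seq: str, *, what: str, row: object = None) -> None:
    bad = set(seq) - _DNA
    if bad:
        where = "" if row is None else f" (row {row})"
        raise CatalogError(
            f"{what}{where}: sequence {seq!r} contains non-ACGT characters "
            f"{sorted(bad)}"
        )


@dataclass(frozen=True)
class BarcodeEntry:
    """One strain-identifying (or decoy) tag sequence.

    ``strain_id`` is an opaque identifier; decoy entries live in their own
    identifier namespace, disjoint from active/control strains.
    """

    strain_id: str
    gene: str
    tag_kind: TagKind
    sequence: str
    status: EntryStatus = EntryStatus.ACTIVE

    def __post_init__(self) -> None:
        if not 1 <= len(self.sequence) <= MAX_BARCODE_LEN:
            raise CatalogError(
                f"barcode for {self.strain_id}/{self.tag_kind}: length "
                f"{len(self.sequence)} outside 1..{MAX_BARCODE_LEN}"
            )
        _check_dna(self.sequence, what=f"barcode for {self.strain_id}")

    @property
    def is_decoy(self) -> bool:
        return self.status is EntryStatus.DECOY


class Catalog:
    """Validated collection of :class:`BarcodeEntry`.

    Enforces (strain_id, tag_kind) uniqueness across ACTIVE + CONTROL
    entries and a decoy identifier namespace disjoint from them.
    """

    def __init__(self, entries: Iterable[BarcodeEntry]):
        self.entries: list[BarcodeEntry] = list(entries)
        if not self.entries:
            raise FormatError("catalog is empty")
        seen: dict[tuple[str, TagKind], int] = {}
        decoy_seen: dict[tuple[str, TagKind], int] = {}
        problems: list[str] = []
        for i, e in enumerate(self.entries):
            pool = decoy_seen if e.is_decoy else seen
            key = (e.strain_id, e.tag_kind)
            if key in pool:
                problems.append(
                    f"duplicate ({e.strain_id}, {e.tag_kind.value}) at rows "
                    f"{pool[key]} and {i}"
                )
            else:
                pool[key] = i
        strain_ids = {k[0] for k in seen}
        decoy_ids = {k[0] for k in decoy_seen}
        overlap = strain_ids & decoy_ids
        if overlap:
            problems.append(
                f"decoy strain_ids collide with active/control ids: {sorted(overlap)}"
            )
        if problems:
            raise CatalogError("catalog validation failed: " + "; ".join(problems))
        self._strain_ids = strain_ids
        self._decoy_ids = decoy_ids

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def strain_ids(self) -> set[str]:
        """Identifiers of non-decoy strains (ACTIVE plus controls)."""
        return set(self._strain_ids)

    @property
    def decoy_ids(self) -> set[str]:
        return set(self._decoy_ids)

    def by_tag(self, tag_kind: TagKind) -> list[BarcodeEntry]:
        return [e for e in self.entries if e.tag_kind is tag_kind]

    def by_status(self, status: EntryStatus) -> list[BarcodeEntry]:
        return [e for e in self.entries if e.status is status]

    def gene_of(self, strain_id: str) -> str:
        for e in self.entries:
            if e.strain_id == strain_id:
                return e.gene
        raise KeyError(strain_id)

    def status_of(self, strain_id: str) -> EntryStatus:
        for e in self.entries:
            if e.strain_id == strain_id:
                return e.status
        raise KeyError(strain_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "strain_id": [e.strain_id for e in self.entries],
                "gene": [e.gene for e in self.entries],
                "tag_kind": [e.tag_kind.value for e in self.entries],
                "sequence": [e.sequence for e in self.entries],
                "status": [e.status.value for e in self.entries],
            }
        )


_CATALOG_COLUMNS = ("strain_id", "gene", "tag_kind", "sequence", "status")


def load_catalog(path: str | Path) -> Catalog:
    """Load a catalog from a TSV file.

    The file must have a header with columns strain_id, gene, tag_kind,
    sequence, status; lines starting with ``#`` are ignored.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: catalog file is empty") from None
    missing = [c for c in _CATALOG_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    if df.empty:
        raise FormatError(f"{path}: catalog has no rows")
    entries = []
    for row in df.itertuples():
        try:
            entries.append(
                BarcodeEntry(
                    strain_id=row.strain_id,
                    gene=row.gene,
                    tag_kind=TagKind(row.tag_kind),
                    sequence=row.sequence,
                    status=EntryStatus(row.status),
                )
            )
        except (ValueError, CatalogError) as exc:
            raise CatalogError(f"{path}, row {row.Index}: {exc}") from None
    return Catalog(entries)


def write_catalog(catalog: Catalog, path: str | Path) -> None:
    catalog.to_frame().to_csv(path, sep="\t", index=False)


def prefix_collision_report(
    catalog: Catalog, seed_len: int = DEFAULT_SEED_LEN
) -> list[tuple[BarcodeEntry, BarcodeEntry]]:
    """Report pairs of same-tag barcodes that are indistinguishable over
    their seed prefixes.

    Two entries of the same tag kind collide when their first
    ``min(seed_len, len_a, len_b)`` bases agree: a read matching one of them
    exactly over the seed then matches both, making seed-exact assignment
    ambiguous.  An empty report means exact matching is unambiguous.
    """
    if seed_len < 1:
        raise ValueError("seed_len must be >= 1")
    out: list[tuple[BarcodeEntry, BarcodeEntry]] = []
    for tag in TagKind:
        pool = catalog.by_tag(tag)
        for i, a in enumerate(pool):
            for b in pool[i + 1 :]:
                k = min(seed_len, len(a.sequence), len(b.sequence))
                if a.sequence[:k] == b.sequence[:k]:
                    out.append((a, b))
    return out


@dataclass(frozen=True)
class ReadLayout:
    """Read geometry: where each tag's barcode is expected to start.

    Offsets are 0-based half-open internally; the UpTag anchor is
    index_len + len(U1) = 22 and the DownTag anchor index_len + len(D1) = 21
    for the standard primers, with jitter offsets {0, +1, -1} tried in that
    order.
    """

    index_len: int
    up_primer_len: int
    down_primer_len: int
    anchor_jitter: tuple[int, ...] = (0, 1, -1)

    def __post_init__(self) -> None:
        if 0 not in self.anchor_jitter:
            raise CatalogError("anchor_jitter must contain 0")

    def anchor(self, tag_kind: TagKind) -> int:
        if tag_kind is TagKind.UP:
            return self.index_len + self.up_primer_len
        return self.index_len + self.down_primer_len


@dataclass(frozen=True)
class PrimerSet:
    """Common amplification primers and the sample-index length.

    Lengths other than the standard 18 (U1) / 17 (D1) only raise a warning;
    all downstream anchors are recomputed from the actual lengths.
    """

    u1: str = DEFAULT_U1
    d1: str = DEFAULT_D1
    index_len: int = 4

    def __post_init__(self) -> None:
        _check_dna(self.u1, what="U1 primer")
        _check_dna(self.d1, what="D1 primer")
        if len(self.u1) != 18 or len(self.d1) != 17:
            warnings.warn(
                f"non-standard primer lengths (U1={len(self.u1)}, "
                f"D1={len(self.d1)}); anchors recomputed from actual lengths",
                stacklevel=2,
            )

    def primer(self, tag_kind: TagKind) -> str:
        return self.u1 if tag_kind is TagKind.UP else self.d1

    def layout(self, anchor_jitter: tuple[int, ...] = (0, 1, -1)) -> ReadLayout:
        return ReadLayout(
            index_len=self.index_len,
            up_primer_len=len(self.u1),
            down_primer_len=len(self.d1),
            anchor_jitter=anchor_jitter,
        )


def load_primers(path: str | Path) -> PrimerSet:
    """Load a primers config (YAML key-value: u1, d1, optional index_len)."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, Mapping) or "u1" not in data or "d1" not in data:
        raise FormatError(f"{path}: primers config must define keys 'u1' and 'd1'")
    unknown = set(data) - {"u1", "d1", "index_len"}
    if unknown:
        raise FormatError(f"{path}: unknown primer config keys {sorted(unknown)}")
    return PrimerSet(
        u1=str(data["u1"]).upper(),
        d1=str(data["d1"]).upper(),
        index_len=int(data.get("index_len", 4)),
    )


def write_primers(primers: PrimerSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {"u1": primers.u1, "d1": primers.d1, "index_len": primers.index_len},
            fh,
            sort_keys=True,
        )


@dataclass(frozen=True)
class Sample:
    """One indexed sample: a 4-nt index mapped to (antibody, timepoint)."""

    index: str
    sample_id: str
    antibody: Antibody
    timepoint: str

    def __post_init__(self) -> None:
        _check_dna(self.index, what=f"index for sample {self.sample_id}")


class SampleSheet:
    """Sample sheet: pairwise-distinct fixed-length indexes, each
    (antibody, timepoint) pair at most once."""

    def __init__(self, samples: Iterable[Sample], index_len: int = 4):
        self.samples: list[Sample] = list(samples)
        self.index_len = index_len
        if not self.samples:
            raise FormatError("sample sheet is empty")
        problems = []
        seen_idx: dict[str, str] = {}
        seen_cond: dict[tuple[Antibody, str], str] = {}
        for s in self.samples:
            if len(s.index) != index_len:
                problems.append(
                    f"index {s.index!r} for {s.sample_id} is not {index_len} nt"
                )
            if s.index in seen_idx:
                problems.append(
                    f"duplicate index {s.index!r} ({seen_idx[s.index]} and {s.sample_id})"
                )
            seen_idx.setdefault(s.index, s.sample_id)
            cond = (s.antibody, s.timepoint)
            if cond in seen_cond:
                problems.append(
                    f"condition ({s.antibody.value}, {s.timepoint}) assigned to both "
                    f"{seen_cond[cond]} and {s.sample_id}"
                )
            seen_cond.setdefault(cond, s.sample_id)
        if problems:
            raise CatalogError("sample sheet validation failed: " + "; ".join(problems))

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def index_map(self) -> dict[str, str]:
        return {s.index: s.sample_id for s in self.samples}

    def sample(self, sample_id: str) -> Sample:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    def design(
        self, timepoints: Sequence[str] = ("t1", "t3")
    ) -> dict[tuple[Antibody, str], str]:
        """Map (antibody, timepoint) -> sample_id for the ChIP design.

        Raises :class:`CatalogError` if any required (HA, t) / (T7, t) pair
        is missing from the sheet.
        """
        lookup = {(s.antibody, s.timepoint): s.sample_id for s in self.samples}
        design: dict[tuple[Antibody, str], str] = {}
        missing = []
        for tp in timepoints:
            for ab in (Antibody.HA, Antibody.T7):
                if (ab, tp) not in lookup:
                    missing.append(f"({ab.value}, {tp})")
                else:
                    design[(ab, tp)] = lookup[(ab, tp)]
        if missing:
            raise CatalogError(
                f"sample sheet lacks required ChIP samples: {', '.join(missing)}"
            )
        return design

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": [s.index for s in self.samples],
                "sample_id": [s.sample_id for s in self.samples],
                "antibody": [s.antibody.value for s in self.samples],
                "timepoint": [s.timepoint for s in self.samples],
            }
        )


_SHEET_COLUMNS = ("index", "sample_id", "antibody", "timepoint")


def load_sample_sheet(path: str | Path) -> SampleSheet:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: sample sheet file is empty") from None
    missing = [c for c in _SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    samples = []
    for i, (idx, sid, ab, tp) in enumerate(
        zip(df["index"], df["sample_id"], df["antibody"], df["timepoint"])
    ):
        try:
            samples.append(
                Sample(index=idx, sample_id=sid, antibody=Antibody(ab), timepoint=tp)
            )
        except (ValueError, CatalogError) as exc:
            raise CatalogError(f"{path}, row {i}: {exc}") from None
    return SampleSheet(samples)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.to_frame().to_csv(path, sep="\t", index=False)
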