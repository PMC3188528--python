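"""Ground-truth simulator for pooled barcode-ChIP turnover screens.

The generative model mirrors the measurement model the analysis assumes.
Each clone i carries an abundance weight a_i (pool representation), a tag
switch efficiency e_i and a new-histone fraction f_i(t) per timepoint
(f <= e: cells that never switched cannot deposit new-tag histone; f is
monotone in t).  For one indexed sample, the expected read share of clone
i's barcode is proportional to

    HA (old) ChIP:  a_i * (1 - f_i(t))
    T7 (new) ChIP:  a_i * f_i(t)
    input:          a_i

and the sequenced counts are one multinomial draw per sample at the
configured depth over all barcodes of both tag kinds plus the decoy pairs
(decoys receive a small configurable share, emulating index hopping and
chimeric amplification).  Reads are then assembled as

    index + common primer + barcode + fixed downstream context

truncated/padded to the read length, and corrupted with i.i.d. per-base
substitutions at rate ``error_rate``.  A per-clone, per-tag new-fraction
override supports injecting UpTag/DownTag-discordant clones (barcode
specific artifacts), and a low switch efficiency emulates a
recombination-failure clone whose ratio is depressed without true low
turnover.

Everything is deterministic per seed, including FASTQ byte content.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from ._align import encode as _encode
from .catalog import (
    Antibody,
    BarcodeEntry,
    Catalog,
    CatalogError,
    EntryStatus,
    PrimerSet,
    Sample,
    SampleSheet,
    TagKind,
    write_catalog,
    write_primers,
    write_sample_sheet,
)

__all__ = [
    "CloneTruth",
    "TruthManifest",
    "make_catalog",
    "default_sample_sheet",
    "make_manifest",
    "simulate_counts",
    "simulate_reads",
    "simulate_pool",
    "parameter_recovery_report",
]

# long enough to cover index + U1 + a full 20-nt barcode (42 nt) with margin
DEFAULT_READ_LENGTH = 50
DEFAULT_DEPTH = 100_000
DEFAULT_ERROR_RATE = 0.01
DEFAULT_DECOY_FRACTION = 0.002

#: fixed downstream context appended after the barcode (arbitrary, constant)
FILLER = "GACCTGCAGCGTACGAAGCTTGCTAGCATCGATCCGGTCA"

_INDEX_POOL = [
    "AACC", "AAGG", "CCAA", "CCTT", "GGAA", "GGTT", "TTCC",
    "ACAC", "AGAG", "CACA", "CTCT", "GAGA", "GTGT", "TCTC",
]

_LETTERS = np.frombuffer(b"ACGT", dtype=np.uint8)


def ratio_of(f: float) -> float:
    """True T7/HA ratio implied by a new-histone fraction f."""
    return f / (1.0 - f) if f < 1.0 else np.inf


def fraction_of(r: float) -> float:
    """Inverse of :func:`ratio_of`."""
    return r / (1.0 + r)


@dataclass
class CloneTruth:
    """Ground truth for one pooled clone (or control)."""

    strain_id: str
    abundance: float
    switch_efficiency: float
    f_up: dict[str, float]
    f_down: dict[str, float]
    status: EntryStatus = EntryStatus.ACTIVE

    def f(self, tag: TagKind, timepoint: str) -> float:
        return (self.f_up if tag is TagKind.UP else self.f_down)[timepoint]

    def validate(self) -> None:
        if self.abundance <= 0:
            raise CatalogError(f"{self.strain_id}: abundance must be > 0")
        if not 0 <= self.switch_efficiency <= 1:
            raise CatalogError(f"{self.strain_id}: switch efficiency outside [0,1]")
        for fs in (self.f_up, self.f_down):
            tps = sorted(fs)  # timepoint labels sort chronologically (t0<t1<t3)
            vals = [fs[t] for t in tps]
            if any(not 0 <= v <= 1 for v in vals):
                raise CatalogError(f"{self.strain_id}: new fraction outside [0,1]")
            if any(b < a - 1e-12 for a, b in zip(vals, vals[1:])):
                raise CatalogError(f"{self.strain_id}: new fraction not monotone in t")
            if any(v > self.switch_efficiency + 1e-12 for v in vals):
                raise CatalogError(
                    f"{self.strain_id}: new fraction exceeds switch efficiency"
                )
        if self.status is EntryStatus.CONTROL_HA and any(
            v != 0 for v in list(self.f_up.values()) + list(self.f_down.values())
        ):
            raise CatalogError(f"{self.strain_id}: HA-only control must have f == 0")
        if self.status is EntryStatus.CONTROL_T7 and any(
            v != 1 for v in list(self.f_up.values()) + list(self.f_down.values())
        ):
            raise CatalogError(f"{self.strain_id}: T7-only control must have f == 1")


@dataclass
class TruthManifest:
    """All generator parameters for one simulated screen."""

    clones: list[CloneTruth]
    depths: dict[str, int]
    error_rate: float = DEFAULT_ERROR_RATE
    decoy_fraction: float = DEFAULT_DECOY_FRACTION
    read_length: int = DEFAULT_READ_LENGTH
    indel_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for c in self.clones:
            c.validate()
        if not 0 <= self.decoy_fraction < 1:
            raise CatalogError("decoy_fraction must be in [0, 1)")
        if not 0 <= self.error_rate < 1:
            raise CatalogError("error_rate must be in [0, 1)")
        if not 0 <= self.indel_rate < 1:
            raise CatalogError("indel_rate must be in [0, 1)")

    def clone(self, strain_id: str) -> CloneTruth:
        for c in self.clones:
            if c.strain_id == strain_id:
                return c
        raise KeyError(strain_id)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "depths": dict(self.depths),
            "error_rate": self.error_rate,
            "decoy_fraction": self.decoy_fraction,
            "read_length": self.read_length,
            "indel_rate": self.indel_rate,
            "clones": [
                {
                    "strain_id": c.strain_id,
                    "abundance": c.abundance,
                    "switch_efficiency": c.switch_efficiency,
                    "f_up": dict(c.f_up),
                    "f_down": dict(c.f_down),
                    "status": c.status.value,
                }
                for c in self.clones
            ],
        }

    def write_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TruthManifest":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        clones = [
            CloneTruth(
                strain_id=c["strain_id"],
                abundance=float(c["abundance"]),
                switch_efficiency=float(c["switch_efficiency"]),
                f_up={k: float(v) for k, v in c["f_up"].items()},
                f_down={k: float(v) for k, v in c["f_down"].items()},
                status=EntryStatus(c["status"]),
            )
            for c in d["clones"]
        ]
        return cls(
            clones=clones,
            depths={k: int(v) for k, v in d["depths"].items()},
            error_rate=float(d["error_rate"]),
            decoy_fraction=float(d["decoy_fraction"]),
            read_length=int(d["read_length"]),
            indel_rate=float(d.get("indel_rate", 0.0)),
            seed=int(d["seed"]),
        )


def _random_barcodes(
    rng: np.random.Generator,
    n: int,
    length: int,
    seed_len: int,
    taken: set[str],
) -> list[str]:
    """Draw n barcodes with pairwise-distinct seed prefixes (vs `taken` too)."""
    plen = min(seed_len, length)
    if n + len(taken) > 4 ** plen:
        raise CatalogError(
            f"cannot draw {n} barcodes of length {length} with distinct "
            f"{plen}-nt prefixes"
        )
    out: list[str] = []
    tries = 0
    while len(out) < n:
        tries += 1
        if tries > 1000 * (n + 10):
            raise CatalogError("barcode sampling failed to converge")
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
        if seq[:plen] in taken:
            continue
        taken.add(seq[:plen])
        out.append(seq)
    return out


def make_catalog(
    n_strains: int,
    n_decoys: int,
    barcode_len: int = 20,
    seed: int = 0,
    seed_len: int = 11,
) -> Catalog:
    """Random catalog with collision-free seed prefixes per tag kind.

    Decoys are generated as pairs (one UpTag + one DownTag per decoy id),
    matching how unused deletion-collection barcode positions come in
    pairs.  When n_strains >= 2 the first two strains are the HA-only and
    T7-only constitutive controls.
    """
    if n_strains < 0 or n_decoys < 0:
        raise ValueError("n_strains and n_decoys must be >= 0")
    rng = np.random.default_rng(seed)
    entries: list[BarcodeEntry] = []
    for tag in TagKind:
        taken: set[str] = set()
        strain_bcs = _random_barcodes(rng, n_strains, barcode_len, seed_len, taken)
        decoy_bcs = _random_barcodes(rng, n_decoys, barcode_len, seed_len, taken)
        for i in range(n_strains):
            if n_strains >= 2 and i == 0:
                sid, gene, status = "ctrl_ha", "CTRL-HA", EntryStatus.CONTROL_HA
            elif n_strains >= 2 and i == 1:
                sid, gene, status = "ctrl_t7", "CTRL-T7", EntryStatus.CONTROL_T7
            else:
                sid, gene, status = f"strain{i:04d}", f"GENE{i:03d}", EntryStatus.ACTIVE
            entries.append(BarcodeEntry(sid, gene, tag, strain_bcs[i], status))
        for i in range(n_decoys):
            entries.append(
                BarcodeEntry(f"decoy{i:04d}", "-", tag, decoy_bcs[i], EntryStatus.DECOY)
            )
    return Catalog(entries)


def default_sample_sheet(
    timepoints: Sequence[str] = ("t0", "t1", "t3"),
    include_input: bool = True,
) -> SampleSheet:
    """Standard screen design: HA and T7 ChIP per timepoint plus one input."""
    samples = []
    k = 0
    for tp in timepoints:
        for ab in (Antibody.HA, Antibody.T7):
            samples.append(Sample(_INDEX_POOL[k], f"{ab.value}_{tp}", ab, tp))
            k += 1
    if include_input:
        samples.append(Sample(_INDEX_POOL[k], "input", Antibody.INPUT, "pool"))
    return SampleSheet(samples)


def make_manifest(
    catalog: Catalog,
    sheet: SampleSheet,
    seed: int = 0,
    depth: int = DEFAULT_DEPTH,
    error_rate: float = DEFAULT_ERROR_RATE,
    decoy_fraction: float = DEFAULT_DECOY_FRACTION,
    read_length: int = DEFAULT_READ_LENGTH,
    abundance_sigma: float = 0.5,
    f_t1_range: tuple[float, float] = (0.05, 0.35),
    f_increment_range: tuple[float, float] = (0.02, 0.12),
    n_switch_failure: int = 1,
    switch_failure_efficiency: float = 0.05,
    n_discordant: int = 0,
    discordant_ratio_offset: float = 0.45,
    depths: Optional[dict[str, int]] = None,
) -> TruthManifest:
    """Draw a ground-truth manifest for the catalog's clones.

    Defaults emulate the screen's stated conditions: unequal clone
    abundances (log-normal), modest replication-independent turnover that
    accumulates from t1 to t3, one HA-only and one T7-only control, one
    switch-failure clone (low recombination efficiency), and a small decoy
    read share.  ``n_discordant`` clones get a DownTag new-fraction offset
    so their UpTag and DownTag ratios disagree by ``discordant_ratio_offset``
    (for testing the SD concordance filter).
    """
    rng = np.random.default_rng(seed)
    timepoints = sorted({s.timepoint for s in sheet.samples if s.antibody is not Antibody.INPUT})
    strain_ids = sorted(catalog.strain_ids)
    statuses = {sid: catalog.status_of(sid) for sid in strain_ids}
    ordinary = [
        sid for sid in strain_ids
        if statuses[sid] is EntryStatus.ACTIVE
    ]
    failure_ids = set(ordinary[-n_switch_failure:] if n_switch_failure else [])
    disc_pool = [s for s in ordinary if s not in failure_ids]
    discordant_ids = set(disc_pool[-n_discordant:] if n_discordant else [])

    clones = []
    for sid in strain_ids:
        status = statuses[sid]
        a = float(rng.lognormal(0.0, abundance_sigma))
        if status is EntryStatus.CONTROL_HA:
            f = {tp: 0.0 for tp in timepoints}
            clones.append(CloneTruth(sid, a, 1.0, dict(f), dict(f), status))
            continue
        if status is EntryStatus.CONTROL_T7:
            f = {tp: 1.0 for tp in timepoints}
            clones.append(CloneTruth(sid, a, 1.0, dict(f), dict(f), status))
            continue
        f1 = float(rng.uniform(*f_t1_range))
        inc = float(rng.uniform(*f_increment_range))
        e = switch_failure_efficiency if sid in failure_ids else 1.0
        f_up: dict[str, float] = {}
        for tp in timepoints:
            if tp == timepoints[0] and len(timepoints) > 2:
                f_up[tp] = 0.0  # pre-switch timepoint
            elif tp == timepoints[-1]:
                f_up[tp] = min(f1 + inc, e)
            else:
                f_up[tp] = min(f1, e)
        if sid in discordant_ids:
            f_down = {
                tp: min(fraction_of(ratio_of(v) + discordant_ratio_offset), e)
                if v > 0
                else 0.0
                for tp, v in f_up.items()
            }
        else:
            f_down = dict(f_up)
        clones.append(CloneTruth(sid, a, e, f_up, f_down, status))
    return TruthManifest(
        clones=clones,
        depths=depths or {s.sample_id: depth for s in sheet.samples},
        error_rate=error_rate,
        decoy_fraction=decoy_fraction,
        read_length=read_length,
        seed=seed,
    )


def _entry_weights(
    catalog: Catalog, manifest: TruthManifest, sample: Sample
) -> np.ndarray:
    """Expected (unnormalized) read weight of every catalog entry in a sample."""
    w = np.zeros(len(catalog.entries))
    clone_total = 0.0
    decoy_rows = []
    for i, e in enumerate(catalog.entries):
        if e.is_decoy:
            decoy_rows.append(i)
            continue
        c = manifest.clone(e.strain_id)
        if sample.antibody is Antibody.INPUT:
            w[i] = c.abundance
        elif sample.antibody is Antibody.HA:
            w[i] = c.abundance * (1.0 - c.f(e.tag_kind, sample.timepoint))
        else:
            w[i] = c.abundance * c.f(e.tag_kind, sample.timepoint)
        clone_total += w[i]
    if decoy_rows and manifest.decoy_fraction > 0 and clone_total > 0:
        per_decoy = (
            manifest.decoy_fraction
            / (1.0 - manifest.decoy_fraction)
            * clone_total
            / len(decoy_rows)
        )
        for i in decoy_rows:
            w[i] = per_decoy
    return w


def expected_shares(
    catalog: Catalog, manifest: TruthManifest, sheet: SampleSheet
) -> pd.DataFrame:
    """Expected per-entry read share per sample (columns sum to 1)."""
    idx = pd.MultiIndex.from_tuples(
        [(e.strain_id, e.tag_kind.value) for e in catalog],
        names=["strain_id", "tag_kind"],
    )
    data = {}
    for s in sheet.samples:
        w = _entry_weights(catalog, manifest, s)
        tot = w.sum()
        data[s.sample_id] = w / tot if tot > 0 else w
    return pd.DataFrame(data, index=idx)


def simulate_counts(
    catalog: Catalog,
    manifest: TruthManifest,
    sheet: SampleSheet,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """One multinomial draw per sample; rows = catalog entries."""
    idx = pd.MultiIndex.from_tuples(
        [(e.strain_id, e.tag_kind.value) for e in catalog],
        names=["strain_id", "tag_kind"],
    )
    data = {}
    for s in sheet.samples:
        depth = manifest.depths.get(s.sample_id, 0)
        w = _entry_weights(catalog, manifest, s)
        tot = w.sum()
        if depth == 0 or tot == 0:
            data[s.sample_id] = np.zeros(len(w), dtype=np.int64)
        else:
            data[s.sample_id] = rng.multinomial(depth, w / tot)
    return pd.DataFrame(data, index=idx)


def _read_templates(
    catalog: Catalog, sheet: SampleSheet, primers: PrimerSet, read_length: int
) -> dict[str, np.ndarray]:
    """Per-sample template matrix (n_entries x read_length, base codes)."""
    out = {}
    for s in sheet.samples:
        mat = np.zeros((len(catalog.entries), read_length), dtype=np.uint8)
        for i, e in enumerate(catalog.entries):
            full = s.index + primers.primer(e.tag_kind) + e.sequence + FILLER
            full = (full + "A" * read_length)[:read_length]
            mat[i] = _encode(full)
        out[s.sample_id] = mat
    return out


def simulate_reads(
    catalog: Catalog,
    manifest: TruthManifest,
    sheet: SampleSheet,
    primers: PrimerSet | None = None,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Generate the multiplexed read pool in memory.

    Returns (reads, truth_counts): reads as (read_id, sequence) grouped by
    sample, and the per-entry drawn counts.  Deterministic for a manifest
    (one RNG seeded from manifest.seed drives counts and errors).
    """
    primers = primers or PrimerSet()
    rng = np.random.default_rng(manifest.seed)
    counts = simulate_counts(catalog, manifest, sheet, rng)
    templates = _read_templates(catalog, sheet, primers, manifest.read_length)
    reads: list[tuple[str, str]] = []
    for s in sheet.samples:
        cvec = counts[s.sample_id].to_numpy()
        n = int(cvec.sum())
        if n == 0:
            continue
        block = np.repeat(templates[s.sample_id], cvec, axis=0)
        if manifest.error_rate > 0:
            mask = rng.random(block.shape) < manifest.error_rate
            shift = rng.integers(1, 4, size=block.shape, dtype=np.uint8)
            block = np.where(mask, (block + shift) % 4, block)
        letters = _LETTERS[block]
        for i in range(n):
            seq = letters[i].tobytes().decode("ascii")
            if manifest.indel_rate > 0:
                seq = _apply_indels(seq, manifest.indel_rate, manifest.read_length, rng)
            reads.append((f"sim:{s.sample_id}:{i}", seq))
    return reads, counts


def _apply_indels(
    seq: str, rate: float, read_length: int, rng: np.random.Generator
) -> str:
    """Per-base single-nucleotide indels (deletion/insertion half each),
    re-padded/truncated to the read length."""
    out = []
    for c in seq:
        r = rng.random()
        if r < rate / 2:
            continue  # deletion
        if r < rate:
            out.append("ACGT"[int(rng.integers(0, 4))])  # insertion before c
        out.append(c)
    return ("".join(out) + "A" * read_length)[:read_length]


def simulate_pool(
    catalog: Catalog,
    manifest: TruthManifest,
    sheet: SampleSheet,
    primers: PrimerSet | None = None,
    out_dir: str | Path = ".",
    gzip_fastq: bool = False,
) -> dict[str, Path]:
    """Write a complete simulated dataset (FASTQ + truth tables + configs)."""
    import gzip as _gzip

    primers = primers or PrimerSet()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    reads, counts = simulate_reads(catalog, manifest, sheet, primers)
    fastq_path = out / ("reads.fastq.gz" if gzip_fastq else "reads.fastq")
    opener = (lambda p: _gzip.open(p, "wt")) if gzip_fastq else (lambda p: open(p, "w"))
    with opener(fastq_path) as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
    paths = {"fastq": fastq_path}

    counts_long = counts.stack().rename("count").reset_index()
    counts_long.columns = ["strain_id", "tag_kind", "sample_id", "count"]
    paths["truth_counts"] = out / "truth_counts.tsv"
    counts_long.to_csv(paths["truth_counts"], sep="\t", index=False)

    clone_rows = []
    for c in manifest.clones:
        row = {
            "strain_id": c.strain_id,
            "status": c.status.value,
            "abundance": c.abundance,
            "switch_efficiency": c.switch_efficiency,
        }
        for tp, v in c.f_up.items():
            row[f"f_up_{tp}"] = v
        for tp, v in c.f_down.items():
            row[f"f_down_{tp}"] = v
        clone_rows.append(row)
    paths["truth_clones"] = out / "truth_clones.tsv"
    pd.DataFrame(clone_rows).to_csv(paths["truth_clones"], sep="\t", index=False)

    paths["manifest"] = out / "manifest.yaml"
    manifest.write_yaml(paths["manifest"])
    paths["catalog"] = out / "catalog.tsv"
    write_catalog(catalog, paths["catalog"])
    paths["sample_sheet"] = out / "sample_sheet.tsv"
    write_sample_sheet(sheet, paths["sample_sheet"])
    paths["primers"] = out / "primers.yaml"
    write_primers(primers, paths["primers"])
    return paths


def _truth_ratios(
    shares_or_counts: pd.DataFrame,
    design: dict[tuple[Antibody, str], str],
    timepoints: Sequence[str],
    pseudocount: float,
    depths: Optional[dict[str, int]] = None,
) -> pd.DataFrame:
    """T7/HA rpm ratios computed from a truth table (counts or shares)."""
    df = shares_or_counts
    out = {}
    for tag in TagKind:
        sub = df.xs(tag.value, level="tag_kind")
        for tp in timepoints:
            t7s, has = design[(Antibody.T7, tp)], design[(Antibody.HA, tp)]
            # normalization is per (tag x sample) bin
            t7 = sub[t7s] / max(sub[t7s].sum(), 1e-300) * 1e6
            ha = sub[has] / max(sub[has].sum(), 1e-300) * 1e6
            out[f"ratio_{tag.value.lower()}_{tp}"] = (t7 + pseudocount) / (
                ha + pseudocount
            )
    return pd.DataFrame(out)


def parameter_recovery_report(
    records: pd.DataFrame,
    truth_counts: pd.DataFrame,
    manifest: TruthManifest,
    catalog: Catalog,
    sheet: SampleSheet,
    timepoints: Sequence[str] = ("t1", "t3"),
    pseudocount: float = 0.5,
) -> tuple[pd.DataFrame, dict]:
    """Per-clone recovery errors of the pipeline against ground truth.

    Three reference points per clone and (tag, timepoint):

    * ``truth`` — the ratio implied by the *drawn* truth counts (isolates
      read-assignment error; identical to the estimate in a noiseless run);
    * ``expected`` — the ratio implied by the expected multinomial shares
      (includes the per-timepoint pool normalization factor inherent to
      relative-abundance sequencing);
    * ``se`` — delta-method standard error of the estimated ratio from
      binomial counting noise at the configured depths.

    The summary reports bias/RMSE of the clone mean ratio against both
    references and the fraction of clones within 3 SE of expectation
    (evaluated over ordinary concordant clones with full switch
    efficiency).
    """
    strains = set(records["strain_id"])
    truth_strains = {c.strain_id for c in manifest.clones}
    if strains != truth_strains:
        diff = strains.symmetric_difference(truth_strains)
        raise ValueError(f"clone sets differ between truth and records: {sorted(diff)}")
    design = sheet.design(timepoints)
    shares = expected_shares(catalog, manifest, sheet)
    truth_r = _truth_ratios(truth_counts.astype(float), design, timepoints, pseudocount)
    exp_r = _truth_ratios(shares, design, timepoints, pseudocount)

    # delta-method SE of each ratio from the expected shares and depths;
    # rpm is normalized within the (tag x sample) bin, whose depth is the
    # bin's expected share of the sample depth
    se = {}
    for tag in TagKind:
        sub = shares.xs(tag.value, level="tag_kind")
        for tp in timepoints:
            col = f"ratio_{tag.value.lower()}_{tp}"
            ses = []
            for sid in sub.index:
                parts = 0.0
                val = exp_r.loc[sid, col]
                ok = True
                for ab in (Antibody.T7, Antibody.HA):
                    samp = design[(ab, tp)]
                    N = manifest.depths.get(samp, 0)
                    p_bin = float(sub[samp].sum())
                    if N == 0 or p_bin == 0:
                        ok = False
                        break
                    q = float(sub.loc[sid, samp]) / p_bin
                    n_bin = N * p_bin
                    var_rpm = 1e12 * q * (1 - q) / n_bin
                    rpm = 1e6 * q
                    parts += var_rpm / (rpm + pseudocount) ** 2
                ses.append(val * np.sqrt(parts) if ok else np.nan)
            se[col] = pd.Series(ses, index=sub.index)
    se_df = pd.DataFrame(se)

    rows = []
    for c in manifest.clones:
        sid = c.strain_id
        rec = records[records["strain_id"] == sid].iloc[0]
        est = np.array([rec[f"ratio_{t.value.lower()}_{tp}"] for t in TagKind for tp in timepoints])
        tru = np.array([truth_r.loc[sid, f"ratio_{t.value.lower()}_{tp}"] for t in TagKind for tp in timepoints])
        exp = np.array([exp_r.loc[sid, f"ratio_{t.value.lower()}_{tp}"] for t in TagKind for tp in timepoints])
        ses = np.array([se_df.loc[sid, f"ratio_{t.value.lower()}_{tp}"] for t in TagKind for tp in timepoints])
        est_mean = np.nanmean(est) if np.isfinite(est).any() else np.nan
        se_mean = np.sqrt(np.nansum(ses**2)) / 4
        concordant = all(
            abs(c.f_up[tp] - c.f_down[tp]) < 1e-12 for tp in c.f_up
        )
        rows.append(
            {
                "strain_id": sid,
                "status": c.status.value,
                "evaluable": (
                    c.status is EntryStatus.ACTIVE
                    and c.switch_efficiency == 1.0
                    and concordant
                ),
                "est_mean": est_mean,
                "truth_mean": float(np.nanmean(tru)),
                "expected_mean": float(np.nanmean(exp)),
                "se_mean": float(se_mean),
                "z_mean": float((est_mean - np.nanmean(exp)) / se_mean)
                if se_mean > 0
                else np.nan,
                "included": bool(rec["included"]),
                "exclusion_reason": rec["exclusion_reason"],
            }
        )
    per_clone = pd.DataFrame(rows)
    ev = per_clone[per_clone["evaluable"] & np.isfinite(per_clone["est_mean"])]
    err_truth = per_clone["est_mean"] - per_clone["truth_mean"]
    err_truth = err_truth[np.isfinite(err_truth)]
    summary = {
        "n_clones": len(per_clone),
        "n_evaluable": len(ev),
        "bias": float((ev["est_mean"] - ev["expected_mean"]).mean()) if len(ev) else np.nan,
        "rmse_vs_truth_counts": float(np.sqrt((err_truth**2).mean()))
        if len(err_truth)
        else np.nan,
        "rmse_vs_expected": float(
            np.sqrt(((ev["est_mean"] - ev["expected_mean"]) ** 2).mean())
        )
        if len(ev)
        else np.nan,
        "coverage_3se": float((ev["z_mean"].abs() <= 3).mean()) if len(ev) else np.nan,
        "excluded": {
            r["strain_id"]: r["exclusion_reason"]
            for _, r in per_clone.iterrows()
            if not r["included"]
        },
    }
    return per_clone, summary
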