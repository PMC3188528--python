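"""Turn barcode counts into per-clone histone-turnover calls.

The chromatin readout is the ratio of new (T7-tagged) over old (HA-tagged)
histone H3 ChIP signal at each strain's barcodes.  Counts are first
normalized to reads per million within each (tag kind x sample) bin; the
turnover ratio of a clone is then

    ratio(tag, t) = (RPM_T7(tag, t) + pc) / (RPM_HA(tag, t) + pc)

for t = t1, t3 and both the UpTag and DownTag (pc is a small pseudocount
guarding zero bins).  Three filters follow, in order:

1. MISSING_TAG  - a clone must have both barcodes identified;
2. DECOY_OUTLIER - clones whose UP/DOWN count ratio is extreme against the
   empirical null built from the unused (decoy) barcode pairs (two-sided
   empirical p < alpha in any indexed sample) are discarded as likely
   false assignments;
3. SD_FILTER    - only clones whose four ratios agree (sample SD < 0.17)
   are kept, so UpTag/DownTag and t1/t3 must tell the same story.

HA-only and T7-only control strains flow through unchanged and are used to
report the separation/dynamic range of the screen.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _st

from .catalog import Antibody, Catalog, EntryStatus, SampleSheet, TagKind
from .counting import CountMatrix

__all__ = [
    "NormalizedMatrix",
    "DecoyNull",
    "ScreenResult",
    "normalize_rpm",
    "compute_turnover",
    "decoy_outlier_filter",
    "filter_by_sd",
    "control_separation",
    "concordance_correlations",
    "relative_to_reference",
    "quantify_screen",
    "DEFAULT_MAX_SD",
    "DEFAULT_ALPHA",
    "DEFAULT_PSEUDOCOUNT",
]

logger = logging.getLogger(__name__)

DEFAULT_MAX_SD = 0.17
DEFAULT_ALPHA = 0.01
DEFAULT_PSEUDOCOUNT = 0.5
MIN_DECOYS_FOR_NULL = 20

RATIO_COLUMNS = ("ratio_up_t1", "ratio_up_t3", "ratio_down_t1", "ratio_down_t3")


@dataclass
class NormalizedMatrix:
    """Reads-per-million per (entry, sample), normalized within each
    (tag kind x sample) bin; bins with zero total are flagged undefined
    (NaN), never silently zero."""

    rpm: pd.DataFrame
    undefined_bins: list[tuple[str, str]]
    counts: CountMatrix

    @property
    def catalog(self) -> Catalog:
        return self.counts.catalog


def normalize_rpm(counts: CountMatrix) -> NormalizedMatrix:
    """count * 1e6 / bin_total within each (tag_kind, sample) bin."""
    df = counts.df
    totals = counts.bin_totals()
    rpm = df.astype(float).copy()
    undefined: list[tuple[str, str]] = []
    for tag in df.index.get_level_values("tag_kind").unique():
        mask = df.index.get_level_values("tag_kind") == tag
        for sample in df.columns:
            tot = totals.loc[tag, sample]
            if tot == 0:
                rpm.loc[mask, sample] = np.nan
                undefined.append((tag, sample))
            else:
                rpm.loc[mask, sample] = df.loc[mask, sample] * 1e6 / tot
    return NormalizedMatrix(rpm=rpm, undefined_bins=undefined, counts=counts)


def _strain_order(catalog: Catalog, include_decoys: bool) -> list[str]:
    seen: list[str] = []
    for e in catalog:
        if e.is_decoy and not include_decoys:
            continue
        if e.strain_id not in seen:
            seen.append(e.strain_id)
    return seen


def compute_turnover(
    norm: NormalizedMatrix,
    design: dict[tuple[Antibody, str], str],
    timepoints: Sequence[str] = ("t1", "t3"),
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    include_decoys: bool = False,
) -> pd.DataFrame:
    """Per-clone T7/HA ratios for (UpTag, DownTag) x timepoints.

    Returns a record frame with the four ratios, their mean and sample SD
    (n-1 denominator), a zero-HA flag (denominator rescued only by the
    pseudocount) and a provisional exclusion_reason of MISSING_TAG /
    ZERO_DENOMINATOR where applicable.  Inclusion flags are finalized by
    the downstream filters.
    """
    for key, sample_id in design.items():
        if sample_id not in norm.rpm.columns:
            raise KeyError(f"design references unknown sample_id {sample_id!r}")
    catalog = norm.catalog
    strains = _strain_order(catalog, include_decoys)
    has_tag = {
        (e.strain_id, e.tag_kind): True for e in catalog
    }
    counts_df = norm.counts.df
    design_samples = [design[(ab, tp)] for tp in timepoints for ab in (Antibody.HA, Antibody.T7)]

    rows = []
    for sid in strains:
        rec: dict = {
            "strain_id": sid,
            "gene": catalog.gene_of(sid),
            "status": catalog.status_of(sid).value,
        }
        missing = False
        zero_ha = False
        zero_den = False
        for tag in TagKind:
            tag_present = has_tag.get((sid, tag), False)
            identified = False
            if tag_present:
                c = counts_df.loc[(sid, tag.value), design_samples]
                identified = bool((c > 0).any())
            for tp in timepoints:
                col = f"ratio_{tag.value.lower()}_{tp}"
                if not tag_present or not identified:
                    rec[col] = np.nan
                    continue
                t7 = norm.rpm.loc[(sid, tag.value), design[(Antibody.T7, tp)]]
                ha = norm.rpm.loc[(sid, tag.value), design[(Antibody.HA, tp)]]
                if np.isnan(t7) or np.isnan(ha):
                    rec[col] = np.nan
                    continue
                if ha == 0:
                    zero_ha = True
                    if pseudocount == 0:
                        zero_den = True
                        rec[col] = np.inf
                        continue
                rec[col] = (t7 + pseudocount) / (ha + pseudocount)
            if not tag_present or not identified:
                missing = True
        ratios = np.array([rec.get(c, np.nan) for c in RATIO_COLUMNS], dtype=float)
        finite = np.isfinite(ratios)
        rec["mean_ratio"] = float(np.mean(ratios)) if finite.all() else np.nan
        rec["sd_ratio"] = float(np.std(ratios, ddof=1)) if finite.all() else np.nan
        rec["zero_ha"] = zero_ha
        if missing:
            rec["exclusion_reason"] = "MISSING_TAG"
        elif zero_den:
            rec["exclusion_reason"] = "ZERO_DENOMINATOR"
        else:
            rec["exclusion_reason"] = "none"
        rec["included"] = False
        rows.append(rec)
    return pd.DataFrame(rows)


class DecoyNull:
    """Empirical null of log2(UP RPM / DOWN RPM) built from decoy pairs.

    Decoy barcodes are absent from the pool, so any reads they collect are
    false assignments; the distribution of their up/down ratios calibrates
    how extreme a real clone's up/down imbalance may be before it looks
    like a false assignment.  Inactive below MIN_DECOYS_FOR_NULL pairs.
    """

    def __init__(
        self,
        norm: NormalizedMatrix,
        pseudocount: float = DEFAULT_PSEUDOCOUNT,
        min_decoys: int = MIN_DECOYS_FOR_NULL,
    ):
        catalog = norm.catalog
        decoy_ids = sorted(catalog.decoy_ids)
        pairs = [
            d
            for d in decoy_ids
            if (d, TagKind.UP.value) in norm.rpm.index
            and (d, TagKind.DOWN.value) in norm.rpm.index
        ]
        self.n_decoys = len(pairs)
        self.min_decoys = min_decoys
        self.pseudocount = pseudocount
        self.values: dict[str, np.ndarray] = {}
        for sample in norm.rpm.columns:
            up = norm.rpm.loc[[(d, TagKind.UP.value) for d in pairs], sample].to_numpy()
            down = norm.rpm.loc[
                [(d, TagKind.DOWN.value) for d in pairs], sample
            ].to_numpy()
            vals = np.log2((up + pseudocount) / (down + pseudocount))
            self.values[sample] = np.sort(vals[np.isfinite(vals)])

    @property
    def active(self) -> bool:
        return self.n_decoys >= self.min_decoys

    def p_value(self, sample: str, x: float) -> float:
        """Two-sided empirical p of x against the decoy null for a sample."""
        vals = self.values[sample]
        n = len(vals)
        if n == 0:
            return 1.0
        le = np.searchsorted(vals, x, side="right")
        ge = n - np.searchsorted(vals, x, side="left")
        return min(1.0, 2.0 * min(le, ge) / n)

    def summary(self) -> dict:
        out = {"n_decoy_pairs": self.n_decoys, "active": self.active, "per_sample": {}}
        for sample, vals in self.values.items():
            if len(vals):
                out["per_sample"][sample] = {
                    "median": float(np.median(vals)),
                    "q01": float(np.quantile(vals, 0.01)),
                    "q99": float(np.quantile(vals, 0.99)),
                }
        return out


def decoy_outlier_filter(
    records: pd.DataFrame,
    norm: NormalizedMatrix,
    null: DecoyNull | None = None,
    alpha: float = DEFAULT_ALPHA,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> tuple[pd.DataFrame, DecoyNull | None]:
    """Mark clones whose UP/DOWN ratio is decoy-extreme in ANY sample.

    Modifies exclusion_reason to DECOY_OUTLIER for clones with empirical
    two-sided p < alpha in at least one indexed sample.  When fewer than
    MIN_DECOYS_FOR_NULL decoy pairs are available the filter is skipped
    with a logged warning.
    """
    if null is None:
        null = DecoyNull(norm, pseudocount=pseudocount)
    if not null.active:
        logger.warning(
            "decoy null inactive (%d pairs < %d): outlier filter skipped",
            null.n_decoys,
            null.min_decoys,
        )
        return records, null
    records = records.copy()
    for i, row in records.iterrows():
        if row["exclusion_reason"] != "none":
            continue
        sid = row["strain_id"]
        if (sid, TagKind.UP.value) not in norm.rpm.index or (
            sid,
            TagKind.DOWN.value,
        ) not in norm.rpm.index:
            continue
        for sample in norm.rpm.columns:
            up = norm.rpm.loc[(sid, TagKind.UP.value), sample]
            down = norm.rpm.loc[(sid, TagKind.DOWN.value), sample]
            if np.isnan(up) or np.isnan(down):
                continue
            x = np.log2((up + pseudocount) / (down + pseudocount))
            if null.p_value(sample, x) < alpha:
                records.loc[i, "exclusion_reason"] = "DECOY_OUTLIER"
                break
    return records, null


def filter_by_sd(records: pd.DataFrame, max_sd: float = DEFAULT_MAX_SD) -> pd.DataFrame:
    """Concordance filter: keep clones whose four ratios agree.

    included iff sample SD of the four ratios < max_sd, all four ratios
    finite, and no prior exclusion; otherwise the exclusion reason is set
    (first failing filter wins).
    """
    records = records.copy()
    for i, row in records.iterrows():
        if row["exclusion_reason"] != "none":
            records.loc[i, "included"] = False
            continue
        ratios = row[list(RATIO_COLUMNS)].to_numpy(dtype=float)
        if not np.isfinite(ratios).all():
            records.loc[i, "exclusion_reason"] = "MISSING_TAG"
            records.loc[i, "included"] = False
            continue
        if row["sd_ratio"] < max_sd:
            records.loc[i, "included"] = True
        else:
            records.loc[i, "exclusion_reason"] = "SD_FILTER"
            records.loc[i, "included"] = False
    return records


def control_separation(records: pd.DataFrame, catalog: Catalog) -> dict:
    """Separation of the constitutive controls, bounding the dynamic range.

    separated is True iff every T7-only control ratio exceeds every HA-only
    control ratio across all four (tag, timepoint) cells.
    """
    neg_ids = [e.strain_id for e in catalog.by_status(EntryStatus.CONTROL_HA)]
    pos_ids = [e.strain_id for e in catalog.by_status(EntryStatus.CONTROL_T7)]
    neg = records[records["strain_id"].isin(neg_ids)]
    pos = records[records["strain_id"].isin(pos_ids)]
    if neg.empty or pos.empty:
        warnings.warn("control strains missing; separation diagnostic skipped")
        return {"available": False}
    neg_vals = neg[list(RATIO_COLUMNS)].to_numpy(dtype=float).ravel()
    pos_vals = pos[list(RATIO_COLUMNS)].to_numpy(dtype=float).ravel()
    neg_vals = neg_vals[np.isfinite(neg_vals)]
    pos_vals = pos_vals[np.isfinite(pos_vals)]
    if len(neg_vals) == 0 or len(pos_vals) == 0:
        warnings.warn("control strains have no finite ratios; separation skipped")
        return {"available": False}
    neg_mean = float(neg_vals.mean())
    pos_mean = float(pos_vals.mean())
    return {
        "available": True,
        "neg_mean": neg_mean,
        "pos_mean": pos_mean,
        "dynamic_range": pos_mean / neg_mean if neg_mean > 0 else np.inf,
        "separated": bool(pos_vals.min() > neg_vals.max()),
    }


_CORR_PAIRS = {
    "up_t1_vs_down_t1": ("ratio_up_t1", "ratio_down_t1"),
    "up_t3_vs_down_t3": ("ratio_up_t3", "ratio_down_t3"),
    "up_t1_vs_up_t3": ("ratio_up_t1", "ratio_up_t3"),
    "down_t1_vs_down_t3": ("ratio_down_t1", "ratio_down_t3"),
}


def concordance_correlations(
    records: pd.DataFrame,
    included_only: bool = False,
    exclude_controls: bool = True,
) -> dict[str, float]:
    """Pearson r between tags and between timepoints, pairwise-complete.

    Control strains are excluded by default: their extreme ratios would
    dominate the correlation and mask clone-level concordance.  Pairs with
    fewer than 3 clones are reported as NaN.
    """
    df = records[records["included"]] if included_only else records
    if exclude_controls and "status" in df.columns:
        df = df[~df["status"].str.startswith("CONTROL")]
    out: dict[str, float] = {}
    for name, (a, b) in _CORR_PAIRS.items():
        sub = df[[a, b]].replace([np.inf, -np.inf], np.nan).dropna()
        if len(sub) < 3:
            out[name] = float("nan")
        else:
            out[name] = float(_st.pearsonr(sub[a], sub[b]).statistic)
    return out


def relative_to_reference(records: pd.DataFrame, reference_id: str) -> pd.Series:
    """Mean ratios rescaled so the reference clone equals 1."""
    ref = records[records["strain_id"] == reference_id]
    if ref.empty:
        raise KeyError(f"reference strain {reference_id!r} not in records")
    ref = ref.iloc[0]
    if not ref["included"]:
        raise ValueError(
            f"reference strain {reference_id!r} excluded "
            f"(reason: {ref['exclusion_reason']})"
        )
    return pd.Series(
        (records["mean_ratio"] / ref["mean_ratio"]).to_numpy(),
        index=records["strain_id"],
        name="relative_ratio",
    )


@dataclass
class ScreenResult:
    """Final per-clone records plus QC for one quantified screen."""

    records: pd.DataFrame
    decoy_records: pd.DataFrame
    qc: dict
    norm: NormalizedMatrix
    null: Optional[DecoyNull]

    def included(self) -> pd.DataFrame:
        return self.records[self.records["included"]]

    def exclusion_counts(self) -> dict[str, int]:
        return self.records["exclusion_reason"].value_counts().to_dict()

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.records.to_csv(out / "turnover.tsv", sep="\t", index=False)
        self.decoy_records.to_csv(out / "decoy_turnover.tsv", sep="\t", index=False)
        with open(out / "qc.json", "w") as fh:
            json.dump(self.qc, fh, indent=2, sort_keys=True, default=float)
            fh.write("\n")

    def summary(self) -> str:
        n = len(self.records)
        inc = int(self.records["included"].sum())
        lines = [
            f"clones: {n}, included: {inc}",
            "exclusions: "
            + ", ".join(f"{k}={v}" for k, v in sorted(self.exclusion_counts().items())),
        ]
        cs = self.qc.get("control_separation", {})
        if cs.get("available"):
            lines.append(
                f"controls: neg_mean={cs['neg_mean']:.4f} pos_mean={cs['pos_mean']:.2f} "
                f"dynamic_range={cs['dynamic_range']:.1f} separated={cs['separated']}"
            )
        corr = self.qc.get("concordance", {})
        if corr:
            lines.append(
                "concordance r: "
                + ", ".join(f"{k}={v:.3f}" for k, v in corr.items())
            )
        return "\n".join(lines)


def quantify_screen(
    counts: CountMatrix,
    sheet: SampleSheet,
    max_sd: float = DEFAULT_MAX_SD,
    alpha: float = DEFAULT_ALPHA,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    timepoints: Sequence[str] = ("t1", "t3"),
    min_decoys: int = MIN_DECOYS_FOR_NULL,
) -> ScreenResult:
    """Run the full quantification: RPM, ratios, filters, QC."""
    norm = normalize_rpm(counts)
    design = sheet.design(timepoints)
    records = compute_turnover(norm, design, timepoints, pseudocount)
    null = DecoyNull(norm, pseudocount=pseudocount, min_decoys=min_decoys)
    records, null = decoy_outlier_filter(
        records, norm, null, alpha=alpha, pseudocount=pseudocount
    )
    records = filter_by_sd(records, max_sd=max_sd)
    decoy_records = compute_turnover(
        norm, design, timepoints, pseudocount, include_decoys=True
    )
    decoy_records = decoy_records[
        decoy_records["status"] == EntryStatus.DECOY.value
    ].reset_index(drop=True)
    qc = {
        "control_separation": control_separation(records, counts.catalog),
        "concordance": concordance_correlations(records),
        "decoy_null": null.summary() if null is not None else {},
        "bin_totals": {
            f"{tag}:{sample}": int(counts.bin_totals().loc[tag, sample])
            for tag in counts.bin_totals().index
            for sample in counts.bin_totals().columns
        },
        "undefined_bins": [list(b) for b in norm.undefined_bins],
    }
    logger.info(
        "quantified %d clones: %d included", len(records), int(records["included"].sum())
    )
    return ScreenResult(
        records=records, decoy_records=decoy_records, qc=qc, norm=norm, null=null
    )
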