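"""RPM normalization, turnover ratios, decoy null and filters."""

import numpy as np
import pandas as pd
import pytest

import riteseq as rs
from riteseq import EntryStatus, TagKind
from riteseq.catalog import Antibody
from riteseq.counting import CountMatrix
from riteseq.quantify import (
    DecoyNull,
    RATIO_COLUMNS,
    compute_turnover,
    concordance_correlations,
    control_separation,
    decoy_outlier_filter,
    filter_by_sd,
    normalize_rpm,
    relative_to_reference,
)


def _cm(catalog, sheet, values):
    """CountMatrix from {(strain, tag, sample): count}."""
    cm = CountMatrix.empty(catalog, sheet)
    for (sid, tag, sample), n in values.items():
        cm.df.loc[(sid, tag), sample] = n
    return cm


@pytest.fixture()
def two_strain_catalog():
    e = []
    for i, sid in enumerate(["A", "B"]):
        e.append(rs.BarcodeEntry(sid, f"G{i}", TagKind.UP, "ACGT" * 4 + "AC" + "GT"[i] * 2))
        e.append(rs.BarcodeEntry(sid, f"G{i}", TagKind.DOWN, "TGCA" * 4 + "TG" + "CA"[i] * 2))
    return rs.Catalog(e)


class TestNormalizeRpm:
    def test_definition(self, two_strain_catalog, chip_sheet):
        cm = _cm(
            two_strain_catalog,
            chip_sheet,
            {("A", "UP", "HA_t1"): 50, ("B", "UP", "HA_t1"): 999_950},
        )
        norm = normalize_rpm(cm)
        assert norm.rpm.loc[("A", "UP"), "HA_t1"] == 50.0

    def test_arithmetic(self, two_strain_catalog, chip_sheet):
        cm = _cm(
            two_strain_catalog,
            chip_sheet,
            {("A", "UP", "HA_t1"): 5, ("B", "UP", "HA_t1"): 199_995},
        )
        assert normalize_rpm(cm).rpm.loc[("A", "UP"), "HA_t1"] == 25.0

    def test_zero_bin_flagged_undefined(self, two_strain_catalog, chip_sheet):
        cm = _cm(two_strain_catalog, chip_sheet, {("A", "UP", "HA_t1"): 10})
        norm = normalize_rpm(cm)
        assert ("DOWN", "HA_t1") in norm.undefined_bins
        assert np.isnan(norm.rpm.loc[("A", "DOWN"), "HA_t1"])

    def test_nonempty_bins_sum_to_one_million(self, two_strain_catalog, chip_sheet):
        rng = np.random.default_rng(0)
        vals = {
            (sid, tag, s): int(rng.integers(1, 1000))
            for sid in ("A", "B")
            for tag in ("UP", "DOWN")
            for s in chip_sheet.sample_ids
        }
        norm = normalize_rpm(_cm(two_strain_catalog, chip_sheet, vals))
        for tag in ("UP", "DOWN"):
            sums = norm.rpm.xs(tag, level="tag_kind").sum()
            assert np.allclose(sums, 1e6, rtol=1e-9)


def _ratio_counts(catalog, sheet, ratios_a):
    """Counts giving strain A the requested (tag, tp) T7/HA rpm ratios.

    Strain B absorbs the rest of each bin so bins have equal totals and
    pseudocount effects stay negligible at large counts.
    """
    scale = 1_000_000
    vals = {}
    for (tag, tp), r in ratios_a.items():
        ha, t7 = f"HA_{tp}", f"T7_{tp}"
        a_ha = scale
        a_t7 = int(round(r * scale))
        vals[("A", tag, ha)] = a_ha
        vals[("B", tag, ha)] = 10 * scale - a_ha
        vals[("A", tag, t7)] = a_t7
        vals[("B", tag, t7)] = 10 * scale - a_t7
    return _cm(catalog, sheet, vals)


class TestComputeTurnover:
    def test_symmetric_counts_give_unit_ratios(self, two_strain_catalog, chip_sheet):
        ratios = {(t, tp): 1.0 for t in ("UP", "DOWN") for tp in ("t1", "t3")}
        cm = _ratio_counts(two_strain_catalog, chip_sheet, ratios)
        rec = compute_turnover(normalize_rpm(cm), chip_sheet.design()).set_index("strain_id")
        for col in RATIO_COLUMNS:
            assert rec.loc["A", col] == pytest.approx(1.0, abs=1e-5)
        assert rec.loc["A", "sd_ratio"] == pytest.approx(0.0, abs=1e-5)

    def test_hand_computed_mean_and_sd(self, two_strain_catalog, chip_sheet):
        """Ratios 0.5, 0.5, 0.9, 0.9 -> mean 0.7, sample SD 0.23094."""
        ratios = {("UP", "t1"): 0.5, ("DOWN", "t1"): 0.5, ("UP", "t3"): 0.9, ("DOWN", "t3"): 0.9}
        cm = _ratio_counts(two_strain_catalog, chip_sheet, ratios)
        rec = compute_turnover(normalize_rpm(cm), chip_sheet.design()).set_index("strain_id")
        assert rec.loc["A", "mean_ratio"] == pytest.approx(0.7, abs=1e-4)
        assert rec.loc["A", "sd_ratio"] == pytest.approx(0.23094, abs=1e-4)

    def test_pseudocount_rescues_zero_denominator(self, two_strain_catalog, chip_sheet):
        # rpm_HA = 0, rpm_T7 = 99.5 -> (99.5+0.5)/(0+0.5) = 200
        vals = {}
        for tp in ("t1", "t3"):
            for tag in ("UP", "DOWN"):
                vals[("A", tag, f"T7_{tp}")] = 199
                vals[("B", tag, f"T7_{tp}")] = 2_000_000 - 199
                vals[("A", tag, f"HA_{tp}")] = 0
                vals[("B", tag, f"HA_{tp}")] = 2_000_000
        cm = _cm(two_strain_catalog, chip_sheet, vals)
        rec = compute_turnover(normalize_rpm(cm), chip_sheet.design()).set_index("strain_id")
        assert rec.loc["A", "ratio_up_t1"] == pytest.approx(200.0)
        assert bool(rec.loc["A", "zero_ha"])
        assert rec.loc["A", "exclusion_reason"] == "none"

    def test_unknown_sample_in_design_is_error(self, two_strain_catalog, chip_sheet):
        cm = _cm(two_strain_catalog, chip_sheet, {("A", "UP", "HA_t1"): 1})
        design = chip_sheet.design()
        design[(Antibody.HA, "t1")] = "nope"
        with pytest.raises(KeyError, match="nope"):
            compute_turnover(normalize_rpm(cm), design)

    def test_absent_tag_marks_missing(self, chip_sheet):
        cat = rs.Catalog(
            [
                rs.BarcodeEntry("A", "G", TagKind.UP, "ACGTACGTACGTACGT"),
                rs.BarcodeEntry("B", "G", TagKind.UP, "TTTTACGTACGTACGT"),
                rs.BarcodeEntry("B", "G", TagKind.DOWN, "TGCATGCATGCATGCA"),
            ]
        )
        vals = {
            (sid, tag, s): 100
            for sid, tags in [("A", ["UP"]), ("B", ["UP", "DOWN"])]
            for tag in tags
            for s in chip_sheet.sample_ids
        }
        rec = compute_turnover(
            normalize_rpm(_cm(cat, chip_sheet, vals)), chip_sheet.design()
        ).set_index("strain_id")
        assert rec.loc["A", "exclusion_reason"] == "MISSING_TAG"
        assert np.isnan(rec.loc["A", "ratio_down_t1"])
        assert rec.loc["B", "exclusion_reason"] == "none"


def _decoy_panel(n_decoys=50, clone_up=100, clone_down=100, up_zero_in=None):
    """Catalog + counts: decoy pairs with equal up/down counts (null tight
    at 0) and one clone with configurable up/down counts."""
    sheet = rs.SampleSheet(
        [
            rs.Sample("AACC", "HA_t1", Antibody.HA, "t1"),
            rs.Sample("AAGG", "T7_t1", Antibody.T7, "t1"),
            rs.Sample("CCAA", "HA_t3", Antibody.HA, "t3"),
            rs.Sample("CCTT", "T7_t3", Antibody.T7, "t3"),
        ]
    )
    rng = np.random.default_rng(11)
    entries = []

    def bc():
        return "".join("ACGT"[i] for i in rng.integers(0, 4, 20))

    entries.append(rs.BarcodeEntry("A", "G", TagKind.UP, bc()))
    entries.append(rs.BarcodeEntry("A", "G", TagKind.DOWN, bc()))
    for i in range(n_decoys):
        entries.append(rs.BarcodeEntry(f"d{i}", "-", TagKind.UP, bc(), EntryStatus.DECOY))
        entries.append(rs.BarcodeEntry(f"d{i}", "-", TagKind.DOWN, bc(), EntryStatus.DECOY))
    cat = rs.Catalog(entries)
    vals = {}
    for s in sheet.sample_ids:
        vals[("A", "UP", s)] = 0 if s == up_zero_in else clone_up
        vals[("A", "DOWN", s)] = clone_down
        for i in range(n_decoys):
            vals[(f"d{i}", "UP", s)] = 3
            vals[(f"d{i}", "DOWN", s)] = 3
    return cat, sheet, _cm(cat, sheet, vals)


class TestDecoyOutlierFilter:
    def test_clone_at_decoy_median_retained(self):
        cat, sheet, cm = _decoy_panel()
        norm = normalize_rpm(cm)
        rec = compute_turnover(norm, sheet.design())
        rec, null = decoy_outlier_filter(rec, norm)
        assert null.active and null.n_decoys == 50
        assert rec.set_index("strain_id").loc["A", "exclusion_reason"] == "none"

    def test_zero_up_clone_excluded_against_tight_null(self):
        # UP count 0 in one sample while DOWN stays at pool level
        cat, sheet, cm = _decoy_panel(up_zero_in="HA_t1")
        norm = normalize_rpm(cm)
        rec = compute_turnover(norm, sheet.design())
        rec, _ = decoy_outlier_filter(rec, norm)
        assert rec.set_index("strain_id").loc["A", "exclusion_reason"] == "DECOY_OUTLIER"

    def test_alpha_one_excludes_every_clone(self):
        cat, sheet, cm = _decoy_panel(clone_up=110, clone_down=90)
        norm = normalize_rpm(cm)
        rec = compute_turnover(norm, sheet.design())
        rec, _ = decoy_outlier_filter(rec, norm, alpha=1.0)
        assert (rec["exclusion_reason"] == "DECOY_OUTLIER").all()

    def test_too_few_decoys_skips_filter(self):
        cat, sheet, cm = _decoy_panel(n_decoys=10, up_zero_in="HA_t1")
        norm = normalize_rpm(cm)
        rec = compute_turnover(norm, sheet.design())
        rec, null = decoy_outlier_filter(rec, norm)
        assert not null.active
        assert rec.set_index("strain_id").loc["A", "exclusion_reason"] == "none"


def _records(rows):
    df = pd.DataFrame(rows)
    for col in ("included",):
        if col not in df:
            df[col] = False
    if "exclusion_reason" not in df:
        df["exclusion_reason"] = "none"
    if "status" not in df:
        df["status"] = "ACTIVE"
    ratios = df[list(RATIO_COLUMNS)].to_numpy(dtype=float)
    df["mean_ratio"] = np.nanmean(ratios, axis=1)
    df["sd_ratio"] = np.nanstd(ratios, axis=1, ddof=1)
    return df


class TestFilterBySd:
    def test_zero_sd_included(self):
        rec = _records([{"strain_id": "A", **{c: 0.4 for c in RATIO_COLUMNS}}])
        out = filter_by_sd(rec)
        assert bool(out.loc[0, "included"])

    def test_hand_computed_sd_excluded_at_default_threshold(self):
        rec = _records(
            [
                {
                    "strain_id": "A",
                    "ratio_up_t1": 0.5,
                    "ratio_down_t1": 0.5,
                    "ratio_up_t3": 0.9,
                    "ratio_down_t3": 0.9,
                }
            ]
        )
        out = filter_by_sd(rec)
        assert out.loc[0, "sd_ratio"] == pytest.approx(0.23094, abs=1e-5)
        assert not out.loc[0, "included"]
        assert out.loc[0, "exclusion_reason"] == "SD_FILTER"

    def test_missing_ratio_is_missing_tag_regardless_of_sd(self):
        rec = _records(
            [
                {
                    "strain_id": "A",
                    "ratio_up_t1": 0.5,
                    "ratio_down_t1": np.nan,
                    "ratio_up_t3": 0.5,
                    "ratio_down_t3": np.nan,
                }
            ]
        )
        out = filter_by_sd(rec)
        assert not out.loc[0, "included"]
        assert out.loc[0, "exclusion_reason"] == "MISSING_TAG"

    def test_prior_exclusion_wins(self):
        rec = _records([{"strain_id": "A", **{c: 0.4 for c in RATIO_COLUMNS}}])
        rec["exclusion_reason"] = "DECOY_OUTLIER"
        out = filter_by_sd(rec)
        assert not out.loc[0, "included"]
        assert out.loc[0, "exclusion_reason"] == "DECOY_OUTLIER"

    def test_huge_threshold_keeps_everything_finite(self):
        rec = _records(
            [
                {"strain_id": "A", **{c: v for c, v in zip(RATIO_COLUMNS, [0.1, 2.0, 0.4, 1.5])}}
            ]
        )
        out = filter_by_sd(rec, max_sd=1e9)
        assert bool(out.loc[0, "included"])


class TestControlSeparation:
    def _cat(self):
        return rs.Catalog(
            [
                rs.BarcodeEntry("nha", "CTRL-HA", TagKind.UP, "ACGTACGTACGTACGT", EntryStatus.CONTROL_HA),
                rs.BarcodeEntry("pt7", "CTRL-T7", TagKind.UP, "TTGGACGTACGTACGT", EntryStatus.CONTROL_T7),
                rs.BarcodeEntry("A", "G", TagKind.UP, "GGCCACGTACGTACGT"),
            ]
        )

    def test_clean_separation(self):
        rec = _records(
            [
                {"strain_id": "nha", "status": "CONTROL_HA", **{c: 0.01 for c in RATIO_COLUMNS}},
                {"strain_id": "pt7", "status": "CONTROL_T7", **{c: 50.0 for c in RATIO_COLUMNS}},
                {"strain_id": "A", **{c: 0.5 for c in RATIO_COLUMNS}},
            ]
        )
        out = control_separation(rec, self._cat())
        assert out["separated"] is True
        assert out["dynamic_range"] == pytest.approx(5000.0)

    def test_identical_controls_not_separated(self):
        rec = _records(
            [
                {"strain_id": "nha", "status": "CONTROL_HA", **{c: 1.0 for c in RATIO_COLUMNS}},
                {"strain_id": "pt7", "status": "CONTROL_T7", **{c: 1.0 for c in RATIO_COLUMNS}},
            ]
        )
        out = control_separation(rec, self._cat())
        assert out["separated"] is False
        assert out["dynamic_range"] == pytest.approx(1.0)

    def test_missing_controls_skipped_with_warning(self):
        rec = _records([{"strain_id": "A", **{c: 0.5 for c in RATIO_COLUMNS}}])
        with pytest.warns(UserWarning):
            out = control_separation(
                rec, rs.Catalog([rs.BarcodeEntry("A", "G", TagKind.UP, "ACGTACGTACGT")])
            )
        assert out == {"available": False}


class TestConcordance:
    def test_identical_vectors_r_one(self):
        rows = [
            {"strain_id": f"s{i}", **{c: v for c in RATIO_COLUMNS}}
            for i, v in enumerate([0.1, 0.5, 0.9, 1.3])
        ]
        out = concordance_correlations(_records(rows))
        for v in out.values():
            assert v == pytest.approx(1.0)

    def test_reversed_vectors_r_minus_one(self):
        up = [1.0, 2.0, 3.0]
        down = [3.0, 2.0, 1.0]
        rows = [
            {
                "strain_id": f"s{i}",
                "ratio_up_t1": u,
                "ratio_down_t1": d,
                "ratio_up_t3": u,
                "ratio_down_t3": d,
            }
            for i, (u, d) in enumerate(zip(up, down))
        ]
        out = concordance_correlations(_records(rows))
        assert out["up_t1_vs_down_t1"] == pytest.approx(-1.0)
        assert out["up_t1_vs_up_t3"] == pytest.approx(1.0)

    def test_fewer_than_three_clones_is_nan(self):
        rows = [{"strain_id": "a", **{c: 0.5 for c in RATIO_COLUMNS}}]
        out = concordance_correlations(_records(rows))
        assert all(np.isnan(v) for v in out.values())


class TestRelativeToReference:
    def _rec(self):
        rec = _records(
            [
                {"strain_id": "wt", **{c: 1.2 for c in RATIO_COLUMNS}},
                {"strain_id": "m1", **{c: 0.6 for c in RATIO_COLUMNS}},
                {"strain_id": "m2", **{c: 1.2 for c in RATIO_COLUMNS}},
            ]
        )
        rec["included"] = True
        return rec

    def test_reference_itself_is_one(self):
        out = relative_to_reference(self._rec(), "wt")
        assert out["wt"] == pytest.approx(1.0)

    def test_half_ratio(self):
        out = relative_to_reference(self._rec(), "wt")
        assert out["m1"] == pytest.approx(0.5)
        assert out["m2"] == pytest.approx(1.0)

    def test_excluded_reference_raises_with_reason(self):
        rec = self._rec()
        rec.loc[rec["strain_id"] == "wt", "included"] = False
        rec.loc[rec["strain_id"] == "wt", "exclusion_reason"] = "SD_FILTER"
        with pytest.raises(ValueError, match="SD_FILTER"):
            relative_to_reference(rec, "wt")
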