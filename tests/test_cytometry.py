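"""Per-cell measurement, positivity thresholds, and both classification
schemes, including the exhaustive rule truth tables."""

import itertools

import numpy as np
import pandas as pd
import pytest

from wsicyto.cytometry import (EPITHELIAL_LABELS, IMMUNE_LABELS,
                               CytometryError, PanelConfig,
                               assign_compartment, call_positives,
                               classify_glands_and_epithelial,
                               classify_immune, measure_cells,
                               positivity_threshold, summarize_panel)


class TestMeasureCells:
    def test_uniform_object_mean_and_normalization(self):
        nuclei = np.zeros((20, 20), dtype=np.int32)
        nuclei[5:15, 5:15] = 1
        chan = np.zeros((20, 20), dtype=np.uint8)
        chan[nuclei == 1] = 100
        cells = measure_cells(nuclei, {"cd4": chan})
        assert cells.cd4_raw.iloc[0] == pytest.approx(100.0)
        assert cells.cd4_norm.iloc[0] == pytest.approx(100.0 / 255.0)

    def test_mean_radius_is_equivalent_circle_radius(self):
        nuclei = np.zeros((20, 20), dtype=np.int32)
        nuclei.flat[:100] = 1  # area exactly 100 px
        cells = measure_cells(nuclei, {})
        assert cells.mean_radius_px.iloc[0] == pytest.approx(
            np.sqrt(100 / np.pi), abs=1e-9)

    def test_empty_mask_gives_empty_table(self):
        cells = measure_cells(np.zeros((10, 10), dtype=np.int32),
                              {"cd4": np.zeros((10, 10), np.uint8)})
        assert len(cells) == 0

    def test_gland_membership_from_centroid(self):
        nuclei = np.zeros((30, 30), dtype=np.int32)
        nuclei[2:8, 2:8] = 1
        nuclei[20:26, 20:26] = 2
        glands = np.zeros((30, 30), dtype=np.int32)
        glands[15:30, 15:30] = 7
        cells = measure_cells(nuclei, {}, glands=glands)
        assert list(cells.gland_id) == [0, 7]

    def test_mask_overlap_fraction(self):
        nuclei = np.zeros((10, 10), dtype=np.int32)
        nuclei[0:4, 0:4] = 1  # 16 px
        mask = np.zeros((10, 10), dtype=bool)
        mask[0:2, 0:4] = True  # covers half the nucleus
        cells = measure_cells(nuclei, {}, masks={"cd45": mask})
        assert cells.cd45_overlap.iloc[0] == pytest.approx(0.5)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(CytometryError):
            measure_cells(np.ones((5, 5), dtype=np.int32),
                          {"cd4": np.zeros((6, 5), np.uint8)})


class TestPositivity:
    def test_equal_values_yield_no_positives(self):
        vals = np.full(50, 0.3)
        thr = positivity_threshold(vals, k=1.0)
        assert thr == pytest.approx(0.3)
        assert not (vals > thr).any()  # strict inequality

    def test_nine_zeros_and_a_one(self):
        vals = np.array([0.0] * 9 + [1.0])
        thr = positivity_threshold(vals, k=1.0)
        assert thr == pytest.approx(0.4)  # mean 0.1 + population SD 0.3
        assert (vals > thr).sum() == 1

    def test_ki67_defaults_to_three_sd(self):
        panel = PanelConfig(scheme="immune")
        assert panel.sd_multipliers["ki67"] == 3.0
        assert panel.sd_multipliers["cd4"] == 1.0

    def test_threshold_commutes_with_raw_normalized_rescaling(self, rng):
        raw = rng.uniform(0, 255, 200)
        cells = pd.DataFrame({"m_raw": raw, "m_norm": raw / 255.0})
        pos_raw = call_positives(cells, ["m"], suffix="_raw")["m_positive"]
        pos_norm = call_positives(cells, ["m"], suffix="_norm")["m_positive"]
        assert pos_raw.equals(pos_norm)

    def test_empty_input_rejected(self):
        with pytest.raises(CytometryError):
            positivity_threshold([])


def _immune_cells(rows):
    df = pd.DataFrame(rows)
    df["gland_id"] = df.pop("in_gland").astype(int)  # 1 = inside a gland
    return df


class TestImmuneRuleTable:
    @staticmethod
    def expected_label(cd45, cd4, cd8, foxp3, in_gland):
        """Independent restatement of the published immune decision rules."""
        comp = "epithelial" if in_gland else "stromal"
        if not cd45:
            return "epithelial_cell" if in_gland else "other"
        if cd4 and foxp3 and not cd8:
            return f"{comp}_treg"
        if cd4 and not foxp3 and not cd8:
            return f"{comp}_th"
        if cd8 and not cd4 and not foxp3:
            return f"{comp}_te"
        return f"{comp}_leukocyte_other"

    def test_every_marker_combination_maps_to_documented_label(self):
        rows, expected = [], []
        for cd45, cd4, cd8, foxp3, in_gland in itertools.product(
                [False, True], repeat=5):
            rows.append({
                "cd45_overlap": 0.5 if cd45 else 0.0,
                "cd4_positive": cd4, "cd8_positive": cd8,
                "foxp3_positive": foxp3, "in_gland": in_gland,
            })
            expected.append(self.expected_label(cd45, cd4, cd8, foxp3,
                                                in_gland))
        out = classify_immune(_immune_cells(rows))
        assert list(out.class_label) == expected
        # partition property: one label each, drawn from the closed set
        assert out.class_label.isin(IMMUNE_LABELS).all()

    def test_cd45_overlap_below_ten_percent_is_not_a_leukocyte(self):
        rows = [{"cd45_overlap": 0.09, "cd4_positive": True,
                 "cd8_positive": False, "foxp3_positive": False,
                 "in_gland": True},
                {"cd45_overlap": 0.10, "cd4_positive": True,
                 "cd8_positive": False, "foxp3_positive": False,
                 "in_gland": True}]
        out = classify_immune(_immune_cells(rows))
        assert list(out.class_label) == ["epithelial_cell", "epithelial_th"]

    def test_double_positive_cd4_cd8_is_leukocyte_other(self):
        rows = [{"cd45_overlap": 1.0, "cd4_positive": True,
                 "cd8_positive": True, "foxp3_positive": False,
                 "in_gland": False}]
        out = classify_immune(_immune_cells(rows))
        assert out.class_label.iloc[0] == "stromal_leukocyte_other"


class TestEpithelialRules:
    def _cells(self, rows):
        return pd.DataFrame(rows)

    def test_gland_with_basal_cell_is_benign(self):
        cells = self._cells([
            {"gland_id": 1, "ck5p63_overlap": 0.5},   # basal
            {"gland_id": 1, "ck5p63_overlap": 0.0},   # luminal
            {"gland_id": 2, "ck5p63_overlap": 0.0},   # cancer gland
            {"gland_id": 0, "ck5p63_overlap": 0.9},   # stroma despite overlap
        ])
        glands, out = classify_glands_and_epithelial(cells)
        assert list(out.class_label) == ["basal", "benign_luminal", "cancer",
                                         "stromal"]
        g = glands.set_index("gland_id")
        assert not g.loc[1, "malignant"] and g.loc[1, "n_basal_cells"] == 1
        assert g.loc[2, "malignant"] and g.loc[2, "n_basal_cells"] == 0

    def test_nine_percent_overlap_is_below_the_minimum(self):
        cells = self._cells([
            {"gland_id": 1, "ck5p63_overlap": 0.10},
            {"gland_id": 1, "ck5p63_overlap": 0.09},
        ])
        glands, out = classify_glands_and_epithelial(cells)
        assert list(out.class_label) == ["basal", "benign_luminal"]

    def test_malignant_implies_zero_basal_everywhere(self, rng):
        cells = self._cells([
            {"gland_id": int(g), "ck5p63_overlap": float(o)}
            for g, o in zip(rng.integers(0, 6, 200), rng.random(200))])
        glands, out = classify_glands_and_epithelial(cells)
        assert (~glands.malignant | (glands.n_basal_cells == 0)).all()
        assert out.class_label.isin(EPITHELIAL_LABELS).all()

    def test_required_markers_enforced(self):
        with pytest.raises(CytometryError):
            PanelConfig(scheme="epithelial",
                        marker_channels={"pan_epi": "pan_epi"})
        with pytest.raises(CytometryError):
            PanelConfig(scheme="immune", marker_channels={"cd45": "cd45"})


class TestSummaries:
    def _ten_cell_table(self):
        # 4 epithelial cells, 2 stromal ("other"), 4 leukocytes:
        # 2 epithelial Th + 2 stromal Te
        rows = []
        for _ in range(4):
            rows.append({"class_label": "epithelial_cell",
                         "cell_class": "epithelial_cell",
                         "compartment": "epithelial", "ki67_positive": False})
        for _ in range(2):
            rows.append({"class_label": "other", "cell_class": "other",
                         "compartment": "stromal", "ki67_positive": False})
        for _ in range(2):
            rows.append({"class_label": "epithelial_th", "cell_class": "th",
                         "compartment": "epithelial", "ki67_positive": True})
        for _ in range(2):
            rows.append({"class_label": "stromal_te", "cell_class": "te",
                         "compartment": "stromal", "ki67_positive": False})
        return pd.DataFrame(rows)

    def test_hand_built_ten_cell_example(self):
        tables = summarize_panel(self._ten_cell_table(), "immune")
        dist = tables["class_distribution"].set_index("class_label")
        leuk_pct = dist.loc[["epithelial_th", "stromal_te"],
                            "percent_of_cells"].sum()
        assert leuk_pct == pytest.approx(40.0)
        t = tables["t_cells"]
        th = t[(t.t_class == "th") & (t.compartment == "epithelial")]
        assert th.percent_of_leukocytes.iloc[0] == pytest.approx(50.0)
        assert th.ki67_positive_percent.iloc[0] == pytest.approx(100.0)
        share = tables["leukocyte_compartments"].set_index("compartment")
        assert share.loc["epithelial",
                         "percent_of_leukocytes"] == pytest.approx(50.0)

    def test_empty_table_gives_zero_filled_summary(self):
        tables = summarize_panel(pd.DataFrame(columns=["class_label"]),
                                 "immune")
        assert (tables["class_distribution"].percent_of_cells == 0).all()
        assert (tables["t_cells"].n_cells == 0).all()

    def test_epithelial_marker_means_and_ar_stratification(self):
        cells = pd.DataFrame({
            "class_label": ["cancer", "cancer", "benign_luminal", "stromal"],
            "cell_class": ["cancer", "cancer", "benign_luminal", "stromal"],
            "compartment": ["epithelial"] * 3 + ["stromal"],
            "ar_norm": [0.3, 0.1, 0.2, 0.05],
            "ck18_norm": [0.2, 0.2, 0.1, 0.02],
            "amacr_positive": [True, False, False, False],
        })
        tables = summarize_panel(cells, "epithelial")
        expr = tables["marker_expression"].set_index("class_label")
        assert expr.loc["cancer", "ck18_norm_mean"] == pytest.approx(0.2)
        ar = tables["ar_by_amacr"].set_index("group")
        assert ar.loc["cancer_amacr_pos", "ar_norm_mean"] == pytest.approx(0.3)
        assert ar.loc["cancer_amacr_neg", "ar_norm_mean"] == pytest.approx(0.1)


def test_compartment_follows_gland_membership():
    cells = pd.DataFrame({"gland_id": [0, 3, 1, 0]})
    comp = assign_compartment(cells)
    assert list(comp) == ["stromal", "epithelial", "epithelial", "stromal"]
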