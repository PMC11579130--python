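"""Overlap metrics, boundary distances, thickness, anchors, rank-sum test."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from laminaseg import (
    AnchorPair,
    BoundaryPointSet,
    LayerMask,
    MetricsConfig,
    RegionOverlay,
    acceptable_range,
    anchor_error,
    boundary_points,
    compare_pipelines,
    distance_metrics,
    evaluate,
    layer_thickness,
    overlap_metrics,
    perturb_mask,
)

CFG = MetricsConfig()


def _mask(labels, spacing=1.0):
    return LayerMask(np.asarray(labels, dtype=np.uint8), spacing)


def _band_mask(heights=(4, 4, 4, 4, 4, 4), width=24, top=2, spacing=1.0):
    h = top * 2 + sum(heights)
    labels = np.zeros((h, width), dtype=np.uint8)
    row = top
    for k, bh in enumerate(heights, start=1):
        labels[row : row + bh, :] = k
        row += bh
    return _mask(labels, spacing)


class TestOverlapMetrics:
    def test_identity_scores_one_everywhere(self):
        y = _band_mask()
        res = overlap_metrics(y, y, CFG)
        for k in range(1, 7):
            for m in ("iou", "dsc", "recall", "precision"):
                assert res["per_class"][k][m] == 1.0
        assert res["means"]["iou"] == 1.0

    def test_disjoint_regions_smoothed_dice(self):
        # two disjoint 10-pixel regions: IoU 0, DSC (2*0+1)/(10+10+1) = 1/21
        y = np.zeros((5, 10), dtype=np.uint8)
        y[0, :] = 1
        p = np.zeros((5, 10), dtype=np.uint8)
        p[2, :] = 1
        res = overlap_metrics(_mask(y), _mask(p), CFG)
        cls = res["per_class"][1]
        assert cls["iou"] == 0.0
        assert cls["dsc"] == pytest.approx(1 / 21)
        assert cls["recall"] == 0.0 and cls["precision"] == 0.0

    def test_false_positives_halve_precision(self):
        # 4-px true region plus 4 extra predicted px: IoU 4/8, DSC 9/13
        y = np.zeros((4, 4), dtype=np.uint8)
        y[0, :] = 1
        p = y.copy()
        p[1, :] = 1
        res = overlap_metrics(_mask(y), _mask(p), CFG)["per_class"][1]
        assert res["iou"] == pytest.approx(0.5)
        assert res["recall"] == 1.0
        assert res["precision"] == pytest.approx(0.5)
        assert res["dsc"] == pytest.approx(9 / 13)

    def test_class_absent_from_both_is_flagged_and_excluded(self):
        y = np.zeros((4, 4), dtype=np.uint8)
        y[0, 0] = 1
        res = overlap_metrics(_mask(y), _mask(y), CFG)
        assert res["per_class"][3]["absent"]
        assert res["means"]["iou"] == 1.0  # mean over classes present in y only

    def test_unsmoothed_dice_iou_identity(self):
        """DSC = 2*IoU/(1+IoU) holds exactly without smoothing."""
        rng = np.random.default_rng(5)
        cfg = MetricsConfig(smoothing=False)
        from tests.conftest import random_blob_mask

        for _ in range(5):
            y = _mask(random_blob_mask(rng))
            p = _mask(random_blob_mask(rng))
            res = overlap_metrics(y, p, cfg)
            for k in range(1, 7):
                cls = res["per_class"][k]
                if cls["absent"]:
                    continue
                assert cls["dsc"] == pytest.approx(2 * cls["iou"] / (1 + cls["iou"]))

    def test_smoothing_gap_shrinks_with_region_size(self):
        for n in (10, 100, 1000):
            y = np.zeros((1, 2 * n), dtype=np.uint8)
            y[0, :n] = 1
            res_s = overlap_metrics(_mask(y), _mask(y), MetricsConfig(smoothing=True))
            res_u = overlap_metrics(_mask(y), _mask(y), MetricsConfig(smoothing=False))
            gap = abs(res_s["per_class"][1]["dsc"] - res_u["per_class"][1]["dsc"])
            assert gap < 1 / (2 * n + 1)


class TestBoundaryPoints:
    def test_single_pixel_region_is_its_own_boundary(self):
        labels = np.zeros((5, 5), dtype=np.uint8)
        labels[2, 2] = 1
        pts = boundary_points(_mask(labels), 1, CFG)
        assert pts.points.tolist() == [[2, 2]]

    def test_filled_square_keeps_perimeter_only(self):
        labels = np.zeros((5, 5), dtype=np.uint8)
        labels[1:4, 1:4] = 2
        pts = boundary_points(_mask(labels), 2, CFG)
        assert len(pts) == 8
        assert [2, 2] not in pts.points.tolist()

    def test_full_canvas_region_boundary_is_the_canvas_edge(self):
        labels = np.ones((4, 6), dtype=np.uint8)
        pts = boundary_points(_mask(labels), 1, CFG)
        expected = {(r, c) for r in range(4) for c in range(6)
                    if r in (0, 3) or c in (0, 5)}
        assert {tuple(p) for p in pts.points.tolist()} == expected

    def test_absent_layer_raises_naming_it(self):
        with pytest.raises(ValueError, match="layer 4"):
            boundary_points(_mask(np.zeros((3, 3), dtype=np.uint8)), 4, CFG)


class TestDistanceMetrics:
    def test_identical_sets_are_all_zero(self):
        a = BoundaryPointSet(np.array([[0, 0], [3, 4], [7, 1]]), 1.0)
        d = distance_metrics(a, a, CFG)
        assert all(v == 0 for v in d.values())

    def test_three_four_five_triangle(self):
        a = BoundaryPointSet(np.array([[0, 0]]), 1.0)
        b = BoundaryPointSet(np.array([[3, 4]]), 1.0)
        d = distance_metrics(a, b, CFG)
        for key in ("hd_um", "ahd_um", "hd95_um", "assd_um"):
            assert d[key] == pytest.approx(5.0)

    def test_asymmetric_pair_enumeration(self):
        # directed A->B {0, 10}, B->A {0}: HD 10, AHD (5+0)/2, ASSD 10/3
        a = BoundaryPointSet(np.array([[0, 0], [0, 10]]), 1.0)
        b = BoundaryPointSet(np.array([[0, 0]]), 1.0)
        d = distance_metrics(a, b, CFG)
        assert d["hd_um"] == pytest.approx(10.0)
        assert d["ahd_um"] == pytest.approx(2.5)
        assert d["ahd_ab_um"] == pytest.approx(5.0)
        assert d["ahd_ba_um"] == pytest.approx(0.0)
        assert d["assd_um"] == pytest.approx(10 / 3)

    def test_distances_scale_linearly_with_spacing(self):
        a = BoundaryPointSet(np.array([[0, 0], [0, 10]]), 9.2)
        b = BoundaryPointSet(np.array([[0, 0]]), 9.2)
        d = distance_metrics(a, b, CFG)
        assert d["hd_um"] == pytest.approx(92.0)
        assert d["assd_um"] == pytest.approx(9.2 * 10 / 3)

    def test_empty_set_is_an_error(self):
        a = BoundaryPointSet(np.zeros((0, 2)), 1.0)
        b = BoundaryPointSet(np.array([[0, 0]]), 1.0)
        with pytest.raises(ValueError):
            distance_metrics(a, b, CFG)

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_symmetry_and_ordering_invariants(self, seed):
        """ASSD symmetric; HD95 <= HD; AHD <= HD; percentile 100 -> HD."""
        rng = np.random.default_rng(seed)
        a = BoundaryPointSet(rng.integers(0, 30, size=(rng.integers(1, 40), 2)), 1.0)
        b = BoundaryPointSet(rng.integers(0, 30, size=(rng.integers(1, 40), 2)), 1.0)
        d_ab = distance_metrics(a, b, CFG)
        d_ba = distance_metrics(b, a, CFG)
        assert d_ab["assd_um"] == pytest.approx(d_ba["assd_um"])
        assert d_ab["hd95_um"] <= d_ab["hd_um"] + 1e-12
        assert d_ab["ahd_um"] <= d_ab["hd_um"] + 1e-12
        d100 = distance_metrics(a, b, MetricsConfig(percentile=100))
        assert d100["hd95_um"] == pytest.approx(d_ab["hd_um"])

    def test_agrees_with_bruteforce_on_random_masks(self):
        """KD-tree implementation vs O(|A||B|) pairwise enumeration."""
        from tests.conftest import random_blob_mask

        rng = np.random.default_rng(17)
        for _ in range(5):
            labels = random_blob_mask(rng, shape=(32, 32))
            present = [k for k in range(1, 7) if (labels == k).any()]
            a = boundary_points(_mask(labels), present[0], CFG)
            b = boundary_points(_mask(labels), present[-1], CFG)
            d = distance_metrics(a, b, CFG)
            brute = _bruteforce_distances(a.points, b.points, 1.0)
            for key, val in brute.items():
                assert d[key] == pytest.approx(val, abs=1e-9)


def _bruteforce_distances(a: np.ndarray, b: np.ndarray, spacing: float) -> dict:
    """Independent O(|A| |B|) oracle for the Hausdorff-family metrics."""
    dab = np.array([min(np.hypot(p[0] - q[0], p[1] - q[1]) for q in b) for p in a])
    dba = np.array([min(np.hypot(q[0] - p[0], q[1] - p[1]) for p in a) for q in b])
    return {
        "hd_um": spacing * max(dab.max(), dba.max()),
        "ahd_um": spacing * (dab.mean() + dba.mean()) / 2,
        "hd95_um": spacing * max(np.percentile(dab, 95), np.percentile(dba, 95)),
        "assd_um": spacing * (dab.sum() + dba.sum()) / (len(dab) + len(dba)),
    }


class TestLayerThickness:
    @pytest.mark.parametrize("height", [1, 3, 10])
    def test_horizontal_band_measures_its_height(self, height):
        labels = np.zeros((height + 4, 12), dtype=np.uint8)
        labels[2 : 2 + height, :] = 1
        labels[2 + height, :] = 2  # give layer 1 a lower neighbor
        t = layer_thickness(_mask(labels, spacing=2.0), 1)
        assert t == pytest.approx(height * 2.0)

    def test_phantom_truth_recovers_configured_thickness(self, train_phantom):
        from laminaseg import PhantomConfig

        cfg = PhantomConfig()
        for k in range(1, 7):
            t = layer_thickness(train_phantom.truth, k)
            assert abs(t - cfg.layer_thickness_um[k - 1]) <= cfg.spacing_um

    def test_degenerate_layer_raises(self):
        labels = np.zeros((5, 5), dtype=np.uint8)
        labels[2, 2] = 3  # island with no layer-2 or layer-4 contact
        with pytest.raises(ValueError, match="contour"):
            layer_thickness(_mask(labels), 3)


class TestEvaluate:
    def test_perfect_prediction(self, train_phantom):
        rep = evaluate(train_phantom.truth, train_phantom.truth)
        assert rep.means["iou"] == 1.0
        assert rep.per_layer["hd95_um"].max() == 0.0

    def test_translation_invariance(self):
        y = _band_mask()
        rolled = _mask(np.roll(np.roll(y.labels, 1, axis=0), 2, axis=1))
        y2 = _mask(np.roll(np.roll(y.labels, 1, axis=0), 2, axis=1))
        rep_a = evaluate(y, y)
        rep_b = evaluate(rolled, y2)
        assert rep_a.means["iou"] == rep_b.means["iou"] == 1.0

    def test_perturbed_mask_bounds_hd95(self, train_phantom):
        pred = perturb_mask(train_phantom.truth, 2, seed=3)
        rep = evaluate(train_phantom.truth, pred)
        bound = 2 * np.sqrt(2) * train_phantom.truth.spacing_um
        assert rep.per_layer["hd95_um"].max() <= bound + 1e-9
        assert rep.means["iou"] < 1.0

    def test_region_rows_match_cropped_recomputation(self, train_phantom):
        """Per-region metrics equal metrics of the region-masked sub-problem."""
        truth = train_phantom.truth
        pred = perturb_mask(truth, 2, seed=8)
        h, w = truth.shape
        ids = np.zeros((h, w), dtype=np.int64)
        ids[:, : w // 2] = 3
        ids[:, w // 2 :] = 5
        overlay = RegionOverlay(ids, truth.spacing_um)
        rep = evaluate(truth, pred, regions=overlay)
        # manual crop oracle for region id 3
        ymask = _mask(np.where(ids == 3, truth.labels, 0), truth.spacing_um)
        pmask = _mask(np.where(ids == 3, pred.labels, 0), truth.spacing_um)
        sub = evaluate(ymask, pmask)
        assert rep.per_region.loc["3", "iou"] == pytest.approx(
            sub.per_layer["iou"].mean()
        )

    def test_missing_layer_reported_absent_not_fatal(self):
        y = _band_mask()
        pred_labels = np.asarray(y.labels).copy()
        pred_labels[pred_labels == 4] = 3  # prediction never emits layer 4
        rep = evaluate(y, _mask(pred_labels))
        assert np.isnan(rep.per_layer.loc[4, "hd95_um"])
        assert rep.per_layer.loc[4, "iou"] == 0.0


class TestAnchorsAndRankSum:
    def test_zero_shift_anchors(self):
        pairs = [AnchorPair((1, 2), (1, 2), 9.2), AnchorPair((5, 5), (5, 5), 9.2)]
        assert anchor_error(pairs) == (0.0, 0.0)

    def test_single_pair_sd_is_zero(self):
        mean, sd = anchor_error([AnchorPair((0, 0), (3, 4), 1.0)])
        assert (mean, sd) == (5.0, 0.0)

    def test_two_pair_mean_and_sample_sd(self):
        pairs = [AnchorPair((0, 0), (3, 0), 1.0), AnchorPair((0, 0), (0, 5), 1.0)]
        mean, sd = anchor_error(pairs)
        assert mean == pytest.approx(4.0)
        assert sd == pytest.approx(np.sqrt(2))

    def test_acceptable_range_boundary_is_inclusive(self):
        assert acceptable_range(0.0, 1800.630)
        assert acceptable_range(1800.630, 1800.630)
        assert not acceptable_range(1800.631, 1800.630)

    def test_measured_mapping_error_is_within_default_range(self):
        # the workflow's own verdict for its measured registration error
        assert acceptable_range(1274.750)
        # under the stricter halved reading it would not be
        assert not acceptable_range(1274.750, halved=False)

    def test_identical_samples_give_p_one(self):
        res = compare_pipelines([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == pytest.approx(1.0)

    def test_fully_separated_samples_exact_p(self):
        res = compare_pipelines([1, 2, 3], [4, 5, 6])
        assert res.u == 0.0
        assert res.p_value == pytest.approx(0.1)
        assert res.method == "exact"

    def test_symmetric_in_group_order(self):
        a, b = [1.0, 2.5, 3.5, 7.0], [2.0, 4.0, 6.0, 8.0]
        assert compare_pipelines(a, b).p_value == pytest.approx(
            compare_pipelines(b, a).p_value
        )

    def test_small_groups_are_rejected(self):
        with pytest.raises(ValueError):
            compare_pipelines([1, 2], [3, 4, 5])
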