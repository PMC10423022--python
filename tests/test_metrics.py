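import numpy as np
import pytest
from scipy import ndimage

from phdseg import (
    BinaryMask,
    METRIC_DIRECTIONS,
    betti_error,
    betti_numbers,
    cldice,
    confusion_metrics,
    distance_metrics,
    evaluate_metric,
    generate_phantom,
    perturb,
    region_metrics,
    with_skeletonization,
)
from phdseg.metrics import full_report


def mask(arr):
    return BinaryMask(np.asarray(arr, np.uint8))


class TestConfusionMetrics:
    def test_perfect_prediction(self, phantom):
        rep = confusion_metrics(phantom.gt, phantom.gt)
        assert rep["f1"] == 1.0 and rep["iou"] == 1.0 and rep["rvd"] == 0.0

    def test_disjoint_masks(self):
        a = np.zeros((4, 4)); a[0, 0] = 1
        b = np.zeros((4, 4)); b[3, 3] = 1
        rep = confusion_metrics(mask(a), mask(b))
        assert rep["f1"] == 0.0 and rep["iou"] == 0.0

    def test_counts_fixture(self):
        # TP=2, FP=1, FN=1 by construction on a 4x4 frame
        gt = np.zeros((4, 4)); gt[0, 0] = gt[0, 1] = gt[0, 2] = 1
        pred = np.zeros((4, 4)); pred[0, 0] = pred[0, 1] = pred[1, 0] = 1
        rep = confusion_metrics(mask(pred), mask(gt))
        assert rep["f1"] == pytest.approx(2 / 3)
        assert rep["iou"] == pytest.approx(1 / 2)
        assert rep["rvd"] == pytest.approx(0.0)  # equal foreground counts
        assert rep["tpvf"] == pytest.approx(2 / 3)

    def test_signed_vs_absolute_rvd(self):
        gt = np.zeros((4, 4)); gt[0, :2] = 1
        pred = np.zeros((4, 4)); pred[0, 0] = 1
        assert confusion_metrics(mask(pred), mask(gt))["rvd"] == pytest.approx(-0.5)
        assert confusion_metrics(mask(pred), mask(gt), signed_rvd=False)["rvd"] == pytest.approx(0.5)

    def test_shape_mismatch_and_empty_gt(self):
        with pytest.raises(ValueError):
            confusion_metrics(mask(np.zeros((2, 2))), mask(np.zeros((3, 3))))
        with pytest.raises(ValueError):
            confusion_metrics(mask(np.ones((2, 2))), mask(np.zeros((2, 2))))


class TestDistanceMetrics:
    def test_perfect_prediction(self, phantom):
        rep = distance_metrics(phantom.gt, phantom.gt)
        assert rep["hd"] == 0.0 and rep["assd"] == 0.0

    def test_single_pixel_pair(self):
        a = np.zeros((8, 8)); a[0, 0] = 1
        b = np.zeros((8, 8)); b[3, 4] = 1
        rep = distance_metrics(mask(a), mask(b))
        assert rep["hd"] == 5.0 and rep["assd"] == 5.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_double_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = (rng.random((16, 16)) > 0.8).astype(np.uint8)
        b = (rng.random((16, 16)) > 0.8).astype(np.uint8)
        if not a.any() or not b.any():
            pytest.skip("degenerate draw")
        pa, pb = np.argwhere(a).astype(float), np.argwhere(b).astype(float)
        pair = np.sqrt(((pa[:, None] - pb[None]) ** 2).sum(-1))
        hd_ref = max(pair.min(1).max(), pair.min(0).max())
        assd_ref = np.concatenate([pair.min(1), pair.min(0)]).mean()
        rep = distance_metrics(mask(a), mask(b))
        assert rep["hd"] == pytest.approx(hd_ref, abs=1e-9)
        assert rep["assd"] == pytest.approx(assd_ref, abs=1e-9)

    def test_symmetry(self):
        rng = np.random.default_rng(9)
        a = (rng.random((16, 16)) > 0.8).astype(np.uint8); a[0, 0] = 1
        b = (rng.random((16, 16)) > 0.8).astype(np.uint8); b[5, 5] = 1
        assert distance_metrics(mask(a), mask(b)) == distance_metrics(mask(b), mask(a))


class TestBetti:
    def test_ring_numbers(self, ring, broken_ring):
        assert betti_numbers(ring) == (1, 1)
        assert betti_numbers(broken_ring) == (1, 0)

    def test_broken_ring_error_is_one(self, ring, broken_ring):
        assert betti_error(broken_ring, ring) == 1.0

    def test_two_rings_vs_one(self, ring):
        two = np.zeros((12, 26), np.uint8)
        two[:, :12] = ring.grid
        two[:, 14:26] = ring.grid
        one = np.zeros((12, 26), np.uint8)
        one[:, :12] = ring.grid
        assert betti_error(mask(one), mask(two)) == 2.0

    def test_empty_mask_zero_betti(self):
        assert betti_numbers(mask(np.zeros((5, 5)))) == (0, 0)

    def test_perfect_prediction(self, phantom):
        assert betti_error(phantom.gt, phantom.gt) == 0.0


class TestClDice:
    def test_perfect_prediction(self, phantom):
        assert cldice(phantom.gt, phantom.gt) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((10, 10)); a[1, 1:4] = 1
        b = np.zeros((10, 10)); b[8, 5:9] = 1
        assert cldice(mask(a), mask(b)) == 0.0

    def test_thick_ring_vs_dilated_ring(self):
        # 4-px-thick ring: after a 2-px dilation each skeleton still lies
        # inside the other mask, so both topology fractions are 1
        g = np.zeros((20, 20), np.uint8)
        g[2:18, 2:18] = 1
        g[6:14, 6:14] = 0
        dilated = ndimage.binary_dilation(g, structure=np.ones((5, 5))).astype(np.uint8)
        assert cldice(mask(dilated), mask(g)) == 1.0

    def test_empty_skeleton_raises(self, ring):
        with pytest.raises(ValueError):
            cldice(mask(np.zeros((12, 12))), ring)


class TestRegionMetrics:
    def test_perfect_prediction(self, phantom):
        rep = region_metrics(phantom.gt, phantom.gt)
        assert rep["vrand"] == 1.0 and rep["vinfo"] == 1.0
        assert rep["ari"] == 1.0 and rep["voi"] == 0.0

    def test_merged_cells_voi_equals_gt_entropy(self):
        g = np.zeros((10, 10)); g[:, 5] = 1  # two cells: 50 and 40 px
        rep = region_metrics(mask(np.zeros((10, 10))), mask(g))
        p = np.array([50, 40]) / 90
        expected = float(-(p * np.log(p)).sum())
        assert rep["voi"] == pytest.approx(expected, abs=1e-12)
        assert rep["ari"] == 0.0

    def test_relabeling_invariance_under_symmetry_swap(self, phantom):
        pred = perturb(phantom, "delete_edges", seed=1, fraction=0.3)
        a = region_metrics(pred, phantom.gt)
        b = region_metrics(phantom.gt, pred)
        assert a["ari"] == pytest.approx(b["ari"], abs=1e-12)
        assert a["voi"] == pytest.approx(b["voi"], abs=1e-12)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            region_metrics(mask(np.zeros((2, 2))), mask(np.zeros((3, 3))))


class TestSkeletonizedVariants:
    def test_sk_variant_on_dilated_skeleton(self, phantom):
        skel = phantom.skeleton.to_mask()
        dilated = BinaryMask(ndimage.binary_dilation(
            skel.grid, structure=np.ones((5, 5))).astype(np.uint8))
        plain = evaluate_metric("f1", dilated, skel)
        sk = with_skeletonization("f1", dilated, skel)
        assert sk > plain

    def test_sk_equals_plain_on_thin_masks(self, ring, broken_ring):
        assert with_skeletonization("f1", broken_ring, ring) == \
            evaluate_metric("f1", broken_ring, ring)

    def test_iou_sk_self_is_one(self, phantom):
        assert with_skeletonization("iou", phantom.gt, phantom.gt) == 1.0


class TestPerfectFixpoints:
    def test_every_metric_attains_its_perfect_value(self, phantom):
        rep = full_report(phantom.gt, phantom.gt)
        for key, value in rep.items():
            if METRIC_DIRECTIONS[key] == "lower":
                assert value == 0.0, key
            elif key == "rvd":
                assert value == 0.0
            else:
                assert value == 1.0, key


class TestThicknessVsStructureOrdering:
    """The perceptual ranking: thickening hurts far less than deleting edges."""

    def test_phd_ranks_dilation_below_edge_deletion(self):
        wins = 0
        n = 40
        for seed in range(n):
            phantom = generate_phantom(seed)
            dil = perturb(phantom, "dilate", r=2)
            cut = perturb(phantom, "delete_edges", seed=seed, fraction=0.3)
            phd_dil = evaluate_metric("phd", dil, phantom.gt, tau=3)
            phd_cut = evaluate_metric("phd", cut, phantom.gt, tau=3)
            f1_dil = evaluate_metric("f1", dil, phantom.gt)
            wins += (phd_dil < phd_cut) and (f1_dil < 1.0)
        assert wins >= 0.95 * n
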