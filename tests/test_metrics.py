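"""DSC, aggregated DSC, Hausdorff and HD95 against brute-force oracles."""

import numpy as np
import pytest

from scdunet import (dsc_agg, dsc_pair, evaluate_volume, hausdorff, hd95)
from scdunet.metrics import MetricReport, boundary_points

from oracles import brute_boundary, brute_hausdorff, brute_hd95


@pytest.fixture
def rng():
    return np.random.default_rng(17)


class TestDscPair:
    def test_identical_nonempty_masks(self, rng):
        m = rng.random((6, 6, 4)) > 0.7
        m[0, 0, 0] = True
        assert dsc_pair(m, m) == pytest.approx(1.0)

    def test_worked_half_overlap(self):
        gt = np.zeros((4, 4), bool)
        pred = np.zeros((4, 4), bool)
        gt[0, 0] = gt[0, 1] = True
        pred[0, 1] = pred[0, 2] = True
        assert dsc_pair(gt, pred) == pytest.approx(0.5)

    def test_both_empty_undefined(self):
        empty = np.zeros((3, 3), bool)
        assert dsc_pair(empty, empty) is None

    def test_one_empty_gives_zero(self):
        gt = np.zeros((3, 3), bool)
        pred = gt.copy()
        pred[1, 1] = True
        assert dsc_pair(gt, pred) == 0.0

    def test_symmetry(self, rng):
        a = rng.random((5, 5)) > 0.5
        b = rng.random((5, 5)) > 0.5
        assert dsc_pair(a, b) == dsc_pair(b, a)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            dsc_pair(np.zeros((2, 2)), np.zeros((3, 3)))


class TestDscAgg:
    def test_single_case_reduces_to_pair(self, rng):
        gt = rng.random((6, 6)) > 0.6
        pred = rng.random((6, 6)) > 0.6
        gt[0, 0] = True
        assert dsc_agg([(gt, pred)]) == pytest.approx(dsc_pair(gt, pred))

    def test_worked_pooled_counts(self):
        # case A: |gt|=|pred|=10 overlap 5 (DSC 0.5); case B: 2/2 overlap 2
        # (DSC 1.0) -> pooled 2*7/(12+12) = 14/24
        gt_a = np.zeros(30, bool); gt_a[:10] = True
        pr_a = np.zeros(30, bool); pr_a[5:15] = True
        gt_b = np.zeros(30, bool); gt_b[:2] = True
        pr_b = gt_b.copy()
        assert dsc_pair(gt_a, pr_a) == pytest.approx(0.5)
        assert dsc_pair(gt_b, pr_b) == pytest.approx(1.0)
        assert dsc_agg([(gt_a, pr_a), (gt_b, pr_b)]) == pytest.approx(14 / 24)

    def test_all_empty_pool_undefined(self):
        empty = np.zeros((2, 2), bool)
        assert dsc_agg([(empty, empty), (empty, empty)]) is None

    def test_weighted_mean_identity(self, rng):
        """DSCagg equals the (|gt|+|pred|)-weighted mean of per-case DSC,
        hence lies between the per-case extremes."""
        for _ in range(10):
            pool = []
            for _ in range(4):
                gt = rng.random((5, 5)) > 0.5
                pred = rng.random((5, 5)) > 0.5
                gt[0, 0] = True
                pool.append((gt, pred))
            dscs = np.array([dsc_pair(g, p) for g, p in pool])
            weights = np.array([g.sum() + p.sum() for g, p in pool], float)
            expected = (dscs * weights).sum() / weights.sum()
            agg = dsc_agg(pool)
            assert agg == pytest.approx(expected)
            assert dscs.min() - 1e-12 <= agg <= dscs.max() + 1e-12


class TestHausdorff:
    def test_identical_sets_zero(self):
        pts = [[0, 0, 0], [1, 2, 3]]
        assert hausdorff(pts, pts) == 0.0

    def test_singletons_five_mm_apart(self):
        assert hausdorff([[0, 0, 0]], [[10, 0, 0]], (0.5, 0.5, 2.0)) == pytest.approx(5.0)

    def test_empty_set_undefined(self):
        assert hausdorff(np.empty((0, 3)), [[1, 1, 1]]) is None

    def test_matches_brute_force(self, rng):
        for _ in range(10):
            p = rng.integers(0, 20, (rng.integers(1, 50), 3))
            q = rng.integers(0, 20, (rng.integers(1, 50), 3))
            spacing = rng.uniform(0.5, 2.5, 3)
            assert hausdorff(p, q, spacing) == pytest.approx(
                brute_hausdorff(p, q, spacing), abs=1e-12)

    def test_symmetry_and_identity(self, rng):
        p = rng.integers(0, 10, (20, 3))
        q = rng.integers(0, 10, (15, 3))
        assert hausdorff(p, q) == pytest.approx(hausdorff(q, p))
        # h = 0 iff equal as sets
        pu = np.unique(p, axis=0)
        shuffled = pu[rng.permutation(len(pu))]
        assert hausdorff(pu, shuffled) == 0.0
        moved = pu.copy().astype(float)
        moved[0] += 0.5
        assert hausdorff(pu, moved) > 0


def _random_blob(rng, shape=(10, 10, 6)):
    mask = np.zeros(shape, bool)
    c = rng.integers(2, np.array(shape) - 2)
    mask[c[0] - 1:c[0] + 2, c[1] - 1:c[1] + 2, c[2] - 1:c[2] + 1] = True
    extra = rng.random(shape) > 0.97
    return mask | extra


class TestHd95:
    def test_identical_masks_zero(self, rng):
        m = _random_blob(rng)
        assert hd95(m, m, (1, 1, 1)) == 0.0

    def test_empty_mask_undefined(self, rng):
        m = _random_blob(rng)
        assert hd95(m, np.zeros_like(m), (1, 1, 1)) is None
        assert hd95(np.zeros_like(m), m, (1, 1, 1)) is None

    def test_spacing_linearity(self, rng):
        a, b = _random_blob(rng), _random_blob(rng)
        base = hd95(a, b, (0.5, 0.5, 2.0))
        doubled = hd95(a, b, (1.0, 1.0, 4.0))
        assert doubled == pytest.approx(2 * base, rel=1e-12)

    def test_boundary_extraction_matches_brute_force(self, rng):
        m = _random_blob(rng)
        mine = set(map(tuple, boundary_points(m).astype(int)))
        ref = set(map(tuple, brute_boundary(m).astype(int)))
        assert mine == ref

    def test_matches_brute_force_percentile(self, rng):
        for _ in range(5):
            a, b = _random_blob(rng), _random_blob(rng)
            spacing = (0.5, 0.5, 2.0)
            assert hd95(a, b, spacing) == pytest.approx(
                brute_hd95(a, b, spacing), abs=1e-9)

    def test_hd95_bounded_by_hausdorff(self, rng):
        for _ in range(5):
            a, b = _random_blob(rng), _random_blob(rng)
            spacing = (1.0, 1.0, 2.0)
            hd = hausdorff(boundary_points(a), boundary_points(b), spacing)
            assert hd95(a, b, spacing) <= hd + 1e-12


class TestEvaluateVolume:
    def test_perfect_prediction(self, rng):
        mask = np.zeros((8, 8, 4), np.int16)
        mask[2:4, 2:4, 1] = 1
        mask[5:7, 5:7, 2] = 2
        rows = evaluate_volume(mask, mask.copy(), (0.5, 0.5, 2.0), "p")
        for row in rows:
            assert row["dsc"] == pytest.approx(1.0)
            assert row["hd95_mm"] == 0.0

    def test_absent_structure_undefined_and_excluded(self):
        mask = np.zeros((6, 6, 3), np.int16)
        mask[1:3, 1:3, 1] = 2       # GTVn only; GTVp absent from both
        rows = evaluate_volume(mask, mask.copy(), (1, 1, 1), "q")
        by_structure = {r["structure"]: r for r in rows}
        assert by_structure["GTVp"]["dsc"] is None
        assert by_structure["GTVp"]["hd95_mm"] is None
        report = MetricReport(rows=rows)
        assert report.mean_dsc() == pytest.approx(1.0)   # GTVn only
        assert report.undefined_counts()["dsc"] == 1

    def test_rows_match_direct_metric_calls(self, default_case):
        pred = default_case.mask.copy()
        # perturb: shift one axial slice of the prediction
        pred[:, :, :] = np.roll(pred, 1, axis=0)
        rows = evaluate_volume(default_case.mask, pred,
                               default_case.spacing_mm, default_case.case_id)
        for row in rows:
            label = 1 if row["structure"] == "GTVp" else 2
            assert row["dsc"] == dsc_pair(default_case.mask == label, pred == label)
            assert row["hd95_mm"] == hd95(default_case.mask == label, pred == label,
                                          default_case.spacing_mm)

    def test_bad_label_rejected(self):
        gt = np.zeros((4, 4, 2), np.int16)
        bad = gt.copy()
        bad[0, 0, 0] = 5
        with pytest.raises(ValueError, match="labels"):
            evaluate_volume(gt, bad, (1, 1, 1))
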