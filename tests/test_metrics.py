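import numpy as np
import pytest

from mammoseg.io import LabelMask
from mammoseg.metrics import (
    GofInput,
    MetricError,
    PairedOutcomeTable,
    accuracy,
    auc,
    chisq_gof,
    dice_coefficient,
    hd95,
    iou,
    mcnemar_chi2,
)


def brute_force_overlap(a, b):
    """Literal voxel-counting oracle for Dice and IoU."""
    inter = total_a = total_b = union = 0
    for idx in np.ndindex(a.shape):
        av, bv = a[idx] > 0, b[idx] > 0
        inter += av and bv
        union += av or bv
        total_a += av
        total_b += bv
    d = 1.0 if total_a + total_b == 0 else 2 * inter / (total_a + total_b)
    j = 1.0 if union == 0 else inter / union
    return d, j


def brute_force_hd95(a, b, spacing):
    """Exhaustive symmetric surface-distance oracle."""

    def surface(m):
        pts = []
        for idx in np.argwhere(m):
            on_border = False
            for ax in range(3):
                for d in (-1, 1):
                    n = list(idx)
                    n[ax] += d
                    if not (0 <= n[ax] < m.shape[ax]) or not m[tuple(n)]:
                        on_border = True
            if on_border:
                pts.append(idx)
        return np.array(pts)

    sa, sb = surface(a), surface(b)
    sp = np.asarray(spacing)
    d_ab = [np.min(np.sqrt((((p - sb) * sp) ** 2).sum(axis=1))) for p in sa]
    d_ba = [np.min(np.sqrt((((p - sa) * sp) ** 2).sum(axis=1))) for p in sb]
    return np.percentile(np.concatenate([d_ab, d_ba]), 95)


class TestOverlapMetrics:
    def _masks(self, a, b):
        return (
            LabelMask(data=a.astype(np.uint8), spacing=(1, 1, 1)),
            LabelMask(data=b.astype(np.uint8), spacing=(1, 1, 1)),
        )

    def test_identity_and_disjoint(self):
        a = np.zeros((4, 4, 4))
        a[:2] = 1
        b = np.zeros((4, 4, 4))
        b[2:] = 1
        ma, mb = self._masks(a, a)
        assert dice_coefficient(ma, mb) == 1.0
        assert iou(ma, mb) == 1.0
        ma, mb = self._masks(a, b)
        assert dice_coefficient(ma, mb) == 0.0
        assert iou(ma, mb) == 0.0

    def test_worked_examples(self):
        a = np.zeros((4, 4, 4))
        a.flat[:4] = 1
        b = np.zeros((4, 4, 4))
        b.flat[2:6] = 1  # |A|=4, |B|=4, overlap 2, union 6
        ma, mb = self._masks(a, b)
        assert dice_coefficient(ma, mb) == pytest.approx(0.5)
        assert iou(ma, mb) == pytest.approx(1 / 3)

    def test_both_empty_convention(self):
        z = np.zeros((3, 3, 3))
        ma, mb = self._masks(z, z)
        assert dice_coefficient(ma, mb) == 1.0
        assert iou(ma, mb) == 1.0

    def test_misaligned_rejected(self):
        a = LabelMask(data=np.zeros((4, 4, 4), np.uint8), spacing=(1, 1, 1))
        b = LabelMask(data=np.zeros((4, 4, 4), np.uint8), spacing=(2, 2, 2))
        with pytest.raises(MetricError):
            dice_coefficient(a, b)

    def test_oracle_agreement_50_random_pairs(self):
        rng = np.random.default_rng(99)
        for _ in range(50):
            side = int(rng.integers(2, 7))
            a = rng.random((side,) * 3) > 0.6
            b = rng.random((side,) * 3) > 0.6
            ma, mb = self._masks(a, b)
            d_o, j_o = brute_force_overlap(a, b)
            assert abs(dice_coefficient(ma, mb) - d_o) < 1e-9
            assert abs(iou(ma, mb) - j_o) < 1e-9

    def test_dice_iou_identity(self):
        rng = np.random.default_rng(100)
        for _ in range(20):
            a = rng.random((5, 5, 5)) > 0.5
            b = rng.random((5, 5, 5)) > 0.5
            ma, mb = self._masks(a, b)
            j = iou(ma, mb)
            assert dice_coefficient(ma, mb) == pytest.approx(2 * j / (1 + j), abs=1e-9)


class TestHD95:
    def test_identical_masks(self, blob_mask):
        assert hd95(blob_mask, blob_mask) == 0.0

    def test_two_points_three_apart(self):
        a = np.zeros((8, 8, 8), np.uint8)
        b = np.zeros((8, 8, 8), np.uint8)
        a[2, 2, 2] = 1
        b[2, 2, 5] = 1
        ma = LabelMask(data=a, spacing=(1, 1, 1))
        mb = LabelMask(data=b, spacing=(1, 1, 1))
        assert hd95(ma, mb) == pytest.approx(3.0)

    def test_symmetry(self):
        rng = np.random.default_rng(7)
        a = rng.random((6, 6, 6)) > 0.6
        b = rng.random((6, 6, 6)) > 0.6
        ma = LabelMask(data=a.astype(np.uint8), spacing=(1, 1, 2))
        mb = LabelMask(data=b.astype(np.uint8), spacing=(1, 1, 2))
        assert hd95(ma, mb) == pytest.approx(hd95(mb, ma))

    def test_empty_mask_rejected(self, blob_mask):
        empty = LabelMask(
            data=np.zeros(blob_mask.shape, np.uint8), spacing=blob_mask.spacing
        )
        with pytest.raises(MetricError):
            hd95(blob_mask, empty)

    def test_oracle_agreement(self):
        rng = np.random.default_rng(8)
        count = 0
        while count < 10:
            a = rng.random((5, 5, 5)) > 0.5
            b = rng.random((5, 5, 5)) > 0.5
            if a.sum() == 0 or b.sum() == 0:
                continue
            count += 1
            ma = LabelMask(data=a.astype(np.uint8), spacing=(1, 1.5, 2))
            mb = LabelMask(data=b.astype(np.uint8), spacing=(1, 1.5, 2))
            assert hd95(ma, mb) == pytest.approx(
                brute_force_hd95(a, b, (1, 1.5, 2)), abs=1e-9
            )


class TestClassificationMetrics:
    def test_accuracy(self):
        assert accuracy([0, 1, 1, 0], [0, 1, 0, 0]) == 0.75

    def test_auc_worked_example(self):
        assert auc([0, 0, 1, 1], [0.1, 0.4, 0.35, 0.8]) == pytest.approx(0.75)

    def test_auc_perfect_and_ties(self):
        assert auc([0, 0, 1, 1], [0.1, 0.2, 0.7, 0.9]) == 1.0
        assert auc([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5]) == 0.5

    def test_auc_single_class_rejected(self):
        with pytest.raises(MetricError):
            auc([1, 1, 1], [0.2, 0.3, 0.4])

    def test_auc_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(12)
        y = rng.integers(0, 2, 50)
        y[0], y[1] = 0, 1
        s = rng.random(50).round(1)  # force ties
        assert auc(y, s) == pytest.approx(roc_auc_score(y, s), abs=1e-12)


class TestMcNemar:
    def test_published_counts(self):
        """(a,b,c,d) = (63,1,12,124): chi2 = 121/13 = 9.31, p = 0.0023."""
        chi2, p = mcnemar_chi2(PairedOutcomeTable(a=63, b=1, c=12, d=124))
        assert round(chi2, 2) == 9.31
        assert round(p, 4) == 0.0023

    def test_symmetric_counts(self):
        chi2, p = mcnemar_chi2(PairedOutcomeTable(a=0, b=7, c=7, d=0))
        assert chi2 == 0.0
        assert p == pytest.approx(1.0)

    def test_one_sided_discordance(self):
        chi2, _ = mcnemar_chi2(PairedOutcomeTable(a=0, b=5, c=0, d=0))
        assert chi2 == pytest.approx(5.0)

    def test_swap_invariance(self):
        t1 = PairedOutcomeTable(a=3, b=9, c=4, d=10)
        t2 = PairedOutcomeTable(a=3, b=4, c=9, d=10)
        assert mcnemar_chi2(t1)[0] == pytest.approx(mcnemar_chi2(t2)[0])

    def test_no_discordance_rejected(self):
        with pytest.raises(MetricError):
            mcnemar_chi2(PairedOutcomeTable(a=5, b=0, c=0, d=5))

    def test_corrected_variant_matches_statsmodels(self):
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

        table = PairedOutcomeTable(a=63, b=1, c=12, d=124)
        chi2_c, p_c = mcnemar_chi2(table, correction=True)
        sm = sm_mcnemar([[63, 1], [12, 124]], exact=False, correction=True)
        assert chi2_c == pytest.approx(float(sm.statistic))
        assert p_c == pytest.approx(float(sm.pvalue))

    def test_from_predictions(self):
        p1 = [1, 1, 0, 0, 1]
        p2 = [1, 0, 0, 1, 1]
        t = PairedOutcomeTable.from_predictions(p1, p2)
        assert (t.a, t.b, t.c, t.d) == (2, 1, 1, 1)
        assert t.total == 5


class TestChisqGof:
    def test_published_tables(self):
        """Observed (64,136) and (75,125) vs ground truth (83,117)."""
        gt = np.array([83, 117])
        chi2, p = chisq_gof(GofInput(observed=np.array([64, 136]), expected_source=gt))
        assert round(chi2, 2) == 7.43
        assert round(p, 4) == 0.0064
        chi2, p = chisq_gof(GofInput(observed=np.array([75, 125]), expected_source=gt))
        assert round(chi2, 2) == 1.32
        assert round(p, 4) == 0.2509

    def test_identity_gives_zero(self):
        chi2, p = chisq_gof(
            GofInput(observed=np.array([30, 70]), expected_source=np.array([30, 70]))
        )
        assert chi2 == 0.0
        assert p == pytest.approx(1.0)

    def test_scaling_of_expected(self):
        """Reference scaled to the observed total before comparison."""
        chi2, _ = chisq_gof(
            GofInput(observed=np.array([30, 70]), expected_source=np.array([3, 7]))
        )
        assert chi2 == 0.0

    def test_zero_expected_rejected(self):
        with pytest.raises(MetricError):
            GofInput(observed=np.array([1, 2]), expected_source=np.array([0, 3]))
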