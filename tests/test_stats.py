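"""ROC pooling, AUC oracle checks, and the correlated-AUC framework."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import norm

from cdis.stats import (
    TASKS,
    auc,
    auc_score,
    compare_auc,
    empirical_roc,
    estimate_r,
    hanley_mcneil_se,
    interpolate_r_table,
    pool_voxels,
    tissue_histograms,
)
from cdis.volumes import ImageVolume, TissueLabelSet


def pair_counting_auc(scores, labels):
    """All-pairs concordance oracle: ties credited one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def _label_set(shape=(6, 6, 2), cs=None, ins=None):
    gland = ImageVolume(np.ones(shape, dtype=np.uint8), (2.0, 2.0, 3.0))
    zeros = gland.with_data(np.zeros(shape, dtype=np.uint8))
    lesions = []
    for mask, cls in ((cs, "csPCa"), (ins, "insPCa")):
        if mask is not None:
            m = np.zeros(shape, dtype=np.uint8)
            m[mask] = 1
            lesions.append((gland.with_data(m), cls))
    return TissueLabelSet(gland, zeros, lesions)


class TestPoolVoxels:
    def test_counts_by_class(self):
        shape = (4, 2, 1)
        labels = _label_set(shape, cs=(slice(0, 3), 0, 0), ins=(slice(0, 2), 1, 0))
        vol = ImageVolume(np.arange(8, dtype=float).reshape(shape), (2.0, 2.0, 3.0))
        s, y = pool_voxels([vol], [labels], "cspca-vs-healthy")
        assert len(s) == 3 + 3  # 3 csPCa positives, 8 - 3 - 2 = 3 healthy
        assert int(y.sum()) == 3

    def test_cspca_vs_inspca_excludes_healthy(self):
        shape = (4, 2, 1)
        labels = _label_set(shape, cs=(slice(0, 3), 0, 0), ins=(slice(0, 2), 1, 0))
        vol = ImageVolume(np.zeros(shape), (2.0, 2.0, 3.0))
        s, y = pool_voxels([vol], [labels], "cspca-vs-inspca")
        assert len(s) == 5
        assert int(y.sum()) == 3

    def test_two_cases_concatenate_order_stably(self):
        shape = (4, 2, 1)
        labels = _label_set(shape, cs=(0, 0, 0))
        v1 = ImageVolume(np.full(shape, 1.0), (2.0, 2.0, 3.0))
        v2 = ImageVolume(np.full(shape, 2.0), (2.0, 2.0, 3.0))
        s, y = pool_voxels([v1, v2], [labels, labels], "cspca-vs-healthy")
        s_single, _ = pool_voxels([v1], [labels], "cspca-vs-healthy")
        assert len(s) == 2 * len(s_single)
        assert (s[: len(s_single)] == 1.0).all() and (s[len(s_single):] == 2.0).all()

    def test_empty_class_rejected(self):
        labels = _label_set((4, 2, 1), ins=(0, 0, 0))
        vol = ImageVolume(np.zeros((4, 2, 1)), (2.0, 2.0, 3.0))
        with pytest.raises(ValueError, match="positive"):
            pool_voxels([vol], [labels], "cspca-vs-healthy")


class TestEmpiricalRoc:
    def test_perfect_separation_hits_top_left(self):
        curve = empirical_roc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert auc(curve) == 1.0
        assert any((f == 0.0 and t == 1.0) for f, t in zip(curve.fpr, curve.tpr))

    def test_all_ties_gives_half(self):
        curve = empirical_roc([5.0] * 6, [0, 1, 0, 1, 0, 1])
        assert auc(curve) == pytest.approx(0.5, abs=1e-12)
        assert curve.n_pos == 3 and curve.n_neg == 3

    def test_worked_example_pair_oracle(self):
        scores = [0.1, 0.4, 0.35, 0.8]
        labels = [0, 0, 1, 1]
        assert auc_score(scores, labels) == pytest.approx(0.75, abs=1e-12)
        assert pair_counting_auc(scores, labels) == 0.75

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            empirical_roc([1.0, 2.0], [1, 1])

    def test_curve_monotone(self, rng):
        s = rng.normal(size=200)
        y = (rng.uniform(size=200) > 0.4).astype(int)
        curve = empirical_roc(s, y)
        assert (np.diff(curve.tpr) >= 0).all()
        assert (np.diff(curve.fpr) >= 0).all()
        assert curve.tpr[0] == 0.0 and curve.tpr[-1] == 1.0

    @given(st.integers(0, 10_000))
    def test_auc_equals_pair_counting(self, seed):
        """Trapezoidal AUC == all-pairs concordance with half-credit ties."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 120))
        # coarse grid of scores forces plenty of ties
        s = rng.integers(0, 8, n).astype(float)
        y = rng.integers(0, 2, n)
        if y.sum() in (0, n):
            y[0] = 0
            y[1] = 1
        assert auc_score(s, y) == pytest.approx(pair_counting_auc(s, y), abs=1e-12)

    @given(st.integers(0, 10_000))
    def test_auc_invariant_to_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        s = rng.normal(size=60)
        y = np.r_[np.ones(30, int), np.zeros(30, int)]
        base = auc_score(s, y)
        assert auc_score(3.0 * s + 11.0, y) == pytest.approx(base, abs=1e-12)
        assert auc_score(np.exp(s), y) == pytest.approx(base, abs=1e-12)


class TestHanleyMcNeilSE:
    def test_closed_form_corner_cases(self):
        assert hanley_mcneil_se(0.5, 1, 1) == pytest.approx(0.5, abs=1e-15)
        assert hanley_mcneil_se(1.0, 10, 20) == 0.0
        assert hanley_mcneil_se(1.0, 1, 1) == 0.0

    def test_closed_form_oracle(self):
        # A=0.9, nP=nN=50:
        # Q1 = 0.9/1.1, Q2 = 1.62/1.9
        # var = (0.09 + 49*(Q1-0.81) + 49*(Q2-0.81)) / 2500
        q1 = 0.9 / 1.1
        q2 = 2 * 0.81 / 1.9
        var = (0.9 * 0.1 + 49 * (q1 - 0.81) + 49 * (q2 - 0.81)) / 2500.0
        assert hanley_mcneil_se(0.9, 50, 50) == pytest.approx(np.sqrt(var), rel=1e-12)

    @pytest.mark.parametrize("A", [0.6, 0.75, 0.9, 0.99])
    def test_decreases_with_sample_size(self, A):
        for n_pos, n_neg, bigger in [(10, 10, (20, 10)), (10, 10, (10, 25))]:
            assert hanley_mcneil_se(A, *bigger) < hanley_mcneil_se(A, n_pos, n_neg)

    def test_invalid_auc_rejected(self):
        with pytest.raises(ValueError):
            hanley_mcneil_se(1.2, 10, 10)


class TestCompareAuc:
    def test_equal_aucs_give_zero(self):
        for r in (-0.5, 0.0, 0.9):
            c = compare_auc(0.8, 0.01, 0.8, 0.01, r)
            assert c.z == 0.0 and c.p == 1.0

    def test_zero_correlation_reduces_to_independent_ses(self):
        c = compare_auc(0.9, 0.01, 0.85, 0.02, 0.0)
        assert c.z == pytest.approx(0.05 / np.hypot(0.01, 0.02), rel=1e-12)

    def test_closed_form_oracle(self):
        # z = 0.03 / sqrt(1e-4 + 1.44e-4 - 2*0.5*1e-2*1.2e-2)
        denom = np.sqrt(0.01**2 + 0.012**2 - 2 * 0.5 * 0.01 * 0.012)
        c = compare_auc(0.92, 0.01, 0.89, 0.012, 0.5)
        assert c.z == pytest.approx(0.03 / denom, rel=1e-12)
        assert c.p == pytest.approx(2 * norm.sf(abs(c.z)), rel=1e-12)
        assert np.sign(c.z) == np.sign(c.A1 - c.A2)

    def test_degenerate_denominator_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            compare_auc(0.9, 0.01, 0.8, 0.01, 1.0)


class TestEstimateR:
    def _cases(self, rng, n_cases=6, transform=None):
        maps1, maps2, labels = [], [], []
        shape = (6, 6, 2)
        for _ in range(n_cases):
            lab = _label_set(shape, cs=(slice(0, 2), slice(0, 2), 0))
            base = rng.uniform(1.0, 5.0, shape)
            base[:2, :2, 0] += 4.0  # cancer hyperintense
            m1 = ImageVolume(base, (2.0, 2.0, 3.0))
            other = transform(base) if transform else base.copy()
            maps1.append(m1)
            maps2.append(ImageVolume(other, (2.0, 2.0, 3.0)))
            labels.append(lab)
        return maps1, maps2, labels

    def test_identical_maps_give_r_one(self, rng):
        m1, m2, labs = self._cases(rng)
        assert estimate_r(m1, m2, labs, "cspca-vs-healthy") == 1.0

    def test_affine_map_gives_r_one(self, rng):
        m1, m2, labs = self._cases(rng, transform=lambda d: 2.0 * d + 3.0)
        assert estimate_r(m1, m2, labs, "cspca-vs-healthy") == pytest.approx(
            1.0, abs=1e-6
        )

    def test_pearson_matches_textbook_oracle(self, rng):
        """The per-case class medians drive a plain Pearson correlation."""
        from cdis.stats import _class_mask  # noqa: PLC2701 - checking internals

        m1, m2, labs = self._cases(rng, transform=lambda d: d + rng.normal(0, 1, d.shape))
        med1p, med2p = [], []
        for v1, v2, lab in zip(m1, m2, labs):
            pos = _class_mask(lab, "csPCa")
            med1p.append(np.median(v1.data[pos]))
            med2p.append(np.median(v2.data[pos]))
        x, y = np.array(med1p), np.array(med2p)
        r_oracle = float(
            ((x - x.mean()) * (y - y.mean())).sum()
            / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        )
        from scipy.stats import pearsonr

        assert pearsonr(x, y).statistic == pytest.approx(r_oracle, abs=1e-12)

    def test_zero_variance_rejected(self, rng):
        m1, _, labs = self._cases(rng)
        flat = [v.with_data(np.ones_like(v.data)) for v in m1]
        with pytest.raises(ValueError, match="variance"):
            estimate_r(flat, m1, labs, "cspca-vs-healthy")

    def test_too_few_cases_rejected(self, rng):
        m1, m2, labs = self._cases(rng, n_cases=2)
        with pytest.raises(ValueError, match=">= 3"):
            estimate_r(m1, m2, labs, "cspca-vs-healthy")


class TestRTable:
    def test_boundary_conventions(self):
        assert interpolate_r_table(1.0, 0.8) == 1.0
        assert interpolate_r_table(0.0, 0.75) == pytest.approx(0.0, abs=1e-12)

    def test_monotone_in_mean_r(self):
        vals = [interpolate_r_table(r, 0.85) for r in np.linspace(0, 1, 21)]
        assert (np.diff(vals) >= -1e-12).all()

    def test_low_auc_folds(self):
        assert interpolate_r_table(0.5, 0.3) == interpolate_r_table(0.5, 0.7)


class TestTissueHistograms:
    def test_frequencies_sum_to_one(self, rng):
        shape = (6, 6, 2)
        lab = _label_set(shape, cs=(slice(0, 2), slice(0, 2), 0),
                         ins=(slice(4, 6), slice(4, 6), 1))
        vol = ImageVolume(rng.uniform(0, 10, shape), (2.0, 2.0, 3.0))
        h = tissue_histograms([vol], [lab], bins=16)
        assert set(h.frequencies) == {"healthy", "insPCa", "csPCa"}
        for freqs in h.frequencies.values():
            assert freqs.sum() == pytest.approx(1.0, abs=1e-9)

    def test_constant_single_class_in_one_bin(self):
        shape = (4, 4, 1)
        lab = _label_set(shape)  # no lesions: healthy only
        vol = ImageVolume(np.full(shape, 3.0), (2.0, 2.0, 3.0))
        with pytest.warns(UserWarning):
            h = tissue_histograms([vol], [lab], bins=8)
        assert (h.frequencies["healthy"] == 1.0).sum() == 1

    def test_gaussian_overlap_matches_analytic(self, rng):
        """Histogram overlap of two equal-variance Gaussians approximates
        the closed form 2*Phi(-|mu1-mu2| / (2 sigma))."""
        shape = (40, 40, 12)
        n = int(np.prod(shape))
        half = (slice(0, 20), slice(None), slice(None))
        lab = _label_set(shape, cs=half)
        data = np.empty(shape)
        mu1, mu2, sigma = 0.0, 1.5, 1.0
        data[half] = rng.normal(mu2, sigma, (20, 40, 12))
        data[20:, :, :] = rng.normal(mu1, sigma, (20, 40, 12))
        vol = ImageVolume(data, (2.0, 2.0, 3.0))
        with pytest.warns(UserWarning):  # no insPCa voxels
            h = tissue_histograms([vol], [lab], bins=60)
        overlap = np.minimum(h.frequencies["csPCa"], h.frequencies["healthy"]).sum()
        analytic = 2 * norm.cdf(-abs(mu2 - mu1) / (2 * sigma))
        assert overlap == pytest.approx(analytic, abs=0.05)
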