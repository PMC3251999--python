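"""Level-set segmentation: region statistics, energies, evolution and the
full segmenter, checked against direct summation and a pure Chan-Vese
oracle."""

import numpy as np
import pytest

from actikit.errors import ContractError, DegenerateRegionError
from actikit.segmentation import (
    BhattacharyyaChanVese,
    RegionHistogram,
    SegmentationParams,
    bhattacharyya_coefficient,
    circle_level_set,
    evolution_step,
    region_histograms,
    region_means,
    segment,
    smoothed_delta,
    smoothed_heaviside,
    total_energy,
)
from actikit.synthetic import make_body_image


def iou(a, b):
    return (a & b).sum() / (a | b).sum()


class TestRegionMeans:
    def test_constant_image(self):
        img = np.full((8, 8), 0.5)
        field = circle_level_set((8, 8))
        assert region_means(img, field) == pytest.approx((0.5, 0.5))

    def test_sharp_partition(self):
        img = np.array([[0.0, 0.0], [1.0, 1.0]])
        field = np.array([[1.0, 1.0], [-1.0, -1.0]])  # inside = row 1
        c_in, c_out = region_means(img, field, epsilon=1e-8)
        assert c_in == pytest.approx(1.0, abs=1e-6)
        assert c_out == pytest.approx(0.0, abs=1e-6)

    def test_matches_masked_average_oracle(self):
        # the arctan Heaviside has 1/x tails, so phi is kept away from 0
        # and epsilon made tiny to reach 1e-10 agreement with hard masking
        rng = np.random.default_rng(0)
        img = rng.random((8, 8))
        field = np.sign(rng.normal(size=(8, 8))) * rng.uniform(0.5, 3.0, (8, 8))
        c_in, c_out = region_means(img, field, epsilon=1e-14)
        inside = field < 0
        assert c_in == pytest.approx(img[inside].mean(), abs=1e-10)
        assert c_out == pytest.approx(img[~inside].mean(), abs=1e-10)

    def test_empty_region_error(self):
        img = np.full((4, 4), 0.3)
        with pytest.raises(DegenerateRegionError):
            region_means(img, np.full((4, 4), 10.0), epsilon=1e-6)


class TestRegionHistograms:
    def test_separated_intensities(self):
        img = np.where(np.arange(16).reshape(4, 4) < 8, 0.0, 1.0)
        field = np.where(np.arange(16).reshape(4, 4) < 8, -1.0, 1.0)
        p_in, p_out = region_histograms(img, field, n_bins=4, epsilon=1e-14)
        assert p_in.mass[0] == pytest.approx(1.0, abs=1e-9)
        assert p_out.mass[-1] == pytest.approx(1.0, abs=1e-9)

    def test_constant_image_identical_histograms(self):
        img = np.full((6, 6), 0.4)
        field = circle_level_set((6, 6))
        p_in, p_out = region_histograms(img, field, n_bins=8)
        np.testing.assert_allclose(p_in.mass, p_out.mass, atol=1e-12)
        assert p_in.mass.sum() == pytest.approx(1.0, abs=1e-9)

    def test_matches_weighted_count_oracle(self):
        rng = np.random.default_rng(1)
        img = rng.random((8, 8))
        field = rng.normal(size=(8, 8))
        eps = 1.3
        n_bins = 8
        p_in, p_out = region_histograms(img, field, n_bins=n_bins, epsilon=eps)
        h_in = smoothed_heaviside(-field, eps)
        edges = np.linspace(0, 1, n_bins + 1)
        expect = np.zeros(n_bins)
        for v, wgt in zip(img.ravel(), h_in.ravel()):
            b = min(int(np.floor(v * n_bins)), n_bins - 1)
            expect[b] += wgt
        np.testing.assert_allclose(p_in.mass, expect / h_in.sum(), atol=1e-12)
        assert p_out.mass.sum() == pytest.approx(1.0, abs=1e-9)


class TestBhattacharyya:
    def test_identical_distributions(self):
        edges = np.linspace(0, 1, 5)
        p = RegionHistogram(edges, np.array([0.25, 0.25, 0.25, 0.25]))
        assert bhattacharyya_coefficient(p, p) == pytest.approx(1.0)

    def test_disjoint_supports(self):
        edges = np.linspace(0, 1, 3)
        a = RegionHistogram(edges, np.array([1.0, 0.0]))
        b = RegionHistogram(edges, np.array([0.0, 1.0]))
        assert bhattacharyya_coefficient(a, b) == 0.0

    def test_hand_value(self):
        edges = np.linspace(0, 1, 3)
        a = RegionHistogram(edges, np.array([0.5, 0.5]))
        b = RegionHistogram(edges, np.array([1.0, 0.0]))
        assert bhattacharyya_coefficient(a, b) == pytest.approx(np.sqrt(0.5))

    def test_mismatched_bins_rejected(self):
        a = RegionHistogram(np.linspace(0, 1, 3), np.array([0.5, 0.5]))
        b = RegionHistogram(np.linspace(0, 1, 4), np.array([0.4, 0.3, 0.3]))
        with pytest.raises(ContractError):
            bhattacharyya_coefficient(a, b)


class TestTotalEnergy:
    def test_beta_one_reduces_to_chan_vese(self):
        rng = np.random.default_rng(2)
        img = rng.random((8, 8))
        field = circle_level_set((8, 8))
        p = SegmentationParams(beta=1.0, gamma=0.3, eta=0.1)
        eps = p.epsilon
        h_in = smoothed_heaviside(-field, eps)
        c_in, c_out = region_means(img, field, eps)
        gy, gx = np.gradient(field)
        expect = (
            0.3 * np.sum(smoothed_delta(field, eps) * np.hypot(gx, gy))
            + 0.1 * h_in.sum()
            + np.sum((img - c_in) ** 2 * h_in + (img - c_out) ** 2 * (1 - h_in))
        )
        assert total_energy(img, field, p) == pytest.approx(expect, rel=1e-12)

    def test_perfect_piecewise_fit_is_zero(self):
        img = np.zeros((10, 10))
        img[3:7, 3:7] = 1.0
        field = np.where(img > 0.5, -1.0, 1.0) * 1e8  # near-sharp partition
        p = SegmentationParams(beta=1.0, gamma=0.0, eta=0.0, epsilon=1e-6)
        assert total_energy(img, field, p) == pytest.approx(0.0, abs=1e-6)

    def test_beta_zero_identical_histograms_gives_area(self):
        img = np.full((9, 9), 0.6)
        field = circle_level_set((9, 9))
        p = SegmentationParams(beta=0.0, gamma=0.0, eta=0.0)
        assert total_energy(img, field, p) == pytest.approx(img.size, rel=1e-9)


class TestEvolutionStep:
    def test_homogeneous_input_is_stationary(self):
        img = np.full((12, 12), 0.5)
        field = circle_level_set((12, 12))
        p = SegmentationParams(beta=0.5, gamma=0.0, eta=0.0)
        out = evolution_step(img, field, p)
        np.testing.assert_allclose(out, field, atol=1e-9)

    def test_small_step_does_not_increase_energy(self):
        img, _ = make_body_image(seed=3)
        field = circle_level_set(img.shape)
        p = SegmentationParams(dt=1e-4)
        e0 = total_energy(img, field, p)
        e1 = total_energy(img, evolution_step(img, field, p), p)
        assert e1 <= e0 + 1e-6

    def test_beta_one_matches_pure_chan_vese_oracle(self):
        rng = np.random.default_rng(4)
        img = rng.random((8, 8))
        field = rng.normal(size=(8, 8)) * 2
        p = SegmentationParams(beta=1.0, gamma=0.4, eta=0.2, dt=0.05)
        got = evolution_step(img, field, p)

        # independent Chan-Vese step written from scratch
        eps = p.epsilon
        h_in = 0.5 * (1 + (2 / np.pi) * np.arctan(-field / eps))
        a_in, a_out = h_in.sum(), (1 - h_in).sum()
        c_in = (img * h_in).sum() / a_in
        c_out = (img * (1 - h_in)).sum() / a_out
        gy, gx = np.gradient(field)
        norm = np.sqrt(gx**2 + gy**2) + 1e-8
        ny, _ = np.gradient(gy / norm)
        _, nx = np.gradient(gx / norm)
        kappa = nx + ny
        bracket = p.gamma * kappa + p.eta + (img - c_in) ** 2 - (img - c_out) ** 2
        expect = field + p.dt * np.sqrt(gx**2 + gy**2) * bracket
        np.testing.assert_allclose(got, expect, atol=1e-10)


class TestSegment:
    def test_body_fixture_iou_and_cv_ordering(self):
        img, truth = make_body_image(seed=7)
        full = BhattacharyyaChanVese().fit(img)
        cv = BhattacharyyaChanVese(beta=1.0).fit(img)
        assert iou(full.mask_, truth) >= 0.90
        assert iou(cv.mask_, truth) < iou(full.mask_, truth)

    def test_energy_trace_monotone_and_final_below_initial(self):
        img, _ = make_body_image(seed=5)
        res = segment(img, circle_level_set(img.shape), SegmentationParams(max_iters=200))
        trace = np.asarray(res.energy_trace)
        assert len(trace) == res.iterations
        assert np.all(np.diff(trace) <= 1e-9)
        assert trace[-1] <= trace[0]

    def test_uniform_image_degenerates_without_crash(self):
        res = segment(np.full((24, 24), 0.7), circle_level_set((24, 24)))
        assert res.degenerate

    def test_bhattacharyya_stays_in_unit_interval_every_iteration(self):
        img, _ = make_body_image(seed=6)
        rec = []
        segment(img, circle_level_set(img.shape),
                SegmentationParams(max_iters=150), record_b=rec)
        assert rec and all(0.0 <= b <= 1.0 for b in rec)

    def test_invariance_to_global_intensity_shift(self):
        img, _ = make_body_image(seed=8, noise_sigma=0.0, fg_intensities=(0.3, 0.7),
                                 bg_intensity=0.1)
        shift = 0.2
        p0 = SegmentationParams(max_iters=120)
        p1 = SegmentationParams(max_iters=120, value_range=(shift, 1.0 + shift))
        r0 = segment(img, circle_level_set(img.shape), p0)
        r1 = segment(img + shift, circle_level_set(img.shape), p1)
        assert np.array_equal(r0.mask, r1.mask)

    def test_single_sign_init_rejected(self):
        with pytest.raises(ContractError):
            segment(np.random.default_rng(0).random((8, 8)), np.ones((8, 8)))

    def test_estimator_follows_sklearn_conventions(self):
        est = BhattacharyyaChanVese(beta=0.4)
        assert est.get_params()["beta"] == 0.4
        est.set_params(beta=0.6)
        img, _ = make_body_image(seed=9)
        mask = est.fit_predict(img)
        assert mask.dtype == bool and mask.shape == img.shape
        assert hasattr(est, "energy_trace_") and hasattr(est, "degenerate_")
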