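"""Seed construction, edge indicator, and level-set evolution behavior."""

import numpy as np
import pytest

from busseg.drls import (DRLSConfig, LevelSetField, edge_indicator, evolve,
                         make_seed, segment_drls)
from busseg.metrics import dice, fpf
from busseg.phantom import SegmentationMask


def brute_force_erosion(mask: np.ndarray, radius: int) -> np.ndarray:
    """A pixel survives iff every disk offset stays inside the mask."""
    h, w = mask.shape
    offsets = [(dr, dc) for dr in range(-radius, radius + 1)
               for dc in range(-radius, radius + 1)
               if dr * dr + dc * dc <= radius * radius]
    out = np.zeros_like(mask)
    for r in range(h):
        for c in range(w):
            if mask[r, c] and all(
                0 <= r + dr < h and 0 <= c + dc < w and mask[r + dr, c + dc]
                for dr, dc in offsets
            ):
                out[r, c] = 1
    return out


class TestMakeSeed:
    def _square(self, side, frame=60):
        m = np.zeros((frame, frame), np.uint8)
        lo = (frame - side) // 2
        m[lo : lo + side, lo : lo + side] = 1
        return m

    def test_small_lesion_eroded_by_4(self):
        m = self._square(20)  # area 400 < 500
        seed = make_seed(SegmentationMask(m))
        assert seed.area == 12 * 12
        assert np.array_equal(seed.pixels, brute_force_erosion(m, 4))

    def test_large_lesion_eroded_by_8(self):
        m = self._square(30)  # area 900 > 500
        seed = make_seed(SegmentationMask(m))
        assert seed.area == 14 * 14
        assert np.array_equal(seed.pixels, brute_force_erosion(m, 8))

    def test_exactly_500_treated_as_large(self):
        m = self._square(25)[:, :]  # 625 -- trim to exactly 500
        rows, cols = np.nonzero(m)
        m[rows[:125], cols[:125]] = 0
        assert m.sum() == 500
        seed = make_seed(SegmentationMask(m))
        assert np.array_equal(seed.pixels, brute_force_erosion(m, 8))

    def test_seed_contained_in_truth(self):
        m = self._square(24)
        seed = make_seed(SegmentationMask(m))
        assert np.all(seed.pixels <= m)

    def test_centroid_fallback_for_tiny_mask(self, caplog):
        m = np.zeros((32, 32), np.uint8)
        m[15:18, 15:18] = 1  # erosion by 4 empties it
        seed = make_seed(SegmentationMask(m))
        assert seed.area == 1
        assert np.all(seed.pixels <= m)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            make_seed(SegmentationMask(np.zeros((8, 8), np.uint8)))


class TestEdgeIndicator:
    def test_constant_image_is_one(self):
        g = edge_indicator(np.full((20, 20), 7.0), sigma_smooth=1.5)
        assert np.allclose(g, 1.0)

    def test_step_edge_minimum_below_flat(self):
        img = np.zeros((30, 30)); img[:, 15:] = 100.0
        g = edge_indicator(img, 1.5)
        assert g.min() < 0.01
        assert g[:, :5].min() > 0.9

    def test_ramp_matches_closed_form(self):
        s = 0.75
        img = np.outer(np.ones(40), np.arange(40) * s)
        g = edge_indicator(img, 1.5)
        interior = g[10:-10, 10:-10]
        assert np.allclose(interior, 1.0 / (1.0 + s * s), atol=1e-3)


class TestEvolve:
    def _disk_phi(self, frame=64, radius=10, c=2.0):
        rr, cc = np.mgrid[0:frame, 0:frame]
        inside = (rr - frame // 2) ** 2 + (cc - frame // 2) ** 2 <= radius**2
        return np.where(inside, -c, c).astype(float)

    def test_balloon_expands_without_edges(self):
        cfg = DRLSConfig()
        field = LevelSetField(self._disk_phi())
        g = np.ones((64, 64))
        areas = [int((field.phi < 0).sum())]
        for _ in range(10):
            evolve(field, g, cfg, steps=5)
            areas.append(int((field.phi < 0).sum()))
        assert all(b > a for a, b in zip(areas, areas[1:]))
        assert np.all(np.isfinite(field.phi))

    def test_pure_regularization_is_stationary(self):
        cfg = DRLSConfig(lambda_weight=0.0, alpha_weight=-0.0)
        rr, cc = np.mgrid[0:64, 0:64]
        sd = np.sqrt((rr - 32.0) ** 2 + (cc - 32.0) ** 2) - 12.0  # signed distance
        field = LevelSetField(sd.copy())
        evolve(field, np.ones((64, 64)), cfg, steps=50)
        area0 = int((sd < 0).sum())
        area1 = int((field.phi < 0).sum())
        assert abs(area1 - area0) / area0 < 0.02

    def test_stability_invariant_enforced(self):
        with pytest.raises(ValueError, match="stability"):
            DRLSConfig(mu_weight=0.1, timestep=5.0)


class TestSegmentDrls:
    def test_high_contrast_phantom_converges(self, disk_phantom):
        img, mask = disk_phantom
        pred = segment_drls(img.pixels, mask)
        assert dice(pred.pixels, mask.pixels) >= 0.9

    def test_alpha_zero_near_stationary_from_truth_seed(self, disk_phantom):
        img, mask = disk_phantom
        # seed ~ the truth itself (1-px erosion), no balloon force: near-stationary
        cfg = DRLSConfig(alpha_weight=0.0, erosion_small=0, erosion_large=1,
                         n_iterations=100)
        big = SegmentationMask(mask.pixels)
        pred = segment_drls(img.pixels, big, cfg)
        assert dice(pred.pixels, mask.pixels) >= 0.95

    def test_blank_image_negative_control(self, disk_phantom):
        _, mask = disk_phantom
        blank = np.full(mask.shape, 10.0)  # featureless: no lesion contrast
        pred = segment_drls(blank, mask, DRLSConfig(n_iterations=200))
        assert pred.area > mask.area  # expands past the truth
        assert fpf(pred.pixels, mask.pixels) > 0
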