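"""Fold construction and majority-vote fusion against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from busseg.ensemble import (EnsembleConfig, FoldPlan, majority_vote,
                             make_folds, member_count_sweep,
                             vote_threshold_sweep)


def brute_force_vote(maps, binarize_t, vote_t):
    """Per-pixel vote counting, one pixel at a time."""
    n = len(maps)
    h, w = maps[0].shape
    out = np.zeros((h, w), np.uint8)
    for i in range(h):
        for j in range(w):
            votes = sum(1 for m in maps if m[i, j] >= binarize_t)
            out[i, j] = 1 if votes / n >= vote_t else 0
    return out


class TestMakeFolds:
    def test_even_split(self):
        plan = make_folds([f"p{i}" for i in range(100)], 10, rng_seed=0)
        sizes = [len(plan.patients_in(k)) for k in range(10)]
        assert sizes == [10] * 10

    def test_remainder_split(self):
        plan = make_folds([f"p{i}" for i in range(101)], 10, rng_seed=1)
        sizes = sorted(len(plan.patients_in(k)) for k in range(10))
        assert sizes == [10] * 9 + [11]

    def test_images_of_patient_stay_together(self):
        ids = ["a", "a", "a", "b", "c", "c"]
        plan = make_folds(ids, 3, rng_seed=2)
        assert len({plan.fold_of("a")}) == 1
        assert set(plan.assignments) == {"a", "b", "c"}

    def test_deterministic(self):
        ids = [f"p{i}" for i in range(23)]
        assert make_folds(ids, 5, 7).assignments == make_folds(ids, 5, 7).assignments

    def test_too_many_folds(self):
        with pytest.raises(ValueError):
            make_folds(["a", "b"], 3)


class TestMajorityVote:
    def test_five_of_ten_tie_is_positive(self):
        maps = [np.full((2, 2), 1.0)] * 5 + [np.zeros((2, 2))] * 5
        fused = majority_vote(maps, EnsembleConfig(vote_threshold=0.5))
        assert np.all(fused.pixels == 1)

    def test_unanimity_independent_of_threshold(self, rng):
        m = rng.random((8, 8))
        for t in (0.1, 0.5, 1.0):
            fused = majority_vote([m] * 7, EnsembleConfig(vote_threshold=t))
            assert np.array_equal(fused.pixels, (m >= 0.5).astype(np.uint8))

    def test_mixed_grids_rejected(self, rng):
        with pytest.raises(ValueError, match="grid"):
            majority_vote([rng.random((4, 4)), rng.random((5, 5))])

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(3, 11),
           st.sampled_from([0.3, 0.5, 0.7]))
    def test_matches_brute_force_counting(self, seed, n_members, threshold):
        rng = np.random.default_rng(seed)
        maps = [rng.random((6, 6)) for _ in range(n_members)]
        fused = majority_vote(maps, EnsembleConfig(vote_threshold=threshold))
        oracle = brute_force_vote(maps, 0.5, threshold)
        assert np.array_equal(fused.pixels, oracle)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_permutation_invariance_and_nesting(self, seed):
        rng = np.random.default_rng(seed)
        maps = [rng.random((5, 5)) for _ in range(6)]
        perm = [maps[i] for i in rng.permutation(6)]
        cfg = EnsembleConfig(vote_threshold=0.5)
        assert np.array_equal(majority_vote(maps, cfg).pixels,
                              majority_vote(perm, cfg).pixels)
        lo = majority_vote(maps, EnsembleConfig(vote_threshold=0.3)).pixels
        hi = majority_vote(maps, EnsembleConfig(vote_threshold=0.7)).pixels
        assert np.all(hi <= lo)  # higher threshold is a subset


class TestSweeps:
    def _maps_and_truths(self, rng, n_images=4, n_members=5):
        maps = [[rng.random((8, 8)) for _ in range(n_members)]
                for _ in range(n_images)]
        truths = [(rng.random((8, 8)) > 0.5).astype(np.uint8)
                  for _ in range(n_images)]
        return maps, truths

    def test_area_nonincreasing_in_threshold(self, rng):
        maps, truths = self._maps_and_truths(rng)
        thresholds = np.arange(0.1, 1.01, 0.1)
        for image_maps in maps:
            areas = [majority_vote(image_maps,
                                   EnsembleConfig(vote_threshold=t)).area
                     for t in thresholds]
            assert all(a >= b for a, b in zip(areas, areas[1:]))

    def test_unanimity_nested_in_any_vote(self, rng):
        maps, _ = self._maps_and_truths(rng)
        for image_maps in maps:
            n = len(image_maps)
            any_vote = majority_vote(image_maps,
                                     EnsembleConfig(vote_threshold=1.0 / n)).pixels
            unanimity = majority_vote(image_maps,
                                      EnsembleConfig(vote_threshold=1.0)).pixels
            assert np.all(unanimity <= any_vote)

    def test_threshold_sweep_needs_two_thresholds(self, rng):
        maps, truths = self._maps_and_truths(rng)
        with pytest.raises(ValueError):
            vote_threshold_sweep(maps, truths, [0.5])

    def test_count_sweep_degenerate_and_full(self, rng):
        from busseg.metrics import dice
        maps, truths = self._maps_and_truths(rng)
        curve = member_count_sweep(maps, truths, [1, 5])
        single = np.mean([
            dice((m[0] >= 0.5).astype(np.uint8), t) for m, t in zip(maps, truths)])
        full = np.mean([
            dice(majority_vote(m, EnsembleConfig()).pixels, t)
            for m, t in zip(maps, truths)])
        assert curve[1] == pytest.approx(single)
        assert curve[5] == pytest.approx(full)

    def test_count_exceeding_members_rejected(self, rng):
        maps, truths = self._maps_and_truths(rng)
        with pytest.raises(ValueError):
            member_count_sweep(maps, truths, [6])


def test_fold_plan_accessors():
    plan = FoldPlan(n_folds=2, assignments={"a": 0, "b": 1, "c": 0})
    assert plan.fold_of("b") == 1
    assert plan.patients_in(0) == ["a", "c"]
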