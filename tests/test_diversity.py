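"""Simpson diversity/clonality, Jaccard, and the resampling normalization,
checked against brute-force enumeration oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from repsubsets import (RepLabel, jaccard_index, overlap_means,
                        pairwise_overlap_matrix, resampled_clonality,
                        resampled_jaccard, simpson_clonality,
                        simpson_diversity, subsample_unique)
from repsubsets.exceptions import (SizeError, UndefinedStatisticError,
                                   ValidationError)

from conftest import make_keyed_repertoire, make_repertoire


def pair_fraction_oracle(counts):
    """Probability two distinct cells (ordered pair) share a clone, by
    explicit enumeration over the expanded cell list."""
    cells = [i for i, c in enumerate(counts) for _ in range(c)]
    same = total = 0
    for a in range(len(cells)):
        for b in range(len(cells)):
            if a != b:
                total += 1
                same += cells[a] == cells[b]
    return same / total


class TestSimpson:
    def test_single_clone_is_monoclonal(self):
        assert simpson_diversity([7]) == 1.0
        assert simpson_clonality([7]) == 1.0

    def test_all_singletons_fully_polyclonal(self):
        assert simpson_diversity([1] * 20) == 0.0
        assert simpson_clonality([1] * 20) == 0.0

    def test_small_example_matches_pair_enumeration(self):
        # counts [2,1,1]: 2 same-clone ordered pairs of 12
        assert simpson_diversity([2, 1, 1]) == pytest.approx(2 / 12, abs=1e-15)
        assert simpson_clonality([2, 1, 1]) == pytest.approx(
            math.sqrt(1 / 6), abs=1e-15)

    def test_undefined_below_two_cells(self):
        with pytest.raises(UndefinedStatisticError):
            simpson_diversity([1])

    @pytest.mark.parametrize("bad", [[0, 2], [-1, 3], [1.5, 2]])
    def test_invalid_counts_rejected(self, bad):
        with pytest.raises(ValidationError):
            simpson_diversity(bad)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(counts=st.lists(st.integers(1, 6), min_size=1, max_size=8)
           .filter(lambda c: sum(c) >= 2))
    def test_matches_brute_force_on_small_repertoires(self, counts):
        assert simpson_diversity(counts) == pytest.approx(
            pair_fraction_oracle(counts), abs=1e-12)
        assert simpson_clonality(counts) ** 2 == pytest.approx(
            simpson_diversity(counts), abs=1e-12)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(counts=st.lists(st.integers(1, 10), min_size=2, max_size=10))
    def test_merging_two_clones_increases_diversity(self, counts):
        merged = [counts[0] + counts[1]] + counts[2:]
        assert simpson_diversity(merged) > simpson_diversity(counts)


class TestJaccard:
    def test_identical_sets_give_one(self):
        assert jaccard_index({"a", "b"}, {"a", "b"}) == 1.0

    def test_disjoint_sets_give_zero(self):
        assert jaccard_index({"a"}, {"b"}) == 0.0

    def test_partial_overlap(self):
        assert jaccard_index({"a", "b", "c"}, {"b", "c", "d"}) == 0.5

    def test_empty_set_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            jaccard_index(set(), {"a"})

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(a=st.sets(st.integers(0, 30), min_size=1, max_size=20),
           b=st.sets(st.integers(0, 30), min_size=1, max_size=20))
    def test_symmetric_and_bounded(self, a, b):
        j = jaccard_index(a, b)
        assert j == jaccard_index(b, a)
        assert 0.0 <= j <= 1.0


class TestSubsampleUnique:
    def test_full_depth_returns_input(self, rng):
        rep = make_repertoire([3, 2, 1])
        assert subsample_unique(rep, rep.R, rng) == rep

    def test_size_errors(self, rng):
        rep = make_repertoire([1, 1])
        with pytest.raises(SizeError):
            subsample_unique(rep, 3, rng)
        with pytest.raises(ValidationError):
            subsample_unique(rep, 0, rng)

    def test_k1_selection_uniform_within_binomial_error(self, rng):
        rep = make_repertoire([5, 2, 1])
        hits = {r.cdr3_nt: 0 for r in rep.clonotypes}
        n_draws = 30_000
        for _ in range(n_draws):
            hits[subsample_unique(rep, 1, rng).clonotypes[0].cdr3_nt] += 1
        se = math.sqrt((1 / 3) * (2 / 3) / n_draws)
        for count in hits.values():
            assert abs(count / n_draws - 1 / 3) < 3 * se

    def test_k2_subsets_equally_likely(self, rng):
        rep = make_repertoire([1, 1, 1])
        freq: dict = {}
        n_draws = 9_000
        for _ in range(n_draws):
            sub = subsample_unique(rep, 2, rng)
            key = frozenset(r.cdr3_nt for r in sub.clonotypes)
            freq[key] = freq.get(key, 0) + 1
        assert len(freq) == 3
        se = math.sqrt((1 / 3) * (2 / 3) / n_draws)
        for count in freq.values():
            assert abs(count / n_draws - 1 / 3) < 4 * se

    def test_counts_are_retained(self, rng):
        rep = make_repertoire([10, 1, 1, 1])
        sub = subsample_unique(rep, 2, rng)
        originals = {r.cdr3_nt: r.templates for r in rep.clonotypes}
        for r in sub.clonotypes:
            assert r.templates == originals[r.cdr3_nt]


class TestResampledClonality:
    def test_full_depth_reproduces_point_value_with_zero_sd(self):
        rep = make_repertoire([4, 2, 1])
        res = resampled_clonality(rep, k=rep.R, n_iter=50, seed=9)
        assert res.resampled_mean == res.point_value
        assert res.resampled_sd == 0.0

    def test_same_seed_is_bit_identical(self):
        rep = make_repertoire([10] + [1] * 9)
        a = resampled_clonality(rep, k=5, n_iter=300, seed=42)
        b = resampled_clonality(rep, k=5, n_iter=300, seed=42)
        assert a == b

    def test_matches_exhaustive_subset_expectation(self):
        # counts (10,1,...,1), k=5: enumerate all C(10,5)=252 subsets
        counts = [10] + [1] * 9
        rep = make_repertoire(counts)
        vals = [simpson_clonality([counts[i] for i in sub])
                for sub in itertools.combinations(range(10), 5)]
        exact_mean, exact_sd = np.mean(vals), np.std(vals)
        n_iter = 10_000
        res = resampled_clonality(rep, k=5, n_iter=n_iter, seed=7)
        mc_se = exact_sd / math.sqrt(n_iter)
        assert abs(res.resampled_mean - exact_mean) < 3 * mc_se

    def test_spread_shrinks_with_iteration_count(self):
        # Monte-Carlo error of the mean scales as 1/sqrt(n_iter)
        rep = make_repertoire([10] + [1] * 9)
        means = {n_iter: [resampled_clonality(rep, 5, n_iter, seed).resampled_mean
                          for seed in range(12)]
                 for n_iter in (100, 10_000)}
        ratio = np.std(means[100]) / np.std(means[10_000])
        assert 3 < ratio < 33  # expected ~10


def _shared_pair():
    rep_a = make_keyed_repertoire([1, 2, 3, 4, 5, 6],
                                  label=RepLabel(donor_id="A"))
    rep_b = make_keyed_repertoire([4, 5, 6, 7, 8, 9],
                                  label=RepLabel(donor_id="B"))
    return rep_a, rep_b


class TestResampledJaccard:
    def test_identical_repertoires_at_full_depth_give_one(self):
        rep = make_repertoire([3, 2, 1])
        res = resampled_jaccard(rep, rep, k=rep.R, n_iter=20, seed=1)
        assert res.jaccard_mean == 1.0 and res.jaccard_sd == 0.0

    def test_disjoint_repertoires_give_zero(self):
        rep_a = make_keyed_repertoire([1, 2, 3], label=RepLabel(donor_id="A"))
        rep_b = make_keyed_repertoire([7, 8, 9], label=RepLabel(donor_id="B"))
        res = resampled_jaccard(rep_a, rep_b, k=2, n_iter=50, seed=1)
        assert res.jaccard_mean == 0.0
        assert res.n_shared_full == 0

    def test_matches_exhaustive_pair_enumeration(self):
        # 6 vs 6 clonotypes, 3 shared, k=3: all C(6,3)^2 = 400 subsample pairs
        rep_a, rep_b = _shared_pair()
        keys_a, keys_b = rep_a.keys(), rep_b.keys()
        vals = [jaccard_index(set(sa), set(sb))
                for sa in itertools.combinations(keys_a, 3)
                for sb in itertools.combinations(keys_b, 3)]
        assert len(vals) == 400
        exact_mean, exact_sd = np.mean(vals), np.std(vals)
        n_iter = 10_000
        res = resampled_jaccard(rep_a, rep_b, k=3, n_iter=n_iter, seed=11)
        assert abs(res.jaccard_mean - exact_mean) < 3 * exact_sd / math.sqrt(n_iter)
        assert res.n_shared_full == 3

    def test_symmetric_under_argument_swap(self):
        rep_a, rep_b = _shared_pair()
        ab = resampled_jaccard(rep_a, rep_b, k=3, n_iter=500, seed=5)
        ba = resampled_jaccard(rep_b, rep_a, k=3, n_iter=500, seed=5)
        assert ab.jaccard_mean == ba.jaccard_mean
        assert ab.jaccard_sd == ba.jaccard_sd

    def test_k_exceeding_either_r_rejected(self):
        rep_a, rep_b = _shared_pair()
        with pytest.raises(SizeError):
            resampled_jaccard(rep_a, rep_b, k=7, n_iter=10, seed=0)


class TestOverlapMatrix:
    def test_identical_repertoires_off_diagonal_one(self):
        rep = make_repertoire([2, 1, 1])
        other = rep.with_label(RepLabel(donor_id="other"))
        mat = overlap_means(pairwise_overlap_matrix(
            [rep, other], n_iter=50, seed=2))
        assert mat.iloc[0, 1] == 1.0
        assert np.all(np.diag(mat) == 1.0)

    def test_disjoint_repertoires_all_zero_off_diagonal(self):
        reps = [make_keyed_repertoire(range(10 * i, 10 * i + 4),
                                      label=RepLabel(donor_id=f"D{i}"))
                for i in range(3)]
        mat = overlap_means(pairwise_overlap_matrix(reps, n_iter=30, seed=3))
        off = mat.to_numpy()[~np.eye(3, dtype=bool)]
        assert np.all(off == 0.0)

    def test_matrix_is_symmetric(self):
        reps = [make_keyed_repertoire([1, 2, 3, 4], label=RepLabel(donor_id="A")),
                make_keyed_repertoire([3, 4, 5, 6], label=RepLabel(donor_id="B")),
                make_keyed_repertoire([1, 4, 6, 8], label=RepLabel(donor_id="C"))]
        mat = overlap_means(pairwise_overlap_matrix(reps, n_iter=200, seed=4))
        assert np.allclose(mat.to_numpy(), mat.to_numpy().T)

    def test_fewer_than_two_repertoires_rejected(self):
        with pytest.raises(ValidationError):
            pairwise_overlap_matrix([make_repertoire([1, 1])],
                                    n_iter=10, seed=0)
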