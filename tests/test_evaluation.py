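import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gtascan.evaluation import (
    C_GRID,
    T_GRID,
    CVResult,
    GridPoint,
    cross_validate,
    enumerate_grid,
    kfold_split,
    mcc,
    select_best,
)
from gtascan.io import LabeledTrainingSet
from gtascan.synthetic import sample_training_set


class TestKfold:
    def test_even_split(self):
        labels = np.array([-1] * 5 + [1] * 5)
        folds = kfold_split(labels, 5, np.random.default_rng(0))
        assert sorted(len(f) for f in folds) == [2] * 5

    def test_folds_partition_indices(self):
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(10, 40))
            labels = np.where(rng.random(n) < 0.3, -1, 1)
            labels[:5] = -1  # ensure 5 in the minority class
            folds = kfold_split(labels, 5, rng)
            joined = np.concatenate(folds)
            assert sorted(joined.tolist()) == list(range(n))
            sizes = [len(f) for f in folds]
            assert max(sizes) - min(sizes) <= 1

    def test_stratification_keeps_both_classes(self):
        labels = np.array([-1] * 6 + [1] * 24)
        folds = kfold_split(labels, 5, np.random.default_rng(1))
        for f in folds:
            assert set(labels[f]) == {-1, 1}

    def test_same_seed_identical_folds(self):
        labels = np.array([-1] * 10 + [1] * 10)
        a = kfold_split(labels, 5, np.random.default_rng(42))
        b = kfold_split(labels, 5, np.random.default_rng(42))
        assert all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            kfold_split(np.array([1, -1]), 5)


class TestMCC:
    @pytest.mark.parametrize(
        "counts,expected",
        [((10, 10, 0, 0), 1.0), ((5, 5, 5, 5), 0.0), ((0, 0, 5, 5), -1.0)],
    )
    def test_known_values(self, counts, expected):
        assert mcc(*counts) == pytest.approx(expected)

    def test_matches_brute_force_formula(self):
        tp, tn, fp, fn = 8, 6, 2, 4
        expected = (8 * 6 - 2 * 4) / np.sqrt((8 + 2) * (8 + 4) * (6 + 2) * (6 + 4))
        assert mcc(tp, tn, fp, fn) == pytest.approx(expected)

    def test_zero_denominator_convention(self):
        assert mcc(5, 0, 0, 5) == 0.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            mcc(-1, 0, 0, 0)

    @settings(max_examples=300, derandomize=True, deadline=None)
    @given(st.tuples(*[st.integers(0, 500)] * 4))
    def test_bounded_on_random_confusion_tables(self, counts):
        if sum(counts) == 0:
            return
        assert -1.0 <= mcc(*counts) <= 1.0


class TestGrid:
    def test_default_grid_has_1435_points(self):
        grid = enumerate_grid()
        assert len(grid) == 1435

    def test_feature_combinations_count(self):
        combos = {
            (gp.kmer_k, gp.pseaac_lambda, gp.physchem) for gp in enumerate_grid()
        }
        assert len(combos) == 41  # (6+1)(2+1)(1+1) - 1

    def test_all_points_valid(self):
        for gp in enumerate_grid():
            assert gp.C in C_GRID and gp.t in T_GRID

    def test_out_of_grid_values_rejected(self):
        with pytest.raises(ValueError):
            GridPoint(2, None, False, 7.0, 0)
        with pytest.raises(ValueError):
            GridPoint(None, None, False, 100, 0)


def _result(k=2, lam=None, pc=False, C=100.0, t=0.0, was=100.0, m=1.0):
    aas = was / 100.0
    return CVResult(GridPoint(k, lam, pc, C, t), aas, aas, m)


def independent_cascade(results):
    """Plain re-implementation of the selection cascade for cross-checking."""
    best = max(r.was for r in results)
    cand = [r for r in results if abs(r.was - best) < 1e-9]
    if len(cand) > 1:
        k_mean = {}
        for r in cand:
            k = r.grid_point.kmer_k
            vals = [x.was for x in results if x.grid_point.kmer_k == k]
            k_mean[k] = sum(vals) / len(vals)
        top = max(k_mean.values())
        cand = [r for r in cand if k_mean[r.grid_point.kmer_k] >= top - 1e-9]
    if len(cand) > 1:
        plain = [r for r in cand if r.grid_point.pseaac_lambda is None
                 and not r.grid_point.physchem]
        cand = plain or cand
    if len(cand) > 1:
        c_mean = {}
        for r in cand:
            C = r.grid_point.C
            vals = [x.was for x in cand if x.grid_point.C == C]
            c_mean[C] = sum(vals) / len(vals)
        top = max(c_mean.values())
        cand = [r for r in cand if c_mean[r.grid_point.C] >= top - 1e-9]
    if len(cand) > 1:
        t_mean = {}
        for r in cand:
            t = r.grid_point.t
            vals = [x.was for x in cand if x.grid_point.t == t]
            t_mean[t] = sum(vals) / len(vals)
        top = max(t_mean.values())
        cand = [r for r in cand if t_mean[r.grid_point.t] >= top - 1e-9]
    return min(cand, key=lambda r: r.grid_point.sort_key()).grid_point


class TestSelectBest:
    def test_single_maximum_returned(self):
        results = [_result(was=90.0), _result(k=3, was=99.0)]
        assert select_best(results).kmer_k == 3

    def test_plain_kmer_preferred_over_composite(self):
        results = [
            _result(k=2, was=99.0),
            _result(k=2, lam=3, was=99.0),
        ]
        best = select_best(results)
        assert best.pseaac_lambda is None and not best.physchem

    def test_constructed_tie_matches_independent_cascade(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            results = []
            for k in (2, 3):
                for C in (0.1, 100.0):
                    for t in (0.0, 0.02, 0.05):
                        was = float(rng.choice([97.0, 100.0]))
                        results.append(_result(k=k, C=C, t=t, was=was))
            assert select_best(results) == independent_cascade(results)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            select_best([])


class TestCrossValidate:
    def test_separable_classes_score_perfectly(self):
        # two disjoint homopolymer classes are linearly separable at k=1
        from gtascan.io import SequenceRecord, make_training_set

        gta = [SequenceRecord(f"g{i}", "A" * (30 + i)) for i in range(10)]
        virus = [SequenceRecord(f"v{i}", "L" * (30 + i)) for i in range(10)]
        ts = make_training_set(gta, virus)
        r = cross_validate(ts, None, GridPoint(1, None, False, 100, 0),
                           repeats=2, seed=0)
        assert r.was == 100.0
        assert r.mcc == 1.0

    def test_eq9_identity(self):
        r = CVResult(GridPoint(2, None, False, 100, 0), 0.9, 0.8, 0.5)
        assert r.was == pytest.approx(85.0)

    def test_shuffled_labels_near_chance(self, skewed_training_set):
        rng = np.random.default_rng(0)
        ts = skewed_training_set
        shuffled = LabeledTrainingSet(
            ts.records, rng.permutation(ts.labels), ts.weights
        )
        r = cross_validate(shuffled, None, GridPoint(2, None, False, 100, 0),
                           repeats=2, seed=0)
        assert 30.0 < r.was < 70.0
        assert abs(r.mcc) < 0.4

    def test_determinism_same_seed(self, skewed_training_set):
        gp = GridPoint(2, None, False, 100, 0)
        a = cross_validate(skewed_training_set, None, gp, repeats=1, seed=9)
        b = cross_validate(skewed_training_set, None, gp, repeats=1, seed=9)
        assert a.aas_gta == b.aas_gta
        assert a.aas_virus == b.aas_virus
        assert a.confusion == b.confusion

    def test_weighting_requires_distances(self, skewed_training_set):
        with pytest.raises(ValueError, match="distance matrix"):
            cross_validate(skewed_training_set, None,
                           GridPoint(2, None, False, 100, 0.05), repeats=1, seed=0)
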