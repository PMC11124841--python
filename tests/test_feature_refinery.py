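from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from motionloc.core_io import FeatureMatrix, SignalWindow
from motionloc.errors import (
    DegenerateSignalError,
    EmptySelectionError,
    ParameterError,
    SchemaError,
)
from motionloc.feature_refinery import (
    apply_refinery,
    balance_classes,
    feature_variance,
    fit_lambda,
    fit_refinery,
    permute_window,
    select_by_variance,
    yeo_johnson,
    RefineryState,
)


def _matrix(rows, names=None, labels=None):
    rows = np.asarray(rows, dtype=float)
    names = names or [f"f{i}" for i in range(rows.shape[1])]
    labels = labels or ["a"] * rows.shape[0]
    return FeatureMatrix(names, rows, labels, np.zeros(rows.shape[0], dtype=bool))


def _window(channels, label="walk", n=12):
    return SignalWindow(
        source_id="rec",
        channels=channels,
        start_time=0.0,
        duration=n / 32.0,
        sample_rate_hz=32.0,
        label=label,
    )


class TestVariance:
    def test_constant_column_zero(self):
        assert feature_variance(np.full(10, 3.0)) == 0.0

    def test_exact_value(self):
        assert feature_variance(np.array([1.0, 2.0, 3.0])) == pytest.approx(2.0 / 3.0)

    def test_shift_invariance(self, rng):
        x = rng.normal(size=100)
        assert feature_variance(x + 42.0) == pytest.approx(feature_variance(x))


class TestSelectByVariance:
    def test_zero_threshold_drops_only_constants(self, rng):
        fm = _matrix(np.column_stack([rng.normal(size=20), np.full(20, 5.0)]))
        selected, state = select_by_variance(fm, 0.0)
        assert selected.feature_names == ["f0"]
        assert state.kept_features == ["f0"]

    def test_threshold_monotonicity(self, rng):
        fm = _matrix(rng.normal(size=(50, 8)) * rng.uniform(0.1, 3.0, size=8))
        kept_low, _ = select_by_variance(fm, 0.05)
        kept_high, _ = select_by_variance(fm, 0.5)
        assert set(kept_high.feature_names) <= set(kept_low.feature_names)

    def test_all_removed_raises(self):
        fm = _matrix(np.ones((5, 2)))
        with pytest.raises(EmptySelectionError, match="lower"):
            select_by_variance(fm, 0.0)

    def test_column_order_preserved(self, rng):
        fm = _matrix(rng.normal(size=(30, 5)))
        selected, _ = select_by_variance(fm, 0.0)
        assert selected.feature_names == fm.feature_names


class TestPermuteWindow:
    def _channels(self, n=12):
        return {"acc_x": np.arange(float(n)), "acc_y": 100.0 + np.arange(float(n))}

    def test_sample_multiset_preserved(self):
        w = _window(self._channels())
        out = permute_window(w, 3, rng_seed=0)
        for ch in w.channels:
            assert sorted(out.channels[ch]) == sorted(w.channels[ch])

    def test_result_is_non_identity(self):
        w = _window(self._channels())
        for seed in range(10):
            out = permute_window(w, 3, rng_seed=seed)
            assert not np.array_equal(out.channels["acc_x"], w.channels["acc_x"])

    def test_same_permutation_applies_to_all_channels(self):
        w = _window(self._channels())
        out = permute_window(w, 3, rng_seed=5)
        # both ramps are offset copies, so the rearrangement must match exactly
        assert np.array_equal(out.channels["acc_y"] - 100.0, out.channels["acc_x"])

    def test_fixed_seed_reproducible(self):
        w = _window(self._channels())
        a = permute_window(w, 3, rng_seed=9)
        b = permute_window(w, 3, rng_seed=9)
        assert np.array_equal(a.channels["acc_x"], b.channels["acc_x"])

    def test_flags_and_label_propagate(self):
        w = _window(self._channels(), label="run")
        out = permute_window(w, 3, rng_seed=0)
        assert out.augmented and out.label == "run" and out.source_id == w.source_id

    def test_too_many_segments_rejected(self):
        w = _window(self._channels(4), n=4)
        with pytest.raises(ParameterError):
            permute_window(w, 5, rng_seed=0)


class TestBalanceClasses:
    def _windows(self, counts):
        out = []
        for label, count in counts.items():
            for i in range(count):
                out.append(
                    _window({"acc_x": np.arange(12.0) + i}, label=label)
                )
        return out

    def test_minority_raised_to_majority(self):
        balanced = balance_classes(self._windows({"a": 100, "b": 20}), rng_seed=0)
        counts = Counter(w.label for w in balanced)
        assert counts == {"a": 100, "b": 100}
        assert sum(w.augmented for w in balanced) == 80

    def test_already_balanced_is_identity(self):
        windows = self._windows({"a": 10, "b": 10})
        assert balance_classes(windows, rng_seed=0) == windows

    def test_augmented_windows_trace_to_original_sources(self):
        windows = self._windows({"a": 30, "b": 5})
        balanced = balance_classes(windows, rng_seed=0)
        original_ids = {(w.label, w.source_id) for w in windows}
        for w in balanced:
            if w.augmented:
                assert (w.label, w.source_id) in original_ids

    def test_majority_class_untouched(self):
        windows = self._windows({"a": 20, "b": 4})
        balanced = balance_classes(windows, rng_seed=0)
        majority = [w for w in balanced if w.label == "a"]
        assert majority == [w for w in windows if w.label == "a"]

    def test_single_class_rejected(self):
        with pytest.raises(ParameterError):
            balance_classes(self._windows({"a": 5}), rng_seed=0)


class TestYeoJohnson:
    def test_lambda_one_is_identity_for_nonnegative(self):
        x = np.linspace(0.0, 10.0, 21)
        assert np.allclose(yeo_johnson(x, 1.0), x)

    def test_lambda_zero_log_branch(self):
        assert yeo_johnson(np.e - 1.0, 0.0) == pytest.approx(1.0, abs=1e-12)

    def test_lambda_two_negative_branch(self):
        assert yeo_johnson(-(np.e - 1.0), 2.0) == pytest.approx(-1.0, abs=1e-12)

    @pytest.mark.parametrize("lam", [-2.0, -1.0, 0.0, 0.5, 1.0, 2.0, 3.0])
    def test_zero_maps_to_zero(self, lam):
        assert yeo_johnson(0.0, lam) == 0.0

    @settings(max_examples=50, derandomize=True)
    @given(
        lam=st.sampled_from([-2.0, -1.0, 0.0, 0.5, 1.0, 2.0, 3.0]),
        pair=st.tuples(st.floats(-50.0, 50.0), st.floats(-50.0, 50.0)),
    )
    def test_strictly_increasing(self, lam, pair):
        lo, hi = sorted(pair)
        if hi - lo > 1e-9:  # below float resolution the map cannot separate
            assert yeo_johnson(lo, lam) < yeo_johnson(hi, lam)

    def test_continuity_in_lambda_at_branch_points(self):
        x = np.array([-3.0, -0.5, 0.5, 3.0])
        for eps in (1e-6, 1e-8):
            assert np.allclose(yeo_johnson(x, eps), yeo_johnson(x, 0.0), atol=1e-5)
            assert np.allclose(yeo_johnson(x, 2.0 - eps), yeo_johnson(x, 2.0), atol=1e-5)

    def test_matches_scipy_transform(self, rng):
        x = rng.normal(size=200)
        for lam in (-1.5, 0.0, 0.7, 2.0, 3.2):
            assert np.allclose(yeo_johnson(x, lam), stats.yeojohnson(x, lam), atol=1e-10)


class TestFitLambda:
    def test_normal_sample_lambda_near_one(self):
        x = np.random.default_rng(42).standard_normal(5000)
        assert fit_lambda(x) == pytest.approx(1.0, abs=0.15)

    def test_exponential_sample_reduces_skew(self):
        x = np.random.default_rng(7).exponential(size=5000)
        lam = fit_lambda(x)
        assert lam < 0.5
        assert abs(stats.skew(yeo_johnson(x, lam))) < abs(stats.skew(x))

    def test_agrees_with_grid_search_oracle(self, rng):
        from scipy.stats import yeojohnson_llf

        for _ in range(3):
            x = rng.gamma(2.0, size=400)
            grid = np.linspace(-5.0, 5.0, 10_001)
            llf = np.array([yeojohnson_llf(l, x) for l in grid])
            oracle = grid[int(np.argmax(llf))]
            assert fit_lambda(x) == pytest.approx(oracle, abs=1e-3)

    def test_constant_column_rejected(self):
        with pytest.raises(DegenerateSignalError):
            fit_lambda(np.full(100, 2.0))


class TestFitApplyRefinery:
    def _training_matrix(self, rng):
        rows = np.column_stack(
            [
                rng.exponential(size=80),
                rng.normal(5.0, 2.0, size=80),
                np.full(80, 9.0),  # constant; must be dropped
            ]
        )
        return _matrix(rows, names=["expo", "gauss", "flat"])

    def test_training_columns_standardized(self, rng):
        fm = self._training_matrix(rng)
        state = fit_refinery(fm, 0.0)
        out = apply_refinery(fm, state)
        assert out.feature_names == ["expo", "gauss"]
        assert np.allclose(out.rows.mean(axis=0), 0.0, atol=1e-9)
        assert np.allclose(out.rows.std(axis=0), 1.0, atol=1e-9)

    def test_apply_deterministic_given_state(self, rng):
        fm = self._training_matrix(rng)
        state = fit_refinery(fm, 0.0)
        assert np.array_equal(apply_refinery(fm, state).rows, apply_refinery(fm, state).rows)

    def test_state_round_trips_through_serialization(self, rng, tmp_path):
        fm = self._training_matrix(rng)
        state = fit_refinery(fm, 0.0)
        path = tmp_path / "state.json"
        state.save(path)
        restored = RefineryState.load(path)
        assert np.array_equal(
            apply_refinery(fm, state).rows, apply_refinery(fm, restored).rows
        )

    def test_unseen_feature_names_rejected_at_apply(self, rng):
        fm = self._training_matrix(rng)
        state = fit_refinery(fm, 0.0)
        other = _matrix(rng.normal(size=(10, 2)), names=["x", "y"])
        with pytest.raises(SchemaError):
            apply_refinery(other, state)
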