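"""Transform vocabulary, session replay/undo semantics, summaries."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from chmforge import LabeledMatrix, MatrixSession, TransformStep, summarize
from chmforge.errors import ValidationError
from chmforge.transforms import (
    axis_sd,
    correlation,
    filter_missing,
    filter_top_sd,
    log_transform,
    mean_center,
    replace_missing,
    replay,
    threshold_na,
    transpose,
)
from tests.conftest import random_labeled_matrix


def lm(values, row_labels=None, col_labels=None):
    a = np.asarray(values, dtype=float)
    return LabeledMatrix(
        row_labels or [f"r{i}" for i in range(a.shape[0])],
        col_labels or [f"c{j}" for j in range(a.shape[1])],
        a,
    )


class TestThreshold:
    def test_strictly_below_becomes_missing(self):
        m = threshold_na(lm([[1e-6, 0.00001, 2.0]]), 0.00001)
        assert np.isnan(m.values[0, 0])
        assert m.values[0, 1] == 0.00001  # boundary survives
        assert m.values[0, 2] == 2.0

    def test_identity_when_all_at_or_above(self):
        src = lm([[1.0, 2.0], [3.0, 4.0]])
        assert threshold_na(src, 0.5).equals(src)


class TestLog:
    def test_log10_values(self):
        m = log_transform(lm([[1000.0, 1.0, 0.0, -3.0]]), 10)
        assert m.values[0, 0] == pytest.approx(3.0)
        assert m.values[0, 1] == pytest.approx(0.0)
        assert np.isnan(m.values[0, 2]) and np.isnan(m.values[0, 3])

    def test_invalid_base(self):
        with pytest.raises(ValidationError):
            log_transform(lm([[1.0]]), 1)


class TestMeanCenter:
    def test_row_example(self):
        m = mean_center(lm([[1.0, 2.0, 3.0]]), "row")
        assert m.values.tolist() == [[-1.0, 0.0, 1.0]]

    def test_missing_ignored_in_mean(self):
        m = mean_center(lm([[5.0, np.nan, 7.0]]), "row")
        assert m.values[0, 0] == -1.0 and m.values[0, 2] == 1.0
        assert np.isnan(m.values[0, 1])

    @pytest.mark.parametrize("axis", ["row", "col"])
    def test_postcondition_zero_means(self, axis):
        rng = np.random.default_rng(11)
        m = mean_center(random_labeled_matrix(rng, 10, 8, missing_frac=0.2), axis)
        means = np.nanmean(m.values, axis=1 if axis == "row" else 0)
        ok = ~np.isnan(means)
        assert np.all(np.abs(means[ok]) < 1e-12)

    def test_all_missing_vector_unchanged(self):
        m = mean_center(lm([[np.nan, np.nan], [1.0, 3.0]]), "row")
        assert np.isnan(m.values[0]).all()
        assert m.values[1].tolist() == [-1.0, 1.0]


class TestTranspose:
    def test_involution_and_labels(self):
        rng = np.random.default_rng(3)
        m = random_labeled_matrix(rng, 2, 3)
        t = transpose(m)
        assert (t.row_labels, t.col_labels) == (m.col_labels, m.row_labels)
        assert transpose(t).equals(m)


class TestCorrelation:
    def test_identical_and_negated_rows(self):
        m = correlation(lm([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [-1.0, -2.0, -3.0]]), "row")
        assert m.values[0, 1] == pytest.approx(1.0)
        assert m.values[0, 2] == pytest.approx(-1.0)
        assert np.allclose(np.diag(m.values), 1.0)
        assert m.row_labels == m.col_labels

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(3, 50))
        m = correlation(lm(x), "row")
        for i in range(3):
            for j in range(3):
                a, b = x[i] - x[i].mean(), x[j] - x[j].mean()
                expected = np.dot(a, b) / np.sqrt((a**2).sum() * (b**2).sum())
                assert m.values[i, j] == pytest.approx(expected, abs=1e-10)

    def test_zero_variance_pair_missing(self):
        m = correlation(lm([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]]), "row")
        assert np.isnan(m.values[0, 1])
        assert m.values[0, 0] == 1.0


class TestReplaceAndFilters:
    def test_replace_missing_constant(self):
        m = replace_missing(lm([[np.nan, 1.0], [np.nan, np.nan]]), 0.0)
        assert not np.isnan(m.values).any()
        assert (m.values == 0).sum() == 3

    def test_filter_missing_boundary_kept_strict_removed(self):
        rows = [
            [1.0, 2.0, np.nan, np.nan],  # exactly 50% -> kept
            [1.0, np.nan, np.nan, np.nan],  # 75% -> removed
            [1.0, 2.0, 3.0, 4.0],
        ]
        m = filter_missing(lm(rows), "row", 50)
        assert m.row_labels == ["r0", "r2"]

    def test_filter_missing_100_keeps_all(self):
        src = lm([[np.nan, np.nan], [1.0, 2.0]])
        assert filter_missing(src, "row", 100).n_rows == 2

    def test_filter_missing_all_removed_errors(self):
        with pytest.raises(ValidationError):
            filter_missing(lm([[np.nan, np.nan]]), "row", 0)

    def test_filter_top_sd_brute_force(self):
        rows = [[1.0, 1.0, 1.0], [0.0, 1.0, 2.0], [0.0, 2.0, 4.0]]  # SDs 0, 1, 2
        m = filter_top_sd(lm(rows), "row", 2)
        assert m.row_labels == ["r1", "r2"]

    def test_filter_top_sd_identity_when_small(self):
        src = lm([[1.0, 2.0], [3.0, 4.0]])
        assert filter_top_sd(src, "row", 5).equals(src)

    def test_filter_top_sd_tie_prefers_earlier_row(self):
        rows = [[0.0, 2.0], [0.0, 2.0], [0.0, 10.0]]
        m = filter_top_sd(lm(rows), "row", 2)
        assert m.row_labels == ["r0", "r2"]

    def test_kept_sds_dominate_removed(self):
        rng = np.random.default_rng(21)
        src = random_labeled_matrix(rng, 30, 10, missing_frac=0.1)
        kept = filter_top_sd(src, "row", 12)
        kept_set = set(kept.row_labels)
        sds = dict(zip(src.row_labels, axis_sd(src, "row")))
        min_kept = min(sds[r] for r in kept_set)
        max_dropped = max(sds[r] for r in sds if r not in kept_set)
        assert min_kept >= max_dropped

    def test_sd_short_vectors_sort_last(self):
        rows = [[5.0, np.nan, np.nan], [0.0, 1.0, 2.0]]
        assert filter_top_sd(lm(rows), "row", 1).row_labels == ["r1"]


class TestSession:
    def _steps(self):
        return [
            TransformStep("threshold_na", {"cutoff": 0.5}),
            TransformStep("log", {"base": 10}),
            TransformStep("mean_center_row", {}),
            TransformStep("filter_missing_row", {"max_pct": 50}),
        ]

    def test_apply_appends_history(self, small_matrix):
        s = MatrixSession(original=lm(np.abs(np.random.default_rng(0).normal(size=(8, 5))) + 0.1))
        for step in self._steps():
            s.apply_step(step)
        assert len(s.history) == 4

    def test_failed_step_is_atomic(self, small_matrix):
        s = MatrixSession(original=small_matrix)
        before = s.working.copy()
        with pytest.raises(ValidationError):
            s.apply_step(TransformStep("log", {"base": 1}))
        assert s.working.equals(before) and s.history == []

    def test_undo_to_zero_restores_original(self, small_matrix):
        s = MatrixSession(original=small_matrix)
        s.apply_step(TransformStep("mean_center_row", {}))
        s.undo_to(0)
        assert s.working.equals(small_matrix) and s.history == []

    def test_undo_prefix_equals_fresh_replay(self):
        rng = np.random.default_rng(5)
        original = lm(np.abs(rng.normal(size=(12, 6))) + 0.01)
        steps = self._steps()
        for k in range(len(steps) + 1):
            s = MatrixSession(original=original)
            for step in steps:
                s.apply_step(step)
            s.undo_to(k)
            fresh = MatrixSession(original=original)
            for step in steps[:k]:
                fresh.apply_step(step)
            assert s.working.equals(fresh.working)
            assert s.working.equals(replay(original, steps[:k]))

    def test_undo_out_of_range(self, small_matrix):
        with pytest.raises(ValidationError):
            MatrixSession(original=small_matrix).undo_to(1)

    @given(st.lists(st.sampled_from(["threshold_na", "mean_center_row", "transpose", "replace_missing"]), max_size=6))
    def test_session_invariant_any_sequence(self, actions):
        """working == replay(original, history) after arbitrary sequences."""
        rng = np.random.default_rng(42)
        s = MatrixSession(original=lm(rng.normal(size=(6, 5))))
        params = {"threshold_na": {"cutoff": 0.0}, "replace_missing": {"value": 0.0}}
        for a in actions:
            s.apply_step(TransformStep(a, params.get(a, {})))
        assert s.working.equals(replay(s.original, s.history))


class TestStepSerialization:
    @pytest.mark.parametrize(
        "step",
        [
            TransformStep("threshold_na", {"cutoff": 1e-05}),
            TransformStep("dedupe", {"axis": "col", "mode": "rename"}),
            TransformStep("filter_sd_row", {"keep_n": 500}),
            TransformStep("mean_center_row", {}),
        ],
    )
    def test_round_trip_replays_identically(self, step):
        rng = np.random.default_rng(9)
        m = lm(np.abs(rng.normal(size=(10, 6))) + 1e-7)
        back = TransformStep.deserialize(step.serialize())
        assert back == step
        assert back.apply(m).equals(step.apply(m))


class TestSummarize:
    def test_two_bin_histogram(self):
        stats = summarize(lm([[1.0, 2.0], [3.0, 4.0]]), n_bins=2)
        assert stats.bin_counts.tolist() == [2, 2]

    def test_histogram_conservation(self):
        rng = np.random.default_rng(2)
        m = random_labeled_matrix(rng, 15, 9, missing_frac=0.25)
        stats = summarize(m)
        assert stats.bin_counts.sum() == (~np.isnan(m.values)).sum()

    def test_size_flag(self):
        m = LabeledMatrix(["r"], [f"c{j}" for j in range(9)], np.zeros((1, 9)))
        stats = summarize(m, size_limit=8)
        assert any("limit" in f for f in stats.flags)

    def test_duplicate_label_flag(self):
        m = LabeledMatrix(["r"], ["A", "A"], np.zeros((1, 2)))
        assert any("duplicate" in f for f in summarize(m).flags)

    def test_constant_data_single_bin(self):
        stats = summarize(lm([[2.0, 2.0, 2.0]]))
        assert stats.bin_counts.tolist() == [3]
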