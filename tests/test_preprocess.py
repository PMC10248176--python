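"""Segmentation, filtering, feature extraction, splitting, windowing."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gazeintent import preprocess, simulate
from gazeintent.preprocess import (FeatureStream, MovementSegment, PreprocessError,
                                   WindowSpec, augment, apply_normalizer,
                                   default_step, default_window_size,
                                   extract_features, fit_normalizer,
                                   invert_normalizer, length_filter, relabel,
                                   segment_movements, split_stream, windowize)


def make_stream(T, n_features=6, seed=0, movement_len=50):
    rng = np.random.default_rng(seed)
    mv = np.arange(T) // movement_len
    return FeatureStream(X=rng.normal(size=(T, n_features)),
                         cls=rng.integers(0, 10, T), vert=rng.integers(0, 2, T),
                         movement=mv, orig_index=np.arange(T))


# --------------------------------------------------------------------------
# segmentation
# --------------------------------------------------------------------------

class TestSegmentation:
    def test_segments_reproduce_constructed_lengths(self, small_logs):
        log = small_logs[0]
        segs = segment_movements(log)
        starts = np.concatenate([[0], np.flatnonzero(np.diff(log.movement) != 0) + 1])
        expected = [int(np.sum(log.movement == log.movement[s]))
                    for s in starts if not log.warmup[s]]
        assert [s.length for s in segs] == expected

    def test_warmup_movements_absent(self, small_logs):
        segs = segment_movements(small_logs[0])
        warm_ids = set(np.unique(small_logs[0].movement[small_logs[0].warmup]))
        assert warm_ids  # the generator did emit warm-up movements
        assert not warm_ids & {s.movement for s in segs}

    def test_segments_partition_the_non_warmup_log(self, small_logs):
        log = small_logs[0]
        segs = segment_movements(log)
        assert sum(s.length for s in segs) == int((~log.warmup).sum())
        for a, b in zip(segs, segs[1:]):
            assert a.end == b.start


class TestLengthFilter:
    def test_worked_example_mean175_sd66(self):
        # construct lengths with exact mean 175 and SD 66
        lengths = [175 - 66, 175 + 66] * 5
        segs = [MovementSegment(0, L, 0, i) for i, L in enumerate(lengths)]
        stats, kept = length_filter(segs)
        assert stats.mean == 175
        assert stats.sd == 66
        assert stats.threshold == 175 + 3 * 66 == 373
        assert len(kept) == len(segs)

    def test_equal_lengths_remove_nothing(self):
        segs = [MovementSegment(i * 100, (i + 1) * 100, 0, i) for i in range(5)]
        stats, kept = length_filter(segs)
        assert stats.sd == 0 and stats.threshold == 100
        assert len(kept) == 5

    def test_matches_bruteforce_comprehension(self):
        rng = np.random.default_rng(9)
        lengths = rng.integers(50, 600, size=200)
        segs = [MovementSegment(0, int(L), 0, i) for i, L in enumerate(lengths)]
        stats, kept = length_filter(segs)
        thr = lengths.mean() + 3 * lengths.std()
        oracle = [s for s in segs if s.length <= thr]
        assert kept == oracle
        assert all(s.length <= stats.threshold for s in kept)

    def test_single_segment_rejected(self):
        with pytest.raises(PreprocessError):
            length_filter([MovementSegment(0, 10, 0, 0)])


# --------------------------------------------------------------------------
# features and labels
# --------------------------------------------------------------------------

class TestFeatures:
    def _tiny_log(self, eye_l, eye_r, pupil=None, T=None):
        T = T or len(eye_l)
        z = np.zeros((T, 3))
        head = np.tile([1.6, 0.1, 0.2], (T, 1))
        return simulate.SessionLog(
            timestamp=np.arange(T) / 120, eye_left=np.asarray(eye_l, float),
            eye_right=np.asarray(eye_r, float),
            pupil_left=np.asarray(pupil if pupil is not None else np.full(T, 3.0)),
            pupil_right=np.full(T, 4.0), head=head, ctrl_left=z, ctrl_right=z,
            box=np.zeros(T, int), warmup=np.zeros(T, bool), movement=np.zeros(T, int))

    def test_eye_average_is_plain_mean_not_renormalized(self):
        log = self._tiny_log([[1, 0, 0]], [[0, 1, 0]])
        X = extract_features(log)
        assert np.allclose(X[0, :3], [0.5, 0.5, 0.0])  # norm < 1, by design

    def test_pupil_average_and_head_axis_selection(self):
        log = self._tiny_log([[1, 0, 0]], [[1, 0, 0]])
        X = extract_features(log)
        assert X[0, 3] == pytest.approx(3.5)
        assert np.allclose(X[0, 4:], [0.1, 0.2])  # head axes 1-2; height dropped

    def test_nan_takes_previous_sample(self):
        eye = [[1, 0, 0], [np.nan] * 3, [0, 0, 1]]
        log = self._tiny_log(eye, eye)
        X = extract_features(log)
        assert np.allclose(X[1], X[0])
        assert not np.isnan(X).any()

    def test_leading_nan_backfilled_from_first_valid(self):
        eye = [[np.nan] * 3, [np.nan] * 3, [0, 1, 0]]
        log = self._tiny_log(eye, eye)
        X = extract_features(log)
        assert np.allclose(X[0], X[2])
        assert np.allclose(X[1], X[2])

    def test_all_nan_channel_rejected(self):
        eye = [[np.nan] * 3] * 4
        with pytest.raises(PreprocessError):
            extract_features(self._tiny_log(eye, eye))


@pytest.mark.parametrize("box,expected", [
    (0, (0, 0)), (9, (9, 0)), (10, (1, 1)), (14, (5, 1)), (18, (9, 1))])
def test_relabel(box, expected):
    assert relabel(box) == expected


def test_relabel_out_of_range():
    with pytest.raises(PreprocessError):
        relabel(19)


# --------------------------------------------------------------------------
# split / normalize / augment
# --------------------------------------------------------------------------

class TestSplit:
    def test_45_5_50_proportions(self):
        tr, va, te = split_stream(make_stream(1000))
        assert (len(tr), len(va), len(te)) == (450, 50, 500)

    @pytest.mark.parametrize("T", [10, 101, 997, 1234])
    def test_boundaries_use_floor_rounding(self, T):
        tr, va, te = split_stream(make_stream(T))
        assert len(tr) == int(np.floor(0.45 * T))
        assert len(tr) + len(va) == int(np.floor(0.50 * T))
        assert len(tr) + len(va) + len(te) == T

    def test_concatenation_recovers_input(self):
        s = make_stream(200)
        tr, va, te = split_stream(s)
        assert np.array_equal(np.vstack([tr.X, va.X, te.X]), s.X)
        assert np.array_equal(np.concatenate([tr.cls, va.cls, te.cls]), s.cls)

    def test_too_short_rejected(self):
        with pytest.raises(PreprocessError):
            split_stream(make_stream(2))


class TestNormalizer:
    def test_min_max_map_to_unit_interval(self):
        s = make_stream(3, n_features=1)
        s.X = np.array([[0.0], [5.0], [10.0]])
        stats = fit_normalizer(s)
        out = apply_normalizer(s, stats)
        assert np.allclose(out.X[:, 0], [-1, 0, 1])

    def test_fit_split_lands_in_band_val_may_escape(self, datasets):
        assert datasets.train_stream.X.min() >= -1 - 1e-12
        assert datasets.train_stream.X.max() <= 1 + 1e-12

    def test_roundtrip_inverse(self):
        s = make_stream(100)
        stats = fit_normalizer(s)
        out = apply_normalizer(s, stats)
        assert np.allclose(invert_normalizer(out.X, stats), s.X, atol=1e-12)

    def test_constant_column_named_in_error(self):
        s = make_stream(10)
        s.X[:, 3] = 7.0
        with pytest.raises(PreprocessError, match="pupil"):
            fit_normalizer(s)


class TestAugment:
    def test_copy_count(self):
        s = make_stream(450)
        assert len(augment(s, 10)) == 4950
        assert len(augment(s, 0)) == 450

    def test_copies_are_verbatim(self):
        s = make_stream(100)
        out = augment(s, 2)
        assert np.array_equal(out.X[:100], out.X[100:200])
        assert np.array_equal(out.X[:100], out.X[200:])

    def test_replication_adds_phase_shifted_windows(self):
        # stream length not divisible by the step -> each copy starts at a
        # new window phase, so windows are not just duplicated
        spec = WindowSpec(w=20, w_s=5, N_s=10, N_T=2)
        s = make_stream(35, movement_len=7)
        one = windowize(s, spec)
        rep = windowize(augment(s, 2), spec)
        assert len(rep) > 3 * len(one)
        uniq = {w.tobytes() for w in rep.X}
        assert len(uniq) > len(one)


# --------------------------------------------------------------------------
# windowize
# --------------------------------------------------------------------------

class TestWindowize:
    def test_boundary_single_window(self):
        ws = windowize(make_stream(350))
        assert len(ws) == 1

    def test_count_formula_matches_enumeration(self):
        for T in (350, 420, 423, 1000):
            ws = windowize(make_stream(T))
            oracle = len([s for s in range(0, T, 70) if s + 350 <= T])
            assert len(ws) == (T - 350) // 70 + 1 == oracle

    def test_each_window_has_35_subwindow_labels(self):
        ws = windowize(make_stream(700))
        assert ws.cls.shape[1] == 35 and ws.vert.shape[1] == 35

    def test_labels_are_last_sample_of_each_subwindow(self):
        s = make_stream(420, movement_len=13)
        ws = windowize(s)
        for i, start in enumerate(ws.starts):
            for k in range(35):
                j = start + (k + 1) * 10 - 1
                assert ws.cls[i, k] == s.cls[j]
                assert ws.vert[i, k] == s.vert[j]

    def test_short_stream_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            ws = windowize(make_stream(100))
        assert len(ws) == 0

    def test_join_spanning_windows_flagged(self):
        s = make_stream(700)
        s.orig_index = np.concatenate([np.arange(400), np.arange(600, 900)])
        ws = windowize(s)
        crosses = (ws.starts < 400) & (ws.starts + 350 > 400)
        assert np.array_equal(ws.spans_join, crosses)
        assert ws.spans_join.any() and not ws.spans_join.all()

    @given(T=st.integers(350, 2000), step=st.sampled_from([35, 50, 70, 175]))
    @settings(max_examples=20, deadline=None)
    def test_window_count_property(self, T, step):
        spec = WindowSpec(w=350, w_s=10, N_s=step, N_T=0)
        ws = windowize(make_stream(T, seed=1), spec)
        assert len(ws) == (T - 350) // step + 1


def test_spec_invariants():
    with pytest.raises(PreprocessError):
        WindowSpec(w=350, w_s=9)
    with pytest.raises(PreprocessError):
        WindowSpec(w=350, N_s=60)


def test_default_window_and_step_derivations():
    assert default_window_size(175) == 350
    assert default_step(350, 73) == 70
    assert default_step(350, 74) == 70


class TestPipeline:
    def test_deterministic(self, small_logs, datasets):
        again = preprocess.prepare_datasets(small_logs)
        assert np.array_equal(again.train.X, datasets.train.X)
        assert np.array_equal(again.test.cls, datasets.test.cls)

    def test_window_labels_decode_via_provenance(self, datasets):
        """Oracle re-lookup: every stored label equals the stream label at the
        provenance index."""
        ws, stream = datasets.test, datasets.test_stream
        off = (np.arange(ws.spec.N_w) + 1) * ws.spec.w_s - 1
        for i in range(len(ws)):
            assert np.array_equal(ws.cls[i], stream.cls[ws.starts[i] + off])

    def test_kept_lengths_below_threshold(self, small_logs, datasets):
        segs = [s for lg in small_logs for s in segment_movements(lg)]
        stats = datasets.filter_stats
        lengths = np.array([s.length for s in segs])
        assert stats.threshold == pytest.approx(lengths.mean() + 3 * lengths.std())
        kept_lengths = np.diff(np.flatnonzero(
            np.diff(datasets.test_stream.movement, prepend=-1) != 0))
        assert (kept_lengths <= stats.threshold).all()
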