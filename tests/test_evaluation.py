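"""Stochastic prediction, certainty gating, streaming metrics, threshold scan."""

import numpy as np
import pytest

from gazeintent import evaluation
from gazeintent.evaluation import (EvaluationError, StreamEval, StreamPredictions,
                                   UEPrediction, accept_prediction,
                                   compute_metrics, continuous_stream_eval,
                                   gate_predictions, predict_with_ue,
                                   scan_thresholds, stream_predictions)
from gazeintent.networks import EncoderConfig, UEConfig, build_encoder
from gazeintent.preprocess import FeatureStream

RNG = np.random.default_rng(1)


def small_net(seed=0):
    return build_encoder(EncoderConfig(C=4, H=2, ff=4, N_x=1), seed=seed)


def toy_stream(T=100, seed=0, movement_len=25):
    rng = np.random.default_rng(seed)
    return FeatureStream(X=rng.normal(size=(T, 6)), cls=rng.integers(0, 10, T),
                         vert=rng.integers(0, 2, T),
                         movement=np.arange(T) // movement_len,
                         orig_index=np.arange(T))


class TestPredictWithUE:
    def test_mean_std_match_recomputation_from_stacked_passes(self):
        net = small_net()
        win = RNG.normal(size=(350, 6))
        rng = np.random.default_rng(7)
        pred = predict_with_ue(net, win, n_passes=8, rng=rng)
        rng2 = np.random.default_rng(7)
        stack = np.stack([net.predict(win, rng=rng2, mc_dropout=True)[0]
                          for _ in range(8)])
        assert np.allclose(pred.mean, stack.mean(0), atol=1e-12)
        assert np.allclose(pred.std, stack.std(0), atol=1e-12)

    def test_passes_vary_hence_positive_std(self):
        pred = predict_with_ue(small_net(), RNG.normal(size=(350, 6)),
                               n_passes=10, rng=np.random.default_rng(0))
        assert pred.std.max() > 0

    def test_fewer_than_two_passes_rejected(self):
        with pytest.raises(EvaluationError):
            predict_with_ue(small_net(), np.zeros((350, 6)), n_passes=1)

    def test_mc_mean_is_consistent_across_seeds(self):
        """Two independent N=30 estimates differ by less than 5x the standard
        error of the mean."""
        net = small_net()
        win = RNG.normal(size=(350, 6))
        a = predict_with_ue(net, win, 30, np.random.default_rng(1))
        b = predict_with_ue(net, win, 30, np.random.default_rng(2))
        # pooled SEM of the difference of two independent N=30 means
        sem = np.sqrt((a.std**2 + b.std**2) / 30)
        diff = np.abs(a.mean - b.mean)[-1]  # the evaluated (last) subwindow
        assert (diff < 5 * np.maximum(sem[-1], 1e-4)).all()


class TestAcceptRule:
    def _pred(self, mean, std):
        m = np.zeros(10)
        s = np.zeros(10)
        m[3], s[3] = mean, std
        return UEPrediction(mean=m, std=s, bin_mean=np.zeros(1),
                            bin_std=np.zeros(1), n_passes=10)

    def test_printed_arithmetic(self):
        assert accept_prediction(self._pred(0.9, 0.1), 0.69) == 3  # 0.7 > 0.69

    def test_boundary_is_strict(self):
        assert accept_prediction(self._pred(0.9, 0.1), 0.70) is None

    def test_fully_certain_accepted_below_one(self):
        assert accept_prediction(self._pred(1.0, 0.0), 0.99) == 3
        assert accept_prediction(self._pred(1.0, 0.0), 1.0) is None


class TestContinuousEval:
    def test_first_window_zero_padded(self):
        """The network at timestep 0 must see zeros everywhere except the
        newest sample; verify via a probe network replaced by a recorder."""
        stream = toy_stream(T=5)
        seen = []

        class Probe:
            def predict(self, X, rng=None, mc_dropout=False):
                seen.append(X.copy())
                return np.full((len(X), 35, 10), 0.1), np.full((len(X), 35, 1), 0.5)

        stream_predictions(Probe(), stream, n_passes=2, n_p=1,
                           rng=np.random.default_rng(0))
        first = seen[0][0]
        assert np.allclose(first[:-1], 0.0)
        assert np.allclose(first[-1], stream.X[0])
        last = seen[0][4]
        assert np.allclose(last[-5:], stream.X[:5])

    @pytest.mark.parametrize("T,n_p,expected", [(100, 1, 100), (100, 10, 10),
                                                (101, 10, 11), (5, 3, 2)])
    def test_record_count(self, T, n_p, expected):
        net = small_net()
        se = continuous_stream_eval(net, toy_stream(T), th_l=0.0, n_passes=2,
                                    n_p=n_p, rng=np.random.default_rng(0))
        assert len(se.t) == expected == int(np.ceil(T / n_p))

    def test_empty_stream_rejected(self):
        with pytest.raises(EvaluationError):
            stream_predictions(small_net(), toy_stream(0), n_passes=2)


def manual_record():
    """Hand-built trace: 3 movements; 10 accepted timesteps, 7 correct,
    2 movements covered."""
    movement = np.array([0] * 5 + [1] * 5 + [2] * 5)
    true_cls = np.array([1] * 5 + [2] * 5 + [3] * 5)
    pred_cls = np.array([1, 1, 1, 1, 1,    2, 2, 2, 2, 9,    9, 9, 9, 9, 9])
    accepted = np.array([1, 1, 1, 1, 0,    1, 1, 1, 0, 1,    1, 1, 0, 0, 0], bool)
    # accepted: 4 + 4 + 2 = 10; accepted & correct: 4 + 3 + 0 = 7; covered: {0, 1}
    bin_mean = np.array([0.9] * 15)
    true_vert = np.ones(15, int)
    return StreamEval(t=np.arange(15), movement=movement,
                      offset_in_movement=np.tile(np.arange(5), 3),
                      movement_length=np.full(15, 5), true_cls=true_cls,
                      true_vert=true_vert, pred_cls=pred_cls,
                      mean_sel=np.where(accepted, 0.9, 0.1), std_sel=np.zeros(15),
                      bin_mean=bin_mean, n_passes=5, th_l=0.5, accepted=accepted)


def metrics_oracle(se):
    """Exhaustive recount of every metric from the raw record."""
    acc = [i for i in range(len(se.t)) if se.accepted[i]]
    correct = [i for i in acc if se.pred_cls[i] == se.true_cls[i]]
    movements = sorted(set(se.movement))
    covered = sorted({se.movement[i] for i in correct})
    a_p = 100 * len(correct) / len(acc) if acc else None
    a_m = 100 * len(covered) / len(movements)
    if acc:
        a_vp = 100 * np.mean([(se.bin_mean[i] > 0.5) == se.true_vert[i] for i in acc])
    else:
        a_vp = None
    return a_p, a_m, a_vp


class TestMetrics:
    def test_manual_fixture_counts(self):
        se = manual_record()
        m = compute_metrics(se)
        assert m.n_accepted == 10
        assert m.n_correct == 7
        assert m.A_P == pytest.approx(70.0)
        assert m.A_M == pytest.approx(200.0 / 3)  # 2 of 3 movements
        assert m.A_VP == pytest.approx(100.0)

    def test_all_correct_gives_100(self):
        se = manual_record()
        se.pred_cls = se.true_cls.copy()
        assert compute_metrics(se).A_P == pytest.approx(100.0)

    def test_nothing_accepted_is_undefined_not_zero(self):
        se = manual_record()
        se.accepted[:] = False
        m = compute_metrics(se)
        assert m.undefined and m.A_P is None and m.A_VP is None
        assert m.A_M == 0.0

    def test_matches_bruteforce_recount_on_random_records(self):
        rng = np.random.default_rng(5)
        for trial in range(20):
            n = int(rng.integers(5, 200))
            se = StreamEval(
                t=np.arange(n), movement=rng.integers(0, 6, n),
                offset_in_movement=np.zeros(n, int), movement_length=np.ones(n, int),
                true_cls=rng.integers(0, 10, n), true_vert=rng.integers(0, 2, n),
                pred_cls=rng.integers(0, 10, n), mean_sel=rng.random(n),
                std_sel=rng.random(n) * 0.2, bin_mean=rng.random(n), n_passes=2,
                th_l=0.3, accepted=rng.random(n) < 0.6)
            m = compute_metrics(se)
            a_p, a_m, a_vp = metrics_oracle(se)
            assert (m.A_P is None) == (a_p is None)
            if a_p is not None:
                assert m.A_P == pytest.approx(a_p)
                assert m.A_VP == pytest.approx(a_vp)
            assert m.A_M == pytest.approx(a_m)

    def test_gated_record_matches_stored_eval(self, stream_eval):
        a_p, a_m, a_vp = metrics_oracle(stream_eval)
        m = compute_metrics(stream_eval)
        assert m.A_P == pytest.approx(a_p) and m.A_M == pytest.approx(a_m)


def raw_from(se: StreamEval) -> StreamPredictions:
    return StreamPredictions(
        t=se.t, movement=se.movement, offset_in_movement=se.offset_in_movement,
        movement_length=se.movement_length, true_cls=se.true_cls,
        true_vert=se.true_vert, pred_cls=se.pred_cls, mean_sel=se.mean_sel,
        std_sel=se.std_sel, bin_mean=se.bin_mean, n_passes=se.n_passes)


class TestThresholdScan:
    def test_grid_has_101_points(self, stream_eval):
        res = scan_thresholds(raw_from(stream_eval))
        assert len(res.grid) == 101
        assert res.grid[0] == 0.0 and res.grid[-1] == 1.0

    def test_closed_form_crossing(self):
        """Synthetic linear curves A_P = Th*100 and A_M = (1-Th)*100 cross at
        Th = 0.5 with A_I = 50."""
        grid = np.round(np.arange(0, 1.0001, 0.01), 2)
        th, a_i = evaluation._crossing(grid, grid * 100, (1 - grid) * 100)
        assert th == pytest.approx(0.5) and a_i == pytest.approx(50.0)

    def test_acceptance_sets_nested_and_am_monotone(self, stream_eval):
        raw = raw_from(stream_eval)
        res = scan_thresholds(raw)
        prev = None
        for th in res.grid[::5]:
            acc = set(np.flatnonzero(gate_predictions(raw, th).accepted))
            if prev is not None:
                assert acc <= prev
            prev = acc
        assert (np.diff(res.A_M) <= 1e-12).all()

    def test_am_100_at_zero_threshold_when_every_movement_hit(self):
        se = manual_record()
        se.pred_cls = se.true_cls.copy()
        res = scan_thresholds(raw_from(se))
        assert res.A_M[0] == pytest.approx(100.0)

    def test_scan_values_match_explicit_gating(self, stream_eval):
        raw = raw_from(stream_eval)
        res = scan_thresholds(raw)
        for i in [0, 25, 50]:
            m = compute_metrics(gate_predictions(raw, res.grid[i]))
            if m.A_P is None:
                assert np.isnan(res.A_P[i])
            else:
                assert res.A_P[i] == pytest.approx(m.A_P)
            assert res.A_M[i] == pytest.approx(m.A_M)

    def test_all_rejected_raises(self):
        se = manual_record()
        raw = raw_from(se)
        raw.mean_sel = np.zeros(15)
        raw.std_sel = np.ones(15)
        with pytest.raises(EvaluationError):
            scan_thresholds(raw)
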