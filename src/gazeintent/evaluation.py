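"""Monte-Carlo-dropout prediction, certainty gating, and streaming metrics.

Prediction with uncertainty: run N stochastic forward passes (dropout in
the UE stack left active) and summarize them element-wise by mean and
standard deviation.  A prediction is *accepted* when the predicted class's
mean minus two standard deviations strictly exceeds a threshold Th_L.

Continuous evaluation mimics a live system: the input window starts as all
zeros and shifts in one new sample per timestep; only the final subwindow's
outputs (the most recent data) are scored.  From the per-timestep record
three accuracies are computed:

* A_P  - accuracy of accepted predictions,
* A_M  - fraction of movements correctly predicted at least once,
* A_VP - upper/lower-arc accuracy at accepted timesteps,

and the operating threshold is chosen on validation data as the crossing of
the A_P and A_M curves over a 101-point threshold grid (combined accuracy
A_I at the crossing).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .networks import Network
from .preprocess import FeatureStream

N_PASSES_DEFAULT = 30


class EvaluationError(ValueError):
    pass


# --------------------------------------------------------------------------
# stochastic prediction
# --------------------------------------------------------------------------

@dataclass
class UEPrediction:
    mean: np.ndarray      # (..., 10) element-wise mean over passes
    std: np.ndarray       # (..., 10)
    bin_mean: np.ndarray  # (..., 1)
    bin_std: np.ndarray   # (..., 1)
    n_passes: int


def predict_with_ue(net: Network, window: np.ndarray, n_passes: int = N_PASSES_DEFAULT,
                    rng: Optional[np.random.Generator] = None) -> UEPrediction:
    """Mean and SD of n_passes independent stochastic forward passes."""
    if n_passes < 2:
        raise EvaluationError("need at least 2 passes for a standard deviation")
    rng = np.random.default_rng() if rng is None else rng
    ys, bs = [], []
    for _ in range(n_passes):
        y1, y2 = net.predict(window, rng=rng, mc_dropout=True)
        ys.append(y1)
        bs.append(y2)
    ys = np.stack(ys)
    bs = np.stack(bs)
    return UEPrediction(mean=ys.mean(0), std=ys.std(0),
                        bin_mean=bs.mean(0), bin_std=bs.std(0), n_passes=n_passes)


def accept_prediction(pred: UEPrediction, th_l: float) -> Optional[int]:
    """Gate one prediction (a single 10-vector): the argmax class is accepted
    iff mean - 2*SD strictly exceeds th_l; returns the class or None."""
    mean = np.asarray(pred.mean)
    std = np.asarray(pred.std)
    if mean.ndim != 1:
        raise EvaluationError("accept_prediction gates a single subwindow output")
    c = int(np.argmax(mean))
    return c if mean[c] - 2.0 * std[c] > th_l else None


# --------------------------------------------------------------------------
# continuous-stream prediction
# --------------------------------------------------------------------------

@dataclass
class StreamPredictions:
    """Raw per-evaluated-timestep stochastic-prediction record (ungated)."""
    t: np.ndarray                  # global sample index in the stream
    movement: np.ndarray
    offset_in_movement: np.ndarray
    movement_length: np.ndarray    # samples of that movement inside this stream
    true_cls: np.ndarray
    true_vert: np.ndarray
    pred_cls: np.ndarray           # argmax of the mean 10-vector
    mean_sel: np.ndarray           # mean of the predicted class
    std_sel: np.ndarray
    bin_mean: np.ndarray
    n_passes: int

    @property
    def margin(self) -> np.ndarray:
        return self.mean_sel - 2.0 * self.std_sel


@dataclass
class StreamEval(StreamPredictions):
    """StreamPredictions after certainty gating at a fixed threshold."""
    th_l: float = 0.0
    accepted: np.ndarray = field(default_factory=lambda: np.empty(0, bool))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t": self.t, "movement": self.movement,
            "offset_in_movement": self.offset_in_movement,
            "movement_length": self.movement_length,
            "true_cls": self.true_cls, "true_vert": self.true_vert,
            "pred_cls": self.pred_cls, "mean": self.mean_sel, "std": self.std_sel,
            "bin_mean": self.bin_mean, "accepted": self.accepted.astype(int)})


def _movement_offsets(movement: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample (offset within movement, movement length) for a stream."""
    offs = np.zeros(len(movement), int)
    lens = np.zeros(len(movement), int)
    for m in np.unique(movement):
        idx = np.flatnonzero(movement == m)
        offs[idx] = np.arange(idx.size)
        lens[idx] = idx.size
    return offs, lens


def stream_predictions(net: Network, stream: FeatureStream,
                       n_passes: int = N_PASSES_DEFAULT, n_p: int = 1,
                       rng: Optional[np.random.Generator] = None,
                       window: int = 350, batch_size: int = 512) -> StreamPredictions:
    """Stochastic predictions for every n_p-th timestep of a continuous stream.

    The input window at timestep t holds samples (t-w, t] left-padded with
    zeros, so the very first window is all zeros except the newest sample.
    Only the final subwindow's outputs are recorded.
    """
    if len(stream) < 1:
        raise EvaluationError("empty evaluation stream")
    if n_passes < 2:
        raise EvaluationError("need at least 2 passes for a standard deviation")
    rng = np.random.default_rng() if rng is None else rng
    T = len(stream)
    steps = np.arange(0, T, n_p)
    padded = np.vstack([np.zeros((window - 1, stream.X.shape[1])), stream.X])
    view = np.lib.stride_tricks.sliding_window_view(padded, window, axis=0)  # (T, 6, w)

    mean_sel = np.empty(len(steps))
    std_sel = np.empty(len(steps))
    pred_cls = np.empty(len(steps), int)
    bin_mean = np.empty(len(steps))
    for lo in range(0, len(steps), batch_size):
        sel = steps[lo:lo + batch_size]
        wins = np.ascontiguousarray(view[sel].transpose(0, 2, 1))  # (b, w, 6)
        ys = np.empty((n_passes, len(sel), 10))
        bs = np.empty((n_passes, len(sel)))
        for k in range(n_passes):
            y1, y2 = net.predict(wins, rng=rng, mc_dropout=True)
            ys[k] = y1[:, -1, :]
            bs[k] = y2[:, -1, 0]
        mu = ys.mean(0)
        sd = ys.std(0)
        cls = mu.argmax(axis=1)
        rows = np.arange(len(sel))
        pred_cls[lo:lo + len(sel)] = cls
        mean_sel[lo:lo + len(sel)] = mu[rows, cls]
        std_sel[lo:lo + len(sel)] = sd[rows, cls]
        bin_mean[lo:lo + len(sel)] = bs.mean(0)

    offs, lens = _movement_offsets(stream.movement)
    return StreamPredictions(
        t=steps, movement=stream.movement[steps],
        offset_in_movement=offs[steps], movement_length=lens[steps],
        true_cls=stream.cls[steps], true_vert=stream.vert[steps],
        pred_cls=pred_cls, mean_sel=mean_sel, std_sel=std_sel,
        bin_mean=bin_mean, n_passes=n_passes)


def gate_predictions(raw: StreamPredictions, th_l: float) -> StreamEval:
    """Apply the certainty gate (mean - 2 SD > Th_L, strict) per timestep."""
    return StreamEval(
        t=raw.t, movement=raw.movement, offset_in_movement=raw.offset_in_movement,
        movement_length=raw.movement_length, true_cls=raw.true_cls,
        true_vert=raw.true_vert, pred_cls=raw.pred_cls, mean_sel=raw.mean_sel,
        std_sel=raw.std_sel, bin_mean=raw.bin_mean, n_passes=raw.n_passes,
        th_l=float(th_l), accepted=raw.margin > th_l)


def continuous_stream_eval(net: Network, stream: FeatureStream, th_l: float,
                           n_passes: int = N_PASSES_DEFAULT, n_p: int = 1,
                           rng: Optional[np.random.Generator] = None,
                           window: int = 350, batch_size: int = 512) -> StreamEval:
    raw = stream_predictions(net, stream, n_passes, n_p, rng, window, batch_size)
    return gate_predictions(raw, th_l)


# --------------------------------------------------------------------------
# metrics
# --------------------------------------------------------------------------

@dataclass
class MetricsReport:
    A_P: Optional[float]   # % accuracy of accepted predictions (None if none accepted)
    A_M: float             # % movements correctly predicted at least once
    A_VP: Optional[float]  # % vertical accuracy at accepted timesteps
    n_accepted: int
    n_correct: int
    n_movements: int
    n_movements_covered: int
    th_l: float

    @property
    def undefined(self) -> bool:
        return self.A_P is None

    def to_dict(self) -> dict:
        return {"A_P": self.A_P, "A_M": self.A_M, "A_VP": self.A_VP,
                "n_accepted": self.n_accepted, "n_correct": self.n_correct,
                "n_movements": self.n_movements,
                "n_movements_covered": self.n_movements_covered, "Th_L": self.th_l}


def compute_metrics(se: StreamEval) -> MetricsReport:
    if len(se.t) == 0:
        raise EvaluationError("empty StreamEval")
    acc = se.accepted
    correct = acc & (se.pred_cls == se.true_cls)
    movements = np.unique(se.movement)
    covered = np.unique(se.movement[correct])
    n_acc = int(acc.sum())
    a_p = 100.0 * correct.sum() / n_acc if n_acc else None
    a_m = 100.0 * covered.size / movements.size
    if n_acc:
        vert_call = (se.bin_mean[acc] > 0.5).astype(int)
        a_vp = 100.0 * (vert_call == se.true_vert[acc]).mean()
    else:
        a_vp = None
    return MetricsReport(A_P=a_p, A_M=a_m, A_VP=a_vp, n_accepted=n_acc,
                         n_correct=int(correct.sum()), n_movements=int(movements.size),
                         n_movements_covered=int(covered.size), th_l=se.th_l)


# --------------------------------------------------------------------------
# threshold scan
# --------------------------------------------------------------------------

@dataclass
class ScanResult:
    grid: np.ndarray
    A_P: np.ndarray   # NaN where no prediction is accepted
    A_M: np.ndarray
    th_l: float
    a_i: float

    def curves_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold": self.grid, "A_P": self.A_P, "A_M": self.A_M})


def scan_thresholds(raw: StreamPredictions, grid: Optional[np.ndarray] = None) -> ScanResult:
    """A_P and A_M over the threshold grid (default 0..1 step 0.01), reusing
    one set of stochastic predictions; Th_L is the crossing of the curves.

    The crossing is linearly interpolated between adjacent grid points; with
    several crossings the lowest is taken; with none, the grid point
    maximizing min(A_P, A_M).
    """
    grid = np.round(np.arange(0, 1.0001, 0.01), 2) if grid is None else np.asarray(grid)
    margin = raw.margin
    correct = raw.pred_cls == raw.true_cls
    movements = np.unique(raw.movement)
    # per movement: best margin among its correct predictions
    best = np.full(movements.size, -np.inf)
    for i, m in enumerate(movements):
        c = correct & (raw.movement == m)
        if c.any():
            best[i] = margin[c].max()

    acc = margin[None, :] > grid[:, None]           # (G, T)
    n_acc = acc.sum(axis=1)
    n_cor = (acc & correct[None, :]).sum(axis=1)
    with np.errstate(invalid="ignore"):
        a_p = np.where(n_acc > 0, 100.0 * n_cor / np.maximum(n_acc, 1), np.nan)
    a_m = 100.0 * (best[None, :] > grid[:, None]).mean(axis=1)

    if np.isnan(a_p).all():
        raise EvaluationError("no prediction accepted at any threshold; A_P undefined")

    th_l, a_i = _crossing(grid, a_p, a_m)
    return ScanResult(grid=grid, A_P=a_p, A_M=a_m, th_l=th_l, a_i=a_i)


def _crossing(grid, a_p, a_m):
    valid = ~np.isnan(a_p)
    f = a_p - a_m
    for i in range(len(grid) - 1):
        if not (valid[i] and valid[i + 1]):
            continue
        if f[i] == 0.0:
            return float(grid[i]), float(a_p[i])
        if f[i] * f[i + 1] < 0:
            dp = a_p[i + 1] - a_p[i]
            dm = a_m[i + 1] - a_m[i]
            s = (a_m[i] - a_p[i]) / (dp - dm)
            th = grid[i] + s * (grid[i + 1] - grid[i])
            return float(th), float(a_p[i] + s * dp)
    if valid[-1] and f[-1] == 0.0:
        return float(grid[-1]), float(a_p[-1])
    # no crossing: best compromise grid point
    score = np.where(valid, np.minimum(a_p, a_m), -np.inf)
    i = int(np.argmax(score))
    return float(grid[i]), float(min(a_p[i], a_m[i]))


def threshold_scan(net: Network, val_stream: FeatureStream,
                   n_passes: int = N_PASSES_DEFAULT, n_p: int = 1,
                   rng: Optional[np.random.Generator] = None,
                   window: int = 350, batch_size: int = 512
                   ) -> tuple[float, float, ScanResult]:
    """Scan the certainty threshold on a validation stream.

    Returns (Th_L, A_I, full scan curves)."""
    raw = stream_predictions(net, val_stream, n_passes, n_p, rng, window, batch_size)
    res = scan_thresholds(raw)
    return res.th_l, res.a_i, res
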