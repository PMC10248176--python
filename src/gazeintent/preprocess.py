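"""Session logs -> normalized, windowed, per-subwindow-labeled streams.

Stages, in pipeline order: segment each log into click-to-click movements,
discard warm-up, drop movements longer than mean + 3 SD of the observed
lengths, reduce to the six classification features, relabel boxes to a
10-way horizontal class plus an upper/lower flag, concatenate sessions into
one continuous stream, split 45/5/50 in order of appearance, min-max
normalize to [-1, 1] with statistics fit on the training split, replicate
the training stream, and cut sliding windows of 350 samples (step 70) whose
35 subwindows are each labeled by their last sample.

Feature columns, fixed order:
``[avg eye dir 0, 1, 2, avg pupil, head axis 1, head axis 2]``
(axis 0 of head position - the participant's height - is dropped; the eye
direction is the plain left/right average and is deliberately not
renormalized to unit length).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .simulate import SessionLog

FEATURE_NAMES = ["eye_0", "eye_1", "eye_2", "pupil", "head_1", "head_2"]


class PreprocessError(ValueError):
    pass


# --------------------------------------------------------------------------
# windowing constants and their derivations
# --------------------------------------------------------------------------

def default_window_size(mean_length: float = 175) -> int:
    """Window = twice the mean movement length, so most windows span a transition."""
    return int(round(2 * mean_length))


def default_step(window: int = 350, shortest_movement: int = 73) -> int:
    """Largest divisor of the window size not exceeding the shortest movement."""
    for step in range(min(window, shortest_movement), 0, -1):
        if window % step == 0:
            return step
    raise PreprocessError("no feasible step size")


@dataclass(frozen=True)
class WindowSpec:
    w: int = 350       # window length, samples
    w_s: int = 10      # subwindow length
    N_s: int = 70      # sliding step
    N_T: int = 10      # training-stream replication count

    def __post_init__(self):
        if self.w % self.w_s:
            raise PreprocessError(f"subwindow size {self.w_s} must divide window {self.w}")
        if self.w % self.N_s:
            raise PreprocessError(f"step {self.N_s} must divide window {self.w}")

    @property
    def N_w(self) -> int:
        return self.w // self.w_s


# --------------------------------------------------------------------------
# segmentation and length filter
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MovementSegment:
    start: int   # inclusive sample index into the session log
    end: int     # exclusive
    box: int
    movement: int

    @property
    def length(self) -> int:
        return self.end - self.start


def segment_movements(log: SessionLog) -> list[MovementSegment]:
    """One segment per click-to-click movement, warm-up excluded, in order."""
    segs: list[MovementSegment] = []
    move = log.movement
    if len(move) == 0:
        return segs
    bounds = np.flatnonzero(np.diff(move) != 0) + 1
    starts = np.concatenate([[0], bounds])
    ends = np.concatenate([bounds, [len(move)]])
    for s, e in zip(starts, ends):
        if log.warmup[s]:
            continue
        segs.append(MovementSegment(start=int(s), end=int(e),
                                    box=int(log.box[s]), movement=int(move[s])))
    return segs


@dataclass(frozen=True)
class FilterStats:
    mean: float
    sd: float
    threshold: float  # mean + 3 * sd
    n_before: int
    n_after: int


def length_filter(segments: Sequence[MovementSegment]) -> tuple[FilterStats, list[MovementSegment]]:
    """Drop movements longer than mean + 3 SD of the observed lengths."""
    if len(segments) < 2:
        raise PreprocessError("length filter needs >= 2 segments (SD undefined)")
    lengths = np.array([s.length for s in segments], float)
    mu = float(lengths.mean())
    sigma = float(lengths.std(ddof=0))
    thr = mu + 3.0 * sigma
    kept = [s for s in segments if s.length <= thr]
    stats = FilterStats(mean=mu, sd=sigma, threshold=thr,
                        n_before=len(segments), n_after=len(kept))
    return stats, kept


# --------------------------------------------------------------------------
# features and labels
# --------------------------------------------------------------------------

def relabel(box: int) -> tuple[int, int]:
    """Box 0-18 -> (horizontal class 0-9, upper-arc flag)."""
    if not (0 <= box <= 18):
        raise PreprocessError(f"box index {box} outside [0, 18]")
    return (box, 0) if box <= 9 else (box - 9, 1)


def extract_features(log: SessionLog) -> np.ndarray:
    """(T, 6) feature matrix: averaged gaze, averaged pupil, horizontal head.

    Samples containing NaN (blinks) take the previous sample's values;
    leading NaNs are back-filled from the first valid sample.
    """
    eye = 0.5 * (log.eye_left + log.eye_right)
    pupil = 0.5 * (log.pupil_left + log.pupil_right)
    X = np.column_stack([eye, pupil, log.head[:, 1], log.head[:, 2]])
    bad = np.isnan(X).any(axis=1)
    if bad.all():
        raise PreprocessError("all samples are NaN")
    # previous-sample imputation (vectorized forward fill), then back-fill the head
    idx = np.arange(len(X))
    last_valid = np.where(~bad, idx, -1)
    np.maximum.accumulate(last_valid, out=last_valid)
    first_valid = int(np.flatnonzero(~bad)[0])
    last_valid[last_valid < 0] = first_valid
    return X[last_valid]


# --------------------------------------------------------------------------
# continuous streams
# --------------------------------------------------------------------------

@dataclass
class FeatureStream:
    """A continuous per-sample stream with aligned labels and provenance."""
    X: np.ndarray          # (T, 6)
    cls: np.ndarray        # (T,) int 0-9
    vert: np.ndarray       # (T,) int 0/1
    movement: np.ndarray   # (T,) global movement id
    orig_index: np.ndarray  # (T,) sample index in the source log (joins visible as gaps)

    def __len__(self):
        return len(self.X)

    def slice(self, a: int, b: int) -> "FeatureStream":
        return FeatureStream(self.X[a:b], self.cls[a:b], self.vert[a:b],
                             self.movement[a:b], self.orig_index[a:b])

    @staticmethod
    def concatenate(streams: Sequence["FeatureStream"]) -> "FeatureStream":
        return FeatureStream(*[np.concatenate([getattr(s, f) for s in streams])
                               for f in ("X", "cls", "vert", "movement", "orig_index")])


def build_stream(log: SessionLog, segments: Sequence[MovementSegment],
                 movement_offset: int = 0, index_offset: int = 0) -> FeatureStream:
    """Assemble the continuous stream for one session from its kept segments.

    Filtered-out movements are excised and the remainder re-concatenated;
    the original sample indices are kept so windows spanning a join can be
    flagged downstream.
    """
    feats = extract_features(log)
    parts = []
    for seg in segments:
        cls, vert = relabel(seg.box)
        n = seg.length
        parts.append(FeatureStream(
            X=feats[seg.start:seg.end],
            cls=np.full(n, cls, dtype=int),
            vert=np.full(n, vert, dtype=int),
            movement=np.full(n, seg.movement + movement_offset, dtype=int),
            orig_index=np.arange(seg.start, seg.end) + index_offset))
    if not parts:
        raise PreprocessError("no segments to assemble")
    return FeatureStream.concatenate(parts)


def split_stream(stream: FeatureStream,
                 fractions: tuple[float, float] = (0.45, 0.50)
                 ) -> tuple[FeatureStream, FeatureStream, FeatureStream]:
    """Contiguous train/val/test split in order of appearance (default 45/5/50)."""
    T = len(stream)
    if T < 3:
        raise PreprocessError("stream too short to split")
    i1 = int(np.floor(fractions[0] * T))
    i2 = int(np.floor(fractions[1] * T))
    return stream.slice(0, i1), stream.slice(i1, i2), stream.slice(i2, T)


@dataclass(frozen=True)
class NormStats:
    minimum: np.ndarray  # per-column
    maximum: np.ndarray


def fit_normalizer(stream: FeatureStream) -> NormStats:
    if len(stream) == 0:
        raise PreprocessError("cannot fit normalizer on an empty stream")
    lo = stream.X.min(axis=0)
    hi = stream.X.max(axis=0)
    const = np.flatnonzero(hi <= lo)
    if const.size:
        names = ", ".join(FEATURE_NAMES[i] for i in const)
        raise PreprocessError(f"constant feature column(s): {names}")
    return NormStats(minimum=lo, maximum=hi)


def apply_normalizer(stream: FeatureStream, stats: NormStats) -> FeatureStream:
    """Affine map sending the fit-split [min, max] to [-1, 1] per column."""
    X = 2.0 * (stream.X - stats.minimum) / (stats.maximum - stats.minimum) - 1.0
    return FeatureStream(X, stream.cls, stream.vert, stream.movement, stream.orig_index)


def invert_normalizer(X: np.ndarray, stats: NormStats) -> np.ndarray:
    return (X + 1.0) / 2.0 * (stats.maximum - stats.minimum) + stats.minimum


def augment(stream: FeatureStream, n_copies: int = 10) -> FeatureStream:
    """Append n_copies verbatim copies of the stream (no shuffling, no noise).

    Because the stream length is generally not a multiple of the window
    step, each appended copy starts at a new window phase and so yields
    extra distinct windows.
    """
    if n_copies == 0:
        return stream
    return FeatureStream.concatenate([stream] * (n_copies + 1))


# --------------------------------------------------------------------------
# windows
# --------------------------------------------------------------------------

@dataclass
class WindowSet:
    """Stacked labeled windows plus provenance."""
    X: np.ndarray          # (n, w, 6)
    cls: np.ndarray        # (n, N_w) subwindow class labels
    vert: np.ndarray       # (n, N_w)
    starts: np.ndarray     # (n,) start offset in the source stream
    spans_join: np.ndarray  # (n,) True if the window crosses an excision join
    spec: WindowSpec

    def __len__(self):
        return len(self.X)


def windowize(stream: FeatureStream, spec: WindowSpec = WindowSpec()) -> WindowSet:
    """Sliding windows of w samples at step N_s; subwindow k is labeled by
    the per-sample label at offset (k + 1) * w_s - 1 (its last sample)."""
    T = len(stream)
    w, step = spec.w, spec.N_s
    if T < w:
        warnings.warn(f"stream of {T} samples is shorter than one window ({w})")
        return WindowSet(X=np.empty((0, w, stream.X.shape[1])),
                         cls=np.empty((0, spec.N_w), int),
                         vert=np.empty((0, spec.N_w), int),
                         starts=np.empty(0, int), spans_join=np.empty(0, bool),
                         spec=spec)
    n = (T - w) // step + 1
    starts = np.arange(n) * step
    label_off = (np.arange(spec.N_w) + 1) * spec.w_s - 1
    X = np.stack([stream.X[s:s + w] for s in starts])
    cls = np.stack([stream.cls[s + label_off] for s in starts])
    vert = np.stack([stream.vert[s + label_off] for s in starts])
    joins = np.diff(stream.orig_index) != 1
    spans = np.array([bool(joins[s:s + w - 1].any()) for s in starts])
    return WindowSet(X=X, cls=cls, vert=vert, starts=starts,
                     spans_join=spans, spec=spec)


# --------------------------------------------------------------------------
# full pipeline
# --------------------------------------------------------------------------

@dataclass
class Datasets:
    train: WindowSet
    val: WindowSet
    test: WindowSet
    train_stream: FeatureStream
    val_stream: FeatureStream
    test_stream: FeatureStream
    norm: NormStats
    filter_stats: FilterStats
    spec: WindowSpec


def prepare_datasets(logs: Iterable[SessionLog], spec: WindowSpec = WindowSpec(),
                     ) -> Datasets:
    """Run the whole preprocessing pipeline over one or more session logs."""
    logs = list(logs)
    all_segs: list[list[MovementSegment]] = [segment_movements(lg) for lg in logs]
    flat = [s for segs in all_segs for s in segs]
    stats, kept = length_filter(flat)
    kept_ids = {id(s) for s in kept}

    streams = []
    mv_off, ix_off = 0, 0
    for lg, segs in zip(logs, all_segs):
        mine = [s for s in segs if id(s) in kept_ids]
        if mine:
            streams.append(build_stream(lg, mine, mv_off, ix_off))
        mv_off += int(lg.movement.max()) + 1
        ix_off += len(lg)
    stream = FeatureStream.concatenate(streams)

    train_s, val_s, test_s = split_stream(stream)
    norm = fit_normalizer(train_s)
    train_n = apply_normalizer(train_s, norm)
    val_n = apply_normalizer(val_s, norm)
    test_n = apply_normalizer(test_s, norm)
    train_aug = augment(train_n, spec.N_T)
    return Datasets(train=windowize(train_aug, spec),
                    val=windowize(val_n, spec),
                    test=windowize(test_n, spec),
                    train_stream=train_n, val_stream=val_n, test_stream=test_n,
                    norm=norm, filter_stats=stats, spec=spec)


def load_windows(path) -> dict:
    """Read back the container written by save_windows.

    Returns a dict with WindowSets under 'train'/'val'/'test' plus the
    NormStats and WindowSpec used."""
    with np.load(path) as z:
        spec = WindowSpec(*(int(v) for v in z["spec"]))
        out = {nm: WindowSet(X=z[f"{nm}_X"], cls=z[f"{nm}_cls"],
                             vert=z[f"{nm}_vert"], starts=z[f"{nm}_starts"],
                             spans_join=z[f"{nm}_spans_join"], spec=spec)
               for nm in ("train", "val", "test")}
        out["norm"] = NormStats(minimum=z["norm_min"], maximum=z["norm_max"])
        out["spec"] = spec
    return out


def save_windows(path, ds: Datasets):
    """Single-file container for the windowed datasets (numpy archive)."""
    np.savez_compressed(
        path,
        **{f"{nm}_{f}": getattr(getattr(ds, nm), f)
           for nm in ("train", "val", "test") for f in ("X", "cls", "vert", "starts", "spans_join")},
        norm_min=ds.norm.minimum, norm_max=ds.norm.maximum,
        spec=np.array([ds.spec.w, ds.spec.w_s, ds.spec.N_s, ds.spec.N_T]),
        filter_stats=np.array([ds.filter_stats.mean, ds.filter_stats.sd,
                               ds.filter_stats.threshold,
                               ds.filter_stats.n_before, ds.filter_stats.n_after]))
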