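"""Hand-movement progress, velocity toward target, and earliness analysis.

For a movement with controller positions p_i, start p_start and end p_end:

* normalized distance progress  d_i = 1 - |p_end - p_i| / |p_end - p_start|
  (0 at the first sample, 1 at the last);
* velocity toward the target    v_i = f_s * (p_i - p_{i-1})^T (p_end - p_i) / |p_end - p_i|
  in m/s, with samples whose magnitude exceeds 2.5 m/s flagged as tracking
  glitches and excluded from aggregates.

The earliness analysis (time ahead of movement completion, TAMC) takes the
first accepted-and-correct prediction of each covered movement, expressed in
normalized movement time, and summarizes the distribution by percentiles and
by the milliseconds of hand movement still remaining for a reference
movement length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

VELOCITY_LIMIT = 2.5  # m/s; beyond this the position tracker glitched

TAMC_PERCENTILES = (5, 25, 50, 75, 95, 99)


class KinematicsError(ValueError):
    pass


def normalized_distance(positions: np.ndarray) -> np.ndarray:
    """d_i series for one movement's controller trace (first 0, last 1)."""
    p = np.asarray(positions, float)
    p_start, p_end = p[0], p[-1]
    denom = np.linalg.norm(p_end - p_start)
    if denom == 0:
        raise KinematicsError("zero start-to-end displacement; progress undefined")
    return 1.0 - np.linalg.norm(p_end - p, axis=1) / denom


@dataclass
class VelocitySeries:
    v: np.ndarray          # (T,) m/s; v[0] is NaN (no preceding sample)
    undefined: np.ndarray  # True where p_i coincides with the target
    removed: np.ndarray    # True where |v| exceeds the tracking limit

    @property
    def valid(self) -> np.ndarray:
        ok = ~(self.undefined | self.removed)
        ok[0] = False
        return ok


def velocity_toward_target(positions: np.ndarray, f_s: float) -> VelocitySeries:
    """v_i series; glitch samples (|v| > 2.5 m/s) are flagged, not zeroed."""
    p = np.asarray(positions, float)
    if len(p) < 2:
        raise KinematicsError("velocity needs at least two samples")
    p_end = p[-1]
    to_target = p_end - p
    dist = np.linalg.norm(to_target, axis=1)
    undefined = dist == 0
    v = np.full(len(p), np.nan)
    step = p[1:] - p[:-1]
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = to_target[1:] / dist[1:, None]
        v[1:] = f_s * np.einsum("ij,ij->i", step, unit)
    removed = np.zeros(len(p), bool)
    good = ~undefined & ~np.isnan(v)
    removed[good] = np.abs(v[good]) > VELOCITY_LIMIT
    return VelocitySeries(v=v, undefined=undefined, removed=removed)


# --------------------------------------------------------------------------
# earliness of first correct prediction
# --------------------------------------------------------------------------

def first_correct_times(se) -> dict[int, float]:
    """Normalized time of the earliest accepted-and-correct prediction per
    movement; movements never correctly predicted are absent.

    `se` is a StreamEval (see evaluation module).  Normalized time is the
    one-based sample position within the movement over the movement length.
    """
    times: dict[int, float] = {}
    mv = se.movement
    hits = se.accepted & (se.pred_cls == se.true_cls)
    for m in np.unique(mv):
        span = mv == m
        length = se.movement_length[span][0] if se.movement_length is not None else span.sum()
        t_hit = np.flatnonzero(span & hits)
        if t_hit.size == 0:
            continue
        offset = se.offset_in_movement[t_hit[0]]
        times[int(m)] = float((offset + 1) / length)
    return times


@dataclass
class TAMCReport:
    times: np.ndarray          # normalized first-correct times, one per covered movement
    percentiles: dict[int, float]
    ms_ahead: dict[int, float]  # remaining movement time at each percentile
    reference_length: float     # samples
    f_s: float


def tamc_report(times, reference_length: float = 151, f_s: float = 120.0) -> TAMCReport:
    """Percentile summary of normalized first-correct times.

    ms_ahead converts each percentile to the milliseconds of movement that
    remain for a movement of `reference_length` samples:
    (1 - t) * reference_length / f_s * 1000.
    """
    arr = np.sort(np.asarray(list(times.values()) if isinstance(times, dict) else times, float))
    if arr.size == 0:
        raise KinematicsError("no first-correct times to summarize")
    pct = {q: float(np.percentile(arr, q)) for q in TAMC_PERCENTILES}
    ms = {q: (1.0 - t) * reference_length / f_s * 1000.0 for q, t in pct.items()}
    return TAMCReport(times=arr, percentiles=pct, ms_ahead=ms,
                      reference_length=reference_length, f_s=f_s)
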