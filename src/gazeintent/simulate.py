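"""Synthetic reach-to-target VR sessions.

Emulates the statistical structure of a seated/standing VR pick-task: a
participant faces two semicircular arcs of 9 boxes each (inner arc at height
h1 / radius r1, outer at h2 / r2) plus a neutral box 0 placed 0.30 m in
front at height h0 = h1 - 0.10 m.  Boxes light up one at a time; the
participant looks at the lit box and reaches for it with the active hand.
Logged channels (120 Hz): per-eye gaze direction and pupil diameter, head
position, both controller positions, the active box label and a warm-up
flag.

Coordinate convention: axis 0 is vertical (height), axes 1-2 span the
horizontal plane with axis 1 pointing straight ahead.

Movement model, per click-to-click segment of L samples (L is drawn from a
Beta-shaped duration distribution):

* samples [0, cue_delay): the next box is not yet lit; gaze lingers on the
  previous target.  The segment is nevertheless labeled with the *next*
  target, because the log is segmented click-to-click - this reproduces the
  "lucky-shot" structure of real recordings.
* gaze saccades to the new target one saccade latency after the cue and then
  fixates with small angular noise; blinks insert NaN runs into both eye
  channels.
* the active hand idles (jitter about its previous position) and then
  executes a minimum-jerk reach occupying the final portion of the segment,
  arriving at the box center on the last sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml


class ValidationError(ValueError):
    pass


class ConfigurationError(ValueError):
    pass


# --------------------------------------------------------------------------
# profile / layout / config
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ParticipantProfile:
    """Per-participant geometry and noise parameters."""
    h1: float = 1.15           # inner-arc height (m): forearm horizontal
    h2: float = 1.40           # outer-arc height (m): arm extended
    r1: float = 0.30           # inner radius (m)
    r2: float = 0.65           # outer radius (m)
    right_handed: bool = True
    gaze_noise_deg: float = 1.0       # fixation angular noise SD (degrees)
    saccade_latency_ms: float = 200.0  # cue onset -> gaze lands on target
    blink_rate_per_min: float = 15.0
    blink_duration_ms: float = 150.0

    def __post_init__(self):
        if not (self.h2 > self.h1 > 0):
            raise ValidationError(f"need h2 > h1 > 0, got h1={self.h1}, h2={self.h2}")
        if not (self.r2 > self.r1 > 0):
            raise ValidationError(f"need r2 > r1 > 0, got r1={self.r1}, r2={self.r2}")
        for nm in ("gaze_noise_deg", "saccade_latency_ms",
                   "blink_rate_per_min", "blink_duration_ms"):
            if getattr(self, nm) < 0:
                raise ValidationError(f"{nm} must be >= 0")

    @property
    def h0(self) -> float:
        return self.h1 - 0.10


@dataclass(frozen=True)
class DurationModel:
    """Beta-shaped click-to-click movement lengths, in samples.

    Moments are matched on the support [minimum, maximum] by the method of
    moments; draws are rounded to integers and clipped at the minimum.
    """
    mean: float = 175.0
    sd: float = 66.0
    minimum: int = 74
    maximum: int = 598

    def beta_params(self) -> tuple[float, float]:
        span = self.maximum - self.minimum
        if span <= 0:
            raise ConfigurationError("duration maximum must exceed minimum")
        m = (self.mean - self.minimum) / span
        if not (0.0 < m < 1.0):
            raise ConfigurationError("duration mean outside (min, max)")
        if self.sd == 0:
            return np.inf, np.inf
        v = (self.sd / span) ** 2
        if v >= m * (1.0 - m):
            raise ConfigurationError(
                f"duration SD {self.sd} too large for support [{self.minimum}, {self.maximum}]")
        nu = m * (1.0 - m) / v - 1.0
        return m * nu, (1.0 - m) * nu


@dataclass(frozen=True)
class SimulationConfig:
    f_s: float = 120.0
    cue_delay_s: float = 0.2
    n_movements: int = 152
    duration: DurationModel = field(default_factory=DurationModel)
    warmup_movements: int = 5
    arc_span_deg: float = 180.0
    reach_fraction: float = 0.5   # final fraction of each movement spent reaching
    hand_jitter_sd: float = 0.003  # idle-phase controller jitter (m)
    head_sway_sd: float = 0.002    # head-position noise (m)
    pupil_noise_sd: float = 0.05   # per-eye pupil noise (mm)
    pupil_mean_mm: float = 3.5

    def __post_init__(self):
        if self.f_s <= 0:
            raise ValidationError("sampling rate must be positive")
        if self.duration.minimum < 1:
            raise ValidationError("minimum duration must be >= 1 sample")
        if self.n_movements % 2:
            raise ValidationError("n_movements must be even (balanced left/right hand)")

    @property
    def cue_delay_samples(self) -> int:
        return int(round(self.cue_delay_s * self.f_s))


N_BOXES = 19


@dataclass(frozen=True)
class BoxLayout:
    """19 box centers: index 0 = neutral; 1-9 inner arc; 10-18 outer arc.

    Arc boxes are indexed by increasing azimuth, measured in the horizontal
    plane from the participant's right (azimuth 0) through straight ahead
    (90 degrees, for a semicircular span) to the left.
    """
    positions: np.ndarray  # (19, 3)

    def __post_init__(self):
        if self.positions.shape != (N_BOXES, 3):
            raise ValidationError("layout requires 19 box centers")


def make_layout(profile: ParticipantProfile, arc_span_deg: float = 180.0,
                standing: np.ndarray | None = None) -> BoxLayout:
    """Box centers for a profile, arcs centered on the standing position."""
    stand = np.zeros(3) if standing is None else np.asarray(standing, float)
    pos = np.zeros((N_BOXES, 3))
    pos[0] = stand + np.array([profile.h0, 0.30, 0.0])
    span = np.deg2rad(arc_span_deg)
    offset = (np.pi - span) / 2.0  # center the span on straight-ahead
    az = offset + span * np.arange(9) / 8.0
    for arc, (h, r) in enumerate([(profile.h1, profile.r1), (profile.h2, profile.r2)]):
        for j in range(9):
            pos[1 + 9 * arc + j] = stand + np.array(
                [h, r * np.sin(az[j]), r * np.cos(az[j])])
    return BoxLayout(positions=pos)


def sample_movement_length(cfg: SimulationConfig, rng: np.random.Generator) -> int:
    """One Beta-distributed click-to-click length, in samples (>= minimum)."""
    d = cfg.duration
    if d.sd == 0:
        return int(round(d.mean))
    a, b = d.beta_params()
    x = d.minimum + (d.maximum - d.minimum) * rng.beta(a, b)
    return max(d.minimum, int(round(x)))


# --------------------------------------------------------------------------
# session log
# --------------------------------------------------------------------------

@dataclass
class SessionLog:
    """Per-sample multichannel record of one session."""
    timestamp: np.ndarray       # (T,) seconds
    eye_left: np.ndarray        # (T, 3) unit vectors or NaN
    eye_right: np.ndarray       # (T, 3)
    pupil_left: np.ndarray      # (T,) mm or NaN
    pupil_right: np.ndarray     # (T,)
    head: np.ndarray            # (T, 3) m
    ctrl_left: np.ndarray       # (T, 3) m
    ctrl_right: np.ndarray      # (T, 3) m
    box: np.ndarray             # (T,) int 0-18, target of the current movement
    warmup: np.ndarray          # (T,) bool
    movement: np.ndarray        # (T,) int movement index

    def __len__(self):
        return len(self.timestamp)

    def to_frame(self) -> pd.DataFrame:
        cols = {"timestamp": self.timestamp}
        for nm, arr in [("eye_l", self.eye_left), ("eye_r", self.eye_right),
                        ("head", self.head), ("ctrl_l", self.ctrl_left),
                        ("ctrl_r", self.ctrl_right)]:
            for ax in range(3):
                cols[f"{nm}_{ax}"] = arr[:, ax]
        cols["pupil_l"] = self.pupil_left
        cols["pupil_r"] = self.pupil_right
        cols["box"] = self.box
        cols["warmup"] = self.warmup.astype(int)
        cols["movement"] = self.movement
        return pd.DataFrame(cols)

    @staticmethod
    def from_frame(df: pd.DataFrame) -> "SessionLog":
        vec = lambda nm: df[[f"{nm}_{ax}" for ax in range(3)]].to_numpy(float)
        return SessionLog(
            timestamp=df["timestamp"].to_numpy(float),
            eye_left=vec("eye_l"), eye_right=vec("eye_r"),
            pupil_left=df["pupil_l"].to_numpy(float),
            pupil_right=df["pupil_r"].to_numpy(float),
            head=vec("head"), ctrl_left=vec("ctrl_l"), ctrl_right=vec("ctrl_r"),
            box=df["box"].to_numpy(int),
            warmup=df["warmup"].to_numpy(int).astype(bool),
            movement=df["movement"].to_numpy(int))


def write_session(log: SessionLog, path: str | Path,
                  profile: ParticipantProfile | None = None,
                  cfg: SimulationConfig | None = None,
                  seed: int | None = None) -> None:
    """Write one session as CSV (NaN as empty cell) with a YAML sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    log.to_frame().to_csv(path, index=False, na_rep="")
    meta: dict = {"seed": seed}
    if profile is not None:
        meta["profile"] = asdict(profile)
    if cfg is not None:
        c = asdict(cfg)
        meta["config"] = c
    with open(path.with_suffix(".yaml"), "w") as fh:
        yaml.safe_dump(meta, fh)


def read_session(path: str | Path) -> SessionLog:
    return SessionLog.from_frame(pd.read_csv(path))


# --------------------------------------------------------------------------
# kinematic/gaze building blocks
# --------------------------------------------------------------------------

def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v, axis=-1, keepdims=True)


def _smooth_noise(rng: np.random.Generator, n: int, sd: float,
                  win: int = 24) -> np.ndarray:
    """Temporally correlated positional noise (moving-average filtered white
    noise, rescaled to SD `sd`): a resting hand or head drifts slowly rather
    than jumping frame to frame."""
    if sd == 0 or n == 0:
        return np.zeros((n, 3))
    white = rng.normal(0.0, sd, size=(n + win - 1, 3))
    kernel = np.ones(win) / win
    sm = np.apply_along_axis(lambda c: np.convolve(c, kernel, mode="valid"), 0, white)
    return sm * np.sqrt(win)  # restore the per-sample SD


def minimum_jerk(p0: np.ndarray, p1: np.ndarray, n: int) -> np.ndarray:
    """Minimum-jerk positional profile from p0 to p1 over n samples (inclusive ends)."""
    s = np.linspace(0.0, 1.0, n)
    blend = 10 * s**3 - 15 * s**4 + 6 * s**5
    return p0 + blend[:, None] * (p1 - p0)


def _balanced_sequence(n: int, rng: np.random.Generator) -> np.ndarray:
    """Target sequence covering all 19 boxes as evenly as n allows, shuffled."""
    base = np.tile(np.arange(N_BOXES), n // N_BOXES)
    extra = rng.choice(N_BOXES, size=n - len(base), replace=False) if n % N_BOXES else []
    seq = np.concatenate([base, extra]).astype(int)
    rng.shuffle(seq)
    return seq


# --------------------------------------------------------------------------
# main generator
# --------------------------------------------------------------------------

def simulate_session(cfg: SimulationConfig, profile: ParticipantProfile,
                     seed: int | None) -> SessionLog:
    """Generate one full session (warm-up + main block) at f_s Hz."""
    if seed is None:
        raise ValidationError("simulate_session requires an explicit seed")
    rng = np.random.default_rng(seed)
    layout = make_layout(profile, cfg.arc_span_deg)
    boxes = layout.positions

    n_wu = cfg.warmup_movements
    seq_main = _balanced_sequence(cfg.n_movements, rng)
    seq = np.concatenate([rng.integers(0, N_BOXES, size=n_wu), seq_main])
    n_total = len(seq)

    lengths = np.array([sample_movement_length(cfg, rng) for _ in range(n_total)])
    T = int(lengths.sum())
    delay = cfg.cue_delay_samples
    latency = int(round(profile.saccade_latency_ms / 1000.0 * cfg.f_s))

    head_base = np.array([profile.h2 + 0.25, 0.0, 0.0])  # eyes above the outer arc
    head = head_base + _smooth_noise(rng, T, cfg.head_sway_sd)

    rest_r = np.array([0.9, 0.05, -0.20])
    rest_l = np.array([0.9, 0.05, 0.20])
    ctrl = {"r": np.empty((T, 3)), "l": np.empty((T, 3))}
    hand_pos = {"r": rest_r.copy(), "l": rest_l.copy()}

    gaze_target = np.empty((T, 3))
    box_col = np.empty(T, dtype=int)
    warm = np.zeros(T, dtype=bool)
    move_col = np.empty(T, dtype=int)

    # right hand for the first half of the main block, then left (warm-up: dominant)
    dominant = "r" if profile.right_handed else "l"
    other = "l" if dominant == "r" else "r"
    half = n_wu + cfg.n_movements // 2

    prev_box = 0  # gaze starts on the neutral box
    t0 = 0
    for m in range(n_total):
        L = lengths[m]
        sl = slice(t0, t0 + L)
        target = seq[m]
        box_col[sl] = target
        move_col[sl] = m
        warm[sl] = m < n_wu

        # gaze: previous box through delay + latency, then the new target
        switch = min(L, delay + latency)
        gaze_target[t0:t0 + switch] = boxes[prev_box]
        gaze_target[t0 + switch:t0 + L] = boxes[target]

        # hands
        active = dominant if m < half else other
        passive = other if active == dominant else dominant
        n_reach = max(2, int(round(cfg.reach_fraction * L)))
        n_idle = L - n_reach
        start = hand_pos[active]
        idle = start + _smooth_noise(rng, n_idle, cfg.hand_jitter_sd)
        reach = minimum_jerk(start, boxes[target], n_reach)
        ctrl[active][sl] = np.vstack([idle, reach])
        ctrl[passive][sl] = hand_pos[passive] + _smooth_noise(rng, L, cfg.hand_jitter_sd)
        hand_pos[active] = boxes[target].copy()

        prev_box = target
        t0 += L

    # gaze directions with angular noise, per eye
    sigma = np.deg2rad(profile.gaze_noise_deg)
    base_dir = _unit(gaze_target - head)
    eyes = []
    for _ in range(2):
        if sigma > 0:
            d = _unit(base_dir + rng.normal(0.0, sigma, size=(T, 3)))
        else:
            d = base_dir.copy()
        eyes.append(d)
    eye_l, eye_r = eyes

    pupil_l = cfg.pupil_mean_mm + rng.normal(0.0, cfg.pupil_noise_sd, size=T)
    pupil_r = cfg.pupil_mean_mm + rng.normal(0.0, cfg.pupil_noise_sd, size=T)

    # blinks: Poisson onsets, fixed duration, NaN in every eye channel
    if profile.blink_rate_per_min > 0 and profile.blink_duration_ms > 0:
        p_onset = profile.blink_rate_per_min / 60.0 / cfg.f_s
        n_blink = max(1, int(round(profile.blink_duration_ms / 1000.0 * cfg.f_s)))
        onsets = np.flatnonzero(rng.random(T) < p_onset)
        for on in onsets:
            blk = slice(on, min(T, on + n_blink))
            eye_l[blk] = np.nan
            eye_r[blk] = np.nan
            pupil_l[blk] = np.nan
            pupil_r[blk] = np.nan

    return SessionLog(
        timestamp=np.arange(T) / cfg.f_s,
        eye_left=eye_l, eye_right=eye_r,
        pupil_left=pupil_l, pupil_right=pupil_r,
        head=head, ctrl_left=ctrl["l"], ctrl_right=ctrl["r"],
        box=box_col, warmup=warm, movement=move_col)
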