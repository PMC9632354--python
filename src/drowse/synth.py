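"""Synthetic facial-landmark streams with fatigue-dependent statistics.

The simulator stands in for an infrared dashboard camera plus a landmark
detector.  It emits per-frame 2D coordinates for a canonical 6-point eye,
an 8-point mouth and the 5 face points used for head-pose recovery,
together with timestamps, a driver state and a Karolinska Sleepiness Scale
(KSS) label.  Event schedules are Poisson processes whose rates and
durations depend on the driver state:

* blinks last 0.2-0.3 s awake and well over 1 s when fatigued, with a
  piecewise-cosine close/hold/open envelope on the eyelid-pair distances;
* yawns (~4 s, fatigued only) drive the lip-pair gap towards 90% of the
  mouth width; speech episodes open the mouth briefly and shallowly in
  both states;
* fatigued head motion adds nod (pitch) and tilt (roll) excursions of
  20-40 degrees on top of a slow postural wander.

All randomness flows from a single seed, so a (profile, state, duration,
fps, seed) tuple reproduces the identical session.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import headpose

__all__ = [
    "SubjectProfile",
    "LandmarkFrame",
    "Session",
    "simulate_session",
    "binarize_kss",
    "NON_FATIGUE",
    "FATIGUE",
    "EXCLUDED",
]

NON_FATIGUE = "non_fatigue"
FATIGUE = "fatigue"
EXCLUDED = "excluded"

_STATES = ("awake", "fatigued")


@dataclass(frozen=True)
class SubjectProfile:
    """Behavioural rates and geometry of one simulated driver.

    Rates are events per minute; durations are seconds; landmark jitter is
    isotropic Gaussian per point, in pixels.
    """

    blink_rate_awake: float = 15.0
    blink_rate_fatigued: float = 18.0
    blink_dur_awake: tuple[float, float] = (0.2, 0.3)
    blink_dur_fatigued: tuple[float, float] = (1.0, 2.0)
    yawn_rate_fatigued: float = 1.0
    yawn_dur: float = 4.0
    speech_rate: float = 0.5
    nod_rate_fatigued: float = 2.0
    tilt_rate_fatigued: float = 1.0
    landmark_noise_sd: float = 0.5
    eye_width: float = 40.0
    mouth_width: float = 60.0

    def __post_init__(self) -> None:
        rates = (
            self.blink_rate_awake,
            self.blink_rate_fatigued,
            self.yawn_rate_fatigued,
            self.speech_rate,
            self.nod_rate_fatigued,
            self.tilt_rate_fatigued,
        )
        if any(r < 0 for r in rates):
            raise ValueError("event rates must be non-negative")
        if not (self.blink_dur_awake[0] <= self.blink_dur_awake[1]):
            raise ValueError("blink_dur_awake range must be ordered")
        if not (self.blink_dur_fatigued[0] <= self.blink_dur_fatigued[1]):
            raise ValueError("blink_dur_fatigued range must be ordered")
        if self.blink_dur_fatigued[0] <= self.blink_dur_awake[1]:
            raise ValueError(
                "fatigued blinks must outlast awake blinks "
                f"({self.blink_dur_fatigued[0]} s <= {self.blink_dur_awake[1]} s)"
            )
        if self.yawn_dur <= 0 or self.eye_width <= 0 or self.mouth_width <= 0:
            raise ValueError("durations and widths must be positive")
        if self.landmark_noise_sd < 0:
            raise ValueError("landmark_noise_sd must be non-negative")

    @classmethod
    def from_dict(cls, d: dict) -> "SubjectProfile":
        d = dict(d)
        for key in ("blink_dur_awake", "blink_dur_fatigued"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["blink_dur_awake"] = list(self.blink_dur_awake)
        d["blink_dur_fatigued"] = list(self.blink_dur_fatigued)
        return d


@dataclass(frozen=True)
class LandmarkFrame:
    """One timestamped frame of landmark coordinates plus labels.

    Eye points follow the canonical order (p1, p6 eye corners; (p2, p3) and
    (p4, p5) the vertical lid pairs); mouth points have corners M1, M5 and
    vertical lip pairs (M2, M8), (M3, M7), (M4, M6).
    """

    t: float
    eye_pts: np.ndarray  # (6, 2)
    mouth_pts: np.ndarray  # (8, 2)
    pose_pts: np.ndarray  # (5, 2)
    kss: int
    state: str

    def __post_init__(self) -> None:
        if not (1 <= self.kss <= 9):
            raise ValueError(f"kss must lie in [1, 9], got {self.kss}")
        for name in ("eye_pts", "mouth_pts", "pose_pts"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"{name} must be finite")
        if np.linalg.norm(self.eye_pts[5] - self.eye_pts[0]) <= 0:
            raise ValueError("eye corners must be distinct")


_CSV_COLUMNS = (
    ["t", "kss", "state"]
    + [f"eye_p{i}_{c}" for i in range(1, 7) for c in "xy"]
    + [f"m{i}_{c}" for i in range(1, 9) for c in "xy"]
    + [f"pose{i}_{c}" for i in range(1, 6) for c in "xy"]
)


@dataclass
class Session:
    """A simulated (or ingested) landmark recording.

    Coordinates live in dense arrays (``eye_pts`` is ``(n, 6, 2)`` etc.);
    :attr:`frames` materialises per-frame :class:`LandmarkFrame` objects on
    demand.
    """

    fps: float
    seed: int | None
    t: np.ndarray
    eye_pts: np.ndarray
    mouth_pts: np.ndarray
    pose_pts: np.ndarray
    kss: np.ndarray
    state: np.ndarray
    ground_truth_events: list[tuple[str, float, float]] = field(default_factory=list)
    euler_true: np.ndarray | None = None  # (n, 3) pitch/yaw/roll, degrees

    @property
    def n_frames(self) -> int:
        return len(self.t)

    @property
    def frames(self) -> list[LandmarkFrame]:
        return [
            LandmarkFrame(
                t=float(self.t[i]),
                eye_pts=self.eye_pts[i],
                mouth_pts=self.mouth_pts[i],
                pose_pts=self.pose_pts[i],
                kss=int(self.kss[i]),
                state=str(self.state[i]),
            )
            for i in range(self.n_frames)
        ]

    def events(self, kind: str) -> list[tuple[str, float, float]]:
        return [e for e in self.ground_truth_events if e[0] == kind]

    def to_dataframe(self) -> pd.DataFrame:
        data = {"t": self.t, "kss": self.kss, "state": self.state}
        blocks = {"eye_p": self.eye_pts, "m": self.mouth_pts, "pose": self.pose_pts}
        for prefix, arr in blocks.items():
            for i in range(arr.shape[1]):
                data[f"{prefix}{i + 1}_x"] = arr[:, i, 0]
                data[f"{prefix}{i + 1}_y"] = arr[:, i, 1]
        return pd.DataFrame(data, columns=_CSV_COLUMNS)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, fps: float | None = None, seed: int | None = None
    ) -> "Session":
        missing = [c for c in _CSV_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"landmark table missing columns: {missing[:4]}...")
        t = df["t"].to_numpy(float)
        if fps is None:
            fps = 1.0 / np.median(np.diff(t)) if len(t) > 1 else 1.0

        def block(prefix: str, k: int) -> np.ndarray:
            cols = [f"{prefix}{i}_{c}" for i in range(1, k + 1) for c in "xy"]
            return df[cols].to_numpy(float).reshape(len(df), k, 2)

        return cls(
            fps=float(fps),
            seed=seed,
            t=t,
            eye_pts=block("eye_p", 6),
            mouth_pts=block("m", 8),
            pose_pts=block("pose", 5),
            kss=df["kss"].to_numpy(int),
            state=df["state"].to_numpy(str),
        )

    @classmethod
    def read_csv(cls, path, fps: float | None = None) -> "Session":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"landmark file not found: {path}")
        return cls.from_dataframe(pd.read_csv(path), fps=fps)


def binarize_kss(kss: int) -> str:
    """Map a KSS score to the binary driving state.

    Scores below 3 are non-fatigued and scores above 4 fatigued; 3 and 4
    fall in neither rule's range and are excluded from the labelled data.
    """
    kss = int(kss)
    if not 1 <= kss <= 9:
        raise ValueError(f"kss must lie in [1, 9], got {kss}")
    if kss < 3:
        return NON_FATIGUE
    if kss > 4:
        return FATIGUE
    return EXCLUDED


# ---------------------------------------------------------------------------
# event scheduling and envelopes


def _schedule_events(
    rng: np.random.Generator,
    rate_per_min: float,
    duration: float,
    dur_sampler,
    min_gap: float = 0.05,
) -> list[tuple[float, float]]:
    """Poisson start times pushed apart so same-kind events never overlap."""
    if rate_per_min <= 0:
        return []
    events: list[tuple[float, float]] = []
    mean_gap = 60.0 / rate_per_min
    start = rng.exponential(mean_gap)
    while start < duration:
        if events and start < events[-1][1] + min_gap:
            start = events[-1][1] + min_gap
            if start >= duration:
                break
        d = float(dur_sampler())
        events.append((start, min(start + d, duration)))
        start = start + rng.exponential(mean_gap)
    return events


def _cosine_bump(t: np.ndarray, start: float, end: float, ramp: float) -> np.ndarray:
    """0->1->0 envelope on [start, end]: cosine ramps of `ramp` seconds around a hold."""
    dur = end - start
    ramp = min(ramp, dur / 2.0)
    x = t - start
    env = np.zeros_like(t)
    inside = (x >= 0) & (x <= dur)
    xi = x[inside]
    e = np.ones_like(xi)
    if ramp > 0:
        up = xi < ramp
        e[up] = 0.5 * (1.0 - np.cos(np.pi * xi[up] / ramp))
        down = xi > dur - ramp
        e[down] = 0.5 * (1.0 - np.cos(np.pi * (dur - xi[down]) / ramp))
    env[inside] = e
    return env


def _apply_events(
    t: np.ndarray, events: list[tuple[float, float]], ramp_frac: float | None, ramp_abs: float | None
) -> np.ndarray:
    """Max-combine cosine bumps for every event onto the frame grid."""
    env = np.zeros_like(t)
    if not events:
        return env
    fps_dt = t[1] - t[0] if len(t) > 1 else 1.0
    for start, end in events:
        ramp = ramp_abs if ramp_abs is not None else ramp_frac * (end - start)
        i0 = max(int(np.floor((start - t[0]) / fps_dt)) - 1, 0)
        i1 = min(int(np.ceil((end - t[0]) / fps_dt)) + 2, len(t))
        env[i0:i1] = np.maximum(env[i0:i1], _cosine_bump(t[i0:i1], start, end, ramp))
    return env


def _smooth_wander(rng: np.random.Generator, n: int, fps: float, sd: float) -> np.ndarray:
    """Slow zero-mean postural drift: white noise low-passed over ~2 s."""
    w = max(int(round(2.0 * fps)), 1)
    noise = rng.normal(0.0, sd, n + w)
    kernel = np.ones(w) / w
    return np.convolve(noise, kernel, mode="valid")[:n] * np.sqrt(w)


# ---------------------------------------------------------------------------
# the simulator


def simulate_session(
    profile: SubjectProfile,
    state: str,
    duration: float,
    fps: float = 15.0,
    seed: int = 0,
) -> Session:
    """Simulate one continuous recording in a fixed driver state.

    ``duration`` is in seconds; the session has ``round(fps * duration)``
    frames at strictly increasing timestamps ``i / fps``.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if fps <= 0:
        raise ValueError("fps must be positive")
    if state not in _STATES:
        raise ValueError(f"state must be one of {_STATES}, got {state!r}")
    fatigued = state == "fatigued"
    rng = np.random.default_rng(seed)

    n = int(round(fps * duration))
    t = np.arange(n) / fps

    # --- event schedules -------------------------------------------------
    blink_rate = profile.blink_rate_fatigued if fatigued else profile.blink_rate_awake
    blink_dur = profile.blink_dur_fatigued if fatigued else profile.blink_dur_awake
    blinks = _schedule_events(
        rng, blink_rate, duration, lambda: rng.uniform(*blink_dur)
    )
    yawns = (
        _schedule_events(
            rng,
            profile.yawn_rate_fatigued,
            duration,
            lambda: rng.uniform(profile.yawn_dur - 0.4, profile.yawn_dur + 0.4),
        )
        if fatigued
        else []
    )
    speech = _schedule_events(
        rng, profile.speech_rate, duration, lambda: rng.uniform(0.8, 2.5)
    )
    # the mouth can't speak mid-yawn
    speech = [
        (s, e)
        for (s, e) in speech
        if not any(s < ye and e > ys for (ys, ye) in yawns)
    ]
    nods = (
        _schedule_events(rng, profile.nod_rate_fatigued, duration, lambda: rng.uniform(1.0, 3.0))
        if fatigued
        else []
    )
    tilts = (
        _schedule_events(rng, profile.tilt_rate_fatigued, duration, lambda: rng.uniform(1.0, 3.0))
        if fatigued
        else []
    )

    # --- eye geometry -----------------------------------------------------
    a = profile.eye_width
    lid_open = 0.35 * a  # fully-open eyelid gap
    closure = _apply_events(t, blinks, ramp_frac=0.3, ramp_abs=None)
    lid = lid_open * (1.0 - 0.98 * closure)

    ex, ey = 320.0, 200.0
    eye = np.zeros((n, 6, 2))
    eye[:, 0] = (ex - a / 2, ey)  # p1 outer corner
    eye[:, 5] = (ex + a / 2, ey)  # p6 inner corner
    for idx, xoff in ((1, -a / 6), (3, a / 6)):  # p2, p4 upper lid
        eye[:, idx, 0] = ex + xoff
        eye[:, idx, 1] = ey - lid / 2
    for idx, xoff in ((2, -a / 6), (4, a / 6)):  # p3, p5 lower lid
        eye[:, idx, 0] = ex + xoff
        eye[:, idx, 1] = ey + lid / 2

    # --- mouth geometry ---------------------------------------------------
    w = profile.mouth_width
    g0 = 0.04 * w  # lips at rest
    yawn_env = _apply_events(t, yawns, ramp_frac=None, ramp_abs=0.4)
    speech_env = _apply_events(t, speech, ramp_frac=None, ramp_abs=0.2)
    # speech modulates the gap at syllable rate, never near the yawn gate
    syllables = 0.5 + 0.5 * np.sin(2.0 * np.pi * 3.0 * t + rng.uniform(0, 2 * np.pi))
    gap = g0 + (0.9 * w - g0) * yawn_env + 0.3 * w * speech_env * syllables
    gap = np.minimum(gap, 0.95 * w)

    mx, my = 320.0, 300.0
    mouth = np.zeros((n, 8, 2))
    mouth[:, 0] = (mx - w / 2, my)  # M1 left corner
    mouth[:, 4] = (mx + w / 2, my)  # M5 right corner
    side = 0.8  # outer lip pairs open less than the midline
    for idx, xoff, frac, sign in (
        (1, -w / 4, side, -1),  # M2 upper-left
        (2, 0.0, 1.0, -1),  # M3 upper-mid
        (3, w / 4, side, -1),  # M4 upper-right
        (5, w / 4, side, 1),  # M6 lower-right
        (6, 0.0, 1.0, 1),  # M7 lower-mid
        (7, -w / 4, side, 1),  # M8 lower-left
    ):
        mouth[:, idx, 0] = mx + xoff
        mouth[:, idx, 1] = my + sign * frac * gap / 2

    # --- head pose --------------------------------------------------------
    euler = np.zeros((n, 3))
    for k in range(3):
        euler[:, k] = _smooth_wander(rng, n, fps, 2.0 if k != 1 else 1.5)
    for start, end in nods:
        amp = rng.uniform(20.0, 40.0)
        euler[:, 0] += amp * _cosine_bump(t, start, end, 0.3 * (end - start))
    for start, end in tilts:
        amp = rng.uniform(20.0, 40.0) * rng.choice([-1.0, 1.0])
        euler[:, 2] += amp * _cosine_bump(t, start, end, 0.3 * (end - start))

    cam = headpose.default_intrinsics()
    model = headpose.default_face_model()
    R = headpose.euler_to_rotation(euler)
    translation = np.broadcast_to(np.array([0.0, 0.0, 600.0]), (n, 3))
    pose = headpose.project_points(model.points, R, translation, cam)

    # --- labels and jitter ------------------------------------------------
    kss = np.empty(n, dtype=int)
    seg = max(int(round(300.0 * fps)), 1)  # expert re-scores every 5 min
    choices = np.array([5, 6, 7, 8, 9]) if fatigued else np.array([1, 2])
    for i0 in range(0, n, seg):
        kss[i0 : i0 + seg] = rng.choice(choices)

    if profile.landmark_noise_sd > 0:
        eye = eye + rng.normal(0.0, profile.landmark_noise_sd, eye.shape)
        mouth = mouth + rng.normal(0.0, profile.landmark_noise_sd, mouth.shape)
        pose = pose + rng.normal(0.0, profile.landmark_noise_sd, pose.shape)

    events = sorted(
        [("blink", s, e) for s, e in blinks]
        + [("yawn", s, e) for s, e in yawns]
        + [("speech", s, e) for s, e in speech]
        + [("nod", s, e) for s, e in nods]
        + [("tilt", s, e) for s, e in tilts],
        key=lambda ev: ev[1],
    )
    return Session(
        fps=float(fps),
        seed=int(seed),
        t=t,
        eye_pts=eye,
        mouth_pts=mouth,
        pose_pts=pose,
        kss=kss,
        state=np.full(n, state, dtype=object),
        ground_truth_events=events,
        euler_true=euler,
    )
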