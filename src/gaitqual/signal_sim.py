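"""Synthetic trunk-accelerometer gait signals with known ground truth.

Generates tri-axial acceleration episodes that mimic the structure of
trunk-worn sensor recordings during walking: vertical (VT) and
anteroposterior (AP) power concentrated at harmonics of the step
frequency, mediolateral (ML) power at harmonics of the stride frequency
(one stride = two steps, so f_step = 2 * f_stride), a 1 g gravity offset
on the vertical axis, optional sensor mis-orientation, per-stride phase
jitter, and white sensor noise. The sensor range is clipped at +/-6 g and
the sampling rate defaults to 100 samples/s, matching common trunk-worn
accelerometers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: fixed anatomical axis order used throughout the package
AXES = ("vt", "ml", "ap")

#: sensor measurement range in g
SENSOR_RANGE_G = 6.0


def rotation_matrix(yaw_deg: float = 0.0, pitch_deg: float = 0.0,
                    roll_deg: float = 0.0) -> np.ndarray:
    """Rotation in (VT, ML, AP) coordinates.

    yaw rotates about the VT axis (mixes ML/AP), pitch about the ML axis
    (mixes VT/AP), roll about the AP axis (mixes VT/ML). Composition order
    is yaw @ pitch @ roll.
    """
    cy, sy = np.cos(np.radians(yaw_deg)), np.sin(np.radians(yaw_deg))
    cp, sp = np.cos(np.radians(pitch_deg)), np.sin(np.radians(pitch_deg))
    cr, sr = np.cos(np.radians(roll_deg)), np.sin(np.radians(roll_deg))
    # axes indices: 0=VT, 1=ML, 2=AP
    r_yaw = np.array([[1, 0, 0], [0, cy, -sy], [0, sy, cy]])
    r_pitch = np.array([[cp, 0, -sp], [0, 1, 0], [sp, 0, cp]])
    r_roll = np.array([[cr, -sr, 0], [sr, cr, 0], [0, 0, 1]])
    return r_yaw @ r_pitch @ r_roll


@dataclass(frozen=True)
class GaitSignalParams:
    """Ground-truth parameters of one simulated locomotion episode.

    Harmonic amplitude lists are in g: ``vt_harmonics[k]`` / ``ap_harmonics[k]``
    is the amplitude at (k+1) times the step frequency, ``ml_harmonics[k]``
    the amplitude at (k+1) times the stride frequency. ``asymmetry`` moves
    the given fraction of total ML power from stride harmonics to the step
    frequency, emulating left-right asymmetric gait. ``phase_jitter_sd``
    (radians per stride) drives a random-walk stride phase accumulating
    that variance per stride — the single knob that degrades regularity,
    dynamic stability and entropy measures from perfectly periodic to noisy.
    """

    duration_s: float = 60.0
    fs: float = 100.0
    f_stride: float = 0.9
    vt_harmonics: tuple[float, ...] = (0.22, 0.10, 0.04)
    ap_harmonics: tuple[float, ...] = (0.18, 0.08, 0.03)
    ml_harmonics: tuple[float, ...] = (0.12, 0.0, 0.03)
    asymmetry: float = 0.0
    phase_jitter_sd: float = 0.0
    noise_sd: float = 0.0
    gravity_g: float = 1.0
    yaw_deg: float = 0.0
    pitch_deg: float = 0.0
    roll_deg: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be > 0")
        if self.f_stride <= 0:
            raise ValueError("f_stride must be > 0")
        if self.asymmetry < 0 or self.asymmetry > 1:
            raise ValueError("asymmetry must lie in [0, 1]")
        for name in ("vt_harmonics", "ap_harmonics", "ml_harmonics"):
            if any(a < 0 for a in getattr(self, name)):
                raise ValueError(f"{name} amplitudes must be >= 0")
        f_max = self.max_frequency()
        if self.fs <= 2 * f_max:
            raise ValueError(
                f"sampling rate {self.fs} samples/s cannot represent the "
                f"highest generated harmonic at {f_max:.3g} Hz "
                f"(Nyquist limit {self.fs / 2:.3g} Hz)")

    @property
    def f_step(self) -> float:
        return 2.0 * self.f_stride

    def max_frequency(self) -> float:
        f = 0.0
        if self.vt_harmonics:
            f = max(f, len(self.vt_harmonics) * self.f_step)
        if self.ap_harmonics:
            f = max(f, len(self.ap_harmonics) * self.f_step)
        if self.ml_harmonics:
            f = max(f, len(self.ml_harmonics) * self.f_stride)
        if self.asymmetry > 0:
            f = max(f, self.f_step)
        return f


@dataclass
class AccelEpisode:
    """One locomotion episode of tri-axial trunk acceleration.

    ``samples`` is an (N, 3) array in g with column order (VT, ML, AP)
    once ``aligned`` is True; raw episodes may carry arbitrary sensor axes.
    """

    samples: np.ndarray
    fs: float
    subject_id: int = 0
    week: int = 1
    day: int = 1
    aligned: bool = False
    rotation: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError("samples must be an (N, 3) array")
        if self.samples.shape[0] < 2:
            raise ValueError("an episode needs at least 2 samples")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def axis(self, name: str) -> np.ndarray:
        return self.samples[:, AXES.index(name)]

    def copy_with(self, **kwargs) -> "AccelEpisode":
        return replace(self, **kwargs)

    def to_frame(self) -> pd.DataFrame:
        t = np.arange(self.n_samples) / self.fs
        return pd.DataFrame({
            "subject": self.subject_id, "week": self.week, "day": self.day,
            "t": t,
            "acc_vt": self.samples[:, 0],
            "acc_ml": self.samples[:, 1],
            "acc_ap": self.samples[:, 2],
        })


def _jitter_phase(t: np.ndarray, f_stride: float, sd: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Brownian stride-phase noise accumulating variance sd^2 per stride.

    Realized as independent per-sample increments so the phase random walk
    roughens the waveform at every time scale — which is what lets one knob
    degrade regularity, local dynamic stability and sample entropy together.
    """
    if sd == 0:
        return np.zeros_like(t)
    dt = t[1] - t[0]
    inc = rng.normal(0.0, sd * np.sqrt(f_stride * dt), len(t))
    inc[0] = 0.0
    return np.cumsum(inc)


def simulate_gait_episode(params: GaitSignalParams, subject_id: int = 0,
                          week: int = 1, day: int = 1) -> AccelEpisode:
    """Generate one gait-like episode; bit-identical for identical seeds.

    Construction: VT and AP are cosine series at multiples of the step
    frequency sharing one jittered stride phase; ML is a cosine series at
    multiples of the stride frequency with an asymmetry-controlled leakage
    term at step frequency. Gravity is added to VT, the mis-orientation
    rotation is applied last, then white noise, then clipping to the
    +/-6 g sensor range.
    """
    rng = np.random.default_rng(params.seed)
    n = int(round(params.duration_s * params.fs))
    t = np.arange(n) / params.fs

    phi = 2 * np.pi * params.f_stride * t + _jitter_phase(
        t, params.f_stride, params.phase_jitter_sd, rng)
    step_phi = 2.0 * phi

    vt = np.full(n, params.gravity_g)
    for k, a in enumerate(params.vt_harmonics, start=1):
        vt = vt + a * np.cos(k * step_phi)
    ap = np.zeros(n)
    for k, a in enumerate(params.ap_harmonics, start=1):
        # fixed per-harmonic phase offset so AP is not proportional to VT
        ap = ap + a * np.cos(k * step_phi + k * np.pi / 3)
    ml = np.zeros(n)
    keep = np.sqrt(1.0 - params.asymmetry)
    for k, a in enumerate(params.ml_harmonics, start=1):
        ml = ml + keep * a * np.cos(k * phi + np.pi / 2)
    if params.asymmetry > 0:
        total_amp = np.sqrt(sum(a ** 2 for a in params.ml_harmonics))
        ml = ml + np.sqrt(params.asymmetry) * total_amp * np.cos(step_phi)

    samples = np.column_stack([vt, ml, ap])
    rot = rotation_matrix(params.yaw_deg, params.pitch_deg, params.roll_deg)
    samples = samples @ rot.T
    if params.noise_sd > 0:
        samples = samples + rng.normal(0.0, params.noise_sd, samples.shape)

    n_clipped = int(np.sum(np.abs(samples) > SENSOR_RANGE_G))
    if n_clipped:
        logger.warning("clipped %d samples to the +/-%.0f g sensor range",
                       n_clipped, SENSOR_RANGE_G)
    samples = np.clip(samples, -SENSOR_RANGE_G, SENSOR_RANGE_G)

    identity = (params.yaw_deg == 0 and params.pitch_deg == 0
                and params.roll_deg == 0)
    return AccelEpisode(samples=samples, fs=params.fs, subject_id=subject_id,
                        week=week, day=day, aligned=identity)


# ---------------------------------------------------------------------------
# episode text I/O: header subject,week,day,t,acc_vt,acc_ml,acc_ap
# ---------------------------------------------------------------------------

def write_episodes(episodes: list[AccelEpisode], path: str | Path,
                   sep: str = ",") -> None:
    frames = [ep.to_frame() for ep in episodes]
    pd.concat(frames, ignore_index=True).to_csv(path, sep=sep, index=False,
                                                float_format="%.6g")


def read_episodes(path: str | Path, sep: str = ",",
                  column_map: dict[str, str] | None = None,
                  aligned: bool = False) -> list[AccelEpisode]:
    """Read episodes from delimiter-separated text.

    ``column_map`` remaps non-standard column names, e.g.
    ``{"acc_x": "acc_vt"}`` for a sensor whose x axis is nominally vertical.
    One episode is emitted per (subject, week, day) group, rows taken in
    file order.
    """
    df = pd.read_csv(path, sep=sep)
    if column_map:
        df = df.rename(columns=column_map)
    required = {"subject", "week", "day", "acc_vt", "acc_ml", "acc_ap"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"episode file {path} is missing columns {sorted(missing)}")
    episodes = []
    for (subj, week, day), grp in df.groupby(["subject", "week", "day"], sort=True):
        t = grp["t"].to_numpy()
        if len(t) < 2:
            logger.warning("skipping episode (%s, %s, %s): fewer than 2 samples",
                           subj, week, day)
            continue
        fs = 1.0 / np.median(np.diff(t))
        samples = grp[["acc_vt", "acc_ml", "acc_ap"]].to_numpy()
        episodes.append(AccelEpisode(samples=samples, fs=float(round(fs, 6)),
                                     subject_id=int(subj), week=int(week),
                                     day=int(day), aligned=aligned))
    return episodes
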