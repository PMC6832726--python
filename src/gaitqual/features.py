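"""Gait-quality characteristics from realigned trunk acceleration epochs.

The characteristics cover the families used in daily-life gait analysis of
older adults: pace (walking speed, stride frequency, stride length),
intensity (per-axis standard deviation and range), regularity (stride
autocorrelation), frequency-domain structure (dominant-peak amplitude and
width, index of harmonicity, harmonic ratio), dynamic stability (local
divergence rate, Rosenstein method), complexity (sample entropy), and a
weighted composite score.

All functions operate on epochs that have already been realigned to the
anatomical axes (VT, ML, AP) with gravity removed; :func:`realign_axes`
performs that realignment from the raw sensor orientation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, signal, stats

from .signal_sim import AXES, AccelEpisode, rotation_matrix

logger = logging.getLogger(__name__)

G_TO_MS2 = 9.81


@dataclass
class CompositeWeights:
    """Weights and standardization constants for the gait-quality composite.

    The composite is a weighted sum of z-scored inputs: stride-frequency
    autocorrelation, power at step frequency, root-mean-square acceleration
    and index of harmonicity. Exact cohort-specific weights can be supplied;
    defaults are equal weights with identity standardization.
    """

    inputs: dict[str, str] = field(default_factory=lambda: {
        "stride_regularity": "stride_autocorr_vt",
        "step_power": "dominant_amp_vt",
        "rms": "rms",
        "index_of_harmonicity": "ih_vt",
    })
    weights: dict[str, float] = field(default_factory=lambda: {
        "stride_regularity": 0.25, "step_power": 0.25,
        "rms": 0.25, "index_of_harmonicity": 0.25,
    })
    means: dict[str, float] = field(default_factory=dict)
    sds: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, sd in self.sds.items():
            if sd <= 0:
                raise ValueError(f"standardization SD for {name!r} must be > 0")
        for name, w in self.weights.items():
            if not np.isfinite(w):
                raise ValueError(f"weight for {name!r} must be finite")


@dataclass
class FeatureConfig:
    """Tunable parameters of the extraction pipeline (units in docstrings)."""

    epoch_s: float = 10.0            # epoch window length, s
    min_episode_s: float = 10.0      # episodes shorter than this are skipped
    step_band: tuple[float, float] = (1.0, 4.0)   # step-frequency search, Hz
    stride_search_frac: float = 0.25  # stride-lag search half-width around 2/f_step
    min_stride_autocorr: float = 0.15  # below this the epoch is non-gait
    welch_segment_s: float = 5.0
    welch_overlap: float = 0.5
    ih_n_harmonics: int = 6
    ih_halfwidth_hz: float = 0.1
    hr_n_harmonics: int = 20
    hr_cap: float = 100.0
    lde_dim: int = 5                 # embedding dimension
    lde_delay: int = 10              # embedding delay, samples
    lde_fit_frac: float = 0.5        # divergence fit horizon, strides
    lde_min_points: int = 100
    sampen_m: int = 2
    sampen_r_frac: float = 0.2       # tolerance as fraction of the axis SD
    units: str = "m/s2"              # "m/s2" or "g" for dispersion features
    leg_length_default: float = 0.9  # m, used when no leg length is supplied
    composite: CompositeWeights = field(default_factory=CompositeWeights)
    features: tuple[str, ...] | None = None  # None = compute everything

    def __post_init__(self) -> None:
        if self.epoch_s <= 0:
            raise ValueError("epoch_s must be > 0")
        if self.units not in ("m/s2", "g"):
            raise ValueError("units must be 'm/s2' or 'g'")

    def unit_factor(self) -> float:
        return G_TO_MS2 if self.units == "m/s2" else 1.0


class EpochInvalid(Exception):
    """Raised when an epoch cannot yield valid gait characteristics."""


# ---------------------------------------------------------------------------
# realignment
# ---------------------------------------------------------------------------

def _power_at_freq(x: np.ndarray, fs: float, f: float) -> float:
    """Squared magnitude of the DFT of x at an arbitrary frequency f."""
    t = np.arange(len(x)) / fs
    c = np.sum(x * np.exp(-2j * np.pi * f * t))
    return float(np.abs(c) ** 2) / len(x)


def _gravity_rotation(mean_vec: np.ndarray) -> np.ndarray:
    """Rotation mapping the unit mean-acceleration vector onto +VT."""
    u = mean_vec / np.linalg.norm(mean_vec)
    e = np.array([1.0, 0.0, 0.0])
    axis = np.cross(u, e)
    s = np.linalg.norm(axis)
    c = float(np.dot(u, e))
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate 180 deg about the ML axis
        return np.diag([-1.0, 1.0, -1.0])
    axis = axis / s
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    angle = np.arctan2(s, c)
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


def realign_axes(episode: AccelEpisode, config: FeatureConfig | None = None) -> AccelEpisode:
    """Realign raw sensor axes with the anatomical axes and remove gravity.

    Two stages: (1) rotate so the episode-mean acceleration (gravity) lies
    on +VT; (2) resolve the remaining rotation about the vertical (yaw) by
    minimizing mediolateral power at the step frequency — left-right
    symmetric gait concentrates ML power at the stride, not the step,
    frequency, so residual yaw leaks step-frequency AP power into ML.
    Gravity (the column means) is subtracted afterwards.
    """
    config = config or FeatureConfig()
    if episode.duration_s < 2.0:
        raise ValueError("realignment needs an episode of at least 2 s")
    x = episode.samples
    mean_vec = x.mean(axis=0)
    if np.linalg.norm(mean_vec) < 0.1:
        raise ValueError(
            "episode-mean acceleration is near zero; cannot identify the "
            "gravity direction (free fall or corrupted data)")
    r1 = _gravity_rotation(mean_vec)
    x1 = x @ r1.T

    # detect step frequency on the (yaw-invariant) vertical channel
    vt = x1[:, 0] - x1[:, 0].mean()
    freqs, pxx = signal.periodogram(vt, fs=episode.fs)
    band = (freqs >= config.step_band[0]) & (freqs <= config.step_band[1])
    yaw = 0.0
    if band.any() and pxx[band].max() > 0:
        f_step = float(freqs[band][np.argmax(pxx[band])])
        ml, ap = x1[:, 1] - x1[:, 1].mean(), x1[:, 2] - x1[:, 2].mean()

        def ml_step_power(psi: float) -> float:
            return _power_at_freq(np.cos(psi) * ml - np.sin(psi) * ap,
                                  episode.fs, f_step)

        # coarse 1-degree grid brackets the minimum (objective is a
        # sinusoid in 2*yaw); ties broken toward the smallest |yaw|
        grid = np.radians(np.arange(-90.0, 90.0, 1.0))
        vals = np.array([ml_step_power(p) for p in grid])
        if vals.max() - vals.min() <= 1e-12 * max(vals.max(), 1e-30):
            logger.warning("yaw objective is flat; keeping yaw = 0")
        else:
            best = np.flatnonzero(vals <= vals.min() * (1 + 1e-9))
            i0 = best[np.argmin(np.abs(grid[best]))]
            mid = grid[i0]
            lo, hi = mid - np.radians(1.5), mid + np.radians(1.5)
            try:
                yaw = float(optimize.golden(ml_step_power,
                                            brack=(lo, mid, hi), tol=1e-12))
            except ValueError:   # degenerate bracket: keep the grid minimum
                yaw = float(mid)
    else:
        logger.warning("no step-frequency power found; keeping yaw = 0")

    cy, sy = np.cos(yaw), np.sin(yaw)
    r_yaw = np.array([[1, 0, 0], [0, cy, -sy], [0, sy, cy]])
    rot = r_yaw @ r1
    aligned = x @ rot.T
    aligned = aligned - aligned.mean(axis=0)
    return episode.copy_with(samples=aligned, aligned=True, rotation=rot)


# ---------------------------------------------------------------------------
# epoch handling and basic frequency structure
# ---------------------------------------------------------------------------

def split_epochs(episode: AccelEpisode, epoch_s: float) -> list[AccelEpisode]:
    """Consecutive non-overlapping windows of exactly ``epoch_s`` seconds;
    the trailing remainder is discarded."""
    if epoch_s <= 0:
        raise ValueError("epoch_s must be > 0")
    w = int(round(epoch_s * episode.fs))
    n_ep = episode.n_samples // w
    return [episode.copy_with(samples=episode.samples[i * w:(i + 1) * w])
            for i in range(n_ep)]


def autocorr_unbiased(x: np.ndarray, max_lag: int | None = None) -> np.ndarray:
    """Lag-corrected (unbiased) autocorrelation coefficients rho[0..max_lag]."""
    x = np.asarray(x, float)
    n = len(x)
    xc = x - x.mean()
    if max_lag is None:
        max_lag = n - 1
    f = np.fft.rfft(xc, 2 * n)
    acov = np.fft.irfft(f * np.conj(f))[:max_lag + 1]
    acov = acov / (n - np.arange(max_lag + 1))
    var = acov[0]
    if var <= 0:
        return np.zeros(max_lag + 1)
    return acov / var


def _parabolic_refine(y: np.ndarray, i: int) -> float:
    """Sub-sample peak location by parabolic interpolation around index i."""
    if i <= 0 or i >= len(y) - 1:
        return float(i)
    denom = y[i - 1] - 2 * y[i] + y[i + 1]
    if denom == 0:
        return float(i)
    return i + 0.5 * (y[i - 1] - y[i + 1]) / denom


@dataclass
class FreqInfo:
    f_step: float
    f_stride: float
    stride_time: float
    stride_peak: float


def detect_frequencies(epoch: AccelEpisode,
                       config: FeatureConfig | None = None) -> FreqInfo:
    """Step and stride frequency of a realigned epoch.

    The step frequency is the location of maximum combined VT+AP
    periodogram power in the configured band; the stride frequency comes
    from the highest unbiased-autocorrelation peak within +/-25% of twice
    the step time, refined by parabolic interpolation. Epochs without a
    sufficiently strong stride-periodicity peak are rejected as non-gait.
    """
    config = config or FeatureConfig()
    fs = epoch.fs
    vt = epoch.axis("vt") - epoch.axis("vt").mean()
    ap = epoch.axis("ap") - epoch.axis("ap").mean()
    freqs, p_vt = signal.periodogram(vt, fs=fs)
    _, p_ap = signal.periodogram(ap, fs=fs)
    p = p_vt + p_ap
    band = (freqs >= config.step_band[0]) & (freqs <= config.step_band[1])
    if not band.any() or p[band].max() <= 0:
        raise EpochInvalid("no spectral power in the step-frequency band")
    i_band = np.flatnonzero(band)
    i_pk = i_band[np.argmax(p[band])]
    f_step = float(np.interp(_parabolic_refine(p, i_pk),
                             np.arange(len(freqs)), freqs))
    f_step = float(np.clip(f_step, config.step_band[0], config.step_band[1]))

    stride_t0 = 2.0 / f_step
    lag_lo = int(np.floor((1 - config.stride_search_frac) * stride_t0 * fs))
    lag_hi = int(np.ceil((1 + config.stride_search_frac) * stride_t0 * fs))
    lag_hi = min(lag_hi, epoch.n_samples - 2)
    if lag_lo < 1 or lag_lo >= lag_hi:
        raise EpochInvalid("epoch too short for the stride-lag search band")
    rho = autocorr_unbiased(vt, lag_hi + 1)
    seg = rho[lag_lo:lag_hi + 1]
    i_rel = int(np.argmax(seg))
    peak = float(seg[i_rel])
    if peak < config.min_stride_autocorr:
        raise EpochInvalid(
            f"stride autocorrelation peak {peak:.3f} below "
            f"{config.min_stride_autocorr} — no gait periodicity")
    lag = _parabolic_refine(rho, lag_lo + i_rel)
    stride_time = lag / fs
    return FreqInfo(f_step=f_step, f_stride=1.0 / stride_time,
                    stride_time=stride_time, stride_peak=peak)


# ---------------------------------------------------------------------------
# pace: inverted-pendulum walking speed and stride length
# ---------------------------------------------------------------------------

def walking_speed_and_stride_length(epoch: AccelEpisode, f_step: float,
                                    leg_length: float | None = None,
                                    config: FeatureConfig | None = None,
                                    ) -> tuple[float, float]:
    """Walking speed (m/s) and stride length (m) from vertical acceleration.

    The vertical channel (g) is converted to m/s^2, band-passed, doubly
    integrated to vertical position of the trunk, and the mean per-step
    peak-to-peak excursion h feeds the inverted-pendulum step length
    2*sqrt(2*l*h - h^2) with leg length l; speed = step length x step
    frequency, stride length = 2 x step length.
    """
    config = config or FeatureConfig()
    if leg_length is None:
        logger.warning("no leg length supplied; using default %.2f m",
                       config.leg_length_default)
        leg_length = config.leg_length_default
    if leg_length <= 0:
        raise ValueError("leg_length must be > 0")
    fs = epoch.fs
    acc = (epoch.axis("vt") - epoch.axis("vt").mean()) * G_TO_MS2
    hi = min(3.0 * f_step, 0.45 * fs)
    # band-limited double integration in the frequency domain: divide the
    # spectrum by -(2*pi*f)^2 inside [0.1 Hz, 3*f_step] and zero it outside;
    # avoids the low-frequency drift that time-domain integration accumulates
    n = len(acc)
    spec = np.fft.rfft(acc)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    keep = (f >= 0.1) & (f <= hi)
    spec[~keep] = 0.0
    spec[keep] /= -(2.0 * np.pi * f[keep]) ** 2
    pos = np.fft.irfft(spec, n)

    w = int(round(fs / f_step))
    n_steps = len(pos) // w
    if n_steps < 1:
        raise EpochInvalid("epoch shorter than one step")
    seg = pos[:n_steps * w].reshape(n_steps, w)
    h = float(np.mean(seg.max(axis=1) - seg.min(axis=1)))
    if h >= leg_length:
        raise ValueError(
            f"vertical excursion h={h:.3f} m exceeds leg length "
            f"{leg_length:.3f} m — non-physical; check units/alignment")
    step_length = 2.0 * np.sqrt(2.0 * leg_length * h - h ** 2)
    return step_length * f_step, 2.0 * step_length


# ---------------------------------------------------------------------------
# intensity, regularity, spectral shape
# ---------------------------------------------------------------------------

def dispersion_features(epoch: AccelEpisode,
                        config: FeatureConfig | None = None) -> dict[str, float]:
    """Per-axis standard deviation and range (max - min)."""
    config = config or FeatureConfig()
    f = config.unit_factor()
    out = {}
    for ax in AXES:
        x = epoch.axis(ax) * f
        out[f"sd_{ax}"] = float(np.std(x, ddof=1))
        out[f"range_{ax}"] = float(x.max() - x.min())
    return out


def stride_regularity(x: np.ndarray, fs: float, stride_time: float) -> float:
    """Unbiased autocorrelation at one stride lag (local max within +/-10%)."""
    lag0 = int(round(stride_time * fs))
    n = len(x)
    if lag0 >= n // 2:
        raise EpochInvalid("stride lag exceeds half the epoch length")
    lo = max(1, int(np.floor(0.9 * lag0)))
    hi = min(n - 2, int(np.ceil(1.1 * lag0)))
    rho = autocorr_unbiased(x, hi + 1)
    return float(np.clip(rho[lo:hi + 1].max(), -1.0, 1.0))


def _welch(x: np.ndarray, fs: float,
           config: FeatureConfig) -> tuple[np.ndarray, np.ndarray]:
    nper = min(len(x), int(round(config.welch_segment_s * fs)))
    return signal.welch(x - x.mean(), fs=fs, window="hann", nperseg=nper,
                        noverlap=int(nper * config.welch_overlap))


def spectral_peak_features(epoch: AccelEpisode,
                           config: FeatureConfig | None = None,
                           ) -> dict[str, float]:
    """Dominant-peak power fraction and half-height width per axis.

    The Welch spectrum is normalized to unit total power; the dominant
    amplitude is the power fraction in the contiguous run of bins around
    the peak that stay above half the peak height, and the width is the
    frequency span (in Hz) of that run.
    """
    config = config or FeatureConfig()
    out = {}
    for ax in AXES:
        freqs, pxx = _welch(epoch.axis(ax), epoch.fs, config)
        total = pxx.sum()
        if total <= 0:
            out[f"dominant_amp_{ax}"] = np.nan
            out[f"dominant_width_{ax}"] = np.nan
            continue
        p = pxx / total
        i0 = int(np.argmax(p))
        if p[i0] < 2.0 * p.mean():
            warnings.warn(f"near-flat spectrum on {ax}; width covers the full band")
        half = p[i0] / 2.0
        # the peak's immediately adjacent bins always belong to the peak
        # (window leakage spreads a pure tone over them); beyond that the
        # region extends while bins stay above half height
        lo = max(0, i0 - 1)
        while lo > 0 and p[lo - 1] >= half:
            lo -= 1
        hi = min(len(p) - 1, i0 + 1)
        while hi < len(p) - 1 and p[hi + 1] >= half:
            hi += 1
        df = freqs[1] - freqs[0]
        out[f"dominant_amp_{ax}"] = float(p[lo:hi + 1].sum())
        out[f"dominant_width_{ax}"] = float((hi - lo + 1) * df)
    return out


def index_of_harmonicity(epoch: AccelEpisode, freq: FreqInfo,
                         config: FeatureConfig | None = None) -> dict[str, float]:
    """Power fraction of the fundamental among the first six harmonics.

    The fundamental is the step frequency for VT/AP and the stride
    frequency for ML; power is integrated over +/-0.1 Hz around each
    harmonic on a Hann-windowed periodogram.
    """
    config = config or FeatureConfig()
    out = {}
    for ax in AXES:
        f0 = freq.f_stride if ax == "ml" else freq.f_step
        x = epoch.axis(ax)
        freqs, pxx = signal.periodogram(x - x.mean(), fs=epoch.fs, window="hann")
        powers = []
        for k in range(1, config.ih_n_harmonics + 1):
            sel = np.abs(freqs - k * f0) <= config.ih_halfwidth_hz + 1e-12
            powers.append(pxx[sel].sum())
        total = sum(powers)
        if total <= 0:
            out[f"ih_{ax}"] = np.nan
        else:
            out[f"ih_{ax}"] = float(powers[0] / total)
    return out


def harmonic_ratio(epoch: AccelEpisode, f_stride: float,
                   config: FeatureConfig | None = None) -> dict[str, float]:
    """Even/odd spectral-amplitude ratio over the first 20 stride harmonics.

    For VT and AP, even harmonics of the stride frequency (i.e. power at
    multiples of the step frequency) dominate in symmetric gait, so
    HR = sum(even amplitudes)/sum(odd amplitudes); ML uses odd/even. A
    vanishing denominator is capped at the configured maximum.
    """
    config = config or FeatureConfig()
    t = np.arange(epoch.n_samples) / epoch.fs
    out = {}
    for ax in AXES:
        x = epoch.axis(ax) - epoch.axis(ax).mean()
        amps = []
        for k in range(1, config.hr_n_harmonics + 1):
            f = k * f_stride
            if f >= epoch.fs / 2:
                break
            amps.append(2.0 / len(x) * np.abs(
                np.sum(x * np.exp(-2j * np.pi * f * t))))
        amps = np.array(amps)
        even = amps[1::2].sum()
        odd = amps[0::2].sum()
        num, den = (odd, even) if ax == "ml" else (even, odd)
        if den < 1e-12 * max(num, 1.0) or num / max(den, 1e-300) > config.hr_cap:
            warnings.warn(f"harmonic-ratio denominator vanished on {ax}; "
                          f"capped at {config.hr_cap}")
            out[f"hr_{ax}"] = config.hr_cap
        else:
            out[f"hr_{ax}"] = float(num / den)
    return out


# ---------------------------------------------------------------------------
# stability and complexity
# ---------------------------------------------------------------------------

def _embed(x: np.ndarray, dim: int, delay: int) -> np.ndarray:
    n = len(x) - (dim - 1) * delay
    if n < 1:
        return np.empty((0, dim))
    return np.lib.stride_tricks.sliding_window_view(
        x, (dim - 1) * delay + 1)[:, ::delay].copy()


def local_divergence_rate(x: np.ndarray, fs: float, stride_time: float,
                          config: FeatureConfig | None = None) -> float:
    """Short-term local divergence exponent per stride (Rosenstein method).

    The axis signal is delay-embedded; each point's nearest neighbour
    (excluding temporal neighbours within one stride) seeds a divergence
    curve; the mean log-divergence is fit by least squares over the first
    half stride and the slope is expressed per stride.
    """
    config = config or FeatureConfig()
    y = _embed(np.asarray(x, float), config.lde_dim, config.lde_delay)
    horizon = int(round(config.lde_fit_frac * stride_time * fs))
    m = len(y) - horizon
    if m < config.lde_min_points:
        raise EpochInvalid("too few embedded points for divergence estimate")
    theiler = int(round(stride_time * fs))
    pts = y[:m]
    # pairwise distances with a temporal exclusion window
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    idx = np.arange(m)
    mask = np.abs(idx[:, None] - idx[None, :]) < theiler
    d2[mask] = np.inf
    nn = np.argmin(d2, axis=1)
    if not np.isfinite(d2[idx, nn]).any():
        raise EpochInvalid("no admissible nearest neighbours")

    # distance floor at 1e-10 of the signal scale: below it separations are
    # numerical rounding, and their log would produce spurious slopes on
    # noiseless periodic signals
    floor = max(1e-10 * float(np.std(x)), 1e-300)
    steps = np.arange(horizon + 1)
    curve = np.empty(horizon + 1)
    for t in steps:
        d = np.linalg.norm(y[idx + t] - y[nn + t], axis=1)
        curve[t] = np.mean(np.log(np.maximum(d, floor)))
    slope = float(np.polyfit(steps / fs, curve, 1)[0])
    return slope * stride_time


def sample_entropy(x: np.ndarray, m: int = 2, r: float | None = None,
                   r_frac: float = 0.2) -> float:
    """SampEn(m, r): -ln of the conditional template-match probability.

    Templates of length m and m+1 are compared with the Chebyshev distance;
    self-matches are excluded and r defaults to ``r_frac`` times the signal
    SD. Returns NaN (invalid) when either match count is zero.
    """
    x = np.asarray(x, float)
    n = len(x)
    if n < m + 2:
        raise EpochInvalid("signal too short for sample entropy")
    if r is None:
        r = r_frac * float(np.std(x))
    # both template lengths use the same N - m starting positions so that a
    # constant signal gives A = B exactly (SampEn = 0)
    n_tpl = n - m
    tm = np.lib.stride_tricks.sliding_window_view(x, m)[:n_tpl]
    tm1 = np.lib.stride_tricks.sliding_window_view(x, m + 1)
    # Chebyshev distances between all template pairs
    db = np.abs(tm[:, None, :] - tm[None, :, :]).max(-1)
    da = np.abs(tm1[:, None, :] - tm1[None, :, :]).max(-1)
    iu = np.triu_indices(n_tpl, k=1)
    b = int(np.sum(db[iu] <= r))
    a = int(np.sum(da[iu] <= r))
    if b == 0 or a == 0:
        return np.nan
    return float(-np.log(a / b))


# ---------------------------------------------------------------------------
# composite and batch extraction
# ---------------------------------------------------------------------------

def composite_score(values: dict[str, float] | pd.Series,
                    weights: CompositeWeights) -> float:
    """Weighted sum of standardized composite inputs; NaN if any is missing."""
    total = 0.0
    for name, column in weights.inputs.items():
        v = values.get(column, np.nan) if isinstance(values, dict) else values.get(column)
        if v is None or not np.isfinite(v):
            return np.nan
        z = (v - weights.means.get(name, 0.0)) / weights.sds.get(name, 1.0)
        total += weights.weights.get(name, 0.0) * z
    return float(total)


_FEATURE_GROUPS = ("pace", "dispersion", "regularity", "spectral",
                   "harmonicity", "harmonic_ratio", "stability", "complexity",
                   "composite")


def extract_epoch_features(epoch: AccelEpisode, config: FeatureConfig,
                           leg_length: float | None = None) -> dict[str, float]:
    """Full characteristic set for one realigned epoch (raises EpochInvalid)."""
    groups = config.features or _FEATURE_GROUPS
    freq = detect_frequencies(epoch, config)
    row: dict[str, float] = {"stride_frequency": freq.f_stride}
    if "pace" in groups:
        speed, stride_len = walking_speed_and_stride_length(
            epoch, freq.f_step, leg_length, config)
        row["walking_speed"] = speed
        row["stride_length"] = stride_len
    if "dispersion" in groups:
        disp = dispersion_features(epoch, config)
        row.update(disp)
        row["rms"] = float(np.sqrt(disp["sd_vt"] ** 2 + disp["sd_ml"] ** 2
                                   + disp["sd_ap"] ** 2))
    if "regularity" in groups:
        for ax in AXES:
            row[f"stride_autocorr_{ax}"] = stride_regularity(
                epoch.axis(ax), epoch.fs, freq.stride_time)
    if "spectral" in groups:
        row.update(spectral_peak_features(epoch, config))
        # absolute VT power near the step frequency (composite alternative)
        f, pxx = _welch(epoch.axis("vt"), epoch.fs, config)
        sel = np.abs(f - freq.f_step) <= config.ih_halfwidth_hz
        row["step_power"] = float(np.trapezoid(pxx[sel], f[sel])) if sel.sum() > 1 \
            else float(pxx[sel].sum() * (f[1] - f[0]))
    if "harmonicity" in groups:
        row.update(index_of_harmonicity(epoch, freq, config))
    if "harmonic_ratio" in groups:
        row.update(harmonic_ratio(epoch, freq.f_stride, config))
    if "stability" in groups:
        for ax in ("vt", "ap", "ml"):
            row[f"lde_{ax}"] = local_divergence_rate(
                epoch.axis(ax), epoch.fs, freq.stride_time, config)
    if "complexity" in groups:
        for ax in AXES:
            row[f"sampen_{ax}"] = sample_entropy(
                epoch.axis(ax), config.sampen_m, r_frac=config.sampen_r_frac)
    if "composite" in groups:
        row["composite"] = composite_score(row, config.composite)
    return row


def extract_all(episode: AccelEpisode, config: FeatureConfig | None = None,
                leg_length: float | None = None,
                ) -> tuple[pd.DataFrame, list[str]]:
    """Realign an episode, split it into epochs and extract every epoch.

    Returns a feature table with one row per epoch (``valid`` flags epochs
    where extraction failed; their reason is kept in ``invalid_reason``)
    and a list of episode-level messages. Errors never abort the batch.
    """
    config = config or FeatureConfig()
    report: list[str] = []
    base = {"subject": episode.subject_id, "week": episode.week,
            "day": episode.day}
    if episode.duration_s < config.min_episode_s:
        report.append(f"episode shorter than {config.min_episode_s} s; skipped")
        return pd.DataFrame(), report
    try:
        aligned = episode if episode.aligned else realign_axes(episode, config)
    except ValueError as exc:
        report.append(f"realignment failed: {exc}")
        return pd.DataFrame(), report
    if leg_length is None:
        logger.info("no leg length supplied; using default %.2f m",
                    config.leg_length_default)
        leg_length = config.leg_length_default
    rows = []
    for i, epoch in enumerate(split_epochs(aligned, config.epoch_s)):
        row = dict(base, epoch=i, valid=True, invalid_reason="")
        try:
            row.update(extract_epoch_features(epoch, config, leg_length))
        except (EpochInvalid, ValueError) as exc:
            row["valid"] = False
            row["invalid_reason"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows), report
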