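"""Independent brute-force reference implementations used as test oracles.

Deliberately written with explicit Python loops and the most direct
formulas available, independent of the vectorized code paths they check.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats


def autocorr_brute(x, lag: int) -> float:
    """Unbiased autocorrelation coefficient at one lag, direct O(N) sum."""
    x = np.asarray(x, float)
    n = len(x)
    mean = sum(x) / n
    var = sum((v - mean) ** 2 for v in x) / n
    acov = sum((x[t] - mean) * (x[t + lag] - mean) for t in range(n - lag))
    return (acov / (n - lag)) / var


def sampen_brute(x, m: int = 2, r: float | None = None,
                 r_frac: float = 0.2) -> float:
    """Sample entropy by direct template counting, O(N^2) loops."""
    x = list(map(float, x))
    n = len(x)
    if r is None:
        mean = sum(x) / n
        sd = math.sqrt(sum((v - mean) ** 2 for v in x) / n)
        r = r_frac * sd
    n_tpl = n - m
    b = a = 0
    for i in range(n_tpl):
        for j in range(i + 1, n_tpl):
            if max(abs(x[i + k] - x[j + k]) for k in range(m)) <= r:
                b += 1
                if max(abs(x[i + k] - x[j + k]) for k in range(m + 1)) <= r:
                    a += 1
    if a == 0 or b == 0:
        return float("nan")
    return -math.log(a / b)


def lde_brute(x, fs: float, stride_time: float, dim: int = 5,
              delay: int = 10, fit_frac: float = 0.5) -> float:
    """Rosenstein local divergence rate with exhaustive neighbour search."""
    x = np.asarray(x, float)
    n_pts = len(x) - (dim - 1) * delay
    y = np.array([[x[i + k * delay] for k in range(dim)] for i in range(n_pts)])
    horizon = int(round(fit_frac * stride_time * fs))
    m = n_pts - horizon
    theiler = int(round(stride_time * fs))
    floor = max(1e-10 * float(np.std(x)), 1e-300)
    nn = []
    for i in range(m):
        # exhaustive scan; keeps the first strict minimum
        best_j, best_d = -1, math.inf
        for j in range(m):
            if abs(i - j) < theiler:
                continue
            d = sum((y[i][k] - y[j][k]) ** 2 for k in range(dim))
            if d < best_d:
                best_d, best_j = d, j
        nn.append(best_j)
    curve = []
    for t in range(horizon + 1):
        logs = []
        for i in range(m):
            d = math.sqrt(sum((y[i + t][k] - y[nn[i] + t][k]) ** 2
                              for k in range(dim)))
            logs.append(math.log(max(d, floor)))
        curve.append(np.mean(logs))
    slope = np.polyfit(np.arange(horizon + 1) / fs, curve, 1)[0]
    return float(slope * stride_time)


def periodogram_peak_fraction(x, fs: float, half_width_hz: float = 0.3) -> float:
    """Fraction of total power near the dominant peak of a plain
    rectangular-window periodogram."""
    x = np.asarray(x, float) - np.mean(x)
    n = len(x)
    spec = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    f_peak = freqs[int(np.argmax(spec))]
    sel = np.abs(freqs - f_peak) <= half_width_hz
    return float(spec[sel].sum() / spec.sum())


def required_n_scan(s2_total: float, s2_bs: float, d: float, r: float,
                    alpha: float = 0.05, power: float = 0.8,
                    n_max: int = 10_000) -> int:
    """Smallest n >= 2 with n >= f(n), by direct upward scan."""
    rho = s2_bs / s2_total
    for n in range(2, n_max + 1):
        tq = stats.t.ppf(power, n - 1) + stats.t.ppf(1 - alpha / 2, n - 1)
        if n >= 2.0 * (1.0 - r * rho) * tq ** 2 / d ** 2:
            return n
    raise RuntimeError("scan exhausted")
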