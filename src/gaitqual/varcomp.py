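"""Variance components and between-week agreement of weekly gait characteristics.

For two measurement weeks per subject, a two-way repeated-measures ANOVA
decomposes the total sum of squares into subject, week and error terms.
The between-subject variance component follows from the method of moments,
s2_bs = (MS_subject - MS_error) / J with J = 2 weeks. MS_error mixes true
week-to-week (within-subject) variability with the sampling error of the
weekly median; the two can only be separated when day-level values are
available, from which the sampling variance of the weekly median is
estimated directly. Without day-level data the split is not identifiable
and the full MS_error is reported as error variance with
``separable_error=False`` — the sample-size formula downstream only needs
the total and between-subject components, so this does not affect power
planning.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .aggregate import paired_weeks

logger = logging.getLogger(__name__)

#: Monte-Carlo draws used to calibrate the variance factor of a median
_CALIBRATION_DRAWS = 100_000
_CALIBRATION_SEED = 20_190_413


@dataclass
class VarComp:
    """Mean and variance decomposition of one gait characteristic."""

    characteristic: str
    mean: float
    s2_bs: float           # between-subject
    s2_ws: float           # within-subject (between weeks)
    s2_e: float            # sampling error of the weekly value
    s2_total: float
    p_week: float
    pearson_r: float
    n_subjects: int
    separable_error: bool
    truncated: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        d = asdict(self)
        d["truncated"] = list(self.truncated)
        return d


def between_week_agreement(week1: np.ndarray, week2: np.ndarray,
                           ) -> tuple[float, float, float]:
    """Week-effect F (repeated-measures ANOVA), its p-value, and Pearson r.

    The week effect is tested on (1, n-1) degrees of freedom; with two
    levels F equals the squared paired-t statistic. Pearson r is NaN when
    either week has zero variance.
    """
    w1 = np.asarray(week1, float)
    w2 = np.asarray(week2, float)
    if len(w1) != len(w2):
        raise ValueError("weeks must be paired")
    n = len(w1)
    if n < 3:
        raise ValueError("need at least 3 paired subjects")
    ss = _two_way_ss(w1, w2)
    ms_error = ss["error"] / (n - 1)
    if ms_error == 0:
        f = 0.0 if ss["week"] == 0 else np.inf
    else:
        f = ss["week"] / ms_error
    p = float(stats.f.sf(f, 1, n - 1)) if np.isfinite(f) else 0.0
    # exact-range check: np.std of a constant array can round to ~1e-16
    if np.ptp(w1) == 0 or np.ptp(w2) == 0:
        logger.warning("zero variance in one week; Pearson r undefined")
        r = np.nan
    else:
        r = float(stats.pearsonr(w1, w2)[0])
    return float(f), p, r


def _two_way_ss(w1: np.ndarray, w2: np.ndarray) -> dict[str, float]:
    """Sums of squares of the subject x week two-way layout (J = 2)."""
    x = np.column_stack([w1, w2])
    grand = x.mean()
    subj_means = x.mean(axis=1)
    week_means = x.mean(axis=0)
    ss_subject = 2.0 * np.sum((subj_means - grand) ** 2)
    ss_week = len(w1) * np.sum((week_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    return {"subject": float(ss_subject), "week": float(ss_week),
            "error": float(ss_total - ss_subject - ss_week),
            "total": float(ss_total)}


def median_variance_factor(k: int, n_draws: int = _CALIBRATION_DRAWS,
                           seed: int = _CALIBRATION_SEED) -> float:
    """Variance of the median of k standard normal draws (Monte Carlo).

    The asymptotic pi/(2k) approximation is poor at small k, so the factor
    is computed by simulation with a fixed internal seed, making it a
    deterministic constant of k.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k == 1:
        return 1.0
    rng = np.random.default_rng(seed)
    med = np.median(rng.standard_normal((n_draws, k)), axis=1)
    return float(med.var())


def median_sampling_variance(day_values: pd.DataFrame,
                             method: str = "calibrated",
                             n_boot: int = 200, seed: int = 0) -> float:
    """Mean (over subject-weeks) sampling variance of the weekly median.

    ``day_values`` has columns subject, week, value (one row per day).
    ``calibrated``: variance factor of a Gaussian median (Monte Carlo,
    see :func:`median_variance_factor`) times the within-week day-to-day
    variance, pooled over subject-weeks — unbiased under a Gaussian day
    model. ``bootstrap``: per-cell nonparametric bootstrap of the median
    (upward-biased at small day counts; kept for sensitivity analyses).
    """
    groups = [g["value"].to_numpy() for _, g in
              day_values.groupby(["subject", "week"], sort=True)]
    ks = {len(g) for g in groups}
    estimates = []
    if method == "calibrated":
        factors = {k: median_variance_factor(k) for k in ks}
        for g in groups:
            k = len(g)
            if k < 2:
                estimates.append(np.nan)
                continue
            estimates.append(factors[k] * g.var(ddof=1))
    elif method == "bootstrap":
        rng = np.random.default_rng(seed)
        for g in groups:
            k = len(g)
            if k < 2:
                estimates.append(np.nan)
                continue
            idx = rng.integers(0, k, size=(n_boot, k))
            estimates.append(np.median(g[idx], axis=1).var(ddof=1))
    else:
        raise ValueError(f"unknown method {method!r}")
    est = np.asarray(estimates, float)
    if np.isnan(est).all():
        raise ValueError("day-level data has fewer than 2 days everywhere")
    return float(np.nanmean(est))


def variance_components(table: pd.DataFrame, characteristic: str,
                        day_level: pd.DataFrame | None = None,
                        median_variance_method: str = "calibrated",
                        n_boot: int = 200, seed: int = 0) -> VarComp:
    """Mean, variance components and between-week agreement of one characteristic.

    ``table`` is a weekly feature table with subject/week columns; subjects
    missing either week are excluded (complete-case). ``day_level``, when
    given, carries day-resolved values (columns subject, week, value) used
    to estimate the sampling variance of the weekly median and thereby
    separate within-subject from error variance.
    """
    w1, w2, subjects = paired_weeks(table, characteristic)
    n_all = table["subject"].nunique()
    if len(subjects) < n_all:
        logger.info("%s: %d of %d subjects excluded (incomplete weeks)",
                    characteristic, n_all - len(subjects), n_all)
    n = len(subjects)
    if n < 3:
        raise ValueError(
            f"{characteristic}: need >= 3 complete-case subjects, got {n}")
    f, p, r = between_week_agreement(w1, w2)
    ss = _two_way_ss(w1, w2)
    ms_subject = ss["subject"] / (n - 1)
    ms_error = ss["error"] / (n - 1)
    truncated = []
    s2_bs = (ms_subject - ms_error) / 2.0
    if s2_bs < 0:
        truncated.append("s2_bs")
        logger.warning("%s: negative between-subject estimate truncated to 0",
                       characteristic)
        s2_bs = 0.0
    if day_level is not None:
        sub = day_level[day_level["subject"].isin(subjects)]
        s2_e = median_sampling_variance(sub, median_variance_method,
                                        n_boot=n_boot, seed=seed)
        s2_ws = ms_error - s2_e
        if s2_ws < 0:
            truncated.append("s2_ws")
            logger.warning("%s: negative within-subject estimate truncated to 0",
                           characteristic)
            s2_ws = 0.0
        separable = True
    else:
        s2_ws, s2_e, separable = 0.0, ms_error, False
    return VarComp(characteristic=characteristic,
                   mean=float(np.mean(np.concatenate([w1, w2]))),
                   s2_bs=float(s2_bs), s2_ws=float(s2_ws), s2_e=float(s2_e),
                   s2_total=float(s2_bs + s2_ws + s2_e),
                   p_week=p, pearson_r=r, n_subjects=n,
                   separable_error=separable, truncated=tuple(truncated))


def variance_components_table(table: pd.DataFrame,
                              characteristics: list[str] | None = None,
                              day_level: dict[str, pd.DataFrame] | None = None,
                              **kwargs) -> list[VarComp]:
    """Variance components for every requested characteristic column."""
    if characteristics is None:
        characteristics = [c for c in table.columns
                           if c not in ("subject", "week")
                           and not c.startswith("n_epochs_")]
    out = []
    for c in characteristics:
        day = day_level.get(c) if day_level else None
        try:
            out.append(variance_components(table, c, day_level=day, **kwargs))
        except ValueError as exc:
            logger.warning("skipping %s: %s", c, exc)
    return out


def write_report(varcomps: list[VarComp], path: str | Path) -> None:
    Path(path).write_text(json.dumps(
        {vc.characteristic: vc.to_dict() for vc in varcomps}, indent=2))


def read_report(path: str | Path) -> list[VarComp]:
    data = json.loads(Path(path).read_text())
    return [VarComp(**{**d, "truncated": tuple(d.get("truncated", ()))})
            for d in data.values()]
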