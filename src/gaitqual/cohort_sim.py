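"""Feature-level synthetic cohorts under the additive variance-component model.

A subject i's weekly value of a gait characteristic in week j is

    x_ij = mu + b_i + u_ij + e_ij,
    b_i ~ N(0, sigma2_bs),  u_ij ~ N(0, sigma2_ws),  e_ij ~ N(0, sigma2_e),

i.e. a stable subject level, genuine week-to-week change, and sampling
error of the weekly summary. With day-level simulation enabled
(days_per_week > 1) the weekly value is the median of day values whose
noise variance is calibrated so that the median's sampling variance equals
sigma2_e; this reproduces how weekly medians acquire error variance from a
finite number of observed days.

``PUBLISHED_PRESETS`` parameterizes the generator with published means and
variance components of daily-life gait characteristics measured over two
weeks in 163 community-dwelling older adults (trunk accelerometry).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .varcomp import median_variance_factor

#: published weekly-median parameters: week-effect p, between-week r,
#: mean, and between-subject / within-subject / error variance components
PUBLISHED_PRESETS: dict[str, dict[str, float]] = {
    "composite":        dict(p=0.64, r=0.81, mean=0.51369, s2_bs=0.54700, s2_ws=0.08068, s2_e=0.05759),
    "walking_speed":    dict(p=0.39, r=0.93, mean=0.45073, s2_bs=0.01030, s2_ws=0.00027, s2_e=0.00036),
    "stride_frequency": dict(p=0.51, r=0.95, mean=0.82482, s2_bs=0.01119, s2_ws=0.00013, s2_e=0.00030),
    "sd_vt":            dict(p=0.77, r=0.92, mean=1.32658, s2_bs=0.17858, s2_ws=0.00061, s2_e=0.00733),
    "sd_ml":            dict(p=0.18, r=0.94, mean=1.16407, s2_bs=0.09332, s2_ws=0.00560, s2_e=0.00305),
    "range_ap":         dict(p=0.40, r=0.91, mean=7.33318, s2_bs=7.13497, s2_ws=0.23150, s2_e=0.32894),
    "stride_autocorr_vt": dict(p=0.54, r=0.82, mean=0.37464, s2_bs=0.01051, s2_ws=0.00040, s2_e=0.00103),
    "stride_autocorr_ap": dict(p=0.63, r=0.83, mean=0.32881, s2_bs=0.00945, s2_ws=0.00021, s2_e=0.00088),
    "dominant_amp_vt":  dict(p=0.68, r=0.93, mean=0.49412, s2_bs=0.04264, s2_ws=0.00026, s2_e=0.00155),
    "dominant_amp_ml":  dict(p=1.00, r=0.91, mean=0.47481, s2_bs=0.05827, s2_ws=9.26e-9, s2_e=0.00263),
    "dominant_amp_ap":  dict(p=0.11, r=0.85, mean=0.51044, s2_bs=0.02357, s2_ws=0.00501, s2_e=0.00198),
    "dominant_width_ap": dict(p=0.14, r=0.80, mean=0.75841, s2_bs=0.00611, s2_ws=0.00167, s2_e=0.00075),
    "ih_vt":            dict(p=0.19, r=0.96, mean=0.62043, s2_bs=0.04940, s2_ws=0.00156, s2_e=0.00092),
    "ih_ml":            dict(p=0.68, r=0.92, mean=0.64420, s2_bs=0.06977, s2_ws=0.00048, s2_e=0.00276),
    "hr_vt":            dict(p=0.47, r=0.90, mean=1.53576, s2_bs=0.07348, s2_ws=0.00211, s2_e=0.00406),
    "lde_vt":           dict(p=0.75, r=0.87, mean=2.11436, s2_bs=0.13693, s2_ws=0.00097, s2_e=0.00919),
    "lde_ap":           dict(p=0.58, r=0.86, mean=2.19507, s2_bs=0.09652, s2_ws=0.00217, s2_e=0.00707),
    "sampen_ml":        dict(p=0.74, r=0.91, mean=0.31207, s2_bs=0.00394, s2_ws=2.07e-5, s2_e=0.00018),
}


@dataclass(frozen=True)
class CohortSpec:
    """Generator parameters for one characteristic's two-week cohort."""

    n_subjects: int
    mu: float
    sigma2_bs: float
    sigma2_ws: float
    sigma2_e: float
    weeks: int = 2
    days_per_week: int = 1
    seed: int = 0
    week2_shift: float = 0.0   # additive intervention effect on week 2
    characteristic: str = "value"

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if min(self.sigma2_bs, self.sigma2_ws, self.sigma2_e) < 0:
            raise ValueError("variance components must be >= 0")
        if self.days_per_week < 1:
            raise ValueError("days_per_week must be >= 1")

    @classmethod
    def from_preset(cls, name: str, n_subjects: int, **kwargs) -> "CohortSpec":
        try:
            p = PUBLISHED_PRESETS[name]
        except KeyError:
            raise KeyError(f"unknown preset {name!r}; available: "
                           f"{sorted(PUBLISHED_PRESETS)}") from None
        return cls(n_subjects=n_subjects, mu=p["mean"], sigma2_bs=p["s2_bs"],
                   sigma2_ws=p["s2_ws"], sigma2_e=p["s2_e"],
                   characteristic=name, **kwargs)


def simulate_cohort(spec: CohortSpec,
                    ) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Simulate weekly values (and optionally day-level values) of a cohort.

    Returns a weekly table with columns (subject, week, <characteristic>)
    and, when ``days_per_week > 1``, a day-level table (subject, week, day,
    value) from which the weekly value is the median over days. Day noise
    is scaled so the weekly median's sampling variance equals ``sigma2_e``.
    Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n, j, k = spec.n_subjects, spec.weeks, spec.days_per_week
    b = rng.normal(0.0, np.sqrt(spec.sigma2_bs), n)
    u = rng.normal(0.0, np.sqrt(spec.sigma2_ws), (n, j))
    level = spec.mu + b[:, None] + u
    level[:, 1:] += spec.week2_shift if j > 1 else 0.0

    if k == 1:
        weekly = level + rng.normal(0.0, np.sqrt(spec.sigma2_e), (n, j))
        day_df = None
    else:
        c_k = median_variance_factor(k)
        sigma_day = np.sqrt(spec.sigma2_e / c_k)
        days = level[:, :, None] + rng.normal(0.0, sigma_day, (n, j, k))
        weekly = np.median(days, axis=2)
        subj, week, day = np.meshgrid(np.arange(1, n + 1),
                                      np.arange(1, j + 1),
                                      np.arange(1, k + 1), indexing="ij")
        day_df = pd.DataFrame({"subject": subj.ravel(), "week": week.ravel(),
                               "day": day.ravel(), "value": days.ravel()})

    subj, week = np.meshgrid(np.arange(1, n + 1), np.arange(1, j + 1),
                             indexing="ij")
    weekly_df = pd.DataFrame({"subject": subj.ravel(), "week": week.ravel(),
                              spec.characteristic: weekly.ravel()})
    return weekly_df, day_df


def implied_between_week_correlation(spec: CohortSpec) -> float:
    """Model-implied Pearson correlation between the two weekly values.

    Both weeks share the subject effect, so corr = sigma2_bs / sigma2_total.
    """
    total = spec.sigma2_bs + spec.sigma2_ws + spec.sigma2_e
    if total <= 0:
        raise ValueError("total variance must be > 0")
    return spec.sigma2_bs / total
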