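"""End-to-end batch pipeline: episodes -> features -> weekly medians ->
variance components -> sample-size grid.

Every stage writes delimiter-separated text (or JSON for the variance
report) into the configured output directory and logs row counts and
exclusion reasons; per-record problems are logged and skipped, and only an
empty stage output aborts the downstream stages.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import aggregate, features, powercalc, signal_sim, varcomp
from .config import RunConfig

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.6g"


def simulate_episode_batch(n_subjects: int = 20, weeks: int = 2,
                           days_per_week: int = 1, duration_s: float = 60.0,
                           fs: float = 100.0, seed: int = 0,
                           noise_sd: float = 0.02,
                           jitter_mean: float = 0.15,
                           ) -> list[signal_sim.AccelEpisode]:
    """A small cohort of synthetic episodes with subject-specific gait.

    Subjects differ in stride frequency, harmonic amplitudes and phase
    jitter (stable per subject across weeks), so the downstream weekly
    characteristics carry genuine between-subject variance.
    """
    rng = np.random.default_rng(seed)
    episodes = []
    for s in range(1, n_subjects + 1):
        f_stride = float(np.clip(rng.normal(0.9, 0.06), 0.7, 1.1))
        amp = float(np.clip(rng.normal(1.0, 0.15), 0.6, 1.4))
        jitter = float(np.abs(rng.normal(jitter_mean, 0.05)))
        for w in range(1, weeks + 1):
            for d in range(1, days_per_week + 1):
                params = signal_sim.GaitSignalParams(
                    duration_s=duration_s, fs=fs, f_stride=f_stride,
                    vt_harmonics=tuple(a * amp for a in (0.22, 0.10, 0.04)),
                    ap_harmonics=tuple(a * amp for a in (0.18, 0.08, 0.03)),
                    ml_harmonics=tuple(a * amp for a in (0.12, 0.0, 0.03)),
                    phase_jitter_sd=jitter, noise_sd=noise_sd,
                    seed=int(rng.integers(0, 2 ** 31)))
                episodes.append(signal_sim.simulate_gait_episode(
                    params, subject_id=s, week=w, day=d))
    return episodes


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run all stages; returns the paths of the written artifacts."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    fcfg = config.feature_config()

    if config.episodes:
        episodes = signal_sim.read_episodes(config.episodes,
                                            column_map=config.column_map)
        logger.info("read %d episodes from %s", len(episodes), config.episodes)
    else:
        sim_args = dict(config.simulate)
        sim_args.setdefault("seed", config.seed)
        episodes = simulate_episode_batch(**sim_args)
        path = out / "episodes.csv"
        signal_sim.write_episodes(episodes, path)
        artifacts["episodes"] = path
        logger.info("simulated %d episodes -> %s", len(episodes), path)
    if not episodes:
        raise RuntimeError("no episodes to process")

    frames, n_skipped = [], 0
    for ep in episodes:
        df, report = features.extract_all(ep, fcfg, config.leg_length)
        for msg in report:
            logger.warning("episode (%s, w%s, d%s): %s",
                           ep.subject_id, ep.week, ep.day, msg)
        if df.empty:
            n_skipped += 1
        else:
            frames.append(df)
    if not frames:
        raise RuntimeError("feature extraction produced no epochs")
    epoch_rows = pd.concat(frames, ignore_index=True)
    n_invalid = int((~epoch_rows["valid"]).sum())
    logger.info("extracted %d epochs (%d invalid) from %d episodes "
                "(%d episodes skipped)", len(epoch_rows), n_invalid,
                len(episodes), n_skipped)
    path = out / "features.csv"
    epoch_rows.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    artifacts["features"] = path

    weekly = aggregate.weekly_median_table(epoch_rows, config.min_epochs)
    if weekly.empty:
        raise RuntimeError("weekly aggregation produced no rows")
    path = out / "weekly.csv"
    weekly.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    artifacts["weekly"] = path
    logger.info("weekly table: %d (subject, week) rows", len(weekly))

    vcs = varcomp.variance_components_table(weekly)
    if not vcs:
        raise RuntimeError("no characteristic had enough complete cases")
    path = out / "varcomp.json"
    varcomp.write_report(vcs, path)
    artifacts["varcomp"] = path
    logger.info("variance components for %d characteristics", len(vcs))

    usable = [vc for vc in vcs if vc.s2_total > 0]
    grid = powercalc.sample_size_grid(
        usable,
        d_list=tuple(config.power.get("d_list", powercalc.DEFAULT_D)),
        r_list=tuple(config.power.get("r_list", powercalc.DEFAULT_R)),
        alpha=config.power.get("alpha", 0.05),
        power=config.power.get("power", 0.8))
    path = out / "power_grid.csv"
    grid.to_csv(path, float_format=FLOAT_FORMAT)
    artifacts["power_grid"] = path
    logger.info("sample-size grid: %d characteristics x %d cells",
                grid.shape[0], grid.shape[1])
    return artifacts
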