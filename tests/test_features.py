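import numpy as np
import pytest

import gaitqual as gq
from gaitqual import features as F
from gaitqual.signal_sim import GaitSignalParams, simulate_gait_episode

from conftest import axis_epoch
from oracles import (autocorr_brute, periodogram_peak_fraction,
                     sampen_brute)

FS = 100.0
T1000 = np.arange(1000) / FS


class TestSplitEpochs:
    @pytest.mark.parametrize("duration,expected", [(35, 3), (10, 1), (9.99, 0)])
    def test_epoch_counts(self, duration, expected):
        n = int(round(duration * FS))
        ep = gq.AccelEpisode(np.zeros((max(n, 2), 3)), FS, aligned=True)
        assert len(gq.split_epochs(ep, 10.0)) == (expected if n >= 2 else 0)

    def test_epochs_partition_the_signal(self, noiseless_epoch):
        ep = noiseless_epoch
        halves = gq.split_epochs(ep, 5.0)
        joined = np.vstack([h.samples for h in halves])
        np.testing.assert_array_equal(joined, ep.samples)


class TestDetectFrequencies:
    def test_ground_truth_frequencies_recovered(self, noiseless_epoch):
        freq = gq.detect_frequencies(noiseless_epoch)
        assert freq.f_step == pytest.approx(1.8, rel=0.02)
        assert freq.f_stride == pytest.approx(0.9, rel=0.01)
        assert freq.stride_time == pytest.approx(1 / 0.9, rel=0.01)

    def test_white_noise_flagged_invalid(self):
        rng = np.random.default_rng(21)
        ep = axis_epoch(rng.standard_normal(1000))
        with pytest.raises(gq.EpochInvalid):
            gq.detect_frequencies(ep)

    def test_stride_frequency_robust_to_jitter(self):
        p = GaitSignalParams(duration_s=12, f_stride=0.9, phase_jitter_sd=0.3,
                             seed=8)
        ep = gq.split_epochs(simulate_gait_episode(p).copy_with(aligned=True),
                             10.0)[0]
        ep = ep.copy_with(samples=ep.samples - ep.samples.mean(axis=0))
        freq = gq.detect_frequencies(ep)
        assert freq.f_stride == pytest.approx(0.9, rel=0.05)


class TestWalkingSpeed:
    def test_double_integration_matches_closed_form(self):
        # a(t) = A sin(2 pi f t): position amplitude A/(2 pi f)^2
        A, f = 1.0, 2.0
        ep = axis_epoch(A * np.sin(2 * np.pi * f * T1000) / 9.81)
        speed, stride_len = gq.walking_speed_and_stride_length(
            ep, f_step=f, leg_length=0.9)
        h = 2 * A / (2 * np.pi * f) ** 2      # peak-to-peak excursion
        assert h == pytest.approx(0.012666, rel=1e-3)
        step = 2 * np.sqrt(2 * 0.9 * h - h ** 2)
        assert speed == pytest.approx(step * f, rel=0.02)
        assert stride_len == pytest.approx(2 * step, rel=0.02)

    def test_pendulum_formula_arithmetic(self):
        # h = 0.02 m, leg 0.9 m -> step length 2*sqrt(0.036 - 0.0004)
        assert 2 * np.sqrt(2 * 0.9 * 0.02 - 0.02 ** 2) == pytest.approx(
            0.37736, abs=1e-5)

    def test_full_chain_on_synthetic_vt(self):
        A_g, f = 0.25, 1.8
        ep = axis_epoch(A_g * np.sin(2 * np.pi * f * T1000))
        speed, _ = gq.walking_speed_and_stride_length(ep, f_step=f,
                                                      leg_length=0.95)
        h = 2 * A_g * 9.81 / (2 * np.pi * f) ** 2
        expected = 2 * np.sqrt(2 * 0.95 * h - h ** 2) * f
        assert speed == pytest.approx(expected, rel=0.02)

    def test_excursion_beyond_leg_length_rejected(self):
        ep = axis_epoch(5.0 * np.sin(2 * np.pi * 1.0 * T1000))
        with pytest.raises(ValueError, match="non-physical"):
            gq.walking_speed_and_stride_length(ep, f_step=1.0, leg_length=0.2)


class TestDispersion:
    def test_constant_epoch_has_zero_spread(self):
        ep = axis_epoch(np.zeros(1000))
        out = gq.dispersion_features(ep)
        assert out["sd_vt"] == 0 and out["range_ap"] == 0

    def test_sinusoid_moments(self):
        # 2.5 Hz puts the sinusoid's extrema exactly on the sample grid
        A = 0.4
        ep = axis_epoch(A * np.sin(2 * np.pi * 2.5 * T1000))
        out = gq.dispersion_features(ep, F.FeatureConfig(units="g"))
        assert out["sd_ml"] == pytest.approx(A / np.sqrt(2), rel=1e-3)
        assert out["range_ml"] == pytest.approx(2 * A, rel=1e-3)

    def test_white_noise_sd_recovered_in_ms2(self):
        rng = np.random.default_rng(3)
        ep = axis_epoch(rng.normal(0, 0.1, 5000))
        out = gq.dispersion_features(ep)    # default m/s^2 units
        assert out["sd_ap"] == pytest.approx(0.1 * 9.81, rel=0.05)


class TestStrideRegularity:
    def test_perfectly_periodic_is_one(self, noiseless_epoch):
        freq = gq.detect_frequencies(noiseless_epoch)
        rho = gq.stride_regularity(noiseless_epoch.axis("vt"), FS,
                                   freq.stride_time)
        assert rho >= 0.999

    def test_white_noise_is_near_zero(self):
        rng = np.random.default_rng(14)
        rho = gq.stride_regularity(rng.standard_normal(1000), FS, 1.0)
        assert abs(rho) < 0.1

    def test_matches_brute_force_autocovariance(self, jittered_epoch):
        freq = gq.detect_frequencies(jittered_epoch)
        x = jittered_epoch.axis("ap")
        lag0 = int(round(freq.stride_time * FS))
        lags = range(max(1, int(np.floor(0.9 * lag0))),
                     int(np.ceil(1.1 * lag0)) + 1)
        expected = max(autocorr_brute(x, lag) for lag in lags)
        got = gq.stride_regularity(x, FS, freq.stride_time)
        assert got == pytest.approx(expected, abs=1e-9)

    def test_long_stride_lag_rejected(self):
        with pytest.raises(gq.EpochInvalid):
            gq.stride_regularity(np.zeros(100), FS, 1.0)


class TestSpectralPeak:
    def test_pure_cosine_concentrates_power(self):
        ep = axis_epoch(np.cos(2 * np.pi * 2 * T1000))
        out = gq.spectral_peak_features(ep)
        assert out["dominant_amp_vt"] >= 0.95

    def test_two_equal_cosines_split_power(self):
        ep = axis_epoch(np.cos(2 * np.pi * 1.5 * T1000)
                        + np.cos(2 * np.pi * 3.1 * T1000))
        out = gq.spectral_peak_features(ep)
        assert out["dominant_amp_vt"] == pytest.approx(0.5, abs=0.05)

    def test_noisy_cosine_fraction_matches_periodogram_oracle(self):
        rng = np.random.default_rng(6)
        x = np.cos(2 * np.pi * 2 * T1000) + rng.normal(0, 0.2, 1000)
        out = gq.spectral_peak_features(axis_epoch(x))
        expected = periodogram_peak_fraction(x, FS)
        assert out["dominant_amp_vt"] == pytest.approx(expected, rel=0.05)

    def test_flat_spectrum_warns_and_covers_band(self):
        impulse = np.zeros(1000)
        impulse[500] = 1.0            # exactly flat magnitude spectrum
        with pytest.warns(UserWarning, match="flat"):
            out = gq.spectral_peak_features(axis_epoch(impulse))
        assert out["dominant_width_vt"] > 40.0   # covers most of the band


class TestIndexOfHarmonicity:
    FREQ = F.FreqInfo(f_step=2.0, f_stride=1.0, stride_time=1.0,
                      stride_peak=1.0)

    def test_single_harmonic_is_one(self):
        ep = axis_epoch(np.cos(2 * np.pi * 2 * T1000))
        assert gq.index_of_harmonicity(ep, self.FREQ)["ih_vt"] == pytest.approx(1.0, abs=1e-6)

    def test_two_equal_harmonics_give_half(self):
        ep = axis_epoch(np.cos(2 * np.pi * 2 * T1000)
                        + np.cos(2 * np.pi * 4 * T1000))
        assert gq.index_of_harmonicity(ep, self.FREQ)["ih_vt"] == pytest.approx(0.5, abs=1e-6)

    def test_multi_harmonic_matches_parseval(self):
        amps = (0.3, 0.2, 0.1)
        x = sum(a * np.cos(2 * np.pi * 2 * (k + 1) * T1000 + k)
                for k, a in enumerate(amps))
        expected = amps[0] ** 2 / sum(a ** 2 for a in amps)
        got = gq.index_of_harmonicity(axis_epoch(x), self.FREQ)["ih_vt"]
        assert got == pytest.approx(expected, rel=1e-3)

    def test_ml_uses_stride_fundamental(self):
        # power only at the stride frequency: perfect ML harmonicity
        ep = axis_epoch(np.cos(2 * np.pi * 1.0 * T1000))
        out = gq.index_of_harmonicity(ep, self.FREQ)
        assert out["ih_ml"] == pytest.approx(1.0, abs=1e-6)


class TestHarmonicRatio:
    def test_even_over_odd_arithmetic(self):
        # odd amplitudes 0.5 + 0.5 = 1, even 1.0 + 1.0 = 2 -> HR = 2
        f0 = 1.0
        x = (0.5 * np.cos(2 * np.pi * f0 * T1000)
             + 1.0 * np.cos(2 * np.pi * 2 * f0 * T1000)
             + 0.5 * np.cos(2 * np.pi * 3 * f0 * T1000)
             + 1.0 * np.cos(2 * np.pi * 4 * f0 * T1000))
        out = gq.harmonic_ratio(axis_epoch(x), f0)
        assert out["hr_vt"] == pytest.approx(2.0, rel=1e-3)
        assert out["hr_ml"] == pytest.approx(0.5, rel=1e-3)

    def test_four_harmonic_example(self):
        f0 = 1.0
        x = sum((0.1 if k % 2 == 1 else 0.3)
                * np.cos(2 * np.pi * k * f0 * T1000) for k in range(1, 5))
        out = gq.harmonic_ratio(axis_epoch(x), f0)
        assert out["hr_vt"] == pytest.approx(3.0, rel=1e-3)

    def test_pure_step_frequency_hits_cap(self):
        # all power at the 2nd stride harmonic: no odd power on VT
        x = np.cos(2 * np.pi * 2.0 * T1000)
        with pytest.warns(UserWarning, match="capped"):
            out = gq.harmonic_ratio(axis_epoch(x), 1.0)
        assert out["hr_vt"] == 100.0


class TestLocalDivergence:
    def test_limit_cycle_has_near_zero_divergence(self, noiseless_epoch):
        freq = gq.detect_frequencies(noiseless_epoch)
        lde = gq.local_divergence_rate(noiseless_epoch.axis("vt"), FS,
                                       freq.stride_time)
        assert abs(lde) < 0.1

    def test_divergence_increases_along_jitter_ladder(self):
        values = []
        for jitter in (0.0, 0.2, 0.5):
            p = GaitSignalParams(duration_s=12, f_stride=0.9,
                                 phase_jitter_sd=jitter, seed=3)
            ep = gq.split_epochs(gq.realign_axes(simulate_gait_episode(p)),
                                 10.0)[0]
            values.append(gq.local_divergence_rate(ep.axis("vt"), FS,
                                                   1 / 0.9))
        assert values[0] < values[1] < values[2]

    def test_too_short_signal_rejected(self):
        with pytest.raises(gq.EpochInvalid):
            gq.local_divergence_rate(np.sin(T1000[:180]), FS, 1.0)


class TestSampleEntropy:
    def test_constant_signal_is_zero(self):
        assert gq.sample_entropy(np.ones(300), r=0.1) == 0.0

    def test_slow_sinusoid_is_nearly_deterministic(self):
        x = np.sin(2 * np.pi * 0.5 * T1000)
        assert gq.sample_entropy(x) < 0.3

    def test_white_noise_matches_bruteforce_exactly(self):
        rng = np.random.default_rng(19)
        x = rng.standard_normal(400)
        assert gq.sample_entropy(x) == pytest.approx(sampen_brute(x),
                                                     abs=1e-12)

    def test_alternating_signal_with_tiny_tolerance_invalid(self):
        x = np.tile([0.0, 1.0], 100) + np.linspace(0, 5, 200)
        assert np.isnan(gq.sample_entropy(x, r=1e-9))


class TestComposite:
    def test_zero_standardized_inputs_give_zero(self):
        w = gq.CompositeWeights(means={"stride_regularity": 0.5},
                                sds={"stride_regularity": 0.1})
        vals = {"stride_autocorr_vt": 0.5, "dominant_amp_vt": 0.0,
                "rms": 0.0, "ih_vt": 0.0}
        assert gq.composite_score(vals, w) == pytest.approx(0.0)

    def test_single_weight_passes_z_score_through(self):
        w = gq.CompositeWeights(weights={"stride_regularity": 1.0,
                                         "step_power": 0.0, "rms": 0.0,
                                         "index_of_harmonicity": 0.0},
                                means={"stride_regularity": 0.4},
                                sds={"stride_regularity": 0.2})
        vals = {"stride_autocorr_vt": 0.6, "dominant_amp_vt": 1.0,
                "rms": 2.0, "ih_vt": 0.5}
        assert gq.composite_score(vals, w) == pytest.approx(1.0)

    def test_linearity_in_each_input(self):
        w = gq.CompositeWeights()
        base = {"stride_autocorr_vt": 0.2, "dominant_amp_vt": 0.4,
                "rms": 1.0, "ih_vt": 0.6}
        doubled = dict(base, stride_autocorr_vt=0.4)
        delta = gq.composite_score(doubled, w) - gq.composite_score(base, w)
        assert delta == pytest.approx(0.25 * 0.2)

    def test_missing_input_propagates(self):
        w = gq.CompositeWeights()
        vals = {"stride_autocorr_vt": np.nan, "dominant_amp_vt": 0.4,
                "rms": 1.0, "ih_vt": 0.6}
        assert np.isnan(gq.composite_score(vals, w))

    def test_nonpositive_standardization_sd_rejected(self):
        with pytest.raises(ValueError, match="SD"):
            gq.CompositeWeights(sds={"rms": 0.0})


class TestExtractAll:
    def test_sixty_second_episode_yields_six_epochs(self):
        p = GaitSignalParams(duration_s=60, f_stride=0.9, phase_jitter_sd=0.1,
                             noise_sd=0.02, seed=10)
        ep = simulate_gait_episode(p)
        cfg = F.FeatureConfig(features=("dispersion", "regularity",
                                        "harmonicity", "composite"))
        df, report = gq.extract_all(ep, cfg)
        assert len(df) == 6
        assert df["valid"].all()

    def test_noise_only_episode_flags_every_epoch(self):
        rng = np.random.default_rng(4)
        samples = rng.normal([1, 0, 0], 0.05, (3000, 3))
        ep = gq.AccelEpisode(samples, FS)
        df, _ = gq.extract_all(ep)
        assert len(df) == 3
        assert not df["valid"].any()
        assert (df["invalid_reason"] != "").all()

    def test_same_episode_gives_identical_features(self):
        p = GaitSignalParams(duration_s=12, phase_jitter_sd=0.2,
                             noise_sd=0.02, seed=2)
        dfs = [gq.extract_all(simulate_gait_episode(p))[0] for _ in range(2)]
        num = dfs[0].select_dtypes(float)
        np.testing.assert_array_equal(num.to_numpy(),
                                      dfs[1][num.columns].to_numpy())


class TestBoundedRanges:
    def test_bounded_characteristics_respect_ranges(self):
        """Bounded quantities stay in their documented ranges on a batch of
        randomized synthetic epochs."""
        rng = np.random.default_rng(99)
        cfg = F.FeatureConfig()
        checked = 0
        for _ in range(12):
            p = GaitSignalParams(
                duration_s=12, f_stride=float(rng.uniform(0.7, 1.1)),
                phase_jitter_sd=float(rng.uniform(0, 0.5)),
                noise_sd=float(rng.uniform(0, 0.1)),
                asymmetry=float(rng.uniform(0, 0.5)),
                yaw_deg=float(rng.uniform(-45, 45)),
                pitch_deg=float(rng.uniform(-15, 15)),
                seed=int(rng.integers(1 << 31)))
            df, _ = gq.extract_all(simulate_gait_episode(p), cfg)
            valid = df[df["valid"]]
            if valid.empty:
                continue
            checked += len(valid)
            for ax in ("vt", "ml", "ap"):
                assert valid[f"stride_autocorr_{ax}"].between(-1, 1).all()
                assert valid[f"dominant_amp_{ax}"].between(0, 1).all()
                assert valid[f"ih_{ax}"].between(0, 1).all()
                assert (valid[f"hr_{ax}"] > 0).all()
                assert (valid[f"sampen_{ax}"].dropna() >= 0).all()
                assert (valid[f"sd_{ax}"] >= 0).all()
            assert np.isfinite(valid["walking_speed"]).all()
        assert checked >= 5


class TestRotationInvariance:
    def test_characteristics_survive_misalignment_and_realignment(self):
        base = GaitSignalParams(duration_s=12, f_stride=0.9,
                                phase_jitter_sd=0.1, noise_sd=0.01, seed=17)
        rot = GaitSignalParams(duration_s=12, f_stride=0.9,
                               phase_jitter_sd=0.1, noise_sd=0.01, seed=17,
                               yaw_deg=35, pitch_deg=8, roll_deg=-6)
        rows = []
        for p in (base, rot):
            df, _ = gq.extract_all(simulate_gait_episode(p))
            rows.append(df.iloc[0])
        a, b = rows
        # orientation-invariant characteristics: < 1%
        for col in ("walking_speed", "stride_frequency", "rms"):
            assert b[col] == pytest.approx(a[col], rel=0.01)
        # per-axis characteristics recover within 5%
        for col in ("sd_vt", "sd_ml", "ih_vt", "stride_autocorr_vt"):
            assert b[col] == pytest.approx(a[col], rel=0.05)
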