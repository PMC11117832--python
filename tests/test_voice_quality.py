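"""Jitter/shimmer formulas, HNR, CPPS, LTAS and the AVQI composite."""

import warnings

import numpy as np
import pytest

from voxsced import AudioClip, cpps, hnr, jitter_local, ltas_features, \
    shimmer_local, track_pitch, extract_periods, avqi
from voxsced.core_signal import PeriodSequence
from voxsced.sced_stats import MeasureUndefined
from voxsced.voice_quality import AvqiCoefficients, load_avqi_coefficients
from voxsced.synthetic_data import VowelSpec, synth_vowel

SR = 16000


def _seq(periods, amps=None):
    periods = np.asarray(periods, float)
    if amps is None:
        amps = np.ones_like(periods)
    starts = np.concatenate([[0.0], np.cumsum(periods[:-1])])
    return PeriodSequence(starts, periods, np.asarray(amps, float))


class TestJitterShimmerFormulas:
    def test_constant_periods_zero_jitter(self):
        assert jitter_local(_seq([0.005] * 10)) == 0.0

    def test_alternating_periods_worked_example(self):
        # mean |ΔT| = 0.1 ms, mean T = 5.05 ms -> 1.9802%
        assert jitter_local(_seq([5.0e-3, 5.1e-3, 5.0e-3, 5.1e-3])) == \
            pytest.approx(1.9802, abs=1e-4)

    def test_constant_amplitudes_zero_shimmer(self):
        pct, db = shimmer_local(_seq([0.005] * 6))
        assert pct == 0.0 and db == 0.0

    def test_alternating_amplitudes_worked_example(self):
        pct, db = shimmer_local(_seq([0.005] * 4, [1.0, 0.9, 1.0, 0.9]))
        assert pct == pytest.approx(10.526, abs=1e-3)
        assert db == pytest.approx(0.915, abs=1e-3)

    def test_too_few_cycles_undefined(self):
        with pytest.raises(MeasureUndefined, match="insufficient_cycles"):
            jitter_local(_seq([0.005]))

    def test_nonpositive_amplitudes_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="nonpositive"):
            pct, _ = shimmer_local(_seq([0.005] * 5,
                                        [1.0, -0.1, 1.0, 0.9, 1.0]))
        assert pct > 0

    def test_scale_invariance(self, clean_vowel, clean_vowel_pitch):
        clip, _ = clean_vowel
        per = extract_periods(clip, clean_vowel_pitch)
        scaled = extract_periods(clip.scaled(0.5),
                                 track_pitch(clip.scaled(0.5)))
        assert jitter_local(scaled) == pytest.approx(jitter_local(per),
                                                     rel=0.02)
        assert shimmer_local(scaled)[0] == pytest.approx(
            shimmer_local(per)[0], rel=0.02)


class TestHnr:
    def test_pure_periodic_exceeds_40db_and_cap(self, clean_vowel_pitch):
        clip, _ = synth_vowel(VowelSpec(f0_hz=150.0, duration_s=3.0,
                                        jitter_pct=0.0, shimmer_pct=0.0,
                                        target_hnr_db=60.0, seed=101))
        val = hnr(clip, track_pitch(clip))
        assert 40.0 <= val <= 60.0

    def test_monotone_recovery_within_3db(self):
        vals = []
        for target in (10.0, 20.0, 30.0):
            clip, _ = synth_vowel(VowelSpec(f0_hz=150.0, duration_s=2.0,
                                            jitter_pct=0.1, shimmer_pct=0.5,
                                            target_hnr_db=target, seed=33))
            vals.append(hnr(clip, track_pitch(clip)))
        assert vals[0] < vals[1] < vals[2]
        for v, target in zip(vals, (10.0, 20.0, 30.0)):
            assert abs(v - target) <= 3.0

    def test_silence_undefined(self):
        clip = AudioClip(np.zeros(SR) + 1e-12, SR)
        with pytest.raises(MeasureUndefined):
            hnr(clip, track_pitch(clip))


class TestCpps:
    def test_clean_vowel_exceeds_vowel_cutoff(self, clean_vowel):
        clip, _ = clean_vowel
        assert cpps(clip) >= 14.45

    def test_white_noise_below_cutoff(self):
        rng = np.random.default_rng(5)
        assert cpps(AudioClip(rng.normal(0, 0.1, 3 * SR), SR)) < 14.45

    def test_strictly_decreasing_under_added_noise(self, clean_vowel):
        clip, _ = clean_vowel
        rng = np.random.default_rng(6)
        noise = rng.normal(0, 1, clip.samples.size)
        sig_rms = clip.samples.std()
        vals = []
        for snr_db in (30, 20, 10, 0):
            n = sig_rms / 10 ** (snr_db / 20) * noise
            vals.append(cpps(AudioClip(np.clip(clip.samples + n, -1, 1), SR)))
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_short_clip_undefined(self):
        with pytest.raises(MeasureUndefined, match="too_short"):
            cpps(AudioClip(np.ones(SR // 10), SR))


class TestLtas:
    def test_white_noise_flat_within_1db(self):
        rng = np.random.default_rng(7)
        slope, tilt = ltas_features(AudioClip(rng.normal(0, 0.1, 10 * SR), SR))
        assert abs(slope) < 1.0
        assert abs(tilt) < 1.0

    def test_one_over_f_noise_has_positive_low_band_contrast(self):
        rng = np.random.default_rng(8)
        white = rng.normal(0, 1, 10 * SR)
        spec = np.fft.rfft(white)
        f = np.fft.rfftfreq(white.size, 1 / SR)
        f[0] = f[1]
        pink = np.fft.irfft(spec / np.sqrt(f), n=white.size)
        pink = AudioClip(0.5 * pink / np.max(np.abs(pink)), SR)
        slope_pink, tilt_pink = ltas_features(pink)
        slope_white, _ = ltas_features(
            AudioClip(0.5 * white / np.max(np.abs(white)), SR))
        assert slope_pink > slope_white + 3.0
        assert tilt_pink > 3.0

    def test_low_tone_strongly_positive(self, sine_clip):
        slope, _ = ltas_features(sine_clip(200.0, 2.0, amp=0.5))
        assert slope > 20.0


class TestAvqi:
    def test_zero_weights_return_intercept(self, clean_vowel):
        clip, _ = clean_vowel
        speech, _ = synth_vowel(VowelSpec(f0_hz=120.0, duration_s=6.0,
                                          seed=55))
        coeffs = AvqiCoefficients(intercept=2.0, cpps=0, hnr=0,
                                  shimmer_pct=0, shimmer_db=0, ltas_slope=0,
                                  ltas_tilt=0, scale=1.0)
        res = avqi(clip, speech, coeffs)
        assert res.score == pytest.approx(2.0)
        assert not res.clipped

    def test_degraded_voice_exceeds_french_cutoff(self):
        vowel, _ = synth_vowel(VowelSpec(f0_hz=150.0, duration_s=3.5,
                                         jitter_pct=3.0, shimmer_pct=10.0,
                                         target_hnr_db=5.0, seed=77))
        speech, _ = synth_vowel(VowelSpec(f0_hz=120.0, duration_s=9.0,
                                          jitter_pct=3.0, shimmer_pct=10.0,
                                          target_hnr_db=5.0, seed=78))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = avqi(vowel, speech)
        assert res.score >= 2.33
        assert 0.0 <= res.score <= 10.0

    def test_score_non_decreasing_with_degradation(self):
        scores = []
        for jit, shim, target in [(0.3, 2.0, 30.0), (1.0, 5.0, 15.0),
                                  (3.0, 10.0, 5.0)]:
            vowel, _ = synth_vowel(VowelSpec(f0_hz=150.0, duration_s=3.5,
                                             jitter_pct=jit, shimmer_pct=shim,
                                             target_hnr_db=target, seed=91))
            speech, _ = synth_vowel(VowelSpec(f0_hz=120.0, duration_s=9.0,
                                              jitter_pct=jit,
                                              shimmer_pct=shim,
                                              target_hnr_db=target, seed=92))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                scores.append(avqi(vowel, speech).score)
        assert scores[0] <= scores[1] <= scores[2]

    def test_insufficient_vowel_material_undefined(self, clean_vowel):
        clip, _ = clean_vowel
        short = AudioClip(clip.samples[:SR], SR)
        with pytest.raises(MeasureUndefined, match="insufficient"):
            avqi(short, clip)

    def test_coefficient_sets_are_versioned(self):
        coeffs = load_avqi_coefficients()
        assert coeffs.version_label
        assert coeffs.cutoff == pytest.approx(2.33)
        with pytest.raises(KeyError):
            load_avqi_coefficients("no-such-version")
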