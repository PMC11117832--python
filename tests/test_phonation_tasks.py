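"""Sustained-vowel intensity gating, glide analysis, vowel-peak loudness."""

import numpy as np
import pytest

from voxsced import (AnnotationTier, AudioClip, analyze_glide,
                     extract_periods, flag_artifacts, intensity_contour,
                     sentence_vowel_loudness, sustained_mean_intensity,
                     track_pitch, verb_final_loudness)
from voxsced.core_signal import IntensityContour, PitchContour
from voxsced.sced_stats import MeasureUndefined
from voxsced.synthetic_data import (GlideSpec, PassageSpec, VowelSpec,
                                    synth_glide, synth_passage, synth_vowel)

SR = 16000


def _analyzed(clip):
    pitch = track_pitch(clip)
    return pitch, extract_periods(clip, pitch), intensity_contour(clip)


class TestSustainedMeanIntensity:
    def test_constant_level_vowel(self, sine_clip):
        clip = sine_clip(150.0, 1.5, amp=10 ** (-10 / 20) * np.sqrt(2))
        pitch, per, inten = _analyzed(clip)
        assert sustained_mean_intensity(clip, per, inten) == \
            pytest.approx(-10.0, abs=0.5)

    def test_leading_trailing_silence_ignored(self):
        spec = VowelSpec(f0_hz=150.0, duration_s=1.5, jitter_pct=0.3,
                         shimmer_pct=1.0, target_hnr_db=30.0, seed=4)
        bare, _ = synth_vowel(spec)
        spec_padded = VowelSpec(f0_hz=150.0, duration_s=1.5, jitter_pct=0.3,
                                shimmer_pct=1.0, target_hnr_db=30.0, seed=4,
                                lead_silence_s=1.0, trail_silence_s=1.0)
        padded, _ = synth_vowel(spec_padded)
        v1 = sustained_mean_intensity(bare, *_analyzed(bare)[1:])
        v2 = sustained_mean_intensity(padded, *_analyzed(padded)[1:])
        assert v2 == pytest.approx(v1, abs=0.5)

    def test_linear_crescendo_mean_is_midpoint(self, sine_clip):
        # 6 dB amplitude ramp: level ramps linearly in dB, mean ≈ midpoint
        t = np.arange(int(2.0 * SR)) / SR
        gain_db = 3.0 * (t - 1.0)  # -3 dB .. +3 dB
        x = 0.25 * 10 ** (gain_db / 20) * np.sin(2 * np.pi * 150 * t)
        clip = AudioClip(x, SR)
        pitch, per, inten = _analyzed(clip)
        mid = 20 * np.log10(0.25 / np.sqrt(2))
        assert sustained_mean_intensity(clip, per, inten) == \
            pytest.approx(mid, abs=0.3)

    def test_no_cycles_undefined(self):
        clip = AudioClip(np.zeros(SR) + 1e-9, SR)
        pitch, per, inten = _analyzed(clip)
        with pytest.raises(MeasureUndefined, match="no_cycles"):
            sustained_mean_intensity(clip, per, inten)


class TestAnalyzeGlide:
    def test_octave_glide_with_two_second_hold(self):
        clip, _ = synth_glide(GlideSpec(start_f0_hz=200.0, peak_f0_hz=400.0,
                                        glide_duration_s=1.5,
                                        hold_duration_s=2.0, seed=1))
        pitch = track_pitch(clip)
        g = analyze_glide(pitch, flag_artifacts(pitch), "up")
        assert g.method == "stable_hold"
        assert g.range_st == pytest.approx(12.0, abs=0.3)
        assert not g.reversal_detected

    def test_short_hold_falls_back_to_windowed_mean(self):
        clip, _ = synth_glide(GlideSpec(start_f0_hz=200.0, peak_f0_hz=400.0,
                                        glide_duration_s=1.5,
                                        hold_duration_s=0.3, seed=2))
        pitch = track_pitch(clip)
        g = analyze_glide(pitch, flag_artifacts(pitch), "up")
        assert g.method == "fallback_mean"
        assert g.extreme_f0_st == pytest.approx(12 * np.log2(400.0), abs=0.5)

    def test_direction_contradiction_detected(self):
        clip, _ = synth_glide(GlideSpec(start_f0_hz=200.0, peak_f0_hz=400.0,
                                        hold_duration_s=2.0, seed=3))
        pitch = track_pitch(clip)
        g = analyze_glide(pitch, flag_artifacts(pitch), "down")
        assert g.reversal_detected

    def test_downward_glide(self):
        clip, _ = synth_glide(GlideSpec(start_f0_hz=300.0, peak_f0_hz=150.0,
                                        direction="down",
                                        hold_duration_s=2.0, seed=4))
        pitch = track_pitch(clip)
        g = analyze_glide(pitch, flag_artifacts(pitch), "down")
        assert g.method == "stable_hold"
        assert g.range_st == pytest.approx(12.0, abs=0.3)
        assert not g.reversal_detected

    def test_monotone_rising_contour_with_hold_is_stable_never_reversal(self):
        # constructed contour: rise then perfectly flat hold
        times = np.arange(300) * 0.01
        f0 = np.concatenate([np.linspace(200, 400, 150), np.full(150, 400.0)])
        pitch = PitchContour(times, f0, np.ones(300, bool))
        g = analyze_glide(pitch, flag_artifacts(pitch), "up")
        assert g.method == "stable_hold"
        assert not g.reversal_detected

    def test_amplitude_scaling_and_silence_invariance(self):
        clip, _ = synth_glide(GlideSpec(start_f0_hz=200.0, peak_f0_hz=400.0,
                                        hold_duration_s=2.0, seed=5))
        pitch = track_pitch(clip)
        g1 = analyze_glide(pitch, flag_artifacts(pitch), "up")
        mod = AudioClip(np.concatenate([0.5 * clip.samples,
                                        np.zeros(SR)]), SR)
        pitch2 = track_pitch(mod)
        g2 = analyze_glide(pitch2, flag_artifacts(pitch2), "up")
        assert g2.range_st == pytest.approx(g1.range_st, abs=0.1)

    def test_insufficient_voicing_undefined(self):
        times = np.arange(50) * 0.01
        pitch = PitchContour(times, np.full(50, 200.0), np.ones(50, bool))
        with pytest.raises(MeasureUndefined, match="insufficient_voicing"):
            analyze_glide(pitch, flag_artifacts(pitch), "up")


def _contour(levels, hop=0.01):
    times = (np.arange(len(levels)) + 0.5) * hop
    return IntensityContour(times, np.asarray(levels, float))


class TestLoudness:
    def test_mean_of_three_vowel_peaks(self):
        levels = np.full(100, 40.0)
        levels[10:15] = 70.0
        levels[40:45] = 72.0
        levels[70:75] = 74.0
        tier = AnnotationTier("vowels", [(0.05, 0.2, "a"), (0.35, 0.5, "e"),
                                         (0.65, 0.8, "i")])
        res = sentence_vowel_loudness(_contour(levels), tier)
        assert res.mean_db == pytest.approx(72.0)
        assert res.n_units == 3
        assert res.unit_peaks_db == [70.0, 72.0, 74.0]

    def test_single_vowel_mean_is_its_peak(self):
        levels = np.full(50, 30.0)
        levels[20] = 65.0
        res = sentence_vowel_loudness(
            _contour(levels), AnnotationTier("vowels", [(0.1, 0.4, "a")]))
        assert res.mean_db == 65.0 and res.n_units == 1

    def test_verb_final_two_units(self):
        levels = np.full(100, 30.0)
        levels[20] = 65.0
        levels[70] = 69.0
        tier = AnnotationTier("verb_final", [(0.1, 0.3, "v1"),
                                             (0.6, 0.8, "v2")])
        res = verb_final_loudness(_contour(levels), tier)
        assert res.mean_db == pytest.approx(67.0)

    def test_empty_tier_undefined(self):
        with pytest.raises(MeasureUndefined, match="no_units"):
            verb_final_loudness(_contour(np.zeros(50)),
                                AnnotationTier("verb_final", []))

    def test_interval_outside_contour_skipped_with_warning(self):
        levels = np.full(50, 30.0)
        tier = AnnotationTier("vowels", [(0.1, 0.2, "a"), (5.0, 6.0, "b")])
        with pytest.warns(UserWarning, match="outside"):
            res = sentence_vowel_loudness(_contour(levels), tier)
        assert res.n_units == 1

    def test_generator_vowel_gains_recovered(self):
        gains = [[2.0, -1.0, 0.5, 1.5, -2.0, 0.0]]
        clip, tiers, truth = synth_passage(PassageSpec(
            pattern=(("speech", 3.0),), syllables_per_span=(6,),
            syllable_gains_db=gains, seed=9))
        inten = intensity_contour(clip)
        res = sentence_vowel_loudness(inten, tiers["vowels"])
        # relative pattern of injected per-vowel gains is reproduced
        peaks = np.asarray(res.unit_peaks_db)
        rel = peaks - peaks.mean()
        inj = np.asarray(gains[0]) - np.mean(gains[0])
        assert np.max(np.abs(rel - inj)) < 0.5
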