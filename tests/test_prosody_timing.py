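"""Pause segmentation, timing measures, prosodic variability, DDK rates."""

import numpy as np
import pytest

from voxsced import (intensity_contour, prosodic_variability, segment_speech,
                     timing_measures, track_pitch, ddk_rate)
from voxsced.core_signal import IntensityContour, PitchContour
from voxsced.prosody_timing import segmentation_to_tier, SpeechSegmentation
from voxsced.sced_stats import MeasureUndefined
from voxsced.synthetic_data import PassageSpec, synth_passage

HOP = 0.01


def make_timeline(spans, level_speech=-20.0, level_silence=-80.0):
    """Frame-grid intensity+pitch contours from (kind, duration) spans."""
    total = sum(d for _, d in spans)
    n = int(round(total / HOP))
    times = (np.arange(n) + 0.5) * HOP
    level = np.full(n, level_silence)
    voiced = np.zeros(n, bool)
    f0 = np.full(n, np.nan)
    cursor = 0.0
    for kind, dur in spans:
        m = (times >= cursor) & (times < cursor + dur)
        if kind == "speech":
            level[m] = level_speech
            voiced[m] = True
            f0[m] = 120.0
        cursor += dur
    return (IntensityContour(times, level),
            PitchContour(times, f0, voiced))


FIXTURE = (("speech", 2.0), ("silence", 0.15), ("speech", 1.85),
           ("silence", 0.5), ("speech", 1.5))


class TestSegmentation:
    def test_constructed_fixture_one_pause_two_segments(self):
        inten, pitch = make_timeline(FIXTURE)
        seg = segment_speech(inten, pitch)
        assert len(seg.pauses) == 1
        assert seg.pauses[0][1] - seg.pauses[0][0] == pytest.approx(0.5,
                                                                    abs=1e-9)
        durs = [b - a for a, b in seg.speech_segments]
        assert durs == [pytest.approx(4.0, abs=1e-9),
                        pytest.approx(1.5, abs=1e-9)]
        assert seg.total_duration_s == pytest.approx(6.0, abs=1e-9)

    def test_continuous_speech_single_segment(self):
        inten, pitch = make_timeline((("speech", 3.0),))
        seg = segment_speech(inten, pitch)
        assert seg.pauses == []
        assert len(seg.speech_segments) == 1

    def test_exactly_200ms_counts_as_pause(self):
        inten, pitch = make_timeline((("speech", 1.0), ("silence", 0.20),
                                      ("speech", 1.0)))
        seg = segment_speech(inten, pitch)
        assert len(seg.pauses) == 1

    def test_just_below_threshold_merges(self):
        inten, pitch = make_timeline((("speech", 1.0), ("silence", 0.19),
                                      ("speech", 1.0)))
        seg = segment_speech(inten, pitch)
        assert seg.pauses == []

    def test_leading_trailing_silence_excluded(self):
        inten, pitch = make_timeline((("silence", 1.0), ("speech", 2.0),
                                      ("silence", 1.0)))
        seg = segment_speech(inten, pitch)
        assert seg.total_duration_s == pytest.approx(2.0, abs=1e-9)

    def test_tiling_invariant(self):
        inten, pitch = make_timeline(FIXTURE)
        seg = segment_speech(inten, pitch)
        tiled = sum(b - a for a, b in seg.speech_segments) + seg.pause_total_s
        assert tiled == pytest.approx(seg.total_duration_s, abs=1e-12)

    def test_all_silent_input_empty(self):
        inten, pitch = make_timeline((("silence", 2.0),))
        seg = segment_speech(inten, pitch)
        assert seg.speech_segments == [] and seg.total_duration_s == 0.0

    def test_amplitude_scaling_invariance(self):
        inten, pitch = make_timeline(FIXTURE)
        shifted = IntensityContour(inten.times, inten.level_db + 12.0)
        s1 = segment_speech(inten, pitch)
        s2 = segment_speech(shifted, pitch)
        assert s1.pauses == s2.pauses

    def test_audit_tier_export(self):
        inten, pitch = make_timeline(FIXTURE)
        tier = segmentation_to_tier(segment_speech(inten, pitch))
        labels = [lab for _, _, lab in tier.intervals]
        assert labels.count("pause") == 1 and labels.count("speech") == 2


class TestTimingMeasures:
    def test_fixture_arithmetic(self):
        inten, pitch = make_timeline(FIXTURE)
        seg = segment_speech(inten, pitch)
        tm = timing_measures(seg, 18)
        assert tm.speaking_rate_syl_per_s == pytest.approx(3.0, abs=1e-9)
        assert tm.percent_pause == pytest.approx(100 * 0.5 / 6.0, abs=1e-9)
        assert tm.mean_speech_duration_s == pytest.approx(2.75, abs=1e-9)

    def test_no_pauses_zero_percent(self):
        inten, pitch = make_timeline((("speech", 3.0),))
        tm = timing_measures(segment_speech(inten, pitch), 9)
        assert tm.percent_pause == 0.0

    def test_articulatory_group_mean(self):
        inten, pitch = make_timeline(FIXTURE)
        tm = timing_measures(segment_speech(inten, pitch), 13, [6, 7])
        assert tm.mean_articulatory_group_syllables == pytest.approx(6.5)

    def test_zero_duration_undefined(self):
        with pytest.raises(MeasureUndefined, match="zero_duration"):
            timing_measures(SpeechSegmentation([], [], 0.0), 10)


class TestProsodicVariability:
    def test_constant_contours_zero_cv(self):
        inten, pitch = make_timeline((("speech", 2.0),))
        seg = segment_speech(inten, pitch)
        var = prosodic_variability(pitch, inten, seg)
        assert var.cv_f0 == pytest.approx(0.0, abs=1e-12)
        assert var.cv_intensity == pytest.approx(0.0, abs=1e-12)

    def test_three_frame_formula_path(self):
        times = (np.arange(12) + 0.5) * HOP
        voiced = np.zeros(12, bool)
        voiced[[2, 5, 8]] = True
        f0 = np.full(12, np.nan)
        f0[[2, 5, 8]] = 120.0
        pitch = PitchContour(times, f0, voiced)
        inten = IntensityContour(times, np.full(12, 10.0))
        inten.level_db[[2, 5, 8]] = [8.0, 10.0, 12.0]
        seg = SpeechSegmentation([(0.0, 0.12)], [], 0.12)
        # relax the frame-count floor by tiling the pattern
        times2 = (np.arange(48) + 0.5) * HOP
        pitch2 = PitchContour(times2, np.tile(f0, 4), np.tile(voiced, 4))
        inten2 = IntensityContour(times2, np.tile(inten.level_db, 4))
        seg2 = SpeechSegmentation([(0.0, 0.48)], [], 0.48)
        var = prosodic_variability(pitch2, inten2, seg2)
        # sample sd of repeated [8,10,12] / mean 10
        vals = np.tile([8.0, 10.0, 12.0], 4)
        assert var.cv_intensity == pytest.approx(
            np.std(vals, ddof=1) / 10.0, abs=1e-12)

    def test_alternating_levels_increase_cv(self):
        flat, _, = synth_passage(PassageSpec(
            pattern=(("speech", 3.0),), syllables_per_span=(6,),
            syllable_gains_db=[[0.0] * 6], seed=2))[::2]
        alt_clip, _, _ = synth_passage(PassageSpec(
            pattern=(("speech", 3.0),), syllables_per_span=(6,),
            syllable_gains_db=[[6.0, -6.0, 6.0, -6.0, 6.0, -6.0]], seed=2))

        def cv_of(clip):
            pitch = track_pitch(clip)
            inten = intensity_contour(clip)
            seg = segment_speech(inten, pitch)
            return prosodic_variability(pitch, inten, seg).cv_intensity

        assert cv_of(alt_clip) > cv_of(flat)

    def test_insufficient_frames_undefined(self):
        inten, pitch = make_timeline((("speech", 0.05),))
        seg = SpeechSegmentation([(0.0, 0.05)], [], 0.05)
        with pytest.raises(MeasureUndefined):
            prosodic_variability(pitch, inten, seg)


class TestDdkRate:
    @pytest.mark.parametrize("counts,expected", [
        ([28, 30, 26], 6.0),
        ([20], 4.0),
        ([0, 0, 0], 0.0),
    ])
    def test_best_of_trials(self, counts, expected):
        assert ddk_rate(counts) == expected

    def test_empty_undefined(self):
        with pytest.raises(MeasureUndefined, match="no_trials"):
            ddk_rate([])

    def test_more_than_three_trials_rejected(self):
        with pytest.raises(ValueError):
            ddk_rate([10, 10, 10, 10])
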