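"""Speech-timing, prosodic-variability and DDK-rate measures.

Pause/speech segmentation (pauses are silences of at least 200 ms),
speaking rate, percent pause, mean speech-segment duration, articulatory
group length, coefficients of variation of F0 (semitones) and intensity
(dB) over voiced speech, and diadochokinetic syllable rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_signal import IntensityContour, PitchContour, _bool_runs
from .io_formats import AnnotationTier
from .sced_stats import MeasureUndefined

__all__ = [
    "SpeechSegmentation",
    "TimingResult",
    "VariabilityResult",
    "segment_speech",
    "timing_measures",
    "prosodic_variability",
    "ddk_rate",
    "estimate_syllable_nuclei",
    "segmentation_to_tier",
]

DEFAULT_MIN_PAUSE_S = 0.200
#: adaptive silence threshold: this many dB below the clip's maximum level
DEFAULT_SILENCE_DROP_DB = 25.0


@dataclass
class SpeechSegmentation:
    """Alternating speech segments and pauses tiling the spoken span.

    Sub-threshold silences (< min pause) are absorbed into speech segments,
    so segment and pause durations sum exactly to ``total_duration_s``.
    """

    speech_segments: list[tuple[float, float]]
    pauses: list[tuple[float, float]]
    total_duration_s: float

    @property
    def pause_total_s(self) -> float:
        return sum(b - a for a, b in self.pauses)


@dataclass
class TimingResult:
    speaking_rate_syl_per_s: float
    percent_pause: float
    mean_speech_duration_s: float
    mean_articulatory_group_syllables: float | None = None


@dataclass
class VariabilityResult:
    cv_f0: float
    cv_intensity: float
    n_frames: int


def segment_speech(intensity: IntensityContour, pitch: PitchContour,
                   min_pause_s: float = DEFAULT_MIN_PAUSE_S,
                   silence_drop_db: float = DEFAULT_SILENCE_DROP_DB
                   ) -> SpeechSegmentation:
    """Classify the recording into speech segments and pauses.

    A frame is silent when its level falls more than ``silence_drop_db``
    below the clip maximum AND it is unvoiced. Silent runs of at least
    ``min_pause_s`` (inclusive) become pauses; shorter ones merge into the
    surrounding speech. Leading/trailing silence is excluded: the timeline
    spans first speech onset to last speech offset.
    """
    if min_pause_s <= 0:
        raise ValueError("min_pause_s must be > 0")
    times = intensity.times
    level = intensity.level_db
    if times.size == 0 or not pitch.voiced.any():
        # speech requires voicing somewhere; an all-unvoiced recording has
        # no detectable speech onset
        return SpeechSegmentation([], [], 0.0)
    hop = intensity.step or 0.01
    # voicing resampled to the intensity frame grid (nearest frame)
    voiced = np.zeros(times.size, dtype=bool)
    if pitch.times.size:
        idx = np.clip(np.searchsorted(pitch.times, times), 0, pitch.times.size - 1)
        left = np.clip(idx - 1, 0, pitch.times.size - 1)
        use_left = np.abs(pitch.times[left] - times) < np.abs(pitch.times[idx] - times)
        idx = np.where(use_left, left, idx)
        voiced = pitch.voiced[idx]

    silent = (level < level.max() - silence_drop_db) & (~voiced)
    speech = ~silent
    if not speech.any():
        return SpeechSegmentation([], [], 0.0)
    first = int(np.argmax(speech))
    last = speech.size - 1 - int(np.argmax(speech[::-1]))
    speech = speech[first:last + 1]

    # frame i covers [t0 + i·hop, t0 + (i+1)·hop); durations are exact
    # multiples of the hop so tiling is exact by construction
    t0 = times[first] - hop / 2.0

    segs: list[tuple[float, float]] = []
    pauses: list[tuple[float, float]] = []
    min_frames = int(round(min_pause_s / hop))
    silent_runs = [(a, b) for a, b in _bool_runs(~speech)
                   if (b - a) >= min_frames]
    cursor = 0
    for a, b in silent_runs:
        if a > cursor:
            segs.append((t0 + cursor * hop, t0 + a * hop))
        pauses.append((t0 + a * hop, t0 + b * hop))
        cursor = b
    if cursor < speech.size:
        segs.append((t0 + cursor * hop, t0 + speech.size * hop))
    total = speech.size * hop
    return SpeechSegmentation(segs, pauses, float(total))


def timing_measures(seg: SpeechSegmentation, n_syllables: int,
                    group_syllables: list[int] | None = None) -> TimingResult:
    """Speaking rate, percent pause, mean speech duration, group length.

    Total duration runs from first speech onset to last offset. Speaking
    rate divides the syllable count by that duration; percent pause divides
    the summed pause time by it; mean speech duration averages segment
    durations; articulatory-group length averages the supplied per-group
    syllable counts when given.
    """
    if n_syllables < 0:
        raise ValueError("n_syllables must be >= 0")
    total = seg.total_duration_s
    if total <= 0:
        raise MeasureUndefined("zero_duration")
    rate = n_syllables / total
    pct_pause = 100.0 * seg.pause_total_s / total
    mean_speech = float(np.mean([b - a for a, b in seg.speech_segments]))
    group = (float(np.mean(group_syllables))
             if group_syllables else None)
    return TimingResult(speaking_rate_syl_per_s=float(rate),
                        percent_pause=float(pct_pause),
                        mean_speech_duration_s=mean_speech,
                        mean_articulatory_group_syllables=group)


def prosodic_variability(pitch: PitchContour, intensity: IntensityContour,
                         seg: SpeechSegmentation) -> VariabilityResult:
    """Coefficients of variation of F0 (ST re 1 Hz) and intensity (dB).

    Computed over voiced frames inside speech segments, concatenated; CV is
    the sample (n-1) standard deviation divided by the mean. The semitone
    CV depends on the 1 Hz reference and is not invariant to changing it.
    """
    st = pitch.f0_st
    voiced = pitch.voiced & np.isfinite(st)
    in_speech = np.zeros(pitch.times.size, dtype=bool)
    for a, b in seg.speech_segments:
        in_speech |= (pitch.times >= a) & (pitch.times < b)
    use = voiced & in_speech
    if use.sum() < 10:
        raise MeasureUndefined("insufficient_voiced_frames",
                               f"{int(use.sum())} < 10")
    f0_vals = st[use]
    lvl = np.interp(pitch.times[use], intensity.times, intensity.level_db)
    cv_f0 = float(np.std(f0_vals, ddof=1) / np.mean(f0_vals))
    cv_int = float(np.std(lvl, ddof=1) / np.mean(lvl))
    return VariabilityResult(cv_f0=abs(cv_f0), cv_intensity=abs(cv_int),
                             n_frames=int(use.sum()))


def ddk_rate(trial_syllable_counts_first_5s: list[int]) -> float:
    """Best-of-trials DDK rate: max over trials of (count in first 5 s)/5."""
    counts = list(trial_syllable_counts_first_5s)
    if not counts:
        raise MeasureUndefined("no_trials")
    if len(counts) > 3:
        raise ValueError("at most 3 DDK trials expected")
    return max(c / 5.0 for c in counts)


def estimate_syllable_nuclei(intensity: IntensityContour,
                             seg: SpeechSegmentation,
                             min_prominence_db: float = 2.0) -> int:
    """Rough syllable count from intensity peaks inside speech segments.

    A convenience estimator only — syllable counts used for reported
    measures are inputs (counted against a known passage), never detected.
    """
    from scipy.signal import find_peaks

    count = 0
    for a, b in seg.speech_segments:
        mask = (intensity.times >= a) & (intensity.times < b)
        if mask.sum() < 3:
            continue
        peaks, _ = find_peaks(intensity.level_db[mask],
                              prominence=min_prominence_db)
        count += max(1, peaks.size)
    return count


def segmentation_to_tier(seg: SpeechSegmentation) -> AnnotationTier:
    """Export a segmentation as a 'speech'/'pause' interval tier for audit."""
    ivs = [(a, b, "speech") for a, b in seg.speech_segments]
    ivs += [(a, b, "pause") for a, b in seg.pauses]
    return AnnotationTier("speech", ivs)
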