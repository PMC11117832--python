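"""Task-specific phonation measurements.

Sustained-vowel mean intensity gated by the first/last glottal cycle,
pitch-glide stable-extreme analysis with semitone ranges and reversal
detection, and vowel-peak loudness averaging for sentence and spontaneous
speech tasks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io_formats import AudioClip, AnnotationTier
from .core_signal import (ArtifactFlags, IntensityContour, PeriodSequence,
                          PitchContour)
from .sced_stats import MeasureUndefined

__all__ = [
    "GlideResult",
    "LoudnessResult",
    "sustained_mean_intensity",
    "analyze_glide",
    "sentence_vowel_loudness",
    "verb_final_loudness",
]


@dataclass
class GlideResult:
    """Outcome of a pitch-glide trial.

    ``method`` records whether a qualifying >= ``hold_s`` stable region was
    found (stable_hold) or the fallback windowed mean around the extreme
    frame was used. ``reversal_detected`` is true when the achieved extreme
    lies on the opposite side of the neutral pitch from the instructed
    direction — speakers sometimes glide the wrong way.
    """

    neutral_f0_st: float
    extreme_f0_st: float
    range_st: float
    direction: str
    method: str
    reversal_detected: bool


@dataclass
class LoudnessResult:
    mean_db: float
    n_units: int
    unit_peaks_db: list[float]


def sustained_mean_intensity(clip: AudioClip, periods: PeriodSequence,
                             intensity: IntensityContour) -> float:
    """Mean intensity from phonation onset to offset, in dB.

    Onset/offset are the first and last detected glottal cycle, so leading
    and trailing silence never dilute the mean.
    """
    if len(periods) < 1:
        raise MeasureUndefined("no_cycles")
    t0 = float(periods.cycle_starts[0])
    t1 = float(periods.cycle_starts[-1] + periods.periods[-1])
    mask = (intensity.times >= t0) & (intensity.times <= t1)
    if not mask.any():
        raise MeasureUndefined("no_frames_in_phonation_span")
    return float(intensity.level_db[mask].mean())


def analyze_glide(pitch: PitchContour, flags: ArtifactFlags, direction: str,
                  stability_tol_st: float = 1.0, hold_s: float = 0.5,
                  neutral_f0_st: float | None = None) -> GlideResult:
    """Measure a pitch glide: neutral pitch, stable extreme, semitone range.

    Neutral pitch defaults to the median F0 of the first 250 ms of voicing.
    The second half of the voiced span is searched for the most extreme
    contiguous region of at least ``hold_s`` whose peak-to-peak F0 spread
    is <= ``stability_tol_st``; its median is the extreme. Without such a
    region the fallback is the mean F0 over a 500 ms total window centered
    on the extreme voiced frame, excluding frames flagged as voice breaks
    or octave jumps.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    st = pitch.f0_st
    voiced = pitch.voiced & np.isfinite(st)
    vt = pitch.times[voiced]
    vs = st[voiced]
    if vt.size == 0 or vt[-1] - vt[0] < 1.0:
        raise MeasureUndefined("insufficient_voicing", "need >= 1 s of voicing")

    if neutral_f0_st is None:
        head = vs[vt <= vt[0] + 0.25]
        neutral = float(np.median(head))
    else:
        neutral = float(neutral_f0_st)

    midpoint = (vt[0] + vt[-1]) / 2.0
    jump_flags = flags.octave_jump_frames[voiced]
    sel = vt >= midpoint
    t2, s2, j2 = vt[sel], vs[sel], jump_flags[sel]

    best_val: float | None = None
    step = pitch.step or 0.01
    n = t2.size
    # enumerate stable windows on the contiguous-voiced frame grid
    i = 0
    while i < n:
        lo = s2[i]
        hi = s2[i]
        j = i
        while j + 1 < n and (t2[j + 1] - t2[j]) <= 1.5 * step:
            nlo, nhi = min(lo, s2[j + 1]), max(hi, s2[j + 1])
            if nhi - nlo > stability_tol_st:
                break
            lo, hi = nlo, nhi
            j += 1
        if t2[j] - t2[i] + step >= hold_s:
            med = float(np.median(s2[i:j + 1]))
            if best_val is None:
                best_val = med
            elif direction == "up":
                best_val = max(best_val, med)
            else:
                best_val = min(best_val, med)
        i += 1

    if best_val is not None:
        extreme = best_val
        method = "stable_hold"
    else:
        usable = ~j2
        if not usable.any():
            raise MeasureUndefined("no_usable_frames")
        idx = (int(np.argmax(np.where(usable, s2, -np.inf))) if direction == "up"
               else int(np.argmin(np.where(usable, s2, np.inf))))
        t_c = t2[idx]
        win = (t2 >= t_c - 0.25) & (t2 <= t_c + 0.25) & usable
        extreme = float(np.mean(s2[win]))
        method = "fallback_mean"

    reversal = (direction == "up" and extreme < neutral) or \
               (direction == "down" and extreme > neutral)
    return GlideResult(neutral_f0_st=neutral, extreme_f0_st=extreme,
                       range_st=abs(extreme - neutral), direction=direction,
                       method=method, reversal_detected=reversal)


def _peak_loudness(intensity: IntensityContour, tier: AnnotationTier,
                   empty_reason: str) -> LoudnessResult:
    if len(tier) == 0:
        raise MeasureUndefined("no_units", f"tier {tier.name!r} is empty")
    t0, t1 = intensity.times[0], intensity.times[-1]
    peaks: list[float] = []
    for a, b, lab in tier.intervals:
        mask = (intensity.times >= a) & (intensity.times < b)
        if not mask.any():
            warnings.warn(f"interval ({a:.3f}, {b:.3f}, {lab!r}) outside "
                          f"contour span [{t0:.3f}, {t1:.3f}]; skipped")
            continue
        peaks.append(float(intensity.level_db[mask].max()))
    if not peaks:
        raise MeasureUndefined(empty_reason, "all intervals outside contour")
    return LoudnessResult(mean_db=float(np.mean(peaks)), n_units=len(peaks),
                          unit_peaks_db=peaks)


def sentence_vowel_loudness(intensity: IntensityContour,
                            vowel_tier: AnnotationTier) -> LoudnessResult:
    """Mean of per-vowel peak intensities across a sentence task."""
    return _peak_loudness(intensity, vowel_tier, "all_intervals_skipped")


def verb_final_loudness(intensity: IntensityContour,
                        verb_final_tier: AnnotationTier) -> LoudnessResult:
    """Mean peak intensity over annotated verb-final-syllable vowels.

    Verbs usually occupy stressed positions, so their final-syllable vowels
    standardize loudness sampling in content-varying spontaneous speech.
    """
    return _peak_loudness(intensity, verb_final_tier, "all_intervals_skipped")
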