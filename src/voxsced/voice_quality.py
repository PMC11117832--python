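"""Perturbation and spectral voice-quality measures.

Local jitter and shimmer from a cycle sequence, autocorrelation-based HNR,
smoothed cepstral peak prominence (CPPS), long-term-average-spectrum slope
and tilt, and the six-parameter AVQI composite.

The AVQI weights are data, not code: coefficient sets live in
``avqi_coefficients.json`` keyed by version label, and every result is
tagged with the label used, since different validation scripts ship
different weights.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.signal import welch

from .io_formats import AudioClip
from .core_signal import (PitchContour, PeriodSequence, track_pitch,
                          _frame_signal, _bool_runs)
from .sced_stats import MeasureUndefined

__all__ = [
    "VoiceQualityResult",
    "AvqiCoefficients",
    "AvqiResult",
    "jitter_local",
    "shimmer_local",
    "hnr",
    "cpps",
    "ltas_features",
    "avqi",
    "voice_quality_battery",
    "load_avqi_coefficients",
]

HNR_CAP_DB = 60.0
#: quefrency band searched for the cepstral peak: 60-330 Hz equivalent
CPPS_F0_BAND = (60.0, 330.0)


@dataclass
class VoiceQualityResult:
    jitter_local_pct: float | None = None
    shimmer_local_pct: float | None = None
    shimmer_local_db: float | None = None
    hnr_db: float | None = None
    cpps_db: float | None = None
    ltas_slope_db: float | None = None
    ltas_tilt_db: float | None = None
    avqi: float | None = None
    reasons: dict = field(default_factory=dict)


@dataclass
class AvqiCoefficients:
    intercept: float
    cpps: float
    hnr: float
    shimmer_pct: float
    shimmer_db: float
    ltas_slope: float
    ltas_tilt: float
    scale: float = 1.0
    version_label: str = "custom"
    cutoff: float = 2.33

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be > 0")
        for f in (self.intercept, self.cpps, self.hnr, self.shimmer_pct,
                  self.shimmer_db, self.ltas_slope, self.ltas_tilt, self.scale):
            if not math.isfinite(f):
                raise ValueError("AVQI coefficients must be finite")


@dataclass
class AvqiResult:
    score: float
    raw_score: float
    parameters: dict
    clipped: bool
    version_label: str


def load_avqi_coefficients(version: str = "default") -> AvqiCoefficients:
    """Load a named coefficient set from the packaged JSON config."""
    text = resources.files("voxsced").joinpath("avqi_coefficients.json").read_text()
    table = json.loads(text)
    if version == "default":
        version = table["default"]
    if version not in table["sets"]:
        raise KeyError(f"no AVQI coefficient set named {version!r}; "
                       f"available: {sorted(table['sets'])}")
    entry = table["sets"][version]
    return AvqiCoefficients(version_label=version, **entry)


def jitter_local(periods: PeriodSequence) -> float:
    """Local jitter: 100·mean|T_{i+1}−T_i| / mean(T_i), in percent."""
    T = periods.periods
    if T.size < 2:
        raise MeasureUndefined("insufficient_cycles", f"{T.size} cycles")
    return float(100.0 * np.mean(np.abs(np.diff(T))) / np.mean(T))


def shimmer_local(periods: PeriodSequence) -> tuple[float, float]:
    """Local shimmer as (percent, dB).

    percent = 100·mean|A_{i+1}−A_i| / mean(A); dB = mean|20·log10(A_{i+1}/A_i)|.
    Cycles with nonpositive amplitude are dropped with a warning.
    """
    A = periods.peak_amplitudes
    bad = A <= 0
    if bad.any():
        warnings.warn(f"dropping {int(bad.sum())} nonpositive-amplitude cycles")
        A = A[~bad]
    if A.size < 2:
        raise MeasureUndefined("insufficient_cycles", f"{A.size} usable cycles")
    pct = float(100.0 * np.mean(np.abs(np.diff(A))) / np.mean(A))
    db = float(np.mean(np.abs(20.0 * np.log10(A[1:] / A[:-1]))))
    return pct, db


def hnr(clip: AudioClip, pitch: PitchContour, frame_s: float = 0.05,
        hop_s: float = 0.01) -> float:
    """Mean harmonics-to-noise ratio over voiced frames, in dB.

    Per frame, r is the window-compensated normalized autocorrelation peak
    near the expected lag 1/F0 (parabolically refined); the frame HNR is
    10·log10(r/(1−r)), capped at +60 dB. The 50 ms default window spans
    many glottal cycles at speaking F0, which stabilizes the estimate at
    high harmonicity; the estimator's practical ceiling is ~40 dB.
    """
    x = clip.samples
    sr = clip.sample_rate
    voiced_times = pitch.times[pitch.voiced]
    if voiced_times.size == 0:
        raise MeasureUndefined("no_voiced_frames")
    if voiced_times[-1] - voiced_times[0] < 0.1:
        raise MeasureUndefined("voiced_region_too_short")

    frame_len = max(8, int(round(frame_s * sr)))
    hop = max(1, int(round(hop_s * sr)))
    if x.size < frame_len:
        x = np.pad(x, (0, frame_len - x.size))
    frames = _frame_signal(x, frame_len, hop)
    times = (np.arange(frames.shape[0]) * hop + frame_len / 2) / sr
    window = np.hanning(frame_len)
    nfft = 1 << int(math.ceil(math.log2(2 * frame_len)))
    w_ac = np.fft.irfft(np.abs(np.fft.rfft(window, nfft)) ** 2)[:frame_len]
    w_ac /= w_ac[0]

    fw = (frames - frames.mean(axis=1, keepdims=True)) * window
    ac = np.fft.irfft(np.abs(np.fft.rfft(fw, nfft, axis=1)) ** 2,
                      axis=1)[:, :frame_len]
    r0 = ac[:, 0].copy()
    r0[r0 <= 0] = 1.0
    acn = ac / r0[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        acn = np.where(w_ac[None, :] > 0.25, acn / w_ac[None, :], 0.0)

    vals = []
    for fi, t in enumerate(times):
        f0 = pitch.f0_at(t)
        if not np.isfinite(f0) or f0 <= 0:
            continue
        lag = sr / f0
        lo = int(max(2, math.floor(lag * 0.8)))
        hi = int(min(frame_len - 2, math.ceil(lag * 1.2)))
        if hi <= lo:
            continue
        r = acn[fi]
        p = lo + int(np.argmax(r[lo:hi + 1]))
        y0, y1, y2 = r[p - 1], r[p], r[p + 1]
        denom = y0 - 2 * y1 + y2
        rmax = y1
        if abs(denom) > 1e-12:
            d = float(np.clip(0.5 * (y0 - y2) / denom, -0.5, 0.5))
            rmax = y1 - 0.25 * (y0 - y2) * d
        rmax = float(np.clip(rmax, 1e-6, 1 - 1e-6))
        vals.append(min(HNR_CAP_DB, 10.0 * math.log10(rmax / (1.0 - rmax))))
    if not vals:
        raise MeasureUndefined("no_voiced_frames")
    return float(np.mean(vals))


def cpps(clip: AudioClip, frame_s: float = 0.04, hop_s: float = 0.01,
         time_smooth_frames: int = 10, quef_smooth_s: float = 0.001,
         trend_start_s: float = 0.001) -> float:
    """Smoothed cepstral peak prominence, in dB.

    Per frame: Hann-windowed log power spectrum (dB) → amplitude cepstrum
    in dB (20·log10 |FFT| / N). The cepstrogram is moving-average smoothed
    across time then across quefrency; a least-squares line is fit against
    quefrency over [trend_start_s, max]; CPPS is the mean over frames of
    (peak in the 60–330 Hz-equivalent band − trend at that quefrency).
    """
    x = clip.samples
    sr = clip.sample_rate
    if x.size / sr < 0.5:
        raise MeasureUndefined("clip_too_short", "need >= 0.5 s")
    frame_len = int(round(frame_s * sr))
    hop = max(1, int(round(hop_s * sr)))
    frames = _frame_signal(x, frame_len, hop)
    # skip near-silent frames (they carry no voice information)
    peak = np.max(np.abs(x)) or 1.0
    keep = np.max(np.abs(frames), axis=1) > 0.02 * peak
    if not keep.any():
        raise MeasureUndefined("all_silent")
    frames = frames[keep]
    window = np.hanning(frame_len)
    nfft = 1 << int(math.ceil(math.log2(2 * frame_len)))
    spec = np.abs(np.fft.rfft(frames * window, nfft, axis=1)) ** 2
    log_spec = 10.0 * np.log10(spec + 1e-300)
    ceps = np.abs(np.fft.rfft(log_spec, axis=1)) / log_spec.shape[1]
    ceps_db = 20.0 * np.log10(ceps + 1e-12)

    # quefrency axis: log-spectrum "sampling rate" is nfft/sr bins per Hz,
    # so cepstral bin k corresponds to quefrency k/sr · ... derived below
    n_spec = log_spec.shape[1]
    df = sr / nfft
    quef = np.arange(ceps_db.shape[1]) / (n_spec * df)

    # moving-average smoothing: across time, then across quefrency
    def smooth(a: np.ndarray, w: int, axis: int) -> np.ndarray:
        if w <= 1 or a.shape[axis] < 2:
            return a
        kernel = np.ones(min(w, a.shape[axis])) / min(w, a.shape[axis])
        return np.apply_along_axis(
            lambda v: np.convolve(v, kernel, mode="same"), axis, a)

    ceps_db = smooth(ceps_db, time_smooth_frames, axis=0)
    dq = quef[1] - quef[0]
    ceps_db = smooth(ceps_db, max(1, int(round(quef_smooth_s / dq))), axis=1)

    fit_mask = quef >= trend_start_s
    band = (quef >= 1.0 / CPPS_F0_BAND[1]) & (quef <= 1.0 / CPPS_F0_BAND[0])
    if not band.any():
        raise MeasureUndefined("quefrency_band_empty")
    q_fit = quef[fit_mask]
    vals = []
    for row in ceps_db:
        slope, intercept = np.polyfit(q_fit, row[fit_mask], 1)
        bi = np.flatnonzero(band)
        pk = bi[int(np.argmax(row[bi]))]
        vals.append(row[pk] - (slope * quef[pk] + intercept))
    return float(np.mean(vals))


def ltas_features(clip: AudioClip, band_edge_hz: float = 1000.0,
                  top_hz: float = 10000.0) -> tuple[float, float]:
    """Long-term average spectrum slope and tilt, in dB.

    slope = mean level in [0, 1 kHz] − mean level in [1, 10 kHz];
    tilt = the same contrast evaluated on the least-squares regression line
    through the LTAS. Bands are truncated at Nyquist.
    """
    x = clip.samples
    sr = clip.sample_rate
    if x.size / sr < 0.5:
        raise MeasureUndefined("clip_too_short", "need >= 0.5 s")
    nper = min(x.size, 4096)
    f, pxx = welch(x, fs=sr, nperseg=nper)
    ltas = 10.0 * np.log10(pxx + 1e-300)
    top = min(top_hz, sr / 2.0)
    low = (f >= 0) & (f < band_edge_hz)
    high = (f >= band_edge_hz) & (f <= top)
    if not low.any() or not high.any():
        raise MeasureUndefined("band_empty")
    slope = float(ltas[low].mean() - ltas[high].mean())
    mask = f <= top
    b, a = np.polyfit(f[mask], ltas[mask], 1)
    line = b * f + a
    tilt = float(line[low].mean() - line[high].mean())
    return slope, tilt


def _voiced_concatenation(clip: AudioClip, need_s: float = 3.0) -> np.ndarray:
    """Concatenate voiced-frame sample spans, up to ``need_s`` seconds."""
    pitch = track_pitch(clip)
    sr = clip.sample_rate
    hop = pitch.step or 0.01
    pieces = []
    got = 0
    need = int(need_s * sr)
    for a, b in _bool_runs(pitch.voiced):
        i0 = int(max(0, (pitch.times[a] - hop / 2) * sr))
        i1 = int(min(clip.samples.size, (pitch.times[b - 1] + hop / 2) * sr))
        pieces.append(clip.samples[i0:i1])
        got += i1 - i0
        if got >= need:
            break
    if not pieces:
        return np.array([])
    return np.concatenate(pieces)[:need]


def avqi(vowel_clip: AudioClip, speech_clip: AudioClip,
         coeffs: AvqiCoefficients | None = None) -> AvqiResult:
    """Acoustic Voice Quality Index on 3 s vowel + 3 s voiced speech.

    The central 3 s of the sustained vowel and the first 3 s of voiced
    material from the connected-speech clip are concatenated; the six
    parameters (CPPS, HNR, shimmer % and dB, LTAS slope and tilt) are
    computed on the concatenation and combined linearly; the score is
    clipped to [0, 10] with a warning when the raw value falls outside.
    """
    if coeffs is None:
        coeffs = load_avqi_coefficients()
    sr = vowel_clip.sample_rate
    if vowel_clip.duration < 3.0:
        raise MeasureUndefined("insufficient_vowel", "need 3 s of phonation")
    mid = vowel_clip.samples.size // 2
    half = int(1.5 * sr)
    vowel3 = vowel_clip.samples[max(0, mid - half):mid + half]

    sp = speech_clip
    if sp.sample_rate != sr:
        t_old = np.arange(sp.samples.size) / sp.sample_rate
        t_new = np.arange(int(sp.duration * sr)) / sr
        sp = AudioClip(np.interp(t_new, t_old, sp.samples), sr)
    speech3 = _voiced_concatenation(sp, 3.0)
    if speech3.size < 3.0 * sr:
        raise MeasureUndefined("insufficient_speech",
                               "need 3 s of voiced connected speech")

    concat = AudioClip(np.concatenate([vowel3, speech3]), sr)
    pitch = track_pitch(concat)
    from .core_signal import extract_periods  # local import avoids cycle noise

    periods = extract_periods(concat, pitch)
    sh_pct, sh_db = shimmer_local(periods)
    h = hnr(concat, pitch)
    c = cpps(concat)
    slope, tilt = ltas_features(concat)

    raw = coeffs.scale * (
        coeffs.intercept + coeffs.cpps * c + coeffs.hnr * h
        + coeffs.shimmer_pct * sh_pct + coeffs.shimmer_db * sh_db
        + coeffs.ltas_slope * slope + coeffs.ltas_tilt * tilt)
    score = float(np.clip(raw, 0.0, 10.0))
    clipped = score != raw
    if clipped:
        warnings.warn(f"AVQI raw score {raw:.2f} outside [0, 10]; clipped")
    return AvqiResult(score=score, raw_score=float(raw),
                      parameters={"cpps_db": c, "hnr_db": h,
                                  "shimmer_local_pct": sh_pct,
                                  "shimmer_local_db": sh_db,
                                  "ltas_slope_db": slope,
                                  "ltas_tilt_db": tilt},
                      clipped=clipped, version_label=coeffs.version_label)


def voice_quality_battery(clip: AudioClip,
                          pitch: PitchContour | None = None) -> VoiceQualityResult:
    """All single-clip voice-quality measures, with per-measure reason codes."""
    from .core_signal import extract_periods

    result = VoiceQualityResult()
    if pitch is None:
        pitch = track_pitch(clip)
    periods = extract_periods(clip, pitch)
    for name, fn in [("jitter_local_pct", lambda: jitter_local(periods)),
                     ("hnr_db", lambda: hnr(clip, pitch)),
                     ("cpps_db", lambda: cpps(clip))]:
        try:
            setattr(result, name, fn())
        except MeasureUndefined as exc:
            result.reasons[name] = exc.reason
    try:
        pct, db = shimmer_local(periods)
        result.shimmer_local_pct, result.shimmer_local_db = pct, db
    except MeasureUndefined as exc:
        result.reasons["shimmer_local_pct"] = exc.reason
    try:
        result.ltas_slope_db, result.ltas_tilt_db = ltas_features(clip)
    except MeasureUndefined as exc:
        result.reasons["ltas_slope_db"] = exc.reason
    return result
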