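"""Low-level acoustic primitives.

Framewise pitch tracking (normalized autocorrelation with octave-cost bias
and Viterbi path smoothing), intensity contours, per-cycle period/amplitude
extraction for perturbation measures, voice-break / octave-jump flagging,
and semitone conversion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io_formats import AudioClip

__all__ = [
    "PitchContour",
    "IntensityContour",
    "PeriodSequence",
    "ArtifactFlags",
    "track_pitch",
    "intensity_contour",
    "extract_periods",
    "flag_artifacts",
    "hz_to_semitones",
]

#: Defaults (conventions; the measurement protocol this emulates relied on
#: interactive correction, modeled here as the `correction` override table).
DEFAULT_F_MIN = 60.0
DEFAULT_F_MAX = 600.0
DEFAULT_VOICING_THRESHOLD = 0.45
DEFAULT_OCTAVE_COST = 0.02
DEFAULT_OCTAVE_JUMP_COST = 0.25
DEFAULT_SILENCE_THRESHOLD = 0.01
INTENSITY_FLOOR_DB = -120.0


def hz_to_semitones(f: float | np.ndarray, ref: float = 1.0):
    """Convert frequency to semitones re `ref`: 12·log2(f/ref)."""
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0) or ref <= 0:
        raise ValueError("frequencies must be positive for semitone conversion")
    out = 12.0 * np.log2(f / ref)
    return float(out) if out.ndim == 0 else out


@dataclass
class PitchContour:
    """Framewise F0 track: times (s), f0_hz (NaN where unvoiced), voicing flags."""

    times: np.ndarray
    f0_hz: np.ndarray
    voiced: np.ndarray
    strength: np.ndarray | None = None  # periodicity strength per frame

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.f0_hz = np.asarray(self.f0_hz, dtype=float)
        self.voiced = np.asarray(self.voiced, dtype=bool)

    @property
    def step(self) -> float:
        return float(self.times[1] - self.times[0]) if self.times.size > 1 else 0.0

    @property
    def f0_st(self) -> np.ndarray:
        """F0 in semitones re 1 Hz; NaN where unvoiced."""
        out = np.full_like(self.f0_hz, np.nan)
        v = self.voiced & (self.f0_hz > 0)
        out[v] = 12.0 * np.log2(self.f0_hz[v])
        return out

    def f0_at(self, t: float) -> float:
        """Nearest-frame F0 (NaN if unvoiced)."""
        i = int(np.clip(np.searchsorted(self.times, t), 0, self.times.size - 1))
        if i > 0 and abs(self.times[i - 1] - t) < abs(self.times[i] - t):
            i -= 1
        return float(self.f0_hz[i]) if self.voiced[i] else float("nan")


@dataclass
class IntensityContour:
    """Framewise level in dB (re full scale + calibration offset)."""

    times: np.ndarray
    level_db: np.ndarray
    calibration_offset_db: float = 0.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.level_db = np.asarray(self.level_db, dtype=float)

    @property
    def step(self) -> float:
        return float(self.times[1] - self.times[0]) if self.times.size > 1 else 0.0


@dataclass
class PeriodSequence:
    """Per-cycle glottal periods and peak amplitudes."""

    cycle_starts: np.ndarray
    periods: np.ndarray
    peak_amplitudes: np.ndarray

    def __post_init__(self) -> None:
        self.cycle_starts = np.asarray(self.cycle_starts, dtype=float)
        self.periods = np.asarray(self.periods, dtype=float)
        self.peak_amplitudes = np.asarray(self.peak_amplitudes, dtype=float)

    def __len__(self) -> int:
        return self.periods.size


@dataclass
class ArtifactFlags:
    """Per-frame voice-break and octave-jump flags (aligned to a PitchContour)."""

    voice_break_frames: np.ndarray
    octave_jump_frames: np.ndarray


def _frame_signal(x: np.ndarray, frame_len: int, hop: int) -> np.ndarray:
    n = 1 + max(0, (x.size - frame_len)) // hop
    idx = np.arange(frame_len)[None, :] + hop * np.arange(n)[:, None]
    return x[idx]


def track_pitch(
    clip: AudioClip,
    f_min: float = DEFAULT_F_MIN,
    f_max: float = DEFAULT_F_MAX,
    hop_s: float = 0.01,
    voicing_threshold: float = DEFAULT_VOICING_THRESHOLD,
    octave_cost: float = DEFAULT_OCTAVE_COST,
    octave_jump_cost: float = DEFAULT_OCTAVE_JUMP_COST,
    silence_threshold: float = DEFAULT_SILENCE_THRESHOLD,
    correction: dict[float, float | None] | None = None,
) -> PitchContour:
    """Track F0 by normalized autocorrelation with path smoothing.

    Each frame (length 3/f_min, Hann-windowed) yields pitch candidates from
    local maxima of the window-compensated normalized autocorrelation in the
    lag range [1/f_max, 1/f_min], refined by parabolic interpolation. A
    higher-F0 bias (``octave_cost``) and a Viterbi pass with transition cost
    ``octave_jump_cost``·|Δlog2 F0| pick the path; frames whose best
    candidate strength falls below ``voicing_threshold``, or whose amplitude
    is below ``silence_threshold`` of the clip peak, are unvoiced.

    ``correction`` is an optional override table {frame_time_s: f0_hz or
    None} applied last; None forces a frame unvoiced. It stands in for the
    interactive pitch correction of a human analyst.
    """
    if not f_min < f_max:
        raise ValueError("f_min must be < f_max")
    x = clip.samples
    sr = clip.sample_rate
    frame_len = int(round(3.0 / f_min * sr))
    hop = max(1, int(round(hop_s * sr)))
    if x.size < frame_len:
        x = np.pad(x, (0, frame_len - x.size))
    frames = _frame_signal(x, frame_len, hop)
    n_frames = frames.shape[0]
    times = (np.arange(n_frames) * hop + frame_len / 2) / sr

    window = np.hanning(frame_len)
    # Window autocorrelation for Boersma-style normalization.
    nfft = 1 << int(math.ceil(math.log2(2 * frame_len)))
    w_ac = np.fft.irfft(np.abs(np.fft.rfft(window, nfft)) ** 2)[:frame_len]
    w_ac /= w_ac[0]

    lag_min = max(2, int(math.floor(sr / f_max)))
    lag_max = min(frame_len - 2, int(math.ceil(sr / f_min)))

    global_peak = float(np.max(np.abs(x))) or 1.0
    n_cand = 4
    cand_f0 = np.zeros((n_frames, n_cand))
    cand_str = np.full((n_frames, n_cand), -np.inf)

    fw = (frames - frames.mean(axis=1, keepdims=True)) * window
    spec = np.fft.rfft(fw, nfft, axis=1)
    ac = np.fft.irfft(np.abs(spec) ** 2, axis=1)[:, :frame_len]
    r0 = ac[:, 0].copy()
    r0[r0 <= 0] = 1.0
    acn = ac / r0[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        acn = np.where(w_ac[None, :] > 0.25, acn / w_ac[None, :], 0.0)
    acn = np.clip(acn, -1.0, 1.0)

    frame_peak = np.max(np.abs(frames), axis=1)
    silent = frame_peak < silence_threshold * global_peak

    for fi in range(n_frames):
        if silent[fi]:
            continue
        r = acn[fi]
        seg = r[lag_min:lag_max + 1]
        # local maxima
        locs = np.flatnonzero((seg[1:-1] > seg[:-2]) & (seg[1:-1] >= seg[2:])) + 1
        if locs.size == 0:
            continue
        # rank candidates by the octave-cost-biased score: subharmonic lags
        # of a periodic frame all reach r ~ 1, so raw r cannot separate them
        biased = seg[locs] + octave_cost * np.log2((sr / (lag_min + locs)) / f_max)
        order = np.argsort(biased)[::-1][:n_cand]
        for ci, li in enumerate(locs[order]):
            lag = lag_min + li
            y0, y1, y2 = r[lag - 1], r[lag], r[lag + 1]
            denom = y0 - 2 * y1 + y2
            delta = 0.5 * (y0 - y2) / denom if abs(denom) > 1e-12 else 0.0
            delta = float(np.clip(delta, -0.5, 0.5))
            lag_ref = lag + delta
            strength = y1 - 0.25 * (y0 - y2) * delta
            f0 = sr / lag_ref
            if not (f_min * 0.9 <= f0 <= f_max * 1.1):
                continue
            cand_f0[fi, ci] = f0
            cand_str[fi, ci] = strength + octave_cost * math.log2(f0 / f_max)

    # Viterbi over candidates + an explicit unvoiced state (index n_cand).
    n_states = n_cand + 1
    delta_cost = np.full((n_frames, n_states), np.inf)
    back = np.zeros((n_frames, n_states), dtype=int)
    UNVOICED_SCORE = voicing_threshold

    def local_cost(fi: int, s: int) -> float:
        if s == n_cand:
            return -UNVOICED_SCORE
        if cand_str[fi, s] == -np.inf:
            return np.inf
        return -cand_str[fi, s]

    for s in range(n_states):
        delta_cost[0, s] = local_cost(0, s)
    for fi in range(1, n_frames):
        for s in range(n_states):
            lc = local_cost(fi, s)
            if lc == np.inf:
                continue
            best, best_prev = np.inf, 0
            for sp in range(n_states):
                prev = delta_cost[fi - 1, sp]
                if prev == np.inf:
                    continue
                trans = 0.0
                if s < n_cand and sp < n_cand:
                    trans = octave_jump_cost * abs(
                        math.log2(cand_f0[fi, s] / cand_f0[fi - 1, sp]))
                elif (s < n_cand) != (sp < n_cand):
                    trans = 0.14  # voiced/unvoiced switching cost
                total = prev + trans
                if total < best:
                    best, best_prev = total, sp
            delta_cost[fi, s] = best + lc
            back[fi, s] = best_prev

    path = np.zeros(n_frames, dtype=int)
    path[-1] = int(np.argmin(delta_cost[-1]))
    for fi in range(n_frames - 2, -1, -1):
        path[fi] = back[fi + 1, path[fi + 1]]

    f0_out = np.full(n_frames, np.nan)
    voiced = np.zeros(n_frames, dtype=bool)
    strength_out = np.zeros(n_frames)
    for fi in range(n_frames):
        s = path[fi]
        if s < n_cand and cand_str[fi, s] > -np.inf:
            # voicing decision on the raw strength, not the biased score
            if cand_str[fi, s] >= voicing_threshold and not silent[fi]:
                f0_out[fi] = cand_f0[fi, s]
                voiced[fi] = True
                strength_out[fi] = cand_str[fi, s]

    if correction:
        for t, val in correction.items():
            i = int(np.argmin(np.abs(times - t)))
            if val is None or (isinstance(val, float) and math.isnan(val)):
                voiced[i] = False
                f0_out[i] = np.nan
            else:
                voiced[i] = True
                f0_out[i] = float(val)

    return PitchContour(times, f0_out, voiced, strength_out)


def intensity_contour(
    clip: AudioClip,
    frame_s: float = 0.04,
    hop_s: float = 0.01,
    calibration_offset_db: float = 0.0,
) -> IntensityContour:
    """Framewise RMS level in dB over raised-cosine-windowed frames.

    level = 20·log10(RMS_w) + calibration_offset_db, where RMS_w is the
    window-weighted root mean square; degenerate frames are floored at
    -120 dB (before the offset).
    """
    x = clip.samples
    sr = clip.sample_rate
    frame_len = max(4, int(round(frame_s * sr)))
    hop = max(1, int(round(hop_s * sr)))
    if x.size < frame_len:
        x = np.pad(x, (0, frame_len - x.size))
    frames = _frame_signal(x, frame_len, hop)
    times = (np.arange(frames.shape[0]) * hop + frame_len / 2) / sr
    w = np.hanning(frame_len)
    ms = (frames ** 2 * w).sum(axis=1) / w.sum()
    with np.errstate(divide="ignore"):
        level = 10.0 * np.log10(ms)
    level = np.maximum(level, INTENSITY_FLOOR_DB) + calibration_offset_db
    return IntensityContour(times, level, calibration_offset_db)


def _lp_residual(x: np.ndarray, sr: int, order: int | None = None) -> np.ndarray:
    """Linear-prediction residual (autocorrelation method).

    Inverse filtering concentrates each glottal excitation into a sharp
    spike, which makes epoch detection robust to the multi-peaked cycle
    shapes that formant ringing produces.
    """
    from scipy.linalg import solve_toeplitz
    from scipy.signal import lfilter

    if order is None:
        order = min(2 + sr // 1000, 24)
    xw = x - x.mean()
    r = np.correlate(xw, xw, mode="full")[xw.size - 1:xw.size + order]
    if r[0] <= 0:
        return x.copy()
    r = r / r[0]
    try:
        a = solve_toeplitz((r[:-1], r[:-1]), r[1:])
    except np.linalg.LinAlgError:
        return x.copy()
    return lfilter(np.concatenate([[1.0], -a]), [1.0], x)


def extract_periods(clip: AudioClip, pitch: PitchContour) -> PeriodSequence:
    """Locate glottal cycles by epoch detection on the LP residual.

    Within each voiced run of the pitch contour, successive excitation
    spikes of the linear-prediction residual are found one expected period
    apart (search window ±30% of the local period from the F0 track) and
    refined to sub-sample precision by parabolic interpolation. The
    per-cycle amplitude is the absolute waveform extreme inside [epoch,
    epoch + 0.8·period], a window that contains exactly one excitation's
    response. Cycles never span unvoiced frames: epochs stay within single
    voiced runs.
    """
    x = clip.samples
    sr = clip.sample_rate
    voiced = pitch.voiced.copy()
    if not voiced.any():
        return PeriodSequence(np.array([]), np.array([]), np.array([]))

    # bridge brief tracker dropouts (a true voice break is much longer than
    # a couple of frames); epochs may cross them, real breaks still split runs
    step = pitch.step or 0.01
    max_gap = max(1, int(round(0.04 / step)))
    gaps = [(a, b) for a, b in _bool_runs(~voiced) if (b - a) <= max_gap]
    for a, b in gaps:
        if a > 0 and b < voiced.size:
            voiced[a:b] = True

    res = np.abs(_lp_residual(x, sr))
    peak_times: list[float] = []
    peak_amps: list[float] = []
    peak_periods: list[float] = []

    def refine(p: int) -> float:
        if 0 < p < res.size - 1:
            y0, y1, y2 = res[p - 1], res[p], res[p + 1]
            den = y0 - 2 * y1 + y2
            if abs(den) > 1e-12:
                return p + float(np.clip(0.5 * (y0 - y2) / den, -0.5, 0.5))
        return float(p)

    for start_f, end_f in _bool_runs(voiced):
        t0 = pitch.times[start_f]
        t1 = pitch.times[end_f - 1]
        f0_local = pitch.f0_hz[start_f:end_f].copy()
        t_local = pitch.times[start_f:end_f]
        f0_med = float(np.nanmedian(f0_local))
        if not f0_med > 0:
            continue
        # guard the guidance track against octave errors and bridged NaNs
        bad = ~np.isfinite(f0_local)
        with np.errstate(invalid="ignore"):
            bad |= np.abs(12.0 * np.log2(np.where(bad, f0_med, f0_local)
                                         / f0_med)) > 5.0
        f0_local[bad] = f0_med

        def f0_at(t: float) -> float:
            return float(np.interp(t, t_local, f0_local))

        T = 1.0 / f0_at(t0)
        i0 = max(0, int(t0 * sr))
        i1 = min(res.size - 1, int((t0 + 1.5 * T) * sr))
        if i1 - i0 < 3:
            continue
        m = refine(i0 + int(np.argmax(res[i0:i1])))
        epochs = [m]
        while True:
            t = epochs[-1] / sr
            T = 1.0 / f0_at(min(t, t1))
            lo = int(epochs[-1] + 0.7 * T * sr)
            hi = int(epochs[-1] + 1.3 * T * sr) + 1
            if hi > res.size or t + T > t1 + 0.5 * T or hi - lo < 3:
                break
            epochs.append(refine(lo + int(np.argmax(res[lo:hi]))))

        if len(epochs) >= 2:
            ep = np.asarray(epochs)
            pers = np.diff(ep) / sr
            for pos, per in zip(ep[:-1], pers):
                if per <= 0:
                    continue
                lo = int(pos)
                hi = min(x.size, int(pos + 0.8 * per * sr) + 1)
                amp = float(np.max(np.abs(x[lo:hi]))) if hi > lo else 0.0
                peak_times.append(pos / sr)
                peak_amps.append(amp)
                peak_periods.append(per)

    starts = np.asarray(peak_times)
    periods = np.asarray(peak_periods)
    amps = np.asarray(peak_amps)
    if starts.size == 0:
        return PeriodSequence(np.array([]), np.array([]), np.array([]))
    # drop implausible cycles (octave errors at run boundaries)
    med = float(np.median(periods))
    ok = (periods > 0.4 * med) & (periods < 2.5 * med) if med > 0 else periods > 0
    return PeriodSequence(starts[ok], periods[ok], amps[ok])


def _bool_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """[start, end) index pairs of True runs."""
    if mask.size == 0:
        return []
    d = np.diff(mask.astype(int))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts = [0] + starts
    if mask[-1]:
        ends = ends + [mask.size]
    return list(zip(starts, ends))


def flag_artifacts(pitch: PitchContour,
                   jump_threshold_st: float = 7.0) -> ArtifactFlags:
    """Flag voice breaks and octave jumps in a pitch contour.

    A voice break is an unvoiced frame strictly inside the span from first
    to last voiced frame. An octave jump flags both frames of any
    consecutive voiced pair whose |ΔF0| is at least ``jump_threshold_st``
    semitones.
    """
    voiced = pitch.voiced
    n = voiced.size
    breaks = np.zeros(n, dtype=bool)
    jumps = np.zeros(n, dtype=bool)
    vi = np.flatnonzero(voiced)
    if vi.size == 0:
        return ArtifactFlags(breaks, jumps)
    breaks[vi[0]:vi[-1] + 1] = ~voiced[vi[0]:vi[-1] + 1]
    st = pitch.f0_st
    for a, b in zip(vi[:-1], vi[1:]):
        if b - a == 1 and abs(st[b] - st[a]) >= jump_threshold_st:
            jumps[a] = True
            jumps[b] = True
    return ArtifactFlags(breaks, jumps)
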