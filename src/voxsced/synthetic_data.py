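"""Ground-truth signal and study generators.

Synthetic sustained vowels, pitch glides and passage-like speech with
controlled F0, jitter, shimmer and harmonics-to-noise ratio, plus
multi-session measure series with known baseline trend and treatment
effects. Every injected quantity is returned in a TruthRecord so the
analysis modules can be verified without patient audio.

The source model is a band-limited impulse train (windowed-sinc pulses at
sub-sample-accurate instants) driving a cascade of two-pole formant
resonators; additive Gaussian noise is injected at the source, scaled to a
target harmonic-to-noise power ratio, and filtered through the same
resonators so harmonic and noise components share a spectral envelope.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .io_formats import AudioClip, AnnotationTier
from .sced_stats import PhaseSeries

__all__ = [
    "VowelSpec",
    "GlideSpec",
    "PassageSpec",
    "ScedSpec",
    "TruthRecord",
    "synth_vowel",
    "synth_glide",
    "synth_passage",
    "synth_sced",
    "make_synthetic_study",
]

DEFAULT_SR = 16000
#: /a/-like resonances (center Hz, bandwidth Hz)
DEFAULT_FORMANTS = ((700.0, 110.0), (1220.0, 120.0))
#: i.i.d. Gaussian perturbation of sd s has E|x_{i+1}-x_i| = (2/sqrt(pi))·s;
#: scaling the injected sd by sqrt(pi)/2 makes the expected *local*
#: jitter/shimmer equal the nominal percentage
LOCAL_CAL = 0.8862269254527580
PHASES = ("Pre", "Post", "FU1", "FU2", "FU3")


@dataclass
class TruthRecord:
    """Injected ground-truth values for one synthetic artifact."""

    params: dict = field(default_factory=dict)

    def __getitem__(self, key):
        return self.params[key]

    def get(self, key, default=None):
        return self.params.get(key, default)


@dataclass
class VowelSpec:
    """Sustained-vowel synthesis parameters.

    ``jitter_pct`` / ``shimmer_pct`` are the *local* jitter/shimmer the
    rendered signal is calibrated to carry: cycles get i.i.d. Gaussian
    period/amplitude perturbations whose sd is scaled by sqrt(pi)/2 so that
    the expected mean absolute consecutive difference — the local measure —
    equals the nominal percentage. ``target_hnr_db`` sets the
    harmonic-to-noise power ratio of the source before formant filtering.
    """

    f0_hz: float = 150.0
    duration_s: float = 2.0
    jitter_pct: float = 0.5
    shimmer_pct: float = 3.0
    target_hnr_db: float = 25.0
    formants: Sequence[tuple[float, float]] = DEFAULT_FORMANTS
    sample_rate: int = DEFAULT_SR
    lead_silence_s: float = 0.0
    trail_silence_s: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.duration_s < 0.5:
            raise ValueError("vowel duration must be >= 0.5 s")
        if self.jitter_pct < 0 or self.shimmer_pct < 0:
            raise ValueError("perturbation percentages must be >= 0")
        if self.f0_hz <= 0:
            raise ValueError("f0 must be positive")


@dataclass
class GlideSpec:
    """Pitch-glide synthesis: onset plateau, glide, terminal hold.

    The 0.5 s onset plateau at ``start_f0_hz`` models the habitual-pitch
    stretch at the start of the task; the terminal hold defaults to the
    protocol's 2 s.
    """

    start_f0_hz: float = 200.0
    peak_f0_hz: float = 400.0
    glide_duration_s: float = 1.5
    hold_duration_s: float = 2.0
    onset_hold_s: float = 0.5
    direction: str = "up"
    jitter_pct: float = 0.2
    shimmer_pct: float = 1.0
    target_hnr_db: float = 30.0
    voice_breaks: Sequence[tuple[float, float]] = ()
    octave_jumps: Sequence[tuple[float, float]] = ()
    formants: Sequence[tuple[float, float]] = DEFAULT_FORMANTS
    sample_rate: int = DEFAULT_SR
    seed: int = 0

    def validate(self) -> None:
        if self.peak_f0_hz == self.start_f0_hz:
            raise ValueError("peak F0 must differ from start F0")
        if self.hold_duration_s < 0:
            raise ValueError("hold duration must be >= 0")


@dataclass
class PassageSpec:
    """Passage-like speech: alternating speech/silence spans with
    syllable-level amplitude modulation."""

    pattern: Sequence[tuple[str, float]] = (("speech", 2.0), ("silence", 0.5),
                                            ("speech", 1.5))
    syllables_per_span: Sequence[int] = (6, 5)
    f0_hz: float = 120.0
    syllable_gains_db: Sequence[Sequence[float]] | None = None
    verb_final_every: int = 4
    target_hnr_db: float = 25.0
    formants: Sequence[tuple[float, float]] = DEFAULT_FORMANTS
    sample_rate: int = DEFAULT_SR
    seed: int = 0


@dataclass
class ScedSpec:
    """Multi-session measure series with baseline trend and treatment effect.

    y = mu + beta·t + delta·1[phase >= Post] + eps, eps ~ N(0, sigma²);
    t is the session index continuing across phases (baseline continuation).
    """

    baseline_mean: float = 70.0
    baseline_trend: float = 0.0
    treatment_effect: float = 0.0
    noise_sd: float = 1.0
    sessions_per_phase: Sequence[int] = (3, 3, 3, 3, 3)
    trials_per_session: int = 1
    effect_decay: Sequence[float] | None = None  # per post-phase multiplier
    seed: int = 0

    def validate(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if any(s < 1 for s in self.sessions_per_phase):
            raise ValueError("session counts must be >= 1")


# ---------------------------------------------------------------------------
# source synthesis
# ---------------------------------------------------------------------------

def _place_pulse(buf: np.ndarray, t: float, amp: float, sr: int,
                 half_width: int = 16) -> None:
    """Add a Hann-windowed sinc pulse at fractional time t (seconds)."""
    center = t * sr
    n0 = int(np.floor(center)) - half_width
    n = np.arange(n0, n0 + 2 * half_width + 1)
    valid = (n >= 0) & (n < buf.size)
    if not valid.any():
        return
    arg = n[valid] - center
    w = 0.5 * (1 + np.cos(np.pi * arg / (half_width + 1)))
    buf[n[valid]] += amp * np.sinc(arg) * w


def _resonator_cascade(x: np.ndarray, formants, sr: int) -> np.ndarray:
    from scipy.signal import lfilter

    y = x
    for fc, bw in formants:
        r = np.exp(-np.pi * bw / sr)
        theta = 2 * np.pi * fc / sr
        a = [1.0, -2 * r * np.cos(theta), r * r]
        gain = 1 - r  # rough level normalization
        y = lfilter([gain], a, y)
    return y


def _voiced_source(pulse_times: np.ndarray, pulse_amps: np.ndarray,
                   n_samples: int, sr: int) -> np.ndarray:
    src = np.zeros(n_samples)
    for t, a in zip(pulse_times, pulse_amps):
        _place_pulse(src, t, a, sr)
    return src


def _add_source_noise(src: np.ndarray, active: slice, hnr_db: float,
                      rng: np.random.Generator) -> np.ndarray:
    p_harm = float(np.mean(src[active] ** 2))
    if p_harm <= 0:
        raise ValueError("no harmonic energy; cannot calibrate HNR")
    p_noise = p_harm / (10.0 ** (hnr_db / 10.0))
    noise = np.zeros_like(src)
    noise[active] = rng.normal(0.0, np.sqrt(p_noise), active.stop - active.start)
    return src + noise


def _normalize(x: np.ndarray, peak: float = 0.8) -> np.ndarray:
    m = np.max(np.abs(x))
    return x * (peak / m) if m > 0 else x


def synth_vowel(spec: VowelSpec) -> tuple[AudioClip, TruthRecord]:
    """Render a sustained vowel with controlled perturbations.

    Same spec + seed always yields the identical waveform.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    sr = spec.sample_rate
    T0 = 1.0 / spec.f0_hz

    times, amps = [], []
    t = T0  # leave headroom for the pulse kernel
    while t < spec.duration_s - T0:
        times.append(t)
        amps.append(max(0.05, 1.0 + LOCAL_CAL * (spec.shimmer_pct / 100.0)
                        * rng.normal()))
        t += T0 * max(0.2, 1.0 + LOCAL_CAL * (spec.jitter_pct / 100.0)
                      * rng.normal())
    times = np.asarray(times)
    amps = np.asarray(amps)

    n_total = int(round((spec.lead_silence_s + spec.duration_s
                         + spec.trail_silence_s) * sr))
    offset = spec.lead_silence_s
    n_voiced = int(round(spec.duration_s * sr))
    src = np.zeros(n_total)
    seg = np.zeros(n_voiced)
    for tt, aa in zip(times, amps):
        _place_pulse(seg, tt, aa, sr)
    i0 = int(round(offset * sr))
    active = slice(i0, i0 + n_voiced)
    src[active] = seg
    src = _add_source_noise(src, active, spec.target_hnr_db, rng)
    out = _normalize(_resonator_cascade(src, spec.formants, sr))

    truth = TruthRecord({
        "f0_hz": spec.f0_hz,
        "jitter_pct": spec.jitter_pct,
        "shimmer_pct": spec.shimmer_pct,
        "target_hnr_db": spec.target_hnr_db,
        "pulse_times": times + offset,
        "pulse_amps": amps,
        "duration_s": spec.duration_s,
        "lead_silence_s": spec.lead_silence_s,
    })
    return AudioClip(out, sr, task_label="sustained"), truth


def synth_glide(spec: GlideSpec) -> tuple[AudioClip, TruthRecord]:
    """Render a pitch glide with an onset plateau and a terminal hold.

    Optional voice breaks (source silenced) and momentary octave jumps
    (F0 doubled) can be injected as (start_s, duration_s) spans.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    sr = spec.sample_rate
    total = spec.onset_hold_s + spec.glide_duration_s + spec.hold_duration_s

    log_start = np.log2(spec.start_f0_hz)
    log_peak = np.log2(spec.peak_f0_hz)

    def f0_of(t: float) -> float:
        if t < spec.onset_hold_s:
            f = spec.start_f0_hz
        elif t < spec.onset_hold_s + spec.glide_duration_s:
            frac = (t - spec.onset_hold_s) / spec.glide_duration_s
            f = 2.0 ** (log_start + frac * (log_peak - log_start))
        else:
            f = spec.peak_f0_hz
        for s0, d in spec.octave_jumps:
            if s0 <= t < s0 + d:
                f *= 2.0
        return f

    times, amps = [], []
    t = 1.0 / spec.start_f0_hz
    while t < total - 0.01:
        in_break = any(s0 <= t < s0 + d for s0, d in spec.voice_breaks)
        if not in_break:
            times.append(t)
            amps.append(max(0.05, 1.0 + LOCAL_CAL * (spec.shimmer_pct / 100.0)
                            * rng.normal()))
        T = 1.0 / f0_of(t)
        t += T * max(0.2, 1.0 + LOCAL_CAL * (spec.jitter_pct / 100.0)
                     * rng.normal())
    times = np.asarray(times)
    amps = np.asarray(amps)

    n_total = int(round(total * sr))
    src = _voiced_source(times, amps, n_total, sr)
    src = _add_source_noise(src, slice(0, n_total), spec.target_hnr_db, rng)
    out = _normalize(_resonator_cascade(src, spec.formants, sr))

    grid = np.arange(0.0, total, 0.001)
    truth = TruthRecord({
        "start_f0_hz": spec.start_f0_hz,
        "peak_f0_hz": spec.peak_f0_hz,
        "direction": spec.direction,
        "range_st": abs(12.0 * (log_peak - log_start)),
        "f0_trajectory": (grid, np.array([f0_of(t) for t in grid])),
        "hold_duration_s": spec.hold_duration_s,
        "onset_hold_s": spec.onset_hold_s,
        "voice_breaks": tuple(spec.voice_breaks),
        "octave_jumps": tuple(spec.octave_jumps),
    })
    task = "glide_up" if spec.direction == "up" else "glide_down"
    return AudioClip(out, sr, task_label=task), truth


def synth_passage(spec: PassageSpec) -> tuple[AudioClip, dict[str, AnnotationTier], TruthRecord]:
    """Render passage-like speech from a speech/silence pattern.

    Each speech span carries its planned number of syllable-like
    amplitude-modulated voiced bursts; the inter-syllable envelope dips stay
    well above the silence-detection floor so only the pattern's silence
    spans segment as pauses. Returns the audio, "vowels" and "verb_final"
    annotation tiers, and the ground truth (pause set, segment durations,
    syllable counts, per-vowel peak gains in dB).
    """
    rng = np.random.default_rng(spec.seed)
    sr = spec.sample_rate
    total = sum(d for _, d in spec.pattern)
    n_total = int(round(total * sr))

    speech_spans: list[tuple[float, float]] = []
    silence_spans: list[tuple[float, float]] = []
    cursor = 0.0
    for kind, dur in spec.pattern:
        span = (cursor, cursor + dur)
        (speech_spans if kind == "speech" else silence_spans).append(span)
        cursor += dur
    if len(spec.syllables_per_span) != len(speech_spans):
        raise ValueError("syllable plan length must match number of speech spans")

    # per-syllable gains (dB re the nominal syllable level)
    gains_db: list[list[float]] = []
    if spec.syllable_gains_db is not None:
        gains_db = [list(g) for g in spec.syllable_gains_db]
        if [len(g) for g in gains_db] != list(spec.syllables_per_span):
            raise ValueError("syllable_gains_db shape must match syllable plan")
    else:
        for n_syl in spec.syllables_per_span:
            gains_db.append(list(rng.uniform(-2.0, 2.0, n_syl)))

    env = np.zeros(n_total)
    vowel_ivs: list[tuple[float, float, str]] = []
    verb_ivs: list[tuple[float, float, str]] = []
    syl_index = 0
    for (a, b), n_syl, g_db in zip(speech_spans, spec.syllables_per_span, gains_db):
        syl_dur = (b - a) / n_syl
        tgrid = np.arange(int(a * sr), int(b * sr))
        local = (tgrid / sr - a) / syl_dur
        # raised-cosine syllable envelope dipping to 0.35 (≈ -9 dB), above
        # the -25 dB adaptive silence threshold
        base_env = 0.35 + 0.65 * 0.5 * (1 - np.cos(2 * np.pi * local))
        gain_lin = np.ones_like(base_env)
        for k in range(n_syl):
            s0, s1 = a + k * syl_dur, a + (k + 1) * syl_dur
            m = (tgrid / sr >= s0) & (tgrid / sr < s1)
            gain_lin[m] = 10.0 ** (g_db[k] / 20.0)
            core = 0.25 * syl_dur
            vowel_ivs.append((s0 + core, s1 - core, f"v{syl_index}"))
            if spec.verb_final_every and (syl_index % spec.verb_final_every
                                          == spec.verb_final_every - 1):
                verb_ivs.append((s0 + core, s1 - core, f"vf{syl_index}"))
            syl_index += 1
        env[tgrid] = base_env * gain_lin

    # voiced source across speech spans
    times, amps = [], []
    for a, b in speech_spans:
        t = a + 1.0 / spec.f0_hz
        while t < b - 1.0 / spec.f0_hz:
            times.append(t)
            amps.append(1.0)
            t += (1.0 / spec.f0_hz) * (1.0 + 0.002 * rng.normal())
    src = _voiced_source(np.asarray(times), np.asarray(amps), n_total, sr)
    src *= env
    active = slice(0, n_total)
    p_harm = float(np.mean(src[active] ** 2))
    p_noise = p_harm / (10.0 ** (spec.target_hnr_db / 10.0))
    noise = rng.normal(0.0, np.sqrt(p_noise), n_total) * np.maximum(env, 0.0)
    src = src + noise
    out = _normalize(_resonator_cascade(src, spec.formants, sr))

    tiers = {
        "vowels": AnnotationTier("vowels", vowel_ivs),
        "verb_final": AnnotationTier("verb_final", verb_ivs),
    }
    truth = TruthRecord({
        "speech_spans": speech_spans,
        "silence_spans": silence_spans,
        "pauses_ge_200ms": [s for s in silence_spans if s[1] - s[0] >= 0.2],
        "segment_durations": _merged_segments(speech_spans, silence_spans),
        "n_syllables": int(sum(spec.syllables_per_span)),
        "syllable_gains_db": gains_db,
        "total_duration_s": total,
    })
    return AudioClip(out, sr, task_label="passage"), tiers, truth


def _merged_segments(speech_spans, silence_spans) -> list[float]:
    """Speech-segment durations after merging across sub-200 ms silences."""
    events = sorted(speech_spans + [s for s in silence_spans
                                    if s[1] - s[0] < 0.2])
    merged: list[list[float]] = []
    for a, b in events:
        if merged and abs(merged[-1][1] - a) < 1e-9:
            merged[-1][1] = b
        else:
            merged.append([a, b])
    # drop leading/trailing sub-threshold silences that are not inside speech
    speech_set = set()
    for a, b in speech_spans:
        speech_set.add((round(a, 6), round(b, 6)))
    out = []
    for a, b in merged:
        # only count spans that contain at least one speech span
        if any(sa >= a - 1e-9 and sb <= b + 1e-9 for sa, sb in speech_spans):
            out.append(b - a)
    return out


def synth_sced(spec: ScedSpec, participant_id: str = "SYN01",
               measure_name: str = "measure", task_label: str = "sustained"
               ) -> dict[str, PhaseSeries]:
    """Simulate a five-phase single-case measure series.

    Returns one :class:`PhaseSeries` per phase, trials in session order.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    out: dict[str, PhaseSeries] = {}
    t = 0
    for pi, phase in enumerate(PHASES):
        n_sessions = spec.sessions_per_phase[pi]
        vals: list[float] = []
        for _ in range(n_sessions):
            effect = 0.0
            if pi >= 1:
                decay = 1.0
                if spec.effect_decay is not None:
                    decay = spec.effect_decay[pi - 1]
                effect = spec.treatment_effect * decay
            for _ in range(spec.trials_per_session):
                vals.append(spec.baseline_mean + spec.baseline_trend * t
                            + effect + spec.noise_sd * rng.normal())
            t += 1
        out[phase] = PhaseSeries(participant_id, measure_name, task_label,
                                 phase, vals)
    return out


# ---------------------------------------------------------------------------
# full synthetic study
# ---------------------------------------------------------------------------

def make_synthetic_study(
    out_dir: str | Path,
    seed: int = 0,
    participants: Sequence[str] = ("SYN01",),
    tasks: Sequence[str] = ("sustained", "glide_up", "passage", "ddk"),
    trials_per_visit: int = 2,
    vowel_duration_s: float = 3.5,
    intensity_effect_db: float = 0.0,
    intensity_noise_db: float = 1.0,
    drop_slots: Sequence[tuple[str, str, str, int]] = (),
) -> Path:
    """Write a complete synthetic study: WAVs, TextGrids, manifest, truth.

    The treatment model injects ``intensity_effect_db`` into the sustained
    vowel's amplitude from the Post phase onward (the trained-loudness
    effect); every vowel also gets a per-recording random level perturbation
    of sd ``intensity_noise_db`` as session-to-session variability. DDK
    syllable counts vary around a stable mean with no phase effect, so DDK
    rows act as a no-effect control. ``drop_slots`` lists (participant,
    task, phase, visit) sessions to omit, emulating missing data.

    Returns the path to the manifest YAML.
    """
    import yaml

    from .io_formats import write_textgrid, write_wav

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    recordings = []
    truths = {}
    dropped = {tuple(s) for s in drop_slots}

    for part in participants:
        for task in tasks:
            for phase in PHASES:
                for visit in (1, 2, 3):
                    if (part, task, phase, visit) in dropped:
                        continue
                    treated = phase != "Pre"
                    n_trials = trials_per_visit if task in (
                        "sustained", "glide_up", "glide_down") else 1
                    if task == "ddk":
                        n_trials = 3
                    for trial in range(1, n_trials + 1):
                        stem = f"{part}_{task}_{phase}-{visit}_t{trial}"
                        rec = {"participant": part, "task": task,
                               "phase": phase, "visit": visit, "trial": trial}
                        sub_seed = int(rng.integers(0, 2**31 - 1))
                        if task == "sustained":
                            clip, tr = synth_vowel(VowelSpec(
                                f0_hz=140 + 10 * (hash(part) % 3),
                                duration_s=vowel_duration_s,
                                jitter_pct=0.5, shimmer_pct=3.0,
                                target_hnr_db=25.0, seed=sub_seed))
                            level_db = rng.normal(0.0, intensity_noise_db)
                            if treated:
                                level_db += intensity_effect_db
                            clip = clip.scaled(10.0 ** ((level_db - 6.0) / 20.0))
                            write_wav(out / f"{stem}.wav", clip)
                            rec["audio"] = f"{stem}.wav"
                            truths[stem] = {"level_offset_db": level_db,
                                            **{k: v for k, v in tr.params.items()
                                               if np.isscalar(v)}}
                        elif task in ("glide_up", "glide_down"):
                            up = task == "glide_up"
                            clip, tr = synth_glide(GlideSpec(
                                start_f0_hz=200.0,
                                peak_f0_hz=400.0 if up else 100.0,
                                direction="up" if up else "down",
                                glide_duration_s=1.0, hold_duration_s=1.0,
                                seed=sub_seed))
                            write_wav(out / f"{stem}.wav", clip)
                            rec["audio"] = f"{stem}.wav"
                            truths[stem] = {"range_st": tr["range_st"]}
                        elif task == "passage":
                            clip, tiers, tr = synth_passage(PassageSpec(
                                pattern=(("speech", 2.0), ("silence", 0.4),
                                         ("speech", 2.0)),
                                syllables_per_span=(7, 7), seed=sub_seed))
                            write_wav(out / f"{stem}.wav", clip)
                            write_textgrid(out / f"{stem}.TextGrid",
                                           list(tiers.values()),
                                           xmax=clip.duration)
                            rec["audio"] = f"{stem}.wav"
                            rec["annotation"] = f"{stem}.TextGrid"
                            rec["syllable_count"] = tr["n_syllables"]
                            rec["group_syllables"] = [7, 7]
                            truths[stem] = {"n_syllables": tr["n_syllables"]}
                        elif task in ("personalized_sentences",
                                      "standardized_sentences",
                                      "picture_description", "conversation"):
                            clip, tiers, tr = synth_passage(PassageSpec(
                                pattern=(("speech", 2.5),),
                                syllables_per_span=(8,), seed=sub_seed))
                            write_wav(out / f"{stem}.wav", clip)
                            write_textgrid(out / f"{stem}.TextGrid",
                                           list(tiers.values()),
                                           xmax=clip.duration)
                            rec["audio"] = f"{stem}.wav"
                            rec["annotation"] = f"{stem}.TextGrid"
                        elif task == "ddk":
                            rec["syllable_count"] = int(28 + rng.integers(-3, 4))
                        recordings.append(rec)

    manifest = {"participants": list(participants), "recordings": recordings}
    mpath = out / "manifest.yaml"
    mpath.write_text(yaml.safe_dump(manifest, sort_keys=False))
    (out / "truth.json").write_text(json.dumps(truths, indent=1))
    return mpath
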