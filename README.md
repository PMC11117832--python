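# voxsced

Acoustic voice and speech outcome measures with single-case experimental
design (SCED) statistics.

`voxsced` is for speech scientists and clinician-researchers who evaluate
voice/speech therapy in single-case designs — for example intensive loudness
therapy in speakers with progressive motor speech disorders — and need the
whole measurement-to-statistics chain to be scripted, auditable and testable
without access to patient audio. It provides:

- **Acoustic primitives** — autocorrelation pitch tracking with
  octave-cost/Viterbi path selection and a manual-correction override,
  intensity contours, glottal-cycle extraction on the linear-prediction
  residual, voice-break and octave-jump flagging;
- **Voice quality** — local jitter and shimmer (% and dB), HNR, smoothed
  cepstral peak prominence (CPPS), long-term-average-spectrum slope/tilt,
  and the six-parameter AVQI composite with version-labeled coefficient
  sets;
- **Task procedures** — sustained-vowel mean intensity gated by the first
  and last glottal pulse, pitch-glide stable-extreme analysis with semitone
  ranges and reversal detection, vowel-peak and verb-final-syllable
  loudness;
- **Prosody/timing** — pause segmentation (pauses ≥ 200 ms), speaking rate,
  percent pause, mean speech-segment duration, articulatory-group length,
  CV of F0 and intensity over voiced speech, DDK rates (best of three
  trials);
- **SCED statistics** — Tau-U with optional baseline-trend correction,
  exact permutation p-values (the authoritative choice at 3-visit phase
  sizes), two-way mixed-effects ICC for interrater reliability;
- **A synthetic-data generator** — vowels, glides and passage-like speech
  with controlled F0, jitter, shimmer and HNR, plus multi-session measure
  series with known trend and treatment effects, so every stage is
  verifiable against injected ground truth;
- **A pipeline and CLI** — study manifest in, per-phase Tau-U outcome table
  and QC report out.

## The statistic at the core

For a baseline phase A = (a₁…a_{n_a}) and comparison phase B, Tau-U counts
signed pairwise nonoverlap,

    S_AB = #{(i,j): b_j > a_i} − #{(i,j): b_j < a_i},    τ = S / (n_a·n_b),

optionally replacing S by S_AB − S_trend(A), where S_trend(A) is Kendall's S
within the baseline (trend correction). Alongside the usual normal
approximation with Var(S) = n_a·n_b·(n_a+n_b+1)/3, the package computes the
exact permutation p by enumerating all phase-label assignments whenever
n_a + n_b ≤ 12 — essential at single-case sizes, where the normal
approximation is unreliable and the smallest attainable two-sided p for
3-vs-3 single values is 0.10.

## Worked example

```python
from voxsced import (track_pitch, extract_periods, intensity_contour,
                     jitter_local, shimmer_local, hnr, cpps,
                     sustained_mean_intensity, tau_u)
from voxsced.synthetic_data import VowelSpec, ScedSpec, synth_vowel, synth_sced

# a moderately dysphonic 3 s synthetic vowel with known ground truth
clip, truth = synth_vowel(VowelSpec(f0_hz=150, duration_s=3.0,
                                    jitter_pct=1.0, shimmer_pct=4.0,
                                    target_hnr_db=20.0, seed=7))
pitch = track_pitch(clip)
periods = extract_periods(clip, pitch)
inten = intensity_contour(clip)
print(f"jitter  : {jitter_local(periods):5.2f} %   (injected 1.0)")
print(f"shimmer : {shimmer_local(periods)[0]:5.2f} %   (injected 4.0)")
print(f"HNR     : {hnr(clip, pitch):5.2f} dB  (target 20)")
print(f"CPPS    : {cpps(clip):5.2f} dB")
print(f"level   : {sustained_mean_intensity(clip, periods, inten):6.2f} dB re FS")

# a simulated study: +5·sigma treatment effect, 2 trials per visit
series = synth_sced(ScedSpec(baseline_mean=70, treatment_effect=5,
                             noise_sd=1.0, trials_per_session=2, seed=3))
res = tau_u(series["Pre"], series["Post"])
print(f"tau = {res.tau:.3f}, exact p = {res.p_exact:.4f}")
```

prints

```
jitter  :  1.00 %   (injected 1.0)
shimmer :  5.46 %   (injected 4.0)
HNR     : 14.08 dB  (target 20)
CPPS    : 13.06 dB
level   : -12.36 dB re FS
tau = 1.000, exact p = 0.0022
```

The jitter estimate recovers the injected 1.0 % exactly here; shimmer and
HNR show the expected interaction with the injected noise (added noise
reads partly as amplitude perturbation and lowers measured harmonicity —
see `docs/methods.md`). CPPS at 13.1 dB sits below the 14.45 dB
normal-voice vowel cutoff, consistent with the injected degradation. The
complete phase separation (τ = 1) of baseline versus post-treatment values
yields the smallest exact p available at 6-vs-6, p = 2/924 ≈ 0.0022.

Whole studies run from a manifest:

```bash
voxsced fixtures make-study --seed 1 --out demo_study --participants 1
voxsced analyze demo_study/manifest.yaml --out demo_out --alpha 0.05
```

`demo_out/` then contains `outcomes.csv` (one row per participant × measure
× task × comparison with tau, exact and normal p, significance flag and
missing-data notes), a per-participant Markdown checkmark matrix,
`measures.csv` with every session-level value, and a QC report (glide
reversals, skipped recordings with reasons).

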