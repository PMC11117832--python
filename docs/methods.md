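# Methods

`voxsced` reimplements, at desk scale, the measurement and analysis chain of
a single-case voice-therapy outcome study: acoustic measures of phonation,
prosody and articulation computed per recording session, organized into a
five-phase schedule (Pre, Post, FU1, FU2, FU3 — three visits each), and
compared phase-against-baseline with the Tau-U nonoverlap statistic. Because
such studies rest on patient audio that cannot be shared, the package pairs
every measurement module with a synthetic-signal generator whose injected
ground truth the module must recover. This note records the models,
parameter choices and their rationale, and what the synthetic evidence does
and does not show.

## Signal model of the synthetic voice

Sustained vowels, glides and passage-like speech are rendered as a
band-limited impulse train — Hann-windowed sinc pulses placed at
sub-sample-accurate glottal instants — driving a cascade of two two-pole
resonators (defaults 700/110 Hz and 1220/120 Hz center/bandwidth, an
/a/-like envelope). Gaussian noise is added to the source, scaled so the
harmonic-to-noise power ratio equals `target_hnr_db`, and filtered through
the same resonators so the harmonic and noise components share a spectral
envelope; this keeps the autocorrelation-based HNR estimate close to the
nominal target.

Jitter and shimmer are injected as i.i.d. Gaussian perturbations of each
cycle's period and amplitude. For an i.i.d. perturbation of standard
deviation *s*, the expected *local* measure (mean absolute consecutive
difference over the mean) is (2/√π)·s ≈ 1.128·s, so the injected sd is
scaled by √π/2: the nominal `jitter_pct`/`shimmer_pct` is the local
jitter/shimmer the signal is calibrated to carry, which is the quantity the
analysis modules recover. Recovery tolerances (±25 % relative for
perturbations, ±3 dB for HNR) were established by oracle sweeps under
isolation conditions — each parameter swept while the other two are held
low (jitter sweep at shimmer 1 %, HNR 35 dB; shimmer sweep at jitter 0.3 %,
HNR 35 dB; HNR sweep at jitter 0.1 %, shimmer 0.5 %) — because the
perturbations are physically coupled: period jitter is itself aperiodicity
and caps the measurable HNR.

What the generator does **not** emulate: articulation (no formant movement,
no consonants), naturalistic prosody, room acoustics, microphone or codec
coloration, and the within-speaker covariance structure of real dysphonia.
Passing recovery tests therefore demonstrates the *measurement chain* is
correct and calibrated, not that the measures behave identically on
clinical recordings.

## Acoustic measures

**Pitch tracking.** Normalized autocorrelation per 3/f_min Hann-windowed
frame (default floor 60 Hz, ceiling 600 Hz, 10 ms hop), window-compensated
(the frame autocorrelation is divided by the window's own autocorrelation).
Candidates are local maxima ranked by an octave-cost-biased score
(0.02/octave toward higher F0) — necessary because every subharmonic lag of
a periodic frame reaches r ≈ 1 — and a Viterbi pass with a transition cost
of 0.25·|Δlog₂F0| plus a voiced/unvoiced switching cost selects the path.
Frames below the 0.45 periodicity threshold (or below 1 % of the clip's
peak amplitude) are unvoiced. The published workflow relied on interactive
correction of pitch tracks; that is modeled by an optional override table
(time → F0 or unvoiced) applied after tracking.

**Cycle extraction.** Glottal epochs are detected on the linear-prediction
residual (autocorrelation-method LPC, order ≈ 2 + sr/1000): inverse
filtering concentrates each excitation into a spike, making epoch picking
robust to the multi-peaked cycle shapes formant ringing produces (raw
waveform peak-picking was found to hop between F1 sub-peaks ~1.4 ms apart,
inflating jitter at perturbation levels ≥ 2 %). Epochs advance one expected
period at a time (±30 % search window from the F0 track) with parabolic
sub-sample refinement. Brief voicing dropouts (≤ 40 ms) in the tracker are
bridged for cycle tracking — a genuine voice break is an order of magnitude
longer — and the guiding F0 is de-spiked against the run median (> 5 ST
deviations replaced) so single octave errors cannot corrupt the search
windows.

**Jitter/shimmer.** Local forms: 100·mean|T_{i+1}−T_i|/mean(T) and the
amplitude analogue, with shimmer also in dB as mean|20·log₁₀(A_{i+1}/A_i)|.
Per-cycle amplitude is the waveform extreme in [epoch, epoch + 0.8·period],
a window containing exactly one excitation's response (a full-period window
can straddle two pulses and the max operator then suppresses real
amplitude variation).

**HNR.** Per voiced frame, r is the window-compensated autocorrelation peak
near lag 1/F0; frame HNR = 10·log₁₀(r/(1−r)), capped at +60 dB, averaged
over voiced frames. The 50 ms analysis window spans many cycles at speaking
F0 and was chosen from a window sweep as the best bias/variance compromise;
the estimator's practical ceiling is ~40 dB (at that point r is within
10⁻⁴ of 1 and interpolation error dominates).

**CPPS.** Per 40 ms frame (10 ms hop): log power spectrum in dB, then the
amplitude cepstrum in dB (20·log₁₀ of |FFT| of the log spectrum, normalized
by length). The cepstrogram is moving-average smoothed across time
(10 frames) then quefrency (1 ms); a least-squares line over quefrencies
≥ 1 ms is the trend; CPPS is the mean over frames of the cepstral peak in
the 60–330 Hz-equivalent band minus the trend at that quefrency. With these
conventions a clean synthetic vowel measures ≈ 16.5 dB, comfortably above
the 14.45 dB normal-voice vowel cutoff used as the acceptance reference,
and white noise measures ≈ 3 dB; CPPS decreases strictly under added
broadband noise.

**LTAS slope/tilt.** Welch spectrum; slope = mean level in 0–1 kHz minus
mean level in 1–10 kHz (truncated at Nyquist); tilt is the same contrast on
the least-squares regression line through the LTAS. Note the sign
convention: positive values mean low-frequency dominance.

**AVQI.** The central 3 s of the sustained vowel is concatenated with 3 s
of voiced material extracted from the connected-speech clip (voiced frames
concatenated in order — the dialect choice of the automated script family
this follows); the six parameters (CPPS, HNR, shimmer % and dB, LTAS slope
and tilt) are computed on the concatenation and combined linearly. The
coefficients are *data*: a JSON config keyed by version label, because the
source study cites but does not print the formula and published versions
differ. The shipped default uses the published six-parameter weighted form
(intercept 3.295, scale 2.571, the v3-family weights) with this package's
LTAS sign convention, labeled `v3-adapted`; every result carries its
coefficient label. Scores are clipped to [0, 10] with a warning. The 2.33
cutoff (validated for French speakers) is carried as metadata on the
coefficient set.

**Sustained-vowel intensity.** Mean of the 40 ms/10 ms RMS contour between
the first and last detected glottal cycle, so leading/trailing silence
never dilutes the mean. Levels are dB re full scale plus a per-study
`calibration_offset_db`; absolute SPL claims would require a calibration
recording, but within-participant phase comparisons — the design's use —
are offset-invariant.

**Pitch glides.** Neutral pitch = median F0 of the first 250 ms of voicing
(configurable to an external value; the protocol never defines how neutral
was measured). The second half of the voiced span is searched for the most
extreme contiguous region of ≥ 500 ms whose F0 spread is ≤ 1 ST
(tolerance is a convention; the protocol says only "stable"); its median is
the extreme, method `stable_hold`. Without one, the fallback is the mean F0
over a 500 ms *total* window centered on the extreme unflagged frame
(voice-break and octave-jump frames excluded; the protocol's "mean value
around the highest value … (500 ms)" is ambiguous between total and half
window — total is implemented). A reversal is reported when the extreme
lies on the wrong side of neutral for the instructed direction. The
synthetic glide includes a 0.5 s onset plateau at the start F0 so the
neutral estimate reflects habitual pitch rather than a point mid-glide.

**Timing.** Frames are silent when ≥ 25 dB below the clip maximum *and*
unvoiced; silent runs ≥ 200 ms (inclusive) are pauses, shorter ones merge
into speech; the timeline spans first to last speech frame, so segment and
pause durations tile the total exactly. Speaking rate divides the known
syllable count (an input — syllables are counted against a known passage,
not detected; a peak-counting estimator exists for convenience only) by the
total duration. CVs of F0 (ST re 1 Hz) and intensity (dB) use the sample
(n−1) standard deviation over voiced frames inside speech segments; the
semitone CV depends on the 1 Hz reference and is not invariant to changing
it. DDK rate = syllables in the first 5 s / 5, best of up to three trials.

## Single-case statistics

For baseline A (n_a values) and comparison phase B (n_b values):
S_AB = #(b > a) − #(b < a) over all pairs (ties count 0);
tau = S/(n_a·n_b). Baseline correction subtracts the baseline Kendall S
(all ordered pairs) from S_AB while keeping the n_a·n_b denominator — one
of several published conventions; the brute-force oracle in the test suite
pins exactly this one. Var(S) = n_a·n_b·(n_a+n_b+1)/3 (Mann–Whitney
equivalent, no tie correction) feeds a normal-approximation p, but at this
design's sizes (3 baseline visits) the *exact permutation p* — full
enumeration of phase-label assignments whenever n_a+n_b ≤ 12, seeded
sampling above — is the authoritative value and is what the significance
flag uses when available. With 3-vs-3 single values the smallest attainable
two-sided exact p is 0.10, so single-value-per-visit outcomes can never be
significant at α = 0.05; pooling trials (the default, following the
protocol's use of all individual trial values) is what provides resolution.
No multiplicity correction is applied by default, matching the source
design's reporting; Benjamini–Hochberg is available behind a flag.
Calibration: under an exchangeable null the exact test rejects at α = 0.10
in 10.2 % of 2000 seeded replicates.

ICC for interrater reliability is the two-way mixed-effects *consistency*
form from the ANOVA mean squares — single (MS_R−MS_E)/(MS_R+(k−1)·MS_E) or
average (MS_R−MS_E)/MS_R — cross-checked in tests against an independent
implementation.

## Pipeline

`run_study` maps each manifest recording through its task's measures,
groups values into phase series ordered by (visit, trial), and compares
each of Post/FU1/FU2/FU3 against the pooled three-visit baseline
(per-block, mirroring the outcome tables' column structure; a pooled
follow-up mode is deliberately not the default). Missing sessions are
explicit: manifest gaps are listed, comparisons with fewer than three
contributing visits carry a `missing_data` note, and unanalyzable
recordings land in a skip list with a reason code rather than disappearing.
DDK is computed and tested like every outcome but expected null — its flag
rate is the pipeline's specificity control.

## Problem sizes and seeds

All synthetic evidence is desk-scale by design: vowels 2–3.5 s at 16 kHz,
end-to-end replicate studies use one participant, 15 visits × 2 sustained
trials plus DDK counts, 50 seeded replicates; the permutation calibration
uses 2000 replicates of the 3-vs-3 design. Every stochastic component takes
an explicit seed and identical spec+seed reproduces outputs bit for bit.

## Known limitations

- The CPPS and AVQI scales depend on implementation conventions; the
  shipped coefficient set is version-labeled precisely so scores are only
  compared within a coefficient version.
- The HNR estimator saturates near 40 dB; values above ~35 dB should be
  read as "very harmonic" rather than as calibrated ratios.
- The pitch tracker's voicing decisions fragment at local jitter ≳ 3 %;
  cycle extraction bridges short dropouts, but perturbation measures on
  severely aperiodic voices are, as in all period-based measures,
  interpretable only qualitatively.
- Syllable counts, vowel intervals and verb-final-syllable intervals are
  inputs (annotations), not detected; the package deliberately does not
  replicate automatic vowel-peak detection beyond peak-picking inside given
  intervals.
- dB levels are relative to full scale unless a calibration offset is
  supplied; no absolute SPL metrology is attempted.
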