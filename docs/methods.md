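# Methods

This note documents the models implemented in `tremorbench`, the parameter
choices that matter, the numerical details, and what the synthetic-data
generators do and do not capture.

## Signal model

Every recording is a two-channel force trace (`force_x`, `force_y`) on a
uniform grid at sampling rate `fs` (default 50 Hz, matching the haptic
control loop). The simulator composes each channel additively:

    mixed(t) = voluntary(t) + tremor(t) + noise(t)

* **Tremor** — `A · (1 + m(t)) · sin(2π f t + φ)` with fundamental `f` from
  a named preset: 6 Hz (`pd_resting`, the most frequent parkinsonian
  resting-tremor frequency) or 8 Hz (`pd_severe`, the upper bound reported
  for severe cases). `m(t)` is an optional slow (≤ 0.5 Hz) multiplicative
  amplitude modulation with relative SD `amplitude_jitter_sd` (default 0,
  keeping tests deterministic) mimicking physiological nonstationarity.
  The y-channel is phase-shifted by π/2 so the two axes trace an ellipse.
  Amplitude is a free parameter (default 1, in the Newton-scaled units of
  the force sensors); no published amplitude calibration exists for the
  stimulation protocol this emulates.
* **Voluntary motion** — a parametric stand-in for intentional hand
  movement, band-limited below `band_limit` (default 2 Hz): either a sum of
  three equal-amplitude sinusoids at seeded random frequencies in
  (0.1, band_limit] (default; simple, exactly band-limited, reproducible)
  or a low-passed integrated random walk. The constructor enforces
  `band_limit < f − 1` so the adaptive attenuation boundary can separate
  the components — the same structural assumption the filter itself makes.
* **Noise** — white Gaussian with SD `noise_sd` (default 0.05 in the
  end-to-end scenarios). Sensor noise is not characterised in any source;
  white Gaussian is the assumption under which the universal threshold is
  derived, so it is also the correct null for testing that stage.

All randomness flows through purpose-keyed `numpy.random.SeedSequence`
children of one seed: identical arguments give bit-identical recordings,
and the noise sequence can be regenerated exactly, which is what makes the
additivity invariant (`mixed − voluntary − tremor = noise`) testable to
machine precision.

## Filtering pipeline

Six stages per channel; stages 2–5 are the computational core.

**Stage 2 — wavelet denoising.** Discrete wavelet transform (db4, symmetric
extension), soft thresholding of all detail coefficients at the universal
threshold λ = σ·√(2 ln N), with σ = median(|D₁|)/0.6745 estimated from the
first-level (finest) details only and N the signal length. Approximation
coefficients are untouched. The decomposition depth defaults to 3: at
50 Hz the detail bands then cover ≈ 3.1–25 Hz, entirely above the
voluntary band, so shrinkage cannot distort intentional motion (measured:
a 1 Hz unit tone keeps 99.9 % of its band power while > 99 % of the
power above 10 Hz is removed). One level deeper would expose a
1.6–3.1 Hz detail band into which sub-2 Hz motion leaks; we measured a
≈ 10 % band-power loss of a 1 Hz tone there, which violates the stage's
purpose of preserving motion dynamics. The depth is configurable and is
capped at the maximum admissible level for the segment length.

**Stage 3 — Kalman smoothing.** Scalar constant-position state-space model
with A = H = 1, process noise Q = 0.01 and measurement noise R = 0.1
(both configurable). The standard predict/update cycle is used:
p⁻ = p + Q, k = p⁻/(p⁻ + R), p = (1−k)p⁻. The state is initialised at the
first sample to avoid an artificial start-up transient. With the default
Q/R the steady-state gain is ≈ 0.27 (an exponential smoother attenuating
6 Hz by ≈ 8 dB while passing ≤ 1 Hz nearly unchanged); the covariance
converges to the unique positive Riccati fixed point, verified in tests
against an independently iterated recursion to 1e−10.

**Stage 4 — dominant-frequency tracking.** Magnitude spectrum of 2 s
windows with 50 % overlap (periodic Hann taper by default; rectangular
available — on-bin tones keep their peak bin either way), peak restricted
to a search band, f_dom = k_peak·fs/N, ties broken toward the lowest
frequency. A peak counts only if it exceeds 3× the median in-band
magnitude *and* 1 % of the overall spectral maximum; otherwise the window
is flagged undefined (NaN in the track) — the behaviour for tremor-free
signal, which no source specifies, is to report no peak rather than a
noise bin. Two search-band defaults coexist deliberately:

* standalone `SpectrumConfig`: [0.5, 12] Hz — excludes DC (an offset
  signal would otherwise always "peak" at 0 Hz) but is otherwise
  agnostic;
* inside `run_pipeline`: [3, 12] Hz — the tracker's job there is to locate
  the *tremor* fundamental that drives the attenuation boundary. With
  voluntary motion present, the voluntary peak is routinely larger than
  the (already Kalman-attenuated) tremor peak; searching the full band
  would lock f_dom onto ~1 Hz, push the boundary to 0 Hz and disable the
  attenuation stage entirely. Restricting the pipeline's search band to
  the physiological tremor range (3–12 Hz) is the same design move as
  excluding DC, one octave further.

**Stage 5 — adaptive wavelet-packet attenuation.** Full wavelet-packet
decomposition (db4, depth 4, symmetric mode); the 16 terminal nodes in
natural/frequency order tile [0, 25] Hz into 1.5625 Hz bands. Nodes whose
band *overlaps* frequencies above f_dom − 1 Hz (i.e. band upper edge above
the boundary) are classified tremor-dominant and their coefficients are
multiplied by the attenuation gain (default 0 = zeroing); the rest are
reconstructed unchanged. The overlap rule matters: at f_dom = 6 Hz the
tone lies inside the node [4.6875, 6.25), whose *lower* edge is below the
5 Hz boundary — a lower-edge rule would leave the tremor node untouched.
Node ordering is explicitly natural (frequency) ordering, not Gray-code
ordering, a classic wavelet-packet pitfall. When f_dom − 1 ≤ 0 the rule is
vacuous; the stage warns and passes the signal through. Measured on a
1 Hz + 6 Hz mixture, zeroing removes ≥ 99 % of the 5–7 Hz band power while
keeping the 0.5–1.5 Hz band within 1 %.

**Orchestration and streaming.** Processing is frame-synchronous: the
signal is consumed in hop-sized frames (1 s at the default window
settings). Denoising sees each frame with 128 samples of left context and
64 samples of lookahead from the raw signal; the Kalman state threads
through sequentially; a frequency-track window completes at each frame
boundary and its estimate (when defined) becomes the boundary for the
wavelet-packet stage, which likewise sees 128 + 64 samples of context
around the frame in the smoothed signal. Because every emitted sample is a
deterministic function of a bounded, fixed neighbourhood, the streaming
entry point (`run_pipeline_stream`, arbitrary block size) produces output
*bit-identical* to the offline one — the offline path simply feeds the
whole record through the same machinery. The lookahead implies a constant
reporting delay of ≈ 1.3 s in the simulated stream; per-frame wall-clock
time is recorded in `PipelineResult.block_latency` for reporting only and
is never asserted against any hardware figure. A trailing partial frame is
zero-padded, processed, flagged (`partial_final`), and the output truncated
to the true length. Until the first 2 s window completes (and whenever no
peak is defined), the attenuation stage is bypassed and the output is the
denoised, smoothed signal.

End-to-end on simulator ground truth (6 Hz tremor amplitude 1, voluntary
amplitude 1 at band limit 1 Hz, noise 0.05, 60 s): tremor-band (5–7 Hz)
power ratio out/in ≈ 0.002, voluntary-band ratio ≈ 0.85–0.90, correlation
with the ground-truth voluntary component ≈ 0.94. The voluntary loss is
almost entirely the Kalman stage's |H(1 Hz)|² ≈ 0.86; it is the price of
the prescribed Q/R, not of the wavelet stages.

## Task engine and metrics

Puzzles are generated by randomized backtracking fill and carved by
seeded greedy removal — a cell is removed only if an exhaustive
most-constrained-first counter still finds exactly one completion — to
exactly 35/45/55 blanks for easy/medium/hard. Once a removal breaks
uniqueness it stays broken as further cells are removed, so one pass per
removal order suffices; orders that fall short are reshuffled from an
internal sub-seed (hard cap 100, never reached in practice; a hard carve
takes ≈ 30 ms). Uniqueness is a deliberate strengthening over any stated
requirement: it is the standard Sudoku convention and is what makes
correctness flags deterministic. Entry validation locks correct cells,
flags wrong entries, and counts *every* wrong entry event including
repeats. The voice vocabulary accepts exactly nine digit words per
language (English "one"–"nine", Romanian "unu"–"nouă", diacritic forms);
everything else maps to "ignored" without raising. The countdown emits
"3", "2", "1", "Start" at 1 s spacing (the cue text is fixed; the spacing
is our choice).

Cell Completion Time is the interval from the first confirmed selection of
the target cell to the first correct (locking) entry, bound to the *final*
target cell: selecting a different cell abandons the previous episode,
re-selecting the same cell does not restart it, and wrong entries on the
current cell do not end it. A correct entry with no live selection episode
is a malformed log. The session clock starts at the "Start" cue when a
countdown is present (else at the first event); a missing completion event
censors total time but leaves the other metrics defined. "Response-time
variability" is implemented as the SD of the CCT values; the SD of
inter-event intervals would be the alternative reading. Canonical formats
are JSON-lines event logs and CSV metric tables; an Excel mirror exists
because the original platform logged to a spreadsheet, but CSV is the
format of record (diff-able, portable).

## Statistical analysis

One-factor repeated-measures ANOVA from the classical decomposition
SS_total = SS_subject + SS_condition + SS_residual (exact to 1e−9 by
construction, property-tested), F = MS_cond/MS_res on (k−1, (k−1)(n−1))
degrees of freedom, partial η² = SS_cond/(SS_cond+SS_res). Sphericity
diagnostics operate on the covariance of the data projected onto
orthonormal (Helmert) contrasts: Mauchly's W = det(S)/(tr(S)/(k−1))^(k−1)
with the standard χ² approximation, and Greenhouse–Geisser
ε = tr(S)²/((k−1)·tr(S²)) clamped to [1/(k−1), 1]. Both the uncorrected p
and the ε-corrected p are always reported so either reporting convention
is reproducible. Post hoc: paired t-tests for all k(k−1)/2 pairs,
Bonferroni-adjusted p = min(1, m·p_raw), and paired Cohen's d = mean
difference / SD of differences (the paired rather than pooled convention).
Zero-variance difference vectors are flagged degenerate (p = 1 when the
mean difference is also zero). Residual diagnostics emit plottable tables
(fitted values, residuals, Blom normal quantiles) rather than figures. The
three outcome measures are treated as pre-specified endpoints; no
correction is applied across outcomes, only across pairwise contrasts
within an outcome. The implementation is cross-checked in the test suite
against statsmodels' AnovaRM (F, p) and pingouin (Mauchly, ε) on the same
tables; those libraries are oracles, not dependencies of the package.

## Synthetic cohorts

Two generators exist with different purposes.

`simulate_session_logs` is *statistical*: per subject i and condition c the
latent mean CCT is `base + b_i + effect_c + w_ic` with b_i ~ N(0, subject_sd²)
between subjects and w_ic ~ N(0, within_sd²) within, plus N(0, cell_sd²)
per cell; wrong entries occur at a fixed rate. Defaults (base 4 s, all
three SDs 1 s, 35 cells = one easy puzzle, wrong-entry rate 0.1) are a
plausible scale for a seated pointing task; with a zero effect profile the
generator is an exact null for the ANOVA (type-I error 0.05 within
Monte-Carlo error over 1000 replicates, verified in the suite).

`run_session`/`run_batch` are *mechanistic*: a simulated recording supplies
the cursor (12 s at 50 Hz per session — long enough for a stable jitter
estimate at negligible cost), filtered when the condition requires it, and
a noisy proportional-control pointer turns a perturbation index into
per-cell acquisition times, entry delays and miss probabilities, played
through the real game-state validator on a real carved puzzle (one shared
easy puzzle per batch, matching the single standardized difficulty level
of the protocol). The index is `visual_jitter + 0.5 · physical_rms`, where
visual jitter is the > 3 Hz RMS of the *displayed* cursor and physical RMS
that of the *pre-filter* signal: the suppression is visual-only, the hand
still shakes, and that physical term is precisely why filtering restores
performance only partially — the simulated cohorts reproduce the
baseline < filtered < unfiltered ordering on all three outcomes in ≈ 100 %
of batches (asserted ≥ 90 % over 100 seeds).

What these generators do *not* capture: real tremor is nonstationary and
non-sinusoidal (harmonics, amplitude bursts); real voluntary motion is
goal-directed, not a stationary band-limited process; real users learn,
fatigue and strategise. Passing tests therefore demonstrate that the
pipeline and analysis behave correctly under their stated assumptions,
not that the filter performs identically on pathological tremor — the
platform's own evaluation makes the same caveat for electrically induced
oscillations in healthy participants.

## Numerical choices and degenerate inputs

* Symmetric signal extension for all wavelet transforms; reconstructions
  trimmed to input length.
* σ = 0 (hence λ = 0) short-circuits to the plain DWT round trip, avoiding
  0/0 in the soft-threshold kernel; perfect reconstruction ≤ 1e−8 RMS.
* Non-finite Kalman measurements raise without touching the state.
* Frequency-tracker ties break toward the lowest frequency (first argmax).
* Segments shorter than the wavelet filter (denoise) or 2^depth (WPD) pass
  through unmodified inside the pipeline; the standalone functions raise.
* Zero residual variance raises a degenerate-data error in the ANOVA
  (F undefined); missing cells are rejected, never imputed.
* Every stochastic component is seeded; pipeline configurations are
  serialised into the result object for provenance.

## Known limitations

* The pipeline's lookahead makes the "streaming" mode a faithful but
  delayed simulation of real-time operation; a hard-real-time deployment
  would trade the lookahead for boundary artefacts at frame edges.
* Wavelet-packet bands are 1.5625 Hz wide at depth 4, so the effective
  attenuation boundary quantises to band edges; tremor within ~1.5 Hz of
  strong voluntary content would not be separable.
* Mauchly's test is undefined (warned, NaN) when n − 1 < k − 1 leaves the
  contrast covariance singular.
* The pointer model's gains are face-plausible, not fitted to human data;
  only the qualitative ordering of conditions, not effect magnitudes,
  should be read off the simulated cohorts.
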