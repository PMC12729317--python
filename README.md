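# tremorbench

Simulation, real-time filtering and evaluation of tremor-perturbed cursor
control in a cognitive–haptic Sudoku task.

Pathological tremor (typically 4–8 Hz in Parkinson's disease) corrupts the
cursor signal of haptic rehabilitation interfaces, making fine cognitive–motor
tasks slow and error-prone. `tremorbench` implements the computational core of
such a platform for engineers and researchers working on visual tremor
compensation:

* **Tremor simulator** — two-axis force recordings built from a band-limited
  voluntary component (< 2 Hz), a tremor-band oscillation (named presets at
  6 Hz "pd_resting" and 8 Hz "pd_severe"), and white Gaussian sensor noise,
  with the ground-truth decomposition returned alongside the mixture.
* **Suppression pipeline** — the six-stage real-time filter: db4 discrete
  wavelet denoising with soft thresholding at the universal threshold
  λ = σ√(2 ln N), σ = median(|D₁|)/0.6745; scalar Kalman smoothing
  (A = H = 1, Q = 0.01, R = 0.1); windowed-FFT dominant-frequency tracking
  (2 s windows, 50 % overlap, f_dom = k_peak·fs/N); and adaptive depth-4
  wavelet-packet attenuation of every band overlapping frequencies above
  f_dom − 1 Hz. The streaming entry point is bit-identical to the offline one.
* **Sudoku engine** — puzzle generation at three difficulty levels (35/45/55
  removals, uniqueness-verified), entry validation with red-flag semantics,
  bilingual (en/ro) digit-word voice tokens, and the "3, 2, 1, Start" cue.
* **Session metrics** — Cell Completion Time (first confirmed selection of the
  final target cell to the locking entry), total time, error counts and
  response-time variability from JSON-lines event logs.
* **Statistics** — one-factor repeated-measures ANOVA (df = (k−1, (k−1)(n−1)),
  partial η², Mauchly's W, Greenhouse–Geisser ε), Bonferroni-adjusted paired
  comparisons with paired Cohen's d, descriptives and residual diagnostics.
* **Headless cohort simulation** — a simulated user plays real puzzles under
  three within-subject conditions (no tremor / tremor unfiltered / tremor
  filtered), producing event logs and metrics end to end.

## Worked example

```python
import numpy as np
import tremorbench as tb
from tremorbench.signal import band_power

rec = tb.simulate_recording(
    tb.TremorProfile.preset("pd_resting"),          # 6 Hz tremor, amplitude 1 N
    tb.VoluntaryMotionModel(band_limit=1.0, amplitude=1.0),
    noise_sd=0.05, duration=60.0, fs=50.0, seed=42,
)
res = tb.run_pipeline(rec.mixed)
x_in, x_out = rec.mixed["force_x"], res.filtered["force_x"]
print(f"tremor band 5-7 Hz power ratio: {band_power(x_out,50,5,7)/band_power(x_in,50,5,7):.4f}")
print(f"voluntary band <1.5 Hz power ratio: {band_power(x_out,50,0.1,1.5)/band_power(x_in,50,0.1,1.5):.3f}")
```

prints

```
tremor band 5-7 Hz power ratio: 0.0019
voluntary band <1.5 Hz power ratio: 0.897
```

i.e. the pipeline removes 99.8 % of the power around the 6 Hz tremor while
keeping ~90 % of the voluntary-motion power. A simulated 15-subject cohort then
reproduces the qualitative study pattern — tremor degrades performance,
filtering partially (not fully) restores it:

```python
from tremorbench.metrics import metrics_frame
from tremorbench.stats import RMTable, rm_anova

df = metrics_frame(tb.run_batch(n_subjects=15, seed=0))
print(df.groupby("condition")[["cct_mean_s", "total_time_s", "n_errors"]].mean().round(2))
a = rm_anova(RMTable.from_long(df, value="cct_mean_s"))
print(f"F({a.df1}, {a.df2}) = {a.f:.2f}, p = {a.p:.2e}, partial eta2 = {a.eta_sq_partial:.2f}")
```

```
                   cct_mean_s  total_time_s  n_errors
condition
no_tremor                0.71         85.33      1.47
tremor_filtered          1.19        133.52      4.93
tremor_unfiltered        2.52        252.74     11.87
F(2, 28) = 629.23, p = 5.35e-24, partial eta2 = 0.98
```

Here `cct_mean_s` is the mean Cell Completion Time in seconds, `total_time_s`
the puzzle completion time from the "Start" cue, and `n_errors` the count of
wrong entries; F is tested on (2, 28) degrees of freedom as expected for 15
subjects and 3 conditions.

The same flows are available from a shell:

```bash
tremorbench simulate --preset pd_resting --band-limit 1.0 --seed 5 --out trace.csv
tremorbench filter --in trace.csv --out filtered.csv --fdom-out fdom.csv
tremorbench puzzle --difficulty hard --seed 2 --out puzzle.json
tremorbench run-batch --subjects 15 --seed 0 --out metrics.csv
tremorbench analyze --metrics metrics.csv --outcome cct_mean_s --out anova.json
```

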