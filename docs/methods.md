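# Methods

This note documents the analysis model, the synthetic-data generator, the
numerical choices, and the limits of what the test suite demonstrates.

## Signal model and HFA extraction

The pipeline treats high-frequency activity (HFA, 50–150 Hz amplitude) as
a proxy for local population activity. Raw monopolar signals (512 Hz
typical) are re-referenced to a bipolar montage: every pair of adjacent
contacts `(i, i+1)` on one electrode shaft yields `contact_i − contact_{i+1}`,
which cancels line noise and volume-conducted far-field activity common to
both contacts.

Extraction runs per sub-band: the 50–150 Hz range is split into ten 10 Hz
bands. Each band is filtered with a linear-phase FIR band-pass applied as
a single centered convolution — an odd-length symmetric kernel applied
this way is exactly zero-phase (verified by a burst-alignment test at
±1 output sample). The design is a Kaiser-windowed sinc with a 0.5 Hz
transition band and ≥ 60 dB stop-band attenuation; at 512 Hz that kernel
spans ~6.6 s, so sessions should be tens of seconds or longer. The
analytic (Hilbert) envelope is computed at the native rate, anti-alias
filtered and decimated by an integer factor to 64 Hz, divided by its
session mean and multiplied by 100, and the ten normalized envelopes are
averaged. Consequences:

* the output series averages exactly 100 over the session (the
  normalization mean excludes 1 s at each session edge, where FIR
  start-up transients live; outputs keep those samples but the interior
  defines the mean);
* normalization is scale-invariant, and per-band normalization
  equalizes band contributions, compensating the 1/f amplitude drop-off;
* sub-bands containing line-frequency harmonics are kept by default (the
  bipolar montage is the line-noise defense); `drop_line_bands` removes
  them.

Decimating after the envelope (rather than filtering at a reduced rate)
preserves sub-band energy; envelope samples that ring slightly negative
after the anti-alias FIR are clipped at zero before normalization.

## Time conventions

Session times are seconds (floats); windows are half-open `[start, end)`.
At 64 Hz a window maps to samples `round(start·64) + [0, round(len·64))`,
so 2 s windows hold exactly 128 samples and the `[−1, 3) s` epoch 256.
The 200 ms pre-stimulus baseline is the 12 samples `k/64 s, k = 1..12`
before the onset sample (0.2 × 64 = 12.8 is not integral; the strict
half-open rule keeps 12).

## Binarization

`Vmed` is computed per site and per session as the median of the pooled
baseline samples of the ⌊n/2⌋ fastest correct trials (ties in RT broken
by trial order). "On" means strictly greater than `Vmed`; equality is
"off" (ties have measure zero for continuous data). Pooling across trials
before taking the median (rather than per-trial medians) follows the
definition of a single quiescent reference distribution. Per-session
`Vmed` keeps cross-session comparisons robust to gain and line-noise
drift, which is the point of binarizing at all.

Raster display order groups incorrect trials (misses included, sorted as
RT = 3 s) above correct trials, each sorted by RT — a bookkeeping
convention preserved in row metadata.

## Statistics

All surrogate p-values use the add-one convention `(k+1)/(n+1)` and are
never zero; with 10,000 surrogates an observation above all of them
reports `p = 1/10001 < 10⁻⁴`.

* **Behavioral randomization** — trials belong to a window iff their
  target onset lies in it; RT statistics use correct responded trials,
  accuracy counts misses as errors. Surrogates draw N T2-free windows
  without replacement per repeat, independently across repeats. Both
  tests are one-sided (slower / less accurate), α = 0.01.
* **Rank-sum on binary data** — the Mann–Whitney statistic with midrank
  ties is a strictly increasing function of the number of "on" values in
  one group, so for combined n ≤ 20 the p-value is computed exactly from
  the hypergeometric configuration distribution (equal to full
  enumeration); larger samples use the tie-corrected, continuity-corrected
  normal approximation (cross-checked against an independent asymptotic
  implementation).
* **T1-evoked detection** — each epoch column over the fastest correct
  trials vs the pooled baseline samples, two-sided (activations and
  suppressions), Benjamini–Hochberg across the 256 samples at q = 0.05;
  contiguous significant samples are reported as segments. A degenerate
  (all-equal) baseline yields p = 1 everywhere with a warning.
* **T2 density** — one-sided (denser), Bonferroni α/n_sites; the
  implementation refuses configurations where the Bonferroni threshold is
  finer than the surrogate resolution 1/(n+1).
* **Interference** — one-sided signed-rank pairing the i-th chronological
  T2-window with the i-th fastest correct trial's `[−800, 1200) ms`
  window. The pairing is a convention (no natural correspondence exists);
  an unpaired rank-sum variant is available via `paired=False`. Fewer
  than 5 pairs returns an "underpowered" result with no verdict; if
  fewer correct trials than T2-windows exist, the first min(N, n_correct)
  of each are paired with a warning.
* **ST/DT comparison** — M = half the DT correct-trial count, fastest
  correct trials of each condition, per-sample two-sided rank-sum with
  FDR; M < 10 flags the result underpowered.
* **Automatization** — per-trial on-density in `[900, 1200) ms`, first vs
  last 20% of trials (chronological), two-sided rank-sum at α = 0.05.
* **Coupling** — Pearson correlation of HFA segments over `[−6, +4) s`
  around each verbal response (Spearman available by flag). One pooled
  null of surrogate coefficients serves all pairs: each surrogate pairs
  two sites more than 30 mm apart (Euclidean distance of bipolar-midpoint
  MNI coordinates) with two non-overlapping response windows, uniformly
  with replacement. An observed R+ is significant iff strictly greater
  than every surrogate R−.

## Synthetic sessions

The generator's defaults are the study conditions: 250 trials of
200 ms target + 500 ms mask + array until response (3 s timeout) + 800 ms
pause, equal target-present/absent counts, ~16 verbal responses with a
minimum 8 s spacing (so the T2-free tiling is non-empty). Reaction times
are log-normal (median 750 ms, σ_log 0.25); trials whose onset falls in
an *engagement window* have RT multiplied by 1.5 and an error probability
of 0.35 vs 0.05 outside. Engagement windows span the 2–6 s (uniform)
before each verbal onset: covert engagement precedes the overt response
by an unknown margin, so the analysis's fixed 2 s T2-window is a subset.
This window model is an assumption of the generator, not a measured
quantity.

Raw signals are, per contact, unit-variance 1/f Gaussian background plus
a band-limited 50–150 Hz carrier (sd 0.4 relative to background) whose
instantaneous amplitude is multiplied by `(1 + Σ task templates) ×
(1 + t2_gain · engaged(t)) × (1 + c · latent(t))`. Task templates are
either a double transient (peaks ~150 and ~450 ms) or a plateau sustained
until the response; `latent` is a shared < 1 Hz Gaussian envelope driving
coupled site groups; line noise, when enabled, is added identically to
both contacts of a pair so the bipolar derivation cancels it exactly. The
carrier is added at full weight to the first contact and `1 − contrast`
to the second, so the bipolar signal retains the effect at configurable
contrast. One `numpy` Generator drives schedule, behavior and signal:
identical seeds give bit-identical sessions.

The canonical desk-scale scenario has 8 sites: three "interfering"
(sustained task template, engagement gain 2, two of them coupled at 0.8),
three task-responsive only, and two null.

What the generator does *not* emulate: epileptiform or movement
artifacts, eye movements, non-stationary background, speech acoustics,
phase structure (amplitude-only effects), and realistic anatomical
covariance. Passing tests demonstrate that the detectors recover the
modeled effect classes at the modeled SNR, not performance on clinical
recordings.

## Calibration, problem sizes, and known limitations

* The behavioral randomization and the T2-density test resample a finite
  pool of T2-free windows, which slightly underestimates the observed
  statistic's sampling variance when the pool is small relative to N: at
  desk scale (60 trials, ~150 s, ~50 free windows) the density test
  rejects ~10% of null sites at α = 0.05 instead of 5%. At the study
  scale (250 trials, ~10 min, ~250 free windows) both tests calibrate
  inside the 95% binomial band; the calibration suite therefore runs at
  the study scale. This behavior is inherent to the procedure, not an
  implementation artifact.
* The per-sample binary rank-sum tests are discrete and
  continuity-corrected, hence conservative: under the global null the
  FDR-corrected detectors flag nothing in ≥ 95% of runs (measured
  family-wise rate ≈ 0.02 at q = 0.05).
* The response-locked correlation flags any common drive — a shared
  latent envelope, but also engagement-locked or task-locked
  comodulation. Surrogate pairs differ in both site and time, so
  time-locked common structure is genuine signal to this method;
  "uncoupled" false-positive rates are meaningful only for site pairs
  with no shared injected modulation.
* Calibration and recovery suites use reduced problem sizes chosen to
  keep the default run practical: 1,000 surrogates and 200–3,000 null
  replicates per detector, 20 recovery seeds at 60 trials / 12 responses
  per session, and 2,000-surrogate coupling nulls. Larger sizes sharpen
  the same estimates.
* EDF I/O quantizes to 16 bits over a per-channel symmetric physical
  range: round trips are exact to ~3 × 10⁻⁵ relative, not bit-exact.
* The automatization statistic's 19-sample window makes per-trial
  densities heavily tied; its asymptotic level stays within the binomial
  band but individual seed blocks can drift (measured 0.0536 over 5,000
  null runs).
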