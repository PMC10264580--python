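# Methods

This note records the models, operational definitions and numerical choices
behind `vepwave`, in the spirit of a package's statistical documentation: it
states what is computed and why, not results — every number quoted here is
recomputed by the test suite or by `scripts/acceptance.py`.

## Signal model and the synthetic cohort generator

A recording session is modeled as `sweeps_per_average × averages_per_session`
stimulus-locked epochs (defaults 20 × 3) of duration 500 ms at 4096 Hz
(2048 samples), matching the acquisition protocol the pipeline targets. Each
simulated sweep is

```
x(t) = Σ_c  a_c · exp(−(t − τ_c − j_c)² / 2σ_c²)  +  b(t)  +  m(t)
```

* **Components.** Each of P1, N1, P2 is a Gaussian bump with amplitude `a_c`
  (signed: P1, P2 > 0, N1 < 0), latency `τ_c` and half-width-at-half-maximum
  `w_c` (`σ_c = w_c / √(2 ln 2)`). The kernel peak is snapped to the sample
  nearest `τ_c`, so the sampled extremum equals `a_c` exactly and ground
  truth is unambiguous. A Gaussian was chosen because it is unimodal,
  smooth, and places its peak exactly — the real waveform's shape is not
  published in parametric form, and nothing downstream depends on tail
  behavior. Default morphology: P1 25 ms / +8 µV / 5 ms, N1 50 ms / −15 µV /
  8 ms, P2 90 ms / +10 µV / 12 ms. **The baseline latencies are conventions
  of this simulator** (plausible for anesthetized mouse flash VEP), not
  measured values; they are configurable and all endpoints are relative
  (percent change), so conclusions do not hinge on them.
* **Background** `b(t)`: Gaussian 1/f^α noise (default α = 1, per-sample SD
  3 µV — one fifth of |N1|, the signal-to-noise regime the validation
  criteria specify). Generated by spectral shaping of white noise with the
  gain normalized via Parseval so the time-domain SD is calibrated for any
  α; the empirical log-log PSD slope matches −α within 0.2 over 2–100 Hz.
* **Mains** `m(t)`: a 50 Hz sinusoid (default 2 µV) with per-sweep random
  phase, included to exercise the notch.
* **Jitter** `j_c`: per-sweep, per-component latency jitter, N(0, 1 ms) by
  default, so averaging is exercised realistically (slightly widening and
  shrinking the averaged peaks, as in real data).

Longitudinal structure: a cohort design is a list of groups (label, number
of eyes, trajectory) × timepoints (day 0 = baseline, then days
post-immunization). A **trajectory** maps each component to percent latency
delay as a piecewise-linear function of day, zero at baseline by
construction; the ground-truth latency at day *d* is
`τ_c(0) · (1 + delay(d)/100)`. Treatment and disease arms are *only*
latency-trajectory modifiers — no biophysics of demyelination or
stimulation is modeled. Dropout is per-eye right-censoring. Two eyes share
a mouse id; eyes are the analysis unit, matching how such cohorts are
counted. All randomness derives from one seed through `SeedSequence`
spawning (one child per eye × day, consumed even for censored sessions), so
cohorts are bit-reproducible and dropout does not perturb surviving eyes.

Premade designs mirror the two study layouts the pipeline is aimed at:
disease characterization (healthy 16 eyes; 24 eyes with early N1 + P2
delay; 16 eyes with early P2 delay only, N1 delay appearing later) and a
stimulation experiment at day 8 (healthy 16; sham 34 with N1 + P2 delay;
anodal 30 with the P2 delay removed; cathodal 28 with both removed). The
default effect size for "early delay" is +15% — large against the ~1%
eye-level measurement noise at the default SNR, as a clear-cut delay should
be.

**What the generator does not emulate:** amplitude pathology, trial-to-trial
amplitude variability, non-stationary or non-Gaussian artifacts (blinks,
movement), electrode drift, inter-eye baseline latency differences, and any
correlation between the two eyes of a mouse. Passing tests therefore show
that the *analysis* is correct and calibrated under a realistic noise
floor — not that it is robust to every pathology of real recordings.

## Preprocessing

The analysis band is a 4th-order Butterworth 5–100 Hz bandpass plus a
2nd-order IIR notch at 50 Hz (Q = 30), both applied forward-backward
(`sosfiltfilt` / `filtfilt`). Zero-phase application is a hard requirement:
the pipeline's endpoints are latencies, and a causal filter's group delay
would bias every one of them. Block averages are pointwise means; the grand
average is the sweep-count-weighted mean of block averages (equal to the
mean over all sweeps). Filtering is linear, so filtering block averages and
averaging filtered sweeps are the same operation; the pipeline filters the
averages.

Two numerical facts worth recording:

* The Q = 30 notch has a settling time of ~0.2 s, comparable to the epoch.
  Steady-state attenuation at 50 Hz (≈ 39 dB for the forward-backward pass)
  is therefore measured on a 2 s tone with 0.5 s trimmed at each end; on a
  single 0.5 s epoch the edge transients dominate any padding scheme.
  Hardware notches act on the continuous recording, so steady state is the
  faithful measurement. Residual epoch-level hum is further suppressed
  ~√60 by averaging over random-phase sweeps.
* The chain is latency-neutral to ≤ 1 sample (0.244 ms) on the default
  morphology, but it does distort the waveform: for geometries that move
  P2's spectral content into the notch region, the apex can shift up to
  ~1 ms. This is a property of the stated filter chain itself (real
  recordings pass through the same one), and the end-to-end noise-free
  fidelity test budgets for it explicitly (quantization + 1.2 ms).

## Component marking

The ordinal definitions are: P1 = first positive peak after the 10 ms
stimulus-artifact blanking, N1 = first negative trough after P1, P2 = first
subsequent positive peak occurring *before the complete signal
hyperpolarization*. "First", not "largest" — two operational rules turn
this into an algorithm:

1. **Candidate quality.** Candidates are local extrema of the trace after a
   1.2 ms moving average, refined by hill-climbing to the nearest extremum
   of the *unsmoothed* trace (ties resolve to the earliest sample, matching
   "first peak" semantics); latency and amplitude are read from the raw
   trace. A candidate must additionally have topographic prominence of at
   least 15% of the trace's absolute peak (configurable, plus an absolute
   µV floor). The prominence floor is the operational form of a human
   marker ignoring small ripples: smoothing alone is not sufficient,
   because the 5 Hz high-pass produces a *wide* ~1 µV rebound after a deep
   N1 that a pure first-extremum rule would otherwise mark as P2.
2. **Hyperpolarization bound.** The P2 search (window 10–45 / 25–80 /
   45–150 ms defaults for P1/N1/P2) is cut at the onset of the first
   sustained negative excursion after 60 ms: the smoothed trace must stay
   ≤ 0 for ≥ 40 ms *and* dip below 20% of the trace's absolute peak within
   that run. The depth requirement distinguishes a genuine late
   hyperpolarization from near-zero baseline hover (filter undershoot),
   which otherwise truncates the search when P2 is delayed.

Search windows are analysis conventions, not measured values; the ordinal
ordering (N1 after P1, P2 after N1) is enforced regardless. Absent
components are reported as absent with a quality flag, never fabricated; if
no positive peak precedes the trough, N1 and P2 are still reported with P1
flagged absent. Amplitudes are peak minus the mean over the blanking
interval; the N1-P2 amplitude is peak-to-peak (always ≥ 0 when both peaks
exist). Implicit times are exact subtractions and inherit absence. Marking
is done on the grand average by default; the three block averages are also
marked, and the maximum pairwise latency spread per component (tolerance
5 ms) is reported as a reproducibility flag.

Because sample times are exact dyadic rationals (k·1000/4096 ms), marked
latencies and implicit times are exact in floating point, and the closure
identity `(P1-N1) + (N1-P2) = (P1-P2)` holds to the bit — the test suite
asserts bit equality, not approximate equality.

## Endpoints and stratification

Percent change is `100 · (t_d − t_0)/t_0` against the same eye's day-0
value; it is exactly 0 at baseline and absent (never imputed) when either
end is missing. The endpoint table is long-format (eye × day × measure)
with absences explicit.

Stratification of diseased eyes into "with" / "without early latency
delay": an eye is *with delay* when its N1 percent change at day 7 exceeds
the healthy eyes' mean + 2 SD at the same timepoint (an absolute threshold
can be substituted; healthy eyes are never relabeled; eyes missing the rule
timepoint are `unclassifiable`). The 2 SD rule is a reproducible surrogate
for an expert's by-eye judgment — the original criterion is not quantified
anywhere — and implies ~2.3% of truly-undelayed eyes will be mislabeled by
chance, which the label-recovery checks account for.

## Statistics

Per measure × timepoint cell: a D'Agostino–Pearson K² omnibus test per
group (recorded as a gate; requires n ≥ 8), then Kruskal–Wallis H with tie
correction across groups, then Dunn's post-hoc z on pooled ranks with
tie-corrected variance,

```
z_ij = (R̄_i − R̄_j) / sqrt( (N(N+1)/12 − ΣT/(12(N−1))) · (1/n_i + 1/n_j) )
```

two-sided, Bonferroni-adjusted over the *requested* comparison family
(explicit in configuration — e.g. the stimulation design tests
healthy-vs-each and sham-vs-active, not all pairs). Stars follow the usual
convention (* < 0.05, ** < 0.01, *** < 0.001, **** < 0.0001), α = 0.05.
The within-eye N1-vs-P2 contrast is a paired Student's *t* on per-eye
(ΔP2% − ΔN1%).

Longitudinal data are analyzed as independent per-timepoint comparisons of
within-eye changes; no repeated-measures/mixed model is fitted. This is a
deliberate simplification — the endpoints are already within-eye changes
from baseline, per-timepoint tests reproduce the figure-level contrast
structure, and every result row records which branch produced it — but it
does not model within-eye correlation across days, so cross-timepoint
inferences should not be chained from these rows.

Kruskal–Wallis and Dunn are validated against independent brute-force rank
computations (hand formulas on integer data, agreement to 1e-10), and the
whole detection path against an independently coded first-extremum scan.
Calibration is checked by simulation: the Kruskal–Wallis type-I rate on
2000 null three-group cohorts (n = 16 each) must lie in [0.035, 0.065], and
paired-contrast power at effect size d = 1 with 40 eyes must exceed 0.9.

## Pipeline and reproducibility

A run is a `RunConfig` (YAML-serializable) plus a seed; artifacts are plain
CSVs stamped with the config hash and seed, written with a fixed float
format so reruns are byte-identical. Stages communicate only through
artifacts and can be re-run individually. Figures show group mean ± SEM
percent change by day with post-hoc stars.

Validation problem sizes (chosen to give stable estimates at desk scale):
200 sessions for latency recovery, 100 randomized fixtures for oracle
equivalence, 1000 replicates for the averaging-gain check, 2000/1000
replicates for type-I/power calibration, and the full two study designs
(56 and 108 eyes, 3 × 20 sweeps per session) for stratification recovery
and the end-to-end contrast pattern.

## Known limitations

* The prominence floor (15%) and hyperpolarization depth (20%) are scale-
  relative heuristics; traces whose genuine P1 is under 15% of the dominant
  deflection would need the floor lowered.
* EDF export quantizes to 16 bits over the configured physical range
  (≤ 0.01 µV error at ±300 µV); the writer targets EDF+C with one EEG
  channel and flash annotations, not arbitrary montages.
* Percent-change endpoints inherit latency quantization (0.244 ms ≈ 0.5% of
  a 50 ms latency per session); at the default SNR, eye-level endpoint noise
  is ~1%, so effects well below ~3% per-eye are not resolvable at these
  group sizes.
* The normality gate is recorded but the battery always takes the
  nonparametric branch; a parametric branch is not implemented.
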