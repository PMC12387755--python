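# Methods notes

This note records the model assumptions, parameter choices, numerical
decisions and known limitations of the `epscorr` pipeline, in the spirit of
a package's statistical documentation. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Data model and units

Event times are seconds, amplitudes picoamperes, voltages millivolts,
currents picoamperes, resistances megaohms; file columns carry unit
suffixes (`_s`, `_pA`, `_mV`). One canonical time unit end to end avoids
ms/s conversion bugs. An `EventTrain` enforces sorted times within
[0, duration] and positive amplitudes at construction; a `PairedSession`
enforces equal durations and derives its pair class (LL / LU / UU) from the
two labels. UU sessions are read but ignored by all group analyses.

## Cross-correlation profile

* **Normalization.** R(k) = coincident occupied bins at lag k divided by
  `sqrt(N'_A · N'_B)` with N' the occupied-bin counts. This non-centered
  form keeps R in [0, 1], avoids inflation from joint absence of events in
  mostly empty timelines, and reproduces the expected magnitude scale
  (R ≈ 0.1–0.2 for tens of coincidences among hundreds of events).
* **Lag grid.** 21 lags kΔ for k = −10…10 with Δ = W/10, so the grid spans
  exactly ±W; the center bin is the same-bin (zero-lag) coincidence count.
* **Binarization.** Bin counts are collapsed to 0/1. At ~1 Hz and Δ ≤ 10 ms
  multiplicity within a bin is rare (~1% of bins), and binarization makes
  the coincidence-count interpretation exact — the double-loop counting
  oracle in the tests agrees to 1e-12.
* **Binning convention.** Half-open bins [bΔ, (b+1)Δ), an event at exactly
  t = T is assigned to the last bin; bin index is `floor(t/Δ)` in floating
  point (the tests' oracle shares this primitive, since one-ulp differences
  at representable bin edges are a float artifact, not a counting issue).
* **Chance level.** For independent stationary Poisson trains,
  E[R(k)] ≈ `sqrt(N_A·N_B)·Δ/T`; the tests verify flatness and level at
  Δ = 5 and 10 ms over 50 seeds.

## Jitter null

Per iteration one offset ~ Uniform(−J, +J) (J = 0.5 s, K = 100 by default)
shifts *every* event of the second-listed cell (`train_b`) with circular
wrap modulo the duration. A fixed designated cell, rather than a random
one, keeps the null exactly reproducible; wrapping preserves event count
and rate so aligned and null profiles are directly comparable. Offsets much
larger than the detection window destroy shared structure, so the ensemble
mean center-bin value relaxes to the Poisson chance level; iterations whose
offset happens to fall within the window retain genuine coincidences and
are part of the null as constructed.

## Pooled threshold

θ = mean + 2·SD (sample SD, n−1) over the pooled 21 × n_sessions lag values
of *both* pair classes for a given window — one θ per window. Threshold
crossing uses strict inequality (R > θ). Pooling across classes is a design
choice: it reads "total mean correlation" as the grand pool and makes θ a
property of the cohort, not of a group.

## Alignment ANOVA

Two-way ANOVA on center-bin correlations with factors alignment
(aligned/jittered) and pair class (LL/LU), Type II sums of squares because
group sizes are unequal (7 vs 8), via `statsmodels` OLS. Post hoc pairwise
cell contrasts use the residual MSE with Šídák family-wise adjustment
1−(1−p)^m, computed via `expm1/log1p` to avoid underflow at tiny p. An
all-constant response is reported as degenerate (all SS = 0, F undefined)
rather than an error. By default every jitter iteration enters as an
observation; a per-session jitter mean is available
(`jitter_summary="mean"`) when a balanced 2-observations-per-session layout
is wanted.

## ROC construction

Histogram grid fixed at 0–0.5 in 500 bins of 0.001; left-closed bins with
the final bin closed at 0.5 (numpy's convention) so edge assignment is
deterministic; values above 0.5 are clipped into the top bin with a
warning. The reverse cumulative sums normalized by group size trace
TPR/FPR from the highest threshold down, and the trapezoidal area is the
AUROC in percent. On the binned values this construction is algebraically
the Mann-Whitney U/(n₁n₂) with ties counted half — the tests exploit this
as an independent oracle. Agreement with ranks of the *raw* values is only
as fine as the 0.001 discretization, which matters when two values share a
bin.

## Synthetic paired trains

The generator realizes the study conditions rather than being a free dial:

* per-cell rate r (default 1.0 Hz) split into a shared Poisson source at
  rate c·r copied into both cells and independent backgrounds at (1−c)·r;
* each shared copy jittered independently per cell by N(0, σ_c²) with
  σ_c = 2 ms, modeling a common presynaptic source with independent
  synaptic latencies (pairwise offset SD √2·σ_c);
* detector-style dead time of 2 ms enforced by merging (keep earliest), not
  redrawing, so the Poisson law is otherwise untouched;
* amplitudes i.i.d. lognormal (median 16.69 pA, log-SD 0.39, matching a
  median/IQR of roughly 16.7/8.8 pA), independent of timing since timing
  and amplitude analyses are separate;
* the default cohort is 7 L-L sessions at c = 0.08 and 8 L-U sessions at
  c = 0, with per-session rates and durations drawn around 0.89 Hz/498 s
  (L-L) and 1.06 Hz/397 s (L-U) — SDs chosen as the reported group SEMs
  scaled by √n — reproducing the recorded cohort's count/rate/duration
  envelope. c itself has no measured ground truth; 0.08 is calibrated once
  so the synthetic center-bin correlations land on the observed ~0.05–0.12
  scale.

**Shared-fraction recovery.** E[R(0)] ≈ c·p_det + chance, where
p_det = E[(1−|u|/Δ)₊], u ~ N(0, 2σ_c²), is the closed-form probability that
both copies of a shared event fall in the same bin (≈0.77 at σ_c = 2 ms,
Δ = 10 ms; ≈0.49 at σ_c = Δ/2). The estimator therefore divides the excess
over chance by p_det; without this attenuation correction the estimate is
biased low by a factor p_det and cannot meet a ±0.02 recovery band once
σ_c approaches Δ/2.

What the generator does **not** emulate: amplitude-timing dependence,
bursting/refractory structure beyond the dead time, nonstationary rates,
and recording noise in event detection. Passing tests therefore demonstrate
correctness of the analysis chain under Poisson-like conditions, not
robustness to every property of real recordings.

## Synthetic sweeps and feature extraction

Sweeps are built by **template insertion** on a passive membrane model
(exponential charging toward RMP + R_in·I, τ = 15 ms), not by a conductance
model: the purpose is exact ground truth for the extractor. The spike
template is piecewise linear with nodes snapped to the 10 kHz sample grid: a
shallow approach ramp (≤5 mV/ms, below the detection criterion), a
symmetric triangular spike whose width at half amplitude equals the
programmed half-width, a fast AHP trough at +2 ms, recovery to a plateau
1.5 mV below threshold, and a medium AHP dip bottoming at +25 ms inserted
when the next spike is ≥48 ms away. Spike trains use geometric ISI growth
(programmed divisor adaptation ratio) and geometric per-spike amplitude
decay (programmed 15th/1st attenuation ratio) with a 45 mV amplitude floor
so late spikes in long trains stay above the peak-detection level, as real
attenuating spikes do. Gaussian noise (SD 0.2 mV) is additive.

Extraction decisions:

* threshold by the first-derivative method, criterion 20 mV/ms
  (configurable) — the standard criterion range is 10–30 mV/ms;
* 200 kHz interpolation uses a shape-preserving piecewise cubic (PCHIP)
  rather than a natural cubic spline: a global spline rings at the fast
  rise/fall of a spike and biases the derivative-criterion threshold by
  ~1 mV, while PCHIP is monotone between samples;
* amplitude and AHP depths are referenced to the threshold voltage of that
  spike; AHP search windows (0–3 ms fast, 10–50 ms medium) are anchored at
  the spike peak — a reproducible fiducial — and truncated at the next
  spike's onset and at the pulse offset; a window truncated below 80% of
  its span is reported NaN rather than mismeasured;
* first-spike latency is pulse onset to first AP peak; the divisor
  adaptation ratio accepts ≥3 spikes (first and last interval share the
  middle spike at exactly 3); the attenuation ratio needs ≥15 spikes, else
  NaN.

Round-trip tolerances (50 random configurations, frozen in the tests): RMP
±0.5 mV, R_in ±2%, threshold ±1 mV, amplitude ±1.5 mV, half-width ±0.1 ms,
fAHP/mAHP ±1 mV, latency ±1 ms, adaptation ±0.03, attenuation ±0.05. The
AHP tolerances absorb a small positive bias (~0.3 mV) from taking a minimum
over a noisy window.

## QC and matching

Sessions below the configured minima (defaults: 100 events per cell, 120 s
duration, 0.2 Hz per-cell rate — placeholders, since no published numeric
cut-offs exist) are excluded with a named reason. Group matching reports
pooled-variance Student t-tests (Welch optional) for per-session event
count, duration and rate between LL and LU.

## Problem sizes

Defaults everywhere are the study-scale conditions (15 sessions of
~400–500 s at ~1 Hz; 100 jitter iterations; 1000 repeats for the chance
AUROC; 50 seeds for seed-averaged checks; 50 random sweep configurations
for the extractor round trip). The full test suite runs in well under a
minute of CPU on these sizes.

## Known limitations

* The K-S p-value is the asymptotic approximation; with hundreds of events
  per cell the exact method adds nothing, but for n < 25 prefer
  `scipy.stats.ks_2samp(..., method="exact")` directly.
* The jitter null conditions on the aligned event times of the non-jittered
  cell; it is a null of *temporal alignment*, not of rate heterogeneity.
* Peri-occurrence is reported both as the window maximum (R_max) and as the
  maximum excluding the center bin, since both readings exist in practice;
  downstream summaries use R_max.
* The AUROC construction has no variance estimate attached; it is a
  descriptive classification measure, not a test statistic.
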