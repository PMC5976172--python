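# Methods

This note documents the models and procedures `dendricap` implements,
the defaults it ships, and what its synthetic-data tests do and do not
demonstrate about real recordings.

## Two-compartment capacitance decomposition

A Purkinje neuron under somatic voltage clamp is modelled as a
two-compartment equivalent circuit: a somatic/proximal compartment of
capacitance C1 charged through the series resistance R1 (pipette access
plus somatic internal resistance), and a distal dendritic compartment of
capacitance C2 coupled through the intermediate dendritic resistance R2.
After a voltage step ΔV the capacitative current decays as

    I(t) = A1·e^(−t/τ1) + A2·e^(−t/τ2),

and the circuit follows algebraically:

    C1 = τ1(A1+A2)² / (A1·ΔV)      C2 = A2·τ2 / ΔV
    R1 = ΔV / (A1+A2)              R2 = ΔV/A2 − ΔV/(A1+A2)

With pA/ms/mV units these come out in pF and GΩ; resistances are
reported in MΩ. The fast component (τ1 < τ2) is somatic by convention.
The closed-form inverse of these equations
(`compartments_to_biexponential`) drives the simulator and is
property-tested as an exact round trip.

**Preprocessing.** Ten repeated sweeps are averaged; the average is
low-pass filtered (zero-phase 4th-order Butterworth, 5 kHz cutoff); the
steady-state leak is estimated as the mean current over the final
100 ms of the step and subtracted, so the corrected transient decays to
zero. Cells with input resistance below 100 MΩ are excluded (strict
inequality: 100 MΩ exactly passes).

**Fitting.** Nonlinear least squares with a peel-off initialization
(log-linear fit of the slow tail, then of the fast residual). The fit
window runs from one sample after the post-step peak of |I|, plus a
guard interval of 5/f_c (1 ms at the 5 kHz cutoff), to the end of the
step: the zero-phase filter's edge response rings for several filter
time constants around the step edge, and fitting inside that region
biases the fast component by a few percent. Away from the edge a
filtered exponential is again an exact exponential (the gain error at
these time constants is ~1e−10), so the guard removes the bias without
touching the estimand. Time in the model is measured from the step
onset, so amplitudes always refer to onset regardless of the window.
The model includes a constant offset absorbing residual leak error,
constrained to ±5% of the peak current. Windows longer than 20 000
samples are uniformly strided down before fitting — a 1 s step at
100 kHz oversamples a 10 ms time constant enormously, and striding
changes the estimates negligibly while keeping each fit ~100 ms.
Non-convergence and collapsed time constants (τ1 ≈ τ2) are flagged,
never silently returned.

## Spike features

* **Threshold** — the earliest point on the upstroke where dV/dt
  (central differences on the filtered trace) reaches 5% of its maximum
  within the spike window.
* **Amplitude** — peak minus anti-peak, where the anti-peak is the
  minimum between a peak and the following spike's threshold (or the
  end of the analysis region). Per-trace statistics average all spikes
  in a fixed-duration region (10 s by default).
* **Half-width** — the time above the level halfway between threshold
  and peak, with linear interpolation between samples (sub-sample
  accuracy is essentially free at 100 kHz and removes quantization
  bias). Per-cell values average the first five consecutive spikes.
* **Junction potential** — recorded voltages are corrected by
  subtracting 10 mV (the true membrane potential is more negative than
  the pipette reading for a K-gluconate internal). The sign convention
  is configurable; a metadata flag makes the correction non-repeatable.

Amplitude and half-width inputs are deliberately independent operations:
the two statistics may come from different recordings of the same cell.

## Distance-dependent attenuation and the nested F test

bAP amplitude versus soma-to-patch distance x is fit with the
two-parameter decay y = A·e^(−bx), half-width with the growth form
y = A·e^(bx). Fits are unweighted nonlinear least squares on the
original scale; the log-linear regression of ln y on x serves only to
seed the optimizer (a global, deterministic start). The length constant
λ = 1/b is reported to one decimal. Zero responses (distally clipped
noisy amplitudes) may enter the least-squares objective but not the
log-linear initializer.

Group comparison uses the extra sum-of-squares F test for nested curve
models: RSS_pooled from one curve on all n points (df = n−2) against
RSS_sep from one curve per group (df = n−4);

    F = ((RSS_pooled − RSS_sep)/2) / (RSS_sep/(n−4)),

referred to the F(2, n−4) upper tail. Calibration is verified by
simulation: with both groups drawn from one curve (σ = 2 mV, n = 12 per
group) the empirical type-I error over 1000 seeded replicates is ~0.05,
and power at the planted wild-type/mutant rate difference exceeds 0.9.
Parametric standard errors from the fit covariance give ~95% CI
coverage for b in the same regime.

## Dendritic calcium-spike threshold

The detection criterion is a package default, configurable and logged:
a step response contains a calcium spike when it exceeds the passive
prediction by ≥ 20 mV for ≥ 2 ms during the step. The passive
prediction scales the smallest step's deviation from baseline by the
current ratio (the smallest step is assumed subthreshold). The
threshold current is the smallest step with a spike; a spike present at
some step but absent at a larger one is reported at the smallest step
and flagged non-monotonic rather than discarded.

Input resistance is the slope of the steady-state V–I relation
(steady state = mean over the final 20% of the step) restricted to
steady-state potentials between −80 and −75 mV, which excludes the
voltage range where active conductances distort the relation. Fewer
than two in-window steps yields a flagged missing value.

Non-firing-cell usability follows a strict decision table: firing ⇒
usable; non-firing and baseline Vm ≤ −45 mV ⇒ excluded (slicing
injury); non-firing, depolarized, hyperpolarizing below −55 mV under
TTX + CdCl₂ ⇒ usable (depolarization block); otherwise excluded;
missing blocker measurement ⇒ pending, never a silent default.
Inequalities are strict on both bounds, following the
"more depolarized/hyperpolarized than" wording of the rules.

## Channel-gene screen

The screen consumes published differential-expression statistics (fold
change mutant/wild-type, p, q) and never recomputes them. Tables are
subset to the 145-gene voltage-gated ion channel superfamily with
official IUPHAR classification; significance is q ≤ 0.05 *inclusive*;
heat maps are log₂ fold changes with rows optionally restricted to
significant genes per timepoint; the persistent set is the intersection
of significant sets at the two ages, with per-age direction. The
packaged channel list (`data/vgic_channels.csv`) is a pinned snapshot
assembled from the IUPHAR superfamily structure (Kv, KCa, Kir, K2P,
Cav, Nav, CatSper/TPC, CNG, HCN, TRP, Hv) totalling exactly 145 mouse
gene symbols; because the classification evolves, the list is shipped
as data and can be replaced by a caller's own file.

## Synthetic-data generators

Every generator is a pure function of (spec, seed) — the same inputs
reproduce bit-identical output — and each zero-noise output agrees with
its closed form at every sample.

* **Capacitance sweeps**: the biexponential-plus-leak current of a known
  circuit, sampled at 100 kHz, plus additive i.i.d. Gaussian current
  noise (5 pA per sweep, 10 sweeps by default). The defaults
  (C1 = 112.5 pF, C2 = 500 pF, R1 = 6.67 MΩ, R2 = 13.33 MΩ,
  R_input = 150 MΩ) describe a healthy adult Purkinje neuron and pass
  the 100 MΩ QC bar.
* **bAP datasets**: one cell per distance (10–120 μm in 10 μm steps,
  n = 12), amplitude a0·e^(−b·x) plus 2 mV Gaussian noise clipped at 0,
  half-width hw0·e^(b_hw·x) plus 0.02 ms noise.
* **Spike trains**: piecewise-linear stereotyped spikes with onsets
  snapped to the sample grid, so planted amplitude and half-width are
  exact to round-off. Ground truth is returned with the trace.
* **Current-step families**: passive charging curves (τ_m = 15 ms)
  whose slope is set by the planted input resistance, with an identical
  alpha-function depolarization (35 mV, 4 ms time-to-peak ⇒ ≥ 20 mV
  excess for ~8.5 ms) superimposed on every step at or above the
  planted threshold — all-or-none by construction. This generator
  defaults to 10 kHz sampling: the slow events it carries are fully
  resolved there, and a 13-step family stays small; the rate is
  configurable like the others.
* **Expression tables**: exactly the requested number of channel genes
  with q ≤ 0.05 (fold-change magnitudes log-uniform in [1.5, 3] with
  random direction), all other channel genes q > 0.05 with fold changes
  near 1, and 5% of non-channel filler genes also significant so the
  channel subset is a genuine subset of a larger screen.

The noise model everywhere is additive i.i.d. Gaussian — the simplest
model sufficient for calibration. Real recordings differ in ways these
generators do not emulate: correlated (1/f and line) noise, electrode
drift, series-resistance changes, bridge-balance error, biological
cell-to-cell variability beyond a single noise scale, and true channel
kinetics (the calcium-spike bump is a parameterized waveform, not a
conductance model — only its all-or-none appearance above threshold
matters to the analysis). Passing tests therefore demonstrate
correctness of the estimators under the stated statistical assumptions,
not robustness to every artifact of slice electrophysiology.

## Numerical choices and degenerate inputs

* Component ordering is fixed τ1 < τ2; a2 = 0 denotes a
  single-compartment cell (C2 = 0, R2 undefined, flagged).
* Amplitude signs follow the transient (negative for hyperpolarizing
  steps); the compartment equations then give positive circuit values
  for either step polarity.
* Fits driven to b = 0 are flagged flat; R² of a constant response with
  zero residual is defined as 1.
* Identical data in both F-test groups gives F clamped at 0 and p = 1;
  RSS_sep = 0 is handled in the limit (F = ∞, p = 0) and flagged.
* Missing features (no spikes, too few spikes, no half-level crossing,
  too few in-window steps) return NaN-flagged values, never silent
  defaults; invalid inputs raise a validation error naming the field.

## Problem sizes

Default problem sizes were chosen so the whole suite runs comfortably
on a laptop: 200 replicates for noisy capacitance recovery, 1000/500
replicates for F-test type-I/power calibration, 12 cells per synthetic
attenuation dataset, 2000-gene screens, 13-step current families.
These match the sizes at which the calibration statements in this note
were computed.

## Known limitations

* No mixed-effects or per-animal nesting in the attenuation models:
  cells are pooled across animals, as in the analysis this package
  reproduces; a hierarchical extension would be the natural next step.
* No conductance-based neuron simulation; the generators reproduce the
  statistical structure the estimators assume, not biophysics.
* The calcium-spike detection criterion (20 mV / 2 ms above passive) is
  a package default, not a community standard; sensitivity to it should
  be reported alongside any real-data use.
* The passive prediction assumes the smallest current step is
  subthreshold; a family whose smallest step already spikes will
  under-detect.
* The packaged 145-gene list is a pinned approximation of the official
  classification at one point in time; users comparing against a
  specific supplementary table should load that table's own gene list.
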