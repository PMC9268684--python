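# Methods

This note documents the models, conventions, and numerical choices behind
dgephys, and what the synthetic-data generators do and do not emulate.

## Extracellular unit features

Input is one mean spike waveform per sorted unit (μV, default 20 kHz; one
sample = 0.05 ms) plus the unit's spike times in seconds.

**Trough-to-peak latency.** Extracellular spikes are negative-going: the
trough is the waveform's global minimum, the peak the first local maximum
after it.  Latency is the time between them.  Two refinements:

* *Noise guard.* "First local maximum" is restricted to maxima rising at
  least 50% (configurable) of the largest post-trough excursion above the
  trough; otherwise a single noise sample on the rising flank would
  terminate the search early.  For unimodal post-trough shapes this equals
  the plain rule.
* *Sub-sample interpolation.* A 3-point parabolic fit around each extremum,
  on by default.  The vertex offset is clamped to ±half a sample.

Waveforms whose global maximum precedes the global minimum are treated as
polarity-inverted, flipped with a warning (configurable off).  A trough at
the first/last sample, or no positive-going local maximum after the trough,
is a degenerate waveform: the unit keeps its spike-train features and is
reported unclassifiable rather than aborting the run.

**Burst index (BI).** ISIs between successive spikes are counted in two
half-open windows, [0, 10) ms and [200, 300) ms.  The default index is the
ratio of mean per-ms frequencies, (n_early/10) / (n_late/100), which makes
the index dimensionless and comparable to the 1.8 bursting threshold even
though the windows differ in width; the raw-count ratio is available as an
option.  An empty early window gives BI = 0 regardless of the late window;
an empty late window with a populated early window gives BI = +inf with an
explicit flag.  These zero-window rules keep the classifier total without
inventing pseudo-counts.  Histogram bin width is 1 ms (the choice does not
affect BI, which is computed from window counts directly).

**AHP derivative metric.** The first derivative (central differences, μV/ms,
one-sided at the boundaries) is taken over the mean waveform, and the metric
is the maximum |dV/dt| in the window strictly after the post-trough peak.
Working on the derivative removes the amplitude attenuation from variable
electrode-to-cell distance (the metric is homogeneous of degree 1 in
amplitude, so a *ratio*-based threshold on a bimodal population is robust).
The exact window/extremum convention is not pinned down by the published
threshold alone; post-peak max |dV/dt| is the default, with post-peak
most-negative and full-tail variants available.

**Firing rate.** Spike count over recording duration.

## Classification

Staged thresholds: latency ≤ 0.4 ms → putative PV; else BI > 1.8 →
putative excitatory, split at 70 μV/ms into putative mossy (< 70) and
putative granule (≥ 70); else wide interneuron.  Boundary conventions:
0.4 ms counts as narrow; BI exactly 1.8 is not bursting; AHP exactly at
threshold goes to granule (configurable).  A unit that is both narrow and
bursting is resolved by precedence, latency-first by default — a
fast-spiking narrow unit can easily exceed BI 1.8, so the physiological
reading takes latency first; the bi-first order is kept as an option and
both are tested.

**Data-driven AHP split.** With `ahp_threshold_mode="data_driven"` the AHP
values of units reaching the excitatory stage are density-estimated
(Gaussian KDE, Scott bandwidth, 512-point grid).  The two highest local
maxima are the modes; the threshold is the midpoint of the minimal-density
plateau between them.  The plateau rule matters: with well-separated modes
the inter-mode density underflows to a flat ~0 stretch and a bare argmin
would sit at an arbitrary end of it.  Bimodality is asserted before
returning (valley density ≤ 0.9 × the lower mode); on failure the caller
falls back to the fixed 70 μV/ms with a recorded warning.  At least 20
values are required.

## Intracellular analysis

Current-clamp sweeps (default 50 kHz) from a −70 mV holding potential with
square current steps.  Spike onset is where dV/dt first crosses 20 mV/ms
(the published protocol does not state its criterion; 20 mV/ms is a common
convention, configurable) with the voltage subsequently exceeding −20 mV
within 2 ms, and a 1 ms lockout.  dV/dt is boxcar-smoothed over 0.1 ms by
default because raw 50 kHz central differences amplify even 0.1 mV of noise
into spurious threshold crossings; smoothing can be disabled.

F–I curves report spike count over the step window divided by its duration,
ordered by current; duplicate currents are averaged with a warning.  Step
duration defaults to 500 ms (configurable; the protocol is silent).

First-AP properties: threshold = voltage at the detection crossing;
amplitude = peak − threshold; AHP = threshold − minimum within 10 ms after
the peak (window configurable); half-width = time between the two crossings
of threshold + amplitude/2, with linear interpolation between samples
(exact on piecewise-linear test spikes).  Half-width is
threshold-referenced, not baseline-referenced.

## Behavior

SI ratio = phase-2 / phase-1 interaction-zone time (150 s phases).
Defeated animals with ratio < 1 are susceptible; ratio ≥ 1 resilient — the
boundary is assigned to resilient, following the figure-level definition
("SI ratio ≥ 1") over the stricter methods-text wording.  Zero phase-1 time
makes the ratio undefined; such records are flagged `excluded` and kept in
the table rather than mapped to +inf, so no phenotype is invented from
undefined behavior.  Sucrose preference = sucrose / (sucrose + water) × 100.
Marker–SI correlations are Pearson product-moment with two-sided p; missing
pairs are deleted listwise and the effective n reported.

## Group statistics

Each group is screened with the D'Agostino–Pearson omnibus test (needs
n ≥ 8; smaller groups route directly to the nonparametric branch).  All
groups Gaussian-looking → one-way ANOVA, with pairwise post hoc t-tests on
the pooled within-group variance (N − k df) and Bonferroni adjustment
(raw p × number of pairs, capped at 1; all-pairs family by default).
Otherwise → Kruskal–Wallis with tie correction, followed by Dunn's pairwise
z-tests on mean ranks with the standard tie-corrected variance, Bonferroni
adjusted.  Dunn's test is implemented in-package (standard formula) and
cross-checked against a brute-force rank computation in the tests.

Two-factor designs use OLS with type-II sums of squares — a robust default
for unbalanced data that coincides with the classical decomposition when
balanced.  Repeated-measures designs are approximated by adding the subject
as a blocking factor; sphericity corrections are out of scope.  Alpha is
0.05 throughout.  The unit of analysis is the neuron; animal identity is
carried through the tables but not modeled.

## Synthetic data

The generators define the study conditions under which the pipeline is
exercised; every generator is a pure function of its parameters and seed.

**Waveforms.** Piecewise analytic template: flat baseline → cubic-Hermite
descent → quadratic trough cap → cubic-Hermite rise → Gaussian peak-decay
lobe.  This family was chosen so each measured feature is one closed-form
parameter: the trough-to-peak distance is exact by construction, and the
Gaussian decay's maximum |dV/dt| equals the `ahp_slope_uv_per_ms` parameter
(for decay V(u) = P·exp(−u²/2σ²), max |V′| = P·e^(−1/2)/σ, so σ is solved
from the requested slope).  Both extrema sit on the sample grid whenever
the latency is a multiple of the sample period, with mirror-symmetric
±1-sample neighborhoods, making parabolic refinement exact at zero noise.
The peak amplitude is 40% of the trough magnitude.  Default template noise
is 0.25 μV: the input is a *mean* over thousands of spikes, so residual
noise is sub-μV; this matters because central differences at 20 kHz amplify
waveform noise ~14× in the derivative.  Slow decays are truncated by the
3 ms window; the metric stays within 5% of truth for slopes ≥ ~35 μV/ms at
the default amplitudes, which covers both excitatory classes.

**Spike trains.** Poisson mode uses exponential ISIs with refractory
thinning; the kept process is renewal with mean ISI = refractory + 1/rate
(closed form used in the tests).  Bursty mode: Poisson burst onsets,
geometric within-burst counts (mean 3), intra-burst ISIs jittered around
4 ms — placing BI far above 1.8 by construction.  Regular mode: a jittered
lattice at 1/rate (jitter SD 10% of the period), giving BI exactly 0
because no ISI falls in either window.

**Cohorts.** Four classes × four groups (ND, Res, Sus, Sus+Ket), default
5 animals × 2 units per class per animal (160 units — tens of units per
class per group, the order of magnitude of the real recordings), 300 s per
unit.  Class parameters place latencies on either side of 0.4 ms (PV
0.25 ms; others 0.65–0.75 ms), AHP slopes on either side of 70 μV/ms
(mossy 45, granule 105), and train modes on either side of BI 1.8.  Wide
interneurons use the regular mode deliberately: a Poisson train above
~2.5 Hz exceeds BI 1.8 purely from its exponential ISI mass, which would
misrepresent a non-bursting class; PV units stay Poisson and are therefore
genuinely narrow *and* bursting, realizing the precedence sensitivity the
classifier documents.  Unit-level rate scatter is log-normal (σ = 0.35);
group effects are rate multipliers — PV ×1.5 in Sus only, granule ×0.6 in
Sus, mossy ×1.5 in Sus+Ket, all else 1 — encoding the reported effect
directions (PV up and granule down in susceptible animals, both reversed by
ketamine, mossy up under ketamine, wide flat).  The published study gives
no distributional parameters for any class; these defaults are tuned only
to satisfy the classification thresholds with realistic margins, not to
match real dentate statistics.

**Behavior.** Phase-1 time is log-normal (median 60 s of the 150 s phase,
σ = 0.25, clipped to the phase); phase-2 = phase-1 × a log-normal ratio
with per-group median (ND 1.0, Res 1.3, Sus 0.55, Sus+Ket 1.0; ratio
σ = 0.35), so defeated groups produce both phenotypes.  Note the Res/Sus
group labels are a priori draws emulating the post hoc selected
populations.  Volumes are log-normal with sucrose:water medians 3:1 scaled
per group.

**Intracellular sweeps.** Spike count per step = round(max(0, slope ×
(I − rheobase)) × step duration), spikes evenly spaced, piecewise-linear AP
kinetics with grid-snapped vertices so recovered properties match the shape
parameters; 0.1 mV additive noise by default.

**What the generators do not emulate:** spike sorting and its errors,
electrode drift, multi-channel probe geometry, LFP, correlated firing
between units, within-unit rate nonstationarity, video-tracking artifacts.
Passing tests therefore demonstrate correctness of the *analysis* under the
stated statistical structure, not robustness to raw-data pathologies.

## Problem sizes

The test suite and the acceptance script use: a 160-unit default cohort
(300 s per unit) for label recovery; 200 cohorts of 35 PV units per group
for detection power (with an equal number of label-permuted cohorts as the
negative control); 2000 null replicates for test calibration; 20 seeds ×
600 values for bimodal-threshold recovery; and a 90-point generator grid
for feature recovery.  These sizes give Monte-Carlo standard errors well
inside the asserted tolerances.

## Known limitations

* No mixed-effects modeling of the animal level; per-neuron pseudo-
  replication mirrors the published analysis but is a real limitation.
* The BI normalization (per-ms frequency ratio) is an interpretation of
  "ratio of the frequency distribution"; the raw-count alternative changes
  the scale of the index and is provided but not the default.
* The AHP statistic's window/extremum and the intracellular threshold
  criterion are declared conventions, not published facts.
* The data-driven AHP threshold assumes a genuinely bimodal excitatory
  population and at least 20 units; it falls back to 70 μV/ms otherwise.
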