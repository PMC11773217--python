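# Methods

`songrec` models how female crickets recognise the pulse pattern of male
calling song, built around the resonant preference of *Anurogryllus
muticus*: females respond to the conspecific pulse period (Ts ≈ 8.6 ms,
duty cycles 33–80%) and, unusually, to twice that period (2Ts ≈ 17.2 ms) at
high (≈90%) and, weakly, low (≈25%) duty cycle. This note records the
models, the conventions chosen where published parameter tables do not pin
the implementation down, and the limits of what the tests demonstrate.

## Stimuli and scoring

Stimuli are rectangular 0/1 envelopes: pulse duration D (ms) and pause P
(ms), period T = D + P, duty cycle DC = D/T, 400 ms total, rendered by
integer-sample onset/offset placement (no float-modulo jitter at pulse
edges). The fitting lattice is every (D, P) combination in 0.5 ms steps up
to 20 ms — 1600 stimuli; lattices start at one step because a 0 ms pulse is
no stimulus and a 0 ms pause is a tone.

Every model's predicted phonotaxis is the time average of its output over
the stimulus, excluding the first 25 ms and last 10 ms to suppress onset
and offset transients: p = ∫ r(t) dt / (Ds − 35 ms).

## Preference fields

Scattered (D, P, score) records are interpolated onto a regular lattice by
Delaunay-based piecewise-linear interpolation (exact at the data points,
continuous, local), with nearest-inside fill beyond the convex hull and
negative values clipped to zero. Natural-neighbour interpolation satisfies
the same contract; the linear variant is used because it ships with scipy
and passes identical contract tests. Transects are bilinear slices: period
tuning along (DC·T, (1−DC)·T), DC tuning along (D, T−D). Peak significance
between paired per-female scores uses a one-sided paired t-test; with zero
variance of the differences the p-value degenerates to 0.5 (identical
vectors) or 0 (uniform positive shift, with a warning).

## Minimal models

**Autocorrelation** — r(t) = g_ac · s(t) · s(t − Δac): a delay line and a
multiplicative coincidence detector. Peaks at periods Δac/n; response grows
monotonically with duty cycle. Fitted values: Δac = 17.0 ms, g_ac = 0.21.

**Rebound** — the non-delayed path is sign-inverted and filtered by a
two-lobe rectangular kernel (inhibitory lobe −gi over Ti, then excitatory
+ge over Te), rectified, and multiplied with the delayed raw stimulus.
The published equation's double negation leaves the effective sign and
lobe order open; we read the kernel as indexed over time *into the past*,
i.e. the effective convolution kernel is −ge over the most recent Te, then
+gi over the preceding Ti. This single reading reproduces the whole
documented phenomenology with the fitted values (Δrb = 22.93 ms,
gi = 0.045, Ti = 5.06 ms, ge = 0.1, Te = 2.0 ms):

* a rebound transient at each pulse offset, peaking ≈Te after offset;
* a small positive plateau gi·Ti − ge·Te ≈ 0.028 during long pulses —
  reduced but non-zero responses to continuous tones;
* rebound saturation once the pulse covers the Ti lobe, truncation when
  the next pulse arrives within the rebound;
* band-pass DC tuning at Ts peaking near DC 60%.

One consequence: the rectified output vanishes when gi = 0 (not ge = 0) —
under this reading the positive rebound mass is carried by the gi lobe
(the withdrawal of inhibition *is* the rebound). Period-tuning peaks at
fixed D sit up to ~1.5 ms below the idealised law T = (Δrb − D)/n for
n = 1 (less for higher n), because the rebound has finite width and the
best product overlap occurs slightly early; tests assert the law to 1.5 ms.

**Rebound + feedforward inhibition** — an additional delayed pathway
filters the stimulus with a second biphasic kernel (same past-indexed
convention); its negative part is added to the coincidence output and the
sum rectified (threshold 0, gain 1). With the fitted branch parameters
(Δffi = 7.29 ms, gfi = 1.01, Tfi = 2.43 ms, gfe = 0.63, Tfe = 2.45 ms,
rebound base frozen) the inhibition cancels the excitation when both
arrive together, suppressing DC ≈ 50% at 2Ts while sparing higher and
lower duty cycles, with the high-DC lobe dominant.

## Resonate-and-fire neuron

Two coupled variables, dx/dt = b·x − ω·y + gs·s(t), dy/dt = ω·x + b·y,
forward Euler at dt = 0.1 ms, ω = 2π·f_rf/1000 rad/ms, b per ms. Fitted:
f_rf = 109.34 Hz, b = −0.0005, gs = 0.027, spike gain 0.0025. A spike is
recorded on an *upward crossing* of y through 1, with reset x←0, y←1;
because the reset leaves y at threshold, retriggering requires y to fall
below threshold first (a literal ≥ test would spike every step). Each
spike is treated as a unit-area event scaled by the output gain, so the
windowed integral equals gain × spike count — the only scale on which the
fitted 0.0025 produces phonotaxis-sized numbers.

Numerical caveat: forward Euler amplifies a near-undamped oscillator by
|1 + (b + iω)dt| ≈ 1.0024 per step, which dwarfs the fitted damping.
Spike counts are therefore dt-dependent (the subthreshold trajectory
converges first-order in dt, and the tests check exactly that); the
printed integrator and step are used as-is. This artificial amplification
also sustains a non-zero background response at non-resonant periods.

## Five-neuron network

AN1→{LN2, LN3}, LN2→{LN5, LN4}, LN5→LN3, LN3→LN4, rate-based, each neuron
a cascade of delayed-gained input sum → linear filters → static
nonlinearity → optional divisive normalisation (a(t) a first-order
low-pass of the signal, output x/(x0 + w·a)). Functional forms: truncated
Gaussian lobes (mean duration/2 unless stated), truncated decaying
exponentials, a zero-DC differentiated Gaussian (σ = duration/6, second
lobe scaled to the stated gain), sigmoid baseline + gain/(1+e^(−slope(x−shift))),
rectifier gain·max(0, x − threshold). Every nonlinearity is
rest-subtracted (its response to zero input removed, rectifiers
re-rectified) so silence propagates as silence; without this the printed
sigmoid baseline of −0.29 and the −0.003 rectifier threshold make the
network tonically active at rest. The published parameter set has 45 free
parameters once the fixed values (zero thresholds, 1000 ms lobe
truncations, x0 = 1, unprinted unit gains) and the rectifier gain 6.82
shared by LN3 and LN4 (treated as one tied parameter) are accounted for.

Four conventions were fixed once, by calibration against the published
qualitative behaviour, and are recorded in `anurogryllus_network`: AN1's slow
inhibitory Gaussian sits at the kernel origin (as a delayed lobe it
silences AN1 mid-train); LN2's unprinted inhibitory-lobe gain is −0.4
(LN2 then follows the pulse pattern instead of firing only at train
onset); LN5's differentiated Gaussian has leading-edge polarity; LN5's
slow rebound-filter exponential acts positively (with an inhibitory sign
its printed magnitude silences LN5 entirely).

What the configured network reproduces: resonant peaks near 8.5 and
17 ms, no comparable response near 4.3 ms, and an effective delay between
LN3's two input drives of ≈25 ms (cross-correlation lag on an isolated
pulse), matching the published ≈25.3 ms and the simple rebound model's
23 ms. What it does **not** reproduce with these forms: the bimodal DC
tuning at 2Ts with a DC-50% notch attributable to LN2→LN4 inhibition —
the LN5 rebound is smeared over the ~17 ms rebound-filter time constant,
too broad for pulse-by-pulse excitation–inhibition timing at LN4 (the
same mechanism *is* demonstrated by the minimal rebound+FFI model); and
sustained AN1 activity through a 400 ms train under the printed divisive
normalisation (w = 85.75 halves AN1 within the train). The corresponding
acceptance assertions are left failing rather than weakened. The
sustained-activity constraint used when fitting the network is
implemented as a loss penalty: AN1's peak in the last 100 ms of a
conspecific train must reach 50% of its global peak.

## LIFAC peak isolation

τm·dV/dt = −V + I − A, τada·dA/dt = −A; on V ≥ 0.5 mV: spike, V←0,
A←A+10 mV, both frozen for 1 ms. Shared values: τada = 5 ms, α = 10 mV,
Vthres = 0.5 mV, τref = 1 ms; V_reset = 0 (unprinted; the conventional
baseline). The input is the instantaneous rebound-model output scaled by
a single gain of 150 at dt = 0.1 ms, chosen once so that the
membrane-time-constant switch between the published per-period rows
(τm = 8.8 vs 12 ms) reverses the ordering of the ≈9 ms and ≈14–17 ms
peaks along the DC-66% transect — the saltatory-evolution mechanism. At
this calibration preferred stimuli elicit ~50–90 spikes per train; the
printed spike-count thresholds 72 and 125 exceed the respective
variants' peak counts, so those thresholded fields are empty — the count
scale the thresholds imply and the adaptation strength needed for peak
isolation could not be reconciled at any input gain tried (50–400).
Peak-isolation results are therefore stated on raw spike counts;
threshold behaviour is covered by monotonicity tests.

## Fitting

Nelder-Mead (scipy) on the mean squared error between predicted and
target scores over the 0.5 ms grid, multi-start from seeded jittered
initial vectors (restart 0 unjittered), in log-magnitude space with signs
fixed from the start vector so positivity needs no constraints. An
optional polish stage re-runs Nelder-Mead from the incumbent best with a
freshly inflated simplex — on the piecewise-constant spike-count losses
the simplex otherwise collapses on a plateau short of the basin optimum.
Two exact fast paths make grid fits cheap: the autocorrelation score
table is a precomputed windowed cross-correlation (lookup per delay), and
the rebound's rectangular-lobe convolution reduces to shifted differences
of the stimulus cumulative sum, with fractional-sample interpolation of
durations and delay so the objective is smooth in all parameters
(coinciding with the direct simulation at integer-sample values).

Parameter recovery at the study conditions (0.5 ms grid, 400 ms trains,
4 kHz simulation): autocorrelation and rebound recover exactly; the R&F
model recovers frequency and gains to <1% and its damping to <10% when
the optimiser reaches the exact-zero basin. The damping is only
marginally identifiable: |b| = 5×10⁻⁴/ms produces ~18% amplitude decay
over an entire train, and solutions one spike away from the generating
model can carry ~25% damping error, so recovery of that parameter
depends on the multi-start finding the global basin.

## Song-period overlap statistic

The observed statistic is the fraction of a genus-wide sample of
individual song periods inside the closed A. muticus response bands
[6.5, 9] ∪ [13.5, 17] ms. The 68-song sample is reconstructed from the
published species table: the three species with individual specimen
measurements contribute n Gaussian draws at their own mean ± sd (their
raw values are unpublished — this declared stand-in is why the observed
overlap is quoted with a tolerance), and the four species with a single
reported period contribute 10 draws each at sd 0.3 ms (the A. muticus
value). The reconstruction averages 42% overlap across seeds (the real
specimen values gave 45%; the difference comes from boundary species such
as A. arboreus at 13.5 ± 0.3 ms). The null draws 68 periods uniformly on
[0, 40] ms per trial, 100,000 trials: mean 6/40 = 15%, sd ≈ 4.3%
(binomial). The tail probability is the upper Gaussian tail of the
observed fraction under that null; at the published summary values
(45% vs 15 ± 4%) it is ≈3×10⁻¹⁴.

## Song segmentation

Envelope = zero-phase 4th-order Butterworth low-pass (200 Hz) of the
squared waveform, normalised to its peak; pulses are maximal intervals at
or above a threshold fraction (default 0.125, the midpoint of the 10–15%
convention); edge-partial pulses are dropped. Zero-phase filtering avoids
onset bias, but the ~2.5 ms envelope smear still widens pulses at the low
threshold (≈+1.4 ms on synthetic song), so absolute durations are only
accurate to the envelope resolution; onset-to-onset periods are immune to
symmetric smear and recover to ±0.3 ms. Carrier frequency is the
magnitude-spectrum argmax of the raw waveform.

## Synthetic data

The synthetic preference field is a sum of Gaussians in (period, DC)
space mapped onto the (pulse, pause) lattice: amplitude 1.0 at
(8.6 ms, DC 0.56) with sds (1.5 ms, 0.18), 0.9 at (17.2 ms, 0.90) and
0.4 at (17.2 ms, 0.25) with sds (1.5 ms, 0.12), plus an optional weak
peak at (4.3 ms, 0.33). These are fixture constants chosen once so the
transect orderings match the documented behaviour. Synthetic phonotaxis
tables draw 3–8 females per stimulus with unclipped Gaussian score noise
(real phonotaxis scores can fall below 0 or above 1); synthetic song is a
7 kHz carrier gated by the rectangular envelope. What passing tests on
these fixtures do *not* show: robustness to per-female motivation drift,
non-Gaussian score noise, or the irregular stimulus placement of real
experiments.

## Problem sizes

Default test and analysis sizes: 400 ms trains; 1600-stimulus grids at
0.5 ms; 4 kHz simulation for rebound-family models and recovery fits,
10 kHz for autocorrelation, R&F, network and LIFAC; 100,000 Monte-Carlo
trials for the null; 20 reconstruction seeds for the observed overlap.
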