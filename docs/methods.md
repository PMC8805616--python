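# Methods

This note documents the measurement definitions, the synthetic-recording
models used to validate them, the numerical choices, and the known
limitations. Units are mV (current clamp), pA (voltage clamp, inward
currents reported as positive magnitudes), µV (field potentials), seconds
for time axes and ms for reported latencies and time constants.

## Measurement definitions

**Intrinsic properties** are extracted from a 600-ms step family
(−100…+120 pA in 20-pA increments, 200-ms pre-step baseline, 10-kHz
sampling required so spike shapes are resolved).

- *RMP*: mean of the pre-step baseline (≥ 100 ms). A spike inside the
  baseline window logs a warning but does not abort.
- *R_in*: Ohm's law on the −60 pA sweep, (steady − baseline)/I, with the
  steady state averaged over the last 100 ms of the step.
- *τ_m*: least-squares monoexponential fit V(t) = V_ss + A·e^(−t/τ) over
  the first 200 ms of the −60 pA step. The fit sweep matches the R_in
  sweep for internal consistency; the fit reports RMSE and a convergence
  flag, and a flat trace (< 1 mV deflection) raises an estimation error
  rather than returning a meaningless τ.
- *C_m* = τ_m / R_in, computed from the same τ_m and R_in values that are
  reported (single code path).
- *Sag* (−100 pA sweep): 100 × (|peak| − |steady|)/|peak|, where the peak
  is the extremal deflection within the first 200 ms of the step and the
  steady state averages the final 100 ms. The peak is picked on a
  5-ms-moving-average copy of the segment: the raw maximum of a noisy
  trace is a biased statistic (≈ +1.5 points at small deflections), and
  the smoothing suppresses that bias without moving the noiseless
  extremum of responses with ≥ 30-ms kinetics.
- *AP features*: threshold at the first sample of the contiguous run
  (within 10 ms before a peak) where the centered-difference dV/dt
  exceeds 10 mV/ms; amplitude threshold-to-peak; halfwidth at
  threshold + amplitude/2 with linear interpolation at both crossings.
- *Rheobase*: smallest step amplitude whose sweep fires ≥ 1 AP inside
  the step window; resolution is the 20-pA protocol grid; a fully
  subthreshold family yields an undefined flag, not an exception.
- *Firing rate*: AP count in the +80 pA step window divided by 0.6 s.

**Synaptic currents.** Spontaneous events are detected by sliding
scaled-template regression: a unit-peak biexponential template (default
rise 2 ms, decay 12 ms — slow neonatal kinetics) is fitted at every
offset with free scale and offset, and the detection criterion is
scale / SE(scale) (a t-statistic), thresholded at 4. Candidates within
one template rise time merge to the larger; fitted amplitudes < 3 pA are
discarded. At the default threshold the false-positive rate on pure
noise is far below 0.2 events/s because sub-3-pA noise fits are removed
by the floor.

Evoked responses are measured on the trial-mean trace (10–20 stimulus
repetitions; fewer computes with a warning and withholds the responsive
flag): baseline = 10-ms pre-stimulus mean, amplitude = peak inward
deflection within a 50-ms window, onset = first post-stimulus point
where |dI/dt| > 10 pA/ms, rise τ from a monoexponential fit of the
10–90% rising phase, CV = SD/mean of per-trial peak amplitudes. Two
numerical guards matter at realistic noise: the peak is taken on a
2-ms-moving-average copy (the raw max rides on trial-mean noise and
biases amplitudes and paired-pulse ratios upward), and the onset
derivative is computed on a 1-ms-smoothed mean (otherwise the slope
estimate's noise SD at 10-kHz sampling is comparable to the 10 pA/ms
criterion and produces spurious early onsets). Both windows are short
against the 2-ms rise and shift the noiseless measurements by < 1%.
Note the onset criterion is a speed threshold: events smaller than
≈ 25 pA with 2-ms rise never reach 10 pA/ms, so their onset — and hence
responsiveness — is legitimately undefined.

*Responsiveness* of a cell is amplitude > 3 × baseline noise SD **and**
onset within 1–20 ms (the monosynaptic window; later onsets are flagged
putatively polysynaptic). The criterion and window are configurable.

*PPR* = A2/A1 on the trial-mean trace, each amplitude with its own local
10-ms pre-stimulus baseline so the residual decay of the first response
is subtracted from the second. Trial-mean amplitudes (not the mean of
per-trial ratios) are used: the ratio of means is far less biased when
A1 approaches the noise floor, and an A1 at the floor flags the ratio
undefined. Train responses normalize per-pulse amplitudes (local
baselines) to the first pulse.

**Field potentials.** Preprocessing is a third-order Butterworth bandpass
applied forward and backward (zero phase), then integer decimation to
1 kHz; the bandpass is the anti-alias filter, so no second filter is
applied before subsampling. Spectra use Welch's method with
non-overlapping 1-s Hann windows (1-Hz resolution); band power is the
rectangle-rule integral over [low, high). Ramp modulation compares mean
band power in the 1.5 s before ramp onset with the last 1.5 s of the
3-s ramp; per-trial powers (Hann periodogram of each 1.5-s segment) are
averaged across trials *before* the (stim − pre)/pre ratio. Evoked LFP
responses average pulse-aligned, 10-ms-baseline-subtracted epochs over
all pulses and trials; amplitude is the magnitude of the extremal
deflection in a 5–50 ms window regardless of polarity (field polarity
depends on electrode geometry; the sign is kept as a diagnostic) and
delay is the time of that extremum.

**Single units.** MI = (stim − pre)/(stim + pre) over duration-matched
windows (3-s pre immediately before each 3-s stimulation). Units are
classified with a paired within-trial label-permutation test on the mean
per-trial count difference (default 2000 permutations, two-sided,
α = 0.05, seeded and therefore reproducible): activated/inhibited by MI
sign when significant, otherwise unmodulated. Response latency comes
from a pooled PSTH (2-ms bins, 0–50 ms) as the center of the first bin
exceeding the pre-pulse baseline mean + 3 SD for ≥ 2 consecutive bins;
a response concentrated in a single bin (e.g. a perfectly locked spike
with no jitter) does not form a 2-bin run, so the run length is
configurable. Population fractions use the same half-away-from-zero
rounding as the responsive-fraction arithmetic.

**Statistics.** Outliers are removed in a single pass when farther than
1.5 × IQR from the 25th/75th percentile, with type-7 (linear
interpolation) quartiles — the fence rule depends on the quartile
convention, so it is pinned here. The rule is deliberately not
iterated: re-computed quartiles on the kept values can flag additional
points, and repeated application would not converge to the published
convention. Group cells are summarized as mean ± SEM (SD/√n, ddof = 1;
a single value flags SEM undefined). Comparisons dispatch to one-way
ANOVA, two-way ANOVA (statsmodels OLS + type-II table) when two factors
are named, or Kruskal–Wallis for the rank-based path, each followed by
pairwise tests with Bonferroni adjustment (p·m capped at 1). Reports
also verify that any "n/N (x%)" claim reproduces from its own counts
and flag the ones that do not.

## Synthetic-recording models

The generator is the package's oracle: every inserted quantity is known
exactly, and a JSON/CSV manifest accompanies each simulation.

*Current clamp.* Sub-threshold responses follow a leaky RC membrane:
steady deflection I·R_in and monoexponential charging with τ_m. Sag is a
single slow exponential relaxation (τ_sag = 150 ms) whose depth is
solved numerically (Brent) so that the *measured* sag definition —
early extremum vs late steady state — returns exactly the configured
fraction at −100 pA, with the response normalized so the steady
deflection still equals I·R_in. Across steps the sag depth is scaled by
a Boltzmann HCN activation curve of the steady hyperpolarized voltage
(V½ = −100 mV, k = 5 mV): activation is steeply voltage-dependent, so
the −60 pA sweep used for the τ_m fit carries only a small sag
contamination. The residual model mismatch still biases the
monoexponential τ_m fit low by ≈ 5–8% (median ≈ 6% across the test
population) — an inherent property of fitting one exponential to a
two-exponential response, documented rather than hidden.

Action potentials are parametric stereotypes: from the exact threshold,
a linear rise at 100 mV/ms, a 0.2-ms flat peak (so the sampled maximum
equals the true peak at any grid alignment), and an exponential
repolarization toward threshold − 8 mV whose time constant is chosen in
closed form to produce the configured halfwidth. Crossing times are
computed analytically on the noiseless trajectory and waveforms are
pasted starting on the first grid sample at/after the crossing, so the
detected threshold sample is exact; Gaussian measurement noise
(0.3 mV SD) is added afterwards. Spiking dynamics between APs restart
the RC relaxation from the reset voltage, which yields regular,
amplitude-dependent firing and an exactly known rheobase on the
protocol grid.

*Voltage clamp.* Spontaneous events are a homogeneous Poisson process
with log-normal amplitudes (median 7 pA); evoked events occur at
pulse onset + latency with amplitudes governed by a depletion +
facilitation state: resources R (from 1) release a fraction u per
pulse and recover with τ_rec; u starts at U, is incremented by
facilitation and decays back to U with τ_fac (τ_fac = 0 gives pure
depression, for which A2/A1 = 1 − U·e^(−Δt/τ_rec) in closed form).
Trial-to-trial variability multiplies evoked amplitudes by a mean-1
log-normal factor with the configured CV. All events use a unit-peak
biexponential kernel and are listed in the manifest. Baseline noise is
Gaussian (2 pA SD).

*Extracellular.* The LFP is 1/f-shaped Gaussian background plus one
sinusoid per band (at the band center, random phase) whose amplitude is
multiplied by a configured gain inside each stimulation window — power
therefore scales as gain², giving the (stim − pre)/pre = g² − 1 oracle —
plus a negative alpha-function transient after each pulse peaking at
the configured latency with the configured amplitude, plus white noise
(15 µV SD). Units are inhomogeneous Poisson: baseline rate everywhere,
rate × gain inside stimulation windows (so MI → (g − 1)/(g + 1)), with
optional pulse-locked spikes at a fixed latency for latency tests. One
named RNG stream per modality derives from the master seed.

Defaults throughout are the recorded control conditions: deep-layer
membrane parameters (R_in 401.8 MΩ, τ_m 83.9 ms, sag 10.2%, threshold
−42.4 mV, amplitude 71.5 mV, halfwidth 3.56 ms), evoked-EPSC amplitude
63.6 pA with 5.15-ms latency and CV 0.236, spontaneous rate 0.24 Hz at
≈ 7 pA, evoked LFP 144.9 µV at 19.3 ms, and stimulation protocols of
3-s ramps or 5-ms/8-Hz pulse trains repeated 60× at 7-s intervals
in vivo, and 10-ms pulses every 15 s, 2/4/8-Hz trains and 125/250/500-ms
pulse pairs in vitro. Release-model parameters (U = 0.5,
τ_rec = 300 ms) and unit gain (2, baseline 2 Hz) are the documented
oracle regimes. Noise SDs (0.3 mV / 2 pA / 15 µV) were chosen once to
place the synthetic SNR near typical recordings of this preparation.

The validation population for parameter recovery draws 100 cells
uniformly over R_in 150–550 MΩ, τ_m 30–90 ms, sag 4–30%, threshold
−48…−38 mV, amplitude 60–95 mV, halfwidth 1.5–3.6 ms, RMP −72…−64 mV,
rejection-sampled so every cell reaches rheobase within the +120 pA
protocol ceiling (recorded neurons all fired on sustained
depolarization).

## What the generator does and does not emulate

It reproduces the statistical structure the estimators rely on —
RC charging, sag relaxation, stereotyped spikes, biexponential PSCs with
short-term plasticity and trial variability, band-limited oscillations
with stimulus gain, Poisson spiking. It does **not** contain
conductance-based spike generation, voltage-dependent PSC kinetics,
electrode/access-resistance artifacts, non-stationary oscillations,
volume conduction, or spike-sorting errors (sorting is upstream of this
pipeline). Passing recovery tests therefore demonstrates estimator
correctness on in-model data, not robustness to every artifact of real
recordings; the fixed band-center sinusoids in particular make the
8-Hz theta component phase-locked to an 8-Hz pulse train, so evoked-LFP
validation uses oscillation-free configurations.

## Numerical choices and degenerate inputs

Sub-sample positions (AP halfwidth crossings) use linear interpolation;
quartiles use linear interpolation (type 7); proportion rounding is
half-away-from-zero at the requested precision; τ fits use bounded
least squares with analytic initial guesses; zero-deflection sweeps,
empty spike trains, both-zero rates, first amplitudes at the noise
floor, and sub-minimum trial counts all return flagged/undefined values
or warnings rather than raising, while malformed inputs (wrong unit,
non-finite samples, inconsistent protocols, bands outside Nyquist)
raise typed errors at construction or entry. Decimation requires the
input rate to be an integer multiple of 1 kHz. The junction-potential
correction (−8.65 mV, measured for the gluconate electrode solution) is
opt-in, applied exactly once, and recorded on the trace; whether
published resting potentials include it is left to the user.

## Problem sizes

The test suite and the acceptance script use 100-cell recovery
populations, 10–20 trial voltage-clamp cohorts, 60-trial stimulation
blocks, and 100–500-unit classifier calibrations; these sizes make the
Monte-Carlo brackets tight (binomial/SE-based tolerances are stated in
each test) while keeping a full run within a couple of minutes on one
CPU.
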