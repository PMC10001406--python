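# Methods

`measpike` analyzes multielectrode-array (MEA) extracellular recordings of
cultured neural networks the way such studies are analyzed in practice:
continuous voltage is reduced to per-electrode spike trains, the trains to a
per-device feature vector (activity census, firing, bursting, synchrony,
waveform classes), and the device-by-session feature tables to longitudinal
mixed-model statistics.  A ground-truthed generator produces the synthetic
recordings and study designs the test suite validates against.  This note
documents the models, the parameters that matter, and the choices made where
the design was genuinely open.

## Spike detection

Raw traces are high-pass filtered with a zero-phase (forward–backward)
4th-order Butterworth at 300 Hz.  Zero-phase filtering is chosen because the
downstream trough-to-peak width measurement needs undistorted waveform
timing; the effective magnitude response is the square of the single-pass
filter, which preserves the 1 kHz spike band within a few percent and
rejects sub-100 Hz field potentials.

The noise SD of each filtered channel is estimated as `median(|x|)/0.6745`,
the median-based scale that is consistent for Gaussian noise but, unlike the
plain SD, nearly unaffected by the spikes riding on it (a 1% contamination
of large spikes moves it by under 3% while inflating the plain SD by more
than 10%).

Events are threshold crossings beyond ±k·σ with k = 8, localized to the
extremum sample rather than the crossing sample (stable alignment for
averaging).  A biphasic spike can cross both thresholds and produce a
positive and a negative detection ~0.2 ms apart; opposite-polarity pairs
within a 0.5 ms dedupe window therefore collapse to the larger-magnitude
event.  Surviving events are separated by a 1 ms dead time.  Dead time,
dedupe window and the snippet window (0.6 ms before to 1.0 ms after the
extremum) are package defaults — commercial detectors do not publish theirs
— and all are configurable.  Detection is invariant to global gain: scaling
the trace and σ together leaves event times unchanged.

## Activity census and aggregation

An electrode is active when it registers at least 10 spikes in the
recording, applied as an absolute count on the standard 10-minute session.
For other durations a `rate_scaled` flag prorates the threshold; the
absolute rule remains the default.  Statistics are per-device: features are
unweighted means over the active electrodes.  Burst features average only
over active electrodes that contain at least one burst — imputing zeros
would conflate "no bursting" with "short bursts" — and the number of
contributing electrodes is recorded; both inclusion modes are available
since published per-electrode burst statistics rarely state this rule.

## Max-interval burst detection

A burst opens at an inter-spike interval ≤ 0.1 s and extends while ISIs
stay ≤ 0.25 s; candidate bursts closer than 0.5 s (last spike to first
spike) merge; merged candidates are re-measured and then filtered to
duration ≥ 0.05 s and ≥ 6 spikes.  The operation order
detect → merge → filter is pinned and tested — merging before filtering lets
two sub-threshold clusters survive as one burst, and the order materially
changes output.  Burst duration is last-spike minus first-spike time.  The
implementation is validated against an independent brute-force checker that
enumerates all maximal windows satisfying the defining predicates.

## SPIKE-distance synchrony

Network synchrony uses the parameter-free, time-resolved SPIKE-distance
between spike trains.  For each train n at time t, with preceding/following
spikes at distances x_P, x_F, local ISI x_ISI, and Δt_P, Δt_F the distances
from those spikes to the nearest spike of the other train:

    S_n(t) = (Δt_P·x_F + Δt_F·x_P) / x_ISI
    S(t)   = (S_1·x_ISI,2 + S_2·x_ISI,1) / (2·⟨x_ISI⟩²)

S(t) is 0 exactly where the trains locally coincide, stays in [0, 1], and is
piecewise linear between the pooled spike times, so its time average (the
distance) is computed exactly from the corner values.  Auxiliary spikes at
the interval endpoints define the profile for sparse or empty trains.  The
original (rate-weighted) form is pinned; the rate-adaptive variant is not
used.  Device synchrony is 1 minus the mean pairwise distance over active
electrodes (equivalently, by linearity, 1 minus the time average of the mean
profile), computed on channel-level trains rather than sorted units; with
fewer than two active trains it is undefined and reported missing.  Tests
check the metric axioms and 1e-9 agreement with an independently coded
direct-definition evaluator.

## Unit assignment and E/I classification

Sparse cultures on wide-pitch arrays nearly always show one unit per
electrode, so unit assignment is deliberately simple: snippets are projected
onto their top two principal components and assigned to modes of the local
density by hill climbing (mean shift), with the kernel bandwidth set to a
pairwise-distance quantile of the projected cloud scaled by a Parzen-style
multiplier of 2.0.  Minor modes holding under 20% of a channel's snippets
are outlier artifacts (e.g. collision-distorted waveforms) and are absorbed
into the nearest major mode, so sparse single-unit channels stay one unit.
Well separated, roughly balanced mixtures (e.g. opposite-polarity units at
SNR 12) still split with ≥95% assignment accuracy; a genuinely unbalanced
mixture below the 20% floor would be absorbed — an accepted limitation for
sparse cultures.  Clusters whose mean waveforms match at some lag
(normalized cross-correlation > 0.95) and whose spike times coincide within
0.5 ms are duplicate detections of one unit and merge.  Channels with fewer
than 10 snippets (the census floor) are excluded from waveform analysis.

The width of the mean waveform is measured from its global minimum
(depolarization trough) to the subsequent global maximum (repolarization
peak), in µs — the extracellular negative-first convention; "peak-trough
duration" in the MEA literature names this same width.  Units are narrow-
spiking/putative inhibitory below 280 µs and broad-spiking/putative
excitatory above; exact equality is assigned excitatory with a tie flag,
since the rule is stated with strict inequalities.  Width resolution is one
sample period (16.7 µs at 30 kHz), an order of magnitude finer than the
160 µs separation between the two waveform classes (~220 vs ~380 µs).

## Longitudinal statistics

Each feature is modeled as y_ij = f_g(t_ij) + u_i + e_ij with a separate
cubic B-spline curve per group, a random intercept u_i per device, and REML
fitting (statsmodels `MixedLM`; gradient optimizers cascade to direct-search
methods when a variance component sits near its boundary).  Boundary knots
sit at the first and last session and interior knots are chosen from the
interior sessions so the basis has exactly one column per session: full rank
on the observed grid, letting each group's curve interpolate its session
means — the saturated mean structure that marginal-mean comparisons at the
session timepoints require.  No penalization is applied.

Estimated marginal means are the fitted curve values; contrasts
(each later timepoint vs baseline within group, and group pairs at each
timepoint) use delta-method standard errors from the fixed-effect
covariance.  That covariance is computed explicitly by GLS at the
estimated variance components, (Σ_d X_d′V_d⁻¹X_d)⁻¹ with
V_d = σ̂_e²I + σ̂_u²J per device, which is positive semidefinite by
construction — the observed-information covariance a mixed-model optimizer
reports can be indefinite near a variance boundary.  Degrees of freedom follow a between-within residual partition:
contrasts comparing groups (between-device information) use
n_devices − n_groups, within-group time contrasts use
n_obs − n_devices − (k_fixed − n_groups).  Plain residual df on
between-device contrasts is anti-conservative; the partition keeps the
null family-wise error of Holm-adjusted between-group contrasts at or below
0.05 in simulation.  All contrasts for one feature form a single Holm
step-down family by default (matching per-figure significance marking);
the family definition is configurable.  Sessions whose features are
uncomputable (no active channels after an insult) are dropped, not imputed.
The E/I percentage at the final session is compared between cultures with a
two-sided pooled-variance Student's t-test.

## Synthetic data: what it emulates, and what it does not

Each simulated channel superposes a homogeneous Poisson "tonic" train with
burst episodes from an explicit two-state renewal construction: onsets
arrive at `burst_onset_rate`, each episode draws its spike count uniformly
from {6…12} and its intra-burst gaps uniformly from 20–80 ms.  The
parameter constraints (gaps < 0.1 s, ≥ 6 spikes, shortest episode ≥ 0.05 s,
expected onset spacing minus maximal episode span > 0.5 s, enforced at
validation) guarantee every generated episode is detectable under the five
max-interval criteria — bursts are generated by construction, not fitted.
Synchrony is induced by a device-wide mother process on burst onsets: with
probability `sync_copy_prob` a channel's onset is a jittered copy
(SD 5 ms) of a mother event, the remaining rate is channel-private.  Onset
coupling (not per-spike copying) matches the network-burst phenomenology of
cultures.

Waveforms are biphasic difference-of-Gaussians templates, trough-normalized,
with trough-to-peak widths of 220 µs (narrow) and 380 µs (broad) placed
trough-aligned at each spike time over additive white Gaussian noise;
spike amplitude defaults to 12 noise-SD.  Spikes closer than the template
span superpose linearly with a warning (configurable to reject).  Traces
are quantized to int16 at the Intan-style 0.195 µV/bit used by the
recording hardware this emulates.

Study scenarios: *maturation* records co- and tri-cultures (8 devices each)
at DIV {7, 10, 14, 17, 21} with monotone increasing activation (0.30 → 0.80),
tonic rate (0.3 → 0.6 Hz), burst rate (0.04 → 0.14 /s) and onset coupling
(0.1 → 0.8); the two cultures share trajectories by default, mirroring a
study design in which culture composition did not change these features.
*lps* records co/tri × control/treated arms (4 devices each) at
{0, 3, 12, 24, 48, 72} h post-exposure from a mature baseline; in the
treated tri-culture arm only, each channel draws an exponential death time
(hazard 0.032/h, ~90% loss by 72 h) and surviving channels' rates decay at
0.05/h, so firing falls faster than the channel census — the
microglia-mediated response pattern.  The hour grid beyond the 3/12/72 h
landmarks is a package choice made for smooth spline fitting.  Device
heterogeneity is a lognormal frailty (SD 0.15 log units) on activity and
rates, constant within a device — the random intercept the mixed model
targets.  Channel identity persists within a device: a channel activates
when the session's activation probability exceeds its recruitment quantile
(monotone electrode recruitment) and, once dead, stays silent.

What the generator does **not** emulate: biophysical membrane dynamics,
local field potentials and oscillations, electrode drift, amplitude
nonstationarity, correlated or non-Gaussian noise, multi-unit electrodes
with overlapping amplitude distributions, and within-burst rate structure.
Passing tests therefore demonstrate that the analysis chain is correct and
well calibrated under its own assumptions — they do not certify detector or
sorter performance on real recordings, where noise structure and waveform
variability are harsher.

## Numerical choices and problem sizes

Detection tolerance for matching a detected event to a ground-truth spike
is ±0.2 ms (half the dedupe window).  Snippet stacks use float64; raw
synthesis uses float32 before int16 quantization.  Trains with duplicate
timestamps are deduplicated at generation; burst detection rejects unsorted
trains.  The dissimilarity profile stores left/right values per segment, so
jump discontinuities at spikes integrate exactly.  Test problem sizes are
chosen to give each check real statistical power while keeping the suite
runnable on one CPU: the detector-fidelity check runs the full 32-channel ×
600 s × 30 kHz geometry; calibration simulations use 500 null replicates
and 100 power replicates; oracle equivalence uses 1000 random trains and
100 train pairs.

## Known limitations

- The valley-seeking sorter is a density-mode stand-in with the same
  intent, not a reimplementation of any commercial algorithm; only its
  testable surface (single-unit default, duplicate merging, width
  round-trips) is pinned.
- Contrast degrees of freedom are an approximation; with very few devices a
  Kenward–Roger-style correction would be preferable but is not available
  in the fitting backend.
- The spline basis interpolates the session grid; it is a description of
  the observed sessions, not a forecasting model between or beyond them.
- Synchrony is computed on threshold-crossing channel trains; sorted-unit
  synchrony would differ on multi-unit electrodes.
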