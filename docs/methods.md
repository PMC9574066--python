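# Methods notes

This note records the scientific and numerical choices behind `neurocfc`:
what each stage computes, the defaults and why, what the synthetic data do
and do not emulate, and the known limitations.

## Stimulation waveform design

The stimulus is an amplitude-modulated gamma carrier riding on a theta
oscillation, `s(t) = (A_fA/2)(sin 2πf_P t + 1) sin 2πf_A t + A_fP sin 2πf_P t`,
with amplitude constants A_fA = 0.2 and A_fP = 0.8 and a gamma frequency
locked to the 16th theta harmonic, confined to 50–100 Hz. Defaults: 1 kHz
sampling, 20-minute duration, 10-s ramps.

- **Theta selection.** The dominant theta frequency is the highest interior
  local maximum of the retention-period spectrum inside 3–8 Hz; when the
  band-restricted spectrum is monotone (no interior peak, e.g. pure 1/f
  background), the band-restricted global maximum is used and the result is
  flagged as a fallback. Ties break toward the lower frequency.
- **Ramp shape** is linear (0→1 over the ramp, mirrored at the end); nothing
  in the protocol constrains the ramp beyond its 10-s duration.
- **Sham timing**: ramp-up immediately followed by ramp-down at session
  start, repeated at session end — total 4 × ramp = 40 s of current for the
  default 10-s ramp. This is one reading of an ambiguous protocol sentence
  ("a 10-s ramp-up and ramp-down for each stimulus") and is isolated in
  `sham_waveform` should a different timing be needed.
- **Initial phases** of both sinusoids are zero at t = 0; no phase-offset
  parameter is part of the design.
- **Peak-to-peak**: treating the theta and gamma phases as independent, the
  formula's range is exactly [−A_fP, A_fP + A_fA] = [−0.8, 1.0], i.e. 1.8 at
  unit current scale (`analytic_extrema`, dense phase grid that includes the
  exact critical phases). The *realized* sampled waveform cannot exceed this
  envelope and typically falls slightly short of it, because with f_A = 16 f_P
  the two phases are locked and the extremal phase combination need not
  occur on the sampling grid; both numbers are reported by the module.
- Waveforms export at 6 significant digits — adequate for a 1 µA device
  resolution.

## Preprocessing

0.5-Hz high-pass (4th-order Butterworth) and 60-Hz notch (second-order IIR,
quality factor 30), both zero-phase (forward–backward). Only the cutoff
frequencies are protocol-level facts; the realizations are ours. Epochs run
from −2.5 to +0.5 s around test-stimulus onset; the 2-s retention period is
split into half-open 1-s halves [−2, −1) and [−1, 0) s so the −1.0 s sample
is counted once. Trials are rejected when any channel exceeds ±100 µV or a
50 µV/ms gradient (max absolute first difference divided by the sample
interval in ms). Rejection is monotone in both thresholds. Manual
eye-movement inspection has no automatic counterpart here and is simply
omitted; the amplitude/gradient rules are the only rejection stages.

High-pass edge transients persist for seconds at a 0.5-Hz cutoff, so tests
and analyses evaluate filter behavior on interior samples via
single-frequency demodulation rather than broadband RMS.

## Morlet spectral analysis

Constant-ratio family: σ_f = f0/7, σ_t = 1/(2πσ_f), normalization
A = σ_t^(−1/2) π^(−1/4) (unit energy at every scale); grid 3–13 Hz in 0.5-Hz
steps. At f0 = 10 Hz this gives 2σ_t = 222.8 ms and 2σ_f ≈ 2.9 Hz. Wavelet
support is truncated at ±4σ_t (tail mass < 10⁻⁴). Per-trial magnitudes are
averaged across trials *before* any squaring; the default output unit is
power (µV², the square of the averaged magnitude), with an amplitude flag
for the raw averaged magnitude — the underlying estimator averages absolute
values, and squared units are provided for results-style reporting. No
padding is applied; samples within 2σ_t of an epoch edge are flagged in an
edge mask rather than extrapolated. Individual peak detection breaks ties
toward the lower frequency and flags band-edge maxima. Z-scoring of
post-minus-pre values across electrodes uses the sample standard deviation
(n−1) and raises on zero variance instead of propagating NaNs.

Because the 3 Hz wavelet needs ≈2.2 s of support, decomposition runs on the
full −2.5…+0.5 s epoch and power is then averaged within the retention
halves, never on the 1-s halves directly.

## Phase-to-power coherence

P_t(f2) is estimated by complex demodulation with a six-cycle Hanning taper
(adaptive window ΔT = 6/f2), squared magnitude, normalized so a unit
carrier yields unit power. Coherency between the phase channel's raw signal
and P_t(f2) is computed from Hanning-tapered Fourier coefficients at f1 over
pooled segments; coherence is its modulus (Cauchy–Schwarz bounds it in
[0, 1], and it is invariant to separate amplitude rescaling of either
channel). Numerical choices:

- Segment length defaults to 2048 samples with 50% overlap **within**
  trials; a trial shorter than one segment contributes a single full-trial
  segment (the taper adapts to its length). Segments never cross trial
  boundaries. At the default 500 Hz / 3-s epochs every trial is one segment,
  so M equals the trial count.
- Power segments are mean-subtracted before the f1 coefficient is taken, to
  keep the large DC offset of a power trace from leaking into low f1 bins.
- Default grids: f1 = 1–13 Hz (0.5-Hz steps), f2 = 20–100 Hz (2-Hz steps);
  both are free choices within the analysis ranges.
- With M independent segments and unrelated inputs, E[coherence²] ≈ 1/M —
  the expected estimator bias, used as a calibration check.

A six-cycle window at f2 has a spectral half-width of roughly f2/3 Hz, so
for a noiseless, perfectly coupled signal the coherence plateaus at 1 over
every f2 whose window still contains the carrier: the argmax over f2 is
then degenerate up to ties. Under the generator's default 1/f noise the
carrier bin dominates and the planted (f1, f2) cell is recovered as the
map argmax; recovery tests therefore run at the default noisy conditions.

Trough-locked spectrograms band-pass the trace at the delta band (4th-order
Butterworth, zero-phase), mark local minima (minimum separation of half a
cycle of the band's upper edge), extract ±1-s windows, and average their
Morlet decompositions (20–100 Hz family).

## Connectivity and network analysis

Relative phases come from a Hanning-tapered DFT over a 1-s window (1-Hz bin
resolution, nearest bin, no zero padding), after common average referencing;
differences are wrapped to (−π, π]. PPC is evaluated by the pairwise-cosine
double sum; it equals the closed form (N·R² − 1)/(N − 1) with R the mean
resultant length, which serves as an independent oracle in tests, never as
the implementation. The analysis pair set crosses the frontal
{Fz, F3, F4, FC1, FC2} and parieto-occipital {Pz, P3, P4, Oz, O1, O2}
regions.

Graph construction from a PPC matrix is not protocol-determined; the
package clips negative PPC to zero, keeps the strongest 30% of positive
edges (proportional thresholding, so graph density is matched between
conditions and sessions), and sets edge distance to 1/weight. All three
choices are configuration knobs. Nodal efficiency uses Dijkstra shortest
paths; unreachable nodes contribute 0 (the 1/∞ convention), so an isolated
node scores 0 and values stay in [0, 1] whenever all finite distances are
at least 1.

## Cluster permutation statistics

*Map test (unpaired, one-sided).* Cells are scored by a rank-sum z
(tie-corrected); cells beyond the cell-defining threshold (α = 0.05) form
clusters under 4-neighbourhood grid adjacency; the cluster statistic is its
size; the null is the distribution of the maximum cluster size over group
relabelings, with the observed labelling included among the n = 5000
samples (so the smallest attainable p is 1/n). When n exceeds the number of
distinct relabelings, all relabelings are enumerated exactly and the result
flagged. The default direction tests treated < sham.

*Channel test (paired, two-tailed).* The per-channel statistic is the mean
post−pre difference; its null comes from within-subject pre/post swaps
(sign flips). Channels beyond the 2.5th/97.5th quantiles of their own
permutation distribution form clusters under spatial adjacency (< 6 cm);
positive and negative clusters are evaluated separately against the
max-cluster null.

Cluster-*size* statistics on integer sizes are discretely distributed, which
makes both procedures conservative rather than anticonservative: on small
grids the empirical familywise error at α = 0.05 can fall well below 0.05.
The calibration test uses a 20 × 20 grid with 8 subjects per group, where
the attained rate is measurably within [0.02, 0.08]; larger or smaller
grids shift it downward, never above α.

*Behavioral analysis.* Normalized change is (post − pre)/pre (a ratio
convention, scale-invariant). The 95% reaction-time filter keeps values
within mean ± 1.96 sd of the subject's correct-trial RTs in a single pass —
the prediction-interval reading; a confidence-interval-of-the-mean reading
would remove nearly all trials at large n. Rank tests use exact null
distributions up to n = 25 where ties permit, otherwise the tie-corrected
normal approximation.

## Synthetic data: what it emulates, and what it does not

Each channel carries (i) a theta oscillation at the subject's planted
frequency whose phase is the trial's hub-channel reference phase plus a
fixed per-channel lag plus wrapped-normal jitter (per-channel sd; the hub
carries none, so hub-involving pairs are the most phase-consistent and the
hub attains top nodal efficiency at jitter contrast ≥ 2:1); (ii) optionally
an alpha rhythm of configurable amplitude with random phase (needed to
plant alpha-power suppression contrasts); (iii) a gamma carrier whose
amplitude follows the channel's own theta phase with depth m in [0, 1]
(peak-coupled, mirroring the stimulus geometry); (iv) 1/f pink noise (the
standard EEG background surrogate) with a configurable exponent. Artifact
trials inject either a smooth 130 µV bump (amplitude rule only) or a ±60 µV
square alternation (gradient rule only), one morphology per planted trial,
with the trial indices and types recorded in the ground truth. Reaction
times are lognormal around per-subject baselines; the treated group's post
session is scaled by the multiplicative `rt_effect` (default 0.85, a 15%
speed-up at the n = 12/group design size).

Simulation defaults reflect the experimental design: 60 trials/session,
500 Hz, epochs −2.5…+0.5 s, theta 5 Hz, gamma 80 Hz, 28-channel 10-20/10-10
montage. Amplitude scales (a_θ = 10 µV, a_γ = 4 µV, noise sd 5 µV) are free
parameters chosen as plausible retention-period magnitudes — no recording
to calibrate against exists in the package — and the tests' conclusions are
about estimator correctness at these signal-to-noise ratios, not about
hardware realism.

Not emulated: biophysical forward modeling, volume conduction (channels are
conditionally independent given the planted phase structure), ocular or
muscle artifact morphology, non-stationarity within a session. Passing
recovery tests therefore demonstrates that the estimators extract what was
planted under controlled conditions, not that they are robust to every
pathology of real scalp EEG.

## Montage geometry

Electrodes sit on a spherical head at their 10-20 arc positions (vertex at
the pole, outer ring at 72° polar angle; 10-10 intermediates by spherical
interpolation along their rows), flattened by an azimuthal-equidistant
projection that preserves scalp arc distance from the vertex. The head
radius is 9.2 cm — an average adult head — giving 20%-step neighbour
distances of 5.5–6.5 cm; a 10-cm radius would push midline neighbours just
past the 6-cm adjacency criterion and disconnect the neighbour graph along
the midline. At 9.2 cm the 6-cm adjacency graph over the default 28
channels is connected and non-complete, with node degrees 1–8.

## Problem sizes

Test-suite simulations are sized for desk-scale runtimes: recovery tests use
5–60 trials, 4–12 channels, 6–12 subjects per group, and 200–1024-sample
coherence segments; permutation calibration uses 200 runs at 500
permutations each. The pipeline's analysis defaults (5000 permutations,
2048-sample segments, full grids) remain the package defaults and are
exercised at reduced cohort sizes in the end-to-end tests.

## Known limitations

- The coherence segmentation scheme (within-trial segments, 50% overlap,
  whole-trial fallback) is one of several defensible readings of a
  segment-based coherency on epoched data; results at other overlap or
  pooling conventions will differ in variance, not in expectation.
- The graph threshold (30% proportional) materially affects absolute nodal
  efficiency; only comparisons at matched density are meaningful.
- Cluster-size inference is conservative on small grids (see above); cluster
  mass would be better calibrated but is deliberately out of scope.
- `detect_individual_peak` assumes a unimodal band peak; closely spaced
  double peaks resolve to the stronger one, flagged only when exactly tied.
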