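# Methods

This note documents the models, parameter choices and numerical conventions
behind `opmbursts`, and what the synthetic validation does and does not show
about real recordings.

## Task model

A session is a sequence of 16 s trials. Task trials contain a bilateral
braille *target* presentation in [1, 3) s, a left/right visual *cue* in
[4, 6) s, and five 260 ms *probe* stimuli at 7.0, 8.1, 9.2, 10.3 and 11.4 s.
Five fixed braille patterns are used, each with exactly 4 of 8 pins raised.
The number of target-pattern presentations on the cued hand per trial is
gamma(shape 4, scale 0.3), rounded to the nearest integer and clipped to
[0, 5]; counts must be integers and only five probe slots exist, and the
discretisation is otherwise unconstrained, so round-and-clip is the natural
rule. Non-target probes land on each hand with independent fair coins;
target probes are by definition on the cued hand with the target pattern.
Cue order is a seeded uniform permutation of a balanced label vector, so a
session of `n` trials has exactly `n/2` left cues (odd `n` is rejected). One
16 s rest block follows every 10 task trials; with 80 task trials this gives
88 × 16 = 1408 s. All windows are half-open `[a, b)` in seconds, and sample
indices are `round(t * fs)`.

Simulated subjects also make response errors: each probe carries a Bernoulli
"incorrect button press" flag (default rate 5%) so the exclusion path used by
the probe analyses is exercised.

## Forward model

Sources are current dipoles inside a homogeneous spherical conductor
(radius 0.09 m); the external field is the closed-form solution
B(r) = (μ0/4π F²)(F Q×r₀ − (Q×r₀·r)∇F), with
F = a(ra + r² − r₀·r) and
∇F = (a²/r + a·r/a + 2a + 2r) r − (a + 2r + a·r/a) r₀. Radial dipole
moments are magnetically silent, so all simulated dipoles are tangential and
the beamformer's orientation search is restricted to the tangential plane.
The spherical model replaces a realistic single-shell head model by design:
it is exact, anatomy-free, and preserves the properties the pipeline depends
on (silent radial sources, linearity, smooth lead fields). Sensors are
triaxial field samplers (one radial, two tangential orthonormal axes) on a
Fibonacci lattice over the upper helmet hemisphere (radius 0.12 m) with a
small seeded jitter.

## Source dynamics

Each region's activity is a 1/f background plus transient oscillatory burst
packets. Burst onsets follow an inhomogeneous Poisson process realised by
thinning: baseline rate 1.2 bursts/s, multiplied by an
`attended_rate_factor` (default 0.65) during the cue window and probe span
of trials whose cue points at the region's driving hand, and by a
`stim_suppression_factor` (default 0.5) for 300 ms after each stimulus on
that hand (and during the bilateral target window). Packet durations are
log-normal (median 0.25 s, σ = 0.4 log-units, clipped to [0.08, 1.2] s);
each packet is a Tukey(0.5)-windowed sum of an alpha sinusoid (~10 Hz) and a
beta sinusoid (~21 Hz, weight 0.6) with random phases and small frequency
jitter — reproducing the pan-spectral (alpha-peaked, beta-shouldered) burst
spectrum qualitatively, without claiming its exact parameters. The dipole
moment scale is 20 nAm; sensor noise is white (default 150 fT per sample at
the simulation rate) plus a spatially uniform drift field built from three
low-pass-filtered (< 2 Hz) random walks.

No quantitative generative burst parameters are established for this
paradigm; the defaults above were chosen once to produce attention and
stimulus effects of the order reported for sensorimotor burst probability
(tens of percent, relative) and are exposed in the configuration, not
asserted as ground truth. Left/right postcentral regions respond to the
contralateral hand; all other regions are task-silent.

## Preprocessing

Welch spectra use 2 s Hann segments with 50% overlap (the classical
default). Channel QC flags any channel whose **median** in-band
(5–150 Hz) amplitude spectral density exceeds 16 fT/√Hz — the median is
robust to narrow line-noise spikes — or whose spectrum is identically zero.
By default the QC spectra are computed on the first 120 s of the recording,
which is ample to estimate a channel noise floor. Trial rejection computes
one pooled SD per trial (over channels × samples) and rejects trials
exceeding 3× the combined-data SD; pooling (rather than any-channel-exceeds)
keeps the rule scale-invariant and simple, and rest blocks are included.
HFC solves the least-squares fit of the three uniform field components
through the channel-orientation matrix `S` and subtracts the fitted
component; the projector is idempotent, and the same projector is applied to
the lead fields before beamforming so that the source model lives in the
corrected subspace (otherwise the minimum-variance weights would retain a
spurious uniform-field component amplified by the regularisation ridge).

## Beamformer

Band-pass filtering is a zero-phase (forward–backward) 4th-order
Butterworth. Covariance is estimated per band over all samples belonging to
kept trials (rest blocks included; a mask argument allows excluding them)
and regularised as C + 0.05 λ_max I. Source orientation is the unit vector
maximising unit-gain output power — the smallest-eigenvalue eigenvector of
Lᵀ C⁻¹ L restricted to the subspace where the lead field is non-null
(singular values above 1e−8 of the largest); its sign is fixed by making the
first non-zero component positive. Weights are the standard unit-gain LCMV
solution computed through a Cholesky factorisation (no explicit inverse).

## Envelope analysis

The Hilbert envelope is computed once on the whole continuous beta-band
virtual electrode (FFT length padded to the next fast size); the first and
last 0.5 s are edge-affected, which no analysis window touches in the
standard schedule. Baseline statistics come from the last 8 s of each kept
rest block. Probe epochs span [−180, +650) ms around probe onset in four
cue × stimulated-hand categories; target probes and error-response probes
are excluded, and attended/non-attended sets for a given stimulated hand are
equalised by seeded random subsampling, mirroring the statistical contrasts.
The cue-window average uses [4, 6) s of trial time and the probe-window
average [0, 260) ms of probe time.

## TDE-HMM

The broadband virtual electrode is polyphase-resampled to the HMM grid
(default 50 Hz in the desk profile, 100 Hz in the full profile), embedded in
a centred window of `n_lags` samples (default 11 at 50 Hz ≈ ±100 ms —
within the range used in the burst-HMM literature), optionally PCA-reduced
(default 6 components), and column-z-scored (scale stored in the model).
Emissions are full-covariance Gaussians; fitting is maximum-likelihood EM
(Baum–Welch) rather than variational Bayes — at this model size the state
decoding semantics are identical and an exhaustive-enumeration oracle can
verify the recursion exactly. Initialisation is k-means on the embedded
rows; restarts use distinct seeds and the best converged log-likelihood wins
(ties to the lowest restart index). Convergence is declared when the
relative log-likelihood gain falls below `tol` (desk default 2e−4, 20
iterations max; full profile 1e−4/100); covariance eigenvalues are floored
at 1e−6 of the mean data variance. The forward–backward recursion is scaled
per step (no underflow) and has a numba-compiled fast path; a pure-numpy
implementation is the fallback and the two are tested for equality.

Posteriors are binarised at strictly > 2/3, so at most one state is active
per sample. The burst state maximises the Pearson correlation between its
binary timecourse and the beta envelope resampled to the HMM grid;
degenerate (constant) state timecourses are excluded with a warning rather
than aborting — a state that never crosses threshold is a legitimate fit
outcome — and an error is raised only if the envelope is constant or all
states are degenerate. Burst events are maximal runs of the burst state;
their amplitude is the peak Hilbert envelope of the broadband series at the
HMM rate within the run. Burst counts use the full-encapsulation rule
(onset ≥ a and offset < b) with windows [4, 6) s of trial time and
[0, 1.1) s of probe time. State-wise spectra are sliding-window DPSS
multitaper estimates (1 s windows, 0.5 s step, NW = 4, 7 tapers) weighted by
each state's mean occupancy per window; a never-occupied state yields a
flagged NaN spectrum, not a fabricated one.

## Statistics

The Wilcoxon sign-rank test drops zero differences, midranks ties, and uses
the exact null distribution of W⁺ for ≤ 25 effective pairs — built by the
generating-polynomial convolution over doubled midranks, so ties are handled
exactly — and a tie- and continuity-corrected normal approximation above.
Two families are corrected separately with Benjamini–Hochberg at q = 0.05
(4 envelope tests; 12 burst-metric tests), matching the two correction
rounds of the analysis design; a flag merges them. Tests are two-sided, with
the effect direction reported alongside.

## Profiles and problem sizes

Two configuration profiles exist. The **full-scale** profile mirrors the
acquisition geometry (1200 Hz, 64 triaxial sensors, 78 regions, 16 subjects,
HMM at 100 Hz with 15 lags and 5 restarts). The **desk-scale** profile — the
default, used by the test suite and `scripts/acceptance.py` — keeps every
algorithmic step and the full 1408 s session structure but shrinks the
geometry and numerical budget to commodity-laptop scale: 200 Hz sampling,
8 triaxial sensors (24 channels), 4 regions (both postcentral plus two
task-silent interference regions), HMM grid at 50 Hz with 11 lags, 6 PCA
components, 1 restart and 20 EM iterations. The end-to-end validation runs
20 seeded 8-subject cohorts with the injected suppression and 20 with the
attended rate factor set to 1.

## What passing tests show — and what they do not

The synthetic generator validates *algorithmic correctness*: linear
source-to-sensor physics, known burst intervals, known effect directions.
Real OPM data differ in ways the generator does not emulate: non-spherical
head geometry and co-registration error, sensor gain/orientation
calibration error, movement and muscle artefacts, non-white sensor noise,
heterogeneous interference beyond a uniform field, and burst dynamics that
are neither Poisson nor stationary within condition. Passing the suite
therefore certifies the implementation, not the neuroscience; effect sizes
and p-values from synthetic cohorts say nothing about human effect sizes.

## Known limitations

- The spherical conductor makes radial sources invisible; regions are
  modelled with purely tangential dipoles, so depth/orientation biases of
  realistic head models are not exercised.
- The HMM is univariate per region; cross-region burst coincidence is not
  modelled or analysed.
- Bursts mix alpha and beta components within one packet; the pipeline does
  not attempt to separate alpha-only from beta-only events.
- With high burst rates, overlapping packets merge into single detected
  events, which couples detected burst duration to burst rate; the
  rate-suppression conditions therefore also shift detected durations
  slightly. This mirrors a genuine ambiguity of threshold-based burst
  detection rather than a bug.
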