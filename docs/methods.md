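# Methods

This note documents the models implemented in `latentnav`, the synthetic
data they are tested against, the numerical choices that matter, and the
limits of what passing tests demonstrate.

## Task and behavior simulator (`latentnav.task`)

The task is firefly-style navigation: a target flashes for 300 ms at a
random location (0.7–4 m, ±40° of straight ahead, uniform over ground-plane
*area*, so the radial density grows ∝ r; a uniform-in-(r, θ) alternative is
available via `TaskConfig.area_uniform_targets=False`), and the subject
steers to the remembered location with a joystick controlling linear and
angular velocity (limits 2 m/s and 90 °/s), stopping inside a 0.6 m reward
zone.  Trials abort at 7 s; feedback follows a truncated-exponential delay
(0.1–0.6 s, mean 0.25 s).

Kinematics are a unicycle — ḣ = ω, ẋ = v sin h, ẏ = v cos h, heading 0
straight ahead (+y), positive ω rightward — integrated by forward Euler at
the behavioral sample rate (833⅓ Hz; error is negligible at task speeds, and
a unit test checks the positions against a midpoint-rule oracle).

Because no subject exists in a synthetic experiment, a steering agent stands
in: it path-integrates its *observed* velocity (true velocity plus
Ornstein–Uhlenbeck sensory noise emulating unreliable optic flow; defaults
sd 0.30 m/s and 12 °/s, correlation time 0.6 s), computes the egocentric
target position from that estimate, and issues saturating proportional
joystick commands (gains 0.9 /s linear on distance, 3 /s angular on bearing,
plus OU motor noise on the deflection).  It releases the joystick when its
estimated distance falls below 0.1 m; a stop is detected when speed stays
below 1 cm/s and 1 °/s for 50 ms.  The noise defaults were calibrated once so
the agent's summary statistics sit where trained subjects sit in this task
(≈61% rewarded, shuffle-referenced AUC ≈0.89, response-regression slopes
≈1.0/0.94); the agent is *not* a model of any subject's control policy, and
no analysis depends on its internals.

Manipulations: `density` multiplies only the agent's sensory-noise scale
(×5 by default — kinematics untouched); `gain` multiplies both executed
velocities by a common factor (1.5× or 2×); `perturbation` adds a
Gaussian-profile velocity pulse (sd 0.2 s, support 1 s, amplitudes within
±2 m/s and ±120 °/s, onset 0–1 s after movement onset).  Disengaged trials —
stationary throughout, or still moving at timeout — are flagged and excluded
from every downstream analysis.

Reaction time is drawn uniform 0.2–0.5 s; nothing constrains this choice and
no analysis is sensitive to it.

## Synthetic neural sessions (`latentnav.neural`)

Spikes are generated from exactly the coupled Poisson model that the
encoding stage fits, so recovery tests compare coefficients directly.  Trial
epochs (target onset to feedback) are binned at dt = 6 ms — the smallest
decay constant of the coupling re-expression basis, making it the natural
resolution — and concatenated on a session clock; filters never cross trial
boundaries.  Per bin the log rate sums boxcar tuning terms over seven
continuous variables (linear/angular velocity, distance/angle to target, LFP
phase, two gaze coordinates), raised-cosine filters of target-onset and
reward events, acausal kernels of two motor channels, a causal spike-history
term, sparse causal coupling terms, and a baseline; emission is Poisson
(counts ≥ 2 allowed) with spike times placed uniformly within their bin.
Generation is sequential so history/coupling act on realized spikes; the
rate is capped at 400 Hz with a warning.

Default ground truth mirrors the qualitative structure reported for parietal
populations in this task: tuning preferences tile each variable's range, with
the documented skews (distance preferences concentrated at small distances
but spread over the full range, angle preferences eccentric), LFP-phase
tuning peaks ~18° before the oscillation trough, target onset evokes an ON
response at ~120 ms latency, and history filters are refractory.  Coupling is
either sparse (explicit source–target–amplitude triples, ~20–50 ms decay) or
dense: every directed pair coupled with random sign and strength decaying
with inter-electrode distance, emulating the continuous, distance-decaying
coupling structure of real arrays.  Sparse truth is the right substrate for
support-recovery tests; dense truth for stability analyses, whose median
pair-filter statistics are meaningless when most pairs carry no signal.  Baselines are
recentred after the behavioral channels are drawn so each neuron's realized
mean rate equals its nominal rate (summed tuning bumps otherwise inflate the
mean because E[e^f] > e^{E[f]}).

The motor channels are an invertible linear mix of the joystick commands
plus substantial independent low-pass noise (sd 0.4, τ 150 ms).  The noise
is essential, not cosmetic: with near-deterministic channels, the acausal
motor kernels span the velocity tuning directions and the model becomes
non-identifiable (fits can trade velocity tuning against motor kernels with
no likelihood cost).  Real hand tracking carries exactly this kind of
joystick-independent variability.  Gaze channels are smoothed noise with
near-flat tuning (amplitude 0.1): they complete the nine-variable predictor
set; their tuning shapes are not recovery targets.

What the generator does *not* emulate: retinotopic receptive fields, real
LFP waveforms (phase only), oculomotor behavior, undershoot biases for
distant targets, non-Poisson dispersion, or slow nonstationarities.  Passing
recovery tests therefore shows the estimators are correct and well
conditioned under the model class, not that the model class captures every
property of real recordings.

## Encoding model (`latentnav.gam`, `latentnav.design`)

Bases: ten equal-width boxcars per continuous variable over its 1st–99th
percentile range at fit time (LFP phase keeps the full circular domain and a
wrap-around smoothness penalty — the only circular variable); ten raised
cosines spanning 600 ms for events ([0, 600] ms causal for target onset,
[−300, 300] ms otherwise, including motor kernels); ten causal log-spaced
raised cosines spanning 350 ms (history) and 1.375 s (coupling), starting at
one bin of lag so no filter acts on the bin it predicts.

The MAP objective is the Poisson negative log likelihood plus λ‖Df‖² per
tuning function, γ‖Dg‖² per event/motor filter, α‖Dh‖² for history (D =
first differences of the reconstructed filter values, matching the printed
prior; defaults λ=100, γ=α=10) and β‖p‖₁ on coupling coefficients (β=10).
Two numerical choices matter:

* *Gauge ridge.* Each boxcar group's columns sum to the intercept, so a
  constant shift of any tuning function is exactly absorbed by the baseline.
  A small ridge (0.5) on tuning weights pins this gauge at zero-mean tuning;
  generated tuning is zero-mean, so the ridge fixes the parameterization
  without biasing shape.
* *Solver.* Proximal Newton: each outer iteration forms the exact Hessian of
  the smooth part, eliminates the smooth block through its Cholesky factor,
  and runs coordinate descent with soft-thresholding on the coupling block
  against the Schur complement; a backtracking line search guarantees
  monotone descent and the stopping rule uses the model-predicted decrease
  (immune to float32 objective noise).  Quasi-Newton methods crawl on this
  design (boxcar/intercept collinearity plus strongly overlapping cosine
  bases); the proximal-Newton path converges in ~10–20 iterations and
  produces exact zeros where the Laplace prior dominates.  Convexity makes
  the optimum start-independent (tested to 10⁻⁶ relative objective
  tolerance).

A note on sparsity strength: at session sizes of a few hundred trials the
per-column Poisson score noise on coupling predictors (≈15–140 in these
units) exceeds β=10, so the MAP solution carries *small* nonzero
coefficients on truly absent pairs — their reconstructed gain stays within
~1% of unity (functionally null) but they are not numerically zero.  Exact
support recovery under these conditions requires β larger by roughly an
order of magnitude (demonstrated in the unit tests); β=10 is kept as the
default because it is the published operating point.

Backward elimination treats each continuous variable, each event filter,
each motor kernel, the spike history, and *all* coupling filters as one
group.  A 10% test split is held out; the rest forms ten trial-level
cross-validation folds (each fold 9% of trials, so selection uses 90% of the
data).  A group is dropped when removing it does not lower the mean CV log
likelihood by more than one standard error of the *paired* per-fold
differences — pairing is essential; unpaired fold variance swamps real
effects at small trial counts.

Goodness of fit: pseudo-R² = 1 − (L∞ − L_M)/(L∞ − L₀) with the saturated
model at μ = observed counts and the null at the mean rate; conventional R²
against rates smoothed with a 60 ms Gaussian, and a population R² pooling
variance sums across neurons.  Marginal tuning curves follow the
factorized-marginal expectation (including the exp(b) factor so curves carry
rate units), with history/coupling gains treated as unity.  Coupling
strength is the time-average of the exponentiated filter (exactly 1 for a
null filter, >1 excitatory); fitted coupling filters can be re-expressed on
seven octave-spaced exponentials (6–384 ms) with a log-log power-law fit to
the weight magnitudes.

## Sequence statistics (`latentnav.sequences`)

Spike times between target onset and movement end are rescaled to [0, 1]
per trial, histogrammed into M = 50 bins (a default; the statistic is
insensitive to M at these scales), trial-averaged, peak-normalized, and
sorted by peak bin (earliest bin wins ties).  Sql uses natural logs with
0·log 0 = 0; silent neurons are excluded; empty rescaled-time bins count as
maximally sparse.  The printed cross-correlogram normalization
R̂ij(τ) = (1/(T r̄ᵢ)) Σ rᵢ(t) rⱼ(t−τ) − r̄ᵢ leaves independent trains at
r̄ⱼ − r̄ᵢ rather than zero; both this form (`baseline="target"`) and the
zero-centered alternative subtracting r̄ⱼ (`baseline="source"`) are
computed and labeled, and tests pin the offset of each.

## Decoding (`latentnav.decoding`)

Rates are causal exponentially smoothed counts (unit-gain kernel, restarted
at trial boundaries).  Per variable, trials split 80/10/10; η is searched on
eight log-spaced points in [25, 250] ms by validation decoding error
ε = √Σ(wᵀRₜ − xₜ)²; performance is the test-split Pearson r.  An intercept
column is included by default (the r metric is offset-invariant, but the
weights then need not synthesize the offset from rate baselines); decoding
uses the bins between target onset and stop, where the latent variables are
defined, and distance/angle to target are the time-varying quantities
recomputed along the trajectory.  Behavioral error is signed as stop
distance minus target distance (negative = undershoot), so an underestimated
distance-to-target pairs with undershooting at positive correlation.  The
surrogate null projects activity onto random mode pairs separated by the
decoder angle φ (v = cos φ·u + sin φ·u⊥); for isotropic activity its mean
correlation is cos φ, verified against Monte-Carlo sampling.

## Stability and dimensionality (`latentnav.stability`)

Filter similarity correlates reconstructed coupling filters per directed
pair, or per-neuron concatenated tuning curves per representation class
(sensory = linear+angular velocity concatenated; latent = distance+angle;
motor = the fitted kernels), always evaluated over the *baseline* fit's
variable domain so range-shifting manipulations stay comparable.  The
shuffled floor uses a random derangement of unit identities.  SI may fall
outside [0, 1] with noisy inputs and is reported unclipped.  CCA runs
iteratively — each canonical pair maximizes the correlation of projections
after residualizing both blocks against all previous canonical variables —
and the task-relevant dimensionality is the participation ratio of the
|covariances| of the unit-norm canonical projections (covariances, not
correlations, as the flatness of the covariance spectrum is the quantity of
interest).  The six task variables entering CCA are the velocities, the two
latent variables, and the two motor channels (LFP phase and gaze excluded).
Coupling-vs-distance profiles bin directed pairs by the exact discrete
inter-electrode distances on the 400 µm grid and summarize |log gain|
separately for excitatory and inhibitory pairs.

## Closed-loop network (`latentnav.rnn`)

Eq. of motion τṙ = −r + tanh(W_rec r + W_in x̃), y = W_out r, with N=100,
τ=20 ms, Euler step dt=10 ms (τ/2).  Channels 1–2 carry a 300 ms pulse whose
amplitude encodes the Cartesian target scaled by the 4 m task range;
channels 3–4 carry the velocity feedback (gain 0.5) plus sensory noise
(sd 0.05/step).  The output is acceleration: integrated once (plus process
noise, sd 0.05/step — without it the network can learn an open-loop policy
and feedback ablation would be free) to velocity, and again to position.
The deadline t* is the arc length of the circle tangent to the initial
heading through the target, over the 2 m/s maximum speed; trials last
clip(t* + 0.6 s hold, 2, 3) s and the loss sums |s − x|² over t > t*, with
optional metabolic terms on ‖y‖², ‖ẏ‖², ‖r‖², ‖ṙ‖² (zero in the base
variant; the activity-amplitude penalty is the one that raises
sequentiality).  Training is hand-written batched BPTT (exact reverse-mode
gradients through the closed loop, including the feedback path; verified
against finite differences) with Adam (lr 2·10⁻³), global gradient clipping,
batch 32, targets resampled every batch, and stops when the behavioral AUC
of fresh rollouts reaches the criterion (default 0.88, the trained-subject
level).  Typical runs reach AUC 0.88 within ~5,000 trials.  Manipulation
retraining freezes W_in/W_out exactly (they are simply never updated);
added sensory noise is evaluated without retraining, motor gain and
feedback-pulse perturbations with recurrent-only retraining.

Unit-level analyses treat the units as neurons: rescaled-time activity maps
use |r| (a silent tanh unit should read as inactive); tuning and coupling
use a Gaussian-likelihood encoding model — ridge regression of (r+1)/2 on
boxcar expansions of the six task variables, with one-step-lagged activities
of all units as history/coupling terms — because unit activity is not a
count.  Latent tuning is declared by the same selection logic as the spiking
pipeline (held-out R² loss beyond one standard error of paired fold
differences when the distance/angle terms are removed).

## Problem sizes used in the test suite

Generative checks run at deliberately chosen scales: the recovery session is
20 neurons × 500 trials with 10 true couplings (median tuning recovery
≈0.99); stability calibration uses 10 neurons × 460 trials per condition
with dense coupling — the smallest design at which the same-condition
coupling SI resolves within the ±0.1 calibration band (weaker or sparser
coupling leaves the median pair correlation noise-dominated and the SI ratio
unstable); the network criterion trains the full 100-unit model with a
20k-trial budget.  These sizes were chosen as the smallest at which the statistics are
stable; conclusions about much larger populations or sessions are
extrapolations.

## Known limitations

* The agent is a proportional controller, not a learned policy; behavioral
  phenomena beyond its structure (e.g. systematic undershoot of distant
  targets) are out of scope.
* The Gaussian-likelihood unit encoding model for the network is a linear
  stand-in for the Poisson GAM; a Poisson path via stochastic spike emission
  from unit activities would be the strict analogue.
* Backward elimination refits every candidate group per fold and is
  intended for targeted hypotheses at these session sizes, not for
  exhaustive per-neuron selection over all nine variables on large sessions.
* The hyperparameter grid search (10⁻³–10³) is supported but slow; the
  defaults are used throughout.
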