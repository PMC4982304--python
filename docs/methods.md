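# Methods

## Signal model

`ppvtrack` models a mean-centered arterial blood pressure (ABP) waveform
sampled at rate 1/T_s as

    y_n = γ_n + Σ_{k=1..N_c} ρ_{k,n} κ_{k,n} + v_n

with

* respiratory baseline γ_n = Σ_j r_{1,j} cos(j θ^r_n) + r_{2,j} sin(j θ^r_n),
* k-th cardiac partial κ_{k,n} = c_{1,k} cos(k θ^c_n) + c_{2,k} sin(k θ^c_n),
* amplitude-modulation factor
  ρ_{k,n} = 1 + Σ_j m_{1,k,j} cos(j θ^r_n) + m_{2,k,j} sin(j θ^r_n),
* white Gaussian measurement noise v_n with variance r.

The hidden state has a *kinematic* part — the instantaneous angles θ^r, θ^c,
instantaneous frequencies f^r, f^c and instantaneous mean frequencies
f̄^r, f̄^c of the two rhythms — and a *coefficient* part (r, c, m).  Angles
integrate their frequencies (θ_{n+1} = θ_n + 2π T_s f_n); mean frequencies
follow random walks confined to known physiological bands by a *reflecting*
clip (an excursion past a bound bounces back by the overshoot); the
instantaneous frequencies mean-revert toward the mean frequency with AR
coefficient α; and all coefficients follow independent Gaussian random
walks.  The reflection matters in a particle filter: a saturating clip
leaves particles stuck at the band edge, whereas reflection keeps them
moving.  We additionally pass the instantaneous frequencies through the
same reflection so that the reported maximum-a-posteriori (MAP) frequencies
can never leave their bands; with the default noise scales the reflection
is almost never active, so this is a guard, not a behavioral change.

PPV follows from the model state.  For fixed coefficients the cardiac
oscillation's extrema over the cardiac angle give upper/lower signal
envelopes; the modulated pulse-pressure expression's extrema over the
respiratory angle give continuous pulse-pressure envelopes ε_μ, ε_ℓ; and

    PPV (%) = 100 (ε_μ − ε_ℓ) / ((ε_μ + ε_ℓ)/2)

is a continuous-in-time counterpart of the classical once-per-respiratory-
cycle index computed from beat-wise systolic/diastolic differences.

## Dual MAM-PF tracker

The posterior over the two instantaneous frequencies is multimodal, so they
are estimated with particles; conditional on a frequency/angle trajectory
the coefficients are close to linear-Gaussian, so each particle carries an
extended Kalman filter (EKF) over the full coefficient vector
(Rao-Blackwellization).  The measurement is bilinear in (c, m); the EKF
linearizes at the predicted mean, where the gradient entries are
cos(jθ^r)/sin(jθ^r) for the r block, ρ_k cos(kθ^c)/ρ_k sin(kθ^c) for the c
block, and κ_k cos(jθ^r)/κ_k sin(jθ^r) for the m block.

Rather than one cloud over the 2-D (respiratory, cardiac) frequency space,
the tracker runs two 1-D clouds of N_p particles (2 N_p total instead of
N_p²), treating the frequencies as independent.  Each cloud assumes the
*other* rhythm's kinematics known — the "dual" contract borrowed from dual
Kalman filtering.

Per sample, per space: each particle propagates its kinematics with fresh
process noise; a Viterbi-style search scores every candidate ancestor by
accumulated MAP score plus the Gaussian transition density of the proposed
frequency; the particle's EKF performs the time update (covariance grows by
the diagonal process noise) and the measurement update; and its score
becomes ancestor score + transition log-density + measurement
log-likelihood, normalized per space so log Σ exp(score) = 0.  The
covariance measurement update uses the optimal-gain Joseph form, which
collapses algebraically to P − (PH)(PHᵀ)/S and is symmetric by
construction.

### Design choices where the recursion is underdetermined

* **Score vs. state ancestry.**  The trajectory search reassigns the
  *accumulated score*; each particle's Kalman state evolves within its own
  lineage.  We initially implemented the alternative — inheriting the
  chosen ancestor's coefficient state — and found it catastrophic: once
  score spreads exceed the transition-density scale, the argmax collapses
  onto leader particles and transplants coefficient states between
  particles whose angle histories have diverged by large fractions of a
  cycle.  A transplanted state is phase-inconsistent with its new carrier,
  every EKF in the cloud is perpetually re-converging, and both frequency
  identification and the modulation estimate degrade badly (innovation RMS
  ~10× the noise floor in simulation).  With per-lineage states the same
  simulations track cleanly.  Both variants remain available
  (`inherit_kalman`), as does including each ancestor's predicted
  measurement likelihood in the search (`exact_search`).
* **Dual coupling clock.**  The cross-space angles each cloud conditions on
  are *consensus clocks*: cumulative angles advanced every sample by the
  current MAP frequency of the other space.  Freezing instead the previous
  step's MAP particle angle injects a discontinuity whenever the MAP index
  changes hands, which corrupts the modulation coefficients conditioned on
  it.  The consensus clock is continuous by construction and tracks the MAP
  frequency exactly.  Spaces update in fixed order (respiratory first);
  both use the clocks of the previous completed sample.
* **MAP extraction hysteresis.**  The reported MAP particle of a space
  changes only when a challenger exceeds the incumbent's score by
  `map_hysteresis` (default 3 nats).  Near-tied particles can carry
  substantially different phases; flapping between them corrupts every
  quantity computed from the reported trajectory.  The same margin governs
  which space donates the coefficient estimate.
* **Rejuvenation.**  There is no weight-proportional resampling (the
  trajectory search plays that role).  An optional guard re-spreads the
  worst-scoring 10 % of a cloud over its frequency band when the top score
  has exceeded the median by `rejuv_gap` for `rejuv_patience` consecutive
  steps, re-entering them mid-pack with the MAP particle's coefficient
  state.  It is **off by default**: in the synthetic study conditions it
  destabilized the modulation estimate (transplanted states again) more
  often than it rescued a stuck cloud.  All four knobs are configuration
  fields.

### Initialization

Both clouds start on an even frequency grid over their band plus a small
deterministic-seeded jitter (1/20 grid step), angles at zero, coefficient
means zero except the first harmonic of each block at the configured
initial amplitude, and a diagonal covariance of squared initial amplitudes.
Scores start uniform.

## Parameter defaults

| parameter | default | notes |
|---|---|---|
| N_c, N_r (harmonics) | 10, 3 | config default; the assessment preset uses 5, 2 |
| total particles 2 N_p | 500 | |
| respiratory band | 6–30 breaths/min (0.1–0.5 Hz) | |
| cardiac band | 50–140 beats/min (0.83–2.33 Hz) | |
| r (measurement noise var) | var(y)/10³ | from the signal |
| frequency process var | 10⁻⁶ · T_s Hz² per step | both rhythms, both walks |
| r-, c-coefficient process var | var(y) · 10⁻⁶ · T_s per step | |
| m-coefficient process var | var(y) · 10⁻⁸ · T_s per step | |
| initial r-, c-amplitude | std(y)/10 | |
| initial m-amplitude | std(y)/10³ | |
| α (AR coefficient) | 0.95 | slow mean reversion; not pinned by the design table |
| angle grid | 256 points + golden-section refinement | envelope searches |

The harmonic counts deserve a flag: the design table lists 10 cardiac and 3
respiratory components, while the assessment protocol that produced the
published agreement numbers states 5 and 2.  The config defaults follow the
table; the package's own tests and the acceptance script run the 5/2
assessment preset, which is also 6-7× cheaper (the coefficient vector has
34 rather than 86 entries).

One variance per rhythm serves both the mean-frequency walk and the
instantaneous-frequency AR step, the minimal reading of a design table that
prints a single "frequency variance" per rhythm.

## Synthetic generator

The generator renders the forward model exactly: deterministic frequency
profiles (constant, linear chirp, sinusoidal drift) with closed-form phase
integrals, fixed coefficient values, a DC offset (~90 mm Hg; the model has
no DC state, so signals are mean-centered before tracking and the mean is
restored on export), and white Gaussian noise.  Because the truth is known
in closed form, the generator computes its own envelope and PPV traces by
running the envelope chain on the true coefficients.

Default study condition: 120 s at 40 Hz, respiration 0.25 Hz, heart rate
1.2 Hz, cardiac amplitudes (30, 12, 6) mm Hg, respiratory baseline
(3, 1) mm Hg, uniform first-respiratory-harmonic modulation depth
m = 0.075 on every cardiac partial — which makes the true continuous PPV
exactly 200·m = 15 %, mid-range of clinically reported values — and
1 mm Hg noise.

What the generator does *not* emulate: real pressure morphology (dicrotic
notch, reflected waves), arrhythmia, baseline drift slower than the
respiratory band, measurement artifacts, or non-stationary modulation.
Passing the synthetic recovery tests therefore demonstrates correctness of
the estimation machinery under the model's own assumptions, not clinical
performance; agreement on real recordings must be assessed against manual
annotations through the `assess` pipeline.

## Envelope and PPV numerics

Both envelope searches optimize a trigonometric polynomial in one angle:
coarse evaluation on a 256-point grid over [0, 2π) (ties toward the smaller
angle) followed by 40 golden-section iterations in the bracketing interval,
vectorized over samples; if refinement cannot beat the grid point (flat
objective), the grid point stands.  Against a 100 000-point dense grid the
error is below 10⁻⁴ of the envelope scale on random states.  Negative
pulse-pressure envelope values (possible during early transients) are
clamped at zero and logged; PPV is 0 where both envelopes are 0.
Respiratory cycles are delimited by the unwrapped MAP respiratory angle
crossing multiples of 2π.

## Assessment protocol

Five measurements per record, anchored 120 s apart (anchors configurable),
each the average of the continuous PPV over the first five complete
respiratory cycles after the anchor (or the mean of five per-cycle values
when the comparator is a beat-annotation-derived cycle list).  Agreement is
summarized by Bland-Altman bias, sample (n−1) standard deviation, limits
bias ± 1.96 sd, and the worst absolute difference, plus a per-record
mean ± sd table.

## Problem sizes in tests and the acceptance script

The recovery suite tracks the default 120-s condition over 20 noise seeds
at the full 500-particle budget with the 5/2 assessment preset (~15-20 s
per record on one core).  Windowed PPV is measured on one steady-state
window of five true respiratory cycles anchored at 90 s, and compared with
the generator truth; frequencies are scored by the median absolute error
over the last 60 s.  Unit tests use smaller clouds (3-100 particles) and
shorter records.

## Known limitations

* **Respiratory subharmonic locks.**  In a sizeable fraction of synthetic
  runs (roughly half in the default condition) the respiratory cloud locks
  at half the true rate, with the second respiratory harmonic absorbing the
  fundamental.  The modulation model is
  closed under this relabeling, so the PPV estimate is usually unaffected,
  but the reported respiratory rate and cycle segmentation are then wrong
  by a factor of two.
* **Start-up transient.**  The first ~10-20 s of a run carry the burn-in of
  both frequency clouds and the coefficient EKFs; envelopes and PPV in that
  span are unreliable (hence steady-state measurement windows).
* **Mild PPV noise bias.**  The PP-envelope extremes are maxima/minima of a
  noisy estimated function, so estimation noise in m inflates PPV slightly
  (typically +1-2 percentage points at PPV 15 % in the default condition).
* **No smoothing.**  Estimation is forward-only filtering; no backward pass
  is applied, and none of the reported trajectories are post-processed
  beyond the extraction hysteresis.
* The built-in WFDB reader covers single-segment headers and signal
  formats 16 and 212 only.
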