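# Methods

`ctxlearn` re-implements, on synthetic data with known ground truth, the
computational analysis of an instrumental avoidance-learning fMRI
experiment with contextual cues: a Q-learning behavioral model fitted by
exhaustive grid maximum likelihood, model-based parametric regressors in an
ROI-level GLM, the accompanying behavioral statistics, and a simplified
two-process effective-connectivity model selection over a four-node
habenula–hippocampus network.

## Task and behavioral model

Each trial of the task shows two shapes (square, rhombus) against one of
two background pictures (contexts A and B, 30 trials each in a 60-trial
session).  Choosing a shape delivers a painful stimulus with a probability
that depends on the shape and the context.  By default the mapping is
reversed between contexts — context A: rhombus 80%, square 20%; context B:
square 80%, rhombus 20% — so the background picture is informative.  The
task narrative implies this reversal (participants were told "some factors
could reverse this situation"); the alternative in which both contexts
share the same shape roles is available via `printed_contingency()`.

The agent maintains action values Q(s, a) per (context, shape) pair,
updated by the delta rule

    RPE_t = kappa * R_t - Q_t(s_t, a_t)
    Q_{t+1}(s_t, a_t) = Q_t(s_t, a_t) + alpha * RPE_t

with learning rate `alpha` in (0, 1] and subjective painfulness `kappa`
<= 0 (pain maps to negative return), and chooses between the shapes
currently on the left and right of the screen through a unit-temperature
softmax over their action values.  The state value is the
choice-probability-weighted mean V_t(s) = sum_a P_t(a|s) Q_t(s, a); a
variant in which the left-choice probability multiplies both action values
is provided behind a flag for comparison, since the two readings differ
only when the action values differ.

Design choices the task description leaves open, fixed here once:

- **Q initialization**: Q_1(s, a) = 0 for all pairs, the conventional
  neutral prior; it makes the first choice in each context uninformative
  (P = 0.5), which in turn pins the first likelihood term at ln 0.5.
- **Trial timing**: trials are 12.6 s so that 60 trials exactly tile the
  756 s scan (252 volumes at TR = 3 s).  Shapes appear at trial onset
  (response window 3 s), a fixation grid follows for 6 s, and the outcome
  arrives at +9.0 s.  The selection event is placed at the simulated
  response time; reaction times are log-normal (median 1100 ms, log-scale
  0.3, truncated to (0, 3000] ms) with optional additive effects of
  probability level and context for calibrating the RT ANOVA.
- **Cohort generation**: per-subject parameters are truncated-normal draws
  (alpha ~ N(0.3, 0.15) on (0, 1], kappa ~ N(-3, 1.5) on [-10, 0]),
  a population with moderate learning and clearly aversive but not extreme
  pain weighting.  Seven trait scores per subject are linear functions of
  a designated subject-level signal (by default the painfulness magnitude
  -kappa) plus Gaussian noise; the default coupling is zero so that the
  trait-correlation stage is calibrated under its null.

## Grid maximum-likelihood fitting

The session log-likelihood replays the update/softmax equations over the
recorded (context, side, action, outcome) sequence from Q = 0 and sums the
log-probability of each recorded choice.  Estimation evaluates this at
every point of the default grid alpha in {0.01, ..., 1.00} x kappa in
{-10.0, ..., 0.0} (100 x 101 cells, vectorized over the grid) and returns
the maximizer.

The likelihood surface has genuine flat regions — the kappa = 0 row never
moves Q, so every alpha there is equivalent — and so ties are real.  Two
cells within 1e-9 nats are treated as tied (floating-point guard), ties
are broken deterministically by the smallest kappa index then the smallest
alpha index, and the number of tied cells is reported so degeneracy stays
visible.  A 60-trial session identifies the parameters only weakly; the
trial count is therefore a free simulation knob, and the recovery analyses
use extended 600-trial sessions, where the estimator recovers
(alpha = 0.30, kappa = -3.0) within (+-0.10, +-1.0) in well over 90% of
replicates.

## ROI GLM

First-level analysis follows standard event-related practice on ROI-mean
series.  Five conditions enter as stick functions on a 0.1 s microtime
grid: pain outcome, no-pain outcome, shape onset under context A, shape
onset under context B, and shape selection.  The aversive prediction error
attaches to the two outcome conditions (one modulator per condition by
default; a merge flag collapses them into one column) and the state value
to the selection condition; modulator values are mean-centered within
condition before convolution, with no serial orthogonalization.  Sticks
are convolved with a canonical double-gamma HRF (delay parameters 6 s and
16 s, unit dispersions, peak:undershoot ratio 6, 32 s kernel, unit peak)
and sampled at volume acquisition times.  Six rigid-body motion traces and
an intercept complete the design.

Estimation is ordinary least squares without prewhitening — a deliberate
first-level approximation; the synthetic noise generator is AR(1) plus
white precisely so that this assumption can be stress-tested.  The
headline contrast is beta(pain) - beta(no-pain); group inference is a
one-sample t-test across subjects, and trait correlations use Pearson r
with a Bonferroni threshold of 0.05/7 = 0.0071 over the seven trait
scales.  Degenerate inputs raise explicit errors: rank-deficient designs
name the collinear columns, zero-variance group vectors are refused, and
all-zero modulators (a frozen kappa = 0 model) are dropped with a warning.

## Effective-connectivity model selection

The connectivity stage preserves the two-process selection logic of
DCM-style analyses while replacing the bilinear neural model, hemodynamic
state equations and variational evidence with a desk-scale forward model
that has exact ground truth:

- **Neural dynamics**: dz/dt = A z + C u over four nodes (left/right
  habenula, left/right hippocampus).  Self-connections are fixed at
  -1 s^-1 for identifiability; free weights are the masked inter-regional
  A entries and input C entries.  "Symmetric connectivity" is interpreted
  as hemispheric mirroring — each weight is tied to its left/right
  homologue — not forced bidirectionality, because the selected structure
  is directional (HC -> Hb); a flag disables the tying.
- **Discretization**: the exact exponential propagator
  z[k+1] = e^(A dt) z[k] + dt * C u[k] on the 0.1 s microtime grid, with
  stick inputs treated as impulses.  This reproduces the analytic impulse
  response at grid points for any stable A, including the defective
  (purely feedforward) matrices that arise for one-directional coupling
  patterns, which are handled through a complex Schur triangularization
  rather than an eigendecomposition.
- **Observation**: each node's state convolved with the same canonical
  HRF, sampled at volume times, plus white noise.
- **Inputs**: four candidate streams built from a session — background
  images (unit stick per trial onset), pain (unit stick per painful
  outcome), state value (V_t at selection), and aversive prediction error
  (RPE_t at outcome).  Values enter uncentered; the streams share their
  event timing with the GLM's event sets.
- **Scoring**: free weights are fitted by least squares.  The fit is
  separable — given the connection weights the input weights solve
  linearly — and because the discrete dynamics and the HRF are both
  linear time-invariant, inputs are HRF-convolved once up front, leaving
  a nonlinear search over at most six tied connection weights (bounded to
  [-1.5, 1.5] with a stability guard).  Log evidence is approximated by
  -BIC/2 = -1/2 [sum_r n ln(SSE_r / n) + k ln n] over the four regions,
  with k the number of free weights; posterior model probabilities follow
  from a uniform prior.  A per-region SSE floor of 1e-8 per volume keeps
  noiseless comparisons among exactly-fitting nested models decided by
  the parameter-count penalty rather than optimizer round-off.

Process 1 compares 24 fully-connected candidates: 8 input bundles (images
plus any subset of pain, state value, APE) crossed with 3 target options
(hippocampus pair, habenula pair, both).  The exact 24-way composition of
the original analysis is not recoverable from the available description,
so this enumeration is a declared reconstruction, configurable in code,
that contains the reported winner.  Process 2 fixes the winning inputs and
compares connection patterns (none, HC->Hb, Hb->HC, bidirectional, each
with or without interhemispheric within-pair links).

Model recovery generates data from the reported winning structure —
images, pain and state value into the hippocampus pair, positive HC->Hb
couplings (ipsilateral 0.35, crossed 0.20; inputs 0.4, state value 0.2) —
and runs both processes.  Selection is exact in the noiseless case and
remains modal for the true structure at an SNR of about 1 (noise standard
deviation equal to the noiseless BOLD standard deviation).

## What the synthetic data do and do not show

The generators emulate the study's printed design exactly where stated:
60 trials balanced 30/30, the 80%/20% contingencies, the 252-volume TR=3 s
timeline, 19-subject cohorts, seven trait scales, and session-locked event
timing.  They do not emulate scanner drift and physiological noise beyond
AR(1)+white, hemodynamic nonlinearity or regional HRF variability,
attentional lapses or response omissions, or anatomical ROI extraction
error.  Passing tests therefore demonstrate the correctness and
calibration of the analysis machinery under its own assumptions — not that
the original empirical effect sizes would replicate; the human-data t
statistics and correlations are outside what desk-scale simulation can
reproduce and are deliberately not targets.

## Numerical conventions and problem sizes

All tabular outputs are tab-separated with headers, floats at 10
significant digits.  Every stochastic stage derives its seed
deterministically from the master seed and stage/participant labels
(SHA-256, folded below 2^31), making reruns byte-identical.  Default
problem sizes keep a full pipeline run on one CPU in minutes: 19 subjects
x 60 trials, 100x101 likelihood grids, 252-volume designs, 10,000-trial
forced-choice probes, 100-replicate recovery studies at T = 600, and
50-run connectivity recovery at SNR 1.  The power utility scans n upward
using exact noncentral-t power; the printed minimum sample size of the
original study is not cleanly reproducible under standard two-sided
conventions, so the utility documents its convention instead of
hard-coding that number.

## Known limitations

- Grid estimation inherits the grid's resolution; no continuous refinement
  is attempted, by design.
- OLS first-level estimation is anticonservative under strong AR(1) noise;
  the group stage absorbs this in the null calibration but single-subject
  t statistics are not computed for this reason.
- BIC evidence is an asymptotic approximation and the noiseless SSE floor,
  while necessary for determinate comparisons, makes "evidence" there a
  function of parameter counts alone.
- The Process-1 model space is a reconstruction; substantive conclusions
  about the original 24 candidates cannot be checked against it.
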