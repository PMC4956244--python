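# Methods

This note documents the models implemented in `tempreg`, the choices made
where the design was genuinely open, and what the synthetic cohorts do and
do not show about real data.

## Experimental designs

Two tasks are generated.  In the **regularity task** five tones are
presented with a base IOI of 700 ms; each of the first three intervals is
perturbed by an independent uniform draw on ±jitter, with jitter levels
{0, 10, 20, 30} ms (regular environment) or {0, 50, 100, 150} ms
(irregular environment); the final tone deviates from the isochronous grid
by an anisochrony in {0, ±20, ±40, ±60, ±80, ±100, ±150, ±200} ms, eight
repetitions per cell.  In the **TOJ task** the final tone deviates by
±40 ms and is judged against a flash at one of nine SOAs
(0, ±40, ±80, ±120, ±200 ms), ten repetitions per cell; a practice phase
presents a single tone and flash at eleven SOAs (0, ±20, ±90, ±170, ±250,
±350 ms), six repetitions.  Grids are full factorial crosses, shuffled by
a per-session seed; with four balanced jitter levels, 25 % of trials are
perfectly isochronous in both environments.

Two conventions had to be fixed where the design description leaves room:

- **Anisochrony reference.**  In jittered sequences the final tone is
  placed on the *nominal* grid (4 × IOI + anisochrony), not relative to the
  jittered fourth onset.  Jitter is a perturbation of the context; anchoring
  the deviant to the nominal grid keeps "expected time point" well defined
  across jitter levels.
- **SOA reference.**  The flash is timed relative to the *actual* final
  tone onset (flash = final tone + SOA), so a PSS shift directly measures a
  shift in the perceived timing of the tone.

The inter-trial interval (1.5–2 s) and tone/flash physical parameters are
metadata only; no waveform synthesis is attempted.

## The Bayesian observer

The observer is a conjugate Gaussian recursion over absolute onset times
(a Kalman-style filter with known interval length):

1. after the first tone, predict the next onset one IOI ahead with sd
   `initial_prior_sd`;
2. sense each tone with i.i.d. Gaussian noise (`sensory_sd`), fuse
   prediction and evidence by precision weighting, and take the posterior
   mean as the perceived onset;
3. shift the posterior one IOI forward; prediction uncertainty grows by
   `interval_sd`, the observer's estimate of the environment's interval
   variability;
4. perceive the final tone by the same fusion; the perceived anisochrony is
   the perceived onset minus the predicted onset, with expectation w·a,
   w = σ_p²/(σ_p² + σ_s²) at the final fusion.

The prior is over onsets, not intervals, and the IOI estimate itself is
fixed at 700 ms — joint interval inference is out of scope.  A plausible
alternative formalization places the prior on the inter-onset interval;
for fixed-length sequences the two are equivalent up to the bookkeeping of
where interval noise accumulates.

**Environment learning.**  `interval_sd` is updated *between* sequences by
exponential smoothing toward the RMS prediction error of the context tones
(rate `env_learning_rate`; 0 disables learning).  Two deliberate
restrictions: the deviant final tone never feeds the update (it is the
probe, and including it would let the manipulated anisochronies inflate
the learned statistics), and no update occurs inside a sequence (the
environment statistics are a slow variable; observers cannot know the
upcoming sequence's jitter level, and the within-sequence fast variable is
the onset prediction itself).  Under this scheme the learned `interval_sd`
converges to ≈ 23 ms in the regular environment and ≈ 58 ms in the
irregular one (sensory noise included), giving final-fusion sensory
weights of roughly 0.65 and 0.9: strong regularisation in the regular
group, weak in the irregular group.

**Responses.**  Regularity judgments draw an early and a late criterion
from independent Gaussians and respond "regular" iff the sensed
anisochrony lies between them.  TOJ responses compare the perceived tone
onset with the flash onset plus Gaussian visual latency noise
(`visual_latency_sd`); exact ties resolve as "light first" (a measure-zero
convention).  Any fixed audiovisual latency offset would be absorbed into
the PSS and is set to 0, so flat-prior cohorts have PSS ≈ 0 by
construction.  A symmetric lapse flips any response with probability
`lapse_rate`.

### Default observer parameters

| parameter | default (cohort mean ± sd) | units | rationale |
|---|---|---|---|
| `sensory_sd` | 20 ± 4 | ms | auditory onset-timing acuity at ~1 kHz tones |
| `initial_prior_sd` | 150 ± 20 | ms | weak first-interval prediction |
| `interval_sd` | 30 ± 5 | ms | starting estimate; overwritten by learning |
| `env_learning_rate` | 0.1 | — | converges within ~30 sequences, slow thereafter |
| `criterion_early/late` | −100 / +100 ± 15 | ms | regularity tolerated within ≈ ±100 ms |
| `criterion_sd_early/late` | 30 ± 5 | ms | trial-to-trial criterion noise |
| `visual_latency_sd` | 40 ± 8 | ms | yields audiovisual TOJ JNDs ≈ 45–65 ms |
| `lapse_rate` | 0.02 | — | occasional keypress errors |

Cohort draws are truncated Gaussians (sd 0 fixes a parameter).  Cohort
sizes default to the study sizes: 10 observers per environment group for
the regularity experiment, 12 per group for the TOJ experiment.

## Analyses

**Spearman–Kärber.**  PSS and JND are the mean and sd of the discrete mass
dp_i placed at the midpoints of consecutive padded levels.  Numerical
choices:

- The second moment is returned as the *square root* of the normalized
  central moment — one standard deviation, which is exactly the offset
  producing the .16/.84 proportions for a Gaussian-shaped curve.
- Padding bounds default to ±250 ms; for the practice phase, whose SOAs
  reach ±350 ms, the pipeline uses ±400 ms (bounds must strictly bracket
  the levels).  The estimator is generic in the number of levels.
- Non-monotone proportion series are monotonized by pooled adjacent
  violators (trial-count weighted, via scikit-learn's isotonic regression)
  before the moments are taken, and flagged in the output.  Padding alone
  does not guarantee non-negative increments.
- Normalization by Σ dp_i (= 1 after padding) is kept explicit.

TOJ curves are analysed on the tone-minus-flash axis with "light first" as
the positive response, so proportions rise 0 → 1 across the padded range
and a positive PSS means the light had to lead the sound — under this
convention the regularisation index 100·(PSS_late − PSS_early)/80 is
positive when perception compresses the deviants toward regularity.  The
index is normalized by the 80 ms early-to-late span; normalizing by the
40 ms one-sided anisochrony is the other defensible reading and simply
doubles the number (`anisochrony_span=40`).

**Two-noisy-criteria model.**  P(regular | x) = Φ((x−c_e)/σ_e) −
Φ((x−c_l)/σ_l), fitted by binomial maximum likelihood: multi-start
Nelder-Mead (default 20 moment-based jittered starts) under box
constraints σ ∈ [1, 500] ms, criteria within ±500 ms, probabilities
clipped at 1e−6 to guard the log-likelihood.  All-regular or all-irregular
data are non-identifiable and returned unconverged with a diagnostic.
Because the criteria are drawn independently, the exact generative
response probability is Φ_e·(1−Φ_l); it differs from the difference-of-
CDFs curve by at most Φ_l·(1−Φ_e), which is negligible whenever the
criteria are separated by a few slope units — the fitted form is the
standard one.  Both the σ parameters and the slopes at threshold
(1/(σ√(2π))) are reported, since conventions differ on which is "the
slope".

**Exclusion rule.**  An observer is dropped when the practice-phase JND
exceeds 250 ms, or when the test-phase JND exceeds 200 ms; values exactly
at the threshold are retained (strict inequality).  The test-phase rule is
applied to the observer's mean JND across jitter × anisochrony cells; the
rule's original statement does not specify a cell, and the mean is the
least noisy per-observer summary.

## Pipeline and reproducibility

`run_experiment1` / `run_experiment2` simulate both environment groups end
to end and emit tidy CSV tables (group proportion curves with bounded
probit transforms and per-observer two-criteria fits; practice and test SK
estimates, exclusions, per-jitter regularisation summaries and JND
tables).  Everything is a pure function of (config, master seed): session
seeds are drawn once from the master seed, and `report` writes
byte-identical CSVs plus a run log with every session seed, the config
hash and the package version.  Plots are deliberately not part of the
report path.  A full TOJ cohort (12 observers/group, 10 repetitions) runs
in well under a minute on one CPU; the test suite uses reduced cohorts for
the structural checks and full-size cohorts only where the claim is about
cohort statistics.

## What the synthetic cohorts show — and what they do not

The generator reproduces the *structure* of the behavioral experiments
(designs, response types, exclusion screening) and the *mechanism* under
test (prior-driven regularisation with environment-dependent strength).
Passing tests therefore demonstrate internal consistency: the analysis
chain recovers the parameters and effects that the generative model
planted, at the trial counts of the real designs.  They do not show that
human observers are described by these parameter values.  In particular,
the regularisation index of the default learning cohort at jitter 0
(typically 25–45 % across seeds) depends on the chosen noise parameters;
only its sign, its ordering between environments, and its vanishing for
flat-prior observers are model predictions.  Known limitations: no
adaptation of the decision criteria across environments, no sequential
(trial-history) effects beyond the interval-sd recursion, Gaussian
likelihoods throughout, and a regularity judgment driven solely by the
final tone's sensed anisochrony rather than by the whole sequence — real
observers judging high-jitter sequences surely also use the context
intervals themselves.
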