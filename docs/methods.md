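# Methods

This note documents the models implemented in `distcue`, the conventions the
implementation fixes where the model family leaves choices open, what the
synthetic-cohort generator does and does not emulate, and the study sizes
used by the test suite.

## Cue construction

A cue is ten ratings on the 0–100 VAS drawn to match a design cell (mean ∈
{30, 40, 50, 60, 70} for the expectation task or {30, 70} for the
cued-perception task; SD ∈ {5, 12.5}; skew category negative / symmetric /
positive). Realized statistics use the arithmetic mean, the ddof = 1 sample
SD, and the adjusted Fisher–Pearson standardized third moment G1.

Symmetric cues are ten normal draws at the target mean/SD. Skewed cues take
nine draws from a shifted log-normal law (log-scale shape σ = 0.5, giving the
sampling law a skewness of ≈ 1.75; location and scale solved from the
two-moment equations; mirrored about the target for negative skew) plus a
tenth, injected extreme element. The extreme element is placed by drawing a
standardized distance d ~ U(2.0, 2.5) and solving a quadratic for the value
whose distance from the *final ten-value* realized mean, in realized SDs,
equals d exactly; the nine-draw moments are pre-compensated (mean offset
∓dS/9, variance S²(81 − 10d²)/72) so the ten-value set lands near the target.
Candidate sets are redrawn until every value lies in [0, 100], the realized
mean and SD are within ±1 VAS unit of target (the construction tolerance;
skew is matched by its category band only: |G1| ≤ 0.035 symmetric, G1 > 0.3
positive, G1 < −0.3 negative). Rejection runs in vectorized batches of 256;
the default attempt budget is 10,000 per cue, and generation is
bit-reproducible under a fixed seed. A non-positive target SD is rejected
(the skewness band is undefined at zero variance); tiny positive SDs produce
near-constant cues. Cue values are kept at full floating precision — no
rounding to display resolution.

The expectation design runs as six single-modality blocks of 60 trials
(three consecutive blocks per modality), each within-modality cell appearing
twice per same-modality block, for six repetitions per cell in total. The
cued-perception design runs as six 24-trial blocks split into two 12-trial
single-modality mini-blocks; the two stimulus intensities are mapped to
levels 2 and 4 of the stimulus–response task's five-level scale. Trial order
is randomized within block under the caller's seed.

## Expectation model

Deviations `X_i` come from per-cue min-max rescaling to [0, 1] followed by
demeaning. Rescaling within the cue (rather than dividing by the global
100-point range) was a genuinely open choice; it is adopted here because
(a) it matches the natural reading of "rescaled to [0, 1]" for a set of ten
values, and (b) the power weights are mathematically invariant to any per-cue
positive rescaling (the scale factor cancels in sum-normalization), so the
choice only affects the effective units of b — and under global rescaling the
joint (k, b) least-squares surface becomes so ridge-like at realistic noise
that k is unrecoverable (pilot Spearman ≈ 0.6 versus ≈ 0.9 under per-cue
rescaling at the same noise). A constant cue maps to X = 0.

The power weight is implemented as `|X_i|^(k-1)` — the algebraic
simplification of `sign(X)·|X|^k / X` — with |X_i| floored at ε = 1e−6
before exponentiation so that k < 1 cannot divide by zero; if every |X_i|
falls below ε the weights degrade gracefully to equal weighting. The
logistic weight uses an overflow-safe expit. Bounds: k ∈ (0, 1000]
(optimizer lower bound 1e−3), b ∈ [−1000, 1000].

Fitting is ordinary least squares over (k, b) by the bounded trust-region
reflective method with a multi-start grid k₀ ∈ {0.3, 1, 2, 5} ×
b₀ ∈ {−8, 0, 8} and tolerances 1e−10; the best converged start is kept.
On noiseless data the fit recovers generating parameters to < 1e−3 and
matches an exhaustive grid oracle (k log-spaced 0.05–50, b ∈ [−30, 30]).
Group inference: two-sided Wilcoxon signed-rank tests of k against 1 and b
against 0 per modality (zero differences dropped; an all-zero sample returns
p = 1 by convention) and Spearman correlations of each parameter across
modalities.

**Identifiability.** At realistic noise (SD ≈ 6 VAS) the k-likelihood is
informative above k ≈ 1.5 and nearly flat below; when the logistic term is
strong, a small fraction of fits collapse to the k lower bound even though
they are global OLS minima (the k → 0 regime concentrates weight on the
value nearest the cue mean and can beat the truth by < 1% RSS through noise
alone). This is intrinsic to the model family under OLS, not an optimizer
failure, and it bounds how well k can be rank-recovered at 180 trials per
modality: with cues freshly generated per participant, true-vs-recovered
Spearman reaches ≈ 0.8 when the group's k centre is 1.66 (the pain median)
but only ≈ 0.7 at a centre of 1.47 (the vision median), where more of the
truth mass sits in the flat region. Sharing one cue design across
participants removes design-level variance from the between-participant
ranking and raises the apparent recovery by ≈ 0.1 — recovery studies should
therefore re-sample cues per participant, as the task itself does. b is
essentially unaffected (recovery Spearman ≈ 0.95).

## Perception models

All five observer models scale the participant's calibrated stimulus
response (`intensity(t)`: the stimulus–response task's cell mean for that
modality × intensity) by s ∈ [0, 5] per modality. M2/M4 mix in the cue-based
expectation with a static weight w ∈ [0, 1] (global or per modality); M3/M5
update the weight from the trial's prediction error with learning rate
α ∈ [−1, 1]. Conventions this implementation fixes:

- the PE is computed on a 0–1 scale (rating and expectation divided by 100)
  so that α ∈ [−1, 1] yields stable trajectories;
- `rating(t)` in the PE is the observed rating during fitting (one-step-ahead
  prediction) and the realized noisy rating during simulation;
- w is clamped to [0, 1] after every update, keeping the mixture convex;
- M3 carries one weight stream across both modalities in presentation order;
  M5 carries separate (w, α) streams per modality, each updated only by its
  own modality's trials.

Per-trial expectations for M2–M5 come from each participant's own fitted
(k, b); an option substitutes the generating truth for sensitivity analyses.
Fitting is bounded multi-start least squares; models are fitted simple to
complex, each complex model warm-started from its nested parents, which
enforces the nesting inequality (complex RSS ≤ simple RSS) up to optimizer
tolerance. Comparison: per-participant nested F tests
(F = ((RSS_s − RSS_c)/(p_c − p_s)) / (RSS_c/(n − p_c)), negative numerators
floored at zero) over the declared nesting graph M1⊂M2⊂M3, M2⊂M4⊂M5, M3⊂M5;
a group F computed from the mean RSS across participants with n taken as the
mean trial count (a reporting convention — the participant-level tests carry
the inferential weight); and Gaussian-OLS AIC = n·ln(RSS/n) + 2p per
participant, summed across participants (RSS floored at 1e−10 inside the log
so numerically perfect fits keep a finite criterion). Because the true w = 0
lies on the parameter boundary under the baseline model, the M1-vs-M2 F test
is conservative in principle; empirically its type-I rate at the study's
design sits near 0.04–0.05.

## Synthetic cohorts

Each synthetic participant carries: per-modality (k, b); an observer model
with its parameters; a calibration line (rating = intercept + slope × level,
intercept ~ N(15, 5), slope ~ N(13, 2) truncated ≥ 1, in VAS units); rating
noise SD (default 6 VAS for all tasks, which reproduces the observed fit
regime — predicted-vs-observed r ≈ 0.92 and RMSE ≈ 6); and a response-time
law. Truth sampling defaults: k log-normal about medians 1.66 (pain) / 1.47
(vision) with log-scale SD 1.0 — an order-of-magnitude range of individual
differences (≈ 0.2–12), wide enough that rank recovery is assessable against
the estimation noise analysed above — and b normal about −1.64 / 0.16 with
SD 2.5, spanning both modality centres. Observer-model truths: s ~ N(1,
0.15) truncated to [0.2, 3], w ~ U(0.2, 0.8), |α| ~ U(0.1, 0.4) with random
sign. Ratings are model predictions plus additive Gaussian noise clipped to
[0, 100]; at noise SD 6 and cue means 30–70 clipping is rare and its bias
negligible.

Response times are log-normal (median 0.9 s, log-SD 0.35) truncated into the
kept window, plus an out-of-window mixture (default 5%, half too fast, half
too slow). Only the exclusion rule matters — trials with RT < 0.2 s or
> 4.5 s are removed, boundary values kept (the rule uses strict
inequalities) — so the RT law is a stand-in, not a model of real latencies.

What the simulator does *not* emulate: sequential effects other than the
modelled weight learning (habituation, sensitization, drift), within-session
noise non-stationarity, rating discretization or anchoring, and any
physiological signal. Passing recovery tests therefore show that the
estimation machinery is sound under the stated observation model, not that
real data will be as well behaved.

## Study sizes in the test suite

The acceptance tests run: cue-constraint checks at 1000 cues per design
cell; optimizer-vs-grid equivalence on 20 noiseless 60-trial problems;
expectation-parameter recovery at the study scale (45 participants × 180
trials/modality, noise SD 6), averaged over four replicate cohorts to reduce
the Monte-Carlo error of the recovery estimate; w-recovery bias on one full
45-participant M2 cohort; Wilcoxon type-I calibration over 500 replicate
10-participant cohorts with a reduced 9-point start grid; F-test type-I
calibration over 500 synthetic participants; and model identification with
three 6-participant cohorts per generating model. These sizes are the
package's chosen trade-off between the precision of each Monte-Carlo
estimate and a test suite that runs in minutes.

## Known limitations

- k below ≈ 1 is weakly identified at realistic noise (see above); recovery
  claims for k should be read as rank-level, boundary-collapsed fits (k at
  1e−3) occur in a few percent of noisy fits (≈ 20% at true k = 1), and at
  the study's scale the k-recovery Spearman for a vision-like parameter
  regime falls short of 0.8.
- The Wilcoxon test of k against 1 relies on symmetry of the estimate about
  the null; the collapse mass makes this only approximate, and the test's
  empirical size at the study design is ≈ 0.06 at nominal 0.05.
- The group-level F test's degrees of freedom under mean RSS are a
  convention, not an exact sampling distribution.
- The regressor-coding export covers the study's conventions (±1 binary
  codes, symmetric-reference skew dummies, z-scored covariates); the
  mixed-effects models themselves are left to the user's statistics stack.
- The M1-vs-M2 F test is conservative at the w = 0 boundary; its empirical
  type-I rate is acceptable at the study design but would not generalize to
  much larger trial counts.
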