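# Methods

## Scientific setting

The package analyzes a two-alternative motion-direction discrimination task
with post-decision wagering (PDW).  On each trial a random-dot stimulus of
signed coherence *C* (% coherent dots; positive = toward the preferred
direction of a recorded neural cluster) is shown for an
experimenter-controlled duration *D*.  On a random half of trials a
"sure-bet" target is offered during the delay; choosing it yields a small
guaranteed reward, so its choice rate operationalizes decision confidence.
On a random half of trials the sensory cluster is optogenetically
suppressed for the duration of the stimulus ("laser" trials), and a
multi-unit spike count is recorded per trial.

The analyses quantify (1) how suppression shifts the choice and confidence
psychometric functions, (2) how those shifts scale with the measured degree
of suppression, and (3) how they attenuate with trial number within a
session and with stimulus duration within a trial ("compensation"), while
the neural suppression itself stays constant.

## Models

**Choice.**  Binomial logistic regression of preferred-direction choices,

    P_pref = {1 + e^(-Q)}^(-1),
    Q = b0 + b1*C + b2*I_L + b3*C*I_L,

with I_L the laser indicator.  The laser-induced bias in coherence units is
the ratio **b2/b1** ("choice shift"); b3 captures a sensitivity change.  A
two-parameter version (b0, b1) fits single trial groups for plotted curves.
Coefficients are ML estimates; standard errors are square roots of the
diagonal of the inverse Hessian at the optimum; Wald t and p per
coefficient.  The shift's SE comes from first-order (delta-method)
propagation of the ratio through the coefficient covariance.  Complete or
quasi-complete separation raises an error naming the degenerate direction
rather than silently regularizing — a shift ratio is meaningless under
separation.  Choice analyses pool sure-bet-unavailable and sure-bet-waived
trials; sure-bet outcomes are excluded.

**Confidence.**  The sure-bet probability is a Gaussian in coherence,

    P_sb = A * exp(-(C + mu + delta*I_L)^2 / (2 sigma^2)),

fit by binomial maximum likelihood on sure-bet-available trials (a
count-weighted least-squares mode on per-condition proportions exists as a
cross-check).  **delta** is the confidence shift in % coh.  Optimization is
multi-start L-BFGS-B from a deterministic list of initial points (A from
the largest observed proportion, mu from the peak coherence, a spread of
sigma values, delta = 0), with analytic gradients and objective tolerance
1e-10; SEs come from the numeric Hessian at the optimum.  Whether a
resampling SE or a Hessian SE is "the" right uncertainty for delta is
underdetermined; the Hessian is the default and the bootstrap utility can
be applied when wanted.  Amplitude estimates at the box boundary are
flagged (`at_boundary`).

**Suppression index.**  For each laser trial,

    dR = (R_laser - Rbar_no_laser) / Rbar_no_laser,

where R_laser is the multi-unit rate counted from 60 ms after stimulus
onset to 60 ms after offset (window length = D) and Rbar is the mean rate
of no-laser trials matched on session, motion direction, coherence, and
stimulus-duration quartile.  Quartiles are computed per session over all
trials (laser and no-laser); the reference population for the quartile is
not otherwise pinned down, and this choice keeps matched groups balanced.
Empty or zero-mean matched groups leave dR undefined (flagged and counted,
never silently dropped).  For analyses that need dR on no-laser trials
(sham sorting, the dR median-split GLM) a leave-self-out matched mean is
used to avoid self-contamination.

**Sliding effect curves.**  Laser trials passing the conditioning filters
are sorted by dR, trial number, or duration; a window of fixed trial count
slides over them (dR filters apply to laser trials only; other filters to
all trials).  Each window is fit jointly with the *entire* filtered
no-laser set — the baseline stays fixed while the laser subset varies — and
contributes one choice shift (b2/b1) and one confidence shift (delta).  The
abscissa is the window mean of the sorting variable; ties break by stable
original order; the final window is anchored so every laser trial is
covered.  Per-window SEs are the fit SEs (the window construction does not
define an obvious resampling unit).  Default widths/steps follow the
analysis conventions (2100/1750/1600 trials, step 10), all overridable.

**Sham-laser null.**  An exact random half of the no-laser trials is
relabeled "sham"; sham dR is computed against the remaining half; the
sliding-curve machinery runs with the sham label in place of the laser
flag; the procedure repeats (default 100 relabelings) and curves average
pointwise.  Any systematic deviation from zero reflects intrinsic
covariation between rate fluctuations and behavior (choice probability),
not the perturbation.  Two SE columns are reported: the between-relabeling
spread of the mean (shrinks as 1/sqrt(n_rep); measures Monte-Carlo error of
the average) and the mean per-curve fit SE (the sampling scale of the
cohort itself — relabelings share the cohort's realized choices, so the
between-rep spread understates cohort-level noise; tests against zero use
the fit SE).

**Interaction GLMs.**  Whether the laser effect depends on duration, trial
number, or dR is tested with the seven-coefficient logistic model

    Q = b0 + b1*C + b2*I_L + b3*I_S + b4*C*I_L + b5*C*I_S + b6*I_L*I_S,

where I_S is a median-type split indicator (D < 300 ms; T < 578 for choice
or < 300 for confidence, whose trial-number relation is non-monotonic;
dR < -0.35).  b6 and its Wald p measure the modulation.  Confidence
outcomes use piecewise fits on each flank of the bell curve (C < 0 and
C > 0) with a Bonferroni x2 correction; C = 0 trials enter both flanks
(they carry peak information for both; toggleable).  Conditioning defaults:
the duration test keeps dR < -0.25 and T < 500; the trial-number test keeps
dR < -0.25 and D < 300 ms.  Designs with an empty indicator cell or a
split confounded with the laser indicator raise informative errors.

**Split comparisons.**  Early/late compares T <= 500 vs > 500 within
sessions of at least 800 trials; short/long compares D < 300 vs >= 300 ms
within the first 500 trials.  Each group gets the full choice and
confidence fits (laser trials with dR < -0.25 vs all no-laser trials of the
group), the group's mean dR ± SEM, and coherence-resolved no-laser rate
summaries (a direction-selectivity check).  Trial number counts completed
trials (the within-session trial index); whether aborted trials should
count is unknowable from a completed-trials table.

**Neurometric threshold.**  Per session, rates are normalized to the mean
rate at 51.2% coherence in the preferred direction; normalized rates pool
across sessions (normalize-then-pool; the alternative order is ambiguous
in standard descriptions and normalizing first removes session scale
differences).  Per unsigned coherence, the preferred- vs null-direction
rate distributions give an ROC area = ideal-observer proportion correct;
PC vs |C| is fit with a cumulative Weibull

    P(x) = 1 - 0.5 * exp(-(x/alpha)^k),

by binomial ML with per-level effective n = n_pref + n_null; **alpha** is
the coherence at 82% correct.  Zero coherence has no direction label and
is excluded; levels missing one side are dropped with a log entry; chance
performance everywhere is rejected as unidentifiable.

**PSTH.**  Per-trial spike counts in 1 ms bins, averaged over trials,
convolved with a 40 ms causal boxcar (truncated and renormalized at the
window start), scaled to spikes/s.

**Utilities.**  Mean dR differences between trial groups use a percentile
bootstrap (resampling trials with replacement, >= 100 resamples enforced).
Proportions are summarized with 95% Wilson score intervals.  Reward rates
weight correct direction choices as 1 and sure-bet choices as the
session's reward ratio.

## Synthetic cohorts

The generator produces sessions with the statistical structure the
analyses assume.  Task variables: |C| uniform on
{0, 3.2, 6.4, 12.8, 25.6, 51.2} with random sign; D from an exponential
truncated to [95, 925] ms whose rate is solved by 1-D root finding so the
truncated mean is exactly 350 ms (the ~300 ms median then *emerges* and is
checked, not imposed); laser and sure-bet availability Bernoulli(0.5).

Behavior: on sure-bet-available trials the sure bet is drawn first with the
Gaussian probability; remaining trials draw a direction choice from the
logistic model.  Both use one injected shift

    s_eff = s0 * f(T) * g(D) * I_L,

where f and g are pluggable compensation kernels mapping into [0, 1]
(constant, step, or logistic decay).  Compensation is modeled as
multiplicative attenuation of an additive coherence shift because the
phenomenon (effects fading with time and duration) constrains only the
product, not a mechanism; the kernels are descriptive devices, not a
circuit model.  An independent confidence shift can be configured to
emulate choice/confidence dissociations; by default both measures share
s_eff (the common-mechanism premise).

Neural activity: expected no-laser rate = baseline + gain*C floored at 0
(40 sp/s + 0.4 sp/s per % coh by default); laser trials multiply by
(1 + u), u drawn from a normal truncated to [-1, 0] whose *truncated* mean
equals the configured suppression mean (-0.33 default; the location is
solved, since truncation would otherwise bias the realized mean).  Counts
are Poisson over the analysis window, with an optional gamma mixing
parameter because per-trial count dispersion is a convention here, not a
measured quantity.  Spike trains are inhomogeneous-Poisson with a 40 ms
visual latency, suppression stepping in at laser onset (20 ms) + 5 ms
opsin delay, a linear ramp-down of the suppression after offset when
configured, and a rebound burst after abrupt offset otherwise.

Defaults were chosen once as the study conditions: 23 sessions x 900
trials (~20.7k trials); choice slope b1 = 0.12 logits/% coh (a realistic
monkey psychometric slope: ~59% preferred at 3.2% coh, ~99.8% at 51.2%);
confidence A = 0.62, mu = 0, sigma = 16% coh, which yields the ~60%
sure-bet rate at the weakest coherences that the reward-ratio calibration
targets; suppression mean -0.33, SD 0.25.  The plain `SimConfig` defaults
to s0 = 0 so a perturbation is always explicit;
`SimConfig.study_conditions()` injects s0 = -5% coh with a logistic trial
decay (midpoint 400 trials, scale 100) and a duration step at 300 ms.  At
0% coherence the reward is random 50/50 by default (configurable to
always-rewarded); the true task rule is not recoverable from outcome
tables.

What the generator does *not* emulate — and hence what passing tests do
not establish about real data: no bounded evidence-accumulation dynamics
(choices depend on C only through the static logistic, so no
duration-dependent sensitivity or choice-rate coupling); no choice
probability (rate fluctuations are independent of behavior, which is
exactly why the sham curve is a clean null here and only a *weak* trend in
real data); no session-to-session heterogeneity in tuning, slope, or
suppression beyond trial-level draws; no eye movements, lapses, or serial
dependence.  The injected shift enters additively in coherence units, so
recovery tests validate estimator calibration under the model's own
assumptions, not the biological mechanism.

## Numerical choices

- Logistic fits use Newton-Raphson ML (statsmodels) with a hard error on
  separation (coefficient magnitude guard at 25 logits) instead of ridge
  fallbacks.
- The confidence and Weibull objectives are smooth and low-dimensional;
  multi-start covers the A/sigma trade-off; box bounds keep sigma >= 1 and
  A <= 1.
- Duration quartiles degrade gracefully: sessions with fewer than four
  distinct durations collapse to one bin.
- Sliding windows wider than the available laser trials fall back to a
  single window with a warning; non-convergent windows are flagged in the
  output table, never dropped.
- All stochastic stages are pure functions of (config, seed); the pipeline
  expands one root seed through `numpy.random.SeedSequence` spawning.

## Problem sizes

Tests and the acceptance script run on synthetic cohorts of 5k-120k
trials: large enough that 3-SE recovery bands are a few tenths of a % coh
and calibration rates are estimated to ~±1.5%, small enough to keep the
full suite in minutes on one core.  The study-conditions cohort (23 x 900)
matches the scale of the experimental dataset the analysis conventions
come from.

## Known limitations

- The sham-laser "weak trend" seen with real choice-probability coupling
  has no generative counterpart here; the sham machinery is validated as a
  null, and its sensitivity to genuine coupling is exercised only
  qualitatively.
- The dR-sorted effect curve is flat under the default generator (the
  injected shift does not depend on the realized suppression draw); the
  curve's machinery is validated through the duration and trial-number
  kernels instead.
- Weibull threshold SEs are not currently propagated (the point estimate
  recovery is tested); bootstrap over sessions would be the natural
  extension.
- MAT-file ingestion is a best-effort adapter for tables stored as named
  column arrays; the tab-separated dialect is the contract.
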