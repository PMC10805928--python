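# Methods

## The generative observer

Each trial presents a 49-element ensemble with `majority_count` elements of
one class. The observer receives scalar evidence

    x ~ N(± s·k/2, 1),    k = 2·majority_count − 49,

where `s` (`sensitivity_slope`, default 0.22 d′ per element of imbalance) is
the type 1 sensitivity per unit of ratio imbalance and the sign follows the
majority class. The type 1 response is the side of `x` relative to the
decision criterion `c` (default 0); with probability `lapse_rate`
(default 0) the response is instead random. The default slope places the
staircase equilibrium near a 27:22 array (d′ ≈ 1.1), the regime human
observers occupy on this task.

Each confidence report reads a noisy copy of the same evidence,

    y_i = x + ε_i,   (ε₁, ε₂) ~ N(0, Σ),   i = 1, 2,

with per-report SDs `meta_noise_sd_1`, `meta_noise_sd_2` and correlation
`meta_noise_corr`. The defaults (0.6, 0.3, 0.5) encode the hypothesis the
paradigm was built to probe: the second report carries *smaller, partially
independent* metacognitive noise. Because the noise sources are only
partially shared, the trial-averaged confidence has lower noise variance
(0.16) than either single report (0.36 and 0.09 + shared part), so both the
"second > first" and "average > first" orderings of metacognitive
sensitivity follow from the defaults.

### Confidence mapping and scale use

Confidence is the magnitude `|y_i − c|` thresholded through nine ordered
criteria into 10 levels (scale values 10…100). Two calibration choices
matter:

* **Per-report normalization** (`normalize_confidence`, default on): the
  criteria are interpreted in units of each report's total evidence SD
  `sqrt(1 + meta_noise_sd_i²)`. Observers spread ratings over the range of
  confidence signals they actually experience; without this, the noisier
  first report would systematically occupy more extreme rating levels than
  the second and the up/down-shift balance would be an artifact of scale
  use rather than of evidence. The rescaling is monotone per report, so
  the information a report carries about accuracy is untouched.
* **Decile criteria**: the default thresholds are the deciles of the folded
  normal |N(0.5, 1)| — the normalized evidence distribution at the
  staircase design point — giving near-uniform use of the 10 levels. This
  mimics the protocol's nudge to use the whole scale (the response pointer
  starts at a random scale position) and reproduces the observed share of
  early-terminated trials: the two endpoint levels jointly hold ≈ 20% of
  trials (≈ 19–21% in the human data).

A first rating at either endpoint ends the trial (`EXTREME`; no second
rating). Otherwise the second rating is the thresholded second read; if it
would repeat the first rating, it is nudged one level toward the sign of
the continuous difference between the two (normalized) evidence magnitudes,
ties going one level down. This implements the forced re-evaluation with
minimal distortion.

Random draws occur in a fixed, documented order (stimulus sequence first,
then per trial: lapse uniform, evidence, noise pair, plus one uniform on
lapse trials only), so a session is byte-reproducible from its seed. Cohort
runs draw per-participant sub-seeds (< 2³¹) from a master generator;
`CohortVariation` adds lognormal jitter (CV 0.15) to the slope and noise
SDs and N(0, 0.05) jitter to the criterion, the scale of individual
differences typical of online psychophysics cohorts.

### Staircase

Two consecutive correct responses decrement the majority count by one
element (harder); any error increments it (easier); bounds are 25 (smallest
possible majority) and 39 (keeps the minority class clearly visible). The
rule converges where p² = ½, i.e. ≈ 70.7% correct. With integer steps of
~0.22 d′ the simulated asymptote sits at 71–72%, within the protocol's
"around 70%" target.

## Preprocessing

Participants are excluded (in this order) when (1) their type 1 accuracy
falls more than 2.5 *sample* SDs (n − 1 denominator) from the group mean,
both computed over all submitted participants; or (2) they have fewer than
50 up-shift or fewer than 50 down-shift trials. Extreme trials are dropped
from all confidence analyses — including the first-interval meta-d′, whose
first rating is technically valid — so that the first, second and averaged
streams are fitted on one and the same trial set and remain directly
comparable.

## meta-d′ estimation

Confidence values are collapsed into K = 5 equal-width bins over (0, 100]
by default (half-step averaged values fall unambiguously into the half-open
bins); K = 5 avoids sparse cells at the ~360 usable trials of a session and
is configurable, with all three streams always sharing edges. Type 1 d₁ and
c₁ come from the response marginals with the 1/(2N) edge correction. The
fit maximizes the multinomial likelihood of confidence counts conditional
on stimulus and response over meta-d′ and 2(K−1) type 2 criteria,
parameterized as log-gaps around the scaled criterion `c₁·meta-d′/d₁` so
ordering is maintained by construction. Each type 2 cell is padded by
1/(2K) before fitting (uniformly across all fits). Optimization is
Nelder-Mead from three deterministic starts (meta-d′ at 0.5×, 1×, 1.5× d₁;
criteria at empirical half-normal quantiles); non-convergence is reported
via a flag, and fully degenerate tables (all confidence in one bin) return
meta-d′ = 0 with a warning.

On counts from a plain SDT observer with deterministic confidence the
estimator recovers meta-d′ = d′ (within 0.1 at n = 20,000) and matches a
0.01-step profile-likelihood grid search within 0.02. Note that *paradigm*
sessions do not satisfy meta-d′ = d′ even for a noiseless observer: the
extreme-trial exclusion truncates the confidence distribution (a selection
on the confidence variable itself), deflating meta-d′ relative to the d₁ of
the retained trials. All three streams share this truncation, so
between-stream comparisons are unaffected.

## Second-step statistic and its chance level

On a participant's up/down trials, hits = correct ∧ up-shift,
false alarms = incorrect ∧ up-shift; d₂ and c₂ use the conventional
formulas with the same 1/(2N) correction. Chance is calibrated per
participant by permuting the correctness labels across those trials (shift
labels fixed, 1000 permutations by default, per-participant seeds from a
master seed), which preserves P(up) by construction. The group test
compares observed d₂ against the per-participant null means in a paired t
test; a per-participant one-sided permutation p-value is also reported.

**A structural prediction.** Any observer that re-samples its evidence in
this design shows a small *down*-shift excess and hence a slightly positive
c₂ (≈ +0.06 at the defaults): conditioning on a non-extreme first rating
interacts with the asymmetric tail dependence of the two confidence reads
(they agree tightly at high confidence, decorrelate near zero evidence
where sign flips occur). The human data show the same direction — down
counts exceeded up counts in both experiments — and their precision for
"criterion no different from zero" is about ±0.1, which is the band the
package's own checks use. A pure-noise *second* report does not produce a
null d₂: the informative first rating anchors the comparison, making d₂
genuinely negative (≈ −0.21). The exchangeable null — shifts independent of
correctness — requires both reports to be uninformative, which is how the
calibration checks construct it.

## Group statistics

Paired t tests report t, df, two-sided p (one-sided available), Cohen's
d_z = mean(diff)/SD(diff), and the two-sided 95% CI of the mean difference.
The cohort report runs seven comparisons: the three pairwise meta-d′
contrasts, d′(up) vs d′(down), d₂ vs chance, c₂ vs 0, and up vs down
counts. Sample-size planning iterates n upward from 2 using exact
noncentral-t power (ncp = d_z·√n, critical value from the central t); the
reference computation (d_z = 0.62, α = .05, power = .95, one-sided) gives
n = 30. Group comparisons default to two-sided tests; the sample-size
default is one-sided, matching the convention under which that reference
value was produced.

## What the simulator does and does not emulate

It emulates the task structure (450 trials in 9 blocks, staircase, 10-level
scale, no-repeat rule, early termination), SDT-style perceptual noise,
per-report metacognitive noise with tunable correlation, scale-use
calibration, lapses, and modest between-subject heterogeneity. It does not
model reaction times, learning or fatigue across blocks, confidence leak
(autocorrelation across trials), pointer-position response habits, or
deliberate rating strategies (e.g. the polarized all-extreme style that got
human participants excluded). Passing tests therefore show that the
analysis stack recovers the planted structure under SDT assumptions — not
that those assumptions exhaust human confidence behavior.

## Numerical choices and problem sizes

Edge rates are corrected to 1/(2N); meta-d′ fits tolerate 1e−6 on the
log-likelihood; d′/criterion agree with root-found normal quantiles to
1e−9. The packaged checks use: 12,000 staircase trials (500 burn-in) for
the convergence measurement; 20,000 trials for estimator self-consistency;
20 participants × 450 trials for the cohort-level effects (500
permutations); 20 cohorts of 8 participants for null calibration — sizes
chosen so each check is decisively powered while the whole suite runs in a
few minutes on one core.
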