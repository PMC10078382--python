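# Methods

`streaklab` models and analyses a standard behavioral design: an observer
watches a sequence of eight binary outcomes (Red/Blue draws from a bingo
cage, Up/Down moves of an analyst's portfolio or a stock price) and states
the probability that the streak at the end of the sequence will continue on
the ninth outcome.  Two opposing response patterns are of interest: the
*hot hand* (repetition probability rises with streak length) and the
*gambler's fallacy* (it falls).  The package provides the stimulus
generator, two normative observer families that produce these patterns,
exact pattern-occurrence statistics, a synthetic-participant simulator, and
the per-participant strategy analysis.

## Stimulus design

A session is 18 eight-outcome sequences: six *targets* ending in terminal
streaks of 2, 3, 4, 5, 6 and 7 (one each), and twelve *fillers* ending in a
reversal (terminal streak 1).  Symbols are abstract `a`/`b`; `a` is the
focal symbol.  The design intent is that role should not be predictable
from surface statistics, so the generator enforces a hard constraint — the
144 session outcomes contain exactly 72 of each symbol — and a soft one:
among a bounded number of random filler drafts (default 64, each repaired
to exact balance by flipping free filler positions), it keeps the draft
whose internal run-length profile is closest in L1 distance to the
targets'.  Target prefixes are sampled uniformly, with the outcome before
the streak forced to the opposite symbol; half the targets end in each
symbol.  Everything is a pure function of `(seed, config)`; trial order is
a uniform shuffle.  The generator does not reproduce any particular
historical stimulus list — only the design constraints.

## Observer models

Both families map a sequence to the probability its terminal streak
repeats. Sequences have at most nine relevant outcomes, so all probability
arithmetic is exact (`fractions.Fraction`); there is no floating-point
tolerance anywhere in the model layer.

**i.i.d. Bayesian updater.**  Outcomes are Bernoulli(θ) in the focal
symbol.  Priors over θ may be a point mass, a discrete distribution
(the distributional-rate design uses {.25, .50, .75} with weight 1/3 each),
or Beta(α, β).  The ordered-sequence likelihood is θ^{n_a}(1−θ)^{n_b}; the
reported quantity is the posterior-predictive probability of the terminal
symbol, which in the Beta case is the Laplace form (n_t + α_t)/(n + α + β).
For the unknown-rate regime the default prior is Beta(1, 1) — the least
committal choice, exposed as a configuration knob.  Any nondegenerate
prior yields a nondecreasing curve on pure-streak targets (hot hand), and
with the three-point prior predictions are bounded in [.25, .75].

**Finite urn (sampling without replacement).**  The Law-of-Small-Numbers
observer imagines the generator as an urn of N signals containing exactly
θN focal signals; θN integrality is *required*, not rounded, because silent
rounding changes the model.  One urn spans the eight observed outcomes plus
the predicted ninth draw (hence N ≥ 9) and is never refreshed mid-sequence;
that renewal policy matches a one-prediction-per-sequence task.  With a
known composition the next-draw probability is (θ_t N − k_t)/(N − n):
strictly decreasing in the drawn streak (gambler's fallacy).  Under a
discrete composition prior, the ordered-draw likelihood is the
falling-factorial ratio (θN)_{n_a}((1−θ)N)_{n_b}/(N)_n; compositions with
zero likelihood are dropped and the rest renormalised (standard
conditioning — an error is raised only when every composition dies).  As
N → ∞ the urn prediction converges to the i.i.d. one (verified to 10⁻³ at
N = 10⁵).

**Regime transition.**  With a composition prior concentrated on θ = .5
(the tested configuration is N = 20, prior {.25: .1, .50: .8, .75: .1}),
the curve over terminal streaks 1–7 first dips below its streak-1 level
(depletion dominates) and then rises above it (updating dominates).  The
uniform three-point prior at N = 20 does *not* dip on eight-outcome
sequences: with that much prior mass on extreme rates, updating dominates
from streak 2 onward.  The transition requires genuine prior anchoring on
the balanced composition.

`model_curve` averages predictions by terminal streak length over a
session.  Streak-1 points are filler-derived and flagged; they appear in
curves but never in inferential summaries.

## Pattern waiting times

For i.i.d. tosses, the expected wait until a pattern first occurs is the
expected absorption time of the Markov chain on the pattern's KMP prefix
automaton, solved exactly over rationals (sympy).  For a fair coin this
equals the Conway leading number Σ 2^k over self-overlap lengths k, kept as
an independent cross-check: HHHH → 30, HHTT → 16.  Finite-horizon
occurrence probabilities ("at least once within n tosses", overlaps
allowed) come from stepping the exact state distribution n times; the test
suite confirms the horizon-20 values against full 2²⁰ enumeration.

## Synthetic cohorts

Simulated participants hold one of four latent strategies: *updater*
(responds with an observer model's prediction), *reverser* (its mirror,
p ↦ 1 − p), *constant*, or *alternation-expecter* (expects reversal at a
fixed .60 alternation rate, the level typically judged "random", so repeat
probability is .40).  Response links:

* continuous: `clip(100·p + Normal(0, noise_sd), 0, 100)`.  Default
  `noise_sd = 10` points on the 0–100 scale — a realistic rating
  dispersion; clipping slightly biases means near the scale ends.
* dichotomous: `Bernoulli(sigmoid(temperature · (p − .5)))`.  Default
  `temperature = 8` (a latent p of .7 yields a repeat choice ~83% of the
  time); temperature → ∞ recovers deterministic thresholding.  The logistic
  link is the simplest monotone stochastic choice rule; no claim is made
  that humans implement it.

Six presets named `1A`–`3B` carry the six studies' per-condition cohort
sizes, response formats, latent updaters per base-rate regime (Beta(1,1)
for unknown rates; Beta(4,4) for the fixed-.50 regime, i.e. anchored,
conservative updating; the three-point prior for the distributional
regime), and reverser shares mimicking each study's reported share of
reversal-leaning participants.  They are qualitative presets for
exercising the pipeline, not ground truth.  Simulation is fully
reproducible from `(config, seed)`: stimulus, assignment and per-participant
response streams are derived sub-seeds.

What the generator does not emulate: trial-order effects, learning or
drift across trials, response times, scale-use idiosyncrasies (end
aversion, rounding to multiples of 5), or within-participant strategy
mixing.  Passing recovery tests therefore show the pipeline is consistent
under the stated response model, not that human data are this clean.

## Strategy analysis

* **Aggregate curves**: per-participant means by condition × streak length,
  then across-participant mean and standard error (sample SD/√n).  Filler
  points are carried but flagged.
* **Continuous fits**: ordinary least squares of a participant's six target
  ratings on streak length; the slope is the strategy measure.
* **Dichotomous fits**: logistic regression of the six repeat/reverse
  choices on streak length.  With six binary points, complete or
  quasi-separation is common and maximum likelihood diverges, so the
  coefficient is estimated by Firth's penalized likelihood (Jeffreys-prior
  score correction, Newton iteration with step damping), additionally
  capped at |β| ≤ 5 with a flag; an unbounded β would make the
  percent-change transform 100·(e^β − 1) meaningless.  Constant responses
  and separated patterns are flagged, never raised.
* **Classification**: a participant is *negative* (reversal-increasing),
  *positive* (repetition-increasing) or *flat* by the sign of the slope or
  percent-change under a |·| < 10⁻⁹ tolerance — a numerically principled
  zero, since exact-zero estimates occur only for degenerate inputs.
* **Dichotomization** of ratings for cross-format comparison: >50 → repeat,
  <50 → reverse; ratings of exactly 50 express indifference and are
  excluded with an audit count.
* **Group comparison**: Welch's unequal-variance t from its closed form
  with Welch–Satterthwaite degrees of freedom, applied to per-participant
  repeat rates.  Omnibus mixed-model machinery (repeated-measures ANOVA
  with sphericity corrections, Bonferroni families) is deliberately out of
  scope; the pipeline exports tidy per-participant tables so any standard
  routine can be applied externally.

## Numerical and design choices

* Exact rationals for all observer and pattern computations; floats only at
  the presentation/simulation boundary.
* Degenerate inputs: empty histories give the prior rate; histories
  impossible under every composition raise a specific error; validation of
  stimulus sets reports rule names and never raises.
* The stimulus balance search can in principle exhaust its budget (the
  repair step fails only when the fillers cannot supply the required symbol
  count); it then raises naming the violated constraint.
* Problem sizes in the test suite (cohorts of up to 300 participants,
  enumeration horizons of 20 tosses, urns to N = 10⁵) were chosen as the
  smallest sizes at which each property is sharply testable.

## Known limitations

* The urn observer's N is a free parameter; no fitting of observer
  parameters to response data is provided.
* Only uniform trial shuffling is implemented; constrained interleaving of
  targets and fillers is not.
* The dichotomous link and the preset mixtures are modeling conveniences;
  conclusions about human strategy shares require real response tables,
  which the pipeline ingests through the documented CSV schema.
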