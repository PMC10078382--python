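# streaklab

Tools for studying how observers predict the next outcome of a binary
sequence — the *hot hand* (expecting streaks to continue) versus the
*gambler's fallacy* (expecting them to reverse) — built for researchers in
judgment and decision making who run streak-prediction experiments or model
them.

The package covers the full loop of a standard design:

* **Stimuli** — balanced 18-trial sessions of eight-outcome binary
  sequences: six targets ending in streaks of 2–7, twelve reversal-ending
  fillers, exact 72/72 symbol balance per session.
* **Observer models** — two normative accounts, computed exactly:
  * *i.i.d. Bayesian updating*: with prior π(θ) over the base rate and a
    sequence containing n_t terminal-symbol outcomes among n, the repeat
    probability is E[rate_t(θ) | data]; for a Beta(α, β) prior this is the
    Laplace form (n_t + α_t)/(n + α + β) — nondecreasing in streak length
    (hot hand).
  * *finite urn, sampling without replacement*: the generator is imagined
    as an urn of N signals with θN of the focal type; with a known rate the
    repeat probability is (θ_t N − k_t)/(N − n) — strictly decreasing in
    the drawn streak (gambler's fallacy).  Under rate uncertainty the
    falling-factorial likelihood (θN)_{n_a}((1−θ)N)_{n_b}/(N)_n makes the
    curve fall, then rise, as updating overtakes depletion.
* **Pattern statistics** — exact expected waiting times and finite-horizon
  occurrence probabilities for binary patterns under i.i.d. tosses
  (absorbing Markov chain on the prefix automaton; Conway leading-number
  cross-check).  A fair coin takes 30 tosses on average to show HHHH but
  only 16 to show HHTT.
* **Synthetic cohorts** — trial-level response tables (0–100 ratings or
  repeat/reverse choices) from mixtures of latent strategies, with presets
  matching the six-study design (3 generators × 3 base-rate regimes ×
  2 response formats).
* **Analysis** — aggregate streak-length curves with standard errors,
  per-participant slopes (OLS) and log-odds coefficients (Firth-penalized
  logistic) with the percent-change-in-odds transform 100·(e^β − 1),
  strategy classification, dichotomization, and Welch's unequal-variance
  t tests between groups.

## Worked example

```python
import streaklab as sl

# A balanced session and the three-rate Bayesian observer's curve
session = sl.build_stimulus_set(1)
observer = sl.ObserverSpec.iid(sl.PriorSpec.three_rate())
for pt in sl.model_curve(observer, session).points:
    print(pt.streak_length, round(pt.p_repeat, 3), pt.filler_flag)
```

```
1 0.532 True
2 0.603 False
3 0.681 False
4 0.603 False
5 0.681 False
6 0.723 False
7 0.723 False
```

The flagged streak-1 row averages the twelve filler trials; rows 2–7 are
the targets.  The curve climbs toward .75 — the highest rate in the prior —
as longer streaks make the extreme base rate more credible (it is not
strictly monotone because target prefixes also carry evidence).

```python
# Simulate a fixed-.50 continuous-rating study and classify strategies
table = sl.simulate_study(sl.study_preset("2A"), 42)
fits = sl.fit_participants(table)
print(sl.classify_strategies(fits).round(3))
```

```
strategy   negative  positive  flat   n
condition
Analyst       0.212     0.788   0.0  52
Bingo         0.464     0.536   0.0  56
Stock         0.104     0.896   0.0  48
```

Each participant's six target ratings are regressed on streak length;
`negative` is the share with reversal-leaning (negative) slopes.  The
Bingo condition's large negative share reflects that preset's
gambler's-fallacy-heavy mixture for a random device with a stated fixed
rate.

The same stages are available from the shell:

```
streaklab generate-stimuli --seed 1 --sessions 1 --out stimuli/
streaklab simulate --preset 2A --seed 42 --out responses.csv
streaklab analyze --responses responses.csv --format continuous --out results/
streaklab pattern-wait HHTT --horizon 20
streaklab run --config run.yaml       # full pipeline with a JSON manifest
```

External response tables are ingested through the documented CSV schema
(`participant_id, study_tag, condition, format, trial_index, role,
terminal_streak, sequence, response`) via `streaklab.io.read_response_table`,
which validates ranges and key uniqueness with row numbers.

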