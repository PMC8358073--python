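# Methods

## Observation model

Every Matrix-test sentence contributes one binomial observation: `n_correct ~
Binomial(n_words = 5, p)`, treating words within a sentence as independent.
The recognition probability chains four pure components:

1. **Auditory channel.** A logistic in SNR, `F_A(x) = [1 + exp(−(2 ln 9/ω)(x −
   θ_A))]^(−1)`.  `θ_A` (dB) is the 50% point; the `2 ln 9/ω` slope factor
   makes `ω` (dB) exactly the 10–90% range, i.e. `F_A(θ_A ± ω/2) = 0.9/0.1`.
2. **Visual channel.** A single-parameter exponential in blur, `F_V(x) =
   exp(−x²/θ_V²)`; `F_V(0) = 1` and `F_V(θ_V) = e^(−1) ≈ 0.368`.  Defined for
   blur ≥ 0 and `θ_V > 0`.
3. **Lapses.** `Ψ_{m,e} = (1 − λ_{m,e}) F_m`: with probability `λ` the answer
   is stimulus-independent, capping asymptotic performance.  The final model
   shares the visual lapse across tasks and lets only the auditory lapse
   differ between focused and divided attention.
4. **Race and guess.** Channels combine by probability summation `Ψ = Ψ_A +
   Ψ_V − Ψ_A Ψ_V`, then the closed-set guess floor `p = 0.9 Ψ + 0.1`.

Both channels are always combined through the race formula: an absent acoustic
signal enters as `Ψ_A = 0` (a sentinel, not an SNR of −∞), an absent video as
`Ψ_V = 0`, and the 70-pixel blur of divided-task auditory trials as a
numerically negligible visual channel (`F_V(70) < 10⁻⁶` at realistic `θ_V`) —
one code path for every condition.

**Ordering of the guess transform.** The enhancement index is `MEI =
Ψ_trade-off/Ψ_strict − 1` with *post-guess* probabilities.  The alternative
(ratio before guess correction) was evaluated by brute force at the CI group
means (SNR 0 dB, blur 20 px): post-guess gives 0.221, pre-guess 0.266; only
the post-guess ordering reproduces the published index of 0.22, so it is the
package's definition (the race itself operates pre-guess, because guessing
happens at the response stage, once per word).

## Synthetic cohorts

The generator is the statistical twin of the fitted model and defines the
conditions under which every downstream claim is tested.

* **Group locations** default to the published group-level estimates.  NH:
  `θ_A = −12` dB, `ω = 7.4` dB, `θ_V = 18.3` px, `λ_V = 0.54`; the focused
  auditory lapse is implied by the 90% saturation level (`0.9(1 − λ) + 0.1 =
  0.90 → λ ≈ 0.111`) and the divided lapse adds the reported 0.039 task
  difference.  CI: `θ_A = −3.1` dB, `ω = 10.4` dB, `θ_V = 17.7` px, `λ_V =
  0.46`, focused lapse from the 84% saturation (`λ ≈ 0.178`), divided lapse
  +0.22.
* **Between-participant scales** are not reported; they are fixed once at
  values typical for this kind of psychophysics: sd 1.5 dB (NH) / 2.5 dB (CI)
  for the threshold, log-sd 0.15 for the width, log-sd 0.2 for the visual
  threshold, logit-sd 0.35 for all lapses.  Widths and visual thresholds are
  log-normal, lapses logit-normal, so every draw respects the parameter
  supports; the stated location is the median on the natural scale.
* **Designs.** Focused attention: an auditory block (default 40 sentences over
  8 individualized SNRs) and a visual block (40 sentences over the common
  blurs 0/6/12/16/20 px).  Divided attention: 80–120 trials on a 5×5 grid of
  4 individualized SNRs plus a signal-absent column and 4 individualized blurs
  plus the 70-px row, balanced and pseudo-randomly interleaved with unique,
  never-repeated sentence ids.
* **Level individualization** inverts the participant's own psychometric chain
  at target proportions (auditory: 8 targets evenly spaced on [0.15, 0.85];
  divided-task targets 0/25/50/75% for SNR and 50/35/25/15% for blur).  This
  stands in for the adaptive familiarization track of the original procedure,
  which estimates the same quantities.  Targets beyond the lapse-limited
  ceiling or below the guess floor are clipped to psychometric bounds
  (F ∈ [10⁻⁴, 0.995]) with a warning — real sessions run into the same
  ceiling.

What the generator does **not** emulate: lexical content and semantic priming,
serial dependencies and fatigue within a block, word-position effects inside a
sentence (words are exchangeable Bernoulli trials), response omissions, and
the historical 60-vs-40-sentence inconsistency of the first participants.
Passing recovery tests therefore show that the estimation machinery is
faithful to this generative model at study-scale sample sizes, not that real
data satisfy its independence assumptions.

## Hierarchical inference

* **Transforms.** `θ_A` is sampled on its natural (dB) scale, `ω` and `θ_V`
  on the log scale, lapses on the logit scale.  Each family gets a normal
  group distribution per cohort.
* **Priors** (the original specification is not public, so these are the
  package's own weakly informative choices): group location `θ_A ~ N(0, 20
  dB)`, `log ω ~ N(log 8, 1)`, `log θ_V ~ N(log 15, 1)`, lapse logits
  `N(−1.5, 1.5)` auditory / `N(0, 1.5)` visual; all group scales half-normal
  (10 dB for the threshold, 0.5 for log scales, 1 for logits).  All are
  overridable per family.
* **Sampler.** Affine-invariant ensemble MCMC (emcee) with differential-
  evolution and snooker moves, on a *non-centered* parameterization
  (participant values as standard-normal offsets), which removes the
  location–scale funnel that stalls mixing in the centered form.  `chains`
  independent ensembles are seeded deterministically from one seed;
  `samples`/`burn_in` count ensemble sweeps per chain, so a chain retains
  `samples × n_walkers` draws (walkers default to `max(2·ndim + 8, 32)`).
  Stored draws are converted back to centered, transformed-scale values.
* **Budgets.** Defaults mirror a 10,000-sweep burn-in and retention per
  chain; all tests and the acceptance script use the smoke budget of 3 chains
  × 2,000 retained sweeps after 2,000 burn-in, which keeps a cohort fit in
  the 1–3 minute range on one CPU at the study's trial counts and is
  sufficient for the recovery tolerances checked.
* **Diagnostics.** Rank-normalized split-R̂ and bulk ESS (arviz), treating
  every walker of every ensemble as a chain; pass criterion R̂ < 1.1 and ESS >
  1,000.  Under the smoke budget the hyper-scale parameters occasionally sit
  just above 1.1 while group locations are stable; summaries warn (and the CLI
  exits with a dedicated status) rather than fail.
* **Summaries.** Posterior means and *shortest* 95%-HDIs over pooled draws.
  Derived quantities — natural-scale group parameters and the
  divided-minus-focused auditory lapse difference — are computed sample-wise,
  never from summary statistics.

## Model comparison

`BIC = ln(n) k − 2 ln(L̂)` with `n` counted at the word level (the binomial
observations; sentence- or condition-level counts are exposed through the
inputs, word level is the default).  `L̂` comes from bounded L-BFGS-B
maximization of the binomial likelihood on transformed parameters — the
likelihood factorizes over participants, so each participant is optimized
separately with multi-start, optionally initialized at hierarchical posterior
means.  The strict and trade-off variants share the same free parameters
(they differ only in *which* auditory lapse predicts AV trials), so `k`
cancels in ΔBIC whenever both tasks contribute data.  `R²` is the squared
Pearson correlation between observed and predicted condition-level
proportions; the mean signed error is `mean(observed − predicted)`, optionally
restricted to one modality (the AV restriction isolates the strict model's
underprediction of audiovisual performance).

## Numerical choices

* Trial probabilities are clipped to `[10⁻¹², 1 − 10⁻¹²]` inside the
  likelihood; binomial coefficients are included so `L̂` is the true pmf.
* Degenerate inputs: zero group scale collapses draws to the location; a
  single-participant fit is allowed (hypers prior-dominated); a trial with
  both stimulus dimensions absent is a data error; non-positive widths and
  thresholds and negative blurs are invalid parameters.
* HDI ties: the shortest window over sorted pooled samples, first index wins.
* Determinism: every simulate/fit entry point takes one integer seed; child
  seeds are spawned via `numpy.random.SeedSequence` and kept below 2³¹.

## Known limitations

* The ensemble sampler's walker-as-chain ESS is optimistic relative to
  gradient-based samplers' per-chain ESS; R̂ across 3 independent ensembles is
  the load-bearing check.
* With 7 participants the cohort-level recovery of lapse differences carries
  a sampling error of several percentage points by construction; tolerances
  in the tests reflect that.
* Posterior values on the original study's deposited data cannot be expected
  to match beyond HDI-level agreement: the original prior specification and
  hierarchical transforms are not public, and this package makes its own
  (documented) choices.
* The published ΔBIC table values depend on the deposited data; only the
  selection direction is reproducible synthetically and that is what is
  tested.
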