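# avspeech

Audiovisual speech recognition under focused and divided attention: a
psychophysical modelling pipeline for closed-set Matrix-test experiments with
normal-hearing (NH) listeners and cochlear-implant (CI) users.

## The problem

Matrix sentences (5 words, 10 alternatives per word) are presented acoustically
in speech-shaped noise, visually as a blurred video of the talker, or both.
Listeners either know the upcoming modality (focused attention, blocked
unisensory presentation) or not (divided attention, interleaved A/V/AV trials).
Two questions drive the analysis: does dividing attention degrade unisensory
recognition, and is audiovisual recognition anything more than two independent
channels racing?

## The model

Word recognition is binomial at the word level with probability

```
p = 0.9 Ψ + 0.1                                   (10-alternative guess floor)
Ψ = Ψ_A + Ψ_V − Ψ_A Ψ_V                           (probability summation)
Ψ_A = (1 − λ_A,e) F_A(x_A),  F_A = [1 + e^(−(2 ln 9/ω)(x_A − θ_A))]^(−1)
Ψ_V = (1 − λ_V)   F_V(x_V),  F_V = e^(−x_V²/θ_V²)
```

where `x_A` is the acoustic SNR (dB), `x_V` the video blur (pixel sd), `θ_A`
the 50% auditory threshold, `ω` the 10–90% width, `θ_V` the blur at which
recognition drops to 36.8%, and `λ_{m,e}` a lapse probability per modality `m`
and attention task `e`.  In the final model only the auditory lapse may differ
between tasks.

Audiovisual trials can be predicted with the divided-task auditory lapse
(**strict** probability summation) or the focused-task lapse (**trade-off**
model).  The multisensory enhancement index

```
MEI = Ψ_trade-off / Ψ_strict − 1
```

is zero under pure statistical facilitation and positive when a task-dependent
lapse increase is traded for multisensory enhancement.

Participant parameters sit in a hierarchical Bayesian model (normal group
distributions on transformed scales, per cohort) fitted by ensemble MCMC with
a binomial likelihood; variants are compared with `BIC = ln(n) k − 2 ln(L̂)`.

## Worked example

```python
from avspeech import GroupHyperParams, StimulusCondition, mei, predict_recognition

ci = GroupHyperParams.ci_defaults().group_means()   # published CI group means
cond = StimulusCondition("AV", "divided", snr=0.0, blur=20.0)
print(predict_recognition(cond, ci, "trade-off"))   # 0.7305320049264846
print(predict_recognition(cond, ci, "strict"))      # 0.5980943459966804
print(mei(cond, ci))                                # 0.22143272180429419
```

At an SNR of 0 dB and a 20-pixel blur, a CI-group listener is predicted to
recognize 73% of words under the trade-off model but only 60% under strict
probability summation — an enhancement index of 0.22, the lapse-rate
difference between the two attention tasks re-expressed as a multisensory
benefit.

The `analysis/` scripts run the full narrative on synthetic cohorts:

1. `01_psychometric_checks.py` — analytic identities and MEI surfaces,
2. `02_simulate_cohorts.py` — 14 NH + 7 CI participants, focused + divided
   sessions (writes `results/trials.csv`),
3. `03_fit_hierarchical.py` — hierarchical MCMC fits with convergence reports,
4. `04_compare_models.py` — strict vs. trade-off BIC table and signed errors.

The same pipeline is scriptable from the shell:

```
avspeech simulate --seed 1 --out run/
avspeech fit run/trials.csv --smoke --out run/fit/
avspeech compare run/trials.csv --out run/cmp/
```

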