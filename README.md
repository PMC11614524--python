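# forage

Generative modelling of human visual foraging: a four-parameter
"sampling without replacement" choice model, hierarchical Bayesian
fitting with participant random effects, and posterior-contrast
hypothesis tests for scarcity, stickiness, proximity and direction
effects.

## The problem

In a visual foraging task an observer clicks away every target in a
display that mixes two target classes (say red and green circles) with
distractors.  Traditional summaries — run lengths, switch counts — are
confounded by display layout and class imbalance: with 5 targets of one
class and 15 of the other, fewer switches are possible no matter what the
observer prefers.  This package instead models each selection directly.
Foraging is weighted sampling without replacement over the remaining
targets: after each pick, the probability that remaining target *i* is
chosen next is

    P(i) ∝ p_A^[i∈A] (1−p_A)^[i∈B] · p_S^[same] (1−p_S)^[diff]
           · exp(−σ_ρ d_i) · exp(σ_d cos φ_i)

with `b_A = logit(p_A)` the class bias, `b_S = logit(p_S)` the tendency to
stick with the class just selected, `σ_ρ` the preference for nearby items
(`d_i` = distance from the last selection, normalised by the display
diagonal), and `σ_d` the preference for items ahead of (`σ_d > 0`) or
behind (`σ_d < 0`) the current direction of movement.  The four
parameters are fitted per experimental condition (feature vs conjunction
search × three target-ratio levels) in a multilevel model with
independent per-participant random effects, and questions like "do people
prefer the scarcer target?" become posterior contrasts such as
`Pr(b_A(scarceA) − b_A(equal) > 0 | D) > 0.99`.

The package is for researchers who want to simulate such experiments,
fit the model to event-level selection data, and run the associated
decision criteria and descriptive analyses.

## Worked example

Simulate a small feature-search experiment with a built-in scarcity bias
(p_A = 0.6 toward the rarer class), fit it, and test the scarcity
criterion:

```python
import numpy as np
from forage import (
    ConditionKey, DisplayGeometry, ExperimentDesign, McmcConfig,
    evaluate_h1, fit_model, posterior_summary, simulate_experiment,
)
from forage.synth import power_analysis_group_params

conditions = tuple(ConditionKey("feature", r) for r in ("scarceA", "equal", "scarceB"))
group = power_analysis_group_params(conditions=conditions)   # b_A = ±0.405 / 0
design = ExperimentDesign(n_participants=12, trials_per_condition=5,
                          conditions=conditions)
data = simulate_experiment(group, design, DisplayGeometry(),
                           np.random.default_rng(0))

draws, diag = fit_model(data, cfg=McmcConfig(n_chains=2, n_warmup=400,
                                             n_samples=500, seed=1))
print(f"max R-hat: {diag.max_rhat:.3f}")
summary = posterior_summary(draws)
for cond in conditions:
    row = summary.loc[f"b_A[{cond}]"]
    print(f"b_A[{cond}] = {row['mean']:+.3f}  (97% CI {row['ci97_low']:+.3f} "
          f"to {row['ci97_high']:+.3f})")

h1 = evaluate_h1(draws, marginalize=False)
print(h1.scarceA_vs_equal)
print(h1.equal_vs_scarceB)
print("scarcity effect detected:", h1.passed)
```

Output (about a minute on one core):

```
max R-hat: 1.026
b_A[feature:scarceA] = +0.328  (97% CI -0.085 to +0.686)
b_A[feature:equal] = -0.050  (97% CI -0.438 to +0.277)
b_A[feature:scarceB] = -0.532  (97% CI -0.907 to -0.159)
H1[feature]: b_A(scarceA) - b_A(equal): Pr(>0) = 0.935 [fail at 0.99]
H1[feature]: b_A(equal) - b_A(scarceB): Pr(>0) = 0.975 [fail at 0.99]
scarcity effect detected: False
```

The fitted class-bias means straddle their generating values (+0.405, 0,
−0.405) and both contrasts lean the right way (0.94 and 0.98), but with
only 12 participants neither reaches the 0.99 decision threshold — the
planned design uses 36 participants precisely so that an effect of this
size is detected reliably (see the recovery analysis below).

The same pipeline is available from the shell:

```bash
forage config --show                 # every configurable default
forage simulate --seed 1 --out data/
forage exclusions --data data/       # 5 s gap rule, terminated attempts
forage fit --data data/ --seed 2 --out draws.csv
forage test --draws draws.csv        # H1–H4 + per-participant effects
forage describe --data data/         # run-length / switch statistics
```

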