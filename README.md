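# otternbda

Network-based diffusion analysis (NBDA) for social-learning studies in
animal groups, built around the continuous-time **TADA** (time of
acquisition diffusion analysis) variant, with the full inference pipeline
used in captive-group foraging experiments: scan-derived association
networks, social-transmission hazard models with AIC model competition,
derived social-transmission statistics, and a latency gamma GLMM for
long-term-memory questions. A synthetic-study generator with known ground
truth makes every stage verifiable end to end.

## Who this is for

Behavioural ecologists analysing diffusion experiments: a group of animals
(here modelled on family groups of Asian short-clawed otters) is presented
with novel extractive foraging tasks, and the order and timing at which
individuals first interact with or solve each task is scored from video.
The question is whether acquisition spreads along the group's social
network (social learning), how strongly, and whether individuals remember
solutions months later.

## The model

During a diffusion, a naive individual *i* acquires the behaviour with
hazard

```
lambda_i(t) = lambda0(t) * R_i(t),      T_i(t) = sum_j a_ij z_j(t)
```

where `lambda0` is the baseline asocial rate (constant, or a gamma
distribution's hazard to allow time variation), `a_ij` is the simple ratio
association index between *i* and *j*, `z_j` indicates whether *j* is
already informed, and the relative rate `R_i` combines the social
transmission rate `s` with individual-level variables (ILVs) `x_i`
(age in years; sex, female = 1):

| model type      | R_i                          |
|-----------------|------------------------------|
| asocial         | `exp(B x_i)`                 |
| additive        | `s T_i + exp(B x_i)`         |
| multiplicative  | `exp(B x_i) (s T_i + 1)`     |
| no-ILV social   | `s T_i + 1`                  |

`s` is the transmission rate per unit network connection relative to the
baseline asocial rate; `s = 0` recovers pure asocial learning. The model
space crosses model type x ILV subset x same/different `s` across task
types x constant/gamma baseline x social/homogeneous ("group") network —
64 models for two ILVs and five tasks — compared by Akaike weights.
Profile likelihood gives CIs on `s`, and the percentage of non-innovator
acquisitions attributable to social transmission (%ST) is the mean social
share `s T / (s T + asocial)` over events. The long-term-memory stage
models interact-to-solve latency with a gamma GLMM (log link, individual
random intercept, ML fit) under exhaustive AIC subset selection with the
nesting rule.

## Worked example

```python
from otternbda import (StudyConfig, simulate_study, TadaModel, TadaModelSpec,
                       FitOptions, social_differentiation)

study = simulate_study(StudyConfig(seed=11, s_interact=5.0))
print(round(social_differentiation(study.networks[("A", 1)]), 3))

data = study.diffusion_set("interact", 1)       # 15 diffusions, 3 groups
spec = TadaModelSpec("multiplicative", "gamma", network_kind="social",
                     s_constraint="same", ilv_subset=("age",))
fit = TadaModel(data, spec).fit(FitOptions(starts=3, seed=0))
print(fit.summary())
print("s 95% CI:", fit.profile_ci("s"))
```

prints

```
0.364
TADA fit
  spec:      multiplicative/gamma/ilv=age/social/s-same
  loglik:    -814.9987
  k:         4
  AIC:       1637.9973
  converged: True (3/3 starts agree)
  parameters:
             s = 2.96928
         B:age = 0.171966
         shape = 2.38896
          rate = 0.0053419
s 95% CI: (1.5332353682365565, 5.725071329089147)
```

The social transmission rate estimate 2.97 (CI 1.53–5.73) covers the
generating truth `s = 5`; the age coefficient 0.17 reads as a
`exp(0.17) = 1.19x` acquisition-rate multiplier per year of age. A full
model competition and the latency stage run from the command line:

```bash
otternbda run-all --run-dir runs/demo --seed 1
```

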