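# springmatch

Simulation and analysis of **sensory force/position weighting** in a
virtual-spring force-matching task, modelled on the catch-trial paradigm used
to probe sensorimotor integration in Complex Regional Pain Syndrome (CRPS)
with fixed dystonia.

## The problem

When a hand loads a spring, the nervous system can estimate the exerted force
from two channels: force sense directly, and position sense mapped through
the spring's stiffness `K` (`F = K·x`). Maximum-likelihood cue fusion says
the channels should be weighted by their reliability after putting them in
common units:

```
w_f = (1/σ_f²) / (1/σ_f² + 1/(K²σ_x²)),     w_p = 1 − w_f
```

where `σ_f` (N) is force-sense noise and `σ_x` (m) position-sense noise.
Position dominates on soft springs, force on stiff ones, and the weights
cross at `K = σ_f/σ_x`. The hypothesis under study is that patients with
CRPS-related dystonia, whose force feedback is thought unreliable, weight
position more heavily and fail to shift weights with stiffness.

The paradigm makes the weights measurable. Subjects train to produce a 10 N
target on a linear spring, then reproduce it blind. Occasionally the spring
is covertly swapped at the zero-length position for a *catch* spring that
exerts 1 N more at the position where the linear spring would reach the
target. A pure force-weighter reproduces the trained force (ΔF = catch −
blind force = 0 N); a pure position-weighter reproduces the trained position
(ΔF = 1 N). In between, ΔF scaled by the catch/linear force gap at the blind
position gives the position weight, and the blind-minus-catch position
difference scaled by the position gap at the blind force gives the force
weight.

`springmatch` provides:

* exact spring laws and their inverses (`springmatch.springs`),
* a Bayesian/MLE observer producing trials as quasi-static equilibria
  (`springmatch.observer`),
* a synthetic-cohort generator with the full trial protocol — 15 training
  trials per block, reference/blind alternation, exactly 12 catch trials per
  block, sensor-accuracy blocks at infinite and zero stiffness
  (`springmatch.cohort`),
* the analysis pipeline — 5 N exclusion rule, condition averaging, ΔF,
  weight scaling, σ̂_f/σ̂_x recovery, seeded permutation tests
  (`springmatch.extraction`),
* a CLI for reproducible end-to-end runs (`springmatch.cli`).

## Worked example

```sh
cat > cohort.yaml <<'YAML'
n_per_group: 10
stiffness_list: [30, 100, 300, 1000]
YAML
springmatch --quiet simulate --config cohort.yaml --seed 7 --out demo
springmatch --quiet extract demo/trials.csv --seed 7 --out demo
springmatch report demo/summary.json
```

prints (abridged):

```
Catch - blind force difference ΔF:
  control  K=   30 N/m: 1.355 ± 0.056 N
  control  K=  100 N/m: 0.968 ± 0.128 N
  control  K=  300 N/m: 0.478 ± 0.234 N
  control  K= 1000 N/m: 0.126 ± 0.134 N
  patient  K=   30 N/m: 1.669 ± 0.123 N
  patient  K=  100 N/m: 1.601 ± 0.192 N
  patient  K=  300 N/m: 1.356 ± 0.247 N
  patient  K= 1000 N/m: 1.687 ± 1.041 N

Force-weight slope per decade of stiffness:
  control  +0.567
  patient  +0.198

Sensor accuracy (group means):
  control  sigma_f 2.08 N, sigma_x 9.2 mm, ratio 279 N/m
  patient  sigma_f 2.81 N, sigma_x 12.6 mm, ratio 253 N/m

Group comparison (two-sided permutation p):
  K=   30 N/m: ΔF p=0.0353, w_f p=0.0715
  K=  100 N/m: ΔF p=0.0097, w_f p=0.4746
  ...
```

Reading it: control ΔF falls from 1.36 N to 0.13 N as stiffness grows — the
signature of re-weighting toward force feedback on stiff springs — while
simulated patients (stiffness-independent force weight 0.25, larger blind
overshoot) keep ΔF high at every stiffness; the permutation tests pick up the
group difference in ΔF at most stiffnesses even at n = 10 per group. The
sensor-accuracy block recovers each subject's generating `σ_f` and `σ_x`;
their ratio (~200–300 N/m) marks the stiffness where both cues are equally
reliable.

`simulate` also writes `config_resolved.json` with every default made
explicit; `extract` writes tidy `weights.csv` and `accuracy.csv` tables
alongside `summary.json`.

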