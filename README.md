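# crowdmix

Mixture-model analysis of orientation-report errors in visual crowding.

In a continuous-report crowding experiment, an observer estimates the
orientation of a peripheral target that is either shown alone or surrounded
by four flankers arranged at the corners of an imaginary rectangle. The
flankers carry their own ("local") orientations, and jointly form a global
configuration — an illusory Kanizsa-style rectangle when aligned — with its
own orientation. The question the analysis answers: when crowded observers
err, do they guess, report a flanker's orientation, or report the orientation
of the global configuration?

`crowdmix` is aimed at psychophysicists analysing such trial-level data. It
implements:

- **Three nested response models** on the 180°-periodic orientation circle
  (angle-doubled von Mises components, shared SD σ):
  - *Standard mixture*: `p(θ̂) = (1−γ)·φ_σ(θ̂−θ) + γ/180`
  - *Local*: adds flanker misreports,
    `+ β_loc·(1/m)·Σᵢ φ_σ(θ̂−φᵢ_loc)`, m = 4
  - *Global–Local*: further adds `+ β_glo·φ_σ(θ̂−φ_glo)`
  with guessing rate γ, local/global misreport rates β, and target-report
  rate `P_T = 1 − γ − β_loc − β_glo`.
- **Multi-start maximum-likelihood fitting** (20 Latin-hypercube starts,
  L-BFGS-B on softmax-transformed weights, boundary snapping, seeded and
  bit-reproducible) with **AICc model comparison** per observer × condition.
- A **perpendicular control**: refitting with the global component moved to
  the +90° orientation, whose rate should degenerate to ~0.
- A **group-level pipeline**: mean error and precision (1/SD of wrapped
  errors), repeated-measures ANOVAs with Greenhouse–Geisser correction and
  Bonferroni pairwise comparisons, paired *t* / Cohen's *d* on AICc, and
  one-sample tests of the misreport rates.
- A **synthetic-experiment generator** (27 observers × 3 conditions × 200
  trials by default, with between-observer parameter jitter and a
  ground-truth ledger) so every stage is testable end-to-end.

## Worked example

`python examples/fit_one_observer.py` simulates 200 flankers-aligned trials
from the Global–Local model (γ=0.10, σ=8°, β_loc=0.15, β_glo=0.08) and fits
all three models:

```
    standard: loglik=  -869.18  AICc= 1742.43  gamma=0.288 sigma= 7.70 beta_loc=0.000 beta_glo=0.000
       local: loglik=  -854.83  AICc= 1715.79  gamma=0.122 sigma= 8.01 beta_loc=0.161 beta_glo=0.000
global_local: loglik=  -853.41  AICc= 1715.03  gamma=0.094 sigma= 8.01 beta_loc=0.165 beta_glo=0.024

winner: global_local
dAICc GL - Standard: -27.39 (negative favors Global-Local)
dAICc GL - Local:    -0.76
```

Reading the numbers: the Standard fit must absorb all misreports into its
guess rate (γ=0.29); the Local fit recovers the flanker-swap rate
(β_loc≈0.16) and halves γ; the Global–Local fit adds the global component
and wins the AICc comparison despite its extra parameter. Single-observer
estimates scatter around the generating values — group means converge much
more tightly (see `examples/group_analysis.py`, which also prints the
GG-corrected precision ANOVA and the perpendicular-control rates).

Other entry points: `examples/simulate_dataset.py` writes a full synthetic
experiment + ground-truth ledger, and a thin CLI covers batch use:

```bash
crowdmix simulate --seed 1 --out data/
crowdmix fit      --trials data/trials.csv --models standard,local --out fits/
crowdmix analyze  --trials data/trials.csv --out report/
```

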