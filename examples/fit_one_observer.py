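"""Fit the three nested mixture models to one observer's crowded trials.

Simulates 200 flankers-aligned trials from the Global-Local model, fits
Standard / Local / Global-Local by multi-start MLE and compares them by
AICc.  The fitted rates should sit near the generating values and the
Global-Local model should win the AICc comparison (negative deltas mean
the Global-Local fit is better).
"""

import numpy as np

from crowdmix import Condition, Model, ModelParams, compare_models, fit_mle
from crowdmix.simulate import DesignConfig, gen_dataset

truth = ModelParams(gamma=0.10, sigma=8.0, beta_loc=0.15, beta_glo=0.08)
cfg = DesignConfig(n_observers=1, trials_per_condition=200,
                   conditions=(Condition.FA,), seed=7,
                   params_per_condition={Condition.FA: (Model.GLOBAL_LOCAL, truth)},
                   rate_jitter_sd=0.0, sigma_jitter=0.0)
trials, _ = gen_dataset(cfg)

fits = [fit_mle(m, trials, rng=np.random.default_rng([7, i]))
        for i, m in enumerate((Model.STANDARD, Model.LOCAL, Model.GLOBAL_LOCAL))]
for f in fits:
    p = f.params
    print(f"{f.model.value:>12}: loglik={f.loglik:9.2f}  AICc={f.aicc:8.2f}  "
          f"gamma={p.gamma:.3f} sigma={p.sigma:5.2f} "
          f"beta_loc={p.beta_loc:.3f} beta_glo={p.beta_glo:.3f}")

cmp = compare_models(fits)
print(f"\nwinner: {cmp['winner']}")
print(f"dAICc GL - Standard: {cmp['delta_gl_minus_standard']:+.2f} "
      "(negative favors Global-Local)")
print(f"dAICc GL - Local:    {cmp['delta_gl_minus_local']:+.2f}")
print(f"\ngenerating truth: gamma=0.10 sigma=8.0 beta_loc=0.15 beta_glo=0.08; "
      "single-observer estimates scatter around these values.")
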