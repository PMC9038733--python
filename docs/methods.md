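# Methods

## The orientation circle and the σ ↔ κ convention

Orientations are 180°-periodic: all arithmetic runs through the standard
angle-doubling device, mapping the orientation circle onto the ordinary
circle by `x → 2x`. The von Mises density on the orientation scale is

    f(x) = exp(κ·cos(2x·π/180)) / (180·I₀(κ)),

which integrates to 1 over any 180° window. The spread parameter σ is
expressed in degrees of orientation and tied to κ through the circular SD of
the doubled-angle distribution: κ solves

    (180/π)·sqrt(−2·ln(I₁(κ)/I₀(κ))) = 2σ,

inverted numerically (Brent, |residual| < 1e−12). Consequences worth
knowing: σ is directly comparable to the SD of concentrated report errors in
degrees; the map is strictly decreasing; and σ = 90° corresponds to
κ ≈ 0.0144, not exactly 0 — the exactly-uniform density is a limit
(`kappa_to_sd(0)` returns 90 by convention). Report errors are wrapped into
(−90, 90] with the boundary assigned to +90, so every error has a unique
representative.

Mean error is the *arithmetic* mean of wrapped errors (the conventional
report when errors concentrate near 0); a circular-mean variant
(`circular_mean_error`) is provided but not the default. Precision defaults
to 1/SD of wrapped errors in 1/degrees, with `kind="inverse_variance"` as a
config switch — the two definitions appear interchangeably in the
literature, and 1/SD is the one used for the group ANOVA here.

## The mixture models

All components share one σ. The guess component is the continuous uniform
1/180 in the likelihood; the generative counterpart draws guesses from the
180 discrete wheel values, matching a real response apparatus. The flanker
term keeps m = 4 with weight 1/m even though the four flankers carry only
two unique orientations (diagonal pairs); this is algebraically identical to
weighting the two unique values by 1/2 and is asserted by test. Local and
Global–Local evaluation on uncrowded trials is an error, never a silent
fallback. The perpendicular control is a separate 4-parameter fit with the
global component at +90° of the configuration's orientation — not a
5-component model — so a near-zero fitted rate is the expected, meaningful
outcome on data whose global misreports follow the true orientation.

## Fitting

Per observer × condition, maximum likelihood with box/simplex constraints:
γ, β ≥ 0, γ + β_loc + β_glo ≤ 1, σ ∈ [0.5°, 90°]. The σ lower bound avoids
near-singular densities; values below half a degree are psychophysically
meaningless for this task. The simplex is handled by optimising softmax
logits of (P_T, γ, β_loc, β_glo) (target logit pinned at 0) and a scaled
logistic for σ; L-BFGS-B runs from 20 Latin-hypercube starts (rates in
[0.01, 0.56], σ in [1°, 45°], rescaled if the weight sum exceeds 0.9). The
best finishing point wins; ties within 1e−6 log-likelihood break toward the
lower start index, and a final polish at tight tolerances follows. Because
softmax reaches a zero rate only asymptotically, rates below 1e−3 are
snapped to exactly 0 when that attains a higher likelihood — without this, a
nested model can numerically out-fit a richer one by ~1e−6 when the richer
model's extra rate has its MLE on the boundary. Estimates are MLE point
fits; no Bayesian posterior, bootstrap CI or likelihood-ratio machinery is
provided. Fits are bit-reproducible for a given seed.

AICc uses the per-cell trial count: `−2lnL + 2k + 2k(k+1)/(n−k−1)` with
k = 2/3/4 for Standard/Local/Global–Local (and 4 for the perpendicular
control). ΔAICc is reported as AICc(Global–Local) minus each rival, so
negative values favour the Global–Local model.

## Group statistics

One-way repeated-measures ANOVAs (display condition as the within factor)
are computed via pingouin; partial η² is derived from the SS table
(SS_effect/(SS_effect+SS_error), exact for this one-way design). Mauchly's
test at α = 0.05 (configurable) triggers the Greenhouse–Geisser correction;
both corrected and uncorrected dfs/p are always reported because corrected
dfs are non-integer and rounding conventions differ across packages.
Pairwise comparisons are Bonferroni-corrected paired t tests. Misreport
rates get one-sample t tests against 0 (Cohen's d = mean/SD) and paired
FA-vs-FM contrasts. The pipeline designates the analysis model per
condition — Standard for uncrowded, Global–Local for the crowded displays —
regardless of per-observer AICc winners, which are reported alongside.

## The synthetic experiment

The generator emulates the experimental design: 27 observers, 200 trials
per condition per observer, targets and flankers drawn uniformly from the
180 integer orientations 1°–180°, flankers rotated in diagonal pairs with
two distinct values, and a global orientation drawn independently of both.
Default generating parameters: uncrowded — Standard(γ=0.05, σ=4°); flankers
aligned — Global–Local(γ=0.10, σ=8°, β_loc=0.15, β_glo=0.08); flankers
misaligned — the same with β_loc=0.22, capturing the qualitative pattern the
models are built to detect (more flanker swaps when misaligned, equal global
rate, uncrowded reports precise with few guesses). Between-observer
heterogeneity: each rate jittered by a truncated normal (SD 0.03, resampled
until weights stay valid), σ jittered uniformly ±2°; every observer's true
parameters are recorded in a ledger for recovery checks.

What the generator does *not* emulate — and hence what passing tests cannot
show about real data: geometric rendering of stimuli (the global
orientation is not derived from flanker positions), eccentricity and
hemifield effects, sequential dependencies, motor noise beyond σ, lapses in
fixation, or any systematic relation between flanker and global
orientations. Tests demonstrate that the estimator and pipeline are correct
and well-calibrated under the models' own assumptions, not that those
assumptions hold for human observers. Note one consequence of the mixture:
with uniform guesses at rate γ, raw error variance is
`(1−γ)·σ² + γ·180²/12 + …`, so descriptive precision is far below 1/σ even
for small γ (e.g. γ=0.05, σ=4 gives 1/SD ≈ 0.082, not 0.25).

## Problem sizes and numerical choices

The test suite and acceptance script run everything at the design's native
scale (27 × 200 per condition) except where replication multiplies cost:
estimator-consistency checks use 12 replicates per sample size
(n ∈ {200, 1000, 5000}) and the ANOVA size simulation uses 1000 null runs —
sizes chosen to make the checked quantities stable. Orientation storage in
CSV uses 1–180 (0 is written as 180); internal canonical form is [0, 180).
Degenerate inputs (zero-variance differences, < 3 pairs, < 20 trials per
cell, incomplete ANOVA cases) raise with explicit messages rather than
returning NaNs; observers with undersized cells are excluded with a logged
warning.

## Known limitations

- A single shared σ across target/flanker/global components, by design;
  per-component precision and variable-precision models are out of scope.
- No spatial weighting of flankers (all four enter with equal weight 1/4).
- The generator's FA/FM difference is a β_loc shift only; real
  condition differences may also involve σ or γ.
- External datasets must be adapted to the trial-table schema by hand
  (`crowdmix.io.convert_external_stub` documents the mapping).
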