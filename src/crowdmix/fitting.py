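"""Maximum-likelihood fitting and AICc model comparison.

Each observer x condition is fitted independently.  The mixture weights
(P_T, gamma, beta_loc, beta_glo) are optimised through a softmax
reparameterisation (the target weight's logit fixed at 0), which turns the
simplex constraint into an unconstrained problem; sigma is mapped into
[SIGMA_LO, SIGMA_HI] by a scaled logistic.  L-BFGS-B is run from R
Latin-hypercube starting points and the best finishing point is kept
(ties within 1e-6 log-likelihood broken by lower start index), which makes
fits reproducible for a given seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.stats import qmc

from .models import Model, ModelParams, TrialArrays, _loglik_arrays

__all__ = ["FitConfig", "FitResult", "aicc", "fit_mle", "compare_models",
           "target_report_rate"]

#: sigma bounds in degrees: the lower bound avoids the near-singular
#: densities of a sub-degree von Mises; above 90° the density is flat.
SIGMA_LO = 0.5
SIGMA_HI = 90.0

MIN_TRIALS = 20


@dataclass(frozen=True)
class FitConfig:
    """Optimiser settings for :func:`fit_mle`."""

    n_restarts: int = 20
    maxiter: int = 500
    tol: float = 1e-10
    loglik_tie_tol: float = 1e-6


@dataclass(frozen=True)
class FitResult:
    """MLE fit of one model to one observer x condition trial set."""

    model: Model
    params: ModelParams
    loglik: float
    n_trials: int
    k_params: int
    aicc: float
    n_restarts: int
    converged: bool
    best_start_index: int

    def as_dict(self) -> dict:
        return {
            "model": self.model.value,
            "estimator": "MLE",
            "params": self.params.as_dict(),
            "p_target": self.params.p_target,
            "loglik": self.loglik,
            "n_trials": self.n_trials,
            "k_params": self.k_params,
            "aicc": self.aicc,
            "n_restarts": self.n_restarts,
            "converged": self.converged,
            "best_start_index": self.best_start_index,
        }


def aicc(loglik: float, k: int, n: int) -> float:
    """Akaike information criterion with small-sample correction:
    ``-2 lnL + 2k + 2k(k+1)/(n - k - 1)``."""
    if n <= k + 1:
        raise ValueError(f"AICc requires n > k + 1 (n={n}, k={k})")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def target_report_rate(params: ModelParams) -> float:
    """P_T = 1 - gamma - beta_loc - beta_glo (betas are 0 where absent)."""
    return params.p_target


# ---------------------------------------------------------------------------
# parameter transforms

def _n_rates(model: Model) -> int:
    return {Model.STANDARD: 1, Model.LOCAL: 2,
            Model.GLOBAL_LOCAL: 3, Model.GLOBAL_PERP: 3}[model]


def _theta_to_params(theta: np.ndarray, model: Model) -> ModelParams:
    """Unconstrained vector -> ModelParams (softmax weights, logistic sigma)."""
    nr = _n_rates(model)
    logits = np.concatenate([[0.0], theta[:nr]])
    logits = logits - logits.max()
    w = np.exp(logits)
    w = w / w.sum()
    t = float(theta[nr])
    if t >= 0:  # overflow-safe logistic
        z = 1.0 / (1.0 + math.exp(-t))
    else:
        e = math.exp(t)
        z = e / (1.0 + e)
    z = min(max(z, 1e-12), 1 - 1e-12)
    sigma = SIGMA_LO + (SIGMA_HI - SIGMA_LO) * z
    rates = w[1:]
    kwargs = {"gamma": float(rates[0]), "sigma": float(sigma)}
    if nr >= 2:
        kwargs["beta_loc"] = float(rates[1])
    if nr >= 3:
        kwargs["beta_glo"] = float(rates[2])
    return ModelParams(**kwargs)


def _params_to_theta(params: ModelParams, model: Model) -> np.ndarray:
    nr = _n_rates(model)
    eps = 1e-6
    w = np.array([params.p_target, params.gamma, params.beta_loc,
                  params.beta_glo][: nr + 1])
    w = np.clip(w, eps, None)
    w = w / w.sum()
    logits = np.log(w) - np.log(w[0])
    z = (params.sigma - SIGMA_LO) / (SIGMA_HI - SIGMA_LO)
    z = min(max(z, eps), 1 - eps)
    return np.concatenate([logits[1:], [math.log(z / (1 - z))]])


def _lhs_starts(model: Model, n_starts: int, rng: np.random.Generator) -> list:
    """Latin-hypercube starting points over a plausible parameter region."""
    nr = _n_rates(model)
    sampler = qmc.LatinHypercube(d=nr + 1, seed=rng)
    u = sampler.random(n_starts)
    starts = []
    for row in u:
        rates = 0.01 + 0.55 * row[:nr]
        total = rates.sum()
        if total > 0.9:
            rates = rates * (0.9 / total)
        sigma = 1.0 + 44.0 * row[nr]
        kwargs = {"gamma": float(rates[0]), "sigma": float(sigma)}
        if nr >= 2:
            kwargs["beta_loc"] = float(rates[1])
        if nr >= 3:
            kwargs["beta_glo"] = float(rates[2])
        starts.append(_params_to_theta(ModelParams(**kwargs), model))
    return starts


# ---------------------------------------------------------------------------

def fit_mle(model: Model, trials, config: Optional[FitConfig] = None,
            rng: Optional[np.random.Generator] = None) -> FitResult:
    """Fit `model` to a trial set by multi-start maximum likelihood.

    `trials` is a sequence of TrialRecord (or a prebuilt TrialArrays); all
    trials must be valid for the model.  Reproducible for a given `rng` seed.
    """
    model = Model(model)
    config = config or FitConfig()
    rng = rng if rng is not None else np.random.default_rng(0)
    arrays = trials if isinstance(trials, TrialArrays) else TrialArrays.from_trials(trials)
    if arrays.n < MIN_TRIALS:
        raise ValueError(f"need at least {MIN_TRIALS} trials, got {arrays.n}")
    if model is not Model.STANDARD and arrays.flankers is None:
        raise ValueError(f"{model.value} model requires crowded trials")

    def nll(theta):
        ll = _loglik_arrays(model, _theta_to_params(theta, model), arrays)
        return -ll if np.isfinite(ll) else 1e12

    best = None  # (loglik, start_index, theta, success)
    for i, theta0 in enumerate(_lhs_starts(model, config.n_restarts, rng)):
        res = minimize(nll, theta0, method="L-BFGS-B", tol=config.tol,
                       options={"maxiter": config.maxiter})
        ll = -res.fun
        if best is None or ll > best[0] + config.loglik_tie_tol:
            best = (ll, i, res.x, bool(res.success))
    if best is None or not np.isfinite(best[0]):
        raise RuntimeError(f"all {config.n_restarts} starts failed for model {model.value}")

    ll, idx, theta, success = best
    # polish the winning start at tight tolerances so nested models can
    # never out-fit a richer one by a residual optimizer gap
    res = minimize(nll, theta, method="L-BFGS-B",
                   options={"maxiter": 2 * config.maxiter,
                            "ftol": 1e-14, "gtol": 1e-9})
    if -res.fun >= ll:
        ll, theta, success = -res.fun, res.x, bool(res.success) or success
    params = _theta_to_params(theta, model)
    # the softmax transform reaches rate = 0 only asymptotically; snap
    # near-zero rates onto the boundary when that attains a higher
    # likelihood (the boundary MLE of a nested-model-truth dataset)
    snapped = {n: (0.0 if 0.0 < v < 1e-3 else v)
               for n, v in params.as_dict().items() if n != "sigma"}
    if any(snapped[n] != getattr(params, n) for n in snapped):
        cand = ModelParams(sigma=params.sigma, **snapped)
        ll_cand = _loglik_arrays(model, cand, arrays)
        if ll_cand >= ll:
            ll, params = ll_cand, cand
    k = model.k_params
    return FitResult(
        model=model, params=params, loglik=float(ll), n_trials=arrays.n,
        k_params=k, aicc=aicc(ll, k, arrays.n), n_restarts=config.n_restarts,
        converged=success, best_start_index=idx,
    )


def compare_models(fits: Sequence[FitResult]) -> Dict[str, object]:
    """AICc comparison of a set of fits on the same trial set.

    Returns the winning model (minimum AICc) and, when the Global-Local fit
    is present together with the Standard and/or Local fits, the signed
    differences AICc(GL) - AICc(Standard) and AICc(GL) - AICc(Local)
    (negative values favor the Global-Local model).
    """
    if not fits:
        raise ValueError("no fits to compare")
    ns = {f.n_trials for f in fits}
    if len(ns) != 1:
        raise ValueError(f"fits computed on different trial sets (n = {sorted(ns)})")
    by_model = {f.model: f for f in fits}
    if len(by_model) != len(fits):
        raise ValueError("duplicate model in comparison")
    aiccs = {m.value: f.aicc for m, f in by_model.items()}
    best_aicc = min(aiccs.values())
    winners = sorted(m for m, a in aiccs.items() if abs(a - best_aicc) < 1e-9)
    out: Dict[str, object] = {
        "aicc": aiccs,
        "winner": winners[0],
        "tie": len(winners) > 1,
    }
    gl = by_model.get(Model.GLOBAL_LOCAL)
    if gl is not None:
        if Model.STANDARD in by_model:
            out["delta_gl_minus_standard"] = gl.aicc - by_model[Model.STANDARD].aicc
        if Model.LOCAL in by_model:
            out["delta_gl_minus_local"] = gl.aicc - by_model[Model.LOCAL].aicc
    return out
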