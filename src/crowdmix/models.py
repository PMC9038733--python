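"""Probabilistic mixture models of continuous orientation reports.

Three nested models describe the distribution of the reported orientation
``theta_hat`` given a display:

* Standard mixture — target von Mises + uniform guessing:
  ``(1-g) * vm(theta_hat - theta) + g/180``
* Local — adds misreports of any of the m = 4 flanker orientations, each
  with weight ``b_loc / m``.
* Global–Local — further adds misreports of the orientation of the global
  configuration formed by the flankers, with weight ``b_glo``.

All components share one von Mises SD ``sigma``.  A perpendicular-control
variant replaces the global orientation by its +90° perpendicular; fitted to
data generated (or collected) under the true global orientation, its global
rate should degenerate to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.special import i0e

from .circular import sd_to_kappa, vm_pdf_180, wrap_orientation, wrap180

__all__ = [
    "Condition",
    "Model",
    "ModelParams",
    "TrialRecord",
    "N_FLANKERS",
    "pdf_standard",
    "pdf_local",
    "pdf_global_local",
    "pdf_global_perpendicular",
    "log_likelihood",
    "sample_response",
]

#: number of non-target items in the display (four flankers, in two
#: diagonally-paired orientations)
N_FLANKERS = 4


class Condition(str, Enum):
    """Display condition: uncrowded, flankers aligned, flankers misaligned."""

    U = "U"
    FA = "FA"
    FM = "FM"


class Model(str, Enum):
    STANDARD = "standard"
    LOCAL = "local"
    GLOBAL_LOCAL = "global_local"
    GLOBAL_PERP = "global_perp"

    @property
    def k_params(self) -> int:
        """Number of free parameters of the model."""
        return {
            Model.STANDARD: 2,
            Model.LOCAL: 3,
            Model.GLOBAL_LOCAL: 4,
            Model.GLOBAL_PERP: 4,
        }[self]


@dataclass(frozen=True)
class ModelParams:
    """Mixture parameters: guessing rate, von Mises SD, misreport rates.

    ``beta_loc``/``beta_glo`` are only meaningful for the models that have
    the corresponding component and must be 0 otherwise.  The implied
    target-report rate is ``1 - gamma - beta_loc - beta_glo``.
    """

    gamma: float
    sigma: float
    beta_loc: float = 0.0
    beta_glo: float = 0.0

    def __post_init__(self):
        for name in ("gamma", "beta_loc", "beta_glo"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.gamma + self.beta_loc + self.beta_glo > 1.0 + 1e-12:
            raise ValueError("gamma + beta_loc + beta_glo must be <= 1")
        if not (0.0 < self.sigma <= 90.0):
            raise ValueError(f"sigma must be in (0, 90], got {self.sigma}")

    @property
    def p_target(self) -> float:
        """Target-report rate P_T = 1 - gamma - beta_loc - beta_glo."""
        return max(0.0, 1.0 - self.gamma - self.beta_loc - self.beta_glo)

    def as_dict(self) -> dict:
        return {
            "gamma": self.gamma,
            "sigma": self.sigma,
            "beta_loc": self.beta_loc,
            "beta_glo": self.beta_glo,
        }


@dataclass(frozen=True)
class TrialRecord:
    """One behavioral trial of the orientation continuous-report task."""

    observer: str
    condition: Condition
    target: float
    flankers: Optional[Tuple[float, float, float, float]] = None
    global_ori: Optional[float] = None
    response: Optional[float] = None
    #: hidden ground truth of the generating mixture component
    #: ("target" | "guess" | "local" | "global"), None for real data
    component: Optional[str] = field(default=None, compare=False)

    def __post_init__(self):
        object.__setattr__(self, "condition", Condition(self.condition))
        object.__setattr__(self, "target", wrap_orientation(self.target))
        if self.response is not None:
            object.__setattr__(self, "response", wrap_orientation(self.response))
        if self.condition is Condition.U:
            if self.flankers is not None or self.global_ori is not None:
                raise ValueError("uncrowded trials carry no flankers/global orientation")
        else:
            if self.flankers is None or self.global_ori is None:
                raise ValueError(f"{self.condition.value} trials require flankers and global_ori")
            fl = tuple(wrap_orientation(f) for f in self.flankers)
            if len(fl) != N_FLANKERS:
                raise ValueError("exactly four flanker orientations required")
            if fl[0] != fl[2] or fl[1] != fl[3]:
                raise ValueError(
                    "flankers must be rotated in diagonal pairs "
                    "(flankers[0]==flankers[2], flankers[1]==flankers[3])"
                )
            object.__setattr__(self, "flankers", fl)
            object.__setattr__(self, "global_ori", wrap_orientation(self.global_ori))

    def with_response(self, response: float, component: Optional[str] = None) -> "TrialRecord":
        return replace(self, response=wrap_orientation(response), component=component)


# ---------------------------------------------------------------------------
# densities

def _require(cond: bool, msg: str):
    if not cond:
        raise ValueError(msg)


def pdf_standard(response, target, params: ModelParams):
    """Standard-mixture density of a response given the target orientation."""
    _require(params.beta_loc == 0.0 and params.beta_glo == 0.0,
             "Standard model has no misreport components")
    err = wrap180(np.asarray(response, dtype=float) - target)
    return (1.0 - params.gamma) * vm_pdf_180(err, params.sigma) + params.gamma / 180.0


def _flanker_term(response, trial: TrialRecord, params: ModelParams):
    resp = np.asarray(response, dtype=float)
    s = 0.0
    for phi in trial.flankers:
        s = s + vm_pdf_180(wrap180(resp - phi), params.sigma)
    return params.beta_loc * s / N_FLANKERS


def pdf_local(response, trial: TrialRecord, params: ModelParams):
    """Local-model density: adds flanker-misreport components to the standard mixture."""
    _require(trial.condition is not Condition.U, "Local model undefined for uncrowded trials")
    _require(params.beta_glo == 0.0, "Local model has no global component")
    resp = np.asarray(response, dtype=float)
    w_t = 1.0 - params.gamma - params.beta_loc
    out = (
        w_t * vm_pdf_180(wrap180(resp - trial.target), params.sigma)
        + params.gamma / 180.0
        + _flanker_term(resp, trial, params)
    )
    return out if np.ndim(out) else float(out)


def _pdf_global(response, trial: TrialRecord, params: ModelParams, global_shift: float):
    _require(trial.condition is not Condition.U,
             "Global–Local model undefined for uncrowded trials")
    resp = np.asarray(response, dtype=float)
    w_t = 1.0 - params.gamma - params.beta_loc - params.beta_glo
    glo = wrap_orientation(trial.global_ori + global_shift)
    out = (
        w_t * vm_pdf_180(wrap180(resp - trial.target), params.sigma)
        + params.gamma / 180.0
        + _flanker_term(resp, trial, params)
        + params.beta_glo * vm_pdf_180(wrap180(resp - glo), params.sigma)
    )
    return out if np.ndim(out) else float(out)


def pdf_global_local(response, trial: TrialRecord, params: ModelParams):
    """Global–Local density: target, guess, flanker and global-configuration components."""
    return _pdf_global(response, trial, params, 0.0)


def pdf_global_perpendicular(response, trial: TrialRecord, params: ModelParams):
    """Control variant: the global component sits at the +90° perpendicular
    of the configuration's orientation — the most distant orientation, so its
    fitted rate should be ~0 on data whose misreports follow the true global."""
    return _pdf_global(response, trial, params, 90.0)


def pdf_for(model: Model, response, trial: TrialRecord, params: ModelParams):
    """Dispatch a trial's density under `model`."""
    if model is Model.STANDARD:
        return pdf_standard(response, trial.target, params)
    if model is Model.LOCAL:
        return pdf_local(response, trial, params)
    if model is Model.GLOBAL_LOCAL:
        return pdf_global_local(response, trial, params)
    if model is Model.GLOBAL_PERP:
        return pdf_global_perpendicular(response, trial, params)
    raise ValueError(f"unknown model {model!r}")


# ---------------------------------------------------------------------------
# vectorised likelihood over a trial set

@dataclass(frozen=True)
class TrialArrays:
    """Column-wise view of a trial list for fast likelihood evaluation."""

    response: np.ndarray
    target: np.ndarray
    flankers: Optional[np.ndarray]  # (n, 4)
    global_ori: Optional[np.ndarray]

    @classmethod
    def from_trials(cls, trials: Sequence[TrialRecord]) -> "TrialArrays":
        if not trials:
            raise ValueError("empty trial list")
        if any(t.response is None for t in trials):
            raise ValueError("all trials must carry a response")
        crowded = trials[0].condition is not Condition.U
        if any((t.condition is not Condition.U) != crowded for t in trials):
            raise ValueError("trial set mixes uncrowded and crowded conditions")
        resp = np.array([t.response for t in trials])
        targ = np.array([t.target for t in trials])
        if crowded:
            fl = np.array([t.flankers for t in trials])
            glo = np.array([t.global_ori for t in trials])
        else:
            fl = glo = None
        return cls(resp, targ, fl, glo)

    @property
    def n(self) -> int:
        return self.response.size


def _loglik_arrays(model: Model, params: ModelParams, arrays: TrialArrays) -> float:
    """Sum of per-trial log densities, vectorised; -inf if any density is 0."""
    kappa = sd_to_kappa(params.sigma)

    def vm(delta_deg):
        c = np.cos(np.deg2rad(2.0 * delta_deg))
        return np.exp(kappa * (c - 1.0)) / (180.0 * i0e(kappa))

    dens = params.p_target * vm(arrays.response - arrays.target) + params.gamma / 180.0
    if model is not Model.STANDARD:
        if arrays.flankers is None:
            raise ValueError(f"{model.value} model requires crowded trials")
        fl = vm(arrays.response[:, None] - arrays.flankers).mean(axis=1)
        dens = dens + params.beta_loc * fl
        if model in (Model.GLOBAL_LOCAL, Model.GLOBAL_PERP):
            shift = 90.0 if model is Model.GLOBAL_PERP else 0.0
            dens = dens + params.beta_glo * vm(arrays.response - arrays.global_ori - shift)
    elif params.beta_loc or params.beta_glo:
        raise ValueError("Standard model has no misreport components")
    if np.any(dens <= 0.0):
        return -np.inf
    return float(np.sum(np.log(dens)))


def log_likelihood(model: Model, params: ModelParams, trials) -> float:
    """Log-likelihood of `params` under `model` for a list of trials.

    Returns -inf (never raises) when some trial has zero density, which can
    only happen at gamma = 0 with a degenerate sigma.
    """
    model = Model(model)
    if model is not Model.STANDARD:
        if any(t.condition is Condition.U for t in trials):
            raise ValueError(f"{model.value} model cannot be evaluated on uncrowded trials")
    arrays = trials if isinstance(trials, TrialArrays) else TrialArrays.from_trials(trials)
    return _loglik_arrays(model, params, arrays)


# ---------------------------------------------------------------------------
# generative counterpart

def _sample_vm_orientation(mean_deg: float, sigma: float, rng: np.random.Generator) -> float:
    """Draw an orientation: von Mises around mean (angle doubling)."""
    kappa = sd_to_kappa(sigma)
    doubled = rng.vonmises(0.0, kappa)  # radians in (-pi, pi]
    return wrap_orientation(mean_deg + np.rad2deg(doubled) / 2.0)


def sample_response(trial: TrialRecord, model: Model, params: ModelParams,
                    rng: np.random.Generator) -> Tuple[float, str]:
    """Draw one response from the model's generative process.

    Picks a mixture component with probabilities (P_T, gamma, beta_loc,
    beta_glo); target/flanker/global components add von Mises noise around
    the respective orientation (the flanker component picks one of the four
    flankers uniformly); the guess component draws uniformly from the 180
    integer orientation values of the response wheel.

    Returns ``(response_deg, component_label)``.
    """
    model = Model(model)
    if model is not Model.STANDARD and trial.condition is Condition.U:
        raise ValueError(f"{model.value} model cannot generate uncrowded trials")
    weights = [params.p_target, params.gamma]
    labels = ["target", "guess"]
    if model is not Model.STANDARD:
        weights.append(params.beta_loc)
        labels.append("local")
        if model in (Model.GLOBAL_LOCAL, Model.GLOBAL_PERP):
            weights.append(params.beta_glo)
            labels.append("global")
    elif params.beta_loc or params.beta_glo:
        raise ValueError("Standard model has no misreport components")
    weights = np.asarray(weights)
    weights = weights / weights.sum()
    label = labels[rng.choice(len(labels), p=weights)]
    if label == "guess":
        return float(rng.integers(1, 181) % 180), label
    if label == "target":
        mean = trial.target
    elif label == "local":
        mean = trial.flankers[rng.integers(0, N_FLANKERS)]
    else:  # global
        shift = 90.0 if model is Model.GLOBAL_PERP else 0.0
        mean = wrap_orientation(trial.global_ori + shift)
    return _sample_vm_orientation(mean, params.sigma, rng), label
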