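"""Synthetic experiment generator.

Emulates the structure of the orientation continuous-report crowding
experiment: each observer completes 200 trials in each of three display
conditions (uncrowded U, flankers aligned FA, flankers misaligned FM).
Target and flanker orientations are drawn uniformly from the 180 integer
orientation values 1°..180°; the four flankers take two unique orientations
assigned to diagonal pairs; the global-configuration orientation is drawn
independently of both.  Responses are sampled from a chosen generative
mixture model, and each observer's true parameters (jittered around the
group values to create realistic between-observer variance) are kept in a
ground-truth ledger so that recovery can be measured end-to-end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .models import (Condition, Model, ModelParams, TrialRecord,
                     sample_response)

__all__ = ["DesignConfig", "default_params", "gen_design", "gen_responses",
           "gen_dataset", "GroundTruth"]

#: group-level generating parameters per condition.  U follows the Standard
#: mixture with the low guess rate / variability typical of uncrowded
#: reports; FA and FM follow the Global-Local model with a higher local
#: misreport rate when the flankers are misaligned and an equal global rate,
#: the qualitative pattern the models are meant to detect.
DEFAULT_PARAMS: Dict[Condition, Tuple[Model, ModelParams]] = {
    Condition.U: (Model.STANDARD, ModelParams(gamma=0.05, sigma=4.0)),
    Condition.FA: (Model.GLOBAL_LOCAL,
                   ModelParams(gamma=0.10, sigma=8.0, beta_loc=0.15, beta_glo=0.08)),
    Condition.FM: (Model.GLOBAL_LOCAL,
                   ModelParams(gamma=0.10, sigma=8.0, beta_loc=0.22, beta_glo=0.08)),
}


def default_params(condition: Condition) -> Tuple[Model, ModelParams]:
    """Generating model and group-level parameters for a display condition."""
    return DEFAULT_PARAMS[Condition(condition)]


@dataclass(frozen=True)
class DesignConfig:
    """Shape and generating parameters of a synthetic experiment."""

    n_observers: int = 27
    trials_per_condition: int = 200
    conditions: Tuple[Condition, ...] = (Condition.U, Condition.FA, Condition.FM)
    seed: int = 0
    #: per-condition (model, group params); defaults to DEFAULT_PARAMS
    params_per_condition: Optional[Dict[Condition, Tuple[Model, ModelParams]]] = None
    #: SD of the truncated-normal between-observer jitter on each rate
    rate_jitter_sd: float = 0.03
    #: half-width (degrees) of the uniform between-observer jitter on sigma
    sigma_jitter: float = 2.0

    def __post_init__(self):
        if self.n_observers < 1 or self.trials_per_condition < 1:
            raise ValueError("n_observers and trials_per_condition must be >= 1")
        object.__setattr__(self, "conditions",
                           tuple(Condition(c) for c in self.conditions))

    def condition_params(self, condition: Condition) -> Tuple[Model, ModelParams]:
        table = self.params_per_condition or DEFAULT_PARAMS
        return table[Condition(condition)]


@dataclass
class GroundTruth:
    """Ledger of every observer's true generating parameters."""

    seed: int
    params: Dict[str, Dict[str, dict]] = field(default_factory=dict)  # obs -> cond -> dict

    def record(self, observer: str, condition: Condition, model: Model,
               params: ModelParams):
        self.params.setdefault(observer, {})[condition.value] = {
            "model": model.value, **params.as_dict(), "p_target": params.p_target,
        }

    def group_mean(self, condition: Condition, name: str) -> float:
        vals = [obs[Condition(condition).value][name] for obs in self.params.values()]
        return float(np.mean(vals))

    def as_dict(self) -> dict:
        return {"seed": self.seed, "observers": self.params}


def _draw_orientation(rng: np.random.Generator) -> int:
    """One of the 180 integer orientation values, 1..180."""
    return int(rng.integers(1, 181))


def gen_design(config: DesignConfig, rng: np.random.Generator,
               observer: str = "obs01") -> List[TrialRecord]:
    """Generate the stimulus design (responses empty) for one observer.

    Targets and globals are independent uniform draws from {1..180}; the two
    unique flanker orientations are independent draws (re-drawn if equal)
    assigned to diagonal pairs [a, b, a, b].
    """
    trials: List[TrialRecord] = []
    for cond in config.conditions:
        for _ in range(config.trials_per_condition):
            target = _draw_orientation(rng)
            if cond is Condition.U:
                trials.append(TrialRecord(observer, cond, target))
                continue
            a = _draw_orientation(rng)
            b = _draw_orientation(rng)
            while b == a:
                b = _draw_orientation(rng)
            glo = _draw_orientation(rng)
            trials.append(TrialRecord(observer, cond, target,
                                      flankers=(a, b, a, b), global_ori=glo))
    return trials


def gen_responses(design: List[TrialRecord], generating_model: Model,
                  params: ModelParams, rng: np.random.Generator) -> List[TrialRecord]:
    """Fill in responses for a (single-condition or mixed) design.

    Crowded trials are sampled from `generating_model`; uncrowded trials are
    always sampled from the Standard mixture restricted to (gamma, sigma).
    The generating component of every trial is retained as ground truth.
    """
    out = []
    for t in design:
        if t.condition is Condition.U:
            model = Model.STANDARD
            p = ModelParams(gamma=params.gamma, sigma=params.sigma)
        else:
            model, p = Model(generating_model), params
        resp, label = sample_response(t, model, p, rng)
        out.append(t.with_response(resp, component=label))
    return out


def _jitter_params(params: ModelParams, model: Model, config: DesignConfig,
                   rng: np.random.Generator) -> ModelParams:
    """Observer-level parameters: truncated-normal jitter on rates, uniform
    jitter on sigma; resampled until the mixture weights stay valid."""
    for _ in range(1000):
        g = rng.normal(params.gamma, config.rate_jitter_sd)
        bl = rng.normal(params.beta_loc, config.rate_jitter_sd) if params.beta_loc else 0.0
        bg = rng.normal(params.beta_glo, config.rate_jitter_sd) if params.beta_glo else 0.0
        s = params.sigma + rng.uniform(-config.sigma_jitter, config.sigma_jitter)
        if g < 0 or bl < 0 or bg < 0 or g + bl + bg > 0.95 or not (0.5 < s <= 90):
            continue
        return ModelParams(gamma=g, sigma=s, beta_loc=bl, beta_glo=bg)
    raise RuntimeError("could not draw valid jittered parameters")


def gen_dataset(config: DesignConfig) -> Tuple[List[TrialRecord], GroundTruth]:
    """Generate the full synthetic experiment.

    Returns all trial records (n_observers x len(conditions) x
    trials_per_condition rows) plus the ground-truth parameter ledger.
    Deterministic: the same config (including seed) yields the same dataset.
    """
    rng = np.random.default_rng(config.seed)
    truth = GroundTruth(seed=config.seed)
    all_trials: List[TrialRecord] = []
    width = max(2, len(str(config.n_observers)))
    for i in range(config.n_observers):
        observer = f"obs{i + 1:0{width}d}"
        design = gen_design(config, rng, observer=observer)
        by_cond: Dict[Condition, List[TrialRecord]] = {}
        for t in design:
            by_cond.setdefault(t.condition, []).append(t)
        for cond, trials in by_cond.items():
            model, group_params = config.condition_params(cond)
            obs_params = _jitter_params(group_params, model, config, rng)
            truth.record(observer, cond, model, obs_params)
            all_trials.extend(gen_responses(trials, model, obs_params, rng))
    return all_trials, truth
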