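"""Group-level analysis pipeline.

Reproduces the full analysis chain for a trial table, real or synthetic:

1. per observer x condition descriptive statistics (mean signed error,
   precision = 1/SD of errors);
2. per observer x condition maximum-likelihood fits of every applicable
   model (Standard only for uncrowded; Standard/Local/Global-Local, plus
   optionally the +90 degree perpendicular control, for crowded conditions)
   and AICc comparison;
3. group statistics: one-way repeated-measures ANOVAs with
   Greenhouse-Geisser correction when Mauchly's test rejects sphericity,
   Bonferroni-corrected pairwise comparisons, paired t tests with Cohen's d
   on AICc differences, and one-sample t tests of the misreport rates
   against zero.

The designated "best" model per condition follows the study logic rather
than per-observer AICc winners: the Standard mixture for the uncrowded
display and the Global-Local model for the crowded displays (per-observer
winners are reported alongside).
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

from .circular import mean_error, precision, signed_error
from .fitting import FitConfig, FitResult, compare_models, fit_mle
from .models import Condition, Model, ModelParams, TrialRecord

__all__ = ["ObserverSummary", "GroupResult", "summarize_observers",
           "rm_anova_gg", "paired_t_cohen", "misreport_tests", "run_pipeline"]

#: fewest trials per observer x condition for a fit to be attempted
MIN_TRIALS_PER_CELL = 20

#: study-designated analysis model per condition
BEST_MODEL = {Condition.U: Model.STANDARD,
              Condition.FA: Model.GLOBAL_LOCAL,
              Condition.FM: Model.GLOBAL_LOCAL}

MODELS_FOR_CONDITION = {
    Condition.U: (Model.STANDARD,),
    Condition.FA: (Model.STANDARD, Model.LOCAL, Model.GLOBAL_LOCAL),
    Condition.FM: (Model.STANDARD, Model.LOCAL, Model.GLOBAL_LOCAL),
}


@dataclass
class ObserverSummary:
    """Descriptives and fits for one observer."""

    observer: str
    mean_error: Dict[str, float] = field(default_factory=dict)
    precision: Dict[str, float] = field(default_factory=dict)
    fits: Dict[str, Dict[str, FitResult]] = field(default_factory=dict)  # cond -> model -> fit
    winner: Dict[str, str] = field(default_factory=dict)
    comparison: Dict[str, dict] = field(default_factory=dict)

    def best_fit(self, condition: Condition) -> FitResult:
        """The fit of the study-designated model for this condition."""
        return self.fits[Condition(condition).value][BEST_MODEL[Condition(condition)].value]


@dataclass
class GroupResult:
    """Outcome of one group-level test."""

    name: str
    statistic: float
    df: object
    p_value: float
    effect_size: Optional[float] = None
    effect_size_name: Optional[str] = None
    pairwise: Optional[pd.DataFrame] = None
    extra: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {"name": self.name, "statistic": self.statistic, "df": self.df,
             "p_value": self.p_value, "effect_size": self.effect_size,
             "effect_size_name": self.effect_size_name}
        d.update(self.extra)
        if self.pairwise is not None:
            d["pairwise"] = self.pairwise.to_dict(orient="records")
        return d


# ---------------------------------------------------------------------------

def summarize_observers(trials: Sequence[TrialRecord],
                        fit_config: Optional[FitConfig] = None,
                        seed: int = 0,
                        include_perp_control: bool = False,
                        log=None) -> List[ObserverSummary]:
    """Per-observer descriptive statistics and model fits.

    Observers contributing fewer than 20 trials to a condition have that
    cell skipped with a warning (via `log`, default print to stderr).
    """
    import sys

    def warn(msg):
        (log or (lambda m: print(m, file=sys.stderr)))(msg)

    cells: Dict[str, Dict[Condition, List[TrialRecord]]] = {}
    for t in trials:
        if t.response is None:
            raise ValueError("all trials must have responses")
        cells.setdefault(t.observer, {}).setdefault(t.condition, []).append(t)

    summaries = []
    for observer in sorted(cells):
        summary = ObserverSummary(observer=observer)
        for cond in sorted(cells[observer], key=lambda c: c.value):
            cell = cells[observer][cond]
            if len(cell) < MIN_TRIALS_PER_CELL:
                warn(f"observer {observer}, condition {cond.value}: only "
                     f"{len(cell)} trials (< {MIN_TRIALS_PER_CELL}); cell excluded")
                continue
            errors = signed_error(np.array([t.response for t in cell]),
                                  np.array([t.target for t in cell]))
            summary.mean_error[cond.value] = mean_error(errors)
            summary.precision[cond.value] = precision(errors)
            models = list(MODELS_FOR_CONDITION[cond])
            if include_perp_control and cond is not Condition.U:
                models.append(Model.GLOBAL_PERP)
            fits = {}
            for j, model in enumerate(models):
                rng = np.random.default_rng(
                    [seed, zlib.crc32(observer.encode()), ord(cond.value[0]), j])
                fits[model.value] = fit_mle(model, cell, fit_config, rng)
            summary.fits[cond.value] = fits
            comparable = [f for m, f in fits.items() if m != Model.GLOBAL_PERP.value]
            cmp = compare_models(comparable)
            summary.comparison[cond.value] = cmp
            summary.winner[cond.value] = cmp["winner"]
        summaries.append(summary)
    return summaries


def rm_anova_gg(values: np.ndarray, labels: Sequence[str],
                name: str = "rm_anova", alpha_sphericity: float = 0.05,
                n_decimals: Optional[int] = None) -> GroupResult:
    """One-way repeated-measures ANOVA (observers x conditions).

    Mauchly's test at `alpha_sphericity` decides whether Greenhouse-Geisser
    corrected degrees of freedom and p-value are reported as primary; both
    the corrected and uncorrected versions are always included.  Pairwise
    condition differences use Bonferroni-corrected paired t tests.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValueError("values must be observers x conditions")
    if np.any(~np.isfinite(values)):
        bad = np.argwhere(~np.isfinite(values))
        raise ValueError(f"incomplete cases: missing cells at (observer, condition) {bad.tolist()}")
    n_obs, n_cond = values.shape
    if n_cond != len(labels):
        raise ValueError("labels must match the number of condition columns")

    long = pd.DataFrame({
        "observer": np.repeat(np.arange(n_obs), n_cond),
        "condition": np.tile(np.asarray(labels, dtype=object), n_obs),
        "value": values.ravel(),
    })
    table = pg.rm_anova(data=long, dv="value", within="condition",
                        subject="observer", correction=True, detailed=True)
    row = table.iloc[0]
    ss_effect, ss_error = float(table["SS"].iloc[0]), float(table["SS"].iloc[1])
    eta_p2 = ss_effect / (ss_effect + ss_error)
    df1, df2 = float(table["DF"].iloc[0]), float(table["DF"].iloc[1])
    eps = float(row["eps"])
    sphericity_ok = bool(row.get("sphericity", True))
    if n_cond > 2 and "p_spher" in table.columns and np.isfinite(row.get("p_spher", np.nan)):
        sphericity_ok = float(row["p_spher"]) >= alpha_sphericity
    use_gg = (n_cond > 2) and not sphericity_ok
    p_unc = float(row["p_unc"])
    p_gg = float(row["p_GG_corr"]) if "p_GG_corr" in table.columns and np.isfinite(
        row.get("p_GG_corr", np.nan)) else p_unc
    p_primary = p_gg if use_gg else p_unc
    df_primary = (df1 * eps, df2 * eps) if use_gg else (df1, df2)

    pairs = []
    m = n_cond * (n_cond - 1) // 2
    for i, j in itertools.combinations(range(n_cond), 2):
        t, p = stats.ttest_rel(values[:, i], values[:, j])
        pairs.append({"A": labels[i], "B": labels[j], "t": float(t),
                      "df": n_obs - 1, "p_unc": float(p),
                      "p_bonf": min(1.0, m * float(p))})
    pairwise = pd.DataFrame(pairs)

    return GroupResult(
        name=name, statistic=float(row["F"]), df=df_primary, p_value=p_primary,
        effect_size=eta_p2, effect_size_name="partial_eta2", pairwise=pairwise,
        extra={"df_uncorrected": (df1, df2), "p_uncorrected": p_unc,
               "gg_epsilon": eps, "gg_applied": use_gg,
               "sphericity_ok": sphericity_ok, "p_gg": p_gg},
    )


def paired_t_cohen(x, y, name: str = "paired_t") -> GroupResult:
    """Paired t test with Cohen's d = mean(diff) / SD(diff)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d paired samples")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    diff = x - y
    sd = np.std(diff, ddof=1)
    if sd == 0:
        raise ValueError("zero-variance differences: t undefined")
    t, p = stats.ttest_rel(x, y)
    d = float(np.mean(diff) / sd)
    return GroupResult(name=name, statistic=float(t), df=n - 1,
                       p_value=float(p), effect_size=d, effect_size_name="cohen_d")


def one_sample_t(x, popmean: float = 0.0, name: str = "one_sample_t") -> GroupResult:
    """One-sample t test against `popmean`, with Cohen's d."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    sd = np.std(x, ddof=1)
    if sd == 0:
        return GroupResult(name=name, statistic=np.nan, df=n - 1, p_value=np.nan,
                           effect_size=np.nan, effect_size_name="cohen_d",
                           extra={"degenerate": True, "mean": float(np.mean(x))})
    t, p = stats.ttest_1samp(x, popmean)
    d = float((np.mean(x) - popmean) / sd)
    return GroupResult(name=name, statistic=float(t), df=n - 1, p_value=float(p),
                       effect_size=d, effect_size_name="cohen_d",
                       extra={"mean": float(np.mean(x))})


def misreport_tests(summaries: Sequence[ObserverSummary]) -> Dict[str, GroupResult]:
    """Tests on the misreport rates of the Global-Local fits.

    One-sample t vs 0 for beta_glo and beta_loc in each crowded condition;
    paired t (FA vs FM) for each rate; mean fitted perpendicular-control
    global rate per condition when those fits are present.
    """
    out: Dict[str, GroupResult] = {}
    rates: Dict[str, Dict[str, List[float]]] = {}
    perp: Dict[str, List[float]] = {}
    for cond in (Condition.FA, Condition.FM):
        for s in summaries:
            fits = s.fits.get(cond.value, {})
            gl = fits.get(Model.GLOBAL_LOCAL.value)
            if gl is None:
                raise ValueError(f"observer {s.observer} lacks a Global-Local fit for {cond.value}")
            rates.setdefault(cond.value, {}).setdefault("beta_glo", []).append(gl.params.beta_glo)
            rates[cond.value].setdefault("beta_loc", []).append(gl.params.beta_loc)
            pf = fits.get(Model.GLOBAL_PERP.value)
            if pf is not None:
                perp.setdefault(cond.value, []).append(pf.params.beta_glo)
        for rate in ("beta_glo", "beta_loc"):
            out[f"{rate}_vs0_{cond.value}"] = one_sample_t(
                rates[cond.value][rate], 0.0, name=f"{rate} vs 0 ({cond.value})")
    for rate in ("beta_glo", "beta_loc"):
        out[f"{rate}_FA_vs_FM"] = paired_t_cohen(
            rates["FA"][rate], rates["FM"][rate], name=f"{rate} FA vs FM")
    for cond, vals in perp.items():
        out[f"perp_global_rate_{cond}"] = GroupResult(
            name=f"perpendicular-control global rate ({cond})",
            statistic=float(np.mean(vals)), df=len(vals) - 1, p_value=np.nan,
            extra={"mean": float(np.mean(vals)), "sd": float(np.std(vals, ddof=1))})
    return out


# ---------------------------------------------------------------------------

def run_pipeline(trials: Sequence[TrialRecord],
                 fit_config: Optional[FitConfig] = None,
                 seed: int = 0,
                 include_perp_control: bool = True) -> dict:
    """Run the full analysis and return a report bundle (plain dict).

    Deterministic given the trial table and seed.  The bundle contains the
    observer summaries, group descriptive tests (precision ANOVA), AICc
    comparisons, parameter ANOVAs (gamma, sigma, P_T) over the designated
    best models, and the misreport-rate tests.
    """
    summaries = summarize_observers(trials, fit_config=fit_config, seed=seed,
                                    include_perp_control=include_perp_control)
    conds = sorted({c for s in summaries for c in s.precision},
                   key=lambda c: ["U", "FA", "FM"].index(c))
    complete = [s for s in summaries if all(c in s.precision for c in conds)]

    report: dict = {
        "estimator": "MLE",
        "sigma_convention": ("von Mises SD in degrees of the 180-deg orientation "
                             "space via angle doubling (doubled-space circular SD = 2*sigma)"),
        "seed": seed,
        "n_observers": len(summaries),
        "n_complete": len(complete),
        "conditions": conds,
    }

    report["descriptives"] = {
        c: {"mean_error": float(np.mean([s.mean_error[c] for s in complete])),
            "sd_error": float(np.std([s.mean_error[c] for s in complete], ddof=1)),
            "mean_precision": float(np.mean([s.precision[c] for s in complete]))}
        for c in conds
    }

    group: Dict[str, GroupResult] = {}
    if len(conds) >= 2 and len(complete) >= 3:
        prec = np.array([[s.precision[c] for c in conds] for s in complete])
        group["anova_precision"] = rm_anova_gg(prec, conds, name="precision ANOVA")
        for pname in ("gamma", "sigma", "p_target"):
            vals = np.array([[getattr(s.best_fit(Condition(c)).params, pname)
                              if pname != "p_target" else s.best_fit(Condition(c)).params.p_target
                              for c in conds] for s in complete])
            group[f"anova_{pname}"] = rm_anova_gg(vals, conds, name=f"{pname} ANOVA")

    # AICc paired comparisons per crowded condition
    delta_tables: Dict[str, dict] = {}
    for cond in (Condition.FA, Condition.FM):
        if cond.value not in conds:
            continue
        gl = [s.fits[cond.value][Model.GLOBAL_LOCAL.value].aicc for s in complete]
        std = [s.fits[cond.value][Model.STANDARD.value].aicc for s in complete]
        loc = [s.fits[cond.value][Model.LOCAL.value].aicc for s in complete]
        delta_tables[cond.value] = {
            "mean_delta_gl_minus_standard": float(np.mean(np.array(gl) - np.array(std))),
            "mean_delta_gl_minus_local": float(np.mean(np.array(gl) - np.array(loc))),
            "winner_counts": dict(pd.Series([s.winner[cond.value] for s in complete])
                                  .value_counts()),
        }
        if len(complete) >= 3:
            group[f"aicc_gl_vs_standard_{cond.value}"] = paired_t_cohen(
                gl, std, name=f"AICc GL vs Standard ({cond.value})")
            group[f"aicc_gl_vs_local_{cond.value}"] = paired_t_cohen(
                gl, loc, name=f"AICc GL vs Local ({cond.value})")
    report["delta_aicc"] = delta_tables

    if {"FA", "FM"} <= set(conds) and len(complete) >= 3:
        group.update(misreport_tests(complete))

    report["group_tests"] = {k: v.as_dict() for k, v in group.items()}
    report["observers"] = [
        {"observer": s.observer,
         "mean_error": s.mean_error, "precision": s.precision,
         "winner": s.winner,
         "fits": {c: {m: f.as_dict() for m, f in fits.items()}
                  for c, fits in s.fits.items()}}
        for s in summaries
    ]
    report["_summaries"] = summaries  # in-memory convenience, dropped on serialisation
    return report
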