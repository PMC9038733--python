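"""Trial-table CSV readers/writers, report serialisation, configuration.

Trial table schema (one row per trial):

    observer, condition (U|FA|FM), target_deg, flanker1_deg..flanker4_deg,
    global_deg, response_deg

Stimulus orientations are integers 1..180 (the response wheel's parameter
space); responses may be decimal.  Uncrowded (U) rows leave the flanker and
global cells empty; crowded rows must fill all of them and satisfy the
diagonal-pairing constraint (flanker1 == flanker3, flanker2 == flanker4).
Violations are reported with their row numbers.

Adapting an external deposit (e.g. a per-observer spreadsheet export) means
mapping its columns onto this schema; see `convert_external_stub`.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Sequence

import numpy as np
import pandas as pd
import yaml

from .models import Condition, TrialRecord

__all__ = ["SCHEMA_VERSION", "REQUIRED_COLUMNS", "read_trials", "write_trials",
           "trials_to_frame", "write_report", "load_config"]

SCHEMA_VERSION = "crowdmix-trials-v1"

REQUIRED_COLUMNS = ["observer", "condition", "target_deg", "flanker1_deg",
                    "flanker2_deg", "flanker3_deg", "flanker4_deg",
                    "global_deg", "response_deg"]

_STIM_COLS = ["target_deg", "flanker1_deg", "flanker2_deg", "flanker3_deg",
              "flanker4_deg", "global_deg"]


def _store_deg(x: float) -> float:
    """Canonical [0,180) -> stored (0,180] (0 is written as 180)."""
    return 180.0 if x == 0.0 else float(x)


def trials_to_frame(trials: Sequence[TrialRecord]) -> pd.DataFrame:
    rows = []
    for t in trials:
        row = {"observer": t.observer, "condition": t.condition.value,
               "target_deg": _store_deg(t.target),
               "flanker1_deg": np.nan, "flanker2_deg": np.nan,
               "flanker3_deg": np.nan, "flanker4_deg": np.nan,
               "global_deg": np.nan,
               "response_deg": _store_deg(t.response) if t.response is not None else np.nan}
        if t.condition is not Condition.U:
            for i, f in enumerate(t.flankers, start=1):
                row[f"flanker{i}_deg"] = _store_deg(f)
            row["global_deg"] = _store_deg(t.global_ori)
        rows.append(row)
    return pd.DataFrame(rows, columns=REQUIRED_COLUMNS)


def write_trials(trials: Sequence[TrialRecord], path) -> None:
    """Write a trial table CSV (schema version in a leading comment line)."""
    path = Path(path)
    frame = trials_to_frame(trials)
    with open(path, "w") as fh:
        fh.write(f"# schema: {SCHEMA_VERSION}\n")
        frame.to_csv(fh, index=False)


def _check_range(value: float, row: int, col: str, errors: List[str]):
    if not np.isfinite(value) or not (0.0 < value <= 180.0):
        errors.append(f"row {row}: {col}={value!r} outside (0, 180]")


def read_trials(path, log=None) -> List[TrialRecord]:
    """Read and validate a trial table CSV; raises with row numbers on errors.

    Extra columns are ignored with a logged note.  Row numbers refer to data
    rows (header = row 0).
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    extra = [c for c in df.columns if c not in REQUIRED_COLUMNS]
    if extra and log is not None:
        log(f"{path}: ignoring extra columns {extra}")

    errors: List[str] = []
    trials: List[TrialRecord] = []
    for idx, row in enumerate(df.itertuples(index=False), start=1):
        rec = row._asdict()
        try:
            cond = Condition(str(rec["condition"]))
        except ValueError:
            errors.append(f"row {idx}: unknown condition {rec['condition']!r}")
            continue
        row_errors: List[str] = []
        _check_range(rec["target_deg"], idx, "target_deg", row_errors)
        _check_range(rec["response_deg"], idx, "response_deg", row_errors)
        flankers = global_ori = None
        if cond is Condition.U:
            filled = [c for c in _STIM_COLS[1:] if np.isfinite(rec[c])]
            if filled:
                row_errors.append(f"row {idx}: U trial has non-empty {filled}")
        else:
            for c in _STIM_COLS[1:]:
                _check_range(rec[c], idx, c, row_errors)
            if not row_errors:
                fl = tuple(float(rec[f"flanker{i}_deg"]) for i in range(1, 5))
                if fl[0] != fl[2] or fl[1] != fl[3]:
                    row_errors.append(
                        f"row {idx}: flankers not diagonally paired "
                        f"(flanker1 {fl[0]} != flanker3 {fl[2]} or "
                        f"flanker2 {fl[1]} != flanker4 {fl[3]})")
                else:
                    flankers = fl
                    global_ori = float(rec["global_deg"])
        if row_errors:
            errors.extend(row_errors)
            continue
        trials.append(TrialRecord(
            observer=str(rec["observer"]), condition=cond,
            target=float(rec["target_deg"]), flankers=flankers,
            global_ori=global_ori, response=float(rec["response_deg"])))
    if errors:
        raise ValueError(f"{path}: {len(errors)} invalid rows:\n" + "\n".join(errors))
    return trials


# ---------------------------------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items() if not str(k).startswith("_")}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def write_report(report: dict, out_dir, seed: int) -> None:
    """Serialise a pipeline report bundle: JSON + Markdown + CSV tables."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = {"schema": SCHEMA_VERSION, "seed": seed, **_jsonable(report)}
    (out_dir / "report.json").write_text(json.dumps(payload, indent=2) + "\n")

    lines = ["# Crowding mixture-model analysis report", "",
             f"- schema: {SCHEMA_VERSION}",
             f"- seed: {seed}",
             f"- estimator: {report.get('estimator', 'MLE')}",
             f"- sigma convention: {report.get('sigma_convention', '')}", ""]
    lines.append("## Descriptives (group means)")
    for cond, d in report.get("descriptives", {}).items():
        lines.append(f"- {cond}: mean error {d['mean_error']:+.2f} deg "
                     f"(SD {d['sd_error']:.2f}), precision {d['mean_precision']:.3f} /deg")
    lines.append("")
    if report.get("delta_aicc"):
        lines.append("## AICc model comparison (negative favors Global-Local)")
        for cond, d in report["delta_aicc"].items():
            lines.append(f"- {cond}: mean dAICc GL-Standard = "
                         f"{d['mean_delta_gl_minus_standard']:+.2f}; GL-Local = "
                         f"{d['mean_delta_gl_minus_local']:+.2f}; "
                         f"per-observer winners: {d['winner_counts']}")
        lines.append("")
    if report.get("group_tests"):
        lines.append("## Group tests")
        for key, t in report["group_tests"].items():
            stat, p = t.get("statistic"), t.get("p_value")
            df = t.get("df")
            es, esn = t.get("effect_size"), t.get("effect_size_name")
            desc = f"- {t.get('name', key)}: stat = {stat:.3f}" if stat is not None else f"- {key}:"
            if df is not None:
                desc += f", df = {df}"
            if p is not None:
                desc += f", p = {p:.4g}"
            if es is not None and esn:
                desc += f", {esn} = {es:.3f}"
            lines.append(desc)
        lines.append("")
    (out_dir / "report.md").write_text("\n".join(lines) + "\n")

    obs = report.get("observers", [])
    if obs:
        rows = []
        for o in obs:
            for cond, fits in o["fits"].items():
                for model, f in fits.items():
                    rows.append({"observer": o["observer"], "condition": cond,
                                 "model": model, **f["params"],
                                 "p_target": f["p_target"], "loglik": f["loglik"],
                                 "aicc": f["aicc"], "converged": f["converged"]})
        pd.DataFrame(rows).to_csv(out_dir / "fits.csv", index=False)
        desc_rows = [{"observer": o["observer"], "condition": c,
                      "mean_error": o["mean_error"][c], "precision": o["precision"][c]}
                     for o in obs for c in o["mean_error"]]
        pd.DataFrame(desc_rows).to_csv(out_dir / "descriptives.csv", index=False)


def load_config(path) -> dict:
    """Load a YAML configuration file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    return cfg


def convert_external_stub(path):
    """Adapter point for external deposits whose layout is not standardised.

    Map the deposit's columns onto REQUIRED_COLUMNS (orientations in degrees
    1..180, conditions coded U/FA/FM) and write with `write_trials`; this
    function only documents the expected mapping and raises.
    """
    raise NotImplementedError(
        "external deposit layouts vary; write a small adapter that maps the "
        "deposit's columns onto the crowdmix trial-table schema "
        f"({', '.join(REQUIRED_COLUMNS)}) and save it with write_trials()")
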