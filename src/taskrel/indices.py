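"""Summary scores: condition means, difference scores, AX-CPT derived indices.

These are the "mean point estimate" (MPE) layer of the analysis: one number
per subject and cell, computed by averaging trials.  The four headline
reaction-time difference scores are interference minus control:

* ``stroop_effect``     = incongruent - congruent (Stroop)
* ``bx_interference``   = BX - BY (AX-CPT)
* ``trce``              = incongruent - congruent (cued task switching;
  the task-rule congruency effect)
* ``recency_effect``    = RN - NN (Sternberg; recent-negative probes)

AX-CPT also yields signal-detection style indices (d'-context, A-cue bias)
and the proactive behavioral index (PBI).  Extreme hit / false-alarm
proportions are adjusted by the 1/(2N) rule before the normal-quantile
transform; PBI on error rates uses additive smoothing (+0.5 errors, +1
trial) so the ratio is defined for error-free cells.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .schema import CONTRASTS, NOGO_TYPES, TrialDataset

RT_INDICES = tuple(c[2] for c in CONTRASTS.values())


def condition_means(ds: TrialDataset) -> pd.DataFrame:
    """Per-cell summary: mean correct RT, error rate, and counts.

    Returns one row per subject x task x session x phase x trial_type with
    ``mean_rt_ms`` (correct responded trials; absent when there are none),
    ``error_rate`` (errors / completed trials, where completed means a
    response was recorded), ``n_correct``, ``n_completed`` and ``n_trials``.
    """
    df = ds.trials.copy()
    df["_completed"] = df["rt_ms"].notna()
    df["_correct"] = (df["accuracy"] == 1) & df["_completed"]
    df["_correct_rt"] = df["rt_ms"].where(df["_correct"])
    out = (
        df.groupby(["subject", "task", "session", "phase", "trial_type"], sort=True)
        .agg(mean_rt_ms=("_correct_rt", "mean"),
             n_correct=("_correct", "sum"),
             n_completed=("_completed", "sum"),
             n_trials=("trial_index", "size"))
        .reset_index()
    )
    out["error_rate"] = np.where(
        out["n_completed"] > 0,
        1.0 - out["n_correct"] / out["n_completed"].replace(0, np.nan),
        np.nan,
    )
    return out


def difference_score(summary: pd.DataFrame, task: str, channel: str = "rt") -> pd.DataFrame:
    """Interference-minus-control difference scores for one task.

    ``channel="rt"`` differences mean correct RTs (ms); ``channel="error"``
    differences error rates (proportions).  An index is emitted only when
    both constituent cells exist (missing cells yield no row).
    """
    if channel not in ("rt", "error"):
        raise ValueError("channel must be 'rt' or 'error'")
    control, interference, name = CONTRASTS[task]
    value = "mean_rt_ms" if channel == "rt" else "error_rate"
    sub = summary.loc[summary["task"] == task]
    wide = sub.pivot_table(index=["subject", "session", "phase"],
                           columns="trial_type", values=value)
    if control not in wide.columns or interference not in wide.columns:
        return pd.DataFrame(columns=["subject", "task", "session", "phase", "index", "value"])
    diff = (wide[interference] - wide[control]).dropna()
    out = diff.rename("value").reset_index()
    out["task"] = task
    out["index"] = name if channel == "rt" else f"{name}_error"
    return out[["subject", "task", "session", "phase", "index", "value"]]


def _adjust_rate(k: float, n: float) -> float:
    """Proportion k/n with the 1/(2N) adjustment for 0 and 1."""
    if n < 1:
        raise ValueError("need at least one trial")
    r = k / n
    if r <= 0.0:
        return 1.0 / (2.0 * n)
    if r >= 1.0:
        return 1.0 - 1.0 / (2.0 * n)
    return r


def dprime_context(ax_hits: float, ax_n: float, bx_fa: float, bx_n: float) -> float:
    """AX-CPT d'-context: z(AX hit rate) - z(BX false-alarm rate).

    Hits are correct target responses on AX trials; false alarms are
    erroneous target responses on BX trials.  Rates are 1/(2N)-adjusted.
    """
    if ax_n < 1 or bx_n < 1:
        raise ValueError("need at least one AX and one BX trial")
    h = _adjust_rate(ax_hits, ax_n)
    fa = _adjust_rate(bx_fa, bx_n)
    return float(stats.norm.ppf(h) - stats.norm.ppf(fa))


def a_cue_bias(ax_hits: float, ax_n: float, ay_fa: float, ay_n: float) -> float:
    """Criterion-style A-cue bias: 0.5 * [z(AX hit rate) + z(AY false-alarm rate)].

    Higher values indicate a stronger A-cue-driven target expectancy (more
    target responses after an A cue, whatever the probe).
    """
    if ax_n < 1 or ay_n < 1:
        raise ValueError("need at least one AX and one AY trial")
    h = _adjust_rate(ax_hits, ax_n)
    fa = _adjust_rate(ay_fa, ay_n)
    return float(0.5 * (stats.norm.ppf(h) + stats.norm.ppf(fa)))


def pbi(ay: float, bx: float) -> float:
    """Proactive behavioral index (AY - BX) / (AY + BX).

    Positive values mean AY trials are harder than BX trials, the signature
    of proactive cue use.  Returns NaN when the denominator is zero.
    """
    if ay < 0 or bx < 0:
        raise ValueError("pbi inputs must be non-negative")
    denom = ay + bx
    if denom == 0:
        return float("nan")
    return float((ay - bx) / denom)


def pbi_error(ay_errors: float, ay_n: float, bx_errors: float, bx_n: float) -> float:
    """PBI on error rates with additive smoothing (+0.5 errors, +1 trial)."""
    if ay_n < 1 or bx_n < 1:
        raise ValueError("need at least one AY and one BX trial")
    ay = (ay_errors + 0.5) / (ay_n + 1.0)
    bx = (bx_errors + 0.5) / (bx_n + 1.0)
    return pbi(ay, bx)


def derived_axcpt_indices(summary: pd.DataFrame) -> pd.DataFrame:
    """Per-subject AX-CPT derived indices from a condition-mean summary.

    Emits ``dprime_context``, ``a_cue_bias``, ``pbi_rt`` and ``pbi_error``
    for every subject x session x phase with the necessary cells.
    """
    sub = summary.loc[(summary["task"] == "axcpt")
                      & ~summary["trial_type"].isin(NOGO_TYPES)]
    rows = []
    for (subject, session, phase), cell in sub.groupby(["subject", "session", "phase"]):
        c = cell.set_index("trial_type")
        need = {"AX", "AY", "BX", "BY"}
        if not need.issubset(c.index) or (c.loc[list(need), "n_completed"] < 1).any():
            continue
        ax_n = c.at["AX", "n_completed"]
        ay_n = c.at["AY", "n_completed"]
        bx_n = c.at["BX", "n_completed"]
        ax_hits = c.at["AX", "n_correct"]
        ay_err = ay_n - c.at["AY", "n_correct"]
        bx_err = bx_n - c.at["BX", "n_correct"]
        vals = {
            "dprime_context": dprime_context(ax_hits, ax_n, bx_err, bx_n),
            "a_cue_bias": a_cue_bias(ax_hits, ax_n, ay_err, ay_n),
            "pbi_error": pbi_error(ay_err, ay_n, bx_err, bx_n),
        }
        ay_rt = c.at["AY", "mean_rt_ms"]
        bx_rt = c.at["BX", "mean_rt_ms"]
        if np.isfinite(ay_rt) and np.isfinite(bx_rt):
            vals["pbi_rt"] = pbi(ay_rt, bx_rt)
        for name, value in vals.items():
            rows.append({"subject": subject, "task": "axcpt", "session": session,
                         "phase": phase, "index": name, "value": value})
    return pd.DataFrame(rows, columns=["subject", "task", "session", "phase", "index", "value"])


def index_table(ds: TrialDataset, channels=("rt",), include_derived: bool = True) -> pd.DataFrame:
    """Tidy IndexTable over all tasks present in the dataset."""
    summary = condition_means(ds)
    parts = []
    for task in sorted(ds.trials["task"].unique()):
        if task not in CONTRASTS:
            continue
        for channel in channels:
            parts.append(difference_score(summary, task, channel=channel))
    if include_derived and (ds.trials["task"] == "axcpt").any():
        parts.append(derived_axcpt_indices(summary))
    if not parts:
        return pd.DataFrame(columns=["subject", "task", "session", "phase", "index", "value"])
    return pd.concat(parts, ignore_index=True)
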