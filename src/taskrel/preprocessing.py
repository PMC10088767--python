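"""Trial- and subject-level filtering for battery reaction-time data.

The pipeline order is fixed: :func:`trim_rt` -> :func:`retention_filter` ->
:func:`error_rate_filter`.  Bivariate outlier screening
(:func:`mahalanobis_filter`) applies only at the correlation stage, on
complete pairs of subject-level estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .schema import CELL_KEYS, TrialDataset

#: 0.999 quantile of chi-squared with 1 df; the conventional bivariate
#: outlier cutoff for squared Mahalanobis distance (alpha = .001, df = 1).
DEFAULT_MAHALANOBIS_CUTOFF = 10.828


@dataclass
class TrimReport:
    """Accounting of RT trimming, per task and per subject-level cell."""

    per_task: pd.DataFrame       # task, n_correct_before, n_removed, fraction_removed
    per_cell: pd.DataFrame       # cell keys, n_before, n_removed_fast, n_removed_slow
    small_cells: pd.DataFrame    # cells with < 2 correct trials (no slow trim applied)


@dataclass
class RetentionReport:
    """Subjects removed per task, with the triggering reason and detail."""

    removed: pd.DataFrame        # subject, task, reason, detail
    reason: str = ""


def trim_rt(ds: TrialDataset, floor_ms: float = 200.0, sd_mult: float = 3.0
            ) -> tuple[TrialDataset, TrimReport]:
    """Remove implausible correct-trial reaction times.

    Among correct trials only, removes trials faster than ``floor_ms`` or
    slower than ``mean + sd_mult * sd``, where mean and sd are computed over
    the correct trials of that subject x task x session x phase x trial-type
    cell *including* prospective outliers (single pass; the slow rule is
    never iterated).  Incorrect and non-response trials are untouched.
    Cells with fewer than two correct trials get no slow trim (sd
    undefined) and are flagged in the report.
    """
    if floor_ms <= 0 or sd_mult <= 0:
        raise ValueError("floor_ms and sd_mult must be positive")
    df = ds.trials
    correct = (df["accuracy"] == 1) & df["rt_ms"].notna()
    sub = df.loc[correct]
    grp = sub.groupby(CELL_KEYS)["rt_ms"]
    mean = grp.transform("mean")
    sd = grp.transform("std")            # ddof=1; NaN for single-trial cells
    n = grp.transform("size")

    fast = sub["rt_ms"] < floor_ms
    slow = (n >= 2) & (sub["rt_ms"] > mean + sd_mult * sd)
    slow = slow.fillna(False)
    removed = fast | slow

    cell = sub.assign(_fast=fast, _slow=slow, _n=n)
    per_cell = (
        cell.groupby(CELL_KEYS)
        .agg(n_before=("rt_ms", "size"),
             n_removed_fast=("_fast", "sum"),
             n_removed_slow=("_slow", "sum"))
        .reset_index()
    )
    small_cells = per_cell.loc[per_cell["n_before"] < 2].reset_index(drop=True)

    per_task = (
        cell.assign(_rm=removed)
        .groupby("task")
        .agg(n_correct_before=("rt_ms", "size"), n_removed=("_rm", "sum"))
        .reset_index()
    )
    per_task["fraction_removed"] = per_task["n_removed"] / per_task["n_correct_before"]

    keep_index = df.index.difference(sub.index[removed])
    out = TrialDataset(df.loc[keep_index].reset_index(drop=True),
                       provenance=ds.provenance + " | trim_rt", design=ds.design)
    return out, TrimReport(per_task, per_cell, small_cells)


def retention_filter(ds_before: TrialDataset, ds_after: TrialDataset,
                     min_retained: float = 0.5
                     ) -> tuple[TrialDataset, RetentionReport]:
    """Drop subjects whose trimming removed more than half of a cell.

    A subject is removed from a *task* (all sessions and phases of that
    task) if any trial-type cell retains a fraction of its pre-trim correct
    trials strictly below ``min_retained``.  Retaining exactly half passes:
    the criterion is "no more than half removed".
    """
    def cell_counts(ds):
        d = ds.trials
        c = d.loc[(d["accuracy"] == 1) & d["rt_ms"].notna()]
        return c.groupby(CELL_KEYS).size()

    before = cell_counts(ds_before)
    after = cell_counts(ds_after).reindex(before.index, fill_value=0)
    frac = after / before
    bad = frac[frac < min_retained]
    removed = (
        bad.reset_index()[["subject", "task"]]
        .drop_duplicates()
        .assign(reason="over_half_trimmed")
    )
    detail = [
        "; ".join(
            f"{s}/{p}/{tt}: kept {after[(subj, task, s, p, tt)]}/{before[(subj, task, s, p, tt)]}"
            for (subj_, task_, s, p, tt) in bad.index
            if subj_ == subj and task_ == task
        )
        for subj, task in zip(removed["subject"], removed["task"], strict=True)
    ]
    removed["detail"] = detail

    df = ds_after.trials
    drop = pd.MultiIndex.from_frame(removed[["subject", "task"]]) if len(removed) else None
    if drop is not None:
        key = pd.MultiIndex.from_frame(df[["subject", "task"]])
        df = df.loc[~key.isin(drop)]
    out = TrialDataset(df.reset_index(drop=True),
                       provenance=ds_after.provenance + " | retention_filter",
                       design=ds_after.design)
    return out, RetentionReport(removed.reset_index(drop=True), "over_half_trimmed")


def error_rate_filter(ds: TrialDataset, cutoff: float = 0.40
                      ) -> tuple[TrialDataset, RetentionReport]:
    """Drop subjects with an excessive error rate in any trial-type cell.

    Error rate is errors / completed trials per cell, where completed means
    a response was recorded (non-responses count as neither correct nor
    error).  A subject is removed from a task when any of that task's cells
    exceeds ``cutoff`` (strictly greater).
    """
    if not 0 < cutoff < 1:
        raise ValueError("cutoff must be a proportion in (0, 1)")
    df = ds.trials
    comp = df.loc[df["rt_ms"].notna()]
    rate = comp.groupby(CELL_KEYS)["accuracy"].agg(["size", "mean"])
    rate["error_rate"] = 1.0 - rate["mean"]
    bad = rate.loc[rate["error_rate"] > cutoff]
    removed = (
        bad.reset_index()[["subject", "task"]]
        .drop_duplicates()
        .assign(reason="error_rate_cutoff")
    )
    detail = []
    for subj, task in zip(removed["subject"], removed["task"], strict=True):
        cells = bad.loc[(bad.index.get_level_values(0) == subj)
                        & (bad.index.get_level_values(1) == task)]
        detail.append("; ".join(
            f"{s}/{p}/{tt}: {er:.0%} of {n}"
            for (_, _, s, p, tt), (n, _, er) in cells.iterrows()
        ))
    removed["detail"] = detail

    if len(removed):
        drop = pd.MultiIndex.from_frame(removed[["subject", "task"]])
        key = pd.MultiIndex.from_frame(df[["subject", "task"]])
        df = df.loc[~key.isin(drop)]
    out = TrialDataset(df.reset_index(drop=True),
                       provenance=ds.provenance + " | error_rate_filter",
                       design=ds.design)
    return out, RetentionReport(removed.reset_index(drop=True), "error_rate_cutoff")


def error_rate_sweep(ds: TrialDataset, cutoffs=(0.20, 0.30, 0.40, 0.50)) -> pd.DataFrame:
    """Multiverse helper: subjects removed per task at each candidate cutoff."""
    rows = []
    for cutoff in cutoffs:
        _, report = error_rate_filter(ds, cutoff=cutoff)
        n = report.removed.groupby("task").size() if len(report.removed) else pd.Series(dtype=int)
        for task in sorted(ds.trials["task"].unique()):
            rows.append({"cutoff": cutoff, "task": task, "n_removed": int(n.get(task, 0))})
    return pd.DataFrame(rows)


def preprocess(ds: TrialDataset, floor_ms: float = 200.0, sd_mult: float = 3.0,
               error_cutoff: float = 0.40):
    """Full fixed-order preprocessing pipeline; returns (dataset, reports)."""
    trimmed, trim_report = trim_rt(ds, floor_ms=floor_ms, sd_mult=sd_mult)
    retained, retention_report = retention_filter(ds, trimmed)
    final, error_report = error_rate_filter(retained, cutoff=error_cutoff)
    return final, {"trim": trim_report, "retention": retention_report,
                   "error_rate": error_report}


def chi2_cutoff(alpha: float, df: int) -> float:
    """(1 - alpha) quantile of the chi-squared distribution with ``df`` dof.

    ``chi2_cutoff(0.001, 1)`` gives the conventional 10.828 squared-distance
    cutoff for bivariate outlier screening.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie strictly between 0 and 1")
    if not (isinstance(df, (int, np.integer)) and df >= 1):
        raise ValueError("df must be a positive integer")
    return float(stats.chi2.ppf(1.0 - alpha, df))


def mahalanobis_filter(x, y, cutoff: float = DEFAULT_MAHALANOBIS_CUTOFF) -> np.ndarray:
    """Keep-mask for bivariate outlier screening.

    True where the squared Mahalanobis distance from the bivariate sample
    mean (sample covariance, denominator n-1) is at most ``cutoff``.
    Requires complete pairs; the caller drops incomplete cases first.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("complete pairs only: drop missing values before screening")
    xy = np.column_stack([x, y])
    centered = xy - xy.mean(axis=0)
    cov = np.cov(centered, rowvar=False, ddof=1)
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as err:
        raise ValueError(
            "singular covariance matrix: the points are (near-)collinear; "
            "inspect the data before outlier screening"
        ) from err
    z = np.linalg.solve(L, centered.T)
    d2 = (z ** 2).sum(axis=0)
    return d2 <= cutoff
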