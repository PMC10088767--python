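"""Classical psychometrics: permutation split-half and intraclass correlation.

Split-half internal consistency is estimated by repeatedly (default 5000
permutations) splitting each subject's trials randomly into halves,
computing the index in each half, Pearson-correlating the halves across
subjects, applying the Spearman-Brown correction, and averaging the
corrected correlations.  Splits are stratified within trial type so that
every half supports the difference score.

Test-retest reliability uses the single-rater intraclass correlations of
Shrout and Fleiss: ICC(3,1) (two-way mixed effects, consistency -- robust
to constant session shifts such as practice effects) and ICC(2,1) (two-way
random effects, absolute agreement -- penalised by them).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .indices import RT_INDICES
from .schema import CONTRASTS, TrialDataset


def spearman_brown(r: float) -> float:
    """Spearman-Brown step-up correction 2r / (1 + r) for a half-test correlation."""
    r = float(r)
    if r <= -1.0:
        raise ValueError("Spearman-Brown correction undefined at r = -1")
    return 2.0 * r / (1.0 + r)


@dataclass
class SplitHalfResult:
    mean_r: float                # average Spearman-Brown corrected correlation
    ci: tuple[float, float]      # 2.5 / 97.5 percentiles of the permutation distribution
    n_permutations: int
    seed: int
    n_subjects: int
    dropped_subjects: list
    n_undefined: int = 0         # permutations with undefined correlation (excluded)


# Index definitions: required trial types, per-trial value channel, combiner.
# Channel "rt" uses correct-trial RTs; "acc" uses 0/1 accuracy of completed trials.
def _combine_diff_rt(stats_, a, b):
    return stats_[b]["mean"] - stats_[a]["mean"]


def _combine_diff_err(stats_, a, b):
    return (1.0 - stats_[b]["mean"]) - (1.0 - stats_[a]["mean"])


def _zadj(rate, n):
    lo = 1.0 / (2.0 * n)
    return stats.norm.ppf(np.clip(rate, lo, 1.0 - lo))


def _index_definition(index: str):
    for task, (control, interference, name) in CONTRASTS.items():
        if index == name:
            return task, {control: "rt", interference: "rt"}, (
                lambda s, a=control, b=interference: _combine_diff_rt(s, a, b))
        if index == f"{name}_error":
            return task, {control: "acc", interference: "acc"}, (
                lambda s, a=control, b=interference: _combine_diff_err(s, a, b))
    if index == "dprime_context":
        return "axcpt", {"AX": "acc", "BX": "acc"}, (
            lambda s: _zadj(s["AX"]["mean"], s["AX"]["n"])
            - _zadj(1.0 - s["BX"]["mean"], s["BX"]["n"]))
    if index == "a_cue_bias":
        return "axcpt", {"AX": "acc", "AY": "acc"}, (
            lambda s: 0.5 * (_zadj(s["AX"]["mean"], s["AX"]["n"])
                             + _zadj(1.0 - s["AY"]["mean"], s["AY"]["n"])))
    if index == "pbi_rt":
        return "axcpt", {"AY": "rt", "BX": "rt"}, (
            lambda s: (s["AY"]["mean"] - s["BX"]["mean"])
            / (s["AY"]["mean"] + s["BX"]["mean"]))
    if index == "pbi_error":
        def _pbi_err(s):
            ay = ((1.0 - s["AY"]["mean"]) * s["AY"]["n"] + 0.5) / (s["AY"]["n"] + 1.0)
            bx = ((1.0 - s["BX"]["mean"]) * s["BX"]["n"] + 0.5) / (s["BX"]["n"] + 1.0)
            return (ay - bx) / (ay + bx)
        return "axcpt", {"AY": "acc", "BX": "acc"}, _pbi_err
    raise ValueError(f"unknown index {index!r}")


def _half_means(values: np.ndarray, n_perm: int, rng: np.random.Generator):
    """Random-half means of one trial-value vector for every permutation.

    Returns dicts for half A and half B with keys ``mean`` (n_perm,) and
    ``n``.  For odd counts the extra trial goes to a half at random per
    permutation.
    """
    L = len(values)
    order = np.argsort(rng.random((n_perm, L)), axis=1)
    shuffled = values[order]
    csum = np.cumsum(shuffled, axis=1)
    if L % 2 == 0:
        s = np.full(n_perm, L // 2)
    else:
        s = L // 2 + rng.integers(0, 2, size=n_perm)
    total = csum[:, -1]
    sum_a = csum[np.arange(n_perm), s - 1]
    mean_a = sum_a / s
    mean_b = (total - sum_a) / (L - s)
    return {"mean": mean_a, "n": s}, {"mean": mean_b, "n": L - s}


def permutation_split_half(
    ds: TrialDataset,
    index: str,
    session: str,
    phase: str,
    n_perm: int = 5000,
    seed: int | None = None,
    min_trials: int = 2,
) -> SplitHalfResult:
    """Permutation split-half reliability of one index in one cell.

    Each subject's trials are split randomly into halves, stratified within
    trial type; the index is computed per half, halves are Pearson-correlated
    across subjects, Spearman-Brown corrected, and averaged over
    permutations.  Subjects with fewer than ``min_trials`` usable trials in
    any required trial type are dropped (and logged on the result).
    """
    if seed is None:
        raise ValueError("seed is a required parameter for stochastic estimates")
    task, requirements, combine = _index_definition(index)
    rng = np.random.default_rng(seed)
    df = ds.trials
    mask = ((df["task"] == task) & (df["session"] == session) & (df["phase"] == phase)
            & df["trial_type"].isin(requirements))
    sub = df.loc[mask]

    per_subject: dict = {}
    dropped = []
    for subject, d in sub.groupby("subject"):
        arrays = {}
        for tt, channel in requirements.items():
            t = d.loc[d["trial_type"] == tt]
            if channel == "rt":
                vals = t.loc[(t["accuracy"] == 1) & t["rt_ms"].notna(), "rt_ms"].to_numpy(float)
            else:
                vals = t.loc[t["rt_ms"].notna(), "accuracy"].to_numpy(float)
            arrays[tt] = vals
        if any(len(v) < min_trials for v in arrays.values()):
            dropped.append(subject)
            continue
        per_subject[subject] = arrays
    subjects = sorted(per_subject)
    if len(subjects) < 3:
        raise ValueError(f"need >= 3 usable subjects, have {len(subjects)}")

    idx_a = np.empty((n_perm, len(subjects)))
    idx_b = np.empty((n_perm, len(subjects)))
    for j, subject in enumerate(subjects):
        halves_a, halves_b = {}, {}
        for tt in requirements:
            a, b = _half_means(per_subject[subject][tt], n_perm, rng)
            halves_a[tt], halves_b[tt] = a, b
        idx_a[:, j] = combine(halves_a)
        idx_b[:, j] = combine(halves_b)

    ca = idx_a - idx_a.mean(axis=1, keepdims=True)
    cb = idx_b - idx_b.mean(axis=1, keepdims=True)
    denom = np.sqrt((ca ** 2).sum(axis=1) * (cb ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (ca * cb).sum(axis=1) / denom, np.nan)
        corrected = 2.0 * r / (1.0 + r)
    ok = np.isfinite(corrected)
    n_undefined = int((~ok).sum())
    if ok.sum() == 0:
        raise ValueError("correlation undefined in every permutation (zero variance)")
    corrected = corrected[ok]
    return SplitHalfResult(
        mean_r=float(corrected.mean()),
        ci=(float(np.percentile(corrected, 2.5)), float(np.percentile(corrected, 97.5))),
        n_permutations=n_perm,
        seed=seed,
        n_subjects=len(subjects),
        dropped_subjects=dropped,
        n_undefined=n_undefined,
    )


@dataclass
class IccResult:
    value: float
    form: str                    # "ICC21" or "ICC31"
    ci: tuple[float, float]
    n: int                       # subjects (rows)
    k: int                       # occasions (columns)


def _anova(scores) -> tuple[float, float, float, int, int]:
    x = np.asarray(scores, dtype=float)
    if x.ndim != 2:
        raise ValueError("scores must be an n_subjects x k_occasions matrix")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 occasions")
    if np.isnan(x).any():
        raise ValueError("missing entries: complete cases only (drop them upstream)")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = max(ss_err, 0.0) / ((n - 1) * (k - 1))
    return msr, msc, mse, n, k


def icc_consistency(scores, confidence: float = 0.95) -> IccResult:
    """ICC(3,1): two-way mixed effects, consistency, single rater.

    Invariant to a constant shift of an occasion (e.g., uniform practice
    gains); only the consistency of the subject rank order matters.
    """
    msr, msc, mse, n, k = _anova(scores)
    denom = msr + (k - 1) * mse
    value = np.nan if denom == 0 else (msr - mse) / denom
    alpha = 1.0 - confidence
    if mse > 0:
        f_obs = msr / mse
        df1, df2 = n - 1, (n - 1) * (k - 1)
        fl = f_obs / stats.f.ppf(1 - alpha / 2, df1, df2)
        fu = f_obs * stats.f.ppf(1 - alpha / 2, df2, df1)
        ci = ((fl - 1) / (fl + k - 1), (fu - 1) / (fu + k - 1))
    else:
        ci = (np.nan, np.nan)
    return IccResult(float(value), "ICC31", (float(ci[0]), float(ci[1])), n, k)


def icc_agreement(scores, confidence: float = 0.95) -> IccResult:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    Sensitive to systematic mean differences between occasions; always at
    most the consistency form on the same matrix.
    """
    msr, msc, mse, n, k = _anova(scores)
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    value = np.nan if denom == 0 else (msr - mse) / denom
    alpha = 1.0 - confidence
    if mse > 0 and np.isfinite(value):
        icc = value
        a = (k * icc) / (n * (1 - icc)) if icc < 1 else np.inf
        b = 1 + (k * icc * (n - 1)) / (n * (1 - icc)) if icc < 1 else np.inf
        if np.isfinite(a):
            v = (a * msc + b * mse) ** 2 / (
                (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1)))
            f1 = stats.f.ppf(1 - alpha / 2, n - 1, v)
            f2 = stats.f.ppf(1 - alpha / 2, v, n - 1)
            lower = n * (msr - f1 * mse) / (
                f1 * (k * msc + (k * n - k - n) * mse) + n * msr)
            upper = n * (f2 * msr - mse) / (
                k * msc + (k * n - k - n) * mse + n * f2 * msr)
            ci = (lower, upper)
        else:
            ci = (np.nan, np.nan)
    else:
        ci = (np.nan, np.nan)
    return IccResult(float(value), "ICC21", (float(ci[0]), float(ci[1])), n, k)


def classical_reliability_table(
    ds: TrialDataset,
    indices: tuple[str, ...] = RT_INDICES,
    n_perm: int = 5000,
    seed: int = 0,
    index_values: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Split-half + ICC(2,1)/ICC(3,1) per index and session (table-shaped).

    Split-half is the average of the test- and retest-phase estimates.  The
    ICCs are computed on subjects with an index value in both phases, from
    ``index_values`` (a tidy IndexTable; computed from ``ds`` if omitted).
    """
    from .indices import index_table

    if index_values is None:
        index_values = index_table(ds)
    sessions = sorted(ds.trials["session"].unique())
    rows = []
    for si, session in enumerate(sessions):
        for i, index in enumerate(indices):
            halves = []
            for phase in ("test", "retest"):
                try:
                    res = permutation_split_half(
                        ds, index, session, phase,
                        n_perm=n_perm, seed=seed + 1000 * i + 97 * si)
                    halves.append(res.mean_r)
                except ValueError:
                    pass
            split_half = float(np.mean(halves)) if halves else np.nan

            iv = index_values.loc[(index_values["index"] == index)
                                  & (index_values["session"] == session)]
            wide = iv.pivot_table(index="subject", columns="phase", values="value")
            row = {"session": session, "measure": index, "split_half": split_half,
                   "icc21": np.nan, "icc31": np.nan, "mean": np.nan, "n": 0}
            if {"test", "retest"}.issubset(wide.columns):
                wide = wide.dropna()
                if len(wide) >= 3:
                    mat = wide[["test", "retest"]].to_numpy()
                    row["icc21"] = icc_agreement(mat).value
                    row["icc31"] = icc_consistency(mat).value
                    row["mean"] = float(mat.mean())
                    row["n"] = len(wide)
            rows.append(row)
    return pd.DataFrame(rows)
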