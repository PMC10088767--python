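"""Within- and between-task correlation analyses of effect estimates.

Compares subject-level difference-score estimates from the mean-point-
estimate (MPE) approach and from hierarchical-Bayesian posterior means:
within-task correlations between session variants (baseline / proactive /
reactive), between-task correlations within a session, the pattern
similarity of reliabilities and within-task correlations (after Fisher
r-to-z), and a paired Wilcoxon contrast between two sets of correlations.

Estimates enter as tidy frames with columns ``subject``, ``task``,
``session`` and ``value``; every bivariate analysis uses complete pairs and
(by default) Mahalanobis bivariate-outlier screening.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .preprocessing import DEFAULT_MAHALANOBIS_CUTOFF, mahalanobis_filter

_EST_COLUMNS = {"subject", "task", "session", "value"}


def _pair_values(est: pd.DataFrame, key_a: dict, key_b: dict,
                 screen: bool, cutoff: float) -> tuple[np.ndarray, np.ndarray]:
    def pick(key):
        m = np.ones(len(est), dtype=bool)
        for col, val in key.items():
            m &= (est[col] == val).to_numpy()
        return est.loc[m, ["subject", "value"]].set_index("subject")["value"]

    a, b = pick(key_a), pick(key_b)
    joined = pd.concat([a, b], axis=1, keys=["a", "b"]).dropna()
    x = joined["a"].to_numpy(float)
    y = joined["b"].to_numpy(float)
    if screen and len(x) >= 3:
        keep = mahalanobis_filter(x, y, cutoff=cutoff)
        x, y = x[keep], y[keep]
    return x, y


def within_task_correlations(est: pd.DataFrame, screen: bool = True,
                             cutoff: float = DEFAULT_MAHALANOBIS_CUTOFF) -> pd.DataFrame:
    """Pearson r between session variants of the same task.

    One row per task x unordered session pair with at least 3 complete
    pairs after outlier screening; insufficient cells are skipped.
    """
    if not _EST_COLUMNS.issubset(est.columns):
        raise ValueError(f"estimate frame needs columns {_EST_COLUMNS}")
    rows = []
    for task in sorted(est["task"].unique()):
        sessions = sorted(est.loc[est["task"] == task, "session"].unique())
        for sa, sb in combinations(sessions, 2):
            x, y = _pair_values(est, {"task": task, "session": sa},
                                {"task": task, "session": sb}, screen, cutoff)
            if len(x) < 3:
                continue
            r = stats.pearsonr(x, y).statistic
            rows.append({"task": task, "session_a": sa, "session_b": sb,
                         "r": float(r), "n": len(x)})
    return pd.DataFrame(rows, columns=["task", "session_a", "session_b", "r", "n"])


def between_task_correlations(est: pd.DataFrame, method: str = "pearson",
                              screen: bool = True,
                              cutoff: float = DEFAULT_MAHALANOBIS_CUTOFF) -> pd.DataFrame:
    """Same-session correlations between different tasks.

    ``method`` is ``"pearson"`` (difference-score convention) or
    ``"spearman"`` (rank-based, for comprehensive index sets where
    linearity is doubtful).
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    if not _EST_COLUMNS.issubset(est.columns):
        raise ValueError(f"estimate frame needs columns {_EST_COLUMNS}")
    fn = stats.pearsonr if method == "pearson" else stats.spearmanr
    rows = []
    for session in sorted(est["session"].unique()):
        tasks = sorted(est.loc[est["session"] == session, "task"].unique())
        for ta, tb in combinations(tasks, 2):
            x, y = _pair_values(est, {"task": ta, "session": session},
                                {"task": tb, "session": session}, screen, cutoff)
            if len(x) < 3:
                continue
            r = fn(x, y).statistic if method == "pearson" else fn(x, y).statistic
            rows.append({"session": session, "task_a": ta, "task_b": tb,
                         "r": float(r), "n": len(x)})
    return pd.DataFrame(rows, columns=["session", "task_a", "task_b", "r", "n"])


def r_to_z(r):
    """Fisher transformation atanh(r); linearises correlations for comparison."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1.0):
        raise ValueError("r-to-z requires |r| < 1")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def reliability_correlation_similarity(reliabilities: pd.DataFrame,
                                       within_rs: pd.DataFrame) -> tuple[float, int]:
    """Pattern similarity of reliabilities and within-task correlations.

    ``reliabilities`` has columns (task, session, r); ``within_rs`` is the
    output of :func:`within_task_correlations`.  Each within-task
    correlation (task, session pair) is matched with the mean of the two
    sessions' r-to-z transformed reliabilities; the result is the Pearson r
    between those matched vectors (both on the z scale).
    """
    rel = reliabilities.set_index(["task", "session"])["r"]
    xs, ys = [], []
    for _, row in within_rs.iterrows():
        key_a = (row["task"], row["session_a"])
        key_b = (row["task"], row["session_b"])
        if key_a not in rel.index or key_b not in rel.index:
            continue
        xs.append(0.5 * (r_to_z(rel[key_a]) + r_to_z(rel[key_b])))
        ys.append(r_to_z(row["r"]))
    if len(xs) != len(within_rs):
        missing = len(within_rs) - len(xs)
        raise ValueError(f"{missing} within-task cell(s) lack matching reliabilities")
    if len(xs) < 3:
        raise ValueError("need >= 3 matched pairs")
    return float(stats.pearsonr(xs, ys).statistic), len(xs)


@dataclass
class CompareResult:
    statistic: float
    pvalue: float
    n: int
    degenerate: bool = False     # all paired differences were zero


def compare_estimate_sets(a, b, method: str = "approx") -> CompareResult:
    """Paired Wilcoxon signed-rank contrast of two sets of correlations.

    ``method="approx"`` uses the normal approximation with continuity
    correction (the convention for moderate samples); ``method="exact"``
    enumerates the signed-rank distribution (small n, no ties).  All-zero
    differences are degenerate: reported as p = 1 with a flag.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be paired 1-D vectors")
    if len(a) < 5:
        raise ValueError("need at least 5 pairs")
    if np.all(a == b):
        return CompareResult(0.0, 1.0, len(a), degenerate=True)
    scipy_method = {"approx": "approx", "exact": "exact"}[method]
    res = stats.wilcoxon(a, b, correction=(method == "approx"),
                         method=scipy_method, alternative="two-sided")
    return CompareResult(float(res.statistic), float(res.pvalue), len(a))
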