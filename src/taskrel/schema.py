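"""Trial-level data model for cognitive-control task batteries.

The unit of analysis is one task trial: a subject, in one task (Stroop,
AX-CPT, cued task switching, Sternberg item recognition), one session
variant (baseline / proactive / reactive control mode), one phase (test or
retest), produces a reaction time in milliseconds and an accuracy flag.
Datasets are tidy long-format tables, one row per trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TASKS = ("stroop", "axcpt", "cuedts", "sternberg")
SESSIONS = ("baseline", "proactive", "reactive")
PHASES = ("test", "retest")

#: Task-specific trial-type vocabularies.  AX-CPT no-go types (Ang/Bng) are
#: parsed but carry no reaction time and are excluded from all RT indices.
TRIAL_TYPES = {
    "stroop": ("congruent", "incongruent"),
    "axcpt": ("AX", "AY", "BX", "BY", "Ang", "Bng"),
    "cuedts": ("congruent", "incongruent"),
    "sternberg": ("NP", "NN", "RN"),
}
NOGO_TYPES = frozenset({"Ang", "Bng"})

#: Headline difference-score contrast per task:
#: (control trial type, interference trial type, index name).
CONTRASTS = {
    "stroop": ("congruent", "incongruent", "stroop_effect"),
    "axcpt": ("BY", "BX", "bx_interference"),
    "cuedts": ("congruent", "incongruent", "trce"),
    "sternberg": ("NN", "RN", "recency_effect"),
}

COLUMNS = ("subject", "task", "session", "phase",
           "trial_index", "trial_type", "rt_ms", "accuracy")

CELL_KEYS = ["subject", "task", "session", "phase", "trial_type"]


class ValidationError(ValueError):
    """Raised by strict readers on malformed trial tables."""

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        shown = "\n  ".join(self.problems[:20])
        more = "" if len(self.problems) <= 20 else f"\n  ... {len(self.problems) - 20} more"
        super().__init__(f"invalid trial table:\n  {shown}{more}")


@dataclass
class DesignSpec:
    """Expected trial counts per task x session x phase x trial type.

    ``counts`` maps ``(task, session, phase, trial_type) -> n``.  Use
    :meth:`from_session_counts` when the two phases share a design.
    """

    counts: dict[tuple[str, str, str, str], int]

    def __post_init__(self) -> None:
        for key, n in self.counts.items():
            if n < 1:
                raise ValueError(f"design count must be >= 1, got {n} for {key}")

    @classmethod
    def from_session_counts(cls, per_session: dict[tuple[str, str, str], int]) -> "DesignSpec":
        counts = {}
        for (task, session, tt), n in per_session.items():
            for phase in PHASES:
                counts[(task, session, phase, tt)] = n
        return cls(counts)


@dataclass
class TrialDataset:
    """A tidy trial table plus provenance and (optionally) its design."""

    trials: pd.DataFrame
    provenance: str = ""
    design: DesignSpec | None = None

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.trials.columns]
        if missing:
            raise ValueError(f"trial table missing columns: {missing}")
        self.trials = self.trials.loc[:, list(COLUMNS)].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.trials)

    def copy(self) -> "TrialDataset":
        return TrialDataset(self.trials.copy(), self.provenance, self.design)


@dataclass
class ValidationReport:
    ok: bool
    problems: list[str]
    cell_counts: pd.DataFrame
    response_rate: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        head = "OK" if self.ok else f"{len(self.problems)} problem(s)"
        return f"ValidationReport({head}, {len(self.cell_counts)} cells)"


def _find_problems(df: pd.DataFrame) -> list[str]:
    problems: list[str] = []
    bad_task = ~df["task"].isin(TASKS)
    for row in df.index[bad_task]:
        problems.append(f"row {row}: unknown task {df.at[row, 'task']!r}")
    bad_session = ~df["session"].isin(SESSIONS)
    for row in df.index[bad_session]:
        problems.append(f"row {row}: unknown session {df.at[row, 'session']!r}")
    bad_phase = ~df["phase"].isin(PHASES)
    for row in df.index[bad_phase]:
        problems.append(f"row {row}: unknown phase {df.at[row, 'phase']!r}")

    ok_rows = ~(bad_task | bad_session | bad_phase)
    sub = df.loc[ok_rows]
    for task, vocab in TRIAL_TYPES.items():
        mask = (sub["task"] == task) & ~sub["trial_type"].isin(vocab)
        for row in sub.index[mask]:
            problems.append(
                f"row {row}: trial_type {sub.at[row, 'trial_type']!r} "
                f"not in vocabulary of task {task!r}"
            )

    rt = df["rt_ms"]
    bad_rt = rt.notna() & (rt <= 0)
    for row in df.index[bad_rt]:
        problems.append(f"row {row}: rt_ms must be > 0 when present, got {rt[row]}")

    bad_acc = ~df["accuracy"].isin((0, 1))
    for row in df.index[bad_acc]:
        problems.append(f"row {row}: accuracy must be 0 or 1, got {df.at[row, 'accuracy']}")

    dup = df.duplicated(
        subset=["subject", "task", "session", "phase", "trial_index"], keep=False
    )
    if dup.any():
        rows = list(df.index[dup])
        problems.append(f"duplicate (subject, task, session, phase, trial_index) keys at rows {rows}")
    return problems


def read_trial_table(
    path,
    sep: str | None = None,
    column_map: dict[str, str] | None = None,
    provenance: str | None = None,
    design: DesignSpec | None = None,
) -> TrialDataset:
    """Read a delimited trial table into a validated :class:`TrialDataset`.

    Parameters
    ----------
    path : str or Path
        CSV/TSV file with a header row.  Header names are matched
        case-insensitively against the canonical column names.
    sep : str, optional
        Field delimiter; inferred (``\\t`` for ``.tsv``, else ``,``) if omitted.
    column_map : dict, optional
        Mapping of canonical name -> file column name, for files whose
        headers differ from the canonical vocabulary.

    Missing reaction times (non-responses) may be encoded as empty fields or
    ``NA``; they are stored as missing values, never as zero.
    """
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    raw = pd.read_csv(path, sep=sep)
    raw.columns = [str(c).strip().lower() for c in raw.columns]
    rename = {}
    if column_map:
        rename.update({v.lower(): k for k, v in column_map.items()})
    raw = raw.rename(columns=rename)
    missing = [c for c in COLUMNS if c not in raw.columns]
    if missing:
        raise ValidationError([f"file is missing required columns: {missing}"])
    df = raw.loc[:, list(COLUMNS)].copy()
    df["rt_ms"] = pd.to_numeric(df["rt_ms"], errors="coerce")
    df["accuracy"] = pd.to_numeric(df["accuracy"], errors="coerce")
    df["trial_index"] = pd.to_numeric(df["trial_index"], errors="coerce")
    problems = _find_problems(df)
    if len(df) == 0:
        problems.insert(0, "trial table is empty")
    if problems:
        raise ValidationError(problems)
    df["accuracy"] = df["accuracy"].astype(np.int64)
    df["trial_index"] = df["trial_index"].astype(np.int64)
    return TrialDataset(df, provenance=provenance or f"read from {path}", design=design)


def write_trial_table(ds: TrialDataset, path, sep: str = ",") -> None:
    """Write a dataset as delimited text (UTF-8, header row, NA for missing RT)."""
    ds.trials.to_csv(path, sep=sep, index=False, na_rep="NA")


def validate_dataset(ds: TrialDataset, design: DesignSpec | None = None) -> ValidationReport:
    """Total validation: always returns a report, never raises.

    The report carries per-cell trial counts, per-cell response rates
    (fraction of trials with a recorded reaction time; no-go trial types are
    ignored for response rate), any vocabulary/range violations, and -- when
    a :class:`DesignSpec` is available -- count mismatches against it.
    """
    df = ds.trials
    problems = _find_problems(df)
    if len(df) == 0:
        problems.insert(0, "dataset is empty")
        return ValidationReport(False, problems, pd.DataFrame(), pd.DataFrame())

    counts = (
        df.groupby(["subject", "task", "session", "phase", "trial_type"], sort=True)
        .agg(n_trials=("trial_index", "size"), n_missing_rt=("rt_ms", lambda s: int(s.isna().sum())))
        .reset_index()
    )

    go = df[~df["trial_type"].isin(NOGO_TYPES)]
    response_rate = (
        go.assign(responded=go["rt_ms"].notna())
        .groupby(["subject", "task", "session", "phase"])["responded"]
        .mean()
        .rename("response_rate")
        .reset_index()
    )

    spec = design or ds.design
    if spec is not None:
        observed = counts.set_index(["task", "session", "phase", "trial_type"]).sort_index()
        for (task, session, phase, tt), expected in spec.counts.items():
            try:
                got = observed.loc[(task, session, phase, tt), "n_trials"]
            except KeyError:
                problems.append(f"design cell {(task, session, phase, tt)} absent from data")
                continue
            got = np.atleast_1d(np.asarray(got))
            bad = got != expected
            if bad.any():
                problems.append(
                    f"design cell {(task, session, phase, tt)}: expected {expected} "
                    f"trials/subject, observed counts include {sorted(set(got[bad]))}"
                )
    return ValidationReport(len(problems) == 0, problems, counts, response_rate)
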