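"""Synthetic trial-level battery data with known ground truth.

The generator runs the hierarchical lognormal model forward: subject-level
location and log-spread parameters are drawn from a multivariate normal
construction with a controllable cross-phase correlation of the
difference-score parameter delta (the ground-truth test-retest
reliability), trial reaction times are lognormal around them, and accuracy
is Bernoulli per trial type.  It emulates a battery of four tasks (Stroop,
AX-CPT, cued task switching, Sternberg) x three session variants
(baseline / proactive / reactive) x two phases (test / retest), with
right-skewed trial RT distributions, subject-specific location and spread,
and task-specific trial-type vocabularies.

Correlation structure (exact, by construction)
----------------------------------------------
With g a battery-general factor, q a task factor, s a session factor and
e phase noise, all iid standard normal::

    L[i,task,ses]        = sqrt(ct) g + sqrt(wt - ct) q + sqrt(1 - wt) s
    delta[i,task,ses,ph] = delta_mean + delta_sd * (sqrt(rho) L + sqrt(1-rho) e)

so corr(delta_test, delta_retest) = rho (the target reliability),
corr across sessions within a task = rho * wt, and corr across tasks
= rho * ct (``ct = cross_task_coupling``, ``wt = within_task_coupling``).
Base log-locations and log-spreads get analogous shared-plus-jitter
structure so the implied 4x4 cell covariances are non-singular.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .schema import (CONTRASTS, DesignSpec, PHASES, SESSIONS, TASKS,
                     TRIAL_TYPES, TrialDataset)

#: Typical correct-RT scale per task (log-seconds of the control condition).
DEFAULT_BASE_LOG_MEAN = {
    "stroop": math.log(0.75),
    "axcpt": math.log(0.50),
    "cuedts": math.log(0.85),
    "sternberg": math.log(0.85),
}

#: Headline effect magnitudes (ms) used to set the group delta means; loosely
#: motivated by published battery means (e.g. a ~137 ms baseline Stroop
#: effect), with no claim of matching any particular population.
DEFAULT_EFFECT_MS = {
    ("stroop", "baseline"): 137, ("stroop", "proactive"): 83, ("stroop", "reactive"): 93,
    ("axcpt", "baseline"): 75, ("axcpt", "proactive"): 51, ("axcpt", "reactive"): 125,
    ("cuedts", "baseline"): 77, ("cuedts", "proactive"): 62, ("cuedts", "reactive"): 94,
    ("sternberg", "baseline"): 117, ("sternberg", "proactive"): 169, ("sternberg", "reactive"): 85,
}

#: Location offsets (log units, relative to the control condition) for trial
#: types outside the headline contrast pair.
DEFAULT_TYPE_OFFSETS = {
    ("axcpt", "AX"): -0.08,
    ("axcpt", "AY"): 0.10,
    ("sternberg", "NP"): -0.02,
}

DEFAULT_ERROR_RATES = {
    ("stroop", "congruent"): 0.02, ("stroop", "incongruent"): 0.05,
    ("axcpt", "AX"): 0.03, ("axcpt", "AY"): 0.12,
    ("axcpt", "BX"): 0.08, ("axcpt", "BY"): 0.02,
    ("cuedts", "congruent"): 0.04, ("cuedts", "incongruent"): 0.09,
    ("sternberg", "NP"): 0.05, ("sternberg", "NN"): 0.05, ("sternberg", "RN"): 0.12,
}


def default_trial_counts(tasks=TASKS, sessions=SESSIONS) -> dict:
    """Battery-like per-phase trial counts.

    The Sternberg recent-negative cell is deliberately sparse (8 trials in
    the baseline and proactive sessions, with the scarcity moving to novel
    negatives in the reactive session); other counts are declared
    approximations of a plausible battery design.
    """
    counts = {}
    per_task = {
        "stroop": {"congruent": 36, "incongruent": 36},
        "axcpt": {"AX": 32, "AY": 8, "BX": 8, "BY": 16},
        "cuedts": {"congruent": 32, "incongruent": 32},
        "sternberg": {"NP": 24, "NN": 24, "RN": 8},
    }
    for task in tasks:
        for session in sessions:
            tt_counts = dict(per_task[task])
            if task == "sternberg" and session == "reactive":
                tt_counts = {"NP": 24, "NN": 8, "RN": 24}
            for tt, n in tt_counts.items():
                counts[(task, session, tt)] = n
    return counts


@dataclass
class GroundTruth:
    """Generating parameters of a synthetic battery study.

    All location parameters are on the log-seconds scale.  ``rho_delta`` is
    the true cross-phase correlation of the subject-level difference-score
    parameter -- the ground-truth test-retest reliability that estimators
    are judged against.
    """

    seed: int
    n_subjects: int = 120
    tasks: tuple = TASKS
    sessions: tuple = SESSIONS
    base_log_mean: dict = field(default_factory=lambda: dict(DEFAULT_BASE_LOG_MEAN))
    base_sd: float = 0.15
    base_stability: float = 0.9
    base_session_stability: float = 0.6
    delta_mean: dict = field(default_factory=dict)
    delta_sd: float = 0.065
    rho_delta: float = 0.8
    within_task_coupling: float = 0.6
    cross_task_coupling: float = 0.0
    sigma_mean: float = math.log(0.13)
    sigma_sd: float = 0.20
    sigma_stability: float = 0.8
    trial_counts: dict = field(default_factory=dict)
    error_rates: dict = field(default_factory=lambda: dict(DEFAULT_ERROR_RATES))
    type_offsets: dict = field(default_factory=lambda: dict(DEFAULT_TYPE_OFFSETS))
    miss_rate: float = 0.0

    def __post_init__(self) -> None:
        if not -1.0 <= self.rho_delta <= 1.0:
            raise ValueError("rho_delta must lie in [-1, 1]")
        if not 0.0 <= self.cross_task_coupling <= self.within_task_coupling <= 1.0:
            raise ValueError(
                "need 0 <= cross_task_coupling <= within_task_coupling <= 1 "
                "(otherwise the latent correlation structure is not positive definite)")
        for name in ("base_sd", "sigma_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.delta_sd < 0:
            raise ValueError("delta_sd must be >= 0")
        for name in ("base_stability", "base_session_stability", "sigma_stability"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError("stability shares must lie in [0, 1]")
        if not self.delta_mean:
            self.delta_mean = {
                (task, session): math.log1p(
                    DEFAULT_EFFECT_MS[(task, session)] / 1000.0
                    / math.exp(self.base_log_mean[task]))
                for task in self.tasks for session in self.sessions
            }
        if not self.trial_counts:
            self.trial_counts = default_trial_counts(self.tasks, self.sessions)
        for key, n in self.trial_counts.items():
            if n < 1:
                raise ValueError(f"trial count must be >= 1 for {key}")
        if not 0.0 <= self.miss_rate < 1.0:
            raise ValueError("miss_rate must lie in [0, 1)")

    @classmethod
    def single_cell(cls, seed: int, task: str = "stroop", session: str = "baseline",
                    n_subjects: int = 60, n_trials: int = 48, **overrides) -> "GroundTruth":
        """Truth restricted to one task x session (the unit the model fits)."""
        control, interference, _ = CONTRASTS[task]
        counts = {(task, session, control): n_trials,
                  (task, session, interference): n_trials}
        return cls(seed=seed, tasks=(task,), sessions=(session,),
                   n_subjects=n_subjects, trial_counts=counts, **overrides)

    def design_spec(self) -> DesignSpec:
        return DesignSpec.from_session_counts(dict(self.trial_counts))

    def to_json(self, path) -> None:
        payload = asdict(self)
        for key in ("delta_mean", "trial_counts", "error_rates", "type_offsets",
                    "base_log_mean"):
            value = payload[key]
            payload[key] = {("|".join(k) if isinstance(k, tuple) else k): v
                            for k, v in value.items()}
        payload["tasks"] = list(self.tasks)
        payload["sessions"] = list(self.sessions)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        for key in ("delta_mean", "trial_counts", "error_rates", "type_offsets"):
            payload[key] = {tuple(k.split("|")): v for k, v in payload[key].items()}
        payload["tasks"] = tuple(payload["tasks"])
        payload["sessions"] = tuple(payload["sessions"])
        return cls(**payload)


@dataclass
class SimulatedStudy:
    dataset: TrialDataset
    truth: GroundTruth
    true_deltas: pd.DataFrame     # subject, task, session, delta_test, delta_retest
    flags: list = field(default_factory=list)


def _subject_ids(n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"s{i:0{width}d}" for i in range(1, n + 1)]


def _latents(truth: GroundTruth, rng: np.random.Generator):
    """Subject-level parameters, drawn in a fixed order for determinism."""
    N, T, S = truth.n_subjects, len(truth.tasks), len(truth.sessions)
    ct, wt = truth.cross_task_coupling, truth.within_task_coupling
    g = rng.standard_normal(N)
    q = rng.standard_normal((N, T))
    s_lat = rng.standard_normal((N, T, S))
    e_phase = rng.standard_normal((N, T, S, 2))
    B = rng.standard_normal((N, T))
    C = rng.standard_normal((N, T, S))
    eta = rng.standard_normal((N, T, S, 2))
    z_sig = rng.standard_normal((N, T))
    zeta = rng.standard_normal((N, T, S, 2, 2))

    L = (math.sqrt(ct) * g[:, None, None]
         + math.sqrt(wt - ct) * q[:, :, None]
         + math.sqrt(1.0 - wt) * s_lat)
    rho = truth.rho_delta
    dmean = np.array([[truth.delta_mean[(task, ses)] for ses in truth.sessions]
                      for task in truth.tasks])
    delta = dmean[None, :, :, None] + truth.delta_sd * (
        math.sqrt(rho) * L[..., None] + math.sqrt(1.0 - rho) * e_phase)

    # Base speed: a task-level trait shared across session variants only
    # partially (the variants are distinct task contexts run in different
    # weeks), plus phase jitter within a variant.
    bs, bss = truth.base_stability, truth.base_session_stability
    base = np.array([truth.base_log_mean[task] for task in truth.tasks])
    stable = math.sqrt(bss) * B[:, :, None] + math.sqrt(1.0 - bss) * C
    b = base[None, :, None, None] + truth.base_sd * (
        math.sqrt(bs) * stable[..., None] + math.sqrt(1.0 - bs) * eta)

    ss = truth.sigma_stability
    sigma = truth.sigma_mean + truth.sigma_sd * (
        math.sqrt(ss) * z_sig[:, :, None, None, None]
        + math.sqrt(1.0 - ss) * zeta)
    return b, delta, sigma


def simulate_study(truth: GroundTruth) -> SimulatedStudy:
    """Draw a full synthetic study; bit-reproducible from (truth, seed)."""
    rng = np.random.default_rng(truth.seed)
    subjects = _subject_ids(truth.n_subjects)
    b, delta, sigma = _latents(truth, rng)
    flags = []
    if truth.delta_sd == 0:
        flags.append("degenerate_delta: all subjects share one delta; "
                     "true reliability undefined")

    cols = {name: [] for name in ("subject", "task", "session", "phase",
                                  "trial_index", "trial_type", "rt_ms", "accuracy")}
    N = truth.n_subjects
    for ti, task in enumerate(truth.tasks):
        control, interference, _ = CONTRASTS[task]
        for si, session in enumerate(truth.sessions):
            types = [tt for tt in TRIAL_TYPES[task]
                     if (task, session, tt) in truth.trial_counts]
            for pi, phase in enumerate(PHASES):
                offset = 0
                for tt in types:
                    n = truth.trial_counts[(task, session, tt)]
                    if tt == interference:
                        mu = b[:, ti, si, pi] + delta[:, ti, si, pi]
                        cond = 1
                    elif tt == control:
                        mu = b[:, ti, si, pi]
                        cond = 0
                    else:
                        mu = b[:, ti, si, pi] + truth.type_offsets.get((task, tt), 0.0)
                        cond = 0
                    sdlog = np.exp(sigma[:, ti, si, pi, cond])
                    z = rng.standard_normal((N, n))
                    rt_ms = 1000.0 * np.exp(mu[:, None] + sdlog[:, None] * z)
                    err_p = truth.error_rates.get((task, tt), 0.05)
                    acc = (rng.random((N, n)) >= err_p).astype(np.int64)
                    if truth.miss_rate > 0:
                        missing = rng.random((N, n)) < truth.miss_rate
                        rt_ms = np.where(missing, np.nan, rt_ms)
                        acc = np.where(missing, 0, acc)
                    cols["subject"].append(np.repeat(subjects, n))
                    cols["task"].append(np.full(N * n, task))
                    cols["session"].append(np.full(N * n, session))
                    cols["phase"].append(np.full(N * n, phase))
                    cols["trial_index"].append(np.tile(np.arange(offset, offset + n), N))
                    cols["trial_type"].append(np.full(N * n, tt))
                    cols["rt_ms"].append(rt_ms.ravel())
                    cols["accuracy"].append(acc.ravel())
                    offset += n

    df = pd.DataFrame({name: np.concatenate(parts) for name, parts in cols.items()})
    df["trial_index"] = df["trial_index"].astype(np.int64)
    df["accuracy"] = df["accuracy"].astype(np.int64)
    dataset = TrialDataset(df, provenance=f"simulated battery, seed={truth.seed}",
                           design=truth.design_spec())

    rows = []
    for ti, task in enumerate(truth.tasks):
        for si, session in enumerate(truth.sessions):
            rows.append(pd.DataFrame({
                "subject": subjects, "task": task, "session": session,
                "delta_test": delta[:, ti, si, 0],
                "delta_retest": delta[:, ti, si, 1],
            }))
    true_deltas = pd.concat(rows, ignore_index=True)
    return SimulatedStudy(dataset, truth, true_deltas, flags)


def simulate_mpe_difference_scores(truth: GroundTruth, task: str, session: str,
                                   n_studies: int, seed: int) -> np.ndarray:
    """Fast path: MPE difference scores (ms) for replicate studies.

    Returns an (n_studies, n_subjects, 2) array of mean-point-estimate
    difference scores (interference minus control mean RT) for the test and
    retest phases, drawn from the same generative construction as
    :func:`simulate_study` but skipping the trial-table plumbing.  Used for
    Monte-Carlo validation of :func:`attenuation_oracle`.
    """
    rng = np.random.default_rng(seed)
    control, interference, _ = CONTRASTS[task]
    n_con = truth.trial_counts[(task, session, control)]
    n_int = truth.trial_counts[(task, session, interference)]
    K, N = n_studies, truth.n_subjects
    rho, bs, ss = truth.rho_delta, truth.base_stability, truth.sigma_stability

    L = rng.standard_normal((K, N))
    e = rng.standard_normal((K, N, 2))
    delta = truth.delta_mean[(task, session)] + truth.delta_sd * (
        math.sqrt(rho) * L[..., None] + math.sqrt(1 - rho) * e)
    B = rng.standard_normal((K, N))
    eta = rng.standard_normal((K, N, 2))
    b = truth.base_log_mean[task] + truth.base_sd * (
        math.sqrt(bs) * B[..., None] + math.sqrt(1 - bs) * eta)
    z = rng.standard_normal((K, N))
    zeta = rng.standard_normal((K, N, 2, 2))
    sigma = truth.sigma_mean + truth.sigma_sd * (
        math.sqrt(ss) * z[..., None, None] + math.sqrt(1 - ss) * zeta)

    out = np.empty((K, N, 2))
    for p in range(2):
        sd_con = np.exp(sigma[:, :, p, 0])
        sd_int = np.exp(sigma[:, :, p, 1])
        con = np.exp(b[:, :, p, None] + sd_con[..., None]
                     * rng.standard_normal((K, N, n_con))).mean(axis=-1)
        intf = np.exp(b[:, :, p, None] + delta[:, :, p, None] + sd_int[..., None]
                      * rng.standard_normal((K, N, n_int))).mean(axis=-1)
        out[:, :, p] = 1000.0 * (intf - con)
    return out


def attenuation_oracle(truth: GroundTruth, task: str | None = None,
                       session: str | None = None, n_mc: int = 200_000) -> float:
    """Expected MPE test-retest correlation under trial-sampling noise.

    Computes r = cov(m_test, m_retest) / sqrt(prod_p [var(m_p) + vbar_p]),
    where m_p is a subject's true expected millisecond difference score in
    phase p, var/cov are over the subject-parameter distribution (evaluated
    by a large deterministic Monte Carlo sample of subject parameters), and
    vbar_p is the mean trial-sampling variance of the per-subject mean
    difference -- the analytic lognormal variance of a mean,
    Var(RT)/n = (exp(w) - 1) exp(2 mu + w)/n with w = exp(sigma)^2, summed
    over the two conditions.  In the small-effect linear regime this
    reduces to rho_delta * var(delta) / (var(delta) + vbar): reliability is
    the true correlation attenuated by the trial-noise share of variance.

    Returns NaN when ``delta_sd`` is zero (no between-subject signal).
    """
    task = task or truth.tasks[0]
    session = session or truth.sessions[0]
    if truth.delta_sd == 0:
        return float("nan")
    control, interference, _ = CONTRASTS[task]
    n_con = truth.trial_counts[(task, session, control)]
    n_int = truth.trial_counts[(task, session, interference)]
    rng = np.random.default_rng(202301)   # fixed: the oracle is deterministic
    rho, bs, ss = truth.rho_delta, truth.base_stability, truth.sigma_stability

    L = rng.standard_normal(n_mc)
    e = rng.standard_normal((n_mc, 2))
    delta = truth.delta_mean[(task, session)] + truth.delta_sd * (
        math.sqrt(rho) * L[:, None] + math.sqrt(1 - rho) * e)
    B = rng.standard_normal(n_mc)
    eta = rng.standard_normal((n_mc, 2))
    b = truth.base_log_mean[task] + truth.base_sd * (
        math.sqrt(bs) * B[:, None] + math.sqrt(1 - bs) * eta)
    z = rng.standard_normal(n_mc)
    zeta = rng.standard_normal((n_mc, 2, 2))
    sigma = truth.sigma_mean + truth.sigma_sd * (
        math.sqrt(ss) * z[:, None, None] + math.sqrt(1 - ss) * zeta)

    w = np.exp(sigma) ** 2                               # (n_mc, 2, 2): phase, cond
    mu_con = b                                           # (n_mc, 2)
    mu_int = b + delta
    mean_con = np.exp(mu_con + w[:, :, 0] / 2.0)
    mean_int = np.exp(mu_int + w[:, :, 1] / 2.0)
    m = 1000.0 * (mean_int - mean_con)                   # true ms difference, per phase

    var_con = (np.exp(w[:, :, 0]) - 1.0) * np.exp(2 * mu_con + w[:, :, 0])
    var_int = (np.exp(w[:, :, 1]) - 1.0) * np.exp(2 * mu_int + w[:, :, 1])
    v_noise = 1000.0 ** 2 * (var_int / n_int + var_con / n_con)

    cov = np.cov(m[:, 0], m[:, 1])[0, 1]
    denom = math.sqrt((m[:, 0].var(ddof=1) + v_noise[:, 0].mean())
                      * (m[:, 1].var(ddof=1) + v_noise[:, 1].mean()))
    return float(cov / denom)


def make_fixture(profile: str, seed: int | None = None) -> SimulatedStudy:
    """Seeded study fixtures.

    ``tiny``: 12 subjects, 16 trials in every cell -- fast integration
    checks.  ``battery``: 120 subjects with battery-like trial counts
    (including the 8-trial Sternberg baseline recent-negative cell) and a
    1% non-response rate.
    """
    if profile == "tiny":
        counts = {(task, session, tt): 16
                  for task in TASKS for session in SESSIONS
                  for tt in TRIAL_TYPES[task] if tt not in ("Ang", "Bng")}
        truth = GroundTruth(seed=7 if seed is None else seed, n_subjects=12,
                            trial_counts=counts)
    elif profile == "battery":
        truth = GroundTruth(seed=42 if seed is None else seed, n_subjects=120,
                            miss_rate=0.01)
    else:
        raise ValueError(f"unknown profile {profile!r}")
    return simulate_study(truth)
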