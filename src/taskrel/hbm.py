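"""Hierarchical Bayesian lognormal model of trial-level reaction times.

Model
-----
For subject i, condition c in {control, interference} and phase p in
{test, retest} (four cells per subject), correct-trial reaction times in
seconds are lognormal::

    RT[i,c,p] ~ Lognormal(mu[i,c,p], exp(sigma[i,c,p]))

so ``mu`` is the location of log RT (log median, log-seconds) and
``exp(sigma)`` is the trial-level sd of log RT.  The four-vectors of
individual locations and log-spreads are each drawn from group-level
multivariate normals with unknown means and covariances::

    mu[i,:]    ~ MVNormal(mu_mean,    S_mu)
    sigma[i,:] ~ MVNormal(sigma_mean, S_sigma)

Priors: Normal(0, 1) on the group means, Half-Normal(0, 1) on the group
sds, and a prior uniform over valid correlation matrices on each 4x4
correlation matrix (each covariance is decomposed as diag(sd) R diag(sd)).

The difference-score parameter is the log-scale location contrast
``delta[i,p] = mu[i,interference,p] - mu[i,control,p]`` (a log median
ratio, not a millisecond difference); test-retest reliability is the
per-MCMC-draw Pearson correlation of delta across subjects between phases,
giving a posterior distribution of reliabilities.

Sampling
--------
A Metropolis-within-Gibbs scheme: the individual locations and both group
mean vectors have conjugate Gaussian full conditionals and are drawn
exactly; individual log-spreads use component-wise random-walk Metropolis
(vectorised over subjects); group sds (on the log scale, with Jacobian)
and correlation matrices use adaptive joint random-walk Metropolis with
positive-definiteness rejection.  Step sizes adapt only during warmup.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CELLS = ("control_test", "control_retest", "interference_test", "interference_retest")
_IDX_CONTROL_TEST, _IDX_CONTROL_RETEST = 0, 1
_IDX_INTERF_TEST, _IDX_INTERF_RETEST = 2, 3
_OFFDIAG = np.triu_indices(4, k=1)


@dataclass
class HbmSpec:
    """MCMC configuration.  ``seed`` is required for every fit."""

    seed: int
    chains: int = 3
    warmup: int = 1000
    draws: int = 3000
    rhat_threshold: float = 1.01
    ess_threshold: float = 400.0

    def __post_init__(self) -> None:
        if self.chains < 1 or self.warmup < 1 or self.draws < 1:
            raise ValueError("chains, warmup and draws must be positive")

    @classmethod
    def reduced(cls, seed: int, chains: int = 2, warmup: int = 500, draws: int = 1000) -> "HbmSpec":
        """Scaled-down configuration used by the test-suite simulations."""
        return cls(seed=seed, chains=chains, warmup=warmup, draws=draws)


@dataclass
class CellData:
    """Per-subject sufficient statistics of log RT (seconds) in the 4 cells."""

    subjects: list
    n: np.ndarray      # (N, 4) trial counts
    s1: np.ndarray     # (N, 4) sums of log RT
    s2: np.ndarray     # (N, 4) sums of squared log RT
    dropped: list      # subjects lacking trials in some cell

    @property
    def ybar(self) -> np.ndarray:
        return self.s1 / self.n

    def cell_sd(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            var = (self.s2 - self.n * self.ybar ** 2) / np.maximum(self.n - 1, 1)
        return np.sqrt(np.clip(var, 1e-6, None))


def prepare_cell_data(ds, task: str, session: str, min_subjects: int = 5) -> CellData:
    """Extract correct-trial log RTs (converted ms -> seconds) for one fit.

    Subjects must have at least one correct trial in all four condition x
    phase cells; others are dropped and listed on the result.
    """
    from .schema import CONTRASTS

    control, interference, _ = CONTRASTS[task]
    df = ds.trials
    mask = ((df["task"] == task) & (df["session"] == session)
            & (df["accuracy"] == 1) & df["rt_ms"].notna()
            & df["trial_type"].isin((control, interference)))
    sub = df.loc[mask].copy()
    sub["_cell"] = (np.where(sub["trial_type"] == interference, 2, 0)
                    + np.where(sub["phase"] == "retest", 1, 0))
    sub["_y"] = np.log(sub["rt_ms"].to_numpy(float) / 1000.0)

    agg = sub.groupby(["subject", "_cell"])["_y"].agg(["size", "sum", lambda v: (v ** 2).sum()])
    agg.columns = ["n", "s1", "s2"]
    wide_n = agg["n"].unstack("_cell").reindex(columns=range(4))
    complete = wide_n.notna().all(axis=1)
    subjects = sorted(wide_n.index[complete])
    dropped = sorted(wide_n.index[~complete])
    if len(subjects) < min_subjects:
        raise ValueError(
            f"hierarchical fit needs >= {min_subjects} subjects with trials in all "
            f"four cells of {task}/{session}; have {len(subjects)}")
    n = wide_n.loc[subjects].to_numpy(float)
    s1 = agg["s1"].unstack("_cell").loc[subjects, range(4)].to_numpy(float)
    s2 = agg["s2"].unstack("_cell").loc[subjects, range(4)].to_numpy(float)
    return CellData(list(subjects), n, s1, s2, list(dropped))


@dataclass
class PosteriorDraws:
    """MCMC draws, shaped (chains, draws, ...), plus fit metadata."""

    mu: np.ndarray           # (C, D, N, 4) individual log-locations
    sigma: np.ndarray        # (C, D, N, 4) individual log-spreads (pre-exponentiation)
    mu_mean: np.ndarray      # (C, D, 4) group means of mu
    sigma_mean: np.ndarray   # (C, D, 4)
    mu_sd: np.ndarray        # (C, D, 4) group sds of mu
    sigma_sd: np.ndarray     # (C, D, 4)
    mu_corr: np.ndarray      # (C, D, 6) upper-triangle correlations of S_mu
    sigma_corr: np.ndarray   # (C, D, 6)
    subjects: list
    task: str
    session: str
    spec: HbmSpec
    accept_rates: dict = field(default_factory=dict)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def to_inference_data(self):
        """Package the draws as an arviz InferenceData (e.g. for NetCDF export)."""
        import arviz as az

        coords = {"subject": self.subjects, "cell": list(CELLS),
                  "pair": [f"{CELLS[i]}|{CELLS[j]}" for i, j in zip(*_OFFDIAG)]}
        dims = {"mu": ["subject", "cell"], "sigma": ["subject", "cell"],
                "mu_mean": ["cell"], "sigma_mean": ["cell"],
                "mu_sd": ["cell"], "sigma_sd": ["cell"],
                "mu_corr": ["pair"], "sigma_corr": ["pair"]}
        posterior = {name: getattr(self, name) for name in dims}
        return az.from_dict(posterior=posterior, coords=coords, dims=dims,
                            attrs={"task": self.task, "session": self.session,
                                   "seed": self.spec.seed})


def _mvn_sum_logpdf(x: np.ndarray, m: np.ndarray, sd: np.ndarray, corr: np.ndarray) -> float:
    """Sum over rows of log MVN(x_i; m, diag(sd) corr diag(sd)), const dropped."""
    S = corr * np.outer(sd, sd)
    try:
        L = np.linalg.cholesky(S)
    except np.linalg.LinAlgError:
        return -np.inf
    dev = x - m
    z = np.linalg.solve(L, dev.T)
    logdet = 2.0 * np.log(np.diag(L)).sum()
    return -0.5 * (x.shape[0] * logdet + (z ** 2).sum())


def _corr_from_offdiag(v: np.ndarray) -> np.ndarray:
    R = np.eye(4)
    R[_OFFDIAG] = v
    R[(_OFFDIAG[1], _OFFDIAG[0])] = v
    return R


# Correlation matrices are sampled through canonical partial correlations
# (vine parameterisation): every point of (-1, 1)^6 maps to a valid
# positive-definite correlation matrix, so component-wise Metropolis moves
# are never blocked by the positive-definiteness constraint.  The prior
# uniform over correlation matrices factorises into independent symmetric
# Beta densities on the partials: (1 - p^2)^(b - 1) with b = 1 + (d-1-lag)/2.
_PC_LAGS = _OFFDIAG[1] - _OFFDIAG[0]
_PC_BETA = 1.0 + (4.0 - 1.0 - _PC_LAGS) / 2.0


def _pc_to_corr(pc: np.ndarray) -> np.ndarray:
    """Map the 6 canonical partial correlations to a 4x4 correlation matrix."""
    P = _corr_from_offdiag(pc)
    R = np.eye(4)
    for i in range(3):
        R[i, i + 1] = R[i + 1, i] = P[i, i + 1]
    for lag in (2, 3):
        for i in range(4 - lag):
            j = i + lag
            S = list(range(i + 1, j))
            R2 = R[np.ix_(S, S)]
            r1 = np.linalg.solve(R2, R[i, S])
            r3 = R[j, S]
            c1 = 1.0 - r1 @ R[i, S]
            c3 = 1.0 - r3 @ np.linalg.solve(R2, r3)
            R[i, j] = R[j, i] = P[i, j] * math.sqrt(max(c1 * c3, 0.0)) + r1 @ r3
    return R


def _corr_to_pc(R: np.ndarray) -> np.ndarray:
    """Inverse of :func:`_pc_to_corr` (used only for initialisation)."""
    P = np.eye(4)
    for i in range(3):
        P[i, i + 1] = R[i, i + 1]
    for lag in (2, 3):
        for i in range(4 - lag):
            j = i + lag
            S = list(range(i + 1, j))
            R2 = R[np.ix_(S, S)]
            r1 = np.linalg.solve(R2, R[i, S])
            r3 = R[j, S]
            c1 = 1.0 - r1 @ R[i, S]
            c3 = 1.0 - r3 @ np.linalg.solve(R2, r3)
            P[i, j] = (R[i, j] - r1 @ r3) / max(math.sqrt(max(c1 * c3, 1e-12)), 1e-12)
    return np.clip(P[_OFFDIAG], -0.99, 0.99)


def _invwishart_rvs(df: float, psi: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One inverse-Wishart(df, psi) draw via the Bartlett decomposition."""
    d = psi.shape[0]
    L = np.linalg.cholesky(np.linalg.inv(psi))
    A = np.zeros((d, d))
    for i in range(d):
        A[i, i] = math.sqrt(rng.chisquare(df - i))
        A[i, :i] = rng.standard_normal(i)
    W = L @ A @ A.T @ L.T
    return np.linalg.inv(W)


def _precision(sd: np.ndarray, corr: np.ndarray) -> tuple[np.ndarray, float]:
    S = corr * np.outer(sd, sd)
    P = np.linalg.inv(S)
    return 0.5 * (P + P.T), float(np.linalg.slogdet(S)[1])


class _Adapt:
    """Robbins-Monro step-size adaptation toward a target acceptance rate."""

    def __init__(self, step: float, target: float):
        self.step = step
        self.target = target
        self.t = 0

    def update(self, accept_rate: float) -> None:
        self.t += 1
        self.step *= math.exp((accept_rate - self.target) / math.sqrt(self.t))
        self.step = min(max(self.step, 1e-4), 10.0)


def _run_chain(data: CellData, warmup: int, draws: int, rng: np.random.Generator) -> dict:
    N = data.n.shape[0]
    n, s1, s2 = data.n, data.s1, data.s2

    # Empirical initialisation with chain-specific jitter.
    mu = data.ybar + 0.05 * rng.standard_normal((N, 4))
    sig = np.log(data.cell_sd()) + 0.05 * rng.standard_normal((N, 4))
    m_mu = mu.mean(axis=0)
    m_sig = sig.mean(axis=0)
    tau_mu = np.clip(mu.std(axis=0, ddof=1), 0.05, None)
    tau_sig = np.clip(sig.std(axis=0, ddof=1), 0.05, None)

    def _init_corr(x):
        R = np.corrcoef(x, rowvar=False)
        R = np.nan_to_num(R, nan=0.0)
        R = 0.8 * R + 0.2 * np.eye(4)
        return 0.5 * (R + R.T)

    pc_mu = _corr_to_pc(_init_corr(mu))
    pc_sig = _corr_to_pc(_init_corr(sig))
    R_mu = _pc_to_corr(pc_mu)
    R_sig = _pc_to_corr(pc_sig)

    adapt_sig = [_Adapt(1.0, 0.30)]
    adapt_tau = {"mu": [_Adapt(0.2, 0.44) for _ in range(4)],
                 "sig": [_Adapt(0.2, 0.44) for _ in range(4)]}
    adapt_corr = {"mu": [_Adapt(0.2, 0.44) for _ in range(6)],
                  "sig": [_Adapt(0.2, 0.44) for _ in range(6)]}
    adapt_tau_nc = {"mu": [_Adapt(0.1, 0.44) for _ in range(4)],
                    "sig": [_Adapt(0.1, 0.44) for _ in range(4)]}
    adapt_corr_nc = {"mu": [_Adapt(0.1, 0.44) for _ in range(6)],
                     "sig": [_Adapt(0.1, 0.44) for _ in range(6)]}
    acc_counts: dict = {"sigma": 0, "tau": 0, "corr": 0}
    acc_trials: dict = {"sigma": 0, "tau": 0, "corr": 0}

    store = {key: [] for key in
             ("mu", "sigma", "mu_mean", "sigma_mean", "mu_sd", "sigma_sd",
              "mu_corr", "sigma_corr")}

    P_mu, _ = _precision(tau_mu, R_mu)
    P_sig, _ = _precision(tau_sig, R_sig)
    group_ll_mu = _mvn_sum_logpdf(mu, m_mu, tau_mu, R_mu)
    group_ll_sig = _mvn_sum_logpdf(sig, m_sig, tau_sig, R_sig)

    eye4 = np.eye(4)
    total = warmup + draws
    for it in range(total):
        warm = it < warmup

        # --- individual locations mu_i: exact Gaussian draw -------------
        d = n * np.exp(-2.0 * sig)                      # (N, 4) likelihood precisions
        A = P_mu[None, :, :] + d[:, None, :] * eye4[None, :, :]
        b = (P_mu @ m_mu)[None, :] + s1 * np.exp(-2.0 * sig)
        mean = np.linalg.solve(A, b[:, :, None])[:, :, 0]
        L = np.linalg.cholesky(A)
        z = rng.standard_normal((N, 4))
        noise = np.linalg.solve(np.transpose(L, (0, 2, 1)), z[:, :, None])[:, :, 0]
        mu = mean + noise

        # --- individual log-spreads sigma_i: joint preconditioned MH ----
        # Proposal covariance approximates the conditional posterior:
        # (prior precision + Fisher information 2*n per cell)^-1, so the
        # move respects the strong prior correlation across the four cells.
        SS = s2 - 2.0 * mu * s1 + n * mu ** 2
        A_sig = P_sig[None, :, :] + 2.0 * n[:, None, :] * eye4[None, :, :]
        L_sig = np.linalg.cholesky(A_sig)
        step = adapt_sig[0].step
        z = rng.standard_normal((N, 4))
        jump = step * np.linalg.solve(np.transpose(L_sig, (0, 2, 1)), z[:, :, None])[:, :, 0]
        prop = sig + jump
        ll_cur = (-n * sig - 0.5 * SS * np.exp(-2.0 * sig)).sum(axis=1)
        ll_new = (-n * prop - 0.5 * SS * np.exp(-2.0 * prop)).sum(axis=1)
        dev = sig - m_sig
        dev_new = prop - m_sig
        quad = np.einsum("ni,ij,nj->n", dev, P_sig, dev)
        quad_new = np.einsum("ni,ij,nj->n", dev_new, P_sig, dev_new)
        accept = np.log(rng.random(N)) < (ll_new - ll_cur) - 0.5 * (quad_new - quad)
        sig[accept] = prop[accept]
        if warm:
            adapt_sig[0].update(float(accept.mean()))
        else:
            acc_counts["sigma"] += int(accept.sum())
            acc_trials["sigma"] += N

        # Second sigma move: Laplace independence proposal.  The full
        # conditional of each subject's 4-vector is log-concave (Gaussian
        # prior + concave likelihood in sigma), so a few batched Newton
        # steps find its mode and curvature; proposing from the resulting
        # Gaussian yields near-independent draws with high acceptance,
        # which is what lets the group covariance of the spreads mix.
        SSc = np.clip(SS, 1e-12, None)

        def _f(x):
            lik = (-n * x - 0.5 * SSc * np.exp(-2.0 * x)).sum(axis=1)
            dv = x - m_sig
            return lik - 0.5 * np.einsum("ni,ij,nj->n", dv, P_sig, dv)

        mode = sig.copy()
        for _ in range(4):
            e = np.exp(-2.0 * mode)
            grad = -n + SSc * e - np.einsum("ij,nj->ni", P_sig, mode - m_sig)
            prec = P_sig[None, :, :] + (2.0 * SSc * e)[:, None, :] * eye4[None, :, :]
            delta = np.linalg.solve(prec, grad[:, :, None])[:, :, 0]
            mode = mode + np.clip(delta, -1.0, 1.0)
        e = np.exp(-2.0 * mode)
        prec = P_sig[None, :, :] + (2.0 * SSc * e)[:, None, :] * eye4[None, :, :]
        Lp = np.linalg.cholesky(prec)

        def _logq(x):
            dv = x - mode
            return -0.5 * np.einsum("ni,nij,nj->n", dv, prec, dv)

        z = rng.standard_normal((N, 4))
        prop = mode + np.linalg.solve(np.transpose(Lp, (0, 2, 1)), z[:, :, None])[:, :, 0]
        log_alpha = _f(prop) - _f(sig) + _logq(sig) - _logq(prop)
        accept = np.log(rng.random(N)) < log_alpha
        sig[accept] = prop[accept]
        if not warm:
            acc_counts["sigma_ind"] = acc_counts.get("sigma_ind", 0) + int(accept.sum())
            acc_trials["sigma_ind"] = acc_trials.get("sigma_ind", 0) + N

        # --- group means: exact Gaussian draws --------------------------
        for (x, P, which) in ((mu, P_mu, "mu"), (sig, P_sig, "sig")):
            A_m = eye4 + N * P
            b_m = P @ x.sum(axis=0)
            Lm = np.linalg.cholesky(A_m)
            mean_m = np.linalg.solve(A_m, b_m)
            noise_m = np.linalg.solve(Lm.T, rng.standard_normal(4))
            if which == "mu":
                m_mu = mean_m + noise_m
            else:
                m_sig = mean_m + noise_m
        group_ll_mu = _mvn_sum_logpdf(mu, m_mu, tau_mu, R_mu)
        group_ll_sig = _mvn_sum_logpdf(sig, m_sig, tau_sig, R_sig)

        # --- group covariances (sd vectors + correlation matrices) ------
        for which in ("mu", "sig"):
            x = mu if which == "mu" else sig
            m = m_mu if which == "mu" else m_sig
            tau = tau_mu if which == "mu" else tau_sig
            R = R_mu if which == "mu" else R_sig
            pc = pc_mu if which == "mu" else pc_sig
            ll = group_ll_mu if which == "mu" else group_ll_sig

            if N >= 9:
                # Inverse-Wishart independence proposal for the whole
                # covariance: with df = N - d - 1 the Gaussian likelihood of
                # the subject effects cancels against the proposal kernel
                # exactly, so the acceptance ratio reduces to the prior
                # ratio -- Half-Normal(0,1) on the sds, uniform on the
                # correlation matrix, with the separation-strategy Jacobian
                # prod(tau_j^d).  Acceptance is near 1 and successive draws
                # of (tau, R) given the effects are essentially independent.
                dev = x - m
                psi = dev.T @ dev
                S_prop = _invwishart_rvs(N - 5, psi, rng)
                tau_prop = np.sqrt(np.diag(S_prop))
                R_prop = S_prop / np.outer(tau_prop, tau_prop)
                np.fill_diagonal(R_prop, 1.0)
                log_alpha = float(
                    -0.5 * ((tau_prop ** 2).sum() - (tau ** 2).sum())
                    + 4.0 * (np.log(tau) - np.log(tau_prop)).sum())
                accepted = math.log(rng.random()) < log_alpha
                if accepted:
                    tau, R = tau_prop, R_prop
                    pc = _corr_to_pc(R)
                    ll = _mvn_sum_logpdf(x, m, tau, R)
                if not warm:
                    acc_counts["tau"] += int(accepted)
                    acc_trials["tau"] += 1
            else:
                # Fallback for very small cohorts: componentwise Metropolis
                # on log tau (Half-Normal prior + Jacobian) and on the
                # canonical partial correlations (uniform-over-correlation-
                # matrices prior = symmetric Beta factors).
                for j, a in enumerate(adapt_tau[which]):
                    tau_prop = tau.copy()
                    tau_prop[j] = tau[j] * math.exp(a.step * rng.standard_normal())
                    ll_prop = _mvn_sum_logpdf(x, m, tau_prop, R)
                    logp_cur = ll - 0.5 * tau[j] ** 2 + math.log(tau[j])
                    logp_prop = ll_prop - 0.5 * tau_prop[j] ** 2 + math.log(tau_prop[j])
                    accepted = math.log(rng.random()) < logp_prop - logp_cur
                    if accepted:
                        tau, ll = tau_prop, ll_prop
                    if warm:
                        a.update(1.0 if accepted else 0.0)
                    else:
                        acc_counts["tau"] += int(accepted)
                        acc_trials["tau"] += 1
                for k, a in enumerate(adapt_corr[which]):
                    v = pc.copy()
                    v[k] += a.step * rng.standard_normal()
                    accepted = False
                    if abs(v[k]) < 1.0:
                        R_prop = _pc_to_corr(v)
                        ll_prop = _mvn_sum_logpdf(x, m, tau, R_prop)
                        dprior = (_PC_BETA[k] - 1.0) * (
                            math.log1p(-v[k] ** 2) - math.log1p(-pc[k] ** 2))
                        if (np.isfinite(ll_prop)
                                and math.log(rng.random()) < ll_prop - ll + dprior):
                            R, ll = R_prop, ll_prop
                            pc = v
                            accepted = True
                    if warm:
                        a.update(1.0 if accepted else 0.0)
                    else:
                        acc_counts["corr"] += int(accepted)
                        acc_trials["corr"] += 1

            # Interweaved non-centered update: hold the standardised subject
            # effects eps = L^-1 (x - m) fixed and re-propose (tau, pc),
            # transporting every subject's parameter with the group scale.
            # The MVN prior term cancels; only the data likelihood and the
            # (tau or pc) prior enter the ratio.  This breaks the strong
            # coupling between group covariance and individual parameters
            # that stalls purely centered samplers.
            if which == "mu":
                def _datalik(xx):
                    SSx = s2 - 2.0 * xx * s1 + n * xx ** 2
                    return float(-0.5 * (SSx * np.exp(-2.0 * sig)).sum())
            else:
                def _datalik(xx):
                    # extreme proposals overflow to -inf and are rejected
                    SSm = s2 - 2.0 * mu * s1 + n * mu ** 2
                    with np.errstate(over="ignore"):
                        return float((-n * xx - 0.5 * SSm * np.exp(-2.0 * xx)).sum())

            S_cur = R * np.outer(tau, tau)
            L_cur = np.linalg.cholesky(S_cur)
            eps = np.linalg.solve(L_cur, (x - m).T).T
            dl = _datalik(x)
            # The spread side carries the least data information per cell and
            # therefore the strongest covariance/effects coupling; give it
            # extra interweave sweeps.
            n_sweeps = 6 if which == "sig" else 4
            for j, a in enumerate(adapt_tau_nc[which] * n_sweeps):
                j = j % 4
                tau_prop = tau.copy()
                tau_prop[j] = tau[j] * math.exp(a.step * rng.standard_normal())
                L_prop = np.linalg.cholesky(R * np.outer(tau_prop, tau_prop))
                x_prop = m + eps @ L_prop.T
                dl_prop = _datalik(x_prop)
                dprior = (-0.5 * (tau_prop[j] ** 2 - tau[j] ** 2)
                          + math.log(tau_prop[j] / tau[j]))
                accepted = math.log(rng.random()) < dl_prop - dl + dprior
                if accepted:
                    tau, x, dl = tau_prop, x_prop, dl_prop
                if warm:
                    a.update(1.0 if accepted else 0.0)
            for k, a in enumerate(adapt_corr_nc[which] * n_sweeps):
                v = pc.copy()
                v[k % 6] += a.step * rng.standard_normal()
                accepted = False
                if abs(v[k % 6]) < 1.0:
                    R_prop = _pc_to_corr(v)
                    L_prop = np.linalg.cholesky(R_prop * np.outer(tau, tau))
                    x_prop = m + eps @ L_prop.T
                    dl_prop = _datalik(x_prop)
                    dprior = (_PC_BETA[k % 6] - 1.0) * (
                        math.log1p(-v[k % 6] ** 2) - math.log1p(-pc[k % 6] ** 2))
                    accepted = math.log(rng.random()) < dl_prop - dl + dprior
                    if accepted:
                        pc, R, x, dl = v, R_prop, x_prop, dl_prop
                if warm:
                    a.update(1.0 if accepted else 0.0)
            ll = _mvn_sum_logpdf(x, m, tau, R)

            if which == "mu":
                mu = x
                tau_mu, R_mu, pc_mu, group_ll_mu = tau, R, pc, ll
                P_mu, _ = _precision(tau_mu, R_mu)
            else:
                sig = x
                tau_sig, R_sig, pc_sig, group_ll_sig = tau, R, pc, ll
                P_sig, _ = _precision(tau_sig, R_sig)

        if not warm:
            store["mu"].append(mu.copy())
            store["sigma"].append(sig.copy())
            store["mu_mean"].append(m_mu.copy())
            store["sigma_mean"].append(m_sig.copy())
            store["mu_sd"].append(tau_mu.copy())
            store["sigma_sd"].append(tau_sig.copy())
            store["mu_corr"].append(R_mu[_OFFDIAG].copy())
            store["sigma_corr"].append(R_sig[_OFFDIAG].copy())

    out = {key: np.asarray(val) for key, val in store.items()}
    out["accept_rates"] = {key: acc_counts[key] / max(acc_trials[key], 1)
                           for key in acc_counts}
    return out


def fit_hbm(ds, task: str, session: str, spec: HbmSpec) -> PosteriorDraws:
    """Fit the hierarchical lognormal model to one task x session cell.

    Reaction times are converted to seconds internally (the Normal(0,1)
    group-mean prior is calibrated for log-seconds).  Returns the joint
    posterior draws over individual and group parameters.
    """
    data = prepare_cell_data(ds, task, session)
    seeds = np.random.SeedSequence(spec.seed).spawn(spec.chains)
    chains = [_run_chain(data, spec.warmup, spec.draws, np.random.default_rng(s))
              for s in seeds]
    stacked = {key: np.stack([c[key] for c in chains])
               for key in ("mu", "sigma", "mu_mean", "sigma_mean",
                           "mu_sd", "sigma_sd", "mu_corr", "sigma_corr")}
    rates = {key: float(np.mean([c["accept_rates"][key] for c in chains]))
             for key in chains[0]["accept_rates"]}
    return PosteriorDraws(subjects=data.subjects, task=task, session=session,
                          spec=spec, accept_rates=rates, **stacked)


@dataclass
class DeltaDraws:
    """Per-draw log-scale difference scores, (chains, draws, subjects)."""

    test: np.ndarray
    retest: np.ndarray
    subjects: list

    def posterior_mean(self) -> pd.DataFrame:
        return pd.DataFrame({
            "subject": self.subjects,
            "delta_test": self.test.mean(axis=(0, 1)),
            "delta_retest": self.retest.mean(axis=(0, 1)),
        })


def delta_draws(post: PosteriorDraws) -> DeltaDraws:
    """Difference-score parameter per draw: interference minus control location.

    Delta is a difference of lognormal location parameters (a log median
    ratio), not a millisecond difference.
    """
    mu = post.mu
    return DeltaDraws(
        test=mu[..., _IDX_INTERF_TEST] - mu[..., _IDX_CONTROL_TEST],
        retest=mu[..., _IDX_INTERF_RETEST] - mu[..., _IDX_CONTROL_RETEST],
        subjects=post.subjects,
    )


@dataclass
class ReliabilityPosterior:
    r_draws: np.ndarray          # (chains, draws), NaN where undefined
    mean: float
    median: float
    ci: tuple[float, float]
    n_excluded: int              # draws with zero delta variance (r undefined)

    def density(self, grid: int = 512) -> pd.DataFrame:
        """Gaussian-KDE posterior density on [-1, 1] for plotting/export."""
        from scipy.stats import gaussian_kde

        r = self.r_draws[np.isfinite(self.r_draws)].ravel()
        xs = np.linspace(-1, 1, grid)
        return pd.DataFrame({"r": xs, "density": gaussian_kde(r)(xs)})


def retest_reliability(deltas: DeltaDraws) -> ReliabilityPosterior:
    """Posterior distribution of test-retest reliability.

    Per MCMC draw, the Pearson correlation over subjects between the test-
    and retest-phase deltas; draws in which either phase has zero variance
    across subjects are excluded and counted.
    """
    t, rt = deltas.test, deltas.retest
    if t.shape[-1] < 3:
        raise ValueError("need >= 3 subjects for a reliability correlation")
    tc = t - t.mean(axis=-1, keepdims=True)
    rc = rt - rt.mean(axis=-1, keepdims=True)
    var_t = (tc ** 2).sum(axis=-1)
    var_r = (rc ** 2).sum(axis=-1)
    # a draw is degenerate when a phase's spread is zero up to rounding
    tol_t = (1e-9 * (np.abs(t).max(axis=-1) + 1e-30)) ** 2
    tol_r = (1e-9 * (np.abs(rt).max(axis=-1) + 1e-30)) ** 2
    ok = (var_t > tol_t) & (var_r > tol_r)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(ok, (tc * rc).sum(axis=-1) / np.sqrt(var_t * var_r), np.nan)
    finite = r[np.isfinite(r)]
    if finite.size == 0:
        raise ValueError("reliability undefined in every draw (zero delta variance)")
    return ReliabilityPosterior(
        r_draws=r,
        mean=float(finite.mean()),
        median=float(np.median(finite)),
        ci=(float(np.percentile(finite, 2.5)), float(np.percentile(finite, 97.5))),
        n_excluded=int(np.size(r) - finite.size),
    )


def convergence_report(post: PosteriorDraws,
                       rhat_threshold: float | None = None,
                       ess_threshold: float | None = None) -> tuple[pd.DataFrame, bool]:
    """Per-parameter split-R-hat and bulk effective sample size via arviz.

    Monitors every stored scalar (individual mu/sigma, group means and sds,
    correlation off-diagonals).  Passes iff max R-hat <= threshold and
    min ESS >= threshold (defaults from the fit's :class:`HbmSpec`).
    """
    import arviz as az

    rhat_threshold = rhat_threshold or post.spec.rhat_threshold
    ess_threshold = ess_threshold or post.spec.ess_threshold
    posterior = {
        "mu": post.mu, "sigma": post.sigma,
        "mu_mean": post.mu_mean, "sigma_mean": post.sigma_mean,
        "mu_sd": post.mu_sd, "sigma_sd": post.sigma_sd,
        "mu_corr": post.mu_corr, "sigma_corr": post.sigma_corr,
    }
    idata = az.from_dict(posterior=posterior)
    rhat = az.rhat(idata)
    ess = az.ess(idata)
    rows = []
    for var in posterior:
        rh = np.asarray(rhat[var]).ravel()
        es = np.asarray(ess[var]).ravel()
        for i, (a, b) in enumerate(zip(rh, es, strict=True)):
            rows.append({"parameter": f"{var}[{i}]", "rhat": float(a), "ess": float(b)})
    table = pd.DataFrame(rows)
    passed = bool((table["rhat"].max() <= rhat_threshold)
                  and (table["ess"].min() >= ess_threshold))
    return table, passed
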