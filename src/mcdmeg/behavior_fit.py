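"""Joint psychometric fit of the detector to causality / temporal-order data.

Trial-level binary responses ("same cause" in the causality task, "visual
first" in the temporal-order task) are modelled with a mixed-effects logistic
regression whose predictor is the z-scored time-averaged detector output
(CORR for causality, LAG for temporal order):

    P(resp = 1 | b_p) = logistic(beta0_task + beta1_task * z + b_p),
    b_p ~ Normal(0, sigma_task^2)   (random intercept per participant)

The marginal likelihood integrates the random intercepts out with
Gauss-Hermite quadrature.  Seven fixed parameters are fitted jointly by
maximum likelihood: the three filter time constants (shared across tasks,
they shape the per-stimulus z values) and an intercept and slope per task.
The search is a particle swarm over log time constants with the link
parameters profiled out by an inner quasi-Newton fit, refined by Nelder-Mead
simplex, repeated over random restarts keeping the best.

The module also provides the per-participant pseudo-R^2 (squared Pearson
correlation between predicted and observed per-stimulus response
proportions), the paired-t comparison of fit quality across tasks, and the
Monte-Carlo observational power analysis with an exact binomial confidence
interval.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, logsumexp
from statsmodels.stats.proportion import proportion_confint

from .mcd_core import (
    DEFAULT_RATE,
    MCDParams,
    ParameterError,
    score_sequences,
    zscore_across,
)
from .stimulus_design import StimulusSet, default_stimulus_set

__all__ = [
    "TrialTable", "BehaviorFit", "MixedLogisticResult",
    "aggregate_trials", "nll_mixed_logistic", "fit_mixed_logistic",
    "fit_mcd_behavior", "pseudo_r2", "compare_task_fit", "power_mc",
    "stimulus_z_summaries",
]

TASKS = ("causality", "temporal_order")

#: Node count for the adaptive Gauss-Hermite random-intercept integral.
GH_NODES = 15

#: Search box for the log time constants (ms).
TAU_BOUNDS = (20.0, 3000.0)


@functools.lru_cache(maxsize=8)
def _gh(n_nodes: int):
    return np.polynomial.hermite.hermgauss(n_nodes)


# ---------------------------------------------------------------------------
# Trial tables
# ---------------------------------------------------------------------------


REQUIRED_COLUMNS = ("participant", "task", "stimulus", "response")


def validate_trials(trials: pd.DataFrame) -> pd.DataFrame:
    missing = set(REQUIRED_COLUMNS) - set(trials.columns)
    if missing:
        raise ParameterError(f"trial table missing columns {missing}")
    bad = set(trials["task"].unique()) - set(TASKS)
    if bad:
        raise ParameterError(f"unknown tasks {bad}; expected {TASKS}")
    if not trials["response"].isin([0, 1]).all():
        raise ParameterError("responses must be binary 0/1")
    return trials


@dataclass
class TrialTable:
    """Per-trial behavioral records."""

    data: pd.DataFrame

    def __post_init__(self):
        self.data = validate_trials(self.data)

    @classmethod
    def from_csv(cls, path: str | Path) -> "TrialTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    @property
    def participants(self) -> list:
        return sorted(self.data["participant"].unique())

    @property
    def stimuli(self) -> list:
        return sorted(self.data["stimulus"].unique())


def aggregate_trials(trials: pd.DataFrame, task: str,
                     participants=None, stimuli=None):
    """Aggregate binary responses to per-(participant, stimulus) counts.

    Returns (y, n): two (P, S) integer arrays of successes and trials.
    """
    sub = trials[trials["task"] == task]
    participants = participants or sorted(trials["participant"].unique())
    stimuli = stimuli or sorted(trials["stimulus"].unique())
    g = sub.groupby(["participant", "stimulus"])["response"].agg(["sum", "count"])
    y = np.zeros((len(participants), len(stimuli)), dtype=int)
    n = np.zeros_like(y)
    for (p, s), row in g.iterrows():
        y[participants.index(p), stimuli.index(s)] = row["sum"]
        n[participants.index(p), stimuli.index(s)] = row["count"]
    return y, n


# ---------------------------------------------------------------------------
# Mixed logistic likelihood (Gauss-Hermite marginalisation)
# ---------------------------------------------------------------------------


def _cell_loglik(y, n, eta):
    """Bernoulli-trial log-likelihood per cell, safe against saturation."""
    eta = np.clip(eta, -700.0, 700.0)
    return -(y * np.logaddexp(0.0, -eta) + (n - y) * np.logaddexp(0.0, eta))


def nll_mixed_logistic(beta0: float, beta1: float, sigma: float,
                       y: np.ndarray, n: np.ndarray, x: np.ndarray,
                       n_nodes: int = GH_NODES) -> float:
    """Negative marginal log-likelihood of the random-intercept logistic model.

    ``y``/``n`` are (P, S) success/trial counts, ``x`` the per-cell predictor
    ((P, S) or (S,)).  Trials are treated as exchangeable Bernoulli draws
    (no binomial coefficient), so with beta0 = beta1 = sigma = 0 the NLL is
    exactly (number of trials) * ln 2.

    Participant intercepts are integrated out by *adaptive* Gauss-Hermite
    quadrature: a Newton search locates each participant's posterior mode,
    the nodes are recentred there and scaled by the posterior curvature, so
    accuracy stays high even when the posterior is narrow and far from the
    prior's centre (many trials, large sigma).
    """
    y = np.asarray(y, float)
    n = np.asarray(n, float)
    x = np.broadcast_to(np.asarray(x, float), y.shape)
    if sigma < 0:
        raise ParameterError("sigma must be >= 0")
    # an intercept SD beyond ~1e3 logits is indistinguishable from flat;
    # capping keeps the Newton step finite when the optimizer overshoots
    sigma = min(float(sigma), 1e3)
    eta0 = beta0 + beta1 * x  # (P, S)
    if sigma < 1e-12:
        total = _cell_loglik(y, n, eta0).sum()
        if not np.isfinite(total):
            raise FloatingPointError("non-finite likelihood (degenerate sigma)")
        return float(-total)

    # posterior mode and curvature per participant (Laplace step)
    b = np.zeros(y.shape[0])
    inv_var = 1.0 / sigma ** 2
    hess = None
    for _ in range(100):
        mu = expit(np.clip(eta0 + b[:, None], -700, 700))
        grad = (y - n * mu).sum(axis=1) - b * inv_var
        hess = -(n * mu * (1 - mu)).sum(axis=1) - inv_var
        step = grad / hess
        b = np.clip(b - step, -1e3, 1e3)
        if np.max(np.abs(step)) < 1e-12:
            break
    c = 1.0 / np.sqrt(-hess)  # posterior SD scale

    nodes, weights = _gh(n_nodes)
    logw = np.log(weights)
    bk = b[:, None] + np.sqrt(2.0) * c[:, None] * nodes[None, :]  # (P, K)
    ll = _cell_loglik(y[:, :, None], n[:, :, None],
                      eta0[:, :, None] + bk[:, None, :]).sum(axis=1)  # (P, K)
    log_prior = (-0.5 * (bk / sigma) ** 2 - 0.5 * np.log(2 * np.pi)
                 - np.log(sigma))
    log_terms = logw[None, :] + nodes[None, :] ** 2 + ll + log_prior
    per_participant = (logsumexp(log_terms, axis=1)
                       + 0.5 * np.log(2.0) + np.log(c))
    total = per_participant.sum()
    if not np.isfinite(total):
        bad = np.flatnonzero(~np.isfinite(per_participant))
        raise FloatingPointError(
            f"non-finite likelihood for participants {bad}")
    return float(-total)


@dataclass
class MixedLogisticResult:
    beta0: float
    beta1: float
    sigma: float
    nll: float
    se_beta1: float
    z_beta1: float
    p_beta1: float
    converged: bool

    @property
    def params(self) -> np.ndarray:
        return np.array([self.beta0, self.beta1, self.sigma])


def fit_mixed_logistic(y: np.ndarray, n: np.ndarray, x: np.ndarray,
                       n_nodes: int = GH_NODES,
                       start: tuple[float, float, float] = (0.0, 0.5, 0.5),
                       compute_se: bool = True) -> MixedLogisticResult:
    """ML fit of (beta0, beta1, sigma) with a Wald test on the slope."""

    def f(theta):
        return nll_mixed_logistic(theta[0], theta[1], np.exp(theta[2]), y, n, x,
                                  n_nodes=n_nodes)

    x0 = np.array([start[0], start[1], np.log(max(start[2], 1e-3))])
    res = optimize.minimize(f, x0, method="BFGS",
                            options={"gtol": 1e-6, "maxiter": 400})
    # BFGS can stop on a precision-loss line search with the gradient
    # already negligible; treat that as converged
    grad_norm = float(np.max(np.abs(res.jac))) if res.jac is not None else np.inf
    converged = bool(res.success or grad_norm < 1e-2)
    b0, b1, s = res.x[0], res.x[1], float(np.exp(res.x[2]))
    se = z = p = np.nan
    if compute_se:
        se = _wald_se_beta1(b0, b1, s, y, n, x, n_nodes)
        z = b1 / se if se > 0 else np.nan
        p = 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
    return MixedLogisticResult(float(b0), float(b1), s, float(res.fun),
                               float(se), float(z), float(p), converged)


def _wald_se_beta1(b0, b1, sigma, y, n, x, n_nodes) -> float:
    """Standard error of the slope from a finite-difference Hessian of the
    NLL in (beta0, beta1, log sigma)."""
    theta = np.array([b0, b1, np.log(max(sigma, 1e-8))])

    def f(t):
        return nll_mixed_logistic(t[0], t[1], np.exp(t[2]), y, n, x, n_nodes=n_nodes)

    h = 1e-4 * np.maximum(1.0, np.abs(theta))
    k = theta.size
    H = np.zeros((k, k))
    f0 = f(theta)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(theta + ei + ej) - f(theta + ei) - f(theta + ej) + f0
            ) / (h[i] * h[j])
    try:
        cov = np.linalg.inv(H)
        v = cov[1, 1]
        return float(np.sqrt(v)) if v > 0 else np.nan
    except np.linalg.LinAlgError:
        return np.nan


# ---------------------------------------------------------------------------
# Per-stimulus predictors under candidate time constants
# ---------------------------------------------------------------------------


def stimulus_z_summaries(stimuli: StimulusSet | list, params: MCDParams,
                         rate: float = DEFAULT_RATE) -> dict[str, np.ndarray]:
    """Z-scored time-averaged CORR and LAG across a stimulus set."""
    seqs = list(stimuli.sequences) if isinstance(stimuli, StimulusSet) else list(stimuli)
    raw = score_sequences(seqs, params, rate=rate)
    return {"corr_z": zscore_across(raw[:, 0]), "lag_z": zscore_across(raw[:, 1]),
            "corr_avg": raw[:, 0], "lag_avg": raw[:, 1]}


#: Predictor used for each task: causality reads the correlation output,
#: temporal order the lag output.
TASK_PREDICTOR = {"causality": "corr_z", "temporal_order": "lag_z"}


# ---------------------------------------------------------------------------
# Joint 7-parameter fit
# ---------------------------------------------------------------------------


@dataclass
class BehaviorFit:
    mcd_params: MCDParams
    link_params: dict  # task -> {"beta0", "beta1", "sigma"}
    random_intercepts: dict  # task -> per-participant posterior mode array
    loglik: float
    r2: pd.DataFrame  # participant x task
    n_restarts_used: int
    restart_nlls: list[float] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        return {
            "mcd_params": {"tau_a": self.mcd_params.tau_a,
                           "tau_v": self.mcd_params.tau_v,
                           "tau_av": self.mcd_params.tau_av},
            "link_params": self.link_params,
            "random_intercepts": {t: list(map(float, v))
                                  for t, v in self.random_intercepts.items()},
            "loglik": self.loglik,
            "r2": self.r2.to_dict(),
            "n_restarts_used": self.n_restarts_used,
            "restart_nlls": self.restart_nlls,
        }


class FitFailureError(RuntimeError):
    def __init__(self, msg, restart_nlls=None):
        super().__init__(msg)
        self.restart_nlls = restart_nlls or []


def _pso(objective, bounds, n_particles, n_iter, rng,
         inertia=0.7, c_cog=1.5, c_soc=1.5):
    """Minimal particle-swarm minimiser on a box; returns (x_best, f_best)."""
    lo, hi = np.asarray(bounds[0], float), np.asarray(bounds[1], float)
    dim = lo.size
    x = rng.uniform(lo, hi, size=(n_particles, dim))
    v = rng.uniform(-(hi - lo), hi - lo, size=(n_particles, dim)) * 0.1
    f = np.array([objective(xi) for xi in x])
    pbest, fbest = x.copy(), f.copy()
    g = int(np.argmin(fbest))
    for _ in range(n_iter):
        r1, r2 = rng.random((2, n_particles, dim))
        v = inertia * v + c_cog * r1 * (pbest - x) + c_soc * r2 * (pbest[g] - x)
        x = np.clip(x + v, lo, hi)
        f = np.array([objective(xi) for xi in x])
        upd = f < fbest
        pbest[upd], fbest[upd] = x[upd], f[upd]
        g = int(np.argmin(fbest))
    return pbest[g], float(fbest[g])


def _profiled_nll_factory(trials: pd.DataFrame, stimuli, rate, n_nodes):
    """Objective over log tau (3,) with link parameters profiled out.

    Returns (objective, details) where details(log_tau) re-fits and returns
    the per-task link parameters and counts.
    """
    participants = sorted(trials["participant"].unique())
    stim_ids = sorted(trials["stimulus"].unique())
    counts = {t: aggregate_trials(trials, t, participants, stim_ids) for t in TASKS}
    seqs = list(stimuli.sequences) if isinstance(stimuli, StimulusSet) else list(stimuli)
    if len(seqs) != len(stim_ids):
        raise ParameterError(
            f"{len(seqs)} stimulus sequences but {len(stim_ids)} stimulus ids in trials")
    cache: dict[tuple, float] = {}
    warm = {t: (0.0, 0.5, 0.5) for t in TASKS}  # warm starts for the inner fits

    def inner(log_tau, want_details=False):
        key = tuple(np.round(log_tau, 10))
        if not want_details and key in cache:
            return cache[key]
        tau = np.exp(log_tau)
        params = MCDParams(tau_a=tau[0], tau_v=tau[1], tau_av=tau[2])
        try:
            z = stimulus_z_summaries(seqs, params, rate=rate)
        except Exception:
            return np.inf if not want_details else (np.inf, None)
        total = 0.0
        details = {}
        for task in TASKS:
            y, n = counts[task]
            x = z[TASK_PREDICTOR[task]]
            res = fit_mixed_logistic(y, n, x, n_nodes=n_nodes, compute_se=False,
                                     start=warm[task])
            # a cold restart guards against a poor warm-started local step
            if not np.isfinite(res.nll):
                res = fit_mixed_logistic(y, n, x, n_nodes=n_nodes,
                                         compute_se=False)
            warm[task] = (res.beta0, res.beta1, res.sigma)
            total += res.nll
            details[task] = res
        cache[key] = total
        if want_details:
            return total, details
        return total

    return inner, counts, participants, stim_ids


def fit_mcd_behavior(trials: TrialTable | pd.DataFrame, stimuli,
                     n_restarts: int = 10, seed: int = 0,
                     rate: float = DEFAULT_RATE, n_nodes: int = GH_NODES,
                     n_particles: int = 10, n_iter: int = 15) -> BehaviorFit:
    """Joint maximum-likelihood fit of the 7 fixed parameters.

    Particle-swarm over log time constants (link parameters profiled by an
    inner quasi-Newton fit) followed by Nelder-Mead simplex refinement; the
    whole procedure is restarted ``n_restarts`` times from fresh swarms and
    the best solution kept.  Deterministic given ``seed``.
    """
    df = trials.data if isinstance(trials, TrialTable) else validate_trials(trials)
    for task in TASKS:
        if task not in df["task"].values:
            raise ParameterError(f"both tasks required for the joint fit; missing {task}")
    objective, counts, participants, stim_ids = _profiled_nll_factory(
        df, stimuli, rate, n_nodes)
    lo = np.log([TAU_BOUNDS[0]] * 3)
    hi = np.log([TAU_BOUNDS[1]] * 3)
    rng = np.random.default_rng(seed)
    best_x, best_f, restart_nlls = None, np.inf, []
    for _ in range(n_restarts):
        x0, f0 = _pso(objective, (lo, hi), n_particles, n_iter, rng)
        res = optimize.minimize(objective, x0, method="Nelder-Mead",
                                options={"xatol": 1e-3, "fatol": 1e-3,
                                         "maxfev": 200})
        fv = res.fun if np.isfinite(res.fun) else f0
        xv = res.x if res.fun <= f0 else x0
        restart_nlls.append(float(fv))
        if fv < best_f:
            best_x, best_f = xv, fv
    if best_x is None or not np.isfinite(best_f):
        raise FitFailureError("all restarts failed", restart_nlls)
    total, details = objective(best_x, want_details=True)
    tau = np.exp(best_x)
    params = MCDParams(tau_a=tau[0], tau_v=tau[1], tau_av=tau[2])
    z = stimulus_z_summaries(
        list(stimuli.sequences) if isinstance(stimuli, StimulusSet) else list(stimuli),
        params, rate=rate)
    link = {t: {"beta0": d.beta0, "beta1": d.beta1, "sigma": d.sigma}
            for t, d in details.items()}
    rints = {t: _posterior_intercepts(details[t], *counts[t], z[TASK_PREDICTOR[t]])
             for t in TASKS}
    r2 = pseudo_r2_table(counts, link, rints, z, participants)
    return BehaviorFit(params, link, rints, loglik=-float(total), r2=r2,
                       n_restarts_used=n_restarts, restart_nlls=restart_nlls)


def _posterior_intercepts(res: MixedLogisticResult, y, n, x) -> np.ndarray:
    """Posterior modes of the per-participant random intercepts."""
    x = np.broadcast_to(np.asarray(x, float), y.shape)
    out = np.zeros(y.shape[0])
    if res.sigma < 1e-8:
        return out
    for p in range(y.shape[0]):
        def neg_post(b):
            eta = res.beta0 + res.beta1 * x[p] + b
            ll = -(y[p] * np.logaddexp(0.0, -eta)
                   + (n[p] - y[p]) * np.logaddexp(0.0, eta)).sum()
            return -(ll - 0.5 * (b / res.sigma) ** 2)
        out[p] = optimize.minimize_scalar(neg_post, bounds=(-10, 10),
                                          method="bounded").x
    return out


# ---------------------------------------------------------------------------
# Goodness of fit and task comparison
# ---------------------------------------------------------------------------


def pseudo_r2(predicted: np.ndarray, observed: np.ndarray) -> float:
    """Squared Pearson correlation between predicted and observed per-stimulus
    response proportions.  Undefined (raises) for zero-variance observations."""
    predicted = np.asarray(predicted, float)
    observed = np.asarray(observed, float)
    if observed.std() == 0 or predicted.std() == 0:
        raise ParameterError("zero variance: pseudo-R^2 undefined")
    return float(np.corrcoef(predicted, observed)[0, 1] ** 2)


def pseudo_r2_table(counts, link, rints, z, participants) -> pd.DataFrame:
    rows = {}
    for task in TASKS:
        y, n = counts[task]
        x = z[TASK_PREDICTOR[task]]
        vals = []
        for p in range(y.shape[0]):
            ok = n[p] > 0
            pred = expit(link[task]["beta0"] + link[task]["beta1"] * x[ok]
                         + rints[task][p])
            obs = y[p, ok] / n[p, ok]
            try:
                vals.append(pseudo_r2(pred, obs))
            except ParameterError:
                vals.append(np.nan)
        rows[task] = vals
    return pd.DataFrame(rows, index=participants)


def compare_task_fit(r2_causality: np.ndarray, r2_temporal: np.ndarray):
    """Paired t-test on per-participant R^2 across the two tasks.

    Returns (t, df, p); a zero-variance difference is flagged by returning
    p = nan with a degenerate marker in the tuple's t slot sign.
    """
    a = np.asarray(r2_causality, float)
    b = np.asarray(r2_temporal, float)
    if a.shape != b.shape:
        raise ParameterError("R^2 vectors must be paired by participant")
    d = a - b
    df = a.size - 1
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d, 0.0):
            return 0.0, df, 1.0
        return np.inf * np.sign(d.mean()), df, np.nan  # degenerate: flagged
    t, p = stats.ttest_rel(a, b)
    return float(t), df, float(p)


# ---------------------------------------------------------------------------
# Monte-Carlo observational power
# ---------------------------------------------------------------------------


@functools.lru_cache(maxsize=4)
def _default_power_predictor(seed: int = 0) -> tuple[float, ...]:
    """Z-scored CORR values of the packaged default stimulus set."""
    sset = default_stimulus_set(seed=seed)
    return tuple(zscore_across(sset.summaries[:, 0]))


def power_mc(beta: float, n_participants: int = 13, trials_per_cell: int = 75,
             n_sim: int = 1000, alpha: float = 0.05, seed: int = 0,
             predictor_z: np.ndarray | None = None, beta0: float = 0.0,
             sigma_b: float = 1.0, n_nodes: int = GH_NODES):
    """Monte-Carlo observational power for a fixed-effect slope.

    Each simulated dataset has ``n_participants`` x len(predictor) cells of
    ``trials_per_cell`` Bernoulli trials with
    P(resp) = logistic(beta0 + beta * z + b_p), b_p ~ N(0, sigma_b^2).
    The mixed logistic model is refitted per dataset and the slope tested by
    a two-sided Wald z-test at ``alpha``.  Returns (power_pct, (lo_pct,
    hi_pct), n_significant) with a Clopper-Pearson exact 95% CI.
    """
    if n_sim < 50:
        raise ParameterError("n_sim must be >= 50")
    if predictor_z is None:
        predictor_z = np.array(_default_power_predictor())
    z = np.asarray(predictor_z, float)
    rng = np.random.default_rng(seed)
    n = np.full((n_participants, z.size), trials_per_cell, dtype=int)
    n_sig = 0
    for _ in range(n_sim):
        b = rng.normal(0.0, sigma_b, n_participants)
        p = expit(beta0 + beta * z[None, :] + b[:, None])
        y = rng.binomial(n, p)
        res = fit_mixed_logistic(y, n, z, n_nodes=n_nodes)
        if np.isfinite(res.p_beta1) and res.p_beta1 < alpha:
            n_sig += 1
    lo, hi = proportion_confint(n_sig, n_sim, alpha=0.05, method="beta")
    return 100.0 * n_sig / n_sim, (100.0 * lo, 100.0 * hi), n_sig
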