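"""Trial-to-evoked processing for multichannel (MEG-style) epochs.

Covers the sensor-level steps between raw trialwise signals and the
brain-behavior statistics: epoching around sequence onset, peak-to-peak
artifact rejection, merging of sensor triplets into virtual channels,
removal of unisensory evoked components by per-sensor regression on passive
localizer responses,

    residual(n, t) = task(n, t) - (beta_A(n) * aud(n, t) + beta_V(n) * vis(n, t)),

cluster RMS extraction, and the mixed regressions relating cluster activity
to the detector summaries and to single-trial responses.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal, stats

from .mcd_core import ParameterError

__all__ = [
    "EpochSet", "Evoked", "UnisensoryWeights",
    "epoch", "reject_peak_to_peak", "merge_sensor_triplets",
    "remove_unisensory", "cluster_rms", "regress_evoked_on_mcd",
    "single_trial_brain_behavior", "bandpass_resample",
]

EPOCH_WINDOW = (-0.2, 1.8)  # s around the first event of the sequence
EPOCH_RATE = 250.0          # Hz
MAG_PTP_THRESHOLD = 2e-11   # tesla, magnetometer peak-to-peak rejection
GRAD_PTP_THRESHOLD = 9e-9   # T/cm, planar-gradient rejection (config-overridable)


class CollinearityWarning(UserWarning):
    pass


@dataclass
class EpochSet:
    """Trials x sensors x time array with sampling metadata.

    The window is half-open: ``n_times = round((t1 - t0) * rate)`` samples,
    so the default [-0.2, 1.8) s window at 250 Hz holds 500 samples.
    """

    data: np.ndarray
    rate: float = EPOCH_RATE
    window: tuple[float, float] = EPOCH_WINDOW
    trial_meta: pd.DataFrame | None = None
    sensor_names: list[str] | None = None
    kept_mask: np.ndarray | None = None
    units: str = "T"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ParameterError("EpochSet data must be trials x sensors x time")
        n_expected = int(round((self.window[1] - self.window[0]) * self.rate))
        if self.data.shape[2] != n_expected:
            raise ParameterError(
                f"window {self.window} at {self.rate} Hz implies "
                f"{n_expected} samples, got {self.data.shape[2]}")
        if self.trial_meta is not None and len(self.trial_meta) != self.data.shape[0]:
            raise ParameterError("trial_meta rows must align with trials")
        if self.sensor_names is None:
            self.sensor_names = [f"S{i:03d}" for i in range(self.data.shape[1])]
        if self.kept_mask is None:
            self.kept_mask = np.ones(self.data.shape[0], dtype=bool)

    @property
    def times(self) -> np.ndarray:
        return self.window[0] + np.arange(self.data.shape[2]) / self.rate

    def save(self, stem: str | Path) -> None:
        """Write data as .npy plus a JSON sidecar (and a trial-meta CSV)."""
        stem = Path(stem)
        np.save(stem.with_suffix(".npy"), self.data)
        sidecar = {"rate": self.rate, "window": list(self.window),
                   "sensor_names": self.sensor_names, "units": self.units,
                   "kept_mask": self.kept_mask.tolist()}
        stem.with_suffix(".json").write_text(json.dumps(sidecar))
        if self.trial_meta is not None:
            self.trial_meta.to_csv(stem.with_suffix(".trials.csv"), index=False)

    @classmethod
    def load(cls, stem: str | Path) -> "EpochSet":
        stem = Path(stem)
        data = np.load(stem.with_suffix(".npy"))
        meta = json.loads(stem.with_suffix(".json").read_text())
        trials_csv = stem.with_suffix(".trials.csv")
        trial_meta = pd.read_csv(trials_csv) if trials_csv.exists() else None
        return cls(data, rate=meta["rate"], window=tuple(meta["window"]),
                   trial_meta=trial_meta, sensor_names=meta["sensor_names"],
                   kept_mask=np.array(meta["kept_mask"], dtype=bool),
                   units=meta.get("units", "T"))


@dataclass
class Evoked:
    """Condition-averaged sensors x time array."""

    data: np.ndarray
    rate: float = EPOCH_RATE
    window: tuple[float, float] = EPOCH_WINDOW
    n_trials_averaged: int = 0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ParameterError("Evoked data must be sensors x time")


@dataclass
class UnisensoryWeights:
    beta_a: np.ndarray  # per sensor
    beta_v: np.ndarray

    def to_json_dict(self) -> dict:
        return {"beta_a": self.beta_a.tolist(), "beta_v": self.beta_v.tolist()}


# ---------------------------------------------------------------------------
# Epoching and artifact rejection
# ---------------------------------------------------------------------------


def epoch(recording: np.ndarray, onsets: np.ndarray, rate: float = EPOCH_RATE,
          window: tuple[float, float] = EPOCH_WINDOW,
          trial_meta: pd.DataFrame | None = None,
          sensor_names: list[str] | None = None) -> EpochSet:
    """Cut fixed-length epochs around each onset of a continuous recording.

    ``recording`` is sensors x time starting at t = 0; ``onsets`` are the
    first-event times (s) of each trial.  Trials whose window is not fully
    covered raise, listing the offending trials.
    """
    recording = np.asarray(recording, dtype=float)
    onsets = np.atleast_1d(np.asarray(onsets, dtype=float))
    n_times = int(round((window[1] - window[0]) * rate))
    if onsets.size == 0:
        return EpochSet(np.zeros((0, recording.shape[0], n_times)), rate=rate,
                        window=window, sensor_names=sensor_names)
    i0 = np.round((onsets + window[0]) * rate).astype(int)
    bad = np.flatnonzero((i0 < 0) | (i0 + n_times > recording.shape[1]))
    if bad.size:
        raise ParameterError(
            f"trials {bad.tolist()} extend beyond the recording "
            f"(onsets {onsets[bad].tolist()})")
    data = np.stack([recording[:, i:i + n_times] for i in i0])
    return EpochSet(data, rate=rate, window=window, trial_meta=trial_meta,
                    sensor_names=sensor_names)


def reject_peak_to_peak(epochs: EpochSet,
                        threshold: float = MAG_PTP_THRESHOLD) -> np.ndarray:
    """Keep a trial iff its max-min range over all sensors is <= threshold."""
    if threshold <= 0:
        raise ParameterError("threshold must be > 0")
    ptp = epochs.data.max(axis=(1, 2)) - epochs.data.min(axis=(1, 2))
    return ptp <= threshold


def merge_sensor_triplets(data306: np.ndarray, grouping: list[tuple[int, ...]],
                          weights: np.ndarray | None = None) -> np.ndarray:
    """Combine sensor triplets into virtual channels by a weighted sum.

    ``grouping`` must partition the sensor axis into disjoint triplets; the
    default rule is a unit-weight sum.  (The vendor field transformation
    behind real triplet merging needs proprietary sensor geometry and is out
    of scope; synthetic layouts are generated directly at the merged count.)
    """
    data306 = np.asarray(data306, dtype=float)
    seen: set[int] = set()
    for g in grouping:
        if len(g) != 3:
            raise ParameterError(f"incomplete triplet {g}")
        if seen & set(g):
            raise ParameterError(f"triplet {g} overlaps another group")
        seen |= set(g)
    if seen != set(range(data306.shape[0])):
        raise ParameterError("grouping must partition all sensors into triplets")
    if weights is None:
        weights = np.ones(3)
    out = np.empty((len(grouping),) + data306.shape[1:])
    for k, g in enumerate(grouping):
        out[k] = np.tensordot(weights, data306[list(g)], axes=(0, 0))
    return out


# ---------------------------------------------------------------------------
# Unisensory removal (per-sensor OLS on localizer evoked responses)
# ---------------------------------------------------------------------------


def remove_unisensory(task_evoked: np.ndarray, aud_evoked: np.ndarray,
                      vis_evoked: np.ndarray) -> tuple[np.ndarray, UnisensoryWeights]:
    """Subtract the best-fitting weighted sum of unisensory evoked responses.

    All inputs are sensors x time (or sensors x stimuli x time; the
    regression pools across all time points and stimuli per sensor).
    Returns the residual (same shape as ``task_evoked``) and the per-sensor
    weights.  Near-collinear auditory/visual regressors trigger a warning
    carrying the per-sensor condition numbers.
    """
    t = np.asarray(task_evoked, float)
    a = np.asarray(aud_evoked, float)
    v = np.asarray(vis_evoked, float)
    if not (t.shape == a.shape == v.shape):
        raise ParameterError("task, auditory and visual arrays must share a grid")
    orig_shape = t.shape
    n_sensors = orig_shape[0]
    tf = t.reshape(n_sensors, -1)
    af = a.reshape(n_sensors, -1)
    vf = v.reshape(n_sensors, -1)
    beta_a = np.zeros(n_sensors)
    beta_v = np.zeros(n_sensors)
    conds = np.zeros(n_sensors)
    resid = np.empty_like(tf)
    for s in range(n_sensors):
        X = np.column_stack([af[s], vf[s]])
        conds[s] = np.linalg.cond(X)
        sol, *_ = np.linalg.lstsq(X, tf[s], rcond=None)
        beta_a[s], beta_v[s] = sol
        resid[s] = tf[s] - X @ sol
    if np.any(conds > 1e8):
        warnings.warn(
            f"near-collinear unisensory regressors; condition numbers up to "
            f"{conds.max():.2e} (per-sensor: {np.round(conds, 1).tolist()})",
            CollinearityWarning)
    return resid.reshape(orig_shape), UnisensoryWeights(beta_a, beta_v)


# ---------------------------------------------------------------------------
# Cluster RMS and brain-behavior statistics
# ---------------------------------------------------------------------------


def cluster_rms(data: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Root-mean-square amplitude over a sensor x time cluster mask.

    ``data`` is (..., sensors, time); the RMS is taken over the masked
    samples, returning one scalar per leading index (per trial or per
    condition).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ParameterError("empty cluster mask")
    data = np.asarray(data, float)
    vals = data[..., mask]  # (..., n_masked)
    return np.sqrt(np.mean(vals ** 2, axis=-1))


def regress_evoked_on_mcd(rms: pd.DataFrame, predictor: str = "corr_z"):
    """Mixed linear regression of cluster RMS on a detector summary, per task.

    ``rms`` has columns participant, task, stimulus, rms and the predictor
    column (z-scored summary).  Fits, per task, a linear mixed model with a
    participant random intercept, and tests the task x predictor interaction
    in a pooled model.  Returns a dict
    ``{task: {"slope", "se", "p"}, "interaction_p": float}``.
    """
    import statsmodels.formula.api as smf

    out = {}
    for task, sub in rms.groupby("task"):
        md = smf.mixedlm(f"rms ~ {predictor}", sub, groups=sub["participant"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = md.fit(reml=True)
        out[task] = {"slope": float(fit.params[predictor]),
                     "se": float(fit.bse[predictor]),
                     "p": float(fit.pvalues[predictor])}
    tasks = sorted(rms["task"].unique())
    if len(tasks) == 2:
        pooled = rms.copy()
        pooled["task_c"] = (pooled["task"] == tasks[1]).astype(float)
        md = smf.mixedlm(f"rms ~ {predictor} * task_c", pooled,
                         groups=pooled["participant"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = md.fit(reml=True)
        out["interaction_p"] = float(fit.pvalues[f"{predictor}:task_c"])
    return out


def single_trial_brain_behavior(rms: np.ndarray, responses: np.ndarray,
                                tasks: np.ndarray, participants: np.ndarray,
                                n_nodes: int = 12):
    """Nested mixed-logistic comparison of single-trial activity models.

    Candidate models for P(response=1): null (intercept only), activity,
    activity + task, activity x task, each with a participant random
    intercept.  Models are compared by likelihood-ratio tests between nested
    pairs with AIC as tie-break; per-task simple effects of activity are
    reported from separate per-task fits.  Perfect separation (deterministic
    responses given activity) is detected from a diverging slope and flagged.
    """
    rms = np.asarray(rms, float)
    responses = np.asarray(responses, int)
    tasks = np.asarray(tasks)
    participants = np.asarray(participants)
    act = (rms - rms.mean()) / rms.std()
    task_names = sorted(set(tasks.tolist()))
    task_c = (tasks == task_names[-1]).astype(float) if len(task_names) > 1 else np.zeros_like(act)

    def fit_glmm(X):
        """ML fit of a mixed logistic with design X (columns incl. intercept)."""
        from scipy import optimize as opt
        from scipy.special import logsumexp as lse
        p_ids = {p: i for i, p in enumerate(sorted(set(participants.tolist())))}
        pidx = np.array([p_ids[p] for p in participants])
        nodes, logw = np.polynomial.hermite.hermgauss(n_nodes)
        logw = np.log(logw) - 0.5 * np.log(np.pi)

        def nll(theta):
            beta, s = theta[:-1], np.exp(theta[-1])
            eta = X @ beta  # (n,)
            b = np.sqrt(2.0) * s * nodes  # (K,)
            e = eta[:, None] + b[None, :]
            ll = -(responses[:, None] * np.logaddexp(0, -e)
                   + (1 - responses)[:, None] * np.logaddexp(0, e))
            per = np.zeros((len(p_ids), n_nodes))
            np.add.at(per, pidx, ll)
            return -lse(per + logw, axis=1).sum()

        x0 = np.zeros(X.shape[1] + 1)
        res = opt.minimize(nll, x0, method="BFGS", options={"maxiter": 300})
        return res.x, -res.fun, X.shape[1] + 1

    ones = np.ones_like(act)
    designs = {
        "null": np.column_stack([ones]),
        "activity": np.column_stack([ones, act]),
        "activity+task": np.column_stack([ones, act, task_c]),
        "activity*task": np.column_stack([ones, act, task_c, act * task_c]),
    }
    fits = {k: fit_glmm(X) for k, X in designs.items()}
    lls = {k: v[1] for k, v in fits.items()}
    ks = {k: v[2] for k, v in fits.items()}
    aics = {k: 2 * ks[k] - 2 * lls[k] for k in fits}

    nested = [("null", "activity"), ("activity", "activity+task"),
              ("activity+task", "activity*task")]
    selected = "null"
    lrt = {}
    for small, big in nested:
        lr = 2 * (lls[big] - lls[small])
        df = ks[big] - ks[small]
        p = stats.chi2.sf(max(lr, 0.0), df)
        lrt[f"{small}->{big}"] = {"lr": float(lr), "p": float(p)}
        if p < 0.05 and selected == small:
            selected = big
    # AIC tie-break: if LRT path stopped but a larger model has lower AIC by >2
    best_aic = min(aics, key=aics.get)
    if aics[best_aic] < aics[selected] - 2:
        selected = best_aic

    interaction = float(fits["activity*task"][0][3])
    separation = abs(fits["activity"][0][1]) > 15  # diverging slope on z-scored activity

    simple = {}
    for tname in task_names:
        m = tasks == tname
        simple[tname] = _simple_effect(act[m], responses[m], participants[m],
                                       n_nodes)
    return {"selected": selected, "lrt": lrt, "aic": aics,
            "interaction_beta": interaction, "separation_flag": bool(separation),
            "simple_effects": simple}


def _simple_effect(act, resp, part, n_nodes):
    """Trial-level random-intercept logistic slope of response on activity."""
    parts = sorted(set(part.tolist()))
    from scipy import optimize as opt
    from scipy.special import logsumexp as lse
    pidx = np.array([parts.index(p) for p in part])
    nodes, logw = np.polynomial.hermite.hermgauss(n_nodes)
    logw = np.log(logw) - 0.5 * np.log(np.pi)

    def nll(theta):
        b0, b1, ls = theta
        s = np.exp(ls)
        e = (b0 + b1 * act)[:, None] + np.sqrt(2) * s * nodes[None, :]
        ll = -(resp[:, None] * np.logaddexp(0, -e)
               + (1 - resp)[:, None] * np.logaddexp(0, e))
        per = np.zeros((len(parts), n_nodes))
        np.add.at(per, pidx, ll)
        return -lse(per + logw, axis=1).sum()

    res = opt.minimize(nll, np.zeros(3), method="BFGS", options={"maxiter": 300})
    h = 1e-4  # finite-difference step for the Hessian-based SE
    th = res.x
    H = np.zeros((3, 3))
    f0 = nll(th)
    for i in range(3):
        for j in range(i, 3):
            ei = np.eye(3)[i] * h
            ej = np.eye(3)[j] * h
            H[i, j] = H[j, i] = (nll(th + ei + ej) - nll(th + ei)
                                 - nll(th + ej) + f0) / h ** 2
    try:
        se = float(np.sqrt(np.linalg.inv(H)[1, 1]))
    except (np.linalg.LinAlgError, ValueError):
        se = np.nan
    z = th[1] / se if se and np.isfinite(se) and se > 0 else np.nan
    p = 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
    return {"beta": float(th[1]), "se": se, "p": float(p) if np.isfinite(p) else np.nan}


# ---------------------------------------------------------------------------
# Filtering / resampling (pass-through for band-limited synthetic data)
# ---------------------------------------------------------------------------


def bandpass_resample(recording: np.ndarray, rate: float,
                      band: tuple[float, float] = (1.0, 40.0),
                      target_rate: float = EPOCH_RATE) -> tuple[np.ndarray, float]:
    """Zero-phase band-pass then integer decimation to the target rate."""
    recording = np.asarray(recording, float)
    nyq = rate / 2.0
    sos = signal.butter(4, [band[0] / nyq, band[1] / nyq], btype="band",
                        output="sos")
    filtered = signal.sosfiltfilt(sos, recording, axis=-1)
    factor = int(round(rate / target_rate))
    if factor > 1:
        filtered = signal.decimate(filtered, factor, axis=-1, zero_phase=True)
    return filtered, rate / max(factor, 1)
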