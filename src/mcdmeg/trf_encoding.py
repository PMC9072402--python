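"""Model-based temporal response function (TRF) encoding of sensor data.

Each sensor's time series is modelled as a sum of lagged linear convolutions
of the detector's internal component time courses (auditory input, visual
input, correlation output, lag output):

    MEG(n, t) = sum_i sum_{tau = t_min}^{t_max} TRF(n, i, tau) * MCD(i, t - tau) + eps(n, t)

The filters TRF(n, i, .) are estimated per sensor by ridge regression on a
lagged design matrix, scored by cross-validated Pearson correlation between
predicted and held-out recordings (one fold per participant x stimulus;
13 x 6 = 78 folds at full scale), and attributed per component by zeroing
all other components' weights before prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .evoked_pipeline import EpochSet
from .mcd_core import ParameterError

__all__ = [
    "LagWindow", "TRFModel", "EncodingScore",
    "lagged_design", "fit_trf", "predict_trf", "crossval_score",
    "component_contribution", "windowed_scores", "COMPONENT_NAMES",
]

COMPONENT_NAMES = ("mcd_a", "mcd_v", "corr", "lag")

#: Ridge penalty grid for the nested-CV lambda policy.
LAMBDA_GRID = tuple(float(x) for x in np.logspace(-2, 4, 7))


@dataclass(frozen=True)
class LagWindow:
    """Causal lag range of the filters.  Default 0-500 ms."""

    t_min: float = 0.0
    t_max: float = 0.5
    rate: float = 250.0

    def __post_init__(self):
        if not self.t_min < self.t_max:
            raise ParameterError("t_min must be < t_max")

    @property
    def n_lags(self) -> int:
        return int(round((self.t_max - self.t_min) * self.rate)) + 1

    @property
    def lags(self) -> np.ndarray:
        """Lag offsets in samples (positive = predictor shifted into the past)."""
        i0 = int(round(self.t_min * self.rate))
        return np.arange(i0, i0 + self.n_lags)


@dataclass
class TRFModel:
    weights: np.ndarray  # (sensors, components, lags)
    ridge_lambda: float
    lag_window: LagWindow
    component_names: tuple[str, ...] = COMPONENT_NAMES
    predictor_mean: np.ndarray | None = None  # training standardisation
    predictor_sd: np.ndarray | None = None

    def __post_init__(self):
        if not np.all(np.isfinite(self.weights)):
            raise ParameterError("TRF weights must be finite")
        if self.weights.shape[1] != len(self.component_names):
            raise ParameterError("component axis does not match names")


@dataclass
class EncodingScore:
    rho: np.ndarray  # (sensors, components) fold-averaged correlations
    per_fold: np.ndarray  # (folds, sensors, components)
    component_names: tuple[str, ...] = COMPONENT_NAMES
    constant_prediction: np.ndarray | None = None  # flag: rho defined as 0

    def __post_init__(self):
        if np.any(np.abs(self.rho) > 1 + 1e-9):
            raise ParameterError("correlations must lie in [-1, 1]")


# ---------------------------------------------------------------------------
# Design matrix
# ---------------------------------------------------------------------------


def lagged_design(components: np.ndarray, lag_window: LagWindow) -> np.ndarray:
    """Time-lagged copies of each component, zero-padded at the edges.

    ``components`` is (n_components, n_times) for one trial; the output is
    (n_times, n_components * n_lags) with columns ordered (component, lag).
    Column (i, L) holds component i delayed by L samples.
    """
    comps = np.atleast_2d(np.asarray(components, float))
    n_comp, n_times = comps.shape
    lags = lag_window.lags
    X = np.zeros((n_times, n_comp * lags.size))
    for ci in range(n_comp):
        for li, L in enumerate(lags):
            col = ci * lags.size + li
            if L >= 0:
                if L < n_times:
                    X[L:, col] = comps[ci, :n_times - L]
            else:
                if -L < n_times:
                    X[:n_times + L, col] = comps[ci, -L:]
    return X


def _stack_trials(epochs: np.ndarray, comps_per_trial: np.ndarray,
                  lag_window: LagWindow):
    """Stack per-trial designs and targets along time.

    epochs: (trials, sensors, time); comps_per_trial: (trials, comp, time).
    Returns X (trials*time, comp*lags) and Y (trials*time, sensors); each
    trial is lagged independently (no bleed across trial boundaries).
    """
    Xs = [lagged_design(c, lag_window) for c in comps_per_trial]
    X = np.vstack(Xs)
    Y = np.concatenate([e.T for e in epochs], axis=0)
    return X, Y


# ---------------------------------------------------------------------------
# Ridge fit / prediction
# ---------------------------------------------------------------------------


def fit_trf(epochs: np.ndarray, comps_per_trial: np.ndarray,
            lag_window: LagWindow, ridge_lambda: float = 1.0,
            standardize: bool = True) -> TRFModel:
    """Per-sensor ridge solution of the lagged encoding model.

    All sensors share one Gram matrix, so the solve is a single linear
    system with multiple right-hand sides.  ``ridge_lambda = 0`` requires a
    well-conditioned design (a conditioning error is raised otherwise).
    """
    epochs = np.asarray(epochs, float)
    comps = np.asarray(comps_per_trial, float)
    n_comp = comps.shape[1]
    mean = comps.mean(axis=(0, 2)) if standardize else np.zeros(n_comp)
    sd = comps.std(axis=(0, 2)) if standardize else np.ones(n_comp)
    sd = np.where(sd > 0, sd, 1.0)
    comps = (comps - mean[None, :, None]) / sd[None, :, None]
    X, Y = _stack_trials(epochs, comps, lag_window)
    G = X.T @ X + ridge_lambda * np.eye(X.shape[1])
    if ridge_lambda == 0:
        cond = np.linalg.cond(G)
        if cond > 1e12:
            raise np.linalg.LinAlgError(
                f"singular design (cond {cond:.2e}) with lambda = 0")
    W = np.linalg.solve(G, X.T @ Y)  # (comp*lags, sensors)
    weights = W.T.reshape(Y.shape[1], n_comp, lag_window.n_lags)
    return TRFModel(weights, ridge_lambda, lag_window,
                    component_names=tuple(COMPONENT_NAMES[:n_comp])
                    if n_comp <= len(COMPONENT_NAMES)
                    else tuple(f"c{i}" for i in range(n_comp)),
                    predictor_mean=mean, predictor_sd=sd)


def predict_trf(model: TRFModel, comps_per_trial: np.ndarray,
                component: int | None = None) -> np.ndarray:
    """Predicted (trials, sensors, time) activity; optionally from a single
    component's weights with all others zeroed."""
    comps = np.asarray(comps_per_trial, float)
    comps = (comps - model.predictor_mean[None, :, None]) / model.predictor_sd[None, :, None]
    W = model.weights
    if component is not None:
        keep = np.zeros_like(W)
        keep[:, component] = W[:, component]
        W = keep
    n_trials, _, n_times = comps.shape
    out = np.empty((n_trials, W.shape[0], n_times))
    Wf = W.reshape(W.shape[0], -1)  # (sensors, comp*lags)
    for tr in range(n_trials):
        X = lagged_design(comps[tr], model.lag_window)  # (time, comp*lags)
        out[tr] = Wf @ X.T
    return out


def _safe_rho(pred: np.ndarray, obs: np.ndarray) -> tuple[float, bool]:
    """Pearson correlation; defined as 0 (with a flag) for constant inputs."""
    if pred.std() == 0 or obs.std() == 0:
        return 0.0, True
    return float(np.corrcoef(pred.ravel(), obs.ravel())[0, 1]), False


# ---------------------------------------------------------------------------
# Cross-validated scoring and attribution
# ---------------------------------------------------------------------------


def crossval_score(epochs: np.ndarray, comps_per_trial: np.ndarray,
                   fold_ids: np.ndarray, lag_window: LagWindow,
                   ridge_lambda: float | str = 1.0,
                   time_slice: slice | None = None) -> EncodingScore:
    """Leave-one-fold-out encoding scores, per sensor and per component.

    ``fold_ids`` assigns each trial to a fold (one fold per participant x
    stimulus at full scale).  ``ridge_lambda`` is a fixed penalty or
    ``"nested"``, which selects the penalty on each training set by an inner
    leave-one-fold-out search over a logarithmic grid before touching the
    test fold.  Per-fold Pearson correlations are computed between the
    prediction of each single component (others zeroed) and the held-out
    data, then averaged across folds.
    """
    epochs = np.asarray(epochs, float)
    comps = np.asarray(comps_per_trial, float)
    fold_ids = np.asarray(fold_ids)
    folds = np.unique(fold_ids)
    n_comp = comps.shape[1]
    n_sensors = epochs.shape[1]
    per_fold = np.zeros((folds.size, n_sensors, n_comp))
    const_flag = np.zeros((n_sensors, n_comp), dtype=bool)
    sl = time_slice if time_slice is not None else slice(None)
    if isinstance(sl, slice) and epochs[:, :, sl].shape[-1] == 0:
        raise ParameterError("empty scoring window")
    for fi, f in enumerate(folds):
        train = fold_ids != f
        test = fold_ids == f
        lam = (_nested_lambda(epochs[train], comps[train], fold_ids[train],
                              lag_window)
               if ridge_lambda == "nested" else float(ridge_lambda))
        model = fit_trf(epochs[train], comps[train], lag_window, lam)
        for ci in range(n_comp):
            pred = predict_trf(model, comps[test], component=ci)
            for s in range(n_sensors):
                rho, flagged = _safe_rho(pred[:, s, sl], epochs[test][:, s, sl])
                per_fold[fi, s, ci] = rho
                const_flag[s, ci] |= flagged
    score = EncodingScore(per_fold.mean(axis=0), per_fold,
                          component_names=tuple(COMPONENT_NAMES[:n_comp])
                          if n_comp <= len(COMPONENT_NAMES)
                          else tuple(f"c{i}" for i in range(n_comp)),
                          constant_prediction=const_flag)
    return score


def _nested_lambda(epochs, comps, fold_ids, lag_window,
                   grid=LAMBDA_GRID) -> float:
    """Inner leave-one-fold-out selection of the ridge penalty (full-model
    prediction score, averaged over sensors and inner folds)."""
    folds = np.unique(fold_ids)
    best_lam, best = grid[0], -np.inf
    for lam in grid:
        tot = 0.0
        for f in folds:
            tr = fold_ids != f
            te = fold_ids == f
            model = fit_trf(epochs[tr], comps[tr], lag_window, lam)
            pred = predict_trf(model, comps[te])
            for s in range(epochs.shape[1]):
                rho, _ = _safe_rho(pred[:, s], epochs[te][:, s])
                tot += rho
        if tot > best:
            best, best_lam = tot, lam
    return float(best_lam)


def component_contribution(model: TRFModel, epochs: np.ndarray,
                           comps_per_trial: np.ndarray,
                           component: int) -> np.ndarray:
    """Per-sensor correlation of the single-component prediction with data."""
    pred = predict_trf(model, comps_per_trial, component=component)
    epochs = np.asarray(epochs, float)
    out = np.zeros(epochs.shape[1])
    for s in range(epochs.shape[1]):
        out[s], _ = _safe_rho(pred[:, s], epochs[:, s])
    return out


def windowed_scores(epochs: np.ndarray, comps_per_trial: np.ndarray,
                    fold_ids: np.ndarray, lag_window: LagWindow,
                    epoch_times: np.ndarray, split_at: float = 0.5,
                    ridge_lambda: float | str = 1.0,
                    early: tuple[float, float] = (0.0, None),
                    late: tuple[float, float] = (None, 1.0)):
    """Early/late split of the scoring window (fits are shared; only the
    correlation window differs).  Default split: [0, 0.5) vs [0.5, 1.0) s."""
    t = np.asarray(epoch_times, float)
    e0, e1 = early[0], split_at if early[1] is None else early[1]
    l0, l1 = split_at if late[0] is None else late[0], late[1]
    early_idx = np.flatnonzero((t >= e0) & (t < e1))
    late_idx = np.flatnonzero((t >= l0) & (t < l1))
    if early_idx.size == 0 or late_idx.size == 0:
        raise ParameterError("empty early or late scoring window")
    early_score = crossval_score(epochs, comps_per_trial, fold_ids, lag_window,
                                 ridge_lambda,
                                 time_slice=slice(early_idx[0], early_idx[-1] + 1))
    late_score = crossval_score(epochs, comps_per_trial, fold_ids, lag_window,
                                ridge_lambda,
                                time_slice=slice(late_idx[0], late_idx[-1] + 1))
    return early_score, late_score
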