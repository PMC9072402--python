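"""Generative twin of the study: behavioral and neural data with known truth.

Emulates the structure the analysis assumes so every stage runs without any
download: a factorial trial design (two judgment tasks x 3 blocks x 25
repetitions of 6 audiovisual sequences, plus passive unisensory localizer
blocks; 1500 trials per participant at full scale), logistic observers whose
responses are driven by the z-scored time-averaged detector outputs, and
multichannel epochs built as temporal-response-function convolutions of the
detector component time courses plus weighted unisensory evoked responses
plus noise:

    MEG(n, t) = sum_i TRF_true(n, i, .) * MCD_i(t)
                + beta_A(n) * aud(n, t) + beta_V(n) * vis(n, t) + noise

Localizer epochs contain only the respective unisensory term plus noise.
Ground-truth filters are damped oscillations, so recovery is checkable both
numerically and by eye.  All randomness flows from explicit seeds;
regeneration is bit-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .behavior_fit import TASK_PREDICTOR, TASKS, stimulus_z_summaries
from .cluster_stats import SensorAdjacency
from .evoked_pipeline import EPOCH_RATE, EPOCH_WINDOW, EpochSet
from .mcd_core import (
    MCDParams,
    PARTICIPANT_PARAMS,
    EventSequence,
    ParameterError,
    encode_events,
    mcd_respond,
)
from .trf_encoding import COMPONENT_NAMES, LagWindow

__all__ = [
    "GroundTruth", "SensorLayout", "make_design", "simulate_observer",
    "simulate_epochs", "make_layout", "component_traces",
    "default_ground_truth",
]

LOCALIZER_TASKS = ("localizer_A", "localizer_V")

#: Default link parameters: slopes are the study's fitted effect sizes for
#: the causality (CORR) and temporal-order (LAG) judgments.
DEFAULT_LINK = {"causality": {"beta0": 0.0, "beta1": 1.80},
                "temporal_order": {"beta0": 0.0, "beta1": 1.02}}

#: Between-participant SD of the random intercept (logit units).
DEFAULT_SIGMA_B = 1.0

DEFAULT_SNR = 5.0


@dataclass
class SensorLayout:
    positions: np.ndarray  # (n_sensors, 2) grid coordinates
    adjacency: SensorAdjacency
    grid_shape: tuple[int, int]

    @property
    def n_sensors(self) -> int:
        return self.positions.shape[0]

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.positions, columns=["x", "y"]).to_csv(path, index=False)


def make_layout(n_sensors: int = 102,
                grid_shape: tuple[int, int] | None = None) -> SensorLayout:
    """Planar sensor grid with 8-neighborhood adjacency.

    The default 102-sensor layout (the merged-triplet channel count of a
    306-channel system) is a 6 x 17 grid.  Geometry is synthetic: real
    helmet layouts would come from a user-supplied adjacency file.
    """
    if grid_shape is None:
        if n_sensors == 102:
            grid_shape = (6, 17)
        else:
            rows = int(np.floor(np.sqrt(n_sensors)))
            while n_sensors % rows:
                rows -= 1
            grid_shape = (rows, n_sensors // rows)
    if grid_shape[0] * grid_shape[1] != n_sensors:
        raise ParameterError(f"grid {grid_shape} does not hold {n_sensors} sensors")
    rr, cc = np.meshgrid(np.arange(grid_shape[0]), np.arange(grid_shape[1]),
                         indexing="ij")
    pos = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    diff_r = np.abs(pos[:, 0:1] - pos[:, 0:1].T)
    diff_c = np.abs(pos[:, 1:2] - pos[:, 1:2].T)
    adj = (np.maximum(diff_r, diff_c) == 1)
    return SensorLayout(pos, SensorAdjacency(adj), grid_shape)


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------


def _damped_oscillation(lags_s: np.ndarray, freq: float, decay: float,
                        amplitude: float = 1.0, phase: float = 0.0) -> np.ndarray:
    return amplitude * np.exp(-lags_s / decay) * np.sin(2 * np.pi * freq * lags_s + phase)


@dataclass
class GroundTruth:
    """Everything needed to regenerate a synthetic dataset bit-identically."""

    mcd_params: tuple[MCDParams, ...]
    link_params: dict
    sigma_b: float
    trf_true: np.ndarray  # (sensors, components, lags)
    trf_lag_window: LagWindow
    beta_a: np.ndarray  # per-sensor unisensory mixing weights in task blocks
    beta_v: np.ndarray
    uni_gain_a: np.ndarray  # per-sensor unisensory response topographies
    uni_gain_v: np.ndarray
    snr: float
    noise: str  # "white" or "pink"
    seed: int
    component_sensors: dict = field(default_factory=dict)  # name -> driven sensors

    def to_json(self, path: str | Path) -> None:
        d = {
            "mcd_params": [[p.tau_a, p.tau_v, p.tau_av] for p in self.mcd_params],
            "link_params": self.link_params,
            "sigma_b": self.sigma_b,
            "trf_true": self.trf_true.tolist(),
            "trf_lag_window": [self.trf_lag_window.t_min,
                               self.trf_lag_window.t_max,
                               self.trf_lag_window.rate],
            "beta_a": self.beta_a.tolist(), "beta_v": self.beta_v.tolist(),
            "uni_gain_a": self.uni_gain_a.tolist(),
            "uni_gain_v": self.uni_gain_v.tolist(),
            "snr": self.snr, "noise": self.noise, "seed": self.seed,
            "component_sensors": {k: list(map(int, v))
                                  for k, v in self.component_sensors.items()},
        }
        Path(path).write_text(json.dumps(d))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            mcd_params=tuple(MCDParams(*row) for row in d["mcd_params"]),
            link_params=d["link_params"], sigma_b=d["sigma_b"],
            trf_true=np.array(d["trf_true"]),
            trf_lag_window=LagWindow(*d["trf_lag_window"]),
            beta_a=np.array(d["beta_a"]), beta_v=np.array(d["beta_v"]),
            uni_gain_a=np.array(d["uni_gain_a"]),
            uni_gain_v=np.array(d["uni_gain_v"]),
            snr=d["snr"], noise=d["noise"], seed=d["seed"],
            component_sensors={k: np.array(v)
                               for k, v in d["component_sensors"].items()},
        )


def default_ground_truth(layout: SensorLayout, n_participants: int = 13,
                         seed: int = 0, snr: float = DEFAULT_SNR,
                         noise: str = "white",
                         lag_window: LagWindow | None = None) -> GroundTruth:
    """Damped-oscillation TRFs on component-specific sensor patches.

    Each detector component drives a contiguous quarter of the sensor array
    (with small cross-talk-free amplitude falloff), so that component
    attribution has a known spatial answer.  Participant time constants
    default to the fitted per-participant table, recycled if more
    participants are requested.
    """
    rng = np.random.default_rng(seed)
    lw = lag_window or LagWindow(0.0, 0.3, EPOCH_RATE)
    n_sensors = layout.n_sensors
    lags_s = (lw.lags - lw.lags[0]) / lw.rate
    trf = np.zeros((n_sensors, len(COMPONENT_NAMES), lw.n_lags))
    comp_sensors = {}
    patch = max(n_sensors // len(COMPONENT_NAMES), 1)
    for ci, name in enumerate(COMPONENT_NAMES):
        sensors = np.arange(ci * patch, min((ci + 1) * patch, n_sensors))
        comp_sensors[name] = sensors
        freq = rng.uniform(3.0, 8.0)
        decay = rng.uniform(0.05, 0.15)
        phase = rng.uniform(0, 2 * np.pi)
        kernel = _damped_oscillation(lags_s, freq, decay, 1.0, phase)
        amps = rng.uniform(0.5, 1.5, sensors.size)
        trf[sensors, ci, :] = amps[:, None] * kernel[None, :]
    params = tuple(PARTICIPANT_PARAMS[i % len(PARTICIPANT_PARAMS)]
                   for i in range(n_participants))
    return GroundTruth(
        mcd_params=params, link_params=DEFAULT_LINK, sigma_b=DEFAULT_SIGMA_B,
        trf_true=trf, trf_lag_window=lw,
        beta_a=rng.normal(1.0, 0.1, n_sensors),
        beta_v=rng.normal(1.0, 0.1, n_sensors),
        uni_gain_a=rng.normal(0.0, 1.0, n_sensors),
        uni_gain_v=rng.normal(0.0, 1.0, n_sensors),
        snr=snr, noise=noise, seed=seed, component_sensors=comp_sensors,
    )


# ---------------------------------------------------------------------------
# Trial design
# ---------------------------------------------------------------------------


def _constrained_order(items: np.ndarray, rng: np.random.Generator,
                       prefix: list, max_run: int = 3,
                       max_tries: int = 200) -> np.ndarray:
    """Permutation of ``items`` with no value repeated more than ``max_run``
    times consecutively (counting a trailing prefix from the previous block)."""
    items = np.asarray(items)
    for _ in range(max_tries):
        order = rng.permutation(items)
        seq = list(prefix) + order.tolist()
        ok = True
        run = 1
        for i in range(1, len(seq)):
            run = run + 1 if seq[i] == seq[i - 1] else 1
            if run > max_run:
                ok = False
                break
        if ok:
            return order
    raise ParameterError("could not satisfy the run-length constraint")


def make_design(n_participants: int = 13, reps: int = 25,
                task_blocks: int = 3, localizer_blocks: int = 2,
                n_stimuli: int = 6, seed: int = 0) -> pd.DataFrame:
    """Full factorial trial listing with pseudo-random stimulus order.

    Defaults give 2 x 3 x 25 x 6 + 2 x 2 x 25 x 6 = 1500 trials per
    participant, 75 presentations of each stimulus per judgment task, and no
    stimulus more than three times consecutively within a participant's
    trial stream.
    """
    rng = np.random.default_rng(seed)
    stimuli = np.array([f"s{i}" for i in range(n_stimuli)])
    rows = []
    for p in range(n_participants):
        blocks = ([(t, b) for t in TASKS for b in range(task_blocks)]
                  + [(t, b) for t in LOCALIZER_TASKS for b in range(localizer_blocks)])
        rng.shuffle(blocks)
        prefix: list = []
        for task, b in blocks:
            items = np.repeat(stimuli, reps)
            order = _constrained_order(items, rng, prefix)
            prefix = order[-3:].tolist()
            for s in order:
                rows.append((p, task, s, f"{task}_b{b}"))
    df = pd.DataFrame(rows, columns=["participant", "task", "stimulus", "block"])
    df.insert(0, "trial_index", np.arange(len(df)))
    return df


# ---------------------------------------------------------------------------
# Behavioral observer
# ---------------------------------------------------------------------------


def simulate_observer(truth: GroundTruth, design: pd.DataFrame,
                      stimuli, seed: int = 0) -> pd.DataFrame:
    """Bernoulli responses from the logistic observer model.

    response ~ Bernoulli(logistic(beta0_task + beta1_task * z + b_p)) where z
    is the participant-specific z-scored detector summary of the presented
    stimulus (CORR for causality, LAG for temporal order) and b_p is the
    participant's random intercept for that task.  Localizer trials are
    passive and get response = 0.
    """
    rng = np.random.default_rng(seed)
    seqs = list(stimuli.sequences) if hasattr(stimuli, "sequences") else list(stimuli)
    participants = sorted(design["participant"].unique())
    stim_ids = sorted(design["stimulus"].unique())
    if len(stim_ids) != len(seqs):
        raise ParameterError("design stimuli do not match the sequence list")
    z_by_p = {}
    for pi, p in enumerate(participants):
        params = truth.mcd_params[pi % len(truth.mcd_params)]
        z_by_p[p] = stimulus_z_summaries(seqs, params)
    b = {(p, t): rng.normal(0.0, truth.sigma_b)
         for p in participants for t in TASKS}
    out = design.copy()
    resp = np.zeros(len(design), dtype=int)
    for i, row in enumerate(design.itertuples(index=False)):
        if row.task not in TASKS:
            continue
        z = z_by_p[row.participant][TASK_PREDICTOR[row.task]]
        x = z[stim_ids.index(row.stimulus)]
        lp = truth.link_params[row.task]
        pr = expit(lp["beta0"] + lp["beta1"] * x + b[(row.participant, row.task)])
        resp[i] = rng.binomial(1, pr)
    out["response"] = resp
    return out


# ---------------------------------------------------------------------------
# Neural epochs
# ---------------------------------------------------------------------------


def component_traces(seq: EventSequence, params: MCDParams,
                     rate: float = EPOCH_RATE,
                     window: tuple[float, float] = EPOCH_WINDOW,
                     sim_rate: float = 1000.0) -> np.ndarray:
    """Detector component time courses on the epoch grid.

    Simulated at ``sim_rate`` then decimated by integer stride; samples
    before stimulus onset (t < 0) are zero.  Returns (4, n_times) ordered as
    (mcd_a, mcd_v, corr, lag).
    """
    stride = int(round(sim_rate / rate))
    n_times = int(round((window[1] - window[0]) * rate))
    n_pre = int(round(-window[0] * rate))
    horizon = window[1]
    s_a, s_v = encode_events(seq, sim_rate, horizon=horizon)
    resp = mcd_respond(s_a, s_v, params, first_onset=seq.first_onset)
    out = np.zeros((4, n_times))
    for ci, name in enumerate(COMPONENT_NAMES):
        trace = getattr(resp, name).samples
        dec = trace[::stride]
        out[ci, n_pre:n_pre + dec.size] = dec[:n_times - n_pre]
    return out


def _unisensory_templates(seq: EventSequence, rate: float,
                          window: tuple[float, float]) -> tuple[np.ndarray, np.ndarray]:
    """Per-modality evoked templates: event train convolved with a fixed
    damped-oscillation response kernel (one per modality)."""
    n_times = int(round((window[1] - window[0]) * rate))
    n_pre = int(round(-window[0] * rate))
    t_kernel = np.arange(int(0.4 * rate)) / rate
    h_a = _damped_oscillation(t_kernel, freq=9.0, decay=0.08)
    h_v = _damped_oscillation(t_kernel, freq=6.0, decay=0.12)
    out = []
    for onsets, h in ((seq.auditory_onsets, h_a), (seq.visual_onsets, h_v)):
        train = np.zeros(n_times - n_pre)
        for on in onsets:
            i = int(round(on * rate))
            if i < train.size:
                train[i] += 1.0
        sig = np.convolve(train, h)[:train.size]
        full = np.zeros(n_times)
        full[n_pre:] = sig
        out.append(full)
    return out[0], out[1]


def simulate_epochs(truth: GroundTruth, design: pd.DataFrame, stimuli,
                    layout: SensorLayout, rate: float = EPOCH_RATE,
                    window: tuple[float, float] = EPOCH_WINDOW,
                    seed: int = 0) -> EpochSet:
    """Sensor epochs for every trial of the design (tasks and localizers).

    Task trials carry the TRF-convolved detector components plus the
    beta-weighted unisensory responses; localizer trials carry only their
    modality's unisensory response.  White (or 1/f) noise is scaled so that
    the dataset-wide deterministic-signal-to-noise variance ratio equals
    ``truth.snr``.
    """
    rng = np.random.default_rng(seed)
    seqs = list(stimuli.sequences) if hasattr(stimuli, "sequences") else list(stimuli)
    stim_ids = sorted(design["stimulus"].unique())
    participants = sorted(design["participant"].unique())
    n_times = int(round((window[1] - window[0]) * rate))
    n_sensors = layout.n_sensors
    if truth.trf_true.shape[0] != n_sensors:
        raise ParameterError("ground-truth TRFs do not match the layout")

    # per (participant, stimulus) deterministic task/localizer signals
    Wf = truth.trf_true.reshape(n_sensors, -1)
    lw = truth.trf_lag_window
    from .trf_encoding import lagged_design

    cache: dict[tuple, dict[str, np.ndarray]] = {}
    comp_cache: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}

    def comps_for(p_idx: int):
        if p_idx not in comp_cache:
            params = truth.mcd_params[p_idx % len(truth.mcd_params)]
            all_comps = np.stack([
                component_traces(q, params, rate, window) for q in seqs])
            mean = all_comps.mean(axis=(0, 2))
            sd = all_comps.std(axis=(0, 2))
            comp_cache[p_idx] = (all_comps, mean, np.where(sd > 0, sd, 1.0))
        return comp_cache[p_idx]

    def signals_for(p_idx: int, s_idx: int) -> dict[str, np.ndarray]:
        key = (p_idx, s_idx)
        if key not in cache:
            all_comps, mean, sd = comps_for(p_idx)
            # components standardized across this participant's stimulus set
            comps_z = (all_comps[s_idx] - mean[:, None]) / sd[:, None]
            X = lagged_design(comps_z, lw)  # (time, comp*lags)
            multi = Wf @ X.T  # (sensors, time)
            aud_t, vis_t = _unisensory_templates(seqs[s_idx], rate, window)
            aud = truth.uni_gain_a[:, None] * aud_t[None, :]
            vis = truth.uni_gain_v[:, None] * vis_t[None, :]
            cache[key] = {
                "task": multi + truth.beta_a[:, None] * aud
                        + truth.beta_v[:, None] * vis,
                "localizer_A": aud, "localizer_V": vis,
                "multi": multi,
            }
        return cache[key]

    data = np.empty((len(design), n_sensors, n_times))
    for i, row in enumerate(design.itertuples(index=False)):
        p_idx = participants.index(row.participant)
        s_idx = stim_ids.index(row.stimulus)
        sig = signals_for(p_idx, s_idx)
        data[i] = sig["task"] if row.task in TASKS else sig[row.task]

    sig_var = float(np.var(data))
    noise_sd = np.sqrt(sig_var / truth.snr) if truth.snr > 0 else 0.0
    if noise_sd > 0:
        if truth.noise == "pink":
            white = rng.normal(0.0, 1.0, data.shape)
            f = np.fft.rfftfreq(n_times, 1 / rate)
            with np.errstate(divide="ignore"):
                scale = np.where(f > 0, 1.0 / np.sqrt(f), 0.0)
            pink = np.fft.irfft(np.fft.rfft(white, axis=-1) * scale, n=n_times,
                                axis=-1)
            pink *= noise_sd / pink.std()
            data = data + pink
        else:
            data = data + rng.normal(0.0, noise_sd, data.shape)
    return EpochSet(data, rate=rate, window=window,
                    trial_meta=design.reset_index(drop=True))
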