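"""Cluster-based permutation inference for sensor x time statistic maps.

A paired t-map is thresholded at |t| > 2.6 (the two-sided critical value at
p = 0.01 for 77 degrees of freedom, i.e. 13 participants x 6 sequences - 1);
supra-threshold samples are grouped into connected components under sensor
adjacency combined with consecutive-time connectivity, positive and negative
clusters separately; cluster mass is the sum of t-values inside a cluster.
Corrected p-values come from a max-cluster-mass null distribution built by
randomly flipping the condition labels within pairs (equivalent to
sign-flipping the paired differences), with

    p = (1 + #{null >= observed}) / (1 + n_permutations).

A spatial-only variant tests per-sensor score maps (e.g. encoding-model
correlations) against zero across participants.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.sparse.csgraph import connected_components

from .mcd_core import ParameterError

__all__ = [
    "SensorAdjacency", "ClusterResult", "paired_tmap", "form_clusters",
    "permutation_p", "spatial_cluster_correct", "critical_t",
]

CLUSTER_THRESHOLD = 2.6
N_PERMUTATIONS = 10000


def critical_t(p: float = 0.01, df: int = 77) -> float:
    """Two-sided critical t value; at p = 0.01, df = 77 this rounds to 2.6."""
    return float(stats.t.ppf(1 - p / 2, df))


@dataclass(frozen=True)
class SensorAdjacency:
    """Symmetric boolean sensor x sensor adjacency with zero diagonal."""

    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=bool)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ParameterError("adjacency must be square")
        if not np.array_equal(m, m.T):
            raise ParameterError("adjacency must be symmetric")
        if m.diagonal().any():
            raise ParameterError("adjacency must have a zero diagonal")
        object.__setattr__(self, "matrix", m)

    @property
    def n_sensors(self) -> int:
        return self.matrix.shape[0]

    def n_components(self) -> int:
        n, _ = connected_components(sparse.csr_matrix(self.matrix))
        return int(n)

    def to_edge_csv(self, path: str | Path) -> None:
        i, j = np.nonzero(np.triu(self.matrix))
        pd.DataFrame({"sensor_i": i, "sensor_j": j}).to_csv(path, index=False)

    @classmethod
    def from_edge_csv(cls, path: str | Path, n_sensors: int) -> "SensorAdjacency":
        df = pd.read_csv(path)
        m = np.zeros((n_sensors, n_sensors), dtype=bool)
        m[df["sensor_i"], df["sensor_j"]] = True
        return cls(m | m.T)


@dataclass
class ClusterResult:
    members: np.ndarray  # (k, 2) int array of (sensor, time) indices
    mass: float
    polarity: int  # +1 or -1
    p_corrected: float = np.nan

    def to_json_dict(self) -> dict:
        return {"members": self.members.tolist(), "mass": self.mass,
                "polarity": self.polarity, "p_corrected": self.p_corrected}


def clusters_to_json(clusters: list[ClusterResult], path: str | Path) -> None:
    Path(path).write_text(json.dumps([c.to_json_dict() for c in clusters]))


# ---------------------------------------------------------------------------
# Statistic maps
# ---------------------------------------------------------------------------


def paired_tmap(cond_a: np.ndarray, cond_b: np.ndarray) -> tuple[np.ndarray, int]:
    """Elementwise paired t contrasting two conditions over observation pairs.

    ``cond_a``/``cond_b`` are (pairs, sensors, time); pairs typically flatten
    participant x stimulus (13 x 6 = 78 pairs giving df = 77).  Returns the
    t map (sensors x time) and its degrees of freedom.
    """
    a = np.asarray(cond_a, float)
    b = np.asarray(cond_b, float)
    if a.shape != b.shape or a.ndim != 3:
        raise ParameterError("conditions must be equal-shape (pairs, sensors, time)")
    d = a - b
    n = d.shape[0]
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, mean / (sd / np.sqrt(n)), 0.0)
    return t, n - 1


# ---------------------------------------------------------------------------
# Cluster formation
# ---------------------------------------------------------------------------


def _components(mask: np.ndarray, adjacency: SensorAdjacency,
                temporal: bool = True) -> list[np.ndarray]:
    """Connected components of a boolean sensor x time mask.

    Connectivity: same sensor at consecutive times (if ``temporal``) and
    adjacent sensors at the same time.
    """
    idx = np.argwhere(mask)
    if idx.size == 0:
        return []
    n_sensors, n_times = mask.shape
    flat = {(s, t): k for k, (s, t) in enumerate(map(tuple, idx))}
    rows, cols = [], []
    adj = adjacency.matrix
    for k, (s, t) in enumerate(idx):
        if temporal and t + 1 < n_times and mask[s, t + 1]:
            rows.append(k); cols.append(flat[(s, t + 1)])
        for s2 in np.flatnonzero(adj[s]):
            if mask[s2, t]:
                rows.append(k); cols.append(flat[(s2, t)])
    g = sparse.csr_matrix((np.ones(len(rows)), (rows, cols)),
                          shape=(len(idx), len(idx)))
    n_comp, labels = connected_components(g, directed=False)
    return [idx[labels == c] for c in range(n_comp)]


def form_clusters(tmap: np.ndarray, adjacency: SensorAdjacency,
                  threshold: float = CLUSTER_THRESHOLD,
                  temporal: bool = True) -> list[ClusterResult]:
    """Group supra-threshold samples (|t| > threshold) into signed clusters."""
    tmap = np.asarray(tmap, float)
    if tmap.shape[0] != adjacency.n_sensors:
        raise ParameterError("t map sensor count does not match adjacency")
    out = []
    for sign in (+1, -1):
        mask = sign * tmap > threshold
        for members in _components(mask, adjacency, temporal):
            mass = float(tmap[members[:, 0], members[:, 1]].sum())
            out.append(ClusterResult(members, mass, sign))
    out.sort(key=lambda c: -abs(c.mass))
    return out


def _max_null_mass(tmap: np.ndarray, adjacency: SensorAdjacency,
                   threshold: float, temporal: bool) -> float:
    best = 0.0
    for sign in (+1, -1):
        mask = sign * tmap > threshold
        for members in _components(mask, adjacency, temporal):
            m = abs(float(tmap[members[:, 0], members[:, 1]].sum()))
            best = max(best, m)
    return best


# ---------------------------------------------------------------------------
# Permutation null
# ---------------------------------------------------------------------------


def permutation_p(cond_a: np.ndarray, cond_b: np.ndarray,
                  adjacency: SensorAdjacency,
                  threshold: float = CLUSTER_THRESHOLD,
                  n_perm: int = N_PERMUTATIONS, seed: int = 0,
                  temporal: bool = True,
                  exhaustive: bool | None = None) -> list[ClusterResult]:
    """Cluster permutation test of a paired condition contrast.

    Within-pair label flips (sign flips of the paired differences) build a
    max-cluster-mass null over both polarities; each observed cluster gets
    p = (1 + #{null >= |mass|}) / (1 + n_draws).  With ``exhaustive`` (the
    default for <= 12 pairs when 2^pairs <= n_perm) all sign patterns are
    enumerated instead of sampled, and the identity pattern convention makes
    the enumeration exact.
    """
    a = np.asarray(cond_a, float)
    b = np.asarray(cond_b, float)
    tmap, _ = paired_tmap(a, b)
    clusters = form_clusters(tmap, adjacency, threshold, temporal)
    if not clusters:
        return []
    d = a - b
    n_pairs = d.shape[0]
    if exhaustive is None:
        exhaustive = n_pairs <= 12 and 2 ** n_pairs <= n_perm

    def tmap_of(signs: np.ndarray) -> np.ndarray:
        ds = d * signs[:, None, None]
        mean = ds.mean(axis=0)
        sd = ds.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(sd > 0, mean / (sd / np.sqrt(n_pairs)), 0.0)

    null = []
    if exhaustive:
        for code in range(2 ** n_pairs):
            signs = 1 - 2 * ((code >> np.arange(n_pairs)) & 1)
            null.append(_max_null_mass(tmap_of(signs), adjacency, threshold, temporal))
        null = np.array(null)
        denom = null.size  # exhaustive: the identity permutation is included
        for c in clusters:
            c.p_corrected = float((null >= abs(c.mass)).sum()) / denom
    else:
        rng = np.random.default_rng(seed)
        for _ in range(n_perm):
            signs = rng.choice([-1.0, 1.0], size=n_pairs)
            null.append(_max_null_mass(tmap_of(signs), adjacency, threshold, temporal))
        null = np.array(null)
        for c in clusters:
            c.p_corrected = float(1 + (null >= abs(c.mass)).sum()) / (1 + n_perm)
    return clusters


def spatial_cluster_correct(score_maps: np.ndarray, adjacency: SensorAdjacency,
                            threshold: float = CLUSTER_THRESHOLD,
                            n_perm: int = N_PERMUTATIONS,
                            seed: int = 0) -> list[ClusterResult]:
    """One-sample spatial cluster test of per-sensor score maps against zero.

    ``score_maps`` is (participants, sensors); clustering is spatial only
    (no time axis) and the null comes from participant-level sign flips.
    """
    maps = np.asarray(score_maps, float)
    if maps.ndim != 2:
        raise ParameterError("score maps must be (participants, sensors)")
    # reuse the paired machinery with a singleton time axis and a zero condition
    a = maps[:, :, None]
    b = np.zeros_like(a)
    return permutation_p(a, b, adjacency, threshold=threshold, n_perm=n_perm,
                         seed=seed, temporal=False)
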