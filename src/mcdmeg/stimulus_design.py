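"""Stimulus-selection procedure for the audiovisual judgment experiment.

A large pool of random 5-click/5-flash one-second sequences is drawn, every
candidate is scored by the detector (time-averaged CORR and LAG), and a small
set is selected that (a) spans a wide range of both outputs and (b) keeps the
Pearson correlation between the two summaries below a threshold, so causality
and temporal-order judgments can vary independently across stimuli.

The spread objective is the product of the CORR and LAG ranges over the set;
the search is greedy seeding from summary-space extremes followed by local
single-element swaps under a fixed evaluation budget.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .mcd_core import (
    DEFAULT_RATE,
    MCDParams,
    MEAN_OBSERVER_PARAMS,
    EventSequence,
    ParameterError,
    score_sequences,
)

__all__ = ["CandidatePool", "StimulusSet", "sample_sequence_pool",
           "select_stimulus_set", "SelectionError", "default_stimulus_set"]

MIN_GAP = 0.020  # within-modality inter-event gap (s): two 10 ms pulses may not overlap


class SelectionError(RuntimeError):
    """No admissible stimulus set found within the search budget."""


@dataclass(frozen=True)
class CandidatePool:
    sequences: tuple[EventSequence, ...]
    summaries: np.ndarray  # (n, 2): corr_avg, lag_avg
    rng_seed: int

    def __post_init__(self):
        if len(self.sequences) != self.summaries.shape[0]:
            raise ParameterError("summaries must align 1:1 with sequences")


@dataclass(frozen=True)
class StimulusSet:
    sequences: tuple[EventSequence, ...]
    summaries: np.ndarray  # (k, 2)
    selection_rho: float


def _draw_onsets(rng: np.random.Generator, n_events: int, duration: float,
                 min_gap: float, max_tries: int = 1000) -> np.ndarray:
    """Uniform onsets in [0, duration - pulse) with pairwise gaps >= min_gap.

    Rejection sampling; the admissible upper edge leaves room for the 10 ms
    physical pulse.
    """
    hi = duration - 0.010
    for _ in range(max_tries):
        t = np.sort(rng.uniform(0.0, hi, n_events))
        if n_events < 2 or np.diff(t).min() >= min_gap:
            return t
    raise ParameterError(
        f"could not draw {n_events} onsets with gap {min_gap} in {duration} s")


def sample_sequence_pool(n_pool: int, duration: float = 1.0, n_events: int = 5,
                         min_gap: float = MIN_GAP, rng_seed: int = 0,
                         params: MCDParams = MEAN_OBSERVER_PARAMS,
                         rate: float = DEFAULT_RATE) -> CandidatePool:
    """Draw random audiovisual sequences and score each with the detector."""
    if n_events * min_gap >= duration:
        raise ParameterError("infeasible: n_events * min_gap >= duration")
    rng = np.random.default_rng(rng_seed)
    seqs = []
    for i in range(n_pool):
        a = _draw_onsets(rng, n_events, duration, min_gap)
        v = _draw_onsets(rng, n_events, duration, min_gap)
        seqs.append(EventSequence(tuple(a), tuple(v), duration, label=f"cand{i:06d}"))
    summaries = score_sequences(seqs, params, rate=rate)
    return CandidatePool(tuple(seqs), summaries, rng_seed)


def _rho(s: np.ndarray) -> float:
    sx, sy = s[:, 0].std(), s[:, 1].std()
    if sx == 0 or sy == 0:
        return np.inf  # degenerate sets are never admissible
    return float(np.corrcoef(s[:, 0], s[:, 1])[0, 1])


def _spread(s: np.ndarray) -> float:
    return float(np.ptp(s[:, 0]) * np.ptp(s[:, 1]))


def select_stimulus_set(pool: CandidatePool, k: int = 6, rho_max: float = 0.2,
                        n_seeds: int = 20, swap_budget: int = 20000,
                        rng_seed: int = 0) -> StimulusSet:
    """Select k sequences maximizing range(CORR) * range(LAG) s.t. |rho| < rho_max.

    Small pools (C(n, k) <= swap_budget) are solved exhaustively; otherwise a
    greedy/extreme seeding plus local single-swap hill climb under a fixed
    candidate-evaluation budget.
    """
    n = len(pool.sequences)
    if n < k:
        raise ParameterError(f"pool of {n} smaller than k={k}")
    S = pool.summaries

    def admissible(idx):
        return abs(_rho(S[list(idx)])) < rho_max

    if n == k:
        idx = tuple(range(n))
        if not admissible(idx):
            raise SelectionError(
                f"the only {k}-subset has |rho| = {abs(_rho(S)):.3f} >= {rho_max}")
        return _build(pool, idx)

    from math import comb
    if comb(n, k) <= swap_budget:
        best, best_obj = None, -np.inf
        for idx in itertools.combinations(range(n), k):
            if admissible(idx):
                obj = _spread(S[list(idx)])
                if obj > best_obj:
                    best, best_obj = idx, obj
        if best is None:
            raise SelectionError(f"no admissible {k}-subset in pool of {n}")
        return _build(pool, best)

    rng = np.random.default_rng(rng_seed)
    # candidate members: extremes of each summary plus quantile anchors
    order_c = np.argsort(S[:, 0])
    order_l = np.argsort(S[:, 1])
    anchors = np.unique(np.concatenate([
        order_c[:k], order_c[-k:], order_l[:k], order_l[-k:]]))

    best, best_obj = None, -np.inf
    evals = 0
    for _ in range(n_seeds):
        seed_idx = list(rng.choice(anchors, size=min(k, anchors.size), replace=False))
        while len(seed_idx) < k:
            c = int(rng.integers(n))
            if c not in seed_idx:
                seed_idx.append(c)
        cur = list(seed_idx)
        cur_obj = _spread(S[cur]) if admissible(cur) else -np.inf
        improved = True
        while improved and evals < swap_budget:
            improved = False
            for pos in range(k):
                cands = rng.integers(0, n, size=30)
                for c in cands:
                    evals += 1
                    if c in cur:
                        continue
                    trial = cur.copy()
                    trial[pos] = int(c)
                    if not admissible(trial):
                        continue
                    obj = _spread(S[trial])
                    if obj > cur_obj:
                        cur, cur_obj, improved = trial, obj, True
        if cur_obj > best_obj:
            best, best_obj = tuple(sorted(cur)), cur_obj
    if best is None or not np.isfinite(best_obj):
        raise SelectionError(
            f"no admissible set found in {evals} evaluations "
            f"(pool {n}, k {k}, rho_max {rho_max})")
    return _build(pool, best)


def _build(pool: CandidatePool, idx) -> StimulusSet:
    idx = list(idx)
    s = pool.summaries[idx]
    return StimulusSet(tuple(pool.sequences[i] for i in idx), s, _rho(s))


def default_stimulus_set(seed: int = 0, n_pool: int = 10000,
                         params: MCDParams = MEAN_OBSERVER_PARAMS) -> StimulusSet:
    """The packaged 6-stimulus set: a reproducible stand-in for the original
    six experimental sequences (whose onset tables are not redistributed),
    drawn and selected with the same procedure at desk scale."""
    pool = sample_sequence_pool(n_pool, rng_seed=seed, params=params)
    return select_stimulus_set(pool, k=6, rho_max=0.2, rng_seed=seed)
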