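"""Greedy coordinate ascent over constrained event orderings.

One move relocates a single event to the best constraint-respecting
position; sweeps repeat until no single-event move improves the (optionally
subject-weighted) data log-likelihood. Ascent is monotone, so the returned
sequence never scores below the initial one.

The inner loop works on plain event lists and scores every candidate slot
of an event in one vectorised pass; `EventSequence` objects are only built
at the boundaries.
"""
from __future__ import annotations

from typing import List, Optional, Sequence

import numpy as np
from scipy.special import logsumexp

from ..markers import MarkerPanel
from .events import (Event, EventSequence, random_sequence,
                     valid_insert_positions)
from .likelihood import subject_logliks

__all__ = ["greedy_optimize_sequence", "multistart_greedy"]

_LOG_2PI = float(np.log(2.0 * np.pi))


def _traj_batch(candidates: List[List[Event]], panel: MarkerPanel) -> np.ndarray:
    """Trajectory matrices for several event orderings; (S, M, N+1)."""
    n_events = len(candidates[0])
    stages = np.arange(n_events + 1, dtype=float)
    out = np.empty((len(candidates), len(panel), n_events + 1))
    thresholds = [np.concatenate(([0.0], np.asarray(m.z_thresholds, float), [m.z_max]))
                  for m in panel]
    for s, events in enumerate(candidates):
        pos: List[List[float]] = [[] for _ in range(len(panel))]
        for k, ev in enumerate(events, start=1):
            pos[ev.marker_index].append(float(k))
        for i in range(len(panel)):
            xp = np.concatenate(([0.0], pos[i], [float(n_events)]))
            out[s, i] = np.interp(stages, xp, thresholds[i])
    return out


def _objectives_batch(Zs: np.ndarray, z_sq: np.ndarray, trajs: np.ndarray,
                      inv_sd: np.ndarray, const: float,
                      weights: Optional[np.ndarray]) -> np.ndarray:
    """Weighted marginal log-likelihood for each candidate trajectory set.

    ``Zs`` is the noise-scaled data (n, M), ``z_sq`` its per-subject squared
    norm, ``trajs`` the candidate trajectories (S, M, K).
    """
    ts = trajs * inv_sd[None, :, None]
    cross = np.tensordot(Zs, ts, axes=([1], [1]))  # (n, S, K)
    t_sq = np.einsum("smk,smk->sk", ts, ts)  # (S, K)
    sq = z_sq[:, None, None] - 2.0 * cross + t_sq[None, :, :]
    stage_ll = const - 0.5 * sq
    subject_ll = logsumexp(stage_ll, axis=2) - np.log(trajs.shape[2])  # (n, S)
    if weights is None:
        return subject_ll.sum(axis=0)
    return weights @ subject_ll


def greedy_optimize_sequence(
    Z: np.ndarray,
    initial: EventSequence,
    panel: MarkerPanel,
    noise_sd: Optional[Sequence[float]] = None,
    weights: Optional[np.ndarray] = None,
    max_sweeps: int = 100,
) -> EventSequence:
    """Locally optimal sequence under single-event relocation moves.

    ``weights`` are per-subject responsibilities for the subtype being
    refitted; ``None`` weights every subject equally. Ties keep the current
    position; equal-scoring new slots resolve to the lowest index.
    """
    Zv = np.atleast_2d(np.asarray(Z, dtype=float))
    n_markers = len(panel)
    sd = np.ones(n_markers) if noise_sd is None else np.asarray(noise_sd, float)
    inv_sd = 1.0 / sd
    Zs = Zv * inv_sd[None, :]
    z_sq = np.einsum("nm,nm->n", Zs, Zs)
    const = -0.5 * n_markers * _LOG_2PI - float(np.sum(np.log(sd)))

    events = list(initial.events)
    cur_obj = float(
        _objectives_batch(Zs, z_sq, _traj_batch([events], panel), inv_sd,
                          const, weights)[0]
    )
    for _ in range(max_sweeps):
        improved = False
        for event in list(events):
            cur_slot = events.index(event)
            rest = events[:cur_slot] + events[cur_slot + 1:]
            slots = list(valid_insert_positions(rest, event))
            if len(slots) == 1:
                continue
            cands = [rest[:s] + [event] + rest[s:] for s in slots]
            objs = _objectives_batch(Zs, z_sq, _traj_batch(cands, panel),
                                     inv_sd, const, weights)
            best = int(np.argmax(objs))
            if objs[best] > cur_obj + 1e-12 and slots[best] != cur_slot:
                events = cands[best]
                cur_obj = float(objs[best])
                improved = True
        if not improved:
            break
    return EventSequence(events, panel)


def multistart_greedy(
    Z: np.ndarray,
    panel: MarkerPanel,
    n_startpoints: int,
    rng: np.random.Generator,
    noise_sd: Optional[Sequence[float]] = None,
    weights: Optional[np.ndarray] = None,
) -> EventSequence:
    """Best greedy optimum over random restarts (deterministic given rng state)."""
    best_seq, best_obj = None, -np.inf
    for _ in range(max(1, n_startpoints)):
        start = random_sequence(panel, rng)
        seq = greedy_optimize_sequence(Z, start, panel, noise_sd, weights)
        ll = subject_logliks(Z, seq, panel, noise_sd)
        obj = float(ll.sum()) if weights is None else float(weights @ ll)
        if obj > best_obj + 1e-12:
            best_obj, best_seq = obj, seq
    return best_seq
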