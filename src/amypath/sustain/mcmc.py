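"""Metropolis-Hastings sampling over constrained event orderings.

The proposal picks a subtype uniformly, removes a uniformly chosen event
from its sequence and reinserts it at a uniformly chosen
constraint-respecting slot. The set of valid slots depends only on the
sequence minus the event, so the proposal is symmetric and the acceptance
probability is min(1, exp(delta log-likelihood)). Mixture fractions are
held fixed at their fitted values; the chain explores ordering uncertainty.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.special import logsumexp

from ..markers import MarkerPanel
from .events import EventSequence, valid_insert_positions
from .likelihood import subject_logliks

__all__ = ["McmcSample", "mcmc_sample"]


@dataclass(frozen=True)
class McmcSample:
    sequences: Tuple[EventSequence, ...]
    fractions: Tuple[float, ...]
    loglik: float


def _total(per_subtype: np.ndarray, logf: np.ndarray) -> float:
    return float(np.sum(logsumexp(per_subtype + logf[None, :], axis=1)))


def mcmc_sample(
    Z: np.ndarray,
    sequences: Sequence[EventSequence],
    fractions: Sequence[float],
    panel: MarkerPanel,
    n_mcmc: int,
    burn_in: int,
    thinning: int,
    rng: np.random.Generator,
    noise_sd: Optional[Sequence[float]] = None,
) -> Tuple[List[McmcSample], np.ndarray]:
    """Run the chain; returns retained samples and the full log-lik trace.

    Samples at iterations ``> burn_in`` are retained every ``thinning``
    steps. Every visited state satisfies the within-marker threshold-order
    constraint by construction of the proposal.
    """
    if not (0 <= burn_in < n_mcmc):
        raise ValueError("require 0 <= burn_in < n_mcmc")
    if thinning < 1:
        raise ValueError("thinning must be >= 1")
    seqs = list(sequences)
    f = np.asarray(fractions, dtype=float)
    with np.errstate(divide="ignore"):
        logf = np.log(f)
    per_subtype = np.column_stack(
        [subject_logliks(Z, s, panel, noise_sd) for s in seqs]
    )
    loglik = _total(per_subtype, logf)

    retained: List[McmcSample] = []
    trace = np.empty(n_mcmc)
    n_events = len(seqs[0])
    for it in range(n_mcmc):
        c = int(rng.integers(len(seqs)))
        events = list(seqs[c].events)
        k = int(rng.integers(n_events))
        event = events.pop(k)
        slots = valid_insert_positions(events, event)
        slot = int(slots[int(rng.integers(len(slots)))])
        proposal = EventSequence(events[:slot] + [event] + events[slot:], panel)
        new_col = subject_logliks(Z, proposal, panel, noise_sd)
        cand = per_subtype.copy()
        cand[:, c] = new_col
        cand_ll = _total(cand, logf)
        if np.log(rng.random()) < cand_ll - loglik:
            seqs[c] = proposal
            per_subtype = cand
            loglik = cand_ll
        trace[it] = loglik
        if it >= burn_in and (it - burn_in) % thinning == 0:
            retained.append(McmcSample(tuple(seqs), tuple(f), loglik))
    return retained, trace
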