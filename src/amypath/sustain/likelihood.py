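"""Likelihood of z-score data under an event-sequence progression model.

Each marker follows a piecewise-linear trajectory in stage: 0 at stage 0,
its z thresholds at the stages where its events occur, and the ceiling
``z_max`` at the final stage N. Observed z-scores are the stage's expected
trajectory plus Gaussian noise (SD 1 by default, the data being z-scored
against controls). A subject's stage is latent with a uniform prior over
{0, ..., N}; a cohort is a mixture of subtypes, each with its own sequence.
All heavy paths work in log space on precomputed stage grids.
"""
from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from scipy.special import logsumexp

from ..markers import MarkerPanel
from .events import EventSequence

__all__ = [
    "expected_trajectory", "trajectory_matrix", "stage_loglik",
    "stage_likelihood", "stage_logliks_matrix", "subject_logliks",
    "subject_likelihood", "mixture_loglik",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


def trajectory_matrix(sequence: EventSequence, panel: MarkerPanel) -> np.ndarray:
    """Expected z for every marker at every stage; shape (M, N+1)."""
    n_events = len(sequence)
    stages = np.arange(n_events + 1, dtype=float)
    out = np.empty((len(panel), n_events + 1))
    for i, spec in enumerate(panel):
        xp = np.concatenate(([0.0], np.asarray(sequence.positions(i), dtype=float),
                             [float(n_events)]))
        fp = np.concatenate(([0.0], np.asarray(spec.z_thresholds, dtype=float),
                             [spec.z_max]))
        out[i] = np.interp(stages, xp, fp)
    return out


def expected_trajectory(sequence: EventSequence, panel: MarkerPanel,
                        marker_index: int, stage: float) -> float:
    """Expected z of one marker at one stage (piecewise-linear interpolation)."""
    n_events = len(sequence)
    if not 0 <= stage <= n_events:
        raise ValueError(f"stage must lie in [0, {n_events}]")
    spec = panel[marker_index]
    xp = np.concatenate(([0.0], np.asarray(sequence.positions(marker_index), dtype=float),
                         [float(n_events)]))
    fp = np.concatenate(([0.0], np.asarray(spec.z_thresholds, dtype=float), [spec.z_max]))
    return float(np.interp(stage, xp, fp))


def _noise(noise_sd, n_markers: int) -> np.ndarray:
    if noise_sd is None:
        return np.ones(n_markers)
    sd = np.asarray(noise_sd, dtype=float)
    if sd.ndim == 0:
        sd = np.full(n_markers, float(sd))
    if sd.shape != (n_markers,) or np.any(sd <= 0):
        raise ValueError("noise_sd must be positive, one per marker")
    return sd


def stage_logliks_matrix(Z: np.ndarray, sequence: EventSequence, panel: MarkerPanel,
                         noise_sd: Optional[Sequence[float]] = None) -> np.ndarray:
    """Log p(z_n | stage k, sequence) for all subjects and stages; (n, N+1).

    Independent Gaussian noise per marker around the stage's expected
    trajectory.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    sd = _noise(noise_sd, len(panel))
    traj = trajectory_matrix(sequence, panel)  # (M, N+1)
    resid = (Z[:, :, None] - traj[None, :, :]) / sd[None, :, None]
    const = -0.5 * len(panel) * _LOG_2PI - float(np.sum(np.log(sd)))
    return const - 0.5 * np.einsum("nmk,nmk->nk", resid, resid)


def stage_loglik(z: Sequence[float], sequence: EventSequence, stage: int,
                 panel: MarkerPanel, noise_sd: Optional[Sequence[float]] = None) -> float:
    """Log-likelihood of one subject's z-vector at a fixed stage."""
    return float(stage_logliks_matrix(np.asarray(z), sequence, panel, noise_sd)[0, int(stage)])


def stage_likelihood(z, sequence, stage, panel, noise_sd=None) -> float:
    return float(np.exp(stage_loglik(z, sequence, stage, panel, noise_sd)))


def subject_logliks(Z: np.ndarray, sequence: EventSequence, panel: MarkerPanel,
                    noise_sd: Optional[Sequence[float]] = None) -> np.ndarray:
    """Stage-marginal log-likelihood per subject under a uniform stage prior."""
    sl = stage_logliks_matrix(Z, sequence, panel, noise_sd)
    return logsumexp(sl, axis=1) - np.log(sl.shape[1])


def subject_likelihood(z, sequence, panel, noise_sd=None) -> float:
    return float(np.exp(subject_logliks(np.atleast_2d(z), sequence, panel, noise_sd)[0]))


def mixture_loglik(Z: np.ndarray, sequences: Sequence[EventSequence],
                   fractions: Sequence[float], panel: MarkerPanel,
                   noise_sd: Optional[Sequence[float]] = None,
                   per_subtype_logliks: Optional[np.ndarray] = None) -> float:
    """Total data log-likelihood of the subtype mixture.

    ``per_subtype_logliks`` (n, C), when supplied, skips recomputation —
    the MCMC hot path updates only the proposed subtype's column.
    """
    f = np.asarray(fractions, dtype=float)
    if abs(f.sum() - 1.0) > 1e-9 or np.any(f < 0):
        raise ValueError("fractions must be non-negative and sum to 1")
    if per_subtype_logliks is None:
        per_subtype_logliks = np.column_stack(
            [subject_logliks(Z, s, panel, noise_sd) for s in sequences]
        )
    with np.errstate(divide="ignore"):
        logf = np.log(f)
    return float(np.sum(logsumexp(per_subtype_logliks + logf[None, :], axis=1)))
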