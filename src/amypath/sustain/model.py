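"""Subtype-and-stage inference: hierarchical fitting and subject assignment.

Fitting is hierarchical in the number of subtypes C. The single-subtype
model is found by multi-start greedy ascent. Each C -> C+1 step splits one
fitted subtype's maximum-likelihood members into two random halves, refits
each half's sequence greedily, and keeps the best-scoring split; the
enlarged model is then polished by EM-style alternation between
responsibility-weighted sequence re-optimization and mixture-fraction
updates. A final Metropolis-Hastings pass at the requested C records
ordering uncertainty, and the best state the chain visits becomes the
point estimate (ascent is never lost).

The public face is statsmodels-like: ``SustainModel(data, panel).fit()``
returns :class:`SustainResults` with sequences, fractions, MCMC samples,
per-subject assignments and a ``summary()``.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .._rng import substream
from ..markers import MarkerPanel
from ..normalization import ZScoreMatrix
from .events import Event, EventSequence, all_events, random_sequence
from .likelihood import mixture_loglik, stage_logliks_matrix, subject_logliks
from .mcmc import McmcSample, mcmc_sample
from .optimize import greedy_optimize_sequence, multistart_greedy

__all__ = [
    "FitSettings", "SubtypeModel", "SubjectAssignment",
    "fit_sustain", "assign_subjects", "SustainModel", "SustainResults",
]


@dataclass(frozen=True)
class FitSettings:
    """Knobs of the fitting procedure.

    ``n_startpoints`` random restarts seed the greedy search; the MCMC
    chain runs ``n_mcmc`` iterations, discards ``burn_in`` and keeps every
    ``thinning``-th state. ``cvic_parsimony_margin`` is the CVIC improvement
    a more complex model must exceed to be preferred (default 6).
    """

    n_startpoints: int = 25
    n_mcmc: int = 100_000
    burn_in: int = 10_000
    thinning: int = 10
    seed: int = 0
    max_subtypes: int = 4
    cv_folds: int = 10
    cvic_parsimony_margin: float = 6.0
    n_bisections: int = 5
    max_alternations: int = 100
    alternation_tol: float = 1e-6

    def __post_init__(self) -> None:
        for name in ("n_startpoints", "n_mcmc", "thinning", "max_subtypes",
                     "cv_folds", "n_bisections", "max_alternations"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.burn_in < self.n_mcmc:
            raise ValueError("burn_in must lie in [0, n_mcmc)")


@dataclass(frozen=True)
class SubtypeModel:
    """Fitted mixture of event sequences."""

    sequences: tuple
    fractions: tuple
    noise_sd: tuple
    n_stages: int
    mcmc_samples: tuple = ()
    loglik: float = np.nan
    loglik_trace: tuple = ()
    settings: Optional[FitSettings] = None

    def __post_init__(self) -> None:
        f = np.asarray(self.fractions, dtype=float)
        if abs(f.sum() - 1.0) > 1e-9 or np.any(f < 0):
            raise ValueError("fractions must be non-negative and sum to 1")
        if len(self.sequences) != len(self.fractions):
            raise ValueError("one fraction per sequence required")

    @property
    def n_subtypes(self) -> int:
        return len(self.sequences)

    def to_json(self, path, panel: MarkerPanel) -> None:
        payload = {
            "n_subtypes": self.n_subtypes,
            "n_stages": self.n_stages,
            "fractions": list(self.fractions),
            "noise_sd": list(self.noise_sd),
            "loglik": self.loglik,
            "marker_names": panel.names,
            "sequences": [
                [[ev.marker_index, ev.threshold_index] for ev in seq.events]
                for seq in self.sequences
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


@dataclass(frozen=True)
class SubjectAssignment:
    """Posterior subtype and stage for one subject.

    A maximum-likelihood stage of 0 means the subject is indistinguishable
    from the control reference on every modelled marker; such subjects are
    flagged ``unsubtyped`` and carry no subtype.
    """

    subject_id: str
    subtype_posterior: tuple
    ml_subtype: Optional[int]
    ml_stage: int
    stage_posterior: tuple
    unsubtyped: bool

    def __post_init__(self) -> None:
        if abs(sum(self.subtype_posterior) - 1.0) > 1e-9:
            raise ValueError("subtype posterior must sum to 1")
        if abs(sum(self.stage_posterior) - 1.0) > 1e-9:
            raise ValueError("stage posterior must sum to 1")
        if self.unsubtyped != (self.ml_stage == 0):
            raise ValueError("unsubtyped flag must mirror ml_stage == 0")


def _as_values(Z: Union[ZScoreMatrix, np.ndarray]) -> Tuple[np.ndarray, List[str]]:
    if isinstance(Z, ZScoreMatrix):
        return Z.values, list(Z.subject_ids)
    arr = np.atleast_2d(np.asarray(Z, dtype=float))
    return arr, [str(i) for i in range(arr.shape[0])]


def _responsibilities(per_subtype: np.ndarray, fractions: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        logw = per_subtype + np.log(fractions)[None, :]
    return np.exp(logw - logsumexp(logw, axis=1, keepdims=True))


def _floor_fractions(f: np.ndarray, n_subjects: int) -> np.ndarray:
    floor = 1.0 / (10.0 * max(n_subjects, 1))
    f = np.maximum(f, floor)
    return f / f.sum()


def _em_alternate(Zv, seqs, fractions, panel, noise_sd, settings, rng=None):
    """Alternate responsibility-weighted sequence refits and fraction updates.

    Each M-step update also tries one random-restart greedy per subtype (when
    an ``rng`` is supplied): relocation moves from the current sequence alone
    leave the ordering stuck in shallow local optima.
    """
    n = Zv.shape[0]
    fractions = np.asarray(fractions, dtype=float)
    per_subtype = np.column_stack([subject_logliks(Zv, s, panel, noise_sd) for s in seqs])
    ll = mixture_loglik(Zv, seqs, fractions, panel, noise_sd, per_subtype_logliks=per_subtype)
    for it in range(settings.max_alternations):
        resp = _responsibilities(per_subtype, fractions)
        # re-seed a subtype that owns no subjects from the worst-fit ones
        owners = resp.argmax(axis=1)
        for c in range(len(seqs)):
            if not np.any(owners == c):
                mix = logsumexp(per_subtype + np.log(fractions)[None, :], axis=1)
                worst = np.argsort(mix)[: max(2, n // (4 * len(seqs)))]
                w = np.zeros(n)
                w[worst] = 1.0
                seqs[c] = greedy_optimize_sequence(Zv, seqs[c], panel, noise_sd, weights=w)
                per_subtype[:, c] = subject_logliks(Zv, seqs[c], panel, noise_sd)
                resp = _responsibilities(per_subtype, fractions)
        fractions = _floor_fractions(resp.mean(axis=0), n)
        for c in range(len(seqs)):
            w = resp[:, c]
            cand = greedy_optimize_sequence(Zv, seqs[c], panel, noise_sd, weights=w)
            cand_obj = float(w @ subject_logliks(Zv, cand, panel, noise_sd))
            if rng is not None:
                fresh = greedy_optimize_sequence(
                    Zv, random_sequence(panel, rng), panel, noise_sd, weights=w
                )
                fresh_obj = float(w @ subject_logliks(Zv, fresh, panel, noise_sd))
                if fresh_obj > cand_obj + 1e-9:
                    cand = fresh
            seqs[c] = cand
            per_subtype[:, c] = subject_logliks(Zv, seqs[c], panel, noise_sd)
        new_ll = mixture_loglik(Zv, seqs, fractions, panel, noise_sd,
                                per_subtype_logliks=per_subtype)
        if abs(new_ll - ll) < settings.alternation_tol:
            ll = new_ll
            break
        ll = new_ll
    return seqs, fractions, ll


def _best_subset_split(Zv_sub, panel, noise_sd, settings, rng):
    """Best two-subtype mixture over one subtype's member rows.

    Each trial starts from a random bisection, refits each half's sequence
    by random-restart greedy, then runs the two-cluster EM on the subset to
    (near) convergence; the highest subset likelihood wins. Random restarts,
    not the parent sequence: the halves must be free to separate from the
    subtype being split.
    """
    short = FitSettings(**{**settings.__dict__, "max_alternations": 15})
    m = Zv_sub.shape[0]
    best = None
    for _ in range(settings.n_bisections):
        mask = rng.random(m) < 0.5
        if mask.sum() < 2 or (~mask).sum() < 2:
            continue
        halves = [
            multistart_greedy(Zv_sub, panel, 2, rng, noise_sd,
                              weights=sel.astype(float))
            for sel in (mask, ~mask)
        ]
        f0 = _floor_fractions(np.array([mask.mean(), 1.0 - mask.mean()]), m)
        es, ef, ell = _em_alternate(Zv_sub, halves, f0, panel, noise_sd, short, rng)
        if best is None or ell > best[0]:
            best = (ell, es, ef)
    return best


def _split_candidates(Zv, seqs, fractions, panel, noise_sd, settings, rng):
    """Candidate C+1 models: for each subtype, replace it by the best
    two-subtype mixture of its maximum-likelihood members."""
    n = Zv.shape[0]
    per_subtype = np.column_stack([subject_logliks(Zv, s, panel, noise_sd) for s in seqs])
    resp = _responsibilities(per_subtype, np.asarray(fractions, dtype=float))
    owners = resp.argmax(axis=1)
    candidates = []
    for c in range(len(seqs)):
        members = np.flatnonzero(owners == c)
        if members.size < 4:
            continue
        split = _best_subset_split(Zv[members], panel, noise_sd, settings, rng)
        if split is None:
            continue
        _, pair, pair_f = split
        cand_seqs = [s for j, s in enumerate(seqs) if j != c] + list(pair)
        cand_f = np.array(
            [fractions[j] for j in range(len(seqs)) if j != c]
            + list(fractions[c] * np.asarray(pair_f))
        )
        candidates.append((cand_seqs, _floor_fractions(cand_f, n)))
    if not candidates:
        raise ValueError("no subtype has enough members to split")
    return candidates


def fit_sustain(
    Z: Union[ZScoreMatrix, np.ndarray],
    panel: MarkerPanel,
    n_subtypes: int,
    settings: FitSettings = FitSettings(),
    noise_sd: Optional[Sequence[float]] = None,
) -> SubtypeModel:
    """Fit the C-subtype model hierarchically; deterministic given the seed."""
    Zv, _ = _as_values(Z)
    n = Zv.shape[0]
    if n == 0:
        raise ValueError("empty z-score matrix")
    if n_subtypes < 1:
        raise ValueError("n_subtypes must be >= 1")
    if n_subtypes > n:
        raise ValueError("more subtypes than subjects")
    sd = np.ones(len(panel)) if noise_sd is None else np.asarray(noise_sd, dtype=float)

    rng_start = substream(settings.seed, "sustain-start")
    rng_split = substream(settings.seed, "sustain-split")
    rng_mcmc = substream(settings.seed, "sustain-mcmc")

    seqs = [multistart_greedy(Zv, panel, settings.n_startpoints, rng_start, sd)]
    fractions = np.array([1.0])
    for _ in range(2, n_subtypes + 1):
        # every candidate split is polished by the full-data EM before the
        # comparison: the likelihood before convergence ranks splits poorly
        candidates = _split_candidates(
            Zv, seqs, fractions, panel, sd, settings, rng_split
        )
        best = None
        for cand_seqs, cand_f in candidates:
            em_seqs, em_f, em_ll = _em_alternate(
                Zv, list(cand_seqs), cand_f, panel, sd, settings, rng_split
            )
            if best is None or em_ll > best[0]:
                best = (em_ll, em_seqs, em_f)
        _, seqs, fractions = best

    ll = mixture_loglik(Zv, seqs, fractions, panel, sd)
    samples, trace = mcmc_sample(
        Zv, seqs, fractions, panel,
        settings.n_mcmc, settings.burn_in, settings.thinning, rng_mcmc, sd,
    )
    if samples:
        best_sample = max(samples, key=lambda s: s.loglik)
        if best_sample.loglik > ll + 1e-9:
            # the chain found a better basin: polish it with EM and draw the
            # uncertainty samples around the refined optimum instead
            seqs2, f2, ll2 = _em_alternate(
                Zv, list(best_sample.sequences), fractions, panel, sd,
                settings, rng_split,
            )
            if ll2 > ll:
                seqs, fractions, ll = seqs2, f2, ll2
                samples, trace = mcmc_sample(
                    Zv, seqs, fractions, panel,
                    settings.n_mcmc, settings.burn_in, settings.thinning,
                    rng_mcmc, sd,
                )
                best_sample = max(samples, key=lambda s: s.loglik)
        if best_sample.loglik > ll:
            seqs = list(best_sample.sequences)
            ll = best_sample.loglik
    return SubtypeModel(
        sequences=tuple(seqs),
        fractions=tuple(float(f) for f in fractions),
        noise_sd=tuple(float(s) for s in sd),
        n_stages=panel.n_events,
        mcmc_samples=tuple(samples),
        loglik=float(ll),
        loglik_trace=tuple(trace),
        settings=settings,
    )


def assign_subjects(
    Z: Union[ZScoreMatrix, np.ndarray],
    model: SubtypeModel,
    panel: MarkerPanel,
) -> List[SubjectAssignment]:
    """Posterior subtype and maximum-likelihood stage per subject.

    Subtype posterior weights each sequence's stage-marginal likelihood by
    its mixture fraction; the stage posterior is computed within the
    maximum-likelihood subtype. Ties break to the lowest index; stage-0
    subjects are unsubtyped.
    """
    Zv, ids = _as_values(Z)
    sd = np.asarray(model.noise_sd, dtype=float)
    per_subtype = np.column_stack(
        [subject_logliks(Zv, s, panel, sd) for s in model.sequences]
    )
    post = _responsibilities(per_subtype, np.asarray(model.fractions, dtype=float))
    out = []
    for i, sid in enumerate(ids):
        ml_subtype = int(np.argmax(post[i]))
        sl = stage_logliks_matrix(Zv[i:i + 1], model.sequences[ml_subtype], panel, sd)[0]
        stage_post = np.exp(sl - logsumexp(sl))
        stage_post = stage_post / stage_post.sum()
        ml_stage = int(np.argmax(stage_post))
        unsub = ml_stage == 0
        out.append(
            SubjectAssignment(
                subject_id=sid,
                subtype_posterior=tuple(post[i]),
                ml_subtype=None if unsub else ml_subtype,
                ml_stage=ml_stage,
                stage_posterior=tuple(stage_post),
                unsubtyped=unsub,
            )
        )
    return out


def assignments_to_dataframe(assignments: Sequence[SubjectAssignment]) -> pd.DataFrame:
    rows = []
    for a in assignments:
        row = {
            "subject_id": a.subject_id,
            "ml_subtype": -1 if a.ml_subtype is None else a.ml_subtype,
            "ml_stage": a.ml_stage,
            "unsubtyped": a.unsubtyped,
        }
        for c, p in enumerate(a.subtype_posterior):
            row[f"p_subtype_{c}"] = p
        rows.append(row)
    return pd.DataFrame(rows)


class SustainModel:
    """Model object over a z-score matrix.

    Parameters
    ----------
    Z : ZScoreMatrix or array-like
        Subjects x markers, control-referenced and direction-aligned.
    panel : MarkerPanel
        Event thresholds and ceilings per marker.
    noise_sd : array-like, optional
        Per-marker observation noise SD; defaults to 1 (z-scale data).
    """

    def __init__(self, Z, panel: MarkerPanel, noise_sd=None):
        self.Z = Z
        self.panel = panel
        self.noise_sd = noise_sd
        values, ids = _as_values(Z)
        if values.shape[1] != len(panel):
            raise ValueError("z-matrix width must match panel size")
        self.nobs = values.shape[0]
        self.subject_ids = ids

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, panel: MarkerPanel, noise_sd=None):
        Z = ZScoreMatrix.from_dataframe(df[panel.names].astype(float))
        return cls(Z, panel, noise_sd)

    def fit(self, n_subtypes: int = 1, settings: FitSettings = FitSettings()) -> "SustainResults":
        model = fit_sustain(self.Z, self.panel, n_subtypes, settings, self.noise_sd)
        return SustainResults(self, model)

    def loglike(self, model: SubtypeModel) -> float:
        Zv, _ = _as_values(self.Z)
        return mixture_loglik(Zv, model.sequences, model.fractions, self.panel,
                              model.noise_sd)


class SustainResults:
    """Fit results: sequences, fractions, uncertainty and assignments."""

    def __init__(self, model: SustainModel, fitted: SubtypeModel):
        self.model = model
        self.fitted = fitted

    @property
    def sequences(self) -> tuple:
        return self.fitted.sequences

    @property
    def fractions(self) -> tuple:
        return self.fitted.fractions

    @property
    def loglik(self) -> float:
        return self.fitted.loglik

    @property
    def mcmc_samples(self) -> tuple:
        return self.fitted.mcmc_samples

    def assign(self) -> List[SubjectAssignment]:
        return assign_subjects(self.model.Z, self.fitted, self.model.panel)

    def assignments_frame(self) -> pd.DataFrame:
        return assignments_to_dataframe(self.assign())

    def positional_variance(self):
        from .pvd import positional_variance
        return positional_variance(self.fitted, self.assign(), self.model.panel)

    def sequence_table(self) -> pd.DataFrame:
        """Event order per subtype as marker/threshold labels."""
        rows = []
        names = self.model.panel.names
        for c, seq in enumerate(self.sequences):
            for pos, ev in enumerate(seq.events, start=1):
                rows.append({
                    "subtype": c, "position": pos,
                    "marker": names[ev.marker_index],
                    "z_threshold": self.model.panel[ev.marker_index].z_thresholds[ev.threshold_index],
                })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        assigns = self.assign()
        n_unsub = sum(a.unsubtyped for a in assigns)
        counts = {c: 0 for c in range(self.fitted.n_subtypes)}
        for a in assigns:
            if a.ml_subtype is not None:
                counts[a.ml_subtype] += 1
        lines = [
            "Subtype and Stage Inference results",
            "=" * 40,
            f"subjects: {self.model.nobs}   events: {self.fitted.n_stages}   "
            f"subtypes: {self.fitted.n_subtypes}",
            f"log-likelihood: {self.loglik:.3f}   "
            f"MCMC samples retained: {len(self.mcmc_samples)}",
            f"unsubtyped (stage 0): {n_unsub} "
            f"({100.0 * n_unsub / max(self.model.nobs, 1):.0f}%)",
        ]
        names = self.model.panel.names
        for c, seq in enumerate(self.sequences):
            lines.append(
                f"subtype {c}: fraction {self.fractions[c]:.3f}, n={counts[c]}"
            )
            order = " -> ".join(
                f"{names[ev.marker_index]}@"
                f"{self.model.panel[ev.marker_index].z_thresholds[ev.threshold_index]:g}"
                for ev in seq.events
            )
            lines.append(f"  {order}")
        return "\n".join(lines)
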