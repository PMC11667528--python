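"""Choosing the number of subtypes by cross-validated predictive fit.

CVIC (cross-validation information criterion) is -2 times the summed
out-of-fold predictive log-likelihood, the predictive density averaging
over the retained MCMC samples of each training fit. Lower is better, but
a more complex model must beat a simpler one by at least the parsimony
margin (default 6) to be preferred.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .._rng import substream
from ..markers import MarkerPanel
from .likelihood import subject_logliks
from .model import FitSettings, _as_values, fit_sustain

__all__ = ["CvicResult", "cross_validate_cvic", "select_n_subtypes"]


@dataclass(frozen=True)
class CvicResult:
    cvic: Dict[int, float]
    selected: int
    fold_logliks: pd.DataFrame
    parsimony_margin: float

    def summary(self) -> str:
        lines = ["CVIC model selection", "-" * 30]
        for c in sorted(self.cvic):
            tag = "  <- selected" if c == self.selected else ""
            lines.append(f"  C={c}: CVIC {self.cvic[c]:.2f}{tag}")
        lines.append(f"  parsimony margin: {self.parsimony_margin:g}")
        return "\n".join(lines)


def _predictive_logliks(Z_test, model, panel) -> np.ndarray:
    """Per-test-subject log predictive density, averaged over MCMC samples."""
    samples = model.mcmc_samples
    if not samples:
        raise ValueError("model carries no MCMC samples")
    logf = np.log(np.asarray(model.fractions, dtype=float))
    per_sample = []
    cache: Dict[tuple, np.ndarray] = {}
    for s in samples:
        cols = []
        for seq in s.sequences:
            key = seq.events
            if key not in cache:
                cache[key] = subject_logliks(Z_test, seq, panel, model.noise_sd)
            cols.append(cache[key])
        per_sample.append(logsumexp(np.column_stack(cols) + logf[None, :], axis=1))
    stacked = np.column_stack(per_sample)  # (n_test, S)
    return logsumexp(stacked, axis=1) - np.log(stacked.shape[1])


def select_n_subtypes(cvic: Dict[int, float], margin: float) -> int:
    """Smallest C no larger model improves on by at least ``margin``."""
    cs = sorted(cvic)
    for c in cs:
        if all(cvic[c] - cvic[c2] < margin for c2 in cs if c2 > c):
            return c
    return cs[-1]


def cross_validate_cvic(
    Z,
    panel: MarkerPanel,
    max_subtypes: int,
    settings: FitSettings = FitSettings(),
    noise_sd: Optional[Sequence[float]] = None,
) -> CvicResult:
    """CVIC per candidate C over seeded folds, plus the selected C.

    Subjects are partitioned into ``settings.cv_folds`` folds by a seeded
    shuffle; for each fold and C, the model is fitted on the training
    subjects and scored on the held-out ones.
    """
    Zv, _ = _as_values(Z)
    n = Zv.shape[0]
    k = settings.cv_folds
    if n < k:
        raise ValueError("fewer subjects than folds")
    order = substream(settings.seed, "cv-folds").permutation(n)
    folds = [np.sort(order[i::k]) for i in range(k)]
    if any(f.size < 2 for f in folds):
        raise ValueError("every fold needs at least 2 subjects")

    rows = []
    cvic: Dict[int, float] = {}
    for c in range(1, max_subtypes + 1):
        total = 0.0
        for fi, test_idx in enumerate(folds):
            train_idx = np.setdiff1d(np.arange(n), test_idx)
            fold_settings = FitSettings(
                **{**settings.__dict__, "seed": (settings.seed * 1009 + fi) % (2 ** 31)}
            )
            fitted = fit_sustain(Zv[train_idx], panel, c, fold_settings, noise_sd)
            test_ll = float(_predictive_logliks(Zv[test_idx], fitted, panel).sum())
            total += test_ll
            rows.append({"n_subtypes": c, "fold": fi, "test_loglik": test_ll,
                         "n_test": int(test_idx.size)})
        cvic[c] = -2.0 * total
    selected = select_n_subtypes(cvic, settings.cvic_parsimony_margin)
    return CvicResult(cvic=cvic, selected=selected,
                      fold_logliks=pd.DataFrame(rows),
                      parsimony_margin=settings.cvic_parsimony_margin)
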