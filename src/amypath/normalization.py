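"""Control-referenced z-scale.

All modelled markers are mapped onto a common scale on which 0 is the
amyloid-negative control mean and larger values are more abnormal:

1. transform (log2 for white-matter hyperintensity volume);
2. direction alignment — markers that worsen downwards (logical memory,
   whole-brain and hippocampal volume) are negated;
3. z-scoring against the control group. Plain markers use the control mean
   and SD. Volumetric markers use a W-score: the control-only ordinary
   least-squares regression on total intracranial volume supplies the
   expected value, and the control residual SD (denominator n-2) the scale.

The composite Trail Making Test score is TMT B (ceiling 300 s) minus TMT A,
computed on the raw seconds scale before z-scoring.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np
import pandas as pd

from .cohort import Cohort, SubjectRecord, TMT_B_CEILING_S
from .markers import LOWER_IS_WORSE, MarkerPanel, MarkerSpec

__all__ = [
    "ControlReference", "ZScoreMatrix", "composite_tmt",
    "fit_control_reference", "zscore_subject", "build_zscore_matrix",
    "WMH_ZERO_OFFSET_ML",
]

#: offset added to a WMH volume of exactly 0 mL before log2
WMH_ZERO_OFFSET_ML = 0.01


def composite_tmt(tmt_a_s: float, tmt_b_s: float) -> Tuple[float, bool]:
    """TMT B minus TMT A in seconds, with the 300 s ceiling on TMT B.

    Returns ``(score, ceiling_flag)``; the flag marks subjects whose TMT B
    hit the ceiling, for the semi-partial correlation adjustment downstream.
    """
    if tmt_a_s <= 0 or tmt_b_s <= 0:
        raise ValueError("TMT times must be positive")
    ceiled = tmt_b_s >= TMT_B_CEILING_S
    return min(tmt_b_s, TMT_B_CEILING_S) - tmt_a_s, ceiled


def _transformed_aligned(spec: MarkerSpec, raw: float) -> float:
    x = float(raw)
    if spec.transform == "log2":
        if x < 0:
            raise ValueError(f"{spec.name}: negative value {x} cannot be log-transformed")
        if x == 0:
            x = WMH_ZERO_OFFSET_ML
        x = np.log2(x)
    if spec.direction == LOWER_IS_WORSE:
        x = -x
    return x


def _marker_raw_value(record: SubjectRecord, spec: MarkerSpec) -> float:
    if spec.name == "composite_tmt_s":
        score, _ = composite_tmt(record.tmt_a_s, record.tmt_b_s)
        return score
    return getattr(record, spec.name)


@dataclass(frozen=True)
class ControlReference:
    """Per-marker normalization parameters estimated in controls.

    ``plain`` maps marker name to (mean, sd) on the transformed, aligned
    scale; ``adjusted`` maps marker name to (intercept, slope, residual_sd)
    of the control-only regression on the marker's covariate.
    """

    plain: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    adjusted: Dict[str, Tuple[float, float, float]] = field(default_factory=dict)
    n_controls: int = 0

    def __post_init__(self) -> None:
        for name, (_, sd) in self.plain.items():
            if not sd > 0:
                raise ValueError(f"{name}: control SD must be positive")
        for name, (_, _, rsd) in self.adjusted.items():
            if not rsd > 0:
                raise ValueError(f"{name}: residual SD must be positive")


@dataclass(frozen=True)
class ZScoreMatrix:
    """Direction-aligned control-referenced z-scores, subjects x markers."""

    subject_ids: tuple
    marker_names: tuple
    values: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2 or vals.shape != (len(self.subject_ids), len(self.marker_names)):
            raise ValueError("z matrix shape mismatch")
        if vals.size and not np.all(np.isfinite(vals)):
            raise ValueError("z matrix contains non-finite entries")
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "subject_ids", tuple(self.subject_ids))
        object.__setattr__(self, "marker_names", tuple(self.marker_names))

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.subject_ids),
                            columns=list(self.marker_names)).rename_axis("subject_id")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, provenance: str = "") -> "ZScoreMatrix":
        return cls(tuple(df.index.astype(str)), tuple(df.columns), df.to_numpy(float),
                   provenance=provenance)


def fit_control_reference(controls: Cohort, panel: MarkerPanel) -> ControlReference:
    """Estimate the normalization parameters from the control group.

    Plain markers: mean and SD (ddof=1). Covariate-adjusted markers:
    ordinary least squares of the transformed, aligned marker on its
    covariate, residual SD with denominator n-2. Cases never enter this fit.
    """
    complete = [s for s in controls if s.is_complete]
    if len(complete) < 10:
        raise ValueError("need at least 10 complete control subjects")
    plain, adjusted = {}, {}
    for spec in panel:
        y = np.array([_transformed_aligned(spec, _marker_raw_value(s, spec)) for s in complete])
        if spec.covariate_adjust is None:
            sd = float(np.std(y, ddof=1))
            if sd <= 0:
                raise ValueError(f"{spec.name}: degenerate control SD")
            plain[spec.name] = (float(np.mean(y)), sd)
        else:
            x = np.array([getattr(s, spec.covariate_adjust) for s in complete])
            slope, intercept = np.polyfit(x, y, 1)
            resid = y - (intercept + slope * x)
            rsd = float(np.sqrt(np.sum(resid ** 2) / (len(complete) - 2)))
            # collinear controls leave only float round-off in the residual
            if rsd <= 1e-8 * max(1.0, float(np.std(y))):
                raise ValueError(f"{spec.name}: degenerate residual SD (collinear controls)")
            adjusted[spec.name] = (float(intercept), float(slope), rsd)
    return ControlReference(plain=plain, adjusted=adjusted, n_controls=len(complete))


def zscore_subject(record: SubjectRecord, ref: ControlReference, panel: MarkerPanel) -> np.ndarray:
    """One subject's z-vector over the panel (higher = more abnormal)."""
    if not record.is_complete:
        raise ValueError(f"{record.subject_id}: incomplete record")
    out = np.empty(len(panel))
    for j, spec in enumerate(panel):
        val = _transformed_aligned(spec, _marker_raw_value(record, spec))
        if spec.covariate_adjust is None:
            mean, sd = ref.plain[spec.name]
            out[j] = (val - mean) / sd
        else:
            intercept, slope, rsd = ref.adjusted[spec.name]
            cov = getattr(record, spec.covariate_adjust)
            out[j] = (val - (intercept + slope * cov)) / rsd
    return out


def build_zscore_matrix(cases: Cohort, ref: ControlReference, panel: MarkerPanel) -> ZScoreMatrix:
    """Z-score matrix over the modelled markers for a (case) cohort."""
    n = len(cases)
    values = np.empty((n, len(panel)))
    for i, s in enumerate(cases):
        values[i] = zscore_subject(s, ref, panel)
    return ZScoreMatrix(
        subject_ids=tuple(cases.subject_ids),
        marker_names=tuple(panel.names),
        values=values,
        provenance=f"controls(n={ref.n_controls})",
    )
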