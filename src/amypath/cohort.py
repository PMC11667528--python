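"""Cohort tables: loading, validation, completeness filtering and the
definition of the amyloid-negative reference-control and amyloid-positive
case groups.

Group definitions
-----------------
*Reference controls* are CSF-amyloid negative (at or above the cut-point),
APOE e4 non-carriers, cognitively normal at baseline and at every recorded
follow-up visit. *Cases* are CSF-amyloid positive (strictly below the
cut-point), with any baseline or follow-up diagnosis. A value exactly at the
cut-point is classified amyloid-negative, keeping the positive set strict.
Subjective-memory-concern (SMC) labels count as cognitively normal for group
definition.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

DIAGNOSES = ("CN", "SMC", "MCI", "AD")
#: labels treated as cognitively normal for group definition
_CN_LIKE = frozenset({"CN", "SMC"})

#: analysis fields that must all be present for a subject to be modelled
REQUIRED_FIELDS = (
    "csf_abeta",
    "csf_ptau181",
    "wmh_ml",
    "wbv_ml",
    "hip_ml",
    "tiv_ml",
    "lm_score",
    "tmt_a_s",
    "tmt_b_s",
)

#: TMT B completion-time ceiling, seconds
TMT_B_CEILING_S = 300.0


@dataclass(frozen=True)
class SubjectRecord:
    """One subject's baseline measurements and follow-up diagnoses.

    Numeric analysis fields may be NaN when missing; ``is_complete``
    reports whether all required analysis fields are present.
    """

    subject_id: str
    baseline_diagnosis: str = "CN"
    age_years: float = np.nan
    sex: str = "female"
    apoe_e4_carrier: bool = False
    education_years: float = np.nan
    csf_abeta: float = np.nan
    csf_ptau181: float = np.nan
    wmh_ml: float = np.nan
    wbv_ml: float = np.nan
    hip_ml: float = np.nan
    tiv_ml: float = np.nan
    lm_score: float = np.nan
    tmt_a_s: float = np.nan
    tmt_b_s: float = np.nan
    mmse: float = np.nan
    nfl_pg_ml: float = np.nan
    hypertension: bool = False
    stroke: bool = False
    lacune_present: bool = False
    cmb_present: bool = False
    followup_diagnoses: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.baseline_diagnosis not in DIAGNOSES:
            raise ValueError(
                f"{self.subject_id}: unknown diagnosis {self.baseline_diagnosis!r}"
            )
        if self.sex not in ("male", "female"):
            raise ValueError(f"{self.subject_id}: unknown sex {self.sex!r}")
        fu = tuple((int(m), str(d)) for m, d in self.followup_diagnoses)
        for _, d in fu:
            if d not in DIAGNOSES:
                raise ValueError(f"{self.subject_id}: unknown follow-up diagnosis {d!r}")
        object.__setattr__(self, "followup_diagnoses", fu)

    @property
    def is_complete(self) -> bool:
        return all(np.isfinite(getattr(self, f)) for f in REQUIRED_FIELDS)

    def missing_fields(self) -> List[str]:
        return [f for f in REQUIRED_FIELDS if not np.isfinite(getattr(self, f))]

    @property
    def diagnostically_cn_throughout(self) -> bool:
        """CN (or SMC) at baseline and at every recorded follow-up visit.

        Subjects with no follow-up visits count as stable.
        """
        if self.baseline_diagnosis not in _CN_LIKE:
            return False
        return all(d in _CN_LIKE for _, d in self.followup_diagnoses)


@dataclass(frozen=True)
class Cohort:
    """An ordered collection of :class:`SubjectRecord` with unique ids."""

    subjects: tuple
    role: str = "unspecified"
    provenance: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "subjects", tuple(self.subjects))
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate subject ids: {dupes}")

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)

    @property
    def subject_ids(self) -> List[str]:
        return [s.subject_id for s in self.subjects]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            row = {
                k: getattr(s, k)
                for k in (
                    "subject_id", "baseline_diagnosis", "age_years", "sex",
                    "apoe_e4_carrier", "education_years", "mmse", "nfl_pg_ml",
                    *REQUIRED_FIELDS,
                    "hypertension", "stroke", "lacune_present", "cmb_present",
                )
            }
            row["followup_diagnoses"] = json.dumps(list(s.followup_diagnoses))
            rows.append(row)
        return pd.DataFrame(rows)

    def with_role(self, role: str, provenance: str = "") -> "Cohort":
        return replace(self, role=role, provenance=provenance or self.provenance)


_BOOL_FIELDS = ("apoe_e4_carrier", "hypertension", "stroke", "lacune_present", "cmb_present")
_FLOAT_FIELDS = (
    "age_years", "education_years", "mmse", "nfl_pg_ml", *REQUIRED_FIELDS,
)

_TRUTHY = {"1", "true", "yes", "y", "t"}
_FALSY = {"0", "false", "no", "n", "f", "", "na", "nan"}


def _parse_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    if isinstance(value, (int, float, np.integer, np.floating)):
        return bool(value) and not (isinstance(value, float) and np.isnan(value))
    text = str(value).strip().lower()
    if text in _TRUTHY:
        return True
    if text in _FALSY:
        return False
    raise ValueError(f"cannot parse boolean {value!r}")


def _parse_float(value) -> float:
    if value is None:
        return np.nan
    text = str(value).strip()
    if text == "" or text.upper() in ("NA", "NAN"):
        return np.nan
    return float(text)


def _parse_followups(value) -> tuple:
    if value is None:
        return ()
    if isinstance(value, float) and np.isnan(value):
        return ()
    text = str(value).strip()
    if text in ("", "NA", "[]"):
        return ()
    if text.startswith("["):
        return tuple((int(m), str(d)) for m, d in json.loads(text))
    # compact "month:dx;month:dx" form
    out = []
    for part in text.split(";"):
        m, d = part.split(":")
        out.append((int(m), d.strip()))
    return tuple(out)


def load_cohort(
    path,
    column_map: Optional[Dict[str, str]] = None,
    role: str = "unspecified",
) -> Cohort:
    """Read a per-subject cohort CSV into a :class:`Cohort`.

    ``column_map`` maps canonical field names to CSV column names for
    sources whose headers differ. Rows whose required fields fail to parse
    are kept with NaN values and logged, never silently dropped; a
    duplicated subject id is an error.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    column_map = column_map or {}
    rename = {v: k for k, v in column_map.items()}
    df = df.rename(columns=rename)
    if "subject_id" not in df.columns:
        raise ValueError("cohort file lacks a subject_id column (after mapping)")

    subjects = []
    n_bad = 0
    for _, row in df.iterrows():
        kwargs = {"subject_id": str(row["subject_id"]).strip()}
        if "baseline_diagnosis" in df.columns:
            kwargs["baseline_diagnosis"] = str(row["baseline_diagnosis"]).strip()
        if "sex" in df.columns:
            kwargs["sex"] = str(row["sex"]).strip().lower()
        for f in _FLOAT_FIELDS:
            if f in df.columns:
                try:
                    kwargs[f] = _parse_float(row[f])
                except ValueError:
                    log.warning("subject %s: unparseable %s=%r, treated as missing",
                                kwargs["subject_id"], f, row[f])
                    kwargs[f] = np.nan
                    n_bad += 1
        for f in _BOOL_FIELDS:
            if f in df.columns:
                kwargs[f] = _parse_bool(row[f])
        if "followup_diagnoses" in df.columns:
            kwargs["followup_diagnoses"] = _parse_followups(row["followup_diagnoses"])
        subjects.append(SubjectRecord(**kwargs))
    if n_bad:
        log.warning("%d unparseable required cells treated as missing", n_bad)
    return Cohort(tuple(subjects), role=role, provenance=str(path))


def apply_completeness_filter(cohort: Cohort) -> Tuple[Cohort, List[Tuple[str, str]]]:
    """Drop subjects missing any required analysis field.

    Returns the filtered cohort plus ``(subject_id, reason)`` pairs for every
    exclusion, so counts are auditable.
    """
    kept, excluded = [], []
    for s in cohort:
        if s.is_complete:
            kept.append(s)
        else:
            excluded.append((s.subject_id, "missing: " + ",".join(s.missing_fields())))
    if not kept:
        log.warning("completeness filter removed every subject")
    return Cohort(tuple(kept), role=cohort.role, provenance=cohort.provenance), excluded


def select_reference_controls(cohort: Cohort, cutpoint) -> Cohort:
    """Amyloid-negative, APOE e4 non-carrier, diagnostically stable CN subjects.

    Amyloid-negative means CSF abeta at or above the cut-point (ties go to
    negative).
    """
    cut = float(getattr(cutpoint, "value", cutpoint))
    kept = tuple(
        s
        for s in cohort
        if np.isfinite(s.csf_abeta)
        and s.csf_abeta >= cut
        and not s.apoe_e4_carrier
        and s.diagnostically_cn_throughout
    )
    if not kept:
        log.warning("no subjects meet the reference-control definition")
    return Cohort(kept, role="reference_controls", provenance=cohort.provenance)


def select_cases(cohort: Cohort, cutpoint) -> Cohort:
    """Amyloid-positive subjects: CSF abeta strictly below the cut-point,
    any diagnosis."""
    cut = float(getattr(cutpoint, "value", cutpoint))
    kept = tuple(
        s for s in cohort if np.isfinite(s.csf_abeta) and s.csf_abeta < cut
    )
    return Cohort(kept, role="cases", provenance=cohort.provenance)


def write_exclusion_report(path, cohort_n: int, retained_n: int,
                           excluded: Sequence[Tuple[str, str]]) -> None:
    """JSON sidecar of exclusion bookkeeping."""
    payload = {
        "n_input": int(cohort_n),
        "n_retained": int(retained_n),
        "n_excluded": len(excluded),
        "exclusions": [{"subject_id": i, "reason": r} for i, r in excluded],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
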