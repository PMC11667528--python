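"""Post-hoc characterization of fitted subtypes.

Descriptive group tables, omnibus group contrasts (linear-regression F-test
for continuous variables, Fisher exact test for categorical ones),
stage-marker correlations (plain Pearson and semi-partial with a covariate
regressed out), and diagnostic-progression summaries within a follow-up
horizon. P-values are reported raw and two-sided, with no multiplicity
correction, matching how such tables are conventionally presented.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
import statsmodels.api as sm

from .cohort import Cohort
from .normalization import composite_tmt
from .sustain.model import SubjectAssignment

__all__ = [
    "SubtypeSummary", "StageCorrelation", "ProgressionTable",
    "group_labels", "summarize_groups", "compare_groups",
    "fisher_exact_2xk", "stage_marker_correlation", "progression_summary",
]

_DX_ORDER = {"CN": 0, "SMC": 0, "MCI": 1, "AD": 2}


def group_labels(assignments: Sequence[SubjectAssignment]) -> Dict[str, str]:
    """subject_id -> 'unsubtyped' or 'subtype_<c>'."""
    out = {}
    for a in assignments:
        out[a.subject_id] = "unsubtyped" if a.unsubtyped else f"subtype_{a.ml_subtype}"
    return out


@dataclass(frozen=True)
class SubtypeSummary:
    """Per-group descriptive table (groups as columns)."""

    table: pd.DataFrame
    group_ns: Dict[str, int]

    def summary(self) -> str:
        return self.table.to_string()


def _fmt_mean_sd(x: np.ndarray) -> str:
    x = x[np.isfinite(x)]
    if x.size == 0:
        return ""
    return f"{np.mean(x):.1f} ({np.std(x, ddof=1):.1f})" if x.size > 1 else f"{x[0]:.1f}"


def _fmt_median_iqr(x: np.ndarray) -> str:
    x = x[np.isfinite(x)]
    if x.size == 0:
        return ""
    q1, q3 = np.percentile(x, [25, 75])
    return f"{np.median(x):.1f} ({q3 - q1:.1f})"


def summarize_groups(
    cases: Cohort,
    assignments: Sequence[SubjectAssignment],
) -> SubtypeSummary:
    """Demographic / marker table per assignment group.

    Continuous variables are mean (SD); WMH volume, being heavily skewed,
    is median (IQR); categorical variables are count (%).
    """
    labels = group_labels(assignments)
    missing = [s.subject_id for s in cases if s.subject_id not in labels]
    if missing:
        raise ValueError(f"unassigned subjects: {missing[:5]}")
    df = cases.to_dataframe()
    df["group"] = df["subject_id"].map(labels)
    df["composite_tmt_s"] = [
        composite_tmt(a, b)[0] for a, b in zip(df["tmt_a_s"], df["tmt_b_s"])
    ]
    groups = sorted(df["group"].unique(), key=lambda g: (g != "unsubtyped", g))

    continuous = [
        ("age_years", "Age, years"),
        ("education_years", "Education, years"),
        ("mmse", "MMSE"),
        ("lm_score", "LM"),
        ("composite_tmt_s", "Composite TMT, s"),
        ("csf_abeta", "CSF abeta, pg/mL"),
        ("csf_ptau181", "CSF p-tau181, pg/mL"),
        ("wbv_ml", "Whole-brain volume, mL"),
        ("hip_ml", "Hippocampal volume, mL"),
        ("tiv_ml", "TIV, mL"),
        ("nfl_pg_ml", "NfL, pg/mL"),
    ]
    categorical = [
        ("sex", "male", "Male, n (%)"),
        ("apoe_e4_carrier", True, "APOE e4 carrier, n (%)"),
        ("hypertension", True, "Hypertension, n (%)"),
        ("stroke", True, "Stroke, n (%)"),
        ("lacune_present", True, "Lacunes present, n (%)"),
        ("cmb_present", True, "CMB present, n (%)"),
    ]

    rows: Dict[str, Dict[str, str]] = {}
    ns = {}
    for g in groups:
        sub = df[df["group"] == g]
        ns[g] = len(sub)
        rows.setdefault("N", {})[g] = str(len(sub))
        dx = sub["baseline_diagnosis"].replace({"SMC": "CN"})
        cn, mci, ad = (int((dx == d).sum()) for d in ("CN", "MCI", "AD"))
        tot = max(len(sub), 1)
        rows.setdefault("Diagnosis CN:MCI:AD (%)", {})[g] = (
            f"{cn}:{mci}:{ad} ({round(100 * cn / tot)}:{round(100 * mci / tot)}:{round(100 * ad / tot)})"
        )
        for col, label in continuous:
            if col in sub:
                rows.setdefault(label, {})[g] = _fmt_mean_sd(sub[col].to_numpy(float))
        rows.setdefault("WMH, mL median (IQR)", {})[g] = _fmt_median_iqr(
            sub["wmh_ml"].to_numpy(float)
        )
        for col, level, label in categorical:
            if col in sub:
                k = int((sub[col] == level).sum())
                rows.setdefault(label, {})[g] = f"{k} ({round(100 * k / tot)})"
    table = pd.DataFrame(rows).T[groups]
    assert sum(ns.values()) == len(cases)
    return SubtypeSummary(table=table, group_ns=ns)


def _log_table_prob(first_row: np.ndarray, col_sums: np.ndarray, r1: int, n: int) -> float:
    """log multivariate-hypergeometric probability of a 2xk table's first row."""
    return float(
        np.sum(gammaln(col_sums + 1) - gammaln(first_row + 1) - gammaln(col_sums - first_row + 1))
        + gammaln(r1 + 1) + gammaln(n - r1 + 1) - gammaln(n + 1)
    )


def _enumerate_first_rows(col_sums: np.ndarray, r1: int):
    k = col_sums.size

    def rec(j: int, remaining: int, prefix: list):
        tail = int(col_sums[j + 1:].sum())
        lo = max(0, remaining - tail)
        hi = min(int(col_sums[j]), remaining)
        if j == k - 1:
            yield prefix + [remaining]
            return
        for a in range(lo, hi + 1):
            yield from rec(j + 1, remaining - a, prefix + [a])

    yield from rec(0, r1, [])


def fisher_exact_2xk(
    table: np.ndarray,
    seed: int = 0,
    max_tables: int = 500_000,
    n_simulations: int = 200_000,
) -> Tuple[float, float]:
    """Two-sided Fisher exact test for a 2xk contingency table.

    Exact enumeration over all fixed-margin tables when their count is
    manageable (probability-mass definition: sum the probabilities of
    tables no more probable than the observed one); otherwise a seeded
    multivariate-hypergeometric Monte Carlo estimate. Returns
    ``(p_value, log-prob of the observed table)``.
    """
    t = np.asarray(table, dtype=int)
    if t.ndim != 2 or t.shape[0] != 2:
        raise ValueError("table must be 2 x k")
    if np.any(t < 0):
        raise ValueError("counts must be non-negative")
    col_sums = t.sum(axis=0)
    keep = col_sums > 0
    t = t[:, keep]
    col_sums = col_sums[keep]
    if t.shape[1] < 2:
        return 1.0, 0.0
    r1, n = int(t[0].sum()), int(t.sum())
    obs_lp = _log_table_prob(t[0].astype(float), col_sums.astype(float), r1, n)
    bound = obs_lp + 1e-7

    n_candidates = float(np.prod(np.minimum(col_sums, r1) + 1.0))
    if n_candidates <= max_tables:
        total = 0.0
        for first in _enumerate_first_rows(col_sums, r1):
            lp = _log_table_prob(np.asarray(first, float), col_sums.astype(float), r1, n)
            if lp <= bound:
                total += math.exp(lp)
        return min(1.0, total), obs_lp
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_hypergeometric(col_sums, r1, size=n_simulations)
    lps = np.array([
        _log_table_prob(d.astype(float), col_sums.astype(float), r1, n) for d in draws
    ])
    hits = int(np.sum(lps <= bound))
    return (hits + 1) / (n_simulations + 1), obs_lp


def compare_groups(
    values_by_group: Dict[str, np.ndarray],
    variable_kind: str,
    seed: int = 0,
) -> Tuple[float, float]:
    """Omnibus contrast across groups: ``(statistic, p_value)``.

    Continuous variables: overall F-test of the linear regression of the
    value on group membership (equivalently one-way ANOVA). Categorical
    variables: ``values_by_group`` maps group -> counts over levels, tested
    with the two-sided Fisher exact test.
    """
    if len(values_by_group) < 2:
        raise ValueError("need at least 2 groups")
    if variable_kind == "continuous":
        y, dummies = [], []
        for gi, (_, vals) in enumerate(sorted(values_by_group.items())):
            vals = np.asarray(vals, dtype=float)
            vals = vals[np.isfinite(vals)]
            y.append(vals)
            dummies.append(np.full(vals.size, gi))
        y = np.concatenate(y)
        g = np.concatenate(dummies)
        if np.ptp(y) == 0:
            raise ValueError("degenerate: all values identical")
        X = pd.get_dummies(pd.Categorical(g), drop_first=True).to_numpy(float)
        res = sm.OLS(y, sm.add_constant(X)).fit()
        return float(res.fvalue), float(res.f_pvalue)
    if variable_kind == "categorical":
        tbl = np.column_stack([np.asarray(values_by_group[g], dtype=int)
                               for g in sorted(values_by_group)])
        if tbl.shape[0] != 2:
            tbl = tbl.T
        if tbl.shape[0] != 2:
            raise ValueError("categorical contrast expects 2 levels per group")
        p, _ = fisher_exact_2xk(tbl, seed=seed)
        return np.nan, p
    raise ValueError(f"unknown variable_kind {variable_kind!r}")


@dataclass(frozen=True)
class StageCorrelation:
    subtype: int
    marker: str
    coefficient: float
    p_value: float
    kind: str  # "pairwise" or "semi_partial"
    adjustment: Optional[str] = None

    def __post_init__(self) -> None:
        if abs(self.coefficient) > 1 + 1e-12:
            raise ValueError("correlation outside [-1, 1]")


def stage_marker_correlation(
    assignments: Sequence[SubjectAssignment],
    marker_values: Dict[str, float],
    subtype: int,
    marker: str,
    adjustment_values: Optional[Dict[str, float]] = None,
    adjustment_name: Optional[str] = None,
) -> StageCorrelation:
    """Correlation of a marker with maximum-likelihood stage within a subtype.

    Plain Pearson by default. With ``adjustment_values`` the marker is first
    regressed on the covariate and the residual correlated with stage — a
    semi-partial correlation (intracranial volume for volumetrics, the TMT-B
    ceiling flag for the composite TMT).
    """
    ids = [a.subject_id for a in assignments if a.ml_subtype == subtype]
    stages = np.array([a.ml_stage for a in assignments if a.ml_subtype == subtype], float)
    if len(ids) < 3:
        raise ValueError("need at least 3 subjects in the subtype")
    y = np.array([float(marker_values[i]) for i in ids])
    if np.ptp(stages) == 0 or np.ptp(y) == 0:
        raise ValueError("constant stage or marker")
    kind = "pairwise"
    if adjustment_values is not None:
        cov = np.array([float(adjustment_values[i]) for i in ids])
        if np.ptp(cov) > 0:
            slope, intercept = np.polyfit(cov, y, 1)
            y = y - (intercept + slope * cov)
        if np.ptp(y) == 0 or np.allclose(y, 0, atol=1e-12):
            raise ValueError("degenerate residual after adjustment")
        kind = "semi_partial"
    r, p = stats.pearsonr(y, stages)
    return StageCorrelation(
        subtype=subtype, marker=marker, coefficient=float(r), p_value=float(p),
        kind=kind, adjustment=adjustment_name,
    )


@dataclass(frozen=True)
class ProgressionTable:
    """Diagnostic progression within a horizon per group x baseline diagnosis."""

    counts: pd.DataFrame  # index (group, baseline_dx), cols stable/progressed/reverted/missing
    horizon_months: int
    fisher_p: Dict[str, float]  # baseline dx -> p for progressed-vs-not across groups


def _classify_progression(record, horizon: int) -> str:
    base = _DX_ORDER[record.baseline_diagnosis]
    visits = [d for m, d in record.followup_diagnoses if m <= horizon]
    if not visits:
        return "missing"
    worst = max(_DX_ORDER[d] for d in visits)
    if worst > base:
        return "progressed"
    if worst < base:
        return "reverted"
    return "stable"


def progression_summary(
    cases: Cohort,
    assignments: Sequence[SubjectAssignment],
    horizon_months: int = 24,
    seed: int = 0,
) -> ProgressionTable:
    """Within-horizon diagnostic outcome by assignment group.

    Each subject is classified by the *worst* diagnosis recorded at visits
    inside the horizon: progressed, reverted, stable, or missing when no
    visit falls inside. Fisher exact tests compare progressed-vs-not
    proportions across groups within each baseline diagnosis.
    """
    labels = group_labels(assignments)
    rows = []
    for s in cases:
        base = "CN" if s.baseline_diagnosis in ("CN", "SMC") else s.baseline_diagnosis
        if base not in ("CN", "MCI"):
            continue
        rows.append({
            "group": labels[s.subject_id],
            "baseline": base,
            "outcome": _classify_progression(s, horizon_months),
        })
    df = pd.DataFrame(rows)
    cats = ["stable", "progressed", "reverted", "missing"]
    counts = (
        df.groupby(["group", "baseline"])["outcome"]
        .value_counts().unstack(fill_value=0).reindex(columns=cats, fill_value=0)
        if len(df) else pd.DataFrame(columns=cats)
    )
    fisher_p = {}
    for base in ("CN", "MCI"):
        sub = df[(df["baseline"] == base) & (df["outcome"] != "missing")]
        groups = sorted(sub["group"].unique())
        if len(groups) >= 2 and len(sub):
            tbl = np.array([
                [int(((sub["group"] == g) & (sub["outcome"] == "progressed")).sum())
                 for g in groups],
                [int(((sub["group"] == g) & (sub["outcome"] != "progressed")).sum())
                 for g in groups],
            ])
            fisher_p[base], _ = fisher_exact_2xk(tbl, seed=seed)
    return ProgressionTable(counts=counts, horizon_months=horizon_months,
                            fisher_p=fisher_p)
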