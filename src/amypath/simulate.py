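"""Seeded synthetic cohorts with planted subtypes.

The generator emulates the structure of an amyloid-stratified observational
cohort: a bimodal CSF abeta distribution separating an amyloid-negative
control group from amyloid-positive cases; controls scattered around the
control mean with unit z-scale noise; cases planted on one of C event
sequences at a sampled stage, observed with Gaussian z-scale noise plus a
stage-0 subpopulation indistinguishable from controls. Raw-scale markers
are produced by inverting the normalization maps exactly (direction flips,
log2 WMH, linear intracranial-volume effects on volumetrics, a TMT pair
consistent with the planted composite), so normalization round-trips the
planted z-scores. The generating normalization parameters travel with the
ground truth for exact-recovery tests.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import substream
from .cohort import Cohort, SubjectRecord
from .markers import LOWER_IS_WORSE, MarkerPanel, MarkerSpec, default_panel
from .normalization import ControlReference
from .sustain.events import EventSequence, Event
from .sustain.likelihood import trajectory_matrix

__all__ = [
    "SyntheticConfig", "GroundTruth", "generate_cohort", "generate_zscore_data",
    "make_paper_shaped_config", "make_tiny_fixture", "paper_sequences",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic cohort.

    ``control_plain`` maps plain marker names to (mean, sd) on the
    transformed, direction-aligned scale; ``control_adjusted`` maps
    covariate-adjusted marker names to (intercept, slope, residual_sd)
    against intracranial volume on that same scale. ``amyloid_components``
    are the (mean, sd, weight) of the abnormal and normal CSF abeta modes,
    ordered by mean; cases sample the lower mode truncated a safety margin
    below the implied cut-point and controls the upper mode above it.
    """

    seed: int = 0
    n_controls: int = 86
    n_cases: int = 376
    planted_sequences: tuple = ()
    fractions: tuple = (1.0,)
    stage0_mass: float = 0.0
    stage_distribution: str = "uniform"  # or "truncated_geometric"
    stage_geometric_rho: float = 0.85
    noise_sd_z: float = 1.0
    amyloid_components: tuple = ((190.0, 40.0, 0.55), (343.0, 50.7, 0.45))
    amyloid_cut_percentile: float = 0.99
    amyloid_margin: float = 15.0
    control_plain: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    control_adjusted: Dict[str, Tuple[float, float, float]] = field(default_factory=dict)
    tiv_mean: float = 1433.0
    tiv_sd: float = 136.9
    tmt_a_mean: float = 31.4
    tmt_a_sd: float = 10.0
    apoe_carrier_prob_cases: float = 0.65
    group_covariate_shifts: Dict[int, Dict[str, float]] = field(default_factory=dict)
    progression_rates: tuple = ((6, 0.02), (12, 0.15), (18, 0.45))  # (stage band upper, p(progress by 24 mo))

    def __post_init__(self) -> None:
        f = np.asarray(self.fractions, dtype=float)
        if abs(f.sum() - 1.0) > 1e-9 or np.any(f < 0):
            raise ValueError("fractions must be non-negative and sum to 1")
        if self.planted_sequences and len(self.planted_sequences) != f.size:
            raise ValueError("one fraction per planted sequence")
        if not 0.0 <= self.stage0_mass < 1.0:
            raise ValueError("stage0_mass must lie in [0, 1)")
        lo, hi = self.amyloid_components
        if lo[0] >= hi[0]:
            raise ValueError("amyloid components must be ordered by mean")

    @property
    def true_cutpoint(self) -> float:
        """Implied amyloid cut-point: upper percentile of the abnormal mode."""
        m, s, _ = self.amyloid_components[0]
        return float(stats.norm.ppf(self.amyloid_cut_percentile, m, s))

    def true_reference(self) -> ControlReference:
        return ControlReference(
            plain=dict(self.control_plain),
            adjusted=dict(self.control_adjusted),
            n_controls=self.n_controls,
        )


@dataclass(frozen=True)
class GroundTruth:
    """Planted latent state per generated case, plus the generating maps."""

    frame: pd.DataFrame  # subject_id, subtype (-1 = stage-0 subpopulation), stage
    z_true: np.ndarray  # planted z before noise, cases x markers
    z_noisy: np.ndarray  # planted z after noise (what normalization recovers)
    reference: ControlReference
    panel: MarkerPanel
    sequences: tuple
    amyloid_cutpoint: float

    @property
    def subtypes(self) -> np.ndarray:
        return self.frame["subtype"].to_numpy()

    @property
    def stages(self) -> np.ndarray:
        return self.frame["stage"].to_numpy()


def paper_sequences(panel: Optional[MarkerPanel] = None) -> tuple:
    """Three qualitatively distinct orderings over the six-marker panel:
    memory-led, vascular (WMH)-led, and p-tau-led."""
    panel = panel or default_panel()
    lm, tmt, ptau, wmh, wbv, hip = (panel.index(n) for n in (
        "lm_score", "composite_tmt_s", "csf_ptau181", "wmh_ml", "wbv_ml", "hip_ml"))

    def seq(order):
        return EventSequence([Event(m, t) for m, t in order], panel)

    memory_led = seq([
        (lm, 0), (lm, 1), (ptau, 0), (hip, 0), (lm, 2), (ptau, 1), (hip, 1),
        (wbv, 0), (ptau, 2), (wbv, 1), (hip, 2), (wmh, 0), (tmt, 0), (wbv, 2),
        (wmh, 1), (tmt, 1), (wmh, 2), (tmt, 2),
    ])
    wmh_led = seq([
        (wmh, 0), (wmh, 1), (lm, 0), (wbv, 0), (wmh, 2), (lm, 1), (tmt, 0),
        (wbv, 1), (lm, 2), (hip, 0), (tmt, 1), (wbv, 2), (hip, 1), (tmt, 2),
        (ptau, 0), (hip, 2), (ptau, 1), (ptau, 2),
    ])
    # p-tau led: both p-tau and memory complete all three z-score events
    # before any other marker changes, then hippocampus, executive function,
    # whole-brain and vascular burden follow
    ptau_led = seq([
        (ptau, 0), (ptau, 1), (lm, 0), (ptau, 2), (lm, 1), (lm, 2), (hip, 0),
        (tmt, 0), (hip, 1), (tmt, 1), (wbv, 0), (hip, 2), (tmt, 2), (wmh, 0),
        (wbv, 1), (wmh, 1), (wbv, 2), (wmh, 2),
    ])
    return memory_led, wmh_led, ptau_led


def make_paper_shaped_config(seed: int = 0, noise_sd_z: float = 1.0) -> SyntheticConfig:
    """Study-shaped conditions: 86 controls, 376 cases, three planted
    subtypes with shares 145/88/100 of the subtyped and an 11% (43/376)
    stage-0 mass; control-scale anchors from the control group's summary
    statistics (memory score 14.6 (2.6), composite TMT 47.8 (43.6), p-tau
    18.8 (7.4), median WMH 2.5 mL, whole-brain 1091.4 (105.4) mL,
    hippocampus 5.6 (0.7) mL, TIV 1433.0 (136.9) mL)."""
    panel = default_panel()
    total = 145 + 88 + 100
    # aligned scale: lower-is-worse markers are negated
    control_plain = {
        "lm_score": (-14.6, 2.6),
        "composite_tmt_s": (47.8, 43.6),
        "csf_ptau181": (18.8, 7.4),
    }
    # intercept/slope/residual SD of aligned value on intracranial volume
    control_adjusted = {
        "wmh_ml": (np.log2(2.5) - 0.0005 * 1433.0, 0.0005, 1.0),
        "wbv_ml": (-303.25, -0.55, 70.0),
        "hip_ml": (-3.45, -0.0015, 0.65),
    }
    return SyntheticConfig(
        seed=seed,
        n_controls=86,
        n_cases=376,
        planted_sequences=paper_sequences(panel),
        fractions=(145 / total, 88 / total, 100 / total),
        stage0_mass=43 / 376,
        noise_sd_z=noise_sd_z,
        control_plain=control_plain,
        control_adjusted=control_adjusted,
        group_covariate_shifts={1: {"age_years": 4.5, "hypertension": 0.18}},
    )


def _sample_stages(n: int, n_stages: int, config: SyntheticConfig,
                   rng: np.random.Generator) -> np.ndarray:
    if config.stage_distribution == "uniform":
        return rng.integers(1, n_stages + 1, size=n)
    if config.stage_distribution == "truncated_geometric":
        k = np.arange(1, n_stages + 1)
        p = config.stage_geometric_rho ** k
        return rng.choice(k, size=n, p=p / p.sum())
    raise ValueError(f"unknown stage distribution {config.stage_distribution!r}")


def generate_zscore_data(
    panel: MarkerPanel,
    sequences: Sequence[EventSequence],
    fractions: Sequence[float],
    n: int,
    noise_sd: float,
    rng: np.random.Generator,
    stage0_mass: float = 0.0,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Z-space cohort: returns (Z, subtypes, stages); subtype -1 = stage 0.

    The light-weight generator for model-core experiments that need no
    raw-scale plumbing.
    """
    f = np.asarray(fractions, dtype=float)
    n_stages = panel.n_events
    subtypes = np.where(
        rng.random(n) < stage0_mass, -1, rng.choice(len(f), size=n, p=f / f.sum())
    )
    stages = np.zeros(n, dtype=int)
    mask = subtypes >= 0
    stages[mask] = rng.integers(1, n_stages + 1, size=int(mask.sum()))
    trajs = [trajectory_matrix(s, panel) for s in sequences]
    Z = np.zeros((n, len(panel)))
    for i in range(n):
        if subtypes[i] >= 0:
            Z[i] = trajs[subtypes[i]][:, stages[i]]
    Z = Z + rng.normal(0.0, noise_sd, size=Z.shape) if noise_sd > 0 else Z
    return Z, subtypes, stages


def _invert_marker(spec: MarkerSpec, aligned: float) -> float:
    x = -aligned if spec.direction == LOWER_IS_WORSE else aligned
    if spec.transform == "log2":
        x = float(2.0 ** x)
    return x


_DX_BANDS = ((3, "CN"), (11, "MCI"), (99, "AD"))


def _baseline_dx(stage: int, rng: np.random.Generator) -> str:
    if stage == 0:
        return "SMC" if rng.random() < 0.3 else "CN"
    jitter = int(rng.integers(-2, 3))
    s = max(stage + jitter, 0)
    for upper, dx in _DX_BANDS:
        if s <= upper:
            return dx
    return "AD"


def _followups(base_dx: str, stage: int, config: SyntheticConfig,
               rng: np.random.Generator) -> tuple:
    if rng.random() < 0.15:  # no usable follow-up inside the horizon
        return ((36, base_dx),)
    p_prog = 0.0
    for upper, p in config.progression_rates:
        if stage <= upper:
            p_prog = p
            break
    else:
        p_prog = config.progression_rates[-1][1]
    order = ["CN", "MCI", "AD"]
    cur = "CN" if base_dx == "SMC" else base_dx
    visits = []
    for month in (6, 12, 24):
        if cur != "AD" and rng.random() < p_prog / 3.0:
            cur = order[order.index(cur) + 1]
        visits.append((month, cur))
    return tuple(visits)


def generate_cohort(
    config: SyntheticConfig,
    seed: Optional[int] = None,
) -> Tuple[Cohort, Cohort, GroundTruth]:
    """Generate (controls, cases, truth) on the raw marker scale.

    Deterministic for a given config and seed; the root seed feeds named
    substreams so each variable block draws independently.
    """
    seed = config.seed if seed is None else seed
    panel = default_panel()
    if not config.planted_sequences:
        raise ValueError("config needs at least one planted sequence")
    ref = config.true_reference()
    cut = config.true_cutpoint

    rng_lat = substream(seed, "latent")
    rng_z = substream(seed, "z-noise")
    rng_raw = substream(seed, "raw-markers")
    rng_demo = substream(seed, "demographics")

    n_stages = panel.n_events
    trajs = [trajectory_matrix(s, panel) for s in config.planted_sequences]

    # --- latent state for cases
    n = config.n_cases
    f = np.asarray(config.fractions, dtype=float)
    subtypes = np.where(
        rng_lat.random(n) < config.stage0_mass,
        -1,
        rng_lat.choice(f.size, size=n, p=f / f.sum()),
    )
    stages = np.zeros(n, dtype=int)
    mask = subtypes >= 0
    stages[mask] = _sample_stages(int(mask.sum()), n_stages, config, rng_lat)

    z_true = np.zeros((n, len(panel)))
    for i in range(n):
        if subtypes[i] >= 0:
            z_true[i] = trajs[subtypes[i]][:, stages[i]]
    noise = rng_z.normal(0.0, config.noise_sd_z, size=z_true.shape) \
        if config.noise_sd_z > 0 else np.zeros_like(z_true)
    z_noisy = z_true + noise

    lo_m, lo_s, _ = config.amyloid_components[0]
    hi_m, hi_s, _ = config.amyloid_components[1]
    margin = config.amyloid_margin

    def _records(z_matrix, ids, is_control, subtypes_arr, stages_arr):
        a, b = (-np.inf, (cut - margin - lo_m) / lo_s)
        c, d = ((cut + margin - hi_m) / hi_s, np.inf)
        recs = []
        for i, sid in enumerate(ids):
            tiv = rng_raw.normal(config.tiv_mean, config.tiv_sd)
            raw = {}
            for j, spec in enumerate(panel):
                zj = z_matrix[i, j]
                if spec.covariate_adjust is None:
                    mean, sd = ref.plain[spec.name]
                    aligned = mean + zj * sd
                else:
                    icpt, slope, rsd = ref.adjusted[spec.name]
                    aligned = icpt + slope * tiv + zj * rsd
                raw[spec.name] = _invert_marker(spec, aligned)
            # keep the pair physical (both times in (0, 300]) without touching
            # the planted composite: B - A is exactly the aligned raw score
            composite = min(raw.pop("composite_tmt_s"), 295.0)
            tmt_a = float(np.clip(
                rng_raw.normal(config.tmt_a_mean, config.tmt_a_sd),
                max(5.0, 5.0 - composite), 300.0 - composite,
            ))
            tmt_b = tmt_a + composite
            if is_control:
                abeta = stats.truncnorm.rvs(c, d, loc=hi_m, scale=hi_s,
                                            random_state=rng_raw)
            else:
                abeta = stats.truncnorm.rvs(a, b, loc=lo_m, scale=lo_s,
                                            random_state=rng_raw)
            stage = 0 if is_control else int(stages_arr[i])
            subtype = -1 if is_control else int(subtypes_arr[i])
            shift = {} if subtype < 0 else config.group_covariate_shifts.get(subtype, {})
            age = rng_demo.normal(72.4 if is_control else 72.0 + 0.15 * stage, 6.0) \
                + shift.get("age_years", 0.0)
            if is_control:
                dx, fu, apoe = "CN", ((12, "CN"), (24, "CN")), False
                hyper = rng_demo.random() < 0.35
            else:
                dx = _baseline_dx(stage, rng_demo)
                fu = _followups(dx, stage, config, rng_demo)
                apoe = rng_demo.random() < config.apoe_carrier_prob_cases
                hyper = rng_demo.random() < 0.45 + shift.get("hypertension", 0.0)
            mmse = float(np.clip(rng_demo.normal(29.0 - 0.30 * stage, 1.3), 12, 30))
            nfl = float(max(rng_demo.normal(
                33.0 + 0.8 * stage + shift.get("nfl_pg_ml", 0.0), 12.0), 5.0))
            recs.append(SubjectRecord(
                subject_id=sid,
                baseline_diagnosis=dx,
                age_years=float(age),
                sex="male" if rng_demo.random() < 0.52 else "female",
                apoe_e4_carrier=bool(apoe),
                education_years=float(np.clip(rng_demo.normal(16.0, 2.6), 6, 22)),
                csf_abeta=float(abeta),
                csf_ptau181=float(max(raw["csf_ptau181"], 0.5)),
                wmh_ml=float(raw["wmh_ml"]),
                wbv_ml=float(raw["wbv_ml"]),
                hip_ml=float(raw["hip_ml"]),
                tiv_ml=float(tiv),
                lm_score=float(max(raw["lm_score"], 0.0)),
                tmt_a_s=tmt_a,
                tmt_b_s=float(tmt_b),
                mmse=mmse,
                nfl_pg_ml=nfl,
                hypertension=bool(hyper),
                stroke=bool(rng_demo.random() < 0.01),
                lacune_present=bool(rng_demo.random() < (0.05 if shift else 0.01)),
                cmb_present=bool(rng_demo.random() < 0.18),
                followup_diagnoses=fu,
            ))
        return recs

    ctrl_z = rng_z.normal(0.0, 1.0, size=(config.n_controls, len(panel)))
    controls = Cohort(
        tuple(_records(ctrl_z, [f"CTL{i:04d}" for i in range(config.n_controls)],
                       True, None, None)),
        role="reference_controls", provenance="synthetic",
    )
    case_ids = [f"CASE{i:04d}" for i in range(n)]
    cases = Cohort(
        tuple(_records(z_noisy, case_ids, False, subtypes, stages)),
        role="cases", provenance="synthetic",
    )
    truth = GroundTruth(
        frame=pd.DataFrame({"subject_id": case_ids, "subtype": subtypes,
                            "stage": stages}),
        z_true=z_true,
        z_noisy=z_noisy,
        reference=ref,
        panel=panel,
        sequences=tuple(config.planted_sequences),
        amyloid_cutpoint=cut,
    )
    return controls, cases, truth


# --- hand-specified miniature cohort -------------------------------------

_TINY_CONTROL_Z = [
    (-0.62, 0.41), (1.17, -0.88), (0.05, 1.32), (-1.43, -0.27),
    (0.88, 0.09), (-0.11, -1.05), (0.53, 0.77), (-0.95, 0.36),
    (1.32, -0.54), (-0.29, 1.08), (0.10, -0.66), (-0.65, -0.63),
]
# planted (stage, z1 + noise, z2 + noise) for 20 cases under the sequence
# (marker 0 event, then marker 1 event), thresholds (1,), z_max 3
_TINY_CASE_STATE = [
    (0, 0.21, -0.33), (0, -0.48, 0.14), (0, 0.05, 0.52), (0, -0.36, -0.20),
    (1, 1.22, 0.31), (1, 0.74, -0.25), (1, 1.41, 0.18), (1, 0.96, 0.44),
    (1, 1.08, -0.12), (1, 0.67, 0.06),
    (2, 3.11, 1.24), (2, 2.78, 0.88), (2, 3.35, 1.02), (2, 2.94, 1.31),
    (2, 3.07, 0.69), (2, 2.69, 1.18), (2, 3.22, 0.95), (2, 2.87, 1.09),
    (2, 3.18, 0.81), (2, 3.02, 1.15),
]


def make_tiny_fixture() -> Tuple[Cohort, Cohort, GroundTruth, MarkerPanel]:
    """Hard-coded 12-control / 20-case two-marker, one-threshold cohort.

    The event space has N = 2 events and exactly 2 valid sequences, so
    posteriors are exhaustively enumerable in well under a second. Markers
    ride on the p-tau and memory fields of the subject record; the planted
    sequence is p-tau before memory.
    """
    panel = MarkerPanel((
        MarkerSpec("csf_ptau181", "higher_is_worse", z_thresholds=(1.0,), z_max=3.0),
        MarkerSpec("lm_score", LOWER_IS_WORSE, z_thresholds=(1.0,), z_max=3.0),
    ))
    ptau_mean, ptau_sd = 20.0, 5.0
    lm_mean, lm_sd = 14.0, 2.0

    def record(sid, z1, z2, abeta):
        return SubjectRecord(
            subject_id=sid, baseline_diagnosis="CN", age_years=72.0,
            csf_abeta=abeta,
            csf_ptau181=ptau_mean + z1 * ptau_sd,
            lm_score=lm_mean - z2 * lm_sd,
            wmh_ml=2.5, wbv_ml=1090.0, hip_ml=5.6, tiv_ml=1433.0,
            tmt_a_s=31.0, tmt_b_s=79.0,
        )

    controls = Cohort(
        tuple(record(f"TC{i:02d}", z1, z2, 340.0 + i)
              for i, (z1, z2) in enumerate(_TINY_CONTROL_Z)),
        role="reference_controls", provenance="tiny synthetic fixture",
    )
    cases = Cohort(
        tuple(record(f"TK{i:02d}", z1, z2, 180.0 + i)
              for i, (_, z1, z2) in enumerate(_TINY_CASE_STATE)),
        role="cases", provenance="tiny synthetic fixture",
    )
    sequence = EventSequence([Event(0, 0), Event(1, 0)], panel)
    states = np.array([s for s, _, _ in _TINY_CASE_STATE])
    z_noisy = np.array([[z1, z2] for _, z1, z2 in _TINY_CASE_STATE])
    traj = trajectory_matrix(sequence, panel)
    z_true = traj[:, states].T
    ref = ControlReference(
        plain={"csf_ptau181": (ptau_mean, ptau_sd), "lm_score": (-lm_mean, lm_sd)},
        adjusted={}, n_controls=len(controls),
    )
    truth = GroundTruth(
        frame=pd.DataFrame({
            "subject_id": [s.subject_id for s in cases],
            "subtype": np.where(states == 0, -1, 0),
            "stage": states,
        }),
        z_true=z_true, z_noisy=z_noisy, reference=ref, panel=panel,
        sequences=(sequence,), amyloid_cutpoint=262.0,
    )
    return controls, cases, truth, panel
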