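"""End-to-end orchestration.

One call runs the full analysis: amyloid cut-point from the bimodal CSF
abeta distribution, control/case group selection, control-referenced
normalization, optional CVIC model selection, subtype-and-stage fitting,
subject assignment, positional variance export and the post-hoc evaluation
tables. All stages draw named substreams from one root seed and a JSON run
report records counts, settings and the output manifest.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .amyloid import AmyloidMixtureModel
from .cohort import (Cohort, apply_completeness_filter, load_cohort,
                     select_cases, select_reference_controls)
from .evaluation import progression_summary, summarize_groups
from .markers import MarkerPanel, default_panel
from .normalization import build_zscore_matrix, fit_control_reference
from .simulate import SyntheticConfig, generate_cohort, make_paper_shaped_config
from .sustain import (FitSettings, SustainModel, assignments_to_dataframe,
                      cross_validate_cvic, positional_variance)

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_full_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    """Everything one pipeline run needs.

    Either ``input_csv`` (a combined cohort table) or ``synthetic=True``
    (a generated study-shaped cohort) supplies the data. ``n_subtypes``
    fixes the model size; leave ``None`` to select it by cross-validated
    CVIC up to ``settings.max_subtypes``.
    """

    out_dir: str = "amypath_run"
    seed: int = 0
    input_csv: Optional[str] = None
    column_map: Dict[str, str] = field(default_factory=dict)
    synthetic: bool = False
    synthetic_config: Optional[SyntheticConfig] = None
    panel: Optional[MarkerPanel] = None
    n_subtypes: Optional[int] = 3
    cut_percentile: float = 0.99
    settings: FitSettings = field(default_factory=FitSettings)


def run_full_pipeline(config: RunConfig) -> dict:
    """Run every stage; returns (and writes) the run report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    panel = config.panel or default_panel()
    settings = FitSettings(**{**config.settings.__dict__, "seed": config.seed})
    manifest = {}
    report = {"seed": config.seed, "settings": settings.__dict__}

    if config.synthetic:
        sim = config.synthetic_config or make_paper_shaped_config(seed=config.seed)
        controls_gen, cases_gen, truth = generate_cohort(sim, seed=config.seed)
        pool = Cohort(tuple(controls_gen) + tuple(cases_gen), role="combined",
                      provenance="synthetic")
        truth.frame.to_csv(out / "truth.csv", index=False)
        manifest["truth"] = "truth.csv"
    elif config.input_csv:
        pool = load_cohort(config.input_csv, config.column_map)
    else:
        raise ValueError("config must name an input CSV or request synthetic data")

    # 1. amyloid cut-point
    abeta = np.array([s.csf_abeta for s in pool if np.isfinite(s.csf_abeta)])
    mixture = AmyloidMixtureModel(abeta).fit(seed=config.seed)
    cut = mixture.cutpoint(percentile=config.cut_percentile)
    cut.to_json(out / "cutpoint.json")
    manifest["cutpoint"] = "cutpoint.json"
    report["cutpoint"] = {"value": cut.value, "percentile": cut.percentile}

    # 2. group selection and completeness
    controls = select_reference_controls(pool, cut)
    cases = select_cases(pool, cut)
    controls, excl_c = apply_completeness_filter(controls)
    cases, excl_k = apply_completeness_filter(cases)
    report["groups"] = {
        "n_pool": len(pool), "n_controls": len(controls), "n_cases": len(cases),
        "n_excluded_incomplete": len(excl_c) + len(excl_k),
    }
    if len(cases) == 0:
        raise RuntimeError("group selection produced no cases")

    # 3. normalization
    ref = fit_control_reference(controls, panel)
    Z = build_zscore_matrix(cases, ref, panel)
    Z.to_dataframe().to_csv(out / "zscores.csv")
    manifest["zscores"] = "zscores.csv"

    # 4. model-size selection
    n_subtypes = config.n_subtypes
    if n_subtypes is None:
        cvic = cross_validate_cvic(Z, panel, settings.max_subtypes, settings)
        report["cvic"] = {str(c): v for c, v in cvic.cvic.items()}
        n_subtypes = cvic.selected
    report["n_subtypes"] = n_subtypes

    # 5. fit + assignment
    results = SustainModel(Z, panel).fit(n_subtypes, settings)
    results.fitted.to_json(out / "model.json", panel)
    manifest["model"] = "model.json"
    assigns = results.assign()
    adf = assignments_to_dataframe(assigns)
    adf.to_csv(out / "assignments.csv", index=False)
    manifest["assignments"] = "assignments.csv"
    report["loglik"] = results.loglik
    group_sizes = adf.groupby(
        adf["ml_subtype"].where(~adf["unsubtyped"], -1)
    ).size()
    report["group_sizes"] = {
        ("unsubtyped" if int(g) < 0 else f"subtype_{int(g)}"): int(k)
        for g, k in group_sizes.items()
    }

    # 6. positional variance diagrams
    pvds = positional_variance(results.fitted, assigns, panel)
    for d in pvds:
        d.to_dataframe().to_csv(out / f"pvd_subtype{d.subtype}.csv")
        manifest[f"pvd_subtype{d.subtype}"] = f"pvd_subtype{d.subtype}.csv"
    report["pvd_dash_start"] = {str(d.subtype): d.dash_start for d in pvds}

    # 7. evaluation tables
    summary = summarize_groups(cases, assigns)
    summary.table.to_csv(out / "subtype_summary.csv")
    manifest["subtype_summary"] = "subtype_summary.csv"
    prog = progression_summary(cases, assigns, seed=config.seed)
    prog.counts.to_csv(out / "progression.csv")
    manifest["progression"] = "progression.csv"
    report["progression_fisher_p"] = prog.fisher_p

    report["manifest"] = manifest
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    log.info("pipeline complete: %s", out / "report.json")
    return report
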