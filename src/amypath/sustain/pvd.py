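"""Positional variance diagrams.

For each subtype, ``P[event, position]`` is the fraction of retained MCMC
samples placing that event at that 1-based position; a concentrated row
means a confidently ordered event, spread means ordering uncertainty. A
dashed line marks low-support late stages: it starts at the first stage
where the subtype's assigned-stage histogram has two consecutive stages
with two subjects or fewer.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from ..markers import MarkerPanel
from .events import all_events
from .model import SubjectAssignment, SubtypeModel

__all__ = ["PositionalVarianceDiagram", "positional_variance", "dash_start_stage",
           "plot_pvd"]


@dataclass(frozen=True)
class PositionalVarianceDiagram:
    subtype: int
    P: np.ndarray  # (n_events, n_events), rows sum to 1
    event_labels: tuple
    stage_histogram: np.ndarray  # counts over stages 0..N
    dash_start: Optional[int]

    def __post_init__(self) -> None:
        if not np.allclose(self.P.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PVD rows must sum to 1")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.P, index=list(self.event_labels),
            columns=[f"stage_{k}" for k in range(1, self.P.shape[1] + 1)],
        )


def dash_start_stage(stage_histogram: np.ndarray, max_count: int = 2) -> Optional[int]:
    """First stage s >= 1 with counts <= ``max_count`` at both s and s+1."""
    counts = np.asarray(stage_histogram)
    for s in range(1, counts.size - 1):
        if counts[s] <= max_count and counts[s + 1] <= max_count:
            return s
    return None


def positional_variance(
    model: SubtypeModel,
    assignments: Sequence[SubjectAssignment],
    panel: MarkerPanel,
) -> List[PositionalVarianceDiagram]:
    if not model.mcmc_samples:
        raise ValueError("model carries no MCMC samples")
    events = all_events(panel)
    index = {ev: i for i, ev in enumerate(events)}
    n_ev = len(events)
    labels = tuple(
        f"{panel.names[ev.marker_index]}@"
        f"{panel[ev.marker_index].z_thresholds[ev.threshold_index]:g}"
        for ev in events
    )
    out = []
    for c in range(model.n_subtypes):
        P = np.zeros((n_ev, n_ev))
        for sample in model.mcmc_samples:
            for pos, ev in enumerate(sample.sequences[c].events):
                P[index[ev], pos] += 1.0
        P /= len(model.mcmc_samples)
        hist = np.zeros(n_ev + 1, dtype=int)
        for a in assignments:
            if a.ml_subtype == c:
                hist[a.ml_stage] += 1
        out.append(
            PositionalVarianceDiagram(
                subtype=c, P=P, event_labels=labels,
                stage_histogram=hist, dash_start=dash_start_stage(hist),
            )
        )
    return out


def plot_pvd(diagrams: Sequence[PositionalVarianceDiagram], path=None):
    """Raster plot of the PVD matrices (one panel per subtype)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(diagrams)
    fig, axes = plt.subplots(1, n, figsize=(5 * n, 4), squeeze=False)
    for ax, d in zip(axes[0], diagrams):
        ax.imshow(d.P, aspect="auto", cmap="Reds", vmin=0, vmax=1)
        ax.set_yticks(range(len(d.event_labels)))
        ax.set_yticklabels(d.event_labels, fontsize=6)
        ax.set_xlabel("sequence position")
        ax.set_title(f"subtype {d.subtype}")
        if d.dash_start is not None:
            ax.axvline(d.dash_start - 0.5, linestyle="--", color="k")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
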