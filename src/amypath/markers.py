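"""Declarative biomarker panel.

Each modelled marker is described by its direction of abnormality, an
optional variance-stabilising transform, an optional head-size covariate
adjustment, and the z-score event thresholds it contributes to the
progression model.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import yaml

#: Direction conventions. ``higher_is_worse`` markers enter the z-scale as-is;
#: ``lower_is_worse`` markers are negated before z-scoring so that a larger z
#: always means more abnormal.
HIGHER_IS_WORSE = "higher_is_worse"
LOWER_IS_WORSE = "lower_is_worse"

_TRANSFORMS = ("identity", "log2")


@dataclass(frozen=True)
class MarkerSpec:
    """One biomarker's place in the model.

    Parameters
    ----------
    name : str
        Column name of the marker on the raw scale.
    direction : {"higher_is_worse", "lower_is_worse"}
        Which way abnormality points on the raw scale.
    transform : {"identity", "log2"}
        Transform applied before direction alignment and z-scoring.
    covariate_adjust : str, optional
        Name of a covariate column (here total intracranial volume for the
        volumetric markers); when set, the z-score is a W-score computed from
        the residual of a control-only regression on this covariate.
    z_thresholds : tuple of float
        Z-score event thresholds, strictly increasing (default ``(1, 2, 3)``).
    z_max : float
        Trajectory ceiling approached after the marker's last event
        (default 5); must exceed the largest threshold.
    """

    name: str
    direction: str
    transform: str = "identity"
    covariate_adjust: Optional[str] = None
    z_thresholds: tuple = (1.0, 2.0, 3.0)
    z_max: float = 5.0

    def __post_init__(self) -> None:
        if self.direction not in (HIGHER_IS_WORSE, LOWER_IS_WORSE):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.transform not in _TRANSFORMS:
            raise ValueError(f"unknown transform {self.transform!r}")
        zt = tuple(float(z) for z in self.z_thresholds)
        if any(z <= 0 for z in zt) or any(b <= a for a, b in zip(zt, zt[1:])):
            raise ValueError("z_thresholds must be positive and strictly increasing")
        object.__setattr__(self, "z_thresholds", zt)
        if not self.z_max > zt[-1]:
            raise ValueError("z_max must exceed the largest z threshold")

    @property
    def n_events(self) -> int:
        return len(self.z_thresholds)


@dataclass(frozen=True)
class MarkerPanel:
    """Ordered collection of :class:`MarkerSpec`."""

    markers: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "markers", tuple(self.markers))
        names = [m.name for m in self.markers]
        if len(set(names)) != len(names):
            raise ValueError("duplicate marker names in panel")

    def __len__(self) -> int:
        return len(self.markers)

    def __iter__(self):
        return iter(self.markers)

    def __getitem__(self, i: int) -> MarkerSpec:
        return self.markers[i]

    @property
    def names(self) -> list:
        return [m.name for m in self.markers]

    @property
    def n_events(self) -> int:
        """Total number of z-score events across markers."""
        return sum(m.n_events for m in self.markers)

    def index(self, name: str) -> int:
        return self.names.index(name)

    @classmethod
    def from_yaml(cls, path) -> "MarkerPanel":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        markers = []
        for entry in raw["markers"]:
            markers.append(
                MarkerSpec(
                    name=entry["name"],
                    direction=entry["direction"],
                    transform=entry.get("transform", "identity"),
                    covariate_adjust=entry.get("covariate_adjust"),
                    z_thresholds=tuple(entry.get("z_thresholds", (1.0, 2.0, 3.0))),
                    z_max=float(entry.get("z_max", 5.0)),
                )
            )
        return cls(tuple(markers))

    def to_yaml(self, path) -> None:
        payload = {
            "markers": [
                {
                    "name": m.name,
                    "direction": m.direction,
                    "transform": m.transform,
                    "covariate_adjust": m.covariate_adjust,
                    "z_thresholds": list(m.z_thresholds),
                    "z_max": m.z_max,
                }
                for m in self.markers
            ]
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


def default_panel(z_thresholds: Sequence[float] = (1.0, 2.0, 3.0), z_max: float = 5.0) -> MarkerPanel:
    """The six-marker panel used throughout: memory, executive function,
    tau pathology, vascular burden and the two brain volumes.

    Logical memory, whole-brain and hippocampal volume worsen downwards and
    are inverted; white-matter hyperintensity volume is log2-transformed; the
    three imaging-derived volumes are adjusted for total intracranial volume.
    """
    zt = tuple(z_thresholds)
    return MarkerPanel(
        (
            MarkerSpec("lm_score", LOWER_IS_WORSE, z_thresholds=zt, z_max=z_max),
            MarkerSpec("composite_tmt_s", HIGHER_IS_WORSE, z_thresholds=zt, z_max=z_max),
            MarkerSpec("csf_ptau181", HIGHER_IS_WORSE, z_thresholds=zt, z_max=z_max),
            MarkerSpec(
                "wmh_ml", HIGHER_IS_WORSE, transform="log2",
                covariate_adjust="tiv_ml", z_thresholds=zt, z_max=z_max,
            ),
            MarkerSpec(
                "wbv_ml", LOWER_IS_WORSE, covariate_adjust="tiv_ml",
                z_thresholds=zt, z_max=z_max,
            ),
            MarkerSpec(
                "hip_ml", LOWER_IS_WORSE, covariate_adjust="tiv_ml",
                z_thresholds=zt, z_max=z_max,
            ),
        )
    )
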