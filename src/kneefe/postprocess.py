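"""Reduce simulated fields to 1-D stance trajectories.

Two summary statistics are computed per biomechanical parameter at each
stance point, both restricted to the cartilage-cartilage contact region of
the tibial cartilage:

- *mean*: unweighted average of element-centroid values over the elements
  whose contact face currently carries pressure;
- *peak*: the value of the extreme element averaged with all elements
  sharing at least one node with it (this neighbor averaging suppresses
  single-element spikes from the contact discretization).

For the (negative-valued) minimum principal strain the "peak" is the most
compressive element; all other parameters peak at their maximum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from kneefe.fe import SimulationResult
from kneefe.mesh import HexMesh

__all__ = [
    "TrajectorySet",
    "PARAMETERS",
    "contact_region",
    "mean_over_contact",
    "peak_with_neighbors",
    "build_trajectories",
    "trajectories_to_frame",
]

PARAMETERS = (
    "max_principal_stress",
    "max_principal_strain",
    "min_principal_strain",
    "fibril_strain",
    "fluid_pressure",
)

#: Contact pressure below this (MPa) does not count as contact.
DEFAULT_PRESSURE_TOL = 0.01


@dataclass(frozen=True)
class TrajectorySet:
    """One parameter x statistic trajectory over the stance grid.

    Stance points with an empty contact region are NaN and excluded from
    downstream statistics pairwise.
    """

    subject_id: str
    modality: str
    parameter: str
    statistic: str  # {"mean", "peak"}
    stance_pct: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.parameter not in PARAMETERS:
            raise ValueError(f"unknown parameter {self.parameter!r}")
        if self.statistic not in ("mean", "peak"):
            raise ValueError(f"unknown statistic {self.statistic!r}")
        if len(self.stance_pct) != len(self.values):
            raise ValueError("grid/value length mismatch")


def contact_region(
    result: SimulationResult, step: int, pressure_tol: float = DEFAULT_PRESSURE_TOL
) -> np.ndarray:
    """Tibial elements whose contact face carries pressure above tolerance."""
    return np.flatnonzero(result.contact_pressure[step] > pressure_tol)


def mean_over_contact(
    result: SimulationResult,
    parameter: str,
    step: int,
    pressure_tol: float = DEFAULT_PRESSURE_TOL,
) -> float:
    """Unweighted mean of centroid values over the contact region (NaN if empty)."""
    region = contact_region(result, step, pressure_tol)
    if len(region) == 0:
        return float("nan")
    return float(getattr(result, parameter)[step][region].mean())


def _adjacency(mesh: HexMesh, mode: str = "vertex") -> list[np.ndarray]:
    if mode == "vertex":
        return mesh.vertex_adjacency()
    if mode == "face":
        return mesh.face_adjacency()
    raise ValueError(f"unknown adjacency mode {mode!r}")


_adjacency_cache: dict[int, list[np.ndarray]] = {}


def _cached_adjacency(mesh: HexMesh, mode: str) -> list[np.ndarray]:
    key = (id(mesh), mode)
    if key not in _adjacency_cache:
        _adjacency_cache[key] = _adjacency(mesh, mode)
    return _adjacency_cache[key]


def peak_with_neighbors(
    result: SimulationResult,
    parameter: str,
    step: int,
    pressure_tol: float = DEFAULT_PRESSURE_TOL,
    adjacency: str = "vertex",
) -> float:
    """Extreme element value averaged with its node-sharing neighbors.

    The extreme element is searched within the contact region (ties broken
    by lowest element id); its neighbors contribute regardless of whether
    they are themselves in contact. For min_principal_strain the extreme is
    the most negative (most compressive) value.
    """
    region = contact_region(result, step, pressure_tol)
    if len(region) == 0:
        return float("nan")
    values = getattr(result, parameter)[step]
    in_region = values[region]
    if parameter == "min_principal_strain":
        peak_elem = int(region[np.argmin(in_region)])
    else:
        peak_elem = int(region[np.argmax(in_region)])
    nbrs = _cached_adjacency(result.tibial_mesh, adjacency)[peak_elem]
    group = np.concatenate([[peak_elem], nbrs])
    return float(values[group].mean())


def build_trajectories(
    result: SimulationResult,
    subject_id: str,
    modality: str,
    pressure_tol: float = DEFAULT_PRESSURE_TOL,
    adjacency: str = "vertex",
) -> list[TrajectorySet]:
    """All 5 parameters x {mean, peak} = 10 stance trajectories."""
    out = []
    n = result.n_steps
    for parameter in PARAMETERS:
        means = np.array(
            [mean_over_contact(result, parameter, s, pressure_tol) for s in range(n)]
        )
        peaks = np.array(
            [peak_with_neighbors(result, parameter, s, pressure_tol, adjacency) for s in range(n)]
        )
        for stat, vals in (("mean", means), ("peak", peaks)):
            out.append(
                TrajectorySet(
                    subject_id=subject_id,
                    modality=modality,
                    parameter=parameter,
                    statistic=stat,
                    stance_pct=result.stance_pct.copy(),
                    values=vals,
                )
            )
    return out


def trajectories_to_frame(trajectories: list[TrajectorySet]) -> pd.DataFrame:
    """Long-format export: subject, modality, parameter, statistic, stance, value."""
    rows = []
    for t in trajectories:
        for q, v in zip(t.stance_pct, t.values):
            rows.append(
                {
                    "subject_id": t.subject_id,
                    "modality": t.modality,
                    "parameter": t.parameter,
                    "statistic": t.statistic,
                    "stance_pct": q,
                    "value": v,
                }
            )
    return pd.DataFrame(rows)


def trajectories_from_frame(df: pd.DataFrame) -> list[TrajectorySet]:
    out = []
    for (sid, mod, par, stat), g in df.groupby(
        ["subject_id", "modality", "parameter", "statistic"], sort=True
    ):
        g = g.sort_values("stance_pct")
        out.append(
            TrajectorySet(
                subject_id=str(sid),
                modality=str(mod),
                parameter=str(par),
                statistic=str(stat),
                stance_pct=g["stance_pct"].to_numpy(),
                values=g["value"].to_numpy(),
            )
        )
    return out
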