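"""Medial-compartment gait load case construction.

The whole-joint axial reaction waveform (in multiples of body weight) is
scaled to the subject's body weight, split to the medial compartment
(default 50% of the total joint force), and reduced by the fraction of
medial load carried through the meniscus, which is not meshed:

    F(q) = axial_BW(q) * BW * medial_fraction * (1 - meniscus_share(q))

Rotational channels (flexion-extension and varus-valgus) pass through
unchanged from the waveforms of the matched template. The stance grid
(0-100%) is mapped onto a physical time axis for the transient solve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from kneefe.atlas import GaitWaveforms

__all__ = ["LoadingConfig", "LoadCase", "build_loadcase", "scale_to_subject"]

#: Default share of the total joint reaction carried by the medial compartment.
DEFAULT_MEDIAL_FRACTION = 0.5

#: Default physical duration of the stance phase, s.
DEFAULT_STANCE_DURATION_S = 0.6


@dataclass(frozen=True)
class LoadingConfig:
    """Inputs for building a medial-compartment load case."""

    body_weight: float  # N
    waveforms: GaitWaveforms
    medial_fraction: float = DEFAULT_MEDIAL_FRACTION
    meniscus_share: float | np.ndarray | None = None  # None -> waveform profile
    stance_duration_s: float = DEFAULT_STANCE_DURATION_S

    def __post_init__(self) -> None:
        if self.body_weight <= 0:
            raise ValueError("body_weight must be > 0")
        if not (0 < self.medial_fraction <= 1):
            raise ValueError("medial_fraction must lie in (0, 1]")
        share = self.resolved_share()
        if ((share < 0) | (share >= 1)).any():
            raise ValueError("meniscus_share must lie in [0, 1)")
        if self.stance_duration_s <= 0:
            raise ValueError("stance_duration_s must be > 0")

    def resolved_share(self) -> np.ndarray:
        n = self.waveforms.n_points
        if self.meniscus_share is None:
            return np.asarray(self.waveforms.meniscus_share, dtype=float)
        share = np.asarray(self.meniscus_share, dtype=float)
        if share.ndim == 0:
            return np.full(n, float(share))
        if len(share) != n:
            raise ValueError(
                f"meniscus_share length {len(share)} != stance grid length {n}"
            )
        return share


@dataclass(frozen=True)
class LoadCase:
    """Per-step applied loading at the femoral reference point."""

    time_s: np.ndarray  # monotone, starts at 0
    stance_pct: np.ndarray
    flexion_rad: np.ndarray
    varus_rad: np.ndarray
    axial_force_n: np.ndarray  # after medial split and meniscus subtraction

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("time grid must be strictly increasing")
        n = len(t)
        for name in ("stance_pct", "flexion_rad", "varus_rad", "axial_force_n"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if len(arr) != n:
                raise ValueError(f"{name} length mismatch")
            object.__setattr__(self, name, arr)
        object.__setattr__(self, "time_s", t)

    @property
    def n_steps(self) -> int:
        return len(self.time_s)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time_s,
                "stance_pct": self.stance_pct,
                "flexion_rad": self.flexion_rad,
                "varus_rad": self.varus_rad,
                "axial_force_n": self.axial_force_n,
            }
        )


def scale_to_subject(axial_bw: np.ndarray, body_weight: float) -> np.ndarray:
    """Axial waveform (BW multiples) -> force series in N; linear in BW."""
    if body_weight <= 0:
        raise ValueError("body_weight must be > 0")
    return np.asarray(axial_bw, dtype=float) * body_weight


def build_loadcase(config: LoadingConfig) -> LoadCase:
    """Assemble the applied medial-compartment loading over stance."""
    wf = config.waveforms
    share = config.resolved_share()
    total = scale_to_subject(wf.axial_bw, config.body_weight)
    applied = total * config.medial_fraction * (1.0 - share)
    time_s = wf.stance_pct / 100.0 * config.stance_duration_s
    return LoadCase(
        time_s=time_s,
        stance_pct=wf.stance_pct,
        flexion_rad=np.deg2rad(wf.flexion_deg),
        varus_rad=np.deg2rad(wf.varus_deg),
        axial_force_n=applied,
    )


def read_waveforms_csv(path) -> GaitWaveforms:
    """CSV import (columns stance_pct, flexion_deg, varus_deg, axial_bw, meniscus_share)."""
    df = pd.read_csv(path)
    return GaitWaveforms(
        stance_pct=df["stance_pct"].to_numpy(),
        flexion_deg=df["flexion_deg"].to_numpy(),
        varus_deg=df["varus_deg"].to_numpy(),
        axial_bw=df["axial_bw"].to_numpy(),
        meniscus_share=df["meniscus_share"].to_numpy(),
    )
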