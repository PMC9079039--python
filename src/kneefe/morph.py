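"""Anisotropic morphing of atlas meshes to subject dimensions.

The selected atlas is scaled independently along the three anatomical axes
by the subject/atlas dimension ratios: AP length along x, ML width along y,
and medial JSW along z (the joint-space/thickness direction). Scaling is
about the centroid of the atlas tibial contact face so the contact region
stays centred; connectivity, sets and normalized depth are untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from kneefe.anatomy import AnatomicalDimensions
from kneefe.atlas import AtlasRecord
from kneefe.mesh import HexMesh, MeshError

__all__ = ["MorphFactors", "MorphError", "compute_factors", "apply_morph", "morph_atlas"]

#: Multiplicative scale factors outside this open band are refused: the
#: template is then too dissimilar for plain anisotropic scaling.
FACTOR_BAND = (0.5, 2.0)


class MorphError(ValueError):
    """Morph factors out of range or the morph would invert elements."""


@dataclass(frozen=True)
class MorphFactors:
    """Per-axis scale factors and the fixed point of the scaling."""

    fx: float  # AP
    fy: float  # ML
    fz: float  # thickness / JSW
    origin: tuple[float, float, float]

    def __post_init__(self) -> None:
        lo, hi = FACTOR_BAND
        for name, f in (("fx", self.fx), ("fy", self.fy), ("fz", self.fz)):
            if not (lo < f < hi):
                raise MorphError(
                    f"morph out of range: {name}={f:.3f} outside ({lo}, {hi}); "
                    "atlas too dissimilar"
                )

    def inverse(self) -> "MorphFactors":
        return MorphFactors(1.0 / self.fx, 1.0 / self.fy, 1.0 / self.fz, self.origin)

    @property
    def volume_ratio(self) -> float:
        return self.fx * self.fy * self.fz


def _tibial_contact_centroid(tibial: HexMesh) -> tuple[float, float, float]:
    nodes = np.unique(tibial.face_node_ids("tibial_contact"))
    return tuple(tibial.coords[nodes].mean(axis=0))


def compute_factors(
    subject: AnatomicalDimensions,
    atlas_dims: AnatomicalDimensions,
    tibial: HexMesh,
) -> MorphFactors:
    """Subject/atlas ratios of AP (x), ML (y) and medial JSW (z).

    Only the medial AP and medial JSW drive the morph: the lateral
    dimensions influence template selection but the meshes cover the medial
    compartment only.
    """
    return MorphFactors(
        fx=subject.ap_medial / atlas_dims.ap_medial,
        fy=subject.ml_width / atlas_dims.ml_width,
        fz=subject.jsw_medial / atlas_dims.jsw_medial,
        origin=_tibial_contact_centroid(tibial),
    )


def apply_morph(mesh: HexMesh, f: MorphFactors) -> HexMesh:
    """Scale nodal coordinates about the origin; everything else is shared."""
    origin = np.asarray(f.origin)
    scale = np.array([f.fx, f.fy, f.fz])
    coords = origin + scale * (mesh.coords - origin)
    out = replace(mesh, coords=coords)
    try:
        out.check_jacobians()
    except MeshError as e:  # cannot occur for positive factors; guard anyway
        raise MorphError(f"mesh inverted after morph: {e}") from e
    return out


def morph_atlas(record: AtlasRecord, subject: AnatomicalDimensions) -> tuple[AtlasRecord, MorphFactors]:
    """Morph both compartment meshes of an atlas to the subject's dimensions."""
    f = compute_factors(subject, record.dimensions, record.tibial_mesh)
    morphed = AtlasRecord(
        atlas_id=record.atlas_id,
        dimensions=subject,
        femoral_mesh=apply_morph(record.femoral_mesh, f),
        tibial_mesh=apply_morph(record.tibial_mesh, f),
        waveforms=record.waveforms,
    )
    return morphed, f
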