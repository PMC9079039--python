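"""Synthetic atlas library: medial-compartment cartilage meshes + gait waveforms.

An atlas record couples (i) the five anatomical dimensions of a template
knee, (ii) hexahedral meshes of the medial femoral and tibial cartilage,
and (iii) the stance-phase loading waveforms that travel with the template.
Real atlas libraries are segmented from MRI; here the geometry is generated
parametrically so the whole pipeline can run from dimensions alone:

- tibial cartilage: a layered hex block spanning the medial plateau
  (AP extent x half the ML width) with a shallow dished superior surface;
- femoral cartilage: a convex condyle cap of constant thickness whose
  inferior surface is an elliptic paraboloid (the condyle is treated as
  ellipsoidal, with the AP extent its major axis);
- the minimum cartilage-surface-to-surface gap at the compartment centre
  equals JSW minus the two cartilage thicknesses, so that the radiographic
  joint space is reproduced by construction.

Axes: x = anterior->posterior, y = medial->lateral, z = inferior->superior,
millimetres. Compartment meshes span half of the stored (whole-joint) ML
width.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace
from pathlib import Path

import numpy as np
from scipy.interpolate import LinearNDInterpolator, NearestNDInterpolator

from kneefe.anatomy import AnatomicalDimensions, ValidationError
from kneefe.mesh import HexMesh, MeshError, read_inp, write_inp

__all__ = [
    "GaitWaveforms",
    "AtlasRecord",
    "GeometryError",
    "generate_atlas",
    "generate_library",
    "measure_mesh_dimensions",
    "save_atlas",
    "load_atlas",
    "load_library",
    "DEFAULT_DIMENSION_RANGES",
]

#: Sagittal / frontal radii of curvature of the synthetic condyle cap, mm.
CONDYLE_RADIUS_AP = 35.0
CONDYLE_RADIUS_ML = 25.0

#: Dish rise of the tibial plateau from centre to the AP/ML edge, mm.
TIBIAL_DISH_MM = 0.3

#: Default uniform sampling ranges for synthetic libraries (mm), spanning
#: the anatomical variation of non-narrowed adult knees.
DEFAULT_DIMENSION_RANGES = {
    "ap_medial": (52.0, 64.0),
    "ap_lateral": (58.0, 68.0),
    "jsw_medial": (4.0, 5.6),
    "jsw_lateral": (4.6, 6.2),
    "ml_width": (76.0, 90.0),
}

#: Cartilage thickness as a fraction of the medial JSW when not given
#: explicitly (the radiographic joint space is mostly cartilage).
THICKNESS_JSW_FRACTION = 0.45


class GeometryError(ValueError):
    """Requested geometry cannot be realised (e.g. negative surface gap)."""


@dataclass(frozen=True)
class GaitWaveforms:
    """Stance-phase loading series on a uniform 0-100% grid.

    axial_force is in multiples of body weight (whole-joint reaction before
    the medial split); meniscus_share is the fraction of the medial
    compartment force transmitted through the meniscus, to be subtracted.
    """

    stance_pct: np.ndarray
    flexion_deg: np.ndarray
    varus_deg: np.ndarray
    axial_bw: np.ndarray
    meniscus_share: np.ndarray

    def __post_init__(self) -> None:
        arrays = {
            "stance_pct": np.asarray(self.stance_pct, dtype=float),
            "flexion_deg": np.asarray(self.flexion_deg, dtype=float),
            "varus_deg": np.asarray(self.varus_deg, dtype=float),
            "axial_bw": np.asarray(self.axial_bw, dtype=float),
            "meniscus_share": np.asarray(self.meniscus_share, dtype=float),
        }
        n = len(arrays["stance_pct"])
        if n < 11:
            raise ValidationError("waveforms need >= 11 stance points")
        for name, arr in arrays.items():
            if len(arr) != n:
                raise ValidationError(f"waveform {name} length {len(arr)} != {n}")
            object.__setattr__(self, name, arr)
        if not np.allclose(self.stance_pct, np.linspace(0.0, 100.0, n)):
            raise ValidationError("stance grid must be uniform over 0-100%")
        if (self.axial_bw < 0).any():
            raise ValidationError("axial_force must be >= 0")
        if ((self.meniscus_share < 0) | (self.meniscus_share >= 1)).any():
            raise ValidationError("meniscus_share must lie in [0, 1)")

    @property
    def n_points(self) -> int:
        return len(self.stance_pct)

    def to_dict(self) -> dict:
        return {
            "stance_pct": self.stance_pct.tolist(),
            "flexion_deg": self.flexion_deg.tolist(),
            "varus_deg": self.varus_deg.tolist(),
            "axial_bw": self.axial_bw.tolist(),
            "meniscus_share": self.meniscus_share.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GaitWaveforms":
        return cls(**{k: np.asarray(v, dtype=float) for k, v in d.items()})


@dataclass
class AtlasRecord:
    atlas_id: str
    dimensions: AnatomicalDimensions
    femoral_mesh: HexMesh
    tibial_mesh: HexMesh
    waveforms: GaitWaveforms

    def check(self, tol: float = 0.02) -> None:
        """Stored dimensions must agree with those measured off the meshes."""
        measured = measure_mesh_dimensions(self.femoral_mesh, self.tibial_mesh, self.dimensions)
        for name in ("ap_medial", "ml_width", "jsw_medial"):
            a, b = getattr(measured, name), getattr(self.dimensions, name)
            if abs(a - b) > tol * b:
                raise ValidationError(
                    f"atlas {self.atlas_id}: measured {name}={a:.3f} vs stored {b:.3f} "
                    f"exceeds {tol:.0%}"
                )


# --------------------------------------------------------------- mesh builders


def _structured_hexes(nx: int, ny: int, nz: int) -> np.ndarray:
    """Connectivity of an (nx, ny, nz)-element structured grid.

    Node index (i, j, k) -> i*(ny+1)*(nz+1) + j*(nz+1) + k. Ordering keeps
    positive Jacobians for grids increasing along +x, +y, +z.
    """

    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    conn = []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                conn.append(
                    [
                        nid(i, j, k),
                        nid(i + 1, j, k),
                        nid(i + 1, j + 1, k),
                        nid(i, j + 1, k),
                        nid(i, j, k + 1),
                        nid(i + 1, j, k + 1),
                        nid(i + 1, j + 1, k + 1),
                        nid(i, j + 1, k + 1),
                    ]
                )
    return np.array(conn, dtype=np.int64)


def _layered_mesh(
    xs: np.ndarray,
    ys: np.ndarray,
    z_bottom,
    z_top,
    nz: int,
    articular: str,
) -> HexMesh:
    """Structured hex block between two surfaces z_bottom(x,y) and z_top(x,y).

    ``articular`` in {"top", "bottom"} selects which surface is the
    articulating one: its faces go into the contact face set and h_z runs
    from 0 there to 1 at the opposite (bone) side.
    """
    nx, ny = len(xs) - 1, len(ys) - 1
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    zb, zt = z_bottom(X, Y), z_top(X, Y)
    coords = np.empty(((nx + 1) * (ny + 1) * (nz + 1), 3))
    idx = 0
    for i in range(nx + 1):
        for j in range(ny + 1):
            for k in range(nz + 1):
                t = k / nz
                coords[idx] = (X[i, j], Y[i, j], zb[i, j] + t * (zt[i, j] - zb[i, j]))
                idx += 1
    elements = _structured_hexes(nx, ny, nz)

    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    def eid(i, j, k):
        return (i * ny + j) * nz + k

    bottom_nodes = np.array(sorted(nid(i, j, 0) for i in range(nx + 1) for j in range(ny + 1)))
    top_nodes = np.array(sorted(nid(i, j, nz) for i in range(nx + 1) for j in range(ny + 1)))
    # local faces in _structured_hexes ordering: S1 = k- (bottom), S2 = k+ (top)
    bottom_faces = np.array([[eid(i, j, 0), 0] for i in range(nx) for j in range(ny)])
    top_faces = np.array([[eid(i, j, nz - 1), 1] for i in range(nx) for j in range(ny)])

    layer = np.array([eid(i, j, k) for i in range(nx) for j in range(ny) for k in range(nz)])
    kk = np.array([k for i in range(nx) for j in range(ny) for k in range(nz)])
    h_z = np.empty(len(elements))
    if articular == "top":
        contact_faces, bone_nodes = top_faces, bottom_nodes
        h_z[layer] = 1.0 - (kk + 0.5) / nz  # 0 at top (articular), 1 at bottom
        bone_name = "tibial_bone_interface"
        contact_name = "tibial_contact"
    else:
        contact_faces, bone_nodes = bottom_faces, top_nodes
        h_z[layer] = (kk + 0.5) / nz  # 0 at bottom (articular), 1 at top
        bone_name = "femoral_bone_interface"
        contact_name = "femoral_contact"

    mesh = HexMesh(
        coords=coords,
        elements=elements,
        node_sets={bone_name: bone_nodes},
        face_sets={contact_name: contact_faces},
        h_z=h_z,
    )
    mesh.face_sets["sealed_exterior"] = mesh.exterior_faces()
    mesh.check_jacobians()
    return mesh


def default_waveforms(n_points: int = 51, seed: int | None = None) -> GaitWaveforms:
    """Canonical stance loading: double-hump axial force, smooth rotations.

    The axial force is piecewise linear through the classic two-peak knee
    reaction profile (peaks near 25% and 75% of stance at ~2.5 BW); flexion
    shows the loading-response hump and the pre-swing rise; varus stays
    within a few degrees. A seed applies a small deterministic perturbation
    (peak amplitudes +-10%, phase shifts +-3% of stance) so that different
    atlases carry different but physiologic waveforms.
    """
    q = np.linspace(0.0, 100.0, n_points)
    rng = np.random.default_rng(seed)
    a1, a2 = 1.0, 1.0
    s1 = s2 = 0.0
    if seed is not None:
        a1, a2 = 1.0 + 0.1 * rng.uniform(-1, 1, 2)
        s1, s2 = 3.0 * rng.uniform(-1, 1, 2)
    knots = np.array(
        [
            [0.0, 0.25],
            [25.0 + s1, 2.5 * a1],
            [50.0, 1.9],
            [75.0 + s2, 2.5 * a2],
            [100.0, 0.25],
        ]
    )
    axial = np.interp(q, knots[:, 0], knots[:, 1])
    flex = 5.0 + 12.0 * np.exp(-(((q - (18.0 + s1)) / 12.0) ** 2)) + 20.0 * np.exp(
        -(((q - 98.0) / 15.0) ** 2)
    )
    varus = 2.0 + 1.5 * np.sin(2.0 * np.pi * q / 100.0)
    share = 0.3 - 0.05 * np.cos(2.0 * np.pi * q / 100.0)
    return GaitWaveforms(q, flex, varus, axial, share)


def generate_atlas(
    dims: AnatomicalDimensions,
    elements_per_axis: tuple[int, int, int] = (4, 4, 3),
    thickness_mm: tuple[float, float] | None = None,
    seed: int | None = None,
    n_stance_points: int = 51,
    atlas_id: str = "atlas",
) -> AtlasRecord:
    """Build one synthetic medial-compartment atlas for given dimensions.

    Parameters
    ----------
    elements_per_axis:
        (nx, ny, nz) of the tibial cartilage block; the femoral cap uses the
        same in-plane resolution with max(2, nz - 1) layers.
    thickness_mm:
        (femoral, tibial) cartilage thickness. Default: 45% of the medial
        JSW each, leaving a 10% free gap at the reference pose.
    seed:
        Perturbs only the gait waveforms; the geometry is deterministic in
        the dimensions.
    """
    nx, ny, nz = elements_per_axis
    if min(nx, ny, nz) < 2:
        raise GeometryError("elements_per_axis must each be >= 2")
    if nx % 2 or ny % 2:
        # an in-plane node must sit at the compartment centre so the minimum
        # surface gap (the JSW location) is represented exactly
        raise GeometryError("in-plane element counts nx, ny must be even")
    if thickness_mm is None:
        t_f = t_t = THICKNESS_JSW_FRACTION * dims.jsw_medial
    else:
        t_f, t_t = thickness_mm
    if min(t_f, t_t) <= 0:
        raise GeometryError("cartilage thicknesses must be > 0")
    gap0 = dims.jsw_medial - t_f - t_t
    if gap0 < 0:
        raise GeometryError(
            f"geometry infeasible: thicknesses {t_f:.2f}+{t_t:.2f} exceed "
            f"medial JSW {dims.jsw_medial:.2f}"
        )

    ap = dims.ap_medial
    half_ml = dims.ml_width / 2.0
    xs = np.linspace(-ap / 2.0, ap / 2.0, nx + 1)
    ys = np.linspace(-half_ml / 2.0, half_ml / 2.0, ny + 1)

    def tib_top(X, Y):
        return t_t + TIBIAL_DISH_MM * ((2 * X / ap) ** 2 + (2 * Y / half_ml) ** 2)

    tibial = _layered_mesh(xs, ys, lambda X, Y: np.zeros_like(X), tib_top, nz, articular="top")

    z0 = t_t + gap0  # femoral inferior apex, directly above the tibial centre

    def fem_low(X, Y):
        return z0 + X**2 / (2 * CONDYLE_RADIUS_AP) + Y**2 / (2 * CONDYLE_RADIUS_ML)

    def fem_up(X, Y):
        return fem_low(X, Y) + t_f

    nz_f = max(2, nz - 1)
    femoral = _layered_mesh(xs, ys, fem_low, fem_up, nz_f, articular="bottom")

    waveforms = default_waveforms(n_stance_points, seed=seed)
    rec = AtlasRecord(
        atlas_id=atlas_id,
        dimensions=dims,
        femoral_mesh=femoral,
        tibial_mesh=tibial,
        waveforms=waveforms,
    )
    rec.check()
    return rec


def generate_library(
    n_atlases: int = 21,
    dimension_ranges: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
    elements_per_axis: tuple[int, int, int] = (4, 4, 3),
    n_stance_points: int = 51,
) -> list[AtlasRecord]:
    """Draw ``n_atlases`` dimension sets uniformly in the ranges and mesh them."""
    if n_atlases < 1:
        raise ValueError("n_atlases must be >= 1")
    ranges = dict(DEFAULT_DIMENSION_RANGES)
    if dimension_ranges:
        ranges.update(dimension_ranges)
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_atlases):
        dims = AnatomicalDimensions(
            **{name: float(rng.uniform(*ranges[name])) for name in ranges}
        )
        records.append(
            generate_atlas(
                dims,
                elements_per_axis=elements_per_axis,
                seed=int(rng.integers(0, 2**31 - 1)),
                n_stance_points=n_stance_points,
                atlas_id=f"atlas_{i:02d}",
            )
        )
    return records


# ------------------------------------------------------------- measurement


def _surface_interpolator(mesh: HexMesh, nodes: np.ndarray):
    pts = mesh.coords[nodes][:, :2]
    z = mesh.coords[nodes][:, 2]
    lin = LinearNDInterpolator(pts, z)
    near = NearestNDInterpolator(pts, z)

    def f(xy):
        v = lin(xy)
        bad = np.isnan(v)
        if np.any(bad):
            v[bad] = near(np.asarray(xy)[bad])
        return v

    return f


def measure_mesh_dimensions(
    femoral: HexMesh,
    tibial: HexMesh,
    metadata_dims: AnatomicalDimensions | None = None,
) -> AnatomicalDimensions:
    """Measure AP, ML and medial JSW back from the compartment meshes.

    - ap_medial: AP (x) extent of the femoral mesh;
    - ml_width: twice the ML (y) extent of the compartment (compartment
      meshes span half the joint);
    - jsw_medial: minimum vertical cartilage-surface gap within a +-10%
      window around the contact-region centre, plus the femoral and tibial
      cartilage thicknesses at that location (radiographic JSW is a
      bone-to-bone distance).

    Lateral fields are not represented by medial-compartment meshes and are
    copied from ``metadata_dims`` when given (otherwise set to plausible
    placeholders just above the medial values).
    """
    if "femoral_contact" not in femoral.face_sets or "tibial_contact" not in tibial.face_sets:
        raise MeshError("contact face sets are required for measurement")
    fem_contact_nodes = np.unique(femoral.face_node_ids("femoral_contact"))
    tib_contact_nodes = np.unique(tibial.face_node_ids("tibial_contact"))
    if len(fem_contact_nodes) == 0 or len(tib_contact_nodes) == 0:
        raise MeshError("empty contact face set")

    ap = float(femoral.coords[:, 0].max() - femoral.coords[:, 0].min())
    ml_half = float(tibial.coords[:, 1].max() - tibial.coords[:, 1].min())
    ml = 2.0 * ml_half

    tib_surf = _surface_interpolator(tibial, tib_contact_nodes)
    fem_bone = _surface_interpolator(femoral, femoral.node_sets["femoral_bone_interface"])
    tib_bone_z = _surface_interpolator(
        tibial, tibial.node_sets["tibial_bone_interface"]
    )

    fem_pts = femoral.coords[fem_contact_nodes]
    xc = 0.5 * (tibial.coords[:, 0].max() + tibial.coords[:, 0].min())
    yc = 0.5 * (tibial.coords[:, 1].max() + tibial.coords[:, 1].min())
    in_window = (np.abs(fem_pts[:, 0] - xc) <= 0.10 * ap) & (
        np.abs(fem_pts[:, 1] - yc) <= 0.10 * ml_half
    )
    if not np.any(in_window):
        d2 = (fem_pts[:, 0] - xc) ** 2 + (fem_pts[:, 1] - yc) ** 2
        in_window = d2 <= d2.min() * (1 + 1e-9)
    sel = fem_pts[in_window]
    gaps = sel[:, 2] - tib_surf(sel[:, :2])
    i = int(np.argmin(gaps))
    loc = sel[i, :2].reshape(1, 2)
    t_f = float(fem_bone(loc)[0] - sel[i, 2])
    t_t = float(tib_surf(loc)[0] - tib_bone_z(loc)[0])
    jsw = float(gaps[i]) + t_f + t_t

    if metadata_dims is not None:
        ap_lat, jsw_lat = metadata_dims.ap_lateral, metadata_dims.jsw_lateral
    else:
        ap_lat, jsw_lat = ap * 1.05, jsw * 1.1
    return AnatomicalDimensions(
        ap_medial=ap, ap_lateral=ap_lat, jsw_medial=jsw, jsw_lateral=jsw_lat, ml_width=ml
    )


# ----------------------------------------------------------------- save/load


def save_atlas(record: AtlasRecord, directory: str | Path) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_inp(record.femoral_mesh, d / "femoral.inp", heading=f"{record.atlas_id} femoral cartilage")
    write_inp(record.tibial_mesh, d / "tibial.inp", heading=f"{record.atlas_id} tibial cartilage")
    meta = {
        "atlas_id": record.atlas_id,
        "dimensions": asdict(record.dimensions),
        "waveforms": record.waveforms.to_dict(),
        "femoral_h_z": record.femoral_mesh.h_z.tolist(),
        "tibial_h_z": record.tibial_mesh.h_z.tolist(),
    }
    (d / "meta.json").write_text(json.dumps(meta, indent=1))


def load_atlas(directory: str | Path) -> AtlasRecord:
    d = Path(directory)
    meta = json.loads((d / "meta.json").read_text())
    femoral = read_inp(d / "femoral.inp")
    tibial = read_inp(d / "tibial.inp")
    femoral.h_z = np.asarray(meta["femoral_h_z"], dtype=float)
    tibial.h_z = np.asarray(meta["tibial_h_z"], dtype=float)
    return AtlasRecord(
        atlas_id=meta["atlas_id"],
        dimensions=AnatomicalDimensions(**meta["dimensions"]),
        femoral_mesh=femoral,
        tibial_mesh=tibial,
        waveforms=GaitWaveforms.from_dict(meta["waveforms"]),
    )


def save_library(records: list[AtlasRecord], directory: str | Path) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    for rec in records:
        save_atlas(rec, d / rec.atlas_id)


def load_library(directory: str | Path) -> list[AtlasRecord]:
    d = Path(directory)
    subdirs = sorted(p for p in d.iterdir() if (p / "meta.json").exists())
    if not subdirs:
        raise FileNotFoundError(f"no atlas records under {d}")
    return [load_atlas(p) for p in subdirs]
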