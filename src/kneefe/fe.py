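"""Displacement-pressure (u-p) poroelastic finite elements with contact.

Small-scale implicit solver for biphasic soft tissue on 8-node hexahedra
with equal-order trilinear interpolation of solid displacement and pore
pressure (the porous-hexahedron element class), stabilized against
checkerboard pressure by local polynomial pressure projection.

Governing equations, backward-Euler in time:

- momentum:    div sigma_t = 0,  sigma_t = sigma_eff(F) - p I, with
  sigma_eff the FRPVE solid stress (nonfibrillar Neo-Hookean + tension-only
  viscoelastic fibrils);
- continuity:  d/dt(J) - div(k grad p) = 0 (incompressible constituents),
  integrated on the reference configuration; sealed exterior surfaces mean
  no flux boundary terms.

Geometric nonlinearity is total-Lagrangian: Cauchy stress from the material
law is pulled back to first Piola-Kirchhoff for assembly. The solid block
of the tangent is built by forward differences of the element internal
force (exact to FD tolerance, including geometric and fibril-history
terms); the u-p coupling blocks and the pressure blocks are analytic.

Contact between the femoral and tibial cartilage surfaces is frictionless
penalty contact enforced at the 2x2 Gauss points of the femoral articular
faces against the triangulated tibial articular surface, with area-weight
scaling so the penalty parameter has units of pressure per penetration
depth (N/mm^3). No fluid crosses the interface.

Joint kinematics: the femoral cartilage-bone interface is rigidly tied to
a reference point midway between the epicondyles; flexion-extension (about
the ML axis) and varus-valgus (about the AP axis) rotations are prescribed
there, the axial force is applied along z, and the remaining in-plane
translations are fixed. The tibial cartilage-bone interface is fully fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from kneefe.atlas import AtlasRecord
from kneefe.loading import LoadCase
from kneefe.materials import (
    FRPVEParams,
    build_fibril_set,
    fibril_stress_update,
    fibril_weights,
    permeability,
    primary_directions,
    _fibonacci_sphere,
    _random_rotation,
)
from kneefe.mesh import FACE_NODES, GAUSS_GRADS, GAUSS_N, HexMesh

__all__ = [
    "SolverSettings",
    "Region",
    "FEModel",
    "FEState",
    "SimulationResult",
    "ConvergenceError",
    "assemble_model",
    "solve_step",
    "run_gait",
    "consolidation_benchmark",
]


class ConvergenceError(RuntimeError):
    """Newton iteration failed; carries the residual history."""

    def __init__(self, msg: str, residuals: list[float]):
        super().__init__(msg)
        self.residuals = residuals


@dataclass(frozen=True)
class SolverSettings:
    """Numerical controls for the implicit solver.

    contact_penalty is contact pressure per unit penetration (N/mm^3);
    adequacy is checked by the doubling-sensitivity sweep in the tests.
    stabilization is the dimensionless coefficient of the local pressure-
    projection term. reference_spring is a weak regularizing stiffness on
    the femoral axial translation so the pre-contact rigid mode stays
    solvable; its force contribution is negligible against joint loads.
    """

    newton_tol: float = 1.0e-5
    force_tol: float = 1.0e-3  # residual as a fraction of the applied force
    balance_tol: float = 2.5e-3  # reaction-sum defect as a fraction of the load
    stagnation_tol: float = 5.0e-3  # acceptance bound when Newton limit-cycles
    max_iterations: int = 40
    contact_penalty: float = 50.0
    stabilization: float = 5.0e-4
    reference_spring: float = 0.05
    max_bisections: int = 8
    fd_step: float = 1.0e-6
    max_increment: float = 0.5  # mm; Newton update clamp (pre-contact approach)

    def __post_init__(self) -> None:
        for name in (
            "newton_tol",
            "max_iterations",
            "contact_penalty",
            "stabilization",
            "reference_spring",
            "fd_step",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class Region:
    """One meshed tissue with its material and precomputed element data."""

    name: str
    mesh: HexMesh
    params: FRPVEParams
    node_offset: int  # into the global node numbering
    fibrils_enabled: bool = True
    fibril_seed: int = 0

    # filled by prepare()
    dNdX: np.ndarray = field(init=False)  # (E, 8gp, 8a, 3)
    detJ0: np.ndarray = field(init=False)  # (E, 8gp)
    dirs: np.ndarray | None = field(init=False, default=None)  # (E, 17, 3)
    weights: np.ndarray | None = field(init=False, default=None)

    def prepare(self) -> None:
        xe = self.mesh.coords[self.mesh.elements]  # (E, 8, 3)
        J0 = np.einsum("gai,eaj->egij", GAUSS_GRADS, xe)  # dX_j/dxi_i
        self.detJ0 = np.linalg.det(np.swapaxes(J0, -1, -2))
        if self.detJ0.min() <= 0:
            raise ValueError(f"region {self.name}: non-positive reference Jacobian")
        # J0[i, j] = dX_j/dxi_i, so inv(J0)[i, j] = dxi_j/dX_i and the chain
        # rule dN/dX_j = dN/dxi_k * dxi_k/dX_j contracts over inv(J0)[j, k]
        Jinv = np.linalg.inv(J0)
        self.dNdX = np.einsum("gak,egjk->egaj", GAUSS_GRADS, Jinv)
        if self.fibrils_enabled:
            rng = np.random.default_rng(self.fibril_seed)
            sec = _fibonacci_sphere(13) @ _random_rotation(rng).T
            dirs = np.empty((self.mesh.n_elements, 17, 3))
            for e, h in enumerate(self.mesh.h_z):
                dirs[e, :4] = primary_directions(float(np.clip(h, 0.0, 1.0)))
                dirs[e, 4:] = sec
            self.dirs = dirs
            self.weights = fibril_weights()

    @property
    def n_elements(self) -> int:
        return self.mesh.n_elements

    def global_elements(self) -> np.ndarray:
        return self.mesh.elements + self.node_offset


@dataclass
class ContactPair:
    """Frictionless penalty contact: slave-face Gauss points vs master facets.

    Contact is enforced at 2x2 integration points of the femoral articular
    faces rather than at nodes: integration points never coincide with
    master vertices or edges, which keeps the penalty force smooth where
    conforming meshes would park every slave node exactly over a master
    vertex (the worst case for node-to-surface contact).
    """

    slave_quads: np.ndarray  # (Q, 4) global node ids of femoral contact faces
    gp_areas: np.ndarray  # (Q, 4) reference area weight of each Gauss point
    master_tris: np.ndarray  # (n_tri, 3) global node ids, outward (up) normals
    master_tri_face: np.ndarray  # (n_tri,) index of the owning tibial contact face
    master_face_elems: np.ndarray  # (n_face,) tibial element of each contact face
    master_face_areas: np.ndarray  # (n_face,) reference areas
    master_quads: np.ndarray = None  # (n_face, 4) corner node ids of each face
    vertex_face_count: dict = None  # master node -> number of faces sharing it


@dataclass
class FEModel:
    """Assembled two-body (or single-body) poroelastic model."""

    coords0: np.ndarray  # (N, 3) reference coordinates, global numbering
    regions: list[Region]
    fixed_u: dict[int, tuple[bool, bool, bool]]  # node -> fixed components
    rigid_nodes: np.ndarray | None  # femoral bone-interface nodes (tied to RP)
    reference_point: np.ndarray | None
    contact: ContactPair | None
    pressure_bc: dict[int, float] = field(default_factory=dict)
    tibial_region: int = 0
    femoral_region: int | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.coords0)

    def n_dofs(self) -> int:
        return 4 * self.n_nodes  # 3 displacement + 1 pressure per node


@dataclass
class FEState:
    """Solution state at one converged time point."""

    U: np.ndarray  # (N, 3)
    P: np.ndarray  # (N,)
    w: float  # femoral reference-point axial translation
    time: float
    J_prev: list[np.ndarray]  # per region, (E, 8gp)
    hist_eps: list[np.ndarray | None]  # per region, (E, 8gp, 17)
    hist_q: list[np.ndarray | None]
    flexion: float = 0.0  # rad, rotations applied at the last converged step
    varus: float = 0.0

    @classmethod
    def initial(cls, model: FEModel) -> "FEState":
        J_prev, he, hq = [], [], []
        for r in model.regions:
            J_prev.append(np.ones((r.n_elements, 8)))
            if r.fibrils_enabled:
                he.append(np.zeros((r.n_elements, 8, 17)))
                hq.append(np.zeros((r.n_elements, 8, 17)))
            else:
                he.append(None)
                hq.append(None)
        return cls(
            U=np.zeros((model.n_nodes, 3)),
            P=np.zeros(model.n_nodes),
            w=0.0,
            time=0.0,
            J_prev=J_prev,
            hist_eps=he,
            hist_q=hq,
        )

    def copy(self) -> "FEState":
        return FEState(
            U=self.U.copy(),
            P=self.P.copy(),
            w=self.w,
            time=self.time,
            J_prev=[a.copy() for a in self.J_prev],
            hist_eps=[None if a is None else a.copy() for a in self.hist_eps],
            hist_q=[None if a is None else a.copy() for a in self.hist_q],
            flexion=self.flexion,
            varus=self.varus,
        )


# ------------------------------------------------------------- model assembly


def _face_area(coords: np.ndarray, quad: np.ndarray) -> float:
    v = coords[quad]
    return 0.5 * (
        np.linalg.norm(np.cross(v[1] - v[0], v[2] - v[0]))
        + np.linalg.norm(np.cross(v[2] - v[0], v[3] - v[0]))
    )


#: 2x2 Gauss points on the reference quad and their bilinear shape values.
_QUAD_CORNERS = np.array([[-1.0, -1.0], [1.0, -1.0], [1.0, 1.0], [-1.0, 1.0]])
_QUAD_GP = _QUAD_CORNERS / np.sqrt(3.0)
_QUAD_N = 0.25 * (1.0 + np.outer(_QUAD_GP[:, 0], _QUAD_CORNERS[:, 0])) * (
    1.0 + np.outer(_QUAD_GP[:, 1], _QUAD_CORNERS[:, 1])
)  # (4 gp, 4 nodes)
_QUAD_DN = np.stack(
    [
        0.25 * _QUAD_CORNERS[:, 0][None, :] * (1.0 + np.outer(_QUAD_GP[:, 1], _QUAD_CORNERS[:, 1])),
        0.25 * _QUAD_CORNERS[:, 1][None, :] * (1.0 + np.outer(_QUAD_GP[:, 0], _QUAD_CORNERS[:, 0])),
    ],
    axis=-1,
)  # (4 gp, 4 nodes, 2)


def _build_contact(femoral: HexMesh, tibial: HexMesh, fem_offset: int) -> ContactPair:
    quads = []
    gp_areas = []
    for e, f in femoral.face_sets["femoral_contact"]:
        quad = femoral.elements[e, FACE_NODES[f]]
        v = femoral.coords[quad]  # (4, 3)
        t1 = np.einsum("gad,ai->gdi", _QUAD_DN, v)  # (gp, 2, 3) tangent vectors
        areas = np.linalg.norm(np.cross(t1[:, 0], t1[:, 1]), axis=1)  # det J2d
        quads.append(quad + fem_offset)
        gp_areas.append(areas)

    faces = tibial.face_sets["tibial_contact"]
    tris, tri_face = [], []
    face_elems = faces[:, 0].copy()
    face_areas = np.empty(len(faces))
    for i, (e, f) in enumerate(faces):
        quad = tibial.elements[e, FACE_NODES[f]]
        face_areas[i] = _face_area(tibial.coords, quad)
        tris.append([quad[0], quad[1], quad[2]])
        tris.append([quad[0], quad[2], quad[3]])
        tri_face += [i, i]
    master_quads = np.array(
        [tibial.elements[e, FACE_NODES[f]] for e, f in faces], dtype=np.int64
    )
    counts: dict[int, int] = {}
    for quad in master_quads:
        for n_ in quad:
            counts[int(n_)] = counts.get(int(n_), 0) + 1
    return ContactPair(
        slave_quads=np.array(quads, dtype=np.int64),
        gp_areas=np.array(gp_areas),
        master_tris=np.array(tris, dtype=np.int64),
        master_tri_face=np.array(tri_face, dtype=np.int64),
        master_face_elems=face_elems,
        master_face_areas=face_areas,
        master_quads=master_quads,
        vertex_face_count=counts,
    )


def assemble_model(
    record: AtlasRecord,
    femoral_params: FRPVEParams,
    tibial_params: FRPVEParams,
    fibril_seed: int = 0,
    overlap_tol: float = 1.0e-6,
) -> FEModel:
    """Build the medial-compartment model from (possibly morphed) atlas meshes."""
    tib, fem = record.tibial_mesh, record.femoral_mesh
    n_t = tib.n_nodes
    coords0 = np.vstack([tib.coords, fem.coords])
    regions = [
        Region("tibial", tib, tibial_params, node_offset=0, fibril_seed=fibril_seed),
        Region("femoral", fem, femoral_params, node_offset=n_t, fibril_seed=fibril_seed),
    ]
    for r in regions:
        r.prepare()

    contact = _build_contact(fem, tib, fem_offset=n_t)
    # initial interpenetration check at the reference pose
    gaps = _contact_gaps(coords0, contact)
    if len(gaps) and gaps.min() < -overlap_tol:
        raise ValueError(f"initial overlap: minimum surface gap {gaps.min():.4f} mm < 0")

    fixed_u = {int(n): (True, True, True) for n in tib.node_sets["tibial_bone_interface"]}
    rigid = fem.node_sets["femoral_bone_interface"] + n_t
    rp = coords0[rigid].mean(axis=0)  # midway between the epicondylar attachments
    return FEModel(
        coords0=coords0,
        regions=regions,
        fixed_u=fixed_u,
        rigid_nodes=rigid,
        reference_point=rp,
        contact=contact,
        tibial_region=0,
        femoral_region=1,
    )


# ---------------------------------------------------------- material response


def _region_stress(
    region: Region,
    F: np.ndarray,
    hist_eps: np.ndarray | None,
    hist_q: np.ndarray | None,
    dt: float,
):
    """Effective (solid) Cauchy stress at all Gauss points; trial history."""
    J = np.linalg.det(F)
    if J.min() <= 0:
        raise FloatingPointError("element inverted: det F <= 0")
    mu, lam = region.params.lame
    B = F @ np.swapaxes(F, -1, -2)
    I = np.eye(3)
    sigma = mu / J[..., None, None] * (B - I) + (
        lam * np.log(J) / J
    )[..., None, None] * I
    new_eps = new_q = None
    if region.fibrils_enabled:
        v = np.einsum("egij,enj->egni", F, region.dirs)
        lam_f = np.linalg.norm(v, axis=-1)
        eps = lam_f - 1.0
        s, new_eps, new_q = fibril_stress_update(
            eps,
            hist_eps,
            hist_q,
            region.params.E_0,
            region.params.E_eps,
            region.params.eta,
            dt,
        )
        m = v / lam_f[..., None]
        sigma = sigma + np.einsum("n,egn,egni,egnj->egij", region.weights, s, m, m)
    return sigma, J, new_eps, new_q


def _region_deformation(region: Region, U: np.ndarray) -> np.ndarray:
    ue = U[region.global_elements()]  # (E, 8, 3)
    gradu = np.einsum("eaj,egai->egji", ue, region.dNdX)
    return np.eye(3) + gradu


def _region_internal_force(region: Region, F: np.ndarray, p_gp: np.ndarray, sigma: np.ndarray, J: np.ndarray):
    """First-PK pullback and nodal internal forces (E, 8, 3)."""
    sig_t = sigma - p_gp[..., None, None] * np.eye(3)
    Finv = np.linalg.inv(F)
    P1 = J[..., None, None] * sig_t @ np.swapaxes(Finv, -1, -2)
    f = np.einsum("egji,egai,eg->eaj", P1, region.dNdX, region.detJ0)
    return f


# ------------------------------------------------------------------- contact


def _contact_gaps(coords: np.ndarray, contact: ContactPair) -> np.ndarray:
    """Signed normal gaps of all slave Gauss points (inf when none project)."""
    tri_xyz = coords[contact.master_tris]
    vnormals = _vertex_normals(coords, contact)
    out = []
    for quad in contact.slave_quads:
        pts = _QUAD_N @ coords[quad]  # (4 gp, 3)
        for x in pts:
            res = _slave_contact(x, tri_xyz, contact, vnormals)
            if res is not None:
                out.append(res[3])
    return np.array(out) if out else np.array([np.inf])


def _closest_master(x: np.ndarray, tri_xyz: np.ndarray):
    """Find the master triangle whose xy-footprint contains x.

    Returns (gap, tri_index, barycentric, normal); gap is the signed
    distance along the triangle normal (positive above the surface).
    The master surface is a height field over (x, y), so the vertical
    footprint search is exact for the geometries built here.
    """
    v0 = tri_xyz[:, 0, :2]
    d1 = tri_xyz[:, 1, :2] - v0
    d2 = tri_xyz[:, 2, :2] - v0
    det = d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0]
    rel = x[:2] - v0
    b1 = (rel[:, 0] * d2[:, 1] - rel[:, 1] * d2[:, 0]) / det
    b2 = (d1[:, 0] * rel[:, 1] - d1[:, 1] * rel[:, 0]) / det
    b0 = 1.0 - b1 - b2
    tol = 1.0e-9
    inside = (b0 >= -tol) & (b1 >= -tol) & (b2 >= -tol)
    if not inside.any():
        # point beyond the master footprint: clamp to the closest facet so
        # the contact force stays continuous when a point slides over the
        # boundary (edge contact at high flexion)
        b = np.clip(np.stack([b0, b1, b2], axis=1), 0.0, None)
        b /= b.sum(axis=1, keepdims=True)
        proj = np.einsum("tk,tki->ti", b, tri_xyz[..., :2])
        d2 = ((proj - x[:2]) ** 2).sum(axis=1)
        tid = int(np.argmin(d2))
        # fade the force to zero over a 2 mm band outside the footprint
        # with a C1 smoothstep: a hard cutoff would make the force jump,
        # and a linear fade kinks its derivative exactly where contact
        # points slide past the plateau edge at high flexion
        s = np.sqrt(d2[tid]) / 2.0
        if s >= 1.0:
            return np.nan, -1, None, None, 0.0
        fade = 1.0 - s * s * (3.0 - 2.0 * s)
        n = np.cross(tri_xyz[tid, 1] - tri_xyz[tid, 0], tri_xyz[tid, 2] - tri_xyz[tid, 0])
        n = n / np.linalg.norm(n)
        if n[2] < 0:
            n = -n
        return float(np.dot(n, x - tri_xyz[tid, 0])), tid, b[tid], n, fade
    # of the containing triangles pick the one whose plane is closest
    idx = np.where(inside)[0]
    best = None
    for tid in idx:
        n = np.cross(tri_xyz[tid, 1] - tri_xyz[tid, 0], tri_xyz[tid, 2] - tri_xyz[tid, 0])
        nn = np.linalg.norm(n)
        if nn == 0:
            continue
        n = n / nn
        if n[2] < 0:
            n = -n
        g = float(np.dot(n, x - tri_xyz[tid, 0]))
        if best is None or abs(g) < abs(best[0]):
            bary = np.array([b0[tid], b1[tid], b2[tid]])
            best = (g, tid, bary, n, 1.0)
    return best if best is not None else (np.nan, -1, None, None, 0.0)


def _vertex_normals(coords: np.ndarray, contact: ContactPair) -> dict[int, np.ndarray]:
    """Area-weighted outward vertex normals of the master surface.

    Interpolating these barycentrically gives a continuous normal field,
    so the penalty force direction does not jump when a contact point
    crosses a facet edge.
    """
    normals: dict[int, np.ndarray] = {}
    for tri in contact.master_tris:
        v = coords[tri]
        n = np.cross(v[1] - v[0], v[2] - v[0])
        if n[2] < 0:
            n = -n
        for node in tri:
            normals[int(node)] = normals.get(int(node), 0.0) + n
    return {k: v / np.linalg.norm(v) for k, v in normals.items()}


def _slave_contact(x, tri_xyz, contact: ContactPair, vnormals):
    """Closest facet, smoothed normal and signed gap for one contact point.

    Returns (tri index, barycentric, unit normal, gap) or None when the
    point is outside the master footprint.
    """
    g0, tid, bary, _, fade = _closest_master(x, tri_xyz)
    if not np.isfinite(g0) or tid < 0:
        return None
    tri = contact.master_tris[tid]
    n = sum(b * vnormals[int(node)] for node, b in zip(tri, bary))
    n = n / np.linalg.norm(n)
    xm = bary @ tri_xyz[tid]
    g = float(np.dot(n, x - xm))
    return tid, bary, n, g, fade


def _gp_force_vector(
    quad_xyz, tri_xyz, contact, vnormals, shape_w, kA, frozen_nodes
):
    """Contact force of one slave Gauss point on the frozen 7-node set.

    frozen_nodes = [4 slave quad nodes, 3 master tri nodes]. Used both for
    assembly and for the local finite-difference tangent; if the perturbed
    point lands on a different facet, force components on nodes outside
    the frozen set are dropped (their barycentric weights vanish at the
    shared edge, so the dropped part is second order).
    """
    out = np.zeros((len(frozen_nodes), 3))
    x = shape_w @ quad_xyz
    res = _slave_contact(x, tri_xyz, contact, vnormals)
    if res is None:
        return out, None
    tid, bary, n, g, fade = res
    if g >= 0.0:
        return out, None
    fmag = -kA * g * fade
    out[:4] = shape_w[:, None] * (fmag * n)
    index = {node: k for k, node in enumerate(frozen_nodes)}
    for node, b in zip(contact.master_tris[tid], bary):
        k = index.get(int(node))
        if k is not None:
            out[k] -= b * fmag * n
    return out, (tid, fmag)


def _contact_assemble(
    model: FEModel, coords: np.ndarray, penalty: float, with_tangent: bool = True
):
    """Penalty contact forces, per-face normal loads, and tangent triplets.

    The tangent of each active contact point is a local finite difference
    of its force vector over the 21 involved dofs (4 slave-face nodes + 3
    master-facet nodes), with the vertex-normal field frozen; this captures
    the facet geometry, normal and barycentric variation that a frozen
    n*n^T approximation misses.
    """
    contact = model.contact
    N = model.n_nodes
    f = np.zeros((N, 3))
    vertex_force = np.zeros(N)  # normal contact load accumulated at master nodes
    rows: list = []
    cols: list = []
    vals: list = []
    tri_xyz = coords[contact.master_tris]
    vnormals = _vertex_normals(coords, contact)
    h = 1.0e-7
    for qi, quad in enumerate(contact.slave_quads):
        quad_xyz = coords[quad]
        for gp in range(4):
            shape_w = _QUAD_N[gp]
            x = shape_w @ quad_xyz
            res = _slave_contact(x, tri_xyz, contact, vnormals)
            if res is None or res[3] >= 0.0:
                continue
            tid = res[0]
            kA = penalty * contact.gp_areas[qi, gp]
            frozen = [int(n_) for n_ in quad] + [int(n_) for n_ in contact.master_tris[tid]]
            base, info = _gp_force_vector(
                quad_xyz, tri_xyz, contact, vnormals, shape_w, kA, frozen
            )
            f[frozen] += base
            fmag = info[1] if info is not None else 0.0
            for node, b in zip(contact.master_tris[tid], res[1]):
                vertex_force[node] += b * fmag
            if not with_tangent:
                continue
            dofs = np.array([3 * node + c for node in frozen for c in range(3)])
            Kloc = np.zeros((21, 21))
            for jd, (local, c) in enumerate(
                (local, c) for local in range(7) for c in range(3)
            ):
                if local < 4:
                    qp = quad_xyz.copy()
                    qp[local, c] += h
                    pert, _ = _gp_force_vector(
                        qp, tri_xyz, contact, vnormals, shape_w, kA, frozen
                    )
                else:
                    node = frozen[local]
                    tri_pert = tri_xyz.copy()
                    mask = contact.master_tris == node
                    tri_pert[..., c][mask] += h
                    pert, _ = _gp_force_vector(
                        quad_xyz, tri_pert, contact, vnormals, shape_w, kA, frozen
                    )
                Kloc[:, jd] = -(pert - base).ravel() / h  # residual = -force
            rows.append(np.repeat(dofs, 21))
            cols.append(np.tile(dofs, 21))
            vals.append(Kloc.ravel())
    trip = (
        (np.concatenate(rows), np.concatenate(cols), np.concatenate(vals))
        if rows
        else ([], [], [])
    )
    # spread vertex loads back over the faces sharing each vertex so the
    # reported per-face pressures are independent of the facet split
    face_force = np.zeros(len(contact.master_face_areas))
    for fi, quad in enumerate(contact.master_quads):
        for node in quad:
            face_force[fi] += vertex_force[node] / contact.vertex_face_count[int(node)]
    pressures = face_force / contact.master_face_areas
    return f, pressures, trip


# ------------------------------------------------------- residual and tangent


class _StepContext:
    """Precomputed constant matrices and constraint maps for one model."""

    def __init__(self, model: FEModel, settings: SolverSettings):
        self.model = model
        self.settings = settings
        N = model.n_nodes
        self.n_u = 3 * N
        self.n_p = N
        # constant pressure blocks: permeability Laplacian and stabilization
        rows, cols, vals = [], [], []
        srows, scols, svals = [], [], []
        for r in model.regions:
            k = permeability(r.params)
            mu, _ = r.params.lame
            alpha = settings.stabilization / mu
            ge = r.global_elements()
            # element permeability matrices: sum_g dNdX dNdX^T k detJ0
            Ke = k * np.einsum("egai,egbi,eg->eab", r.dNdX, r.dNdX, r.detJ0)
            # stabilization: (alpha/mu) * (N - Nbar)(N - Nbar)
            ve = r.detJ0.sum(axis=1)  # element volumes (weights are 1)
            Nbar = np.einsum("ga,eg->ea", GAUSS_N, r.detJ0) / ve[:, None]
            dN = GAUSS_N[None, :, :] - Nbar[:, None, :]  # (E, g, a)
            Se = alpha * np.einsum("ega,egb,eg->eab", dN, dN, r.detJ0)
            for e in range(r.n_elements):
                conn = ge[e]
                for a in range(8):
                    for b in range(8):
                        rows.append(conn[a])
                        cols.append(conn[b])
                        vals.append(Ke[e, a, b])
                        srows.append(conn[a])
                        scols.append(conn[b])
                        svals.append(Se[e, a, b])
        self.K_perm = sp.csr_matrix((vals, (rows, cols)), shape=(N, N))
        self.S_stab = sp.csr_matrix((svals, (srows, scols)), shape=(N, N))

    # -------------------------------------------------------- constraint map

    def build_constraints(self, flexion: float, varus: float):
        """Return (T, g_of_w) with V = T q + g0 + w * e_w implicit.

        q = [free dofs..., w]; prescribed dofs carry the rigid-rotation
        offset g0; the w column adds the axial translation to the rigid
        group's z dofs.
        """
        model = self.model
        N = model.n_nodes
        ndof = self.n_u + self.n_p
        prescribed = np.zeros(ndof)
        is_fixed = np.zeros(ndof, dtype=bool)
        w_col = np.zeros(ndof)

        for node, mask in model.fixed_u.items():
            for c in range(3):
                if mask[c]:
                    is_fixed[3 * node + c] = True
        if model.rigid_nodes is not None:
            Rx = _rot_x(varus)
            Ry = _rot_y(flexion)
            R = Rx @ Ry
            rp = model.reference_point
            for node in model.rigid_nodes:
                disp = R @ (model.coords0[node] - rp) - (model.coords0[node] - rp)
                for c in range(3):
                    is_fixed[3 * node + c] = True
                    prescribed[3 * node + c] = disp[c]
                w_col[3 * node + 2] = 1.0
        for node, val in model.pressure_bc.items():
            is_fixed[self.n_u + node] = True
            prescribed[self.n_u + node] = val

        free = np.where(~is_fixed)[0]
        n_free = len(free)
        has_w = model.rigid_nodes is not None
        ncols = n_free + (1 if has_w else 0)
        data = np.ones(n_free)
        T = sp.csc_matrix(
            (data, (free, np.arange(n_free))), shape=(ndof, ncols)
        )
        if has_w:
            T = T.tolil()
            idx = np.nonzero(w_col)[0]
            T[idx, n_free] = 1.0
            T = T.tocsc()
        return T, prescribed, free, has_w

    # ------------------------------------------------------------- residual

    def residual(self, V: np.ndarray, state: FEState, dt: float, collect=False):
        """Full-space residual R(V); optionally the output field bundle."""
        model = self.model
        N = model.n_nodes
        U = V[: self.n_u].reshape(N, 3)
        P = V[self.n_u :]
        R_u = np.zeros((N, 3))
        R_p = np.zeros(N)
        extra = {} if collect else None
        for ri, r in enumerate(model.regions):
            F = _region_deformation(r, U)
            sigma, J, new_eps, new_q = _region_stress(
                r, F, state.hist_eps[ri], state.hist_q[ri], dt
            )
            ge = r.global_elements()
            p_gp = np.einsum("ga,ea->eg", GAUSS_N, P[ge])
            fe = _region_internal_force(r, F, p_gp, sigma, J)
            np.add.at(R_u, ge, fe)
            # continuity: volume change + Darcy (Darcy added globally below)
            dJ = (J - state.J_prev[ri]) * r.detJ0  # (E, 8)
            np.add.at(R_p, ge, np.einsum("ga,eg->ea", GAUSS_N, dJ))
            if collect:
                extra[r.name] = {
                    "F": F,
                    "sigma_eff": sigma,
                    "J": J,
                    "p_gp": p_gp,
                    "new_eps": new_eps,
                    "new_q": new_q,
                }
        R_p += dt * (self.K_perm @ P) + self.S_stab @ P

        contact_out = None
        if model.contact is not None:
            coords = model.coords0 + U
            f_c, pressures, _ = _contact_assemble(
                model, coords, self.settings.contact_penalty, with_tangent=False
            )
            R_u -= f_c
            contact_out = (pressures, None)
        R = np.concatenate([R_u.ravel(), R_p])
        return R, contact_out, extra

    # -------------------------------------------------------------- tangent

    def tangent(self, V: np.ndarray, state: FEState, dt: float, contact_trip=None):
        model = self.model
        N = model.n_nodes
        U = V[: self.n_u].reshape(N, 3)
        if contact_trip is None and model.contact is not None:
            _, _, contact_trip = _contact_assemble(
                model, model.coords0 + U, self.settings.contact_penalty, with_tangent=True
            )
        P = V[self.n_u :]
        h = self.settings.fd_step
        rows, cols, vals = [], [], []
        up_rows, up_cols, up_vals = [], [], []
        for ri, r in enumerate(model.regions):
            ge = r.global_elements()
            ue = U[ge]  # (E, 8, 3)
            pe = P[ge]
            p_gp = np.einsum("ga,ea->eg", GAUSS_N, pe)

            def elem_force(ue_arr):
                gradu = np.einsum("eaj,egai->egji", ue_arr, r.dNdX)
                F = np.eye(3) + gradu
                sigma, J, _, _ = _region_stress(
                    r, F, state.hist_eps[ri], state.hist_q[ri], dt
                )
                return _region_internal_force(r, F, p_gp, sigma, J), F, J

            f0, F0, J0 = elem_force(ue)
            E = r.n_elements
            Ke = np.empty((E, 24, 24))
            for a in range(8):
                for c in range(3):
                    uep = ue.copy()
                    uep[:, a, c] += h
                    f1, _, _ = elem_force(uep)
                    Ke[:, :, 3 * a + c] = (f1 - f0).reshape(E, 24) / h
            # coupling: df_int/dp_B = -int J F^-T_{ij} dN_a/dX_j N_B
            Finv0 = np.linalg.inv(F0)
            JFinvT = J0[..., None, None] * np.swapaxes(Finv0, -1, -2)
            # Kup[e, a, i, B] = -sum_g JFinvT[e,g,i,j] dNdX[e,g,a,j] N[g,B] detJ0
            Kup = -np.einsum(
                "egij,egaj,gb,eg->eaib", JFinvT, r.dNdX, GAUSS_N, r.detJ0
            )
            gdof = (3 * ge[:, :, None] + np.arange(3)[None, None, :]).reshape(E, 24)
            pg = self.n_u + ge  # (E, 8) pressure dof ids
            kup = Kup.reshape(E, 24, 8)
            rows.append(np.repeat(gdof, 24, axis=1).ravel())
            cols.append(np.tile(gdof, (1, 24)).ravel())
            vals.append(Ke.reshape(E, -1).ravel())
            # u-p and p-u blocks (p-u is the transpose of -Kup)
            up_rows.append(np.repeat(gdof, 8, axis=1).ravel())
            up_cols.append(np.tile(pg, (1, 24)).ravel())
            up_vals.append(kup.reshape(E, -1).ravel())
            up_rows.append(np.repeat(pg, 24, axis=1).ravel())
            up_cols.append(np.tile(gdof, (1, 8)).ravel())
            up_vals.append((-np.swapaxes(kup, 1, 2)).reshape(E, -1).ravel())
        if contact_trip is not None and len(contact_trip[0]):
            rows.append(np.asarray(contact_trip[0]))
            cols.append(np.asarray(contact_trip[1]))
            vals.append(np.asarray(contact_trip[2]))
        ndof = self.n_u + self.n_p
        K = sp.csr_matrix(
            (
                np.concatenate(vals + up_vals),
                (np.concatenate(rows + up_rows), np.concatenate(cols + up_cols)),
            ),
            shape=(ndof, ndof),
        )
        Kpp = dt * self.K_perm + self.S_stab
        K = K + sp.bmat(
            [
                [sp.csr_matrix((self.n_u, self.n_u)), None],
                [None, Kpp],
            ],
            format="csr",
        )
        return K


def _rot_x(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def _rot_y(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])


# ------------------------------------------------------------------ stepping


@dataclass
class StepTarget:
    """Loading target for one implicit step."""

    flexion: float = 0.0  # rad
    varus: float = 0.0  # rad
    axial_force: float = 0.0  # N, positive = compression (applied downward)
    dt: float = 1.0e-3
    nodal_forces: np.ndarray | None = None  # (N, 3) optional direct loads


@dataclass
class StepDiagnostics:
    iterations: int
    residual: float
    reaction_z: float
    applied_z: float
    contact_pressures: np.ndarray | None


def solve_step(
    model: FEModel,
    state: FEState,
    target: StepTarget,
    settings: SolverSettings,
    ctx: _StepContext | None = None,
):
    """One backward-Euler Newton solve to the given loading target.

    Returns (new_state, diagnostics). History variables and the reference
    volume ratios are committed only on convergence.
    """
    if ctx is None:
        ctx = _StepContext(model, settings)
    dt = target.dt
    T, prescribed, free, has_w = ctx.build_constraints(target.flexion, target.varus)
    N = model.n_nodes

    f_ext = np.zeros(ctx.n_u + ctx.n_p)
    if target.nodal_forces is not None:
        f_ext[: ctx.n_u] = target.nodal_forces.ravel()

    # initial guess: previous state, with the rotation increment applied
    # rigidly to the whole femoral body so thin cartilage elements are not
    # sheared between the constrained bone nodes and the lagging free nodes
    U_guess = state.U.copy()
    if has_w and model.femoral_region is not None:
        dR = _rot_x(target.varus) @ _rot_y(target.flexion) - _rot_x(state.varus) @ _rot_y(
            state.flexion
        )
        fr = model.regions[model.femoral_region]
        nodes = np.arange(fr.node_offset, fr.node_offset + fr.mesh.n_nodes)
        U_guess[nodes] += (model.coords0[nodes] - model.reference_point) @ dR.T
    V = np.concatenate([U_guess.ravel(), state.P])
    w = state.w
    q = np.concatenate([V[free], [w]]) if has_w else V[free].copy()

    load_scale = max(abs(target.axial_force), float(np.abs(f_ext).sum()))
    ref_force = load_scale if load_scale > 0 else 1.0
    floor = 1.0e-12 * ref_force

    fixed_z = np.array(
        [3 * n_ + 2 for n_, m_ in model.fixed_u.items() if m_[2]], dtype=np.int64
    )

    def reduced_residual(q_vec):
        V_ = T @ q_vec + prescribed
        R_, contact_, _ = ctx.residual(V_, state, dt)
        r_ = T.T @ (R_ - f_ext)
        balance = 0.0
        if has_w:
            # axial force applied downward at the reference point; weak spring
            r_[-1] += target.axial_force + settings.reference_spring * q_vec[-1]
            # support-reaction sum vs applied load (a sum of sub-tolerance
            # residuals can exceed the inf-norm criterion by a lot)
            balance = abs(float(R_[fixed_z].sum()) - target.axial_force)
        return V_, r_, float(np.linalg.norm(r_, ord=np.inf)), contact_, balance

    try:
        V, r, rnorm, contact_out, balance = reduced_residual(q)
    except FloatingPointError as e:
        raise ConvergenceError(f"initial guess inadmissible: {e}", []) from e
    residuals: list[float] = [rnorm]
    # converged when the defect has dropped far below its initial value, or
    # (after at least one corrector pass) below a small fraction of the
    # applied force scale — the latter keeps penalty-contact steps from
    # chasing the nonsmoothness floor, the former resolves slow transients
    # whose driving residual is small in absolute terms
    rel_tol = max(settings.newton_tol * rnorm, floor)
    balance_ok = lambda: balance <= settings.balance_tol * ref_force  # noqa: E731
    converged = False
    for it in range(settings.max_iterations):
        if rnorm <= rel_tol or (
            it >= 1 and rnorm <= settings.force_tol * ref_force and balance_ok()
        ):
            converged = True
            break
        trip = contact_out[1] if contact_out is not None else None
        K = ctx.tangent(V, state, dt, trip)
        Kr = (T.T @ K @ T).tocsc()
        if has_w:
            Kr = Kr.tolil()
            Kr[-1, -1] += settings.reference_spring
            Kr = Kr.tocsc()
        try:
            dq = spla.spsolve(Kr, -r)
        except RuntimeError as e:
            raise ConvergenceError(f"linear solve failed: {e}", residuals) from e
        if not np.all(np.isfinite(dq)):
            raise ConvergenceError("linear solve produced non-finite update", residuals)
        # clamp oversized updates: before contact engages the femoral axial
        # mode is held only by the weak reference spring and the raw Newton
        # step would overshoot by orders of magnitude
        dmax = float(np.abs(dq).max())
        if dmax > settings.max_increment:
            dq = dq * (settings.max_increment / dmax)
        # backtracking line search on the residual norm; penalty contact
        # makes the residual nonsmooth, so accept the best point tried
        best = None
        s = 1.0
        for _ls in range(6):
            try:
                trial = reduced_residual(q + s * dq)
            except FloatingPointError:
                s *= 0.5
                continue
            if best is None or trial[2] < best[1][2]:
                best = (q + s * dq, trial)
            if trial[2] < (1.0 - 1.0e-4) * rnorm:
                break
            s *= 0.5
        if best is None:
            raise ConvergenceError("line search found no admissible state", residuals)
        q, (V, r, rnorm, contact_out, balance) = best
        residuals.append(rnorm)
        # limit-cycle handling: penalty contact leaves a nonsmoothness
        # floor that plain Newton cannot descend below. A stagnated state
        # whose defect is small against the load and whose support
        # reactions balance is accepted; otherwise fail fast so the
        # adaptive load bisection can take over.
        if len(residuals) > 7 and rnorm > 0.98 * min(residuals[:-6]):
            if rnorm <= settings.stagnation_tol * ref_force and balance_ok():
                converged = True
                break
            raise ConvergenceError(
                f"Newton stagnated at residual {rnorm:.3e}", residuals
            )
    if not converged and (
        rnorm > max(rel_tol, settings.force_tol * ref_force) or not balance_ok()
    ):
        raise ConvergenceError(
            f"Newton did not converge in {settings.max_iterations} iterations "
            f"(residual {rnorm:.3e} vs tol {max(rel_tol, settings.force_tol * ref_force):.3e})",
            residuals,
        )

    # converged: commit
    V = T @ q + prescribed
    R, contact_out, extra = ctx.residual(V, state, dt, collect=True)
    new = state.copy()
    new.U = V[: ctx.n_u].reshape(N, 3)
    new.P = V[ctx.n_u :]
    new.w = float(q[-1]) if has_w else 0.0
    new.time = state.time + dt
    new.flexion, new.varus = target.flexion, target.varus
    for ri, r in enumerate(model.regions):
        new.J_prev[ri] = extra[r.name]["J"]
        if r.fibrils_enabled:
            new.hist_eps[ri] = extra[r.name]["new_eps"]
            new.hist_q[ri] = extra[r.name]["new_q"]

    # global force balance: reactions at fully fixed tibial base vs applied load
    R_u = R[: ctx.n_u].reshape(N, 3)
    fixed_nodes = [n for n, m in model.fixed_u.items() if all(m)]
    reaction_z = float(R_u[fixed_nodes, 2].sum()) if fixed_nodes else 0.0
    diag = StepDiagnostics(
        iterations=len(residuals),
        residual=residuals[-1],
        reaction_z=reaction_z,
        applied_z=-target.axial_force,
        contact_pressures=None if contact_out is None else contact_out[0],
    )
    return new, diag, extra


# ------------------------------------------------------------------ outputs


@dataclass
class SimulationResult:
    """Per-step tibial element-centroid fields over stance.

    Arrays are (n_steps, n_tibial_elements); contact_pressure maps each
    tibial contact face's pressure onto its owning element (zero
    elsewhere). convergence records (step, iterations, residual,
    reaction_z, applied_z). eq1_residual is the audit of the stress
    decomposition identity at the element centroids.
    """

    stance_pct: np.ndarray
    time_s: np.ndarray
    max_principal_stress: np.ndarray
    max_principal_strain: np.ndarray
    min_principal_strain: np.ndarray
    fibril_strain: np.ndarray
    fluid_pressure: np.ndarray
    contact_pressure: np.ndarray
    tibial_mesh: HexMesh
    convergence: list[dict]
    eq1_residual: float
    failed_step: int | None = None

    @property
    def n_steps(self) -> int:
        return len(self.stance_pct)


def _audit_eq1(model: FEModel, state: FEState, extra: dict) -> float:
    """Reassemble the stress decomposition from its parts at every Gauss point.

    The total stress used in assembly must equal nonfibrillar stress plus
    the (density-weighted) fibril stress sum minus pressure times identity;
    the fibril part is rebuilt here directly from the committed per-fibril
    strain and overstress, independently of the assembly path.
    """
    worst = 0.0
    for ri, r in enumerate(model.regions):
        d = extra[r.name]
        F, J, p_gp = d["F"], d["J"], d["p_gp"]
        mu, lam = r.params.lame
        B = F @ np.swapaxes(F, -1, -2)
        I = np.eye(3)
        sig_nf = mu / J[..., None, None] * (B - I) + (lam * np.log(J) / J)[
            ..., None, None
        ] * I
        sig_fib = 0.0
        if r.fibrils_enabled:
            eps_t = state.hist_eps[ri]  # committed tension strain
            q = state.hist_q[ri]  # committed overstress
            s = np.maximum(
                r.params.E_0 * eps_t + r.params.E_eps * eps_t**2 + q, 0.0
            )
            v = np.einsum("egij,enj->egni", F, r.dirs)
            m = v / np.linalg.norm(v, axis=-1, keepdims=True)
            sig_fib = np.einsum("n,egn,egni,egnj->egij", r.weights, s, m, m)
        sig_total = d["sigma_eff"] - p_gp[..., None, None] * I
        recon = sig_nf + sig_fib - p_gp[..., None, None] * I
        worst = max(worst, float(np.abs(sig_total - recon).max()))
    return worst


def _centroid_fields(model: FEModel, state: FEState, extra: dict, dt: float):
    """Tibial element-centroid output fields from the converged step bundle."""
    r = model.regions[model.tibial_region]
    d = extra[r.name]
    # centroid (xi = 0) values averaged from the 2x2x2 Gauss points: for
    # trilinear fields the Gauss average equals the centroid value
    F = d["F"].mean(axis=1)
    p = d["p_gp"].mean(axis=1)
    sigma_eff = d["sigma_eff"].mean(axis=1)
    sig_t = sigma_eff - p[:, None, None] * np.eye(3)
    stress_eigs = np.linalg.eigvalsh(sig_t)
    max_stress = stress_eigs[:, -1]
    C = np.swapaxes(F, -1, -2) @ F
    lam2 = np.linalg.eigvalsh(C)
    log_strain = 0.5 * np.log(lam2)
    max_strain = log_strain[:, -1]
    min_strain = log_strain[:, 0]
    if r.fibrils_enabled:
        v = np.einsum("eij,enj->eni", F, r.dirs)
        eps_f = np.linalg.norm(v, axis=-1) - 1.0
        fib = np.maximum(eps_f, 0.0).max(axis=1)
    else:
        fib = np.zeros(len(F))
    eq1 = _audit_eq1(model, state, extra)
    return max_stress, max_strain, min_strain, fib, p, eq1


def run_gait(
    model: FEModel,
    loadcase: LoadCase,
    settings: SolverSettings | None = None,
) -> SimulationResult:
    """Drive the model through the stance-phase load case.

    The first grid point is reached through a short seating ramp (five
    sub-increments at near-instantaneous dt) that establishes contact; each
    subsequent stance point is one implicit step, bisected adaptively on
    non-convergence. On an unrecoverable failure the partial result is
    returned with ``failed_step`` set.
    """
    settings = settings or SolverSettings()
    ctx = _StepContext(model, settings)
    state = FEState.initial(model)
    if model.contact is not None:
        # seed the femoral approach with the reference-pose surface gap so
        # the first Newton solve starts near touchdown
        g0 = float(np.nanmin(_contact_gaps(model.coords0, model.contact)))
        if np.isfinite(g0) and g0 > 0:
            # pre-place the whole femur slightly into contact so the first
            # Newton solve sees real contact stiffness instead of the weak
            # reference spring
            state.w = -(g0 + 0.01)
            fr = model.regions[model.femoral_region]
            nodes = np.arange(fr.node_offset, fr.node_offset + fr.mesh.n_nodes)
            state.U[nodes, 2] = state.w
    n = loadcase.n_steps
    n_el = model.regions[model.tibial_region].n_elements
    n_faces = len(model.contact.master_face_areas) if model.contact else 0
    fields = {
        k: np.zeros((n, n_el))
        for k in (
            "max_principal_stress",
            "max_principal_strain",
            "min_principal_strain",
            "fibril_strain",
            "fluid_pressure",
            "contact_pressure",
        )
    }
    convergence: list[dict] = []
    eq1_max = 0.0
    failed = None

    # seating ramp to the first stance point: axial force first (establishes
    # contact), then the initial rotations — simultaneous ramping makes the
    # first touchdown needlessly nonlinear
    f0 = loadcase.axial_force_n[0]
    ramp_targets = [
        StepTarget(flexion=0.0, varus=0.0, axial_force=a * f0, dt=1.0e-3)
        for a in (0.3, 0.6, 1.0)
    ] + [
        StepTarget(
            flexion=a * loadcase.flexion_rad[0],
            varus=a * loadcase.varus_rad[0],
            axial_force=f0,
            dt=1.0e-3,
        )
        for a in (0.34, 0.67, 1.0)
    ]
    prev_target = StepTarget(dt=1.0e-3)
    for i in range(n):
        if i == 0:
            targets = ramp_targets
        else:
            dt = loadcase.time_s[i] - loadcase.time_s[i - 1]
            targets = [
                StepTarget(
                    flexion=loadcase.flexion_rad[i],
                    varus=loadcase.varus_rad[i],
                    axial_force=loadcase.axial_force_n[i],
                    dt=dt,
                )
            ]
        try:
            for tgt in targets:
                state, diag, extra = _solve_adaptive(
                    model, state, prev_target, tgt, settings, ctx
                )
                prev_target = tgt
        except ConvergenceError as e:
            failed = i
            convergence.append({"step": i, "error": str(e)})
            break
        ms, mstr, mnstr, fib, p, eq1 = _centroid_fields(model, state, extra, targets[-1].dt)
        fields["max_principal_stress"][i] = ms
        fields["max_principal_strain"][i] = mstr
        fields["min_principal_strain"][i] = mnstr
        fields["fibril_strain"][i] = fib
        fields["fluid_pressure"][i] = p
        if diag.contact_pressures is not None and model.contact is not None:
            cp = np.zeros(n_el)
            cp[model.contact.master_face_elems] = diag.contact_pressures
            fields["contact_pressure"][i] = cp
        eq1_max = max(eq1_max, eq1)
        convergence.append(
            {
                "step": i,
                "iterations": diag.iterations,
                "residual": diag.residual,
                "reaction_z": diag.reaction_z,
                "applied_z": diag.applied_z,
            }
        )
    return SimulationResult(
        stance_pct=loadcase.stance_pct,
        time_s=loadcase.time_s,
        tibial_mesh=model.regions[model.tibial_region].mesh,
        convergence=convergence,
        eq1_residual=eq1_max,
        failed_step=failed,
        **fields,
    )


def _interp_target(a: StepTarget, b: StepTarget, s: float, dt: float) -> StepTarget:
    return StepTarget(
        flexion=a.flexion + s * (b.flexion - a.flexion),
        varus=a.varus + s * (b.varus - a.varus),
        axial_force=a.axial_force + s * (b.axial_force - a.axial_force),
        dt=dt,
        nodal_forces=b.nodal_forces,
    )


def _solve_adaptive(model, state, prev_target, target, settings, ctx):
    """Solve to ``target``, bisecting the load increment on failure."""
    try:
        return solve_step(model, state, target, settings, ctx)
    except ConvergenceError:
        pass
    n_sub = 2
    for attempt in range(settings.max_bisections):
        try:
            st = state
            out = None
            for j in range(1, n_sub + 1):
                tgt = _interp_target(prev_target, target, j / n_sub, target.dt / n_sub)
                out = solve_step(model, st, tgt, settings, ctx)
                st = out[0]
            return out
        except ConvergenceError as e:
            n_sub *= 2
            last = e
    raise last


# --------------------------------------------------------------- benchmark


def consolidation_benchmark(
    n_elements: int = 20,
    n_time_steps: int = 100,
    settings: SolverSettings | None = None,
    load_mpa: float = 0.01,
    check_times: tuple[float, ...] = (0.1, 0.5, 1.0),
) -> float:
    """1-D consolidation of a poroelastic column vs the analytic series.

    A unit-footprint column of linear poroelastic material (fibrils
    disabled, load small enough for the Neo-Hookean matrix to behave
    linearly) is loaded instantaneously on its drained top face; the base
    and sides are sealed and laterally confined. The pore pressure profile
    is compared against the classical single-drainage series solution at
    the given fractions of the characteristic time t_c = L^2 / c_v with
    consolidation coefficient c_v = k (lambda + 2 mu).

    Returns the maximum relative error of pore pressure (relative to the
    applied load) over the checked times and depths.
    """
    settings = settings or SolverSettings()
    L = 1.0  # mm
    params = FRPVEParams(E_m=1.0, E_0=1.0, E_eps=1.0, nu_m=0.15, eta=1.0, k_0=1000.0)
    mu, lam = params.lame
    k = permeability(params)
    c_v = k * (lam + 2 * mu)
    t_char = L**2 / c_v

    nz = n_elements
    coords = np.array(
        [
            [x, y, z * L / nz]
            for x in (0.0, 1.0)
            for y in (0.0, 1.0)
            for z in range(nz + 1)
        ]
    )
    # grid index (i,j,k) -> ((i*2)+j)*(nz+1)+k; build hexes along z
    def nid(i, j, kk):
        return (i * 2 + j) * (nz + 1) + kk

    elements = np.array(
        [
            [
                nid(0, 0, kk),
                nid(1, 0, kk),
                nid(1, 1, kk),
                nid(0, 1, kk),
                nid(0, 0, kk + 1),
                nid(1, 0, kk + 1),
                nid(1, 1, kk + 1),
                nid(0, 1, kk + 1),
            ]
            for kk in range(nz)
        ],
        dtype=np.int64,
    )
    mesh = HexMesh(coords=coords, elements=elements)
    region = Region("column", mesh, params, node_offset=0, fibrils_enabled=False)
    region.prepare()

    # confined compression: all lateral dofs fixed, base fixed vertically
    fixed = {}
    for node in range(mesh.n_nodes):
        zfix = coords[node, 2] < 1e-12
        fixed[node] = (True, True, bool(zfix))
    top_nodes = [n for n in range(mesh.n_nodes) if abs(coords[n, 2] - L) < 1e-12]
    pressure_bc = {n: 0.0 for n in top_nodes}

    model = FEModel(
        coords0=coords,
        regions=[region],
        fixed_u=fixed,
        rigid_nodes=None,
        reference_point=None,
        contact=None,
        pressure_bc=pressure_bc,
    )
    ctx = _StepContext(model, settings)

    # consistent nodal loads on the unit top face: each corner carries 1/4
    f_nodal = np.zeros((mesh.n_nodes, 3))
    for n_ in top_nodes:
        f_nodal[n_, 2] = -load_mpa / 4.0

    t_end = max(check_times) * t_char
    dt = t_end / n_time_steps
    state = FEState.initial(model)
    errors = []
    t = 0.0
    remaining = sorted(check_times)
    zc = mesh.element_centroids()[:, 2]
    while remaining:
        tgt = StepTarget(dt=dt, nodal_forces=f_nodal)
        state, diag, extra = solve_step(model, state, tgt, settings, ctx)
        t += dt
        if t + 1e-12 >= remaining[0] * t_char:
            T = t / t_char
            p_num = np.einsum(
                "ga,ea->eg", GAUSS_N, state.P[mesh.elements]
            ).mean(axis=1)
            p_ana = _terzaghi_series(zc / L, T) * load_mpa
            errors.append(np.abs(p_num - p_ana).max() / load_mpa)
            remaining.pop(0)
    return float(max(errors))


def _terzaghi_series(z_over_L: np.ndarray, T: float, n_terms: int = 200) -> np.ndarray:
    """Single-drainage consolidation: p/p0 at depth from the sealed base.

    Drained surface at z/L = 1, sealed base at z/L = 0; T = c_v t / L^2.
    """
    zeta = np.asarray(z_over_L)
    out = np.zeros_like(zeta, dtype=float)
    for m in range(n_terms):
        M = 0.5 * np.pi * (2 * m + 1)
        out += 2.0 * (-1.0) ** m / M * np.cos(M * zeta) * np.exp(-(M**2) * T)
    return out
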