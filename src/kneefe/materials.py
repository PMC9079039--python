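"""Fibril-reinforced poroviscoelastic (FRPVE) cartilage and meniscus materials.

Articular cartilage is modeled as three interacting constituents:

- a porous, fluid-filled hyperelastic *nonfibrillar matrix* (proteoglycan
  ground substance), here a compressible Neo-Hookean solid parameterized by
  its small-strain modulus ``E_m`` and Poisson's ratio ``nu_m``;
- a *collagen fibril network* of 4 organized primary fibrils following a
  Benninghoff-style arcade (parallel to the articular surface superficially,
  rotating to surface-normal in the deep zone) plus 13 quasi-uniformly
  oriented secondary fibrils, each a tension-only nonlinear viscoelastic
  spring with elastic branch ``sigma_e = E_0*eps + E_eps*eps**2`` and a
  relaxing overstress governed by the damping coefficient ``eta``;
- pressurized interstitial *fluid* whose volume fraction decreases linearly
  with normalized depth, ``n_f(h_z) = n_f_surface - n_f_slope*h_z``.

The total Cauchy stress is the sum of the nonfibrillar stress and all
fibril stresses minus the fluid pressure acting on the unit tensor:

    sigma_t = sigma_nf + sum_i sigma_f^i - p*I

The meniscus is a transversely isotropic linear elastic solid whose stiff
axis (3) is circumferential; it enters the pipeline only through the load
share it carries, but its stiffness assembly is provided for completeness.

Unit system: mm - N - s - MPa. Permeability inputs are given in the
conventional 1e-15 m^4/(N s) and converted once at load time
(1e-15 m^4 = 1e-3 mm^4).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "FRPVEParams",
    "MeniscusParams",
    "FibrilSet",
    "PoroStressState",
    "MaterialError",
    "build_fibril_set",
    "nonfibrillar_stress",
    "fibril_stress_update",
    "total_stress",
    "fluid_fraction",
    "permeability",
    "meniscus_stiffness",
    "load_frpve_params",
    "load_meniscus_params",
]

N_PRIMARY = 4
N_SECONDARY = 13
N_FIBRILS = N_PRIMARY + N_SECONDARY

#: Relative density of one primary fibril vs one secondary fibril. The
#: split of the network modulus between organized and random fibrils is a
#: literature-lineage constant, not an identifiable parameter here.
PRIMARY_SECONDARY_DENSITY_RATIO = 3.009

#: Conversion 1e-15 m^4/(N s) -> mm^4/(N s).
K0_TO_MM = 1.0e-3


class MaterialError(ValueError):
    """Invalid material parameters or state."""


@dataclass(frozen=True)
class FRPVEParams:
    """Cartilage FRPVE parameters (moduli in MPa, eta in MPa s).

    ``k_0`` is the initial permeability in units of 1e-15 m^4/(N s); use
    :func:`permeability` for the converted value in the mm-N-s system.
    """

    E_m: float
    E_0: float
    E_eps: float
    nu_m: float
    eta: float
    k_0: float
    n_f_surface: float = 0.8
    n_f_slope: float = 0.15

    def __post_init__(self) -> None:
        for name in ("E_m", "E_0", "E_eps", "eta", "k_0"):
            if getattr(self, name) <= 0:
                raise MaterialError(f"{name} must be > 0")
        if not (0 <= self.nu_m < 0.5):
            raise MaterialError("nu_m must lie in [0, 0.5)")
        for h in (0.0, 1.0):
            nf = self.n_f_surface - self.n_f_slope * h
            if not (0 < nf < 1):
                raise MaterialError(f"fluid fraction {nf} at h_z={h} outside (0, 1)")

    @property
    def lame(self) -> tuple[float, float]:
        """Shear and first Lame modulus of the nonfibrillar matrix."""
        mu = self.E_m / (2.0 * (1.0 + self.nu_m))
        lam = self.E_m * self.nu_m / ((1.0 + self.nu_m) * (1.0 - 2.0 * self.nu_m))
        return mu, lam


@dataclass(frozen=True)
class MeniscusParams:
    """Transversely isotropic meniscus: axis 3 = circumferential."""

    E_1: float
    E_2: float
    E_3: float
    nu_12: float
    nu_31: float
    G_13: float
    n_f: float = 0.72

    def __post_init__(self) -> None:
        C = meniscus_stiffness(self)  # raises if not positive definite
        del C


@dataclass
class FibrilSet:
    """Fibril directions, density weights, and viscoelastic history.

    ``directions`` is (17, 3) with the 4 primary rows first; ``weights``
    sums to 1 so a fully aligned network recovers the fibril-branch stress
    exactly. History carries the previous fibril strain and the Maxwell
    overstress of each fibril.
    """

    directions: np.ndarray
    weights: np.ndarray
    prev_strain: np.ndarray = field(default=None)  # type: ignore[assignment]
    overstress: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.directions = np.asarray(self.directions, dtype=float)
        if self.directions.shape != (N_FIBRILS, 3):
            raise MaterialError(f"exactly {N_PRIMARY}+{N_SECONDARY} fibril directions required")
        norms = np.linalg.norm(self.directions, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise MaterialError("fibril directions must be unit length")
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (N_FIBRILS,) or (self.weights <= 0).any():
            raise MaterialError("need one positive weight per fibril")
        if self.prev_strain is None:
            self.prev_strain = np.zeros(N_FIBRILS)
        if self.overstress is None:
            self.overstress = np.zeros(N_FIBRILS)


def fibril_weights() -> np.ndarray:
    """Density weights: primary/secondary ratio, normalized to sum 1."""
    c = PRIMARY_SECONDARY_DENSITY_RATIO
    w = np.array([c] * N_PRIMARY + [1.0] * N_SECONDARY)
    return w / w.sum()


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Quasi-uniform unit directions by the spherical Fibonacci lattice."""
    i = np.arange(n) + 0.5
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q *= np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def primary_directions(h_z: float) -> np.ndarray:
    """Benninghoff arcade: 4 organized directions at normalized depth h_z.

    Superficial zone (h_z < 1/3): parallel to the articular surface, two
    orthogonal in-plane pairs (azimuths 0/90 and 45/135 degrees). Deep zone
    (h_z > 2/3): surface-normal. In between the elevation rotates linearly.
    """
    if not (0.0 <= h_z <= 1.0):
        raise MaterialError(f"h_z={h_z} outside [0, 1]")
    t = np.clip((h_z - 1.0 / 3.0) / (1.0 / 3.0), 0.0, 1.0)
    theta = t * np.pi / 2.0  # elevation from the surface plane
    azimuths = np.deg2rad([0.0, 90.0, 45.0, 135.0])
    ct, st = np.cos(theta), np.sin(theta)
    dirs = np.column_stack([ct * np.cos(azimuths), ct * np.sin(azimuths), st * np.ones(4)])
    return dirs / np.linalg.norm(dirs, axis=1, keepdims=True)


def build_fibril_set(h_z: float, seed: int = 0) -> FibrilSet:
    """4 arcade primary + 13 seeded quasi-uniform secondary fibrils."""
    prim = primary_directions(h_z)
    rng = np.random.default_rng(seed)
    sec = _fibonacci_sphere(N_SECONDARY) @ _random_rotation(rng).T
    return FibrilSet(directions=np.vstack([prim, sec]), weights=fibril_weights())


# ------------------------------------------------------------ stress updates


def nonfibrillar_stress(F: np.ndarray, E_m: float, nu_m: float) -> np.ndarray:
    """Compressible Neo-Hookean Cauchy stress of the nonfibrillar matrix.

    sigma = mu/J (B - I) + lam ln(J)/J I, with (mu, lam) from (E_m, nu_m).
    Zero at F = I; matches linear elasticity with modulus E_m at small
    strain; objective (rotations produce no stress).
    """
    F = np.asarray(F, dtype=float)
    J = np.linalg.det(F)
    if np.any(J <= 0):
        raise MaterialError("element inverted: det F <= 0")
    mu = E_m / (2.0 * (1.0 + nu_m))
    lam = E_m * nu_m / ((1.0 + nu_m) * (1.0 - 2.0 * nu_m))
    B = F @ np.swapaxes(F, -1, -2)
    I = np.eye(3)
    Jb = np.asarray(J)[..., None, None]
    return mu / Jb * (B - I) + lam * np.log(Jb) / Jb * I


def fibril_stress_update(
    eps_f,
    prev_strain,
    overstress,
    E_0: float,
    E_eps: float,
    eta: float,
    dt: float,
):
    """Tension-only viscoelastic fibril stress, backward-Euler in time.

    The fibril is a nonlinear spring ``sigma_e = E_0*eps + E_eps*eps**2``
    in parallel with a Maxwell branch (spring of secant modulus
    ``E_M = E_0 + E_eps*eps`` in series with a dashpot ``eta``) carrying the
    overstress q:

        q_{n+1} = (q_n + E_M * d_eps) / (1 + E_M * dt / eta)

    Under loading the transient stress exceeds the elastic branch; at
    constant strain q relaxes exponentially to zero so the stress decays
    monotonically to ``sigma_e``. For ``eta -> 0`` the overstress vanishes
    and the quasi-static elastic branch is recovered exactly. Compressed
    fibrils (eps <= 0) carry no stress and relax their history; the total
    stress is clamped non-negative (fibrils cannot push).

    Returns (stress, new_strain, new_overstress); all arguments broadcast.
    """
    if dt <= 0:
        raise MaterialError("dt must be > 0")
    eps_f = np.asarray(eps_f, dtype=float)
    prev_strain = np.asarray(prev_strain, dtype=float)
    q_n = np.asarray(overstress, dtype=float)
    tension = eps_f > 0.0
    eps_t = np.where(tension, eps_f, 0.0)
    sigma_e = E_0 * eps_t + E_eps * eps_t**2
    E_M = E_0 + E_eps * eps_t
    d_eps = eps_t - np.where(tension, prev_strain, 0.0)
    q = (q_n + E_M * d_eps) / (1.0 + E_M * dt / eta)
    q = np.where(tension, q, 0.0)
    sigma = np.maximum(sigma_e + q, 0.0)
    new_strain = eps_t
    return sigma, new_strain, q


def fibril_strains(F: np.ndarray, directions: np.ndarray):
    """Engineering fibril strain (stretch - 1) and deformed unit directions.

    ``F`` is (..., 3, 3) and ``directions`` (n, 3); returns strains of
    shape (..., n) and unit deformed directions (..., n, 3).
    """
    v = np.einsum("...ij,nj->...ni", np.asarray(F, dtype=float), directions)
    lam = np.linalg.norm(v, axis=-1)
    m = v / lam[..., None]
    return lam - 1.0, m


@dataclass
class PoroStressState:
    """Stress decomposition at one material point (Eq.-of-state audit)."""

    sigma_total: np.ndarray
    sigma_nf: np.ndarray
    sigma_fibrils: np.ndarray  # (17, 3, 3), density-weighted
    pressure: float

    def residual(self) -> float:
        """Defect of the defining identity sigma_t = sigma_nf + sum - p I."""
        recon = self.sigma_nf + self.sigma_fibrils.sum(axis=0) - self.pressure * np.eye(3)
        return float(np.abs(self.sigma_total - recon).max())


def total_stress(
    F: np.ndarray,
    p: float,
    fibrils: FibrilSet,
    params: FRPVEParams,
    dt: float,
    update_history: bool = True,
) -> PoroStressState:
    """Assemble the total Cauchy stress at a material point.

    Fibril strain is the stretch of each reference direction under F minus
    one; each fibril's 1-D stress acts as a rank-1 tensor along its
    deformed direction, weighted by the fibril's density fraction.
    """
    F = np.asarray(F, dtype=float)
    sig_nf = nonfibrillar_stress(F, params.E_m, params.nu_m)
    eps, m = fibril_strains(F, fibrils.directions)
    s, new_eps, new_q = fibril_stress_update(
        eps, fibrils.prev_strain, fibrils.overstress, params.E_0, params.E_eps, params.eta, dt
    )
    sig_f = fibrils.weights[:, None, None] * s[:, None, None] * np.einsum("ni,nj->nij", m, m)
    if update_history:
        fibrils.prev_strain = new_eps
        fibrils.overstress = new_q
    sigma_t = sig_nf + sig_f.sum(axis=0) - p * np.eye(3)
    return PoroStressState(sigma_total=sigma_t, sigma_nf=sig_nf, sigma_fibrils=sig_f, pressure=p)


def fluid_fraction(h_z, params) -> np.ndarray | float:
    """Depth-dependent fluid volume fraction.

    Cartilage: n_f_surface - n_f_slope * h_z. Meniscus: constant n_f.
    """
    if isinstance(params, MeniscusParams):
        return params.n_f
    h = np.asarray(h_z, dtype=float)
    if np.any((h < 0) | (h > 1)):
        raise MaterialError("h_z outside [0, 1]")
    out = params.n_f_surface - params.n_f_slope * h
    return float(out) if out.ndim == 0 else out


def permeability(params: FRPVEParams, void_ratio: float | None = None, strain_dependent: bool = False) -> float:
    """Permeability in mm^4/(N s); constant k_0 by default.

    The optional deformation dependence is disabled by default (identity);
    when enabled it applies the exponential void-ratio law
    k = k_0 * ((1+e)/(1+e_0))^M with M = 1 as a mild default.
    """
    k = params.k_0 * K0_TO_MM
    if strain_dependent and void_ratio is not None:
        e0 = params.n_f_surface / (1.0 - params.n_f_surface)
        k *= (1.0 + void_ratio) / (1.0 + e0)
    return k


def meniscus_stiffness(params: MeniscusParams) -> np.ndarray:
    """6x6 stiffness (Voigt order 11,22,33,23,13,12) of the meniscus.

    Assembled as the inverse of the transversely isotropic compliance with
    the circumferential direction as axis 3; the 1-2 plane is isotropic
    with in-plane shear modulus E_1 / (2 (1 + nu_12)).
    """
    E1, E2, E3 = params.E_1, params.E_2, params.E_3
    S = np.zeros((6, 6))
    S[0, 0], S[1, 1], S[2, 2] = 1 / E1, 1 / E2, 1 / E3
    S[0, 1] = S[1, 0] = -params.nu_12 / E1
    S[0, 2] = S[2, 0] = -params.nu_31 / E3
    S[1, 2] = S[2, 1] = -params.nu_31 / E3
    G12 = E1 / (2.0 * (1.0 + params.nu_12))
    S[3, 3] = 1.0 / params.G_13  # 23 shear
    S[4, 4] = 1.0 / params.G_13  # 13 shear
    S[5, 5] = 1.0 / G12  # 12 shear
    C = np.linalg.inv(S)
    C = 0.5 * (C + C.T)
    eig = np.linalg.eigvalsh(C)
    if eig.min() <= 0:
        raise MaterialError(f"meniscus stiffness not positive definite (min eig {eig.min():.3g})")
    return C


# ------------------------------------------------------------------- loaders

_DATA = importlib.resources.files("kneefe") / "data"


def _load_yaml(name_or_path: str | Path) -> dict:
    p = Path(name_or_path)
    if p.exists():
        return yaml.safe_load(p.read_text())
    res = _DATA / f"{name_or_path}.yaml"
    return yaml.safe_load(res.read_text())


def load_frpve_params(name_or_path: str | Path) -> FRPVEParams:
    """Load cartilage parameters from a shipped name or a YAML path.

    Shipped files: ``cartilage_femoral``, ``cartilage_tibial``.
    """
    return FRPVEParams(**_load_yaml(name_or_path))


def load_meniscus_params(name_or_path: str | Path = "meniscus") -> MeniscusParams:
    return MeniscusParams(**_load_yaml(name_or_path))
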