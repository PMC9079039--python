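"""FRPVE constitutive behavior and meniscus stiffness."""

import numpy as np
import pytest
from scipy.optimize import brentq

from kneefe.materials import (
    FRPVEParams,
    MaterialError,
    MeniscusParams,
    build_fibril_set,
    fibril_stress_update,
    fluid_fraction,
    load_frpve_params,
    load_meniscus_params,
    meniscus_stiffness,
    nonfibrillar_stress,
    permeability,
    total_stress,
)


@pytest.fixture
def femoral():
    return load_frpve_params("cartilage_femoral")


@pytest.fixture
def tibial():
    return load_frpve_params("cartilage_tibial")


class TestFibrilSet:
    @pytest.mark.parametrize("h_z", [0.0, 0.2, 0.5, 0.8, 1.0])
    def test_counts_and_unit_norms_at_every_depth(self, h_z):
        fs = build_fibril_set(h_z, seed=4)
        assert fs.directions.shape == (17, 3)
        np.testing.assert_allclose(np.linalg.norm(fs.directions, axis=1), 1.0, atol=1e-12)

    def test_arcade_boundaries(self):
        surf = build_fibril_set(0.0, seed=0)
        np.testing.assert_allclose(surf.directions[:4, 2], 0.0, atol=1e-12)
        deep = build_fibril_set(1.0, seed=0)
        np.testing.assert_allclose(np.abs(deep.directions[:4, 2]), 1.0, atol=1e-12)

    def test_secondary_deterministic_in_seed(self):
        a = build_fibril_set(0.5, seed=9)
        b = build_fibril_set(0.5, seed=9)
        np.testing.assert_array_equal(a.directions, b.directions)
        c = build_fibril_set(0.5, seed=10)
        assert not np.array_equal(a.directions[4:], c.directions[4:])

    def test_out_of_range_depth_rejected(self):
        with pytest.raises(MaterialError):
            build_fibril_set(1.5)


class TestNonfibrillar:
    def test_zero_at_identity_and_under_rotation(self):
        assert np.abs(nonfibrillar_stress(np.eye(3), 0.215, 0.15)).max() == 0.0
        th = 0.3
        R = np.array(
            [[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]]
        )
        assert np.abs(nonfibrillar_stress(R, 0.215, 0.15)).max() < 1e-14

    def test_small_strain_uniaxial_modulus(self, femoral):
        # uniaxial stress: solve for the lateral stretch that frees the sides
        eps = 1e-5
        E_m, nu = femoral.E_m, femoral.nu_m

        def lateral_stress(lat):
            F = np.diag([1 + eps, 1 + lat, 1 + lat])
            return nonfibrillar_stress(F, E_m, nu)[1, 1]

        lat = brentq(lateral_stress, -10 * eps, 10 * eps, xtol=1e-16)
        sig = nonfibrillar_stress(np.diag([1 + eps, 1 + lat, 1 + lat]), E_m, nu)
        assert sig[0, 0] / eps == pytest.approx(E_m, rel=1e-3)

    def test_inverted_element_rejected(self):
        with pytest.raises(MaterialError, match="inverted"):
            nonfibrillar_stress(np.diag([-1.0, 1.0, 1.0]), 0.2, 0.1)


class TestFibrilUpdate:
    def test_compression_gives_zero(self):
        s, eps, q = fibril_stress_update(-0.05, 0.0, 0.0, 0.92, 150.0, 1062.0, 0.01)
        assert s == 0.0 and q == 0.0

    def test_elastic_limit_matches_closed_form(self):
        # eta -> 0 recovers sigma = E_0*eps + E_eps*eps^2 (femoral constants)
        s, _, _ = fibril_stress_update(0.1, 0.0, 0.0, 0.92, 150.0, 1e-12, 1.0)
        assert s == pytest.approx(0.92 * 0.1 + 150.0 * 0.01, rel=1e-9)
        assert s == pytest.approx(1.592, rel=1e-9)

    def test_relaxation_monotone_toward_elastic(self):
        E0, Ee, eta = 0.92, 150.0, 1062.0
        eps = 0.08
        sigma_e = E0 * eps + Ee * eps**2
        # load in one step, then hold: stress must decay monotonically to sigma_e
        s, h_eps, q = fibril_stress_update(eps, 0.0, 0.0, E0, Ee, eta, 1.0)
        assert s > sigma_e
        prev = s
        for _ in range(200):
            s, h_eps, q = fibril_stress_update(eps, h_eps, q, E0, Ee, eta, 5.0)
            assert s <= prev + 1e-12
            prev = s
        assert s == pytest.approx(sigma_e, rel=1e-3)

    def test_dissipation_over_closed_cycle(self):
        # work integral of the fibril stress over a closed strain cycle >= 0
        E0, Ee, eta = 0.92, 150.0, 1062.0
        path = np.concatenate([np.linspace(0, 0.1, 50), np.linspace(0.1, 0, 50)])
        h_eps = q = 0.0
        work = 0.0
        prev_eps = 0.0
        for eps in path[1:]:
            s, h_eps, q = fibril_stress_update(eps, h_eps, q, E0, Ee, eta, 0.01)
            work += s * (eps - prev_eps)
            prev_eps = eps
        assert work >= 0.0


class TestTotalStress:
    def test_pressure_only(self, femoral):
        fs = build_fibril_set(0.3, seed=0)
        st = total_stress(np.eye(3), 0.5, fs, femoral, dt=0.01)
        np.testing.assert_allclose(st.sigma_total, -0.5 * np.eye(3), atol=1e-14)
        assert st.residual() == 0.0

    def test_zero_state(self, femoral):
        fs = build_fibril_set(0.3, seed=0)
        st = total_stress(np.eye(3), 0.0, fs, femoral, dt=0.01)
        # direction normalization leaves O(eps) fibril strains
        assert np.abs(st.sigma_total).max() < 1e-12

    def test_decomposition_identity_random_states(self, femoral):
        rng = np.random.default_rng(8)
        for _ in range(20):
            F = np.eye(3) + 0.05 * rng.normal(size=(3, 3))
            if np.linalg.det(F) <= 0.2:
                continue
            fs = build_fibril_set(rng.uniform(0, 1), seed=3)
            st = total_stress(F, rng.uniform(-1, 1), fs, femoral, dt=0.01)
            assert st.residual() < 1e-10

    def test_objectivity(self, femoral):
        rng = np.random.default_rng(12)
        for _ in range(5):
            A = rng.normal(size=(3, 3))
            Q, _ = np.linalg.qr(A)
            if np.linalg.det(Q) < 0:
                Q[:, 0] = -Q[:, 0]
            F = np.eye(3) + 0.03 * rng.normal(size=(3, 3))
            fs1 = build_fibril_set(0.4, seed=5)
            fs2 = build_fibril_set(0.4, seed=5)
            s1 = total_stress(F, 0.2, fs1, femoral, dt=0.01).sigma_total
            s2 = total_stress(Q @ F, 0.2, fs2, femoral, dt=0.01).sigma_total
            np.testing.assert_allclose(Q @ s1 @ Q.T, s2, atol=1e-10)

    def test_fibril_tension_only_projection(self, femoral):
        rng = np.random.default_rng(14)
        for _ in range(10):
            F = np.eye(3) + 0.08 * rng.normal(size=(3, 3))
            if np.linalg.det(F) <= 0.2:
                continue
            fs = build_fibril_set(0.5, seed=2)
            st = total_stress(F, 0.0, fs, femoral, dt=0.01)
            sig_f = st.sigma_fibrils.sum(axis=0)
            for m in fs.directions:
                md = F @ m
                md = md / np.linalg.norm(md)
                assert md @ sig_f @ md >= -1e-12


class TestDepthProfiles:
    def test_fluid_fraction_table_values(self, femoral):
        assert fluid_fraction(0.0, femoral) == pytest.approx(0.8)
        assert fluid_fraction(1.0, femoral) == pytest.approx(0.65)
        men = load_meniscus_params()
        assert fluid_fraction(0.3, men) == pytest.approx(0.72)

    def test_permeability_unit_conversion(self, femoral, tibial):
        assert permeability(femoral) == pytest.approx(6.0e-3)
        assert permeability(tibial) == pytest.approx(1.8e-2)

    def test_permeability_flag_off_is_strain_independent(self, femoral):
        assert permeability(femoral, void_ratio=1.5) == permeability(femoral)


class TestMeniscus:
    def test_default_matrix_properties(self):
        C = meniscus_stiffness(load_meniscus_params())
        assert np.array_equal(C, C.T)
        assert np.linalg.eigvalsh(C).min() > 0
        # circumferential direction dominated by E_3 = 159.6 MPa
        assert C[2, 2] > C[0, 0]
        assert C[2, 2] > 159.6  # stiffness exceeds the Young modulus (constrained)

    def test_isotropic_degenerate_matches_hooke(self):
        E, nu = 10.0, 0.3
        G = E / (2 * (1 + nu))
        params = MeniscusParams(E_1=E, E_2=E, E_3=E, nu_12=nu, nu_31=nu, G_13=G, n_f=0.5)
        C = meniscus_stiffness(params)
        lam = E * nu / ((1 + nu) * (1 - 2 * nu))
        expected = np.zeros((6, 6))
        expected[:3, :3] = lam
        expected[np.diag_indices(3)] = lam + 2 * G
        expected[3:, 3:] = np.eye(3) * G
        np.testing.assert_allclose(C, expected, rtol=1e-10)


class TestLoaders:
    def test_table_defaults(self, femoral, tibial):
        assert (femoral.E_m, femoral.E_0, femoral.E_eps) == (0.215, 0.92, 150.0)
        assert (tibial.E_m, tibial.E_0, tibial.E_eps) == (0.106, 0.18, 23.06)
        assert femoral.eta == tibial.eta == 1062.0
        assert (femoral.k_0, tibial.k_0) == (6.0, 18.0)
        assert femoral.nu_m == tibial.nu_m == 0.15

    def test_invalid_params_rejected(self):
        with pytest.raises(MaterialError):
            FRPVEParams(E_m=-1, E_0=1, E_eps=1, nu_m=0.1, eta=1, k_0=1)
        with pytest.raises(MaterialError):
            FRPVEParams(E_m=1, E_0=1, E_eps=1, nu_m=0.6, eta=1, k_0=1)
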