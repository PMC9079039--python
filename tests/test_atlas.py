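"""Synthetic atlas generation, mesh measurement, and serialization."""

import numpy as np
import pytest

from kneefe.anatomy import AnatomicalDimensions
from kneefe.atlas import (
    GaitWaveforms,
    GeometryError,
    generate_atlas,
    generate_library,
    load_atlas,
    measure_mesh_dimensions,
    save_atlas,
)
from kneefe.mesh import read_inp, write_inp


class TestGeneration:
    def test_element_counts_and_sets(self, demo_atlas):
        assert demo_atlas.tibial_mesh.n_elements == 4 * 4 * 3
        assert demo_atlas.femoral_mesh.n_elements == 4 * 4 * 2
        for mesh, bone, contact in (
            (demo_atlas.tibial_mesh, "tibial_bone_interface", "tibial_contact"),
            (demo_atlas.femoral_mesh, "femoral_bone_interface", "femoral_contact"),
        ):
            assert bone in mesh.node_sets
            assert contact in mesh.face_sets
            assert "sealed_exterior" in mesh.face_sets
            mesh.validate_face_sets_exterior()

    def test_positive_jacobians_everywhere(self, demo_atlas):
        assert demo_atlas.tibial_mesh.corner_jacobians().min() > 0
        assert demo_atlas.femoral_mesh.corner_jacobians().min() > 0

    def test_seed_changes_waveforms_not_geometry(self, demo_dims):
        a = generate_atlas(demo_dims, (4, 4, 3), seed=1)
        b = generate_atlas(demo_dims, (4, 4, 3), seed=2)
        np.testing.assert_array_equal(a.tibial_mesh.coords, b.tibial_mesh.coords)
        np.testing.assert_array_equal(a.femoral_mesh.coords, b.femoral_mesh.coords)
        assert not np.array_equal(a.waveforms.axial_bw, b.waveforms.axial_bw)

    def test_infeasible_thickness_rejected(self, demo_dims):
        with pytest.raises(GeometryError, match="infeasible"):
            generate_atlas(demo_dims, (4, 4, 3), thickness_mm=(3.0, 3.0))

    def test_h_z_layering(self, demo_atlas):
        h = demo_atlas.tibial_mesh.h_z
        assert h.min() >= 0 and h.max() <= 1
        # articular-side layer closest to 0, bone side closest to 1
        z = demo_atlas.tibial_mesh.element_centroids()[:, 2]
        top = h[np.argmax(z)]
        bottom = h[np.argmin(z)]
        assert top < bottom


class TestLibrary:
    def test_ids_and_determinism(self):
        lib = generate_library(5, seed=7, elements_per_axis=(2, 2, 2))
        assert [r.atlas_id for r in lib] == [f"atlas_{i:02d}" for i in range(5)]
        lib2 = generate_library(5, seed=7, elements_per_axis=(2, 2, 2))
        for a, b in zip(lib, lib2):
            assert a.dimensions == b.dimensions
            np.testing.assert_array_equal(a.waveforms.axial_bw, b.waveforms.axial_bw)

    def test_all_records_pass_invariants(self, small_library):
        for rec in small_library:
            rec.check(tol=0.02)


class TestMeasurement:
    def test_generator_round_trip(self):
        rng = np.random.default_rng(11)
        from kneefe.atlas import DEFAULT_DIMENSION_RANGES

        for _ in range(20):
            dims = AnatomicalDimensions(
                **{k: rng.uniform(*v) for k, v in DEFAULT_DIMENSION_RANGES.items()}
            )
            rec = generate_atlas(dims, (4, 4, 3))
            meas = measure_mesh_dimensions(rec.femoral_mesh, rec.tibial_mesh, dims)
            for name in ("ap_medial", "ml_width", "jsw_medial"):
                assert getattr(meas, name) == pytest.approx(
                    getattr(dims, name), rel=0.02
                ), name

    def test_translation_shifts_jsw(self, demo_atlas, demo_dims):
        lifted = demo_atlas.femoral_mesh.translated((0.0, 0.0, 1.0))
        m = measure_mesh_dimensions(lifted, demo_atlas.tibial_mesh, demo_dims)
        base = measure_mesh_dimensions(
            demo_atlas.femoral_mesh, demo_atlas.tibial_mesh, demo_dims
        )
        assert m.jsw_medial - base.jsw_medial == pytest.approx(1.0, abs=1e-6)

    def test_isotropic_scaling_doubles_distances(self, demo_atlas, demo_dims):
        from dataclasses import replace

        fem = replace(demo_atlas.femoral_mesh, coords=2 * demo_atlas.femoral_mesh.coords)
        tib = replace(demo_atlas.tibial_mesh, coords=2 * demo_atlas.tibial_mesh.coords)
        m = measure_mesh_dimensions(fem, tib, demo_dims)
        base = measure_mesh_dimensions(
            demo_atlas.femoral_mesh, demo_atlas.tibial_mesh, demo_dims
        )
        for name in ("ap_medial", "ml_width", "jsw_medial"):
            assert getattr(m, name) == pytest.approx(2 * getattr(base, name), rel=1e-9)


class TestSerialization:
    def test_atlas_round_trip_lossless(self, demo_atlas, tmp_path):
        save_atlas(demo_atlas, tmp_path / "a")
        loaded = load_atlas(tmp_path / "a")
        for orig, back in (
            (demo_atlas.femoral_mesh, loaded.femoral_mesh),
            (demo_atlas.tibial_mesh, loaded.tibial_mesh),
        ):
            assert np.abs(orig.coords - back.coords).max() < 1e-9
            np.testing.assert_array_equal(orig.elements, back.elements)
            assert set(orig.node_sets) == set(back.node_sets)
            for k in orig.face_sets:
                np.testing.assert_array_equal(orig.face_sets[k], back.face_sets[k])
            np.testing.assert_array_equal(orig.h_z, back.h_z)
        assert loaded.dimensions == demo_atlas.dimensions
        np.testing.assert_array_equal(
            loaded.waveforms.axial_bw, demo_atlas.waveforms.axial_bw
        )

    def test_hand_written_single_cube(self, tmp_path):
        inp = tmp_path / "cube.inp"
        inp.write_text(
            "*NODE\n"
            "1, 0, 0, 0\n2, 1, 0, 0\n3, 1, 1, 0\n4, 0, 1, 0\n"
            "5, 0, 0, 1\n6, 1, 0, 1\n7, 1, 1, 1\n8, 0, 1, 1\n"
            "*ELEMENT, TYPE=C3D8P\n"
            "1, 1, 2, 3, 4, 5, 6, 7, 8\n"
        )
        mesh = read_inp(inp)
        assert mesh.n_nodes == 8
        assert mesh.n_elements == 1
        assert mesh.element_volumes()[0] == pytest.approx(1.0)

    def test_unknown_element_type_is_parse_error(self, tmp_path):
        from kneefe.mesh import InpParseError

        inp = tmp_path / "bad.inp"
        inp.write_text("*NODE\n1, 0, 0, 0\n*ELEMENT, TYPE=C3D20\n")
        with pytest.raises(InpParseError, match="element type"):
            read_inp(inp)

    def test_waveform_series_survive_reserialization(self, demo_atlas, tmp_path):
        save_atlas(demo_atlas, tmp_path / "w1")
        first = load_atlas(tmp_path / "w1")
        save_atlas(first, tmp_path / "w2")
        second = load_atlas(tmp_path / "w2")
        for name in ("stance_pct", "flexion_deg", "varus_deg", "axial_bw", "meniscus_share"):
            np.testing.assert_array_equal(
                getattr(first.waveforms, name), getattr(second.waveforms, name)
            )


class TestWaveforms:
    def test_validation(self):
        q = np.linspace(0, 100, 21)
        with pytest.raises(Exception):
            GaitWaveforms(q, np.zeros(21), np.zeros(21), -np.ones(21), np.zeros(21))
        with pytest.raises(Exception):
            GaitWaveforms(q[:5], np.zeros(5), np.zeros(5), np.ones(5), np.zeros(5))
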