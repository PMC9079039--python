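"""Contact-region trajectory reduction: means and neighbor-averaged peaks."""

import numpy as np
import pytest

from kneefe.fe import SimulationResult
from kneefe.mesh import HexMesh
from kneefe.postprocess import (
    PARAMETERS,
    build_trajectories,
    contact_region,
    mean_over_contact,
    peak_with_neighbors,
    trajectories_from_frame,
    trajectories_to_frame,
)


def chain_mesh(n: int) -> HexMesh:
    """n unit cubes in a row along x (a 1-D chain with known adjacency)."""
    coords = []
    for i in range(n + 1):
        for y in (0, 1):
            for z in (0, 1):
                coords.append([i, y, z])
    coords = np.array(coords, dtype=float)

    def nid(i, y, z):
        return i * 4 + y * 2 + z

    elements = np.array(
        [
            [nid(i, 0, 0), nid(i + 1, 0, 0), nid(i + 1, 1, 0), nid(i, 1, 0),
             nid(i, 0, 1), nid(i + 1, 0, 1), nid(i + 1, 1, 1), nid(i, 1, 1)]
            for i in range(n)
        ],
        dtype=np.int64,
    )
    return HexMesh(coords=coords, elements=elements)


def toy_result(values, pressures, mesh=None) -> SimulationResult:
    values = np.atleast_2d(np.asarray(values, dtype=float))
    pressures = np.atleast_2d(np.asarray(pressures, dtype=float))
    n_steps, n_elem = values.shape
    mesh = mesh if mesh is not None else chain_mesh(n_elem)
    zeros = np.zeros_like(values)
    return SimulationResult(
        stance_pct=np.linspace(0, 100, n_steps),
        time_s=np.linspace(0, 0.6, n_steps),
        max_principal_stress=values,
        max_principal_strain=values.copy(),
        min_principal_strain=-values,
        fibril_strain=values.copy(),
        fluid_pressure=values.copy(),
        contact_pressure=pressures,
        tibial_mesh=mesh,
        convergence=[],
        eq1_residual=0.0,
    )


class TestContactRegion:
    def test_zero_load_empty(self):
        res = toy_result([1.0, 2.0, 3.0], [0.0, 0.0, 0.0])
        assert len(contact_region(res, 0)) == 0
        assert np.isnan(mean_over_contact(res, "fluid_pressure", 0))

    def test_uniform_pressure_selects_all(self):
        res = toy_result([1.0, 2.0, 3.0], [1.0, 1.0, 1.0])
        np.testing.assert_array_equal(contact_region(res, 0), [0, 1, 2])

    def test_raising_tolerance_shrinks_region(self):
        res = toy_result([1.0] * 5, [0.005, 0.02, 0.5, 1.0, 2.0])
        sizes = [len(contact_region(res, 0, tol)) for tol in (0.001, 0.01, 0.1, 1.5)]
        assert sizes == sorted(sizes, reverse=True)


class TestMean:
    def test_uniform_field(self):
        res = toy_result([4.0, 4.0, 4.0], [1.0, 1.0, 1.0])
        assert mean_over_contact(res, "max_principal_stress", 0) == 4.0

    def test_two_element_region(self):
        res = toy_result([1.0, 3.0, 99.0], [1.0, 1.0, 0.0])
        assert mean_over_contact(res, "max_principal_stress", 0) == 2.0


class TestPeakWithNeighbors:
    def test_isolated_element(self):
        mesh = chain_mesh(1)
        res = toy_result([5.0], [1.0], mesh)
        assert peak_with_neighbors(res, "max_principal_stress", 0) == 5.0

    def test_three_chain_average(self):
        res = toy_result([1.0, 10.0, 2.0], [1.0, 1.0, 1.0])
        assert peak_with_neighbors(res, "max_principal_stress", 0) == pytest.approx(13.0 / 3.0)

    def test_uniform_field_unchanged_by_averaging(self):
        res = toy_result([7.0] * 6, [1.0] * 6)
        assert peak_with_neighbors(res, "max_principal_stress", 0) == 7.0

    def test_neighbors_outside_region_still_average(self):
        # peak at the region edge pulls in its out-of-contact neighbor
        res = toy_result([1.0, 10.0, 4.0], [1.0, 1.0, 0.0])
        assert peak_with_neighbors(res, "max_principal_stress", 0) == pytest.approx(5.0)

    def test_min_strain_peaks_at_most_compressive(self):
        res = toy_result([1.0, 5.0, 2.0], [1.0, 1.0, 1.0])
        # min_principal_strain = -values: extreme element is index 1
        assert peak_with_neighbors(res, "min_principal_strain", 0) == pytest.approx(-8.0 / 3.0)

    def test_exhaustive_adjacency_oracle_on_random_fields(self, demo_atlas):
        mesh = demo_atlas.tibial_mesh
        rng = np.random.default_rng(3)
        n_elem = mesh.n_elements
        values = rng.uniform(0, 10, (1, n_elem))
        pressures = rng.uniform(0, 1, (1, n_elem))
        res = toy_result(values, pressures, mesh)
        got = peak_with_neighbors(res, "max_principal_stress", 0, pressure_tol=0.5)
        # oracle: brute-force node-sharing adjacency
        region = np.flatnonzero(pressures[0] > 0.5)
        peak = region[np.argmax(values[0][region])]
        group = [peak]
        for e in range(n_elem):
            if e != peak and set(mesh.elements[e]) & set(mesh.elements[peak]):
                group.append(e)
        assert got == pytest.approx(values[0][group].mean())

    def test_vertex_adjacency_symmetric_and_self_excluding(self, demo_atlas):
        adj = demo_atlas.tibial_mesh.vertex_adjacency()
        for e, nbrs in enumerate(adj):
            assert e not in nbrs
            for n in nbrs:
                assert e in adj[n]


class TestTrajectories:
    def test_ten_trajectories_and_ordering(self, gait_result):
        trajs = build_trajectories(gait_result, "s1", "xray")
        assert len(trajs) == 10
        by_key = {(t.parameter, t.statistic): t for t in trajs}
        adjacency = gait_result.tibial_mesh.vertex_adjacency()
        for par in PARAMETERS:
            if par == "min_principal_strain":
                continue  # signed: peak is the most compressive, not the max
            peak = by_key[(par, "peak")].values
            mean = by_key[(par, "mean")].values
            for step in range(gait_result.n_steps):
                region = contact_region(gait_result, step)
                if len(region) == 0:
                    assert np.isnan(peak[step]) and np.isnan(mean[step])
                    continue
                values = getattr(gait_result, par)[step]
                peak_elem = region[np.argmax(values[region])]
                neighborhood = set(adjacency[peak_elem]) | {peak_elem}
                if neighborhood <= set(region.tolist()):
                    assert peak[step] >= mean[step] - 1e-9, (par, step)

    def test_zero_simulation_all_nan_or_zero(self, gait_model, demo_atlas):
        import numpy as np

        from kneefe.atlas import GaitWaveforms
        from kneefe.fe import run_gait
        from kneefe.loading import LoadingConfig, build_loadcase

        n = demo_atlas.waveforms.n_points
        q = np.linspace(0, 100, n)
        wf = GaitWaveforms(q, np.zeros(n), np.zeros(n), np.zeros(n), np.zeros(n))
        res = run_gait(gait_model, build_loadcase(LoadingConfig(body_weight=800.0, waveforms=wf)))
        trajs = build_trajectories(res, "s0", "mri")
        for t in trajs:
            assert np.all(np.isnan(t.values))  # no contact anywhere

    def test_csv_round_trip(self, gait_result, tmp_path):
        trajs = build_trajectories(gait_result, "s1", "xray")
        df = trajectories_to_frame(trajs)
        back = trajectories_from_frame(df)
        assert len(back) == len(trajs)
        a = {(t.parameter, t.statistic): t for t in trajs}
        for t in back:
            np.testing.assert_allclose(
                t.values, a[(t.parameter, t.statistic)].values, equal_nan=True
            )
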