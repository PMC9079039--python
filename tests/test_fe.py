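"""Poroelastic solver verification: consolidation, balance, contact, limits."""

import numpy as np
import pytest

from kneefe.atlas import GaitWaveforms, generate_atlas
from kneefe.fe import (
    FEModel,
    FEState,
    Region,
    SolverSettings,
    StepTarget,
    _StepContext,
    assemble_model,
    consolidation_benchmark,
    run_gait,
    solve_step,
)
from kneefe.loading import LoadingConfig, build_loadcase
from kneefe.materials import FRPVEParams, permeability
from kneefe.mesh import HexMesh


def _column_model(nz: int, params: FRPVEParams):
    """Laterally confined unit-footprint column, drained at the top."""
    L = 1.0
    coords = np.array(
        [[x, y, z * L / nz] for x in (0.0, 1.0) for y in (0.0, 1.0) for z in range(nz + 1)]
    )

    def nid(i, j, k):
        return (i * 2 + j) * (nz + 1) + k

    elements = np.array(
        [
            [nid(0, 0, k), nid(1, 0, k), nid(1, 1, k), nid(0, 1, k),
             nid(0, 0, k + 1), nid(1, 0, k + 1), nid(1, 1, k + 1), nid(0, 1, k + 1)]
            for k in range(nz)
        ],
        dtype=np.int64,
    )
    mesh = HexMesh(coords=coords, elements=elements)
    region = Region("column", mesh, params, node_offset=0, fibrils_enabled=False)
    region.prepare()
    fixed = {n: (True, True, bool(coords[n, 2] < 1e-12)) for n in range(mesh.n_nodes)}
    top = [n for n in range(mesh.n_nodes) if abs(coords[n, 2] - L) < 1e-12]
    return (
        FEModel(
            coords0=coords, regions=[region], fixed_u=fixed, rigid_nodes=None,
            reference_point=None, contact=None, pressure_bc={n: 0.0 for n in top},
        ),
        top,
    )


class TestConsolidation:
    def test_twenty_element_column_within_two_percent(self):
        assert consolidation_benchmark(n_elements=20, n_time_steps=100) < 0.02

    def test_refinement_reduces_error(self):
        coarse = consolidation_benchmark(n_elements=10, n_time_steps=50)
        fine = consolidation_benchmark(n_elements=20, n_time_steps=100)
        assert fine < coarse

    def test_drained_limit_pressure_vanishes(self):
        # run far past the characteristic time: pore pressure ~ 0 everywhere
        params = FRPVEParams(E_m=1.0, E_0=1.0, E_eps=1.0, nu_m=0.15, eta=1.0, k_0=1000.0)
        model, top = _column_model(8, params)
        settings = SolverSettings()
        ctx = _StepContext(model, settings)
        mu, lam = params.lame
        t_char = 1.0 / (permeability(params) * (lam + 2 * mu))
        load = 0.01
        f = np.zeros((model.n_nodes, 3))
        for n in top:
            f[n, 2] = -load / 4.0
        state = FEState.initial(model)
        for _ in range(60):
            state, _, _ = solve_step(
                model, state, StepTarget(dt=0.1 * t_char, nodal_forces=f), settings, ctx
            )
        assert np.abs(state.P).max() < 0.01 * load


class TestSingleColumnBiphasic:
    def test_instant_load_pressurizes_then_drains(self):
        params = FRPVEParams(E_m=1.0, E_0=1.0, E_eps=1.0, nu_m=0.15, eta=1.0, k_0=1000.0)
        model, top = _column_model(4, params)
        settings = SolverSettings()
        ctx = _StepContext(model, settings)
        load = 0.01
        f = np.zeros((model.n_nodes, 3))
        for n in top:
            f[n, 2] = -load / 4.0
        state = FEState.initial(model)
        # load applied within 1% of the characteristic time: the fluid
        # carries essentially the whole stress at the sealed base
        mu, lam = params.lame
        t_char = 1.0 / (permeability(params) * (lam + 2 * mu))
        state, _, _ = solve_step(
            model, state, StepTarget(dt=0.01 * t_char, nodal_forces=f), settings, ctx
        )
        base = [n for n in range(model.n_nodes) if model.coords0[n, 2] < 1e-12]
        assert state.P[base].mean() > 0.9 * load

    def test_zero_load_from_rest_stays_at_rest(self):
        params = FRPVEParams(E_m=1.0, E_0=1.0, E_eps=1.0, nu_m=0.15, eta=1.0, k_0=1000.0)
        model, _ = _column_model(4, params)
        settings = SolverSettings()
        ctx = _StepContext(model, settings)
        state = FEState.initial(model)
        state, diag, _ = solve_step(model, state, StepTarget(dt=0.01), settings, ctx)
        assert np.abs(state.U).max() < 1e-12
        assert np.abs(state.P).max() < 1e-12


class TestModelAssembly:
    def test_assembled_model_valid(self, demo_atlas, femoral_params, tibial_params):
        model = assemble_model(demo_atlas, femoral_params, tibial_params)
        assert model.contact is not None
        assert model.reference_point is not None
        assert len(model.fixed_u) == 25  # 5x5 tibial base nodes

    def test_overlapping_meshes_rejected(self, demo_atlas, femoral_params, tibial_params):
        from dataclasses import replace

        from kneefe.atlas import AtlasRecord

        sunk = demo_atlas.femoral_mesh.translated((0.0, 0.0, -2.5))
        rec = AtlasRecord(
            atlas_id="overlap",
            dimensions=demo_atlas.dimensions,
            femoral_mesh=sunk,
            tibial_mesh=demo_atlas.tibial_mesh,
            waveforms=demo_atlas.waveforms,
        )
        with pytest.raises(ValueError, match="overlap"):
            assemble_model(rec, femoral_params, tibial_params)


class TestGaitRun:
    def test_completes_with_physical_outputs(self, gait_result):
        r = gait_result
        assert r.failed_step is None
        assert r.n_steps == 51
        assert r.contact_pressure.max() > 0.1  # MPa, joint carries load
        assert r.fluid_pressure.max() > 0.1  # interstitial pressurization
        assert r.min_principal_strain.min() < -0.02  # compression present
        assert r.fibril_strain.max() > 0.0  # fibrils in tension

    def test_force_balance_every_step(self, gait_result):
        for c in gait_result.convergence:
            rel = abs(c["reaction_z"] + c["applied_z"]) / max(abs(c["applied_z"]), 1.0)
            assert rel < 0.005, f"step {c['step']}: balance error {rel:.2%}"

    def test_stress_decomposition_identity(self, gait_result):
        assert gait_result.eq1_residual <= 1e-10

    def test_contact_pressures_never_tensile(self, gait_result):
        assert gait_result.contact_pressure.min() >= 0.0

    def test_zero_load_control_all_outputs_zero(self, gait_model, demo_atlas):
        n = demo_atlas.waveforms.n_points
        q = np.linspace(0, 100, n)
        wf = GaitWaveforms(q, np.zeros(n), np.zeros(n), np.zeros(n), np.zeros(n))
        res = run_gait(gait_model, build_loadcase(LoadingConfig(body_weight=800.0, waveforms=wf)))
        assert res.failed_step is None
        for name in (
            "max_principal_stress",
            "max_principal_strain",
            "min_principal_strain",
            "fibril_strain",
            "fluid_pressure",
            "contact_pressure",
        ):
            assert np.abs(getattr(res, name)).max() < 1e-8, name

    def test_axial_symmetric_load_gives_symmetric_contact(
        self, demo_atlas, femoral_params, tibial_params
    ):
        n = 11
        q = np.linspace(0, 100, n)
        wf = GaitWaveforms(q, np.zeros(n), np.zeros(n), np.full(n, 1.5), np.zeros(n))
        model = assemble_model(demo_atlas, femoral_params, tibial_params)
        res = run_gait(model, build_loadcase(LoadingConfig(body_weight=800.0, waveforms=wf)))
        assert res.failed_step is None
        cp = res.contact_pressure[n // 2]
        field = np.zeros((4, 4))
        for e in model.contact.master_face_elems:
            field[e // 12, (e // 3) % 4] = cp[e]
        peak = field.max()
        assert peak > 0
        assert np.abs(field - field[:, ::-1]).max() / peak < 0.05  # ML mirror
        assert np.abs(field - field[::-1, :]).max() / peak < 0.05  # AP mirror

    def test_penalty_doubling_changes_peak_pressure_little(
        self, demo_atlas, femoral_params, tibial_params
    ):
        lc = build_loadcase(LoadingConfig(body_weight=800.0, waveforms=demo_atlas.waveforms))
        peaks = {}
        for pen in (50.0, 100.0):
            model = assemble_model(demo_atlas, femoral_params, tibial_params)
            res = run_gait(model, lc, SolverSettings(contact_penalty=pen))
            assert res.failed_step is None
            peaks[pen] = res.contact_pressure.max()
        assert abs(peaks[100.0] - peaks[50.0]) / peaks[50.0] < 0.05
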