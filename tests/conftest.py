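"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from kneefe.anatomy import AnatomicalDimensions, write_subject_records
from kneefe.atlas import generate_atlas, generate_library, save_library
from kneefe.fe import assemble_model, run_gait
from kneefe.loading import LoadingConfig, build_loadcase
from kneefe.materials import load_frpve_params
from kneefe.pipeline import PipelineConfig, StudyNoiseModel, generate_paired_study, run_pipeline

ZERO_NOISE = StudyNoiseModel(
    xray_bias={k: 0.0 for k in ("ap_medial", "ap_lateral", "jsw_medial", "jsw_lateral", "ml_width")},
    noise_sd={k: 0.0 for k in ("ap_medial", "ap_lateral", "jsw_medial", "jsw_lateral", "ml_width")},
)


@pytest.fixture(scope="session")
def demo_dims() -> AnatomicalDimensions:
    return AnatomicalDimensions(
        ap_medial=60.0, ap_lateral=65.0, jsw_medial=5.0, jsw_lateral=5.5, ml_width=84.0
    )


@pytest.fixture(scope="session")
def demo_atlas(demo_dims):
    return generate_atlas(demo_dims, elements_per_axis=(4, 4, 3), seed=1)


@pytest.fixture(scope="session")
def small_library():
    return generate_library(10, seed=7, elements_per_axis=(2, 2, 2))


@pytest.fixture(scope="session")
def femoral_params():
    return load_frpve_params("cartilage_femoral")


@pytest.fixture(scope="session")
def tibial_params():
    return load_frpve_params("cartilage_tibial")


@pytest.fixture(scope="session")
def gait_model(demo_atlas, femoral_params, tibial_params):
    return assemble_model(demo_atlas, femoral_params, tibial_params)


@pytest.fixture(scope="session")
def gait_result(gait_model, demo_atlas):
    """One full stance simulation (51 points, 4x4x3 tibial mesh), shared."""
    loadcase = build_loadcase(
        LoadingConfig(body_weight=800.0, waveforms=demo_atlas.waveforms)
    )
    result = run_gait(gait_model, loadcase)
    assert result.failed_step is None, f"shared gait fixture failed: {result.convergence[-1]}"
    return result


@pytest.fixture(scope="session")
def paired_study_run(tmp_path_factory):
    """Complete zero-bias paired study (3 subjects, 3 atlases), run twice.

    Shared between the orchestration tests and the acceptance suite: the
    simulations dominate the runtime, so one pair of runs serves both.
    """
    root = tmp_path_factory.mktemp("study")
    library = generate_library(3, seed=11, elements_per_axis=(4, 4, 2))
    save_library(library, root / "atlases")
    records = generate_paired_study(3, noise=ZERO_NOISE, seed=4)
    write_subject_records(records, root / "subjects.csv")
    manifests = []
    for run in ("run1", "run2"):
        cfg = PipelineConfig(
            subjects_csv=root / "subjects.csv",
            library_dir=root / "atlases",
            output_dir=root / run,
            n_permutations=200,
            seed=9,
        )
        manifests.append(run_pipeline(cfg))
    return root, manifests
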