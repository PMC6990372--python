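import numpy as np
import pytest

from qrscale import (
    CohortSpec,
    ConductionModel,
    ConductionParams,
    EllipsoidParams,
    make_box,
    make_ellipsoid_lv,
    sample_cohort,
)
from qrscale.cohort import preprocess, preprocess_cohort, run_sex_calibration


#: Canonical small LV fixture: half-ellipsoid shell, cavity 20x20x60 mm, 10 mm wall.
FIXTURE_PARAMS = EllipsoidParams(
    endo_semi_axes=(20.0, 20.0, 60.0),
    wall_thickness=10.0,
    truncation_fraction=1.0,
    target_edge_length=3.0,
)


@pytest.fixture(scope="session")
def lv_mesh():
    return make_ellipsoid_lv(FIXTURE_PARAMS, mesh_id="fixture_lv")


@pytest.fixture(scope="session")
def lv_model(lv_mesh):
    return preprocess(lv_mesh)


@pytest.fixture(scope="session")
def coarse_lv_model():
    """Very coarse LV for tests that need many full solves."""
    p = EllipsoidParams((20.0, 20.0, 60.0), 10.0, 0.9, 6.0)
    return preprocess(make_ellipsoid_lv(p, mesh_id="coarse_lv"))


@pytest.fixture(scope="session")
def iso_slab():
    """Isotropic unit-speed slab: mesh, conduction model, corner source index."""
    mesh = make_box((20.0, 10.0, 10.0), 1.0)
    tensors = np.tile(np.eye(3), (mesh.n_tets, 1, 1))
    model = ConductionModel(
        tensors=tensors,
        region=np.zeros(mesh.n_tets, dtype=np.int64),
        params=ConductionParams(cv_long=1.0),
    )
    src = int(np.argmin(np.linalg.norm(mesh.nodes, axis=1)))
    return mesh, model, src


def axis_aligned_conduction(mesh, vf=1.0, ratio=0.4):
    """Homogeneous tensors with the fiber along +x."""
    f = np.zeros((mesh.n_tets, 3))
    f[:, 0] = 1.0
    t1 = np.zeros((mesh.n_tets, 3))
    t1[:, 1] = 1.0
    t2 = np.zeros((mesh.n_tets, 3))
    t2[:, 2] = 1.0
    vt = ratio * vf
    tensors = (
        vf**2 * np.einsum("mi,mj->mij", f, f)
        + vt**2 * (np.einsum("mi,mj->mij", t1, t1) + np.einsum("mi,mj->mij", t2, t2))
    )
    return ConductionModel(
        tensors=tensors,
        region=np.zeros(mesh.n_tets, dtype=np.int64),
        params=ConductionParams(cv_long=vf, anisotropy_ratio=ratio),
    )


@pytest.fixture(scope="session")
def healthy_pair():
    """Male/female LV pair matched to healthy mean-shape size metrics."""
    from qrscale import params_from_targets

    male = preprocess(
        make_ellipsoid_lv(params_from_targets(138.9, 158.1), "healthy_male", "MALE")
    )
    female = preprocess(
        make_ellipsoid_lv(params_from_targets(114.7, 124.9), "healthy_female", "FEMALE")
    )
    return male, female


@pytest.fixture(scope="session")
def crt_cohort():
    """Seeded 39 M / 11 F synthetic CRT cohort with the full sex-calibration run.

    Expensive (a few minutes); shared by the cohort-level tests.
    """
    meshes = sample_cohort(CohortSpec(seed=1))
    models = preprocess_cohort(meshes)
    males = [m for m in models if m.mesh.sex == "MALE"]
    females = [m for m in models if m.mesh.sex == "FEMALE"]
    result = run_sex_calibration(males, females)
    return males, females, result
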