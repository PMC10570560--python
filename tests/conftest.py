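import numpy as np
import pytest

from krasdyn import RunConfig
from krasdyn.pipeline import analyze_cohort, simulate_cohort
from krasdyn.synthetic import build_template
from krasdyn.trajectory import StructureModel, TrajectoryEnsemble


@pytest.fixture(scope="session")
def template_and_modes():
    return build_template()


@pytest.fixture(scope="session")
def smoke_config():
    return RunConfig(preset="smoke", seed=1, embedding_method="pca_fallback")


@pytest.fixture(scope="session")
def smoke_run(smoke_config):
    """Simulate and analyze the smoke cohort once for the whole session."""
    cohort = simulate_cohort(smoke_config)
    result = analyze_cohort(cohort, smoke_config)
    return cohort, result


def make_structure(coords, residue_ids=None, names=None):
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    residue_ids = np.arange(1, n + 1) if residue_ids is None else np.asarray(residue_ids)
    names = names or tuple("ALA" for _ in range(n))
    return StructureModel(residue_ids=residue_ids, residue_names=names, coords=coords)


def make_ensemble(frames, variant="X", state="GDP", replicate=1, residue_ids=None):
    frames = np.asarray(frames, dtype=float)
    n = frames.shape[1]
    residue_ids = np.arange(1, n + 1) if residue_ids is None else np.asarray(residue_ids)
    return TrajectoryEnsemble(
        variant=variant,
        state=state,
        replicate=replicate,
        coords=frames,
        residue_ids=residue_ids,
    )


def random_rotation(rng):
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=rng).as_matrix()
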