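import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from taphomorph import (
    CohortSpec,
    LandmarkConfiguration,
    apply_exclusions,
    default_scheme,
    gpa,
    make_template,
    pca,
    simulate_cohort,
    tangent_project,
)
from taphomorph.taphosim import SkullTemplateParams

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


def config_from_array(coords, specimen_id="s", start_id=1):
    """LandmarkConfiguration from a K x 3 array with consecutive ids."""
    coords = np.asarray(coords, dtype=float)
    return LandmarkConfiguration(
        specimen_id=specimen_id,
        points={start_id + i: coords[i] for i in range(len(coords))},
    )


def random_rotation(rng):
    """Uniform-ish proper rotation via QR with determinant fix."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


TETRA = np.array(
    [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.3, 1.1, 0.0], [0.2, 0.4, 0.9]]
)


@pytest.fixture(scope="session")
def scheme():
    return default_scheme()


@pytest.fixture(scope="session")
def template():
    return make_template(SkullTemplateParams())


@pytest.fixture(scope="session")
def default_cohort(template):
    return simulate_cohort(template, CohortSpec(seed=11))


@pytest.fixture(scope="session")
def fitted(template, default_cohort, scheme):
    """(configs, ensemble, model) for the default simulated cohort."""
    kept, _ = apply_exclusions(default_cohort, scheme)
    ens = tangent_project(gpa(kept))
    return kept, ens, pca(ens)
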