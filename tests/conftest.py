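import numpy as np
import pytest

import inkmap as im


@pytest.fixture(scope="session")
def cohort():
    """The bundled 19-subject, 45-variable reference cohort."""
    return im.load_fixture()


@pytest.fixture(scope="session")
def scaled45(cohort):
    return im.minmax_scale(cohort)


@pytest.fixture(scope="session")
def cohort47(cohort):
    return im.append_group_indicators(cohort)


@pytest.fixture(scope="session")
def scaled47(cohort47):
    return im.minmax_scale(cohort47)


@pytest.fixture(scope="session")
def autocm_state(scaled47):
    """Default AutoCM training on the 47-variable table (trained once)."""
    return im.train_autocm(scaled47, im.AutoCMConfig())


@pytest.fixture(scope="session")
def associations(autocm_state):
    return im.normalized_associations(autocm_state)


@pytest.fixture(scope="session")
def fixture_mst(associations):
    d = im.association_to_distance(associations)
    return im.minimum_spanning_tree(d, associations.variable_names)


@pytest.fixture(scope="session")
def fixture_embedding(scaled45):
    return im.project_mds(scaled45)


def make_scaled(values, groups=None, names=None, ids=None):
    """Build a ScaledMatrix directly from [0, 1] values (test helper)."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    return im.ScaledMatrix(
        values=values,
        mins=values.min(axis=0),
        maxs=values.max(axis=0),
        variable_names=names or [f"v{j}" for j in range(p)],
        subject_ids=ids or [f"s{i}" for i in range(n)],
        groups=groups or ["AD"] * n,
    )
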