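import numpy as np
import pytest

from igeprofile.cohort import CohortSpec, TraitStatus, generate_cohort
from igeprofile.quantify import iu_matrix_to_class


@pytest.fixture(scope="session")
def default_cohort():
    """One full-size cohort under the default study conditions."""
    return generate_cohort(CohortSpec(seed=42))


@pytest.fixture(scope="session")
def planted_cohort():
    """Strong planted signature (1.5 SD), full-size cohort."""
    spec = CohortSpec(seed=7, signature={j: 1.5 for j in range(0, 24, 2)})
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def planted_features(planted_cohort):
    """Defined-diagnosis class-score features and asthma labels."""
    subjects, matrix = planted_cohort
    scores = iu_matrix_to_class(matrix)
    keep = [i for i, s in enumerate(subjects) if s.asthma is not TraitStatus.UNDEFINED]
    sub = scores.select_subjects([subjects[i].subject_id for i in keep])
    labels = np.array(
        [int(subjects[i].asthma is TraitStatus.AFFECTED) for i in keep]
    )
    return [subjects[i] for i in keep], sub, labels


@pytest.fixture
def three_blob_data():
    """Three well-separated spherical clusters in 5 dimensions."""
    rng = np.random.default_rng(0)
    return np.vstack([rng.normal(c, 0.4, size=(30, 5)) for c in (0.0, 5.0, 10.0)])
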