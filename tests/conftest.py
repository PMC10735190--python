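import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cogload.features import N_FEATURES, FeatureVector
from cogload.io import SubjectMeta

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def published_manifest():
    from cogload.tables import load_completion_manifest

    return load_completion_manifest()


def make_separable_dataset(n_subjects: int = 6, gap: float = 4.0, seed: int = 0,
                           n_informative: int = 40):
    """Synthetic feature vectors where task vectors sit ``gap`` SDs away
    from rest vectors along the first ``n_informative`` features."""
    rng = np.random.default_rng(seed)
    vectors = []
    metas = []
    for i in range(n_subjects):
        sid = f"S{i + 1:02d}"
        base = rng.standard_normal(N_FEATURES)
        shift = np.zeros(N_FEATURES)
        shift[:n_informative] = gap
        vectors.append(FeatureVector(sid, "rest", base + 0.3 * rng.standard_normal(N_FEATURES)))
        vectors.append(FeatureVector(sid, "task",
                                     base + shift + 0.3 * rng.standard_normal(N_FEATURES)))
        metas.append(SubjectMeta(subject_id=sid, X=float(5 + 2 * i)))
    return vectors, metas
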