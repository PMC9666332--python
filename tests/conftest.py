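import numpy as np
import pytest

import sensmed as sm


@pytest.fixture(scope="session")
def moments():
    return sm.study_moments()


@pytest.fixture(scope="session")
def exact_data(moments):
    """N=196 dataset whose sample moments equal the published table exactly."""
    return sm.generate_mvn(moments, n=196, seed=7, exact=True)


@pytest.fixture(scope="session")
def permissive_truth():
    """Structural parameters at the permissive-model posterior values."""
    params = sm.PathParams(a=0.08, w=0.11, k=0.23, b1=0.40, b2=0.22, c1=0.06, c2=0.0)
    return sm.residuals_for_unit_variance(params)


def point_samples(**columns):
    """Build PosteriorSamples from explicit per-parameter draw vectors."""
    names = tuple(columns)
    arrs = [np.asarray(columns[n], dtype=float) for n in names]
    S = arrs[0].size
    draws = np.column_stack(arrs).reshape(1, S, len(names))
    return sm.PosteriorSamples(names, draws, seed=0)
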