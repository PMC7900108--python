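import numpy as np
import pandas as pd
import pytest

from lldnet.connectome import Connectome
from lldnet.inference import CohortDesign


def random_connectome(n, density, rng, labels=None, subject_id="rand"):
    """Random symmetric nonnegative weight matrix at roughly the target density."""
    w = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    present = rng.random(len(iu[0])) < density
    w[iu[0][present], iu[1][present]] = rng.uniform(0.1, 5.0, int(present.sum()))
    w = w + w.T
    return Connectome(
        w, labels or tuple(f"n{i}" for i in range(n)), subject_id
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def triangle_unequal():
    """Triangle with weights w01=1, w02=0.5, w12=0.5."""
    w = np.array([[0, 1.0, 0.5], [1.0, 0, 0.5], [0.5, 0.5, 0]])
    return Connectome(w, ("a", "b", "c"), "triangle")


@pytest.fixture
def small_design(rng):
    """15 subjects, 3 groups of 5, covariates confounded with group."""
    group = pd.Series(["HOA"] * 5 + ["LLD-MCI-A+"] * 5 + ["LLD-MCI-A-"] * 5)
    age = np.concatenate(
        [rng.normal(69, 4, 5), rng.normal(77, 6, 5), rng.normal(76, 5, 5)]
    )
    sex = rng.integers(0, 2, 15)
    edu = np.concatenate(
        [rng.normal(13, 4, 5), rng.normal(7, 4, 5), rng.normal(6, 4, 5)]
    )
    cov = pd.DataFrame({"age": age, "sex": sex, "education": edu})
    return CohortDesign(group, cov)
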