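import numpy as np
import pandas as pd
import pytest

from rhizocorr.io import REQUIRED_COLUMNS, DesignSpec
from rhizocorr.simulate import SimParams, generate_dataset, study_params


@pytest.fixture(scope="session")
def study_dataset():
    """One full 180-plant factorial dataset from the study-like preset."""
    return generate_dataset(study_params(seed=7))


@pytest.fixture(scope="session")
def small_params():
    """A small single-environment design with round-number covariances."""
    return SimParams(
        design=DesignSpec(n_genotypes=3, n_mixes=2, include_control=False,
                          n_soils=1, k=4),
        mu_by_env={"control": (100.0, 3.0)},
        cov_G_by_env={"control": np.array([[400.0, 6.0], [6.0, 0.25]])},
        cov_E=np.array([[900.0, 1.0], [1.0, 0.16]]),
        seed=42,
    )


def make_frame(nodules, fruit, associations, soil="control", k=None):
    """Build a minimal valid plant table from parallel value lists.

    ``associations`` is a list of (genotype, mix) per observation; replicate
    indices are assigned within each association in order of appearance.
    """
    rows = []
    seen = {}
    for i, ((geno, mix), nod, fr) in enumerate(zip(associations, nodules, fruit)):
        rep = seen.get((geno, mix, soil), 0) + 1
        seen[(geno, mix, soil)] = rep
        rows.append((f"P{i + 1:03d}", geno, mix, soil, rep, int(nod), int(fr)))
    return pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))
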