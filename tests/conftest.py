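import numpy as np
import pandas as pd
import pytest

from comorbnet.cohort import CohortTable
from comorbnet.synthetic import SyntheticSpec


def make_cohort(disease_matrix, cb=None, ex=None, names=None) -> CohortTable:
    """Build a CohortTable from a plain nested list / array (NaN = missing)."""
    mat = np.asarray(disease_matrix, dtype=float)
    n, k = mat.shape
    names = names or [f"d{i}" for i in range(k)]
    cb = np.zeros(n) if cb is None else np.asarray(cb, dtype=float)
    ex = np.zeros(n) if ex is None else np.asarray(ex, dtype=float)
    subjects = np.array([f"S{i:03d}" for i in range(n)], dtype=object)
    return CohortTable(subjects, cb, ex, pd.DataFrame(mat, columns=names))


def constant_phi_spec(
    n, prevalences, phi, seed, names=None, **kwargs
) -> SyntheticSpec:
    """Single-population spec with a constant off-diagonal phi target."""
    prevalences = np.asarray(prevalences, dtype=float)
    k = len(prevalences)
    target = np.full((k, k), float(phi))
    np.fill_diagonal(target, 1.0)
    return SyntheticSpec(
        n_subjects=n,
        disease_names=names or [f"d{i}" for i in range(k)],
        prevalences=prevalences,
        target_phi=target,
        cb_fraction=0.5,
        ex_fraction=0.25,
        seed=seed,
        **kwargs,
    )


@pytest.fixture
def four_pattern_cohort():
    """Four subjects realising every joint pattern of two diseases."""
    return make_cohort([[1, 1, 1], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
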