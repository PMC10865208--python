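import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from triage_enrich.cohort import FeatureTable
from triage_enrich.lexicon_nlp import load_lexicon
from triage_enrich.synthetic import CohortSpec, generate_cohort, inject_letter_signal


@pytest.fixture(scope="session")
def lexicon():
    return load_lexicon()


@pytest.fixture(scope="session")
def small_cohort():
    """A 300-patient cohort at full letter signal, shared across tests."""
    spec = inject_letter_signal(CohortSpec(n_patients=300, seed=42), 1.0)
    patients, letters, truth = generate_cohort(spec)
    return spec, patients, letters, truth


def make_table(X, y, split=None, condition="ED", names=None):
    """Build a FeatureTable from arrays (test convenience)."""
    X = np.asarray(X, dtype=float)
    names = names or [f"f{j}" for j in range(X.shape[1])]
    t = FeatureTable(
        features=pd.DataFrame(X, columns=names),
        labels=np.asarray(y, dtype=int),
        condition=condition,
    )
    if split is not None:
        t.split = np.asarray(split, dtype=object)
    return t


@pytest.fixture
def blobs():
    """Two well-separated Gaussian blobs: linearly separable 2-class toy."""
    rng = np.random.default_rng(7)
    n = 50
    X = np.vstack([
        rng.normal([0, 0], 0.3, size=(n, 2)),
        rng.normal([4, 4], 0.3, size=(n, 2)),
    ])
    y = np.array([0] * n + [1] * n)
    return X, y
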