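import numpy as np
import pandas as pd
import pytest

from gtmphen import gtm, preprocessing, synthetic
from gtmphen.cohort import CohortTable, Role, VariableMeta, VType


def make_table(values, names=None, roles=None, vtypes=None, subject_ids=None):
    """Build a CohortTable from a 2-D array (NaN = missing)."""
    values = np.asarray(values, dtype=float)
    n, v = values.shape
    names = names or [f"v{j}" for j in range(v)]
    roles = roles or [Role.MODELLING] * v
    vtypes = vtypes or [VType.CONTINUOUS] * v
    ids = subject_ids if subject_ids is not None else [f"s{i}" for i in range(n)]
    df = pd.DataFrame(values, columns=names, index=ids)
    metas = [VariableMeta(nm, r, t) for nm, r, t in zip(names, roles, vtypes)]
    return CohortTable(data=df, variables=metas)


@pytest.fixture(scope="session")
def blob_fit():
    """Three well-separated planted clusters, preprocessed and fitted."""
    spec = synthetic.CohortSpec(n_subjects=600, n_dims=10, seed=1)
    table, labels = synthetic.generate_cohort(spec)
    clean, _, scaler = preprocessing.run_pipeline(table)
    X, names = clean.modelling_matrix()
    model, trace = gtm.fit(X, side=8, rbf_side=7, lam=1.0, seed=1, max_iter=200)
    return {"X": X, "labels": labels, "model": model, "trace": trace,
            "clean": clean, "scaler": scaler, "names": names}


@pytest.fixture(scope="session")
def smooth_fit():
    """A single smooth manifold (no cluster structure), fitted with a wide
    RBF basis - the regime where topographic ordering is cleanest."""
    spec = synthetic.CohortSpec(n_subjects=500, n_dims=8, n_clusters=1,
                                noise_sd=0.5, skewed_fraction=0.0, seed=3)
    table, _ = synthetic.generate_cohort(spec)
    clean, _, _ = preprocessing.run_pipeline(table)
    X, _ = clean.modelling_matrix()
    model, _ = gtm.fit(X, side=8, rbf_side=4, lam=1.0, seed=3, width_factor=3.0)
    return {"X": X, "model": model}
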