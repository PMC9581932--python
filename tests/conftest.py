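import numpy as np
import pandas as pd
import pytest

from ploidyscale.tables_io import SCALE_LINEAR, RatioMatrix, SampleMeta


def make_samples(ploidies=(1, 2, 3, 4), n_replicates=3):
    return [
        SampleMeta(f"{p}N_r{r}", p, r)
        for p in ploidies
        for r in range(1, n_replicates + 1)
    ]


def make_matrix(values, ploidies=(1, 2, 3, 4), n_replicates=3, scale=SCALE_LINEAR, ids=None):
    """RatioMatrix from a 2-D array laid out ploidy-major, replicate-minor."""
    values = np.asarray(values, dtype=float)
    samples = make_samples(ploidies, n_replicates)
    assert values.shape[1] == len(samples)
    if ids is None:
        ids = [f"P{i:03d}" for i in range(values.shape[0])]
    frame = pd.DataFrame(values, index=pd.Index(ids, name="protein_id"),
                         columns=[s.sample_id for s in samples])
    return RatioMatrix(values=frame, samples=samples, scale=scale)


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
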