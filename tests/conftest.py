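import numpy as np
import pytest

from phositec import msio


def make_matrix(values, sites=None, samples=None):
    """PhosMatrix from a list-of-lists with None for missing."""
    arr = np.array(
        [[np.nan if v is None else float(v) for v in row] for row in values]
    )
    n_sites, n_samples = arr.shape
    if sites is None:
        sites = [msio.PhosSiteID(f"P{i + 1:05d}", "S", 10) for i in range(n_sites)]
    if samples is None:
        samples = [f"S{j + 1}" for j in range(n_samples)]
    return msio.PhosMatrix(sites, samples, arr)


@pytest.fixture
def tiny_matrix():
    return make_matrix([[0.5, None], [0.7, 0.6]])


@pytest.fixture
def small_normalized():
    """A 30-site x 12-sample normalized matrix with scattered missingness."""
    rng = np.random.default_rng(42)
    vals = rng.uniform(0.1, 1.0, size=(30, 12))
    vals[rng.random(vals.shape) < 0.3] = np.nan
    vals[np.isnan(vals).all(axis=1), 0] = 0.5
    m = make_matrix(vals.tolist())
    m.values = np.where(np.isnan(vals), np.nan, vals)
    return msio.impute_and_normalize(m)
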