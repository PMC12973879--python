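import numpy as np
import pandas as pd
import pytest

from enterokit import AbundanceTable


def make_table(values, taxa=None, samples=None, kingdom="bacteria", normalized=None):
    """Build an AbundanceTable from a taxa x samples array."""
    values = np.asarray(values, dtype=float)
    n_taxa, n_samples = values.shape
    if taxa is None:
        taxa = [(kingdom, "genus", f"g{i:02d}") for i in range(n_taxa)]
    else:
        taxa = [t if isinstance(t, tuple) else (kingdom, "genus", t) for t in taxa]
    if samples is None:
        samples = [f"s{j:02d}" for j in range(n_samples)]
    df = pd.DataFrame(
        values,
        index=pd.MultiIndex.from_tuples(taxa, names=["kingdom", "rank", "name"]),
        columns=samples,
    )
    if normalized is None:
        normalized = bool(np.allclose(values.sum(axis=0), 1.0, atol=1e-9))
    return AbundanceTable(df, normalized=normalized)


def random_compositions(rng, n, m, alpha=1.0):
    """n random compositions of length m."""
    return rng.dirichlet(np.full(m, alpha), size=n)


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)


@pytest.fixture
def small_table(rng):
    comps = random_compositions(rng, 8, 5)
    return make_table(comps.T)
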