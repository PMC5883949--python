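import numpy as np
import pytest

from mdcontacts.contact_engine import CutoffScheme, ResiduePairStore


def make_store(values, pairs=None, n_residues=None, times=None,
               cutoffs=None, dtype=np.float64):
    """Build a ResiduePairStore directly from a (P, F) value matrix."""
    values = np.atleast_2d(np.asarray(values, dtype=dtype))
    P, F = values.shape
    if pairs is None:
        pairs = np.array([[0, p + 1] for p in range(P)], dtype=np.intp)
    pairs = np.asarray(pairs, dtype=np.intp)
    if n_residues is None:
        n_residues = int(pairs.max()) + 1
    if times is None:
        times = np.arange(F, dtype=np.float64)
    return ResiduePairStore(pairs=pairs, values=values,
                            times=np.asarray(times, dtype=np.float64),
                            n_residues=n_residues,
                            cutoffs=cutoffs or CutoffScheme())


def brute_force_min(coords, selection, i, j):
    """Exhaustive all-atom-pair minimum distance between residues i and j."""
    gi, gj = selection.groups[i], selection.groups[j]
    best = np.inf
    for a in gi:
        for b in gj:
            d = coords[a] - coords[b]
            best = min(best, np.sqrt((d * d).sum()))
    return best


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
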