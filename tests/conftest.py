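import numpy as np
import pytest

from coexmod.agreement import AgreementMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def worked_example_am():
    """7-gene agreement matrix reproducing the worked selection/clustering
    trace: selection keeps (x, z, t, v); clustering yields (x, z, v) and (t);
    the second round on the removed genes yields (y, u) with w left over.
    """
    ids = ["x", "y", "z", "t", "u", "v", "w"]
    pairs = {
        ("x", "z"): 1.0, ("x", "v"): 1.0, ("z", "v"): 1.0,
        ("t", "x"): 0.0, ("t", "z"): 0.0, ("t", "v"): 0.0,
        ("y", "u"): 0.75,
        ("y", "x"): 0.5, ("y", "z"): 0.5, ("y", "v"): 0.5, ("y", "t"): 0.0,
        ("u", "x"): 0.5, ("u", "z"): 0.5, ("u", "v"): 0.0, ("u", "t"): 0.0,
        ("w", "x"): 0.5, ("w", "z"): 0.5, ("w", "v"): 0.5, ("w", "t"): 0.5,
        ("w", "y"): 0.5, ("w", "u"): 0.5,
    }
    n = len(ids)
    m = np.eye(n)
    pos = {g: i for i, g in enumerate(ids)}
    for (a, b), v in pairs.items():
        m[pos[a], pos[b]] = m[pos[b], pos[a]] = v
    return AgreementMatrix(object_ids=ids, entries=m)


def random_agreement_matrix(rng, n, object_ids=None):
    """Random valid agreement matrix (symmetric, unit diagonal, [0, 1])."""
    m = rng.random((n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 1.0)
    ids = object_ids or [f"g{i}" for i in range(n)]
    return AgreementMatrix(object_ids=ids, entries=m)
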