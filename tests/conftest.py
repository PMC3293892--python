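import numpy as np
import pytest
import scipy.sparse as sp

from grnbench.grn_core import GeneNetwork


def make_network(W_dense, evolvable=None, bias=None, alpha=None, beta=None):
    """Small dense-specified network helper for toy tests."""
    W = np.asarray(W_dense, dtype=float)
    p = W.shape[0]
    return GeneNetwork(
        p=p,
        W=sp.csr_matrix(W),
        evolvable_idx=np.arange(p) if evolvable is None else np.asarray(evolvable),
        alpha=np.ones(p) if alpha is None else alpha,
        beta=np.ones(p) if beta is None else beta,
        bias=np.zeros(p) if bias is None else np.asarray(bias, dtype=float),
    )


@pytest.fixture
def chain_network():
    """Activating chain A -> B -> C with strong weights."""
    W = np.zeros((3, 3))
    W[1, 0] = 4.0  # A activates B
    W[2, 1] = 4.0  # B activates C
    return make_network(W, bias=[3.0, -2.0, -2.0])


@pytest.fixture
def small_random_network():
    from grnbench.grn_core import generate_topology

    return generate_topology(p=120, n_sub=40, nnz_sub=72, seed=11)
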