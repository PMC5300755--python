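import logging
import warnings

import numpy as np
import pytest

import osmophylo as op


@pytest.fixture(autouse=True)
def _quiet_logs():
    logging.disable(logging.WARNING)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield
    logging.disable(logging.NOTSET)


@pytest.fixture
def three_tip_tree():
    return op.read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def random_tree():
    def make(n_tips, seed=0, birth_rate=1.0):
        return op.gen_tree(n_tips, birth_rate=birth_rate, seed=seed)

    return make


def brute_force_patristic(tree):
    """Independent patristic oracle: explicit all-pairs path walking via
    parent chains (no shared code with the matrix construction)."""
    tipn = tree.tip_nodes
    n = len(tipn)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            anc_i = {}
            v, d = int(tipn[i]), 0.0
            while v >= 0:
                anc_i[v] = d
                d += tree.branch_length[v]
                v = int(tree.parent[v])
            v, d = int(tipn[j]), 0.0
            while v not in anc_i:
                d += tree.branch_length[v]
                v = int(tree.parent[v])
            D[i, j] = D[j, i] = d + anc_i[v]
    return D
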