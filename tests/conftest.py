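import numpy as np
import pytest

from ancrebind.containers import AminoAlignment, PhyloTree
from ancrebind.model import LGGammaModel


@pytest.fixture(scope="session")
def model4() -> LGGammaModel:
    return LGGammaModel(alpha=1.0, n_categories=4)


@pytest.fixture
def quartet():
    """Four-tip tree with a gapped three-site alignment."""
    aln = AminoAlignment(names=["a", "b", "c", "d"],
                         rows=["AKD", "ARD", "GK-", "AKE"])
    tree = PhyloTree.from_newick(
        "((a:0.1,b:0.2)X:0.15,(c:0.3,d:0.05)Y:0.2)R;")
    return aln, tree


def brute_force_site_likelihood(model, topology, tip_states, site):
    """Enumerate all internal-node state assignments: independent oracle.

    ``topology`` maps node -> (children, branch length to parent); the root
    has branch length None. ``tip_states`` maps leaf -> list of state codes
    (None for a gap).
    """
    internals = [n for n, (ch, _) in topology.items() if ch]
    leaves = {n: topology[n][1] for n in topology if not topology[n][0]}
    rates = model.category_rates
    lik = 0.0
    for r in rates:
        P = {n: model.transition_matrix(bl * r)
             for n, (ch, bl) in topology.items() if bl is not None}
        total = 0.0
        import itertools
        for assign in itertools.product(range(20), repeat=len(internals)):
            amap = dict(zip(internals, assign))
            p = model.freqs[amap[_root_of(topology)]]
            for n, (ch, bl) in topology.items():
                if bl is None:
                    continue
                parent = _parent_of(topology, n)
                if n in amap:
                    p *= P[n][amap[parent], amap[n]]
                else:
                    st = tip_states[n][site]
                    if st is not None:
                        p *= P[n][amap[parent], st]
            total += p
        lik += total / len(rates)
    return lik


def _root_of(topology):
    for n, (ch, bl) in topology.items():
        if bl is None:
            return n
    raise AssertionError("no root")


def _parent_of(topology, child):
    for n, (ch, _) in topology.items():
        if child in ch:
            return n
    raise AssertionError(f"no parent of {child}")
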