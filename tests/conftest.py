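import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper

from carocontrol.core_model import CarotenoidNetwork, Compound, Reaction


def make_network(label, dietary, derived, edges, deposited=(), reversible=()):
    compounds = [Compound(d, "dietary") for d in dietary] + [
        Compound(m, "derived", deposited=m in set(deposited)) for m in derived
    ]
    reactions = [Reaction(u, v, (u, v) in set(reversible)) for u, v in edges]
    return CarotenoidNetwork(label, compounds, reactions)


@pytest.fixture
def chain():
    """a -> b -> c: single linear pathway, source-controlled."""
    return make_network("chain", ["a"], ["b", "c"], [("a", "b"), ("b", "c")],
                        deposited=["c"])


@pytest.fixture
def star():
    """a -> b, a -> c: one source, two terminal branches."""
    return make_network("star", ["a"], ["b", "c"], [("a", "b"), ("a", "c")])


@pytest.fixture
def merge_branch():
    """d1 -> m <- d2, m -> p1, m -> p2: two redundant inputs feeding an
    expansion point (the internal-control motif)."""
    return make_network(
        "merge", ["d1", "d2"], ["m", "p1", "p2"],
        [("d1", "m"), ("d2", "m"), ("m", "p1"), ("m", "p2")],
        deposited=["p1", "p2"],
    )


@pytest.fixture
def diamond():
    """d -> a -> m, d -> b -> m: two simple paths to m."""
    return make_network(
        "diamond", ["d"], ["a", "b", "m"],
        [("d", "a"), ("d", "b"), ("a", "m"), ("b", "m")],
        deposited=["m"],
    )


@pytest.fixture(scope="session")
def small_tree():
    from carocontrol.trees import TreeArrays, yule_tree

    return TreeArrays.from_phylogeny(yule_tree(8, 50.0, seed=42))


@pytest.fixture(scope="session")
def medium_tree():
    from carocontrol.trees import TreeArrays, yule_tree

    return TreeArrays.from_phylogeny(yule_tree(64, 90.0, seed=42))
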