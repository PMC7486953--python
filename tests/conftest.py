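import numpy as np
import pytest

from repeatscape.asr import Phylogeny
from repeatscape.simulate import RepeatFamilySpec


@pytest.fixture(scope="session")
def two_tip_tree():
    return Phylogeny.from_newick("(focal:0.1,other:0.1)root;")


@pytest.fixture(scope="session")
def study_tree():
    from repeatscape.pipeline import GOMPHOCERINE_NEWICK

    return Phylogeny.from_newick(GOMPHOCERINE_NEWICK)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def satellite_spec():
    return RepeatFamilySpec("satT", "satellite", 170, 40, divergence_rate=0.3)


def random_binary_tree(rng: np.random.Generator, n_tips: int = 6) -> Phylogeny:
    """Random binary topology with branch lengths ~ U(0.2, 2)."""
    nodes = [f"t{i}" for i in range(n_tips)]
    parts = {n: f"{n}:{rng.uniform(0.2, 2.0):.6f}" for n in nodes}
    k = 0
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        a, b = nodes[j], nodes[i]
        nodes.remove(a)
        nodes.remove(b)
        nid = f"n{k}"
        k += 1
        parts[nid] = (f"({parts.pop(a)},{parts.pop(b)}){nid}:"
                      f"{rng.uniform(0.2, 2.0):.6f}")
        nodes.append(nid)
    return Phylogeny.from_newick(
        f"({parts.pop(nodes[0])},{parts.pop(nodes[1])})root;")


def gls_asr_oracle(tree: Phylogeny, tip_states: dict[str, float]):
    """Brute-force GLS reconstruction via explicit BM covariance matrices.

    Independent of the pruning/message-passing implementation: builds the
    full shared-path-length covariance, inverts it, and applies the GLS/BLUP
    formulas directly.
    """
    def ancestors(n):
        out = []
        while n is not None:
            out.append(n)
            n = tree.parent(n)
        return out[::-1]

    def shared(u, v):
        last = tree.root
        for a, b in zip(ancestors(u), ancestors(v)):
            if a == b:
                last = a
            else:
                break
        return tree.root_to_node_length(last)

    tips = tree.tips
    V = np.array([[shared(a, b) for b in tips] for a in tips])
    x = np.array([tip_states[t] for t in tips])
    Vi = np.linalg.inv(V)
    one = np.ones(len(tips))
    mu = one @ Vi @ x / (one @ Vi @ one)
    sigma2 = (x - mu) @ Vi @ (x - mu) / (len(tips) - 1)
    states = {}
    for node in tree.postorder():
        if tree.is_tip(node):
            states[node] = float(tip_states[node])
        else:
            c = np.array([shared(node, t) for t in tips])
            states[node] = float(mu + c @ Vi @ (x - mu))
    return states, float(sigma2)
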