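from __future__ import annotations

import itertools

import numpy as np
import pytest

from lossmap.tree import PhyloTree

SYNDERMATAN_NEWICK = (
    "(Outgroup,(Monogononta,(Bdelloidea,(Seisonidea,Acanthocephala)"
    "Pararotatoria)Hemirotifera)Syndermata)Root;"
)


@pytest.fixture
def syndermatan_tree() -> PhyloTree:
    return PhyloTree.from_newick(SYNDERMATAN_NEWICK)


@pytest.fixture
def small_tree() -> PhyloTree:
    return PhyloTree.from_newick("((A,B)AB,(C,(D,E)DE)CDE)Root;")


def random_tree(rng: np.random.Generator, n_tips: int) -> PhyloTree:
    """Random topology by iterative joining; tips T1..Tn."""
    items = [f"T{i + 1}" for i in range(n_tips)]
    while len(items) > 1:
        i, j = sorted(rng.choice(len(items), 2, replace=False))
        b = items.pop(j)
        a = items.pop(i)
        items.append(f"({a},{b})")
    return PhyloTree.from_newick(items[0] + ";")


def brute_force_min_losses(
    tree: PhyloTree, absent_tips: set[str], present_tips: set[str]
) -> int:
    """Exhaustive minimum number of loss edges consistent with tip states
    under irreversibility (ancestrally present character); unknown tips are
    unconstrained.  Independent oracle: pure enumeration over edge subsets.
    """
    def under(node: str, tip: str) -> bool:
        return node == tip or tree.is_strict_ancestor(node, tip)

    candidates = [child for _p, child in tree.branches()]
    for k in range(len(candidates) + 1):
        for combo in itertools.combinations(candidates, k):
            if any(under(c, t) for c in combo for t in present_tips):
                continue
            if all(any(under(c, t) for c in combo) for t in absent_tips):
                return k
    raise AssertionError("unreachable")  # pragma: no cover
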