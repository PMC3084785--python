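"""Independent brute-force oracles used by the test suite only."""

from __future__ import annotations

import numpy as np
from sympy.utilities.iterables import multiset_partitions

from nifhamp.simulate import AMINO_ACIDS, CONSENSUS


def mutate(seq: str, n_subs: int, rng: np.random.Generator) -> str:
    """Apply ``n_subs`` substitutions at distinct random positions."""
    out = list(seq)
    for pos in rng.choice(len(seq), size=n_subs, replace=False):
        choices = [a for a in AMINO_ACIDS if a != out[pos]]
        out[pos] = choices[rng.integers(len(choices))]
    return "".join(out)


def all_partitions(n: int):
    """Every set partition of range(n) as a list of blocks (lists)."""
    return multiset_partitions(list(range(n)))


def partition_valid(blocks, ident: np.ndarray, threshold: float) -> bool:
    """Diameter property: all within-block identities >= threshold."""
    for block in blocks:
        for i, a in enumerate(block):
            for b in block[i + 1:]:
                if ident[a, b] < threshold - 1e-9:
                    return False
    return True


def refines(fine, coarse) -> bool:
    """True if every block of ``fine`` is contained in a block of ``coarse``."""
    lookup = {}
    for k, block in enumerate(coarse):
        for x in block:
            lookup[x] = k
    for block in fine:
        if len({lookup[x] for x in block}) != 1:
            return False
    return True


def canonical(blocks):
    return sorted(tuple(sorted(b)) for b in blocks)


def random_additive_tree(n_taxa: int, rng: np.random.Generator):
    """Random binary unrooted tree; returns (labels, additive distance matrix).

    Built by randomly joining subtrees with branch lengths in [0.1, 1.0];
    pairwise distances are accumulated path lengths, so the matrix is
    additive by construction.
    """
    labels = [f"T{i}" for i in range(n_taxa)]
    # each live node: (set of (leaf, dist-to-node))
    nodes = [[(i, 0.0)] for i in range(n_taxa)]
    D = np.zeros((n_taxa, n_taxa))
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        li, lj = rng.uniform(0.1, 1.0, size=2)
        a, b = nodes[i], nodes[j]
        for leaf_a, da in a:
            for leaf_b, db in b:
                D[leaf_a, leaf_b] = D[leaf_b, leaf_a] = da + li + db + lj
        merged = [(l, d + li) for l, d in a] + [(l, d + lj) for l, d in b]
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)]
        nodes.append(merged)
    lens = rng.uniform(0.1, 1.0, size=3)
    for x in range(3):
        for y in range(x + 1, 3):
            for leaf_a, da in nodes[x]:
                for leaf_b, db in nodes[y]:
                    D[leaf_a, leaf_b] = D[leaf_b, leaf_a] = (
                        da + lens[x] + db + lens[y]
                    )
    return labels, D
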