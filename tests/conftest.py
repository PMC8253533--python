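import numpy as np
import pytest

from ystrkit import (
    Allele,
    Haplotype,
    PopulationSample,
    YFILER_PLUS_27,
    maoming_like_fixture,
)


@pytest.fixture(scope="session")
def maoming_fixture():
    """The 431-male, 27-locus synthetic cohort with Table-1 shape."""
    return maoming_like_fixture(seed=1)


def make_single_locus_pop(name, values, marker="DYS391"):
    """A population typed at one synthetic single-locus 'panel' slot.

    Used for hand-checkable AMOVA toys: every other marker is held constant
    so only *marker* contributes molecular distance.
    """
    haplotypes = []
    for i, v in enumerate(values):
        calls = {}
        for m in YFILER_PLUS_27.markers:
            if m.name == marker:
                calls[m.name] = (Allele(int(v)),) * m.copy_number
            else:
                calls[m.name] = (Allele(10),) * m.copy_number
        haplotypes.append(Haplotype(f"{name}{i}", calls))
    return PopulationSample(name, YFILER_PLUS_27, haplotypes)


def random_additive_tree(n_taxa, rng):
    """A random binary tree with positive branch lengths and its exact
    leaf-to-leaf path-length matrix — independent of the NJ implementation.

    Returns (labels, distance_matrix, splits) where splits is the set of
    non-trivial bipartitions (frozensets of leaf labels).
    """
    labels = [f"T{i}" for i in range(n_taxa)]
    adjacency = {i: {} for i in range(n_taxa)}
    active = list(range(n_taxa))
    nxt = n_taxa

    def connect(a, b, length):
        adjacency.setdefault(a, {})[b] = length
        adjacency.setdefault(b, {})[a] = length

    while len(active) > 3:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        a, b = active[j], active[i]
        u = nxt
        nxt += 1
        connect(u, a, float(rng.uniform(0.1, 2.0)))
        connect(u, b, float(rng.uniform(0.1, 2.0)))
        active = [x for x in active if x not in (a, b)] + [u]
    center = nxt
    for a in active:
        connect(center, a, float(rng.uniform(0.1, 2.0)))

    D = np.zeros((n_taxa, n_taxa))
    for src in range(n_taxa):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            v = stack.pop()
            for w, length in adjacency[v].items():
                if w not in dist:
                    dist[w] = dist[v] + length
                    stack.append(w)
        for dst in range(n_taxa):
            D[src, dst] = dist[dst]
    return labels, D, tree_splits(adjacency, labels)


def tree_splits(adjacency, labels):
    """Non-trivial bipartitions (as frozensets of labels on one side)."""
    n = len(labels)
    splits = set()
    for a in adjacency:
        for b in adjacency[a]:
            if a >= b:
                continue
            # leaves reachable from a without crossing edge (a, b)
            side = set()
            stack = [a]
            seen = {a, b}
            while stack:
                v = stack.pop()
                if v < n:
                    side.add(labels[v])
                for w in adjacency[v]:
                    if w not in seen:
                        seen.add(w)
                        stack.append(w)
            if 1 < len(side) < n - 1:
                # canonical orientation: the side without the first label
                anchor = sorted(labels)[0]
                if anchor in side:
                    side = set(labels) - side
                splits.add(frozenset(side))
    return splits


def nj_tree_splits(tree):
    """Bipartitions of an :class:`ystrkit.NJTree` (same encoding as above)."""
    return tree_splits(tree.adjacency, tree.labels)
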