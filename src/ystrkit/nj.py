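"""Saitou-Nei neighbor-joining trees from population distance matrices.

Neighbor joining is agglomerative: at each step the pair (i, j) minimising

    Q(i, j) = (m - 2) * d(i, j) - sum_k d(i, k) - sum_k d(j, k)

(m = active clusters) is joined, limb lengths follow the standard formulas,
and the new node's distances are ``d(u, k) = (d(i,k) + d(j,k) - d(i,j))/2``.
On an additive matrix this recovers the generating tree exactly.

Ties on Q are broken by the lexicographically smallest label pair (each
cluster is labelled by its smallest contained taxon), so runs are
reproducible across platforms.  Negative estimated branch lengths are kept
and reported by default; with ``clamp=True`` they are set to 0 and the
difference moved to the sister branch of the same join (Kuhner-Felsenstein
convention), preserving path lengths through the joined node.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["NJTree", "neighbor_joining"]

_QUOTE_TRIGGERS = set(" \t()[]{}:;,'\"")


def _format_label(label: str) -> str:
    if any(c in _QUOTE_TRIGGERS for c in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def _format_length(x: float) -> str:
    return repr(float(x))


@dataclass
class NJTree:
    """An unrooted tree over taxon labels with branch lengths.

    Leaves are nodes 0..n-1 (in input label order); internal nodes follow.
    ``adjacency`` maps node -> {neighbor: branch length}.
    """

    labels: list[str]
    adjacency: dict[int, dict[int, float]]
    root: int  # serialization anchor (final join), not a biological root
    negative_branches: list[tuple[int, int, float]] = field(default_factory=list)

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def to_newick(self) -> str:
        """Deterministic Newick string with branch lengths at full precision."""

        def render(node: int, parent: int | None) -> str:
            children = [c for c in self.adjacency[node] if c != parent]
            if not children:
                return _format_label(self.labels[node])
            parts = [
                f"{render(c, node)}:{_format_length(self.adjacency[node][c])}"
                for c in children
            ]
            return "(" + ",".join(parts) + ")"

        return render(self.root, None) + ";"

    def path_length_matrix(self) -> np.ndarray:
        """Leaf-to-leaf path lengths, in label order (additivity check)."""
        n = self.n_leaves
        out = np.zeros((n, n))
        for src in range(n):
            dist = {src: 0.0}
            stack = [src]
            while stack:
                v = stack.pop()
                for w, length in self.adjacency[v].items():
                    if w not in dist:
                        dist[w] = dist[v] + length
                        stack.append(w)
            for dst in range(n):
                out[src, dst] = dist[dst]
        return out


def _validate(D: np.ndarray, labels: list[str]) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.ndim != 2 or D.shape[1] != n:
        raise ValueError(f"distance matrix must be square, got {D.shape}")
    if n < 2:
        raise ValueError("need at least 2 taxa")
    if len(labels) != n:
        raise ValueError("labels length must match matrix size")
    if len(set(labels)) != n:
        raise ValueError("labels must be unique")
    if not np.allclose(D, D.T, rtol=0, atol=1e-12):
        raise ValueError("distance matrix is not symmetric")
    if not np.allclose(np.diag(D), 0.0, rtol=0, atol=1e-12):
        raise ValueError("distance matrix has a nonzero diagonal")
    return D


def neighbor_joining(
    D: np.ndarray, labels: list[str], clamp: bool = False
) -> NJTree:
    """Build the neighbor-joining tree for a symmetric distance matrix."""
    D = _validate(D, list(labels))
    n = len(labels)
    adjacency: dict[int, dict[int, float]] = {i: {} for i in range(n)}
    negative: list[tuple[int, int, float]] = []
    next_node = n

    def add_edge(a: int, b: int, length: float) -> None:
        if length < 0:
            negative.append((a, b, length))
        adjacency.setdefault(a, {})[b] = length
        adjacency.setdefault(b, {})[a] = length

    def fix_pair(la: float, lb: float) -> tuple[float, float]:
        # Kuhner-Felsenstein: zero a negative limb, move the difference to
        # its sister so the path through the join is preserved.
        if clamp:
            if la < 0:
                lb, la = lb + la, 0.0
            if lb < 0:
                la, lb = max(la + lb, 0.0), 0.0
        return la, lb

    if n == 2:
        # split-evenly convention for the 2-taxon base case
        half = D[0, 1] / 2.0
        root = next_node
        adjacency[root] = {}
        add_edge(root, 0, half)
        add_edge(root, 1, half)
        return NJTree(list(labels), adjacency, root, negative)

    active = list(range(n))  # current cluster representatives
    dist = {(i, j): D[i, j] for i in range(n) for j in range(n) if i < j}
    # tie-break label of a cluster: smallest contained taxon label
    cluster_label = {i: labels[i] for i in range(n)}

    def d(a: int, b: int) -> float:
        return dist[(a, b) if a < b else (b, a)]

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d(i, k) for k in active if k != i) for i in active}
        best: tuple[int, int] | None = None
        best_q = np.inf
        for ii in range(m):
            for jj in range(ii + 1, m):
                a, b = active[ii], active[jj]
                q = (m - 2) * d(a, b) - r[a] - r[b]
                pair_key = tuple(sorted((cluster_label[a], cluster_label[b])))
                if q < best_q - 1e-12 or (
                    abs(q - best_q) <= 1e-12
                    and best is not None
                    and pair_key
                    < tuple(sorted((cluster_label[best[0]], cluster_label[best[1]])))
                ):
                    best_q = q
                    best = (a, b)
        assert best is not None
        i, j = best
        dij = d(i, j)
        li = dij / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = fix_pair(li, lj)
        u = next_node
        next_node += 1
        adjacency[u] = {}
        add_edge(u, i, li)
        add_edge(u, j, lj)
        cluster_label[u] = min(cluster_label[i], cluster_label[j])
        for k in active:
            if k in (i, j):
                continue
            duk = (d(i, k) + d(j, k) - dij) / 2.0
            dist[(min(u, k), max(u, k))] = duk
        active = [k for k in active if k not in (i, j)] + [u]

    # final 3-cluster star: closed-form limb lengths
    a, b, c = active
    la = (d(a, b) + d(a, c) - d(b, c)) / 2.0
    lb = d(a, b) - la
    lc = d(a, c) - la
    if clamp:
        la, lb, lc = (max(x, 0.0) for x in (la, lb, lc))
    root = next_node
    adjacency[root] = {}
    add_edge(root, a, la)
    add_edge(root, b, lb)
    add_edge(root, c, lc)
    return NJTree(list(labels), adjacency, root, negative)
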