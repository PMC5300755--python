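"""Rooted phylogenies with branch lengths, and the distance/covariance
structures consumed by the comparative and regime-fitting layers.

Trees are parsed and serialized with :mod:`dendropy`; internally each tree
is flattened to preorder arrays (parent pointers and branch lengths) so
that patristic distances, Brownian-motion covariances and Hansen weight
matrices are simple vectorized computations.  Trees need not be ultrametric
(branch lengths in genetic-divergence units are fine) and polytomies are
allowed throughout.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import dendropy
import numpy as np

__all__ = [
    "Phylogeny",
    "read_newick",
    "write_newick",
    "patristic_distances",
    "bm_covariance",
    "ou_covariance",
    "OU_ALPHA_FLOOR",
]

#: Below this attraction strength the OU covariance falls back to scaled BM.
OU_ALPHA_FLOOR = 1e-9


class NewickError(ValueError):
    """Raised when a Newick string cannot be parsed or violates invariants."""


class Phylogeny:
    """A rooted tree with tip labels and non-negative branch lengths.

    Nodes are indexed 0..n_nodes-1 in preorder (root = 0); ``parent[i]``
    and ``branch_length[i]`` describe the edge above node ``i`` (the root
    edge has length 0).  Tip labels are unique.  The node indexing is
    stable for a given tree object, so regime paintings expressed as
    per-node labels remain valid across operations that do not rebuild
    the tree.
    """

    def __init__(self, dtree: dendropy.Tree, default_branch_length: float | None = None):
        dtree.is_rooted = True
        self._dtree = dtree
        nodes = list(dtree.preorder_node_iter())
        self._nodes = nodes
        n = len(nodes)
        index = {id(nd): i for i, nd in enumerate(nodes)}
        parent = np.full(n, -1, dtype=int)
        blen = np.zeros(n, dtype=float)
        tip_labels: list[str] = []
        tip_index: dict[str, int] = {}
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                L = nd.edge.length
                if L is None:
                    if default_branch_length is None:
                        raise NewickError(f"missing branch length above node {i}")
                    L = default_branch_length
                if L < 0:
                    raise NewickError(f"negative branch length {L} above node {i}")
                blen[i] = L
            if nd.is_leaf():
                label = nd.taxon.label if nd.taxon is not None else nd.label
                if label is None:
                    raise NewickError("unlabeled tip")
                label = str(label).replace(" ", "_")
                if label in tip_index:
                    raise NewickError(f"duplicate tip label {label!r}")
                tip_index[label] = i
                tip_labels.append(label)
        self.parent = parent
        self.branch_length = blen
        self.tip_labels = tip_labels
        self._tip_index = tip_index
        # node depths (root-to-node path lengths)
        depth = np.zeros(n, dtype=float)
        for i in range(1, n):
            depth[i] = depth[parent[i]] + blen[i]
        self.depth = depth
        self.children: list[list[int]] = [[] for _ in range(n)]
        for i in range(1, n):
            self.children[parent[i]].append(i)

    # ------------------------------------------------------------------ #
    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def tip_nodes(self) -> np.ndarray:
        """Node indices of the tips, in ``tip_labels`` order."""
        return np.array([self._tip_index[t] for t in self.tip_labels], dtype=int)

    def is_tip(self, node: int) -> bool:
        return not self.children[node]

    def tip_node(self, label: str) -> int:
        return self._tip_index[label]

    def tree_height(self) -> float:
        """Maximum root-to-tip path length."""
        return float(self.depth[self.tip_nodes].max())

    def descendant_tips(self, node: int) -> list[int]:
        """Tip node indices in the clade subtended by ``node``."""
        out, stack = [], [node]
        while stack:
            v = stack.pop()
            if self.is_tip(v):
                out.append(v)
            else:
                stack.extend(self.children[v])
        return out

    # ------------------------------------------------------------------ #
    @classmethod
    def from_newick(cls, text: str, default_branch_length: float | None = None) -> "Phylogeny":
        try:
            dtree = dendropy.Tree.get(
                data=text, schema="newick", suppress_internal_node_taxa=True
            )
        except Exception as exc:  # dendropy raises several error classes
            raise NewickError(f"malformed Newick: {exc}") from exc
        return cls(dtree, default_branch_length=default_branch_length)

    def to_newick(self) -> str:
        s = self._dtree.as_string(schema="newick", suppress_rooting=True)
        return s.strip() + "\n"

    # ------------------------------------------------------------------ #
    def prune_to(self, keep: Iterable[str]) -> "Phylogeny":
        """Restrict the tree to the tips in ``keep``.

        Unary nodes produced by pruning are collapsed with their branch
        lengths summed, so patristic distances among kept tips are
        unchanged.  Unknown labels raise ``KeyError`` listing every
        offender (mirroring the exclusion of species absent from the
        phylogeny rather than silently dropping them).
        """
        keep = list(dict.fromkeys(keep))
        unknown = [k for k in keep if k not in self._tip_index]
        if unknown:
            raise KeyError(f"tips not in tree: {unknown}")
        if len(keep) < 2:
            raise ValueError("need at least 2 tips to keep")
        clone = dendropy.Tree(self._dtree)
        labels = set(keep)
        taxa = [t for t in clone.taxon_namespace if str(t.label).replace(" ", "_") in labels]
        clone.retain_taxa(taxa)
        clone.suppress_unifurcations()
        return Phylogeny(clone)

    # ------------------------------------------------------------------ #
    def mrca_depth_matrix(self) -> np.ndarray:
        """depth[MRCA(i, j)] for every tip pair, in ``tip_labels`` order."""
        n = self.n_tips
        pos_of_node = {int(v): i for i, v in enumerate(self.tip_nodes)}
        C = np.zeros((n, n), dtype=float)
        # postorder accumulation of descendant tip sets
        order = list(range(self.n_nodes))[::-1]  # reverse preorder = valid postorder
        tipsets: dict[int, list[int]] = {}
        for v in order:
            if self.is_tip(v):
                tipsets[v] = [pos_of_node[v]]
            else:
                kids = [tipsets[c] for c in self.children[v]]
                for a in range(len(kids)):
                    for b in range(a + 1, len(kids)):
                        ia = np.array(kids[a])[:, None]
                        ib = np.array(kids[b])[None, :]
                        C[ia, ib] = self.depth[v]
                        C[ib.T, ia.T] = self.depth[v]
                merged = [x for k in kids for x in k]
                tipsets[v] = merged
                for c in self.children[v]:
                    del tipsets[c]
        d = self.depth[self.tip_nodes]
        np.fill_diagonal(C, d)
        return C

    def node_distance_matrix(self) -> np.ndarray:
        """All-pairs path lengths between every node (tips and internals)."""
        n = self.n_nodes
        D = np.zeros((n, n), dtype=float)
        # undirected BFS from each node; trees are small so O(n^2) is fine
        adj: list[list[tuple[int, float]]] = [[] for _ in range(n)]
        for i in range(1, n):
            adj[i].append((self.parent[i], self.branch_length[i]))
            adj[self.parent[i]].append((i, self.branch_length[i]))
        for s in range(n):
            seen = np.zeros(n, dtype=bool)
            seen[s] = True
            frontier = [(s, 0.0)]
            while frontier:
                v, dv = frontier.pop()
                D[s, v] = dv
                for w, L in adj[v]:
                    if not seen[w]:
                        seen[w] = True
                        frontier.append((w, dv + L))
        return D


# ---------------------------------------------------------------------- #
def read_newick(text: str, default_branch_length: float | None = None) -> Phylogeny:
    """Parse a Newick string into a :class:`Phylogeny`."""
    return Phylogeny.from_newick(text, default_branch_length=default_branch_length)


def write_newick(tree: Phylogeny) -> str:
    return tree.to_newick()


def patristic_distances(tree: Phylogeny) -> np.ndarray:
    """Tip-by-tip path-length (patristic) distance matrix, tip_labels order."""
    C = tree.mrca_depth_matrix()
    d = np.diag(C)
    return d[:, None] + d[None, :] - 2.0 * C


def bm_covariance(tree: Phylogeny) -> np.ndarray:
    """Brownian-motion tip covariance: shared root-to-MRCA path lengths."""
    return tree.mrca_depth_matrix()


def ou_covariance(tree: Phylogeny, alpha: float, sigma2: float) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck tip covariance.

    V[i, j] = sigma2 / (2 alpha) * exp(-alpha * d_ij) with d_ij the
    patristic distance — the appropriate stationary form for a tree that
    is not ultrametric.  For alpha at or below a tiny floor the process is
    indistinguishable from drift and sigma2 * bm_covariance is returned
    (continuity at alpha = 0).
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be > 0")
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    if alpha <= OU_ALPHA_FLOOR:
        return sigma2 * bm_covariance(tree)
    D = patristic_distances(tree)
    return sigma2 / (2.0 * alpha) * np.exp(-alpha * D)
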