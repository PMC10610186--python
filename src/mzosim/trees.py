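"""Array-backed rooted phylogenies.

Trees are stored as flat preorder arrays (every parent index precedes its
children), which keeps depth computation, pruning and cophenetic-distance
assembly vectorizable for the multi-thousand-tip trees the simulation study
produces.  Newick reading/writing delegates to :mod:`dendropy`.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import dendropy
import numpy as np

__all__ = ["Phylogeny"]


class Phylogeny:
    """A rooted tree with branch lengths in time units (nominally My).

    Parameters
    ----------
    parent
        Integer array, ``parent[i]`` is the index of node *i*'s parent and
        ``parent[0] == -1`` marks the root.  Indices must be in preorder
        (``parent[i] < i`` for every non-root node).
    edge_length
        Branch length subtending each node (``edge_length[0]`` is ignored and
        stored as 0).  All lengths must be >= 0.
    labels
        Per-node labels; tips must carry unique non-empty strings, internal
        nodes may be ``None``.
    """

    __slots__ = ("parent", "edge_length", "labels", "_children", "_depths")

    def __init__(
        self,
        parent: Sequence[int],
        edge_length: Sequence[float],
        labels: Sequence[str | None],
    ) -> None:
        self.parent = np.asarray(parent, dtype=np.int64)
        self.edge_length = np.asarray(edge_length, dtype=np.float64).copy()
        self.labels = list(labels)
        n = self.parent.shape[0]
        if n == 0:
            raise ValueError("empty tree")
        if self.parent[0] != -1:
            raise ValueError("node 0 must be the root (parent -1)")
        if n > 1 and not np.all(self.parent[1:] < np.arange(1, n)):
            raise ValueError("nodes must be in preorder (parent index < child index)")
        if np.any(self.parent[1:] < 0):
            raise ValueError("exactly one root allowed")
        self.edge_length[0] = 0.0
        if np.any(~np.isfinite(self.edge_length)) or np.any(self.edge_length < 0):
            raise ValueError("branch lengths must be finite and >= 0")
        if len(self.labels) != n:
            raise ValueError("labels length mismatch")
        self._children: list[list[int]] | None = None
        self._depths: np.ndarray | None = None
        tips = [self.labels[i] for i in self.tip_indices()]
        if any(t is None or t == "" for t in tips):
            raise ValueError("every tip must be labelled")
        if len(set(tips)) != len(tips):
            raise ValueError("tip labels must be unique")

    # -- basic structure ----------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.parent.shape[0]

    def children(self) -> list[list[int]]:
        if self._children is None:
            ch: list[list[int]] = [[] for _ in range(self.n_nodes)]
            for i in range(1, self.n_nodes):
                ch[self.parent[i]].append(i)
            self._children = ch
        return self._children

    def tip_mask(self) -> np.ndarray:
        mask = np.ones(self.n_nodes, dtype=bool)
        mask[self.parent[self.parent >= 0]] = False
        return mask

    def tip_indices(self) -> np.ndarray:
        return np.flatnonzero(self.tip_mask())

    @property
    def n_tips(self) -> int:
        return int(self.tip_mask().sum())

    def tip_labels(self) -> list[str]:
        return [self.labels[i] for i in self.tip_indices()]

    def is_binary(self) -> bool:
        return all(len(c) in (0, 2) for c in self.children())

    def has_polytomies(self) -> bool:
        return any(len(c) > 2 for c in self.children())

    # -- geometry ------------------------------------------------------------

    def depths(self) -> np.ndarray:
        """Distance from the root to every node."""
        if self._depths is None:
            d = np.zeros(self.n_nodes)
            par, ln = self.parent, self.edge_length
            for i in range(1, self.n_nodes):
                d[i] = d[par[i]] + ln[i]
            self._depths = d
        return self._depths

    def height(self) -> float:
        return float(self.depths().max())

    def tip_depths(self) -> np.ndarray:
        return self.depths()[self.tip_indices()]

    def is_ultrametric(self, rtol: float = 1e-9) -> bool:
        td = self.tip_depths()
        h = td.max()
        if h == 0:
            return True
        return bool((td.max() - td.min()) / h <= rtol)

    def extant_tip_indices(self, rtol: float = 1e-8) -> np.ndarray:
        """Tips whose depth equals the tree height (within relative tolerance)."""
        tips = self.tip_indices()
        d = self.depths()[tips]
        h = self.height()
        return tips[d >= h - rtol * max(h, 1.0)]

    # -- construction helpers ------------------------------------------------

    @classmethod
    def from_children(
        cls,
        children: Sequence[Iterable[int]],
        edge_length: Sequence[float],
        labels: Sequence[str | None],
        root: int = 0,
    ) -> "Phylogeny":
        """Build from an arbitrary-order children-list representation."""
        n = len(children)
        order = np.empty(n, dtype=np.int64)
        new_index = np.empty(n, dtype=np.int64)
        stack = [root]
        k = 0
        while stack:
            node = stack.pop()
            order[k] = node
            new_index[node] = k
            k += 1
            stack.extend(reversed(list(children[node])))
        if k != n:
            raise ValueError("children lists do not form a single rooted tree")
        parent_old = np.full(n, -1, dtype=np.int64)
        for u in range(n):
            for v in children[u]:
                parent_old[v] = u
        parent = np.array(
            [-1 if parent_old[order[i]] < 0 else new_index[parent_old[order[i]]] for i in range(n)]
        )
        lengths = np.asarray(edge_length, dtype=np.float64)[order]
        labs = [labels[i] for i in order]
        return cls(parent, lengths, labs)

    # -- dendropy / newick interop -------------------------------------------

    def to_dendropy(self) -> dendropy.Tree:
        taxon_namespace = dendropy.TaxonNamespace()
        tree = dendropy.Tree(taxon_namespace=taxon_namespace)
        nodes = [dendropy.Node() for _ in range(self.n_nodes)]
        for i in range(1, self.n_nodes):
            nodes[self.parent[i]].add_child(nodes[i])
        for i, nd in enumerate(nodes):
            nd.edge.length = float(self.edge_length[i]) if i else None
            if not nd.child_nodes():
                nd.taxon = taxon_namespace.new_taxon(label=self.labels[i])
        tree.seed_node = nodes[0]
        return tree

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "Phylogeny":
        nodes = list(tree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        parent = np.array(
            [-1 if nd.parent_node is None else index[id(nd.parent_node)] for nd in nodes]
        )
        lengths = np.array(
            [0.0 if nd.edge.length is None else float(nd.edge.length) for nd in nodes]
        )
        labels: list[str | None] = []
        for nd in nodes:
            if nd.is_leaf():
                labels.append(nd.taxon.label if nd.taxon is not None else nd.label)
            else:
                labels.append(nd.label)
        return cls(parent, lengths, labels)

    def to_newick(self) -> str:
        return self.to_dendropy().as_string(schema="newick", suppress_rooting=True).strip()

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        tree = dendropy.Tree.get(data=newick, schema="newick")
        return cls.from_dendropy(tree)

    def write(self, path, schema: str = "newick") -> None:
        self.to_dendropy().write(path=str(path), schema=schema, suppress_rooting=True)

    @classmethod
    def read(cls, path, schema: str = "newick") -> "Phylogeny":
        return cls.from_dendropy(dendropy.Tree.get(path=str(path), schema=schema))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<Phylogeny {self.n_tips} tips, {self.n_nodes} nodes, height {self.height():.3g}>"
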