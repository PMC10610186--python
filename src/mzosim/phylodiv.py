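"""Community phylogenetic diversity: cophenetic distances, MPD and MPD_ses.

MPD is the mean patristic distance over all unordered species pairs in a
community.  MPD_ses standardizes it against a richness-controlled null:
``n_null`` uniform random subsets of the same size drawn from a species pool
(for presence/absence data this is equivalent to a taxa-label shuffle of the
distance matrix restricted to the pool), giving
``ses = (observed - null_mean) / null_sd``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .trees import Phylogeny

__all__ = [
    "DistanceMatrix",
    "MPDResult",
    "cophenetic_matrix",
    "mpd",
    "null_mpd_samples",
    "mpd_ses",
    "resolve_polytomies",
]


class DistanceMatrix:
    """Symmetric patristic distance matrix with a species index."""

    __slots__ = ("values", "labels", "_index")

    def __init__(self, values: np.ndarray, labels: Sequence[str]) -> None:
        values = np.asarray(values, dtype=np.float64)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError("distance matrix must be square")
        if len(labels) != values.shape[0]:
            raise ValueError("label count does not match matrix size")
        self.values = values
        self.labels = list(labels)
        self._index = {l: i for i, l in enumerate(self.labels)}

    def __len__(self) -> int:
        return len(self.labels)

    def positions(self, species: Iterable[str]) -> np.ndarray:
        idx = self._index
        missing = [s for s in species if s not in idx]
        if missing:
            raise KeyError(f"species not in distance matrix: {sorted(missing)[:10]}")
        return np.fromiter((idx[s] for s in species), dtype=np.int64)

    def __contains__(self, species: str) -> bool:
        return species in self._index

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def cophenetic_matrix(tree: Phylogeny) -> DistanceMatrix:
    """All pairwise tip-to-tip path-length (patristic) distances.

    For tips i, j with most recent common ancestor a:
    d(i, j) = depth(i) + depth(j) - 2 depth(a).  Assembled per internal node
    over cross-child tip blocks, O(n^2) overall but vectorized.
    """
    depths = tree.depths()
    tips = tree.tip_indices()
    n_tips = tips.size
    tip_pos = {int(t): p for p, t in enumerate(tips)}
    tip_depth = depths[tips]
    children = tree.children()
    D = np.zeros((n_tips, n_tips))
    tipsets: dict[int, np.ndarray] = {}
    for node in range(tree.n_nodes - 1, -1, -1):
        ch = children[node]
        if not ch:
            tipsets[node] = np.array([tip_pos[node]], dtype=np.int64)
            continue
        blocks = [tipsets.pop(c) for c in ch]
        dn = depths[node]
        for i in range(len(blocks)):
            for j in range(i + 1, len(blocks)):
                a, b = blocks[i], blocks[j]
                d = (tip_depth[a][:, None] + tip_depth[b][None, :]) - 2.0 * dn
                D[np.ix_(a, b)] = d
                D[np.ix_(b, a)] = d.T
        tipsets[node] = np.concatenate(blocks)
    labels = [tree.labels[i] for i in tips]
    return DistanceMatrix(D, labels)


def _pair_mean(values: np.ndarray, idx: np.ndarray) -> float:
    k = idx.size
    sub = values[np.ix_(idx, idx)]
    return float(sub.sum() / (k * (k - 1)))


def mpd(community: Iterable[str], dm: DistanceMatrix) -> float:
    """Mean pairwise distance over all unordered pairs (abundance-unweighted)."""
    idx = dm.positions(community)
    if idx.size < 2:
        raise ValueError("MPD needs at least 2 species")
    if np.unique(idx).size != idx.size:
        raise ValueError("community contains duplicate species")
    return _pair_mean(dm.values, idx)


def null_mpd_samples(
    dm: DistanceMatrix,
    pool: Sequence[str] | np.ndarray,
    k: int,
    n_null: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """MPD of ``n_null`` uniform random k-subsets of the pool."""
    pool_idx = pool if isinstance(pool, np.ndarray) else dm.positions(pool)
    if k > pool_idx.size:
        raise ValueError("community larger than pool")
    out = np.empty(n_null)
    values = dm.values
    for i in range(n_null):
        pick = pool_idx[rng.choice(pool_idx.size, size=k, replace=False)]
        out[i] = _pair_mean(values, pick)
    return out


@dataclass(frozen=True)
class MPDResult:
    observed_mpd: float
    null_mean: float
    null_sd: float
    ses: float
    rank_p: float
    n_null: int
    degenerate: bool = False


def mpd_ses(
    community: Iterable[str],
    dm: DistanceMatrix,
    pool: Sequence[str],
    n_null: int = 999,
    seed_or_rng=None,
    null_samples: np.ndarray | None = None,
) -> MPDResult:
    """Standardized effect size of MPD against a richness-controlled null.

    ``rank_p`` is the one-sided high-tail quantile ``(1 + #{null >= obs}) /
    (n_null + 1)``; the low tail is ``1 + 1/(n_null+1) - rank_p``.  If the
    null has zero spread (e.g. community == pool) the result is flagged
    degenerate with ses = 0.  Precomputed ``null_samples`` (e.g. shared
    across equally rich communities) may be supplied.
    """
    community = list(community)
    pool_set = set(pool)
    missing = [s for s in community if s not in pool_set]
    if missing:
        raise ValueError(f"community species not in pool: {sorted(missing)[:10]}")
    observed = mpd(community, dm)
    if null_samples is None:
        if n_null < 99:
            raise ValueError("n_null must be >= 99")
        rng = (
            seed_or_rng
            if isinstance(seed_or_rng, np.random.Generator)
            else np.random.default_rng(seed_or_rng)
        )
        null_samples = null_mpd_samples(dm, list(pool), len(community), n_null, rng)
    n_null = len(null_samples)
    null_mean = float(null_samples.mean())
    null_sd = float(null_samples.std(ddof=1))
    rank_p = float((1 + np.sum(null_samples >= observed - 1e-12)) / (n_null + 1))
    if null_sd <= 1e-12 * max(abs(null_mean), 1.0) or not np.isfinite(null_sd):
        return MPDResult(observed, null_mean, 0.0, 0.0, rank_p, n_null, degenerate=True)
    ses = (observed - null_mean) / null_sd
    return MPDResult(observed, null_mean, null_sd, float(ses), rank_p, n_null)


def resolve_polytomies(tree: Phylogeny, seed_or_rng=None) -> Phylogeny:
    """Randomly resolve every multifurcation into binary splits.

    Each multifurcation is replaced by a topology drawn uniformly from the
    (2m-3)!! labelled rooted binary arrangements of its m child subtrees,
    built by sequential random attachment of each child to any edge
    (including the stem) of the growing local tree.  All inserted edges have
    length 0, so every pairwise patristic distance is preserved exactly.
    """
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    children = [list(c) for c in tree.children()]
    lengths = list(tree.edge_length)
    labels: list[str | None] = list(tree.labels)
    parent = list(tree.parent)

    def new_node(par: int) -> int:
        children.append([])
        lengths.append(0.0)
        labels.append(None)
        parent.append(par)
        children[par].append(len(children) - 1)
        return len(children) - 1

    STEM = -1  # sentinel: the edge above the local arrangement's root
    for node in range(tree.n_nodes):
        ch = children[node]
        if len(ch) <= 2:
            continue
        items = [ch[i] for i in rng.permutation(len(ch))]
        # grow a rooted binary arrangement of the child subtrees under `node`;
        # `local_edges` holds the node below each proper edge, plus STEM
        children[node] = items[:2]
        local_edges: list[int] = [items[0], items[1], STEM]
        for item in items[2:]:
            below = local_edges[int(rng.integers(len(local_edges)))]
            if below == STEM:
                joint = new_node(node)  # appended to children[node]
                tops = [c for c in children[node] if c != joint]
                children[joint] = tops
                for c in tops:
                    parent[c] = joint
                children[node] = [joint, item]
            else:
                par = parent[below]
                joint = new_node(par)  # appended to children[par]
                children[par].remove(below)
                children[joint] = [below, item]
                parent[below] = joint
            parent[item] = joint if below != STEM else node
            local_edges.extend([item, joint])
    return Phylogeny.from_children(children, lengths, labels, root=0)
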