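"""Constant-rate birth-death phylogeny simulation.

Forward Gillespie simulation of a birth-death process in which every extant
lineage independently waits an exponential time at total rate ``lambda + mu``
and then either bifurcates (probability ``lambda/(lambda+mu)``) or goes
extinct.  The taxa-stop convention cuts the tree at the instant the extant
lineage count first reaches the target N ("simple stop", no GSA resampling);
downstream analyses condition on N, for which any stopping-rule bias is
irrelevant.  Branch lengths are nominally in millions of years, matching
rates quoted per lineage per My.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trees import Phylogeny

__all__ = [
    "BirthDeathParams",
    "CladeExtinctionError",
    "simulate_birth_death",
    "simulate_birth_death_for_time",
    "prune_extinct",
    "lineage_through_time",
]


class CladeExtinctionError(RuntimeError):
    """The whole clade died before reaching the target size in every attempt."""


@dataclass(frozen=True)
class BirthDeathParams:
    """Parameters of the taxa-stop birth-death simulation.

    speciation_rate and extinction_rate are per-lineage per-My; n_tips is the
    extant tip count at which the simulation is cut.
    """

    speciation_rate: float = 0.5
    extinction_rate: float = 0.05
    n_tips: int = 10_000
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.speciation_rate > 0:
            raise ValueError("speciation_rate must be > 0")
        if not 0 <= self.extinction_rate < self.speciation_rate:
            raise ValueError("extinction_rate must satisfy 0 <= mu < lambda")
        if self.n_tips < 2:
            raise ValueError("n_tips must be >= 2")


def _as_rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def _gillespie(
    rng: np.random.Generator,
    lam: float,
    mu: float,
    *,
    n_stop: int | None = None,
    t_stop: float | None = None,
):
    """Run one forward pass; returns (parent, t_start, t_end) or None if the
    clade went fully extinct before the stop condition."""
    total = lam + mu
    p_birth = lam / total
    parent = [-1]
    t_start = [0.0]
    t_end = [np.nan]
    active = [0]
    t = 0.0
    n_alive = 1
    while True:
        if n_stop is not None and n_alive >= n_stop:
            break
        if n_alive == 0:
            return None
        t += rng.exponential(1.0 / (n_alive * total))
        if t_stop is not None and t >= t_stop:
            t = t_stop
            break
        pos = int(rng.integers(n_alive))
        node = active[pos]
        t_end[node] = t
        if rng.random() < p_birth:
            j = len(parent)
            parent.extend((node, node))
            t_start.extend((t, t))
            t_end.extend((np.nan, np.nan))
            active[pos] = j
            active.append(j + 1)
            n_alive += 1
        else:
            active[pos] = active[-1]
            active.pop()
            n_alive -= 1
    for node in active:
        t_end[node] = t
    return np.array(parent), np.array(t_start), np.array(t_end)


def _tables_to_tree(parent, t_start, t_end) -> Phylogeny:
    """Convert simulation tables to a crown Phylogeny (stem of the initial
    lineage dropped; unary initial node suppressed)."""
    lengths = t_end - t_start
    n = len(parent)
    labels: list[str | None] = [None] * n
    tip = np.ones(n, dtype=bool)
    tip[parent[parent >= 0]] = False
    k = 0
    for i in range(n):
        if tip[i]:
            k += 1
            labels[i] = f"t{k}"
    tree = Phylogeny(parent, lengths, labels)
    return tree


def simulate_birth_death(
    params: BirthDeathParams,
    *,
    rng: np.random.Generator | None = None,
    max_retries: int = 100,
) -> Phylogeny:
    """Simulate a birth-death tree with exactly ``params.n_tips`` extant tips.

    The returned tree retains extinct tips (prune with :func:`prune_extinct`).
    If the clade goes extinct before reaching N, the attempt is retried with
    fresh draws from the same stream, up to ``max_retries`` attempts.
    """
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    for _ in range(max_retries):
        out = _gillespie(
            rng, params.speciation_rate, params.extinction_rate, n_stop=params.n_tips
        )
        if out is not None:
            return _tables_to_tree(*out)
    raise CladeExtinctionError(
        f"clade extinct in all {max_retries} attempts "
        f"(lambda={params.speciation_rate}, mu={params.extinction_rate})"
    )


def simulate_birth_death_for_time(
    speciation_rate: float,
    extinction_rate: float,
    duration: float,
    seed_or_rng=None,
) -> Phylogeny | None:
    """Grow a single lineage for a fixed time (no taxa stop).

    Returns ``None`` if the clade went extinct before ``duration`` or if no
    event occurred (a single unbranched lineage has no tree representation
    here); extant tips are the tips at depth == tree height.
    """
    rng = _as_rng(seed_or_rng)
    out = _gillespie(rng, speciation_rate, extinction_rate, t_stop=duration)
    if out is None or len(out[0]) < 3:
        return None
    return _tables_to_tree(*out)


def count_extant_after_time(
    speciation_rate: float, extinction_rate: float, duration: float, seed_or_rng=None
) -> int:
    """Number of lineages alive after growing one lineage for a fixed time."""
    rng = _as_rng(seed_or_rng)
    out = _gillespie(rng, speciation_rate, extinction_rate, t_stop=duration)
    if out is None:
        return 0
    parent, t_start, t_end = out
    tip = np.ones(len(parent), dtype=bool)
    tip[parent[parent >= 0]] = False
    return int(np.sum(tip & (t_end >= duration - 1e-12)))


def prune_extinct(tree: Phylogeny, rtol: float = 1e-8) -> Phylogeny:
    """Drop extinct tips (depth < tree height) and suppress unary nodes,
    summing branch lengths so root-to-tip paths of extant tips are preserved.
    """
    extant = tree.extant_tip_indices(rtol=rtol)
    if extant.size < 2:
        raise ValueError("fewer than 2 extant tips; nothing to prune to")
    n = tree.n_nodes
    keep = np.zeros(n, dtype=bool)
    keep[extant] = True
    par = tree.parent
    # propagate keep flags rootward (children come after parents in preorder)
    for i in range(n - 1, 0, -1):
        if keep[i]:
            keep[par[i]] = True
    children = [[] for _ in range(n)]
    for i in range(1, n):
        if keep[i]:
            children[par[i]].append(i)
    # find new root: descend through unary kept nodes from old root
    root = 0
    while len(children[root]) == 1:
        root = children[root][0]
    new_parent: list[int] = [-1]
    new_length: list[float] = [0.0]
    new_labels: list[str | None] = [tree.labels[root]]
    stack = [(c, 0) for c in reversed(children[root])]
    while stack:
        node, new_par = stack.pop()
        length = tree.edge_length[node]
        while len(children[node]) == 1:  # suppress unary chain
            child = children[node][0]
            length += tree.edge_length[child]
            node = child
        idx = len(new_parent)
        new_parent.append(new_par)
        new_length.append(length)
        new_labels.append(tree.labels[node])
        stack.extend((c, idx) for c in reversed(children[node]))
    return Phylogeny(new_parent, new_length, new_labels)


def lineage_through_time(tree: Phylogeny) -> tuple[np.ndarray, np.ndarray]:
    """(times, counts) of the lineage-through-time curve of an extant-only
    tree: number of lineages just after each internal-node depth."""
    ch = tree.children()
    depths = tree.depths()
    internal = np.array([i for i in range(tree.n_nodes) if len(ch[i]) > 0])
    splits = np.sort(depths[internal])
    counts = 1 + np.arange(1, len(splits) + 1)
    return splits, counts.astype(float)
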