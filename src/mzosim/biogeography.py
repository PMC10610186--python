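"""Biogeographic regions and continuous-time Markov evolution of ranges.

Species occupy exactly one of four regions — tropical lowlands (TrL),
tropical highlands (TrH), temperate lowlands (TeL), temperate highlands
(TeH).  TrH, TeL and TeH share a cold/seasonal climate class; TrL is
warm/wet.  The region is treated as a discrete trait evolving along the
phylogeny under a rate matrix Q in which moves between climatically similar
regions are faster than moves between dissimilar ones; the two scenarios
(single tropical origin vs. two zones of origin) share Q and differ only in
how the root of the tree is constructed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .trees import Phylogeny
from .treesim import BirthDeathParams, simulate_birth_death, prune_extinct

__all__ = [
    "Region",
    "REGIONS",
    "TransitionModel",
    "ScenarioConfig",
    "build_transition_model",
    "simulate_regions",
    "build_scenario",
    "join_trees",
]


class Region(str, Enum):
    TrL = "TrL"
    TrH = "TrH"
    TeL = "TeL"
    TeH = "TeH"

    @property
    def latitude_zone(self) -> str:
        return "tropical" if self in (Region.TrL, Region.TrH) else "temperate"

    @property
    def elevation_zone(self) -> str:
        return "lowland" if self in (Region.TrL, Region.TeL) else "highland"

    @property
    def climate_class(self) -> str:
        return "warm_wet" if self is Region.TrL else "cold_seasonal"

    @property
    def latitude_code(self) -> int:
        """0 = tropical, 1 = temperate."""
        return 0 if self.latitude_zone == "tropical" else 1

    @property
    def elevation_code(self) -> int:
        """0 = lowland, 1 = highland."""
        return 0 if self.elevation_zone == "lowland" else 1


REGIONS: tuple[Region, ...] = (Region.TrL, Region.TrH, Region.TeL, Region.TeH)
_INDEX = {r: i for i, r in enumerate(REGIONS)}

# Dispersal corridors: lowland latitudinal exchange and within-latitude
# elevational exchange.  TrL<->TeL and TrL<->TrH cross climate classes
# (slow); TeL<->TeH and TrH<->TeH stay within the cold/seasonal class (fast).
_ALLOWED_MOVES = (
    (Region.TrL, Region.TeL),
    (Region.TrL, Region.TrH),
    (Region.TeL, Region.TeH),
    (Region.TrH, Region.TeH),
)


@dataclass(frozen=True)
class TransitionModel:
    """4x4 region-shift generator matrix (rows/cols ordered as REGIONS)."""

    scenario: str
    rate_similar: float
    rate_dissimilar: float
    include_trh_tel: bool = False
    matrix: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.scenario not in ("TNC", "MZO"):
            raise ValueError("scenario must be 'TNC' or 'MZO'")
        if self.rate_dissimilar < 0:
            raise ValueError("rates must be >= 0")
        if not self.rate_similar > self.rate_dissimilar:
            raise ValueError("rate_similar must exceed rate_dissimilar")
        q = np.zeros((4, 4))
        moves = _ALLOWED_MOVES + ((Region.TrH, Region.TeL),) if self.include_trh_tel else _ALLOWED_MOVES
        for a, b in moves:
            rate = (
                self.rate_similar
                if a.climate_class == b.climate_class
                else self.rate_dissimilar
            )
            q[_INDEX[a], _INDEX[b]] = rate
            q[_INDEX[b], _INDEX[a]] = rate
        np.fill_diagonal(q, -q.sum(axis=1))
        object.__setattr__(self, "matrix", q)

    def rate(self, a: Region, b: Region) -> float:
        return float(self.matrix[_INDEX[a], _INDEX[b]])

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario,
            "rate_similar": self.rate_similar,
            "rate_dissimilar": self.rate_dissimilar,
            "regions": [r.value for r in REGIONS],
            "matrix": self.matrix.tolist(),
        }


def build_transition_model(
    scenario: str,
    rate_similar: float = 0.1,
    rate_dissimilar: float = 0.01,
    include_trh_tel: bool = False,
) -> TransitionModel:
    """Build the shared TNC/MZO transition model.

    Both scenarios use the same allowed-move set; the scenario tag records
    which root construction :func:`build_scenario` will apply.  The default
    10:1 similar:dissimilar ratio keeps cross-climate colonization rare while
    populating all four regional pools.
    """
    return TransitionModel(scenario, rate_similar, rate_dissimilar, include_trh_tel)


def _simulate_states(
    tree: Phylogeny,
    q: np.ndarray,
    root_states: dict[int, int],
    rng: np.random.Generator,
    count_events: bool = False,
):
    """CTMC simulation down the tree; nodes in ``root_states`` start fresh at
    the given state with no evolution on their own stem edge."""
    n = tree.n_nodes
    state = np.full(n, -1, dtype=np.int64)
    n_events = 0
    par, ln = tree.parent, tree.edge_length
    # per-state embedded jump distributions, precomputed
    for i in range(n):
        if i in root_states:
            state[i] = root_states[i]
            continue
        s = int(state[par[i]])
        t = 0.0
        length = ln[i]
        while True:
            rate = -q[s, s]
            if rate <= 0.0:
                break
            t += rng.exponential(1.0 / rate)
            if t >= length:
                break
            probs = q[s].copy()
            probs[s] = 0.0
            probs /= rate
            s = int(rng.choice(4, p=probs))
            n_events += 1
        state[i] = s
    if count_events:
        return state, n_events
    return state


def simulate_regions(
    tree: Phylogeny,
    model: TransitionModel,
    root_state: Region = Region.TrL,
    seed_or_rng=None,
    return_event_count: bool = False,
):
    """Simulate region identity along every edge of an extant-only tree.

    Returns a dict mapping tip label -> :class:`Region` (and the total number
    of shift events if requested).
    """
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    out = _simulate_states(
        tree, model.matrix, {0: _INDEX[root_state]}, rng, count_events=return_event_count
    )
    state, n_events = out if return_event_count else (out, None)
    tips = tree.tip_indices()
    states = {tree.labels[i]: REGIONS[state[i]] for i in tips}
    if return_event_count:
        return states, n_events
    return states


@dataclass(frozen=True)
class ScenarioConfig:
    """Full configuration of one simulated diversification scenario."""

    scenario: str = "TNC"
    n_tips: int = 10_000
    speciation_rate: float = 0.5
    extinction_rate: float = 0.05
    rate_similar: float = 0.1
    rate_dissimilar: float = 0.01
    tropical_fraction: float = 0.75
    n_communities_per_region: int = 10
    sampling_fraction: float = 0.10
    n_null: int = 999
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.scenario not in ("TNC", "MZO"):
            raise ValueError("scenario must be 'TNC' or 'MZO'")
        if self.scenario == "MZO" and self.n_tips < 8:
            raise ValueError("MZO scenarios need n_tips >= 8 (>=2 tips per clade)")
        if not 0 < self.tropical_fraction < 1:
            raise ValueError("tropical_fraction must be in (0, 1)")

    def transition_model(self) -> TransitionModel:
        return build_transition_model(self.scenario, self.rate_similar, self.rate_dissimilar)


def join_trees(t1: Phylogeny, t2: Phylogeny) -> tuple[Phylogeny, int, int]:
    """Join two ultrametric trees at a new root.

    The deeper crown defines the join depth: that subtree's stem has length 0
    and the shallower subtree's stem is extended so both crowns are
    contemporaneous and the joined tree is ultrametric.  Returns the joined
    tree and the (new) node indices of the two subtree roots.
    """
    h1, h2 = t1.height(), t2.height()
    h = max(h1, h2)
    n1 = t1.n_nodes
    parent = np.concatenate(([-1], t1.parent + 1, t2.parent + 1 + n1))
    parent[1] = 0
    parent[1 + n1] = 0
    lengths = np.concatenate(([0.0], t1.edge_length, t2.edge_length))
    lengths[1] = h - h1
    lengths[1 + n1] = h - h2
    labels = [None] + list(t1.labels) + list(t2.labels)
    return Phylogeny(parent, lengths, labels), 1, 1 + n1


def build_scenario(
    config: ScenarioConfig, *, rng: np.random.Generator | None = None
) -> tuple[Phylogeny, dict[str, Region]]:
    """Simulate a scenario: pruned phylogeny plus tip region states.

    TNC: one clade of N tips with all lineages rooted in TrL.  MZO: two
    independently simulated clades — round(0.75 N) tips rooted in TrL and the
    remainder rooted in TeL — joined at a new root; no region change is
    allowed on the artificial stem edges.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    model = config.transition_model()
    bd = dict(
        speciation_rate=config.speciation_rate, extinction_rate=config.extinction_rate
    )
    if config.scenario == "TNC":
        tree = prune_extinct(
            simulate_birth_death(BirthDeathParams(n_tips=config.n_tips, **bd), rng=rng)
        )
        states = _simulate_states(tree, model.matrix, {0: _INDEX[Region.TrL]}, rng)
    else:
        n_trop = round(config.tropical_fraction * config.n_tips)
        n_temp = config.n_tips - n_trop
        if min(n_trop, n_temp) < 2:
            raise ValueError("each MZO clade needs >= 2 tips")
        t_trop = prune_extinct(
            simulate_birth_death(BirthDeathParams(n_tips=n_trop, **bd), rng=rng)
        )
        t_temp = prune_extinct(
            simulate_birth_death(BirthDeathParams(n_tips=n_temp, **bd), rng=rng)
        )
        t_temp = _relabel(t_temp, offset=_max_tip_number(t_trop))
        tree, c_trop, c_temp = join_trees(t_trop, t_temp)
        states = _simulate_states(
            tree,
            model.matrix,
            {c_trop: _INDEX[Region.TrL], c_temp: _INDEX[Region.TeL]},
            rng,
        )
    tips = tree.tip_indices()
    return tree, {tree.labels[i]: REGIONS[states[i]] for i in tips}


def _max_tip_number(tree: Phylogeny) -> int:
    return max(int(l[1:]) for l in tree.tip_labels())


def _relabel(tree: Phylogeny, offset: int) -> Phylogeny:
    labels = [
        f"t{int(l[1:]) + offset}" if l is not None and l.startswith("t") else l
        for l in tree.labels
    ]
    return Phylogeny(tree.parent, tree.edge_length, labels)
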