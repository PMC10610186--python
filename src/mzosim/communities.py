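"""Regional species pools and random local-community sampling.

Every species belongs to exactly one regional pool (its simulated region).
From each pool a fixed number of local communities is drawn, each an
independent uniform random subset of a fixed fraction of the pool — 10
communities of 10% of the pool per region by default, 40 communities in all.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .biogeography import REGIONS, Region

__all__ = [
    "RegionalPool",
    "Community",
    "CommunitySet",
    "DegeneratePoolError",
    "regional_pools",
    "community_size",
    "sample_communities",
]


class DegeneratePoolError(ValueError):
    """A regional pool is too small to sample meaningful communities from."""

    def __init__(self, region: Region, size: int, minimum: int) -> None:
        self.region, self.size, self.minimum = region, size, minimum
        super().__init__(
            f"pool {region.value} has {size} species (< {minimum}); replicate degenerate"
        )


@dataclass(frozen=True)
class RegionalPool:
    region: Region
    species: tuple[str, ...]

    @property
    def size(self) -> int:
        return len(self.species)


@dataclass(frozen=True)
class Community:
    region: Region
    index: int
    species: tuple[str, ...]


@dataclass(frozen=True)
class CommunitySet:
    communities: tuple[Community, ...]
    sampling_fraction: float
    n_per_region: int

    def __iter__(self):
        return iter(self.communities)

    def __len__(self) -> int:
        return len(self.communities)

    def species_union(self) -> tuple[str, ...]:
        seen: set[str] = set()
        for c in self.communities:
            seen.update(c.species)
        return tuple(sorted(seen))

    def to_frame(self) -> pd.DataFrame:
        """Long format: one row per (region, community_id, species)."""
        rows = [
            (c.region.value, f"{c.region.value}_{c.index}", sp)
            for c in self.communities
            for sp in c.species
        ]
        return pd.DataFrame(rows, columns=["region", "community_id", "species"])

    def incidence(self) -> pd.DataFrame:
        """Binary community x species matrix."""
        long = self.to_frame()
        long["present"] = 1
        return (
            long.pivot_table(
                index="community_id", columns="species", values="present", fill_value=0
            )
            .astype(int)
        )


def regional_pools(states: dict[str, Region]) -> list[RegionalPool]:
    """Partition tip labels into the four regional pools (possibly empty)."""
    if not states:
        raise ValueError("no tip states supplied")
    buckets: dict[Region, list[str]] = {r: [] for r in REGIONS}
    for label, region in states.items():
        buckets[Region(region)].append(label)
    return [RegionalPool(r, tuple(sorted(buckets[r]))) for r in REGIONS]


def community_size(pool_size: int, fraction: float) -> int:
    """round(fraction * pool size), floored at 2 so MPD is defined."""
    return max(2, round(fraction * pool_size))


def sample_communities(
    pools: list[RegionalPool],
    n_per_region: int = 10,
    fraction: float = 0.10,
    seed_or_rng=None,
    min_pool: int = 20,
) -> CommunitySet:
    """Draw ``n_per_region`` independent uniform subsets from every pool.

    Communities within a pool are drawn independently and may overlap.  Any
    pool below ``min_pool`` species raises :class:`DegeneratePoolError`; at
    the study level such replicates are re-drawn with a fresh seed.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    for pool in pools:
        if pool.size < min_pool:
            raise DegeneratePoolError(pool.region, pool.size, min_pool)
    communities = []
    for pool in pools:
        species = np.asarray(pool.species, dtype=object)
        k = community_size(pool.size, fraction)
        for j in range(n_per_region):
            pick = rng.choice(pool.size, size=k, replace=False)
            communities.append(
                Community(pool.region, j, tuple(sorted(species[pick].tolist())))
            )
    return CommunitySet(tuple(communities), fraction, n_per_region)
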