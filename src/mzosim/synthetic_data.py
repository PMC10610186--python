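"""Synthetic inputs with the statistical structure the empirical stage assumes.

Two generators, each emitting a ground-truth JSON alongside the data so
recovery tests never re-derive constants:

* a synthetic Andean plot network — 245 plots spanning 7.1 N to 27.8 S and
  150-3511 m asl with 0.25-1 ha areas and MAT spanning 7.3-23.8 C — whose
  plot communities are drawn from a simulated two-origin (MZO) scenario tree
  with temperate-clade representation increasing with elevation and absolute
  latitude (so "does the pipeline detect the mechanism" is a meaningful
  end-to-end test);
* a height-vessel-diameter table with a biogeographic-origin column and a
  configurable log10 offset for temperate species.

The generators deliberately do not imitate real Andean taxonomic
composition or spatial autocorrelation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .biogeography import Region, ScenarioConfig, build_scenario
from .trees import Phylogeny

__all__ = [
    "NetworkGeneratorConfig",
    "NetworkData",
    "generate_network",
    "write_network",
    "generate_vessels",
    "write_vessels",
]

# Conversion gain from a target standardized MPD_ses slope to the linear
# mixing-weight coefficient per SD of the predictor.  Calibrated once,
# jointly with the default weight_intercept, so the default targets
# (0.24, 0.26) reproduce themselves through the full pipeline at n = 245
# plots; the low intercept keeps plots on the rising flank of the
# (non-monotonic) mix -> dispersion curve.  See docs/methods.md.
WEIGHT_GAIN = 0.13


@dataclass(frozen=True)
class NetworkGeneratorConfig:
    """Defaults emulate the scale and ranges of the Andean plot network."""

    n_plots: int = 245
    lat_range: tuple[float, float] = (-27.8, 7.1)
    elev_range: tuple[float, float] = (150.0, 3511.0)
    areas: tuple[float, ...] = (0.25, 0.5, 1.0)
    area_weights: tuple[float, ...] = (0.2, 0.25, 0.55)
    mat_range: tuple[float, float] = (7.3, 23.8)
    mat_noise_sd: float = 1.0
    scenario: str = "MZO"
    tree_n_tips: int = 1000
    effect_latitude: float = 0.24
    effect_elevation: float = 0.26
    weight_intercept: float = 0.15
    unidentified_fraction: float = 0.061
    base_richness: float = 30.0
    stems_per_ha: float = 160.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.lat_range[0] >= self.lat_range[1] or self.elev_range[0] >= self.elev_range[1]:
            raise ValueError("degenerate latitude/elevation range")
        if not 0 <= self.unidentified_fraction < 1:
            raise ValueError("unidentified_fraction must be in [0, 1)")
        if self.n_plots < 10:
            raise ValueError("n_plots must be >= 10")


@dataclass
class NetworkData:
    stems: pd.DataFrame
    meta: pd.DataFrame
    tree: Phylogeny
    truth: dict


def _zscore_pop(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std()


def generate_network(config: NetworkGeneratorConfig) -> NetworkData:
    """Generate (stems, meta, tree, truth) for one synthetic plot network.

    Each plot's species are drawn from the scenario tree: with probability w
    from the temperate-origin set, otherwise from the tropical set, where
    w is linear in the z-scored elevation and absolute latitude with
    coefficients ``WEIGHT_GAIN * effect``.  A weight outside [0, 1] for any
    plot means the requested effects are infeasible and raises ValueError.
    """
    rng = np.random.default_rng(config.seed)
    scen = ScenarioConfig(
        scenario=config.scenario, n_tips=config.tree_n_tips, seed=None
    )
    tree, states = build_scenario(scen, rng=rng)
    temperate_set = _temperate_affiliated(tree, states, config.scenario)
    tropical_set = sorted(set(states) - set(temperate_set))
    temperate_set = sorted(temperate_set)

    lat = rng.uniform(*config.lat_range, size=config.n_plots)
    elev = rng.uniform(*config.elev_range, size=config.n_plots)
    area = rng.choice(
        config.areas, size=config.n_plots, p=np.asarray(config.area_weights)
    )
    # MAT: cools with elevation (~5.5 C/km lapse) and towards high absolute
    # latitude, then rescaled affinely to span the configured range exactly.
    mat_raw = (
        26.0
        - 0.0055 * elev
        - 0.12 * np.abs(lat)
        + rng.normal(0.0, config.mat_noise_sd, size=config.n_plots)
    )
    lo, hi = config.mat_range
    mat = lo + (mat_raw - mat_raw.min()) * (hi - lo) / np.ptp(mat_raw)

    w = (
        config.weight_intercept
        + WEIGHT_GAIN * config.effect_elevation * _zscore_pop(elev)
        + WEIGHT_GAIN * config.effect_latitude * _zscore_pop(np.abs(lat))
    )
    if w.min() < 0.0 or w.max() > 1.0:
        raise ValueError(
            f"infeasible effect sizes: mixing weight spans [{w.min():.3f}, {w.max():.3f}]"
        )

    stem_rows = []
    meta_rows = []
    for p in range(config.n_plots):
        plot_id = f"P{p + 1:03d}"
        meta_rows.append(
            {
                "plot_id": plot_id,
                "lat": round(float(lat[p]), 4),
                "lon": round(float(rng.uniform(-79.0, -63.0)), 4),
                "elev_m": round(float(elev[p]), 1),
                "area_ha": float(area[p]),
                "mat_c": round(float(mat[p]), 2),
                "map_mm": round(float(rng.uniform(608.0, 4313.0)), 0),
            }
        )
        richness = max(5, int(rng.poisson(config.base_richness * area[p] ** 0.25)))
        n_temp = int(rng.binomial(richness, w[p]))
        n_temp = min(n_temp, len(temperate_set))
        n_trop = min(richness - n_temp, len(tropical_set))
        species = [
            temperate_set[i]
            for i in rng.choice(len(temperate_set), size=n_temp, replace=False)
        ] + [
            tropical_set[i]
            for i in rng.choice(len(tropical_set), size=n_trop, replace=False)
        ]
        n_stems = max(len(species), int(round(config.stems_per_ha * area[p])))
        # every species gets one stem; the remainder are uniform re-draws
        extra = rng.choice(len(species), size=n_stems - len(species), replace=True)
        stem_species = species + [species[i] for i in extra]
        dbh = 10.0 + rng.lognormal(mean=2.3, sigma=0.8, size=n_stems)
        unident = rng.random(n_stems) < config.unidentified_fraction
        for s in range(n_stems):
            stem_rows.append(
                {
                    "plot_id": plot_id,
                    "taxon": "indet" if unident[s] else stem_species[s],
                    "rank": "unidentified" if unident[s] else "species",
                    "dbh_cm": round(float(dbh[s]), 1),
                }
            )
    truth = {
        "scenario": config.scenario,
        "effect_latitude": config.effect_latitude,
        "effect_elevation": config.effect_elevation,
        "weight_gain": WEIGHT_GAIN,
        "weight_intercept": config.weight_intercept,
        "expected_sign_latitude": int(np.sign(config.effect_latitude)),
        "expected_sign_elevation": int(np.sign(config.effect_elevation)),
        "n_temperate_species": len(temperate_set),
        "n_tropical_species": len(tropical_set),
        "unidentified_fraction": config.unidentified_fraction,
        "mat_decreases_with_elevation": True,
    }
    return NetworkData(
        stems=pd.DataFrame(stem_rows),
        meta=pd.DataFrame(meta_rows),
        tree=tree,
        truth=truth,
    )


def _temperate_affiliated(
    tree: Phylogeny, states: dict[str, Region], scenario: str
) -> list[str]:
    """Tips counted as temperate-affiliated for community mixing.

    MZO: membership of the temperate-origin subclade (the clade whose stem
    hangs off the joined root and starts in TeL) — a deep phylogenetic
    split, which is the mechanism the pipeline should detect.  TNC: tips
    whose realized region is cold/seasonal.
    """
    if scenario == "MZO":
        children = tree.children()
        assert len(children[0]) == 2
        # temperate subclade is the second child by construction (higher labels)
        second = children[0][1]
        members: list[str] = []
        stack = [second]
        while stack:
            node = stack.pop()
            if not children[node]:
                members.append(tree.labels[node])
            stack.extend(children[node])
        return members
    return [label for label, r in states.items() if r != Region.TrL]


def write_network(data: NetworkData, out_dir) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "stems": out / "stems.csv",
        "meta": out / "meta.csv",
        "tree": out / "tree.nwk",
        "truth": out / "truth.json",
    }
    data.stems.to_csv(paths["stems"], index=False)
    data.meta.to_csv(paths["meta"], index=False)
    data.tree.write(paths["tree"])
    paths["truth"].write_text(json.dumps(data.truth, indent=2))
    return paths


def generate_vessels(
    n_per_group: int = 150,
    origin_offset_log10: float = -0.08,
    seed: int | None = None,
    height_range_m: tuple[float, float] = (2.0, 60.0),
    intercept_log10: float = 1.30,
    scaling_exponent: float = 0.45,
    noise_sd_log10: float = 0.10,
) -> tuple[pd.DataFrame, dict]:
    """Height-vessel table: log10 D = a + b log10 H + offset * I(temperate) + eps.

    Heights are log-uniform over ``height_range_m``; the temperate offset is
    in log10 um (negative = narrower vessels at equal height).
    """
    if n_per_group < 5:
        raise ValueError("need n >= 5 per origin group")
    rng = np.random.default_rng(seed)
    rows = []
    for origin in ("tropical", "temperate"):
        log_h = rng.uniform(*np.log10(height_range_m), size=n_per_group)
        offset = origin_offset_log10 if origin == "temperate" else 0.0
        log_d = (
            intercept_log10
            + scaling_exponent * log_h
            + offset
            + rng.normal(0.0, noise_sd_log10, size=n_per_group)
        )
        for i in range(n_per_group):
            rows.append(
                {
                    "species": f"{origin[:4]}_{i + 1}",
                    "height_m": round(float(10.0 ** log_h[i]), 2),
                    "vessel_um": round(float(10.0 ** log_d[i]), 2),
                    "origin": origin,
                }
            )
    truth = {
        "origin_offset_log10": origin_offset_log10,
        "intercept_log10": intercept_log10,
        "scaling_exponent": scaling_exponent,
        "noise_sd_log10": noise_sd_log10,
        "n_per_group": n_per_group,
    }
    return pd.DataFrame(rows), truth


def write_vessels(df: pd.DataFrame, truth: dict, out_dir) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"vessels": out / "vessels.csv", "truth": out / "vessel_truth.json"}
    df.to_csv(paths["vessels"], index=False)
    paths["truth"].write_text(json.dumps(truth, indent=2))
    return paths
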