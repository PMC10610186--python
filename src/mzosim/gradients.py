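"""Gradient regressions and replicate-level aggregation of the simulation study.

Per replicate: simulate a scenario, partition the tips into regional pools,
sample 40 local communities, compute MPD_ses for each against a shared null
pool, z-score the 40 values and regress them on the latitude factor
(tropical = 0, temperate = 1) and the elevation factor (lowland = 0,
highland = 1) by OLS.  Across replicates the slope distributions are
summarized (mean, one-sample t vs 0, fraction significant in the predicted
direction) and compared between scenarios with a two-sample
Kolmogorov-Smirnov test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .biogeography import ScenarioConfig, build_scenario
from .communities import DegeneratePoolError, regional_pools, sample_communities
from .phylodiv import cophenetic_matrix, mpd_ses, null_mpd_samples

__all__ = [
    "RegressionResult",
    "StudySummary",
    "ZeroVarianceError",
    "zscore",
    "ols_fit",
    "run_replicate",
    "run_study",
    "summarize_slopes",
    "compare_scenarios",
    "PREDICTED_SIGN",
]

PREDICTED_SIGN = {"TNC": -1, "MZO": +1}


class ZeroVarianceError(ValueError):
    """Input vector has no variance; the replicate is degenerate."""


def zscore(values) -> np.ndarray:
    """Standardize to mean 0, SD 1 (denominator n-1)."""
    x = np.asarray(values, dtype=np.float64)
    if x.size < 2:
        raise ValueError("zscore needs n >= 2")
    sd = x.std(ddof=1)
    if sd <= 0 or not np.isfinite(sd):
        raise ZeroVarianceError("zero variance in input")
    return (x - x.mean()) / sd


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    f_stat: float
    r_squared: float
    p_value: float
    n: int


def ols_fit(y, x) -> RegressionResult:
    """Simple OLS of y on x; F = t^2 for the slope, p from F(1, n-2)."""
    y = np.asarray(y, dtype=np.float64)
    x = np.asarray(x, dtype=np.float64)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("y and x must be 1-D of equal length")
    n = y.size
    if n < 3:
        raise ValueError("OLS needs n >= 3")
    if np.ptp(x) == 0:
        raise ZeroVarianceError("constant predictor")
    res = stats.linregress(x, y)
    r2 = res.rvalue**2
    if res.stderr > 0:
        f = (res.slope / res.stderr) ** 2
        p = float(stats.f.sf(f, 1, n - 2))
    else:  # perfect fit
        f, p = np.inf, 0.0
    return RegressionResult(
        float(res.slope), float(res.intercept), float(f), float(r2), p, n
    )


def run_replicate(
    config: ScenarioConfig,
    *,
    rng: np.random.Generator | None = None,
    null_pool: str = "shared",
    min_pool: int = 20,
) -> dict[str, float]:
    """One simulated dataset: 40 communities -> (slope_lat, p_lat, slope_elev, p_elev).

    ``null_pool`` selects the species pool for the MPD_ses null: "shared"
    (union of species over the 40 sampled communities, matching a taxa-label
    shuffle of the community dataset's distance matrix), "regional" (each
    community against its own regional pool) or "tree" (all simulated
    species).  Null draws are shared across communities of equal richness
    within the replicate, as a permutation-based null would share them.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    tree, states = build_scenario(config, rng=rng)
    pools = regional_pools(states)
    comms = sample_communities(
        pools,
        n_per_region=config.n_communities_per_region,
        fraction=config.sampling_fraction,
        seed_or_rng=rng,
        min_pool=min_pool,
    )
    dm = cophenetic_matrix(tree)
    if null_pool == "shared":
        shared = list(comms.species_union())
        pool_for = {c: shared for c in comms}
    elif null_pool == "tree":
        everything = sorted(states)
        pool_for = {c: everything for c in comms}
    elif null_pool == "regional":
        by_region = {p.region: list(p.species) for p in pools}
        pool_for = {c: by_region[c.region] for c in comms}
    else:
        raise ValueError("null_pool must be 'shared', 'regional' or 'tree'")
    null_cache: dict[tuple[int, int], np.ndarray] = {}
    ses = np.empty(len(comms))
    lat_code = np.empty(len(comms))
    elev_code = np.empty(len(comms))
    for i, comm in enumerate(comms):
        pool = pool_for[comm]
        key = (id(pool), len(comm.species))
        if key not in null_cache:
            null_cache[key] = null_mpd_samples(
                dm, dm.positions(pool), len(comm.species), config.n_null, rng
            )
        res = mpd_ses(comm.species, dm, pool, null_samples=null_cache[key])
        ses[i] = res.ses
        lat_code[i] = comm.region.latitude_code
        elev_code[i] = comm.region.elevation_code
    z = zscore(ses)
    lat = ols_fit(z, lat_code)
    elev = ols_fit(z, elev_code)
    return {
        "slope_lat": lat.slope,
        "p_lat": lat.p_value,
        "slope_elev": elev.slope,
        "p_elev": elev.p_value,
    }


@dataclass
class StudySummary:
    scenario: str
    n_reps: int
    replicates: pd.DataFrame = field(repr=False)
    latitude: dict = field(default_factory=dict)
    elevation: dict = field(default_factory=dict)
    n_degenerate_redraws: int = 0

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario,
            "n_reps": self.n_reps,
            "latitude": self.latitude,
            "elevation": self.elevation,
            "n_degenerate_redraws": self.n_degenerate_redraws,
        }


def summarize_slopes(
    slopes: np.ndarray, p_values: np.ndarray, predicted_sign: int
) -> dict:
    """Mean slope, one-sample two-sided t vs 0, and significance fractions.

    ``frac_significant`` requires two-sided p < 0.05 *and* the
    scenario-predicted sign; ``frac_significant_raw`` ignores the sign.
    A zero-spread slope distribution is flagged degenerate (t undefined).
    """
    slopes = np.asarray(slopes, dtype=np.float64)
    p_values = np.asarray(p_values, dtype=np.float64)
    out: dict = {
        "mean_slope": float(slopes.mean()),
        "sd_slope": float(slopes.std(ddof=1)) if slopes.size > 1 else float("nan"),
        "frac_significant_raw": float(np.mean(p_values < 0.05)),
        "frac_significant": float(
            np.mean((p_values < 0.05) & (np.sign(slopes) == predicted_sign))
        ),
        "predicted_sign": predicted_sign,
    }
    if slopes.size < 2 or out["sd_slope"] == 0:
        out.update(t_stat=float("nan"), t_p=float("nan"), degenerate=True)
    else:
        t, p = stats.ttest_1samp(slopes, 0.0)
        out.update(t_stat=float(t), t_p=float(p), degenerate=False)
    return out


def run_study(
    config: ScenarioConfig,
    n_reps: int = 1000,
    *,
    null_pool: str = "shared",
    max_redraws_per_rep: int = 20,
    progress: bool = False,
) -> StudySummary:
    """Repeat :func:`run_replicate` ``n_reps`` times and aggregate.

    Replicates with a degenerate (< 20 species) regional pool are re-drawn
    with a fresh child stream and counted in ``n_degenerate_redraws``.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    ss = np.random.SeedSequence(config.seed)
    rows = []
    n_redraws = 0
    for rep, child in enumerate(ss.spawn(n_reps)):
        sub_streams = iter(child.spawn(max_redraws_per_rep + 1))
        for _ in range(max_redraws_per_rep + 1):
            rng = np.random.default_rng(next(sub_streams))
            try:
                row = run_replicate(config, rng=rng, null_pool=null_pool)
                break
            except DegeneratePoolError:
                n_redraws += 1
        else:
            raise RuntimeError(
                f"replicate {rep}: degenerate pools in {max_redraws_per_rep + 1} draws"
            )
        row["rep"] = rep
        rows.append(row)
        if progress and (rep + 1) % 25 == 0:  # pragma: no cover
            print(f"  {config.scenario}: {rep + 1}/{n_reps} replicates", flush=True)
    reps = pd.DataFrame(rows)[["rep", "slope_lat", "p_lat", "slope_elev", "p_elev"]]
    sign = PREDICTED_SIGN[config.scenario]
    return StudySummary(
        scenario=config.scenario,
        n_reps=n_reps,
        replicates=reps,
        latitude=summarize_slopes(reps["slope_lat"].values, reps["p_lat"].values, sign),
        elevation=summarize_slopes(reps["slope_elev"].values, reps["p_elev"].values, sign),
        n_degenerate_redraws=n_redraws,
    )


def compare_scenarios(slopes_a, slopes_b) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov statistic and asymptotic p."""
    a = np.asarray(slopes_a, dtype=np.float64)
    b = np.asarray(slopes_b, dtype=np.float64)
    if a.size < 10 or b.size < 10:
        raise ValueError("need >= 10 slopes per scenario")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)
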