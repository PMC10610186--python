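"""Empirical plot-network pipeline and the height-vessel re-analysis.

Reads forest-inventory stem tables (one stem per row with plot id, taxon and
DBH) and plot metadata (coordinates, elevation, area, mean annual
temperature), applies the inventory filters (identified taxa, DBH >= 10 cm),
builds a binary plot x taxon community matrix against a user-supplied
phylogeny, computes MPD_ses per plot against the network-wide species pool,
removes the plot-area effect by residualization, and regresses the residuals
on absolute latitude, elevation or MAT.  A separate model asks whether
species of temperate biogeographic origin have narrower water-conducting
vessels than tropical species of the same plant height.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .gradients import RegressionResult, ols_fit, zscore
from .phylodiv import cophenetic_matrix, mpd_ses, null_mpd_samples, resolve_polytomies
from .trees import Phylogeny

__all__ = [
    "load_inventory",
    "filter_stems",
    "plot_communities",
    "plot_mpd_ses",
    "residualize",
    "empirical_gradient",
    "vessel_model",
    "run_pipeline",
]

STEM_COLUMNS = ["plot_id", "taxon", "rank", "dbh_cm"]
META_COLUMNS = ["plot_id", "lat", "lon", "elev_m", "area_ha", "mat_c"]
RANKS = {"species", "genus", "family", "unidentified"}


def load_inventory(stems_csv, meta_csv) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read and validate the stem and plot-metadata tables.

    Raises ``ValueError`` (with offending row numbers / plot ids) on missing
    columns, non-numeric fields, duplicate plot ids or stems referencing
    unknown plots.
    """
    stems = pd.read_csv(stems_csv, dtype={"plot_id": str, "taxon": str, "rank": str})
    meta = pd.read_csv(meta_csv, dtype={"plot_id": str})
    for df, cols, name in ((stems, STEM_COLUMNS, "stems"), (meta, META_COLUMNS, "meta")):
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ValueError(f"{name} table missing columns: {missing}")
    if meta["plot_id"].duplicated().any():
        dups = meta.loc[meta["plot_id"].duplicated(), "plot_id"].tolist()
        raise ValueError(f"duplicate plot_id in meta: {dups}")
    for col in ("lat", "lon", "elev_m", "area_ha", "mat_c"):
        vals = pd.to_numeric(meta[col], errors="coerce")
        bad = meta.index[vals.isna()].tolist()
        if bad:
            raise ValueError(f"non-numeric {col} in meta rows {bad}")
        meta[col] = vals
    if (meta["elev_m"] < 0).any():
        raise ValueError("negative elevation in meta")
    dbh = pd.to_numeric(stems["dbh_cm"], errors="coerce")
    bad = stems.index[dbh.isna() & stems["dbh_cm"].notna()].tolist()
    if bad:
        raise ValueError(f"non-numeric dbh_cm in stem rows {bad}")
    stems["dbh_cm"] = dbh
    bad_rank = stems.index[~stems["rank"].isin(RANKS)].tolist()
    if bad_rank:
        raise ValueError(f"unknown taxon rank in stem rows {bad_rank}")
    orphan = sorted(set(stems["plot_id"]) - set(meta["plot_id"]))
    if orphan:
        raise ValueError(f"stems reference unknown plot_id(s): {orphan}")
    return stems, meta


@dataclass(frozen=True)
class FilterReport:
    n_input: int
    n_kept: int
    n_unidentified: int
    n_small_dbh: int

    @property
    def retained_fraction(self) -> float:
        return self.n_kept / self.n_input if self.n_input else float("nan")


def filter_stems(stems: pd.DataFrame, min_dbh: float = 10.0) -> tuple[pd.DataFrame, FilterReport]:
    """Drop unidentified stems and stems below the DBH inclusion threshold."""
    unidentified = stems["rank"] == "unidentified"
    small = stems["dbh_cm"].notna() & (stems["dbh_cm"] < min_dbh)
    kept = stems.loc[~unidentified & ~small].copy()
    report = FilterReport(
        n_input=len(stems),
        n_kept=len(kept),
        n_unidentified=int(unidentified.sum()),
        n_small_dbh=int((small & ~unidentified).sum()),
    )
    return kept, report


@dataclass(frozen=True)
class CoverageReport:
    unmatched_taxa: tuple[str, ...]
    excluded_plots: tuple[str, ...]


def plot_communities(
    kept_stems: pd.DataFrame, tree_labels: set[str] | list[str]
) -> tuple[pd.DataFrame, CoverageReport]:
    """Binary plot x taxon incidence matrix restricted to taxa in the tree.

    Genus/family-level stems enter under their own terminal labels, which
    must exist as tips in the supplied tree.  Taxa absent from the tree are
    reported, and plots left with fewer than 2 matched taxa are excluded.
    """
    tree_labels = set(tree_labels)
    taxa = kept_stems["taxon"]
    matched = kept_stems.loc[taxa.isin(tree_labels)]
    unmatched = tuple(sorted(set(taxa) - tree_labels))
    inc = (
        matched.assign(present=1)
        .pivot_table(index="plot_id", columns="taxon", values="present", fill_value=0)
        .astype(int)
    )
    richness = inc.sum(axis=1)
    excluded = tuple(sorted(set(kept_stems["plot_id"]) - set(inc.index[richness >= 2])))
    inc = inc.loc[richness >= 2]
    return inc, CoverageReport(unmatched, excluded)


def plot_mpd_ses(
    incidence: pd.DataFrame,
    tree: Phylogeny,
    n_null: int = 999,
    seed_or_rng=None,
    n_resolutions: int = 1,
    pool: list[str] | None = None,
) -> pd.DataFrame:
    """Per-plot MPD_ses against a shared species pool.

    The null pool defaults to all matched taxa across the network so plot
    values are directly comparable.  If the tree has polytomies it is
    randomly resolved ``n_resolutions`` times and the per-plot values are
    averaged; with zero-length resolutions all resolutions give identical
    distances, so the default is a single resolution.  Null MPD samples are
    shared across plots of equal richness, as a matrix-permutation null
    would share them.
    """
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    if pool is None:
        pool = sorted(incidence.columns)
    trees = (
        [resolve_polytomies(tree, rng) for _ in range(n_resolutions)]
        if tree.has_polytomies()
        else [tree]
    )
    acc: list[pd.DataFrame] = []
    for t in trees:
        dm = cophenetic_matrix(t)
        pool_idx = dm.positions(pool)
        null_cache: dict[int, np.ndarray] = {}
        rows = []
        for plot_id, row in incidence.iterrows():
            species = list(row.index[row.values > 0])
            k = len(species)
            if k not in null_cache:
                null_cache[k] = null_mpd_samples(dm, pool_idx, k, n_null, rng)
            res = mpd_ses(species, dm, pool, null_samples=null_cache[k])
            rows.append(
                {
                    "plot_id": plot_id,
                    "richness": k,
                    "mpd": res.observed_mpd,
                    "null_mean": res.null_mean,
                    "null_sd": res.null_sd,
                    "ses": res.ses,
                    "rank_p": res.rank_p,
                }
            )
        acc.append(pd.DataFrame(rows).set_index("plot_id"))
    if len(acc) == 1:
        return acc[0].reset_index()
    mean = sum(df for df in acc) / len(acc)
    return mean.reset_index()


def residualize(values, area) -> tuple[np.ndarray, RegressionResult | None]:
    """Residuals of OLS of the diversity values on plot area.

    With < 3 plots or zero area variance the values are passed through
    centered, with ``None`` in place of the area fit.
    """
    y = np.asarray(values, dtype=np.float64)
    a = np.asarray(area, dtype=np.float64)
    if y.size < 3 or np.ptp(a) == 0:
        import warnings

        warnings.warn("cannot residualize on area; passing centered values through")
        return y - y.mean(), None
    fit = ols_fit(y, a)
    resid = y - (fit.intercept + fit.slope * a)
    return resid, fit


@dataclass(frozen=True)
class GradientResult:
    predictor: str
    raw: RegressionResult
    standardized_slope: float
    n: int

    def to_dict(self) -> dict:
        return {
            "predictor": self.predictor,
            "slope": self.raw.slope,
            "standardized_slope": self.standardized_slope,
            "f_stat": self.raw.f_stat,
            "r_squared": self.raw.r_squared,
            "p_value": self.raw.p_value,
            "n": self.n,
        }


def empirical_gradient(
    residuals, meta: pd.DataFrame, predictor: str, signed_latitude: bool = False
) -> GradientResult:
    """OLS of area-corrected MPD_ses on a geographic/climatic predictor.

    ``predictor`` is one of ``abs_latitude``, ``elevation``, ``mat``.
    Latitude enters as absolute degrees from the equator by default.  The
    standardized slope is the slope after z-scoring both variables (the
    Pearson correlation).
    """
    y = np.asarray(residuals, dtype=np.float64)
    if y.size < 10:
        raise ValueError("need >= 10 plots")
    if predictor == "abs_latitude":
        x = meta["lat"].abs().values if not signed_latitude else meta["lat"].values
    elif predictor == "elevation":
        x = meta["elev_m"].values
    elif predictor == "mat":
        x = meta["mat_c"].values
    else:
        raise ValueError("predictor must be 'abs_latitude', 'elevation' or 'mat'")
    raw = ols_fit(y, x)
    std = ols_fit(zscore(y), zscore(x))
    return GradientResult(predictor, raw, std.slope, raw.n)


@dataclass(frozen=True)
class VesselModelReport:
    n_tropical: int
    n_temperate: int
    origin_coef: float
    origin_f: float
    origin_p: float
    height_exponent: float
    resid_t: float
    resid_t_p: float

    def to_dict(self) -> dict:
        return self.__dict__.copy() if hasattr(self, "__dict__") else {
            k: getattr(self, k) for k in self.__dataclass_fields__
        }


def vessel_model(records: pd.DataFrame, min_per_group: int = 10) -> VesselModelReport:
    """Does biogeographic origin shift the height-vessel-diameter scaling?

    (a) OLS of log10(vessel diameter, um) on log10(height, m) plus a 0/1
    temperate-origin indicator; F and p for the origin term.  (b) residuals
    of the pooled log-log fit without origin, compared between origins with
    a pooled-variance two-sample t-test (t reported as tropical minus
    temperate).
    """
    required = {"species", "height_m", "vessel_um", "origin"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"vessel table missing columns: {sorted(missing)}")
    origins = set(records["origin"])
    if not {"tropical", "temperate"} <= origins:
        raise ValueError("both tropical and temperate origins must be present")
    counts = records["origin"].value_counts()
    if counts.min() < min_per_group:
        raise ValueError(f"need >= {min_per_group} species per origin group")
    if (records["height_m"] <= 0).any() or (records["vessel_um"] <= 0).any():
        raise ValueError("heights and vessel diameters must be positive")
    log_h = np.log10(records["height_m"].values)
    log_d = np.log10(records["vessel_um"].values)
    temperate = (records["origin"] == "temperate").astype(float).values
    X = sm.add_constant(np.column_stack([log_h, temperate]))
    fit = sm.OLS(log_d, X).fit()
    t_origin = fit.tvalues[2]
    pooled = stats.linregress(log_h, log_d)
    resid = log_d - (pooled.intercept + pooled.slope * log_h)
    t, p = stats.ttest_ind(
        resid[temperate == 0], resid[temperate == 1], equal_var=True
    )
    return VesselModelReport(
        n_tropical=int((temperate == 0).sum()),
        n_temperate=int((temperate == 1).sum()),
        origin_coef=float(fit.params[2]),
        origin_f=float(t_origin**2),
        origin_p=float(fit.pvalues[2]),
        height_exponent=float(fit.params[1]),
        resid_t=float(t),
        resid_t_p=float(p),
    )


def run_pipeline(
    stems_csv,
    meta_csv,
    tree_path,
    n_null: int = 999,
    seed: int | None = None,
    n_resolutions: int = 1,
    signed_latitude: bool = False,
    out_dir=None,
) -> dict:
    """Full empirical analysis from files to gradient regressions.

    Returns a dict with the filter/coverage reports, the per-plot table and
    the three gradient fits; optionally writes per-plot CSV and summary JSON.
    """
    stems, meta = load_inventory(stems_csv, meta_csv)
    tree = Phylogeny.read(tree_path)
    kept, filter_report = filter_stems(stems)
    incidence, coverage = plot_communities(kept, set(tree.tip_labels()))
    per_plot = plot_mpd_ses(
        incidence, tree, n_null=n_null, seed_or_rng=seed, n_resolutions=n_resolutions
    )
    meta_used = meta.set_index("plot_id").loc[per_plot["plot_id"]].reset_index()
    resid, area_fit = residualize(per_plot["ses"].values, meta_used["area_ha"].values)
    per_plot = per_plot.assign(ses_resid=resid)
    gradients = {
        name: empirical_gradient(resid, meta_used, name, signed_latitude=signed_latitude)
        for name in ("abs_latitude", "elevation", "mat")
    }
    result = {
        "filter_report": filter_report,
        "coverage": coverage,
        "per_plot": per_plot,
        "area_fit": area_fit,
        "gradients": gradients,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        per_plot.to_csv(out / "per_plot.csv", index=False)
        summary = {
            "filter": filter_report.__dict__
            if hasattr(filter_report, "__dict__")
            else {k: getattr(filter_report, k) for k in filter_report.__dataclass_fields__},
            "unmatched_taxa": list(coverage.unmatched_taxa),
            "excluded_plots": list(coverage.excluded_plots),
            "gradients": {k: v.to_dict() for k, v in gradients.items()},
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return result
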