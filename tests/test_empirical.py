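"""Empirical pipeline: loading, filtering, communities, gradients, vessels."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mzosim.empirical import (
    empirical_gradient,
    filter_stems,
    load_inventory,
    plot_communities,
    plot_mpd_ses,
    residualize,
    run_pipeline,
    vessel_model,
)
from mzosim.synthetic_data import (
    NetworkGeneratorConfig,
    generate_network,
    generate_vessels,
    write_network,
)


def toy_tables(tmp_path, stems: str, meta: str):
    s = tmp_path / "stems.csv"
    m = tmp_path / "meta.csv"
    s.write_text(stems)
    m.write_text(meta)
    return s, m


META3 = (
    "plot_id,lat,lon,elev_m,area_ha,mat_c,map_mm\n"
    "p1,-10.0,-70.0,500,1.0,20.0,1500\n"
    "p2,-12.0,-71.0,1500,0.5,15.0,1200\n"
    "p3,-14.0,-72.0,2500,1.0,10.0,1000\n"
)


class TestLoading:
    def test_well_formed_tables_parse(self, tmp_path):
        stems = "plot_id,taxon,rank,dbh_cm\np1,sp1,species,12\np2,sp2,genus,30\n"
        s, m = toy_tables(tmp_path, stems, META3)
        st, mt = load_inventory(s, m)
        assert len(st) == 2
        assert len(mt) == 3

    def test_orphan_plot_id_named_in_error(self, tmp_path):
        stems = "plot_id,taxon,rank,dbh_cm\npX,sp1,species,12\n"
        s, m = toy_tables(tmp_path, stems, META3)
        with pytest.raises(ValueError, match="pX"):
            load_inventory(s, m)

    def test_missing_column_rejected(self, tmp_path):
        stems = "plot_id,taxon,dbh_cm\np1,sp1,12\n"
        s, m = toy_tables(tmp_path, stems, META3)
        with pytest.raises(ValueError, match="rank"):
            load_inventory(s, m)

    def test_non_numeric_meta_rejected(self, tmp_path):
        bad_meta = META3.replace("500,1.0", "high,1.0")
        stems = "plot_id,taxon,rank,dbh_cm\np1,sp1,species,12\n"
        s, m = toy_tables(tmp_path, stems, bad_meta)
        with pytest.raises(ValueError, match="elev_m"):
            load_inventory(s, m)


class TestFiltering:
    def test_counts_by_reason(self):
        rows = [("p1", f"sp{i}", "species", 20.0) for i in range(8)]
        rows.append(("p1", "indet", "unidentified", 25.0))
        rows.append(("p1", "sp9", "species", 9.0))
        stems = pd.DataFrame(rows, columns=["plot_id", "taxon", "rank", "dbh_cm"])
        kept, report = filter_stems(stems)
        assert len(kept) == 8
        assert report.n_unidentified == 1
        assert report.n_small_dbh == 1
        assert report.n_input == report.n_kept + report.n_unidentified + report.n_small_dbh

    def test_identity_when_nothing_to_drop(self):
        stems = pd.DataFrame(
            [("p1", "sp1", "species", 15.0), ("p1", "sp2", "genus", 40.0)],
            columns=["plot_id", "taxon", "rank", "dbh_cm"],
        )
        kept, report = filter_stems(stems)
        assert len(kept) == 2 and report.retained_fraction == 1.0


class TestCommunities:
    def test_incidence_collapses_duplicates(self):
        stems = pd.DataFrame(
            [("p1", "A", "species", 15.0)] * 2 + [("p1", "B", "species", 12.0)],
            columns=["plot_id", "taxon", "rank", "dbh_cm"],
        )
        inc, cov = plot_communities(stems, {"A", "B"})
        assert inc.loc["p1"].to_dict() == {"A": 1, "B": 1}

    def test_unmatched_taxa_reported_and_thin_plots_excluded(self):
        stems = pd.DataFrame(
            [
                ("p1", "A", "species", 15.0),
                ("p1", "B", "species", 15.0),
                ("p2", "A", "species", 15.0),
                ("p2", "Z", "species", 15.0),
            ],
            columns=["plot_id", "taxon", "rank", "dbh_cm"],
        )
        inc, cov = plot_communities(stems, {"A", "B"})
        assert cov.unmatched_taxa == ("Z",)
        assert cov.excluded_plots == ("p2",)
        assert list(inc.index) == ["p1"]


class TestResidualize:
    def test_orthogonal_to_area(self, rng):
        area = rng.choice([0.25, 0.5, 1.0], size=60)
        y = 0.5 - 0.8 * area + rng.normal(0, 0.3, size=60)
        resid, fit = residualize(y, area)
        assert resid.mean() == pytest.approx(0.0, abs=1e-10)
        assert np.sum(resid * (area - area.mean())) == pytest.approx(0.0, abs=1e-8)
        assert fit.slope < 0  # injected negative area effect recovered

    def test_no_area_variance_passes_through_centered(self):
        y = np.array([1.0, 2.0, 3.0])
        with pytest.warns(UserWarning):
            resid, fit = residualize(y, np.ones(3))
        assert fit is None
        assert resid == pytest.approx(y - 2.0)


@pytest.fixture(scope="module")
def network(tmp_path_factory):
    data = generate_network(NetworkGeneratorConfig(seed=101))
    paths = write_network(data, tmp_path_factory.mktemp("net"))
    return data, paths


class TestNetworkPipeline:
    def test_recovers_generator_truth(self, network):
        data, paths = network
        result = run_pipeline(
            paths["stems"], paths["meta"], paths["tree"], n_null=199, seed=1
        )
        for name, eff in (
            ("abs_latitude", data.truth["effect_latitude"]),
            ("elevation", data.truth["effect_elevation"]),
        ):
            g = result["gradients"][name]
            assert np.sign(g.standardized_slope) == np.sign(eff)
            assert g.raw.p_value < 0.05
        # MAT decreases with elevation, so its slope has the opposite sign
        assert np.sign(result["gradients"]["mat"].standardized_slope) == -np.sign(
            result["gradients"]["elevation"].standardized_slope
        )

    def test_shuffled_predictor_kills_the_signal(self, network, rng):
        data, paths = network
        stems, meta = load_inventory(paths["stems"], paths["meta"])
        from mzosim.trees import Phylogeny

        tree = Phylogeny.read(paths["tree"])
        kept, _ = filter_stems(stems)
        inc, _ = plot_communities(kept, set(tree.tip_labels()))
        per_plot = plot_mpd_ses(inc, tree, n_null=99, seed_or_rng=rng)
        meta_used = meta.set_index("plot_id").loc[per_plot["plot_id"]].reset_index()
        resid, _ = residualize(per_plot["ses"].values, meta_used["area_ha"].values)
        slopes = []
        for _ in range(30):
            shuffled = meta_used.assign(elev_m=rng.permutation(meta_used["elev_m"].values))
            slopes.append(
                empirical_gradient(resid, shuffled, "elevation").standardized_slope
            )
        # mean shuffled slope ~ 0, well below the real one
        real = empirical_gradient(resid, meta_used, "elevation").standardized_slope
        assert abs(np.mean(slopes)) < 0.05
        assert real > np.percentile(slopes, 97)


class TestVesselModel:
    def test_null_offset_gives_small_origin_term(self):
        df, _ = generate_vessels(n_per_group=150, origin_offset_log10=0.0, seed=4)
        report = vessel_model(df)
        assert report.origin_p > 0.01
        assert abs(report.resid_t) < 3.0

    def test_negative_offset_recovered(self):
        df, truth = generate_vessels(n_per_group=200, origin_offset_log10=-0.1, seed=5)
        report = vessel_model(df)
        assert report.origin_coef < 0
        assert report.origin_p < 0.001
        assert report.resid_t > 0  # tropical residuals larger (wider vessels)

    def test_t_statistic_matches_pooled_formula_oracle(self):
        rows = []
        heights = [3, 5, 8, 12, 20, 30]
        for i, h in enumerate(heights):
            rows.append((f"tr{i}", h, 25.0 + 2 * i, "tropical"))
            rows.append((f"te{i}", h, 20.0 + 2 * i, "temperate"))
        df = pd.DataFrame(rows, columns=["species", "height_m", "vessel_um", "origin"])
        report = vessel_model(df, min_per_group=5)
        # oracle: pooled two-sample t on residuals of the no-origin fit
        log_h = np.log10(df["height_m"].values)
        log_d = np.log10(df["vessel_um"].values)
        fit = stats.linregress(log_h, log_d)
        resid = log_d - fit.intercept - fit.slope * log_h
        a = resid[(df["origin"] == "tropical").values]
        b = resid[(df["origin"] == "temperate").values]
        sp = np.sqrt(
            ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1))
            / (a.size + b.size - 2)
        )
        t = (a.mean() - b.mean()) / (sp * np.sqrt(1 / a.size + 1 / b.size))
        assert report.resid_t == pytest.approx(t, abs=1e-10)

    def test_single_origin_rejected(self):
        df, _ = generate_vessels(n_per_group=20, origin_offset_log10=0.0, seed=1)
        with pytest.raises(ValueError, match="origin"):
            vessel_model(df[df["origin"] == "tropical"])
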