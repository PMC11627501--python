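import numpy as np
import pandas as pd
import pytest

import xbrainage as xb
from xbrainage.association import ranked_significant


def brute_force_bh(p, q=0.05):
    """Step-up definition evaluated directly: largest k with p_(k) <= kq/m."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    k_max = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * q / m:
            k_max = k
    flags = np.zeros(m, bool)
    flags[order[:k_max]] = True
    return flags


class TestClassifyFeatures:
    def test_basic_partition(self):
        fc = xb.classify_features({"a", "b"}, {"b", "c"})
        assert fc.common == ["b"]
        assert fc.human_specific == ["a"]
        assert fc.macaque_specific == ["c"]

    def test_disjoint_sets(self):
        fc = xb.classify_features({"a"}, {"b"})
        assert fc.common == []

    def test_species_swap_symmetry(self, rng, schema):
        names = schema.feature_names
        h = set(rng.choice(names, 40, replace=False))
        m = set(rng.choice(names, 30, replace=False))
        a = xb.classify_features(h, m, schema=schema)
        b = xb.classify_features(m, h, schema=schema)
        assert a.common == b.common
        assert a.human_specific == b.macaque_specific
        assert a.macaque_specific == b.human_specific

    def test_per_measure_percentages_sum_to_100(self, rng, schema):
        names = schema.feature_names
        h = set(rng.choice(names, 60, replace=False))
        m = set(rng.choice(names, 50, replace=False))
        fc = xb.classify_features(h, m, schema=schema)
        sums = fc.per_measure_percent.sum(axis=1)
        for measure, total in sums.items():
            union = (h | m) & set(schema.names_for_measure(measure))
            if union:
                assert total == pytest.approx(100.0)

    def test_gmv_only_macaque_specific_by_construction(self, schema):
        """With fully biased routing, macaque-specific stays in GMV."""
        cfg = xb.SimConfig(n_human=20, n_macaque=15, specific_bias=1.0,
                           rng_seed=14)
        _, _, truth = xb.generate_cohort(cfg)
        fc = xb.classify_features(
            truth.informative_features("human"),
            truth.informative_features("macaque"), schema=schema)
        gmv = set(schema.names_for_measure("GMV"))
        assert set(fc.macaque_specific) <= gmv


class TestTopFeatures:
    def test_ranking_matches_brute_force(self, human_tables, schema):
        cohort, features, _, truth = human_tables
        sel = truth.informative_features("human")
        got = xb.top_features(features, cohort["age"], sel, schema,
                              "white_matter", n=5)
        wm = [f for f in sel
              if f in set(schema.names_for_compartment("white_matter"))]
        absr = {f: abs(np.corrcoef(features[f], cohort["age"])[0, 1])
                for f in wm}
        expect = sorted(absr, key=lambda f: -absr[f])[:5]
        assert list(got.index) == expect

    def test_n_larger_than_available(self, human_tables, schema):
        cohort, features, _, truth = human_tables
        sel = truth.informative_features("macaque")[:3]
        got = xb.top_features(features, cohort["age"], sel, schema,
                              "gray_matter", n=50)
        gm = set(schema.names_for_compartment("gray_matter"))
        assert len(got) == len([f for f in sel if f in gm])

    def test_empty_compartment_subset(self, human_tables, schema):
        cohort, features, _, _ = human_tables
        got = xb.top_features(features, cohort["age"],
                              ["GMV_left_Pu"], schema, "white_matter")
        assert got.empty


class TestPartialCorrelation:
    def test_single_covariate_closed_form(self):
        """(r_xy - r_xz r_yz) / sqrt((1-r_xz^2)(1-r_yz^2)) on seeded tables."""
        for seed in range(20):
            g = np.random.default_rng(seed)
            z = g.normal(size=50)
            x = 0.5 * z + g.normal(size=50)
            y = -0.3 * z + g.normal(size=50)
            r_xy = np.corrcoef(x, y)[0, 1]
            r_xz = np.corrcoef(x, z)[0, 1]
            r_yz = np.corrcoef(y, z)[0, 1]
            expect = (r_xy - r_xz * r_yz) / np.sqrt(
                (1 - r_xz ** 2) * (1 - r_yz ** 2))
            r, p, n = xb.partial_correlation(x, y, z)
            assert r == pytest.approx(expect, abs=1e-12)
            assert n == 50

    def test_agrees_with_pingouin(self, rng):
        import pingouin as pg
        x = rng.normal(size=60)
        z = rng.normal(size=60)
        y = 0.4 * x + 0.6 * z + rng.normal(size=60)
        df = pd.DataFrame({"x": x, "y": y, "z": z})
        ours_r, ours_p, _ = xb.partial_correlation(x, y, z)
        ref = pg.partial_corr(df, x="x", y="y", covar="z")
        assert ours_r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-9)
        assert ours_p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-9)

    def test_no_covariates_equals_pearson(self, rng):
        x, y = rng.normal(size=40), rng.normal(size=40)
        r0, p0 = xb.pearson_r_p(x, y)
        r, p, _ = xb.partial_correlation(x, y)
        assert (r, p) == (pytest.approx(r0, abs=1e-12),
                          pytest.approx(p0, abs=1e-12))

    def test_covariate_removes_confound(self):
        """y driven purely by the covariate: partial r collapses to ~0."""
        rs = []
        for seed in range(30):
            g = np.random.default_rng(seed)
            z = g.normal(size=370)
            x = g.normal(size=370) + 0.8 * z
            y = z + 0.01 * g.normal(size=370)
            r, _, _ = xb.partial_correlation(x, y, z)
            rs.append(abs(r))
        assert np.median(rs) < 0.05

    def test_missing_rows_dropped(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        z = rng.normal(size=30)
        y[3] = np.nan
        r, p, n = xb.partial_correlation(x, y, z)
        assert n == 29
        r2, _, _ = xb.partial_correlation(np.delete(x, 3),
                                          np.delete(y, 3),
                                          np.delete(z, 3))
        assert r == pytest.approx(r2)

    def test_collinear_variable_rejected(self, rng):
        z = rng.normal(size=30)
        with pytest.raises(ValueError):
            xb.partial_correlation(2 * z + 1, rng.normal(size=30), z)


class TestFdrBH:
    def test_all_borderline_flagged_by_step_up(self):
        adj, flags = xb.fdr_bh(np.full(10, 0.01), q=0.05)
        assert flags.all()

    def test_single_p(self):
        adj, flags = xb.fdr_bh([0.04], q=0.05)
        assert flags[0]

    def test_fifteen_p_example_matches_brute_force(self):
        p = [0.001, 0.008, 0.039, 0.041, 0.042, 0.06, 0.074, 0.205,
             0.212, 0.216, 0.222, 0.251, 0.269, 0.275, 0.34]
        _, flags = xb.fdr_bh(p, q=0.05)
        np.testing.assert_array_equal(flags, brute_force_bh(p, 0.05))

    def test_small_families_match_brute_force(self, rng):
        for m in range(1, 9):
            for _ in range(50):
                p = rng.uniform(size=m)
                _, flags = xb.fdr_bh(p, q=0.05)
                np.testing.assert_array_equal(flags, brute_force_bh(p))

    def test_nan_handling(self):
        adj, flags = xb.fdr_bh([0.001, np.nan, 0.9])
        assert np.isnan(adj[1]) and not flags[1]
        assert flags[0]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            xb.fdr_bh([0.5, 1.2])


@pytest.fixture(scope="module")
def bcap_setup(human_tables, macaque_tables):
    h_cohort, h_feats, behaviors, truth = human_tables
    m_cohort, m_feats, _ = macaque_tables
    own = xb.cv_predict(h_feats, h_cohort["age"],
                        xb.screen_once(h_feats, h_cohort["age"], 0.01),
                        n_reps=8, seed=3).predicted
    mm = xb.fit_full_model(
        m_feats, m_cohort["age"],
        xb.screen_once(m_feats, m_cohort["age"], 0.01))
    b = xb.bcap(own, xb.cross_predict(mm, h_feats))["bcap"]
    return h_cohort, h_feats, behaviors, truth, b


class TestBcapAssociations:
    def test_planted_behaviors_survive_fdr(self, bcap_setup):
        h_cohort, _, behaviors, truth, b = bcap_setup
        res = xb.bcap_behavior_associations(b, behaviors, h_cohort["age"])
        assert set(truth.informative_behaviors) <= set(
            res.index[res["significant"]])

    def test_sparse_behavior_skipped(self, bcap_setup):
        h_cohort, _, behaviors, _, b = bcap_setup
        sparse = behaviors.copy()
        sparse["behavior_05"] = np.nan
        sparse.loc[sparse.index[:5], "behavior_05"] = 1.0
        res = xb.bcap_behavior_associations(b, sparse, h_cohort["age"])
        assert np.isnan(res.loc["behavior_05", "p"])
        assert not res.loc["behavior_05", "significant"]

    def test_feature_associations_rank_oracle(self, bcap_setup, schema):
        h_cohort, h_feats, _, _, b = bcap_setup
        res = xb.bcap_feature_associations(b, h_feats, h_cohort["age"],
                                           schema)
        assert len(res) == 260
        # enumeration oracle for the top-3 within one measure
        fa = res[res["measure"] == "FA"]
        recomputed = {f: xb.partial_correlation(
            b.to_numpy(), h_feats[f].to_numpy(),
            h_cohort["age"].to_numpy())[0]
            for f in fa.index}
        expect_top = sorted(recomputed, key=lambda f: -recomputed[f])[:3]
        got_top = list(fa.sort_values("partial_r",
                                      ascending=False).head(3).index)
        assert got_top == expect_top

    def test_human_specific_directional_enrichment(self, bcap_setup,
                                                   schema):
        """Human-specific features correlate with BCAP along their planted
        direction, unlike pure-noise features."""
        h_cohort, h_feats, _, truth, b = bcap_setup
        res = xb.bcap_feature_associations(b, h_feats, h_cohort["age"],
                                           schema)
        hs = truth.human_specific_features
        informative = set(truth.common_features) | set(hs) \
            | set(truth.macaque_specific_features)
        noise = [f for f in res.index if f not in informative]
        dir_r = np.mean([res.loc[f, "partial_r"]
                         * np.sign(truth.slopes_human[f]) for f in hs])
        noise_r = np.mean([abs(res.loc[f, "partial_r"]) for f in noise])
        assert dir_r > 0.02
        assert dir_r > noise_r / 2  # directional signal, not just spread

    def test_ranked_significant_subset(self, bcap_setup, schema):
        h_cohort, h_feats, _, _, b = bcap_setup
        res = xb.bcap_feature_associations(b, h_feats, h_cohort["age"],
                                           schema)
        top = ranked_significant(res, "GMV", 3, 3)
        assert (top["measure"] == "GMV").all()
        assert top["significant"].all()
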