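"""ABC engine: per-locus primitives, summary vectors vs a brute-force
oracle, rejection, regression adjustment, model choice, accuracy
metrics, and scaling."""

import numpy as np
import pandas as pd
import pytest

from gbspopgen.abc import (
    Accepted, PosteriorSample, ReferenceTable, StatLayout,
    _point_estimates, _relative_metrics, admixture_estimate,
    gene_diversity, nei_distance, regression_adjust, reject,
    scale_parameters, select_model_direct, select_model_logistic,
    stats_from_counts, summarize,
)

from conftest import build_matrix

# ----------------------------------------------------------------------
# primitives
# ----------------------------------------------------------------------


class TestPrimitives:
    def test_gene_diversity_closed_form(self):
        assert gene_diversity(0.5, 4) == pytest.approx(2 / 3, abs=1e-12)
        assert gene_diversity(0.0, 4) == 0.0
        assert gene_diversity(1.0, 4) == 0.0
        assert np.isnan(gene_diversity(0.5, 1))

    def test_nei_distance_values(self):
        assert nei_distance(0.3, 0.3) == 0.0
        assert nei_distance(1.0, 0.0) == 10.0  # capped infinity
        # hand-computed: J_XY=0.5, J_X=0.68, J_Y=0.5
        expected = -np.log(0.5 / np.sqrt(0.68 * 0.5))
        assert nei_distance(0.8, 0.5) == pytest.approx(expected, abs=1e-12)

    def test_nei_distance_symmetric_nonnegative(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            x, y = rng.random(2)
            assert nei_distance(x, y) == pytest.approx(nei_distance(y, x))
            assert nei_distance(x, y) >= 0

    def test_admixture_estimate(self):
        assert admixture_estimate(0.6, 1.0, 0.5) == pytest.approx(0.2)
        assert admixture_estimate(0.7, 0.7, 0.2) == pytest.approx(1.0)
        assert np.isnan(admixture_estimate(0.5, 0.4, 0.4))


# ----------------------------------------------------------------------
# summary vector vs straight-line oracle
# ----------------------------------------------------------------------


def oracle_vector(derived, n_alleles, groups, layout):
    """Per-locus loop recomputation with the scalar primitives."""
    gi = {g: k for k, g in enumerate(groups)}
    L = derived.shape[0]
    freq = {}
    for g, k in gi.items():
        freq[g] = [
            derived[j, k] / n_alleles[j, k] if n_alleles[j, k] > 0
            else np.nan
            for j in range(L)
        ]
    out = []
    for g in layout.groups:
        vals = [
            gene_diversity(freq[g][j], int(n_alleles[j, gi[g]]))
            for j in range(L) if n_alleles[j, gi[g]] >= 2
        ]
        null = [v == 0 for v in vals]
        out.append(np.mean(null) if vals else 0.0)
        poly = [v for v in vals if v != 0]
        out.append(np.mean(poly) if poly else 0.0)
    for a, b in layout.pairs:
        vals = [
            nei_distance(freq[a][j], freq[b][j], cap=layout.nei_cap)
            for j in range(L)
            if n_alleles[j, gi[a]] >= 2 and n_alleles[j, gi[b]] >= 2
        ]
        null = [v == 0 for v in vals]
        out.append(np.mean(null) if vals else 0.0)
        nonnull = [v for v in vals if v != 0]
        out.append(np.var(nonnull, ddof=1) if len(nonnull) > 1 else 0.0)
    for a, p1, p2 in layout.trios:
        vals = [
            admixture_estimate(freq[a][j], freq[p1][j], freq[p2][j],
                               tol=layout.adm_tol)
            for j in range(L)
            if all(n_alleles[j, gi[g]] >= 2 for g in (a, p1, p2))
        ]
        vals = [v for v in vals if not np.isnan(v)]
        null = [v == 0 for v in vals]
        out.append(np.mean(null) if vals else 0.0)
        nonnull = [v for v in vals if v != 0]
        out.append(np.mean(nonnull) if nonnull else 0.0)
        out.append(np.var(nonnull, ddof=1) if len(nonnull) > 1 else 0.0)
        out.append(np.mean(vals) if vals else 0.0)
    return np.array(out)


class TestSummarize:
    def test_matches_oracle_exactly(self):
        rng = np.random.default_rng(8)
        groups = ["A", "B", "C"]
        layout = StatLayout.default_for(groups, trios=[("B", "A", "C")])
        for _ in range(10):
            derived = rng.integers(0, 9, size=(10, 3)).astype(float)
            n_alleles = np.full((10, 3), 8.0)
            derived = np.minimum(derived, n_alleles)
            vec = stats_from_counts(derived, n_alleles, groups, layout)
            oracle = oracle_vector(derived, n_alleles, groups, layout)
            np.testing.assert_allclose(vec, oracle, atol=1e-12)

    def test_all_monomorphic_group(self):
        layout = StatLayout(groups=["A"])
        derived = np.zeros((5, 1))
        n_alleles = np.full((5, 1), 6.0)
        vec = stats_from_counts(derived, n_alleles, ["A"], layout)
        assert vec[0] == 1.0  # all loci null gene diversity

    def test_identical_groups_null_nei(self):
        layout = StatLayout(groups=["A", "B"], pairs=[("A", "B")])
        derived = np.tile(np.arange(1, 6, dtype=float)[:, None], (1, 2))
        n_alleles = np.full((5, 2), 6.0)
        vec = stats_from_counts(derived, n_alleles, ["A", "B"], layout)
        # prop null nei = 1, var = 0
        assert vec[4] == 1.0 and vec[5] == 0.0

    def test_bounds_always_hold(self):
        rng = np.random.default_rng(10)
        groups = ["A", "B"]
        layout = StatLayout.default_for(groups)
        for _ in range(20):
            n_alleles = rng.integers(2, 13, size=(8, 2)).astype(float)
            derived = np.floor(rng.random((8, 2)) * (n_alleles + 1))
            vec = stats_from_counts(derived, n_alleles, groups, layout)
            # proportions within [0,1]; variances >= 0
            assert 0 <= vec[0] <= 1 and 0 <= vec[2] <= 1
            assert 0 <= vec[4] <= 1 and vec[5] >= 0

    def test_summarize_from_matrix(self):
        calls = [[0, 2], [1, 1], [2, 0], [2, 2]]
        gm, pm = build_matrix(calls, groups={"A": 2, "B": 2})
        layout = StatLayout.default_for(["A", "B"])
        vec = summarize(gm, pm, layout)
        from gbspopgen.simulate import counts_from_matrix
        counts, n_all = counts_from_matrix(gm, pm, ["A", "B"])
        np.testing.assert_allclose(
            vec, oracle_vector(counts, n_all, ["A", "B"], layout),
            atol=1e-12,
        )

    def test_empty_group_rejected(self):
        gm, pm = build_matrix([[0], [1]], groups={"A": 2})
        layout = StatLayout.default_for(["A", "Z"])
        with pytest.raises(ValueError, match="Z"):
            summarize(gm, pm, layout)


# ----------------------------------------------------------------------
# rejection + regression
# ----------------------------------------------------------------------


def toy_table(n, rng, noise=0.1):
    theta = rng.normal(0.0, 1.0, n)
    s = theta + rng.normal(0.0, noise, n)
    return ReferenceTable(
        params=pd.DataFrame({"scenario": "toy", "theta": theta}),
        stats=s[:, None],
        stat_names=["s"],
    )


class TestReject:
    def test_acceptance_count(self):
        rng = np.random.default_rng(0)
        rt = toy_table(1000, rng)
        acc = reject(rt, np.array([0.5]), 0.01)
        assert len(acc.indices) == 10

    def test_exact_match_ranks_first(self):
        rng = np.random.default_rng(1)
        rt = toy_table(100, rng)
        obs = rt.stats[37].copy()
        acc = reject(rt, obs, 0.05)
        assert acc.indices[0] == 37
        assert acc.distances[0] == 0.0

    def test_empty_table_rejected(self):
        rt = ReferenceTable(
            params=pd.DataFrame({"scenario": [], "theta": []}),
            stats=np.zeros((0, 1)), stat_names=["s"],
        )
        with pytest.raises(ValueError):
            reject(rt, np.array([0.0]), 0.01)


class TestRegressionAdjust:
    def test_conjugate_gaussian_posterior_mean(self):
        # theta ~ N(0,1), s = theta + N(0, 0.1); s_obs = 1 gives
        # posterior mean 1/(1+0.01) = 0.9901
        rng = np.random.default_rng(5)
        rt = toy_table(20_000, rng)
        acc = reject(rt, np.array([1.0]), 0.01)
        post = regression_adjust(
            acc, {"theta": (-np.inf, np.inf)}
        )
        target = 1.0 / 1.01
        assert post.point_estimates.loc["theta", "mean"] == pytest.approx(
            target, abs=0.03
        )

    def test_uninformative_stat_leaves_sample_unchanged(self):
        # statistic independent of the parameter: slopes ~ 0, adjusted
        # mean within Monte-Carlo error of the rejection mean
        rng = np.random.default_rng(6)
        n = 5000
        theta = rng.normal(0.0, 1.0, n)
        s = rng.normal(0.0, 1.0, n)
        rt = ReferenceTable(
            params=pd.DataFrame({"scenario": "t", "theta": theta}),
            stats=s[:, None], stat_names=["s"],
        )
        acc = reject(rt, np.array([0.0]), 0.05)
        post = regression_adjust(acc, {"theta": (-np.inf, np.inf)})
        raw_mean = post.raw["theta"].mean()
        adj_mean = post.point_estimates.loc["theta", "mean"]
        se = post.raw["theta"].std() / np.sqrt(len(post.raw))
        assert abs(adj_mean - raw_mean) < 4 * se

    def test_adjusted_values_respect_prior_bounds(self):
        rng = np.random.default_rng(7)
        n = 2000
        theta = rng.uniform(0.0, 10.0, n)
        s = theta + rng.normal(0, 2.0, n)
        rt = ReferenceTable(
            params=pd.DataFrame({"scenario": "t", "theta": theta}),
            stats=s[:, None], stat_names=["s"],
        )
        acc = reject(rt, np.array([9.5]), 0.05)
        post = regression_adjust(acc, {"theta": (0.0, 10.0)})
        assert (post.adjusted["theta"] >= 0).all()
        assert (post.adjusted["theta"] <= 10).all()

    def test_too_few_accepted_raises(self):
        rng = np.random.default_rng(8)
        rt = toy_table(50, rng)
        acc = reject(rt, np.array([0.0]), 0.02)  # 1 record
        with pytest.raises(ValueError, match="accepted"):
            regression_adjust(acc, {"theta": (-np.inf, np.inf)})


# ----------------------------------------------------------------------
# model selection
# ----------------------------------------------------------------------


def two_cluster_table(n_per, rng, sep=10.0):
    sa = rng.normal(0.0, 1.0, (n_per, 2))
    sb = rng.normal(sep, 1.0, (n_per, 2))
    params = pd.DataFrame({
        "scenario": ["A"] * n_per + ["B"] * n_per,
        "theta": np.zeros(2 * n_per),
    })
    return ReferenceTable(
        params=params, stats=np.vstack([sa, sb]),
        stat_names=["s1", "s2"],
    )


class TestModelSelection:
    def test_direct_all_from_one_scenario(self):
        rng = np.random.default_rng(11)
        rt = two_cluster_table(500, rng)
        res = select_model_direct(rt, np.array([0.0, 0.0]), n_closest=10)
        assert res.loc["A", "probability"] == 1.0
        assert res.loc["B", "probability"] == 0.0

    def test_direct_even_split(self):
        # two identical generators: shares near 1/2
        rng = np.random.default_rng(12)
        s = rng.normal(0, 1, (1000, 2))
        params = pd.DataFrame({
            "scenario": ["A", "B"] * 500, "theta": np.zeros(1000),
        })
        rt = ReferenceTable(params=params, stats=s, stat_names=["a", "b"])
        res = select_model_direct(rt, np.array([0.0, 0.0]), n_closest=500)
        assert res.loc["A", "probability"] == pytest.approx(0.5, abs=0.1)

    def test_direct_ci_contains_probability(self):
        rng = np.random.default_rng(13)
        rt = two_cluster_table(300, rng, sep=2.0)
        res = select_model_direct(rt, np.array([0.5, 0.5]), n_closest=100)
        for _, row in res.iterrows():
            assert row["ci_low"] <= row["probability"] <= row["ci_high"]

    def test_logistic_separable_case(self):
        rng = np.random.default_rng(14)
        rt = two_cluster_table(1000, rng, sep=8.0)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = select_model_logistic(rt, np.array([8.0, 8.0]),
                                        tolerance=0.5)
        assert res.loc["B", "probability"] > 0.99

    def test_logistic_exchangeable_scenarios(self):
        rng = np.random.default_rng(15)
        s = rng.normal(0, 1, (2000, 2))
        params = pd.DataFrame({
            "scenario": ["A", "B"] * 1000, "theta": np.zeros(2000),
        })
        rt = ReferenceTable(params=params, stats=s, stat_names=["a", "b"])
        res = select_model_logistic(rt, np.array([0.0, 0.0]),
                                    tolerance=0.25)
        assert res.loc["A", "probability"] == pytest.approx(0.5, abs=0.1)

    def test_n_closest_exceeding_table(self):
        rng = np.random.default_rng(16)
        rt = two_cluster_table(5, rng)
        with pytest.raises(ValueError):
            select_model_direct(rt, np.array([0.0, 0.0]), n_closest=100)


# ----------------------------------------------------------------------
# accuracy metrics and scaling
# ----------------------------------------------------------------------


def _posterior_from_draws(draws, weights=None):
    df = pd.DataFrame({"theta": draws})
    w = np.ones(len(df)) if weights is None else weights
    return PosteriorSample(
        raw=df.copy(), adjusted=df, weights=w,
        point_estimates=_point_estimates(df, w),
    )


class TestAccuracyMetrics:
    def test_perfect_estimator_zero_metrics(self):
        truths = [{"theta": 2.0}, {"theta": 5.0}]
        posts = [
            _posterior_from_draws(np.full(100, 2.0)),
            _posterior_from_draws(np.full(100, 5.0)),
        ]
        m = _relative_metrics(truths, posts, ["theta"])
        np.testing.assert_allclose(
            m.loc["theta"].tolist(), [0.0, 0.0, 0.0], atol=1e-12
        )

    def test_prior_estimator_matches_analytic_toy(self):
        # posterior == prior U(0,2), truth theta0=1:
        # RRMISE^2 = E[(u-1)^2] = Var = 1/3; RMeanAD = E|u-1| = 1/2;
        # RRMSE uses the prior mean 1 -> 0
        rng = np.random.default_rng(20)
        draws = rng.uniform(0, 2, 200_000)
        post = _posterior_from_draws(draws)
        m = _relative_metrics([{"theta": 1.0}], [post], ["theta"])
        assert m.loc["theta", "rrmise"] == pytest.approx(
            np.sqrt(1 / 3), abs=0.01
        )
        assert m.loc["theta", "rmeanad"] == pytest.approx(0.5, abs=0.01)
        assert m.loc["theta", "rrmse"] == pytest.approx(0.0, abs=0.01)

    def test_zero_truth_excluded(self):
        truths = [{"theta": 0.0}, {"theta": 1.0}]
        posts = [_posterior_from_draws(np.ones(10))] * 2
        m = _relative_metrics(truths, posts, ["theta"])
        assert np.isfinite(m.loc["theta", "rrmse"])


class TestScaleParameters:
    def test_scaled_time_arithmetic(self):
        post = _posterior_from_draws(np.full(50, 0.4))
        natural = scale_parameters(post, 1_275_000, "to_natural")
        assert natural.point_estimates.loc["theta", "mean"] == (
            pytest.approx(510_000)
        )

    def test_mean_ne_one_identity(self):
        post = _posterior_from_draws(np.array([1.0, 2.0, 3.0]))
        out = scale_parameters(post, 1.0, "to_scaled")
        assert np.allclose(out.adjusted["theta"], post.adjusted["theta"])

    def test_round_trip_identity(self):
        post = _posterior_from_draws(np.array([3.0, 7.0, 11.0]))
        back = scale_parameters(
            scale_parameters(post, 1234.5, "to_scaled"), 1234.5,
            "to_natural",
        )
        assert np.allclose(back.adjusted["theta"], post.adjusted["theta"])

    def test_nonpositive_ne_rejected(self):
        post = _posterior_from_draws(np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            scale_parameters(post, 0.0)


class TestReferenceTablePersistence:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(30)
        layout = StatLayout(groups=["A"], pairs=[], trios=[])
        theta = rng.normal(size=20)
        rt = ReferenceTable(
            params=pd.DataFrame({"scenario": "X", "theta": theta}),
            stats=rng.normal(size=(20, 2)),
            stat_names=["prop_null_gd(A)", "mean_gd_poly(A)"],
            layout=layout,
        )
        path = tmp_path / "table.tsv"
        rt.save(path)
        back = ReferenceTable.load(path)
        np.testing.assert_allclose(back.stats, rt.stats)
        np.testing.assert_allclose(back.sd, rt.sd)
        np.testing.assert_allclose(back.params["theta"], theta)
        assert back.stat_names == rt.stat_names
        assert back.layout.groups == ["A"]

    def test_missing_header_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("scenario\ttheta\nX\t1.0\n")
        with pytest.raises(ValueError, match="header"):
            ReferenceTable.load(path)
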