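"""Coalescent simulator checks: closed-form expectations, the neutral
site-frequency spectrum, determinism, and kernel-vs-msprime agreement."""

import numpy as np
import pytest
from scipy import stats as sps

from gbspopgen.abc import StatLayout, stats_from_counts
from gbspopgen.scenarios import DemographicScenario, build_scenarios
from gbspopgen.simulate import (
    assign_positions, counts_from_matrix, simulate_counts, simulate_snps,
)
from gbspopgen.synth import generate


def single_pop_draw(n=100_000.0, t=1.0):
    return {"N_s_saga": n, "N_n_saga": n, "t": t}


SC_NK = build_scenarios()["out_of_nk"]


class TestCoalescentExpectations:
    def test_tmrca_matches_closed_form(self):
        # 4 lineages, size N: E[TMRCA] = sum_k 4N/(k(k-1)) = 3N
        N = 100_000.0
        L = 3000
        _, _, tm = simulate_counts(
            SC_NK, single_pop_draw(N), L, {"S.Saga": 2, "N.Saga": 0}, 7
        )
        var = (4 * N) ** 2 * sum(
            (1.0 / (k * (k - 1))) ** 2 for k in (2, 3, 4)
        )
        se = np.sqrt(var / L)
        assert abs(tm.mean() - 3 * N) < 3 * se

    def test_sfs_proportional_to_inverse_count(self):
        # conditioning on one segregating site (length-biased
        # genealogies, one mutation prop. to branch length) gives
        # P(derived count = i) prop. to 1/i for i = 1..n-1
        n_dip = 5
        L = 20_000
        counts, n_hap, _ = simulate_counts(
            SC_NK, single_pop_draw(), L, {"S.Saga": n_dip, "N.Saga": 0},
            11, conditioning="site",
        )
        derived = counts.sum(axis=1)
        n = 2 * n_dip
        obs = np.bincount(derived, minlength=n)[1:n]
        weights = 1.0 / np.arange(1, n)
        expected = L * weights / weights.sum()
        p = sps.chisquare(obs, expected).pvalue
        assert p > 0.01

    def test_every_locus_polymorphic(self):
        counts, n_hap, _ = simulate_counts(
            SC_NK, single_pop_draw(t=50_000.0), 2000,
            {"S.Saga": 3, "N.Saga": 3}, 5
        )
        total = counts.sum(axis=1)
        assert (total > 0).all() and (total < n_hap.sum()).all()

    def test_recent_split_no_structure(self):
        # split time ~0: between-deme frequency difference matches the
        # difference between two labeled halves of one panmictic sample
        import pandas as pd

        from gbspopgen.genotypes import PopulationMap

        draw = single_pop_draw(t=1.0)
        L = 3000
        counts, n_hap, _ = simulate_counts(
            SC_NK, draw, L, {"S.Saga": 6, "N.Saga": 6}, 21
        )
        d_split = np.abs(
            counts[:, 0] / n_hap[0] - counts[:, 1] / n_hap[1]
        ).mean()

        gm = simulate_snps(SC_NK, single_pop_draw(t=1.0), 1000,
                           {"S.Saga": 12, "N.Saga": 0}, seed=22)
        rows = [
            {"individual": ind, "population": "half1" if k < 6 else "half2",
             "group": "half1" if k < 6 else "half2"}
            for k, ind in enumerate(gm.individuals)
        ]
        pm = PopulationMap(pd.DataFrame(rows))
        c2, n2 = counts_from_matrix(gm, pm, ["half1", "half2"])
        d_halves = np.abs(c2[:, 0] / n2[:, 0] - c2[:, 1] / n2[:, 1]).mean()
        assert d_split == pytest.approx(d_halves, rel=0.1)


class TestDeterminismAndSeeds:
    def test_identical_seeds_identical_output(self):
        a = simulate_counts(SC_NK, single_pop_draw(), 500,
                            {"S.Saga": 3, "N.Saga": 3}, 13)
        b = simulate_counts(SC_NK, single_pop_draw(), 500,
                            {"S.Saga": 3, "N.Saga": 3}, 13)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[2], b[2])

    def test_different_seeds_differ(self):
        a = simulate_counts(SC_NK, single_pop_draw(), 500,
                            {"S.Saga": 3, "N.Saga": 3}, 13)
        c = simulate_counts(SC_NK, single_pop_draw(), 500,
                            {"S.Saga": 3, "N.Saga": 3}, 14)
        assert not np.array_equal(a[0], c[0])

    def test_no_cross_locus_correlation(self):
        counts, n_hap, _ = simulate_counts(
            SC_NK, single_pop_draw(), 4000, {"S.Saga": 3, "N.Saga": 3}, 17
        )
        f = counts.sum(axis=1) / n_hap.sum()
        r = np.corrcoef(f[:-1], f[1:])[0, 1]
        assert abs(r) < 0.05

    def test_msprime_matrix_deterministic(self):
        sc = build_scenarios()["out_of_nk"]
        a = simulate_snps(sc, single_pop_draw(t=1e5), 30,
                          {"S.Saga": 2, "N.Saga": 2}, seed=3)
        b = simulate_snps(sc, single_pop_draw(t=1e5), 30,
                          {"S.Saga": 2, "N.Saga": 2}, seed=3)
        assert np.array_equal(a.calls, b.calls)

    def test_zero_samples_rejected(self):
        with pytest.raises(ValueError, match="zero sampled"):
            simulate_counts(SC_NK, single_pop_draw(), 10, {}, 1)


LAYOUT2 = StatLayout.default_for(["S.Saga", "N.Saga"])


def _mean_stats_kernel(sc, draw, n_rep, n_loci, ss, seed0):
    out = []
    for k in range(n_rep):
        counts, n_hap, _ = simulate_counts(sc, draw, n_loci, ss, seed0 + k)
        n_all = np.broadcast_to(n_hap, counts.shape)
        out.append(
            stats_from_counts(counts, n_all, sc.populations, LAYOUT2)
        )
    return np.array(out)


class TestKernelVsMsprime:
    def test_summary_stat_distributions_agree(self):
        """The fast counts kernel and the msprime engine are the same
        model: their mean summary-statistic vectors agree."""
        draw = {"N_s_saga": 150_000.0, "N_n_saga": 80_000.0, "t": 120_000.0}
        ss = {"S.Saga": 4, "N.Saga": 4}
        kern = _mean_stats_kernel(SC_NK, draw, 40, 150, ss, 100)
        ms = []
        rng = np.random.default_rng(5)
        for k in range(40):
            gm = simulate_snps(SC_NK, draw, 150, ss,
                               seed=int(rng.integers(1, 2**30)))
            groups = ["S.Saga", "N.Saga"]
            import pandas as pd

            from gbspopgen.genotypes import PopulationMap
            rows = [
                {"individual": ind, "population": ind.rsplit("-", 1)[0],
                 "group": ind.rsplit("-", 1)[0]}
                for ind in gm.individuals
            ]
            pm = PopulationMap(pd.DataFrame(rows))
            counts, n_all = counts_from_matrix(gm, pm, groups)
            ms.append(stats_from_counts(counts, n_all, groups, LAYOUT2))
        ms = np.array(ms)
        se = np.sqrt(kern.var(0) / len(kern) + ms.var(0) / len(ms))
        diff = np.abs(kern.mean(0) - ms.mean(0))
        assert (diff < 5 * se + 1e-9).all(), (diff, se)


class TestAdmixtureDegeneracy:
    def test_scenario_iv_rate_zero_equals_pure_split(self):
        """With r -> 0 the admixture origin degenerates to Tajima-Tango
        splitting from Honshu; summary statistics match the explicit
        split topology."""
        sc_iv = build_scenarios()["IV"]
        equiv = DemographicScenario(
            name="IV-degenerate",
            populations=sc_iv.populations,
            size_params=dict(sc_iv.size_params),
            ancestor=sc_iv.ancestor,
            ancestor_size_param=sc_iv.ancestor_size_param,
            events=[
                ("merge", "t1", "Tajima-Tango", "Honshu"),
                ("merge", "t2", "Honshu", "Kyushu"),
                ("merge", "t3", "N.JPN", "Ancestor"),
                ("merge", "t3", "Kyushu", "Ancestor"),
            ],
        )
        draw = {
            "N_njpn": 500_000.0, "N_tajima_tango": 300_000.0,
            "N_kyushu": 800_000.0, "N_honshu": 600_000.0,
            "N_ancestor": 400_000.0,
            "t1": 200_000.0, "t2": 800_000.0, "t3": 3_000_000.0,
        }
        ss = {"N.JPN": 5, "Tajima-Tango": 5, "Kyushu": 5, "Honshu": 5}
        layout = StatLayout.default_for(sc_iv.populations)

        def mean_stats(sc, d, seed0):
            out = []
            for k in range(40):
                counts, n_hap, _ = simulate_counts(sc, d, 200, ss,
                                                   seed0 + k)
                n_all = np.broadcast_to(n_hap, counts.shape)
                out.append(stats_from_counts(counts, n_all,
                                             sc.populations, layout))
            return np.array(out)

        a = mean_stats(sc_iv, {**draw, "r": 1e-9}, 300)
        b = mean_stats(equiv, draw, 700)
        se = np.sqrt(a.var(0) / len(a) + b.var(0) / len(b))
        diff = np.abs(a.mean(0) - b.mean(0))
        assert (diff < 5 * se + 1e-9).all(), (diff, se)


class TestPositionsAndShapes:
    def test_positions_cover_24_chromosomes(self):
        loci = assign_positions(1014)
        assert loci["chrom"].nunique() == 24
        for _, sub in loci.groupby("chrom"):
            assert sub["pos"].is_monotonic_increasing

    def test_generated_shapes(self):
        gm, pm, truth = generate("local-like", seed=1, n_loci=60)
        assert gm.n_individuals == 12 and gm.n_loci == 60
        gm2, pm2, _ = generate("hz2-like", seed=1, n_loci=40)
        assert gm2.n_individuals == 20
        assert len(pm2.populations) == 20
        assert len(pm2.groups) == 4
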