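import numpy as np
import pandas as pd
import pytest

from progmark.enrichment import (RankedList, enrichment_score, gsea,
                                 gsea_from_ranked, signal_to_noise,
                                 zscore_set_comparison)
from progmark.errors import DataError, NumericError
from progmark.io import GeneSet
from progmark.signature import stratify_by_gene


def oracle_running_sum(symbols, metric, members, weight_p):
    """Independent step-by-step running-sum oracle."""
    members = set(members)
    n = len(symbols)
    n_hits = sum(s in members for s in symbols)
    denom_hit = sum(abs(m) ** weight_p for s, m in zip(symbols, metric) if s in members)
    out, total = [], 0.0
    for s, m in zip(symbols, metric):
        if s in members:
            total += (abs(m) ** weight_p) / denom_hit if denom_hit else 1.0 / n_hits
        else:
            total -= 1.0 / (n - n_hits)
        out.append(total)
    return out


class TestSignalToNoise:
    def test_floored_sigmas_closed_form(self):
        df = pd.DataFrame({"a1": [1.0], "a2": [1.0], "a3": [1.0],
                           "b1": [0.0], "b2": [0.0], "b3": [0.0]}, index=["g"])
        ranked = signal_to_noise(df, ["a1", "a2", "a3"], ["b1", "b2", "b3"])
        assert ranked.metric[0] == pytest.approx(2.5)

    def test_identical_groups_all_zero_lexicographic(self):
        df = pd.DataFrame(np.ones((3, 4)), index=["b", "a", "c"],
                          columns=["a1", "a2", "b1", "b2"])
        ranked = signal_to_noise(df, ["a1", "a2"], ["b1", "b2"])
        assert list(ranked.metric) == [0.0, 0.0, 0.0]
        assert ranked.symbols == ["a", "b", "c"]

    def test_overlapping_groups_rejected(self):
        df = pd.DataFrame(np.ones((2, 3)), index=["a", "b"], columns=["x", "y", "z"])
        with pytest.raises(DataError, match="overlap"):
            signal_to_noise(df, ["x", "y"], ["y", "z"])

    def test_matches_per_gene_loop(self, rng):
        df = pd.DataFrame(rng.normal(size=(100, 12)),
                          index=[f"g{i:03d}" for i in range(100)],
                          columns=[f"c{j}" for j in range(12)])
        ga, gb = [f"c{j}" for j in range(6)], [f"c{j}" for j in range(6, 12)]
        ranked = signal_to_noise(df, ga, gb)
        by_symbol = dict(zip(ranked.symbols, ranked.metric))
        for g in df.index:  # brute-force oracle
            a, b = df.loc[g, ga].to_numpy(), df.loc[g, gb].to_numpy()
            sa = max(a.std(ddof=1), 0.2 * abs(a.mean()), 0.2)
            sb = max(b.std(ddof=1), 0.2 * abs(b.mean()), 0.2)
            assert by_symbol[g] == pytest.approx((a.mean() - b.mean()) / (sa + sb), abs=1e-10)


class TestEnrichmentScore:
    def test_top_placed_set_scores_plus_one(self):
        ranked = RankedList(symbols=["a", "b", "c", "d"], metric=[4.0, 3.0, 2.0, 1.0])
        es, leading, running = enrichment_score(
            ranked, GeneSet(name="s", members=["a", "b"]), weight_p=0.0)
        np.testing.assert_allclose(running, [0.5, 1.0, 0.5, 0.0])
        assert es == 1.0 and leading == ["a", "b"]

    def test_bottom_placed_set_scores_minus_one(self):
        ranked = RankedList(symbols=["a", "b", "c", "d"], metric=[4.0, 3.0, 2.0, 1.0])
        es, _, _ = enrichment_score(ranked, GeneSet(name="s", members=["c", "d"]),
                                    weight_p=0.0)
        assert es == -1.0

    def test_matches_running_sum_oracle(self, rng):
        symbols = [f"g{i:02d}" for i in range(50)]
        metric = np.sort(rng.normal(size=50))[::-1]
        members = [symbols[i] for i in rng.choice(50, 8, replace=False)]
        ranked = RankedList(symbols=symbols, metric=metric)
        es, _, running = enrichment_score(ranked, GeneSet(name="s", members=members),
                                          weight_p=1.0)
        expected = oracle_running_sum(symbols, metric, members, 1.0)
        np.testing.assert_allclose(running, expected, atol=1e-12)
        i = int(np.argmax(np.abs(expected)))
        assert es == pytest.approx(expected[i], abs=1e-12)

    def test_scale_invariance_of_metric(self, rng):
        symbols = [f"g{i}" for i in range(30)]
        metric = np.sort(rng.exponential(size=30))[::-1]
        members = symbols[3:9]
        ranked = RankedList(symbols=symbols, metric=metric)
        scaled = RankedList(symbols=symbols, metric=metric * 7.25)
        for p in (0.0, 1.0, 1.5):
            es1, _, _ = enrichment_score(ranked, GeneSet(name="s", members=members), p)
            es2, _, _ = enrichment_score(scaled, GeneSet(name="s", members=members), p)
            assert es1 == pytest.approx(es2, abs=1e-12)

    def test_reversal_negates_unweighted_es(self, rng):
        symbols = [f"g{i}" for i in range(20)]
        metric = np.arange(20, 0, -1.0)
        members = [symbols[i] for i in rng.choice(20, 5, replace=False)]
        es_fwd, _, _ = enrichment_score(RankedList(symbols=symbols, metric=metric),
                                        GeneSet(name="s", members=members), 0.0)
        es_rev, _, _ = enrichment_score(
            RankedList(symbols=symbols[::-1], metric=-metric[::-1]),
            GeneSet(name="s", members=members), 0.0)
        assert es_fwd == pytest.approx(-es_rev, abs=1e-12)

    def test_degenerate_sets_rejected(self):
        ranked = RankedList(symbols=["a", "b"], metric=[1.0, 0.5])
        with pytest.raises(DataError, match="no gene"):
            enrichment_score(ranked, GeneSet(name="s", members=["zz"]))
        with pytest.raises(DataError, match="entire"):
            enrichment_score(ranked, GeneSet(name="s", members=["a", "b"]))


class TestGsea:
    def test_extreme_enrichment_small_p(self):
        n = 200
        symbols = [f"g{i:03d}" for i in range(n)]
        ranked = RankedList(symbols=symbols, metric=np.linspace(5, -5, n))
        res = gsea_from_ranked(ranked, GeneSet(name="top", members=symbols[:10]),
                               n_perm=999, seed=1)
        assert res.es > 0.9
        assert res.p_perm <= 0.01
        assert res.nes_defined and res.nes > 1.0

    def test_p_never_zero_and_reproducible(self, rng):
        symbols = [f"g{i:02d}" for i in range(60)]
        ranked = RankedList(symbols=symbols, metric=np.linspace(3, -3, 60))
        gs = GeneSet(name="s", members=symbols[:5])
        r1 = gsea_from_ranked(ranked, gs, n_perm=200, seed=5)
        r2 = gsea_from_ranked(ranked, gs, n_perm=200, seed=5)
        assert r1.p_perm > 0.0
        assert r1.p_perm == r2.p_perm and r1.es == r2.es

    def test_degenerate_set_rejected(self):
        ranked = RankedList(symbols=[f"g{i}" for i in range(10)],
                            metric=np.arange(10, 0, -1.0))
        with pytest.raises(NumericError, match=">= 2"):
            gsea_from_ranked(ranked, GeneSet(name="s", members=["g1", "zz"]), n_perm=100)

    def test_planted_downstream_set_enriched_in_committed(self, default_sim):
        _, sc_log, truth = default_sim
        committed = truth.committed_mask(sc_log.columns)
        ga = [c for c, m in zip(sc_log.columns, committed) if m]
        gb = [c for c, m in zip(sc_log.columns, committed) if not m]
        res = gsea(sc_log, ga, gb, GeneSet(name="gmp", members=truth.gmp_program_genes),
                   n_perm=500, seed=2)
        assert res.es > 0 and res.p_perm <= 0.05


class TestZscoreSetComparison:
    def test_constant_set_gives_p_one(self):
        df = pd.DataFrame(
            {"c1": [5.0, 1.0], "c2": [5.0, 2.0], "c3": [5.0, 3.0],
             "c4": [5.0, 1.5], "c5": [5.0, 2.5], "c6": [5.0, 3.5]},
            index=["gset", "other"])
        strata = pd.DataFrame({"score": 0.0,
                               "stratum": ["low", "low", "low", "high", "high", "high"]},
                              index=pd.Index([f"c{i}" for i in range(1, 7)], name="cell"))
        summary, p = zscore_set_comparison(df, GeneSet(name="s", members=["gset"]), strata)
        assert p == 1.0
        assert summary.loc["low", "n"] == 3

    def test_handcrafted_two_strata_means(self):
        df = pd.DataFrame([[1.0, 2.0, 3.0, 7.0, 8.0, 9.0]], index=["g"],
                          columns=[f"c{i}" for i in range(6)])
        strata = pd.DataFrame({"score": 0.0,
                               "stratum": ["low"] * 3 + ["high"] * 3},
                              index=pd.Index([f"c{i}" for i in range(6)], name="cell"))
        summary, p = zscore_set_comparison(df, GeneSet(name="s", members=["g"]), strata)
        x = df.loc["g"].to_numpy()
        z = (x - x.mean()) / x.std(ddof=1)
        assert summary.loc["low", "mean"] == pytest.approx(z[:3].mean())
        assert summary.loc["high", "mean"] == pytest.approx(z[3:].mean())
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_marker_strata_separate_downstream_score(self, default_sim):
        _, sc_log, truth = default_sim
        strata = stratify_by_gene(sc_log, truth.planted_marker)
        summary, p = zscore_set_comparison(
            sc_log, GeneSet(name="gmp", members=truth.gmp_program_genes), strata)
        assert summary.loc["high", "mean"] > summary.loc["neg", "mean"]
        assert p < 0.05
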