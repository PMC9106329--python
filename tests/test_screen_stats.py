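"""NT-anchored normalization, mean-variance null, alpha-RRA and gene calls."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import plasmascreen as ps
from plasmascreen.screen_stats import (
    MeanVarModel,
    ScreenConfig,
    alpha_rra_score,
    bh_fdr,
    call_hits,
    fit_mean_variance,
    gene_lfc_and_z,
    normalize_counts,
    permute_gene_pvalues,
    run_screen,
    sgrna_test,
)

from conftest import make_small_library


def _counts_frame(lib, values):
    return pd.DataFrame(values, index=pd.Index(lib.guide_ids, name="guide_id"))


class TestNormalize:
    def test_proportional_columns_give_proportional_factors(self):
        lib = make_small_library(n_genes=0, per_gene=0, n_nt=25)
        rng = np.random.default_rng(0)
        base = rng.integers(10, 100, len(lib))
        m = _counts_frame(lib, {"a": base, "b": 2 * base})
        norm = normalize_counts(m, lib, ScreenConfig(min_nt_guides=20))
        sf = norm.size_factors
        assert sf["b"] / sf["a"] == pytest.approx(2.0)
        # normalized NT values equal across samples
        assert np.allclose(norm.matrix["a"], norm.matrix["b"])

    def test_identical_columns_give_unit_factors(self):
        lib = make_small_library(n_genes=0, per_gene=0, n_nt=20)
        base = np.arange(10, 30)
        m = _counts_frame(lib, {"a": base, "b": base})
        sf = normalize_counts(m, lib, ScreenConfig(min_nt_guides=20)).size_factors
        assert np.allclose(sf, 1.0)

    def test_matches_hand_computed_median_of_ratios(self):
        # 5 NT guides x 2 samples; expected factors computed by hand from
        # ratio-to-geometric-mean per guide, then per-sample median.
        lib = make_small_library(n_genes=0, per_gene=0, n_nt=5)
        a = np.array([10, 20, 40, 80, 100])
        b = np.array([20, 20, 20, 40, 100])
        gm = np.sqrt(a * b)
        exp_a = np.median(a / gm)
        exp_b = np.median(b / gm)
        m = _counts_frame(lib, {"a": a, "b": b})
        sf = normalize_counts(m, lib, ScreenConfig(min_nt_guides=5)).size_factors
        assert sf["a"] == pytest.approx(exp_a, abs=1e-12)
        assert sf["b"] == pytest.approx(exp_b, abs=1e-12)

    def test_nt_median_ratio_invariant(self):
        # after normalization, the median NT ratio to the raw-count
        # geometric-mean pseudo-sample is 1 in every sample
        lib = make_small_library(n_genes=2, per_gene=3, n_nt=30, seed=2)
        rng = np.random.default_rng(1)
        m = _counts_frame(
            lib, {s: rng.integers(50, 500, len(lib)) for s in ("a", "b", "c")}
        )
        norm = normalize_counts(m, lib, ScreenConfig(min_nt_guides=20))
        nt_raw = m.loc[lib.nt_guide_ids].astype(float)
        gm = np.exp(np.log(nt_raw).mean(axis=1))
        nt_norm = norm.matrix.loc[lib.nt_guide_ids]
        for s in nt_norm.columns:
            assert np.median(nt_norm[s] / gm) == pytest.approx(1.0, abs=1e-9)

    def test_too_few_nt_guides_errors_with_advice(self):
        lib = make_small_library(n_genes=2, per_gene=2, n_nt=3)
        m = _counts_frame(lib, {"a": np.arange(7) + 1, "b": np.arange(7) + 2})
        with pytest.raises(ValueError, match="total"):
            normalize_counts(m, lib, ScreenConfig())


class TestMeanVarModel:
    def _norm(self, lib, x1, x2):
        m = _counts_frame(lib, {"a": x1, "b": x2})
        return ps.NormalizedCounts(m.astype(float), pd.Series({"a": 1.0, "b": 1.0}), 0.5)

    def test_poisson_counts_give_near_poisson_model(self):
        rng = np.random.default_rng(10)
        lib = make_small_library(n_genes=0, per_gene=0, n_nt=2000)
        mu = np.exp(rng.uniform(np.log(50), np.log(5000), len(lib)))
        x1, x2 = rng.poisson(mu), rng.poisson(mu)
        model = fit_mean_variance(self._norm(lib, x1, x2), lib, ("a", "b"))
        grid = np.array([100.0, 500.0, 2000.0])
        assert np.all(np.abs(model.predict(grid) / grid - 1) < 0.2)

    def test_recovers_quadratic_overdispersion(self):
        rng = np.random.default_rng(11)
        lib = make_small_library(n_genes=0, per_gene=0, n_nt=5000)
        mu = np.exp(rng.uniform(np.log(50), np.log(5000), len(lib)))
        n = 1 / 0.1  # var = mu + 0.1 mu^2
        x1 = rng.negative_binomial(n, n / (n + mu))
        x2 = rng.negative_binomial(n, n / (n + mu))
        model = fit_mean_variance(self._norm(lib, x1, x2), lib, ("a", "b"))
        assert model.b == pytest.approx(2.0, abs=0.3)
        assert model.k == pytest.approx(0.1, abs=0.05)

    def test_too_few_nt_guides(self):
        lib = make_small_library(n_genes=0, per_gene=0, n_nt=3)
        with pytest.raises(ValueError, match="NT guides"):
            fit_mean_variance(
                self._norm(lib, np.array([10, 20, 30]), np.array([12, 18, 33])),
                lib,
                ("a", "b"),
            )


class TestSgrnaTest:
    def _run(self, lib, c, t, k=0.0, b=1.0):
        m = _counts_frame(lib, {"c": c, "t": t}).astype(float)
        norm = ps.NormalizedCounts(m, pd.Series({"c": 1.0, "t": 1.0}), 0.5)
        model = MeanVarModel(k=k, b=b, fit_n=99)
        return sgrna_test(norm, model, "c", "t", ScreenConfig())

    def test_equal_counts_poisson_tails(self):
        lib = make_small_library(n_genes=1, per_gene=1, n_nt=0)
        df = self._run(lib, np.array([200]), np.array([200]))
        pe, pd_ = df.p_enrich.iloc[0], df.p_deplete.iloc[0]
        assert pe + pd_ == pytest.approx(1 + sps.poisson.pmf(200, 200), abs=1e-12)
        assert 0.4 < pe < 0.6 and 0.4 < pd_ < 0.6

    def test_zero_k_equals_exact_poisson(self):
        lib = make_small_library(n_genes=3, per_gene=3, n_nt=5, seed=3)
        rng = np.random.default_rng(4)
        c = rng.integers(20, 500, len(lib))
        t = rng.integers(20, 500, len(lib))
        df = self._run(lib, c, t, k=0.0)
        assert np.allclose(df.p_enrich, sps.poisson.sf(np.round(t) - 1, c), atol=1e-12)
        assert np.allclose(df.p_deplete, sps.poisson.cdf(np.round(t), c), atol=1e-12)

    def test_enrichment_p_monotone_in_treatment_count(self):
        lib = make_small_library(n_genes=1, per_gene=1, n_nt=0)
        c = 50
        ps_ = [
            self._run(lib, np.array([c]), np.array([t])).p_enrich.iloc[0]
            for t in (c, 2 * c, 5 * c, 10 * c)
        ]
        assert all(a > b for a, b in zip(ps_, ps_[1:]))
        df = self._run(lib, np.array([c]), np.array([10 * c]))
        assert df.p_enrich.iloc[0] < df.p_deplete.iloc[0]

    def test_ranks_are_permutations(self):
        lib = make_small_library(n_genes=5, per_gene=4, n_nt=10, seed=5)
        rng = np.random.default_rng(6)
        df = self._run(
            lib, rng.integers(10, 400, len(lib)), rng.integers(10, 400, len(lib))
        )
        n = len(df)
        for col in ("rank_enrich", "rank_deplete"):
            assert sorted(df[col]) == list(range(1, n + 1))


def brute_force_rra(u_selected, m):
    """Independent oracle: direct Beta CDF evaluation over all k."""
    u = sorted(u_selected)
    if not u:
        return 1.0
    return min(
        sps.beta.cdf(u[k - 1], k, m - k + 1) for k in range(1, len(u) + 1)
    )


class TestAlphaRRA:
    def test_single_selected_guide_is_identity(self):
        assert alpha_rra_score([0.01], 1) == pytest.approx(0.01, abs=1e-15)

    def test_two_guides_closed_form(self):
        # order statistics of m=2 uniforms: Beta(1,2) cdf = 1-(1-u)^2,
        # Beta(2,1) cdf = u^2
        score = alpha_rra_score([0.01, 0.02], 2)
        expected = min(1 - 0.99**2, 0.02**2)
        assert expected == pytest.approx(4e-4, abs=1e-12)
        assert score == pytest.approx(expected, abs=1e-15)

    def test_no_selected_guides_scores_one(self):
        assert alpha_rra_score([], 5) == 1.0

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(123)
        worst = 0.0
        for _ in range(1000):
            m = int(rng.integers(1, 12))
            j = int(rng.integers(0, m + 1))
            u = np.sort(rng.uniform(0, 0.3, size=j))
            got = alpha_rra_score(u, m)
            exp = brute_force_rra(u, m)
            worst = max(worst, abs(got - exp))
        assert worst <= 1e-12


class TestPermutationP:
    def _toy_stats(self, p_by_guide, lib):
        n = len(lib)
        gids = lib.guide_ids
        p = np.array([p_by_guide[g] for g in gids])
        order = np.argsort(p)
        rank = np.empty(n, int)
        rank[order] = np.arange(1, n + 1)
        return pd.DataFrame(
            {
                "lfc": 1.0,
                "p_enrich": p,
                "p_deplete": 1 - p,
                "rank_enrich": rank,
                "rank_deplete": n + 1 - rank,
                "selected_enrich": p < 0.05,
                "selected_deplete": (1 - p) < 0.05,
            },
            index=pd.Index(gids, name="guide_id"),
        )

    def test_floor_and_ceiling(self):
        # GENE1's six guides take the six best ranks; a null draw can only
        # match its score by re-drawing exactly that set (1 in C(60,6)),
        # so its p sits at the 1/(n+1) floor. GENE10 has no selected guide.
        lib = make_small_library(n_genes=10, per_gene=6, n_nt=0, seed=7)
        gids = lib.guide_ids
        p = {g: (1e-9 if g.startswith("GENE1_") else 0.9) for g in gids}
        stats = self._toy_stats(p, lib)
        cfg = ScreenConfig(n_permutations=500)
        out = permute_gene_pvalues(
            stats, lib.gene_map(), "positive", cfg, np.random.default_rng(0)
        )
        assert out["GENE1"][1] == pytest.approx(1 / 501)
        assert out["GENE10"][0] == 1.0 and out["GENE10"][1] == 1.0

    def test_matches_exhaustive_enumeration_on_toy(self):
        """3 genes x 2 guides: all C(6,2)=15 unordered pairs enumerable."""
        lib = make_small_library(n_genes=3, per_gene=2, n_nt=0, seed=9)
        gids = lib.guide_ids
        pvals = dict(zip(gids, [0.001, 0.02, 0.04, 0.2, 0.5, 0.9]))
        stats = self._toy_stats(pvals, lib)
        n_total = len(stats)
        u = stats["rank_enrich"].to_numpy(float) / n_total
        sel = stats["selected_enrich"].to_numpy(bool)

        def score(pair):
            idx = list(pair)
            return alpha_rra_score(u[idx][sel[idx]], 2)

        null = [score(c) for c in itertools.combinations(range(6), 2)]
        cfg = ScreenConfig(n_permutations=10_000)
        got = permute_gene_pvalues(
            stats, lib.gene_map(), "positive", cfg, np.random.default_rng(1)
        )
        for gene, gid_pair in lib.gene_map().items():
            idx = [gids.index(g) for g in gid_pair]
            obs = score(idx)
            exact = np.mean([s <= obs for s in null])
            se = np.sqrt(exact * (1 - exact) / cfg.n_permutations)
            assert abs(got[gene][1] - exact) <= 4 * se + 2 / cfg.n_permutations, gene


class TestBhFdr:
    @pytest.mark.parametrize(
        "p,expected",
        [
            ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
            ([0.5], [0.5]),
            ([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]),
            ([0.03, 0.01, 0.02], [0.03, 0.03, 0.03]),  # order preserved
            ([0.01, 0.4, 0.9], [0.03, 0.6, 0.9]),
        ],
    )
    def test_examples(self, p, expected):
        assert np.allclose(bh_fdr(p), expected, atol=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


class TestGeneLfcZ:
    def test_median_of_same_direction_guides(self):
        lfc, z, flagged = gene_lfc_and_z(
            [1.0, 1.2, 1.4, -0.2], "positive", np.random.default_rng(0).normal(0, 0.5, 50)
        )
        assert lfc == pytest.approx(1.2) and not flagged

    def test_z_arithmetic(self):
        nt = np.array([-0.5, 0.5, -0.5, 0.5])  # mean 0
        sd = nt.std(ddof=1)
        _, z, _ = gene_lfc_and_z([1.2, 1.2, 1.2], "positive", nt)
        assert z == pytest.approx(1.2 / sd)

    def test_gene_lfc_at_nt_mean_gives_zero_z(self):
        nt = np.array([0.2, 0.4, 0.6, 0.8])
        _, z, _ = gene_lfc_and_z([0.5, 0.5], "positive", nt)
        assert z == pytest.approx(0.0)

    def test_no_same_direction_guides_flags(self):
        lfc, z, flagged = gene_lfc_and_z([-1.0, -2.0], "positive", [0.1, -0.1, 0.2])
        assert (lfc, z, flagged) == (0.0, 0.0, True)

    def test_zero_nt_spread_errors(self):
        with pytest.raises(ValueError, match="spread"):
            gene_lfc_and_z([1.0], "positive", [0.5, 0.5, 0.5])


class TestCallHits:
    @pytest.mark.parametrize(
        "z,fdr,expected",
        [
            (2.0, 0.049, True),  # boundary inclusive on z
            (1.9, 0.001, False),
            (-3.0, 0.2, False),
            (-2.0, 0.049, True),
            (2.5, 0.05, False),  # fdr strictly below cutoff
        ],
    )
    def test_hit_rule(self, z, fdr, expected):
        df = pd.DataFrame({"z": [z], "fdr": [fdr]})
        assert call_hits(df, ScreenConfig()).is_hit.iloc[0] == expected


class TestRunScreen:
    def test_byte_identical_under_seed(self):
        cfg = ps.SimConfig(n_genes=20, n_pos_controls=0, n_nt=50, seed=42)
        lib = ps.make_library(cfg)
        counts = ps.simulate_screen_counts(lib, ps.EffectSpec(), cfg)
        sc = ScreenConfig(seed=7, n_permutations=500)
        out1 = run_screen(counts, lib, "day4", "day8", sc)
        out2 = run_screen(counts, lib, "day4", "day8", sc)
        for a, b in zip(out1, out2):
            assert a.to_csv() == b.to_csv()

    def test_nt_pseudo_gene_z_is_calibrated(self):
        """Pseudo-genes of NT guides referenced to the pseudo-gene null
        distribution have mean z near 0 and spread near 1."""
        cfg = ps.SimConfig(n_genes=50, n_pos_controls=0, n_nt=500, seed=21)
        lib = ps.make_library(cfg)
        counts = ps.simulate_screen_counts(lib, ps.EffectSpec(), cfg)
        sc = ScreenConfig(seed=2)
        norm = ps.normalize_counts(counts, lib, sc)
        model = ps.fit_mean_variance(norm, lib, ("day4", "day8"))
        sg = ps.sgrna_test(norm, model, "day4", "day8", sc)
        nt_lfcs = sg.loc[lib.nt_guide_ids, "lfc"].to_numpy()
        def draw_medians(rng, n):
            return np.array(
                [
                    np.median(nt_lfcs[rng.choice(len(nt_lfcs), 10, replace=False)])
                    for _ in range(n)
                ]
            )

        # reference distribution from one stream, test pseudo-genes from another
        ref = draw_medians(np.random.default_rng(3), 400)
        pseudo = draw_medians(np.random.default_rng(4), 400)
        z = (pseudo - ref.mean()) / ref.std(ddof=1)
        assert abs(z.mean()) <= 0.2
        assert 0.7 <= z.std(ddof=1) <= 1.4
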