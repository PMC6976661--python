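"""Community-composition statistics on OTU tables."""

import numpy as np
import pandas as pd
import pytest

from phyllonet.community import (
    OtuTable,
    anosim,
    assign_rank_by_identity,
    bray_curtis,
    filter_otus,
    forward_select,
    hellinger,
    indicator_features,
    permanova,
    rarefaction_curve,
    rarefy,
    richness_diversity_regression,
    wilcoxon_rank_sum,
)
from phyllonet.distmat import DistanceMatrix

from oracles import expected_richness_bruteforce, mannwhitney_exact_bruteforce


def table_from(counts, samples=None, **kw):
    counts = np.asarray(counts)
    samples = samples or [f"s{i}" for i in range(counts.shape[0])]
    otus = [f"o{j}" for j in range(counts.shape[1])]
    return OtuTable(pd.DataFrame(counts, index=samples, columns=otus), **kw)


class TestFilterOtus:
    def test_ten_read_boundary(self):
        t = table_from([[9, 10, 3], [0, 0, 4]])
        filtered, report = filter_otus(t)
        assert filtered.otus == ["o1"]  # 9 and 7 removed, 10 kept
        assert set(report["removed_low_count"]) == {"o0", "o2"}

    def test_zero_threshold_is_identity(self):
        t = table_from([[1, 0], [0, 2]])
        filtered, _ = filter_otus(t, min_reads=0)
        assert filtered.otus == t.otus

    def test_guild_exclusion_with_toy_taxonomy(self):
        t = table_from([[50, 60, 70, 80, 90]])
        tax = pd.DataFrame(
            {"guild": ["undefined", "ectomycorrhizal", "undefined",
                       "animal_pathogen", "undefined"]},
            index=t.otus,
        )
        filtered, report = filter_otus(
            t, taxonomy=tax, exclude_guilds=("ectomycorrhizal", "animal_pathogen")
        )
        assert filtered.otus == ["o0", "o2", "o4"]
        assert set(report["removed_guild"]) == {"o1", "o3"}


class TestRarefy:
    def test_sample_at_depth_unchanged_and_sums_exact(self):
        t = table_from([[5, 5, 0], [20, 10, 10]])
        r = rarefy(t, depth=10, seed=0)
        np.testing.assert_array_equal(r.counts.iloc[0], [5, 5, 0])
        assert (r.counts.sum(axis=1) == 10).all()
        assert r.state == "rarefied"

    def test_below_depth_sample_named_in_error(self):
        t = table_from([[3, 2], [50, 50]], samples=["shallow", "deep"])
        with pytest.raises(ValueError, match="shallow"):
            rarefy(t, depth=10)

    def test_no_new_otus_appear(self, rng):
        counts = rng.integers(0, 40, size=(6, 30))
        counts[:, 0] = 0
        counts += 0
        t = table_from(counts + np.eye(6, 30, dtype=int) * 50)
        r = rarefy(t, depth=int(t.counts.sum(axis=1).min()), seed=1)
        assert not ((r.counts > 0) & (t.counts == 0)).any().any()

    def test_order_independent_per_sample_streams(self):
        t = table_from([[30, 20, 10], [5, 25, 30]], samples=["a", "b"])
        t_rev = OtuTable(t.counts.iloc[::-1])
        r1 = rarefy(t, depth=20, seed=3)
        r2 = rarefy(t_rev, depth=20, seed=3)
        np.testing.assert_array_equal(r1.counts.loc["a"], r2.counts.loc["a"])

    def test_mean_richness_matches_analytic_expectation(self):
        t = table_from([[6, 3, 2, 1]])
        depth = 5
        expected = rarefaction_curve(t, [depth]).expected_richness.iloc[0, 0]
        reps = 200
        rich = [
            (rarefy(t, depth=depth, seed=s).counts.iloc[0] > 0).sum()
            for s in range(reps)
        ]
        se = np.std(rich, ddof=1) / np.sqrt(reps)
        assert abs(np.mean(rich) - expected) < 3 * se + 1e-9


class TestRarefactionCurve:
    def test_single_draw_always_one_species(self):
        t = table_from([[4, 5, 1]])
        assert rarefaction_curve(t, [1]).expected_richness.iloc[0, 0] == pytest.approx(1.0)

    def test_enumeration_oracle_on_tiny_counts(self):
        t = table_from([[2, 1]])
        es2 = rarefaction_curve(t, [2]).expected_richness.iloc[0, 0]
        assert es2 == pytest.approx(5 / 3, abs=1e-12)
        assert es2 == pytest.approx(expected_richness_bruteforce([2, 1], 2))

    def test_full_depth_equals_observed_richness_and_monotone(self):
        t = table_from([[7, 3, 0, 2]])
        depths = [1, 3, 6, 9, 12]
        curve = rarefaction_curve(t, depths).expected_richness.iloc[0]
        assert curve.iloc[-1] == pytest.approx(3)
        assert (np.diff(curve.to_numpy()) >= -1e-12).all()

    def test_depth_beyond_total_rejected(self):
        with pytest.raises(ValueError):
            rarefaction_curve(table_from([[3, 2]]), [6])


class TestTransformsAndBrayCurtis:
    def test_hellinger_row(self):
        t = table_from([[1, 3]])
        h = hellinger(t)
        np.testing.assert_allclose(h.iloc[0], [0.5, np.sqrt(0.75)])

    def test_hellinger_zero_row_rejected_and_unit_norm(self, rng):
        with pytest.raises(ValueError):
            hellinger(table_from([[0, 0]]))
        h = hellinger(table_from(rng.integers(0, 50, (5, 8)) + 1))
        np.testing.assert_allclose((h**2).sum(axis=1), 1.0, atol=1e-12)

    def test_bray_curtis_values(self):
        m = pd.DataFrame([[1, 2], [2, 1], [1, 2], [0, 3]], dtype=float)
        d = bray_curtis(m)
        assert d.values[0, 1] == pytest.approx(2 / 6)
        assert d.values[0, 2] == 0.0
        m2 = pd.DataFrame([[1, 0], [0, 5]], dtype=float)
        assert bray_curtis(m2).values[0, 1] == 1.0

    def test_bray_curtis_two_zero_rows_rejected(self):
        with pytest.raises(ValueError):
            bray_curtis(pd.DataFrame([[0, 0], [0, 0], [1, 1]], dtype=float))


class TestAnosim:
    def test_perfect_separation_r_one(self):
        # 2 groups x 3 members; all between distances exceed all within
        within, between = 1.0, 10.0
        n = 6
        vals = np.full((n, n), between)
        vals[:3, :3] = within
        vals[3:, 3:] = within
        np.fill_diagonal(vals, 0)
        d = DistanceMatrix([f"s{i}" for i in range(n)], vals)
        res = anosim(d, ["a"] * 3 + ["b"] * 3, n_perm=99, seed=0)
        assert res.R == pytest.approx(1.0)

    def test_random_labels_r_centred_at_zero_and_bounded(self, random_distance):
        rs = []
        for seed in range(100):
            d = random_distance(12, seed=seed)
            groups = np.random.default_rng(seed).permutation(["a"] * 6 + ["b"] * 6)
            r = anosim(d, groups, n_perm=99, seed=seed).R
            assert -1.0 - 1e-12 <= r <= 1.0 + 1e-12
            rs.append(r)
        assert abs(np.mean(rs)) < 0.05

    def test_degenerate_groups_rejected(self, random_distance):
        with pytest.raises(ValueError):
            anosim(random_distance(4), ["a", "a", "a", "b"])


class TestPermanova:
    def test_univariate_euclidean_equals_classical_anova_f(self):
        rng = np.random.default_rng(0)
        y = np.concatenate([rng.normal(0, 1, 8), rng.normal(1.2, 1, 8)])
        d = DistanceMatrix(
            [f"s{i}" for i in range(16)], np.abs(y[:, None] - y[None, :])
        )
        x = np.array([0] * 8 + [1] * 8, float)
        res = permanova(d, {"group": x}, n_perm=99, seed=0)
        from scipy.stats import f_oneway

        f_classic = f_oneway(y[:8], y[8:]).statistic
        assert res.table.loc["group", "F"] == pytest.approx(f_classic, abs=1e-9)

    def test_decomposition_identity(self, random_distance):
        d = random_distance(14)
        rng = np.random.default_rng(1)
        terms = {
            "a": rng.normal(size=(14, 2)),
            "b": rng.normal(size=14),
        }
        res = permanova(d, terms, n_perm=99, seed=0)
        ss = res.table
        assert ss.loc["Total", "SS"] == pytest.approx(
            ss.drop("Total").SS.sum(), abs=1e-9
        )

    def test_null_predictor_calibrated(self, random_distance):
        hits = 0
        reps = 100
        for seed in range(reps):
            d = random_distance(16, seed=seed)
            x = np.random.default_rng(seed + 1).normal(size=16)
            p = permanova(d, {"x": x}, n_perm=99, seed=seed).table.loc["x", "p"]
            if p <= 0.05:
                hits += 1
        assert hits / reps <= 0.07

    def test_rank_deficient_term_skipped_with_warning(self, random_distance):
        d = random_distance(10)
        x = np.random.default_rng(2).normal(size=10)
        with pytest.warns(UserWarning, match="rank-deficient"):
            res = permanova(d, {"a": x, "dup": x.copy()}, n_perm=99, seed=0)
        assert "dup" not in res.table.index

    def test_strata_restrict_permutations(self, random_distance):
        # with singleton strata only the identity permutation exists
        d = random_distance(8)
        x = np.random.default_rng(3).normal(size=8)
        res = permanova(d, {"x": x}, strata=np.arange(8), n_perm=99, seed=0)
        assert res.table.loc["x", "p"] == pytest.approx(1.0)


class TestForwardSelect:
    def _candidates(self, n, k, seed):
        rng = np.random.default_rng(seed)
        q, _ = np.linalg.qr(rng.normal(size=(n, k)))
        return pd.DataFrame(q, columns=[f"ax{j}" for j in range(k)])

    def test_alpha_one_admits_every_candidate(self, random_distance):
        d = random_distance(12)
        cands = self._candidates(12, 4, 0)
        sel = forward_select(d, cands, alpha=1.0, n_perm=99, seed=0)
        assert set(sel["axis"]) == set(cands.columns)

    def test_planted_axis_selected_first(self):
        rng = np.random.default_rng(4)
        n = 30
        cands = self._candidates(n, 6, 4)
        y = 3.0 * cands["ax2"].to_numpy() + rng.normal(0, 0.1, n)
        d = DistanceMatrix([f"s{i}" for i in range(n)],
                           np.abs(y[:, None] - y[None, :]))
        sel = forward_select(d, cands, n_perm=99, seed=0)
        assert len(sel) >= 1
        assert sel["axis"].iloc[0] == "ax2"

    def test_pure_noise_rarely_selects(self, random_distance):
        empty = 0
        reps = 50
        for seed in range(reps):
            d = random_distance(15, seed=seed)
            cands = self._candidates(15, 8, 900 + seed)
            if len(forward_select(d, cands, n_perm=99, seed=seed)) == 0:
                empty += 1
        assert empty / reps >= 0.90


class TestWilcoxon:
    def test_exact_p_for_separated_triplets(self):
        u, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_u_zero_when_x_below_y(self):
        u, _ = wilcoxon_rank_sum([1, 2], [3, 4, 5])
        assert u == 0.0

    def test_tied_data_matches_enumeration_oracle(self):
        cases = [
            ([1, 2, 2, 3], [2, 3, 3, 4]),
            ([1, 1, 2], [1, 2, 2, 3]),
            ([5, 5, 5], [5, 5, 6]),
        ]
        for x, y in cases:
            _, p = wilcoxon_rank_sum(x, y)
            _, p_exact = mannwhitney_exact_bruteforce(x, y)
            assert p == pytest.approx(p_exact, abs=1e-12)

    def test_identical_samples_p_one(self):
        u, p = wilcoxon_rank_sum([2, 2], [2, 2, 2])
        assert p == 1.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestRichnessRegression:
    def test_perfect_line_r2_one(self):
        res = richness_diversity_regression([2, 4, 6, 8], [1, 2, 3, 4])
        assert res.r2 == pytest.approx(1.0)
        assert res.slope == pytest.approx(2.0)

    def test_six_point_normal_equations_oracle(self):
        x = np.array([0.41, 0.52, 0.48, 0.61, 0.55, 0.68])
        y = np.array([210.0, 260, 235, 300, 275, 320])
        res = richness_diversity_regression(y, x)
        xc = x - x.mean()
        slope = (xc * (y - y.mean())).sum() / (xc**2).sum()
        r2 = np.corrcoef(x, y)[0, 1] ** 2
        assert res.slope == pytest.approx(slope, abs=1e-9)
        assert res.r2 == pytest.approx(r2, abs=1e-12)
        from scipy.stats import f as fdist

        f_stat = r2 / (1 - r2) * (6 - 2)
        assert res.p == pytest.approx(fdist.sf(f_stat, 1, 4), abs=1e-12)

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError):
            richness_diversity_regression([1, 2, 3], [5, 5, 5])


class TestIndicatorFeatures:
    def _table(self, a_mean, b_mean, n=10, seed=0, n_otus=4):
        rng = np.random.default_rng(seed)
        base = rng.integers(500, 1500, size=(2 * n, n_otus)).astype(float)
        counts = np.column_stack([
            np.concatenate([
                rng.poisson(a_mean, n), rng.poisson(b_mean, n)
            ]),
            base,
        ]).astype(int)
        t = table_from(counts)
        classes = pd.Series(["A"] * n + ["B"] * n, index=t.samples)
        return t, classes

    def test_identical_otu_never_selected(self):
        t, classes = self._table(800, 800, seed=1)
        res = indicator_features(t, classes, seed=0)
        # the focal OTU o0 has no class signal; nothing must be certain
        assert "o0" not in set(res["feature"]) or res.empty

    def test_large_mean_gap_selected_with_expected_effect(self):
        # class means ~50,000 vs ~500 on the per-million scale
        rng = np.random.default_rng(2)
        n = 12
        focal = np.concatenate([rng.poisson(5000, n), rng.poisson(50, n)])
        rest = rng.integers(3000, 5000, size=(2 * n, 20))
        counts = np.column_stack([focal, rest])
        t = table_from(counts)
        classes = pd.Series(["A"] * n + ["B"] * n, index=t.samples)
        res = indicator_features(t, classes, seed=0)
        assert "o0" in set(res["feature"])
        row = res[res["feature"] == "o0"].iloc[0]
        assert row["class"] == "A"
        assert row["effect"] == pytest.approx(np.log10(49_500), abs=0.35)

    def test_default_threshold_is_three(self):
        import inspect

        sig = inspect.signature(indicator_features)
        assert sig.parameters["effect_threshold"].default == 3.0

    def test_exchangeable_classes_false_positive_rate(self):
        rng = np.random.default_rng(3)
        selected = 0
        total = 0
        for seed in range(50):
            counts = np.random.default_rng(seed).integers(
                100, 10_000, size=(12, 10)
            )
            t = table_from(counts)
            classes = pd.Series(["A"] * 6 + ["B"] * 6, index=t.samples)
            res = indicator_features(t, classes, seed=seed)
            selected += len(res)
            total += 10
        assert selected / total <= 0.05

    def test_three_classes_rejected(self):
        t = table_from([[1, 2], [3, 4], [5, 6]])
        classes = pd.Series(["A", "B", "C"], index=t.samples)
        with pytest.raises(ValueError):
            indicator_features(t, classes)


class TestAssignRank:
    LINEAGE = dict(kingdom="Fungi", phylum="Ascomycota", **{"class": "Dothideomycetes"},
                   order="Capnodiales", family="Capnodiaceae", genus="Capnodium")

    @pytest.mark.parametrize(
        "identity,deepest_kept,first_dropped",
        [
            (92.0, "genus", None),
            (87.0, "family", "genus"),
            (83.0, "order", "family"),
            (77.0, "class", "order"),
            (74.0, "kingdom", "phylum"),
        ],
    )
    def test_identity_thresholds(self, identity, deepest_kept, first_dropped):
        out = assign_rank_by_identity(identity, 1e-80, self.LINEAGE)
        assert out[deepest_kept] == self.LINEAGE[deepest_kept]
        if first_dropped:
            assert out[first_dropped] is None

    def test_unreliable_evalue_rejects_record(self):
        assert assign_rank_by_identity(95.0, 1e-40, self.LINEAGE) is None
        assert assign_rank_by_identity(95.0, 1e-60, self.LINEAGE) is not None

    def test_malformed_lineage_rejected(self):
        with pytest.raises(ValueError, match="missing ranks"):
            assign_rank_by_identity(90.0, 1e-80, {"kingdom": "Fungi"})
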