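"""ANOVA, Duncan's multiple range test, letters, and Pearson matrices."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from redoxpheno.stats import (
    DuncanMRT,
    anova_oneway,
    duncan_mrt,
    duncan_quantile,
    lateral_root_density,
    pearson_matrix,
)

# ---------------------------------------------------------------------------
# independent brute-force oracle for Duncan's test


def brute_force_duncan(groups, alpha=0.05):
    """Enumerate every span of the ordered means independently.

    A pair is significant iff the raw range test succeeds for its own span
    AND for every span enclosing it (the containment rule), evaluated
    directly rather than stepwise.
    """
    labels = list(groups)
    means = {g: float(np.mean(groups[g])) for g in labels}
    order = sorted(labels, key=lambda g: (means[g], str(g)))
    m = np.array([means[g] for g in order])
    k = len(order)
    a = anova_oneway(groups)
    ns = np.array([len(groups[g]) for g in order], dtype=float)
    n_eff = float(ns[0]) if np.all(ns == ns[0]) else k / np.sum(1.0 / ns)
    se = np.sqrt(a.mse / n_eff)

    qcache: dict[int, float] = {}
    rawcache: dict[tuple, bool] = {}

    def raw(i, j):
        p = j - i + 1
        if (i, j) not in rawcache:
            if p not in qcache:
                qcache[p] = sps.studentized_range.ppf(
                    (1 - alpha) ** (p - 1), p, a.df_within
                )
            rawcache[(i, j)] = (m[j] - m[i]) > qcache[p] * se
        return rawcache[(i, j)]

    sig = {}
    for i in range(k):
        for j in range(i + 1, k):
            sig[(order[i], order[j])] = all(
                raw(ii, jj) for ii in range(0, i + 1) for jj in range(j, k)
            )
    return sig


def random_instance(rng, max_k=6):
    k = int(rng.integers(2, max_k + 1))
    sep = float(rng.uniform(0.0, 3.0))
    return {
        f"g{i}": rng.normal(i * sep * rng.uniform(0.2, 1.0), 1.0, int(rng.integers(4, 12)))
        for i in range(k)
    }


def partition_from_letters(letters, sig_index):
    """Pairwise decisions implied by a compact letter display."""
    out = {}
    for a in sig_index:
        for b in sig_index:
            if str(a) < str(b):
                shared = set(letters[a]) & set(letters[b])
                out[(a, b)] = len(shared) == 0
    return out


# ---------------------------------------------------------------------------


class TestLateralRootDensity:
    def test_basic_conversion_to_per_cm(self):
        assert lateral_root_density(10, 50.0) == pytest.approx(2.0)

    def test_zero_count(self):
        assert lateral_root_density(0, 33.0) == 0.0

    def test_scale_invariance(self):
        assert lateral_root_density(8, 40.0) == pytest.approx(
            lateral_root_density(16, 80.0)
        )

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            lateral_root_density(4, 0.0)


class TestAnova:
    def test_identical_groups_give_zero_f(self):
        g = {"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]}
        res = anova_oneway(g)
        assert res.f_statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_separated_groups_drive_p_to_zero(self):
        g = {"a": [0.0, 1e-6, -1e-6], "b": [1.0, 1.0 + 1e-6, 1.0 - 1e-6]}
        res = anova_oneway(g)
        assert res.p_value < 1e-12

    def test_three_group_textbook_case_matches_sums_of_squares_oracle(self):
        groups = {
            "a": np.array([6.0, 8.0, 4.0, 5.0, 3.0, 4.0]),
            "b": np.array([8.0, 12.0, 9.0, 11.0, 6.0, 8.0]),
            "c": np.array([13.0, 9.0, 11.0, 8.0, 7.0, 12.0]),
        }
        # brute-force oracle: explicit deviations from means
        allv = np.concatenate(list(groups.values()))
        grand = allv.mean()
        ssb = sum(len(v) * (np.mean(v) - grand) ** 2 for v in groups.values())
        ssw = sum(float(np.sum((np.asarray(v) - np.mean(v)) ** 2)) for v in groups.values())
        f_expected = (ssb / 2) / (ssw / 15)
        res = anova_oneway(groups)
        assert res.f_statistic == pytest.approx(f_expected, rel=1e-12)
        assert res.df_between == 2 and res.df_within == 15
        # independent route
        f_sp, p_sp = sps.f_oneway(*groups.values())
        assert res.f_statistic == pytest.approx(f_sp)
        assert res.p_value == pytest.approx(p_sp)

    def test_degenerate_zero_variance_reported_undefined(self):
        res = anova_oneway({"a": [2.0, 2.0], "b": [2.0, 2.0]})
        assert np.isnan(res.f_statistic)
        assert "degenerate_zero_mse" in res.flags

    def test_input_validation(self):
        with pytest.raises(ValueError):
            anova_oneway({"a": [1.0, 2.0]})
        with pytest.raises(ValueError):
            anova_oneway({"a": [1.0], "b": [1.0, 2.0]})


class TestDuncanQuantiles:
    # critical studentized ranges for Duncan's test at alpha = 0.05, from
    # published tables (3-decimal agreement required)
    PUBLISHED = {
        (2, 10): 3.151, (3, 10): 3.293, (4, 10): 3.376, (5, 10): 3.430,
        (2, 20): 2.950, (3, 20): 3.097, (4, 20): 3.190, (5, 20): 3.255,
    }

    @pytest.mark.parametrize("p,df", sorted(PUBLISHED))
    def test_matches_published_tables(self, p, df):
        assert duncan_quantile(p, df, 0.05) == pytest.approx(
            self.PUBLISHED[(p, df)], abs=5e-4
        )

    def test_adjacent_span_uses_plain_alpha_level(self):
        # p = 2 protection level is alpha itself: never more conservative
        # than an unprotected pairwise studentized-range test
        for df in (5, 10, 30):
            assert duncan_quantile(2, df, 0.05) == pytest.approx(
                float(sps.studentized_range.ppf(0.95, 2, df)), abs=1e-9
            )


class TestDuncan:
    def test_identical_groups_share_one_letter(self):
        rng = np.random.default_rng(0)
        base = rng.normal(10, 1, 8)
        res = duncan_mrt({"a": base, "b": base, "c": base})
        assert len({res.letters[g] for g in "abc"}) == 1

    def test_two_groups_reduce_to_t_type_comparison(self):
        rng = np.random.default_rng(1)
        for trial in range(40):
            n = 6
            delta = rng.uniform(0, 2.5)
            g = {"a": rng.normal(0, 1, n), "b": rng.normal(delta, 1, n)}
            res = duncan_mrt(g)
            # closed-form two-group reduction: pooled t-test at level alpha
            t, p = sps.ttest_ind(g["a"], g["b"])
            assert bool(res.significant.loc["a", "b"]) == bool(p <= 0.05)

    def test_large_separations_give_distinct_letters(self):
        rng = np.random.default_rng(2)
        g = {f"g{i}": rng.normal(i * 30.0, 1.0, 8) for i in range(4)}
        res = duncan_mrt(g)
        assert len({res.letters[k] for k in g}) == 4

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(1000 + seed)
        groups = random_instance(rng)
        res = duncan_mrt(groups)
        oracle = brute_force_duncan(groups)
        for (a, b), expected in oracle.items():
            assert bool(res.significant.loc[a, b]) == expected, (a, b)

    @pytest.mark.parametrize("seed", range(25))
    def test_letter_display_round_trips_pairwise_decisions(self, seed):
        rng = np.random.default_rng(2000 + seed)
        groups = random_instance(rng)
        res = duncan_mrt(groups)
        implied = partition_from_letters(res.letters, list(groups))
        for (a, b), sig in implied.items():
            assert sig == bool(res.significant.loc[a, b]), (a, b)

    def test_unbalanced_groups_flagged_and_use_harmonic_mean(self):
        rng = np.random.default_rng(3)
        g = {"a": rng.normal(0, 1, 5), "b": rng.normal(0, 1, 9), "c": rng.normal(5, 1, 7)}
        res = duncan_mrt(g)
        assert "unbalanced_harmonic_mean" in res.flags
        oracle = brute_force_duncan(g)
        for (a, b), expected in oracle.items():
            assert bool(res.significant.loc[a, b]) == expected

    def test_summary_table_sorted_by_mean(self):
        rng = np.random.default_rng(4)
        g = {"hi": rng.normal(10, 1, 6), "lo": rng.normal(0, 1, 6)}
        summ = DuncanMRT(g).fit().summary()
        assert list(summ["group"]) == ["lo", "hi"]
        assert set(summ.columns) == {"group", "mean", "n", "letters"}


class TestPearsonMatrix:
    def make_table(self, n=30, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, n)
        return pd.DataFrame(
            {
                "genotype": ["Col-0"] * n,
                "x": x,
                "neg": -x,
                "noise": rng.normal(0, 1, n),
                "const": np.ones(n),
            }
        )

    def test_self_correlation_is_one_and_exact_anticorrelation(self):
        t = self.make_table()
        r = pearson_matrix(t, ["x", "neg", "noise"])["overall"]
        assert r.loc["x", "x"] == 1.0
        assert r.loc["x", "neg"] == pytest.approx(-1.0)

    def test_symmetric_unit_diagonal_and_bounded(self):
        t = self.make_table(seed=5)
        r = pearson_matrix(t, ["x", "neg", "noise"])["overall"]
        np.testing.assert_allclose(r.to_numpy(), r.to_numpy().T)
        assert ((r.abs() <= 1.0 + 1e-12) | r.isna()).all().all()

    def test_zero_variance_cells_undefined_not_zero(self):
        t = self.make_table()
        r = pearson_matrix(t, ["x", "const"])["overall"]
        assert np.isnan(r.loc["x", "const"])
        assert np.isnan(r.loc["const", "const"])

    def test_insufficient_n_flagged_undefined(self):
        t = self.make_table(n=2)
        r = pearson_matrix(t, ["x", "noise"], min_n=3)["overall"]
        assert np.isnan(r.loc["x", "noise"])

    def test_per_genotype_grouping(self):
        rng = np.random.default_rng(7)
        t = pd.DataFrame(
            {
                "genotype": ["A"] * 20 + ["B"] * 20,
                "x": rng.normal(0, 1, 40),
                "y": rng.normal(0, 1, 40),
            }
        )
        t.loc[t["genotype"] == "A", "y"] = t.loc[t["genotype"] == "A", "x"]
        mats = pearson_matrix(t, ["x", "y"], grouping="per-genotype")
        assert set(mats) == {"A", "B"}
        assert mats["A"].loc["x", "y"] == pytest.approx(1.0)
        assert abs(mats["B"].loc["x", "y"]) < 0.6
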