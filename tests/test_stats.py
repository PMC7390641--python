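"""Group-comparison battery: omnibus tests, post hocs, calibration."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from tectodist.stats import (
    GroupData,
    analyze_parameter,
    brown_forsythe,
    dunn_posthoc,
    kruskal_wallis,
    levene_test,
    one_way_anova,
    scheffe_posthoc,
    skewness,
    tamhane_t2_posthoc,
)


def _gd(*arrays, labels=None):
    labels = labels or tuple(range(len(arrays)))
    return GroupData(labels=tuple(labels), values=tuple(np.asarray(a, float) for a in arrays))


class TestSkewness:
    def test_symmetric_sample_is_zero(self):
        assert skewness([-1.0, 0.0, 1.0]) == pytest.approx(0.0, abs=1e-12)

    def test_direct_formula_oracle(self):
        # adjusted Fisher-Pearson computed from the raw definition
        x = np.array([1.0, 2.0, 3.0, 4.0, 100.0])
        n = x.size
        m2 = np.mean((x - x.mean()) ** 2)
        m3 = np.mean((x - x.mean()) ** 3)
        g1 = m3 / m2**1.5
        expected = g1 * math.sqrt(n * (n - 1)) / (n - 2)
        assert skewness(x) == pytest.approx(expected, rel=1e-12)

    def test_mirror_antisymmetry(self):
        x = [1.0, 2.0, 3.0, 10.0]
        assert skewness([-v for v in x]) == pytest.approx(-skewness(x), rel=1e-12)

    def test_needs_three_values(self):
        with pytest.raises(ValueError):
            skewness([1.0, 2.0])


class TestOmnibus:
    def test_two_group_anova_equals_pooled_t_squared(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 12), rng.normal(0.8, 1, 15)
        F, df1, df2, p = one_way_anova(_gd(a, b))
        t, p_t = sps.ttest_ind(a, b)
        assert F == pytest.approx(t**2, rel=1e-10)
        assert p == pytest.approx(p_t, rel=1e-10)

    def test_levene_location_invariant(self):
        rng = np.random.default_rng(1)
        a, b, c = (rng.normal(0, s, 10) for s in (1.0, 1.5, 2.0))
        W1, _ = levene_test(_gd(a, b, c))
        W2, _ = levene_test(_gd(a + 100, b - 7, c + 3))
        assert W1 == pytest.approx(W2, rel=1e-10)

    def test_anova_p_matches_permutation_oracle(self):
        rng = np.random.default_rng(2)
        groups = [rng.normal(0, 1, 5), rng.normal(0.5, 1, 5), rng.normal(1.2, 1, 5)]
        F_obs, _, _, p = one_way_anova(_gd(*groups))
        pooled = np.concatenate(groups)
        n_perm = 20000
        count = 0
        prng = np.random.default_rng(3)
        for _ in range(n_perm):
            perm = prng.permutation(pooled)
            F_p, _ = sps.f_oneway(perm[:5], perm[5:10], perm[10:])
            count += F_p >= F_obs
        p_perm = count / n_perm
        # permutation p converges to the F p-value for Normal data
        assert abs(p - p_perm) <= 3.0 * math.sqrt(p_perm * (1 - p_perm) / n_perm) + 0.01

    def test_brown_forsythe_reduces_to_anova_for_equal_ns_and_vars(self):
        # identical variance structure: F* ~ F with df2 <= N - k
        rng = np.random.default_rng(4)
        groups = [rng.normal(m, 1, 20) for m in (0, 0.3, 0.6)]
        F, _, df2a, _ = one_way_anova(_gd(*groups))
        Fb, _, df2b, _ = brown_forsythe(_gd(*groups))
        assert Fb == pytest.approx(F, rel=0.25)
        assert df2b <= df2a + 1e-9

    def test_degenerate_zero_variance(self):
        with pytest.raises(ValueError):
            brown_forsythe(_gd([1.0, 1.0], [2.0, 2.0]))


class TestPosthocs:
    def test_scheffe_two_groups_equals_anova_p(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, 10), rng.normal(1, 1, 10)
        _, _, _, p = one_way_anova(_gd(a, b))
        (res,) = scheffe_posthoc(_gd(a, b))
        assert res.p_adjusted == pytest.approx(p, rel=1e-10)

    def test_equal_means_give_p_near_one(self):
        base = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        gd = _gd(base, base + 1e-9, base - 1e-9)
        for res in scheffe_posthoc(gd):
            assert res.p_adjusted > 0.999
        for res in tamhane_t2_posthoc(gd):
            assert res.p_adjusted > 0.999

    def test_tamhane_matches_hand_welch_sidak(self):
        a = np.array([4.1, 5.2, 6.3, 5.8, 4.9])
        b = np.array([7.4, 8.1, 9.3, 8.8, 7.9, 8.5])
        c = np.array([5.5, 6.1, 5.9, 6.4])
        gd = _gd(a, b, c, labels=("a", "b", "c"))
        res = {r.pair: r for r in tamhane_t2_posthoc(gd)}
        # hand computation for the (a, b) pair
        va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        t = (a.mean() - b.mean()) / math.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
        p_raw = 2 * sps.t.sf(abs(t), df)
        p_sidak = 1 - (1 - p_raw) ** 3
        assert res[("a", "b")].p_adjusted == pytest.approx(p_sidak, abs=1e-6)

    def test_posthoc_p_not_below_unadjusted_pairwise(self):
        rng = np.random.default_rng(6)
        groups = [rng.normal(m, 1, 12) for m in (0, 0.5, 1.0)]
        gd = _gd(*groups)
        for res in tamhane_t2_posthoc(gd):
            i, j = res.pair
            _, p_welch = sps.ttest_ind(groups[i], groups[j], equal_var=False)
            assert res.p_adjusted >= p_welch - 1e-12
        for res in dunn_posthoc(gd):
            assert res.p_adjusted >= dunn_posthoc(gd, adjust="none")[0].p_adjusted - 1.0  # bonferroni >= raw
        raw = {r.pair: r.p_adjusted for r in dunn_posthoc(gd, adjust="none")}
        for res in dunn_posthoc(gd, adjust="bonferroni"):
            assert res.p_adjusted >= raw[res.pair] - 1e-12


class TestKruskalDunn:
    def test_complete_separation_is_maximal_h(self):
        groups = ([1.0, 2.0, 3.0], [4.0, 5.0, 6.0], [7.0, 8.0, 9.0])
        H_obs, df, _ = kruskal_wallis(_gd(*groups))
        assert df == 2
        # exhaustive enumeration over all 1680 partitions of ranks 1..9
        pooled = np.arange(1.0, 10.0)
        H_max = 0.0
        idx = set(range(9))
        for g1 in itertools.combinations(range(9), 3):
            rest = sorted(idx - set(g1))
            for g2 in itertools.combinations(rest, 3):
                g3 = sorted(set(rest) - set(g2))
                H, _ = sps.kruskal(pooled[list(g1)], pooled[list(g2)], pooled[g3])
                H_max = max(H_max, H)
        assert H_obs == pytest.approx(H_max, rel=1e-12)

    def test_two_groups_equals_squared_standardized_mannwhitney(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(0, 1, 8), rng.normal(1, 1, 9)
        H, _, _ = kruskal_wallis(_gd(a, b))
        U = sps.mannwhitneyu(a, b, alternative="two-sided").statistic
        n1, n2 = len(a), len(b)
        z = (U - n1 * n2 / 2) / math.sqrt(n1 * n2 * (n1 + n2 + 1) / 12)
        assert H == pytest.approx(z**2, rel=1e-10)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(8)
        groups = [rng.uniform(0, 1, 10) for _ in range(3)]
        H1, _, p1 = kruskal_wallis(_gd(*groups))
        H2, _, p2 = kruskal_wallis(_gd(*[np.exp(5 * g) for g in groups]))
        assert H1 == pytest.approx(H2, rel=1e-12)
        d1 = {r.pair: r.p_adjusted for r in dunn_posthoc(_gd(*groups))}
        d2 = {r.pair: r.p_adjusted for r in dunn_posthoc(_gd(*[np.exp(5 * g) for g in groups]))}
        for k in d1:
            assert d1[k] == pytest.approx(d2[k], rel=1e-12)

    def test_kruskal_p_matches_permutation_oracle_with_ties(self):
        groups = ([1.0, 1.0, 2.0, 3.0], [2.0, 3.0, 3.0, 4.0], [4.0, 5.0, 5.0, 6.0])
        H_obs, _, p = kruskal_wallis(_gd(*groups))
        pooled = np.concatenate(groups)
        prng = np.random.default_rng(9)
        n_perm = 20000
        count = 0
        for _ in range(n_perm):
            perm = prng.permutation(pooled)
            H, _ = sps.kruskal(perm[:4], perm[4:8], perm[8:])
            count += H >= H_obs - 1e-12
        p_perm = count / n_perm
        # chi-square approximation vs exact permutation null at tiny n
        assert abs(p - p_perm) <= 0.03

    def test_all_identical_degenerate(self):
        with pytest.raises(ValueError):
            kruskal_wallis(_gd([1.0, 1.0], [1.0, 1.0]))
        with pytest.raises(ValueError):
            dunn_posthoc(_gd([1.0, 1.0], [1.0, 1.0]))


class TestInvariances:
    def test_relabeling_invariance(self):
        rng = np.random.default_rng(10)
        groups = [rng.normal(m, 1, 10) for m in (0, 0.5, 1.0)]
        F1, *_ = one_way_anova(_gd(*groups))
        F2, *_ = one_way_anova(_gd(groups[2], groups[0], groups[1]))
        assert F1 == pytest.approx(F2, rel=1e-10)
        H1, _, _ = kruskal_wallis(_gd(*groups))
        H2, _, _ = kruskal_wallis(_gd(groups[1], groups[2], groups[0]))
        assert H1 == pytest.approx(H2, rel=1e-10)


class TestBattery:
    def test_parametric_path_with_homogeneous_variances(self):
        rng = np.random.default_rng(11)
        gd = _gd(*[rng.normal(m, 1, 20) for m in (0, 1, 2)], labels=(18, 23, 28))
        rep = analyze_parameter(gd, parameter="dd")
        assert rep.path == "anova"
        assert rep.pairwise and rep.pairwise[0].method in ("scheffe", "tamhane_t2")
        assert len(rep.pairwise) == 3
        assert 0 <= rep.p_value <= 1

    def test_skewed_data_takes_nonparametric_path(self):
        rng = np.random.default_rng(12)
        gd = _gd(*[np.exp(rng.normal(m, 1.5, 25)) for m in (0, 0.5, 1.0)])
        rep = analyze_parameter(gd)
        if rep.path == "kruskal_wallis":  # lognormal is strongly skewed
            assert rep.omnibus_test == "kruskal_wallis"
            assert all(r.method.startswith("dunn") for r in rep.pairwise)

    def test_as_published_assignment_swaps_posthoc(self):
        rng = np.random.default_rng(13)
        gd = _gd(*[rng.normal(m, 1, 20) for m in (0, 1, 2)])
        conv = analyze_parameter(gd, posthoc_assignment="conventional")
        pub = analyze_parameter(gd, posthoc_assignment="as_published")
        assert {conv.pairwise[0].method, pub.pairwise[0].method} == {"scheffe", "tamhane_t2"}


class TestTypeICalibration:
    @pytest.mark.parametrize("test", ["anova", "kruskal"])
    def test_null_rejection_rate_near_alpha(self, test):
        """Under H0 (3 Normal groups, n=20) both omnibus tests reject ~5%."""
        rng = np.random.default_rng(100)
        n_rep, alpha = 2000, 0.05
        rejections = 0
        for _ in range(n_rep):
            g = [rng.normal(0, 1, 20) for _ in range(3)]
            if test == "anova":
                _, _, _, p = one_way_anova(_gd(*g))
            else:
                _, _, p = kruskal_wallis(_gd(*g))
            rejections += p < alpha
        rate = rejections / n_rep
        assert 0.035 <= rate <= 0.065
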