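"""Statistical tests against closed forms, enumeration oracles and the
reference implementations in scipy / statsmodels / pingouin."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps
from scipy.stats import rankdata

from rootsetup import stats as rst
from rootsetup.errors import InsufficientDataError, UndefinedStatisticError


def block(values, conditions=None):
    v = np.asarray(values, float)
    conditions = conditions or tuple("abc"[: v.shape[1]])
    return rst.RepeatedBlock(tuple(range(len(v))), tuple(conditions), v)


class TestPairedT:
    def test_identical_samples_give_p_one(self):
        x = np.array([1.0, 2.0, 3.0])
        r = rst.paired_t(x, x)
        assert r.p_value == 1.0

    def test_closed_form_t_cdf_oracle(self):
        d = np.array([1.0, 2.0, 3.0, 4.0])
        r = rst.paired_t(d, np.zeros(4))
        t = d.mean() / (d.std(ddof=1) / np.sqrt(4))
        p = 2 * sps.t.sf(abs(t), 3)
        assert r.statistic == pytest.approx(t, abs=1e-9)
        assert r.p_value == pytest.approx(p, abs=1e-9)

    def test_constant_nonzero_difference_gives_p_zero(self):
        x = np.array([1.0, 2.0, 3.0])
        r = rst.paired_t(x + 3.0, x)
        assert r.p_value == 0.0

    def test_single_pair_rejected(self):
        with pytest.raises(InsufficientDataError):
            rst.paired_t([1.0], [2.0])


class TestICC:
    def test_duplicated_ratings_give_one(self):
        r = np.array([[1.0, 1.0], [2.0, 2.0], [5.0, 5.0]])
        assert rst.icc_agreement(r).statistic == pytest.approx(1.0)

    def test_variance_components_closed_form(self):
        # subject variance 9, error variance 1 -> ICC ~ 0.9
        rng = np.random.default_rng(42)
        subj = rng.normal(0, 3, size=(500, 1))
        ratings = subj + rng.normal(0, 1, size=(500, 2))
        assert rst.icc_agreement(ratings).statistic == pytest.approx(0.9, abs=0.05)

    def test_pure_noise_gives_near_zero(self):
        rng = np.random.default_rng(7)
        ratings = rng.normal(size=(500, 2))
        assert abs(rst.icc_agreement(ratings).statistic) < 0.1

    def test_matches_pingouin_icc3(self):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(3)
        ratings = rng.normal(0, 2, size=(12, 1)) + rng.normal(size=(12, 2))
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(12), 2),
                "rater": ["s1", "s2"] * 12,
                "score": ratings.ravel(),
            }
        )
        ref = pg.intraclass_corr(df, targets="subject", raters="rater",
                                 ratings="score")
        icc3 = float(ref.loc[ref["Type"] == "ICC(C,1)", "ICC"].iloc[0])
        assert rst.icc_agreement(ratings).statistic == pytest.approx(icc3,
                                                                     abs=1e-9)

    def test_zero_variance_is_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            rst.icc_agreement(np.ones((5, 2)))


class TestRmAnova:
    def test_identical_columns_give_f_zero_p_one(self):
        v = np.tile(np.array([[1.0], [2.0], [3.0]]), (1, 3))
        rep = rst.rm_anova(block(v))
        assert rep.omnibus.statistic == 0.0
        assert rep.omnibus.p_value == 1.0
        assert rep.labels == ()

    def test_two_conditions_f_equals_t_squared(self):
        rng = np.random.default_rng(11)
        v = rng.normal(size=(14, 2))
        rep = rst.rm_anova(block(v, ("a", "b")))
        t = rst.paired_t(v[:, 0], v[:, 1])
        assert rep.omnibus.statistic == pytest.approx(t.statistic**2, abs=1e-9)
        assert rep.omnibus.p_value == pytest.approx(t.p_value, abs=1e-9)

    def test_matches_pingouin(self):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(5)
        v = rng.normal(size=(12, 3)) + [0.0, 0.5, 1.0]
        df = pd.DataFrame(
            {
                "s": np.repeat(np.arange(12), 3),
                "c": list("abc") * 12,
                "y": v.ravel(),
            }
        )
        ref = pg.rm_anova(data=df, dv="y", within="c", subject="s")
        rep = rst.rm_anova(block(v))
        assert rep.omnibus.statistic == pytest.approx(float(ref["F"].iloc[0]),
                                                      abs=1e-9)
        assert rep.omnibus.p_value == pytest.approx(float(ref["p_unc"].iloc[0]),
                                                    abs=1e-9)
        sph = pg.sphericity(data=df, dv="y", within="c", subject="s")
        assert rep.sphericity.statistic == pytest.approx(float(sph.W), abs=1e-9)
        assert rep.sphericity.p_value == pytest.approx(float(sph.pval), abs=1e-9)

    def test_detects_a_two_sigma_shift(self):
        rng = np.random.default_rng(100)
        hits = 0
        for _ in range(200):
            v = rng.normal(size=(16, 3)) + [0.0, 0.0, 2.0]
            hits += rst.rm_anova(block(v)).omnibus.p_value < 0.05
        assert hits >= 190

    def test_posthoc_labels_point_at_the_larger_condition(self):
        rng = np.random.default_rng(2)
        v = rng.normal(size=(20, 3))
        v[:, 0] += 3.0
        rep = rst.rm_anova(block(v))
        assert "a > b" in rep.labels and "a > c" in rep.labels

    def test_subject_permutation_invariance(self):
        rng = np.random.default_rng(8)
        v = rng.normal(size=(10, 3))
        rep1 = rst.rm_anova(block(v))
        perm = rng.permutation(10)
        rep2 = rst.rm_anova(block(v[perm]))
        assert rep1.omnibus.statistic == pytest.approx(rep2.omnibus.statistic,
                                                       abs=1e-9)

    def test_single_subject_rejected(self):
        with pytest.raises(InsufficientDataError):
            rst.rm_anova(block(np.array([[1.0, 2.0, 3.0]])))


def friedman_enumeration_oracle(values):
    """Independent exact oracle: enumerate all per-subject orderings of
    the raw values and recompute the tie-corrected statistic."""
    v = np.asarray(values, float)
    n, k = v.shape

    def stat(m):
        ranks = np.array([rankdata(row) for row in m])
        col = ranks.sum(axis=0)
        s = 12.0 / (n * k * (k + 1)) * (col**2).sum() - 3.0 * n * (k + 1)
        ties = sum(
            (np.unique(row, return_counts=True)[1] ** 3
             - np.unique(row, return_counts=True)[1]).sum()
            for row in ranks
        )
        corr = 1.0 - ties / (n * k * (k**2 - 1))
        return 0.0 if corr <= 0 else s / corr

    observed = stat(v)
    perms = list(itertools.permutations(range(k)))
    count = total = 0
    for assignment in itertools.product(perms, repeat=n):
        m = np.array([v[i, list(p)] for i, p in enumerate(assignment)])
        total += 1
        if stat(m) >= observed - 1e-12:
            count += 1
    return count / total


class TestFriedman:
    def test_identical_columns_give_zero_statistic_p_one(self):
        v = np.tile(np.arange(5.0)[:, None], (1, 3))
        rep = rst.friedman_wilcoxon(block(v))
        assert rep.omnibus.statistic == 0.0
        assert rep.omnibus.p_value == 1.0

    def test_exact_p_equals_exhaustive_enumeration(self):
        rng = np.random.default_rng(13)
        v = rng.normal(size=(5, 3))
        rep = rst.friedman_wilcoxon(block(v))
        assert rep.omnibus.method == "friedman-exact"
        assert rep.omnibus.p_value == pytest.approx(
            friedman_enumeration_oracle(v), abs=1e-9
        )

    def test_exact_p_with_ties_equals_enumeration(self):
        rng = np.random.default_rng(14)
        v = np.round(rng.normal(size=(5, 3)))  # coarse values force ties
        rep = rst.friedman_wilcoxon(block(v))
        assert rep.omnibus.p_value == pytest.approx(
            friedman_enumeration_oracle(v), abs=1e-9
        )

    def test_large_n_statistic_matches_scipy(self):
        rng = np.random.default_rng(15)
        v = rng.normal(size=(40, 3))
        rep = rst.friedman_wilcoxon(block(v))
        chi2, p = sps.friedmanchisquare(v[:, 0], v[:, 1], v[:, 2])
        assert rep.omnibus.statistic == pytest.approx(chi2, abs=1e-9)
        assert rep.omnibus.p_value == pytest.approx(p, abs=1e-9)

    def test_shifted_condition_flagged_by_wilcoxon_posthoc(self):
        # condition a sits one unit above b and c (noise well below the shift)
        rng = np.random.default_rng(16)
        v = rng.normal(0, 0.5, size=(16, 3))
        v[:, 0] += 1.0
        rep = rst.friedman_wilcoxon(block(v))
        assert "a > b" in rep.labels and "a > c" in rep.labels

    def test_subject_permutation_invariance(self):
        rng = np.random.default_rng(17)
        v = rng.normal(size=(6, 3))
        perm = rng.permutation(6)
        r1 = rst.friedman_wilcoxon(block(v))
        r2 = rst.friedman_wilcoxon(block(v[perm]))
        assert r1.omnibus.p_value == pytest.approx(r2.omnibus.p_value, abs=1e-12)


class TestWilcoxon:
    def test_zero_differences_dropped_and_all_zero_gives_p_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert rst.wilcoxon_signed_rank(x, x).p_value == 1.0

    def test_exact_branch_matches_scipy_exact(self):
        rng = np.random.default_rng(19)
        x, y = rng.normal(size=(2, 12))
        r = rst.wilcoxon_signed_rank(x, y)
        ref = sps.wilcoxon(x, y, zero_method="wilcox", method="exact")
        assert r.p_value == pytest.approx(ref.pvalue, abs=1e-12)
        assert r.method == "wilcoxon-exact"

    def test_large_n_uses_corrected_normal_approximation(self):
        rng = np.random.default_rng(20)
        x, y = rng.normal(size=(2, 40))
        r = rst.wilcoxon_signed_rank(x, y)
        ref = sps.wilcoxon(x, y, zero_method="wilcox", correction=True,
                           method="approx")
        assert r.p_value == pytest.approx(ref.pvalue, abs=1e-12)
        assert r.method == "wilcoxon-approx"


class TestMcNemar:
    def test_eighteen_zero_matches_closed_form(self):
        r = rst.mcnemar(18, 0)
        assert r.p_value == pytest.approx(2 * 0.5**18, rel=1e-12)
        assert r.p_value < 0.001

    def test_no_discordance_gives_p_one(self):
        assert rst.mcnemar(0, 0).p_value == 1.0

    def test_ten_five_binomial_enumeration(self):
        from math import comb

        r = rst.mcnemar(10, 5)
        expected = 2 * sum(comb(15, k) for k in range(10, 16)) / 2**15
        assert r.p_value == pytest.approx(expected, abs=1e-4)
        assert r.p_value == pytest.approx(0.3018, abs=1e-4)

    @pytest.mark.parametrize("b,c", [(3, 1), (7, 7), (12, 4), (0, 9)])
    def test_exact_branch_matches_statsmodels(self, b, c):
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

        table = [[0, b], [c, 0]]
        ref = sm_mcnemar(table, exact=True)
        assert rst.mcnemar(b, c).p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_large_counts_use_corrected_chi_square(self):
        r = rst.mcnemar(30, 12)
        chi2 = (abs(30 - 12) - 1) ** 2 / 42
        assert r.statistic == pytest.approx(chi2)
        assert r.p_value == pytest.approx(sps.chi2.sf(chi2, 1), abs=1e-12)


class TestBonferroni:
    def test_adjusted_p_bounds(self):
        rng = np.random.default_rng(23)
        for p in rng.uniform(size=50):
            for m in (1, 3, 10):
                adj = rst.bonferroni(p, m)
                assert p <= adj <= 1.0
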