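import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import hypergeom

from eflkit.repeatability import (
    AgreementTable2x2,
    between_day_cv,
    cohens_kappa,
    fisher_exact,
    icc,
    icc_class,
    kappa_class,
    paired_t,
)

counts = st.integers(0, 30)


class TestCohensKappa:
    def test_reconstructed_peak_exercise_table(self):
        # 32 participants: 9 flow-limited on visit 1, 7 on visit 2, union
        # 12 -> both-positive cell 9+7-12 = 4, giving (4,5,3,20)
        res = cohens_kappa(AgreementTable2x2(4, 5, 3, 20))
        assert res.kappa == pytest.approx(0.337, abs=5e-4)
        assert kappa_class(res.kappa) == "minimal"

    def test_perfect_agreement(self):
        res = cohens_kappa(AgreementTable2x2(10, 0, 0, 10))
        assert res.kappa == pytest.approx(1.0)

    def test_independence_gives_zero(self):
        # po = pe = 0.5 by construction
        res = cohens_kappa(AgreementTable2x2(10, 10, 10, 10))
        assert res.kappa == pytest.approx(0.0, abs=1e-12)

    def test_constant_rater_flagged_undefined(self):
        res = cohens_kappa(AgreementTable2x2(15, 0, 0, 0))
        assert res.undefined and math.isnan(res.kappa)

    def test_matches_sklearn_point_estimate(self):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(0)
        for _ in range(10):
            x = rng.integers(0, 2, 40)
            y = rng.integers(0, 2, 40)
            if len(set(x)) < 2 or len(set(y)) < 2:
                continue
            t = AgreementTable2x2.from_pairs(list(zip(x == 1, y == 1)))
            assert cohens_kappa(t).kappa == pytest.approx(
                cohen_kappa_score(x, y), abs=1e-12
            )

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(counts, counts, counts, counts)
    def test_symmetric_under_visit_relabel(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        t1 = AgreementTable2x2(a, b, c, d)
        t2 = AgreementTable2x2(a, c, b, d)  # swap visit roles
        r1, r2 = cohens_kappa(t1), cohens_kappa(t2)
        if r1.undefined or r2.undefined:
            assert r1.undefined == r2.undefined
        else:
            assert r1.kappa == pytest.approx(r2.kappa, abs=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(counts, counts, counts, counts, st.integers(2, 5))
    def test_invariant_under_table_scaling(self, a, b, c, d, m):
        if a + b + c + d == 0:
            return
        r1 = cohens_kappa(AgreementTable2x2(a, b, c, d))
        r2 = cohens_kappa(AgreementTable2x2(m * a, m * b, m * c, m * d))
        if r1.undefined or r2.undefined:
            assert r1.undefined == r2.undefined
        else:
            assert r1.kappa == pytest.approx(r2.kappa, abs=1e-12)


class TestKappaBands:
    @pytest.mark.parametrize(
        "value,label",
        [
            (0.337, "minimal"),
            (0.474, "weak"),
            (0.95, "almost perfect"),
            (0.10, "none"),
            (-0.3, "none"),
            (0.20, "none"),
            (0.60, "moderate"),
            (0.85, "strong"),
        ],
    )
    def test_band_lookup(self, value, label):
        assert kappa_class(value) == label


def icc21_oracle(pairs):
    """Brute-force ICC(2,1) from explicit two-way ANOVA mean squares."""
    x = np.asarray(pairs, float)
    n, k = x.shape
    grand = x.mean()
    msr = k * np.sum((x.mean(axis=1) - grand) ** 2) / (n - 1)
    msc = n * np.sum((x.mean(axis=0) - grand) ** 2) / (k - 1)
    sst = np.sum((x - grand) ** 2)
    sse = sst - (msr * (n - 1) + msc * (k - 1))
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestICC:
    def test_identical_pairs_give_one(self):
        pairs = [(1.0, 1.0), (2.5, 2.5), (4.0, 4.0), (0.5, 0.5)]
        res = icc(pairs)
        assert res.icc == pytest.approx(1.0)

    def test_six_pair_table_matches_mean_squares_oracle(self):
        rng = np.random.default_rng(42)
        pairs = rng.normal(10, 3, (6, 2)) + rng.normal(0, 1, (6, 2))
        res = icc(pairs, form="ICC2")
        assert res.icc == pytest.approx(icc21_oracle(pairs), abs=1e-9)

    def test_variance_component_recovery(self):
        # x = subject effect (var 3) + visit noise (var 1): ICC = 3/4
        rng = np.random.default_rng(2024)
        subj = rng.normal(0, np.sqrt(3), 500)
        x = subj[:, None] + rng.normal(0, 1.0, (500, 2))
        res = icc(list(map(tuple, x)))
        assert res.icc == pytest.approx(0.75, abs=0.04)
        assert res.ci95[0] < res.icc < res.ci95[1]

    def test_noise_shrinks_icc_monotonically(self):
        rng = np.random.default_rng(7)
        subj = rng.normal(0, 2.0, 200)
        vals = []
        for noise in (0.01, 0.5, 1.5, 4.0):
            x = subj[:, None] + rng.normal(0, noise, (200, 2))
            vals.append(icc(list(map(tuple, x))).icc)
        assert all(b < a for a, b in zip(vals, vals[1:]))
        assert vals[0] > 0.99

    def test_relabeling_visits_preserves_icc2(self):
        rng = np.random.default_rng(5)
        pairs = rng.normal(5, 2, (12, 2))
        a = icc(pairs, form="ICC2").icc
        b = icc(pairs[:, ::-1], form="ICC2").icc
        assert a == pytest.approx(b, abs=1e-9)

    def test_zero_variance_flagged(self):
        res = icc([(2.0, 2.0)] * 5)
        assert res.undefined

    def test_consistency_form_differs_under_visit_shift(self):
        rng = np.random.default_rng(9)
        base = rng.normal(10, 3, 30)
        pairs = np.stack([base, base + 2.0], axis=1)  # systematic shift
        agree = icc(pairs, form="ICC2").icc
        consist = icc(pairs, form="ICC3").icc
        assert consist == pytest.approx(1.0, abs=1e-9)
        assert agree < consist


class TestICCBands:
    @pytest.mark.parametrize(
        "value,label",
        [
            (0.34, "poor"),
            (0.60, "moderate"),
            (0.99, "excellent"),
            (0.50, "moderate"),
            (0.75, "moderate"),
            (0.90, "good"),
            (0.76, "good"),
        ],
    )
    def test_band_lookup(self, value, label):
        assert icc_class(value) == label


class TestBetweenDayCV:
    def test_identical_pairs_zero(self):
        assert between_day_cv([(3.0, 3.0), (5.0, 5.0)]) == 0.0

    def test_single_pair_closed_form(self):
        # s = |90-110|/√2 = 14.142, mean 100 -> CV 14.14%
        assert between_day_cv([(90.0, 110.0)]) == pytest.approx(14.14, abs=5e-3)

    def test_simulated_cv_recovery(self):
        rng = np.random.default_rng(11)
        mu = rng.uniform(80, 120, 500)
        x = mu[:, None] * (1 + 0.05 * rng.standard_normal((500, 2)))
        assert between_day_cv(x) == pytest.approx(5.0, abs=0.5)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            between_day_cv([(1.0, -1.0)])


class TestPairedTAndFisher:
    def test_identical_pairs_t_zero_p_one(self):
        t, p = paired_t([(1.0, 1.0), (2.0, 2.0), (3.0, 3.0)])
        assert t == 0.0 and p == 1.0

    def test_matches_scipy_on_random_pairs(self):
        from scipy import stats

        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, (15, 2))
        t, p = paired_t(x)
        ref = stats.ttest_rel(x[:, 0], x[:, 1])
        assert (t, p) == (pytest.approx(ref.statistic), pytest.approx(ref.pvalue))

    def test_peak_efl_counts_not_different(self):
        # 9 of 32 vs 7 of 32 flow-limited: exact p ≈ 0.77
        assert fisher_exact(9, 23, 7, 25) == pytest.approx(0.77, abs=5e-3)

    def test_symmetry(self):
        assert fisher_exact(10, 0, 0, 10) == pytest.approx(
            fisher_exact(0, 10, 10, 0)
        )

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_hypergeometric_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c, d = (int(x) for x in rng.integers(0, 11, 4))
        if (a + b) == 0 or (c + d) == 0:
            return
        p = fisher_exact(a, b, c, d)
        # enumeration oracle: sum the probabilities of all tables with
        # the same margins that are no more likely than the observed one
        n = a + b + c + d
        row1, col1 = a + b, a + c
        p_obs = hypergeom.pmf(a, n, col1, row1)
        total = 0.0
        for aa in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
            pp = hypergeom.pmf(aa, n, col1, row1)
            if pp <= p_obs * (1 + 1e-9):
                total += pp
        assert p == pytest.approx(total, abs=1e-9)
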