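"""Mass-univariate inference: oracles for t maps, BH, permutation FWE, ANCOVA."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from normmap import (
    ConfigurationError,
    DataError,
    WScoreMap,
    bonferroni,
    check_normality,
    check_variance_homogeneity,
    correct_fdr,
    correct_fwe_permutation,
    global_ancova,
    massuni_ttest,
)
from normmap.types import StatMap


def wmap(i, values, space="skeleton"):
    values = np.asarray(values, dtype=float)
    return WScoreMap(f"s{i}", "FA", space, values, np.zeros(values.shape, bool))


def wmaps_from(matrix, offset=0):
    return [wmap(i + offset, row) for i, row in enumerate(np.atleast_2d(matrix))]


def scalar_pooled_t(a, b):
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (na + nb - 2)
    return (np.mean(a) - np.mean(b)) / np.sqrt(sp2 * (1 / na + 1 / nb))


def bh_oracle(p, q):
    """Step-up BH written independently: largest k with p_(k) <= k q / m."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    k_star = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * q / m:
            k_star = k
    flags = np.zeros(m, dtype=bool)
    if k_star:
        flags[order[:k_star]] = True
    return flags


def exhaustive_perm_oracle(A, B):
    """Exact max-|t| permutation p per location by enumerating all label splits."""
    D = np.concatenate([A, B])
    n, na = D.shape[0], A.shape[0]
    t_obs = np.array([scalar_pooled_t(A[:, j], B[:, j]) for j in range(D.shape[1])])
    maxes = []
    for idx in combinations(range(n), na):
        sel = np.zeros(n, bool)
        sel[list(idx)] = True
        ts = [scalar_pooled_t(D[sel, j], D[~sel, j]) for j in range(D.shape[1])]
        maxes.append(max(abs(t) for t in ts))
    maxes = np.array(maxes)
    return np.array([(maxes >= abs(t) - 1e-12).mean() for t in t_obs]), t_obs


class TestMassuniTtest:
    def test_identical_groups_t_zero_p_one(self, rng):
        vals = rng.normal(0, 1, (4, 6))
        sm = massuni_ttest(wmaps_from(vals), wmaps_from(vals, offset=4))
        np.testing.assert_allclose(sm.t, 0.0, atol=1e-12)
        np.testing.assert_allclose(sm.p, 1.0, atol=1e-12)

    def test_sign_convention_a_greater_than_b(self, rng):
        B = rng.normal(0, 1, (40, 3))
        A = B + 1.0
        sm = massuni_ttest(wmaps_from(A), wmaps_from(B, offset=40))
        assert (sm.t > 0).all() and (sm.p < 0.01).all()

    def test_matches_scalar_oracle(self, rng):
        A = rng.normal(0, 1, (4, 5))
        B = rng.normal(0.5, 1.3, (4, 5))
        sm = massuni_ttest(wmaps_from(A), wmaps_from(B, offset=4))
        assert sm.df == 6
        for j in range(5):
            t = scalar_pooled_t(A[:, j], B[:, j])
            np.testing.assert_allclose(sm.t[j], t, rtol=1e-10)
            np.testing.assert_allclose(sm.p[j], 2 * sps.t.sf(abs(t), 6), rtol=1e-8)

    def test_masked_locations_excluded(self, rng):
        A, B = rng.normal(0, 1, (3, 4)), rng.normal(0, 1, (3, 4))
        mask = np.array([True, False, True, True])
        sm = massuni_ttest(wmaps_from(A), wmaps_from(B, offset=3), mask=mask)
        assert not sm.in_mask[1] and np.isnan(sm.t[1])
        assert not sm.significant[1]

    def test_space_mismatch_rejected(self, rng):
        A = [wmap(0, rng.normal(0, 1, 4)), wmap(1, rng.normal(0, 1, 4))]
        B = [wmap(2, rng.normal(0, 1, 4), space="surface"),
             wmap(3, rng.normal(0, 1, 4), space="surface")]
        with pytest.raises(DataError, match="space"):
            massuni_ttest(A, B)


def make_statmap(p):
    p = np.asarray(p, dtype=float)
    return StatMap(
        t=np.zeros_like(p),
        p=p,
        significant=np.zeros(len(p), bool),
        in_mask=np.ones(len(p), bool),
        df=10,
        correction="none",
        contrast=("A", "B"),
        alpha=0.05,
    )


class TestCorrectFdr:
    def test_flat_half_pvalues_give_no_flags(self):
        sm = correct_fdr(make_statmap(np.full(100, 0.5)), q=0.05)
        assert not sm.significant.any()

    def test_hand_run_example(self):
        sm = correct_fdr(make_statmap([0.001, 0.002, 0.2, 0.9]), q=0.05)
        np.testing.assert_array_equal(sm.significant, [True, True, False, False])

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(
        st.lists(
            st.integers(min_value=0, max_value=100).map(lambda k: k / 100),
            min_size=1,
            max_size=8,
        )
    )
    def test_equals_bh_oracle_on_grid_pvectors(self, p):
        """BH flags match the independently coded step-up on 0.01-grid p-vectors."""
        sm = correct_fdr(make_statmap(p), q=0.05)
        np.testing.assert_array_equal(sm.significant, bh_oracle(p, 0.05))

    def test_fdr_flags_subset_of_uncorrected(self, rng):
        p = rng.uniform(0, 1, 50) ** 2
        raw = make_statmap(p)
        raw.significant = (p < 0.05) & raw.in_mask
        sm = correct_fdr(raw, q=0.05)
        assert not (sm.significant & ~raw.significant).any()


class TestPermutationFwe:
    def test_identical_groups_min_p_one(self, rng):
        vals = rng.normal(0, 1, (3, 5))
        sm = correct_fwe_permutation(
            wmaps_from(vals), wmaps_from(vals, offset=3), n_perm=50, seed=0
        )
        np.testing.assert_allclose(sm.p_corrected[sm.in_mask], 1.0)
        assert not sm.significant.any()

    def test_three_vs_three_full_enumeration_matches_oracle(self, rng):
        A = rng.normal(1.0, 1.0, (3, 4))
        B = rng.normal(0.0, 1.0, (3, 4))
        sm = correct_fwe_permutation(wmaps_from(A), wmaps_from(B, offset=3),
                                     n_perm=100, seed=1)
        p_oracle, t_oracle = exhaustive_perm_oracle(A, B)
        np.testing.assert_allclose(sm.t[sm.in_mask], t_oracle, rtol=1e-10)
        np.testing.assert_allclose(sm.p_corrected[sm.in_mask], p_oracle, atol=1e-12)
        # with 20 distinct assignments every p is a multiple of 1/20
        np.testing.assert_allclose(
            (sm.p_corrected[sm.in_mask] * 20) % 1.0, 0.0, atol=1e-9
        )

    def test_four_vs_four_full_enumeration_matches_oracle(self, rng):
        A = rng.normal(0.8, 1.0, (4, 6))
        B = rng.normal(0.0, 1.0, (4, 6))
        sm = correct_fwe_permutation(wmaps_from(A), wmaps_from(B, offset=4),
                                     n_perm=100, seed=2)
        p_oracle, _ = exhaustive_perm_oracle(A, B)
        np.testing.assert_allclose(sm.p_corrected[sm.in_mask], p_oracle, atol=1e-12)

    def test_random_permutation_p_bounds_and_monotonicity(self, rng):
        A = rng.normal(0.5, 1.0, (10, 8))
        B = rng.normal(0.0, 1.0, (10, 8))
        n_perm = 99
        sm = correct_fwe_permutation(wmaps_from(A), wmaps_from(B, offset=10),
                                     n_perm=n_perm, seed=3)
        p = sm.p_corrected[sm.in_mask]
        assert (p >= 1 / (n_perm + 1) - 1e-12).all() and (p <= 1.0).all()
        order = np.argsort(-np.abs(sm.t[sm.in_mask]))
        assert (np.diff(p[order]) >= -1e-12).all()  # non-decreasing as |t| falls

    def test_deterministic_given_seed(self, rng):
        A = rng.normal(0.5, 1.0, (8, 5))
        B = rng.normal(0.0, 1.0, (8, 5))
        sm1 = correct_fwe_permutation(wmaps_from(A), wmaps_from(B, offset=8),
                                      n_perm=200, seed=42)
        sm2 = correct_fwe_permutation(wmaps_from(A), wmaps_from(B, offset=8),
                                      n_perm=200, seed=42)
        np.testing.assert_array_equal(sm1.p_corrected, sm2.p_corrected)

    def test_fwe_flags_subset_of_uncorrected(self, rng):
        A = rng.normal(0.8, 1.0, (8, 10))
        B = rng.normal(0.0, 1.0, (8, 10))
        raw = massuni_ttest(wmaps_from(A), wmaps_from(B, offset=8), alpha=0.05)
        fwe = correct_fwe_permutation(wmaps_from(A), wmaps_from(B, offset=8),
                                      n_perm=500, seed=5, alpha=0.05)
        assert not (fwe.significant & ~raw.significant).any()
        assert not (fwe.significant & ~fwe.in_mask).any()

    def test_invalid_n_perm_rejected(self, rng):
        A, B = rng.normal(0, 1, (2, 3)), rng.normal(0, 1, (2, 3))
        with pytest.raises(ConfigurationError, match="n_perm"):
            correct_fwe_permutation(wmaps_from(A), wmaps_from(B, offset=2), n_perm=0)


def ancova_f_oracle(df):
    """Group F via explicit residual sums of squares of nested OLS fits."""
    X_full_cols = [np.ones(len(df)), df["age"].to_numpy(), df["sex"].to_numpy()]
    for g in sorted(df["group"].unique())[1:]:
        X_full_cols.append((df["group"] == g).to_numpy(float))
    X_red = np.column_stack(X_full_cols[:3])
    X_full = np.column_stack(X_full_cols)
    y = df["value"].to_numpy()

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return r @ r

    k = len(df["group"].unique()) - 1
    df2 = len(df) - X_full.shape[1]
    F = ((rss(X_red) - rss(X_full)) / k) / (rss(X_full) / df2)
    return F, sps.f.sf(F, k, df2)


class TestGlobalAncova:
    def _frame(self, rng, effect=0.0):
        n = 20
        rows = []
        for gi, g in enumerate(["g1", "g2", "g3"]):
            for i in range(n):
                age = rng.uniform(50, 85)
                sex = rng.integers(0, 2)
                val = 0.02 * age + 0.1 * sex + rng.normal(0, 1) + effect * gi
                rows.append((f"{g}-{i}", g, age, sex, 1.4e6, val))
        return pd.DataFrame(
            rows, columns=["subject_id", "group", "age", "sex", "icv", "value"]
        )

    def _run(self, df):
        values = dict(zip(df["subject_id"], df["value"]))
        return global_ancova(values, df.drop(columns="value"))

    def test_f_matches_rss_oracle(self, rng):
        df = self._frame(rng, effect=0.5)
        gs = self._run(df)
        F, p = ancova_f_oracle(df)
        assert gs.ancova_f == pytest.approx(F, rel=1e-8)
        assert gs.ancova_p == pytest.approx(p, rel=1e-8)

    def test_age_confound_removed(self, rng):
        """Group differences entirely explained by age vanish after adjustment."""
        rows = []
        for g, age_lo in (("young", 50.0), ("old", 70.0)):
            for i in range(30):
                age = rng.uniform(age_lo, age_lo + 10)
                rows.append((f"{g}-{i}", g, age, int(rng.integers(0, 2)), 1.4e6, age))
        df = pd.DataFrame(rows, columns=["subject_id", "group", "age", "sex", "icv", "value"])
        gs = self._run(df)
        assert gs.ancova_p > 0.2  # value == age: nothing left for the group factor

    def test_bonferroni_multiplication(self):
        assert bonferroni(0.02, 3) == pytest.approx(0.06)
        assert bonferroni(0.5, 3) == 1.0

    def test_pairwise_bonferroni_relation(self, rng):
        gs = self._run(self._frame(rng, effect=0.4))
        assert set(gs.pairwise_p) == {("g1", "g2"), ("g1", "g3"), ("g2", "g3")}
        for pair, p in gs.pairwise_p.items():
            assert gs.pairwise_p_bonferroni[pair] == pytest.approx(min(1.0, 3 * p))

    def test_null_rejection_rate_near_alpha(self, rng):
        """Type-I calibration of the group F test under identical distributions."""
        rejections = 0
        reps = 300
        for _ in range(reps):
            df = self._frame(rng, effect=0.0)
            if self._run(df).ancova_p < 0.05:
                rejections += 1
        rate = rejections / reps
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / reps)

    def test_missing_covariates_rejected(self, rng):
        df = self._frame(rng)
        values = dict(zip(df["subject_id"], df["value"]))
        values["ghost"] = 1.0
        with pytest.raises(DataError, match="ghost"):
            global_ancova(values, df.drop(columns="value"))


class TestDistributionChecks:
    def test_normal_samples_mostly_pass(self, rng):
        """Calibration: standard-normal draws keep p > 0.05 in >= 90% of seeds."""
        passed = sum(check_normality(rng.normal(0, 1, 1000)) > 0.05 for _ in range(40))
        assert passed / 40 >= 0.90 - 3 * np.sqrt(0.05 * 0.95 / 40)

    def test_exponential_samples_fail(self, rng):
        """Power: exponential draws are rejected essentially always at n=1000."""
        assert all(check_normality(rng.exponential(1.0, 1000)) < 0.05 for _ in range(20))

    def test_constant_sample_rejected_as_nonnormal(self):
        assert check_normality(np.full(100, 3.0)) == 0.0

    def test_small_sample_precondition(self):
        with pytest.raises(DataError, match="at least 5"):
            check_normality([1.0, 2.0, 3.0])

    def test_standard_ks_variant(self, rng):
        assert check_normality(rng.normal(0, 1, 500), method="ks_standard") > 0.01
        with pytest.raises(ConfigurationError):
            check_normality(rng.normal(0, 1, 100), method="bogus")

    def test_bartlett_identical_groups(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        stat, p = check_variance_homogeneity(x, x.copy())
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_bartlett_matches_textbook_formula(self, rng):
        groups = [rng.normal(0, s, n) for s, n in ((1.0, 10), (1.5, 12), (0.7, 9))]
        stat, p = check_variance_homogeneity(*groups)
        # closed form, coded independently
        k = len(groups)
        ns = np.array([len(g) for g in groups])
        vs = np.array([np.var(g, ddof=1) for g in groups])
        N = ns.sum()
        sp2 = ((ns - 1) * vs).sum() / (N - k)
        num = (N - k) * np.log(sp2) - ((ns - 1) * np.log(vs)).sum()
        den = 1 + (np.sum(1 / (ns - 1)) - 1 / (N - k)) / (3 * (k - 1))
        np.testing.assert_allclose(stat, num / den, rtol=1e-10)
        np.testing.assert_allclose(p, sps.chi2.sf(num / den, k - 1), rtol=1e-8)

    def test_bartlett_null_rejection_rate(self, rng):
        reps, rej = 300, 0
        for _ in range(reps):
            groups = [rng.normal(0, 1, 15) for _ in range(3)]
            if check_variance_homogeneity(*groups)[1] < 0.05:
                rej += 1
        assert abs(rej / reps - 0.05) < 3 * np.sqrt(0.05 * 0.95 / reps)

    def test_zero_variance_group_rejected(self):
        with pytest.raises(DataError, match="zero variance"):
            check_variance_homogeneity([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
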