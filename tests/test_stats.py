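"""ANCOVA, Freedman-Lane permutation, FDR and rank-sum statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from megconn.stats import (
    CovariateTable,
    ancova_f,
    bh_fdr,
    contrast_connectivity,
    contrast_power,
    permutation_pvalues,
    upper_triangle_edges,
    wilcoxon_ranksum,
)


def make_covars(rng, n1=16, n2=20, confounded=False):
    group = np.r_[np.ones(n1), np.zeros(n2)]
    age = rng.uniform(6, 18, n1 + n2)
    motion = rng.lognormal(0.0, 0.5, n1 + n2)
    if confounded:
        motion = motion * (1 + group)  # patients move twice as much
    return CovariateTable(group=group, age=age, head_motion=motion)


class TestAncovaF:
    def test_outcome_explained_by_covariates_gives_zero_f(self, rng):
        cov = make_covars(rng)
        y = 2.0 + 0.3 * cov.age - 0.5 * cov.head_motion
        assert ancova_f(y, cov) == pytest.approx(0.0, abs=1e-18)

    def test_matches_statsmodels_ols_oracle(self, rng):
        """Independent oracle: F of the group term from a statsmodels
        OLS model comparison, agreement to 1e-10."""
        import statsmodels.api as sm

        cov = make_covars(rng)
        y = rng.standard_normal(cov.n) + 0.8 * cov.group
        X_full = sm.add_constant(
            np.column_stack([cov.group, cov.age, cov.head_motion])
        )
        X_red = sm.add_constant(np.column_stack([cov.age, cov.head_motion]))
        full = sm.OLS(y, X_full).fit()
        red = sm.OLS(y, X_red).fit()
        f_oracle = (red.ssr - full.ssr) / (full.ssr / (cov.n - 4))
        assert ancova_f(y, cov) == pytest.approx(f_oracle, abs=1e-10)

    def test_no_covariate_effect_reduces_to_squared_t(self, rng):
        """With covariates exactly orthogonal to the intercept, the
        group indicator and the outcome, the ANCOVA F equals the
        squared pooled t statistic rescaled for the 2 extra df
        ((n-4)/(n-2)), to 1e-10."""
        n1 = n2 = 12
        n = n1 + n2
        group = np.r_[np.ones(n1), np.zeros(n2)]
        y = rng.standard_normal(n) + group
        basis = np.column_stack([np.ones(n), group, y])
        proj = basis @ np.linalg.pinv(basis)
        raw = rng.standard_normal((n, 2))
        orth = raw - proj @ raw  # covariates in the null space of (1, g, y)
        cov = CovariateTable(group=group, age=orth[:, 0], head_motion=orth[:, 1])
        t, _ = sps.ttest_ind(y[:n1], y[n1:])
        assert ancova_f(y, cov) == pytest.approx(t**2 * (n - 4) / (n - 2), rel=1e-10)

    def test_eight_subject_toy_case_matches_normal_equations(self):
        """Hand-checkable toy: explicit least squares via the normal
        equations computed from scratch."""
        group = np.array([1, 1, 1, 1, 0, 0, 0, 0], dtype=float)
        age = np.array([8.0, 10.0, 12.0, 14.0, 9.0, 11.0, 13.0, 15.0])
        motion = np.array([2.0, 1.0, 3.0, 2.0, 1.0, 0.5, 1.5, 1.0])
        y = np.array([3.1, 2.9, 3.5, 3.3, 2.0, 2.2, 2.6, 2.4])
        cov = CovariateTable(group=group, age=age, head_motion=motion)

        def rss(X):
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            r = y - X @ beta
            return r @ r

        X_full = np.column_stack([np.ones(8), group, age, motion])
        X_red = np.column_stack([np.ones(8), age, motion])
        f_oracle = (rss(X_red) - rss(X_full)) / (rss(X_full) / 4)
        assert ancova_f(y, cov) == pytest.approx(f_oracle, abs=1e-10)

    def test_too_few_subjects_rejected(self, rng):
        cov = CovariateTable(group=[1, 1, 0, 0], age=[8, 9, 10, 11],
                             head_motion=[1, 2, 1, 2])
        with pytest.raises(ValueError):
            ancova_f(np.ones(4), cov)


class TestPermutation:
    def test_extreme_observed_f_hits_add_one_floor(self, rng):
        cov = make_covars(rng, 8, 8)
        y = cov.group * 100 + 0.01 * rng.standard_normal(16)  # huge effect
        df = permutation_pvalues(y[:, None], cov, n_perm=999, rng=1)
        assert df["p_perm"].iloc[0] == pytest.approx(1 / 1000)

    def test_constant_outcome_gives_p_one(self, rng):
        cov = make_covars(rng, 6, 6)
        df = permutation_pvalues(np.ones((12, 1)), cov, n_perm=99, rng=1)
        assert df["p_perm"].iloc[0] == 1.0

    def test_reproducible_with_seed(self, rng):
        cov = make_covars(rng, 8, 8)
        Y = rng.standard_normal((16, 5))
        a = permutation_pvalues(Y, cov, n_perm=200, rng=42)
        b = permutation_pvalues(Y, cov, n_perm=200, rng=42)
        pd.testing.assert_frame_equal(a, b)

    def test_null_pvalues_uniform(self, rng):
        """Freedman-Lane p-values on pure-null data pass a KS test
        against U(0,1) over 500 units at alpha = 0.01."""
        cov = make_covars(rng, confounded=True)
        Y = rng.standard_normal((cov.n, 500))
        df = permutation_pvalues(Y, cov, n_perm=400, rng=7)
        ks = sps.kstest(df["p_perm"], "uniform")
        assert ks.pvalue > 0.01

    def test_covariate_confounding_controlled(self, rng):
        """Outcomes driven by motion (which differs by group) inflate a
        naive t-test but stay nominal under the motion-adjusted
        permutation ANCOVA."""
        cov = make_covars(rng, confounded=True)
        n_units = 200
        Y = 0.8 * cov.head_motion[:, None] + rng.standard_normal((cov.n, n_units))
        naive_p = np.array([
            sps.ttest_ind(Y[cov.group == 1, u], Y[cov.group == 0, u]).pvalue
            for u in range(n_units)
        ])
        adj = permutation_pvalues(Y, cov, n_perm=400, rng=3)
        naive_rate = np.mean(naive_p < 0.05)
        adjusted_rate = np.mean(adj["p_perm"] < 0.05)
        assert naive_rate > 0.15  # grossly inflated
        assert adjusted_rate < 0.10  # nominal within Monte-Carlo tolerance


class TestBHFDR:
    @staticmethod
    def brute_force_bh(p, q=0.05):
        p = np.asarray(p, dtype=float)
        m = p.size
        order = np.argsort(p)
        adj = np.empty(m)
        running_min = 1.0
        for rank in range(m, 0, -1):
            idx = order[rank - 1]
            running_min = min(running_min, p[idx] * m / rank)
            adj[idx] = running_min
        return adj, adj < q

    def test_spec_examples(self):
        adj, mask = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert mask.all()
        adj, mask = bh_fdr([1.0, 1.0, 1.0])
        assert not mask.any()
        adj, mask = bh_fdr([0.01])
        assert adj[0] == pytest.approx(0.01) and mask[0]

    def test_matches_brute_force_step_up(self, rng):
        p = rng.uniform(1e-4, 1, 200)
        adj, mask = bh_fdr(p)
        adj_o, mask_o = self.brute_force_bh(p)
        np.testing.assert_allclose(adj, adj_o, atol=1e-12)
        np.testing.assert_array_equal(mask, mask_o)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=15, deadline=None)
    def test_mask_invariant_under_unit_permutation(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(1e-6, 1, 50)
        perm = rng.permutation(50)
        _, mask = bh_fdr(p)
        _, mask_p = bh_fdr(p[perm])
        np.testing.assert_array_equal(mask[perm], mask_p)

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.0, 0.5])


class TestWilcoxon:
    def test_complete_separation_gives_zero_u(self):
        y = np.r_[np.arange(5), np.arange(10, 16)]
        group = np.r_[np.ones(5), np.zeros(6)]
        U, z, p = wilcoxon_ranksum(y, group)
        assert U == 0.0 and z < 0 and p < 0.05

    def test_identical_values_give_zero_z(self):
        U, z, p = wilcoxon_ranksum(np.ones(10), np.r_[np.ones(5), np.zeros(5)])
        assert z == 0.0 and p == 1.0

    def test_matches_pair_counting_oracle(self, rng):
        """U equals the direct count of (a > b) pairs plus half-ties."""
        a = rng.integers(0, 20, 10).astype(float)
        b = rng.integers(0, 20, 12).astype(float)
        y = np.r_[a, b]
        group = np.r_[np.ones(10), np.zeros(12)]
        U, z, p = wilcoxon_ranksum(y, group)
        count = sum((x > v) + 0.5 * (x == v) for x in a for v in b)
        assert U == pytest.approx(count)
        # p agrees with scipy's tie-corrected normal approximation
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic",
                               use_continuity=False)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_ranksum(np.ones(3), np.ones(3))


class TestContrastMaps:
    def test_connectome_dimensionality(self):
        assert len(upper_triangle_edges(90)) == 4005

    def test_connectivity_contrast_shapes_and_fdr(self, rng):
        n_seeds, n_sub = 12, 20
        conn = rng.uniform(-0.2, 0.6, (n_sub, 2, n_seeds, n_seeds))
        conn = (conn + conn.transpose(0, 1, 3, 2)) / 2
        cov = make_covars(rng, 10, 10)
        maps = contrast_connectivity(conn, cov, n_perm=50, rng=5,
                                     band_names=("delta", "theta"))
        assert set(maps) == {"delta", "theta"}
        df = maps["delta"]
        assert len(df) == 12 * 11 // 2
        assert df["unit"].iloc[0] == (0, 1)
        assert ((df["p_perm"] > 0) & (df["p_perm"] <= 1)).all()
        assert (df["significant"] == (df["p_fdr"] < 0.05)).all()

    def test_power_contrast_recovers_planted_seed_effect(self, rng):
        n_sub = 36
        cov = make_covars(rng, 16, 20)
        table_rows = []
        subjects = [f"s{i:02d}" for i in range(n_sub)]
        for i, sid in enumerate(subjects):
            for seed in range(10):
                base = rng.normal(1.0, 0.1)
                if seed < 3 and cov.group[i] == 1:
                    base *= 2.0
                table_rows.append((sid, seed, "delta", base))
        table = pd.DataFrame(table_rows,
                             columns=["subject_id", "seed", "band", "power"])
        maps = contrast_power(table, cov, subjects, n_perm=300, rng=11,
                              bands=("delta",))
        df = maps["delta"]
        planted = df[df["unit"].isin([0, 1, 2])]
        assert planted["significant"].all()
        assert (planted["direction"] > 0).all()
        assert df[~df["unit"].isin([0, 1, 2])]["significant"].sum() <= 1
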