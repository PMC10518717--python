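"""Moderated statistics, S0 estimation, permutation and BH FDR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import mdscreen as m
from mdscreen import diffexp as de


class TestS0Statistic:
    def test_s0_zero_is_student_t(self):
        from scipy import stats

        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 5), rng.normal(1, 1, 5)
        d, fc, s = m.s0_t_statistic(a, b, s0=0.0)
        t_ref = stats.ttest_ind(a, b).statistic
        assert d == pytest.approx(t_ref)

    def test_identical_vectors_give_zero(self):
        d, fc, s = m.s0_t_statistic([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], 0.5)
        assert d == 0.0 and fc == 0.0

    def test_zero_variance_groups(self):
        d, fc, s = m.s0_t_statistic([2, 2, 2], [1, 1, 1], s0=0.5)
        assert (d, fc, s) == (2.0, 1.0, 0.0)

    def test_insufficient_values_marks_untestable(self):
        d, fc, s = m.s0_t_statistic([1.0], [1.0, 2.0], 0.1)
        assert np.isnan(d)

    def test_antisymmetric_under_group_swap(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 4), rng.normal(0.5, 1, 4)
        d1, _, _ = m.s0_t_statistic(a, b, 0.3)
        d2, _, _ = m.s0_t_statistic(b, a, 0.3)
        assert d1 == pytest.approx(-d2)


class TestEstimateS0:
    def test_constant_s_returns_smallest_candidate(self):
        # all rows share the same within-group spread
        base = np.array([0.0, 1.0, 2.0, 0.0, 1.0, 2.0])
        X = np.vstack([base + i for i in range(50)])
        labels = np.array([1, 1, 1, 0, 0, 0])
        s0 = m.estimate_s0(X, labels)
        _, _, s = m.s0_t_statistic(base[:3], base[3:], 0.0)
        assert s0 == pytest.approx(s)

    def test_heteroscedastic_null_damps_small_s_rows(self):
        rng = np.random.default_rng(2)
        n = 2000
        scales = np.exp(rng.normal(0, 1, n))
        X = rng.normal(0, 1, (n, 10)) * scales[:, None]
        labels = np.array([1] * 5 + [0] * 5)
        s0 = m.estimate_s0(X, labels)
        assert s0 > 0
        ia, ib = np.arange(5), np.arange(5, 10)
        ma, mb, se, *_ = de._group_stats(X, ia, ib)
        d_raw = np.abs(de._moderated_d(ma - mb, se, 0.0))
        d_mod = np.abs(de._moderated_d(ma - mb, se, s0))
        small_s = se <= np.quantile(se, 0.25)
        top_raw = np.argsort(d_raw)[-100:]
        top_mod = np.argsort(d_mod)[-100:]
        assert small_s[top_mod].sum() < small_s[top_raw].sum()

    def test_deterministic_given_input(self):
        rng = np.random.default_rng(3)
        X = rng.normal(0, 1, (300, 8))
        labels = np.array([1] * 4 + [0] * 4)
        assert m.estimate_s0(X, labels) == m.estimate_s0(X, labels)


class TestBhFdr:
    def test_hand_step_up(self):
        q = m.bh_fdr([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert m.bh_fdr([0.123])[0] == pytest.approx(0.123)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            m.bh_fdr([0.1, np.nan])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0, max_value=1), min_size=2,
                 max_size=30)
    )
    def test_monotone_in_p(self, ps):
        ps = sorted(ps)
        q = m.bh_fdr(ps)
        assert (np.diff(q) >= -1e-12).all()


class TestPermutationFdr:
    def test_matches_exhaustive_oracle_on_3v3(self):
        """Sampled-permutation FDR equals brute-force enumeration when
        all 20 distinct 3-vs-3 shuffles are covered."""
        from itertools import combinations

        rng = np.random.default_rng(5)
        X = rng.normal(0, 1, (40, 6))
        X[:6, :3] += 3.0
        labels = np.array([True] * 3 + [False] * 3)
        cfg = m.TestConfig(s0=0.1, n_permutations=100, seed=0)
        table, info = m.permutation_fdr(X, labels, cfg)
        assert info["exhaustive"] and info["n_permutations"] == 20

        def d_stat(a, b, s0):
            na, nb = len(a), len(b)
            sp2 = ((na - 1) * np.var(a, ddof=1)
                   + (nb - 1) * np.var(b, ddof=1)) / (na + nb - 2)
            s = np.sqrt(sp2 * (1 / na + 1 / nb))
            return (np.mean(a) - np.mean(b)) / (s + s0)

        obs = np.array(
            [abs(d_stat(row[:3], row[3:], 0.1)) for row in X]
        )
        perm_vals = []
        picks = list(combinations(range(6), 3))
        for pick in picks:
            other = [i for i in range(6) if i not in pick]
            for row in X:
                perm_vals.append(
                    abs(d_stat(row[list(pick)], row[other], 0.1))
                )
        perm_vals = np.array(perm_vals)
        expected_q = np.empty(len(obs))
        for i, v in enumerate(obs):
            fdrs = [
                min(
                    1.0,
                    ((perm_vals >= thr).sum() / len(picks))
                    / (obs >= thr).sum(),
                )
                for thr in obs[obs <= v]
            ]
            expected_q[i] = min(fdrs)
        np.testing.assert_allclose(table["q"].to_numpy(), expected_q)

    def test_identical_groups_yield_no_significance(self):
        X = np.tile(np.arange(6.0), (30, 1))
        labels = np.array([1, 1, 1, 0, 0, 0])
        table, _ = m.permutation_fdr(
            X, labels, m.TestConfig(s0=0.1, n_permutations=50, seed=1)
        )
        assert table["significant"].sum() == 0

    def test_q_invariant_under_row_permutation(self):
        rng = np.random.default_rng(7)
        X = rng.normal(0, 1, (100, 8))
        X[:10, :4] += 2
        labels = np.array([1] * 4 + [0] * 4)
        cfg = m.TestConfig(s0=0.1, n_permutations=200, seed=3)
        q1, _ = m.permutation_fdr(X, labels, cfg)
        order = rng.permutation(100)
        q2, _ = m.permutation_fdr(X[order], labels, cfg)
        np.testing.assert_allclose(
            q1["q"].to_numpy()[order], q2["q"].to_numpy()
        )


class TestDifferentialExpression:
    @pytest.fixture(scope="class")
    def strong_effect_run(self):
        mat, truth = m.gen_tmt_profile(
            m.ProfileSimConfig(n_proteins=1000, frac_regulated=0.1,
                               effect_log2=2.0, noise_sd_log2=0.2, seed=11)
        )
        # median centering is robust to the 10% regulated mass; a
        # sum-based scale would pick up bias from strong regulation
        normed, _ = m.median_center(mat)
        return normed, truth

    def test_recovers_planted_effects_at_fdr_05(self, strong_effect_run):
        normed, truth = strong_effect_run
        res = m.differential_expression(
            normed, ("B", "A"),
            m.TestConfig(s0="auto", n_permutations=250, seed=1),
        )
        sig = res.table["significant"]
        tp = (truth["regulated"] & sig).sum()
        fp = ((~truth["regulated"]) & sig).sum()
        assert tp >= 95
        assert fp <= 0.05 * max(1, sig.sum()) + 10

    def test_permutation_and_bh_agree_on_strong_effects(
        self, strong_effect_run
    ):
        normed, truth = strong_effect_run
        perm = m.differential_expression(
            normed, ("B", "A"),
            m.TestConfig(s0=0.05, n_permutations=250, seed=1),
        )
        bh = m.differential_expression(
            normed, ("B", "A"),
            m.TestConfig(correction="benjamini-hochberg"),
        )
        sp = set(perm.table.index[perm.table["significant"]])
        sb = set(bh.table.index[bh.table["significant"]])
        jaccard = len(sp & sb) / len(sp | sb)
        assert jaccard > 0.9

    def test_band_boundaries_are_closed(self):
        values = pd.DataFrame(
            np.array([
                [1.0, 1.0, 1.0, 0.0, 0.0, 0.0],       # |FC| = 1
                [2.0, 2.0, 2.0, 0.0, 0.0, 0.0],       # |FC| = 2
                [2.5, 2.5, 2.5, 0.0, 0.0, 0.0],       # |FC| > 2
                [0.5, 0.5, 0.5, 0.0, 0.0, 0.0],       # |FC| < 1
            ]),
            columns=list("abcdef"),
        )
        model = m.TwoGroupModel(values, list("abc"), list("def"))
        res = model.fit(m.TestConfig(s0=0.5, n_permutations=20, seed=0))
        assert list(res.table["band"]) == ["1-2", "1-2", ">2", "<1"]

    def test_summary_reports_band_counts(self, strong_effect_run):
        normed, truth = strong_effect_run
        res = m.differential_expression(
            normed, ("B", "A"),
            m.TestConfig(s0=0.05, n_permutations=100, seed=2),
        )
        text = res.summary()
        assert "significant" in text
        assert sum(res.band_counts.values()) == res.n_significant
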