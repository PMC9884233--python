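import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lateroflux.stats_pipeline import (fdr_correct, mixed_anova,
                                       normality_check, one_way_anova,
                                       paired_test, posthoc_pairwise,
                                       spearman)


class TestPairedTest:
    def test_identical_pre_post_gives_t0_p1(self):
        r = paired_test([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert r.statistic == 0.0
        assert r.p_raw == 1.0
        assert r.degenerate

    def test_constant_nonzero_differences_flag_degenerate(self):
        r = paired_test([1.0, 2.0, 3.0, 4.0], [2.0, 3.0, 4.0, 5.0])
        assert r.degenerate

    def test_matches_textbook_formula(self):
        pre = np.array([12.0, 15.0, 11.0, 9.0, 14.0, 13.0])
        post = np.array([14.0, 14.0, 15.0, 11.0, 18.0, 12.0])
        d = post - pre
        t_oracle = d.mean() / (d.std(ddof=1) / math.sqrt(d.size))
        r = paired_test(pre, post)
        assert r.statistic == pytest.approx(t_oracle, abs=1e-10)
        assert r.df == d.size - 1

    def test_missing_pairs_dropped(self):
        r = paired_test([1.0, np.nan, 3.0, 5.0, 7.0], [2.0, 2.0, 2.0, 6.0, 9.0])
        assert r.n == 4


def mixed_anova_oracle(df):
    """Brute-force sums-of-squares decomposition for a balanced mixed design."""
    g_levels = sorted(df["group"].unique())
    w_levels = sorted(df["window"].unique())
    subjects = sorted(df["subject"].unique())
    g, w, n_sub = len(g_levels), len(w_levels), len(subjects)
    grand = df["value"].mean()
    subj_mean = df.groupby("subject")["value"].mean()
    grp_mean = df.groupby("group")["value"].mean()
    win_mean = df.groupby("window")["value"].mean()
    cell_mean = df.groupby(["group", "window"])["value"].mean()
    n_per_group = df.groupby("group")["subject"].nunique()

    ss_group = w * sum(n_per_group[gl] * (grp_mean[gl] - grand) ** 2
                       for gl in g_levels)
    grp_of = df.drop_duplicates("subject").set_index("subject")["group"]
    ss_subj = w * sum((subj_mean[s] - grp_mean[grp_of[s]]) ** 2 for s in subjects)
    ss_win = n_sub * sum((win_mean[wl] - grand) ** 2 for wl in w_levels)
    ss_int = sum(n_per_group[gl] * (cell_mean[(gl, wl)] - grp_mean[gl]
                                    - win_mean[wl] + grand) ** 2
                 for gl in g_levels for wl in w_levels)
    ss_total = ((df["value"] - grand) ** 2).sum()
    ss_err = ss_total - ss_group - ss_subj - ss_win - ss_int

    df_g, df_s = g - 1, n_sub - g
    df_w, df_e = w - 1, (n_sub - g) * (w - 1)
    return {
        "between": (ss_group / df_g) / (ss_subj / df_s),
        "within": (ss_win / df_w) / (ss_err / df_e),
        "interaction": (ss_int / (df_g * df_w)) / (ss_err / df_e),
    }


class TestMixedAnova:
    @staticmethod
    def _toy_table(n_per_group=5, w=4, seed=0, effect=0.0):
        rng = np.random.default_rng(seed)
        rows = []
        for gi, grp in enumerate(["4C", "10C", "30C"]):
            for s in range(n_per_group):
                sid = f"{grp}_{s}"
                base = rng.normal(100, 5)
                for wi in range(w):
                    val = base + rng.normal(0, 3)
                    if grp == "30C" and wi > 0:
                        val += effect
                    rows.append((sid, grp, f"W{wi}", val))
        return pd.DataFrame(rows, columns=["subject", "group", "window", "value"])

    def test_all_identical_values_give_zero_f(self):
        df = self._toy_table()
        df["value"] = 7.0
        for r in mixed_anova(df):
            assert r.statistic == 0.0
            assert r.degenerate

    def test_matches_brute_force_ss_oracle(self):
        df = self._toy_table(seed=3, effect=4.0)
        oracle = mixed_anova_oracle(df)
        results = {("between" if "between" in r.name else
                    "within" if "within" in r.name else "interaction"): r
                   for r in mixed_anova(df)}
        for key, f_oracle in oracle.items():
            assert results[key].statistic == pytest.approx(f_oracle, abs=1e-8)

    def test_df_shape_matches_balanced_60_subject_design(self):
        # 20/20/20 subjects, 3 within levels: between df (2,57)
        df = self._toy_table(n_per_group=20, w=3, seed=1)
        results = mixed_anova(df)
        by = {r.name.split()[0]: r for r in results}
        assert by["between"].df == (2, 57)
        assert by["within"].df == (2, 114)
        assert by["interaction"].df == (4, 114)

    def test_incomplete_subject_dropped_listwise(self):
        df = self._toy_table(seed=5)
        df = df[~((df.subject == "4C_0") & (df.window == "W2"))]
        results = mixed_anova(df)
        assert all(r.n == 14 for r in results)


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.arange(10.0)
        assert spearman(x, x).statistic == pytest.approx(1.0)
        assert spearman(x, -x).statistic == pytest.approx(-1.0)

    def test_tied_toys_match_midrank_pearson_oracle(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 3.0, 3.0, 5.0, 4.0, 4.0])
        from scipy.stats import rankdata

        rx, ry = rankdata(x), rankdata(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert spearman(x, y).statistic == pytest.approx(oracle, abs=1e-12)

    def test_exact_permutation_p_for_small_n(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=7)
        y = rng.normal(size=7)
        r = spearman(x, y)
        assert "exact" in r.method
        # brute-force enumeration oracle
        from scipy.stats import rankdata

        rx = rankdata(x) - 4.0
        count = 0
        total = 0
        obs = abs(r.statistic)
        for perm in itertools.permutations(rankdata(y)):
            ry = np.array(perm) - 4.0
            rho = (rx @ ry) / math.sqrt((rx @ rx) * (ry @ ry))
            count += abs(rho) >= obs - 1e-12
            total += 1
        assert r.p_raw == pytest.approx(count / total, abs=1e-12)

    def test_t_approximation_for_larger_n(self):
        from scipy.stats import spearmanr

        rng = np.random.default_rng(1)
        x = rng.normal(size=40)
        y = x + rng.normal(0, 2, size=40)
        r = spearman(x, y)
        rho_ref, p_ref = spearmanr(x, y)
        assert r.statistic == pytest.approx(rho_ref, abs=1e-12)
        assert r.p_raw == pytest.approx(p_ref, rel=0.05)

    def test_constant_input_degenerate(self):
        r = spearman(np.ones(8), np.arange(8.0))
        assert r.degenerate


class TestFDR:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(fdr_correct([0.03]), [0.03])

    def test_hand_computed_bh(self):
        # BH: p_(i) * m / i, monotone from the largest: all become 0.04
        np.testing.assert_allclose(fdr_correct([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_all_ones_stay_one(self):
        np.testing.assert_allclose(fdr_correct([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_tail_area_variant_never_exceeds_bh(self):
        p = [0.001, 0.01, 0.2, 0.5, 0.9, 0.95]
        bh = fdr_correct(p, method="bh")
        ta = fdr_correct(p, method="tail-area")
        assert np.all(ta <= bh + 1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=30))
    def test_bh_monotone_and_never_below_raw(self, p):
        adj = fdr_correct(p)
        p = np.asarray(p)
        assert np.all(adj >= p - 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_correct([0.5, 1.5])


class TestNormalityCheck:
    def test_normal_sample_usually_passes(self):
        rng = np.random.default_rng(10)
        r = normality_check(rng.normal(size=50))
        assert r.p_raw > 0.05

    def test_exponential_sample_fails(self):
        rng = np.random.default_rng(10)
        r = normality_check(rng.exponential(size=50))
        assert r.p_raw < 0.05

    def test_constant_degenerate(self):
        assert normality_check(np.full(10, 3.0)).degenerate


class TestOneWayAndPosthoc:
    def test_one_way_df_shape_60_subjects(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(100, 10, 60)
        groups = np.repeat(["4C", "10C", "30C"], 20)
        r = one_way_anova(vals, groups)
        assert r.df == (2, 57)

    def test_posthoc_families_are_fdr_corrected(self):
        rng = np.random.default_rng(3)
        rows = []
        for grp, shift in (("4C", 0.0), ("10C", 0.0), ("30C", 30.0)):
            for s in range(15):
                for win in ("Post1", "Post2", "Post3"):
                    rows.append((f"{grp}{s}", grp, win,
                                 100 + shift + rng.normal(0, 5)))
        df = pd.DataFrame(rows, columns=["subject", "group", "window", "value"])
        results = posthoc_pairwise(df)
        assert len(results) == 9  # 3 windows x 3 pairwise contrasts
        for r in results:
            assert r.p_corrected is not None
            assert r.p_corrected >= r.p_raw - 1e-12
            if "30C" in r.name:
                assert r.p_corrected < 0.05
            else:
                assert r.p_corrected > 0.05
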