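"""BH adjustment, group contrasts, z-scoring and biomarker cascades."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from pgkit.diffexp import (
    bh_adjust,
    biomarker_cascade_exosome,
    compare_groups,
    subtype_marker_screen,
    zscore_rows,
)
from pgkit.io import OmicsMatrix

from conftest import make_matrix


def bh_oracle(p):
    """From-scratch step-up: q_i = min over j>=i(rank) of p_(j) * m / j."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p)
    q = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = min(running, 1.0)
    return q


class TestBhAdjust:
    def test_hand_step_up(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_single_p_identity(self):
        assert bh_adjust([0.5])[0] == pytest.approx(0.5)

    def test_all_one_boundary(self):
        np.testing.assert_allclose(bh_adjust([1.0] * 5), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])
        with pytest.raises(ValueError):
            bh_adjust([-0.1])

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=40))
    @settings(max_examples=100, deadline=None)
    def test_matches_oracle_and_dominates_p(self, p):
        q = bh_adjust(p)
        np.testing.assert_allclose(q, bh_oracle(p), atol=1e-12)
        assert np.all(q >= np.asarray(p) - 1e-12)
        assert np.all((q >= 0) & (q <= 1))


def groups_series(matrix, a_cols, label_a="A", label_b="B"):
    labs = [label_a if c in a_cols else label_b
            for c in matrix.values.columns]
    return pd.Series(pd.Categorical(labs, categories=[label_a, label_b]),
                     index=matrix.values.columns)


class TestCompareGroups:
    def test_identical_groups_null(self, rng):
        block = rng.normal(5, 1, size=(20, 10))
        mat = make_matrix(np.hstack([block, block]))
        groups = groups_series(mat, set(mat.values.columns[:10]))
        res = compare_groups(mat, groups)
        np.testing.assert_allclose(res.table["fc"], 1.0)
        assert (res.table["call"] == "ns").all()

    def test_strong_separation_matches_welch_oracle(self, rng):
        a = rng.normal(10, 1, size=20)
        b = rng.normal(2, 1, size=20)
        mat = make_matrix(np.concatenate([a, b])[None, :])
        groups = groups_series(mat, set(mat.values.columns[:20]))
        res = compare_groups(mat, groups)
        # hand Welch t statistic
        t_hand = (a.mean() - b.mean()) / np.sqrt(a.var(ddof=1) / 20
                                                 + b.var(ddof=1) / 20)
        assert res.table["statistic"].iloc[0] == pytest.approx(t_hand,
                                                               abs=1e-10)
        assert res.table["call"].iloc[0] == "up"
        assert res.table["q"].iloc[0] < 1e-6

    def test_group_swap_inverts_fc_and_calls(self, rng):
        vals = rng.normal(5, 1, size=(30, 16))
        vals[:10, :8] += 3.0
        mat = make_matrix(vals)
        first = set(mat.values.columns[:8])
        labs = ["A" if c in first else "B" for c in mat.values.columns]
        res_ab = compare_groups(mat, pd.Series(
            pd.Categorical(labs, categories=["A", "B"]),
            index=mat.values.columns))
        res_ba = compare_groups(mat, pd.Series(
            pd.Categorical(labs, categories=["B", "A"]),
            index=mat.values.columns))
        np.testing.assert_allclose(res_ab.table["log2fc"],
                                   -res_ba.table["log2fc"], atol=1e-9)
        swapped = res_ba.table["call"].map(
            {"up": "down", "down": "up", "ns": "ns"})
        assert (res_ab.table["call"] == swapped).all()

    def test_sample_order_invariance(self, rng):
        vals = rng.normal(5, 1, size=(15, 12))
        mat = make_matrix(vals)
        groups = groups_series(mat, set(mat.values.columns[:6]))
        perm = rng.permutation(12)
        mat2 = OmicsMatrix(mat.values.iloc[:, perm], "protein", "log2")
        res1 = compare_groups(mat, groups)
        res2 = compare_groups(mat2, groups)
        pd.testing.assert_frame_equal(res1.table, res2.table)

    def test_min_obs_skips_sparse_features(self, rng):
        vals = rng.normal(5, 1, size=(2, 12))
        vals[0, :5] = np.nan
        mat = make_matrix(vals)
        groups = groups_series(mat, set(mat.values.columns[:6]))
        res = compare_groups(mat, groups, min_obs=4)
        assert res.skipped == ["G0"]

    def test_empty_group_rejected(self, rng):
        mat = make_matrix(rng.normal(size=(3, 4)))
        groups = pd.Series(["A"] * 4, index=mat.values.columns)
        with pytest.raises(ValueError):
            compare_groups(mat, groups)

    def test_anova_and_kruskal_three_groups(self, rng):
        vals = np.concatenate([rng.normal(0, 1, (5, 10)),
                               rng.normal(0, 1, (5, 10)) + 4], axis=0)
        mat = make_matrix(vals.T[:6])  # 6 features x 10 samples
        groups = pd.Series(["A"] * 3 + ["B"] * 3 + ["C"] * 4,
                           index=mat.values.columns)
        res = compare_groups(mat, groups, test="anova", min_obs=2)
        arrays = [mat.values.loc["G0", groups == g] for g in "ABC"]
        f_hand = stats.f_oneway(*arrays)
        assert res.table.loc["G0", "statistic"] == pytest.approx(
            f_hand.statistic)
        compare_groups(mat, groups, test="kruskal", min_obs=2)  # smoke


class TestZscoreRows:
    def test_hand_example_population_sd(self):
        z = zscore_rows(make_matrix([[1.0, 2.0, 3.0]]))
        np.testing.assert_allclose(z.values.to_numpy()[0],
                                   [-1.2247448, 0.0, 1.2247448], atol=1e-6)

    def test_constant_row_all_missing(self):
        z = zscore_rows(make_matrix([[2.0, 2.0, 2.0], [1.0, 2.0, 3.0]]))
        assert z.values.iloc[0].isna().all()
        assert not z.values.iloc[1].isna().any()

    def test_idempotent(self, rng):
        mat = make_matrix(rng.normal(size=(10, 8)))
        z1 = zscore_rows(mat)
        z2 = zscore_rows(z1)
        pd.testing.assert_frame_equal(z1.values, z2.values, atol=1e-9)

    def test_moments(self, rng):
        z = zscore_rows(make_matrix(rng.normal(5, 3, size=(20, 15))))
        np.testing.assert_allclose(z.values.mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(z.values.std(axis=1, ddof=0), 1.0,
                                   atol=1e-9)


class TestCascades:
    def test_all_missing_matrix_empty_cascade(self, rng):
        vals = rng.normal(size=(5, 8))
        vals[:, 0] = np.nan  # nothing complete
        tum = make_matrix(vals)
        nat = make_matrix(rng.normal(size=(5, 8)))
        fits = pd.DataFrame({"hr": [], "p": []})
        res = biomarker_cascade_exosome(tum, nat, fits)
        assert res.counts == [0, 0, 0]

    def test_missing_survival_rejected(self, rng):
        tum = make_matrix(rng.normal(size=(3, 4)))
        with pytest.raises(ValueError, match="survival"):
            biomarker_cascade_exosome(tum, tum, None)

    def test_engineered_biomarker_passes_all_stages(self, rng):
        n = 30
        nat = rng.normal(5, 1, size=(4, n))
        tum = nat + rng.normal(0, 0.3, size=(4, n))
        tum[0] += 2.5  # complete, FC ~ 5.6, will be marked hazardous
        tum_m = make_matrix(tum, samples=[f"T{i}" for i in range(n)])
        nat_m = make_matrix(nat, samples=[f"N{i}" for i in range(n)])
        fits = pd.DataFrame({"hr": [3.0, 0.5, 1.0, 2.0],
                             "p": [0.001, 0.9, 0.5, 0.2]},
                            index=[f"G{i}" for i in range(4)])
        res = biomarker_cascade_exosome(tum_m, nat_m, fits)
        assert res.final == ["G0"]

    def test_marker_screen_small_subtype_rejected(self, rng):
        mat = make_matrix(rng.normal(size=(5, 10)))
        labels = pd.Series([1] * 8 + [2] * 2, index=mat.values.columns)
        with pytest.raises(ValueError, match="< 3 samples"):
            subtype_marker_screen(mat, labels, pd.DataFrame({"hr": [],
                                                             "p": []}))

    def test_detection_threshold_excludes_sparse_feature(self, rng):
        vals = rng.normal(5, 0.5, size=(2, 20))
        vals[0, 20 - 4:] = np.nan          # 80% detected -> excluded
        vals[1, :7] += 3.0                 # subtype-1 marker, complete
        mat = make_matrix(vals)
        labels = pd.Series([1] * 7 + [2] * 7 + [3] * 6,
                           index=mat.values.columns)
        fits = pd.DataFrame({"hr": [2.0, 2.0], "p": [0.001, 0.001]},
                            index=["G0", "G1"])
        out = subtype_marker_screen(mat, labels, fits)
        assert list(out["feature"]) == ["G1"]
        assert list(out["subtype"]) == [1]
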