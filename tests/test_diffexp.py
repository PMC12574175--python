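"""Differential expression: quantile normalization, Welch and moderated
t statistics, BH FDR, threshold classification, clustering."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from cernet.diffexp import (
    DiffExpError,
    Thresholds,
    bh_adjust,
    classify_de,
    cluster_features,
    fit_moderated_t,
    quantile_normalize,
    welch_de_table,
    welch_test,
)
from cernet.expression import SENTINEL_NOT_DETECTED, read_expression_table

from conftest import make_design, make_matrix


class TestQuantileNormalize:
    def test_two_columns_become_mean_quantiles(self):
        m = quantile_normalize(make_matrix([[1, 4], [2, 5], [3, 6]]))
        expected = np.array([[2.5, 2.5], [3.5, 3.5], [4.5, 4.5]])
        np.testing.assert_allclose(m.values.to_numpy(), expected)

    def test_one_column_unchanged(self):
        m = quantile_normalize(make_matrix([[3.0], [1.0], [2.0]]))
        np.testing.assert_allclose(m.values.to_numpy().ravel(), [3, 1, 2])

    def test_identical_columns_are_a_fixed_point(self):
        x = [[1.0, 1.0], [5.0, 5.0], [3.0, 3.0]]
        m = quantile_normalize(make_matrix(x))
        np.testing.assert_allclose(m.values.to_numpy(), x)

    def test_ties_get_mean_reference_quantile(self):
        # column 0 has a tie at rank (1,2); both cells get the mean of the
        # two lowest reference quantiles
        m = quantile_normalize(make_matrix([[1, 10], [1, 20], [9, 30]]))
        col0 = m.values.to_numpy()[:, 0]
        ref = np.sort(np.array([[1, 1, 9], [10, 20, 30]]).T, axis=0).mean(axis=1)
        np.testing.assert_allclose(col0[:2], (ref[0] + ref[1]) / 2)

    def test_single_row_becomes_row_mean(self):
        m = quantile_normalize(make_matrix([[2.0, 4.0]]))
        np.testing.assert_allclose(m.values.to_numpy(), [[3.0, 3.0]])

    def test_masked_cells_rejected(self):
        m = make_matrix([[SENTINEL_NOT_DETECTED, 1.0], [2.0, 3.0]]).apply_sentinel(
            SENTINEL_NOT_DETECTED
        )
        with pytest.raises(DiffExpError, match="complete"):
            quantile_normalize(m)


class TestWelch:
    def test_identical_groups_are_null(self):
        t, df, p = welch_test(np.array([1.0, 2, 3]), np.array([1.0, 2, 3]))
        assert t == 0 and p == 1

    def test_textbook_case_against_t_cdf_oracle(self):
        x, y = np.array([1.0, 2, 3]), np.array([4.0, 5, 6])
        t, df, p = welch_test(x, y)
        # hand Welch: t = 3/sqrt(1/3+1/3), Welch-Satterthwaite df = 4
        assert t == pytest.approx(3.0 / np.sqrt(2.0 / 3.0), rel=1e-12)
        assert df == pytest.approx(4.0, rel=1e-12)
        assert p == pytest.approx(2 * stats.t.sf(abs(t), df), rel=1e-12)

    def test_antisymmetry(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=5), rng.normal(size=7)
        t1, _, p1 = welch_test(x, y)
        t2, _, p2 = welch_test(y, x)
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)

    def test_degenerate_variance_raises(self):
        with pytest.raises(DiffExpError, match="degenerate"):
            welch_test(np.array([2.0, 2, 2]), np.array([2.0, 2, 2]))

    def test_zero_variance_with_shift_is_perfect_separation(self):
        t, _, p = welch_test(np.array([1.0, 1, 1]), np.array([2.0, 2, 2]))
        assert np.isinf(t) and t > 0 and p == 0

    def test_masked_sentinel_cell_excluded_from_test(self, tmp_path):
        f = tmp_path / "m.tsv"
        f.write_text(
            "feature\ta1\ta2\ta3\tb1\tb2\tb3\n"
            f"g\t{SENTINEL_NOT_DETECTED}\t1.0\t2.0\t4.0\t5.0\t6.0\n"
        )
        m = read_expression_table(f, sentinel=SENTINEL_NOT_DETECTED)
        det = welch_de_table(m, make_design(3, 3, samples=list(m.sample_ids)))
        assert det.loc["g", "n_ref"] == 2  # sentinel cell dropped
        assert det.loc["g", "mean_ref"] == pytest.approx(1.5)
        assert np.isfinite(det.loc["g", "t"])


class TestModeratedT:
    def test_matches_limma_reference_fixture(self):
        """Frozen oracle: Bioconductor limma lmFit+eBayes on the committed
        200x6 matrix, agreement to <=1e-6 relative."""
        m = read_expression_table("tests/data/ebayes_matrix.tsv")
        design = make_design(3, 3, samples=list(m.sample_ids))
        det, params = fit_moderated_t(m, design)
        ref = pd.read_csv("tests/data/ebayes_limma_reference.tsv", sep="\t", index_col=0)
        for col in ("log2fc", "t", "p"):
            rel = (np.abs(det[col] - ref[col]) / np.abs(ref[col])).max()
            assert rel <= 1e-6, f"{col}: {rel}"
        hyper = open("tests/data/ebayes_limma_hyperparams.txt").read().split()
        d0_ref = float(hyper[0].split("=")[1])
        s0_ref = float(hyper[1].split("=")[1])
        assert params.d0 == pytest.approx(d0_ref, rel=1e-6)
        assert params.s0_sq == pytest.approx(s0_ref, rel=1e-6)

    def test_d0_zero_recovers_ordinary_t(self):
        rng = np.random.default_rng(1)
        m = make_matrix(rng.normal(8, 1, (50, 6)))
        design = make_design(3, 3)
        det, _ = fit_moderated_t(m, design, d0_override=0.0)
        vals = m.values
        for fid in list(m.feature_ids)[:10]:
            x = vals.loc[fid][:3].to_numpy()
            y = vals.loc[fid][3:].to_numpy()
            sp = ((x - x.mean()) ** 2).sum() + ((y - y.mean()) ** 2).sum()
            t_ord = (y.mean() - x.mean()) / np.sqrt(sp / 4 * (2 / 3))
            assert det.loc[fid, "t"] == pytest.approx(t_ord, rel=1e-12)
            assert det.loc[fid, "df"] == 4

    def test_identical_variances_shrink_fully_to_the_prior(self):
        # zero spread of residual variances: the fit concludes d0 = inf,
        # the posterior variance is the (bias-corrected) prior for every
        # feature, and moderated t is ordinary t up to one common scale
        base = np.array([0.0, 1.0, -1.0])
        rows = np.vstack([np.hstack([base + k, base + k + 1]) for k in range(30)])
        det, params = fit_moderated_t(make_matrix(rows), make_design(3, 3))
        s2 = params.s2.iloc[0]
        assert np.isinf(params.d0)
        assert (params.s2 == s2).all()
        post = params.posterior_var()
        assert np.allclose(post, params.s0_sq)
        ratio = det["t"] / (det["log2fc"] / np.sqrt(s2 * (2 / 3)))
        assert np.allclose(ratio, ratio.iloc[0])

    def test_infinite_prior_df_limit(self):
        rng = np.random.default_rng(2)
        m = make_matrix(rng.normal(0, 1, (40, 6)))
        design = make_design(3, 3)
        det, params = fit_moderated_t(m, design, d0_override=np.inf)
        # with d0=inf every feature is scaled by the common prior variance
        lfc = det["log2fc"]
        expected = lfc / np.sqrt(params.s0_sq * (2 / 3))
        np.testing.assert_allclose(det["t"], expected, rtol=1e-12)

    def test_fc_linear_matches_log2fc(self):
        rng = np.random.default_rng(4)
        m = make_matrix(rng.normal(8, 1, (20, 6)))
        det, _ = fit_moderated_t(m, make_design(3, 3))
        np.testing.assert_allclose(det["fc_linear"], 2 ** det["log2fc"], rtol=1e-9)

    def test_single_group_rejected(self):
        m = make_matrix(np.zeros((3, 2)))
        with pytest.raises(DiffExpError):
            fit_moderated_t(m, make_design(2, 0))


def bh_brute_force(p):
    """Independent step-up enumeration: q_i = min over j with p_(j)>=p_i."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = min(running, 1.0)
    return q


class TestBHAdjust:
    def test_hand_enumerated_example(self):
        np.testing.assert_allclose(
            bh_adjust(np.array([0.01, 0.02, 0.03, 0.04])), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert bh_adjust(np.array([0.3]))[0] == pytest.approx(0.3)

    def test_exhaustive_grid_matches_enumeration(self):
        grid = [0.0, 0.01, 0.04, 0.05, 0.2, 0.5, 1.0]
        for n in range(1, 6):
            for p in itertools.product(grid, repeat=n):
                p = np.array(p)
                np.testing.assert_allclose(bh_adjust(p), bh_brute_force(p), atol=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30), st.randoms(use_true_random=False))
    def test_q_dominates_p_and_is_permutation_invariant(self, ps, rnd):
        p = np.array(ps)
        q = bh_adjust(p)
        assert (q >= p - 1e-15).all() and (q <= 1).all()
        perm = list(range(len(p)))
        rnd.shuffle(perm)
        q_perm = bh_adjust(p[perm])
        np.testing.assert_allclose(q_perm, q[perm], atol=1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(DiffExpError):
            bh_adjust(np.array([0.5, 1.5]))


def det_frame(rows):
    df = pd.DataFrame(rows, columns=["log2fc", "q", "p"])
    df.index = [f"g{i}" for i in range(len(rows))]
    df["fc_linear"] = 2.0 ** df["log2fc"]
    return df


class TestClassifyDE:
    def test_panel_style_down_call(self):
        det = det_frame([(-2.41, 0.01, 0.001)])
        s = classify_de(det, Thresholds(1.5, 0.05, True))
        assert "g0" in s.down

    def test_boundary_fc_is_ns(self):
        det = det_frame([(np.log2(1.5), 0.001, 0.001)])
        s = classify_de(det, Thresholds(1.5, 0.05, True))
        assert "g0" in s.ns

    def test_insignificant_q_is_ns_regardless_of_fc(self):
        det = det_frame([(5.0, 0.06, 0.001)])
        assert "g0" in classify_de(det, Thresholds(1.5, 0.05, True)).ns
        # p-based preset honors raw p instead
        assert "g0" in classify_de(det, Thresholds(1.5, 0.05, use_q=False)).up

    def test_partition_is_exhaustive_and_disjoint(self):
        rng = np.random.default_rng(8)
        det = det_frame(list(zip(rng.normal(0, 2, 50), rng.uniform(0, 1, 50), rng.uniform(0, 1, 50))))
        s = classify_de(det)
        assert s.up | s.down | s.ns == set(det.index)
        assert not (s.up & s.down) and not (s.up & s.ns) and not (s.down & s.ns)

    def test_fc_min_at_most_one_rejected(self):
        with pytest.raises(DiffExpError):
            Thresholds(fc_min=1.0)


class TestClusterFeatures:
    def test_duplicate_rows_merge_first_at_height_zero(self):
        m = make_matrix([[1.0, 2.0], [1.0, 2.0], [9.0, 9.0]])
        order, link = cluster_features(m)
        assert link[0, 2] == 0.0 and set(link[0, :2]) == {0, 1}

    def test_three_four_five_distance(self):
        m = make_matrix([[0.0, 0.0], [3.0, 4.0]])
        _, link = cluster_features(m)
        assert link[0, 2] == pytest.approx(5.0)

    def test_merge_tree_invariant_under_row_permutation(self):
        rng = np.random.default_rng(9)
        x = rng.normal(0, 1, (12, 4))
        _, link1 = cluster_features(make_matrix(x))
        perm = rng.permutation(12)
        _, link2 = cluster_features(make_matrix(x[perm]))
        np.testing.assert_allclose(np.sort(link1[:, 2]), np.sort(link2[:, 2]), atol=1e-9)

    def test_fewer_than_two_features_identity(self):
        m = make_matrix([[1.0, 2.0]])
        order, link = cluster_features(m)
        assert order == ["f0"] and link is None
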