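import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from tsswitch import (
    aggregate_t_test,
    bh_adjust,
    build_pair_contrast,
    switch_t_test,
    tpm_normalize,
)
from tsswitch.datatypes import PairContrast

from conftest import make_design, make_matrix


def bh_step_up(p):
    """Brute-force BH step-up adjusted p-values (independent oracle)."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        adj[i] = running
    return adj


class TestTpmNormalize:
    def test_counts_become_per_million_proportions(self):
        design = make_design(["t1"], n_replicates=1)
        m = make_matrix({"A": [10], "B": [90]}, design, unit="counts")
        tpm = tpm_normalize(m)
        assert tpm.values["t1_r1"].tolist() == [100000.0, 900000.0]
        assert tpm.unit == "tpm"

    def test_columns_sum_to_one_million_and_idempotent(self, rng):
        design = make_design(["t1", "t2"], n_replicates=2)
        vals = {f"T{i}": rng.integers(1, 500, 4) for i in range(10)}
        tpm = tpm_normalize(make_matrix(vals, design, unit="counts"))
        np.testing.assert_allclose(tpm.values.sum(axis=0), 1e6, rtol=1e-6)
        again = tpm_normalize(tpm)
        np.testing.assert_allclose(again.values, tpm.values, rtol=1e-12)

    def test_zero_library_names_sample(self):
        design = make_design(["t1"], n_replicates=2)
        m = make_matrix({"A": [0, 5], "B": [0, 5]}, design, unit="counts")
        with pytest.raises(ValueError, match="t1_r1"):
            tpm_normalize(m)


class TestBuildPairContrast:
    def _tpm(self):
        design = make_design(["t1", "t2"], n_replicates=3)
        return make_matrix(
            {"G.A": [10, 12, 11, 3, 4, 5], "G.B": [4, 5, 3, 9, 9, 9]},
            design,
        )

    def test_replicate_paired_differences(self):
        c = build_pair_contrast(self._tpm(), "G", "G.A", "G.B", "t1", "t2")
        assert c.diffs_t1.tolist() == [6.0, 7.0, 8.0]
        assert c.d1 == 7.0
        np.testing.assert_allclose(c.agg_t1, [7.0, 8.5, 7.0])

    def test_swapping_tss_order_negates_d(self):
        tpm = self._tpm()
        c1 = build_pair_contrast(tpm, "G", "G.A", "G.B", "t1", "t2")
        c2 = build_pair_contrast(tpm, "G", "G.B", "G.A", "t1", "t2")
        # canonical pair is restored, so the contrast is identical
        assert (c2.tss_a, c2.tss_b) == ("G.A", "G.B")
        assert c1.d1 == c2.d1 and c1.se_d1 == c2.se_d1

    def test_gene_membership_validated(self):
        with pytest.raises(ValueError, match="belong"):
            build_pair_contrast(
                self._tpm(), "G", "G.A", "G.B", "t1", "t2",
                gene_of={"G.A": "G", "G.B": "OTHER"},
            )


def _contrast(diffs_t1, diffs_t2):
    return PairContrast(
        gene_id="G", tss_a="G.A", tss_b="G.B", t1="t1", t2="t2",
        diffs_t1=diffs_t1, diffs_t2=diffs_t2,
        agg_t1=np.ones(len(diffs_t1)), agg_t2=np.ones(len(diffs_t2)),
    )


class TestWelchTests:
    def test_identical_samples_give_t_zero_p_one(self):
        r = switch_t_test(_contrast([1, 2, 3], [1, 2, 3]))
        assert r.statistic == 0.0 and r.p == 1.0

    def test_hand_computed_welch_example(self):
        # means +-7, unit sample variances, n=3: t = 14/sqrt(2/3), df = 4
        r = switch_t_test(_contrast([6, 7, 8], [-6, -7, -8]))
        np.testing.assert_allclose(r.statistic, 14 / np.sqrt(2 / 3), rtol=1e-12)
        np.testing.assert_allclose(r.df, 4.0, rtol=1e-12)
        ref = sps.ttest_ind([6, 7, 8], [-6, -7, -8], equal_var=False)
        np.testing.assert_allclose(r.p, ref.pvalue, rtol=1e-12)

    def test_scaling_both_samples_leaves_t_and_p(self):
        a, b = [6.0, 7.0, 8.0], [-1.0, 0.5, 2.0]
        r1 = switch_t_test(_contrast(a, b))
        r2 = switch_t_test(_contrast([10 * x for x in a], [10 * x for x in b]))
        np.testing.assert_allclose(
            [r1.statistic, r1.p], [r2.statistic, r2.p], rtol=1e-12
        )

    def test_time_swap_flips_sign_only(self):
        a, b = [6.0, 7.0, 9.0], [-1.0, 0.5, 2.0]
        r1 = switch_t_test(_contrast(a, b))
        r2 = switch_t_test(_contrast(b, a))
        np.testing.assert_allclose(r1.statistic, -r2.statistic, rtol=1e-12)
        np.testing.assert_allclose(r1.p, r2.p, rtol=1e-12)

    @settings(max_examples=50, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_scipy_welch_on_random_samples(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1 + rng.random(), rng.integers(2, 6))
        y = rng.normal(rng.normal(), 1 + rng.random(), rng.integers(2, 6))
        r = switch_t_test(_contrast(x, y))
        ref = sps.ttest_ind(x, y, equal_var=False)
        np.testing.assert_allclose(r.statistic, ref.statistic, rtol=1e-9)
        np.testing.assert_allclose(r.p, ref.pvalue, rtol=1e-9)

    def test_aggregate_test_detects_expression_shift(self):
        c = PairContrast(
            gene_id="G", tss_a="G.A", tss_b="G.B", t1="t1", t2="t2",
            diffs_t1=[0, 0, 0], diffs_t2=[0, 0, 0],
            agg_t1=[100, 101, 99], agg_t2=[10, 11, 9],
        )
        r = aggregate_t_test(c)
        assert r.p < 0.001
        ref = sps.ttest_ind([100, 101, 99], [10, 11, 9], equal_var=False)
        np.testing.assert_allclose(r.p, ref.pvalue, rtol=1e-9)

    def test_aggregate_equal_means_p_one(self):
        c = PairContrast(
            gene_id="G", tss_a="G.A", tss_b="G.B", t1="t1", t2="t2",
            diffs_t1=[0, 1, 2], diffs_t2=[0, 1, 2],
            agg_t1=[5, 6, 7], agg_t2=[7, 5, 6],
        )
        assert aggregate_t_test(c).p == 1.0

    def test_noise_free_unequal_means_do_not_crash(self):
        r = switch_t_test(_contrast([5, 5, 5], [2, 2, 2]))
        assert np.isfinite(r.statistic) and r.p < 1e-6


class TestBhAdjust:
    @pytest.mark.parametrize(
        "pvals, expected",
        [
            ([0.05], [0.05]),
            ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
            ([1.0, 1.0], [1.0, 1.0]),
        ],
    )
    def test_hand_worked_examples(self, pvals, expected):
        np.testing.assert_allclose(bh_adjust(pvals), expected, rtol=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])
        with pytest.raises(ValueError):
            bh_adjust([-0.1])

    @settings(max_examples=100, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_brute_force_step_up(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(rng.integers(1, 40))
        np.testing.assert_allclose(bh_adjust(p), bh_step_up(p), rtol=1e-12)

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_dominates_input_and_capped(self, pvals):
        q = bh_adjust(pvals)
        assert np.all(q >= np.asarray(pvals) - 1e-15)
        assert np.all(q <= 1.0)
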