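import numpy as np
import pytest

from ncruv.core_data import (
    ControlMask,
    CountMatrix,
    LogExpressionMatrix,
    ProbeAnnotation,
    log_transform,
    make_replicate_design,
)
from ncruv.diagnostics import (
    average_stats,
    leave_pair_out_tra,
    pca,
    plot_average,
    plot_pca,
    plot_rle,
    plot_tra,
    rle,
    tra,
)


def log_matrix(values, ids=None):
    values = np.asarray(values, dtype=float)
    m, n = values.shape
    ids = ids or [f"s{i}" for i in range(m)]
    return LogExpressionMatrix(values, ids, [f"g{j}" for j in range(n)])


class TestRLE:
    def test_constant_matrix_is_zero(self):
        res = rle(log_matrix(np.full((3, 4), 5.0)))
        np.testing.assert_array_equal(res.rle_values, 0.0)

    def test_median_subtraction_single_gene(self):
        res = rle(log_matrix([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(res.rle_values.ravel(), [-1, 0, 1])

    def test_gene_wise_medians_are_zero(self, rng):
        res = rle(log_matrix(rng.normal(size=(7, 30))))
        np.testing.assert_allclose(np.median(res.rle_values, axis=0), 0.0, atol=1e-12)

    def test_sample_shift_moves_its_median_by_the_shift(self, rng):
        # a constant added to one sample reappears in that sample's RLE
        # median, less the small drag it exerts on the gene-wise medians
        base = rng.normal(0, 1, size=(25, 1000))
        shifted = base.copy()
        shifted[3] += 0.7
        drag = float(np.mean(np.median(shifted, axis=0) - np.median(base, axis=0)))
        med_base = rle(log_matrix(base)).sample_summaries[3]["median"]
        med_shift = rle(log_matrix(shifted)).sample_summaries[3]["median"]
        assert med_shift - med_base == pytest.approx(0.7 - drag, abs=0.01)
        other_base = rle(log_matrix(base)).sample_summaries[0]["median"]
        other_shift = rle(log_matrix(shifted)).sample_summaries[0]["median"]
        assert other_shift - other_base == pytest.approx(-drag, abs=0.01)


class TestTRA:
    def test_identical_replicates_zero_ratios(self):
        vals = np.array([[1.0, 2.0], [1.0, 2.0], [3.0, 4.0]])
        design = make_replicate_design(["a", "b", "c"], ["x", "x", "y"])
        res = tra(log_matrix(vals, ["a", "b", "c"]), design)
        np.testing.assert_array_equal(res.log_ratios, 0.0)

    def test_unit_offset_pair(self):
        vals = np.array([[5.0, 6.0], [4.0, 5.0]])
        design = make_replicate_design(["a", "b"], ["x", "x"])
        res = tra(log_matrix(vals, ["a", "b"]), design)
        np.testing.assert_array_equal(res.log_ratios, 1.0)
        assert abs(res.pooled_median) == 1.0

    def test_antisymmetric_under_member_swap(self, rng):
        vals = rng.normal(size=(4, 10))
        d1 = make_replicate_design(["a", "b", "c", "d"], ["x", "x", "y", "z"])
        res = tra(log_matrix(vals, ["a", "b", "c", "d"]), d1)
        swapped = vals[[1, 0, 2, 3]]
        res2 = tra(log_matrix(swapped, ["b", "a", "c", "d"]), d1)
        np.testing.assert_allclose(res2.log_ratios, -res.log_ratios)
        assert res2.pooled_iqr == pytest.approx(res.pooled_iqr)

    def test_triple_contributes_three_pairs(self, rng):
        vals = rng.normal(size=(3, 5))
        design = make_replicate_design(["a", "b", "c"], ["x", "x", "x"])
        res = tra(log_matrix(vals, ["a", "b", "c"]), design)
        assert len(res.pair_ids) == 3

    def test_no_pairs_errors(self):
        design = make_replicate_design(["a", "b"], ["x", "y"])
        with pytest.raises(ValueError, match="no replicate pairs"):
            tra(log_matrix(np.zeros((2, 2))), design)

    def test_ruv3_leave_pair_out_narrows_tra(self, codeset_experiment):
        """With batch effects, leave-pair-out RUV-III agreement beats raw."""
        exp = codeset_experiment
        Y = log_transform(exp.counts)
        ctl = ControlMask(np.ones(Y.n_probes, bool), "all_genes")
        raw = tra(Y, exp.design)
        cleaned = leave_pair_out_tra(Y, exp.design, ctl, 1)
        assert cleaned.pooled_iqr < raw.pooled_iqr


class TestPCA:
    def test_duplicated_samples_equal_scores(self, rng):
        vals = rng.normal(size=(5, 8))
        vals[1] = vals[0]
        res = pca(log_matrix(vals))
        np.testing.assert_allclose(res.scores[0], res.scores[1], atol=1e-10)

    def test_variance_ratios_sum_to_one(self, rng):
        res = pca(log_matrix(rng.normal(size=(6, 10))))
        assert res.variance_ratio.sum() == pytest.approx(1.0)
        assert np.all(res.variance_ratio >= 0)

    def test_scores_orthogonal(self, rng):
        res = pca(log_matrix(rng.normal(size=(8, 12))))
        gram = res.scores.T @ res.scores
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) < 1e-8

    def test_planted_factor_dominates_pc1(self, rng):
        factor = rng.normal(size=20)
        loadings = rng.normal(size=50)
        vals = np.outer(factor, loadings) * 3 + rng.normal(0, 0.1, size=(20, 50))
        res = pca(log_matrix(vals))
        assert res.variance_ratio[0] > 5 * res.variance_ratio[1]
        corr = np.corrcoef(res.scores[:, 0], factor)[0, 1]
        assert abs(corr) >= 0.99

    def test_gene_constant_invariance_up_to_sign(self, rng):
        vals = rng.normal(size=(6, 9))
        res1 = pca(log_matrix(vals))
        res2 = pca(log_matrix(vals + rng.normal(size=(1, 9))))
        np.testing.assert_allclose(np.abs(res1.scores), np.abs(res2.scores), atol=1e-8)

    def test_standardized_drops_zero_variance_gene(self, rng):
        vals = rng.normal(size=(5, 4))
        vals[:, 2] = 1.0
        with pytest.warns(UserWarning, match="zero-variance"):
            res = pca(log_matrix(vals), standardized=True)
        assert len(res.probe_names) == 3


class TestAverage:
    def make_counts(self, values, classes):
        names = [f"p{j}" for j in range(len(classes))]
        m = values.shape[0]
        counts = CountMatrix(values, [f"s{i}" for i in range(m)], names)
        return counts, ProbeAnnotation(names, classes)

    def test_all_ones(self):
        classes = ["Negative", "Positive", "Housekeeping", "Endogenous"]
        counts, ann = self.make_counts(np.ones((2, 4)), classes)
        res = average_stats(counts, ann)
        np.testing.assert_array_equal(res.neg_mean, 0.0)
        np.testing.assert_array_equal(res.hk_mean, 0.0)
        np.testing.assert_allclose(res.log_total, np.log2(4))

    def test_doubling_one_sample_adds_one(self, rng):
        classes = ["Negative"] * 2 + ["Positive"] * 2 + ["Housekeeping"] * 2 + ["Endogenous"] * 4
        values = rng.integers(10, 100, size=(3, 10)).astype(float)
        doubled = values.copy()
        doubled[1] *= 2
        counts1, ann = self.make_counts(values, classes)
        counts2, _ = self.make_counts(doubled, classes)
        r1, r2 = average_stats(counts1, ann), average_stats(counts2, ann)
        assert r2.neg_mean[1] - r1.neg_mean[1] == pytest.approx(1.0)
        assert r2.hk_mean[1] - r1.hk_mean[1] == pytest.approx(1.0)
        assert r2.log_total[1] - r1.log_total[1] == pytest.approx(1.0)

    def test_run_order_sorts_series(self, rng):
        classes = ["Negative", "Endogenous"]
        counts, ann = self.make_counts(
            np.array([[1.0, 2.0], [4.0, 8.0], [16.0, 32.0]]), classes
        )
        res = average_stats(counts, ann, run_order=[2, 0, 1])
        assert res.sample_ids == ["s1", "s2", "s0"]

    def test_bad_late_cartridge_pattern(self):
        """Content loss in the last batch: HK/log-total dip, spike-ins flat."""
        from ncruv.simulate import scenario_presets, simulate

        exp = simulate(scenario_presets()["late_bad_cartridge"])
        res = average_stats(exp.counts, exp.annotation, exp.samples.run_order)
        order = [exp.counts.sample_ids.index(s) for s in res.sample_ids]
        last = np.array([exp.samples.batch[i] == "batch5" for i in order])
        assert res.hk_mean[last].mean() < res.hk_mean[~last].mean() - 0.5
        assert res.log_total[last].mean() < res.log_total[~last].mean() - 0.5
        assert abs(res.neg_mean[last].mean() - res.neg_mean[~last].mean()) < 0.2
        assert abs(res.pos_mean[last].mean() - res.pos_mean[~last].mean()) < 0.2


class TestPlots:
    def test_plot_functions_write_files(self, tmp_path, rng, small_experiment):
        exp = small_experiment
        Y = log_transform(exp.counts)
        plot_rle(rle(Y), tmp_path / "rle.png")
        plot_tra(tra(Y, exp.design), tmp_path / "tra.png")
        plot_pca(pca(Y), tmp_path / "pca.png", color_by=exp.samples.batch)
        plot_average(
            average_stats(exp.counts, exp.annotation, exp.samples.run_order),
            tmp_path / "avg.png",
        )
        for name in ("rle", "tra", "pca", "avg"):
            assert (tmp_path / f"{name}.png").stat().st_size > 0
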