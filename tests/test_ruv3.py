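import numpy as np
import pytest

from ncruv.core_data import ControlMask, LogExpressionMatrix, make_replicate_design
from ncruv.ruv3 import (
    leave_pair_out_normalize,
    residual_op,
    ruv3_fit,
    ruv3_normalize,
    split_pair_design,
)


def brute_force_removal(values, M, ctl, k):
    """Independent reference: explicit projector and eigendecomposition of RR'.

    Returns the W @ alpha product (the only identified quantity)."""
    values = np.asarray(values, dtype=float)
    ctl = np.asarray(ctl, dtype=bool)
    m = values.shape[0]
    Y0 = values - values.mean(axis=0)
    P = M @ np.linalg.inv(M.T @ M) @ M.T
    R = (np.eye(m) - P) @ Y0
    evals, evecs = np.linalg.eigh(R @ R.T)
    order = np.argsort(evals)[::-1]
    U = evecs[:, order]
    k_max = min(m - M.shape[1], int(ctl.sum()))
    alpha = (U[:, :k_max].T @ Y0)[:k]
    a_c = alpha[:, ctl]
    W = Y0[:, ctl] @ a_c.T @ np.linalg.pinv(a_c @ a_c.T)
    return W @ alpha


def random_instance(seed):
    rng = np.random.default_rng(seed)
    n_bio = int(rng.integers(3, 8))
    n_extra = int(rng.integers(1, 4))
    bio = list(range(n_bio)) + list(rng.integers(0, n_bio, size=n_extra))
    rng.shuffle(bio)
    m = len(bio)
    n = int(rng.integers(max(6, m), 21))
    values = rng.normal(5, 2, size=(m, n))
    ids = [f"s{i}" for i in range(m)]
    design = make_replicate_design(ids, [f"b{x}" for x in bio])
    ctl = rng.random(n) < 0.7
    if not ctl.any():
        ctl[0] = True
    k_max = min(design.n_replicates, int(ctl.sum()))
    k = int(rng.integers(1, k_max + 1))
    Y = LogExpressionMatrix(values, ids, [f"g{j}" for j in range(n)])
    return Y, design, ControlMask(ctl), k


class TestResidualOp:
    def test_group_mean_subtraction(self):
        Y = LogExpressionMatrix(
            np.array([[1.0], [3.0], [5.0], [9.0]]), list("abcd"), ["g"]
        )
        design = make_replicate_design(list("abcd"), ["x", "x", "y", "y"])
        np.testing.assert_allclose(residual_op(Y, design).ravel(), [-1, 1, -2, 2])

    def test_identity_design_gives_zero(self, rng):
        Y = LogExpressionMatrix(rng.normal(size=(4, 5)), list("abcd"), [f"g{j}" for j in range(5)])
        design = make_replicate_design(list("abcd"), list("wxyz"))
        np.testing.assert_allclose(residual_op(Y, design), 0.0)

    def test_projection_is_idempotent(self, rng, paired_design):
        Y = LogExpressionMatrix(
            rng.normal(size=(8, 6)), paired_design.sample_ids, [f"g{j}" for j in range(6)]
        )
        R1 = residual_op(Y, paired_design)
        Y2 = LogExpressionMatrix(R1, paired_design.sample_ids, Y.probe_names)
        np.testing.assert_allclose(residual_op(Y2, paired_design), R1, atol=1e-12)


class TestFit:
    @pytest.mark.parametrize("seed", range(1, 21))
    def test_matches_brute_force_oracle(self, seed):
        Y, design, ctl, k = random_instance(seed)
        fit = ruv3_fit(Y, design, ctl, k)
        expected = brute_force_removal(Y.values, design.M, ctl.ctl, k)
        assert np.max(np.abs(fit.W @ fit.alpha - expected)) <= 1e-8

    def test_equal_replicate_rows_leave_zero_residual(self, rng):
        vals = rng.normal(size=(6, 8))
        vals[1] = vals[0]
        ids = [f"s{i}" for i in range(6)]
        design = make_replicate_design(ids, ["a", "a", "b", "c", "d", "e"])
        Y = LogExpressionMatrix(vals, ids, [f"g{j}" for j in range(8)])
        R = residual_op(Y, design)
        np.testing.assert_allclose(R[:2], 0.0, atol=1e-12)

    def test_k_max_bounds(self, rng, paired_design):
        Y = LogExpressionMatrix(
            rng.normal(size=(8, 10)), paired_design.sample_ids, [f"g{j}" for j in range(10)]
        )
        # 4 replicates but only 2 control genes: k_max = 2
        ctl = ControlMask(np.array([True, True] + [False] * 8))
        fit = ruv3_fit(Y, paired_design, ctl, 2)
        assert fit.k_max == 2
        with pytest.raises(ValueError, match="k_max"):
            ruv3_fit(Y, paired_design, ctl, 3)

    def test_no_replicates_errors(self, rng):
        Y = LogExpressionMatrix(rng.normal(size=(3, 5)), list("abc"), [f"g{j}" for j in range(5)])
        design = make_replicate_design(list("abc"), list("xyz"))
        with pytest.raises(ValueError, match="no technical replicates"):
            ruv3_fit(Y, design, ControlMask(np.ones(5, bool)), 1)


class TestNormalize:
    def test_k_zero_is_identity(self, rng, paired_design):
        Y = LogExpressionMatrix(
            rng.normal(size=(8, 5)), paired_design.sample_ids, [f"g{j}" for j in range(5)]
        )
        out = ruv3_normalize(Y, paired_design, ControlMask(np.ones(5, bool)), 0)
        np.testing.assert_array_equal(out.values, Y.values)

    def test_exact_removal_in_noiseless_limit(self, rng, paired_design):
        """Y = 1 mu' + W alpha with replicates spanning W's variation is
        restored exactly to 1 mu' at k = rank(W)."""
        m, n, k = 8, 12, 2
        mu = rng.uniform(4, 10, size=n)
        W = rng.normal(size=(m, k))
        W -= W.mean(axis=0)
        alpha = rng.normal(size=(k, n))
        Y = LogExpressionMatrix(
            np.tile(mu, (m, 1)) + W @ alpha, paired_design.sample_ids,
            [f"g{j}" for j in range(n)],
        )
        out = ruv3_normalize(Y, paired_design, ControlMask(np.ones(n, bool)), k)
        assert np.max(np.abs(out.values - mu)) <= 1e-6

    def test_batch_factor_recovery(self, codeset_experiment):
        from ncruv.core_data import log_transform

        exp = codeset_experiment
        Y = log_transform(exp.counts)
        ctl = ControlMask(np.ones(Y.n_probes, bool), "all_genes")
        fit = ruv3_fit(Y, exp.design, ctl, 1)
        corr = np.corrcoef(fit.W[:, 0], exp.truth.W_true[:, 0])[0, 1]
        assert abs(corr) >= 0.9

    def test_permutation_equivariance(self, rng, paired_design):
        n = 6
        Y = LogExpressionMatrix(
            rng.normal(size=(8, n)), paired_design.sample_ids, [f"g{j}" for j in range(n)]
        )
        ctl = ControlMask(np.ones(n, bool))
        out = ruv3_normalize(Y, paired_design, ctl, 2).values
        perm = rng.permutation(8)
        Yp = LogExpressionMatrix(
            Y.values[perm], [paired_design.sample_ids[i] for i in perm], Y.probe_names
        )
        designp = make_replicate_design(
            Yp.sample_ids, [paired_design.biological_ids[i] for i in perm]
        )
        outp = ruv3_normalize(Yp, designp, ctl, 2).values
        np.testing.assert_allclose(outp, out[perm], atol=1e-8)

    def test_average_collapses_replicate_groups(self, rng, paired_design):
        n = 5
        Y = LogExpressionMatrix(
            rng.normal(size=(8, n)), paired_design.sample_ids, [f"g{j}" for j in range(n)]
        )
        out = ruv3_normalize(Y, paired_design, ControlMask(np.ones(n, bool)), 1, average=True)
        assert out.values.shape == (4, n)
        assert out.averaged
        full = ruv3_normalize(Y, paired_design, ControlMask(np.ones(n, bool)), 1)
        np.testing.assert_allclose(out.values, (full.values[::2] + full.values[1::2]) / 2)


class TestLeavePairOut:
    def test_single_pair_boundary_errors(self, rng):
        ids = ["s0", "s1", "s2"]
        design = make_replicate_design(ids, ["a", "a", "b"])
        Y = LogExpressionMatrix(rng.normal(size=(3, 4)), ids, [f"g{j}" for j in range(4)])
        with pytest.raises(ValueError, match="no technical replicates"):
            leave_pair_out_normalize(Y, design, ControlMask(np.ones(4, bool)), 1, ("s0", "s1"))

    def test_k_max_bookkeeping(self, paired_design):
        reduced = split_pair_design(paired_design, ("s0", "s1"))
        assert reduced.n_replicates == paired_design.n_replicates - 1
        assert reduced.m_prime == paired_design.m_prime + 1

    def test_non_replicated_pair_errors(self, paired_design):
        with pytest.raises(ValueError, match="not a replicate pair"):
            split_pair_design(paired_design, ("s0", "s2"))

    def test_shapes_preserved(self, rng, paired_design):
        n = 6
        Y = LogExpressionMatrix(
            rng.normal(size=(8, n)), paired_design.sample_ids, [f"g{j}" for j in range(n)]
        )
        out = leave_pair_out_normalize(
            Y, paired_design, ControlMask(np.ones(n, bool)), 2, ("s2", "s3")
        )
        assert out.values.shape == Y.values.shape
        assert out.sample_ids == Y.sample_ids
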