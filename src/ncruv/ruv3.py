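"""RUV-III: removing unwanted variation using technical replicates and
negative-control genes.

The model is Y = X beta + W alpha + eps on the log2 scale, with W the
sample-level scores of k unwanted factors and alpha their gene loadings.
RUV-III estimates W alpha in three steps:

(i)   project Y onto the orthogonal complement of the replicate structure:
      R = Y - M (M'M)^-1 M' Y removes everything shared within replicate
      groups (biology included), leaving replicate disagreement -- pure
      unwanted variation plus noise;
(ii)  the left singular vectors of R give candidate directions of unwanted
      variation; regressing the negative-control expression on the
      corresponding loadings recovers per-sample scores W even for the
      within-group component that the residuals cannot see;
(iii) subtract the estimate W alpha from Y.

k, the number of unwanted dimensions removed, is capped by
min(m - m', n_ctl): the replicate residuals have rank at most m - m'
(the number of technical replicates), and the loadings regression needs at
least k control genes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from ncruv.core_data import ControlMask, LogExpressionMatrix, ReplicateDesign

logger = logging.getLogger(__name__)


@dataclass
class RUV3Fit:
    W: np.ndarray  # m x k unwanted-factor scores
    alpha: np.ndarray  # k x n gene loadings
    fullalpha: np.ndarray  # k_max x n loadings for all estimable dimensions
    k: int
    k_max: int
    ctl: ControlMask
    gene_means: np.ndarray  # length-n, re-added after subtraction


@dataclass
class NormalizedExpression:
    values: np.ndarray  # m x n (or m' x n when averaged) log2 expression
    sample_ids: list[str]
    probe_names: list[str]
    fit: RUV3Fit | None
    averaged: bool = False

    def as_log_matrix(self, log_offset: float = 1.0) -> LogExpressionMatrix:
        return LogExpressionMatrix(
            self.values, list(self.sample_ids), list(self.probe_names), log_offset
        )


def _group_mean_projector_apply(M: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """M (M'M)^-1 M' Y without forming the m x m projector."""
    group_sizes = M.sum(axis=0)
    group_means = (M.T @ Y) / group_sizes[:, None]
    return M @ group_means


def residual_op(Y: LogExpressionMatrix, design: ReplicateDesign) -> np.ndarray:
    """Residuals after removing replicate-group means: R = Y - M(M'M)^-1 M'Y.

    Rows in singleton groups are exactly zero; applying the operator twice
    equals applying it once (it is an orthogonal projection).
    """
    if Y.n_samples != design.m:
        raise ValueError("expression matrix and design have different sample counts")
    return Y.values - _group_mean_projector_apply(design.M, Y.values)


def _sign_fix(U: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-magnitude coordinate positive."""
    U = U.copy()
    for j in range(U.shape[1]):
        i = int(np.argmax(np.abs(U[:, j])))
        if U[i, j] < 0:
            U[:, j] = -U[:, j]
    return U


def ruv3_fit(
    Y: LogExpressionMatrix,
    design: ReplicateDesign,
    ctl: ControlMask,
    k: int,
) -> RUV3Fit:
    """Estimate W (m x k) and alpha (k x n) from replicates and controls.

    Genes are centered before fitting and the means stored for restoration,
    so the unwanted factors never spend a dimension on the grand mean.
    """
    if Y.n_samples != design.m:
        raise ValueError("expression matrix and design have different sample counts")
    if len(ctl.ctl) != Y.n_probes:
        raise ValueError("control mask length differs from probe count")
    n_ctl = ctl.n_controls
    if n_ctl == 0:
        raise ValueError("control mask selects no genes")
    if design.n_replicates == 0:
        raise ValueError("no technical replicates declared (m' = m)")
    k_max = min(design.n_replicates, n_ctl)
    if not 1 <= k <= k_max:
        raise ValueError(
            f"k={k} outside 1..k_max={k_max} "
            f"(m - m' = {design.n_replicates} technical replicates, "
            f"{n_ctl} control genes)"
        )

    gene_means = Y.values.mean(axis=0)
    Y0 = Y.values - gene_means

    R = Y0 - _group_mean_projector_apply(design.M, Y0)
    # SVD of R rather than eigendecomposition of RR' for numerical stability
    U, svals, _ = np.linalg.svd(R, full_matrices=False)
    U = _sign_fix(U[:, :k_max])

    fullalpha = U.T @ Y0  # k_max x n
    alpha = fullalpha[:k]
    a_c = alpha[:, ctl.ctl]  # k x n_ctl
    gram = a_c @ a_c.T
    try:
        cond = np.linalg.cond(gram)
    except np.linalg.LinAlgError:  # pragma: no cover
        cond = np.inf
    if not np.isfinite(cond) or cond > 1e12:
        warnings.warn(
            "control-gene loading matrix is numerically singular; using the "
            "Moore-Penrose pseudo-inverse"
        )
        W = Y0[:, ctl.ctl] @ a_c.T @ np.linalg.pinv(gram)
    else:
        W = Y0[:, ctl.ctl] @ a_c.T @ np.linalg.inv(gram)
    return RUV3Fit(
        W=W,
        alpha=alpha,
        fullalpha=fullalpha,
        k=k,
        k_max=k_max,
        ctl=ctl,
        gene_means=gene_means,
    )


def ruv3_normalize(
    Y: LogExpressionMatrix,
    design: ReplicateDesign,
    ctl: ControlMask,
    k: int,
    average: bool = False,
) -> NormalizedExpression:
    """Subtract the estimated unwanted variation: Y - W alpha.

    ``k = 0`` returns the input unchanged.  With ``average=True`` each
    replicate group is collapsed to its mean, giving an m' x n matrix.
    """
    if k == 0:
        values = Y.values.copy()
        fit = None
    else:
        fit = ruv3_fit(Y, design, ctl, k)
        values = (Y.values - fit.gene_means) - fit.W @ fit.alpha + fit.gene_means
    sample_ids = list(Y.sample_ids)
    averaged = False
    if average:
        group_sizes = design.M.sum(axis=0)
        values = (design.M.T @ values) / group_sizes[:, None]
        # one id per biological sample: the first member's id
        sample_ids = [Y.sample_ids[g[0]] for g in design.groups()]
        averaged = True
    return NormalizedExpression(
        values=values,
        sample_ids=sample_ids,
        probe_names=list(Y.probe_names),
        fit=fit,
        averaged=averaged,
    )


def split_pair_design(design: ReplicateDesign, pair: tuple[str, str]) -> ReplicateDesign:
    """Rebuild the design with the two samples of ``pair`` as singletons."""
    idx = {s: i for i, s in enumerate(design.sample_ids)}
    for s in pair:
        if s not in idx:
            raise ValueError(f"unknown sample {s!r} in pair")
    i, j = idx[pair[0]], idx[pair[1]]
    col_i = int(np.argmax(design.M[i]))
    col_j = int(np.argmax(design.M[j]))
    if col_i != col_j or np.sum(design.M[:, col_i]) < 2:
        raise ValueError(f"samples {pair[0]!r} and {pair[1]!r} are not a replicate pair")
    bio = list(design.biological_ids)
    bio[i] = f"__left_out__{pair[0]}"
    bio[j] = f"__left_out__{pair[1]}"
    from ncruv.core_data import make_replicate_design

    new = make_replicate_design(design.sample_ids, bio)
    new.pseudo_pairs = list(design.pseudo_pairs)
    return new


def leave_pair_out_normalize(
    Y: LogExpressionMatrix,
    design: ReplicateDesign,
    ctl: ControlMask,
    k: int,
    pair: tuple[str, str],
) -> NormalizedExpression:
    """Refit with one replicate pair left undeclared, then normalize.

    Used for honest TRA assessment: a pair's agreement after RUV-III must be
    measured without that pair having informed the fit.  If dropping the
    pair lowers k_max below the requested k, k is capped at the new k_max
    (with a log message) so the leave-out series stays comparable.
    """
    reduced = split_pair_design(design, pair)
    if reduced.n_replicates == 0:
        raise ValueError(
            "no technical replicates declared once the pair is left out"
        )
    k_max = min(reduced.n_replicates, ctl.n_controls)
    k_use = k
    if k > k_max:
        logger.info("leave-pair-out: capping k at reduced k_max=%d", k_max)
        k_use = k_max
    return ruv3_normalize(Y, reduced, ctl, k_use, average=False)
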