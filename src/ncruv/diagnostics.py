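"""Normalization diagnostics: RLE, TRA, PCA and Average summaries.

Each diagnostic works on any expression matrix — raw, nCounter-normalized
or RUV-III-normalized — so the same battery assesses every candidate
normalization.  The plotting functions render a result object and do no
computation of their own.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np

from ncruv.core_data import (
    CountMatrix,
    LogExpressionMatrix,
    ProbeAnnotation,
    ReplicateDesign,
)

logger = logging.getLogger(__name__)


@dataclass
class RLEResult:
    """Relative log expression: each entry minus its gene-wise median.

    A well-normalized matrix has per-sample RLE boxes tightly centred at
    zero; drifting medians and wide boxes flag unwanted variation.
    """

    rle_values: np.ndarray  # m x n
    sample_ids: list[str]
    sample_summaries: list[dict]  # median, q1, q3, lo_whisker, hi_whisker, n_outliers


@dataclass
class TRAResult:
    """Technical-replicate agreement: gene-wise log ratios within each pair."""

    pair_ids: list[tuple[str, str]]
    log_ratios: np.ndarray  # n_pairs x n genes
    per_pair_median: np.ndarray
    per_pair_iqr: np.ndarray
    pooled_median: float
    pooled_iqr: float


@dataclass
class PCAResult:
    scores: np.ndarray  # m x p
    loadings: np.ndarray  # p x n
    variance_ratio: np.ndarray  # length p
    standardized: bool
    sample_ids: list[str]
    probe_names: list[str]


@dataclass
class AverageResult:
    """Per-assay mean log counts of NEG, POS and HK probes plus log total count,
    in run order.  Trends or dips localize bad cartridges and drifts."""

    sample_ids: list[str]
    run_order: list[int]
    neg_mean: np.ndarray | None
    pos_mean: np.ndarray | None
    hk_mean: np.ndarray | None
    log_total: np.ndarray


def _tukey_summary(x: np.ndarray) -> dict:
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = x[(x >= lo_fence) & (x <= hi_fence)]
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "lo_whisker": float(inside.min()) if inside.size else float(q1),
        "hi_whisker": float(inside.max()) if inside.size else float(q3),
        "n_outliers": int(np.sum((x < lo_fence) | (x > hi_fence))),
    }


def rle(Y: LogExpressionMatrix) -> RLEResult:
    """RLE[i, j] = Y[i, j] - median over samples of Y[., j]."""
    med = np.median(Y.values, axis=0)
    values = Y.values - med
    summaries = [_tukey_summary(row) for row in values]
    return RLEResult(values, list(Y.sample_ids), summaries)


def tra(
    Y: LogExpressionMatrix,
    design: ReplicateDesign,
    normalizer: Callable[[tuple[str, str]], np.ndarray] | None = None,
) -> TRAResult:
    """Gene-wise log ratios between members of each technical-replicate pair.

    Replicate groups of size g contribute all g*(g-1)/2 pairs, members in
    run order.  When ``normalizer`` is given (leave-pair-out RUV-III), it is
    called with each pair's sample ids and must return the full normalized
    m x n matrix from which that pair's ratios are taken; otherwise ratios
    come directly from Y.
    """
    pairs = design.replicate_pairs()
    if not pairs:
        raise ValueError("design declares no replicate pairs")
    ratios = []
    pair_ids = []
    for i, j in pairs:
        sid_i, sid_j = design.sample_ids[i], design.sample_ids[j]
        if normalizer is None:
            mat = Y.values
        else:
            mat = normalizer((sid_i, sid_j))
        ratios.append(mat[i] - mat[j])
        pair_ids.append((sid_i, sid_j))
    log_ratios = np.array(ratios)
    per_pair_median = np.median(log_ratios, axis=1)
    per_pair_iqr = np.percentile(log_ratios, 75, axis=1) - np.percentile(
        log_ratios, 25, axis=1
    )
    pooled = log_ratios.ravel()
    return TRAResult(
        pair_ids=pair_ids,
        log_ratios=log_ratios,
        per_pair_median=per_pair_median,
        per_pair_iqr=per_pair_iqr,
        pooled_median=float(np.median(pooled)),
        pooled_iqr=float(np.percentile(pooled, 75) - np.percentile(pooled, 25)),
    )


def leave_pair_out_tra(
    Y: LogExpressionMatrix,
    design: ReplicateDesign,
    ctl,
    k: int,
) -> TRAResult:
    """TRA for RUV-III with the honest leave-pair-out rule.

    Each pair's log ratios are computed from a normalization refit with that
    pair left undeclared as replicates.
    """
    from ncruv.ruv3 import leave_pair_out_normalize

    def normalizer(pair: tuple[str, str]) -> np.ndarray:
        return leave_pair_out_normalize(Y, design, ctl, k, pair).values

    return tra(Y, design, normalizer=normalizer)


def pca(
    Y: LogExpressionMatrix, standardized: bool = False, n_components: int | None = None
) -> PCAResult:
    """PCA of the samples x genes matrix on gene-mean-centred log counts.

    ``standardized=True`` divides each gene by its standard deviation first
    (the correlation-matrix variant); zero-variance genes are then dropped
    with a warning.  Scores carry the variance (U * s), loadings are unit
    length, and a deterministic sign convention (largest-magnitude score
    coordinate positive) makes results reproducible.
    """
    if Y.n_samples < 2:
        raise ValueError("PCA requires at least 2 samples")
    X = Y.values - Y.values.mean(axis=0)
    probe_names = list(Y.probe_names)
    if standardized:
        sd = X.std(axis=0, ddof=1)
        keep = sd > 0
        if not keep.all():
            warnings.warn(
                f"dropping {int((~keep).sum())} zero-variance gene(s) for "
                "standardized PCA"
            )
            X = X[:, keep]
            probe_names = [p for p, k_ in zip(probe_names, keep) if k_]
        X = X / X.std(axis=0, ddof=1)
    p_max = min(Y.n_samples - 1, X.shape[1])
    p = p_max if n_components is None else min(n_components, p_max)
    U, svals, Vt = np.linalg.svd(X, full_matrices=False)
    # sign convention on scores
    for j in range(p):
        i = int(np.argmax(np.abs(U[:, j])))
        if U[i, j] < 0:
            U[:, j] = -U[:, j]
            Vt[j] = -Vt[j]
    total_var = float(np.sum(svals**2))
    scores = U[:, :p] * svals[:p]
    return PCAResult(
        scores=scores,
        loadings=Vt[:p],
        variance_ratio=svals[:p] ** 2 / total_var,
        standardized=standardized,
        sample_ids=list(Y.sample_ids),
        probe_names=probe_names,
    )


def average_stats(
    counts: CountMatrix,
    annotation: ProbeAnnotation,
    run_order: list[int] | None = None,
) -> AverageResult:
    """Per-sample class means of log2 counts and log2 total count, run order.

    Zero counts are floored at 1 before the log, matching the package's log
    rule at offset 0.
    """
    m = counts.n_samples
    run_order = list(range(m)) if run_order is None else list(run_order)
    order = np.argsort(np.asarray(run_order), kind="stable")
    logv = np.log2(np.maximum(counts.values, 1.0))

    def class_mean(mask: np.ndarray) -> np.ndarray | None:
        if not mask.any():
            return None
        return logv[:, mask].mean(axis=1)[order]

    neg_mean = class_mean(annotation.negative)
    pos_mean = class_mean(annotation.positive)
    hk_mean = class_mean(annotation.housekeeping)
    for name, series in (("NEG", neg_mean), ("POS", pos_mean), ("HK", hk_mean)):
        if series is None:
            warnings.warn(f"no {name} probes; that series is absent from the Average result")
    log_total = np.log2(np.maximum(counts.values.sum(axis=1), 1.0))[order]
    return AverageResult(
        sample_ids=[counts.sample_ids[i] for i in order],
        run_order=[run_order[i] for i in order],
        neg_mean=neg_mean,
        pos_mean=pos_mean,
        hk_mean=hk_mean,
        log_total=log_total,
    )


# ---------------------------------------------------------------------------
# plotting (presentation only)


def _get_axes(ax=None):
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 4))
    return ax


def plot_rle(result: RLEResult, path=None, ax=None, color_by=None):
    ax = _get_axes(ax)
    ax.boxplot(
        list(result.rle_values),
        tick_labels=result.sample_ids,
        showfliers=False,
    )
    ax.axhline(0.0, color="grey", lw=0.8, ls="--")
    ax.set_ylabel("relative log expression")
    ax.tick_params(axis="x", rotation=90, labelsize=6)
    return _finish(ax, path)


def plot_tra(result: TRAResult, path=None, ax=None):
    ax = _get_axes(ax)
    ax.boxplot(result.log_ratios.ravel(), tick_labels=["all pairs"])
    ax.axhline(0.0, color="grey", lw=0.8, ls="--")
    ax.set_ylabel("log2 replicate ratio")
    return _finish(ax, path)


def plot_pca(result: PCAResult, path=None, ax=None, color_by=None):
    ax = _get_axes(ax)
    x, y = result.scores[:, 0], result.scores[:, 1]
    if color_by is not None:
        levels = sorted(set(color_by))
        for lev in levels:
            sel = [i for i, c in enumerate(color_by) if c == lev]
            ax.scatter(x[sel], y[sel], label=str(lev), s=18)
        ax.legend(fontsize=7)
    else:
        ax.scatter(x, y, s=18)
    ax.set_xlabel(f"PC1 ({100 * result.variance_ratio[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({100 * result.variance_ratio[1]:.1f}%)")
    return _finish(ax, path)


def plot_average(result: AverageResult, path=None, ax=None):
    ax = _get_axes(ax)
    x = np.arange(len(result.sample_ids))
    series = [
        ("NEG mean", result.neg_mean),
        ("POS mean", result.pos_mean),
        ("HK mean", result.hk_mean),
        ("log total", result.log_total),
    ]
    for label, values in series:
        if values is not None:
            ax.plot(x, values, marker=".", label=label)
    ax.set_xlabel("run order")
    ax.set_ylabel("mean log2 count")
    ax.legend(fontsize=7)
    return _finish(ax, path)


def _finish(ax, path):
    if path is not None:
        ax.figure.tight_layout()
        ax.figure.savefig(path, dpi=120)
        import matplotlib.pyplot as plt

        plt.close(ax.figure)
    return ax
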