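"""The conventional nCounter normalization grid.

nSolver-style normalization is a pipeline of three per-sample scaling
stages, each with a handful of variants:

* positive-control (CodeCount) scaling — none / sum / geometric mean of the
  six POS spike-ins (3 options),
* background correction from the eight NEG spike-ins — none / mean /
  mean + 2 sd / max (4 options),
* sample-content scaling from reference genes — none / HK sum / HK geo-mean
  / total sum / top-n mean / top-n geo-mean / low-CV geo-mean (7 options),

giving 4 x 3 x 7 = 84 distinct normalizations of the same data.  Stage
order is positive-control scaling, then background, then content, following
the NanoStringNorm convention.  All scaling factors target the arithmetic
mean of the per-sample statistics, so the statistic is equalized across
samples after the stage.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ncruv.core_data import CountMatrix, ProbeAnnotation, ReplicateDesign, log_transform

CODE_COUNT_MODES = ("none", "sum", "geo_mean")
BACKGROUND_MODES = ("none", "mean", "mean_2sd", "max")
CONTENT_MODES = (
    "none",
    "hk_sum",
    "hk_geo_mean",
    "total_sum",
    "top_mean",
    "top_geo_mean",
    "low_cv_geo_mean",
)


@dataclass(frozen=True)
class NCounterOptions:
    code_count: str = "none"
    background: str = "none"
    sample_content: str = "none"
    top_n: int = 75
    low_cv_quantile: float = 0.1

    def __post_init__(self) -> None:
        if self.code_count not in CODE_COUNT_MODES:
            raise ValueError(f"unknown code_count mode {self.code_count!r}")
        if self.background not in BACKGROUND_MODES:
            raise ValueError(f"unknown background mode {self.background!r}")
        if self.sample_content not in CONTENT_MODES:
            raise ValueError(f"unknown sample_content mode {self.sample_content!r}")
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")
        if not 0 < self.low_cv_quantile < 1:
            raise ValueError("low_cv_quantile must be in (0, 1)")

    def label(self) -> str:
        return f"{self.code_count}|{self.background}|{self.sample_content}"


@dataclass
class NormalizedCounts:
    counts: CountMatrix
    options: NCounterOptions
    pos_factors: np.ndarray | None = None
    background_values: np.ndarray | None = None
    content_factors: np.ndarray | None = None


def _geo_mean(x: np.ndarray, axis=None) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        # counts of 0 would zero the geometric mean; floor at 1 (log rule)
        x = np.maximum(x, 1.0)
    return np.exp(np.mean(np.log(x), axis=axis))


def background_correct(
    counts: CountMatrix, annotation: ProbeAnnotation, mode: str = "mean_2sd"
) -> tuple[CountMatrix, np.ndarray]:
    """Subtract a per-sample background estimated from the NEG spike-ins.

    Background b is 0 / mean(NEG) / mean(NEG)+2*sd(NEG) / max(NEG) per mode;
    every non-Negative probe count becomes max(count - b, 0).  NEG probes are
    left untouched.  Returns the corrected matrix and the per-sample b.
    """
    if mode not in BACKGROUND_MODES:
        raise ValueError(f"unknown background mode {mode!r}")
    m = counts.n_samples
    if mode == "none":
        return counts.copy(), np.zeros(m)
    neg = annotation.negative
    n_neg = int(neg.sum())
    if n_neg == 0:
        raise ValueError(f"background mode {mode!r} requires Negative probes")
    if mode == "mean_2sd" and n_neg < 2:
        raise ValueError("background mode 'mean_2sd' requires >= 2 Negative probes")
    neg_counts = counts.values[:, neg]
    if mode == "mean":
        b = neg_counts.mean(axis=1)
    elif mode == "max":
        b = neg_counts.max(axis=1)
    else:  # mean_2sd; unbiased sd
        b = neg_counts.mean(axis=1) + 2.0 * neg_counts.std(axis=1, ddof=1)
    out = counts.values.copy()
    subtract = ~neg
    out[:, subtract] = np.maximum(out[:, subtract] - b[:, None], 0.0)
    return CountMatrix(out, list(counts.sample_ids), list(counts.probe_names)), b


def code_count_normalize(
    counts: CountMatrix, annotation: ProbeAnnotation, mode: str = "geo_mean"
) -> tuple[CountMatrix, np.ndarray]:
    """Scale each sample so its POS spike-in summary matches the study mean.

    The per-sample statistic s_i is the sum or geometric mean of the POS
    probes; the factor mean_j(s_j)/s_i multiplies the whole sample.  Returns
    the scaled matrix and the factors.
    """
    if mode not in CODE_COUNT_MODES:
        raise ValueError(f"unknown code_count mode {mode!r}")
    m = counts.n_samples
    if mode == "none":
        return counts.copy(), np.ones(m)
    pos = annotation.positive
    if not pos.any():
        raise ValueError(f"code_count mode {mode!r} requires Positive probes")
    pos_counts = counts.values[:, pos]
    s = pos_counts.sum(axis=1) if mode == "sum" else _geo_mean(pos_counts, axis=1)
    if np.any(s == 0):
        bad = counts.sample_ids[int(np.argmax(s == 0))]
        raise ValueError(f"sample {bad!r} has zero positive-control statistic")
    factors = s.mean() / s
    out = counts.values * factors[:, None]
    return CountMatrix(out, list(counts.sample_ids), list(counts.probe_names)), factors


def _content_statistic(
    counts: CountMatrix,
    annotation: ProbeAnnotation,
    mode: str,
    top_n: int,
    low_cv_quantile: float,
) -> np.ndarray:
    v = counts.values
    hk = annotation.housekeeping
    endo = annotation.endogenous
    if mode in ("hk_sum", "hk_geo_mean"):
        if not hk.any():
            raise ValueError(f"content mode {mode!r} requires Housekeeping probes")
        sub = v[:, hk]
        return sub.sum(axis=1) if mode == "hk_sum" else _geo_mean(sub, axis=1)
    if not endo.any():
        raise ValueError(f"content mode {mode!r} requires Endogenous probes")
    sub = v[:, endo]
    if mode == "total_sum":
        return sub.sum(axis=1)
    if mode in ("top_mean", "top_geo_mean"):
        top_n = min(top_n, sub.shape[1])
        grand = sub.mean(axis=0)
        top = np.argsort(-grand, kind="stable")[:top_n]
        picked = sub[:, top]
        return picked.mean(axis=1) if mode == "top_mean" else _geo_mean(picked, axis=1)
    if mode == "low_cv_geo_mean":
        mean = sub.mean(axis=0)
        sd = sub.std(axis=0, ddof=1) if sub.shape[0] > 1 else np.zeros(sub.shape[1])
        with np.errstate(divide="ignore", invalid="ignore"):
            cv = np.where(mean > 0, sd / mean, np.inf)
        n_low = max(1, int(np.ceil(low_cv_quantile * sub.shape[1])))
        low = np.argsort(cv, kind="stable")[:n_low]
        return _geo_mean(sub[:, low], axis=1)
    raise ValueError(f"unknown content mode {mode!r}")


def sample_content_normalize(
    counts: CountMatrix,
    annotation: ProbeAnnotation,
    mode: str = "hk_geo_mean",
    top_n: int = 75,
    low_cv_quantile: float = 0.1,
) -> tuple[CountMatrix, np.ndarray]:
    """Scale each sample so its reference-gene content statistic matches the
    study mean (factor = mean_j(t_j)/t_i)."""
    if mode not in CONTENT_MODES:
        raise ValueError(f"unknown sample_content mode {mode!r}")
    m = counts.n_samples
    if mode == "none":
        return counts.copy(), np.ones(m)
    t = _content_statistic(counts, annotation, mode, top_n, low_cv_quantile)
    if np.any(t == 0):
        bad = counts.sample_ids[int(np.argmax(t == 0))]
        raise ValueError(f"sample {bad!r} has zero content statistic for mode {mode!r}")
    factors = t.mean() / t
    out = counts.values * factors[:, None]
    return CountMatrix(out, list(counts.sample_ids), list(counts.probe_names)), factors


def normalize_ncounter(
    counts: CountMatrix, annotation: ProbeAnnotation, options: NCounterOptions
) -> NormalizedCounts:
    """Run one option combination: POS scaling, then background, then content."""
    scaled, pos_factors = code_count_normalize(counts, annotation, options.code_count)
    corrected, background_values = background_correct(scaled, annotation, options.background)
    final, content_factors = sample_content_normalize(
        corrected,
        annotation,
        options.sample_content,
        top_n=options.top_n,
        low_cv_quantile=options.low_cv_quantile,
    )
    return NormalizedCounts(
        counts=final,
        options=options,
        pos_factors=pos_factors,
        background_values=background_values,
        content_factors=content_factors,
    )


def enumerate_grid(top_n: int = 75, low_cv_quantile: float = 0.1) -> list[NCounterOptions]:
    """All 4 x 3 x 7 = 84 option combinations, in deterministic order."""
    return [
        NCounterOptions(cc, bg, sc, top_n=top_n, low_cv_quantile=low_cv_quantile)
        for cc, bg, sc in itertools.product(
            CODE_COUNT_MODES, BACKGROUND_MODES, CONTENT_MODES
        )
    ]


def grid_evaluate(
    counts: CountMatrix,
    annotation: ProbeAnnotation,
    design: ReplicateDesign | None = None,
    gene_pair: tuple[str, str] | None = None,
    options: list[NCounterOptions] | None = None,
) -> pd.DataFrame:
    """Diagnostic summary table, one row per grid option.

    Columns: the option labels, the spread (IQR) of per-sample RLE medians,
    the pooled TRA IQR over technical-replicate pairs (when a design with
    replicates is given), and optionally the across-sample correlation of a
    named gene pair.
    """
    from ncruv.diagnostics import rle, tra

    if options is None:
        options = enumerate_grid()
    rows = []
    for opt in options:
        norm = normalize_ncounter(counts, annotation, opt)
        Y = log_transform(norm.counts, offset=1.0)
        r = rle(Y)
        medians = np.array([s["median"] for s in r.sample_summaries])
        row = {
            "code_count": opt.code_count,
            "background": opt.background,
            "sample_content": opt.sample_content,
            "rle_median_iqr": float(
                np.percentile(medians, 75) - np.percentile(medians, 25)
            ),
        }
        if design is not None and design.n_replicates > 0:
            row["tra_iqr"] = float(tra(Y, design).pooled_iqr)
        if gene_pair is not None:
            g1, g2 = gene_pair
            j1 = Y.probe_names.index(g1)
            j2 = Y.probe_names.index(g2)
            row[f"corr_{g1}_{g2}"] = float(
                np.corrcoef(Y.values[:, j1], Y.values[:, j2])[0, 1]
            )
        rows.append(row)
    return pd.DataFrame(rows)
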