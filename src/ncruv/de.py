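"""Two-group differential expression with empirical-Bayes variance moderation.

Per gene g the log2 fold change is the difference of group means and the
residual variance s_g^2 is pooled over both groups with df = m - 2.
Moderation places a scaled inverse chi-square prior s0^2, d0 on the gene
variances and replaces s_g^2 by the posterior mean

    s~_g^2 = (d0 * s0^2 + df * s_g^2) / (d0 + df),

with (d0, s0^2) estimated by moment-matching on log s_g^2 (Smyth's
empirical-Bayes derivation): for a scaled inverse chi-square prior,
e_g = log s_g^2 - digamma(df/2) + log(df/2) has mean
log s0^2 + digamma(d0/2) - log(d0/2) and variance
trigamma(df/2) + trigamma(d0/2), so d0 comes from inverting the trigamma
function on the excess variance of e_g.  The moderated t statistic
logFC / (s~ * sqrt(1/n1 + 1/n2)) is referred to a t distribution with
df + d0 degrees of freedom.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import special, stats


@dataclass
class DEResult:
    probe_names: list[str]
    logfc: np.ndarray
    t: np.ndarray
    pvalue: np.ndarray
    df_residual: float
    prior_df: float  # d0; may be inf
    prior_var: float  # s0^2
    moderated: bool


@dataclass
class PvalHistogram:
    bin_edges: np.ndarray
    counts: np.ndarray
    fraction_lowest_bin: float
    uniformity_ks: float  # max |ecdf - uniform|


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton, as in the standard eB fit)."""
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match (d0, s0^2) of the scaled inverse chi-square prior.

    Genes with zero residual variance are excluded from the fit (warned).
    Returns d0 = inf when the observed log-variance spread is no larger than
    chi-square sampling noise alone.
    """
    s2 = np.asarray(s2, dtype=float)
    positive = s2 > 0
    if not positive.all():
        warnings.warn(
            f"{int((~positive).sum())} gene(s) with zero residual variance "
            "excluded from the prior fit"
        )
    s2p = s2[positive]
    if s2p.size < 2:
        return math.inf, float(np.mean(s2p)) if s2p.size else 1.0
    z = np.log(s2p)
    e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1))
    excess = e_var - float(special.polygamma(1, df / 2.0))
    if excess <= 0:
        d0 = math.inf
        s0_sq = math.exp(e_mean)
    else:
        d0 = 2.0 * _trigamma_inverse(excess)
        s0_sq = math.exp(e_mean + special.digamma(d0 / 2.0) - math.log(d0 / 2.0))
    return d0, s0_sq


def fit_de(
    Y,
    groups,
    moderation: bool = True,
    prior_df: float | None = None,
) -> DEResult:
    """Gene-wise two-group comparison on log2 expression.

    ``groups`` is a two-level per-sample factor; logFC is mean(level 2) -
    mean(level 1) with levels in order of first appearance.  ``prior_df``
    overrides the estimated d0 (0 recovers the ordinary t test, inf full
    shrinkage to s0^2).
    """
    groups = [str(g) for g in groups]
    if len(groups) != Y.n_samples:
        raise ValueError("groups length differs from sample count")
    levels = list(dict.fromkeys(groups))
    if len(levels) != 2:
        raise ValueError(f"expected exactly 2 group levels, got {levels}")
    g1 = np.array([g == levels[0] for g in groups])
    g2 = ~g1
    n1, n2 = int(g1.sum()), int(g2.sum())
    if min(n1, n2) == 0:
        raise ValueError("both groups must be non-empty")
    df = n1 + n2 - 2
    if df < 1:
        raise ValueError("residual degrees of freedom < 1")
    if not moderation and min(n1, n2) < 2:
        raise ValueError("a group of size 1 needs moderation for a variance estimate")

    V = Y.values
    mean1 = V[g1].mean(axis=0)
    mean2 = V[g2].mean(axis=0)
    logfc = mean2 - mean1
    ss1 = ((V[g1] - mean1) ** 2).sum(axis=0)
    ss2 = ((V[g2] - mean2) ** 2).sum(axis=0)
    s2 = (ss1 + ss2) / df
    se_unit = math.sqrt(1.0 / n1 + 1.0 / n2)

    if moderation:
        if prior_df is None:
            d0, s0_sq = estimate_prior(s2, df)
        else:
            d0 = float(prior_df)
            _, s0_sq = estimate_prior(s2, df)
        if math.isinf(d0):
            post_var = np.full_like(s2, s0_sq)
            total_df = math.inf
        elif d0 == 0:
            post_var = s2
            total_df = float(df)
        else:
            post_var = (d0 * s0_sq + df * s2) / (d0 + df)
            total_df = df + d0
    else:
        d0, s0_sq = 0.0, float("nan")
        post_var = s2
        total_df = float(df)

    with np.errstate(divide="ignore", invalid="ignore"):
        t = logfc / (np.sqrt(post_var) * se_unit)
    t = np.where(np.isfinite(t), t, 0.0)
    if math.isinf(total_df):
        pvalue = 2.0 * stats.norm.sf(np.abs(t))
    else:
        pvalue = 2.0 * stats.t.sf(np.abs(t), total_df)
    return DEResult(
        probe_names=list(Y.probe_names),
        logfc=logfc,
        t=t,
        pvalue=pvalue,
        df_residual=float(df),
        prior_df=d0,
        prior_var=float(s0_sq),
        moderated=moderation,
    )


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional; unadjusted is the default
    reading of a volcano plot)."""
    p = np.asarray(pvalues, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def volcano_data(de: DEResult, ctl=None, scale: str = "log10"):
    """Per-gene (x = logFC, y = -log10 p) pairs, p floored at 1e-300.

    ``scale='10log10'`` multiplies y by 10.  The optional control mask is
    passed through for colouring: ideally negative controls sit near (0, 0)
    and positive controls well away from 0 on both axes.
    """
    p = np.maximum(de.pvalue, 1e-300)
    y = -np.log10(p)
    if scale == "10log10":
        y = 10.0 * y
    elif scale != "log10":
        raise ValueError(f"unknown volcano scale {scale!r}")
    ctl_arr = None if ctl is None else np.asarray(
        ctl.ctl if hasattr(ctl, "ctl") else ctl, dtype=bool
    )
    return de.logfc.copy(), y, ctl_arr


def pval_histogram(de: DEResult, bins: int = 20) -> PvalHistogram:
    """Histogram of unadjusted p-values plus a Kolmogorov-style uniformity gap.

    Under the null the p-values are uniform on (0, 1); unwanted variation
    typically distorts the shape, while true signal adds a spike near zero.
    """
    if bins < 2:
        raise ValueError("bins must be >= 2")
    counts, edges = np.histogram(de.pvalue, bins=bins, range=(0.0, 1.0))
    p_sorted = np.sort(de.pvalue)
    n = p_sorted.size
    ecdf_hi = np.arange(1, n + 1) / n
    ecdf_lo = np.arange(0, n) / n
    ks = float(np.max(np.maximum(np.abs(ecdf_hi - p_sorted), np.abs(p_sorted - ecdf_lo))))
    return PvalHistogram(
        bin_edges=edges,
        counts=counts,
        fraction_lowest_bin=float(counts[0] / max(1, n)),
        uniformity_ks=ks,
    )


def plot_volcano(de: DEResult, path=None, ax=None, ctl=None, scale: str = "log10"):
    from ncruv.diagnostics import _finish, _get_axes

    ax = _get_axes(ax)
    x, y, ctl_arr = volcano_data(de, ctl=ctl, scale=scale)
    if ctl_arr is None:
        ax.scatter(x, y, s=8)
    else:
        ax.scatter(x[~ctl_arr], y[~ctl_arr], s=8, label="other")
        ax.scatter(x[ctl_arr], y[ctl_arr], s=8, color="red", label="controls")
        ax.legend(fontsize=7)
    ax.set_xlabel("log2 fold change")
    ax.set_ylabel("-log10 p" if scale == "log10" else "-10 log10 p")
    return _finish(ax, path)


def plot_pval_histogram(hist: PvalHistogram, path=None, ax=None):
    from ncruv.diagnostics import _finish, _get_axes

    ax = _get_axes(ax)
    widths = np.diff(hist.bin_edges)
    ax.bar(hist.bin_edges[:-1], hist.counts, width=widths, align="edge", edgecolor="k")
    ax.set_xlabel("unadjusted p-value")
    ax.set_ylabel("genes")
    return _finish(ax, path)
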