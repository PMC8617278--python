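"""Detection of biological signal between two cell groups.

Six detector categories are run on log2-CPM expression and summarised as the
*proportion* of genes flagged in each category:

* ``de_lm``   — differential expression via a two-group linear model with
  empirical-Bayes variance moderation (pooled prior variance and degrees of
  freedom fitted by method of moments on the gene-wise variances);
* ``de_rank`` — differential expression via the Wilcoxon rank-sum test, the
  nonparametric second DE criterion;
* ``dv``      — differential variability (Bartlett's test);
* ``dd``      — differential distribution (two-sample Kolmogorov-Smirnov);
* ``dp``      — differential proportion of expressing cells (2x2 chi-square,
  a gene counting as expressed when its log2 expression exceeds 1);
* ``bd``      — bimodally distributed genes by the bimodality index
  BI = |m1 - m2| / (s * sqrt(p (1 - p))).

Selection thresholds: BH-adjusted p < 0.1 for the test-based categories
(combined with |log2 fold change| > 1 for the DE categories) and BI > 0.03
for ``bd``.  Agreement between a simulated and a real profile is scored by
the symmetric mean absolute percentage error, mapped so 1 means identical
proportions and 0 maximal difference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.special
import scipy.stats

from .io import NormalizedMatrix, ValidationError

logger = logging.getLogger(__name__)

SIGNAL_CATEGORIES = ["de_lm", "de_rank", "dv", "dd", "dp", "bd"]

#: shipped defaults — BH-adjusted p, absolute log2 fold change, expression
#: cut-off on the log2 scale, and the bimodality-index cut-off
DEFAULT_ALPHA = 0.1
DEFAULT_LOGFC = 1.0
DEFAULT_EXPR_THRESHOLD = 1.0
DEFAULT_BI_CUTOFF = 0.03


@dataclass
class BioSignalProfile:
    """Per-category proportions of signal genes for one two-group dataset."""

    proportions: dict[str, float]
    n_genes: int
    groups_used: tuple[str, str]


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1) | ~np.isfinite(p)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def _split_groups(
    norm: NormalizedMatrix, groups: tuple[str, str] | None
) -> tuple[np.ndarray, np.ndarray, tuple[str, str]]:
    if norm.groups is None:
        raise ValidationError("matrix has no group labels")
    if groups is None:
        labels, counts = np.unique(norm.groups.astype(str), return_counts=True)
        if labels.size < 2:
            raise ValidationError("need at least two groups")
        # two largest groups; ties broken by label for determinism
        top = labels[np.lexsort((labels, -counts))][:2]
        groups = (str(top[0]), str(top[1]))
    mask1 = norm.groups.astype(str) == groups[0]
    mask2 = norm.groups.astype(str) == groups[1]
    x1 = norm.values[:, mask1]
    x2 = norm.values[:, mask2]
    if x1.shape[1] < 3 or x2.shape[1] < 3:
        raise ValidationError("each group needs at least 3 cells")
    return x1, x2, groups


def _log2_fold_changes(x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    """Difference of group means on the log2-CPM scale."""
    return x2.mean(axis=1) - x1.mean(axis=1)


def _trigamma_inverse(x: np.ndarray) -> np.ndarray:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    x = np.asarray(x, dtype=float)
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = scipy.special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / scipy.special.polygamma(2, y)
        y += dif
        if np.all(np.abs(dif) < 1e-8 * y):
            break
    return y


def _moderate_variances(s2: np.ndarray, df: float) -> tuple[np.ndarray, float]:
    """Empirical-Bayes shrink gene variances toward a common prior.

    Fits a scaled inverse-chi-square prior (s0^2, d0) to the observed
    gene-wise variances by matching the mean and variance of log(s2) against
    their theoretical digamma/trigamma forms, then returns the posterior
    variances (d0*s0^2 + df*s2) / (d0 + df) and the prior df d0.
    """
    ok = s2 > 0
    if ok.sum() < 2:
        return s2, 0.0
    z = np.log(s2[ok])
    e = z - scipy.special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    e_var = z.var(ddof=1) - scipy.special.polygamma(1, df / 2.0)
    if e_var <= 0:
        # variances more concentrated than chi-square sampling alone: the
        # prior is effectively degenerate, shrink fully to the common value
        s0_sq = np.exp(e_mean)
        return np.full_like(s2, s0_sq), np.inf
    d0 = 2.0 * float(_trigamma_inverse(np.array([e_var]))[0])
    s0_sq = np.exp(
        e_mean + scipy.special.digamma(d0 / 2.0) - np.log(d0 / 2.0)
    )
    post = (d0 * s0_sq + df * s2) / (d0 + df)
    return post, d0


def de_genes_lm(
    norm: NormalizedMatrix,
    groups: tuple[str, str] | None = None,
    alpha: float = DEFAULT_ALPHA,
    logfc_threshold: float = DEFAULT_LOGFC,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Moderated-t differential expression between two groups.

    Returns the boolean selection mask and per-gene statistics (logFC, p,
    adjusted p).  Selected genes satisfy |log2FC| > ``logfc_threshold`` AND
    BH-adjusted p < ``alpha``.
    """
    x1, x2, _ = _split_groups(norm, groups)
    n1, n2 = x1.shape[1], x2.shape[1]
    logfc = _log2_fold_changes(x1, x2)
    df = n1 + n2 - 2
    pooled = (
        x1.var(axis=1, ddof=1) * (n1 - 1) + x2.var(axis=1, ddof=1) * (n2 - 1)
    ) / df
    post, d0 = _moderate_variances(pooled, df)
    total_df = df + (d0 if np.isfinite(d0) else 0.0)
    if np.isinf(d0):
        total_df = np.inf
    se = np.sqrt(post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, logfc / np.where(se > 0, se, 1.0), 0.0)
    if np.isinf(total_df):
        p = 2.0 * scipy.stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * scipy.stats.t.sf(np.abs(t), df=total_df)
    adj = bh_adjust(p)
    selected = (np.abs(logfc) > logfc_threshold) & (adj < alpha)
    return selected, {"logfc": logfc, "p": p, "adjusted_p": adj}


def de_genes_rank(
    norm: NormalizedMatrix,
    groups: tuple[str, str] | None = None,
    alpha: float = DEFAULT_ALPHA,
    logfc_threshold: float = DEFAULT_LOGFC,
) -> np.ndarray:
    """Rank-sum (Wilcoxon) differential expression selection mask."""
    x1, x2, _ = _split_groups(norm, groups)
    logfc = _log2_fold_changes(x1, x2)
    res = scipy.stats.mannwhitneyu(
        x1, x2, axis=1, alternative="two-sided", method="asymptotic"
    )
    p = np.asarray(res.pvalue, dtype=float)
    # constant genes give nan p-values; treat as no evidence
    p[~np.isfinite(p)] = 1.0
    adj = bh_adjust(p)
    return (np.abs(logfc) > logfc_threshold) & (adj < alpha)


def dv_genes(
    norm: NormalizedMatrix,
    groups: tuple[str, str] | None = None,
    alpha: float = DEFAULT_ALPHA,
) -> np.ndarray:
    """Bartlett's test of equal variances per gene; BH p < alpha."""
    x1, x2, _ = _split_groups(norm, groups)
    n1, n2 = x1.shape[1], x2.shape[1]
    v1 = x1.var(axis=1, ddof=1)
    v2 = x2.var(axis=1, ddof=1)
    ok = (v1 > 0) | (v2 > 0)
    if (~ok).any():
        logger.info("dv: %d genes with zero variance in both groups skipped",
                    int((~ok).sum()))
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    with np.errstate(divide="ignore", invalid="ignore"):
        num = df * np.log(sp2) - (n1 - 1) * np.log(v1) - (n2 - 1) * np.log(v2)
    c = 1.0 + (1.0 / (n1 - 1) + 1.0 / (n2 - 1) - 1.0 / df) / 3.0
    stat = num / c
    p = np.ones_like(stat)
    valid = ok & np.isfinite(stat)
    p[valid] = scipy.stats.chi2.sf(stat[valid], df=1)
    return bh_adjust(p) < alpha


def _ks_2sample(x1: np.ndarray, x2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised two-sample KS statistic and asymptotic p per gene (rows)."""
    n1, n2 = x1.shape[1], x2.shape[1]
    stats = np.empty(x1.shape[0])
    for g in range(x1.shape[0]):
        a = np.sort(x1[g])
        b = np.sort(x2[g])
        grid = np.concatenate([a, b])
        f1 = np.searchsorted(a, grid, side="right") / n1
        f2 = np.searchsorted(b, grid, side="right") / n2
        stats[g] = np.abs(f1 - f2).max()
    en = np.sqrt(n1 * n2 / (n1 + n2))
    p = scipy.special.kolmogorov(en * stats)
    return stats, np.clip(p, 0.0, 1.0)


def dd_genes(
    norm: NormalizedMatrix,
    groups: tuple[str, str] | None = None,
    alpha: float = DEFAULT_ALPHA,
) -> np.ndarray:
    """Two-sample K-S test per gene; BH p < alpha."""
    x1, x2, _ = _split_groups(norm, groups)
    _, p = _ks_2sample(x1, x2)
    return bh_adjust(p) < alpha


def dp_genes(
    norm: NormalizedMatrix,
    groups: tuple[str, str] | None = None,
    expr_threshold: float = DEFAULT_EXPR_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
) -> np.ndarray:
    """Chi-square test of expressing-cell proportions per gene; BH p < alpha.

    A cell expresses a gene when log2 expression exceeds ``expr_threshold``.
    The 2x2 chi-square uses no continuity correction.  Genes expressed in no
    cell or in every cell of both groups get p = 1 by convention.
    """
    x1, x2, _ = _split_groups(norm, groups)
    n1, n2 = x1.shape[1], x2.shape[1]
    e1 = (x1 > expr_threshold).sum(axis=1)
    e2 = (x2 > expr_threshold).sum(axis=1)
    n = n1 + n2
    tot = e1 + e2
    # chi2 = N (ad - bc)^2 / (row1 row2 col1 col2) for the 2x2 table
    a, b = e1, n1 - e1
    c, d = e2, n2 - e2
    denom = n1 * n2 * tot * (n - tot)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = n * (a * d - b * c) ** 2 / denom
    p = np.ones(x1.shape[0])
    valid = denom > 0
    p[valid] = scipy.stats.chi2.sf(chi2[valid], df=1)
    return bh_adjust(p) < alpha


def bimodality_index(
    x1: np.ndarray, x2: np.ndarray
) -> np.ndarray:
    """BI = |m1 - m2| / (s * sqrt(p (1 - p))) per gene.

    ``s`` is the pooled within-group standard deviation and ``p`` the
    proportion of cells in the larger ("first") group.  Genes with s = 0 are
    returned as NaN (skipped by selection).
    """
    n1, n2 = x1.shape[1], x2.shape[1]
    if n2 > n1:  # "first" cell type = the larger group
        x1, x2 = x2, x1
        n1, n2 = n2, n1
    p = n1 / (n1 + n2)
    m1 = x1.mean(axis=1)
    m2 = x2.mean(axis=1)
    sp = np.sqrt(
        ((n1 - 1) * x1.var(axis=1, ddof=1) + (n2 - 1) * x2.var(axis=1, ddof=1))
        / (n1 + n2 - 2)
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        bi = np.abs(m1 - m2) / (sp * np.sqrt(p * (1.0 - p)))
    bi[sp == 0] = np.nan
    return bi


def bd_genes(
    norm: NormalizedMatrix,
    groups: tuple[str, str] | None = None,
    cutoff: float = DEFAULT_BI_CUTOFF,
) -> np.ndarray:
    """Bimodally distributed genes: bimodality index above ``cutoff``."""
    x1, x2, _ = _split_groups(norm, groups)
    bi = bimodality_index(x1, x2)
    skipped = ~np.isfinite(bi)
    if skipped.any():
        logger.info("bd: %d zero-spread genes skipped", int(skipped.sum()))
    return np.where(skipped, False, bi > cutoff)


def signal_profile(
    norm: NormalizedMatrix,
    groups: tuple[str, str] | None = None,
    alpha: float = DEFAULT_ALPHA,
    logfc_threshold: float = DEFAULT_LOGFC,
    expr_threshold: float = DEFAULT_EXPR_THRESHOLD,
    bi_cutoff: float = DEFAULT_BI_CUTOFF,
) -> BioSignalProfile:
    """All six category proportions for one two-group dataset.

    With more than two groups present, the two largest are used.
    """
    _, _, used = _split_groups(norm, groups)
    n = norm.n_genes
    de_mask, _ = de_genes_lm(norm, used, alpha, logfc_threshold)
    props = {
        "de_lm": float(de_mask.mean()),
        "de_rank": float(de_genes_rank(norm, used, alpha, logfc_threshold).mean()),
        "dv": float(dv_genes(norm, used, alpha).mean()),
        "dd": float(dd_genes(norm, used, alpha).mean()),
        "dp": float(dp_genes(norm, used, expr_threshold, alpha).mean()),
        "bd": float(bd_genes(norm, used, bi_cutoff).mean()),
    }
    return BioSignalProfile(proportions=props, n_genes=n, groups_used=used)


def smape_score(
    sim_proportions: np.ndarray, real_proportions: np.ndarray
) -> float:
    """Similarity of two proportion vectors via SMAPE, mapped to [0, 1].

    SMAPE = mean over pairs of |F - A| / ((A + F) / 2), with pairs where both
    sides are zero contributing 0.  The reported score is 1 - SMAPE / 2 so
    that identical proportions score 1 and maximal difference scores 0.
    """
    f = np.asarray(sim_proportions, dtype=float)
    a = np.asarray(real_proportions, dtype=float)
    if f.shape != a.shape:
        raise ValidationError("proportion vectors must have equal length")
    denom = (a + f) / 2.0
    terms = np.where(denom > 0, np.abs(f - a) / np.where(denom > 0, denom, 1.0), 0.0)
    return float(1.0 - terms.mean() / 2.0)
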