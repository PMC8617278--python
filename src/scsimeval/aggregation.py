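"""Multi-step score aggregation: groups -> datasets -> methods -> ranks.

Per-cell-type scores are combined into one dataset score by a weighted sum
with the cell-type proportions as weights; dataset scores are summarised per
method by the median (failed datasets excluded); methods are ranked within
each criterion (rank 1 = best, average ranks on ties) and ordered overall by
mean rank, then binned into quartile tiers.  A simple least-squares trend of
score against cell number (in thousands) quantifies how fidelity changes
with dataset size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class RankSummary:
    """Ranks per (method, criterion), mean ranks, tiers and failure counts."""

    ranks: pd.DataFrame  # methods x criteria
    mean_rank: pd.Series  # per method, ascending = better
    tiers: pd.Series  # per method, 1 = best tier
    failure_counts: pd.Series

    def ordered_methods(self) -> list[str]:
        return list(self.mean_rank.sort_values(kind="stable").index)


@dataclass
class TrendFit:
    """OLS fit of score on cells/1000: score ~ beta0 + beta1 * x."""

    intercept: float
    slope: float


def aggregate_cell_groups(scores, proportions) -> float:
    """Weighted sum of per-group scores with cell-type-proportion weights."""
    x = np.asarray(scores, dtype=float)
    w = np.asarray(proportions, dtype=float)
    if x.shape != w.shape:
        raise ValidationError("scores and weights must align")
    if (w < 0).any():
        raise ValidationError("weights must be non-negative")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValidationError(f"weights sum to {w.sum()}, expected 1")
    return float(np.sum(x * w))


def summarise_datasets(per_dataset_scores) -> tuple[float | None, int]:
    """Median of the available (non-NaN) per-dataset scores.

    Returns (median, number of datasets that contributed); (None, 0) when no
    dataset produced a score.
    """
    x = np.asarray(list(per_dataset_scores), dtype=float)
    ok = np.isfinite(x)
    if not ok.any():
        logger.warning("no available dataset scores; summary missing")
        return None, 0
    return float(np.median(x[ok])), int(ok.sum())


def rank_methods(summaries: pd.DataFrame, n_tiers: int = 4) -> RankSummary:
    """Rank methods within each criterion and summarise by mean rank.

    ``summaries`` is a methods x criteria table of scores (higher = better;
    NaN = missing).  Criteria with fewer than 2 scored methods are dropped
    from the mean-rank computation with a log message.
    """
    if summaries.shape[0] < 2:
        raise ValidationError("ranking needs at least 2 methods")
    usable = []
    for crit in summaries.columns:
        if summaries[crit].notna().sum() >= 2:
            usable.append(crit)
        else:
            logger.info("criterion %r has < 2 methods; dropped", crit)
    ranks = summaries[usable].rank(axis=0, ascending=False, method="average")
    mean_rank = ranks.mean(axis=1, skipna=True)
    order = mean_rank.sort_values(kind="stable")
    # quartile (n_tiers) bins of mean rank; tier 1 = best
    finite = order.dropna()
    edges = np.quantile(finite, np.linspace(0, 1, n_tiers + 1))
    tiers = pd.Series(index=summaries.index, dtype=float)
    for method in summaries.index:
        mr = mean_rank[method]
        if np.isnan(mr):
            tiers[method] = np.nan
        else:
            tiers[method] = int(np.searchsorted(edges[1:-1], mr, side="left")) + 1
    failures = summaries.isna().sum(axis=1)
    return RankSummary(
        ranks=ranks,
        mean_rank=mean_rank,
        tiers=tiers.astype("Int64"),
        failure_counts=failures,
    )


def fit_cell_number_trend(scores, n_cells) -> TrendFit:
    """Least-squares line of score on the number of cells in thousands."""
    y = np.asarray(scores, dtype=float)
    x = np.asarray(n_cells, dtype=float) / 1000.0
    if y.size < 3:
        raise ValidationError("trend fit needs at least 3 points")
    if (np.asarray(n_cells) <= 0).any():
        raise ValidationError("cell counts must be positive")
    if np.ptp(x) == 0:
        raise ValidationError("constant predictor; slope undefined")
    xm, ym = x.mean(), y.mean()
    slope = float(np.sum((x - xm) * (y - ym)) / np.sum((x - xm) ** 2))
    return TrendFit(intercept=float(ym - slope * xm), slope=slope)


def rank_grid_report(summary: RankSummary) -> str:
    """Plain-text criterion x method rank grid, best method first."""
    methods = summary.ordered_methods()
    lines = ["method      " + "  ".join(f"{c:>18}" for c in summary.ranks.columns)
             + f"  {'mean_rank':>10}  {'tier':>4}"]
    for m in methods:
        row = "  ".join(
            f"{summary.ranks.loc[m, c]:>18.1f}"
            if np.isfinite(summary.ranks.loc[m, c])
            else f"{'-':>18}"
            for c in summary.ranks.columns
        )
        tier = summary.tiers[m]
        lines.append(
            f"{m:<12}{row}  {summary.mean_rank[m]:>10.2f}  "
            f"{'-' if pd.isna(tier) else int(tier):>4}"
        )
    return "\n".join(lines)
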