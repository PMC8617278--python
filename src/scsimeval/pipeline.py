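"""End-to-end evaluation: property comparison, biosignal scoring, ranking.

``evaluate_pair`` compares one simulated matrix against its real reference:
properties are extracted per shared cell group (or on the whole matrix when
labels are absent) and compared with the KDE statistic and any requested
alternative measures; with two or more groups present, biological-signal
profiles are compared by SMAPE.  The resulting long-form score table feeds
``add_transformed`` (collection-wide [0, 1] mapping) and
``aggregate_scores`` (group weighting, dataset medians, method ranking).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import measures as alt
from .aggregation import RankSummary, aggregate_cell_groups, rank_methods
from .biosignal import SIGNAL_CATEGORIES, signal_profile, smape_score
from .config import RunConfig
from .io import CountMatrix, ValidationError, make_score_table, normalize_log2cpm
from .kde import compare_property_sets, transform_scores
from .properties import PROPERTY_NAMES, extract_property_set

logger = logging.getLogger(__name__)


def _group_partitions(m: CountMatrix) -> dict[str, CountMatrix]:
    if m.groups is None:
        return {"all": m}
    out = {}
    for g in pd.unique(m.groups):
        out[str(g)] = m.subset_cells(np.nonzero(m.groups == g)[0])
    return out


def evaluate_pair(
    real: CountMatrix,
    sim: CountMatrix,
    method: str = "method",
    dataset: str = "dataset",
    config: RunConfig | None = None,
    sim_raw_counts: bool = True,
) -> pd.DataFrame:
    """Score one simulated matrix against its real reference.

    Returns a long-form score table with raw values; the ``transformed``
    column is populated later over the relevant score collection (a single
    run, or all methods and datasets in an aggregation).
    """
    cfg = config or RunConfig()
    cfg.validate()

    real_parts = _group_partitions(real)
    sim_parts = _group_partitions(sim)
    shared = [g for g in real_parts if g in sim_parts]
    if not shared:
        logger.warning("no shared cell groups; comparing whole matrices")
        real_parts, sim_parts, shared = {"all": real}, {"all": sim}, ["all"]
    weights = {
        g: real_parts[g].n_cells / sum(real_parts[h].n_cells for h in shared)
        for g in shared
    }

    rows: list[dict] = []
    for g in shared:
        rp = extract_property_set(
            real_parts[g],
            max_features=cfg.correlation_subsample,
            seed=cfg.seed,
        )
        sp = extract_property_set(
            sim_parts[g],
            raw_counts=sim_raw_counts,
            max_features=cfg.correlation_subsample,
            seed=cfg.seed,
        )
        kde_results = compare_property_sets(
            rp, sp, subsample=cfg.kde_subsample, seed=cfg.seed
        )
        for prop in PROPERTY_NAMES:
            res = kde_results[prop]
            rows.append(
                {
                    "method": method,
                    "dataset": dataset,
                    "cell_group": g,
                    "criterion": prop,
                    "measure": "kde",
                    "raw": np.nan if res is None else res.raw_statistic,
                    "weight": weights[g],
                }
            )
        for name in cfg.measures:
            if name == "kde":
                continue
            for prop in PROPERTY_NAMES:
                raw = _alt_measure_raw(name, rp, sp, prop, cfg)
                rows.append(
                    {
                        "method": method,
                        "dataset": dataset,
                        "cell_group": g,
                        "criterion": prop,
                        "measure": name,
                        "raw": raw,
                        "weight": weights[g],
                    }
                )

    rows.extend(
        _biosignal_rows(real, sim, method, dataset, cfg)
    )
    return make_score_table(rows)


def _alt_measure_raw(name, real_set, sim_set, prop, cfg) -> float:
    if prop not in real_set.entries or prop not in sim_set.entries:
        return np.nan
    a, b = real_set.entries[prop], sim_set.entries[prop]
    univariate = a.ndim == 1
    if name in ("ks", "ecdf_area", "runs") and not univariate:
        return np.nan
    if len(a) < 2 or len(b) < 2:
        return np.nan
    # cap point counts before O(n^2) distance work; same-seeded generator per
    # side so identical inputs keep identical subsets
    cap = cfg.kde_subsample
    if len(a) > cap:
        rng = np.random.default_rng(cfg.seed)
        a = a[np.sort(rng.choice(len(a), cap, replace=False))]
    if len(b) > cap:
        rng = np.random.default_rng(cfg.seed)
        b = b[np.sort(rng.choice(len(b), cap, replace=False))]
    try:
        if name == "silhouette":
            return alt.average_silhouette(a, b).raw
        if name == "local_silhouette":
            return alt.average_local_silhouette(a, b, cfg.knn_k).raw
        if name == "nn_rejection":
            return alt.nn_rejection_fraction(a, b, cfg.knn_k, cfg.nn_alpha).raw
        if name == "ks":
            return alt.ks_measure(a, b).raw
        if name == "ecdf_area":
            return alt.ecdf_area(a, b).raw
        if name == "runs":
            return alt.runs_statistic(a, b).raw
    except ValidationError as exc:
        logger.info("measure %s on %s skipped: %s", name, prop, exc)
        return np.nan
    raise ValidationError(f"unknown measure {name!r}")


def _biosignal_rows(real, sim, method, dataset, cfg) -> list[dict]:
    def has_two_groups(m):
        return m.groups is not None and len(set(m.groups)) >= 2

    if not (has_two_groups(real) and has_two_groups(sim)):
        return []
    kwargs = dict(
        alpha=cfg.bh_alpha,
        logfc_threshold=cfg.logfc_threshold,
        expr_threshold=cfg.expr_threshold,
        bi_cutoff=cfg.bi_cutoff,
    )
    real_profile = signal_profile(normalize_log2cpm(real), **kwargs)
    sim_profile = signal_profile(normalize_log2cpm(sim), **kwargs)
    rows = []
    for cat in SIGNAL_CATEGORIES:
        score = smape_score(
            np.array([sim_profile.proportions[cat]]),
            np.array([real_profile.proportions[cat]]),
        )
        rows.append(
            {
                "method": method,
                "dataset": dataset,
                "cell_group": "all",
                "criterion": f"bio_{cat}",
                "measure": "smape",
                "raw": score,
                "transformed": score,
                "weight": 1.0,
            }
        )
    return rows


def add_transformed(table: pd.DataFrame) -> pd.DataFrame:
    """Populate the transformed column over the table's own score collection.

    KDE raw statistics are min-max transformed across all KDE rows of the
    table; alternative measures follow their per-measure rules; SMAPE rows
    are already on the [0, 1] scale.
    """
    table = table.copy()
    for measure, idx in table.groupby("measure").groups.items():
        raws = table.loc[idx, "raw"].to_numpy(dtype=float)
        if measure == "smape":
            table.loc[idx, "transformed"] = raws
        elif measure == "kde":
            table.loc[idx, "transformed"] = _safe_transform(raws)
        else:
            finite = np.isfinite(raws)
            out = np.full(raws.shape, np.nan)
            if finite.any():
                out[finite] = alt.transform_measure_scores(
                    str(measure), raws[finite]
                )
            table.loc[idx, "transformed"] = out
    return table


def _safe_transform(raws: np.ndarray) -> np.ndarray:
    finite = np.isfinite(raws)
    out = np.full(raws.shape, np.nan)
    if finite.sum() >= 2:
        out[finite] = transform_scores(raws[finite])
    elif finite.any():
        out[finite] = 1.0
    return out


def aggregate_scores(
    table: pd.DataFrame, measure: str = "kde"
) -> tuple[pd.DataFrame, RankSummary | None]:
    """Group-weighted dataset scores, dataset medians, and method ranks.

    Returns the methods x criteria summary table (medians of the
    cell-type-weighted transformed scores over datasets) and, when two or
    more methods are present, their :class:`RankSummary`.
    """
    # transformed values are collection-relative: recompute them over this
    # table so scores from separate runs are on one comparable scale
    table = add_transformed(table)
    use = table[(table["measure"] == measure) | (table["measure"] == "smape")]
    records = []
    for (method, dataset, criterion), grp in use.groupby(
        ["method", "dataset", "criterion"]
    ):
        vals = grp["transformed"].to_numpy(dtype=float)
        w = grp["weight"].to_numpy(dtype=float)
        ok = np.isfinite(vals)
        if not ok.any():
            score = np.nan
        elif ok.all():
            score = aggregate_cell_groups(vals, w / w.sum())
        else:
            # groups where the property was unavailable are excluded and the
            # remaining weights renormalised
            score = aggregate_cell_groups(vals[ok], w[ok] / w[ok].sum())
        records.append(
            {"method": method, "dataset": dataset, "criterion": criterion,
             "score": score}
        )
    per_dataset = pd.DataFrame(records)
    summaries = (
        per_dataset.groupby(["method", "criterion"])["score"]
        .median()
        .unstack("criterion")
    )
    rank_summary = None
    if summaries.shape[0] >= 2:
        rank_summary = rank_methods(summaries)
    return summaries, rank_summary
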