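"""Six alternative distribution-similarity measures.

These companions validate the kernel-density statistic: average (and local)
silhouette width, nearest-neighbour rejection fraction, Kolmogorov-Smirnov
statistic, scaled area between empirical CDFs, and the Wald-Wolfowitz runs
statistic.  Each produces a raw value plus a rule mapping it to [0, 1] with
higher meaning more similar.

The silhouette here is *not* the classical clustering silhouette: for a
simulated point i, a(i) is its mean distance to the real points and b(i) its
mean distance to the other simulated points, s(i) = (b - a) / max(a, b).  A
mean s near 0 therefore indicates that simulated points are as close to the
real data as to their own side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats
from sklearn.metrics import pairwise_distances
from sklearn.neighbors import NearestNeighbors

from .io import ValidationError

MEASURE_NAMES = [
    "silhouette",
    "local_silhouette",
    "nn_rejection",
    "ks",
    "ecdf_area",
    "runs",
]

#: measures whose transformed value is Eq-style min-max over a collection
COLLECTION_TRANSFORMED = {"silhouette", "local_silhouette", "ks", "runs"}


@dataclass
class MeasureScore:
    measure: str
    raw: float
    transformed: float | None = None


def _as_2d(points: np.ndarray) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    return pts


def average_silhouette(
    real_points: np.ndarray, sim_points: np.ndarray
) -> MeasureScore:
    """Mean silhouette width over the simulated points (Euclidean)."""
    real = _as_2d(real_points)
    sim = _as_2d(sim_points)
    if real.shape[0] < 2 or sim.shape[0] < 2:
        raise ValidationError("silhouette needs >= 2 points per side")
    d_cross = pairwise_distances(sim, real)
    d_within = pairwise_distances(sim, sim)
    a = d_cross.mean(axis=1)
    b = (d_within.sum(axis=1) - np.diag(d_within)) / (sim.shape[0] - 1)
    denom = np.maximum(a, b)
    s = np.where(denom > 0, (b - a) / np.where(denom > 0, denom, 1.0), 0.0)
    return MeasureScore("silhouette", float(s.mean()))


def average_local_silhouette(
    real_points: np.ndarray, sim_points: np.ndarray, k: int = 5
) -> MeasureScore:
    """Silhouette over the k nearest neighbours within each side."""
    if k <= 0:
        raise ValidationError("k must be positive")
    real = _as_2d(real_points)
    sim = _as_2d(sim_points)
    if real.shape[0] <= k or sim.shape[0] <= k:
        raise ValidationError("each side needs more than k points")
    d_cross = np.sort(pairwise_distances(sim, real), axis=1)
    d_within = pairwise_distances(sim, sim)
    np.fill_diagonal(d_within, np.inf)
    d_within = np.sort(d_within, axis=1)
    a = d_cross[:, :k].mean(axis=1)
    b = d_within[:, :k].mean(axis=1)
    denom = np.maximum(a, b)
    s = np.where(denom > 0, (b - a) / np.where(denom > 0, denom, 1.0), 0.0)
    return MeasureScore("local_silhouette", float(s.mean()))


def nn_rejection_fraction(
    real_points: np.ndarray,
    sim_points: np.ndarray,
    k: int = 5,
    alpha: float = 0.05,
) -> MeasureScore:
    """Fraction of points whose k-NN origin composition rejects the pooled mix.

    For each pooled point, its k nearest neighbours (Euclidean, excluding
    itself) are classified by origin and a chi-square goodness-of-fit test
    compares the composition against the pooled real/simulated proportions.
    Raw is the rejected fraction at level ``alpha``; transformed is 1 - raw.
    """
    real = _as_2d(real_points)
    sim = _as_2d(sim_points)
    pooled = np.vstack([real, sim])
    n = pooled.shape[0]
    if k >= n:
        raise ValidationError("k must be smaller than the pooled size")
    if alpha <= 0:
        return MeasureScore("nn_rejection", 0.0, 1.0)
    labels = np.concatenate([np.zeros(real.shape[0]), np.ones(sim.shape[0])])
    nn = NearestNeighbors(n_neighbors=k + 1).fit(pooled)
    _, idx = nn.kneighbors(pooled)
    neighbour_labels = labels[idx[:, 1:]]  # drop self
    obs_sim = neighbour_labels.sum(axis=1)
    p_sim = sim.shape[0] / n
    exp_sim = k * p_sim
    exp_real = k * (1.0 - p_sim)
    chi2 = (obs_sim - exp_sim) ** 2 / exp_sim + (
        (k - obs_sim) - exp_real
    ) ** 2 / exp_real
    pvals = scipy.stats.chi2.sf(chi2, df=1)
    raw = float((pvals < alpha).mean())
    return MeasureScore("nn_rejection", raw, 1.0 - raw)


def _ecdf_values(sample: np.ndarray, grid: np.ndarray) -> np.ndarray:
    sample = np.sort(np.asarray(sample, dtype=float))
    return np.searchsorted(sample, grid, side="right") / sample.size


def ks_measure(sample1: np.ndarray, sample2: np.ndarray) -> MeasureScore:
    """Two-sample Kolmogorov-Smirnov sup distance between eCDFs."""
    x = np.asarray(sample1, dtype=float)
    y = np.asarray(sample2, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("K-S needs non-empty samples")
    grid = np.concatenate([x, y])
    d = np.abs(_ecdf_values(x, grid) - _ecdf_values(y, grid)).max()
    return MeasureScore("ks", float(d))


def ecdf_area(sample1: np.ndarray, sample2: np.ndarray) -> MeasureScore:
    """Trapezoidal area between eCDFs over a range-rescaled pooled support."""
    x = np.asarray(sample1, dtype=float)
    y = np.asarray(sample2, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("eCDF area needs non-empty samples")
    grid = np.unique(np.concatenate([x, y]))
    span = grid[-1] - grid[0]
    if span == 0:
        return MeasureScore("ecdf_area", 0.0, 1.0)
    scaled = (grid - grid[0]) / span
    diff = np.abs(_ecdf_values(x, grid) - _ecdf_values(y, grid))
    # eCDFs are right-continuous step functions: |F1 - F2| is constant on
    # [t_i, t_{i+1}), so the trapezoidal rule on the step-refined grid
    # reduces to this exact rectangle sum
    raw = float(np.sum(diff[:-1] * np.diff(scaled)))
    return MeasureScore("ecdf_area", raw, 1.0 - raw)


def runs_statistic(sample1: np.ndarray, sample2: np.ndarray) -> MeasureScore:
    """Wald-Wolfowitz runs z-statistic on the pooled sorted sequence.

    The pooled values are sorted ascending (cross-side ties resolved with the
    first sample's values placed first — deterministic) and runs of
    same-origin labels counted.  z = (R - mu_R) / sigma_R; strongly negative
    z (few runs) flags separated, dissimilar samples.
    """
    x = np.asarray(sample1, dtype=float)
    y = np.asarray(sample2, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise ValidationError("runs test needs >= 2 points per side")
    values = np.concatenate([x, y])
    labels = np.concatenate([np.zeros(n1, dtype=int), np.ones(n2, dtype=int)])
    # stable sort on values: equal keys keep original order (sample1 first)
    order = np.argsort(values, kind="stable")
    seq = labels[order]
    runs = 1 + int((seq[1:] != seq[:-1]).sum())
    n = n1 + n2
    mu = 2.0 * n1 * n2 / n + 1.0
    var = 2.0 * n1 * n2 * (2.0 * n1 * n2 - n) / (n**2 * (n - 1.0))
    z = (runs - mu) / np.sqrt(var)
    return MeasureScore("runs", float(z))


def transform_measure_scores(
    measure: str, raws: np.ndarray
) -> np.ndarray:
    """Apply each measure's documented [0, 1] mapping over a collection.

    nn_rejection and ecdf_area are 1 - raw pointwise; silhouette and runs
    min-max scale |raw| over the collection then reverse; K-S does the same
    after a log transform (zero distances floored at machine epsilon).
    """
    from .kde import transform_scores

    raws = np.asarray(raws, dtype=float)
    if measure in ("nn_rejection", "ecdf_area"):
        return 1.0 - raws
    if measure == "ks":
        # min-max on the signed log distance: log D is monotone in D, so the
        # smallest distance maps to 1 and the largest to 0 (zero distances
        # floored at machine epsilon before the log)
        x = np.log(np.maximum(raws, np.finfo(float).eps))
        lo, hi = x.min(), x.max()
        if hi == lo:
            return np.ones_like(x)
        return 1.0 - (x - lo) / (hi - lo)
    if measure in ("silhouette", "local_silhouette", "runs"):
        return transform_scores(raws)
    raise ValidationError(f"unknown measure {measure!r}")


def all_measures(
    real_points: np.ndarray,
    sim_points: np.ndarray,
    k: int = 5,
    alpha: float = 0.05,
) -> dict[str, MeasureScore]:
    """Every applicable measure for one property pair.

    The four univariate-only measures (ks, ecdf_area, runs) are skipped for
    bivariate point sets.
    """
    out: dict[str, MeasureScore] = {}
    out["silhouette"] = average_silhouette(real_points, sim_points)
    out["local_silhouette"] = average_local_silhouette(real_points, sim_points, k)
    out["nn_rejection"] = nn_rejection_fraction(real_points, sim_points, k, alpha)
    real = np.asarray(real_points)
    if real.ndim == 1:
        out["ks"] = ks_measure(real_points, sim_points)
        out["ecdf_area"] = ecdf_area(real_points, sim_points)
        out["runs"] = runs_statistic(real_points, sim_points)
    return out
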