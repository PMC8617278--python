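"""Extraction of the 13 data-property distributions from a count matrix.

A simulator is judged on how well it reproduces the *distributions* of summary
properties of a real dataset — never on matching individual genes or cells.
The property set covers cell-wise summaries (library size, TMM normalisation
factor, effective library size, fraction of zeros per cell), gene-wise
summaries (mean, variance and z-scaled variance of log2-CPM expression,
fraction of zeros per gene), pairwise Spearman correlations among cells and
among genes, and three bivariate relationships (mean-variance, mean-fraction
zero, library size-fraction zero).

TMM (trimmed mean of M-values) is re-implemented from scratch: a reference
cell is chosen by upper-quartile closeness, per-cell log-ratio (M) and
log-abundance (A) values over genes positive in both cell and reference are
doubly trimmed (30% on M, 5% on A), and the precision-weighted mean M is
exponentiated; factors are rescaled so their geometric mean is 1.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats

from .io import CountMatrix, NormalizedMatrix, ValidationError, normalize_log2cpm

logger = logging.getLogger(__name__)

UNIVARIATE_PROPERTIES = [
    "library_size",
    "tmm",
    "effective_library_size",
    "scaled_variance",
    "mean_expression",
    "variance_expression",
    "fraction_zero_cell",
    "fraction_zero_gene",
    "cell_correlation",
    "gene_correlation",
]
BIVARIATE_PROPERTIES = [
    "mean_vs_variance",
    "mean_vs_fraczero",
    "libsize_vs_fraczero",
]
PROPERTY_NAMES = UNIVARIATE_PROPERTIES + BIVARIATE_PROPERTIES

# Properties computable only from raw (unnormalised) counts.
RAW_ONLY_PROPERTIES = frozenset({"tmm", "effective_library_size"})

AXIS_LABELS = {
    "mean_vs_variance": ("mean_log2cpm", "variance_log2cpm"),
    "mean_vs_fraczero": ("mean_log2cpm", "fraction_zero"),
    "libsize_vs_fraczero": ("library_size", "fraction_zero"),
}


@dataclass
class PropertySet:
    """The named property distributions extracted from one matrix.

    ``entries`` maps property name to a 1-D value vector or an (n, 2) point
    set; ``unavailable`` lists properties that could not be computed (e.g.
    TMM on a matrix that is not raw counts).
    """

    entries: dict[str, np.ndarray] = field(default_factory=dict)
    unavailable: list[str] = field(default_factory=list)

    def available(self) -> list[str]:
        return [p for p in PROPERTY_NAMES if p in self.entries]

    def __getitem__(self, name: str) -> np.ndarray:
        return self.entries[name]

    def is_bivariate(self, name: str) -> bool:
        return name in BIVARIATE_PROPERTIES

    def to_dir(self, directory: str | Path) -> None:
        """Serialise to one TSV per property plus a JSON manifest."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {"properties": {}, "unavailable": list(self.unavailable)}
        for name, values in self.entries.items():
            cols = AXIS_LABELS.get(name, (name,))
            arr = np.atleast_2d(values.T).T if values.ndim == 1 else values
            df = pd.DataFrame(arr, columns=list(cols))
            df.to_csv(directory / f"{name}.tsv", sep="\t", index=False)
            manifest["properties"][name] = {
                "file": f"{name}.tsv",
                "n": int(len(values)),
                "axes": list(cols),
            }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))

    @classmethod
    def from_dir(cls, directory: str | Path) -> "PropertySet":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        entries = {}
        for name, meta in manifest["properties"].items():
            df = pd.read_csv(directory / meta["file"], sep="\t")
            arr = df.to_numpy(dtype=float)
            entries[name] = arr[:, 0] if arr.shape[1] == 1 else arr
        return cls(entries=entries, unavailable=list(manifest["unavailable"]))


def library_sizes(m: CountMatrix) -> np.ndarray:
    """Total counts per cell."""
    return m.library_sizes()


def tmm_factors(
    m: CountMatrix, trim_m: float = 0.30, trim_a: float = 0.05
) -> np.ndarray:
    """Weighted trimmed-mean-of-M-values normalisation factor per cell.

    Follows the published TMM algorithm: the reference cell is the one whose
    upper-quartile count proportion is closest to the mean upper-quartile;
    M (log2 ratio of proportions) and A (mean log2 abundance) values over
    genes positive in both samples are doubly trimmed — the middle
    ``1 - 2*trim_m`` of M and ``1 - 2*trim_a`` of A survive — and averaged
    with inverse-variance (binomial delta-method) weights.  Factors are
    divided by their geometric mean.
    """
    counts = m.counts.astype(float)
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        raise ValidationError("every cell must have a positive library size")

    # Reference selection: upper quartile of positive scale, on count/libsize.
    uq = np.quantile(counts / lib[None, :], 0.75, axis=0)
    if np.allclose(uq, 0):
        # Extremely sparse: fall back to upper quartile over positive counts
        uq = np.array(
            [np.quantile(c[c > 0] / l, 0.75) if (c > 0).any() else 0.0
             for c, l in zip(counts.T, lib)]
        )
    ref = int(np.argmin(np.abs(uq - uq.mean())))

    factors = np.empty(m.n_cells)
    for k in range(m.n_cells):
        factors[k] = _tmm_pair(counts[:, k], counts[:, ref], lib[k], lib[ref],
                               trim_m, trim_a)
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


def _tmm_pair(obs, ref, n_obs, n_ref, trim_m, trim_a) -> float:
    """TMM factor of one observation column against the reference column."""
    shared = (obs > 0) & (ref > 0)
    if not shared.any():
        raise ValidationError("cell shares no positive genes with the reference")
    p_obs = obs[shared] / n_obs
    p_ref = ref[shared] / n_ref
    m_vals = np.log2(p_obs) - np.log2(p_ref)
    a_vals = (np.log2(p_obs) + np.log2(p_ref)) / 2.0
    # Delta-method variance of M under binomial sampling.
    w = (n_obs - obs[shared]) / (n_obs * obs[shared]) + (
        n_ref - ref[shared]
    ) / (n_ref * ref[shared])

    if np.max(np.abs(m_vals)) < 1e-6:
        return 1.0

    n = m_vals.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rank_m = scipy.stats.rankdata(m_vals)
    rank_a = scipy.stats.rankdata(a_vals)
    keep = (
        (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    )
    if not keep.any():
        return 1.0
    f = np.sum(m_vals[keep] / w[keep]) / np.sum(1.0 / w[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0 ** f)


def effective_library_sizes(m: CountMatrix, **tmm_kwargs) -> np.ndarray:
    """Library size multiplied by the TMM factor, per cell."""
    return library_sizes(m) * tmm_factors(m, **tmm_kwargs)


def gene_moments(
    norm: NormalizedMatrix,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-gene mean, variance and z-scaled variance of log2-CPM.

    The scaled-variance vector excludes zero-variance genes before
    standardisation; if the remaining variances have no spread the z-scores
    are defined as all zero.
    """
    if norm.n_cells < 2:
        raise ValidationError("variance requires at least 2 cells")
    mean = norm.values.mean(axis=1)
    var = norm.values.var(axis=1, ddof=1)
    nonzero = var > 0
    v = var[nonzero]
    if v.size == 0:
        scaled = np.zeros(0)
    else:
        spread = v.std(ddof=0)
        if spread == 0:
            logger.info("all gene variances equal; scaled variance set to 0")
            scaled = np.zeros(v.size)
        else:
            scaled = (v - v.mean()) / spread
    return mean, var, scaled


def zero_fractions(m: CountMatrix) -> tuple[np.ndarray, np.ndarray]:
    """(fraction of zeros per cell, fraction of zeros per gene)."""
    zero = m.counts == 0
    return zero.mean(axis=0), zero.mean(axis=1)


def _spearman_pairs(values: np.ndarray) -> np.ndarray:
    """All pairwise Spearman correlations between columns of ``values``.

    Average ranks for ties; constant columns yield undefined correlations,
    which are dropped with a logged count.
    """
    ranks = scipy.stats.rankdata(values, axis=0)
    sd = ranks.std(axis=0)
    constant = sd == 0
    if constant.any():
        logger.info("dropping %d constant features from correlation", constant.sum())
    ranks = ranks[:, ~constant]
    if ranks.shape[1] < 2:
        return np.zeros(0)
    corr = np.corrcoef(ranks, rowvar=False)
    iu = np.triu_indices(corr.shape[0], k=1)
    vals = corr[iu]
    return vals[np.isfinite(vals)]


def correlation_distributions(
    norm: NormalizedMatrix, max_features: int = 500, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise Spearman correlations among (subsampled) cells and genes."""
    if norm.n_cells < 3 or norm.n_genes < 3:
        raise ValidationError("need at least 3 cells and 3 genes")
    rng = np.random.default_rng(seed)

    def subsample(n: int) -> np.ndarray:
        if n <= max_features:
            return np.arange(n)
        return np.sort(rng.choice(n, size=max_features, replace=False))

    cells = subsample(norm.n_cells)
    genes = subsample(norm.n_genes)
    cell_corr = _spearman_pairs(norm.values[:, cells])
    gene_corr = _spearman_pairs(norm.values[genes, :].T)
    return cell_corr, gene_corr


def bivariate_properties(
    m: CountMatrix, norm: NormalizedMatrix
) -> dict[str, np.ndarray]:
    """The three bivariate point sets (each an (n, 2) array)."""
    mean = norm.values.mean(axis=1)
    var = norm.values.var(axis=1, ddof=1)
    frac_cell, frac_gene = zero_fractions(m)
    lib = library_sizes(m).astype(float)
    return {
        "mean_vs_variance": np.column_stack([mean, var]),
        "mean_vs_fraczero": np.column_stack([mean, frac_gene]),
        "libsize_vs_fraczero": np.column_stack([lib, frac_cell]),
    }


def extract_property_set(
    m: CountMatrix,
    raw_counts: bool = True,
    max_features: int = 500,
    seed: int = 0,
) -> PropertySet:
    """Extract all 13 properties (11 when the input is not raw counts).

    ``raw_counts=False`` marks TMM and effective library size unavailable,
    mirroring simulators that emit normalised counts.
    """
    norm = normalize_log2cpm(m)
    lib = library_sizes(m).astype(float)
    mean, var, scaled = gene_moments(norm)
    frac_cell, frac_gene = zero_fractions(m)
    cell_corr, gene_corr = correlation_distributions(norm, max_features, seed)

    entries: dict[str, np.ndarray] = {
        "library_size": lib,
        "scaled_variance": scaled,
        "mean_expression": mean,
        "variance_expression": var,
        "fraction_zero_cell": frac_cell,
        "fraction_zero_gene": frac_gene,
        "cell_correlation": cell_corr,
        "gene_correlation": gene_corr,
    }
    entries.update(bivariate_properties(m, norm))
    unavailable: list[str] = []
    if raw_counts:
        factors = tmm_factors(m)
        entries["tmm"] = factors
        entries["effective_library_size"] = lib * factors
    else:
        unavailable = sorted(RAW_ONLY_PROPERTIES)
    return PropertySet(entries=entries, unavailable=unavailable)
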