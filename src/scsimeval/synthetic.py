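"""Synthetic reference/simulated matrix pairs with known ground truth.

The generator emulates what a single-cell simulator produces so the whole
evaluation framework can be exercised without external data.  Counts follow
a hierarchical gamma-Poisson (negative binomial) law — the consensus base
model of published single-cell simulators:

* gene means  lambda_g ~ Gamma(shape, rate) (heavy-tailed, mostly low);
* cell size factors  s_c ~ LogNormal(0, sizefactor_sd);
* counts  K_gc ~ Poisson(lambda_g * s_c * theta_gc)  with
  theta_gc ~ Gamma(1/phi, phi), i.e. NB with dispersion phi;
* optional uniform dropout thinning (independent of expression, keeping
  moment expectations analytic).

Two cell groups are generated and signal genes are planted in disjoint
blocks for group 2: DE (mean shifted by a known log2 fold change), DV
(dispersion multiplied), DP (expressing-cell fraction altered via per-cell
on/off switching) and BD (a mean gap below the DE fold-change threshold).
A "simulated" companion matrix is a fresh draw from the same law with
fidelity knobs (mean shift delta on the log2 scale, dispersion factor,
extra dropout); delta = 0 with a fresh seed is the perfect simulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import CountMatrix, ValidationError


@dataclass
class PlantedSignals:
    """Proportions and effect sizes of planted signal genes (group 2)."""

    de_prop: float = 0.0
    de_log2fc: float = 2.0
    dv_prop: float = 0.0
    dv_factor: float = 4.0
    dp_prop: float = 0.0
    dp_on: tuple[float, float] = (0.9, 0.3)
    bd_prop: float = 0.0
    bd_gap: float = 0.8

    def total(self) -> float:
        return self.de_prop + self.dv_prop + self.dp_prop + self.bd_prop


@dataclass
class Perturbation:
    """Fidelity knobs applied when drawing the simulated companion."""

    mean_shift: float = 0.0  # delta, log2 scale, applied to all gene means
    dispersion_factor: float = 1.0
    dropout_shift: float = 0.0


@dataclass
class FixtureSpec:
    """Full parameterisation of a reference matrix (and its companion)."""

    n_genes: int = 2000
    n_cells: int = 500
    gamma_shape: float = 0.6
    gamma_rate: float = 0.3
    dispersion: float = 0.3
    sizefactor_sd: float = 0.25
    dropout: float = 0.0
    p_group: float = 0.5
    group_labels: tuple[str, str] = ("group1", "group2")
    planted: PlantedSignals = field(default_factory=PlantedSignals)
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1 or self.n_cells < 2:
            raise ValidationError("need at least 1 gene and 2 cells")
        if self.gamma_shape <= 0 or self.gamma_rate <= 0:
            raise ValidationError("gamma parameters must be positive")
        if self.dispersion < 0 or self.sizefactor_sd < 0:
            raise ValidationError("dispersion and sizefactor_sd must be >= 0")
        if not 0 <= self.dropout < 1:
            raise ValidationError("dropout must be in [0, 1)")
        if not 0 < self.p_group < 1:
            raise ValidationError("p_group must be in (0, 1)")
        pl = self.planted
        if min(pl.de_prop, pl.dv_prop, pl.dp_prop, pl.bd_prop) < 0:
            raise ValidationError("planted proportions must be >= 0")
        if pl.total() > 1:
            raise ValidationError(
                "planted proportions overlap: they must sum to <= 1"
            )
        if pl.dv_factor <= 0:
            raise ValidationError("dv_factor must be positive")
        if not all(0 <= f <= 1 for f in pl.dp_on):
            raise ValidationError("dp on-fractions must lie in [0, 1]")


def _signal_blocks(spec: FixtureSpec) -> dict[str, np.ndarray]:
    """Disjoint index blocks for each planted category (deterministic)."""
    pl = spec.planted
    sizes = {
        "de": int(round(pl.de_prop * spec.n_genes)),
        "dv": int(round(pl.dv_prop * spec.n_genes)),
        "dp": int(round(pl.dp_prop * spec.n_genes)),
        "bd": int(round(pl.bd_prop * spec.n_genes)),
    }
    blocks = {}
    start = 0
    for cat, size in sizes.items():
        blocks[cat] = np.arange(start, start + size)
        start += size
    return blocks


def expected_signal_proportions(spec: FixtureSpec) -> dict[str, float]:
    """Ground-truth planted proportions, keyed by category."""
    spec.validate()
    blocks = _signal_blocks(spec)
    return {cat: len(idx) / spec.n_genes for cat, idx in blocks.items()}


def generate_reference(
    spec: FixtureSpec, perturb: Perturbation | None = None
) -> CountMatrix:
    """Draw a grouped count matrix from the spec's gamma-Poisson law."""
    spec.validate()
    perturb = perturb or Perturbation()
    if perturb.dispersion_factor <= 0:
        raise ValidationError("dispersion_factor must be positive")
    dropout = spec.dropout + perturb.dropout_shift
    if not 0 <= dropout < 1:
        raise ValidationError("perturbed dropout outside [0, 1)")

    rng = np.random.default_rng(spec.seed)
    lam = rng.gamma(spec.gamma_shape, 1.0 / spec.gamma_rate, size=spec.n_genes)
    lam = np.maximum(lam, 1e-8) * 2.0 ** perturb.mean_shift
    size_factors = (
        np.exp(rng.normal(0.0, spec.sizefactor_sd, size=spec.n_cells))
        if spec.sizefactor_sd > 0
        else np.ones(spec.n_cells)
    )
    n1 = int(round(spec.p_group * spec.n_cells))
    group = np.array(
        [spec.group_labels[0]] * n1
        + [spec.group_labels[1]] * (spec.n_cells - n1),
        dtype=object,
    )
    in_group2 = group == spec.group_labels[1]

    mean = lam[:, None] * size_factors[None, :]
    blocks = _signal_blocks(spec)
    pl = spec.planted

    # DE: mean shifted by +/- the planted log2FC in group 2 (half up, half down)
    de = blocks["de"]
    if de.size:
        sign = np.where(np.arange(de.size) % 2 == 0, 1.0, -1.0)
        mean[np.ix_(de, in_group2)] *= (2.0 ** (pl.de_log2fc * sign))[:, None]
    # BD: a smaller mean gap, bimodal pooled distribution without large FC
    bd = blocks["bd"]
    if bd.size:
        mean[np.ix_(bd, in_group2)] *= 2.0 ** pl.bd_gap

    disp = np.full(spec.n_genes, spec.dispersion * perturb.dispersion_factor)
    disp_mat = np.repeat(disp[:, None], 2, axis=1)  # per (gene, group)
    dv = blocks["dv"]
    if dv.size:
        disp_mat[dv, 1] *= pl.dv_factor

    counts = np.empty((spec.n_genes, spec.n_cells), dtype=np.int64)
    for gi, members in enumerate((~in_group2, in_group2)):
        mu = mean[:, members]
        phi = disp_mat[:, gi][:, None]
        # gamma-Poisson mixing: theta ~ Gamma(1/phi, scale=phi), E[theta] = 1
        theta = np.ones_like(mu)
        od = np.broadcast_to(phi > 0, mu.shape)
        if od.any():
            shape = np.broadcast_to(
                np.where(phi > 0, 1.0 / np.where(phi > 0, phi, 1.0), 1.0), mu.shape
            )
            scale = np.broadcast_to(np.where(phi > 0, phi, 1.0), mu.shape)
            draws = rng.gamma(shape, scale)
            theta = np.where(od, draws, 1.0)
        counts[:, members] = rng.poisson(mu * theta)

    # DP: per-cell on/off switching with group-specific on-fractions
    dp = blocks["dp"]
    if dp.size:
        on1, on2 = pl.dp_on
        on_prob = np.where(in_group2, on2, on1)
        on = rng.random((dp.size, spec.n_cells)) < on_prob[None, :]
        counts[dp] = np.where(on, counts[dp], 0)

    if dropout > 0:
        keep = rng.random(counts.shape) >= dropout
        counts = np.where(keep, counts, 0)

    # guarantee positive library sizes (all-zero cells break normalisation)
    lib = counts.sum(axis=0)
    for c in np.nonzero(lib == 0)[0]:
        counts[rng.integers(spec.n_genes), c] = 1

    return CountMatrix(
        counts=counts,
        gene_ids=[f"gene{i + 1}" for i in range(spec.n_genes)],
        cell_ids=[f"cell{j + 1}" for j in range(spec.n_cells)],
        groups=group,
    )


def generate_simulated(
    reference_spec: FixtureSpec,
    perturb: Perturbation | None = None,
    seed: int | None = None,
) -> CountMatrix:
    """Fresh draw from the reference law with fidelity perturbations applied.

    With ``perturb`` at its defaults and a fresh seed the result is an
    exchangeable replicate of the reference — the perfect simulator.
    """
    perturb = perturb or Perturbation()
    spec = replace(
        reference_spec,
        seed=reference_spec.seed + 7919 if seed is None else seed,
    )
    return generate_reference(spec, perturb)
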