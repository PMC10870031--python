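"""Synthetic single-cell references and protocol-shifted pseudobulk benchmarks.

The generator emulates the ingredients a deconvolution benchmark needs:
per-cell-type expression programs with planted exclusive markers,
negative-binomial count noise, log-normal per-cell library-size variation, a
gene-wise multiplicative "protocol shift" standing in for capture-efficiency
differences between sequencing platforms, and pseudobulks pooled from
labelled cells at known proportions (the ground truth is the realized,
post-rounding cell composition of each pool).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .io import CellAnnotation, ExpressionMatrix, ProportionTable, ValidationError

__all__ = [
    "SimConfig",
    "BenchmarkData",
    "simulate_reference",
    "apply_protocol_shift",
    "make_pseudobulk",
    "simulate_benchmark",
]


@dataclass
class SimConfig:
    """Study conditions of the synthetic benchmark.

    Defaults describe a modest but realistic tissue: 2000 genes, 3 cell
    types (benchmark tissues in this setting carry 3-9), 300 reference cells
    per type, 50 exclusive markers per type at 5-fold elevation, 10x-like
    negative-binomial dispersion 0.1 and 0.3 log-normal library-size spread.
    ``shift_sigma`` controls the cross-protocol gene-wise bias (0 = none).
    """

    n_genes: int = 2000
    n_types: int = 3
    cells_per_type: int = 300
    markers_per_type: int = 50
    marker_fold: float = 5.0
    nb_dispersion: float = 0.1
    libsize_lognorm_sigma: float = 0.3
    shift_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.n_types):
            raise ValidationError("n_types must be >= 1")
        if self.n_genes < self.n_types * self.markers_per_type:
            raise ValidationError("n_genes must accommodate all planted markers")
        if self.marker_fold <= 1:
            raise ValidationError("marker_fold must exceed 1")
        if self.nb_dispersion <= 0 or self.libsize_lognorm_sigma < 0 or self.shift_sigma < 0:
            raise ValidationError("noise parameters out of range")


@dataclass
class BenchmarkData:
    """Aligned triplet emitted by :func:`simulate_benchmark`."""

    reference: ExpressionMatrix
    annotation: CellAnnotation
    bulk: ExpressionMatrix
    truth: ProportionTable
    true_means: np.ndarray
    pool_cell_ids: tuple[str, ...] = ()  # cells eligible for pseudobulk pooling


def _type_mean_matrix(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-type mean expression (genes x K) with planted exclusive markers."""
    base = rng.lognormal(mean=1.0, sigma=1.0, size=cfg.n_genes)
    means = np.tile(base[:, None], (1, cfg.n_types))
    for k in range(cfg.n_types):
        start = k * cfg.markers_per_type
        marker_rows = slice(start, start + cfg.markers_per_type)
        means[marker_rows, k] = base[marker_rows] * cfg.marker_fold
    # mild non-marker heterogeneity so types differ beyond markers
    means *= rng.lognormal(mean=0.0, sigma=0.15, size=means.shape)
    return means


def _nb_counts(mean: np.ndarray, dispersion: float, rng: np.random.Generator) -> np.ndarray:
    """Negative-binomial draws with var = mu + dispersion * mu^2."""
    n = 1.0 / dispersion
    mean = np.maximum(mean, 1e-12)
    p = n / (n + mean)
    return rng.negative_binomial(n, p).astype(float)


def simulate_reference(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[ExpressionMatrix, CellAnnotation, np.ndarray]:
    """Draw a labelled single-cell count matrix.

    Returns the raw counts, the cell annotation, and the genes x K matrix of
    true per-type mean counts (library-size factors average to one, so
    empirical per-type means converge to these).
    """
    rng = rng or np.random.default_rng(cfg.seed)
    means = _type_mean_matrix(cfg, rng)
    n_cells = cfg.cells_per_type * cfg.n_types
    type_idx = np.repeat(np.arange(cfg.n_types), cfg.cells_per_type)
    sigma = cfg.libsize_lognorm_sigma
    # mean-one library factors: empirical type means match `means`
    lib = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=n_cells)
    mu = means[:, type_idx] * lib[None, :]
    counts = _nb_counts(mu, cfg.nb_dispersion, rng)
    genes = [f"g{i:05d}" for i in range(cfg.n_genes)]
    cells = [f"c{i:05d}" for i in range(n_cells)]
    em = ExpressionMatrix(values=counts, gene_ids=genes, column_ids=cells, layer_tag="raw")
    ann = CellAnnotation(
        cell_ids=cells,
        cell_type=[f"type{k}" for k in type_idx],
        type_order=[f"type{k}" for k in range(cfg.n_types)],
    )
    return em, ann, means


def apply_protocol_shift(
    em: ExpressionMatrix, cfg: SimConfig, rng: np.random.Generator | None = None
) -> ExpressionMatrix:
    """Multiply each gene row by a fixed log-normal capture factor and
    re-round to integer counts; ``shift_sigma = 0`` is the identity."""
    if cfg.shift_sigma == 0:
        return em
    rng = rng or np.random.default_rng(cfg.seed + 104729)
    factors = rng.lognormal(mean=0.0, sigma=cfg.shift_sigma, size=em.n_genes)
    shifted = np.rint(em.values * factors[:, None])
    return em.with_values(shifted)


def make_pseudobulk(
    sc: ExpressionMatrix,
    ann: CellAnnotation,
    proportions: np.ndarray,
    n_cells: int = 500,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Pool raw counts of sampled cells at (approximately) the requested
    proportions.

    Per type, round(p_k * n_cells) cells are drawn without replacement when
    possible, otherwise with replacement. Returns the pooled count vector
    and the realized proportions (sampled counts over their total), which
    are the ground truth.
    """
    p = np.asarray(proportions, dtype=float)
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
        raise ValidationError("proportions must be non-negative and sum to 1")
    if len(p) != ann.n_types:
        raise ValidationError("proportion length does not match number of cell types")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    take = np.floor(p * n_cells + 0.5).astype(int)
    pooled = np.zeros(sc.n_genes)
    for k, t in enumerate(ann.type_order):
        if take[k] == 0:
            continue
        idx = ann.type_indices(t)
        chosen = rng.choice(idx, size=take[k], replace=take[k] > idx.size)
        pooled += sc.values[:, chosen].sum(axis=1)
    if take.sum() == 0:
        raise ValidationError("no cells sampled; n_cells too small for the proportions")
    realized = take / take.sum()
    return pooled, realized


def simulate_benchmark(
    cfg: SimConfig,
    n_samples: int = 10,
    proportion_mode: str = "dirichlet",
    fixed_p: np.ndarray | None = None,
    n_cells: int = 500,
) -> BenchmarkData:
    """Full benchmark triplet: reference, protocol-shifted pseudobulk
    mixtures, and the realized ground-truth proportion table.

    Pseudobulks are pooled from a cell pool disjoint from the reference
    cells (both drawn from the same per-type programs), and the protocol
    shift is applied to the bulk side only.
    """
    if proportion_mode not in ("dirichlet", "fixed"):
        raise ValidationError(f"unknown proportion_mode {proportion_mode!r}")
    if proportion_mode == "fixed" and fixed_p is None:
        raise ValidationError("fixed mode requires fixed_p")
    rng = np.random.default_rng(cfg.seed)
    # double pool drawn jointly, then split disjointly per type
    double = replace(cfg, cells_per_type=2 * cfg.cells_per_type)
    em, ann, means = simulate_reference(double, rng=rng)
    ref_mask = np.zeros(em.n_columns, dtype=bool)
    for t in ann.type_order:
        idx = ann.type_indices(t)
        ref_mask[idx[: cfg.cells_per_type]] = True
    ref_idx = np.flatnonzero(ref_mask)
    pool_idx = np.flatnonzero(~ref_mask)

    reference = ExpressionMatrix(
        values=em.values[:, ref_idx],
        gene_ids=em.gene_ids,
        column_ids=[em.column_ids[i] for i in ref_idx],
        layer_tag="raw",
    )
    ref_ann = CellAnnotation(
        cell_ids=reference.column_ids,
        cell_type=[ann.cell_type[i] for i in ref_idx],
        type_order=list(ann.type_order),
    )
    pool = ExpressionMatrix(
        values=em.values[:, pool_idx],
        gene_ids=em.gene_ids,
        column_ids=[em.column_ids[i] for i in pool_idx],
        layer_tag="raw",
    )
    pool_ann = CellAnnotation(
        cell_ids=pool.column_ids,
        cell_type=[ann.cell_type[i] for i in pool_idx],
        type_order=list(ann.type_order),
    )

    cols = []
    truths = []
    for _ in range(n_samples):
        if proportion_mode == "dirichlet":
            p = rng.dirichlet(np.ones(cfg.n_types))
        else:
            p = np.asarray(fixed_p, dtype=float)
        vec, realized = make_pseudobulk(pool, pool_ann, p, n_cells=n_cells, seed=rng)
        cols.append(vec)
        truths.append(realized)

    bulk = ExpressionMatrix(
        values=np.column_stack(cols),
        gene_ids=em.gene_ids,
        column_ids=[f"pb{j:03d}" for j in range(n_samples)],
        layer_tag="raw",
    )
    bulk = apply_protocol_shift(bulk, cfg, rng=rng)
    truth = ProportionTable(
        sample_ids=list(bulk.column_ids),
        type_order=list(ann.type_order),
        proportions=np.vstack(truths),
    )
    return BenchmarkData(
        reference=reference,
        annotation=ref_ann,
        bulk=bulk,
        truth=truth,
        true_means=means,
        pool_cell_ids=tuple(pool.column_ids),
    )
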