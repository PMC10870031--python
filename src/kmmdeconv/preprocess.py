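"""Gene intersection and per-column normalizations.

All operations work on the linear expression scale; no log transform is
applied anywhere in the pipeline because the mixing model is linear in
expression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ExpressionMatrix, ValidationError

__all__ = ["CommonGeneSpace", "intersect_genes", "normalize_cells", "relative_abundance"]

DEFAULT_TARGET_SUM = 10_000.0


@dataclass(frozen=True)
class CommonGeneSpace:
    """The shared gene set G of a reference/bulk pair and its size d."""

    genes: tuple[str, ...]
    d: int


def intersect_genes(
    sc: ExpressionMatrix, bulk: ExpressionMatrix
) -> tuple[CommonGeneSpace, ExpressionMatrix, ExpressionMatrix]:
    """Restrict both matrices to their common genes G.

    Row order of both outputs follows the bulk matrix (deconvolution is per
    bulk sample, so the bulk ordering is the natural frame).
    """
    sc_set = set(sc.gene_ids)
    common = [g for g in bulk.gene_ids if g in sc_set]
    if len(common) == 0:
        raise ValidationError("no genes shared between reference and bulk")
    space = CommonGeneSpace(genes=tuple(common), d=len(common))
    return space, sc.subset_genes(common), bulk.subset_genes(common)


def normalize_cells(
    em: ExpressionMatrix, target_sum: float = DEFAULT_TARGET_SUM
) -> ExpressionMatrix:
    """Scale every column to a fixed total count (10 000 by default).

    Within-column proportions are unchanged; a raw layer is required so the
    normalization is applied exactly once.
    """
    if target_sum <= 0:
        raise ValidationError("target_sum must be positive")
    sums = em.values.sum(axis=0)
    zero = np.flatnonzero(sums == 0)
    if zero.size:
        raise ValidationError(f"all-zero column(s): {[em.column_ids[i] for i in zero[:5]]}")
    out = em.values * (target_sum / sums)
    return em.with_values(out, layer_tag="cell_normalized")


def relative_abundance(bulk: ExpressionMatrix) -> ExpressionMatrix:
    """Per-sample relative abundance: each column rescaled to sum to one."""
    sums = bulk.values.sum(axis=0)
    zero = np.flatnonzero(sums == 0)
    if zero.size:
        raise ValidationError(f"all-zero sample(s): {[bulk.column_ids[i] for i in zero[:5]]}")
    return bulk.with_values(bulk.values / sums, layer_tag="relative_abundance")
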