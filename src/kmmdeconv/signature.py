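"""Cell-type signature matrix built from cosine-similarity contribution scores.

Rather than averaging expression per cell type, every gene is weighted by a
cell-type-specificity score before entering the design matrix, so the whole
common gene set participates in deconvolution and marker-like genes dominate
in proportion to how exclusively they mark a type.

For gene g and cell type k with ideal indicator vector v_k (1 on cells of
type k, 0 elsewhere):

    cos(g, v_k) = (sum_{j in C_k} x_jg) / (||g||_2 * sqrt(m_k))

    r(g, k)     = cos(g, v_k)^5 / (mu * sum_{t != k} cos(g, v_t)^2 + 1)
    score(g, k) = ln(1 / (1 - r)),   r clipped to <= 1 - clip_delta

The score is 0 when the gene is silent in type k, grows without bound (up to
the clip) for a perfectly exclusive marker, and is damped by off-target
expression through the penalty mu. The signature is S = theta * score
elementwise, where theta_gk is the mean normalized expression of g over
cells of type k; per-type cell sizes S_k (mean raw library size, rescaled to
mean 1) convert RNA fractions to cell-count fractions downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import CellAnnotation, ExpressionMatrix, ValidationError

__all__ = [
    "IdealVectors",
    "SignatureMatrix",
    "build_ideal_vectors",
    "cosine_to_ideal",
    "contribution_scores",
    "mean_expression_by_type",
    "cell_size_factors",
    "assemble_signature",
    "build_signature",
]

DEFAULT_MU = 1.0
DEFAULT_CLIP_DELTA = 1e-10


@dataclass
class IdealVectors:
    """Binary cells x types membership indicators and per-type counts m_k."""

    indicator: np.ndarray
    counts: np.ndarray
    type_order: list[str]


@dataclass
class SignatureMatrix:
    """Score-weighted mean-expression signature with cell-size factors."""

    S: np.ndarray
    theta: np.ndarray
    scores: np.ndarray
    cosines: np.ndarray
    cell_sizes: np.ndarray
    gene_ids: list[str]
    type_order: list[str]
    zero_rows: np.ndarray  # boolean mask of genes with all-zero signature rows

    @property
    def n_types(self) -> int:
        return len(self.type_order)


def build_ideal_vectors(ann: CellAnnotation) -> IdealVectors:
    """Indicator matrix of the ideal, perfectly type-exclusive marker genes."""
    ct = np.asarray(ann.cell_type)
    indicator = np.stack(
        [(ct == t).astype(float) for t in ann.type_order], axis=1
    )
    return IdealVectors(
        indicator=indicator,
        counts=indicator.sum(axis=0).astype(int),
        type_order=list(ann.type_order),
    )


def cosine_to_ideal(sc: ExpressionMatrix, iv: IdealVectors) -> np.ndarray:
    """Cosine similarity between each gene's cell-space vector and each
    ideal vector; genes with no expression anywhere get cosine 0."""
    X = sc.values  # genes x cells
    if X.shape[1] != iv.indicator.shape[0]:
        raise ValidationError("cell count mismatch between expression and annotation")
    # numerator: per-type sums of expression; denominator: ||g|| * sqrt(m_k)
    num = X @ iv.indicator
    gene_norms = np.linalg.norm(X, axis=1)
    denom = gene_norms[:, None] * np.sqrt(iv.counts)[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        cos = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
    return np.clip(cos, 0.0, 1.0)


def contribution_scores(
    cosines: np.ndarray,
    mu: float = DEFAULT_MU,
    clip_delta: float = DEFAULT_CLIP_DELTA,
) -> np.ndarray:
    """Per-gene, per-type specificity weights from the cosine matrix."""
    if mu < 0:
        raise ValidationError("mu must be non-negative")
    cos = np.asarray(cosines, dtype=float)
    if np.any(cos < 0) or np.any(cos > 1):
        raise ValidationError("cosines must lie in [0, 1]")
    sq = cos**2
    off_target = sq.sum(axis=1, keepdims=True) - sq
    r = cos**5 / (mu * off_target + 1.0)
    r = np.minimum(r, 1.0 - clip_delta)
    return -np.log1p(-r)


def mean_expression_by_type(sc: ExpressionMatrix, ann: CellAnnotation) -> np.ndarray:
    """theta_gk: mean normalized expression of gene g over cells of type k."""
    iv = build_ideal_vectors(ann)
    return (sc.values @ iv.indicator) / iv.counts[None, :]


def cell_size_factors(sc_raw: ExpressionMatrix, ann: CellAnnotation) -> np.ndarray:
    """Per-type mean raw library size, rescaled to mean one across types.

    These are the S_k factors converting RNA-content fractions into
    cell-count fractions in the mixing model.
    """
    lib = sc_raw.values.sum(axis=0)
    sizes = np.array(
        [lib[ann.type_indices(t)].mean() for t in ann.type_order]
    )
    return sizes / sizes.mean()


def assemble_signature(
    theta: np.ndarray,
    scores: np.ndarray,
    sc_raw: ExpressionMatrix,
    ann: CellAnnotation,
    gene_ids: list[str] | None = None,
    cosines: np.ndarray | None = None,
) -> SignatureMatrix:
    """S = theta (elementwise *) scores, plus cell sizes and zero-row flags."""
    theta = np.asarray(theta, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if theta.shape != scores.shape:
        raise ValidationError("theta and scores shapes differ")
    S = theta * scores
    zero_rows = np.all(S == 0, axis=1)
    zero_cols = np.flatnonzero(np.all(S == 0, axis=0))
    if zero_cols.size:
        bad = [ann.type_order[i] for i in zero_cols]
        raise ValidationError(f"cell type(s) with identically-zero signature: {bad}")
    return SignatureMatrix(
        S=S,
        theta=theta,
        scores=scores,
        cosines=cosines if cosines is not None else np.zeros_like(S),
        cell_sizes=cell_size_factors(sc_raw, ann),
        gene_ids=list(gene_ids) if gene_ids is not None else list(sc_raw.gene_ids),
        type_order=list(ann.type_order),
        zero_rows=zero_rows,
    )


def build_signature(
    sc_raw: ExpressionMatrix,
    sc_normalized: ExpressionMatrix,
    ann: CellAnnotation,
    mu: float = DEFAULT_MU,
    clip_delta: float = DEFAULT_CLIP_DELTA,
) -> SignatureMatrix:
    """One-call signature construction from raw and normalized reference."""
    iv = build_ideal_vectors(ann)
    cos = cosine_to_ideal(sc_normalized, iv)
    scores = contribution_scores(cos, mu=mu, clip_delta=clip_delta)
    theta = mean_expression_by_type(sc_normalized, ann)
    return assemble_signature(
        theta, scores, sc_raw, ann, gene_ids=sc_normalized.gene_ids, cosines=cos
    )
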