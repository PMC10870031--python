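"""scikit-learn-style estimators wrapping the deconvolution pipeline.

``CellTypeDeconvolver`` is the main entry point: fit it on a labelled
single-cell reference (cells x genes, raw counts) and call ``predict`` on
bulk samples (samples x genes) to obtain cell-type proportion estimates.
``KernelMeanMatcher`` exposes the KMM reweighting step on its own as a
transformer.

Both follow sklearn conventions (``get_params``/``set_params``, fitted
attributes with a trailing underscore, validation on fit) so they compose
with sklearn model selection; note the samples-as-rows orientation here is
sklearn's, transposed from the genes-as-rows convention of the functional
modules.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .io import CellAnnotation, ExpressionMatrix, ProportionTable, ValidationError
from .kmm import KmmConfig, solve_kmm, transform_bulk
from .preprocess import DEFAULT_TARGET_SUM, intersect_genes, normalize_cells
from .signature import DEFAULT_CLIP_DELTA, DEFAULT_MU, build_signature
from .solver import SolverConfig, deconvolve_samples

__all__ = ["KernelMeanMatcher", "CellTypeDeconvolver", "deconvolve"]


def _as_matrix(X, feature_names=None) -> tuple[np.ndarray, list[str] | None]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(c) for c in X.columns]
    return np.asarray(X, dtype=float), feature_names


class KernelMeanMatcher(TransformerMixin, BaseEstimator):
    """Reweight query samples so their kernel mean embedding matches a
    reference point cloud (covariate-shift correction).

    Parameters
    ----------
    B : upper bound on the per-sample weights.
    epsilon : slack of the mean-weight normalization constraint; ``None``
        selects (n_query - 1)/n_query.
    sigma : RBF bandwidth; ``None`` selects the median pairwise distance of
        the pooled points.
    """

    def __init__(self, B: float = 1000.0, epsilon: float | None = None,
                 sigma: float | None = None, qp_tol: float = 1e-9):
        self.B = B
        self.epsilon = epsilon
        self.sigma = sigma
        self.qp_tol = qp_tol

    def fit(self, X, y=None):
        """Store the reference point cloud (samples x features)."""
        X, _ = _as_matrix(X)
        if X.ndim != 2 or X.shape[0] < 1:
            raise ValidationError("reference must be a non-empty 2-D array")
        self.reference_ = X
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        """Estimate weights for the rows of ``X`` against the stored
        reference and return the row-scaled matrix; weights and MMD
        diagnostics are kept on ``kmm_result_``."""
        if not hasattr(self, "reference_"):
            raise ValidationError("KernelMeanMatcher is not fitted")
        X, _ = _as_matrix(X)
        if X.shape[1] != self.n_features_in_:
            raise ValidationError("feature count differs from the fitted reference")
        cfg = KmmConfig(B=self.B, epsilon=self.epsilon, sigma=self.sigma, qp_tol=self.qp_tol)
        self.kmm_result_ = solve_kmm(X.T, self.reference_.T, cfg)
        return X * self.kmm_result_.beta[:, None]


class CellTypeDeconvolver(BaseEstimator):
    """Reference-based bulk RNA-seq deconvolution.

    fit(X, y): X is a cells x genes raw count matrix (DataFrame columns are
    used as gene names), y the per-cell type labels. predict(B) takes bulk
    samples x genes and returns the samples x K proportion matrix.

    Parameters
    ----------
    mu : off-target penalty of the contribution score (default 1).
    solver : ``"wnnls"`` (iteratively gene-reweighted, default) or ``"nnls"``.
    use_kmm : apply kernel-mean-matching transformation of the bulk samples
        toward the reference distribution before solving.
    kmm_B, kmm_epsilon, kmm_sigma : KMM parameters (see KernelMeanMatcher).
    target_sum : per-column normalization total (counts per cell).
    max_iter, tol : weighted-solver iteration controls.
    """

    def __init__(self, mu: float = DEFAULT_MU, solver: str = "wnnls",
                 use_kmm: bool = True, kmm_B: float = 1000.0,
                 kmm_epsilon: float | None = None, kmm_sigma: float | None = None,
                 target_sum: float = DEFAULT_TARGET_SUM,
                 clip_delta: float = DEFAULT_CLIP_DELTA,
                 max_iter: int = 100, tol: float = 1e-6):
        self.mu = mu
        self.solver = solver
        self.use_kmm = use_kmm
        self.kmm_B = kmm_B
        self.kmm_epsilon = kmm_epsilon
        self.kmm_sigma = kmm_sigma
        self.target_sum = target_sum
        self.clip_delta = clip_delta
        self.max_iter = max_iter
        self.tol = tol

    # -- fitting -----------------------------------------------------------
    def fit(self, X, y, feature_names: list[str] | None = None):
        """Store and validate the labelled reference; precompute the
        signature on the reference's own gene space (``signature_``)."""
        X, names = _as_matrix(X, feature_names)
        y = list(np.asarray(y, dtype=object))
        if X.ndim != 2:
            raise ValidationError("reference must be 2-D (cells x genes)")
        if len(y) != X.shape[0]:
            raise ValidationError("one label per reference cell is required")
        if names is None:
            names = [f"feature{i}" for i in range(X.shape[1])]
        self.feature_names_in_ = list(names)
        self.n_features_in_ = X.shape[1]
        ref = ExpressionMatrix(values=X.T, gene_ids=names,
                               column_ids=[f"cell{i}" for i in range(X.shape[0])])
        ann = CellAnnotation(cell_ids=ref.column_ids, cell_type=[str(t) for t in y])
        self._reference = ref
        self._annotation = ann
        self.classes_ = list(ann.type_order)
        sig = build_signature(ref, normalize_cells(ref, self.target_sum), ann,
                              mu=self.mu, clip_delta=self.clip_delta)
        self.signature_ = sig
        self.cell_sizes_ = sig.cell_sizes
        return self

    # -- inference ---------------------------------------------------------
    def _predict_table(self, B, sample_ids=None) -> ProportionTable:
        if not hasattr(self, "_reference"):
            raise ValidationError("CellTypeDeconvolver is not fitted")
        B, names = _as_matrix(B)
        if names is None:
            if B.shape[1] != self.n_features_in_:
                raise ValidationError(
                    "bulk feature count differs from the reference; pass a "
                    "DataFrame with gene-name columns to align by name"
                )
            names = self.feature_names_in_
        if sample_ids is None:
            sample_ids = [f"sample{j}" for j in range(B.shape[0])]
        bulk = ExpressionMatrix(values=B.T, gene_ids=names, column_ids=sample_ids)
        return deconvolve_pipeline(
            self._reference, self._annotation, bulk,
            mu=self.mu, solver=self.solver, use_kmm=self.use_kmm,
            kmm_cfg=KmmConfig(B=self.kmm_B, epsilon=self.kmm_epsilon,
                              sigma=self.kmm_sigma, enabled=self.use_kmm),
            target_sum=self.target_sum, clip_delta=self.clip_delta,
            max_iter=self.max_iter, tol=self.tol,
        )

    def predict(self, B) -> np.ndarray:
        """Cell-type proportions, one simplex row per bulk sample."""
        table = self._predict_table(B)
        self.last_result_ = table
        if isinstance(B, pd.DataFrame):
            return table.to_frame().to_numpy()
        return table.proportions

    def predict_table(self, B, sample_ids=None) -> ProportionTable:
        """Like :meth:`predict` but returns the full diagnostic table."""
        table = self._predict_table(B, sample_ids=sample_ids)
        self.last_result_ = table
        return table

    def score(self, B, P_true) -> float:
        """Negative mean L1 error (percentage points) against known truth."""
        from .metrics import mean_l1_error

        est = self.predict(B)
        P_true = np.asarray(P_true, dtype=float)
        return -float(np.mean([mean_l1_error(e, t) for e, t in zip(est, P_true)]))


def deconvolve_pipeline(
    reference: ExpressionMatrix,
    annotation: CellAnnotation,
    bulk: ExpressionMatrix,
    mu: float = DEFAULT_MU,
    solver: str = "wnnls",
    use_kmm: bool = True,
    kmm_cfg: KmmConfig | None = None,
    target_sum: float = DEFAULT_TARGET_SUM,
    clip_delta: float = DEFAULT_CLIP_DELTA,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> ProportionTable:
    """Full pipeline on genes-as-rows containers:
    intersect -> normalize -> (KMM) -> signature -> constrained solve."""
    _, sc_g, bulk_g = intersect_genes(reference, bulk)
    sc_norm = normalize_cells(sc_g, target_sum)
    bulk_norm = normalize_cells(bulk_g, target_sum)
    if use_kmm and bulk_g.n_columns >= 1:
        cfg = kmm_cfg or KmmConfig()
        kmm = solve_kmm(bulk_norm.values, sc_norm.values, cfg)
        # A per-sample scalar weight cancels under the per-sample
        # relative-abundance normalization, so the proportion estimate is
        # constant in beta_j > 0; beta_j = 0 (a sample the QP discards
        # entirely) is resolved by continuity rather than dropping the sample.
        from dataclasses import replace as _replace

        beta_eff = np.where(kmm.beta > 0, kmm.beta, 1.0)
        bulk_solved = transform_bulk(bulk_norm, _replace(kmm, beta=beta_eff))
    else:
        bulk_solved = bulk_norm
    sig = build_signature(sc_g, sc_norm, annotation, mu=mu, clip_delta=clip_delta)
    scfg = SolverConfig(method=solver, max_iter=max_iter, tol=tol)
    return deconvolve_samples(bulk_solved, sig, scfg)


def deconvolve(reference, labels, bulk, **kwargs) -> ProportionTable:
    """Functional one-call deconvolution on the library's containers."""
    return deconvolve_pipeline(reference, labels, bulk, **kwargs)
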