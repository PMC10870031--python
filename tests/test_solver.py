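import itertools

import numpy as np
import pytest

from kmmdeconv import (
    CellAnnotation,
    ExpressionMatrix,
    SolverConfig,
    ValidationError,
    build_signature,
    deconvolve_samples,
    design_matrix,
    normalize_cells,
    proportions_from_weights,
    solve_nnls,
    solve_wnnls,
)
from kmmdeconv.solver import regression_system


def nnls_by_active_set_enumeration(A, y):
    """Brute-force NNLS: try every support set, keep the feasible
    least-squares solution with the smallest residual."""
    n, k = A.shape
    best_x, best_r = np.zeros(k), np.linalg.norm(y)
    for size in range(1, k + 1):
        for support in itertools.combinations(range(k), size):
            sub = A[:, support]
            sol, *_ = np.linalg.lstsq(sub, y, rcond=None)
            if np.any(sol < 0):
                continue
            x = np.zeros(k)
            x[list(support)] = sol
            r = np.linalg.norm(A @ x - y)
            if r < best_r - 1e-12:
                best_x, best_r = x, r
    return best_x, best_r


@pytest.fixture
def sim_signature():
    from kmmdeconv import SimConfig, simulate_reference

    cfg = SimConfig(n_genes=400, n_types=3, cells_per_type=150,
                    markers_per_type=20, marker_fold=6.0, seed=11)
    em, ann, _ = simulate_reference(cfg)
    return build_signature(em, normalize_cells(em), ann)


class TestDesignMatrix:
    def test_unit_cell_sizes_give_signature(self, sim_signature):
        sig = sim_signature
        sig.cell_sizes = np.ones(3)
        A, genes = design_matrix(sig)
        np.testing.assert_array_equal(A, sig.S[~sig.zero_rows])

    def test_flagged_rows_dropped(self, sim_signature):
        sig = sim_signature
        sig.S[5] = 0.0
        sig.zero_rows[5] = True
        A, genes = design_matrix(sig)
        assert A.shape[0] == sig.S.shape[0] - int(sig.zero_rows.sum())
        assert sig.gene_ids[5] not in genes

    def test_column_scaling_ratio(self, sim_signature):
        sig = sim_signature
        A, _ = design_matrix(sig, drop_zero_rows=False)
        for k in range(3):
            nz = sig.S[:, k] > 0
            np.testing.assert_allclose(
                A[nz, k] / sig.S[nz, k], sig.cell_sizes[k], rtol=1e-12
            )


class TestSolveNnls:
    def test_exact_column_recovers_unit_vector(self, rng):
        A = rng.uniform(0, 2, size=(30, 3))
        x, r = solve_nnls(A, A[:, 1])
        np.testing.assert_allclose(x, [0, 1, 0], atol=1e-10)
        assert r < 1e-10

    def test_exact_mixture_recovered(self, rng):
        A = rng.uniform(0, 2, size=(30, 3))
        x, _ = solve_nnls(A, 0.5 * A[:, 1] + 0.5 * A[:, 2])
        np.testing.assert_allclose(x, [0, 0.5, 0.5], atol=1e-8)

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_matches_active_set_enumeration(self, k):
        rng = np.random.default_rng(100 + k)
        for _ in range(25):
            A = rng.uniform(0, 1, size=(15, k))
            y = rng.uniform(-0.2, 1.0, size=15)
            x, r = solve_nnls(A, y)
            x_ref, r_ref = nnls_by_active_set_enumeration(A, y)
            assert np.max(np.abs(x - x_ref)) < 1e-8
            assert r == pytest.approx(r_ref, abs=1e-8)

    def test_non_finite_rejected(self):
        with pytest.raises(ValidationError):
            solve_nnls(np.array([[np.nan]]), np.array([1.0]))


class TestSolveWnnls:
    def test_exact_fit_converges_immediately(self, rng):
        A = rng.uniform(0.1, 2, size=(40, 3))
        x_true = np.array([0.2, 0.5, 0.3])
        y = A @ x_true
        x, r, n_iter = solve_wnnls(A, y)
        x0, _ = solve_nnls(A, y)
        assert n_iter <= 2
        assert np.max(np.abs(x - x0)) < 1e-8

    def test_homoscedastic_noise_close_to_unweighted(self):
        # equal cross-type variance per gene (rows are permutations of one
        # pattern) and tiny noise: reweighting is then nearly uniform
        diffs = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            base = np.array([0.5, 1.0, 1.5])
            A = np.stack([rng.permutation(base) for _ in range(60)])
            y = A @ np.array([0.3, 0.4, 0.3]) + rng.normal(0, 1e-4, 60)
            xw, _, _ = solve_wnnls(A, y)
            xu, _ = solve_nnls(A, y)
            diffs.append(np.max(np.abs(xw - xu)))
        assert np.mean(diffs) < 1e-3

    def test_outlier_gene_downweighted(self, rng):
        A = rng.uniform(0.5, 1.5, size=(80, 3))
        x_true = np.array([0.5, 0.3, 0.2])
        y = A @ x_true
        y[7] += 50.0  # corrupted gene
        x, _, _ = solve_wnnls(A, y)
        resid = A @ x - y
        nu = np.var(A * x[None, :], axis=1)
        w = 1.0 / (nu + resid**2 + 1e-8)
        assert w[7] < np.percentile(w, 5)

    def test_nonconvergence_warns(self, rng):
        A = rng.uniform(0, 1, size=(20, 3))
        y = rng.uniform(0, 1, size=20)
        with pytest.warns(UserWarning, match="did not converge"):
            solve_wnnls(A, y, SolverConfig(max_iter=1, tol=1e-15))


class TestProportionsFromWeights:
    def test_forced_normalization(self):
        np.testing.assert_allclose(proportions_from_weights(np.array([2.0, 2.0])), [0.5, 0.5])

    def test_idempotent_on_simplex_corner(self):
        np.testing.assert_array_equal(proportions_from_weights(np.array([0.0, 1.0])), [0, 1])

    def test_sums_to_one(self, rng):
        p = proportions_from_weights(rng.uniform(0.1, 5, size=6))
        assert p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValidationError):
            proportions_from_weights(np.zeros(3))


class TestDeconvolveSamples:
    def _bulk_from(self, sig, props, cfg=None):
        cfg = cfg or SolverConfig()
        A, omega, genes = regression_system(sig, cfg)
        cols = (A @ props.T)  # exact forward model in the solved gene space
        vals = np.zeros((len(sig.gene_ids), props.shape[0]))
        lookup = {g: i for i, g in enumerate(sig.gene_ids)}
        for r, g in enumerate(genes):
            vals[lookup[g]] = cols[r]
        return ExpressionMatrix(
            vals, sig.gene_ids, [f"s{j}" for j in range(props.shape[0])]
        )

    def test_forward_inverse_consistency(self, sim_signature):
        props = np.array([[0.6, 0.3, 0.1], [0.2, 0.2, 0.6]])
        bulk = self._bulk_from(sim_signature, props)
        table = deconvolve_samples(bulk, sim_signature)
        np.testing.assert_allclose(table.proportions, props, atol=1e-6)

    def test_rows_on_simplex(self, sim_signature, rng):
        bulk = ExpressionMatrix(
            rng.uniform(0.1, 3, size=(len(sim_signature.gene_ids), 4)),
            sim_signature.gene_ids,
            [f"s{j}" for j in range(4)],
        )
        table = deconvolve_samples(bulk, sim_signature)
        assert np.all(table.proportions >= 0)
        np.testing.assert_allclose(table.proportions.sum(axis=1), 1.0, atol=1e-8)

    def test_identical_samples_identical_rows(self, sim_signature, rng):
        col = rng.uniform(0.1, 3, size=(len(sim_signature.gene_ids), 1))
        bulk = ExpressionMatrix(
            np.tile(col, (1, 3)), sim_signature.gene_ids, ["a", "b", "c"]
        )
        table = deconvolve_samples(bulk, sim_signature)
        np.testing.assert_array_equal(table.proportions[0], table.proportions[1])
        np.testing.assert_array_equal(table.proportions[0], table.proportions[2])

    def test_gene_mismatch_rejected(self, sim_signature, rng):
        bulk = ExpressionMatrix(
            rng.uniform(0.1, 3, size=(5, 2)),
            [f"other{i}" for i in range(5)],
            ["s0", "s1"],
        )
        with pytest.raises(ValidationError):
            deconvolve_samples(bulk, sim_signature)


def test_permutation_equivariance():
    """Permuting cell-type order permutes proportion columns identically."""
    from kmmdeconv import SimConfig, simulate_reference

    cfg = SimConfig(n_genes=300, n_types=3, cells_per_type=100, seed=5)
    em, ann, _ = simulate_reference(cfg)
    rng = np.random.default_rng(0)
    bulk = ExpressionMatrix(
        rng.uniform(1, 10, size=(300, 2)), em.gene_ids, ["s0", "s1"]
    )
    perm = [2, 0, 1]
    ann_perm = CellAnnotation(
        ann.cell_ids, ann.cell_type, type_order=[ann.type_order[i] for i in perm]
    )
    sig = build_signature(em, normalize_cells(em), ann)
    sig_p = build_signature(em, normalize_cells(em), ann_perm)
    t = deconvolve_samples(bulk, sig)
    t_p = deconvolve_samples(bulk, sig_p)
    np.testing.assert_allclose(t.proportions[:, perm], t_p.proportions, atol=1e-10)
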