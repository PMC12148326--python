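"""Sparse local flow, PCA/polynomial bases, ridge smoothing, pipeline."""

import numpy as np
import pytest

from migflow import (
    FlowBasis,
    FlowParams,
    ImageStack,
    ParameterError,
    fit_basis,
    flow_pipeline,
    polynomial_basis,
    smooth_field,
    sparse_flow,
)
from migflow.datatypes import VectorField
from migflow.flow import dense_lk_flow

from conftest import shifted, textured_frame


def _field(vx, vy, valid=None):
    vx = np.asarray(vx, float)
    valid = np.ones(vx.shape, bool) if valid is None else valid
    return VectorField(
        frame_pair=(0, 1),
        grid_x=np.arange(vx.shape[1]),
        grid_y=np.arange(vx.shape[0]),
        vx=vx,
        vy=np.asarray(vy, float),
        valid=valid,
    )


class TestSparseFlow:
    def test_identical_frames_give_zero_vectors(self, textured):
        f = sparse_flow(textured, textured)
        assert f.n_valid > 0
        assert np.allclose(f.vx[f.valid], 0.0, atol=1e-6)
        assert np.allclose(f.vy[f.valid], 0.0, atol=1e-6)

    def test_known_translation_recovered(self, textured):
        f = sparse_flow(textured, shifted(textured, 2.0, 0.0))
        v = f.valid_vectors()
        err = np.hypot(v[:, 0] - 2.0, v[:, 1])
        assert np.median(err) < 0.25

    def test_textureless_frames_are_invalid(self):
        flat = np.full((64, 64), 5.0)
        f = sparse_flow(flat, flat)
        assert f.n_valid == 0

    def test_window_larger_than_frame_rejected(self):
        with pytest.raises(ParameterError):
            sparse_flow(np.zeros((8, 8)), np.zeros((8, 8)), window=9)

    def test_frame_swap_negates_translation(self, textured):
        b = shifted(textured, 3.0, -1.0)
        fwd = sparse_flow(textured, b)
        bwd = sparse_flow(b, textured)
        inner = np.zeros(fwd.vx.shape, bool)
        inner[4:-4, 4:-4] = True
        m = fwd.valid & bwd.valid & inner
        assert np.median(np.abs(fwd.vx[m] + bwd.vx[m])) < 0.1
        assert np.median(np.abs(fwd.vy[m] + bwd.vy[m])) < 0.1

    def test_mirror_flip_negates_vx(self, textured):
        b = shifted(textured, 2.5, 1.0)
        vx, vy, _, _ = dense_lk_flow(textured, b)
        vxm, vym, _, _ = dense_lk_flow(textured[:, ::-1], b[:, ::-1])
        inner = np.s_[10:-10, 10:-10]
        assert np.median(np.abs(vxm[:, ::-1][inner] + vx[inner])) < 0.05
        assert np.median(np.abs(vym[:, ::-1][inner] - vy[inner])) < 0.05


class TestBasis:
    def test_constant_field_training_gives_uniform_pc1(self):
        fields = [_field(np.full((4, 6), c), np.zeros((4, 6))) for c in (1, 2, 5, 9)]
        basis = fit_basis(fields, K=1)
        vx1, vy1 = basis.field(0)
        assert np.allclose(np.abs(vx1), 1.0 / np.sqrt(24), atol=1e-12)
        assert np.allclose(vy1, 0.0, atol=1e-12)
        assert basis.explained_variance[0] == pytest.approx(1.0)

    def test_two_orthogonal_modes_recovered_to_sign(self):
        g = 24
        m1 = np.concatenate([np.ones(g), np.zeros(g)]) / np.sqrt(g)
        m2 = np.concatenate([np.zeros(g), np.ones(g)]) / np.sqrt(g)
        # balanced design: sample covariance of (a, b) exactly diagonal
        fields = []
        for a, b in [(3, 1), (3, -1), (-3, 1), (-3, -1)]:
            vec = a * m1 + b * m2
            fields.append(_field(vec[:g].reshape(4, 6), vec[g:].reshape(4, 6)))
        basis = fit_basis(fields, K=2)
        for comp, mode in zip(basis.components, (m1, m2)):
            assert min(
                np.abs(comp - mode).max(), np.abs(comp + mode).max()
            ) < 1e-6

    def test_pca_matches_sklearn_oracle(self):
        from sklearn.decomposition import PCA

        rng = np.random.default_rng(3)
        fields = [
            _field(rng.normal(size=(3, 5)), rng.normal(size=(3, 5)))
            for _ in range(12)
        ]
        basis = fit_basis(fields, K=3)
        X = np.stack(
            [np.concatenate([f.vx.ravel(), f.vy.ravel()]) for f in fields]
        )
        ref = PCA(n_components=3).fit(X)
        for mine, theirs in zip(basis.components, ref.components_):
            assert min(
                np.abs(mine - theirs).max(), np.abs(mine + theirs).max()
            ) < 1e-8

    def test_invalid_K_rejected(self):
        fields = [_field(np.full((2, 2), c), np.zeros((2, 2))) for c in (1, 2)]
        with pytest.raises(ParameterError):
            fit_basis(fields, K=0)
        with pytest.raises(ParameterError):
            fit_basis(fields, K=3)  # rank 1 training set

    def test_polynomial_basis_is_orthonormal(self):
        basis = polynomial_basis((8, 12), degree=2)
        G = basis.components @ basis.components.T
        assert np.allclose(G, np.eye(basis.K), atol=1e-10)
        assert basis.K == 12


class TestSmoothField:
    def test_in_span_field_reconstructed_exactly(self):
        basis = polynomial_basis((6, 8), degree=2)
        coef = np.linspace(1.0, 0.1, basis.K)
        vec = basis.components.T @ coef
        g = 48
        sparse = _field(vec[:g].reshape(6, 8), vec[g:].reshape(6, 8))
        rec = smooth_field(sparse, basis, ridge=0.0)
        assert np.allclose(rec.vx, sparse.vx, atol=1e-8)
        assert np.allclose(rec.vy, sparse.vy, atol=1e-8)

    def test_ridge_coefficients_match_normal_equations_oracle(self):
        rng = np.random.default_rng(1)
        basis = polynomial_basis((6, 8), degree=2)
        g = 48
        vec = basis.components.T @ rng.normal(size=basis.K)
        noise = rng.normal(0, 0.3, size=2 * g)
        valid = rng.random((6, 8)) > 0.3
        sparse = _field(
            (vec[:g] + noise[:g]).reshape(6, 8),
            (vec[g:] + noise[g:]).reshape(6, 8),
            valid=valid,
        )
        ridge = 0.7
        rec = smooth_field(sparse, basis, ridge=ridge)
        rows = np.concatenate([valid.ravel(), valid.ravel()])
        A = basis.components[:, rows].T
        y = np.concatenate([sparse.vx.ravel(), sparse.vy.ravel()])[rows]
        coef = np.linalg.solve(A.T @ A + ridge * np.eye(basis.K), A.T @ y)
        oracle = basis.components.T @ coef
        assert np.allclose(rec.vx.ravel(), oracle[:g], atol=1e-10)
        assert np.allclose(rec.vy.ravel(), oracle[g:], atol=1e-10)

    def test_infinite_ridge_returns_mean_field(self):
        basis = polynomial_basis((4, 4), degree=1)
        sparse = _field(np.random.default_rng(0).normal(size=(4, 4)), np.zeros((4, 4)))
        rec = smooth_field(sparse, basis, ridge=1e12)
        assert np.allclose(rec.vx, 0.0, atol=1e-9)  # analytic basis mean is 0

    def test_too_few_valid_cells_rejected(self):
        basis = polynomial_basis((4, 4), degree=2)
        valid = np.zeros((4, 4), bool)
        valid[0, :3] = True
        sparse = _field(np.ones((4, 4)), np.zeros((4, 4)), valid=valid)
        with pytest.raises(ParameterError, match="smaller K"):
            smooth_field(sparse, basis)

    def test_reconstruction_error_non_increasing_in_K(self):
        rng = np.random.default_rng(4)
        full = polynomial_basis((6, 8), degree=2)
        sparse = _field(rng.normal(size=(6, 8)), rng.normal(size=(6, 8)))
        target = np.concatenate([sparse.vx.ravel(), sparse.vy.ravel()])
        errs = []
        for K in range(1, full.K + 1):
            basis = FlowBasis(full.grid_shape, full.components[:K], full.mean)
            rec = smooth_field(sparse, basis, ridge=0.0)
            errs.append(
                np.linalg.norm(
                    np.concatenate([rec.vx.ravel(), rec.vy.ravel()]) - target
                )
            )
        assert all(a >= b - 1e-9 for a, b in zip(errs, errs[1:]))


class TestFlowPipeline:
    def test_static_stack_yields_near_zero_fields(self, textured):
        stack = ImageStack(np.stack([textured] * 3))
        fields = flow_pipeline(stack, FlowParams())
        assert len(fields) == 2
        for f in fields:
            assert np.max(np.hypot(f.vx, f.vy)) < 0.1

    def test_translated_stack_recovers_translation(self, textured):
        stack = ImageStack(
            np.stack([textured, shifted(textured, 2.0, 1.0)])
        )
        fields = flow_pipeline(stack, FlowParams(), margin_px=10)
        inner = np.s_[3:-3, 3:-3]
        assert np.median(np.abs(fields[0].vx[inner] - 2.0)) < 0.25
        assert np.median(np.abs(fields[0].vy[inner] - 1.0)) < 0.25

    def test_disciplined_simulation_flows_posterior(self, disciplined_run):
        _, _, _, _, inter = disciplined_run
        signs = [
            np.sign(np.mean(f.vx[f.valid])) for f in inter["sparse"] if f.n_valid
        ]
        assert np.mean(np.array(signs) > 0) >= 0.95
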