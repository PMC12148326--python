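"""Direction statistics: κ, variance share, binarization, Bernoulli entropy."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from migflow import (
    ParameterError,
    binarize_directions,
    binary_entropy,
    estimate_p,
    kappa,
    summarize_directionality,
    variance_share,
)
from migflow.direction import component_variance_share, magnitude_filter_vectors


def vecs(*pairs):
    return np.array(pairs, dtype=float)


class TestKappa:
    def test_degenerate_distribution_returns_common_norm(self):
        assert kappa(vecs((3, 4), (0, 5), (5, 0))) == pytest.approx(5.0)

    def test_linear_interpolation_quantile_convention(self):
        v = np.array([[n, 0.0] for n in range(1, 11)])
        assert kappa(v) == pytest.approx(9.1)

    def test_single_vector(self):
        assert kappa(vecs((0, 3))) == pytest.approx(3.0)

    def test_no_vectors_rejected(self):
        with pytest.raises(ParameterError):
            kappa(np.empty((0, 2)))

    @given(st.floats(0.1, 100.0))
    def test_positive_homogeneity(self, c):
        v = vecs((1, 2), (3, -1), (0.5, 0.5), (-2, 2), (4, 0))
        assert kappa(c * v) == pytest.approx(c * kappa(v), rel=1e-9)


class TestVarianceShare:
    def test_pure_x_spread_gives_share_one(self):
        assert component_variance_share(vecs((1, 0), (2, 0), (5, 0))) == 1.0

    def test_fourfold_symmetry_gives_half(self):
        v = vecs((2, 0), (0, 2), (-2, 0), (0, -2), (1, 1), (-1, 1), (-1, -1), (1, -1))
        assert component_variance_share(v) == pytest.approx(0.5)

    def test_hand_computed_oracle(self):
        import statistics

        v = vecs((1, 0), (-1, 0), (0, 2), (0, -2))
        expected = statistics.variance([1, -1, 0, 0]) / (
            statistics.variance([1, -1, 0, 0]) + statistics.variance([0, 0, 2, -2])
        )
        assert component_variance_share(v) == pytest.approx(expected)
        assert expected == pytest.approx(0.2)

    def test_magnitude_filter_drops_bottom_quantile(self):
        v = np.array([[n, 0.0] for n in range(1, 11)])
        kept = magnitude_filter_vectors(v)
        assert kept[:, 0].min() > np.quantile(np.arange(1, 11), 0.2)

    def test_degenerate_spread_is_undefined_marker(self):
        assert np.isnan(component_variance_share(vecs((1, 1), (1, 1))))

    def test_too_few_vectors_rejected(self):
        with pytest.raises(ParameterError):
            component_variance_share(vecs((1, 0)))

    @given(st.floats(0.01, 50.0))
    def test_scale_invariance(self, c):
        v = vecs((1, 2), (3, -1), (-1, 4), (2, 2), (0.5, -3))
        assert variance_share(c * v) == pytest.approx(variance_share(v), rel=1e-9)

    def test_axis_swap_complement(self):
        v = vecs((1, 2), (3, -1), (-1, 4), (2, 2), (0.5, -3))
        assert variance_share(v) + variance_share(v[:, ::-1]) == pytest.approx(1.0)


class TestBinarize:
    def test_all_positive_x_counts_right(self):
        nl, nr = binarize_directions(vecs((1, 0), (1, 5), (1, -3)), magnitude_filter=False)
        assert (nl, nr) == (0, 3)

    def test_sign_rule_excludes_zero_vx(self):
        nl, nr = binarize_directions(
            vecs((1, 0), (1, 1), (-1, 0), (0, 5)), magnitude_filter=False
        )
        assert (nl, nr) == (1, 2)

    def test_all_excluded_rejected(self):
        with pytest.raises(ParameterError):
            binarize_directions(vecs((0, 1), (0, -2)), magnitude_filter=False)

    def test_balanced_simulation_counts_near_equal(self, tmp_path):
        """A q=0.5 rendering yields near-balanced counts; the 99% bound uses
        the number of cells as the effective sample size (grid votes from
        one cell are correlated)."""
        from migflow import RunConfig, SimulationConfig, simulate_stack
        from migflow.pipeline import analyze_stack

        cfg = SimulationConfig(q=0.5, seed=21)
        stack, _ = simulate_stack(cfg)
        summary, _ = analyze_stack(stack, RunConfig(out_dir=str(tmp_path)))
        bound = 2.576 * np.sqrt(0.25 / cfg.n_cells)
        assert abs(summary.p_hat - 0.5) <= bound + 0.05


class TestEstimateP:
    def test_ratio_formula(self):
        assert estimate_p(3, 1) == pytest.approx(0.75)
        assert estimate_p(0, 7) == 0.0

    def test_matches_bernoulli_mle_oracle(self):
        from scipy.optimize import minimize_scalar

        k, n = 13, 40
        nll = lambda p: -(k * np.log(p) + (n - k) * np.log(1 - p))
        opt = minimize_scalar(nll, bounds=(1e-9, 1 - 1e-9), method="bounded")
        assert estimate_p(k, n - k) == pytest.approx(opt.x, abs=1e-6)

    def test_zero_counts_rejected(self):
        with pytest.raises(ParameterError):
            estimate_p(0, 0)


class TestBinaryEntropy:
    def test_maximum_at_half(self):
        assert binary_entropy(0.5) == 1.0

    def test_determinate_is_zero(self):
        assert binary_entropy(0.0) == 0.0
        assert binary_entropy(1.0) == 0.0

    def test_quarter_against_high_precision_oracle(self):
        import sympy

        p = sympy.Rational(1, 4)
        expected = float(-(p * sympy.log(p, 2) + (1 - p) * sympy.log(1 - p, 2)))
        assert binary_entropy(0.25) == pytest.approx(expected, abs=1e-14)

    def test_matches_scipy_bernoulli_entropy(self):
        from scipy import stats

        for p in np.linspace(0.05, 0.95, 19):
            expected = stats.bernoulli(p).entropy() / np.log(2)
            assert binary_entropy(p) == pytest.approx(float(expected), abs=1e-12)

    @pytest.mark.parametrize("p", [-0.01, 1.01, float("nan")])
    def test_out_of_range_rejected(self, p):
        with pytest.raises(ParameterError):
            binary_entropy(p)

    @given(st.floats(0.0, 1.0))
    def test_symmetry(self, p):
        assert binary_entropy(p) == pytest.approx(binary_entropy(1 - p), abs=1e-12)

    @given(st.floats(0.0, 0.499), st.floats(0.001, 0.5))
    def test_strictly_increasing_on_lower_half(self, p, dp):
        q = min(p + dp, 0.5)
        if q > p:
            assert binary_entropy(q) > binary_entropy(p)

    @given(st.floats(0.0, 1.0))
    def test_bounds(self, p):
        assert 0.0 <= binary_entropy(p) <= 1.0


class TestSummarize:
    def _fields_from(self, arrays):
        from migflow.datatypes import VectorField

        out = []
        for t, (vx, vy) in enumerate(arrays):
            vx = np.asarray(vx, float)
            out.append(
                VectorField(
                    frame_pair=(t, t + 1),
                    grid_x=np.arange(vx.shape[1]),
                    grid_y=np.arange(vx.shape[0]),
                    vx=vx,
                    vy=np.asarray(vy, float),
                    valid=np.ones(vx.shape, bool),
                )
            )
        return out

    def test_mirrored_fields_share_entropy(self):
        rng = np.random.default_rng(0)
        arrays = [(rng.normal(1, 1, (4, 5)), rng.normal(0, 1, (4, 5)))
                  for _ in range(3)]
        mirrored = [(-vx, vy) for vx, vy in arrays]
        s1 = summarize_directionality(self._fields_from(arrays))
        s2 = summarize_directionality(self._fields_from(mirrored))
        assert s1.entropy_bits == pytest.approx(s2.entropy_bits, abs=1e-12)
        assert s1.p_hat == pytest.approx(1 - s2.p_hat, abs=1e-12)

    def test_disciplined_simulation_has_low_entropy(self, disciplined_run):
        *_, summary, _ = disciplined_run
        assert summary.entropy_bits < 0.1

    def test_bidirectional_simulation_has_high_entropy_and_x_variance(
        self, tmp_path, disciplined_run
    ):
        """Bidirectional movies show near-maximal entropy and a larger 1D
        variance share than disciplined ones (opposing vx values dominate
        the motion variance)."""
        from migflow import RunConfig, SimulationConfig, simulate_stack
        from migflow.pipeline import analyze_stack

        cfg = SimulationConfig(q=0.5, seed=31)
        stack, _ = simulate_stack(cfg)
        summary, _ = analyze_stack(stack, RunConfig(out_dir=str(tmp_path)))
        assert summary.entropy_bits > 0.9
        *_, disciplined_summary, _ = disciplined_run
        assert summary.variance_share_x > disciplined_summary.variance_share_x

    def test_kappa_normalization_keeps_share_scale_invariant(self):
        rng = np.random.default_rng(5)
        arrays = [(rng.normal(1, 1, (4, 5)), rng.normal(0, 1, (4, 5)))]
        scaled = [(3.0 * vx, 3.0 * vy) for vx, vy in arrays]
        s1 = summarize_directionality(self._fields_from(arrays))
        s2 = summarize_directionality(self._fields_from(scaled))
        assert s1.variance_share_x == pytest.approx(s2.variance_share_x, abs=1e-12)
        assert s2.kappa_per_frame[0] == pytest.approx(3 * s1.kappa_per_frame[0])
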