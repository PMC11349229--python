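"""Slow feature analysis: pipeline stages, constraints, and oracles."""

import numpy as np
import pytest
from scipy.linalg import eigh as generalized_eigh
from scipy.linalg import subspace_angles

from sfacv import toysim
from sfacv.features import FeatureSeries
from sfacv.sfa import (
    SFAError,
    SFAModel,
    delta_value,
    expand,
    expansion_names,
    fit,
    normalize,
    pullback_affine,
    rank_weights,
    time_derivative,
    transform,
    whiten,
)


def _series(values, names=None, segments=(0,)):
    values = np.asarray(values, dtype=float)
    names = names or [f"f{j}" for j in range(values.shape[1])]
    return FeatureSeries(values=values, names=names,
                         segment_starts=np.array(segments))


class TestNormalize:
    def test_direct_evaluation(self):
        fs = _series(np.array([[1.0], [2.0], [3.0]]))
        out, mu, sigma = normalize(fs)
        np.testing.assert_allclose(out.values[:, 0],
                                   [-1.224745, 0.0, 1.224745], atol=1e-6)
        assert mu[0] == 2.0
        assert sigma[0] == pytest.approx(np.sqrt(2.0 / 3.0))

    def test_fixed_point(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=500)
        x = (x - x.mean()) / x.std()
        out, _, _ = normalize(_series(x[:, None]))
        np.testing.assert_allclose(out.values[:, 0], x, atol=1e-12)

    def test_constant_column_dropped_with_warning(self, caplog):
        vals = np.column_stack([np.arange(10.0), np.full(10, 3.0)])
        with caplog.at_level("WARNING", logger="sfacv.sfa"):
            out, mu, sigma = normalize(_series(vals, names=["a", "b"]))
        assert out.names == ["a"]
        assert out.values.shape[1] == 1
        assert "b" in caplog.text

    def test_all_constant_errors(self):
        with pytest.raises(SFAError, match="constant"):
            normalize(_series(np.ones((5, 2))))


class TestExpand:
    def test_order1_identity(self):
        x = np.random.default_rng(0).normal(size=(10, 3))
        assert expand(x, 1) is x

    def test_order2_row_and_count(self):
        row = np.array([[2.0, 3.0]])
        out = expand(row, 2)
        np.testing.assert_array_equal(out, [[2, 3, 4, 6, 9]])
        assert expansion_names(["c1", "c2"], 2) == \
            ["c1", "c2", "c1*c1", "c1*c2", "c2*c2"]

    def test_order2_column_count(self):
        J = 5
        x = np.random.default_rng(0).normal(size=(7, J))
        assert expand(x, 2).shape[1] == J + J * (J + 1) // 2


class TestWhiten:
    def test_correlated_gaussian_becomes_white(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(10000, 2)) @ np.array([[2.0, 0.0], [1.5, 0.3]])
        z, S, zbar, rank = whiten(x)
        assert rank == 2
        cov = z.T @ z / len(z)
        assert np.linalg.norm(cov - np.eye(2)) < 1e-8

    def test_duplicated_column_truncates_rank(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(1000, 2))
        x = np.column_stack([a, a[:, 0]])
        _, _, _, rank = whiten(x)
        assert rank == 2

    def test_white_input_stays_white(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(20000, 3))
        # pre-whiten exactly, then whiten again
        z0, *_ = whiten(x)
        z1, *_ = whiten(z0)
        cov = z1.T @ z1 / len(z1)
        assert np.linalg.norm(cov - np.eye(3)) < 1e-10

    def test_zero_signal_errors(self):
        with pytest.raises(SFAError):
            whiten(np.zeros((10, 2)))


class TestTimeDerivative:
    def test_single_segment_forward_differences(self):
        z = np.array([[0.0], [1.0], [3.0]])
        np.testing.assert_array_equal(
            time_derivative(z, np.array([0])), [[1.0], [2.0]])

    def test_differences_never_cross_boundaries(self):
        z = np.arange(6.0)[:, None]
        out = time_derivative(z, np.array([0, 3]))
        assert out.shape == (4, 1)
        np.testing.assert_array_equal(out[:, 0], [1, 1, 1, 1])
        # the row 3 - 2 (crossing the boundary) must be absent:
        z2 = np.array([[0.0], [1.0], [2.0], [10.0], [11.0], [12.0]])
        out2 = time_derivative(z2, np.array([0, 3]))
        np.testing.assert_array_equal(out2[:, 0], [1, 1, 1, 1])

    def test_constant_series_zero(self):
        out = time_derivative(np.ones((8, 2)), np.array([0, 4]))
        np.testing.assert_array_equal(out, np.zeros((6, 2)))

    def test_short_segment_errors(self):
        with pytest.raises(SFAError):
            time_derivative(np.zeros((3, 1)), np.array([0, 2]))


class TestFit:
    def test_wiskott_signal_quadratic_recovery(self):
        """The slowest quadratic feature of the canonical two-component
        signal must be (proportional to) the hidden driver sin(t)."""
        n, dt = 5000, 0.002 * 2 * np.pi
        fs = toysim.wiskott_signal(n, dt)
        model = fit(fs, order=2, n_components=2)
        y = transform(model, fs)
        t = np.arange(n) * dt
        corr = np.corrcoef(y.values[:, 0], np.sin(t))[0, 1]
        assert abs(corr) >= 0.99

    def test_flip_dihedral_attribution(self, flip_model):
        """>= 80% of SF1's squared pulled-back weight mass must sit on the
        flipping dihedral's sin/cos columns."""
        ranking = rank_weights(flip_model, 1)
        total = sum(c ** 2 for _, c in ranking)
        flip = sum(c ** 2 for n, c in ranking if n.endswith("_TRP41"))
        assert flip / total >= 0.80
        assert {n for n, _ in ranking[:2]} == \
            {"sin_chi1_TRP41", "cos_chi1_TRP41"}

    def test_eigenvalues_ascending_nonnegative(self, flip_model):
        lam = flip_model.eigenvalues
        assert np.all(lam >= 0)
        assert np.all(np.diff(lam) >= 0)

    def test_too_many_components_errors(self, random_features):
        with pytest.raises(SFAError, match="rank"):
            fit(random_features, order=1, n_components=99)


class TestTrainingConstraints:
    """The defining output constraints, checked on training data."""

    @pytest.mark.parametrize("order", [1, 2])
    def test_zero_mean_unit_variance_decorrelated(self, random_features,
                                                  order):
        model = fit(random_features, order=order, n_components=3)
        y = transform(model, random_features).values
        T = len(y)
        assert np.abs(y.mean(axis=0)).max() < 1e-8
        second = y.T @ y / T
        assert np.abs(np.diag(second) - 1).max() < 1e-6
        off = second - np.diag(np.diag(second))
        assert np.abs(off).max() < 1e-6

    def test_delta_equals_eigenvalue(self, random_features):
        model = fit(random_features, order=1, n_components=3)
        y = transform(model, random_features)
        for k in range(3):
            d = delta_value(y.values[:, k], y.segment_starts)
            assert d == pytest.approx(model.eigenvalues[k], abs=1e-8)


class TestTransform:
    def test_evaluation_at_training_mean_is_zero(self, random_features):
        model = fit(random_features, order=1, n_components=2)
        mean_row = random_features.values.mean(axis=0)
        probe = FeatureSeries(
            values=np.vstack([mean_row, mean_row]),
            names=list(random_features.names))
        y = transform(model, probe)
        np.testing.assert_allclose(y.values, 0.0, atol=1e-10)

    def test_column_permutation_invariance(self, random_features):
        model = fit(random_features, order=1, n_components=2)
        y0 = transform(model, random_features).values
        perm = [3, 0, 5, 1, 4, 2]
        permuted = FeatureSeries(
            values=random_features.values[:, perm],
            names=[random_features.names[j] for j in perm],
            segment_starts=random_features.segment_starts.copy())
        y1 = transform(model, permuted).values
        np.testing.assert_allclose(y0, y1, atol=1e-12)

    def test_scale_invariance_of_outputs(self, random_features):
        """Multiplying a raw input column by a constant changes nothing:
        the normalization absorbs it."""
        model = fit(random_features, order=1, n_components=2)
        y0 = transform(model, random_features).values
        scaled_vals = random_features.values.copy()
        scaled_vals[:, 2] *= -7.5
        scaled = FeatureSeries(values=scaled_vals,
                               names=list(random_features.names),
                               segment_starts=random_features.segment_starts)
        model2 = fit(scaled, order=1, n_components=2)
        y1 = transform(model2, scaled).values
        np.testing.assert_allclose(np.abs(y0), np.abs(y1), atol=1e-8)

    def test_missing_and_unknown_features_error(self, random_features):
        model = fit(random_features, order=1, n_components=2)
        bad = FeatureSeries(values=np.zeros((4, 2)), names=["f0", "nope"])
        with pytest.raises(SFAError):
            transform(model, bad)


class TestOracleEquivalence:
    """fit() must solve the generalized eigenproblem
    Cov(cdot) w = lambda Cov(c) w on the normalized data."""

    @pytest.mark.parametrize("seed", range(5))
    def test_against_generalized_eigenproblem(self, seed):
        rng = np.random.default_rng(seed)
        T, J = 10000, 12
        # smooth mixture of AR(1) processes with varied time constants
        phis = rng.uniform(0.2, 0.999, size=J)
        eps = rng.normal(size=(T, J))
        src = np.empty((T, J))
        src[0] = eps[0]
        for t in range(1, T):
            src[t] = phis * src[t - 1] + eps[t]
        x = src @ rng.normal(size=(J, J))
        fs = _series(x)

        n_comp = 4
        model = fit(fs, order=1, n_components=n_comp)

        normed, _, _ = normalize(fs)
        c = normed.values
        dc = np.diff(c, axis=0)
        A = dc.T @ dc / len(dc)          # raw second moment of differences
        B = c.T @ c / len(c)             # second moment (mean is zero)
        evals, evecs = generalized_eigh(A, B)

        np.testing.assert_allclose(model.eigenvalues, evals[:n_comp],
                                   rtol=1e-8, atol=1e-12)
        # compare spanned subspaces in input space
        ours = (model.weights @ model.sphering).T    # (J, n_comp)
        angles = subspace_angles(ours, evecs[:, :n_comp])
        assert angles.max() < 1e-6

    def test_transform_matches_oracle_series(self):
        rng = np.random.default_rng(99)
        T, J = 5000, 5
        x = np.cumsum(rng.normal(size=(T, J)), axis=0)
        fs = _series(x)
        model = fit(fs, order=1, n_components=2)
        y = transform(model, fs).values

        normed, _, _ = normalize(fs)
        c = normed.values
        dc = np.diff(c, axis=0)
        A = dc.T @ dc / len(dc)
        B = c.T @ c / len(c)
        _, evecs = generalized_eigh(A, B)
        for k in range(2):
            ref = c @ evecs[:, k]
            ref /= ref.std()
            err = min(np.sqrt(np.mean((y[:, k] - ref) ** 2)),
                      np.sqrt(np.mean((y[:, k] + ref) ** 2)))
            assert err < 1e-6


class TestDeltaValue:
    def test_constant_series_zero(self):
        assert delta_value(np.ones(50), np.array([0])) == 0.0

    def test_sine_small_angle_formula(self):
        N = 10000
        t = np.arange(N)
        y = np.sqrt(2.0) * np.sin(2 * np.pi * t / N)
        d = delta_value(y, np.array([0]))
        assert d == pytest.approx((2 * np.pi / N) ** 2, rel=0.01)

    def test_lag1_autocorrelation_identity(self):
        """For one long segment, lambda_k ~ 2 (1 - rho_k) with rho_k the
        lag-1 autocorrelation of y_k, up to O(1/T) boundary terms."""
        rng = np.random.default_rng(12)
        T, J = 100000, 4
        phis = np.array([0.999, 0.9, 0.5, 0.1])
        eps = rng.normal(size=(T, J))
        src = np.empty((T, J))
        src[0] = eps[0]
        for t in range(1, T):
            src[t] = phis * src[t - 1] + eps[t]
        fs = _series(src @ rng.normal(size=(J, J)))
        model = fit(fs, order=1, n_components=4)
        y = transform(model, fs).values
        for k in range(4):
            rho = np.corrcoef(y[:-1, k], y[1:, k])[0, 1]
            assert model.eigenvalues[k] == pytest.approx(
                2 * (1 - rho), abs=1e-3)


class TestRankWeights:
    def test_dominant_feature_ranks_first(self):
        rng = np.random.default_rng(4)
        T = 5000
        slow = np.cumsum(rng.normal(size=T))
        vals = np.column_stack([rng.normal(size=T), rng.normal(size=T),
                                rng.normal(size=T), slow])
        model = fit(_series(vals, names=["a", "b", "c", "d"]),
                    order=1, n_components=1)
        ranking = rank_weights(model, 1)
        assert ranking[0][0] == "d"

    def test_affine_map_reproduces_transform(self, flip_model,
                                             flip_features):
        offset, coeffs = pullback_affine(flip_model, 1)
        pos = {n: j for j, n in enumerate(flip_features.names)}
        cols = [pos[n] for n in flip_model.names]
        manual = flip_features.values[:200, cols] @ coeffs + offset
        y = transform(flip_model, flip_features).values[:200, 0]
        np.testing.assert_allclose(manual, y, atol=1e-8)

    def test_sign_convention_largest_coefficient_positive(self, flip_model):
        for k in (1, 2):
            ranking = rank_weights(flip_model, k)
            assert ranking[0][1] > 0

    def test_component_out_of_range(self, flip_model):
        with pytest.raises(SFAError):
            rank_weights(flip_model, 3)


class TestSerialization:
    def test_round_trip_bit_stable(self, flip_model, flip_features,
                                   tmp_path):
        path = tmp_path / "model.json"
        flip_model.save(path)
        first = path.read_bytes()
        back = SFAModel.load(path)
        back.save(tmp_path / "model2.json")
        assert (tmp_path / "model2.json").read_bytes() == first
        y0 = transform(flip_model, flip_features).values[:100]
        y1 = transform(back, flip_features).values[:100]
        np.testing.assert_array_equal(y0, y1)

    def test_wrong_format_rejected(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text('{"format": "something-else"}')
        with pytest.raises(SFAError):
            SFAModel.load(path)
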