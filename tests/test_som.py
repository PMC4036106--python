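import dataclasses
import math

import numpy as np
import pytest

import somscape as ss
from somscape.exceptions import ValidationError
from somscape.som import _bmu_indices

from reference import ref_batch_epoch, ref_bmu, ref_quantization_error


def _fps(X):
    X = np.asarray(X, dtype=float)
    return ss.Fingerprints(X, [f"p{i}" for i in range(X.shape[0])], X.shape[1])


def _svd_stub(singular_values, k=None):
    s = np.asarray(singular_values, dtype=float)
    k = k or len(s)
    return ss.SVDResult(
        left_vectors=np.eye(max(k, 2), k)[: max(k, 2)],
        singular_values=s,
        right_vectors=np.eye(max(k, 2), k),
        k=k,
        column_mean=np.zeros(max(k, 2)),
    )


class TestLinearInit:
    def test_corner_and_center_of_3x3(self):
        lat = ss.init_lattice_linear(_svd_stub([2.0, 1.0, 0.5], k=3), 3, 3)
        np.testing.assert_allclose(lat.weights[0, 0], [-2, -1, 0])
        np.testing.assert_allclose(lat.weights[1, 1], [0, 0, 0])
        np.testing.assert_allclose(lat.weights[2, 2], [2, 1, 0])

    def test_rank_one_data_varies_only_on_first_axis(self):
        lat = ss.init_lattice_linear(_svd_stub([3.0, 0.0]), 4, 4)
        assert np.all(lat.weights[:, :, 1] == 0)
        assert np.ptp(lat.weights[:, :, 0]) == pytest.approx(6.0)

    def test_matches_direct_formula_on_4x5(self):
        s = [2.5, 1.25, 0.8]
        lat = ss.init_lattice_linear(_svd_stub(s, k=3), 4, 5)
        for r in range(4):
            for c in range(5):
                a = -1 + 2 * r / 3
                b = -1 + 2 * c / 4
                np.testing.assert_allclose(lat.weights[r, c], [a * s[0], b * s[1], 0.0], atol=1e-12)

    def test_too_small_lattice_rejected(self):
        with pytest.raises(ValidationError):
            ss.init_lattice_linear(_svd_stub([1.0, 1.0]), 1, 5)


class TestBMU:
    def test_exact_weight_match(self, random_lattice):
        lat = random_lattice(0)
        assert ss.best_matching_unit(lat, lat.weights[3, 4]) == (3, 4)

    def test_tie_breaks_to_lowest_row_major_index(self):
        lat = ss.Lattice(3, 3, np.ones((3, 3, 2)), 2)
        assert ss.best_matching_unit(lat, [5.0, 5.0]) == (0, 0)

    def test_matches_exhaustive_scan(self, random_lattice):
        rng = np.random.default_rng(42)
        lat = random_lattice(1, rows=6, cols=6)
        for x in rng.normal(size=(10, 3)):
            assert ss.best_matching_unit(lat, x) == ref_bmu(lat.weights, x)

    def test_dimension_mismatch(self, random_lattice):
        with pytest.raises(ValidationError):
            ss.best_matching_unit(random_lattice(0), [1.0])


class TestQuantizationError:
    def test_zero_when_patterns_sit_on_neurons(self, random_lattice):
        lat = random_lattice(2)
        fps = _fps(lat.weights[[0, 1, 2], [0, 3, 5]])
        assert ss.quantization_error(lat, fps) == 0.0

    def test_single_pattern_distance(self):
        lat = ss.Lattice(2, 2, np.zeros((2, 2, 2)), 2)
        fps = _fps([[3.0, 4.0]])
        assert ss.quantization_error(lat, fps) == pytest.approx(5.0)

    def test_matches_brute_force(self, random_lattice):
        rng = np.random.default_rng(8)
        lat = random_lattice(3, rows=3, cols=3)
        fps = _fps(rng.normal(size=(5, 3)))
        want = ref_quantization_error(lat.weights, fps.vectors)
        assert ss.quantization_error(lat, fps) == pytest.approx(want, abs=1e-10)

    def test_empty_fingerprints_rejected(self, random_lattice):
        with pytest.raises(ValidationError):
            ss.quantization_error(random_lattice(0), _fps(np.zeros((0, 3))))


class TestBatchEpoch:
    def test_single_pattern_alpha_one_pulls_all_neurons(self, random_lattice):
        lat = random_lattice(4)
        x = np.array([1.5, -2.0, 0.5])
        out = ss.batch_epoch(lat, _fps(x[None, :]), sigma=2.0, alpha=1.0)
        np.testing.assert_allclose(out.weights, np.broadcast_to(x, out.weights.shape), atol=1e-12)

    def test_sigma_to_zero_is_kmeans_update(self, random_lattice):
        # delta neighborhood: mapped neurons become centroids, others frozen
        rng = np.random.default_rng(12)
        lat = random_lattice(5, rows=3, cols=3)
        X = rng.normal(size=(8, 3))
        out = ss.batch_epoch(lat, _fps(X), sigma=1e-6, alpha=1.0)
        flat = _bmu_indices(lat, X)
        for j in range(9):
            members = X[flat == j]
            want = members.mean(axis=0) if len(members) else lat.flat_weights()[j]
            np.testing.assert_allclose(out.flat_weights()[j], want, atol=1e-10)

    def test_matches_double_loop_reference(self, random_lattice):
        rng = np.random.default_rng(77)
        lat = random_lattice(6, rows=3, cols=4)
        X = rng.normal(size=(8, 3))
        out = ss.batch_epoch(lat, _fps(X), sigma=1.5, alpha=0.5)
        want = ref_batch_epoch(lat.weights, X, 1.5, 0.5)
        np.testing.assert_allclose(out.weights, want, atol=1e-10)

    def test_update_stays_in_coordinate_hull(self, random_lattice):
        # convexity: each new weight is a convex blend of the old weight
        # and the data, so it cannot leave their coordinate-wise bounds
        rng = np.random.default_rng(55)
        for seed in range(5):
            lat = random_lattice(seed)
            X = rng.normal(size=(6, 3))
            out = ss.batch_epoch(lat, _fps(X), sigma=1.0, alpha=0.7)
            lo = np.minimum(lat.weights, X.min(axis=0))
            hi = np.maximum(lat.weights, X.max(axis=0))
            assert np.all(out.weights >= lo - 1e-12)
            assert np.all(out.weights <= hi + 1e-12)

    def test_invalid_sigma_alpha(self, random_lattice):
        lat = random_lattice(0)
        fps = _fps(np.zeros((2, 3)))
        with pytest.raises(ValidationError):
            ss.batch_epoch(lat, fps, sigma=0.0, alpha=0.5)
        with pytest.raises(ValidationError):
            ss.batch_epoch(lat, fps, sigma=1.0, alpha=1.5)


class TestAdaptLearning:
    def test_no_change_stops(self):
        cfg = ss.FLSOMConfig()
        sigma, alpha, stop = ss.adapt_learning(1.0, 1.0, 2.0, 0.5, cfg)
        assert stop
        assert (sigma, alpha) != (None, None)

    def test_productive_phase_cools_fast(self):
        cfg = ss.FLSOMConfig()
        sigma, alpha, stop = ss.adapt_learning(1.0, 0.5, 2.0, 0.5, cfg)
        assert sigma == pytest.approx(2.0 * cfg.decay_fast)
        assert alpha == 0.5
        assert not stop

    def test_slow_phase_damps_alpha(self):
        cfg = ss.FLSOMConfig(stop_epsilon=1e-6)
        sigma, alpha, stop = ss.adapt_learning(1.0, 0.999, 2.0, 0.5, cfg)
        assert sigma == pytest.approx(2.0 * cfg.decay_slow)
        assert alpha == pytest.approx(0.45)
        assert not stop

    def test_worsening_halves_alpha_keeps_sigma(self):
        cfg = ss.FLSOMConfig()
        sigma, alpha, stop = ss.adapt_learning(1.0, 1.2, 2.0, 0.5, cfg)
        assert sigma == 2.0
        assert alpha == pytest.approx(0.25)
        assert not stop

    def test_floors_respected(self):
        cfg = ss.FLSOMConfig(sigma_min=1.0, alpha_min=0.05)
        sigma, alpha, _ = ss.adapt_learning(1.0, 0.5, 1.05, 0.06, cfg)
        assert sigma == 1.0
        sigma, alpha, _ = ss.adapt_learning(1.0, 1.2, 1.0, 0.06, cfg)
        assert alpha == 0.05

    def test_infinite_qe_prev_never_stops(self):
        cfg = ss.FLSOMConfig()
        _, _, stop = ss.adapt_learning(math.inf, 0.0, 2.0, 1.0, cfg)
        assert not stop


class TestTraining:
    def test_single_pattern_converges_to_zero_qe(self):
        svd = _svd_stub([1.0, 0.5])
        fps = _fps([[0.3, -0.2]])
        trained = ss.train_flsom(fps, 4, 4, svd)
        assert trained.stopped_by == "delta_qe"
        assert trained.qe_trace[-1] == pytest.approx(0.0, abs=1e-4)

    def test_runs_are_bit_identical(self, small_blobs):
        svd = ss.truncated_svd(small_blobs.matrix, k=3)
        fps = ss.project_fingerprints(small_blobs.matrix, svd)
        a = ss.train_flsom(fps, 10, 10, svd)
        b = ss.train_flsom(fps, 10, 10, svd)
        assert a.qe_trace == b.qe_trace
        np.testing.assert_array_equal(a.lattice.weights, b.lattice.weights)
        np.testing.assert_array_equal(a.bmu_of_pattern, b.bmu_of_pattern)

    def test_final_qe_not_above_initial(self, small_trained):
        _, _, trained = small_trained
        assert trained.qe_trace[-1] <= trained.qe_trace[0]

    def test_stops_by_delta_qe_before_max_epochs(self, small_trained):
        _, _, trained = small_trained
        assert trained.stopped_by == "delta_qe"
        assert trained.epochs_run < ss.FLSOMConfig().max_epochs

    def test_translation_invariance(self, small_blobs):
        # shifting all fingerprints shifts the map but not the QE trace
        svd = ss.truncated_svd(small_blobs.matrix, k=3)
        fps = ss.project_fingerprints(small_blobs.matrix, svd)
        shift = np.array([100.0, -50.0, 25.0])
        shifted = ss.Fingerprints(fps.vectors + shift, fps.pattern_ids, fps.k)
        a = ss.train_flsom(fps, 8, 8, svd)
        b = ss.train_flsom(shifted, 8, 8, svd)
        np.testing.assert_allclose(a.qe_trace, b.qe_trace, atol=1e-8)
        np.testing.assert_allclose(a.lattice.weights + shift, b.lattice.weights, atol=1e-8)

    def test_bmus_inside_lattice(self, small_trained):
        _, _, trained = small_trained
        assert np.all(trained.bmu_of_pattern >= 0)
        assert np.all(trained.bmu_of_pattern[:, 0] < trained.lattice.rows)
        assert np.all(trained.bmu_of_pattern[:, 1] < trained.lattice.cols)

    def test_qe_trace_length_equals_epochs(self, small_trained):
        _, _, trained = small_trained
        assert len(trained.qe_trace) == trained.epochs_run


class TestConfig:
    @pytest.mark.parametrize(
        "bad",
        [
            dict(sigma0=0.5, sigma_min=1.0),
            dict(alpha0=1.5),
            dict(alpha_min=0.0),
            dict(decay_fast=0.99, decay_slow=0.9),
            dict(stop_epsilon=0.0),
            dict(max_epochs=0),
        ],
    )
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(ValidationError):
            ss.FLSOMConfig(**bad)

    def test_default_sigma0_is_half_max_dimension(self):
        assert ss.FLSOMConfig().resolved_sigma0(30, 20) == 15.0

    def test_suggested_size_covers_emergent_regime(self):
        svd = _svd_stub([4.0, 2.0])
        rows, cols = ss.suggest_lattice_size(50, svd)
        assert rows * cols >= 5 * 50
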