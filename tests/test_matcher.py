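"""Point-set matching network: invariance, loss, training, assignment."""

import warnings

import numpy as np
import pytest

import shwfs
from shwfs.centroid import CentroidSet
from shwfs.forward_model import build_geometry, render_frame
from shwfs.matcher import (
    MatchNetwork,
    SamplerConfig,
    TrainingConfig,
    _bijective_assignment,
    _softmax,
    assign,
    assignment_warnings,
    accuracy,
    make_dataset,
    normalize_points,
    softmax_loss,
    train,
)
from shwfs.zernike import ZernikeCoefficients


@pytest.fixture(scope="module")
def tiny_geometry():
    """Four-lenslet (2x2) sensor."""
    return build_geometry(grid_shape=2, mask_rule="full")


@pytest.fixture(scope="module")
def tiny_net(tiny_geometry):
    """Matcher trained on 200 wavefronts of the tiny sensor."""
    train_set, test_set = make_dataset(
        200,
        tiny_geometry,
        sampler=SamplerConfig(rms_range=(0.2, 4.0)),
        split=0.9,
        rng_seed=3,
        method="extract",
    )
    net = MatchNetwork(tiny_geometry.k_effective, seed=0)
    history = train(net, train_set, TrainingConfig(epochs=20, batch_size=8, seed=0))
    return net, history, train_set, test_set


class TestForward:
    def test_probabilities_normalized_untrained(self):
        net = MatchNetwork(k_classes=6, seed=1)
        pts = np.random.default_rng(0).uniform(-1, 1, (6, 2))
        p = net.forward(pts)
        assert p.shape == (6, 6)
        assert np.all(p >= 0)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_permutation_equivariance_of_outputs(self):
        net = MatchNetwork(k_classes=10, seed=2)
        rng = np.random.default_rng(4)
        pts = rng.uniform(-1, 1, (10, 2))
        perm = rng.permutation(10)
        p1 = net.forward(pts)
        p2 = net.forward(pts[perm])
        np.testing.assert_allclose(p1[perm], p2, atol=1e-6)

    def test_global_feature_identical_under_permutation(self):
        net = MatchNetwork(k_classes=10, seed=2)
        rng = np.random.default_rng(4)
        pts = rng.uniform(-1, 1, (10, 2))
        g1 = net.global_feature(pts)
        g2 = net.global_feature(pts[rng.permutation(10)])
        assert np.array_equal(g1, g2)

    def test_wrong_point_count_rejected(self):
        net = MatchNetwork(k_classes=4, seed=0)
        with pytest.raises(ValueError):
            net.forward(np.zeros((3, 4, 5)))


class TestSoftmaxLoss:
    def test_perfect_prediction_zero_loss(self):
        y = np.eye(5)
        assert softmax_loss(y, y) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_prediction_log_c(self):
        c = 7
        pred = np.full((3, c), 1.0 / c)
        labels = np.eye(c)[[0, 3, 6]]
        assert softmax_loss(pred, labels) == pytest.approx(np.log(c), rel=1e-9)

    def test_matches_direct_sum(self):
        rng = np.random.default_rng(1)
        logits = rng.standard_normal((4, 6))
        pred = _softmax(logits)
        labels = np.eye(6)[rng.integers(0, 6, 4)]
        direct = -sum(
            labels[i, j] * np.log(pred[i, j]) for i in range(4) for j in range(6)
        )
        assert softmax_loss(pred, labels, reduction="sum") == pytest.approx(
            direct, rel=1e-9
        )

    def test_unnormalized_labels_rejected(self):
        with pytest.raises(ValueError):
            softmax_loss(np.full((2, 3), 1 / 3), np.full((2, 3), 0.4))


class TestDataset:
    def test_split_sizes_tiny(self, tiny_geometry):
        a, b = make_dataset(
            2, tiny_geometry, split=0.5, rng_seed=0, method="analytic"
        )
        assert len(a) == 1 and len(b) == 1

    def test_protocol_split_nine_to_one(self, tiny_geometry):
        """10,000 wavefronts split 0.9 -> 9000 train / 1000 test."""
        a, b = make_dataset(
            10_000, tiny_geometry, split=0.9, rng_seed=1, method="analytic"
        )
        assert len(a) == 9000 and len(b) == 1000

    def test_labels_cover_all_lenslets(self, tiny_geometry):
        a, _ = make_dataset(
            10, tiny_geometry, split=0.9, rng_seed=2, method="extract",
            sampler=SamplerConfig(rms_range=(0.2, 2.0)),
        )
        for row in a.labels:
            assert sorted(row) == list(range(tiny_geometry.k_effective))

    def test_normalization_range(self, tiny_geometry):
        pts = normalize_points(tiny_geometry.reference_centers, tiny_geometry)
        assert np.all(np.abs(pts) <= 1.0)


class TestTraining:
    def test_loss_decreases_and_accuracy(self, tiny_net):
        net, history, train_set, test_set = tiny_net
        assert history["epoch_loss"][-1] < history["epoch_loss"][0]
        assert accuracy(net, test_set) >= 0.95

    def test_beats_nearest_center_baseline_beyond_half_pitch(self, net8, geometry8):
        """Once spots move past half a pitch (22 waves of trefoil on the
        scaled sensor) the nearest-reference rule starts mislabelling while
        the trained matcher keeps labelling correctly."""
        from scipy.spatial.distance import cdist
        from shwfs.zernike import index_from_osa

        c = ZernikeCoefficients.single_mode(index_from_osa(6), 22.0, 15)
        frame, gt = render_frame(c, geometry8)
        cset = shwfs.extract_centroids(frame, shwfs.gaussian_template(1.0))
        d = cdist(cset.points, gt.true_centers)
        assert d.min(axis=1).max() < 0.5  # extraction itself is clean
        truth = d.argmin(axis=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            asg = assign(net8, cset, geometry8)
        net_acc = (asg.mapping == truth).mean()
        nearest = cdist(cset.points, geometry8.reference_centers).argmin(axis=1)
        base_acc = (nearest == truth).mean()
        assert net_acc > base_acc

    def test_identical_seeds_identical_loss(self, tiny_geometry):
        train_set, _ = make_dataset(
            40, tiny_geometry, split=0.9, rng_seed=5, method="analytic",
            sampler=SamplerConfig(rms_range=(0.2, 4.0)),
        )
        runs = []
        for _ in range(2):
            net = MatchNetwork(tiny_geometry.k_effective, seed=0)
            h = train(net, train_set, TrainingConfig(epochs=3, batch_size=8, seed=9))
            runs.append(h["epoch_loss"][-1])
        assert runs[0] == runs[1]

    def test_empty_training_set_rejected(self, tiny_geometry):
        net = MatchNetwork(4, seed=0)
        from shwfs.matcher import PointDataset

        with pytest.raises(ValueError):
            train(net, PointDataset(np.zeros((0, 4, 2)), np.zeros((0, 4), int)))


class TestAssignment:
    def test_flat_wavefront_identity(self, tiny_net, tiny_geometry):
        net, _, _, _ = tiny_net
        frame, _ = render_frame(ZernikeCoefficients(np.zeros(15)), tiny_geometry)
        cset = shwfs.cog_all(frame, tiny_geometry)  # lenslet order
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            asg = assign(net, cset, tiny_geometry)
        np.testing.assert_array_equal(asg.mapping, np.arange(tiny_geometry.k_effective))

    def test_assignment_invariant_to_point_order(self, tiny_net, tiny_geometry):
        net, _, _, _ = tiny_net
        frame, _ = render_frame(ZernikeCoefficients(np.zeros(15)), tiny_geometry)
        cset = shwfs.cog_all(frame, tiny_geometry)
        perm = np.array([2, 0, 3, 1])
        permuted = CentroidSet(points=cset.points[perm], source="classical")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a1 = assign(net, cset, tiny_geometry)
            a2 = assign(net, permuted, tiny_geometry)
        pairs1 = {(tuple(cset.points[i]), a1.mapping[i]) for i in range(4)}
        pairs2 = {(tuple(permuted.points[i]), a2.mapping[i]) for i in range(4)}
        assert pairs1 == pairs2

    def test_greedy_and_optimal_are_bijections(self):
        rng = np.random.default_rng(0)
        probs = rng.dirichlet(np.ones(6), size=6)
        for method in ("greedy", "optimal"):
            mapping, conf = _bijective_assignment(probs, method)
            assert sorted(mapping) == list(range(6))
            assert np.all(conf >= 0)

    def test_wrong_centroid_count_rejected(self, tiny_net, tiny_geometry):
        net, _, _, _ = tiny_net
        with pytest.raises(ValueError):
            assign(net, CentroidSet(points=np.zeros((2, 2))), tiny_geometry)

    def test_swap_ambiguity_warning(self):
        """Two points sharing the same top-2 candidate lenslets (the
        irreducible swap degeneracy) are flagged."""
        probs = np.array(
            [
                [0.49, 0.48, 0.02, 0.01],
                [0.47, 0.50, 0.02, 0.01],
                [0.01, 0.01, 0.97, 0.01],
                [0.01, 0.01, 0.01, 0.97],
            ]
        )
        pts = np.array([[10.0, 10.0], [30.0, 10.0], [10.0, 30.0], [30.0, 30.0]])
        warns = assignment_warnings(probs, pts)
        assert any("swap" in w for w in warns)

    def test_merged_spot_warning_from_simulator(self, tiny_net, tiny_geometry):
        """Two overlapping spots (closer than the resolvable separation)
        raise the merged-spot degeneracy warning end to end."""
        net, _, _, _ = tiny_net
        g = tiny_geometry
        pts = g.reference_centers.astype(float).copy()
        mid = (pts[0] + pts[1]) / 2.0
        pts[0] = mid - [0.6, 0.0]
        pts[1] = mid + [0.6, 0.0]
        cset = CentroidSet(points=pts)
        with pytest.warns(UserWarning, match="overlapping|merged"):
            assign(net, cset, g)


class TestPersistence:
    def test_save_load_roundtrip(self, tmp_path, tiny_geometry):
        net = MatchNetwork(4, seed=3)
        pts = np.random.default_rng(0).uniform(-1, 1, (4, 2))
        p_before = net.forward(pts)
        path = tmp_path / "net.npz"
        net.save(path, tiny_geometry)
        net2 = MatchNetwork.load(path, tiny_geometry)
        np.testing.assert_array_equal(p_before, net2.forward(pts))

    def test_geometry_mismatch_warns(self, tmp_path, tiny_geometry):
        net = MatchNetwork(4, seed=3)
        path = tmp_path / "net.npz"
        net.save(path, tiny_geometry)
        other = build_geometry(grid_shape=2, mask_rule="full", focal_length_um=9999.0)
        with pytest.warns(UserWarning, match="geometry"):
            MatchNetwork.load(path, other)
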