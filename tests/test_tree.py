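"""Regression tree: sampling, split objective, training, traversal, I/O."""

import json

import numpy as np
import pytest

import colonialwalk as cw
from colonialwalk.features import FeatureEvaluator, propose_param_array
from colonialwalk.tree import (
    LeafNode,
    ModelFormatError,
    SampleSet,
    SplitNode,
    _sum_sq_dev,
)


def unit_rows(rng, n):
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def grad_volume(shape=(16, 16, 16)):
    """data[x, y, z] = x + 1: features can read off position along X."""
    x = np.arange(shape[0], dtype=np.float32) + 1.0
    return cw.Volume(np.broadcast_to(x[:, None, None], shape).copy())


class TestMakeSamples:
    def test_stride_grid_count(self, small_volume):
        s = cw.make_samples(small_volume, target=(3.5, 3.5, 3.5), stride=8)
        assert len(s) == 2 * 2 * 2

    def test_global_sample_count_at_scale(self):
        vol = cw.Volume(np.ones((128, 128, 64), dtype=np.float32))
        s = cw.make_samples(vol, target=(60.5, 60.5, 30.5), stride=4)
        assert len(s) == 32 * 32 * 16

    @pytest.mark.parametrize(
        "x,target,expected",
        [
            ((0, 0, 0), (3, 0, 0), (1.0, 0.0, 0.0)),
            ((0, 0, 0), (1, 2, 2), (1 / 3, 2 / 3, 2 / 3)),
        ],
    )
    def test_unit_directions(self, small_volume, x, target, expected):
        s = cw.make_samples(small_volume, target=target, stride=1)
        i = np.flatnonzero((s.pos == np.asarray(x)).all(axis=1))[0]
        assert np.allclose(s.u[i], expected)
        assert np.allclose(np.linalg.norm(s.u, axis=1), 1.0, atol=1e-9)

    def test_target_voxel_excluded(self, small_volume):
        s = cw.make_samples(small_volume, target=(4, 4, 4), stride=4)
        assert not ((s.pos == 4).all(axis=1)).any()

    def test_target_outside_rejected(self, small_volume):
        with pytest.raises(cw.ValidationError):
            cw.make_samples(small_volume, target=(99, 0, 0), stride=1)


class TestSplitObjective:
    def test_identical_directions_give_zero(self):
        d = np.tile([0.0, 0.0, 1.0], (5, 1))
        assert cw.split_objective(d, d[:2]) == pytest.approx(0.0)

    def test_two_direction_side_with_empty_other(self):
        left = np.array([[1.0, 0, 0], [0, 1.0, 0]])
        # mean (0.5, 0.5, 0); each deviation has squared norm 0.5.
        assert cw.split_objective(left, np.empty((0, 3))) == pytest.approx(1.0)

    def test_both_empty_is_an_error(self):
        with pytest.raises(cw.ValidationError):
            cw.split_objective(np.empty((0, 3)), np.empty((0, 3)))

    def test_matches_brute_force_mean_deviation(self, rng):
        for _ in range(20):
            l = unit_rows(rng, rng.integers(1, 15))
            r = unit_rows(rng, rng.integers(1, 15))
            brute = sum(
                float(np.sum((s - s.mean(axis=0)) ** 2)) for s in (l, r) if len(s)
            )
            assert cw.split_objective(l, r) == pytest.approx(brute, abs=1e-9)

    def test_any_partition_no_worse_than_unsplit(self, rng):
        """Within-group SS never exceeds the total SS of the pooled set."""
        for _ in range(20):
            d = unit_rows(rng, 20)
            total = float(np.sum((d - d.mean(axis=0)) ** 2))
            mask = rng.random(20) < rng.random()
            if mask.all() or not mask.any():
                continue
            assert cw.split_objective(d[mask], d[~mask]) <= total + 1e-9


class TestBestSplit:
    def make_set(self, vol, pos, u):
        return SampleSet(np.asarray(pos), np.zeros(len(pos)), np.asarray(u))

    def test_perfect_split_reaches_zero_objective(self, rng):
        vol = grad_volume()
        # Samples on both sides of x = 8 with opposite target directions.
        pos = [(2, 8, 8), (3, 8, 8), (13, 8, 8), (14, 8, 8)]
        u = [(1, 0, 0), (1, 0, 0), (-1, 0, 0), (-1, 0, 0)]
        s = self.make_set(vol, pos, u)
        got = cw.best_split(s, [vol], cw.OffsetRange(4, 4, 4), 60, 8, rng)
        assert got is not None
        params, tau, left, right = got
        assert cw.split_objective(left.u, right.u) == pytest.approx(0.0, abs=1e-12)

    def test_identical_directions_return_first_candidate(self, rng):
        vol = grad_volume()
        pos = [(i + 2, 8, 8) for i in range(6)]
        u = [(0, 0, 1)] * 6
        got = cw.best_split(self.make_set(vol, pos, u), [vol], cw.OffsetRange(3, 3, 3), 10, 4, rng)
        if got is not None:  # every candidate ties at 0; argmin keeps the first
            _, _, left, right = got
            assert cw.split_objective(left.u, right.u) == pytest.approx(0.0)

    def test_matches_exhaustive_candidate_enumeration(self, rng):
        """Replay the candidate draws and brute-force the argmin."""
        vol = cw.Volume(
            np.random.default_rng(5).uniform(1, 400, size=(14, 14, 14)).astype(np.float32)
        )
        n_theta, n_tau = 6, 4
        for seed in range(5):
            pos = np.random.default_rng(100 + seed).integers(0, 14, size=(40, 3))
            u = unit_rows(np.random.default_rng(200 + seed), 40)
            s = SampleSet(pos, np.zeros(40), u)
            offset_range = cw.OffsetRange(5, 5, 3)

            got = cw.best_split(
                s, [vol], offset_range, n_theta, n_tau, np.random.default_rng(seed)
            )
            # Independent replay: same draws, brute-force objective per tau.
            rng2 = np.random.default_rng(seed)
            thetas = propose_param_array(offset_range, n_theta, rng2)
            tau_u = rng2.random((n_theta, n_tau))
            ev = FeatureEvaluator([vol])
            F = ev.features(s.vidx, s.pos, thetas)
            best = (np.inf, None)
            n = len(s)
            for t in range(n_theta):
                fs = np.sort(F[t])
                q5, q95 = fs[int(0.05 * (n - 1))], fs[int(0.95 * (n - 1))]
                for j in range(n_tau):
                    tau = q5 + (q95 - q5) * tau_u[t, j]
                    mask = F[t] < tau
                    if mask.all() or not mask.any():
                        continue
                    obj = cw.split_objective(u[mask], u[~mask])
                    if obj < best[0]:
                        best = (obj, (t, tau, mask))
            if got is None:
                assert best[1] is None
                continue
            params, tau, left, right = got
            assert cw.split_objective(left.u, right.u) == pytest.approx(best[0], abs=1e-9)
            t, tau_ref, mask_ref = best[1]
            assert params.v1 == tuple(thetas[t, 0]) and params.v2 == tuple(thetas[t, 1])
            assert tau == pytest.approx(tau_ref, rel=1e-6)
            assert np.array_equal(left.pos, s.pos[mask_ref])

    def test_too_few_samples_rejected(self, rng, small_volume):
        s = SampleSet(np.zeros((1, 3)), np.zeros(1), np.array([[1.0, 0, 0]]))
        with pytest.raises(cw.ValidationError):
            cw.best_split(s, [small_volume], cw.OffsetRange(2, 2, 2), 5, 2, rng)


class TestKMeansLeaves:
    def test_identical_points_collapse_to_one_cluster(self, rng):
        dirs = np.tile([0.0, 1.0, 0.0], (30, 1))
        probs, cent = cw.kmeans_directions(dirs, 8, rng)
        assert len(probs) == 1
        assert probs[0] == pytest.approx(1.0)
        assert np.allclose(cent[0], [0, 1, 0])

    def test_matches_reference_lloyd_with_same_init(self, rng):
        """Cross-check against scikit-learn's Lloyd iteration, same init."""
        from sklearn.cluster import KMeans

        centers = np.array([[1.0, 0, 0], [0, 1.0, 0], [0, 0, 1.0]])
        dirs = np.concatenate(
            [c + 0.05 * rng.normal(size=(40, 3)) for c in centers]
        )
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)

        probe_rng = np.random.default_rng(77)
        init_idx = probe_rng.choice(len(dirs), size=3, replace=False)
        probs, cent = cw.kmeans_directions(dirs, 3, np.random.default_rng(77))

        ref = KMeans(
            n_clusters=3, init=dirs[init_idx], n_init=1, max_iter=50, tol=0.0,
            algorithm="lloyd",
        ).fit(dirs)
        ref_cent = ref.cluster_centers_
        ref_cent = ref_cent / np.linalg.norm(ref_cent, axis=1, keepdims=True)
        ref_probs = np.bincount(ref.labels_, minlength=3) / len(dirs)
        # Same init, separable data: identical clusters (order may differ).
        order = np.argmin(((cent[:, None] - ref_cent[None]) ** 2).sum(-1), axis=1)
        assert sorted(order) == [0, 1, 2]
        assert np.allclose(cent, ref_cent[order], atol=1e-6)
        assert np.allclose(probs, ref_probs[order], atol=1e-12)

    def test_probabilities_sum_to_one(self, rng):
        dirs = unit_rows(rng, 100)
        probs, cent = cw.kmeans_directions(dirs, 8, rng)
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(np.linalg.norm(cent, axis=1), 1.0, atol=1e-9)


def route_samples(tree, vol, sample_set):
    """Partition training samples through the tree, checking SS monotonicity."""

    def recurse(idx, mask):
        node = tree.nodes[idx]
        u = sample_set.u[mask]
        if isinstance(node, LeafNode):
            return
        parent_ss = _sum_sq_dev(u)
        f = np.array(
            [
                cw.feature_value(vol, p, node.params)
                for p in sample_set.pos[mask]
            ]
        )
        left_mask = np.zeros(len(sample_set), dtype=bool)
        idxs = np.flatnonzero(mask)
        left_mask[idxs[f < node.tau]] = True
        right_mask = mask & ~left_mask
        child_ss = _sum_sq_dev(sample_set.u[left_mask]) + _sum_sq_dev(
            sample_set.u[right_mask]
        )
        assert child_ss <= parent_ss + 1e-9
        recurse(node.left, left_mask)
        recurse(node.right, right_mask)

    recurse(0, np.ones(len(sample_set), dtype=bool))


class TestTrainTree:
    def small_problem(self, seed=0):
        vol = cw.generate_phantom(cw.PhantomConfig(shape=(48, 48, 48), seed=seed,
                                                   annulus_radius=10))[0]
        samples = cw.make_samples(vol, (24.0, 24.0, 24.0), stride=4)
        return vol, samples

    def train(self, vol, samples, seed=1, **kw):
        args = dict(min_samples=30, n_theta=10, n_tau=4, k_max=8)
        args.update(kw)
        return cw.train_tree(
            samples, [vol], cw.OffsetRange(6, 6, 6), np.random.default_rng(seed), **args
        )

    def test_consensus_directions_make_root_a_leaf(self, rng, small_volume):
        pos = np.array([[0, 0, 0], [0, 0, 4], [4, 0, 0]])
        u = np.tile([1.0, 0, 0], (3, 1))
        tree = cw.train_tree(
            SampleSet(pos, np.zeros(3), u), [small_volume],
            cw.OffsetRange(3, 3, 3), rng, min_samples=1,
        )
        assert len(tree.nodes) == 1
        leaf = tree.leaf(0)
        assert len(leaf.probs) == 1 and leaf.probs[0] == pytest.approx(1.0)
        assert np.allclose(leaf.dirs[0], [1, 0, 0])

    def test_min_samples_stops_at_root(self, rng):
        vol, samples = self.small_problem()
        tree = self.train(vol, samples, min_samples=len(samples) + 1)
        assert len(tree.nodes) == 1

    def test_empty_sample_set_rejected(self, rng, small_volume):
        s = SampleSet(np.empty((0, 3)), np.empty(0), np.empty((0, 3)))
        with pytest.raises(cw.ValidationError):
            cw.train_tree(s, [small_volume], cw.OffsetRange(2, 2, 2), rng)

    def test_leaf_invariants_tree_wide(self):
        vol, samples = self.small_problem()
        tree = self.train(vol, samples)
        n_leaves = 0
        for node in tree.nodes:
            if isinstance(node, LeafNode):
                n_leaves += 1
                assert node.probs.sum() == pytest.approx(1.0, abs=1e-9)
                assert np.all(node.probs > 0)
                assert np.allclose(np.linalg.norm(node.dirs, axis=1), 1.0, atol=1e-6)
                assert 1 <= len(node.probs) <= 8
            else:
                assert isinstance(node, SplitNode)
        assert n_leaves >= 2

    def test_children_never_increase_direction_scatter(self):
        vol, samples = self.small_problem()
        tree = self.train(vol, samples)
        route_samples(tree, vol, samples)

    def test_training_is_deterministic(self, tmp_path):
        vol, samples = self.small_problem()
        a = self.train(vol, samples, seed=9)
        b = self.train(vol, samples, seed=9)
        cw.save_model(a, tmp_path / "a.json")
        cw.save_model(b, tmp_path / "b.json")
        assert (tmp_path / "a.json").read_bytes() == (tmp_path / "b.json").read_bytes()


class TestTraverse:
    def test_single_leaf_tree(self, small_volume):
        leaf = LeafNode(np.array([1.0]), np.array([[0.0, 0.0, 1.0]]))
        tree = cw.RegressionTree([leaf])
        assert cw.traverse(tree, small_volume, (0, 0, 0)) is leaf
        assert cw.traverse(tree, small_volume, (15, 15, 15)) is leaf

    def test_depth_one_left_when_feature_below_tau(self):
        vol = grad_volume()
        left = LeafNode(np.array([1.0]), np.array([[1.0, 0.0, 0.0]]))
        right = LeafNode(np.array([1.0]), np.array([[-1.0, 0.0, 0.0]]))
        root = SplitNode(cw.FeatureParams((1, 0, 0), (-1, 0, 0)), 2.0 / 10.5, 1, 2)
        tree = cw.RegressionTree([root, left, right])
        # f = 2 / (x + 1): below tau iff x > 9.5
        assert cw.traverse(tree, vol, (12, 8, 8)) is left
        assert cw.traverse(tree, vol, (5, 8, 8)) is right

    def test_agrees_with_recursive_reimplementation(self, rng):
        vol = cw.generate_phantom(cw.PhantomConfig(shape=(48, 48, 48), seed=3,
                                                   annulus_radius=10))[0]
        samples = cw.make_samples(vol, (24.0, 24.0, 24.0), stride=4)
        tree = cw.train_tree(
            samples, [vol], cw.OffsetRange(6, 6, 6), np.random.default_rng(2),
            min_samples=30, n_theta=10, n_tau=4,
        )

        def oracle(idx, pos):
            node = tree.nodes[idx]
            if isinstance(node, LeafNode):
                return idx
            f = cw.feature_value(vol, pos, node.params)
            return oracle(node.left if f < node.tau else node.right, pos)

        pos = rng.integers(0, 48, size=(100, 3))
        batch = tree.traverse_batch(vol, pos)
        for i, p in enumerate(pos):
            leaf_idx = oracle(0, p)
            assert cw.traverse(tree, vol, p) is tree.nodes[leaf_idx]
            assert batch[i] == leaf_idx


class TestSerialization:
    def trained(self):
        vol = cw.generate_phantom(cw.PhantomConfig(shape=(48, 48, 48), seed=5,
                                                   annulus_radius=10))[0]
        samples = cw.make_samples(vol, (24.0, 24.0, 24.0), stride=5)
        tree = cw.train_tree(
            samples, [vol], cw.OffsetRange(5, 5, 5), np.random.default_rng(4),
            min_samples=40, n_theta=8, n_tau=4,
        )
        return vol, tree

    def test_save_load_save_is_byte_identical(self, tmp_path):
        _, tree = self.trained()
        p1, p2 = tmp_path / "m1.json", tmp_path / "m2.json"
        cw.save_model(tree, p1)
        cw.save_model(cw.load_model(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_round_trip_preserves_predictions(self, tmp_path, rng):
        vol, tree = self.trained()
        cw.save_model(tree, tmp_path / "m.json")
        back = cw.load_model(tmp_path / "m.json")
        pos = rng.integers(0, 48, size=(50, 3))
        assert np.array_equal(tree.traverse_batch(vol, pos), back.traverse_batch(vol, pos))

    def test_tampered_probabilities_rejected(self, tmp_path):
        _, tree = self.trained()
        path = tmp_path / "m.json"
        cw.save_model(tree, path)
        doc = json.loads(path.read_text())
        for node in doc["nodes"]:
            if node["type"] == "leaf":
                node["clusters"][0][0] += 0.25  # probs no longer sum to 1
                break
        path.write_text(json.dumps(doc))
        with pytest.raises(ModelFormatError):
            cw.load_model(path)

    def test_garbage_json_rejected(self, tmp_path):
        p = tmp_path / "bad.json"
        p.write_text("{\"nodes\": [{\"type\": \"wat\"}]}")
        with pytest.raises(ModelFormatError):
            cw.load_model(p)
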