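import numpy as np
import pytest
from scipy.stats import spearmanr

from emodyn.trajectory import (EmotionTrajectory, FeatureMatrix, cfs_merit,
                               cfs_select, isomap_embed)


def fm(values, names=None, labels=None, subjects=None):
    names = names or [f"f{i}" for i in range(values.shape[1])]
    return FeatureMatrix(values, tuple(names), labels=labels, subject_ids=subjects)


class TestCFSMerit:
    def test_single_feature_merit_is_rcf(self):
        assert cfs_merit(1, 0.37, 0.9) == pytest.approx(0.37)

    def test_two_uncorrelated_features(self):
        assert cfs_merit(2, 0.5, 0.0) == pytest.approx(2 * 0.5 / np.sqrt(2))
        assert cfs_merit(2, 0.5, 0.0) == pytest.approx(0.7071, abs=5e-5)

    def test_redundancy_penalized(self):
        assert cfs_merit(3, 0.5, 0.9) < cfs_merit(3, 0.5, 0.1)


class TestCFSSelect:
    def test_label_copy_selected_first(self, rng):
        y = rng.integers(0, 2, 200).astype(float)
        X = rng.standard_normal((200, 5))
        X[:, 3] = y  # perfectly class-correlated
        names = [f"f{i}" for i in range(5)]
        sel = cfs_select(fm(X, names, labels=y), n_select=2)
        assert sel[0] == "f3"

    def test_constant_feature_never_preferred(self, rng):
        y = rng.integers(0, 2, 100).astype(float)
        X = rng.standard_normal((100, 3))
        X[:, 0] = 7.0  # constant: correlation treated as 0
        X[:, 1] = y + 0.1 * rng.standard_normal(100)
        sel = cfs_select(fm(X, labels=y), n_select=1)
        assert sel == ["f1"]

    def test_selection_size_and_uniqueness(self, rng):
        y = rng.integers(0, 2, 150).astype(float)
        X = rng.standard_normal((150, 20)) + y[:, None] * rng.random(20)
        sel = cfs_select(fm(X, labels=y), n_select=15)
        assert len(sel) == 15 and len(set(sel)) == 15

    def test_subject_inconsistent_feature_screened_out(self, rng):
        # f0: same class association in every subject; f1: association sign
        # flips subject by subject -> not subject-independent
        rows, subj, y = [], [], []
        for s in range(6):
            flip = 1.0 if s % 2 == 0 else -1.0
            for i in range(40):
                label = float(i % 2)
                rows.append([label + 0.2 * rng.standard_normal(),
                             flip * label + 0.2 * rng.standard_normal()])
                subj.append(f"sub{s}")
                y.append(label)
        X = np.array(rows)
        sel = cfs_select(fm(X, labels=np.array(y), subjects=np.array(subj)),
                         n_select=1)
        assert sel == ["f0"]

    def test_requires_labels(self, rng):
        with pytest.raises(ValueError):
            cfs_select(fm(rng.standard_normal((10, 3))), n_select=1)


class TestIsomap:
    def test_two_points_euclidean_distance(self):
        X = np.array([[0.0, 0.0], [3.0, 4.0]])
        traj = isomap_embed(fm(X), k_neighbors=1)
        d = abs(traj.values[0] - traj.values[1])
        assert d == pytest.approx(5.0, rel=1e-9)
        assert traj.values.mean() == pytest.approx(0.0, abs=1e-12)

    def test_collinear_points_recover_order(self, rng):
        pos = np.sort(rng.random(50))
        direction = rng.standard_normal(5)
        X = pos[:, None] * direction[None, :]
        traj = isomap_embed(fm(X), k_neighbors=5)
        rho = spearmanr(traj.values, pos).statistic
        assert abs(rho) == pytest.approx(1.0)

    def test_quarter_circle_preserves_arc_length(self):
        theta = np.linspace(0.0, np.pi / 2, 100)
        X = np.column_stack([np.cos(theta), np.sin(theta)])
        traj = isomap_embed(fm(X), k_neighbors=5)
        emb_d, arc_d = [], []
        idx = np.arange(0, 100, 7)
        for i in idx:
            for j in idx:
                if i < j:
                    emb_d.append(abs(traj.values[i] - traj.values[j]))
                    arc_d.append(theta[j] - theta[i])
        assert np.corrcoef(emb_d, arc_d)[0, 1] > 0.99

    def test_rigid_motion_invariance(self, rng):
        X = rng.standard_normal((40, 3))
        Q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        Y = X @ Q + np.array([5.0, -2.0, 11.0])
        t1 = isomap_embed(fm(X), k_neighbors=6)
        t2 = isomap_embed(fm(Y), k_neighbors=6)
        agree = np.allclose(t1.values, t2.values, atol=1e-8)
        flipped = np.allclose(t1.values, -t2.values, atol=1e-8)
        assert agree or flipped

    def test_full_graph_equals_classical_mds_oracle(self, rng):
        # points already on a line: geodesics = Euclidean distances, so the
        # embedding must match plain classical MDS coordinates
        pos = np.sort(rng.standard_normal(20))
        X = np.column_stack([pos, np.zeros(20)])
        traj = isomap_embed(fm(X), k_neighbors=19)
        centered = pos - pos.mean()
        expect = centered if np.sign(centered[np.flatnonzero(centered)[0]]) == \
            np.sign(traj.values[np.flatnonzero(traj.values)[0]]) else -centered
        np.testing.assert_allclose(traj.values, expect, atol=1e-8)

    def test_disconnected_graph_autoconnects(self):
        X = np.vstack([np.zeros((5, 2)) + np.arange(5)[:, None] * 0.01,
                       np.ones((5, 2)) * 100 + np.arange(5)[:, None] * 0.01])
        traj = isomap_embed(fm(X), k_neighbors=2)
        assert np.isfinite(traj.values).all()

    def test_zero_mean_enforced_downstream(self, rng):
        X = rng.standard_normal((30, 4))
        traj = isomap_embed(fm(X), k_neighbors=5)
        assert abs(traj.values.mean()) < 1e-9 * traj.values.std()


class TestEmotionTrajectory:
    def test_nonzero_mean_rejected_when_flagged(self):
        with pytest.raises(ValueError):
            EmotionTrajectory(np.array([1.0, 2.0, 3.0]), np.arange(3.0))

    def test_non_zero_mean_allowed_when_unflagged(self):
        t = EmotionTrajectory(np.array([1.0, 2.0]), np.arange(2.0), zero_mean=False)
        assert t.values[0] == 1.0
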