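import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from mdcontacts.contact_engine import build_pair_store
from mdcontacts.dimred_cluster import (INERT_LABEL, cluster_frames,
                                       cluster_residues, interframe_rmsd, pca)
from mdcontacts.synthetic_fixtures import FixtureSpec, make_frames, topology_from_centers
from mdcontacts.trajectory_io import Frame, select_atoms

from conftest import make_store


def brute_rmsd(d):
    """Naive double loop over frames and pairs."""
    P, F = d.shape
    out = np.zeros((F, F))
    for a in range(F):
        for b in range(F):
            out[a, b] = np.sqrt(((d[:, a] - d[:, b]) ** 2).mean())
    return out


def two_state_store(seed, n_frames=100, noise=0.01):
    spec = FixtureSpec(scenario="two_state", n_frames=n_frames,
                       noise_sigma=noise, seed=seed)
    top, frames, gt = make_frames(spec)
    return build_pair_store(frames, select_atoms(top, "heavy")), gt


class TestInterframeRmsd:
    def test_identical_frames_zero(self):
        fdm = interframe_rmsd(make_store([[0.4] * 5, [0.7] * 5],
                                         pairs=[[0, 1], [1, 2]]))
        assert np.all(fdm.D == 0.0)

    def test_single_pair_closed_form(self):
        fdm = interframe_rmsd(make_store([[0.4, 0.6]]))
        assert fdm.D[0, 1] == pytest.approx(0.2)

    def test_matches_brute_force(self, rng):
        vals = rng.uniform(0.2, 1.0, size=(7, 10))
        store = make_store(vals, pairs=[[0, p + 1] for p in range(7)])
        D = interframe_rmsd(store).D
        np.testing.assert_allclose(D, brute_rmsd(vals), atol=1e-10)

    def test_metric_properties(self, rng):
        store, _ = two_state_store(seed=1, n_frames=40)
        D = interframe_rmsd(store).D
        assert np.allclose(D, D.T)
        assert np.all(np.diag(D) == 0.0)
        n = len(D)
        for _ in range(200):
            a, b, c = rng.integers(0, n, size=3)
            assert D[a, c] <= D[a, b] + D[b, c] + 1e-12

    def test_no_live_pairs_rejected(self):
        store = make_store(np.empty((0, 4)), pairs=np.empty((0, 2), dtype=int),
                           n_residues=3)
        with pytest.raises(ValueError, match="live pair"):
            interframe_rmsd(store)


class TestClusterFrames:
    def test_every_frame_its_own_cluster(self, rng):
        vals = rng.uniform(0.2, 1.0, size=(3, 6))
        fdm = interframe_rmsd(make_store(vals, pairs=[[0, 1], [0, 2], [1, 2]]))
        cl = cluster_frames(fdm, k=6)
        assert sorted(cl.labels.tolist()) == list(range(6))
        for c, m in enumerate(cl.medoids):
            assert cl.labels[m] == c
        assert np.all(cl.distance_to_medoid == 0.0)

    def test_two_state_recovery(self):
        store, gt = two_state_store(seed=42)
        cl = cluster_frames(interframe_rmsd(store), k=2)
        assert adjusted_rand_score(gt.state_sequence, cl.labels) == 1.0
        # labels are renumbered by first occurrence: frame 0 is cluster 0
        assert cl.labels[0] == 0

    def test_medoids_minimize_distance_sums(self):
        store, _ = two_state_store(seed=7, n_frames=30)
        D = interframe_rmsd(store).D
        cl = cluster_frames(interframe_rmsd(store), k=2)
        for c in range(cl.n_clusters):
            members = np.flatnonzero(cl.labels == c)
            sums = D[np.ix_(members, members)].sum(axis=1)
            assert cl.medoids[c] == members[np.argmin(sums)]

    def test_height_cut(self):
        store, _ = two_state_store(seed=3, n_frames=40)
        fdm = interframe_rmsd(store)
        # cutting far above the tree height gives one cluster
        cl = cluster_frames(fdm, height=10.0)
        assert cl.n_clusters == 1

    def test_deterministic(self):
        store, _ = two_state_store(seed=5, n_frames=50)
        fdm = interframe_rmsd(store)
        a = cluster_frames(fdm, k=3)
        b = cluster_frames(fdm, k=3)
        assert np.array_equal(a.labels, b.labels)
        assert np.array_equal(a.medoids, b.medoids)

    def test_k_out_of_range(self):
        store, _ = two_state_store(seed=5, n_frames=10)
        fdm = interframe_rmsd(store)
        with pytest.raises(ValueError, match="k must be"):
            cluster_frames(fdm, k=11)


class TestPca:
    def test_identical_frames_zero_variance(self):
        pr = pca(make_store([[0.4] * 6, [0.7] * 6], pairs=[[0, 1], [1, 2]]), 2)
        np.testing.assert_allclose(pr.eigenvalues, 0.0, atol=1e-15)

    def test_two_state_separation_and_variance(self):
        store, gt = two_state_store(seed=13)
        pr = pca(store, 2)
        p1 = pr.projections[gt.state_sequence == 0, 0]
        p2 = pr.projections[gt.state_sequence == 1, 0]
        assert p1.max() < p2.min() or p2.max() < p1.min()  # zero overlap
        assert pr.explained_variance_ratio[0] >= 0.9

    def test_total_variance_conserved(self):
        store, _ = two_state_store(seed=17)
        pr = pca(store, 1)
        total = store.distances().T.var(axis=0).sum()
        assert abs(pr.eigenvalues.sum() - total) <= 1e-8 * total

    def test_full_basis_reconstruction(self):
        store, _ = two_state_store(seed=19, n_frames=40)
        k = min(store.n_pairs, 40)
        pr = pca(store, k)
        X = store.distances().T
        Xc = X - X.mean(axis=0)
        np.testing.assert_allclose(pr.projections @ pr.loadings.T, Xc,
                                   atol=1e-8)

    def test_gram_route_matches_direct(self, rng):
        """More pairs than frames: Gram-trick results equal the covariance
        route computed on the same data."""
        vals = rng.uniform(0.2, 1.0, size=(9, 4))  # P=9 > F=4
        store = make_store(vals, pairs=[[0, p + 1] for p in range(9)])
        pr = pca(store, 3)  # P > F: Gram route
        X = vals.T - vals.T.mean(axis=0)
        w_ref, V_ref = np.linalg.eigh((X.T @ X) / 4)
        w_ref = w_ref[::-1]
        np.testing.assert_allclose(pr.eigenvalues[:3], w_ref[:3], atol=1e-12)
        for c in range(3):
            v = V_ref[:, ::-1][:, c]
            assert abs(abs(v @ pr.loadings[:, c]) - 1.0) < 1e-9

    def test_matches_sklearn(self):
        """Independent eigensolver check (sklearn uses the 1/(F-1) scale)."""
        sklearn_pca = pytest.importorskip("sklearn.decomposition").PCA
        store, _ = two_state_store(seed=23, n_frames=50)
        pr = pca(store, 2)
        ref = sklearn_pca(n_components=2).fit(store.distances().T)
        F = store.n_frames
        np.testing.assert_allclose(pr.eigenvalues[:2] * F / (F - 1),
                                   ref.explained_variance_, rtol=1e-9)
        for c in range(2):
            assert abs(abs(ref.components_[c] @ pr.loadings[:, c]) - 1.0) < 1e-9

    def test_orthonormal_loadings_and_sign(self):
        store, _ = two_state_store(seed=29)
        pr = pca(store, 2)
        np.testing.assert_allclose(pr.loadings.T @ pr.loadings, np.eye(2),
                                   atol=1e-10)
        for c in range(2):
            col = pr.loadings[:, c]
            assert col[np.argmax(np.abs(col))] > 0

    def test_n_components_too_large(self):
        store, _ = two_state_store(seed=1, n_frames=10)
        with pytest.raises(ValueError, match="n_components"):
            pca(store, store.n_pairs + store.n_frames)


def two_block_store(n_frames=100, rupture_frame=10):
    """Two rigid 4-residue blocks (compact squares, all intra-block pairs in
    contact) that separate at a scripted frame."""
    top = topology_from_centers(8, 1)
    sel = select_atoms(top, "heavy")
    square = np.array([[0.0, 0.0], [0.3, 0.0], [0.0, 0.3], [0.3, 0.3]])
    frames = []
    for f in range(n_frames):
        gap = 0.45 if f <= rupture_frame else 5.0
        block_b = square + [0.3 + gap, 0.0]
        xy = np.vstack([square, block_b])
        coords = np.column_stack([xy, np.zeros(8)])
        frames.append(Frame(f, float(f), coords))
    return build_pair_store(frames, sel), sel


class TestClusterResidues:
    def test_two_blocks_recovered_from_last_encounter(self):
        from mdcontacts.aggregate_maps import PERSISTENT_SENTINEL, aggregate
        store, sel = two_block_store()
        agg = aggregate(store)
        m = agg.matrix("last_encounter")
        m[m == PERSISTENT_SENTINEL] = agg.final_time
        features = np.nan_to_num(m, nan=0.0)
        rc = cluster_residues(features, k=2, inert=sel.inert)
        assert rc.labels.tolist() == [0, 0, 0, 0, 1, 1, 1, 1]

    def test_k_one_single_cluster(self, rng):
        features = rng.normal(size=(5, 5))
        rc = cluster_residues(features, k=1)
        assert rc.labels.tolist() == [0] * 5

    def test_permutation_consistency(self, rng):
        features = rng.normal(size=(6, 4))
        rc = cluster_residues(features, k=2)
        perm = rng.permutation(6)
        rc_p = cluster_residues(features[perm], k=2)
        # permuted input gives consistently permuted labels
        assert adjusted_rand_score(rc.labels[perm], rc_p.labels) == 1.0

    def test_inert_reserved_label(self, rng):
        features = rng.normal(size=(4, 3))
        inert = np.array([False, True, False, False])
        rc = cluster_residues(features, k=2, inert=inert)
        assert rc.labels[1] == INERT_LABEL
        assert set(rc.labels[~inert]) <= {0, 1}

    def test_degenerate_features_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            cluster_residues(np.ones((4, 3)), k=2)
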