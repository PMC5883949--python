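"""Contact-map alternatives to coordinate RMSD workflows.

All of these operate on the live-pair distance vectors of a
:class:`~mdcontacts.contact_engine.ResiduePairStore`, so no structural
fitting or average structure is ever needed:

* inter-frame contact RMSD
      D[a, b] = sqrt( (1/P) Σ_p (d_p(a) − d_p(b))² )
  over the P live pairs — a true metric (a scaled Euclidean norm);
* agglomerative hierarchical clustering of frames on D, with per-cluster
  medoids (the member minimizing total distance to its cluster);
* PCA of the mean-centered pair-distance vectors;
* agglomerative clustering of residues on contact-derived feature rows.

Everything here is deterministic: no randomized initialization anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from .contact_engine import ResiduePairStore

__all__ = [
    "FrameDistanceMatrix",
    "ClusterResult",
    "PCAResult",
    "ResidueClusterResult",
    "interframe_rmsd",
    "cluster_frames",
    "pca",
    "cluster_residues",
    "INERT_LABEL",
]

#: reserved residue-cluster label for inert residues
INERT_LABEL = -1


@dataclass
class FrameDistanceMatrix:
    """Symmetric n_frames × n_frames contact-RMSD matrix, entries in nm."""

    D: np.ndarray
    times: np.ndarray

    @property
    def n_frames(self) -> int:
        return len(self.D)


@dataclass
class ClusterResult:
    """Hierarchical frame clustering with medoids.

    labels are 0-based and renumbered by first frame occurrence; ``linkage``
    is the scipy merge-tree record (child_a, child_b, height, size).
    """

    labels: np.ndarray
    medoids: np.ndarray              # per-cluster frame index
    linkage: np.ndarray
    distance_to_medoid: np.ndarray   # per-frame nm

    @property
    def n_clusters(self) -> int:
        return len(self.medoids)


@dataclass
class PCAResult:
    """PCA of mean-centered per-frame pair-distance vectors.

    ``eigenvalues`` (nm², descending) cover the full spectrum so that their
    sum equals the total per-pair variance; loadings/projections are kept
    for the requested leading components only.  Sign convention: each
    component's largest-magnitude loading is positive.
    """

    eigenvalues: np.ndarray    # all eigenvalues, descending
    loadings: np.ndarray       # (P, n_components), orthonormal columns
    projections: np.ndarray    # (F, n_components)
    mean: np.ndarray           # (P,)
    pairs: np.ndarray

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        total = self.eigenvalues.sum()
        k = self.loadings.shape[1]
        return self.eigenvalues[:k] / total if total > 0 else np.zeros(k)


@dataclass
class ResidueClusterResult:
    """Per-residue cluster labels; inert residues carry :data:`INERT_LABEL`."""

    labels: np.ndarray
    feature: str


def interframe_rmsd(store: ResiduePairStore) -> FrameDistanceMatrix:
    """Root-mean-square difference of all live-pair clamped distances
    between every two frames."""
    if store.n_frames < 2:
        raise ValueError("need at least 2 frames")
    if store.n_pairs == 0:
        raise ValueError("no live pairs: inter-frame contact RMSD is undefined")
    X = store.distances().T  # (F, P)
    D = squareform(pdist(X, metric="euclidean")) / np.sqrt(store.n_pairs)
    return FrameDistanceMatrix(D=D, times=store.times)


def _renumber_first_occurrence(raw: np.ndarray) -> np.ndarray:
    mapping: dict[int, int] = {}
    out = np.empty_like(raw)
    for idx, lab in enumerate(raw):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[idx] = mapping[lab]
    return out


def cluster_frames(fdm: FrameDistanceMatrix, k: int | None = None,
                   height: float | None = None,
                   linkage_method: str = "average") -> ClusterResult:
    """Agglomerative clustering of frames on the contact-RMSD matrix.

    Cut the merge tree to ``k`` clusters or at merge ``height`` (nm).
    Medoids minimize the within-cluster distance sum; ties break to the
    lowest frame index.
    """
    if linkage_method not in ("average", "single", "complete"):
        raise ValueError(f"unsupported linkage {linkage_method!r}")
    D = fdm.D
    n = len(D)
    if (k is None) == (height is None):
        raise ValueError("specify exactly one of k or height")
    if k is not None and not (1 <= k <= n):
        raise ValueError(f"k must be in [1, {n}], got {k}")
    Z = linkage(squareform(D, checks=False), method=linkage_method)
    if k is not None:
        raw = fcluster(Z, t=k, criterion="maxclust")
    else:
        raw = fcluster(Z, t=height, criterion="distance")
    labels = _renumber_first_occurrence(raw)
    n_clusters = labels.max() + 1
    medoids = np.empty(n_clusters, dtype=np.intp)
    dist_to_medoid = np.empty(n)
    for c in range(n_clusters):
        members = np.flatnonzero(labels == c)
        sums = D[np.ix_(members, members)].sum(axis=1)
        medoids[c] = members[int(np.argmin(sums))]  # argmin: lowest index on ties
        dist_to_medoid[members] = D[members, medoids[c]]
    return ClusterResult(labels=labels, medoids=medoids, linkage=Z,
                         distance_to_medoid=dist_to_medoid)


def pca(store: ResiduePairStore, n_components: int,
        binary_states: bool = False) -> PCAResult:
    """PCA of the per-frame live-pair vectors.

    By default operates on clamped distances; ``binary_states=True`` uses the
    0/1 hysteretic contact states instead.  The covariance uses the
    population (1/F) convention.  When there are more live pairs than frames
    the frames×frames Gram matrix is decomposed instead — the results are
    identical either way.
    """
    if store.n_frames < 2:
        raise ValueError("need at least 2 frames")
    if binary_states:
        from .contact_engine import contact_states
        X = contact_states(store).states.astype(np.float64).T
    else:
        X = store.distances().T  # (F, P)
    F, P = X.shape
    if not (1 <= n_components <= min(F, P)):
        raise ValueError(
            f"n_components must be in [1, {min(F, P)}], got {n_components}")
    mu = X.mean(axis=0)
    Xc = X - mu
    if P <= F:
        C = (Xc.T @ Xc) / F
        w, V = np.linalg.eigh(C)
        w = np.clip(w[::-1], 0.0, None)
        V = V[:, ::-1]
        loadings = V[:, :n_components]
    else:
        G = (Xc @ Xc.T) / F
        w, U = np.linalg.eigh(G)
        w = np.clip(w[::-1], 0.0, None)
        U = U[:, ::-1]
        total = w.sum()
        loadings = np.empty((P, n_components))
        for c in range(n_components):
            if w[c] <= 1e-15 * max(total, 1.0):
                raise ValueError(
                    f"component {c} has (numerically) zero variance; "
                    f"request fewer components")
            loadings[:, c] = (Xc.T @ U[:, c]) / np.sqrt(F * w[c])
    # deterministic sign: largest-magnitude loading positive
    for c in range(loadings.shape[1]):
        col = loadings[:, c]
        apex = int(np.argmax(np.abs(col)))
        if col[apex] < 0:
            loadings[:, c] = -col
    projections = Xc @ loadings
    return PCAResult(eigenvalues=w, loadings=loadings, projections=projections,
                     mean=mu, pairs=store.pairs)


def cluster_residues(features: np.ndarray, k: int,
                     inert: np.ndarray | None = None,
                     feature_name: str = "features",
                     linkage_method: str = "average") -> ResidueClusterResult:
    """Agglomerative (Euclidean) clustering of residues on feature rows.

    ``features`` has one row per residue — e.g. rows of the mean-distance
    matrix, of the (sentinel-filled) last-encounter matrix, or of the
    cross-correlation matrix.  Inert residues (``inert`` mask) are excluded
    and labeled :data:`INERT_LABEL`.
    """
    features = np.asarray(features, dtype=np.float64)
    R = len(features)
    inert = np.zeros(R, dtype=bool) if inert is None else np.asarray(inert, bool)
    active = np.flatnonzero(~inert)
    if k < 1 or k > len(active):
        raise ValueError(f"k must be in [1, {len(active)}]")
    fa = features[active]
    labels = np.full(R, INERT_LABEL, dtype=np.intp)
    if k == 1:
        labels[active] = 0
        return ResidueClusterResult(labels=labels, feature=feature_name)
    cond = pdist(fa, metric="euclidean")
    if np.all(cond == 0.0):
        raise ValueError("degenerate input: all residue feature rows are "
                         "identical, cannot form k > 1 clusters")
    Z = linkage(cond, method=linkage_method)
    raw = fcluster(Z, t=k, criterion="maxclust")
    labels[active] = _renumber_first_occurrence(raw)
    return ResidueClusterResult(labels=labels, feature=feature_name)
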