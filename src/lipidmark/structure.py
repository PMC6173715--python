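"""Unsupervised structure mapping.

Three independent views of cluster structure in the subjects × markers
space, used to confirm that the marker panel carries the case/control
separation before any supervised fitting:

* an emergent self-organizing map (SOM) on a toroidal neuron grid with
  the U-matrix (per-neuron mean distance to its grid neighbors) and
  best-matching-unit (BMU) projection of the subjects;
* minimum curvilinear embedding (MCE): geodesic distances along the
  minimum spanning tree of the pairwise-distance graph, projected to
  2-D spectrally;
* classical Ward (minimum-variance) agglomerative clustering.

Agreement between an unsupervised two-cluster partition and the
clinical diagnosis is scored as the balanced accuracy under the best
of the two label permutations.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, minimum_spanning_tree, shortest_path
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "ToroidalSOM",
    "compute_umatrix",
    "umatrix_two_cluster_labels",
    "MinimumCurvilinearEmbedding",
    "mce_embed",
    "ward_cluster",
    "diagnosis_agreement",
]


def _toroidal_sq_distances(rows: int, cols: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-axis toroidal coordinate grids for all neurons (flattened)."""
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    return rr.ravel(), cc.ravel()


class ToroidalSOM(BaseEstimator, TransformerMixin):
    """Self-organizing map on a toroidal grid (emergent SOM geometry).

    A large neuron grid (default 50 × 80 = 4,000 units, far more
    neurons than expected clusters) is trained online: weights are
    initialized by sampling the data variables, then updated over
    ``epochs`` passes with a Gaussian neighborhood on the toroidal grid
    distance. The neighborhood radius decays linearly from half the
    smaller grid dimension to 1, the learning rate from 0.5 to 0.01.

    Fitted attributes
    -----------------
    weights_ : ndarray of shape (rows*cols, d)
    bmus_ : ndarray of shape (n_subjects, 2) — (row, col) per subject.
    """

    def __init__(
        self,
        rows: int = 50,
        cols: int = 80,
        epochs: int = 20,
        initial_learning_rate: float = 0.5,
        final_learning_rate: float = 0.01,
        random_state: int = 0,
    ):
        self.rows = rows
        self.cols = cols
        self.epochs = epochs
        self.initial_learning_rate = initial_learning_rate
        self.final_learning_rate = final_learning_rate
        self.random_state = random_state

    def fit(self, X, y=None) -> "ToroidalSOM":
        X = np.asarray(X, dtype=float)
        if self.rows < 2 or self.cols < 2:
            raise ValueError("SOM grid must be at least 2x2")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        n, d = X.shape
        rng = np.random.default_rng(self.random_state)
        n_units = self.rows * self.cols
        # init: each weight component sampled from that variable's data values
        weights = np.empty((n_units, d))
        for j in range(d):
            weights[:, j] = rng.choice(X[:, j], size=n_units, replace=True)

        grid_r, grid_c = _toroidal_sq_distances(self.rows, self.cols)
        total_steps = self.epochs * n
        radius0 = max(min(self.rows, self.cols) / 2.0, 1.0)
        lr0, lr1 = self.initial_learning_rate, self.final_learning_rate
        step = 0
        for _ in range(self.epochs):
            order = rng.permutation(n)
            for i in order:
                frac = step / max(total_steps - 1, 1)
                radius = radius0 + (1.0 - radius0) * frac
                lr = lr0 + (lr1 - lr0) * frac
                x = X[i]
                diff = weights - x
                bmu = int(np.argmin(np.einsum("ij,ij->i", diff, diff)))
                dr = np.abs(grid_r - grid_r[bmu])
                dr = np.minimum(dr, self.rows - dr)
                dc = np.abs(grid_c - grid_c[bmu])
                dc = np.minimum(dc, self.cols - dc)
                h = np.exp(-(dr**2 + dc**2) / (2.0 * radius**2))
                weights -= (lr * h)[:, None] * diff
                step += 1
        self.weights_ = weights
        self.bmus_ = self.project(X)
        return self

    def project(self, X) -> np.ndarray:
        """Best-matching-unit grid coordinates (row, col) per sample."""
        check_is_fitted(self, "weights_")
        X = np.asarray(X, dtype=float)
        w = self.weights_
        d2 = (
            np.einsum("ij,ij->i", X, X)[:, None]
            - 2.0 * X @ w.T
            + np.einsum("ij,ij->i", w, w)[None, :]
        )
        flat = np.argmin(d2, axis=1)
        return np.column_stack(np.unravel_index(flat, (self.rows, self.cols)))

    def transform(self, X) -> np.ndarray:
        return self.project(X)


_NEIGHBOR_SHIFTS = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]


def compute_umatrix(som: ToroidalSOM) -> np.ndarray:
    """U-matrix heights: per neuron, the mean Euclidean distance of its
    weight vector to those of its 8 toroidal grid neighbors."""
    check_is_fitted(som, "weights_")
    w = som.weights_.reshape(som.rows, som.cols, -1)
    heights = np.zeros((som.rows, som.cols))
    for dr, dc in _NEIGHBOR_SHIFTS:
        shifted = np.roll(np.roll(w, dr, axis=0), dc, axis=1)
        heights += np.sqrt(((w - shifted) ** 2).sum(axis=2))
    return heights / len(_NEIGHBOR_SHIFTS)


def _torus_components(mask: np.ndarray) -> np.ndarray:
    """Label 8-connected components of ``mask`` on a torus; -1 outside."""
    rows, cols = mask.shape
    idx = np.flatnonzero(mask.ravel())
    pos = {v: i for i, v in enumerate(idx)}
    src, dst = [], []
    rr, cc = np.unravel_index(idx, (rows, cols))
    for dr, dc in _NEIGHBOR_SHIFTS:
        nb = np.ravel_multi_index(((rr + dr) % rows, (cc + dc) % cols), (rows, cols))
        for a, b in zip(idx, nb):
            if b in pos:
                src.append(pos[a])
                dst.append(pos[b])
    graph = csr_matrix(
        (np.ones(len(src)), (src, dst)), shape=(len(idx), len(idx))
    )
    _, comp = connected_components(graph, directed=False)
    labels = np.full(rows * cols, -1, dtype=int)
    labels[idx] = comp
    return labels.reshape(rows, cols)


def umatrix_two_cluster_labels(
    umatrix: np.ndarray,
    bmus: np.ndarray,
    quantile: float = 0.6,
) -> np.ndarray:
    """Two-basin partition of the U-matrix, inherited by the subjects.

    Neurons with height at or below a quantile threshold form the
    "valleys"; the two largest 8-connected valley components on the
    torus are the basins. Starting from ``quantile``, a descending
    ladder of thresholds is scanned and the threshold whose
    second-largest component is largest is used (an automated stand-in
    for reading the watershed off a topographic U-matrix display).
    Subjects inherit their BMU's basin; BMUs outside both basins join
    the basin with the nearest member neuron (toroidal grid distance).

    Returns per-subject labels in {0, 1}, or all 0 with a warning when
    no threshold yields two components.
    """
    rows, cols = umatrix.shape
    bmus = np.asarray(bmus)
    n = len(bmus)
    bmu_flat = np.ravel_multi_index((bmus[:, 0], bmus[:, 1]), (rows, cols))
    ladder = np.arange(quantile, 0.049, -0.05)
    best = None  # (smaller basin's subject count, component grid, top-2 ids)
    for q in ladder:
        mask = umatrix <= np.quantile(umatrix, q)
        comp = _torus_components(mask)
        ids = np.unique(comp[comp >= 0])
        if len(ids) < 2:
            continue
        # rank components by how many subjects' BMUs they hold
        subj_counts = np.array([(comp.ravel()[bmu_flat] == i).sum() for i in ids])
        order = np.argsort(subj_counts)[::-1]
        score = subj_counts[order[1]]
        if best is None or score > best[0]:
            best = (score, comp, ids[order[:2]])
    if best is None or best[0] == 0:
        warnings.warn("no U-matrix threshold produced two basins; single cluster returned")
        return np.zeros(n, dtype=int)
    _, comp, top2 = best
    basin = np.full(comp.shape, -1, dtype=int)
    basin[comp == top2[0]] = 0
    basin[comp == top2[1]] = 1
    # assign leftover neurons to the nearest basin (toroidal grid distance)
    member_r, member_c = np.nonzero(basin >= 0)
    member_lab = basin[member_r, member_c]
    labels = np.empty(n, dtype=int)
    for i, (r, c) in enumerate(np.asarray(bmus)):
        if basin[r, c] >= 0:
            labels[i] = basin[r, c]
        else:
            dr = np.abs(member_r - r)
            dr = np.minimum(dr, rows - dr)
            dc = np.abs(member_c - c)
            dc = np.minimum(dc, cols - dc)
            labels[i] = member_lab[np.argmin(dr**2 + dc**2)]
    return labels


class MinimumCurvilinearEmbedding(BaseEstimator, TransformerMixin):
    """Minimum curvilinear embedding (MCE) to 2-D.

    Pairwise base distances (Euclidean or correlation) are reduced to
    the minimum spanning tree; geodesic distance is the path length
    along the tree. The 2-D coordinates are the top-2 spectral
    components of the geodesic matrix — of its double-centered Gram
    form in the centered variant (classical MDS on tree geodesics), or
    of the raw geodesic matrix via SVD in the non-centered variant.
    Coordinates are oriented so that each correlates non-negatively
    with the first input feature (reproducible sign convention).
    """

    def __init__(self, base_distance: str = "euclidean", centered: bool = True):
        self.base_distance = base_distance
        self.centered = centered

    def fit_transform(self, X, y=None) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        if n < 3:
            raise ValueError("MCE requires at least 3 samples")
        if self.base_distance == "euclidean":
            D = squareform(pdist(X))
        elif self.base_distance == "correlation":
            D = squareform(pdist(X, metric="correlation"))
        else:
            raise ValueError(f"unknown base_distance {self.base_distance!r}")
        mst = minimum_spanning_tree(csr_matrix(D))
        G = shortest_path(mst, directed=False)
        self.geodesics_ = G
        if self.centered:
            J = np.eye(n) - np.ones((n, n)) / n
            B = -0.5 * J @ (G**2) @ J
            vals, vecs = np.linalg.eigh(B)
            order = np.argsort(vals)[::-1][:2]
            coords = vecs[:, order] * np.sqrt(np.clip(vals[order], 0, None))
        else:
            # the leading singular vector of a raw distance matrix is a
            # near-constant centrality component; the structure lives in
            # the next two
            u, s, _ = np.linalg.svd(G)
            coords = u[:, 1:3] * np.sqrt(s[1:3])
        for k in range(2):
            c = np.corrcoef(coords[:, k], X[:, 0])[0, 1]
            if np.isfinite(c) and c < 0:
                coords[:, k] = -coords[:, k]
        return coords

    def fit(self, X, y=None):
        self.embedding_ = self.fit_transform(X)
        return self


def mce_embed(X, base_distance: str = "euclidean", centered: bool = True) -> np.ndarray:
    """Functional wrapper over :class:`MinimumCurvilinearEmbedding`."""
    return MinimumCurvilinearEmbedding(base_distance, centered).fit_transform(X)


def ward_cluster(X, k: int) -> np.ndarray:
    """Agglomerative minimum-variance (Ward) clustering into ``k`` groups."""
    X = np.asarray(X, dtype=float)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > X.shape[0]:
        raise ValueError("k must not exceed the number of samples")
    Z = linkage(X, method="ward")
    return fcluster(Z, t=k, criterion="maxclust") - 1


def diagnosis_agreement(cluster_labels, diagnosis) -> float:
    """Balanced accuracy (%) of a binary partition against the diagnosis,
    maximized over the two label permutations (cluster ids carry no
    inherent class meaning)."""
    cluster_labels = np.asarray(cluster_labels)
    diagnosis = np.asarray(diagnosis)
    if len(cluster_labels) != len(diagnosis):
        raise ValueError("labelings must have equal length")
    if len(np.unique(diagnosis)) < 2:
        raise ValueError("diagnosis must contain both classes")
    pos = diagnosis == np.max(diagnosis)
    best = 0.0
    for flip in (False, True):
        pred = cluster_labels == (np.min(cluster_labels) if flip else np.max(cluster_labels))
        sens = (pred & pos).sum() / pos.sum()
        spec = (~pred & ~pos).sum() / (~pos).sum()
        best = max(best, (sens + spec) / 2)
    return 100.0 * best
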