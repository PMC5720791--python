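"""Post-pruning to k representatives, assignment, and the Kmeans baseline.

The tree decomposition typically ends with far more leaves than there are
tissue types.  A Lloyd Kmeans pass over the leaf-mean spectra prunes them to
``k`` final representatives (default k = 7); every signature of every image
is then assigned to its nearest representative by Euclidean distance.  The
parallel variant grows one tree per data subset, pools all leaf means into
one matrix Y and prunes Y — the result is a pure function of the set of
subsets and the master seed, independent of processing order.

The in-package Lloyd routine is deliberately deterministic: farthest-point
seeding from a seeded start, first-index tie-breaks, convergence when the
assignment stops changing or after ``max_iters`` (default 1000).  A plain
Kmeans over all signatures with the same settings serves as the flat
baseline the tree method is compared against.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

from .errors import ConsistencyError, ParameterError
from .hsi_io import SpectralMatrix
from .tree import DecompositionTree, grow_tree

__all__ = [
    "ClusterModel",
    "ClusterMap",
    "lloyd_kmeans",
    "kmeans_baseline",
    "prune_to_k",
    "assign",
    "xhc_parallel",
    "quantify_clusters",
    "save_model",
    "load_model",
]

UNLABELLED = 0


@dataclass
class ClusterModel:
    """k representative spectra plus the settings that produced them."""

    representatives: np.ndarray  # k x m
    k: int
    wavelengths: np.ndarray | None = None
    variant: str = "as_printed"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.representatives = np.asarray(self.representatives, dtype=float)
        if self.representatives.ndim != 2 or self.representatives.shape[0] != self.k:
            raise ParameterError("representatives must be a k x m matrix")


@dataclass
class ClusterMap:
    """Per-pixel label grid; 0 marks masked/unlabelled pixels, labels run 1..k."""

    labels: np.ndarray
    k: int
    image_id: str | int | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int32)
        if self.labels.ndim != 2:
            raise ParameterError("label grid must be 2D")

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return self.labels.shape


# ---------------------------------------------------------------------------
# Deterministic Lloyd Kmeans
# ---------------------------------------------------------------------------

def _farthest_point_init(points: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = points.shape[0]
    chosen = [int(rng.integers(n))]
    mind = cdist(points, points[chosen[-1]][None, :]).ravel()
    while len(chosen) < k:
        nxt = int(np.argmax(mind))
        chosen.append(nxt)
        d = cdist(points, points[nxt][None, :]).ravel()
        mind = np.minimum(mind, d)
    return points[chosen].copy()


def lloyd_kmeans(points: np.ndarray, k: int, seed=0, max_iters: int = 1000
                 ) -> tuple[np.ndarray, np.ndarray, int]:
    """Lloyd iterations with farthest-point seeding.

    ``points`` is n x m.  Returns ``(labels, centroids, n_iters)`` with
    0-based labels; assignment ties break to the lowest centroid index, and
    a cluster left empty re-seeds at the point farthest from its assigned
    centroid.  Stops when no assignment changes or at ``max_iters``.
    """
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    if k < 1:
        raise ParameterError("k must be >= 1")
    if n < k:
        raise ParameterError(f"need at least k={k} points, got {n}")
    if np.unique(points, axis=0).shape[0] < k:
        raise ParameterError(f"fewer than k={k} distinct points")

    rng = np.random.default_rng(seed)
    centroids = _farthest_point_init(points, k, rng)
    labels = np.full(n, -1, dtype=int)
    it = 0
    for it in range(1, max_iters + 1):
        d = cdist(points, centroids)
        new_labels = np.argmin(d, axis=1)  # argmin takes the first index on ties
        for j in range(k):
            sel = new_labels == j
            if sel.any():
                centroids[j] = points[sel].mean(axis=0)
            else:
                # re-seed an emptied cluster at the worst-fitting point
                worst = int(np.argmax(d[np.arange(n), new_labels]))
                centroids[j] = points[worst]
                new_labels[worst] = j
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
    return labels, centroids, it


def kmeans_baseline(X, k: int, seed=0, max_iters: int = 1000
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Flat Lloyd Kmeans over all signatures (columns of X).

    Runs until convergence or ``max_iters`` (default 1000) iterations.
    Returns 1-based labels (one per column) and the k x m centroid matrix.
    """
    arr = X.X if isinstance(X, SpectralMatrix) else np.asarray(X, dtype=float)
    labels, centroids, _ = lloyd_kmeans(arr.T, k, seed=seed, max_iters=max_iters)
    return labels + 1, centroids


# ---------------------------------------------------------------------------
# Pruning, assignment, parallel merge
# ---------------------------------------------------------------------------

def _canonical_order(representatives: np.ndarray) -> np.ndarray:
    # stable ids across runs / subset orders: sort by mean reflectance,
    # ties broken lexicographically over the bands
    keys = tuple(representatives[:, j] for j in range(representatives.shape[1] - 1, -1, -1))
    return np.lexsort(keys + (representatives.mean(axis=1),))


def _collect_leaf_means(source) -> np.ndarray:
    if isinstance(source, DecompositionTree):
        return source.leaf_means()
    if isinstance(source, (list, tuple)) and source and isinstance(source[0], DecompositionTree):
        return np.vstack([t.leaf_means() for t in source])
    Y = np.asarray(source, dtype=float)
    if Y.ndim != 2:
        raise ParameterError("leaf means must form an l x m matrix")
    return Y


def prune_to_k(trees_or_leaf_means, k: int = 7, seed=0, kmeans_iters: int = 1000,
               wavelengths=None, variant: str = "as_printed",
               provenance: dict | None = None) -> ClusterModel:
    """Prune leaf means to k representatives via Kmeans.

    Accepts a tree, a list of trees, or an l x m leaf-mean matrix Y.  The
    rows of Y are sorted lexicographically before clustering and the final
    centroids are canonically ordered, so the model depends only on the set
    of leaf means, not on their order.
    """
    Y = _collect_leaf_means(trees_or_leaf_means)
    l = Y.shape[0]
    if l < k:
        raise ParameterError(
            f"only {l} leaf means for k={k}; deepen the tree (max_depth), "
            f"lower min_leaf, or lower k"
        )
    order = np.lexsort(tuple(Y[:, j] for j in range(Y.shape[1] - 1, -1, -1)))
    _, centroids, _ = lloyd_kmeans(Y[order], k, seed=seed, max_iters=kmeans_iters)
    centroids = centroids[_canonical_order(centroids)]
    if wavelengths is None and isinstance(trees_or_leaf_means, DecompositionTree):
        wavelengths = trees_or_leaf_means.wavelengths
    prov = {"seed": seed if np.isscalar(seed) else None,
            "kmeans_iters": kmeans_iters, "n_leaf_means": int(l)}
    prov.update(provenance or {})
    return ClusterModel(representatives=centroids, k=k, wavelengths=wavelengths,
                        variant=variant, provenance=prov)


def assign(X, model: ClusterModel) -> np.ndarray:
    """Label every column of X with its nearest representative (1..k).

    Distance is plain Euclidean; equidistant columns take the lowest
    representative index.
    """
    arr = X.X if isinstance(X, SpectralMatrix) else np.asarray(X, dtype=float)
    if arr.shape[0] != model.representatives.shape[1]:
        raise ParameterError(
            f"signature length {arr.shape[0]} does not match representative "
            f"length {model.representatives.shape[1]}"
        )
    d = cdist(arr.T, model.representatives)
    return np.argmin(d, axis=1) + 1


def _subset_seed(master_seed: int, matrix: SpectralMatrix, position: int):
    import zlib

    ids = matrix.image_ids if isinstance(matrix, SpectralMatrix) else [position]
    key = zlib.crc32(",".join(str(i) for i in ids).encode()) & 0x7FFFFFFF
    return np.random.SeedSequence([int(master_seed), key])


def xhc_parallel(matrices, k: int = 7, max_depth: int = 10, min_leaf: int = 100,
                 seed: int = 0, variant: str = "as_printed",
                 kmeans_iters: int = 1000) -> ClusterModel:
    """Tree decomposition per subset, pooled leaf means, one pruning pass.

    Subset tree seeds are derived from the master seed and the subset's
    image ids, so the model is invariant under subset-order permutation; a
    single subset reduces exactly to the serial grow-then-prune path.
    """
    if not matrices:
        raise ParameterError("need at least one signature matrix")
    m_bands = {m.n_bands if isinstance(m, SpectralMatrix) else np.asarray(m).shape[0]
               for m in matrices}
    if len(m_bands) != 1:
        raise ParameterError(f"inconsistent band counts across subsets: {sorted(m_bands)}")

    trees = []
    for pos, mat in enumerate(matrices):
        sub_seed = seed if len(matrices) == 1 else _subset_seed(seed, mat, pos)
        trees.append(grow_tree(mat, max_depth=max_depth, min_leaf=min_leaf,
                               seed=sub_seed, variant=variant))
    Y = np.vstack([t.leaf_means() for t in trees])
    wavelengths = next((t.wavelengths for t in trees if t.wavelengths is not None), None)
    prov = {"n_subsets": len(matrices), "max_depth": max_depth,
            "min_leaf": min_leaf, "master_seed": int(seed)}
    return prune_to_k(Y, k=k, seed=seed, kmeans_iters=kmeans_iters,
                      wavelengths=wavelengths, variant=variant, provenance=prov)


def quantify_clusters(cluster_map: ClusterMap, roi=None) -> dict:
    """Count labelled pixels per cluster inside a region of interest.

    ``roi`` is a :class:`~xhclust.preprocess.PixelMask` (or boolean
    exclusion grid); ``None`` counts over the whole image.  Returns a dict
    with per-cluster counts (keys 1..k) and ``total`` = labelled in-ROI
    pixels; counts always sum to ``total``.
    """
    labels = cluster_map.labels
    if roi is None:
        inside = np.ones(labels.shape, dtype=bool)
    else:
        excluded = np.asarray(getattr(roi, "excluded", roi), dtype=bool)
        if excluded.shape != labels.shape:
            raise ConsistencyError("ROI shape does not match cluster map")
        inside = ~excluded
    sel = labels[inside & (labels != UNLABELLED)]
    counts = {c: int(np.sum(sel == c)) for c in range(1, cluster_map.k + 1)}
    counts["total"] = int(sel.size)
    return counts


# ---------------------------------------------------------------------------
# Model serialization (plain JSON)
# ---------------------------------------------------------------------------

def save_model(model: ClusterModel, path) -> None:
    doc = {
        "k": model.k,
        "variant": model.variant,
        "wavelengths": None if model.wavelengths is None
        else np.asarray(model.wavelengths, dtype=float).tolist(),
        "representatives": model.representatives.tolist(),
        "provenance": model.provenance,
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_model(path) -> ClusterModel:
    doc = json.loads(Path(path).read_text())
    wl = doc.get("wavelengths")
    return ClusterModel(
        representatives=np.asarray(doc["representatives"], dtype=float),
        k=int(doc["k"]),
        wavelengths=None if wl is None else np.asarray(wl, dtype=float),
        variant=doc.get("variant", "as_printed"),
        provenance=doc.get("provenance", {}),
    )
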