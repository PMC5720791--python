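"""FastMap pivot selection, 1D projection, and the variance-minimising split.

These are the primitives of extreme hierarchical clustering (XHC).  At every
tree node the data are projected onto the line through two pivot signatures
found by a farthest-point heuristic — the pivots approximate the node's most
extreme (archetypal) points — and the projection values are split at the
threshold that minimises the summed within-side mean squared deviation.

Two projection variants are provided.  ``as_printed`` uses the plain
distances,

    Proj(x) = (Dist(a,x) + Dist(a,b) - Dist(b,x)) / (2 Dist(a,b)),

which maps a -> 0 and b -> 1 and is bounded in [0, 1] by the triangle
inequality.  ``law_of_cosines`` is the classical FastMap coordinate with
squared distances,

    Proj(x) = (Dist(a,x)^2 + Dist(a,b)^2 - Dist(b,x)^2) / (2 Dist(a,b)),

the orthogonal projection of x onto the a-b line.  Both induce valid 1D
orderings; ``as_printed`` is the default.
"""

from __future__ import annotations

import numpy as np

from .errors import DegenerateNodeError, DegenerateSplitError, ParameterError

__all__ = [
    "euclidean_dist",
    "choose_pivots",
    "fastmap_project",
    "best_split",
    "PROJECTION_VARIANTS",
]

PROJECTION_VARIANTS = ("as_printed", "law_of_cosines")


def euclidean_dist(a, b) -> float:
    """Euclidean distance between two spectra, sqrt(sum_i (a_i - b_i)^2)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ParameterError(f"dimension mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.sum((a - b) ** 2)))


def _dists_from(X: np.ndarray, col: np.ndarray) -> np.ndarray:
    diff = X - col[:, None]
    return np.sqrt(np.einsum("ij,ij->j", diff, diff))


def choose_pivots(X: np.ndarray, seed=0) -> tuple[int, int]:
    """Farthest-point pivot search over the columns of ``X`` (m x n).

    Three steps: pick a seeded start column, let b be the column farthest
    from it, then let a be the column farthest from b.  Ties resolve to the
    first (lowest) index.  Returns ``(a_index, b_index)``; raises
    :class:`DegenerateNodeError` when all columns coincide.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[1]
    if n < 2:
        raise DegenerateNodeError("need at least 2 points to choose pivots")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    start = int(rng.integers(n))
    d0 = _dists_from(X, X[:, start])
    if not np.any(d0 > 0):
        raise DegenerateNodeError("all points in the node coincide")
    b = int(np.argmax(d0))
    d1 = _dists_from(X, X[:, b])
    a = int(np.argmax(d1))
    return a, b


def fastmap_project(X: np.ndarray, pivot_a, pivot_b,
                    variant: str = "as_printed") -> np.ndarray:
    """Project every column of ``X`` onto the pivot line; one value per column."""
    if variant not in PROJECTION_VARIANTS:
        raise ParameterError(f"unknown projection variant {variant!r}")
    X = np.asarray(X, dtype=float)
    a = np.asarray(pivot_a, dtype=float)
    b = np.asarray(pivot_b, dtype=float)
    d_ab = euclidean_dist(a, b)
    if d_ab == 0:
        raise DegenerateNodeError("coincident pivots: Dist(a, b) = 0")
    d_ax = _dists_from(X, a)
    d_bx = _dists_from(X, b)
    if variant == "as_printed":
        return (d_ax + d_ab - d_bx) / (2.0 * d_ab)
    return (d_ax**2 + d_ab**2 - d_bx**2) / (2.0 * d_ab)


def best_split(s) -> tuple[int, float, float]:
    """Minimise the within-side mean squared deviation over all split points.

    The values are sorted into s_1 <= ... <= s_n and every i in 1..n-1 is
    scored with

        c_i = (1/i) sum_{j<=i} (s_j - mu1)^2 + (1/(n-i)) sum_{j>i} (s_j - mu2)^2,

    where mu1, mu2 are the side means.  Returns ``(i, theta, c_i)`` for the
    minimising i (smallest i on ties) with threshold
    ``theta = (s_i + s_{i+1}) / 2``.  Raises
    :class:`DegenerateSplitError` when all values are equal.
    """
    s = np.asarray(s, dtype=float)
    n = s.size
    if n < 2:
        raise ParameterError("need at least 2 projection values to split")
    t = np.sort(s, kind="stable")
    if t[0] == t[-1]:
        raise DegenerateSplitError("all projection values are equal")

    csum = np.cumsum(t)
    csq = np.cumsum(t * t)
    i = np.arange(1, n)  # left-side counts
    left_sum = csum[i - 1]
    left_sq = csq[i - 1]
    right_sum = csum[-1] - left_sum
    right_sq = csq[-1] - left_sq
    # sum (x - mean)^2 = sum x^2 - (sum x)^2 / count, per side
    left_ss = left_sq - left_sum**2 / i
    right_ss = right_sq - right_sum**2 / (n - i)
    cost = left_ss / i + right_ss / (n - i)
    # the cumulative-sum costs can be off by an ulp from direct summation,
    # which matters only when costs tie; re-score the near-minimal
    # candidates exactly and take the smallest i among true minima
    cmin = cost.min()
    tol = 1e-9 * max(abs(cmin), 1.0) + 1e-12
    candidates = np.flatnonzero(cost <= cmin + tol)

    def exact_cost(split: int) -> float:
        left, right = t[:split], t[split:]
        return float(np.sum((left - left.mean()) ** 2) / split
                     + np.sum((right - right.mean()) ** 2) / (n - split))

    exact = {int(idx) + 1: exact_cost(int(idx) + 1) for idx in candidates}
    best_c = min(exact.values())
    split_i = min(i for i, c in exact.items() if c == best_c)
    theta = (t[split_i - 1] + t[split_i]) / 2.0
    return split_i, float(theta), best_c
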