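"""Recursive FastMap tree decomposition of a signature matrix.

Starting from all columns in one node, each node is split by projecting its
members onto the line through two farthest-point pivots and thresholding
the 1D projection at the variance-minimising cut (``Rule(x) := Proj(x) <=
theta``); members satisfying the rule go to the left (success) child, the
rest to the right (failure) child.  Recursion stops when a node is smaller
than ``2 * min_leaf`` (so no child could reach the minimum leaf size), at
``max_depth``, or when the node is degenerate (coincident points or a
constant projection).  Every leaf records its member columns and their mean
spectrum; the leaf means are what the pruning step clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateNodeError, DegenerateSplitError, ParameterError
from .fastmap import best_split, choose_pivots, fastmap_project
from .hsi_io import SpectralMatrix

__all__ = ["SplitRule", "TreeNode", "DecompositionTree", "grow_tree"]


@dataclass
class SplitRule:
    """A learned split: two pivot spectra, a variant tag, and threshold theta.

    ``evaluate`` returns True (success / left child) for signatures whose
    projection onto the pivot line is <= theta.
    """

    pivot_a: np.ndarray
    pivot_b: np.ndarray
    theta: float
    variant: str = "as_printed"

    def evaluate(self, X: np.ndarray) -> np.ndarray:
        proj = fastmap_project(X, self.pivot_a, self.pivot_b, self.variant)
        return proj <= self.theta


@dataclass
class TreeNode:
    depth: int
    members: np.ndarray  # global column indices of this node's signatures
    rule: SplitRule | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    mean: np.ndarray | None = None  # leaf mean spectrum (leaves only)

    @property
    def is_leaf(self) -> bool:
        return self.rule is None

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class DecompositionTree:
    """Binary tree of split rules over the columns of one signature matrix."""

    root: TreeNode
    max_depth: int
    min_leaf: int
    seed: int
    variant: str
    n_signatures: int
    wavelengths: np.ndarray | None = None

    def leaves(self) -> list[TreeNode]:
        out: list[TreeNode] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                out.append(node)
            else:
                stack.extend([node.right, node.left])
        return out

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    def leaf_means(self) -> np.ndarray:
        """Matrix of leaf mean spectra, one row per leaf (l x m)."""
        return np.vstack([leaf.mean for leaf in self.leaves()])

    def depth(self) -> int:
        best = 0
        stack = [self.root]
        while stack:
            node = stack.pop()
            best = max(best, node.depth)
            if not node.is_leaf:
                stack.extend([node.left, node.right])
        return best


def _grow(X: np.ndarray, members: np.ndarray, depth: int, seed_seq,
          max_depth: int, min_leaf: int, variant: str) -> TreeNode:
    node = TreeNode(depth=depth, members=members)
    sub = X[:, members]
    if len(members) < 2 * min_leaf or depth >= max_depth:
        node.mean = sub.mean(axis=1)
        return node
    try:
        a_idx, b_idx = choose_pivots(sub, np.random.default_rng(seed_seq))
        proj = fastmap_project(sub, sub[:, a_idx], sub[:, b_idx], variant)
        _, theta, _ = best_split(proj)
    except (DegenerateNodeError, DegenerateSplitError):
        node.mean = sub.mean(axis=1)
        return node
    success = proj <= theta
    # duplicate projection values can push every member to one side; such a
    # node cannot be split and becomes a leaf
    if success.all() or not success.any():
        node.mean = sub.mean(axis=1)
        return node
    node.rule = SplitRule(sub[:, a_idx].copy(), sub[:, b_idx].copy(),
                          float(theta), variant)
    left_seq, right_seq = seed_seq.spawn(2)
    node.left = _grow(X, members[success], depth + 1, left_seq,
                      max_depth, min_leaf, variant)
    node.right = _grow(X, members[~success], depth + 1, right_seq,
                       max_depth, min_leaf, variant)
    return node


def grow_tree(X, max_depth: int = 10, min_leaf: int = 100, seed=0,
              variant: str = "as_printed") -> DecompositionTree:
    """Grow a FastMap decomposition tree over the columns of ``X``.

    ``X`` is a :class:`SpectralMatrix` or a plain ``m x n`` array.  Defaults
    follow the reference workflow: ``max_depth=10`` and a minimum leaf of
    100 signatures.  The build is a pure function of ``(X, parameters,
    seed)``; per-node random choices derive from a spawned seed tree, so the
    result does not depend on traversal order.
    """
    wavelengths = None
    if isinstance(X, SpectralMatrix):
        wavelengths = X.wavelengths
        arr = X.X
    else:
        arr = np.asarray(X, dtype=float)
    if arr.ndim != 2 or arr.shape[1] == 0:
        raise ParameterError("X must be a non-empty m x n matrix")
    if min_leaf < 1:
        raise ParameterError("min_leaf must be >= 1")
    if max_depth < 0:
        raise ParameterError("max_depth must be >= 0")

    seed_seq = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    seed_label = int(seed_seq.entropy) if np.isscalar(seed_seq.entropy) else -1
    root = _grow(arr, np.arange(arr.shape[1]), 0, seed_seq,
                 max_depth, min_leaf, variant)
    return DecompositionTree(root=root, max_depth=max_depth, min_leaf=min_leaf,
                             seed=seed_label, variant=variant,
                             n_signatures=arr.shape[1], wavelengths=wavelengths)
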