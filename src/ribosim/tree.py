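"""Binary propensity tree for logarithmic-time event selection.

Leaves hold the partial propensity sums phi_i of the reactions local to
each mRNA (plus one dedicated leaf for pool-level reactions); internal
nodes hold the sums of their children and the root holds the total
propensity Phi.  Selection descends from the root choosing the branch
containing r*Phi, and an update re-traces one root-to-leaf path, so both
cost O(log2 N) per event.

Internal nodes are always recomputed as the exact sum of their children
(never via deltas), so the node-sum invariant holds to floating-point
associativity, not to accumulated drift.
"""

from __future__ import annotations

import numpy as np

__all__ = ["PropensityTree", "build_tree", "select_index", "update_leaf"]


class PropensityTree:
    """Complete binary tree over ``n`` nonnegative leaf propensities."""

    __slots__ = ("n", "cap", "nodes", "last_touched")

    def __init__(self, leaves) -> None:
        leaves = np.asarray(leaves, dtype=float)
        if leaves.ndim != 1:
            raise ValueError("leaves must be a 1-D sequence")
        if (leaves < 0).any():
            raise ValueError("negative leaf propensity")
        self.n = len(leaves)
        cap = 1
        while cap < max(self.n, 1):
            cap *= 2
        self.cap = cap
        # 1-based heap layout: node k has children 2k, 2k+1; leaves at cap+i
        self.nodes = np.zeros(2 * cap, dtype=float)
        self.nodes[cap:cap + self.n] = leaves
        for k in range(cap - 1, 0, -1):
            self.nodes[k] = self.nodes[2 * k] + self.nodes[2 * k + 1]
        self.last_touched = 0

    @property
    def root(self) -> float:
        return float(self.nodes[1]) if self.n else 0.0

    def leaf(self, i: int) -> float:
        return float(self.nodes[self.cap + i])

    def leaves(self) -> np.ndarray:
        return self.nodes[self.cap:self.cap + self.n].copy()

    def update(self, i: int, value: float) -> None:
        """Set leaf ``i`` to ``value`` and restore sums along its path.

        ``last_touched`` records how many nodes were written (the path
        length, ceil(log2 n) + 1), asserting the logarithmic cost."""
        if value < 0:
            raise ValueError("negative leaf propensity")
        if not 0 <= i < self.n:
            raise IndexError(f"leaf {i} out of range")
        k = self.cap + i
        self.nodes[k] = value
        touched = 1
        k //= 2
        while k >= 1:
            self.nodes[k] = self.nodes[2 * k] + self.nodes[2 * k + 1]
            touched += 1
            k //= 2
        self.last_touched = touched

    def select(self, r: float) -> int:
        """Smallest index eta with cumulative leaf sum > r * Phi.

        ``r`` is uniform on [0, 1); the root must be positive."""
        total = self.root
        if total <= 0.0:
            raise ValueError("cannot select from a tree with zero total")
        target = r * total
        nodes = self.nodes
        k = 1
        while k < self.cap:
            left = nodes[2 * k]
            if target < left:
                k = 2 * k
            else:
                target -= left
                k = 2 * k + 1
        i = k - self.cap
        if i >= self.n:  # float round-off at the upper edge
            i = self.n - 1
            while i > 0 and nodes[self.cap + i] == 0.0:
                i -= 1
        return i

    def check_consistency(self, rtol: float = 1e-9) -> None:
        """Assert every internal node equals the sum of its children."""
        nodes = self.nodes
        for k in range(1, self.cap):
            s = nodes[2 * k] + nodes[2 * k + 1]
            if abs(nodes[k] - s) > rtol * max(1.0, abs(s)):
                raise AssertionError(f"node {k} inconsistent: {nodes[k]} != {s}")


def build_tree(phis) -> PropensityTree:
    """Build a tree over per-mRNA propensity sums; root = sum(phis)."""
    return PropensityTree(phis)


def select_index(tree: PropensityTree, r: float) -> int:
    """0-based index of the selected leaf (see :meth:`PropensityTree.select`)."""
    return tree.select(r)


def update_leaf(tree: PropensityTree, eta: int, new_phi: float) -> PropensityTree:
    tree.update(eta, new_phi)
    return tree
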