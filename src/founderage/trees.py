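"""Array-backed intra-allelic genealogies.

A genealogy relates the sampled copies of the mutant allele back to the
founding mutation.  Nodes ``0..n-1`` are the sampled leaves (age 0);
internal nodes are numbered in coalescence order ``n..2n-2`` with the
last internal node the root (MRCA).  ``origin_time`` is the age of the
founding mutation itself, so the stem branch above the MRCA has length
``origin_time - time[root]``.  Ages are in generations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class Genealogy:
    n_leaves: int
    parent: np.ndarray  # (2n-1,) int; parent[root] == -1
    time: np.ndarray  # (2n-1,) float node ages; leaves 0
    origin_time: float

    def __post_init__(self) -> None:
        n = self.n_leaves
        if n < 1:
            raise ValueError("a genealogy needs at least one leaf")
        expected = max(2 * n - 1, 1)
        if len(self.parent) != expected or len(self.time) != expected:
            raise ValueError("parent/time arrays must have length 2n-1")
        if self.origin_time + 1e-12 < float(self.time.max()):
            raise ValueError("origin_time must be at least the root age")

    @property
    def root(self) -> int:
        return 2 * self.n_leaves - 2 if self.n_leaves > 1 else 0

    def branch_length(self, node: int) -> float:
        p = self.parent[node]
        top = self.origin_time if p < 0 else self.time[p]
        return float(top - self.time[node])

    def children(self) -> list[list[int]]:
        kids: list[list[int]] = [[] for _ in range(len(self.parent))]
        for v, p in enumerate(self.parent):
            if p >= 0:
                kids[p].append(v)
        return kids

    def postorder(self) -> list[int]:
        kids = self.children()
        order: list[int] = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(kids[v])
        return order[::-1]

    def leaf_path_lengths(self) -> np.ndarray:
        """Total branch length from each leaf up to the origin (= origin_time)."""
        return np.full(self.n_leaves, self.origin_time)


def star_genealogy(n: int, t: float) -> Genealogy:
    """All leaves attach directly to a root of age ``t`` (zero-length stem)."""
    if n == 1:
        return Genealogy(1, np.array([-1]), np.array([0.0]), float(t))
    size = 2 * n - 1
    parent = np.full(size, -1, dtype=np.int64)
    time = np.zeros(size)
    root = size - 1
    # chain the surplus internal nodes at the root age so the tree stays binary
    internals = list(range(n, size))
    time[internals] = float(t)
    parent[0] = internals[0]
    parent[1] = internals[0]
    for k, node in enumerate(internals[:-1]):
        parent[node] = internals[k + 1]
        parent[k + 2] = internals[k + 1]
    return Genealogy(n, parent, time, float(t))


def join_coalescents(coal_times: np.ndarray, origin_time: float, rng: np.random.Generator) -> Genealogy:
    """Build a genealogy from sorted coalescence ages with uniform random joins."""
    times = np.asarray(coal_times, dtype=float)
    n = len(times) + 1
    if n == 1:
        return Genealogy(1, np.array([-1]), np.array([0.0]), float(origin_time))
    if np.any(np.diff(times) < 0):
        raise ValueError("coalescence times must be sorted ascending")
    size = 2 * n - 1
    parent = np.full(size, -1, dtype=np.int64)
    node_time = np.zeros(size)
    active = list(range(n))
    nxt = n
    for s in times:
        i = int(rng.integers(len(active)))
        a = active.pop(i)
        j = int(rng.integers(len(active)))
        b = active.pop(j)
        parent[a] = nxt
        parent[b] = nxt
        node_time[nxt] = s
        active.append(nxt)
        nxt += 1
    return Genealogy(n, parent, node_time, float(origin_time))
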