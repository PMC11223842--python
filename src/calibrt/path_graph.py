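"""Maximum-weight ascending path through the retained grid cells.

The retained cells form the nodes of a weighted DAG.  A directed edge runs
from cell ``u`` to cell ``v`` whenever ``v`` is at least as large as ``u`` in
both grid indices (and differs from it), so every path is monotone
non-decreasing on both RT axes.  The edge weight is the product of the two
cell frequencies divided by the edge length, with length measured in
grid-index units so the search is invariant to the axis scales.  The node set
of the maximum-weight-sum path is what gets fitted.

Because the node count is bounded by the grid perimeter, the O(K^2) dynamic
program runs in constant time with respect to the raw data size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .exceptions import EmptyInputError, InvalidEdgeError


@dataclass(frozen=True, order=True)
class PathNode:
    """A retained grid cell: indices, representative coordinates, frequency."""

    ix: int
    iy: int
    x: float = field(compare=False)
    y: float = field(compare=False)
    freq: int = field(compare=False, default=1)

    def __post_init__(self) -> None:
        if self.freq < 1:
            raise ValueError("node frequency must be >= 1")


@dataclass(frozen=True)
class AscendingPath:
    """An ordered, componentwise non-decreasing node sequence and its weight."""

    nodes: tuple
    total_weight: float

    def __len__(self) -> int:
        return len(self.nodes)


def edge_weight(u: PathNode, v: PathNode) -> float:
    """freq(u) * freq(v) / Euclidean index distance; requires u != v."""
    dx, dy = v.ix - u.ix, v.iy - u.iy
    if dx == 0 and dy == 0:
        raise InvalidEdgeError("zero-length edge between identical cells")
    return u.freq * v.freq / math.hypot(dx, dy)


def path_weight(nodes) -> float:
    return sum(edge_weight(u, v) for u, v in zip(nodes, nodes[1:]))


def max_weight_path(nodes) -> AscendingPath:
    """Dynamic program for the maximum-weight monotone path.

    Nodes are processed in (ix, iy) order; any comparable pair may be an
    edge (not only grid neighbours).  Ties on total weight prefer the path
    with more nodes, then the lexicographically smallest index sequence.  A
    single node is a valid path of weight 0.
    """
    nodes = sorted(set(nodes))
    if not nodes:
        raise EmptyInputError("cannot search a path over an empty node set")
    k = len(nodes)
    best_w = [0.0] * k  # best weight of a path ending at node i
    best_n = [1] * k  # node count of that path
    pred = [-1] * k
    for i in range(k):
        vi = nodes[i]
        for j in range(i):
            vj = nodes[j]
            if vj.ix <= vi.ix and vj.iy <= vi.iy:
                w = best_w[j] + edge_weight(vj, vi)
                n = best_n[j] + 1
                # strict improvement, or equal weight with more nodes; on a
                # full tie keep the earliest predecessor (sorted order makes
                # that the lexicographically smallest sequence)
                if w > best_w[i] or (w == best_w[i] and n > best_n[i]):
                    best_w[i], best_n[i], pred[i] = w, n, j
    end = 0
    for i in range(1, k):
        if best_w[i] > best_w[end] or (
            best_w[i] == best_w[end] and best_n[i] > best_n[end]
        ):
            end = i
    chain = []
    i = end
    while i != -1:
        chain.append(nodes[i])
        i = pred[i]
    chain.reverse()
    return AscendingPath(nodes=tuple(chain), total_weight=best_w[end])


def brute_force_max_weight_path(nodes) -> AscendingPath:
    """Exhaustive enumeration of every monotone path; oracle for tiny inputs.

    Exponential in the node count -- test use only.
    """
    nodes = sorted(set(nodes))
    if not nodes:
        raise EmptyInputError("cannot search a path over an empty node set")
    best = AscendingPath(nodes=(nodes[0],), total_weight=0.0)

    def extend(chain, weight):
        nonlocal best
        if weight > best.total_weight or (
            weight == best.total_weight
            and (len(chain) > len(best.nodes) or (len(chain) == len(best.nodes) and tuple(chain) < best.nodes))
        ):
            best = AscendingPath(nodes=tuple(chain), total_weight=weight)
        tail = chain[-1]
        for v in nodes:
            if v != tail and tail.ix <= v.ix and tail.iy <= v.iy:
                extend(chain + [v], weight + edge_weight(tail, v))

    for start in nodes:
        extend([start], 0.0)
    return best
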