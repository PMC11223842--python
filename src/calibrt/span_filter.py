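"""Optional trimming of wide-span path endpoints.

True calibration points are dense mid-gradient and sparse at the ends, so
path nodes separated from the rest by a large gap at either end are more
likely to be noise than signal.  When enabled, the filter iteratively drops
an end node whose gap to its inner neighbour exceeds a fraction of the full
data range (10% by default) in either dimension.  Disabled by default: with
in-range noise every point deserves equal consideration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .path_graph import AscendingPath, path_weight

DEFAULT_SPAN_THRESHOLD = 0.10


@dataclass(frozen=True)
class SpanConfig:
    enabled: bool = False
    threshold: float = DEFAULT_SPAN_THRESHOLD  # fraction of the full range, both axes

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("span threshold must be in (0, 1)")


def filter_span(
    path: AscendingPath, config: SpanConfig, x_range: float, y_range: float
) -> AscendingPath:
    """Trim end nodes whose gap to their inner neighbour exceeds the span.

    Trimming repeats from each new end until both end gaps are within the
    allowable span or only two nodes remain; interior nodes are never
    removed, so the result is a contiguous subsequence of the input.
    """
    if not config.enabled or len(path) <= 2:
        return path
    if x_range <= 0 or y_range <= 0:
        raise ValueError("ranges must be positive")
    max_dx = config.threshold * x_range
    max_dy = config.threshold * y_range
    nodes = list(path.nodes)

    def wide(a, b) -> bool:
        return abs(b.x - a.x) > max_dx or abs(b.y - a.y) > max_dy

    changed = True
    while changed and len(nodes) > 2:
        changed = False
        if wide(nodes[0], nodes[1]):
            nodes.pop(0)
            changed = True
        if len(nodes) > 2 and wide(nodes[-2], nodes[-1]):
            nodes.pop()
            changed = True
    if len(nodes) == len(path.nodes):
        return path
    return AscendingPath(nodes=tuple(nodes), total_weight=path_weight(nodes))
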