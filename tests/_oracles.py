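"""Independent oracles used only by the test suite.

These deliberately avoid the library's own code paths: the cutoff oracle is
a plain-Python exhaustive scan over a dense bin list, and the tree-distance
oracle runs breadth-first search over an adjacency graph built directly from
the tree's edges.
"""

from __future__ import annotations

from collections import deque


def cutoff_scan_oracle(
    counts: dict[float, float],
    bin_width: float = 1.0,
    min_peak_support: int = 5,
) -> tuple[float | None, str]:
    """Exhaustive first-local-minimum scan over all bins (no numpy, no smoothing)."""
    support = sum(c for edge, c in counts.items() if edge + bin_width > 99.0)
    if support < min_peak_support:
        return None, "no_peak"
    max_edge = max(counts) if counts else 100.0 - bin_width
    n = int(round(max_edge / bin_width)) + 1
    dense = [0.0] * n
    for edge, c in counts.items():
        dense[int(round(edge / bin_width))] += c
    for i in range(n - 2, 0, -1):
        if dense[i] <= dense[i + 1] and dense[i] < dense[i - 1]:
            return i * bin_width, "found"
    return None, "degenerate"


def bfs_leaf_distance(phylo, a: str, b: str) -> int:
    """Edge count between two leaves via BFS on the tree's adjacency graph."""
    adj: dict[int, list[int]] = {}
    nodes = {}
    for node in phylo.tree.preorder_node_iter():
        nodes[id(node)] = node
        for child in node.child_nodes():
            adj.setdefault(id(node), []).append(id(child))
            adj.setdefault(id(child), []).append(id(node))
    start = id(phylo.leaf_index[a])
    goal = id(phylo.leaf_index[b])
    seen = {start: 0}
    queue = deque([start])
    while queue:
        cur = queue.popleft()
        if cur == goal:
            return seen[cur]
        for nxt in adj.get(cur, []):
            if nxt not in seen:
                seen[nxt] = seen[cur] + 1
                queue.append(nxt)
    raise ValueError("no path between leaves")
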