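"""Minimal unrooted weighted trees for neighbour-joining output.

Kept deliberately small: an undirected adjacency structure with branch
lengths, Newick export, tip-to-tip path lengths and bipartition extraction —
everything the distance-tree analyses and their additivity oracles need.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["UnrootedTree"]


@dataclass
class UnrootedTree:
    """Undirected tree: node ids 0..n-1, tips carry labels."""

    tip_labels: dict[int, str] = field(default_factory=dict)
    adjacency: dict[int, list[tuple[int, float]]] = field(default_factory=dict)

    def add_node(self) -> int:
        node = len(self.adjacency)
        self.adjacency[node] = []
        return node

    def add_tip(self, label: str) -> int:
        node = self.add_node()
        self.tip_labels[node] = label
        return node

    def add_edge(self, a: int, b: int, length: float) -> None:
        self.adjacency[a].append((b, float(length)))
        self.adjacency[b].append((a, float(length)))

    @property
    def tips(self) -> list[str]:
        return [self.tip_labels[n] for n in sorted(self.tip_labels)]

    def path_length_matrix(self, labels: list[str] | None = None) -> np.ndarray:
        """Tip-to-tip path-length matrix in the given (or sorted-id) order."""
        labels = labels if labels is not None else self.tips
        node_of = {lab: n for n, lab in self.tip_labels.items()}
        k = len(labels)
        out = np.zeros((k, k))
        for i, lab in enumerate(labels):
            dist = self._distances_from(node_of[lab])
            for j, lab2 in enumerate(labels):
                out[i, j] = dist[node_of[lab2]]
        return out

    def _distances_from(self, start: int) -> dict[int, float]:
        dist = {start: 0.0}
        stack = [start]
        while stack:
            u = stack.pop()
            for v, w in self.adjacency[u]:
                if v not in dist:
                    dist[v] = dist[u] + w
                    stack.append(v)
        return dist

    def bipartitions(self) -> dict[frozenset[str], float]:
        """Internal-edge bipartitions, each keyed by the tip set on the side
        away from the highest-numbered node, mapped to the edge length."""
        out: dict[frozenset[str], float] = {}
        seen = set()
        for u in self.adjacency:
            for v, w in self.adjacency[u]:
                key = (min(u, v), max(u, v))
                if key in seen:
                    continue
                seen.add(key)
                if u in self.tip_labels or v in self.tip_labels:
                    continue  # pendant edge, trivial bipartition
                side = self._tips_on_side(u, v)
                all_tips = frozenset(self.tip_labels.values())
                canonical = min(side, all_tips - side, key=lambda s: sorted(s))
                out[frozenset(canonical)] = w
        return out

    def _tips_on_side(self, keep: int, cut: int) -> frozenset[str]:
        """Tips reachable from ``keep`` when the edge to ``cut`` is removed."""
        visited = {keep, cut}
        stack = [keep]
        tips = set()
        while stack:
            u = stack.pop()
            if u in self.tip_labels:
                tips.add(self.tip_labels[u])
            for v, _ in self.adjacency[u]:
                if v not in visited:
                    visited.add(v)
                    stack.append(v)
        return frozenset(tips)

    def newick(self) -> str:
        """Newick string rooted at an arbitrary internal node (or a tip for
        trees with fewer than three leaves)."""
        internal = [n for n in self.adjacency if n not in self.tip_labels]
        root = internal[0] if internal else next(iter(self.adjacency))
        return self._newick_from(root, None) + ";"

    def _newick_from(self, node: int, parent: int | None) -> str:
        children = [(v, w) for v, w in self.adjacency[node] if v != parent]
        if not children:
            return self.tip_labels.get(node, "")
        parts = []
        for v, w in children:
            sub = self._newick_from(v, node)
            parts.append(f"{sub}:{w:.10g}")
        label = self.tip_labels.get(node, "")
        return f"({','.join(parts)}){label}"
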