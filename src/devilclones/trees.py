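"""Rooted clone genealogies.

A :class:`CloneTree` is a rooted tree whose nodes may carry dates (decimal
years) and whose edges (identified with their child node) may carry per-class
mutation counts.  It serves both as the simulator's transmission tree, where
every attribute is ground truth, and as the inferred phylogeny, where dates
are estimated by the strict-clock sampler.

Polytomies are first-class: nodes may have any out-degree.
"""

from __future__ import annotations

from typing import Iterable, Iterator

import numpy as np

__all__ = ["CloneTree"]


class CloneTree:
    """Rooted tree over integer node ids with optional dates and edge counts.

    Parameters
    ----------
    parent
        Mapping child node id -> parent node id; the root is absent.
    dates
        Mapping node id -> decimal-year date (may be partial: tips only).
    labels
        Mapping tip node id -> sample id.
    """

    def __init__(
        self,
        parent: dict[int, int],
        dates: dict[int, float] | None = None,
        labels: dict[int, str] | None = None,
    ) -> None:
        self.parent: dict[int, int] = dict(parent)
        self.children: dict[int, list[int]] = {}
        nodes = set(self.parent) | set(self.parent.values())
        if not self.parent:
            nodes = {0}
        for n in nodes:
            self.children.setdefault(n, [])
        for child, par in self.parent.items():
            self.children[par].append(child)
        roots = [n for n in nodes if n not in self.parent]
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {roots}")
        self.root: int = roots[0]
        self.dates: dict[int, float] = dict(dates or {})
        self.labels: dict[int, str] = dict(labels or {})
        # per-edge mutation counts, keyed by child node then class name
        self.branch_counts: dict[int, dict[str, int]] = {}
        # per-edge variant id lists (filled by the simulator / tree builder)
        self.branch_variants: dict[int, list] = {}

    # ---------------------------------------------------------------- basics
    @property
    def nodes(self) -> list[int]:
        return sorted(self.children)

    def tips(self) -> list[int]:
        return [n for n in self.nodes if not self.children[n]]

    def tip_labels(self) -> list[str]:
        return [self.labels.get(n, str(n)) for n in self.tips()]

    def n_tips(self) -> int:
        return len(self.tips())

    def is_tip(self, node: int) -> bool:
        return not self.children[node]

    def postorder(self) -> Iterator[int]:
        stack, out = [self.root], []
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(self.children[n])
        return iter(reversed(out))

    def preorder(self) -> Iterator[int]:
        stack = [self.root]
        while stack:
            n = stack.pop()
            yield n
            stack.extend(reversed(self.children[n]))

    def branch_duration(self, node: int) -> float:
        """Duration in years of the edge above ``node``."""
        return self.dates[node] - self.dates[self.parent[node]]

    def clade_tipset(self, node: int) -> frozenset[str]:
        """Labels of all tips at or below ``node``."""
        out = []
        stack = [node]
        while stack:
            n = stack.pop()
            if self.is_tip(n):
                out.append(self.labels.get(n, str(n)))
            stack.extend(self.children[n])
        return frozenset(out)

    def tipsets(self) -> dict[int, frozenset[str]]:
        """Tip set below every node, computed in one postorder sweep."""
        sets: dict[int, frozenset[str]] = {}
        for n in self.postorder():
            if self.is_tip(n):
                sets[n] = frozenset([self.labels.get(n, str(n))])
            else:
                acc: set[str] = set()
                for c in self.children[n]:
                    acc |= sets[c]
                sets[n] = frozenset(acc)
        return sets

    def path_to_root(self, node: int) -> list[int]:
        path = [node]
        while path[-1] != self.root:
            path.append(self.parent[path[-1]])
        return path

    def total_count(self, node: int, var_class: str | None = None) -> int:
        """Sum of branch counts on the root-to-``node`` path."""
        total = 0
        for n in self.path_to_root(node):
            if n == self.root:
                continue
            counts = self.branch_counts.get(n, {})
            if var_class is None:
                total += sum(counts.values())
            else:
                total += counts.get(var_class, 0)
        return total

    def depth(self, node: int) -> int:
        return len(self.path_to_root(node)) - 1

    # ---------------------------------------------------------------- export
    def newick(self, branch_units: str = "years") -> str:
        """Newick string with branch lengths in ``years`` or ``mutations``."""

        def length(node: int) -> float:
            if branch_units == "years":
                return self.dates[node] - self.dates[self.parent[node]]
            if branch_units == "mutations":
                return float(sum(self.branch_counts.get(node, {}).values()))
            raise ValueError("branch_units must be 'years' or 'mutations'")

        def render(node: int) -> str:
            if self.is_tip(node):
                core = self.labels.get(node, str(node))
            else:
                core = "(" + ",".join(render(c) for c in self.children[node]) + ")"
            if node == self.root:
                return core
            return f"{core}:{length(node):.6f}"

        return render(self.root) + ";"

    # -------------------------------------------------------------- topology
    def topology_key(self) -> frozenset[frozenset[str]]:
        """Unordered set of non-trivial clades; equal keys = same topology."""
        sets = self.tipsets()
        all_tips = sets[self.root]
        return frozenset(
            s
            for n, s in sets.items()
            if n != self.root and 1 < len(s) < len(all_tips)
        )

    def copy(self) -> "CloneTree":
        t = CloneTree(self.parent, self.dates, self.labels)
        t.branch_counts = {k: dict(v) for k, v in self.branch_counts.items()}
        t.branch_variants = {k: list(v) for k, v in self.branch_variants.items()}
        return t

    def __repr__(self) -> str:  # pragma: no cover
        return f"CloneTree(n_tips={self.n_tips()}, n_nodes={len(self.nodes)})"


def robinson_foulds(a: CloneTree, b: CloneTree) -> int:
    """Unrooted-style symmetric clade-set difference between two rooted trees."""
    ka, kb = a.topology_key(), b.topology_key()
    return len(ka ^ kb)
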