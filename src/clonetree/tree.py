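"""Clonal lineage trees: data structure, structural queries and edit moves.

A clonal lineage tree is a rooted directed tree over clones ``1..N`` whose
root (clone 1) is the unmutated normal.  Each non-root clone holds zero or
more sampled cells; a clone with at least one cell is *observed*, a cell-free
non-root clone is an *unobserved* (latent) clone.  Under the infinite-sites
assumption, the mutation set of a clone is a subset of every descendant's
mutation set, which is what the ancestry matrix encodes.

Edit moves defined here are exactly the ones the inference uses:

* ``neighbors`` — single-subtree prune-and-regraft, the local move of the
  initial search;
* ``insert_node_at_branch_point`` — the unobserved-clone insertion move;
* ``merge_edge`` — merging a child clone into its parent (cell clustering);
* ``prune_linear_unobserved`` — removal of latent clones that are not branch
  points and therefore carry no inferable signal.

All operations are functional: they return new trees and never mutate their
input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "ClonalTree",
    "star_tree",
    "ancestry",
    "neighbors",
    "neighbor_moves",
    "apply_move",
    "insert_node_at_branch_point",
    "merge_edge",
    "prune_linear_unobserved",
    "write_edge_list",
    "read_edge_list",
    "to_newick",
    "to_dot",
]

ROOT = 1


@dataclass(frozen=True)
class ClonalTree:
    """Rooted directed tree of clones with a cell-to-clone assignment.

    Parameters
    ----------
    parent : numpy.ndarray
        Length ``N + 1``; ``parent[c]`` is the parent clone of ``c`` for
        ``c in 2..N``.  Index 0 is unused and ``parent[1]`` (the root) is 0.
    assignment : numpy.ndarray
        Length ``n_cells``; ``assignment[k]`` is the clone containing cell
        ``k``.  The root never holds cells.
    cells : tuple of str
        Cell identifiers aligned with ``assignment``.
    """

    parent: np.ndarray = field(repr=False)
    assignment: np.ndarray = field(repr=False)
    cells: tuple[str, ...]

    def __post_init__(self) -> None:
        parent = np.array(self.parent, dtype=np.int64)
        parent[0] = 0  # canonical padding so key() is representation-independent
        assignment = np.asarray(self.assignment, dtype=np.int64)
        parent.setflags(write=False)
        assignment.setflags(write=False)
        object.__setattr__(self, "parent", parent)
        object.__setattr__(self, "assignment", assignment)
        object.__setattr__(self, "cells", tuple(str(c) for c in self.cells))
        self._validate()

    @property
    def n_clones(self) -> int:
        """Total number of clones N, root included."""
        return len(self.parent) - 1

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def clones(self) -> range:
        return range(1, self.n_clones + 1)

    def children(self, c: int) -> np.ndarray:
        return np.flatnonzero(self.parent == c)

    def n_children(self) -> np.ndarray:
        """Child counts indexed by clone (index 0 unused)."""
        counts = np.zeros(self.n_clones + 1, dtype=np.int64)
        np.add.at(counts, self.parent[2:], 1)
        return counts

    def cell_counts(self) -> np.ndarray:
        """Number of cells per clone, indexed by clone (index 0 unused)."""
        counts = np.zeros(self.n_clones + 1, dtype=np.int64)
        np.add.at(counts, self.assignment, 1)
        return counts

    def observed(self) -> np.ndarray:
        """Boolean mask over clones 0..N: True where the clone holds cells."""
        return self.cell_counts() > 0

    def cells_of(self, c: int) -> list[str]:
        return [self.cells[k] for k in np.flatnonzero(self.assignment == c)]

    def depths(self) -> np.ndarray:
        """Edge distance from the root, indexed by clone (root depth 0)."""
        depth = np.zeros(self.n_clones + 1, dtype=np.int64)
        for c in self._topological_order()[1:]:
            depth[c] = depth[self.parent[c]] + 1
        return depth

    def _topological_order(self) -> list[int]:
        """Clones ordered root-first so that parents precede children."""
        kids: list[list[int]] = [[] for _ in range(self.n_clones + 1)]
        for c in range(2, self.n_clones + 1):
            kids[self.parent[c]].append(c)
        order, stack = [], [ROOT]
        while stack:
            c = stack.pop()
            order.append(c)
            stack.extend(reversed(kids[c]))
        return order

    def key(self) -> bytes:
        """Hashable canonical form (labels are part of the identity)."""
        return self.parent.tobytes() + b"|" + self.assignment.tobytes()

    def _validate(self) -> None:
        N = self.n_clones
        if N < 1:
            raise ValueError("tree needs at least the root clone")
        if self.parent[ROOT] != 0:
            raise ValueError("root (clone 1) must have parent sentinel 0")
        if len(self.assignment) != len(self.cells):
            raise ValueError("assignment length does not match cell list")
        if len(set(self.cells)) != len(self.cells):
            raise ValueError("duplicate cell identifiers")
        if self.n_cells and N < 2:
            raise ValueError("a tree holding cells needs at least one tumor clone")
        p = self.parent[2 : N + 1]
        if len(p) and (p.min() < 1 or p.max() > N):
            raise ValueError("parent labels out of range")
        # acyclicity + connectivity: every clone must reach the root
        for c in range(2, N + 1):
            seen, cur = 0, c
            while cur != ROOT:
                cur = int(self.parent[cur])
                seen += 1
                if seen > N:
                    raise ValueError(f"parent map contains a cycle through clone {c}")
        if self.n_cells:
            if self.assignment.min() < 2 or self.assignment.max() > N:
                raise ValueError("cells must be assigned to non-root clones")


def _unsafe_tree(parent: np.ndarray, assignment: np.ndarray, cells: tuple[str, ...]) -> ClonalTree:
    """Construct without validation; for moves whose validity is guaranteed."""
    obj = object.__new__(ClonalTree)
    parent.setflags(write=False)
    object.__setattr__(obj, "parent", parent)
    object.__setattr__(obj, "assignment", assignment)
    object.__setattr__(obj, "cells", cells)
    return obj


def star_tree(cells: list[str]) -> ClonalTree:
    """Start tree of the search: every cell its own clone, all under the root."""
    cells = list(cells)
    if not cells:
        raise ValueError("star tree needs at least one cell")
    n = len(cells)
    parent = np.zeros(n + 2, dtype=np.int64)
    parent[2:] = ROOT
    assignment = np.arange(2, n + 2, dtype=np.int64)
    return ClonalTree(parent, assignment, tuple(cells))


def ancestry(T: ClonalTree) -> np.ndarray:
    """Ancestry matrix A with ``A[c, d]`` True iff ``d`` is ``c`` or below ``c``.

    Row/column index 0 is unused padding.  Row ``c`` is the genotype pattern
    predicted for a mutation originating in clone ``c``: present in ``c`` and
    all of its descendants, absent elsewhere.
    """
    N = T.n_clones
    A = np.zeros((N + 1, N + 1), dtype=bool)
    for c in reversed(T._topological_order()):
        A[c, c] = True
        if c != ROOT:
            A[T.parent[c]] |= A[c]
    A[0, 0] = False
    return A


def neighbor_moves(T: ClonalTree, A: np.ndarray | None = None) -> list[tuple[int, int]]:
    """Prune-and-regraft moves ``(v, t)``: reattach clone ``v`` below ``t``.

    ``v`` ranges over non-root clones and ``t`` over clones outside the
    subtree of ``v`` other than the current parent, so every move yields a
    valid tree distinct from ``T`` and no two moves yield the same tree.
    """
    if A is None:
        A = ancestry(T)
    moves: list[tuple[int, int]] = []
    for v in range(2, T.n_clones + 1):
        inside = A[v]
        for t in T.clones:
            if not inside[t] and t != T.parent[v]:
                moves.append((v, t))
    return moves


def apply_move(T: ClonalTree, v: int, t: int) -> ClonalTree:
    """Tree resulting from reattaching clone ``v`` (with subtree) below ``t``."""
    parent = T.parent.copy()
    parent[v] = t
    return _unsafe_tree(parent, T.assignment, T.cells)


def neighbors(T: ClonalTree) -> list[ClonalTree]:
    """All single-subtree prune-and-regraft neighbors of ``T``.

    Each non-root clone is detached together with its subtree and reattached
    to every clone outside that subtree other than its current parent.  The
    move set is symmetric and the result contains neither duplicates nor
    ``T`` itself.
    """
    return [apply_move(T, v, t) for v, t in neighbor_moves(T)]


def insert_node_at_branch_point(T: ClonalTree, b: int) -> list[ClonalTree]:
    """Insert a fresh unobserved clone below branch point ``b``.

    The new clone ``u = N + 1`` becomes a child of ``b`` and all previous
    children of ``b`` are re-parented to ``u``.  Finer placements (moving a
    subset of children, or relocating ``u``) are left to the subsequent
    local search, so a single insertion tree is returned.
    """
    kids = T.children(b)
    if len(kids) < 2:
        raise ValueError(f"clone {b} is not a branch point (has {len(kids)} children)")
    u = T.n_clones + 1
    parent = np.append(T.parent, b)
    parent[kids] = u
    return [ClonalTree(parent, T.assignment, T.cells)]


def _relabel(parent_map: dict[int, int], assignment_clones: np.ndarray,
             cells: tuple[str, ...], keep: list[int]) -> tuple[ClonalTree, dict[int, int]]:
    """Densely relabel surviving clones 1..N' with the root fixed at 1."""
    keep_sorted = sorted(keep)
    label = {old: new for new, old in enumerate(keep_sorted, start=1)}
    assert label[ROOT] == ROOT
    parent = np.zeros(len(keep_sorted) + 1, dtype=np.int64)
    for old in keep_sorted:
        if old != ROOT:
            parent[label[old]] = label[parent_map[old]]
    assignment = np.array([label[c] for c in assignment_clones], dtype=np.int64)
    return ClonalTree(parent, assignment, cells), label


def merge_edge(T: ClonalTree, child: int, parent: int) -> tuple[ClonalTree, dict[int, int]]:
    """Merge ``child`` into its parent clone along the edge between them.

    The child's cells move to the parent, the child's children are
    re-parented to the parent, and the child clone disappears.  Merging into
    the root is forbidden: the normal never holds cells.  Returns the merged
    tree and the old-to-new clone label map.
    """
    if T.parent[child] != parent:
        raise ValueError(f"clone {parent} is not the parent of clone {child}")
    if parent == ROOT:
        raise ValueError("cells may not be merged into the root (normal) clone")
    pmap = {c: int(T.parent[c]) for c in range(2, T.n_clones + 1)}
    for k in T.children(child):
        pmap[int(k)] = parent
    del pmap[child]
    assignment = np.where(T.assignment == child, parent, T.assignment)
    keep = [c for c in T.clones if c != child]
    return _relabel(pmap, assignment, T.cells, keep)


def prune_linear_unobserved(T: ClonalTree) -> tuple[ClonalTree, dict[int, int]]:
    """Splice out unobserved non-root clones with fewer than two children.

    Such clones linearly connect (or dead-end) observed clones and are not
    identifiable from the data: removing them leaves every predicted mutation
    pattern intact.  Idempotent.  Returns the pruned tree and the label map
    from old to new clone labels (dropped clones are absent from the map).
    """
    pmap = {c: int(T.parent[c]) for c in range(2, T.n_clones + 1)}
    assignment = T.assignment.copy()
    observed = T.observed()
    alive = set(T.clones)
    changed = True
    while changed:
        changed = False
        for c in sorted(alive):
            if c == ROOT or observed[c]:
                continue
            kids = [k for k in alive if k != ROOT and pmap.get(k) == c]
            if len(kids) < 2:
                for k in kids:
                    pmap[k] = pmap[c]
                alive.discard(c)
                del pmap[c]
                changed = True
    tree, label = _relabel(pmap, assignment, T.cells, sorted(alive))
    return tree, label


# ---------------------------------------------------------------------------
# import / export
# ---------------------------------------------------------------------------

def write_edge_list(T: ClonalTree, path: str | Path) -> None:
    """Three-column TSV: parent clone, child clone, comma-separated cells."""
    lines = ["parent\tchild\tcells"]
    for c in range(2, T.n_clones + 1):
        lines.append(f"{T.parent[c]}\t{c}\t{','.join(T.cells_of(c))}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_edge_list(path: str | Path) -> ClonalTree:
    """Inverse of :func:`write_edge_list`."""
    rows = Path(path).read_text().strip().splitlines()[1:]
    edges: list[tuple[int, int, str]] = []
    for row in rows:
        p, c, cell_field = (row.split("\t") + [""])[:3]
        edges.append((int(p), int(c), cell_field))
    N = max((max(p, c) for p, c, _ in edges), default=1)
    parent = np.zeros(N + 1, dtype=np.int64)
    cells: list[str] = []
    assignment: list[int] = []
    for p, c, cell_field in edges:
        parent[c] = p
        for name in filter(None, cell_field.split(",")):
            cells.append(name)
            assignment.append(c)
    return ClonalTree(parent, np.array(assignment, dtype=np.int64), tuple(cells))


def to_newick(T: ClonalTree, branch_lengths: dict[tuple[int, int], float] | None = None) -> str:
    """Newick string with labels ``clone<i>[cellA cellB]``; optional lengths."""

    def label(c: int) -> str:
        members = " ".join(T.cells_of(c))
        return f"clone{c}" + (f"[{members}]" if members else "")

    def render(c: int) -> str:
        kids = [render(k) for k in T.children(c)]
        body = f"({','.join(kids)})" if kids else ""
        length = ""
        if branch_lengths is not None and c != ROOT:
            length = f":{branch_lengths[(int(T.parent[c]), c)]:.2f}"
        return f"{body}{label(c)}{length}"

    return render(ROOT) + ";"


def to_dot(T: ClonalTree) -> str:
    """GraphViz DOT rendering; unobserved clones are drawn dashed."""
    observed = T.observed()
    lines = ["digraph clonal_tree {", "  node [shape=circle];"]
    for c in T.clones:
        members = ", ".join(T.cells_of(c))
        name = "normal" if c == ROOT else f"clone {c}"
        label = f"{name}\\n{members}" if members else name
        style = "" if observed[c] or c == ROOT else ", style=dashed"
        lines.append(f'  n{c} [label="{label}"{style}];')
    for c in range(2, T.n_clones + 1):
        lines.append(f"  n{T.parent[c]} -> n{c};")
    lines.append("}")
    return "\n".join(lines)
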