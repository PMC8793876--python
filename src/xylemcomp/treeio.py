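"""Rooted phylogenies: newick I/O, validation, and Brownian-motion covariance.

The tree model is deliberately small: integer node ids, parent links and
branch lengths.  It provides exactly what the comparative statistics need
(tip depths, shared path lengths, post-order traversal for the pruning
algorithm) and nothing else.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PhyloTree",
    "NewickParseError",
    "TreeValidationError",
    "parse_newick",
    "write_newick",
    "phylo_vcv",
    "PhyloCovariance",
]


class NewickParseError(ValueError):
    """Malformed newick input; carries the character offset of the failure."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at character {offset})")
        self.offset = offset


class TreeValidationError(ValueError):
    pass


@dataclass
class PhyloTree:
    """Rooted tree with branch lengths.

    Nodes are integers ``0 .. n_nodes-1``; ``parent[i]`` is the parent of
    node ``i`` (``-1`` for the root) and ``length[i]`` the length of the
    edge above node ``i`` (0 for the root unless given).  ``children``
    preserves newick ordering.
    """

    parent: list[int]
    length: list[float]
    children: list[list[int]]
    labels: dict[int, str]  # node id -> label (tips always labelled)
    root: int = 0
    # internal labels are kept but ignored by all statistics
    _tip_cache: list[int] | None = field(default=None, repr=False, compare=False)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    def tips(self) -> list[int]:
        if self._tip_cache is None:
            self._tip_cache = [i for i in range(self.n_nodes) if not self.children[i]]
        return self._tip_cache

    def tip_labels(self) -> list[str]:
        return [self.labels[i] for i in self.tips()]

    def is_binary(self) -> bool:
        return all(len(c) in (0, 2) for c in self.children if c is not None)

    def postorder(self) -> list[int]:
        """Children before parents, iterative to cope with deep trees."""
        order: list[int] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            order.append(node)
            stack.extend(self.children[node])
        order.reverse()
        return order

    def depths(self) -> np.ndarray:
        """Root-to-node path length for every node."""
        d = np.zeros(self.n_nodes)
        # parents precede children in a reversed postorder
        for node in reversed(self.postorder()):
            p = self.parent[node]
            if p >= 0:
                d[node] = d[p] + self.length[node]
        return d

    def ultrametricity_error(self) -> float:
        """max |tip depth - mean tip depth|; 0 for a perfectly ultrametric tree."""
        td = self.depths()[self.tips()]
        return float(np.max(np.abs(td - td.mean())))

    def validate(self) -> None:
        n = self.n_nodes
        roots = [i for i in range(n) if self.parent[i] < 0]
        if len(roots) != 1 or roots[0] != self.root:
            raise TreeValidationError(f"expected exactly one root ({self.root}), found {roots}")
        for i, l in enumerate(self.length):
            if not np.isfinite(l) or l < 0:
                raise TreeValidationError(f"branch length of node {i} is {l}")
        # reachability doubles as a cycle check
        seen = set(self.postorder())
        if len(seen) != n:
            raise TreeValidationError("tree contains unreachable nodes or a cycle")
        tl = self.tip_labels()
        if any(not lab for lab in tl):
            raise TreeValidationError("empty tip label")
        if len(set(tl)) != len(tl):
            dups = sorted({x for x in tl if tl.count(x) > 1})
            raise TreeValidationError(f"duplicate tip labels: {dups}")

    def prune_tips(self, drop: list[str]) -> "PhyloTree":
        """Return a copy with the named tips removed and unary nodes collapsed."""
        dropset = set(drop)
        missing = dropset - set(self.tip_labels())
        if missing:
            raise TreeValidationError(f"cannot prune unknown tips: {sorted(missing)}")
        keep_tips = [t for t in self.tips() if self.labels[t] not in dropset]
        if len(keep_tips) < 2:
            raise TreeValidationError("pruning would leave fewer than 2 tips")
        # mark kept nodes: every ancestor of a kept tip
        keep = set()
        for t in keep_tips:
            node = t
            while node >= 0 and node not in keep:
                keep.add(node)
                node = self.parent[node]
        # rebuild top-down, collapsing nodes left with a single child
        new_parent: list[int] = []
        new_length: list[float] = []
        new_children: list[list[int]] = []
        new_labels: dict[int, str] = {}

        def build(old: int, parent_new: int, extra_len: float) -> None:
            kids = [c for c in self.children[old] if c in keep]
            if len(kids) == 1 and parent_new >= 0:
                # unary node: splice it out, its edge length moves onto the child
                build(kids[0], parent_new, extra_len + self.length[old])
                return
            nid = len(new_parent)
            new_parent.append(parent_new)
            new_length.append(self.length[old] + extra_len if parent_new >= 0 else 0.0)
            new_children.append([])
            if parent_new >= 0:
                new_children[parent_new].append(nid)
            if old in self.labels:
                new_labels[nid] = self.labels[old]
            for c in kids:
                build(c, nid, 0.0)

        root = self.root
        # collapse a unary chain at the root
        while len([c for c in self.children[root] if c in keep]) == 1:
            root = [c for c in self.children[root] if c in keep][0]
        build(root, -1, 0.0)
        out = PhyloTree(new_parent, new_length, new_children, new_labels, root=0)
        out.validate()
        return out


def parse_newick(text: str) -> PhyloTree:
    """Parse a newick string into a :class:`PhyloTree`.

    Branch lengths are required on all edges except the root edge, which
    defaults to 0.  Internal node labels are accepted and retained but
    ignored by downstream statistics.  Raises :class:`NewickParseError`
    with the character offset on malformed input.
    """
    if not isinstance(text, str):
        raise TypeError("newick input must be a string")
    s = text.strip()
    if not s:
        raise NewickParseError("empty input", 0)
    if not s.endswith(";"):
        raise NewickParseError("missing terminating ';'", len(s) - 1)
    s = s[:-1]

    parent: list[int] = []
    length: list[float] = []
    children: list[list[int]] = []
    labels: dict[int, str] = {}

    def new_node(par: int) -> int:
        nid = len(parent)
        parent.append(par)
        length.append(0.0)
        children.append([])
        if par >= 0:
            children[par].append(nid)
        return nid

    i = 0
    n = len(s)

    def read_label(i: int) -> tuple[str, int]:
        if i < n and s[i] in ("'", '"'):
            quote = s[i]
            j = s.find(quote, i + 1)
            if j < 0:
                raise NewickParseError("unterminated quoted label", i)
            return s[i + 1 : j], j + 1
        j = i
        while j < n and s[j] not in "(),:;":
            j += 1
        return s[i:j].strip(), j

    def read_length(i: int) -> tuple[float, int]:
        j = i
        while j < n and (s[j].isdigit() or s[j] in ".eE+-"):
            # only allow +- right after e/E or at the start
            if s[j] in "+-" and j > i and s[j - 1] not in "eE":
                break
            j += 1
        try:
            return float(s[i:j]), j
        except ValueError:
            raise NewickParseError(f"invalid branch length {s[i:j]!r}", i) from None

    root = new_node(-1)
    current = root
    just_closed = False  # True right after ')' or a leaf, expecting label/:/,/)

    while i < n:
        ch = s[i]
        if ch == "(":
            if just_closed:
                raise NewickParseError("unexpected '('", i)
            current = new_node(current)
            i += 1
        elif ch == ",":
            if not just_closed and not children[current]:
                raise NewickParseError("empty clade element", i)
            p = parent[current]
            if p < 0:
                raise NewickParseError("',' outside parentheses", i)
            current = new_node(p)
            just_closed = False
            i += 1
        elif ch == ")":
            p = parent[current]
            if p < 0:
                raise NewickParseError("unbalanced ')'", i)
            current = p
            just_closed = True
            i += 1
            # optional internal label
            lab, i = read_label(i)
            if lab:
                labels[current] = lab
        elif ch == ":":
            i += 1
            val, i = read_length(i)
            if val < 0:
                raise NewickParseError("negative branch length", i)
            length[current] = val
            just_closed = True
        else:
            lab, j = read_label(i)
            if not lab:
                raise NewickParseError(f"unexpected character {ch!r}", i)
            if just_closed:
                raise NewickParseError("unexpected label", i)
            labels[current] = lab
            just_closed = True
            i = j

    if parent[current] >= 0 and current != root:
        # parser returns to the root only if parentheses balanced
        raise NewickParseError("unbalanced '('", n - 1)

    tree = PhyloTree(parent, length, children, labels, root=root)
    # require lengths on all non-root edges
    for node in range(tree.n_nodes):
        if node != root and tree.parent[node] >= 0 and not tree.children[node]:
            if node not in labels:
                raise NewickParseError("unlabelled tip", n - 1)
    tree.validate()
    return tree


def write_newick(tree: PhyloTree, precision: int = 12) -> str:
    """Serialize a tree to newick; inverse of :func:`parse_newick`."""
    if not isinstance(tree, PhyloTree):
        raise TypeError("expected a PhyloTree")

    def fmt(x: float) -> str:
        s = f"{x:.{precision}g}"
        return s

    def rec(node: int) -> str:
        if not tree.children[node]:
            core = tree.labels[node]
        else:
            core = "(" + ",".join(rec(c) for c in tree.children[node]) + ")"
            core += tree.labels.get(node, "")
        if node == tree.root:
            return core
        return f"{core}:{fmt(tree.length[node])}"

    return rec(tree.root) + ";"


@dataclass
class PhyloCovariance:
    """Brownian-motion trait covariance induced by a rooted tree."""

    tip_labels: list[str]
    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)


def phylo_vcv(tree: PhyloTree) -> PhyloCovariance:
    """V[i, j] = root-to-MRCA path length of tips i and j (tip depth on the diagonal).

    Tip order follows newick (postorder left-to-right) and matches
    :meth:`PhyloTree.tip_labels`.
    """
    tree.validate()
    tips = tree.tips()
    ntip = len(tips)
    depth = tree.depths()
    # tips under each node, accumulated in postorder
    tip_index = {t: k for k, t in enumerate(tips)}
    under: dict[int, list[int]] = {}
    V = np.zeros((ntip, ntip))
    for node in tree.postorder():
        if not tree.children[node]:
            under[node] = [tip_index[node]]
            V[tip_index[node], tip_index[node]] = depth[node]
            continue
        kids = tree.children[node]
        sets = [under.pop(c) for c in kids]
        d = depth[node]
        for a in range(len(sets)):
            for b in range(a + 1, len(sets)):
                for ia in sets[a]:
                    V[ia, sets[b]] = d
                    V[sets[b], ia] = d
        under[node] = [x for sub in sets for x in sub]
    return PhyloCovariance([tree.labels[t] for t in tips], V)
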