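"""Rooted phylogenetic trees: container, traversals, pruning, rerooting.

The tree is the substrate for the Mk likelihood engine.  Branch lengths are
in the units of the input tree (substitutions/site for an ML gene tree);
polytomies are allowed everywhere and handled natively downstream.
"""

from __future__ import annotations

import itertools
from typing import Iterable, Iterator, Optional


class Node:
    """One node of a rooted tree.

    ``length`` is the branch length to the parent (``None`` at the root,
    and for inputs that omit lengths until a default is supplied).
    """

    __slots__ = ("id", "label", "length", "parent", "children")

    def __init__(self, id: int, label: Optional[str] = None,
                 length: Optional[float] = None):
        self.id = id
        self.label = label
        self.length = length
        self.parent: Optional[Node] = None
        self.children: list[Node] = []

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else "internal"
        return f"<Node {self.id} {kind} label={self.label!r} length={self.length}>"


class PhyloTree:
    """A rooted tree with branch lengths and uniquely labelled leaves."""

    def __init__(self, root: Node):
        self.root = root
        self._reindex()
        labels = [n.label for n in self.leaves()]
        if len(set(labels)) != len(labels):
            dups = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate leaf labels: {dups}")
        if any(l is None for l in labels):
            raise ValueError("every leaf must carry a label")

    # -- construction helpers -------------------------------------------------

    def _reindex(self) -> None:
        """Assign sequential ids in post-order (root gets the last id)."""
        for i, node in enumerate(self.postorder()):
            node.id = i

    def copy(self) -> "PhyloTree":
        mapping: dict[int, Node] = {}
        for node in self.postorder():
            clone = Node(node.id, node.label, node.length)
            mapping[node.id] = clone
            for child in node.children:
                clone.add_child(mapping[child.id])
        return PhyloTree(mapping[self.root.id])

    # -- traversal ------------------------------------------------------------

    def postorder(self) -> Iterator[Node]:
        """Children strictly before parents; every node exactly once."""
        stack: list[tuple[Node, bool]] = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def preorder(self) -> Iterator[Node]:
        """Parents strictly before children."""
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            for child in reversed(node.children):
                stack.append(child)

    def nodes(self) -> list[Node]:
        return list(self.postorder())

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.postorder() if not n.is_leaf]

    def find_leaf(self, label: str) -> Node:
        for leaf in self.leaves():
            if leaf.label == label:
                return leaf
        raise KeyError(label)

    # -- metrics --------------------------------------------------------------

    def depths(self) -> dict[int, float]:
        """Root-to-node path lengths (root depth 0)."""
        out = {self.root.id: 0.0}
        for node in self.preorder():
            if node is self.root:
                continue
            out[node.id] = out[node.parent.id] + (node.length or 0.0)
        return out

    def total_branch_length(self) -> float:
        return sum(n.length or 0.0 for n in self.postorder() if n is not self.root)

    def patristic_distances(self) -> dict[tuple[str, str], float]:
        """Leaf-to-leaf path lengths, keyed by sorted label pairs."""
        depth = self.depths()
        # ancestor sets per leaf
        anc: dict[str, list[Node]] = {}
        for leaf in self.leaves():
            chain, node = [], leaf
            while node is not None:
                chain.append(node)
                node = node.parent
            anc[leaf.label] = chain
        out = {}
        for a, b in itertools.combinations(sorted(anc), 2):
            seen = {n.id for n in anc[a]}
            mrca = next(n for n in anc[b] if n.id in seen)
            da = depth[self.find_leaf(a).id]
            db = depth[self.find_leaf(b).id]
            out[(a, b)] = da + db - 2.0 * depth[mrca.id]
        return out

    # -- pruning --------------------------------------------------------------

    def prune_to_taxa(self, keep: Iterable[str], *,
                      keep_root: bool = False) -> "PhyloTree":
        """Minimal induced tree on the kept leaves.

        Degree-2 internal nodes are suppressed with their branch lengths
        summed.  By default the returned tree is rooted at the MRCA of the
        kept leaves; with ``keep_root=True`` the original root is retained
        even if it has a single child path to that MRCA.
        """
        keep = set(keep)
        labels = set(self.leaf_labels())
        unknown = sorted(keep - labels)
        if unknown:
            raise KeyError(f"taxa not in tree: {unknown}")
        if len(keep) < 2:
            raise ValueError("need at least 2 taxa to keep")

        # rebuild bottom-up, dropping empty subtrees and unary chains
        built: dict[int, Optional[Node]] = {}
        for node in self.postorder():
            if node.is_leaf:
                built[node.id] = (Node(0, node.label, node.length)
                                  if node.label in keep else None)
                continue
            kids = [built[c.id] for c in node.children if built[c.id] is not None]
            if not kids:
                built[node.id] = None
            elif len(kids) == 1 and not (keep_root and node is self.root):
                child = kids[0]
                if child.length is not None or node.length is not None:
                    child.length = (child.length or 0.0) + (node.length or 0.0)
                built[node.id] = child
            else:
                clone = Node(0, node.label, node.length)
                for kid in kids:
                    clone.add_child(kid)
                built[node.id] = clone

        new_root = built[self.root.id]
        assert new_root is not None
        new_root.length = None  # root carries no branch
        return PhyloTree(new_root)

    # -- rerooting ------------------------------------------------------------

    def rerooted_at(self, node_id: int) -> "PhyloTree":
        """Return a copy rooted at the given node (edge directions reversed
        along the old root path; branch lengths preserved).

        Used to validate marginal reconstructions and likelihood invariance
        under root placement for reversible models.
        """
        clone = self.copy()
        target = next(n for n in clone.postorder() if n.id == node_id)
        if target is clone.root:
            return clone
        # reverse the path target -> old root
        path = []
        node = target
        while node is not None:
            path.append(node)
            node = node.parent
        original_length = {n.id: n.length for n in path}
        for child, parent in zip(path, path[1:]):
            parent.children.remove(child)
            child.add_child(parent)
            parent.length = original_length[child.id]
        target.length = None
        target.parent = None
        return PhyloTree(target)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<PhyloTree {len(self.leaves())} leaves, {len(self.nodes())} nodes>"
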