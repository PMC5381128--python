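"""Time-trees: rooted trees with node ages in Ma before present.

The central container of the package. Ages are stored on nodes (extant tips
at age 0, fossil tips at positive ages) and branch durations are derived as
``parent.age - child.age``; storing ages rather than branch lengths avoids
cumulative drift when fossil tips are attached or moved.

Newick/NEXUS parsing is delegated to dendropy; this module converts between
dendropy trees (branch lengths as durations) and :class:`TimeTree`.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import dendropy

__all__ = [
    "AGE_TOL",
    "TimeTree",
    "TreeNode",
    "CladeConstraint",
    "TreeError",
    "ParseError",
    "ValidationError",
    "MonophylyError",
    "parse_tree",
    "write_tree",
    "mrca",
    "stem_node",
    "check_monophyly",
    "prune_tips",
]

#: tips closer to the present than this (Ma) are considered extant
AGE_TOL = 1e-9


class TreeError(Exception):
    """Base class for tree-related errors."""


class ParseError(TreeError):
    pass


class ValidationError(TreeError):
    pass


class MonophylyError(TreeError):
    """A clade constraint required monophyly and the tree violates it."""


class TreeNode:
    """A node of a :class:`TimeTree`.

    Ages are in Ma before present; ``parent`` is ``None`` for the root.
    ``is_sampled_ancestor`` marks degree-2 nodes carrying a fossil label
    (written out as zero-length tips for portability).
    """

    __slots__ = ("label", "age", "parent", "children", "is_fossil",
                 "is_sampled_ancestor", "annotation")

    def __init__(self, label: str | None = None, age: float = 0.0,
                 is_fossil: bool = False):
        self.label = label
        self.age = float(age)
        self.parent: TreeNode | None = None
        self.children: list[TreeNode] = []
        self.is_fossil = is_fossil
        self.is_sampled_ancestor = False
        self.annotation = None

    # -- structure ---------------------------------------------------------
    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def branch_duration(self) -> float:
        """Duration of the branch above this node (0 for the root)."""
        if self.parent is None:
            return 0.0
        return self.parent.age - self.age

    def preorder(self) -> Iterator["TreeNode"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator["TreeNode"]:
        out = list(self.preorder())
        return iter(reversed(out))

    def leaves(self) -> list["TreeNode"]:
        return [n for n in self.preorder() if n.is_leaf]

    def __repr__(self) -> str:  # pragma: no cover
        return f"<TreeNode {self.label!r} age={self.age:.4g}>"


@dataclass(frozen=True)
class CladeConstraint:
    """A named monophyletic taxon set used to anchor calibrations.

    ``crown`` role targets the MRCA of the members; ``stem`` targets the
    parent of that MRCA (the node where the clade's lineage diverged from
    its sister group).
    """

    name: str
    members: frozenset = field(default_factory=frozenset)
    monophyletic: bool = True
    node_role: str = "crown"  # crown | stem

    def __init__(self, name: str, members: Iterable[str],
                 monophyletic: bool = True, node_role: str = "crown"):
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "members", frozenset(members))
        object.__setattr__(self, "monophyletic", bool(monophyletic))
        if node_role not in ("crown", "stem"):
            raise ValueError(f"node_role must be 'crown' or 'stem', got {node_role!r}")
        object.__setattr__(self, "node_role", node_role)
        if not self.members:
            raise ValueError(f"clade {name!r}: member set is empty")


class TimeTree:
    """Rooted tree with node ages (Ma); extant tips at 0, fossil tips > 0."""

    def __init__(self, root: TreeNode):
        self.root = root

    # -- iteration ---------------------------------------------------------
    def preorder(self) -> Iterator[TreeNode]:
        return self.root.preorder()

    def postorder(self) -> Iterator[TreeNode]:
        return self.root.postorder()

    def leaves(self) -> list[TreeNode]:
        return self.root.leaves()

    def internal_nodes(self) -> list[TreeNode]:
        return [n for n in self.preorder() if n.children]

    def tip_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def extant_labels(self) -> list[str]:
        return [n.label for n in self.leaves() if not n.is_fossil]

    def fossil_labels(self) -> list[str]:
        labels = [n.label for n in self.leaves() if n.is_fossil]
        labels += [n.label for n in self.preorder()
                   if n.is_sampled_ancestor and n.label]
        return labels

    def find(self, label: str) -> TreeNode:
        for n in self.preorder():
            if n.label == label:
                return n
        raise KeyError(f"taxon {label!r} not in tree")

    def __contains__(self, label: str) -> bool:
        return any(n.label == label for n in self.preorder())

    # -- queries -----------------------------------------------------------
    def mrca(self, taxa: Iterable[str]) -> TreeNode:
        return mrca(self, taxa)

    def copy(self) -> "TimeTree":
        mapping: dict[int, TreeNode] = {}
        for node in self.preorder():
            clone = TreeNode(node.label, node.age, node.is_fossil)
            clone.is_sampled_ancestor = node.is_sampled_ancestor
            mapping[id(node)] = clone
            if node.parent is not None:
                mapping[id(node.parent)].add_child(clone)
        return TimeTree(mapping[id(self.root)])

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        """Assert age monotonicity and tip-age conventions; raise otherwise."""
        seen: set[str] = set()
        for node in self.preorder():
            if node.age < -AGE_TOL:
                raise ValidationError(f"node {node.label!r} has negative age {node.age}")
            for child in node.children:
                slack = AGE_TOL if not child.is_sampled_ancestor else AGE_TOL
                if node.age - child.age < -slack:
                    raise ValidationError(
                        f"age monotonicity violated: parent {node.label!r} "
                        f"({node.age}) younger than child {child.label!r} ({child.age})")
            if node.is_leaf:
                if node.label is None:
                    raise ValidationError("unlabeled tip")
                if node.label in seen:
                    raise ValidationError(f"duplicate tip label {node.label!r}")
                seen.add(node.label)
                if not node.is_fossil and abs(node.age) > AGE_TOL:
                    raise ValidationError(
                        f"extant tip {node.label!r} has age {node.age} != 0")
                if node.is_fossil and node.age <= 0:
                    raise ValidationError(
                        f"fossil tip {node.label!r} has non-positive age {node.age}")

    # -- serialization -----------------------------------------------------
    def newick(self, precision: int = 12) -> str:
        return write_tree(self, precision=precision)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<TimeTree {len(self.leaves())} tips, root age {self.root.age:.4g}>"


# ---------------------------------------------------------------------------
# parsing / writing
# ---------------------------------------------------------------------------

def _from_dendropy(dtree: dendropy.Tree) -> TimeTree:
    droot = dtree.seed_node
    # depth of each node from the root, branch lengths read as durations
    depth: dict[int, float] = {id(droot): 0.0}
    mapping: dict[int, TreeNode] = {}
    max_depth = 0.0
    for dnode in dtree.preorder_node_iter():
        if dnode is not droot:
            bl = dnode.edge.length if dnode.edge.length is not None else 0.0
            if bl < 0:
                raise ValidationError(f"negative branch length {bl}")
            depth[id(dnode)] = depth[id(dnode.parent_node)] + bl
            if dnode.is_leaf():
                max_depth = max(max_depth, depth[id(dnode)])
    for dnode in dtree.preorder_node_iter():
        label = None
        if dnode.taxon is not None:
            label = dnode.taxon.label
        elif dnode.label:
            label = dnode.label
        age = max_depth - depth[id(dnode)]
        if abs(age) < AGE_TOL:
            age = 0.0
        node = TreeNode(label, age)
        mapping[id(dnode)] = node
        if dnode is not droot:
            mapping[id(dnode.parent_node)].add_child(node)
    tree = TimeTree(mapping[id(droot)])
    for n in tree.leaves():
        n.is_fossil = n.age > AGE_TOL
    # collapse zero-length tips hanging off degree-2-compatible attachment:
    # they stay as tips; sampled-ancestor detection is left to the caller.
    tree.validate()
    return tree


def parse_tree(text: str, schema: str | None = None) -> TimeTree:
    """Parse a Newick or NEXUS tree whose branch lengths are durations (Ma).

    Node ages are assigned so the deepest tip sits at age 0 (the present);
    any tip ending above the present is flagged as a fossil tip.
    """
    if schema is None:
        schema = "nexus" if text.lstrip()[:6].upper() == "#NEXUS" else "newick"
    try:
        dtree = dendropy.Tree.get(data=text, schema=schema,
                                  preserve_underscores=True,
                                  suppress_internal_node_taxa=True)
    except Exception as exc:  # dendropy raises assorted error types
        raise ParseError(f"could not parse {schema} tree: {exc}") from exc
    return _from_dendropy(dtree)


def _quote(label: str) -> str:
    if any(ch in label for ch in " ()[]{}:;,'\""):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_tree(tree: TimeTree, precision: int = 12) -> str:
    """Write Newick with branch lengths = parent age - child age."""
    fmt = "{:." + str(precision) + "g}"

    def rec(node: TreeNode) -> str:
        parts = []
        if node.children:
            inner = ",".join(rec(c) for c in node.children)
            if node.is_sampled_ancestor and node.label:
                inner += f",{_quote(node.label)}:0"
            s = f"({inner})"
        else:
            s = _quote(node.label or "")
        if node.parent is not None:
            s += ":" + fmt.format(node.branch_duration)
        return s

    return rec(tree.root) + ";"


def read_tree_log(text: str) -> list[TimeTree]:
    """Read all trees from a NEXUS (translate-table aware) or Newick log."""
    schema = "nexus" if text.lstrip()[:6].upper() == "#NEXUS" else "newick"
    trees = dendropy.TreeList.get(data=text, schema=schema,
                                  preserve_underscores=True,
                                  suppress_internal_node_taxa=True)
    return [_from_dendropy(t) for t in trees]


def write_tree_log(trees: Sequence[TimeTree], generations: Sequence[int] | None = None) -> str:
    """Write a NEXUS tree log with a translate table (BEAST-log style)."""
    if not trees:
        raise ValueError("no trees to write")
    labels = sorted(trees[0].tip_labels())
    index = {lab: i + 1 for i, lab in enumerate(labels)}
    buf = io.StringIO()
    buf.write("#NEXUS\nBegin taxa;\n\tDimensions ntax=%d;\n\tTaxlabels\n" % len(labels))
    for lab in labels:
        buf.write(f"\t\t{_quote(lab)}\n")
    buf.write("\t\t;\nEnd;\nBegin trees;\n\tTranslate\n")
    buf.write(",\n".join(f"\t\t{i} {_quote(lab)}" for lab, i in index.items()))
    buf.write("\n\t\t;\n")
    for k, tree in enumerate(trees):
        gen = generations[k] if generations is not None else k
        relabeled = tree.copy()
        for leaf in relabeled.leaves():
            leaf.label = str(index[leaf.label])
        for node in relabeled.preorder():
            if node.is_sampled_ancestor and node.label in index:
                node.label = str(index[node.label])
        buf.write(f"tree STATE_{gen} = {write_tree(relabeled)}\n")
    buf.write("End;\n")
    return buf.getvalue()


def read_nexus_tree_log(text: str) -> list[TimeTree]:
    """Read a NEXUS tree log written by :func:`write_tree_log`."""
    return read_tree_log(text)


# ---------------------------------------------------------------------------
# clade queries
# ---------------------------------------------------------------------------

def mrca(tree: TimeTree, taxa: Iterable[str]) -> TreeNode:
    """Most recent common ancestor of a set of tip labels."""
    taxa = set(taxa)
    if not taxa:
        raise ValueError("empty taxon set")
    tips = {n.label: n for n in tree.leaves()}
    for n in tree.preorder():
        if n.is_sampled_ancestor and n.label:
            tips.setdefault(n.label, n)
    missing = taxa - tips.keys()
    if missing:
        raise KeyError(f"taxa not in tree: {sorted(missing)}")
    # walk up from an arbitrary member, collecting ancestor paths
    paths = []
    for t in taxa:
        path = []
        node = tips[t]
        while node is not None:
            path.append(node)
            node = node.parent
        paths.append(set(map(id, path)))
    common = set.intersection(*paths)
    node = tips[next(iter(taxa))]
    while node is not None:
        if id(node) in common:
            return node
        node = node.parent
    raise TreeError("no common ancestor found (disconnected tree?)")


def stem_node(tree: TimeTree, clade: CladeConstraint) -> tuple[TreeNode, bool]:
    """Parent of the clade's crown MRCA; ``(node, at_root)``.

    If the MRCA is the root there is no stem node in the tree; the root is
    returned with ``at_root=True``.
    """
    if clade.monophyletic and not check_monophyly(tree, clade):
        raise MonophylyError(f"clade {clade.name!r} is not monophyletic in tree")
    crown = mrca(tree, clade.members)
    if crown.parent is None:
        return crown, True
    return crown.parent, False


def calibration_node(tree: TimeTree, clade: CladeConstraint) -> TreeNode:
    """Resolve a clade constraint to its target node (crown or stem)."""
    if clade.node_role == "crown":
        return mrca(tree, clade.members)
    return stem_node(tree, clade)[0]


def check_monophyly(tree: TimeTree, clade: CladeConstraint) -> bool:
    """True iff the MRCA's tip descendants equal the member set.

    Fossil tips (and sampled ancestors) descending from the MRCA are counted
    as clade members: fossils are placed inside their assigned clade by
    construction and must not break monophyly of the extant members.
    """
    present = {m for m in clade.members if m in tree}
    if not present:
        raise KeyError(f"no members of clade {clade.name!r} present in tree")
    node = mrca(tree, present)
    extant_desc = {n.label for n in node.preorder()
                   if n.is_leaf and not n.is_fossil}
    extant_members = {m for m in present if not _is_fossil_label(tree, m)}
    return extant_desc == extant_members


def _is_fossil_label(tree: TimeTree, label: str) -> bool:
    for n in tree.preorder():
        if n.label == label:
            return n.is_fossil or n.is_sampled_ancestor
    return False


def prune_tips(tree: TimeTree, labels: Iterable[str]) -> TimeTree:
    """Remove the named tips (and sampled ancestors); suppress the degree-2
    nodes this creates. Ages of all retained nodes are unchanged (exactly).

    A sampled ancestor whose entire below-subtree is pruned becomes a fossil
    tip unless its own label is pruned as well. Raises if fewer than two
    tips would remain.
    """
    labels = set(labels)
    known = set(tree.tip_labels()) | {n.label for n in tree.preorder()
                                      if n.is_sampled_ancestor and n.label}
    unknown = labels - known
    if unknown:
        raise KeyError(f"cannot prune unknown tips: {sorted(unknown)}")
    if len(set(tree.tip_labels()) - labels) < 2:
        raise TreeError("pruning would leave fewer than 2 tips")

    def rec(node: TreeNode) -> TreeNode | None:
        if node.is_leaf:
            if node.label in labels:
                return None
            clone = TreeNode(node.label, node.age, node.is_fossil)
            return clone
        kids = [rec(c) for c in node.children]
        kids = [k for k in kids if k is not None]
        if node.is_sampled_ancestor:
            if node.label in labels:      # drop the sample, pass through
                if not kids:
                    return None
                return kids[0] if len(kids) == 1 else _join(node, kids)
            if not kids:                   # below-subtree gone: fossil tip
                return TreeNode(node.label, node.age, is_fossil=True)
            sa = TreeNode(node.label, node.age)
            sa.is_sampled_ancestor = True
            for k in kids:
                sa.add_child(k)
            return sa
        if not kids:
            return None
        if len(kids) == 1:
            return kids[0]
        return _join(node, kids)

    def _join(node: TreeNode, kids: list[TreeNode]) -> TreeNode:
        new = TreeNode(None, node.age)
        for k in kids:
            new.add_child(k)
        return new

    root = rec(tree.root)
    if root is None:
        raise TreeError("pruned away the whole tree")
    out = TimeTree(root)
    out.validate()
    return out
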