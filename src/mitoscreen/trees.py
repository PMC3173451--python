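"""Phylogenetic tree model and operations.

The tree is the substrate of the whole screen: monophyly checks for marker
coherence, rooting with a bacterial outgroup, neighbor-joining as the built-in
inference backend for the jack-knife replicates, Faith-PD pruning and the
clade-abundance summaries all operate on :class:`LabelledTree`.

Leaves carry a category — reference taxon (with its alphaproteobacterial
order), mitochondrial, environmental (metagenome fragment) or outgroup — so
that downstream operations can reason about clade composition without parsing
label strings.

Branch lengths are in substitutions per site.  Support values (posterior
probabilities or split frequencies) are stored as node annotations and never
affect topology semantics.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "LeafCategory",
    "MITOCHONDRIAL",
    "ENVIRONMENTAL",
    "OUTGROUP",
    "reference",
    "Node",
    "LabelledTree",
    "Bipartition",
    "DistanceMatrix",
    "NewickParseError",
    "parse_newick",
    "write_newick",
    "read_tree_sample",
    "write_tree_sample",
    "is_monophyletic",
    "mrca",
    "root_with_outgroup",
    "pairwise_distance",
    "neighbor_joining",
    "majority_rule_consensus",
    "split_maxdiff",
    "chains_converged",
    "MAXDIFF_CONVERGENCE_THRESHOLD",
]

GAP_CHARS = frozenset("-.")

#: bpcomp-style convergence rule: two tree samples are considered to agree
#: when no split frequency differs by more than this value.
MAXDIFF_CONVERGENCE_THRESHOLD = 0.3


# ---------------------------------------------------------------------------
# leaf categories
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LeafCategory:
    """Category of a leaf: ``reference`` (with order), ``mitochondrial``,
    ``environmental`` or ``outgroup``."""

    kind: str
    order: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in {"reference", "mitochondrial", "environmental", "outgroup"}:
            raise ValueError(f"unknown leaf category kind: {self.kind!r}")
        if self.kind == "reference" and not self.order:
            raise ValueError("reference category requires an order name")
        if self.kind != "reference" and self.order is not None:
            raise ValueError(f"{self.kind} category takes no order name")


MITOCHONDRIAL = LeafCategory("mitochondrial")
ENVIRONMENTAL = LeafCategory("environmental")
OUTGROUP = LeafCategory("outgroup")


def reference(order: str) -> LeafCategory:
    """Reference-taxon category for a named alphaproteobacterial order."""
    return LeafCategory("reference", order)


# ---------------------------------------------------------------------------
# tree structure
# ---------------------------------------------------------------------------

class Node:
    """One tree node.  ``length`` is the length of the branch above the node
    (0 for the root); ``support`` annotates that same branch."""

    __slots__ = ("label", "length", "support", "children", "parent")

    def __init__(
        self,
        label: str | None = None,
        length: float = 0.0,
        support: float | str | None = None,
    ) -> None:
        self.label = label
        self.length = float(length)
        self.support = support
        self.children: list[Node] = []
        self.parent: Node | None = None

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Node {self.label or '*'} len={self.length:g}>"


class LabelledTree:
    """Phylogeny with branch lengths and per-leaf categories.

    ``rooted`` marks whether the root is a meaningful bifurcation (clade
    semantics apply) or merely an arbitrary anchor of an unrooted tree.
    """

    def __init__(
        self,
        root: Node,
        rooted: bool = False,
        categories: Mapping[str, LeafCategory] | None = None,
    ) -> None:
        self.root = root
        self.rooted = bool(rooted)
        self.categories: dict[str, LeafCategory] = dict(categories or {})
        self._validate()

    # -- construction / validation ------------------------------------

    def _validate(self) -> None:
        labels = [leaf.label for leaf in self.leaves()]
        if len(labels) < 2:
            raise ValueError("a tree needs at least 2 leaves")
        if any(lab is None for lab in labels):
            raise ValueError("every leaf must be labelled")
        if len(set(labels)) != len(labels):
            dup = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate leaf labels: {dup}")
        for node in self.preorder():
            if node.length < 0:
                raise ValueError(f"negative branch length at {node.label or 'internal node'}")
        if self.rooted and len(self.root.children) != 2:
            raise ValueError("a rooted tree must have a bifurcating root")
        unknown = set(self.categories) - set(labels)
        if unknown:
            raise ValueError(f"categories for unknown leaves: {sorted(unknown)}")

    # -- traversal -----------------------------------------------------

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def leaves(self) -> Iterator[Node]:
        return (n for n in self.preorder() if n.is_leaf)

    @property
    def leaf_labels(self) -> list[str]:
        return [leaf.label for leaf in self.leaves()]  # type: ignore[misc]

    @property
    def leaf_set(self) -> frozenset[str]:
        return frozenset(self.leaf_labels)

    def find_leaf(self, label: str) -> Node:
        for leaf in self.leaves():
            if leaf.label == label:
                return leaf
        raise KeyError(f"no leaf labelled {label!r}")

    def total_branch_length(self) -> float:
        return sum(n.length for n in self.preorder() if n is not self.root)

    # -- category helpers ----------------------------------------------

    def category_of(self, label: str) -> LeafCategory:
        try:
            return self.categories[label]
        except KeyError:
            raise KeyError(f"leaf {label!r} has no category") from None

    def leaves_of_kind(self, kind: str) -> frozenset[str]:
        return frozenset(
            lab for lab, cat in self.categories.items() if cat.kind == kind
        )

    def reference_orders(self) -> dict[str, frozenset[str]]:
        """Map order name -> reference leaves of that order."""
        orders: dict[str, set[str]] = {}
        for lab, cat in self.categories.items():
            if cat.kind == "reference":
                orders.setdefault(cat.order, set()).add(lab)  # type: ignore[arg-type]
        return {k: frozenset(v) for k, v in orders.items()}

    # -- clade machinery -----------------------------------------------

    def clade_leafsets(self) -> dict[int, frozenset[str]]:
        """Leaf set below every node, keyed by ``id(node)``."""
        sets: dict[int, frozenset[str]] = {}
        for node in self.postorder():
            if node.is_leaf:
                sets[id(node)] = frozenset([node.label])  # type: ignore[list-item]
            else:
                sets[id(node)] = frozenset().union(
                    *(sets[id(c)] for c in node.children)
                )
        return sets

    def bipartitions(self, include_trivial: bool = False) -> set["Bipartition"]:
        """All splits induced by branches of the tree."""
        all_leaves = self.leaf_set
        sets = self.clade_leafsets()
        out: set[Bipartition] = set()
        for node in self.preorder():
            if node is self.root:
                continue
            below = sets[id(node)]
            if not include_trivial and min(len(below), len(all_leaves) - len(below)) < 2:
                continue
            if 0 < len(below) < len(all_leaves):
                out.add(Bipartition.of(below, all_leaves - below))
        return out

    def copy(self) -> "LabelledTree":
        def clone(node: Node) -> Node:
            new = Node(node.label, node.length, node.support)
            for child in node.children:
                new.add(clone(child))
            return new

        return LabelledTree(clone(self.root), self.rooted, dict(self.categories))

    def __repr__(self) -> str:  # pragma: no cover
        kind = "rooted" if self.rooted else "unrooted"
        return f"<LabelledTree {kind}, {len(self.leaf_labels)} leaves>"


@dataclass(frozen=True)
class Bipartition:
    """Unordered split of the leaf set into two blocks.

    Canonical orientation: ``side_a`` holds the lexicographically smallest
    leaf, so equal splits compare equal regardless of construction order.
    """

    side_a: frozenset[str]
    side_b: frozenset[str]

    @staticmethod
    def of(a: Iterable[str], b: Iterable[str]) -> "Bipartition":
        fa, fb = frozenset(a), frozenset(b)
        if not fa or not fb:
            raise ValueError("both sides of a bipartition must be non-empty")
        if fa & fb:
            raise ValueError("bipartition sides must be disjoint")
        anchor = min(min(fa), min(fb))
        return Bipartition(fa, fb) if anchor in fa else Bipartition(fb, fa)

    @property
    def all_leaves(self) -> frozenset[str]:
        return self.side_a | self.side_b

    def compatible_with(self, other: "Bipartition") -> bool:
        """Two splits of the same leaf set are compatible iff one side of one
        is disjoint from one side of the other."""
        return any(
            not (x & y)
            for x in (self.side_a, self.side_b)
            for y in (other.side_a, other.side_b)
        )


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

class NewickParseError(ValueError):
    def __init__(self, message: str, offset: int) -> None:
        super().__init__(f"{message} (at character {offset})")
        self.offset = offset


_LABEL_RE = re.compile(r"[^\s(),:;]+")


def parse_newick(
    text: str, categories: Mapping[str, LeafCategory] | None = None,
    rooted: bool | None = None,
) -> LabelledTree:
    """Parse one Newick string into a :class:`LabelledTree`.

    Branch lengths are optional and default to 0; labels on internal nodes
    are kept as support annotations (numeric when parseable).  ``rooted``
    defaults to True when the basal node is bifurcating.
    """
    text = text.strip()
    pos = 0

    def error(msg: str) -> NewickParseError:
        return NewickParseError(msg, pos)

    def skip_ws() -> None:
        nonlocal pos
        while pos < len(text) and text[pos].isspace():
            pos += 1

    def parse_clade() -> Node:
        nonlocal pos
        skip_ws()
        if pos >= len(text):
            raise error("unexpected end of input")
        node = Node()
        if text[pos] == "(":
            pos += 1
            node.add(parse_clade())
            while True:
                skip_ws()
                if pos >= len(text):
                    raise error("unterminated '('")
                if text[pos] == ",":
                    pos += 1
                    node.add(parse_clade())
                elif text[pos] == ")":
                    pos += 1
                    break
                else:
                    raise error(f"expected ',' or ')', found {text[pos]!r}")
            skip_ws()
            m = _LABEL_RE.match(text, pos)
            if m:  # internal label = support annotation
                raw = m.group(0)
                pos = m.end()
                try:
                    node.support = float(raw)
                except ValueError:
                    node.support = raw
        else:
            m = _LABEL_RE.match(text, pos)
            if not m:
                raise error(f"expected a leaf label, found {text[pos]!r}")
            node.label = m.group(0)
            pos = m.end()
        skip_ws()
        if pos < len(text) and text[pos] == ":":
            pos += 1
            m = re.match(r"[-+]?(\d+\.?\d*|\.\d+)([eE][-+]?\d+)?", text[pos:])
            if not m:
                raise error("expected a branch length after ':'")
            node.length = float(m.group(0))
            pos += m.end()
        return node

    root = parse_clade()
    skip_ws()
    if pos >= len(text) or text[pos] != ";":
        raise error("expected ';' terminating the tree")
    pos += 1
    skip_ws()
    if pos != len(text):
        raise error("trailing characters after ';'")
    if rooted is None:
        rooted = len(root.children) == 2
    return LabelledTree(root, rooted=rooted, categories=categories)


def _format_length(x: float) -> str:
    return "0" if x == 0 else f"{x:.12g}"


def write_newick(tree: LabelledTree, include_lengths: bool = True) -> str:
    def fmt(node: Node) -> str:
        if node.is_leaf:
            s = node.label or ""
        else:
            s = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if node.support is not None:
                s += (
                    _format_length(node.support)
                    if isinstance(node.support, float)
                    else str(node.support)
                )
        if include_lengths and node.parent is not None:
            s += ":" + _format_length(node.length)
        return s

    return fmt(tree.root) + ";"


def read_tree_sample(text: str) -> list[LabelledTree]:
    """Read a multi-tree Newick file (one tree per line)."""
    trees = [parse_newick(line) for line in text.splitlines() if line.strip()]
    if not trees:
        raise ValueError("empty tree sample")
    return trees


def write_tree_sample(trees: Sequence[LabelledTree]) -> str:
    return "\n".join(write_newick(t) for t in trees) + "\n"


# ---------------------------------------------------------------------------
# monophyly / MRCA / rooting
# ---------------------------------------------------------------------------

def _check_leafset(tree: LabelledTree, leafset: Iterable[str]) -> frozenset[str]:
    ls = frozenset(leafset)
    if not ls:
        raise ValueError("leafset must be non-empty")
    unknown = ls - tree.leaf_set
    if unknown:
        raise KeyError(f"labels not in tree: {sorted(unknown)}")
    return ls


def is_monophyletic(tree: LabelledTree, leafset: Iterable[str]) -> bool:
    """Does ``leafset`` form a clade (rooted) / a split (unrooted)?

    On a rooted tree the test asks for a node whose descendant leaves are
    exactly ``leafset``.  On an unrooted tree the set is monophyletic iff the
    bipartition (leafset | rest) is induced by some branch; singleton sets and
    the full or all-but-one leaf set are trivially monophyletic.
    """
    ls = _check_leafset(tree, leafset)
    all_leaves = tree.leaf_set
    if tree.rooted:
        sets = tree.clade_leafsets()
        return any(sets[id(n)] == ls for n in tree.preorder())
    if len(ls) in (1, len(all_leaves)) or len(ls) == len(all_leaves) - 1:
        return True
    sets = tree.clade_leafsets()
    comp = all_leaves - ls
    for node in tree.preorder():
        if node is tree.root:
            continue
        below = sets[id(node)]
        if below == ls or below == comp:
            return True
    return False


def mrca(tree: LabelledTree, leafset: Iterable[str]) -> Node:
    """Most recent common ancestor of ``leafset`` on a rooted tree."""
    if not tree.rooted:
        raise ValueError("mrca requires a rooted tree; root with an outgroup first")
    ls = _check_leafset(tree, leafset)
    sets = tree.clade_leafsets()
    best: Node | None = None
    best_size = math.inf
    for node in tree.preorder():
        below = sets[id(node)]
        if ls <= below and len(below) < best_size:
            best, best_size = node, len(below)
    assert best is not None
    return best


def _edge_graph(tree: LabelledTree):
    """Undirected adjacency view: node -> list of (neighbour, length, support).

    The support stored on a child node annotates the edge to its parent; it is
    carried with the edge so re-rooting keeps annotations on the same split.
    """
    adj: dict[int, list[tuple[Node, float, float | str | None]]] = {}
    for node in tree.preorder():
        adj.setdefault(id(node), [])
        for child in node.children:
            adj.setdefault(id(child), [])
            adj[id(node)].append((child, child.length, child.support))
            adj[id(child)].append((node, child.length, child.support))
    return adj


def root_with_outgroup(tree: LabelledTree, outgroup: Iterable[str]) -> LabelledTree:
    """Root on the branch separating the outgroup from everything else.

    The chosen branch is bisected (the two halves sum to the original length),
    so the total branch length of the tree is conserved.  The outgroup must be
    a bipartition of the (unrooted) tree.
    """
    og = _check_leafset(tree, outgroup)
    all_leaves = tree.leaf_set
    if og == all_leaves:
        raise ValueError("outgroup cannot contain every leaf")
    sets = tree.clade_leafsets()
    target: Node | None = None
    for node in tree.preorder():
        if node is tree.root:
            continue
        below = sets[id(node)]
        if below == og or below == all_leaves - og:
            target = node
            break
    if target is None:
        raise ValueError(
            f"outgroup {sorted(og)} is not a bipartition of the tree; "
            "conflicting splits prevent rooting"
        )

    adj = _edge_graph(tree)
    parent = target.parent
    assert parent is not None
    half = target.length / 2.0

    # Rebuild the tree oriented away from a fresh root placed mid-branch.
    def build(node: Node, come_from: Node | None, length: float,
              support: float | str | None) -> Node:
        new = Node(node.label, length, support)
        for nbr, elen, esup in adj[id(node)]:
            if come_from is not None and nbr is come_from:
                continue
            if (node is target and nbr is parent) or (node is parent and nbr is target):
                continue  # the bisected branch is handled at the root
            new.add(build(nbr, node, elen, esup))
        return new

    root = Node()
    root.add(build(target, None, half, target.support))
    root.add(build(parent, None, half, target.support))
    out = LabelledTree(root, rooted=True, categories=dict(tree.categories))
    # orient the outgroup as the first root child, cosmetic but deterministic
    first = out.root.children[0]
    below = out.clade_leafsets()[id(first)]
    if below != og and len(out.root.children) == 2:
        out.root.children.reverse()
    return out


# ---------------------------------------------------------------------------
# distances and neighbor joining
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances (substitutions/site) between labels."""

    labels: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("distance matrix must have a zero diagonal")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if (self.values < 0).any():
            raise ValueError("distances must be non-negative")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])


def _encode_alignment(aln: Mapping[str, str]) -> tuple[list[str], np.ndarray, np.ndarray]:
    labels = list(aln)
    lengths = {len(s) for s in aln.values()}
    if len(lengths) != 1:
        raise ValueError("alignment sequences must have equal length")
    (L,) = lengths
    if L == 0:
        raise ValueError("alignment has zero columns")
    mat = np.frombuffer(
        "".join(aln[l].upper() for l in labels).encode("ascii"), dtype=np.uint8
    ).reshape(len(labels), L)
    gap = np.zeros_like(mat, dtype=bool)
    for ch in GAP_CHARS:
        gap |= mat == ord(ch)
    return labels, mat, gap


#: Cap for near-saturated corrected distances (substitutions/site).
MAX_CORRECTED_DISTANCE = 7.0


def pairwise_distance(aln: Mapping[str, str], model: str = "poisson") -> DistanceMatrix:
    """Pairwise distances from an alignment.

    ``p``: mismatch fraction over pairwise-comparable columns (gaps skipped
    per pair, so short environmental fragments remain usable).  ``poisson``:
    -ln(1 - p), the Poisson multiple-hit correction.  ``jc20``: the 20-state
    Jukes–Cantor-type correction -ln(1 - 20 p / 19), which is consistent for
    protein sequences whose substitutions land on any residue with equal
    probability; near-saturated pairs are capped at
    :data:`MAX_CORRECTED_DISTANCE` rather than diverging, which keeps deep
    divergences usable for neighbor joining.
    """
    if model not in {"p", "poisson", "jc20"}:
        raise ValueError(f"unknown distance model {model!r}")
    labels, mat, gap = _encode_alignment(aln)
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(gap[i] | gap[j])
            m = int(ok.sum())
            if m == 0:
                raise ValueError(
                    f"no comparable columns between {labels[i]!r} and {labels[j]!r}"
                )
            p = float((mat[i, ok] != mat[j, ok]).sum()) / m
            if model == "poisson":
                if p >= 1.0:
                    raise ValueError(
                        f"saturated distance (p=1) between {labels[i]!r} and "
                        f"{labels[j]!r}: Poisson correction undefined"
                    )
                p = -math.log1p(-p)
            elif model == "jc20":
                arg = 1.0 - 20.0 * p / 19.0
                p = (
                    MAX_CORRECTED_DISTANCE
                    if arg <= math.exp(-MAX_CORRECTED_DISTANCE)
                    else -math.log(arg)
                )
            d[i, j] = d[j, i] = p
    return DistanceMatrix(tuple(labels), d)


def neighbor_joining(
    dm: DistanceMatrix, categories: Mapping[str, LeafCategory] | None = None
) -> LabelledTree:
    """Saitou–Nei neighbor joining.

    Returns an unrooted tree (trifurcating basal node).  Negative estimated
    branch lengths are clamped to zero.  Ties in the Q-matrix minimisation are
    broken by the lexicographically smallest pair of cluster names (a
    cluster's name is its smallest leaf label), making the result
    deterministic.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 labels")
    d = dm.values.copy()
    nodes: list[Node] = [Node(lab) for lab in dm.labels]
    names: list[str] = list(dm.labels)  # cluster sort keys

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        ties = np.argwhere(q == qmin)
        i, j = min(
            (tuple(sorted((names[a], names[b]))), (min(a, b), max(a, b)))
            for a, b in ties
        )[1]
        dij = d[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        parent = Node()
        ci, cj = nodes[i], nodes[j]
        ci.length = max(li, 0.0)
        cj.length = max(lj, 0.0)
        parent.add(ci)
        parent.add(cj)
        newd = 0.5 * (d[i, :] + d[j, :] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        d2 = np.empty((m - 1, m - 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = newd[keep]
        d2[:-1, -1] = newd[keep]
        d2[-1, -1] = 0.0
        d = d2
        nodes = [nodes[k] for k in keep] + [parent]
        names = [names[k] for k in keep] + [min(names[i], names[j])]

    # final three-point join
    (a, b, c) = nodes
    dab, dac, dbc = d[0, 1], d[0, 2], d[1, 2]
    a.length = max(0.5 * (dab + dac - dbc), 0.0)
    b.length = max(0.5 * (dab + dbc - dac), 0.0)
    c.length = max(0.5 * (dac + dbc - dab), 0.0)
    root = Node()
    for nd in (a, b, c):
        root.add(nd)
    return LabelledTree(root, rooted=False, categories=categories)


# ---------------------------------------------------------------------------
# tree-sample utilities: consensus and split-frequency comparison
# ---------------------------------------------------------------------------

def _split_frequencies(trees: Sequence[LabelledTree]) -> dict[Bipartition, float]:
    counts: dict[Bipartition, int] = {}
    for t in trees:
        for bp in t.bipartitions():
            counts[bp] = counts.get(bp, 0) + 1
    return {bp: c / len(trees) for bp, c in counts.items()}


def _common_leafset(trees: Sequence[LabelledTree]) -> frozenset[str]:
    leafsets = {t.leaf_set for t in trees}
    if len(leafsets) != 1:
        raise ValueError("all trees in a sample must share the same leaf set")
    return next(iter(leafsets))


def majority_rule_consensus(
    trees: Sequence[LabelledTree], burnin_fraction: float = 0.25
) -> LabelledTree:
    """Majority-rule consensus of a tree sample.

    The first ``burnin_fraction`` of the sample is discarded (MCMC burn-in
    convention; default 25%).  The consensus contains exactly the non-trivial
    splits whose post-burn-in frequency exceeds 0.5, annotated with that
    frequency as branch support.  Branch lengths are not summarised (set to 0).
    """
    if not trees:
        raise ValueError("empty tree sample")
    if not (0.0 <= burnin_fraction < 1.0):
        raise ValueError("burnin_fraction must be in [0, 1)")
    leaves = _common_leafset(trees)
    kept = trees[int(math.floor(burnin_fraction * len(trees))):]
    freqs = _split_frequencies(kept)
    majority = {bp: f for bp, f in freqs.items() if f > 0.5}

    anchor = min(leaves)
    # Represent each split by its side away from the anchor; these sets form a
    # laminar family because majority splits are pairwise compatible.
    groups = sorted(
        ((bp.side_b if anchor in bp.side_a else bp.side_a), f)
        for bp, f in majority.items()
    )
    groups.sort(key=lambda gf: (-len(gf[0]), sorted(gf[0])))

    root = Node()
    for lab in sorted(leaves):
        root.add(Node(lab))
    for leafgroup, freq in groups:
        sets = {id(n): s for n, s in _node_leafsets(root).items()}
        host = root
        while True:
            child_in = [c for c in host.children if sets[id(c)] <= leafgroup]
            descend = [c for c in host.children if sets[id(c)] >= leafgroup and c.children]
            if descend and sets[id(descend[0])] != leafgroup:
                host = descend[0]
                continue
            break
        moved = [c for c in host.children if sets[id(c)] <= leafgroup]
        if {l for c in moved for l in sets[id(c)]} != leafgroup:
            continue  # incompatible split; cannot occur for majority splits
        new = Node(support=freq)
        for c in moved:
            host.children.remove(c)
            new.add(c)
        host.add(new)
    tree = LabelledTree(root, rooted=False)
    return tree


def _node_leafsets(root: Node) -> dict[Node, frozenset[str]]:
    sets: dict[Node, frozenset[str]] = {}

    def rec(node: Node) -> frozenset[str]:
        if node.is_leaf:
            s = frozenset([node.label])  # type: ignore[list-item]
        else:
            s = frozenset().union(*(rec(c) for c in node.children))
        sets[node] = s
        return s

    rec(root)
    return sets


def split_maxdiff(
    sample_a: Sequence[LabelledTree], sample_b: Sequence[LabelledTree]
) -> float:
    """Maximum absolute split-frequency difference between two tree samples.

    The bpcomp-style convergence diagnostic: 0 for identical split spectra, 1
    when a split is certain in one sample and absent in the other.
    """
    if not sample_a or not sample_b:
        raise ValueError("tree samples must be non-empty")
    leaves_a = _common_leafset(sample_a)
    leaves_b = _common_leafset(sample_b)
    if leaves_a != leaves_b:
        raise ValueError("the two samples must share the same leaf set")
    fa = _split_frequencies(sample_a)
    fb = _split_frequencies(sample_b)
    keys = set(fa) | set(fb)
    if not keys:
        return 0.0
    return max(abs(fa.get(k, 0.0) - fb.get(k, 0.0)) for k in keys)


def chains_converged(
    sample_a: Sequence[LabelledTree],
    sample_b: Sequence[LabelledTree],
    threshold: float = MAXDIFF_CONVERGENCE_THRESHOLD,
) -> bool:
    """Convergence verdict: max split-frequency difference ≤ ``threshold``."""
    return split_maxdiff(sample_a, sample_b) <= threshold
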