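"""Faith phylogenetic diversity and greedy maximum-PD taxon selection.

Bayesian tree inference cannot digest thousands of environmental homologs, so
the pool is pruned to a fixed budget while keeping as much of its phylogenetic
diversity (PD — total branch length of the minimal subtree spanning a taxon
subset) as possible.  Greedy accretion is exactly optimal for PD on trees
(Steel/Pardi), which the test suite asserts by exhaustive enumeration.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Iterable

from .homology import OrthologDataset
from .trees import LabelledTree, Node

__all__ = ["PruneConfig", "faith_pd", "greedy_pd_select", "prune_dataset"]


@dataclass(frozen=True)
class PruneConfig:
    """Target subset size and hard-keep constraints for PD pruning.

    ``target_size`` defaults to 150, a tractable environmental-pool budget for
    downstream Bayesian analysis.  ``must_keep`` (typically the reference
    taxa) seeds the selection; the greedy optimality guarantee then applies
    only to the unconstrained remainder.  ``rooted_pd`` switches Faith PD to
    the rooted convention (spanning subtree includes the path to the root).
    """

    target_size: int = 150
    must_keep: frozenset[str] = frozenset()
    rooted_pd: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "must_keep", frozenset(self.must_keep))
        if self.target_size < 2:
            raise ValueError("target_size must be at least 2")
        if self.target_size < len(self.must_keep):
            raise ValueError("target_size smaller than the must-keep set")


def faith_pd(tree: LabelledTree, subset: Iterable[str], rooted: bool = False) -> float:
    """Faith's PD: branch-length sum of the minimal subtree spanning ``subset``.

    Unrooted convention by default (only branches on paths *between* subset
    leaves count); with ``rooted=True`` the path to the root is included.
    """
    ls = frozenset(subset)
    unknown = ls - tree.leaf_set
    if unknown:
        raise KeyError(f"labels not in tree: {sorted(unknown)}")
    if len(ls) < 2:
        raise ValueError("PD needs a subset of at least 2 leaves")
    total = len(ls)
    pd = 0.0
    counts: dict[int, int] = {}
    for node in tree.postorder():
        if node.is_leaf:
            c = 1 if node.label in ls else 0
        else:
            c = sum(counts[id(ch)] for ch in node.children)
        counts[id(node)] = c
        if node.parent is None:
            continue
        if (rooted and c > 0) or (not rooted and 0 < c < total):
            pd += node.length
    return pd


def _neighbours(node: Node):
    for ch in node.children:
        yield ch, ch.length
    if node.parent is not None:
        yield node.parent, node.length


def _distances_to_region(
    tree: LabelledTree, covered: set[int]
) -> tuple[dict[int, float], dict[int, Node]]:
    """Multi-source sweep outward from the covered region.

    Returns per-node distance to the nearest covered node and the predecessor
    (next hop toward the region).  Exact on trees: each node is reached by a
    single path.
    """
    dist: dict[int, float] = {}
    pred: dict[int, Node] = {}
    queue: deque[Node] = deque()
    for node in tree.preorder():
        if id(node) in covered:
            dist[id(node)] = 0.0
            queue.append(node)
    while queue:
        node = queue.popleft()
        for nbr, w in _neighbours(node):
            if id(nbr) not in dist:
                dist[id(nbr)] = dist[id(node)] + w
                pred[id(nbr)] = node
                queue.append(nbr)
    return dist, pred


def _farthest_leaf_pair(tree: LabelledTree) -> tuple[str, str]:
    """Leaf pair with maximal path length; ties broken by the smallest pair."""
    best_pair: tuple[str, str] | None = None
    best_len = -1.0
    leaves = sorted((leaf.label, leaf) for leaf in tree.leaves())
    for lab, node in leaves:
        dist: dict[int, float] = {id(node): 0.0}
        stack = [node]
        while stack:
            cur = stack.pop()
            for nbr, w in _neighbours(cur):
                if id(nbr) not in dist:
                    dist[id(nbr)] = dist[id(cur)] + w
                    stack.append(nbr)
        for other, onode in leaves:
            if other <= lab:
                continue
            d = dist[id(onode)]
            pair = (lab, other)
            if d > best_len or (d == best_len and pair < best_pair):
                best_len, best_pair = d, pair
    assert best_pair is not None
    return best_pair


def greedy_pd_select(
    tree: LabelledTree, cfg: PruneConfig
) -> tuple[list[str], list[float]]:
    """Greedy maximum-PD subset of ``cfg.target_size`` leaves.

    Starts from ``must_keep`` when given, else from the two leaves with the
    longest path between them; then repeatedly adds the leaf with the largest
    PD increment.  Ties are broken lexicographically, so the selection is
    deterministic.  Returns the ordered selection and the PD value after each
    addition.
    """
    leaves = {leaf.label: leaf for leaf in tree.leaves()}
    k = cfg.target_size
    if k > len(leaves):
        raise ValueError(f"target_size {k} exceeds leaf count {len(leaves)}")
    unknown = cfg.must_keep - set(leaves)
    if unknown:
        raise KeyError(f"must_keep labels not in tree: {sorted(unknown)}")

    covered: set[int] = set()
    pd = 0.0
    selection: list[str] = []
    trajectory: list[float] = []

    if cfg.rooted_pd:
        covered.add(id(tree.root))

    def add_leaf(label: str) -> None:
        nonlocal pd
        node: Node = leaves[label]
        if not covered:  # very first leaf anchors the region at zero cost
            covered.add(id(node))
        else:
            _, pred = _distances_to_region(tree, covered)
            path: list[Node] = []
            cur = node
            while id(cur) not in covered:
                path.append(cur)
                cur = pred[id(cur)]
            for a, b in zip(path, path[1:] + [cur]):
                # edge between a and b is a parent/child edge in either order
                pd += a.length if a.parent is b else b.length
                covered.add(id(a))
        selection.append(label)
        trajectory.append(pd)

    seed = sorted(cfg.must_keep) if cfg.must_keep else list(_farthest_leaf_pair(tree))
    for lab in seed:
        add_leaf(lab)

    while len(selection) < k:
        dist, _ = _distances_to_region(tree, covered)
        gain = {
            lab: dist[id(nd)] for lab, nd in leaves.items() if id(nd) not in covered
        }
        add_leaf(min(gain, key=lambda l: (-gain[l], l)))

    return selection, trajectory


def prune_dataset(
    dataset: OrthologDataset, tree: LabelledTree, cfg: PruneConfig
) -> OrthologDataset:
    """Restrict a dataset to the greedy maximum-PD selection.

    The tree must contain exactly the dataset members as leaves; provenance
    records the PD trajectory.
    """
    if tree.leaf_set != frozenset(dataset.members):
        raise ValueError("tree leaves and dataset members do not match")
    selection, trajectory = greedy_pd_select(tree, cfg)
    out = dataset.restrict(selection, f"PD pruning to {cfg.target_size}")
    out.log("PD trajectory: " + ",".join(f"{v:.6g}" for v in trajectory))
    return out
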