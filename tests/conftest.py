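"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the library's own clade machinery: they
work on a raw undirected adjacency view of the tree (edge-removal BFS), so
that monophyly, distances and spanning-subtree sums are checked against an
independent computation.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from mitoscreen.trees import LabelledTree, Node


def adjacency(tree: LabelledTree) -> dict[int, list[tuple[Node, float]]]:
    adj: dict[int, list[tuple[Node, float]]] = {}
    for node in tree.preorder():
        adj.setdefault(id(node), [])
        for child in node.children:
            adj.setdefault(id(child), [])
            adj[id(node)].append((child, child.length))
            adj[id(child)].append((node, child.length))
    return adj


def leaf_path_length(tree: LabelledTree, a: str, b: str) -> float:
    """Path length between two leaves by BFS over the undirected tree."""
    adj = adjacency(tree)
    start = tree.find_leaf(a)
    dist = {id(start): 0.0}
    stack = [start]
    while stack:
        node = stack.pop()
        if node.label == b and node.is_leaf:
            return dist[id(node)]
        for nbr, w in adj[id(node)]:
            if id(nbr) not in dist:
                dist[id(nbr)] = dist[id(node)] + w
                stack.append(nbr)
    raise KeyError(b)


def leaf_distance_matrix(tree: LabelledTree) -> dict[tuple[str, str], float]:
    labels = sorted(tree.leaf_labels)
    return {
        (a, b): leaf_path_length(tree, a, b)
        for a, b in itertools.combinations(labels, 2)
    }


def component_without_edge(
    tree: LabelledTree, child: Node
) -> frozenset[str]:
    """Leaves on the child side after removing the edge above ``child``."""
    adj = adjacency(tree)
    seen = {id(child)}
    stack = [child]
    leaves = set()
    parent = child.parent
    while stack:
        node = stack.pop()
        if node.is_leaf:
            leaves.add(node.label)
        for nbr, _ in adj[id(node)]:
            if node is child and nbr is parent:
                continue
            if id(nbr) not in seen:
                seen.add(id(nbr))
                stack.append(nbr)
    return frozenset(leaves)


def bruteforce_monophyletic(tree: LabelledTree, leafset: frozenset[str]) -> bool:
    """Monophyly by exhaustive edge-removal bipartition enumeration."""
    all_leaves = tree.leaf_set
    if tree.rooted:
        # clade semantics: some edge-removal component equals the set, with
        # the root's total clade allowed too
        if leafset == all_leaves:
            return True
        for node in tree.preorder():
            if node.parent is None:
                continue
            if component_without_edge(tree, node) == leafset:
                return True
        return False
    if len(leafset) in (1, len(all_leaves) - 1, len(all_leaves)):
        return True
    comp = all_leaves - leafset
    for node in tree.preorder():
        if node.parent is None:
            continue
        side = component_without_edge(tree, node)
        if side == leafset or side == comp:
            return True
    return False


def spanning_length_bruteforce(tree: LabelledTree, subset: frozenset[str]) -> float:
    """Faith PD oracle: sum of edges whose removal separates subset members."""
    total = 0.0
    for node in tree.preorder():
        if node.parent is None:
            continue
        side = component_without_edge(tree, node)
        if subset & side and subset - side:
            total += node.length
    return total


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
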