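"""Clade assignment of environmental sequences and abundance arithmetic.

Environmental leaves are tentatively associated with a reference order by a
nearest-reference majority rule: each environmental leaf takes the order of
the majority of reference leaves in the smallest clade that contains the leaf
together with at least one reference leaf; ties and mixed majorities yield
UNCLASSIFIED, which is kept first-class so that percentages never silently
re-normalise over dropped leaves.

The module also computes collapsed-clade summaries (total within-clade branch
length *l* and environmental-sequence count *n*), the rare-clade fraction
(e.g. 12 of 566 → 2.1%), and the overall-abundance product obtained under an
assumed alphaproteobacterial fraction of all microbial cells.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import pandas as pd

from .trees import LabelledTree, Node

__all__ = [
    "UNCLASSIFIED",
    "AbundanceConfig",
    "assign_to_reference_clades",
    "clade_fractions",
    "clade_summary",
    "rare_clade_fraction",
    "overall_abundance",
    "read_scaffold_site_table",
    "packaged_omac_site_table",
]

UNCLASSIFIED = "UNCLASSIFIED"


@dataclass(frozen=True)
class AbundanceConfig:
    """Assumed fraction of all microbial cells that are alphaproteobacterial
    (default 0.325, an RPS2-based estimate for ocean surface waters)."""

    alpha_fraction_of_cells: float = 0.325

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha_fraction_of_cells <= 1.0):
            raise ValueError("alpha_fraction_of_cells must be in [0, 1]")


def assign_to_reference_clades(tree: LabelledTree) -> dict[str, str]:
    """Assign every environmental leaf to a reference order (or UNCLASSIFIED).

    Rule: walk from the leaf toward the root until the current clade contains
    at least one reference leaf; assign the strict-majority order among the
    reference leaves of that clade, or UNCLASSIFIED on a tie.  Requires a
    rooted tree and reference leaves from at least two orders.
    """
    if not tree.rooted:
        raise ValueError("clade assignment requires a rooted tree")
    orders = tree.reference_orders()
    if len(orders) < 2:
        raise ValueError("need reference leaves from at least two orders")
    order_of = {
        lab: order for order, labs in orders.items() for lab in labs
    }
    env = tree.leaves_of_kind("environmental")
    sets = tree.clade_leafsets()

    assignment: dict[str, str] = {}
    for leaf in tree.leaves():
        if leaf.label not in env:
            continue
        node: Node | None = leaf
        chosen = UNCLASSIFIED
        while node is not None:
            refs_here = [order_of[l] for l in sets[id(node)] if l in order_of]
            if refs_here:
                counts = Counter(refs_here).most_common()
                if len(counts) == 1 or counts[0][1] > counts[1][1]:
                    chosen = counts[0][0]
                break
            node = node.parent
        assignment[leaf.label] = chosen  # type: ignore[index]
    return assignment


def clade_fractions(assignment: Mapping[str, str]) -> dict[str, float]:
    """Percentage of *assigned* environmental leaves per order.

    UNCLASSIFIED leaves are excluded from the denominator; the returned
    percentages sum to 100.
    """
    assigned = [o for o in assignment.values() if o != UNCLASSIFIED]
    if not assigned:
        raise ValueError("no environmental leaves were assigned to any order")
    counts = Counter(assigned)
    n = len(assigned)
    return {order: 100.0 * c / n for order, c in sorted(counts.items())}


def clade_summary(tree: LabelledTree, clade: Node) -> tuple[float, int]:
    """Collapsed-clade annotation (l, n): total branch length within the clade
    (stem excluded) and the number of environmental leaves it contains."""
    env = tree.leaves_of_kind("environmental")
    l = 0.0
    n = 1 if (clade.is_leaf and clade.label in env) else 0
    stack = list(clade.children)
    while stack:
        node = stack.pop()
        l += node.length
        if node.is_leaf:
            if node.label in env:
                n += 1
        else:
            stack.extend(node.children)
    return l, n


def rare_clade_fraction(n_clade: int, n_total: int) -> float:
    """Percentage of sequences attributable to a clade, to one decimal.

    ``rare_clade_fraction(12, 566)`` → 2.1 (percent).
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not (0 <= n_clade <= n_total):
        raise ValueError("n_clade must be between 0 and n_total")
    return round(100.0 * n_clade / n_total, 1)


def overall_abundance(
    clade_pct: float, cfg: AbundanceConfig = AbundanceConfig()
) -> float:
    """Clade share of *all* microbial cells: clade percentage among
    alphaproteobacterial sequences times the assumed alphaproteobacterial
    fraction of cells.

    This is a deliberate first-order approximation (it equates sequence
    fractions with cell fractions and ignores copy-number, genome-size and
    sequencing-depth differences); treat the output as an order-of-magnitude
    statement.
    """
    return clade_pct * cfg.alpha_fraction_of_cells


# ---------------------------------------------------------------------------
# scaffold sampling-site bookkeeping
# ---------------------------------------------------------------------------

SITE_TABLE_COLUMNS = (
    "scaffold_id",
    "sample_id",
    "habitat_type",
    "sample_location",
    "coordinates",
)


def read_scaffold_site_table(path_or_buf) -> pd.DataFrame:
    """Read a scaffold sampling-site table (TSV with a header row:
    scaffold_id, sample_id, habitat_type, sample_location, coordinates)."""
    df = pd.read_csv(path_or_buf, sep="\t", dtype=str)
    missing = set(SITE_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"site table missing columns: {sorted(missing)}")
    return df[list(SITE_TABLE_COLUMNS)]


def packaged_omac_site_table() -> pd.DataFrame:
    """The sampling-site table for the twelve OMAC COX1–COX2 scaffolds
    recovered from the Global Ocean Survey, shipped with the package."""
    ref = resources.files("mitoscreen") / "data" / "omac_cox1_scaffold_sites.tsv"
    with ref.open("r") as fh:
        return read_scaffold_site_table(fh)
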