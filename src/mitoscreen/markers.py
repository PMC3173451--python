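"""Marker selection: phylogenetic coherence and compositional-bias diagnostics.

A marker gene is useful for placing mitochondria among Alphaproteobacteria
only if (a) its single-gene tree is phylogenetically coherent — the
mitochondrial sequences form one clade and the alphaproteobacterial reference
sequences form one clade (markers violating this were likely shaped by
horizontal transfer) — and (b) it is robust to nucleotide compositional bias.

The bias diagnostic works at the protein level: genomes with AT-rich DNA are
enriched in amino acids encoded by AT-rich codon families (F, Y, M, I, N, K)
and depleted in those from GC-rich families (G, A, R, P).  A marker whose
taxa differ strongly in these frequencies is prone to compositional
attraction artefacts; a spread of only a few percent marks a robust marker.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .homology import OrthologDataset
from .trees import LabelledTree, is_monophyletic

__all__ = [
    "AT_RESIDUES",
    "GC_RESIDUES",
    "CoherenceVerdict",
    "CompositionProfile",
    "coherence_test",
    "resolves_reference_orders",
    "select_markers",
    "at_gc_frequencies",
    "composition_spread",
    "composition_report_tsv",
]

#: Amino acids from AT-rich codon families (the "FYMINK" set).
AT_RESIDUES = frozenset("FYMINK")
#: Amino acids from GC-rich codon families (the "GARP" set).
GC_RESIDUES = frozenset("GARP")

#: Spread above this fraction flags a marker as composition-biased
#: ("a few percent" operationalised as 5 percentage points).
DEFAULT_SPREAD_THRESHOLD = 0.05


@dataclass(frozen=True)
class CoherenceVerdict:
    marker_name: str
    mito_monophyletic: bool
    alpha_monophyletic: bool

    @property
    def passed(self) -> bool:
        return self.mito_monophyletic and self.alpha_monophyletic


@dataclass
class CompositionProfile:
    """Per-taxon AT-set and GC-set residue frequencies plus their spreads."""

    marker_name: str
    f_at: dict[str, float]
    f_gc: dict[str, float]
    spread_at: float
    spread_gc: float
    biased: bool = field(default=False)


def coherence_test(tree: LabelledTree, marker_name: str = "") -> CoherenceVerdict:
    """Dual-monophyly criterion on a single-marker tree.

    Requires categorised leaves: at least one mitochondrial and at least two
    reference leaves.  On unrooted trees monophyly means split presence.

    The mitochondrial lineage branches *within* the alphaproteobacterial
    radiation (sister to the Rickettsiales in coherent trees), so the
    alphaproteobacterial clade is assessed over the reference and
    mitochondrial leaves jointly: the criterion fails when outgroup sequences
    intrude into that clade or alphaproteobacterial sequences fall outside it
    — the signature of horizontal transfer or systematic error this filter
    exists to catch.
    """
    mito = tree.leaves_of_kind("mitochondrial")
    alpha = tree.leaves_of_kind("reference")
    if not mito:
        raise ValueError("coherence test needs at least one mitochondrial leaf")
    if len(alpha) < 2:
        raise ValueError("coherence test needs at least two reference leaves")
    uncat = tree.leaf_set - set(tree.categories)
    if uncat:
        raise ValueError(f"leaves without a category: {sorted(uncat)}")
    return CoherenceVerdict(
        marker_name=marker_name,
        mito_monophyletic=is_monophyletic(tree, mito),
        alpha_monophyletic=is_monophyletic(tree, alpha | mito),
    )


def resolves_reference_orders(tree: LabelledTree) -> bool:
    """Does the marker tree recover every reference order as a clade?

    The markers worth carrying into the neighbour screen are those that
    resolve the deep backbone: each alphaproteobacterial order monophyletic
    on the reference tree.  Markers failing this cannot place a divergent
    environmental lineage relative to the mitochondrial clade reliably.
    """
    orders = tree.reference_orders()
    if len(orders) < 2:
        raise ValueError("need reference leaves from at least two orders")
    return all(is_monophyletic(tree, labs) for labs in orders.values())


def select_markers(
    verdicts: Iterable[CoherenceVerdict], shortlist_size: int | None = None
) -> list[str]:
    """Names of passing markers, sorted by name; optionally truncated to a
    shortlist (the detailed-analysis budget)."""
    passing = sorted(v.marker_name for v in verdicts if v.passed)
    if shortlist_size is not None:
        passing = passing[:shortlist_size]
    return passing


def at_gc_frequencies(
    seq: str,
    at_set: frozenset[str] = AT_RESIDUES,
    gc_set: frozenset[str] = GC_RESIDUES,
) -> tuple[float, float]:
    """Fractions of AT-set and GC-set residues in a protein sequence.

    Gaps and ambiguity characters are excluded from the denominator.
    """
    residues = [c for c in seq.upper() if c.isalpha() and c not in "XBZJ"]
    if not residues:
        raise ValueError("sequence has no unambiguous residues")
    n = len(residues)
    n_at = sum(1 for c in residues if c in at_set)
    n_gc = sum(1 for c in residues if c in gc_set)
    return n_at / n, n_gc / n


def composition_spread(
    dataset: OrthologDataset,
    at_set: frozenset[str] = AT_RESIDUES,
    gc_set: frozenset[str] = GC_RESIDUES,
    spread_threshold: float = DEFAULT_SPREAD_THRESHOLD,
    exclude_categories: frozenset[str] = frozenset({"environmental"}),
) -> CompositionProfile:
    """Per-taxon composition frequencies and their max-minus-min spreads.

    By default environmental fragments are excluded (the diagnostic targets
    the reference + mitochondrial taxa whose genomes set the AT/GC contrast).
    """
    seqs = {
        i: s
        for i, s in dataset.sequences.items()
        if dataset.members[i].split(":")[0] not in exclude_categories
    }
    if len(seqs) < 2:
        raise ValueError("composition spread needs at least two taxa")
    f_at: dict[str, float] = {}
    f_gc: dict[str, float] = {}
    for taxon, seq in seqs.items():
        f_at[taxon], f_gc[taxon] = at_gc_frequencies(seq, at_set, gc_set)
    spread_at = max(f_at.values()) - min(f_at.values())
    spread_gc = max(f_gc.values()) - min(f_gc.values())
    return CompositionProfile(
        marker_name=dataset.marker_name,
        f_at=f_at,
        f_gc=f_gc,
        spread_at=spread_at,
        spread_gc=spread_gc,
        biased=max(spread_at, spread_gc) > spread_threshold,
    )


def composition_report_tsv(profiles: Sequence[CompositionProfile]) -> str:
    """TSV report: marker, taxon, f_AT, f_GC (plus per-marker spread rows)."""
    lines = ["marker\ttaxon\tf_AT\tf_GC"]
    for prof in profiles:
        for taxon in sorted(prof.f_at):
            lines.append(
                f"{prof.marker_name}\t{taxon}\t{prof.f_at[taxon]:.4f}\t{prof.f_gc[taxon]:.4f}"
            )
        lines.append(
            f"{prof.marker_name}\t__spread__\t{prof.spread_at:.4f}\t{prof.spread_gc:.4f}"
        )
    return "\n".join(lines) + "\n"
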