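"""The taxon jack-knife screen for neighbours of the mitochondrial clade.

Repeatedly draws random samples (with replacement) from the environmental
pool, infers a tree for sample + reference set, roots it with the outgroup,
and extracts the environmental sequences affiliated with the mitochondrial
clade.  Flag counts accumulate across replicates; sampling everything is
guaranteed in probability, quantified by the closed-form un-sampled fraction
(1 - 1/N)^(m*r).

Affiliation ("neighbour") rules
-------------------------------
``INSIDE_ONLY``
    environmental leaves descending from the MRCA of the mitochondrial
    sequences.
``INSIDE_PLUS_SISTER`` (default)
    additionally, environmental leaves encountered while walking rootward
    from that MRCA: a sister clade containing no reference/outgroup leaves is
    always absorbed and the walk continues; a sister whose reference leaves
    all belong to a *single* order (the local sister-group case — the
    Rickettsiales, when the tree is coherent) is absorbed at most once; the
    walk stops at any other sister.  This captures lineages branching at or
    just below the root of the mitochondrial clade's sister group without
    ever naming that group — it enters the neighbourhood purely through
    topology — while a mitochondrial clade stranded against the tree's
    backbone (sister spanning several orders) contributes only its internal
    environmental leaves.

Flagged sequences sitting on multi-gene scaffolds are concatenated into a
partitioned alignment for downstream analysis with any external engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .homology import OrthologDataset
from .trees import (
    ENVIRONMENTAL,
    MITOCHONDRIAL,
    OUTGROUP,
    LabelledTree,
    LeafCategory,
    Node,
    mrca,
    neighbor_joining,
    pairwise_distance,
    reference,
    root_with_outgroup,
)

__all__ = [
    "ScreenConfig",
    "ScreenResult",
    "ScaffoldMap",
    "BACKENDS",
    "get_backend",
    "register_backend",
    "category_from_tag",
    "jackknife_sample",
    "extract_mito_neighbours",
    "run_screen",
    "unsampled_fraction",
    "scaffold_concat",
]


# ---------------------------------------------------------------------------
# tree-inference backends
# ---------------------------------------------------------------------------

Backend = Callable[[Mapping[str, str], Mapping[str, LeafCategory]], LabelledTree]


def _nj_backend(model: str) -> Backend:
    def infer(aln: Mapping[str, str], categories: Mapping[str, LeafCategory]):
        dm = pairwise_distance(aln, model=model)
        return neighbor_joining(dm, categories=categories)

    return infer


#: Pluggable inference backends: alignment + categories -> LabelledTree.
#: Only distance methods are built in; ML or Bayesian engines can be
#: registered by the caller.
BACKENDS: dict[str, Backend] = {
    "nj-jc20": _nj_backend("jc20"),
    "nj-poisson": _nj_backend("poisson"),
    "nj-p": _nj_backend("p"),
}


def get_backend(name: str) -> Backend:
    try:
        return BACKENDS[name]
    except KeyError:
        raise KeyError(
            f"unknown backend {name!r}; available: {sorted(BACKENDS)}"
        ) from None


def register_backend(name: str, fn: Backend) -> None:
    BACKENDS[name] = fn


def category_from_tag(tag: str) -> LeafCategory:
    """Parse an OrthologDataset member tag (``reference:SAR11``,
    ``mitochondrial``, ``environmental``, ``outgroup``)."""
    kind, _, order = tag.partition(":")
    if kind == "reference":
        return reference(order)
    return LeafCategory(kind)


# ---------------------------------------------------------------------------
# configuration and results
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScreenConfig:
    """Jack-knife screen parameters.

    ``sample_size`` sequences are drawn with replacement per replicate
    (default 100), ``replicates`` times (default 100).  ``min_flag_count``
    and ``min_flag_rate`` are the reproducibility knobs: a sequence enters
    the flagged set once it has been extracted in at least ``min_flag_count``
    replicates *and* in at least ``min_flag_rate`` of the replicates that
    sampled it (majority-of-replicates by default, which suppresses one-off
    placements caused by estimation noise in single replicate trees).
    """

    sample_size: int = 100
    replicates: int = 100
    rng_seed: int = 0
    backend: str = "nj-jc20"
    neighbour_mode: str = "INSIDE_PLUS_SISTER"
    min_flag_count: int = 1
    min_flag_rate: float = 0.5
    max_failure_fraction: float = 0.10

    def __post_init__(self) -> None:
        if self.sample_size < 1 or self.replicates < 1:
            raise ValueError("sample_size and replicates must be >= 1")
        if self.neighbour_mode not in {"INSIDE_ONLY", "INSIDE_PLUS_SISTER"}:
            raise ValueError("neighbour_mode must be INSIDE_ONLY or INSIDE_PLUS_SISTER")
        if self.min_flag_count < 1:
            raise ValueError("min_flag_count must be >= 1")
        if not (0.0 <= self.min_flag_rate <= 1.0):
            raise ValueError("min_flag_rate must be in [0, 1]")


@dataclass
class ScreenResult:
    """Per-sequence sampling and flagging counts plus derived quantities."""

    times_sampled: dict[str, int]
    times_flagged: dict[str, int]
    flagged: frozenset[str]
    unsampled_fraction_estimate: float
    pool_size: int
    replicates_run: int
    replicates_failed: int

    def report_tsv(self) -> str:
        lines = ["id\ttimes_sampled\ttimes_flagged"]
        for sid in sorted(self.times_sampled):
            lines.append(
                f"{sid}\t{self.times_sampled[sid]}\t{self.times_flagged.get(sid, 0)}"
            )
        return "\n".join(lines) + "\n"


@dataclass
class ScaffoldMap:
    """scaffold id -> ordered list of (marker, sequence id).

    Each sequence id appears on exactly one scaffold.
    """

    scaffolds: dict[str, list[tuple[str, str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for scaf, genes in self.scaffolds.items():
            for _, sid in genes:
                if sid in seen:
                    raise ValueError(
                        f"sequence {sid!r} appears on scaffolds {seen[sid]!r} and {scaf!r}"
                    )
                seen[sid] = scaf
        self._scaffold_of = seen

    def scaffold_of(self, seq_id: str) -> str:
        return self._scaffold_of[seq_id]

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self._scaffold_of

    @classmethod
    def read_tsv(cls, path_or_buf) -> "ScaffoldMap":
        df = pd.read_csv(
            path_or_buf, sep="\t", names=["scaffold_id", "marker", "sequence_id"],
            header=None, comment="#", dtype=str,
        )
        scaffolds: dict[str, list[tuple[str, str]]] = {}
        for row in df.itertuples(index=False):
            scaffolds.setdefault(row.scaffold_id, []).append(
                (row.marker, row.sequence_id)
            )
        return cls(scaffolds)

    def to_tsv(self, path_or_buf=None) -> str | None:
        rows = [
            f"{scaf}\t{marker}\t{sid}"
            for scaf, genes in self.scaffolds.items()
            for marker, sid in genes
        ]
        text = "\n".join(rows) + "\n"
        if path_or_buf is None:
            return text
        with open(path_or_buf, "w") as fh:
            fh.write(text)
        return None


# ---------------------------------------------------------------------------
# core operations
# ---------------------------------------------------------------------------

def jackknife_sample(
    pool: Sequence[str], m: int, rng: np.random.Generator
) -> list[str]:
    """Draw ``m`` ids uniformly with replacement (``m`` may exceed the pool)."""
    if len(pool) == 0:
        raise ValueError("cannot sample from an empty pool")
    idx = rng.integers(0, len(pool), size=m)
    return [pool[i] for i in idx]


def unsampled_fraction(n_pool: int, m: int, r: int) -> float:
    """Probability that a given pool member is never drawn across all
    replicates: (1 - 1/N)^(m*r)."""
    if n_pool < 1:
        raise ValueError("pool size must be >= 1")
    return (1.0 - 1.0 / n_pool) ** (m * r)


def _sibling_clades(node: Node) -> list[Node]:
    """Siblings of ``node``; under a polytomous parent, all of them."""
    if node.parent is None:
        return []
    return [c for c in node.parent.children if c is not node]


def extract_mito_neighbours(
    tree: LabelledTree, mode: str = "INSIDE_PLUS_SISTER"
) -> frozenset[str]:
    """Environmental leaves affiliated with the mitochondrial clade.

    Requires a rooted tree with at least one mitochondrial leaf.  See the
    module docstring for the two affiliation rules.
    """
    if not tree.rooted:
        raise ValueError("neighbour extraction requires a rooted tree")
    mito = tree.leaves_of_kind("mitochondrial")
    if not mito:
        raise ValueError("tree contains no mitochondrial leaf")
    env = tree.leaves_of_kind("environmental")
    blockers = tree.leaves_of_kind("reference") | tree.leaves_of_kind("outgroup")
    sets = tree.clade_leafsets()

    a = mrca(tree, mito)
    flagged = set(sets[id(a)] & env)
    if mode == "INSIDE_ONLY":
        return frozenset(flagged)

    order_of = {
        lab: cat.order
        for lab, cat in tree.categories.items()
        if cat.kind == "reference"
    }
    outgroup = tree.leaves_of_kind("outgroup")

    node = a
    sister_order: str | None = None
    in_neighbourhood = True
    while node.parent is not None:
        sibs = _sibling_clades(node)
        sib_leaves = (
            frozenset().union(*(sets[id(s)] for s in sibs)) if sibs else frozenset()
        )
        if sib_leaves & outgroup:
            break
        if sib_leaves & blockers:
            sib_orders = {order_of[l] for l in sib_leaves if l in order_of}
            # the local sister group may be recovered paraphyletically, so
            # successive sisters of one and the same order are stepped over;
            # a sister spanning several orders ends the neighbourhood
            local_sister = (
                in_neighbourhood
                and len(sib_orders) == 1
                and sister_order in (None, next(iter(sib_orders)))
            )
            if local_sister:
                sister_order = next(iter(sib_orders))
                flagged |= sib_leaves & env
            else:
                # deep-survey phase: past the backbone, only purely
                # environmental sisters count — lineages diverging below the
                # whole reference radiation, the "deeply diverging" candidate
                # relatives that single-gene trees cannot place precisely
                in_neighbourhood = False
        else:
            flagged |= sib_leaves & env
        node = node.parent
    return frozenset(flagged)


def run_screen(
    dataset: OrthologDataset,
    reference_set: OrthologDataset,
    cfg: ScreenConfig = ScreenConfig(),
) -> ScreenResult:
    """Run the jack-knife screen for one marker.

    ``dataset`` holds the aligned environmental pool; ``reference_set`` the
    aligned reference taxa and must include mitochondrial and outgroup
    members.  Both alignments must share the same column space.  A replicate
    whose backend or rooting fails is skipped and counted; more than
    ``max_failure_fraction`` failures abort the screen.
    """
    if dataset.alignment is None or reference_set.alignment is None:
        raise ValueError("both datasets must carry alignments")
    ref_cats = {i: category_from_tag(t) for i, t in reference_set.members.items()}
    if not any(c.kind == "mitochondrial" for c in ref_cats.values()):
        raise ValueError("reference set has no mitochondrial member")
    outgroup = frozenset(i for i, c in ref_cats.items() if c.kind == "outgroup")
    if not outgroup:
        raise ValueError("reference set has no outgroup member")

    pool = sorted(dataset.members)
    if not pool:
        raise ValueError("environmental pool is empty")
    backend = get_backend(cfg.backend)
    rng = np.random.default_rng(cfg.rng_seed)

    times_sampled: dict[str, int] = {sid: 0 for sid in pool}
    times_flagged: dict[str, int] = {}
    failures = 0

    for _ in range(cfg.replicates):
        sample = jackknife_sample(pool, cfg.sample_size, rng)
        unique = sorted(set(sample))
        aln = dict(reference_set.alignment)
        aln.update({sid: dataset.alignment[sid] for sid in unique})
        cats = dict(ref_cats)
        cats.update({sid: ENVIRONMENTAL for sid in unique})
        for sid in unique:
            times_sampled[sid] += 1
        try:
            tree = backend(aln, cats)
            try:
                rooted = root_with_outgroup(tree, outgroup)
            except ValueError:
                # outgroup not recovered as a split in this replicate; fall
                # back to rooting on its first member's pendant branch
                rooted = root_with_outgroup(tree, {min(outgroup)})
            for sid in extract_mito_neighbours(rooted, cfg.neighbour_mode):
                times_flagged[sid] = times_flagged.get(sid, 0) + 1
        except Exception:
            failures += 1

    if failures > cfg.max_failure_fraction * cfg.replicates:
        raise RuntimeError(
            f"{failures}/{cfg.replicates} replicates failed "
            f"(> {cfg.max_failure_fraction:.0%})"
        )

    flagged = frozenset(
        sid
        for sid, c in times_flagged.items()
        if c >= cfg.min_flag_count
        and times_sampled[sid] > 0
        and c / times_sampled[sid] >= cfg.min_flag_rate
    )
    return ScreenResult(
        times_sampled=times_sampled,
        times_flagged=times_flagged,
        flagged=flagged,
        unsampled_fraction_estimate=unsampled_fraction(
            len(pool), cfg.sample_size, cfg.replicates
        ),
        pool_size=len(pool),
        replicates_run=cfg.replicates,
        replicates_failed=failures,
    )


# ---------------------------------------------------------------------------
# scaffold-based concatenation
# ---------------------------------------------------------------------------

def scaffold_concat(
    flagged: Iterable[str],
    smap: ScaffoldMap,
    alignments: Mapping[str, Mapping[str, str]],
    reference_taxa: Mapping[str, Mapping[str, str]] | None = None,
) -> tuple[dict[str, str], list[tuple[str, int, int]]]:
    """Concatenate flagged sequences scaffold-wise into a partitioned alignment.

    Scaffolds carrying at least one flagged sequence and more than one gene
    (restricted to markers present in ``alignments``) contribute one
    concatenated row named by the scaffold id; markers a scaffold lacks are
    gap-filled.  ``reference_taxa`` maps taxon -> (marker -> aligned sequence)
    and is concatenated in the same fixed marker order.  Returns the
    concatenated alignment and 1-based inclusive partition boundaries
    (marker, start, end).

    A scaffold carrying the same marker twice trips a paralogy error.
    """
    flagged = frozenset(flagged)
    missing = [sid for sid in flagged if sid not in smap]
    if missing:
        raise KeyError(f"flagged ids absent from the scaffold map: {sorted(missing)}")

    keep: dict[str, dict[str, str]] = {}
    for scaf, genes in smap.scaffolds.items():
        genes_known = [(m, sid) for m, sid in genes if m in alignments]
        if not any(sid in flagged for _, sid in genes_known):
            continue
        if len(genes_known) < 2:
            continue  # single-gene scaffolds cannot be concatenated
        per_marker: dict[str, str] = {}
        for marker, sid in genes_known:
            if marker in per_marker:
                raise ValueError(
                    f"scaffold {scaf!r} carries marker {marker!r} twice (paralogy?)"
                )
            per_marker[marker] = alignments[marker][sid]
        keep[scaf] = per_marker

    markers = sorted({m for pm in keep.values() for m in pm})
    if not markers:
        return {}, []
    lengths = {m: len(next(iter(alignments[m].values()))) for m in markers}

    partitions: list[tuple[str, int, int]] = []
    start = 1
    for m in markers:
        partitions.append((m, start, start + lengths[m] - 1))
        start += lengths[m]

    out: dict[str, str] = {}
    for scaf, per_marker in keep.items():
        out[scaf] = "".join(
            per_marker.get(m, "-" * lengths[m]) for m in markers
        )
    for taxon, per_marker in (reference_taxa or {}).items():
        out[taxon] = "".join(
            per_marker.get(m, "-" * lengths[m]) for m in markers
        )
    return out, partitions
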