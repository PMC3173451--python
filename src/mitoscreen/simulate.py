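"""Synthetic metagenome generator with full truth labels.

Generates datasets with the statistical structure the screen assumes: a
rooted species tree whose ingroup resolves into six alphaproteobacterial
order-like clades with the mitochondrial clade sister to the Rickettsiales, a
rare "planted" clade attached to the Rickettsiales+mitochondria stem (the
ground-truth analogue of an undiscovered free-living mitochondrial relative),
protein evolution with optional lineage-specific AT-composition bias, an
ocean-survey-like environmental pool organised into 1–3-gene scaffolds, and
emulated tabular hit files for the staged homology filter.

Every output is deterministic under ``SimConfig.rng_seed`` (each generation
step draws from its own seed-derived substream, so the individual operations
reproduce the orchestrated run exactly).

The sequence model is a jump process: along a branch of length ``t`` (times
``substitution_rate``), each site jumps with probability 1 - exp(-t) and then
redraws its residue from the governing stationary frequency vector.  Expected
identity between two leaves at path distance ``d`` is therefore
``exp(-d) + (1 - exp(-d)) * sum(pi^2)`` — a closed form the tests check
against.  AT-biased lineages (by default the SAR11-like, Rickettsiales-like,
mitochondrial and planted clades, matching the AT-rich genomes they emulate)
use frequencies shifted toward the FYMINK residue set with strength ``s``.

Alignments are gapless: indel evolution is out of scope, and real data enters
the pipeline pre-aligned.  Hit tables are generated from truth rather than by
running a search — the filters, not the search engine, are under study; each
emission also contains deliberate boundary records (E-value exactly 1e-10,
overlap exactly 0.5 / 0.7) that a strict-threshold filter must reject.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .homology import HitRecord, HitTable, OrthologDataset
from .screen import ScaffoldMap
from .trees import (
    ENVIRONMENTAL,
    MITOCHONDRIAL,
    OUTGROUP,
    LabelledTree,
    LeafCategory,
    Node,
    mrca,
    reference,
)

__all__ = [
    "AA_ALPHABET",
    "HitNoise",
    "SimConfig",
    "SimulatedDataset",
    "random_tree",
    "simulate_species_tree",
    "evolve_alignment",
    "emit_metagenome",
    "emit_hit_tables",
    "simulate_dataset",
    "expected_identity",
    "evaluate_screen",
]

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AT_IDX = np.array([AA_ALPHABET.index(c) for c in "FYMINK"])

DEFAULT_ORDER_SIZES: dict[str, int] = {
    "SAR11": 4,
    "Rhodobacterales": 5,
    "Rhodospirillales": 5,
    "Rhizobiales": 6,
    "Caulobacterales": 4,
    "Rickettsiales": 4,
}  # 28 reference taxa across six orders

DEFAULT_ENV_PROFILE: dict[str, float] = {
    "SAR11": 0.825,
    "Rhodobacterales": 0.093,
    "Rhodospirillales": 0.074,
    "Rhizobiales": 0.006,
    "Rickettsiales": 0.002,
}

DEFAULT_MARKERS: tuple[str, ...] = ("COX1", "COX2", "COB", "NAD7", "RPS2")

DEFAULT_SCAFFOLD_GENE_COUNTS: dict[int, float] = {1: 0.6, 2: 0.3, 3: 0.1}

# substream tags so each generation step has its own reproducible stream
_STREAM_PLAN, _STREAM_TREE, _STREAM_EVOLVE, _STREAM_HITS = 1, 2, 3, 4


@dataclass(frozen=True)
class HitNoise:
    """Jitter applied to emulated hit tables.

    ``evalue_log10_jitter`` perturbs log10 E-values, ``overlap_jitter``
    perturbs coverage fractions (clipped to [0, 1]), ``decoy_rate`` is the
    number of decoy paralogs (cross-group top hits) per true member.
    """

    evalue_log10_jitter: float = 0.0
    overlap_jitter: float = 0.0
    decoy_rate: float = 0.0


@dataclass
class SimConfig:
    """Parameters of the synthetic metagenome.

    ``env_pool_size`` counts environmental gene sequences drawn from
    ``env_order_profile`` (one 1–3-gene scaffold per organism); the planted
    clade contributes ``planted_fraction * env_pool_size`` further sequences
    spread over ``planted_clade_size`` organism lineages (multi-scaffold
    organisms).

    Branch lengths are exponential: within-clade branches with mean
    ``branch_length_mean`` substitutions/site, backbone branches (order
    stems and the internodes joining the major clades) with the larger mean
    ``stem_length_mean`` — the orders being emulated are anciently diverged
    lineages whose stems carry most of the deep signal, which is what makes
    marker trees resolvable at all.  The planted clade's stem is fixed at
    ``planted_stem_length``.
    """

    rng_seed: int = 0
    order_sizes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_ORDER_SIZES)
    )
    mito_count: int = 5
    outgroup_count: int = 2
    planted_clade_size: int = 6
    planted_stem_length: float = 0.3
    env_pool_size: int = 1000
    env_order_profile: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ENV_PROFILE)
    )
    planted_fraction: float = 0.02
    seq_length: int = 500
    substitution_rate: float = 1.0
    branch_length_mean: float = 0.06
    stem_length_mean: float = 0.25
    env_pendant_mean: float = 0.03
    bias_strength: float = 0.0
    at_biased_groups: tuple[str, ...] = (
        "SAR11",
        "Rickettsiales",
        "mitochondria",
        "planted",
    )
    scaffold_gene_counts: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_SCAFFOLD_GENE_COUNTS)
    )
    markers: tuple[str, ...] = DEFAULT_MARKERS
    hit_noise: HitNoise = HitNoise()

    def __post_init__(self) -> None:
        if not (0.0 <= self.bias_strength <= 1.0):
            raise ValueError("bias_strength must be in [0, 1]")
        if any(v < 0 for v in self.order_sizes.values()):
            raise ValueError("order sizes must be non-negative")
        prof_sum = sum(self.env_order_profile.values())
        if prof_sum > 1.0 + 1e-9:
            raise ValueError("env_order_profile proportions must sum to <= 1")
        unknown = set(self.env_order_profile) - set(self.order_sizes)
        if unknown:
            raise ValueError(f"profile orders without reference taxa: {sorted(unknown)}")
        if not (0.0 <= self.planted_fraction <= 1.0):
            raise ValueError("planted_fraction must be in [0, 1]")
        if set(self.scaffold_gene_counts) - {1, 2, 3}:
            raise ValueError("scaffold gene counts must be over {1, 2, 3}")

    @property
    def has_planted(self) -> bool:
        return self.planted_clade_size > 0 and self.planted_fraction > 0


# ---------------------------------------------------------------------------
# metagenome plan (organisms, scaffolds, markers)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Organism:
    label: str
    group: str  # order name or "planted"
    scaffolds: tuple[tuple[str, tuple[str, ...]], ...]  # (scaffold_id, markers)


def _plan_metagenome(cfg: SimConfig) -> list[Organism]:
    rng = np.random.default_rng([cfg.rng_seed, _STREAM_PLAN])
    orders = sorted(cfg.env_order_profile)
    probs = np.array([cfg.env_order_profile[o] for o in orders])
    probs = probs / probs.sum()
    sizes = sorted(cfg.scaffold_gene_counts)
    size_p = np.array([cfg.scaffold_gene_counts[s] for s in sizes], dtype=float)
    size_p /= size_p.sum()
    markers = list(cfg.markers)

    organisms: list[Organism] = []
    total = 0
    idx = 0
    while total < cfg.env_pool_size:
        order = orders[int(rng.choice(len(orders), p=probs))]
        c = int(rng.choice(sizes, p=size_p))
        c = min(c, len(markers), cfg.env_pool_size - total)
        mks = tuple(sorted(rng.choice(markers, size=c, replace=False)))
        scaf = f"SCF{idx:05d}"
        organisms.append(
            Organism(label=f"GOS_{order}_{idx:05d}", group=order,
                     scaffolds=((scaf, mks),))
        )
        total += c
        idx += 1

    if cfg.has_planted:
        target = int(round(cfg.planted_fraction * cfg.env_pool_size))
        used: list[set[str]] = [set() for _ in range(cfg.planted_clade_size)]
        scafs: list[list[tuple[str, tuple[str, ...]]]] = [
            [] for _ in range(cfg.planted_clade_size)
        ]
        placed = 0
        org_i = 0
        while placed < target:
            avail = sorted(set(markers) - used[org_i % cfg.planted_clade_size])
            if not avail:
                org_i += 1
                if all(len(u) == len(markers) for u in used):
                    break  # lineages saturated; cannot place more genes
                continue
            c = int(rng.choice(sizes, p=size_p))
            c = min(c, len(avail), target - placed)
            mks = tuple(sorted(rng.choice(avail, size=c, replace=False)))
            j = org_i % cfg.planted_clade_size
            used[j].update(mks)
            scafs[j].append((f"SCF{idx:05d}", mks))
            placed += c
            idx += 1
            org_i += 1
        for j in range(cfg.planted_clade_size):
            organisms.append(
                Organism(label=f"OMAC_{j:02d}", group="planted",
                         scaffolds=tuple(scafs[j]))
            )
    return organisms


# ---------------------------------------------------------------------------
# tree simulation
# ---------------------------------------------------------------------------

def _join_random(nodes: list[Node], rng: np.random.Generator, mean: float) -> Node:
    """Random sequential pairwise joining into a binary clade."""
    nodes = list(nodes)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = Node(length=float(rng.exponential(mean)))
        parent.add(nodes[i])
        parent.add(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    return nodes[0]


def random_tree(
    labels: Sequence[str],
    rng: np.random.Generator,
    mean_branch: float = 0.1,
    rooted: bool = True,
) -> LabelledTree:
    """Random binary topology over ``labels`` with exponential branch lengths.

    A general-purpose fixture generator (also used by the property tests).
    """
    if len(labels) < 2:
        raise ValueError("need at least two labels")
    leaves = [Node(l, length=float(rng.exponential(mean_branch))) for l in labels]
    top = _join_random(leaves, rng, mean_branch)
    if rooted and len(top.children) == 2:
        top.length = 0.0
        return LabelledTree(top, rooted=True)
    top.length = 0.0
    return LabelledTree(top, rooted=False)


def simulate_species_tree(cfg: SimConfig) -> LabelledTree:
    """Rooted binary organism tree: reference orders with their environmental
    organisms nested inside, mitochondria sister to the Rickettsiales-like
    order, the planted clade on the Rickettsiales+mitochondria stem, and the
    outgroup across the root."""
    rng = np.random.default_rng([cfg.rng_seed, _STREAM_TREE])
    plan = _plan_metagenome(cfg)
    mean = cfg.branch_length_mean
    stem = cfg.stem_length_mean

    env_by_group: dict[str, list[str]] = {}
    for org in plan:
        env_by_group.setdefault(org.group, []).append(org.label)

    categories: dict[str, LeafCategory] = {}
    clades: dict[str, Node] = {}
    for order in sorted(cfg.order_sizes):
        labels = [f"{order}_{i:02d}" for i in range(cfg.order_sizes[order])]
        for lab in labels:
            categories[lab] = reference(order)
        env_labels = env_by_group.get(order, [])
        for lab in env_labels:
            categories[lab] = ENVIRONMENTAL
        members = [Node(l, length=float(rng.exponential(mean))) for l in labels]
        members += [
            Node(l, length=float(rng.exponential(cfg.env_pendant_mean)))
            for l in env_labels
        ]
        if not members:
            continue
        clades[order] = _join_random(members, rng, mean)

    mito_labels = [f"MITO_{i:02d}" for i in range(cfg.mito_count)]
    for lab in mito_labels:
        categories[lab] = MITOCHONDRIAL
    mito = _join_random(
        [Node(l, length=float(rng.exponential(mean))) for l in mito_labels], rng, mean
    )

    out_labels = [f"OUT_{i:02d}" for i in range(cfg.outgroup_count)]
    for lab in out_labels:
        categories[lab] = OUTGROUP
    outgroup = _join_random(
        [Node(l, length=float(rng.exponential(mean))) for l in out_labels], rng, mean
    )

    if "Rickettsiales" not in clades:
        raise ValueError("order_sizes must include a Rickettsiales-like order")
    for clade in clades.values():  # order stems carry the deep signal
        clade.length = float(rng.exponential(stem))
    rick = clades.pop("Rickettsiales")
    mito.length = float(rng.exponential(stem))
    rick_mito = Node(length=float(rng.exponential(stem)))
    rick_mito.add(rick)
    rick_mito.add(mito)

    top_ingroup = rick_mito
    planted_labels = env_by_group.get("planted", [])
    if planted_labels:
        for lab in planted_labels:
            categories[lab] = ENVIRONMENTAL
        planted = _join_random(
            [Node(l, length=float(rng.exponential(mean))) for l in planted_labels],
            rng,
            mean,
        )
        planted.length = cfg.planted_stem_length
        holder = Node(length=float(rng.exponential(stem)))
        holder.add(planted)
        holder.add(rick_mito)
        top_ingroup = holder

    free_living = _join_random(list(clades.values()), rng, stem)
    free_living.length = float(rng.exponential(stem))
    ingroup = Node(length=float(rng.exponential(stem)))
    ingroup.add(free_living)
    ingroup.add(top_ingroup)

    outgroup.length = float(rng.exponential(stem))
    root = Node()
    root.add(outgroup)
    root.add(ingroup)
    return LabelledTree(root, rooted=True, categories=categories)


# ---------------------------------------------------------------------------
# sequence evolution
# ---------------------------------------------------------------------------

_GROUP_PREFIXES = {
    "SAR11": ("SAR11_", "GOS_SAR11_"),
    "Rickettsiales": ("Rickettsiales_", "GOS_Rickettsiales_"),
    "Rhodobacterales": ("Rhodobacterales_", "GOS_Rhodobacterales_"),
    "Rhodospirillales": ("Rhodospirillales_", "GOS_Rhodospirillales_"),
    "Rhizobiales": ("Rhizobiales_", "GOS_Rhizobiales_"),
    "Caulobacterales": ("Caulobacterales_", "GOS_Caulobacterales_"),
    "mitochondria": ("MITO_",),
    "planted": ("OMAC_",),
}


def _biased_frequencies(s: float) -> np.ndarray:
    pi_at = np.zeros(len(AA_ALPHABET))
    pi_at[_AT_IDX] = 1.0 / len(_AT_IDX)
    pi_global = np.full(len(AA_ALPHABET), 1.0 / len(AA_ALPHABET))
    return (1.0 - s) * pi_global + s * pi_at


def expected_identity(d: float, pi: np.ndarray | None = None) -> float:
    """Closed-form expected per-site identity between two sequences separated
    by path distance ``d`` under the jump model with frequencies ``pi``."""
    if pi is None:
        pi = np.full(len(AA_ALPHABET), 1.0 / len(AA_ALPHABET))
    ss = float(np.sum(np.asarray(pi) ** 2))
    return math.exp(-d) + (1.0 - math.exp(-d)) * ss


def evolve_alignment(
    tree: LabelledTree, cfg: SimConfig
) -> dict[str, dict[str, str]]:
    """Evolve one gapless alignment per marker down the tree.

    The global stationary frequency vector is uniform; clades named in
    ``cfg.at_biased_groups`` switch to FYMINK-shifted frequencies with
    strength ``cfg.bias_strength`` from their root downward.
    """
    labels = tree.leaf_set
    pi_global = np.full(len(AA_ALPHABET), 1.0 / len(AA_ALPHABET))
    pi_bias = _biased_frequencies(cfg.bias_strength)

    bias_roots: set[int] = set()
    if cfg.bias_strength > 0:
        for group in cfg.at_biased_groups:
            prefixes = _GROUP_PREFIXES.get(group, (f"{group}_", f"GOS_{group}_"))
            members = [l for l in labels if l.startswith(prefixes)]
            if members:
                bias_roots.add(id(mrca(tree, members)) if len(members) > 1
                               else id(tree.find_leaf(members[0])))

    # per-node governing frequencies
    pi_of: dict[int, np.ndarray] = {}
    for node in tree.preorder():
        if id(node) in bias_roots:
            pi_of[id(node)] = pi_bias
        elif node.parent is None:
            pi_of[id(node)] = pi_global
        else:
            pi_of[id(node)] = pi_of[id(node.parent)]

    out: dict[str, dict[str, str]] = {}
    n_aa = len(AA_ALPHABET)
    decode = np.array(list(AA_ALPHABET))
    for mi, marker in enumerate(cfg.markers):
        rng = np.random.default_rng([cfg.rng_seed, _STREAM_EVOLVE, mi])
        seqs: dict[int, np.ndarray] = {}
        aln: dict[str, str] = {}
        for node in tree.preorder():
            if node.parent is None:
                seq = rng.choice(n_aa, size=cfg.seq_length, p=pi_of[id(node)])
            else:
                t = node.length * cfg.substitution_rate
                jump = rng.random(cfg.seq_length) < (1.0 - math.exp(-t))
                seq = seqs[id(node.parent)].copy()
                k = int(jump.sum())
                if k:
                    seq[jump] = rng.choice(n_aa, size=k, p=pi_of[id(node)])
            seqs[id(node)] = seq
            if node.is_leaf:
                aln[node.label] = "".join(decode[seq])  # type: ignore[index]
        out[marker] = aln
    return out


# ---------------------------------------------------------------------------
# metagenome and hit-table emission
# ---------------------------------------------------------------------------

TRUTH_COLUMNS = ("sequence_id", "scaffold_id", "organism", "group", "is_planted")


def emit_metagenome(
    cfg: SimConfig, tree: LabelledTree, alignments: Mapping[str, Mapping[str, str]]
) -> tuple[dict[str, str], ScaffoldMap, pd.DataFrame]:
    """Environmental FASTA records, scaffold map and truth table.

    Each scaffold's sequences are the evolved marker sequences of its
    organism; sequence ids are ``<scaffold>_<marker>``.
    """
    plan = _plan_metagenome(cfg)
    fasta: dict[str, str] = {}
    scaffolds: dict[str, list[tuple[str, str]]] = {}
    rows: list[tuple[str, str, str, str, bool]] = []
    for org in plan:
        for scaf, mks in org.scaffolds:
            for m in mks:
                sid = f"{scaf}_{m}"
                fasta[sid] = alignments[m][org.label]
                scaffolds.setdefault(scaf, []).append((m, sid))
                rows.append((sid, scaf, org.label, org.group, org.group == "planted"))
    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    return fasta, ScaffoldMap(scaffolds), truth


def emit_hit_tables(
    cfg: SimConfig, truth: pd.DataFrame
) -> tuple[HitTable, dict[str, HitTable], dict[str, HitTable], dict[str, str]]:
    """Emulated hit tables generated from truth labels.

    Returns (seed assignment table, per-marker environmental search tables,
    per-marker reciprocal tables, marker -> ortholog-group map).  True
    orthologs pass both stages comfortably; decoy paralogs (``decoy_rate``)
    pass the first stage but top-hit a different group in the reciprocal
    search; boundary records at the exact threshold values are always present
    and must be rejected by a strict filter.
    """
    rng = np.random.default_rng([cfg.rng_seed, _STREAM_HITS])
    noise = cfg.hit_noise
    og_of = {m: f"OG_{m}" for m in cfg.markers}

    def jitter_ev(log10_ev: float) -> float:
        if noise.evalue_log10_jitter:
            log10_ev += rng.normal(0.0, noise.evalue_log10_jitter)
        return 10.0 ** log10_ev

    def jitter_ov(ov: float) -> float:
        if noise.overlap_jitter:
            ov += rng.normal(0.0, noise.overlap_jitter)
        return float(np.clip(ov, 0.0, 1.0))

    seed_rows: list[HitRecord] = []
    env_tables: dict[str, HitTable] = {}
    rec_tables: dict[str, HitTable] = {}
    for m in cfg.markers:
        og = og_of[m]
        seed = f"SEED_{m}"
        seed_rows += [
            HitRecord(seed, f"{og}_rep", 1e-60, 0.95, 600.0, subject_og=og),
            HitRecord(seed, "OG_OTHER_rep", 1e-12, 0.80, 80.0, subject_og="OG_OTHER"),
            # boundary rows: exactly at the strict thresholds, never qualifying
            HitRecord(seed, f"{og}_ev_boundary", 1e-10, 0.90, 70.0, subject_og="OG_WRONG"),
            HitRecord(seed, f"{og}_ov_boundary", 1e-30, 0.50, 60.0, subject_og="OG_WRONG"),
        ]

        sids = sorted(truth.loc[truth.sequence_id.str.endswith(f"_{m}"), "sequence_id"])
        env_rows: list[HitRecord] = []
        rec_rows: list[HitRecord] = []
        for sid in sids:
            ev = jitter_ev(-float(rng.uniform(20, 50)))
            ov = jitter_ov(float(rng.uniform(0.75, 0.98)))
            env_rows.append(HitRecord(seed, sid, ev, ov, float(rng.uniform(300, 600))))
            rec_rows.append(
                HitRecord(
                    sid, f"{og}_rep", jitter_ev(-float(rng.uniform(20, 50))),
                    jitter_ov(float(rng.uniform(0.75, 0.98))),
                    float(rng.uniform(300, 600)), subject_og=og,
                )
            )
            # a weaker cross-group hit that must lose the top-hit contest
            rec_rows.append(
                HitRecord(
                    sid, "OG_PARALOG_rep", 1e-15, 0.75, 90.0, subject_og="OG_PARALOG"
                )
            )
        n_decoys = int(round(noise.decoy_rate * len(sids)))
        for i in range(n_decoys):
            did = f"DECOY_{m}_{i:03d}"
            env_rows.append(
                HitRecord(seed, did, jitter_ev(-float(rng.uniform(15, 30))),
                          jitter_ov(float(rng.uniform(0.6, 0.9))),
                          float(rng.uniform(150, 300)))
            )
            rec_rows.append(
                HitRecord(did, "OG_PARALOG_rep", 1e-40, 0.90, 500.0,
                          subject_og="OG_PARALOG")
            )
            rec_rows.append(
                HitRecord(did, f"{og}_rep", 1e-20, 0.85, 200.0, subject_og=og)
            )
        # boundary records, present in every emission
        env_rows.append(HitRecord(seed, f"BOUNDARY_EV_{m}", 1e-10, 0.90, 400.0))
        env_rows.append(HitRecord(seed, f"BOUNDARY_OV50_{m}", 1e-30, 0.50, 400.0))
        env_rows.append(HitRecord(seed, f"BOUNDARY_OV70_{m}", 1e-30, 0.90, 400.0))
        rec_rows.append(
            HitRecord(f"BOUNDARY_OV70_{m}", f"{og}_rep", 1e-30, 0.70, 400.0,
                      subject_og=og)
        )
        env_tables[m] = HitTable(env_rows)
        rec_tables[m] = HitTable(rec_rows)
    return HitTable(seed_rows), env_tables, rec_tables, og_of


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    """All outputs of one simulation, with truth labels."""

    config: SimConfig
    tree: LabelledTree
    alignments: dict[str, dict[str, str]]
    env_fasta: dict[str, str]
    scaffold_map: ScaffoldMap
    truth: pd.DataFrame
    seed_hits: HitTable
    env_hits: dict[str, HitTable]
    reciprocal_hits: dict[str, HitTable]
    og_of_marker: dict[str, str]

    def reference_dataset(self, marker: str) -> OrthologDataset:
        """Reference + mitochondrial + outgroup members with alignment."""
        aln = self.alignments[marker]
        members: dict[str, str] = {}
        for lab, cat in self.tree.categories.items():
            if cat.kind == "reference":
                members[lab] = f"reference:{cat.order}"
            elif cat.kind in ("mitochondrial", "outgroup"):
                members[lab] = cat.kind
        seqs = {lab: aln[lab] for lab in members}
        return OrthologDataset(
            marker_name=marker, members=members, sequences=seqs, alignment=dict(seqs)
        )

    def environmental_dataset(
        self, marker: str, ids: Iterable[str] | None = None
    ) -> OrthologDataset:
        """Environmental pool for one marker (optionally restricted)."""
        pool = self.marker_pool(marker) if ids is None else sorted(ids)
        orgs = dict(zip(self.truth.sequence_id, self.truth.organism))
        aln = self.alignments[marker]
        seqs = {sid: aln[orgs[sid]] for sid in pool}
        return OrthologDataset(
            marker_name=marker,
            members={sid: "environmental" for sid in pool},
            sequences=seqs,
            alignment=dict(seqs),
        )

    def marker_pool(self, marker: str) -> list[str]:
        mask = self.truth.sequence_id.str.endswith(f"_{marker}")
        return sorted(self.truth.loc[mask, "sequence_id"])

    def planted_ids(self, marker: str | None = None) -> frozenset[str]:
        sel = self.truth[self.truth.is_planted]
        if marker is not None:
            sel = sel[sel.sequence_id.str.endswith(f"_{marker}")]
        return frozenset(sel.sequence_id)

    def marker_alignment(self, marker: str) -> dict[str, str]:
        """Aligned sequences keyed by *sequence id* for environmental records
        plus taxon labels for reference/mitochondrial/outgroup leaves."""
        aln = dict(self.alignments[marker])
        orgs = dict(zip(self.truth.sequence_id, self.truth.organism))
        for sid in self.marker_pool(marker):
            aln[sid] = self.alignments[marker][orgs[sid]]
        return aln


def simulate_dataset(cfg: SimConfig | None = None) -> SimulatedDataset:
    """Run the full generator under one seed."""
    cfg = cfg or SimConfig()
    tree = simulate_species_tree(cfg)
    alignments = evolve_alignment(tree, cfg)
    env_fasta, smap, truth = emit_metagenome(cfg, tree, alignments)
    seed_hits, env_hits, rec_hits, og_of = emit_hit_tables(cfg, truth)
    return SimulatedDataset(
        config=cfg,
        tree=tree,
        alignments=alignments,
        env_fasta=env_fasta,
        scaffold_map=smap,
        truth=truth,
        seed_hits=seed_hits,
        env_hits=env_hits,
        reciprocal_hits=rec_hits,
        og_of_marker=og_of,
    )


def evaluate_screen(
    flagged: Iterable[str], dataset: SimulatedDataset
) -> tuple[float, float]:
    """Precision and recall of flagged ids against the planted-clade truth.

    Ids pooled across markers; recall is over every planted sequence in the
    environmental pool.
    """
    flagged = frozenset(flagged)
    planted = dataset.planted_ids()
    if not planted:
        raise ValueError("dataset has no planted clade to score against")
    tp = len(flagged & planted)
    precision = tp / len(flagged) if flagged else 0.0
    recall = tp / len(planted)
    return precision, recall
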