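"""Staged filtering of BLAST-style hit tables into curated ortholog datasets.

The screen never runs a similarity search itself: tabular hit files are
inputs.  What this module owns is the decision logic layered on top of them —
seed-to-ortholog-group assignment, retrieval of environmental candidates,
the reciprocal same-group confirmation that removes paralogs and distant
homologs, per-species deduplication, the dataset-size gate, and a transparent
gap-fraction column mask for alignments.

All three numeric thresholds are strict inequalities: a hit with E-value
exactly 1e-10, or coverage exactly at the minimum, does not qualify.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "HitRecord",
    "HitTable",
    "FilterConfig",
    "OrthologDataset",
    "assign_seed_orthologs",
    "dedup_per_species",
    "retrieve_env_candidates",
    "reciprocal_og_filter",
    "dataset_gate",
    "mask_columns",
    "curate_environmental_set",
]

HIT_COLUMNS = (
    "query",
    "subject",
    "pct_identity",
    "aln_len",
    "evalue",
    "bitscore",
    "qcov_fraction",
    "subject_og",
    "subject_species",
)


@dataclass(frozen=True)
class HitRecord:
    """One tabular search match.

    ``hsp_overlap_fraction`` is the best single HSP's coverage of the *query*
    sequence length, in [0, 1]; HSPs are not chained.
    """

    query_id: str
    subject_id: str
    evalue: float
    hsp_overlap_fraction: float
    bitscore: float
    subject_og: str | None = None
    subject_species: str | None = None

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("E-value must be >= 0")
        if not (0.0 <= self.hsp_overlap_fraction <= 1.0):
            raise ValueError("HSP overlap fraction must be in [0, 1]")


class HitTable:
    """An ordered collection of :class:`HitRecord`.

    The on-disk form is a 9-column TSV (a documented superset of the common
    12-column tabular search format): query, subject, pct_identity, aln_len,
    evalue, bitscore, qcov_fraction, subject_og, subject_species.
    """

    def __init__(self, records: Iterable[HitRecord] = ()) -> None:
        self.records: list[HitRecord] = list(records)

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def by_query(self) -> dict[str, list[HitRecord]]:
        out: dict[str, list[HitRecord]] = {}
        for rec in self.records:
            out.setdefault(rec.query_id, []).append(rec)
        return out

    @classmethod
    def read_tsv(cls, path_or_buf) -> "HitTable":
        df = pd.read_csv(
            path_or_buf, sep="\t", names=HIT_COLUMNS, header=None, comment="#",
            dtype={"query": str, "subject": str},
        )
        records = [
            HitRecord(
                query_id=row.query,
                subject_id=row.subject,
                evalue=float(row.evalue),
                hsp_overlap_fraction=float(row.qcov_fraction),
                bitscore=float(row.bitscore),
                subject_og=None if pd.isna(row.subject_og) else str(row.subject_og),
                subject_species=(
                    None if pd.isna(row.subject_species) else str(row.subject_species)
                ),
            )
            for row in df.itertuples(index=False)
        ]
        return cls(records)

    def to_tsv(self, path_or_buf=None) -> str | None:
        df = pd.DataFrame(
            {
                "query": [r.query_id for r in self.records],
                "subject": [r.subject_id for r in self.records],
                "pct_identity": [0.0] * len(self.records),
                "aln_len": [0] * len(self.records),
                "evalue": [r.evalue for r in self.records],
                "bitscore": [r.bitscore for r in self.records],
                "qcov_fraction": [r.hsp_overlap_fraction for r in self.records],
                "subject_og": [r.subject_og for r in self.records],
                "subject_species": [r.subject_species for r in self.records],
            }
        )
        if path_or_buf is None:
            buf = io.StringIO()
            df.to_csv(buf, sep="\t", header=False, index=False)
            return buf.getvalue()
        df.to_csv(path_or_buf, sep="\t", header=False, index=False)
        return None


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the staged filter; all comparisons are strict.

    ``best_hit_order`` chooses how "best hit" is resolved: ``"bitscore"``
    (higher wins; default) or ``"evalue"`` (lower wins).  Ties fall through to
    the other statistic, then the lexicographically smallest subject id.
    """

    evalue_max: float = 1e-10
    seed_overlap_min: float = 0.50
    reciprocal_overlap_min: float = 0.70
    dataset_min_count: int = 500
    best_hit_order: str = "bitscore"

    def __post_init__(self) -> None:
        if self.evalue_max <= 0:
            raise ValueError("evalue_max must be positive")
        for name in ("seed_overlap_min", "reciprocal_overlap_min"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1]")
        if self.dataset_min_count <= 0:
            raise ValueError("dataset_min_count must be positive")
        if self.best_hit_order not in {"bitscore", "evalue"}:
            raise ValueError("best_hit_order must be 'bitscore' or 'evalue'")


@dataclass
class OrthologDataset:
    """One marker's curated sequence set with provenance.

    ``members`` maps sequence id -> category tag (free-form strings such as
    ``reference:SAR11``, ``mitochondrial``, ``environmental``, ``outgroup``);
    ``provenance`` records which filter admitted (or removed) each member.
    """

    marker_name: str
    members: dict[str, str] = field(default_factory=dict)
    sequences: dict[str, str] = field(default_factory=dict)
    alignment: dict[str, str] | None = None
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = set(self.sequences) - set(self.members)
        if missing:
            raise ValueError(f"sequences without a member category: {sorted(missing)}")

    def ids_of(self, category_prefix: str) -> frozenset[str]:
        return frozenset(
            i for i, cat in self.members.items() if cat.split(":")[0] == category_prefix
        )

    def log(self, message: str) -> None:
        self.provenance.append(message)

    def restrict(self, keep: Iterable[str], reason: str) -> "OrthologDataset":
        keep_set = set(keep)
        unknown = keep_set - set(self.members)
        if unknown:
            raise KeyError(f"ids not in dataset: {sorted(unknown)}")
        out = OrthologDataset(
            marker_name=self.marker_name,
            members={i: c for i, c in self.members.items() if i in keep_set},
            sequences={i: s for i, s in self.sequences.items() if i in keep_set},
            alignment=(
                None
                if self.alignment is None
                else {i: s for i, s in self.alignment.items() if i in keep_set}
            ),
            provenance=list(self.provenance),
        )
        out.log(f"{reason}: kept {len(keep_set)}/{len(self.members)} members")
        return out


# ---------------------------------------------------------------------------
# filtering stages
# ---------------------------------------------------------------------------

def _hit_sort_key(cfg: FilterConfig):
    if cfg.best_hit_order == "bitscore":
        return lambda r: (-r.bitscore, r.evalue, r.subject_id)
    return lambda r: (r.evalue, -r.bitscore, r.subject_id)


def _qualifies(rec: HitRecord, cfg: FilterConfig, overlap_min: float) -> bool:
    return rec.evalue < cfg.evalue_max and rec.hsp_overlap_fraction > overlap_min


def assign_seed_orthologs(
    seed_hits: HitTable, cfg: FilterConfig = FilterConfig()
) -> dict[str, str | None]:
    """Assign each seed protein to the ortholog group of its best qualifying
    hit (E-value < ``evalue_max``, overlap > ``seed_overlap_min``).

    A seed with no qualifying hit maps to ``None`` (unassigned, not an error).
    """
    out: dict[str, str | None] = {}
    key = _hit_sort_key(cfg)
    for seed, hits in seed_hits.by_query().items():
        qualifying = [
            h for h in hits
            if _qualifies(h, cfg, cfg.seed_overlap_min) and h.subject_og is not None
        ]
        out[seed] = min(qualifying, key=key).subject_og if qualifying else None
    return out


def dedup_per_species(
    members: Sequence[HitRecord], cfg: FilterConfig = FilterConfig()
) -> list[HitRecord]:
    """Keep at most one member per species: the best-scoring hit against the
    seed.  Members without a species tag are kept as-is (after dropping exact
    duplicate subject ids)."""
    key = _hit_sort_key(cfg)
    best: dict[str, HitRecord] = {}
    untagged: dict[str, HitRecord] = {}
    order: list[str] = []
    for rec in members:
        if rec.subject_species is None:
            untagged.setdefault(rec.subject_id, rec)
            continue
        sp = rec.subject_species
        if sp not in best:
            order.append(sp)
            best[sp] = rec
        elif key(rec) < key(best[sp]):
            best[sp] = rec
    return [best[sp] for sp in order] + list(untagged.values())


def retrieve_env_candidates(
    env_hits: HitTable, cfg: FilterConfig = FilterConfig()
) -> frozenset[str]:
    """Ids of environmental sequences with at least one qualifying hit against
    the seed protein (the seed is the query; environmental ids are subjects)."""
    return frozenset(
        h.subject_id for h in env_hits if _qualifies(h, cfg, cfg.seed_overlap_min)
    )


def reciprocal_og_filter(
    candidate_cog_hits: HitTable,
    expected_og: str,
    cfg: FilterConfig = FilterConfig(),
) -> frozenset[str]:
    """Reciprocal confirmation: a candidate (query) is retained iff its top
    qualifying hit against the reference ortholog-group database belongs to
    ``expected_og`` (E-value < ``evalue_max``, overlap > ``reciprocal_overlap_min``)."""
    key = _hit_sort_key(cfg)
    retained: set[str] = set()
    for cand, hits in candidate_cog_hits.by_query().items():
        qualifying = [h for h in hits if _qualifies(h, cfg, cfg.reciprocal_overlap_min)]
        if qualifying and min(qualifying, key=key).subject_og == expected_og:
            retained.add(cand)
    return frozenset(retained)


def dataset_gate(candidate_count: int, cfg: FilterConfig = FilterConfig()) -> bool:
    """True iff strictly more than ``dataset_min_count`` environmental
    candidates were retrieved in the first search."""
    return candidate_count > cfg.dataset_min_count


def curate_environmental_set(
    env_hits: HitTable,
    reciprocal_hits: HitTable,
    expected_og: str,
    cfg: FilterConfig = FilterConfig(),
) -> tuple[frozenset[str], bool]:
    """Run the two-step environmental filter for one marker.

    Returns the retained id set and the dataset-size gate verdict (which is
    evaluated on the *first*-search candidate count, per the screening
    protocol).
    """
    candidates = retrieve_env_candidates(env_hits, cfg)
    confirmed = reciprocal_og_filter(reciprocal_hits, expected_og, cfg)
    return candidates & confirmed, dataset_gate(len(candidates), cfg)


# ---------------------------------------------------------------------------
# alignment column mask
# ---------------------------------------------------------------------------

def mask_columns(
    aln: Mapping[str, str], max_gap_fraction: float = 0.5
) -> tuple[dict[str, str], list[int]]:
    """Remove alignment columns whose gap fraction exceeds ``max_gap_fraction``.

    A deliberately transparent stand-in for block-based alignment cleaning:
    the returned kept-column index list (0-based, ascending) maps masked
    coordinates back to the input, so any external masker can be substituted.
    """
    if not aln:
        raise ValueError("empty alignment")
    lengths = {len(s) for s in aln.values()}
    if len(lengths) != 1:
        raise ValueError("alignment must be rectangular")
    (ncol,) = lengths
    nrow = len(aln)
    seqs = list(aln.values())
    kept: list[int] = []
    for j in range(ncol):
        gaps = sum(1 for s in seqs if s[j] in "-.")
        if gaps / nrow <= max_gap_fraction:
            kept.append(j)
    if not kept:
        raise ValueError("all columns removed by the gap mask")
    masked = {name: "".join(s[j] for j in kept) for name, s in aln.items()}
    return masked, kept
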