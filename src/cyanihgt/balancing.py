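"""Taxonomic balancing of homology hits.

Reference databases over-represent some lineages by orders of magnitude, so
tree building on the raw top hits would drown genuine donors in whatever
phylum happens to be sequenced most densely.  The mitigation implemented
here caps, for each query, the number of distinct genera admitted per phylum
at ``budget / n_unique_phyla`` (floor, clamped to at least 1), walking hits
in descending bitscore order.  All hits of an admitted genus remain
eligible; one best-bitscore sequence per subject species is then kept for
alignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .records import HitRecord, Volume

logger = logging.getLogger(__name__)

_UNCLASSIFIED = "unclassified"


@dataclass(slots=True)
class BalancedHitSet:
    """Outcome of balancing one query's merged hit list."""

    query_id: str
    selected: list[HitRecord]
    per_phylum_cap: int
    phyla_seen: set[str] = field(default_factory=set)


def _sort_key(hit: HitRecord):
    # descending bitscore; ties: ascending e-value, then subject id
    return (-hit.bitscore, hit.evalue, hit.subject_id)


def merge_volumes(
    per_volume_hits: dict[Volume, list[HitRecord]] | dict[str, list[HitRecord]],
    cap_per_volume: int = 2000,
) -> list[HitRecord]:
    """Truncate each database volume to its top *cap_per_volume* hits by
    bitscore, then merge into a single list sorted by descending bitscore.

    Duplicate subjects across volumes are collapsed, keeping the highest
    bitscore (ties resolved toward the lower e-value).
    """
    pooled: list[HitRecord] = []
    for _, hits in sorted(
        per_volume_hits.items(),
        key=lambda kv: kv[0].value if isinstance(kv[0], Volume) else str(kv[0]),
    ):
        pooled.extend(sorted(hits, key=_sort_key)[:cap_per_volume])
    pooled.sort(key=_sort_key)
    merged: list[HitRecord] = []
    seen: set[str] = set()
    for hit in pooled:
        if hit.subject_id in seen:
            continue
        seen.add(hit.subject_id)
        merged.append(hit)
    return merged


def phylum_genus_cap(n_unique_phyla: int, budget: int = 180) -> int:
    """Per-phylum genus cap: ``floor(budget / n_unique_phyla)``, at least 1."""
    if n_unique_phyla < 1:
        raise ValueError("n_unique_phyla must be >= 1")
    return max(1, budget // n_unique_phyla)


def _phylum_of(hit: HitRecord) -> str:
    return hit.subject_taxon.phylum or _UNCLASSIFIED


def balance_hits(hits: list[HitRecord], budget: int = 180) -> BalancedHitSet:
    """Select a taxonomically broad hit subset for one query.

    *hits* must already be merged and sorted by descending bitscore.  Phyla
    are counted from the full input list; a hit is admitted when its phylum
    has admitted fewer than the cap's worth of genera, or when its
    (phylum, genus) pair is already admitted.  Hits with an empty phylum go
    to a sentinel ``unclassified`` phylum.
    """
    if any(
        _sort_key(a) > _sort_key(b) for a, b in zip(hits, hits[1:])
    ):
        hits = sorted(hits, key=_sort_key)
    phyla = {_phylum_of(h) for h in hits}
    query_id = hits[0].query_id if hits else ""
    if not phyla:
        return BalancedHitSet(query_id, [], budget)
    cap = phylum_genus_cap(len(phyla), budget)
    admitted_genera: dict[str, set[str]] = {}
    selected: list[HitRecord] = []
    n_unclassified = 0
    for hit in hits:
        phylum = _phylum_of(hit)
        if phylum == _UNCLASSIFIED and hit.subject_taxon.phylum == "":
            n_unclassified += 1
        genera = admitted_genera.setdefault(phylum, set())
        genus = hit.subject_taxon.genus or hit.subject_id
        if genus in genera or len(genera) < cap:
            genera.add(genus)
            selected.append(hit)
    if n_unclassified:
        logger.warning(
            "query %s: %d hits lacked a phylum; pooled as %r",
            query_id, n_unclassified, _UNCLASSIFIED,
        )
    return BalancedHitSet(query_id, selected, cap, phyla)


def best_per_species(hits: list[HitRecord]) -> list[HitRecord]:
    """One representative sequence per subject species, keeping the
    best-bitscore hit; order follows the input (bitscore-descending)."""
    out: list[HitRecord] = []
    seen: set[str] = set()
    for hit in sorted(hits, key=_sort_key):
        species = hit.subject_taxon.species or hit.subject_id
        if species in seen:
            continue
        seen.add(species)
        out.append(hit)
    return out
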