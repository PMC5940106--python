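"""Best-hit culling, identity tiers, and per-locus sequence assembly.

Raw homology hit tables may hold several alignments per (promoter, species)
pair.  This module reduces them to a single best hit per pair, applies the
percent-identity tiers used to grade conservation (70/90/95/99%), strips
alignment gaps, and attaches CpG/GC statistics, yielding the per-locus
species tables the phylogenetic regression consumes.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from . import seq_stats
from .io_formats import HomologyHit

logger = logging.getLogger(__name__)

IDENTITY_TIERS = (70.0, 90.0, 95.0, 99.0)


@dataclass(frozen=True)
class LocusEntry:
    """One species' surviving match for one promoter, gap-stripped."""

    species: str
    sequence: str      # ungapped subject sequence
    match_len: int     # ungapped length
    pct_identity: float
    cpg_count: int
    cpg_density: float
    gc_content: float


@dataclass
class LocusTable:
    """Per-promoter map of species to their best conserved match."""

    promoter_id: str
    gene: str = ""
    entries: dict[str, LocusEntry] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def species(self) -> list[str]:
        return list(self.entries)

    def densities(self) -> dict[str, float]:
        return {sp: e.cpg_density for sp, e in self.entries.items()}


def _hit_rank(hit: HomologyHit) -> tuple:
    """Sort key: best hit first.  Max bitscore, then min evalue, then max
    alignment length, then smallest subject accession and start — a fully
    deterministic chain so shuffled input yields identical survivors."""
    return (-hit.bitscore, hit.evalue, -hit.aln_len, hit.subject_acc, hit.s_start)


def best_hit_per_species(
    hits: Iterable[HomologyHit],
) -> dict[tuple[str, str], HomologyHit]:
    """Keep exactly one hit per (promoter, species) pair.

    Selection is by maximum bitscore; ties break by minimum evalue, then
    maximum alignment length, then lexicographically smallest subject
    accession and subject start.
    """
    best: dict[tuple[str, str], HomologyHit] = {}
    for hit in hits:
        key = (hit.query_id, hit.species)
        if key not in best or _hit_rank(hit) < _hit_rank(best[key]):
            best[key] = hit
    return best


def filter_identity(
    hits: Iterable[HomologyHit], threshold: float
) -> list[HomologyHit]:
    """Survivors have pct_identity >= threshold (threshold in (0, 100])."""
    if not 0.0 < threshold <= 100.0:
        raise ValueError(f"identity threshold {threshold} outside (0, 100]")
    return [h for h in hits if h.pct_identity >= threshold]


def tier_counts(hits: Iterable[HomologyHit]) -> dict[float, int]:
    """Cumulative hit counts at the 70/90/95/99% identity tiers.

    A 99% hit counts in all four tiers, so counts are monotone nonincreasing
    with the threshold.
    """
    hits = list(hits)
    return {t: sum(1 for h in hits if h.pct_identity >= t) for t in IDENTITY_TIERS}


def assemble_locus(
    promoter_id: str,
    hits: Iterable[HomologyHit],
    gene: str = "",
    exclude_species: Iterable[str] = (),
) -> LocusTable:
    """Build a LocusTable from culled hits for one promoter.

    Input hits must already be best-per-species and identity-filtered.  The
    stored sequence is the subject (species-side) sequence with gap
    characters removed; CpG density and GC content are computed on it.
    Species on the exclusion list (manual outlier removal, e.g. a single
    aberrant taxon) are dropped before assembly.
    """
    excluded = set(exclude_species)
    locus = LocusTable(promoter_id=promoter_id, gene=gene)
    for hit in hits:
        if hit.query_id != promoter_id:
            raise ValueError(
                f"hit for {hit.query_id!r} passed to locus {promoter_id!r}"
            )
        if hit.species in excluded:
            continue
        if hit.species in locus.entries:
            raise ValueError(
                f"locus {promoter_id}: two hits for species {hit.species} "
                "(run best_hit_per_species first)"
            )
        seq = "".join(c for c in hit.s_seq if c not in seq_stats.GAP_CHARS)
        if not seq:
            logger.warning(
                "locus %s: dropping %s (all-gap subject sequence)",
                promoter_id, hit.species,
            )
            continue
        locus.entries[hit.species] = LocusEntry(
            species=hit.species,
            sequence=seq,
            match_len=len(seq),
            pct_identity=hit.pct_identity,
            cpg_count=seq_stats.cpg_count(seq),
            cpg_density=seq_stats.cpg_density(seq),
            gc_content=seq_stats.gc_content(seq),
        )
    return locus


def loci_from_hits(
    hits: Iterable[HomologyHit],
    identity_threshold: float = 70.0,
    genes: Mapping[str, str] | None = None,
    exclude_species: Iterable[str] = (),
) -> dict[str, LocusTable]:
    """Full filtering chain: best hit per species → identity filter → loci."""
    best = best_hit_per_species(hits)
    kept = filter_identity(best.values(), identity_threshold)
    by_promoter: dict[str, list[HomologyHit]] = defaultdict(list)
    for h in kept:
        by_promoter[h.query_id].append(h)
    genes = genes or {}
    return {
        pid: assemble_locus(pid, rows, gene=genes.get(pid, ""),
                            exclude_species=exclude_species)
        for pid, rows in sorted(by_promoter.items())
    }


def match_length_summary(
    loci: Mapping[str, LocusTable] | Iterable[LocusTable],
    species_partition: Mapping[str, str],
    exclude_species: Iterable[str] = (),
) -> dict[str, float | None]:
    """Mean match length per named species group.

    ``species_partition`` assigns each species a group label (for example
    primates vs non-primate mammals).  The mean is over all (locus, species)
    entries in the group; an empty group reports ``None``.
    """
    if isinstance(loci, Mapping):
        loci = loci.values()
    excluded = set(exclude_species)
    sums: dict[str, float] = defaultdict(float)
    counts: dict[str, int] = defaultdict(int)
    for locus in loci:
        for sp, entry in locus.entries.items():
            if sp in excluded or sp not in species_partition:
                continue
            group = species_partition[sp]
            sums[group] += entry.match_len
            counts[group] += 1
    return {
        group: (sums[group] / counts[group] if counts[group] else None)
        for group in set(species_partition.values())
    }
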