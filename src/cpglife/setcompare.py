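"""Gene-level set comparisons and the direction-skew test.

Multiple promoters can annotate to the same gene, so cross-dataset overlap
is counted on deduplicated gene names.  The headline observation — that the
overwhelming majority of significant loci correlate *positively* with
lifespan — is quantified by an exact two-sided binomial test of the
positive/negative split against a fair-coin null.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import scipy.stats

from .pipeline import LocusResult


@dataclass(frozen=True)
class GeneSetComparison:
    """Shared/exclusive counts for two labelled gene sets."""

    label_a: str
    label_b: str
    size_a: int
    size_b: int
    shared: int
    a_only: int
    b_only: int


def dedup_genes(results: Iterable[LocusResult], direction: str | None = None) -> set[str]:
    """Unique gene names among results, optionally filtered to one direction.

    Gene names are compared case-sensitively; a promoter without a gene
    annotation is kept under its own promoter id so it is never silently
    dropped.
    """
    genes: set[str] = set()
    for r in results:
        if direction is not None and r.direction != direction:
            continue
        genes.add(r.gene if r.gene else r.promoter_id)
    return genes


def overlap(
    set_a: set[str], set_b: set[str],
    label_a: str = "A", label_b: str = "B",
) -> GeneSetComparison:
    """Exact intersection/difference sizes for two gene sets."""
    shared = len(set_a & set_b)
    return GeneSetComparison(
        label_a=label_a, label_b=label_b,
        size_a=len(set_a), size_b=len(set_b),
        shared=shared,
        a_only=len(set_a) - shared,
        b_only=len(set_b) - shared,
    )


def overlap_from_counts(
    size_a: int, size_b: int, shared: int,
    label_a: str = "A", label_b: str = "B",
) -> GeneSetComparison:
    """Overlap arithmetic when only the three counts are known."""
    if shared > min(size_a, size_b) or min(size_a, size_b, shared) < 0:
        raise ValueError("inconsistent overlap counts")
    return GeneSetComparison(
        label_a=label_a, label_b=label_b,
        size_a=size_a, size_b=size_b, shared=shared,
        a_only=size_a - shared, b_only=size_b - shared,
    )


def skew_test(n_pos: int, n_neg: int) -> tuple[float, float]:
    """Proportion of positive calls and its exact binomial two-sided p.

    Tests n_pos successes in n_pos+n_neg trials against probability 0.5,
    two-sided by minimum-likelihood ordering (every outcome whose point
    probability is at most the observed one contributes to p).
    """
    if n_pos < 0 or n_neg < 0:
        raise ValueError("counts must be nonnegative")
    n = n_pos + n_neg
    if n == 0:
        raise ValueError("no significant loci: skew undefined")
    prop_pos = n_pos / n
    p = scipy.stats.binomtest(n_pos, n, p=0.5, alternative="two-sided").pvalue
    return prop_pos, float(p)
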