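"""Per-locus orchestration: fit PGLS across all promoters, adjust for
multiple testing with Benjamini–Hochberg, and classify each locus as
positively correlated, negatively correlated, or not significant.

The multiplicity family is the set of loci with a successful fit within one
dataset; skipped loci (too few species, degenerate predictor) never consume
multiplicity.  Separate datasets (e.g. a primate subset vs all mammals) are
corrected independently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .homology import LocusTable
from .io_formats import Phylogeny, TraitTable
from .pgls import PGLSFit, SkippedLocus, pgls

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Analysis knobs: significance level, minimum species, λ handling."""

    alpha: float = 0.05
    min_n: int = 5
    lam: float | None = None          # None = profile λ by ML
    exclude_species: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha {self.alpha} outside (0, 1)")
        if self.min_n < 3:
            raise ValueError("min_n below 3 leaves no slope degrees of freedom")


@dataclass
class LocusResult:
    """Final per-promoter record: fit, q-value, and direction call."""

    promoter_id: str
    gene: str
    n_species: int
    cpg_density_mean: float
    slope: float
    se: float
    t: float
    p: float
    q: float
    lam: float
    direction: str          # positive | negative | ns | skipped
    skip_reason: str = ""
    pearson_r: float = float("nan")
    pearson_p: float = float("nan")


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, mapped back to input order.

    q_(i) = min_{j>=i} p_(j) * m / j over the sorted p-values, capped at 1.
    All inputs must lie in (0, 1].
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0.0) or np.any(p > 1.0):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def classify(q: float, slope: float, alpha: float = 0.05) -> str:
    """Direction call: significant loci split by slope sign.

    An exactly-zero slope with q < α is called ``ns`` (no direction to
    report).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha {alpha} outside (0, 1)")
    if q < alpha and slope > 0:
        return "positive"
    if q < alpha and slope < 0:
        return "negative"
    return "ns"


@dataclass
class RunReport:
    """Audit counts for one dataset run."""

    n_loci: int = 0
    n_fitted: int = 0
    n_skipped: int = 0
    skip_reasons: dict[str, int] = field(default_factory=dict)
    n_positive: int = 0
    n_negative: int = 0
    n_ns: int = 0
    mean_species_per_locus: float = float("nan")
    mean_species_significant: float = float("nan")
    alpha: float = 0.05

    def as_dict(self) -> dict:
        return {
            "n_loci": self.n_loci,
            "n_fitted": self.n_fitted,
            "n_skipped": self.n_skipped,
            "skip_reasons": dict(sorted(self.skip_reasons.items())),
            "n_positive": self.n_positive,
            "n_negative": self.n_negative,
            "n_ns": self.n_ns,
            "mean_species_per_locus": self.mean_species_per_locus,
            "mean_species_significant": self.mean_species_significant,
            "alpha": self.alpha,
        }


def run_all(
    loci: Mapping[str, LocusTable],
    traits: TraitTable,
    phylo: Phylogeny,
    config: PipelineConfig | None = None,
) -> tuple[list[LocusResult], RunReport]:
    """Fit every locus, BH-correct across fitted loci, classify directions.

    Deterministic given inputs and config.  Species are joined by their
    normalized names across loci, traits, and tree; species missing from
    either the trait table or the tree simply drop out of that locus.
    Raises if no locus is fit-eligible.
    """
    config = config or PipelineConfig()
    excluded = set(config.exclude_species)
    results: list[LocusResult] = []
    fits: list[tuple[int, PGLSFit]] = []
    report = RunReport(alpha=config.alpha)

    for promoter_id in sorted(loci):
        locus = loci[promoter_id]
        report.n_loci += 1
        pairs = {
            sp: (entry.cpg_density, traits.lifespan_yrs[sp])
            for sp, entry in locus.entries.items()
            if sp in traits.lifespan_yrs and sp not in excluded
        }
        densities = [locus.entries[sp].cpg_density for sp in pairs]
        mean_density = float(np.mean(densities)) if densities else float("nan")
        fit = pgls(pairs, phylo, min_n=config.min_n, lam=config.lam)
        if isinstance(fit, SkippedLocus):
            report.n_skipped += 1
            report.skip_reasons[fit.reason] = report.skip_reasons.get(fit.reason, 0) + 1
            results.append(
                LocusResult(
                    promoter_id=promoter_id, gene=locus.gene, n_species=fit.n,
                    cpg_density_mean=mean_density,
                    slope=float("nan"), se=float("nan"), t=float("nan"),
                    p=float("nan"), q=float("nan"), lam=float("nan"),
                    direction="skipped", skip_reason=fit.reason,
                )
            )
            continue
        report.n_fitted += 1
        idx = len(results)
        fits.append((idx, fit))
        results.append(
            LocusResult(
                promoter_id=promoter_id, gene=locus.gene, n_species=fit.n,
                cpg_density_mean=mean_density,
                slope=fit.slope, se=fit.se_slope, t=fit.t, p=fit.p,
                q=float("nan"), lam=fit.lam, direction="ns",
                pearson_r=fit.pearson_r, pearson_p=fit.pearson_p,
            )
        )

    if not fits:
        raise ValueError("no locus passed the fitting requirements")

    qvals = bh_adjust([fit.p for _, fit in fits])
    for (idx, fit), q in zip(fits, qvals):
        results[idx].q = float(q)
        results[idx].direction = classify(float(q), fit.slope, config.alpha)

    fitted = [r for r in results if r.direction != "skipped"]
    signif = [r for r in fitted if r.direction in ("positive", "negative")]
    report.n_positive = sum(1 for r in signif if r.direction == "positive")
    report.n_negative = sum(1 for r in signif if r.direction == "negative")
    report.n_ns = len(fitted) - len(signif)
    report.mean_species_per_locus = float(np.mean([r.n_species for r in fitted]))
    if signif:
        report.mean_species_significant = float(np.mean([r.n_species for r in signif]))
    logger.info(
        "run_all: %d loci, %d fitted, %d skipped, %d positive / %d negative at q<%g",
        report.n_loci, report.n_fitted, report.n_skipped,
        report.n_positive, report.n_negative, config.alpha,
    )
    return results, report


def results_frame(results: Iterable[LocusResult]) -> pd.DataFrame:
    """Results as the canonical TSV-schema DataFrame."""
    rows = [
        {
            "locus": r.promoter_id, "gene": r.gene, "n_species": r.n_species,
            "cpg_density_mean": r.cpg_density_mean, "slope": r.slope,
            "se": r.se, "t": r.t, "p": r.p, "q": r.q, "lambda": r.lam,
            "direction": r.direction,
        }
        for r in results
    ]
    return pd.DataFrame(rows)
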