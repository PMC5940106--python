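"""CpG and GC composition statistics.

CpG density — the count of CG dinucleotides divided by sequence length —
is the quantitative trait fed to the phylogenetic regression.  Density is
per-nucleotide (so it lies in [0, 0.5]); the raw count is also carried so
downstream consumers can renormalize.  The observed/expected CpG ratio of
island-calling literature is deliberately not computed here.
"""

from __future__ import annotations

from dataclasses import dataclass

GAP_CHARS = set("-.")


@dataclass(frozen=True)
class SeqComposition:
    """Composition summary of one ungapped sequence."""

    length: int
    cpg_count: int
    cpg_density: float  # per nt, in [0, 0.5]
    gc_content: float   # percent, over unambiguous bases


def cpg_count(seq: str) -> int:
    """Number of CG dinucleotides (a C immediately followed by a G).

    The input must be gap-free (strip alignment gaps first) and uppercase.
    Any pair involving N (or another ambiguity code) is not a CpG.
    """
    if GAP_CHARS & set(seq):
        raise ValueError("gapped sequence: strip alignment gaps before counting CpGs")
    return seq.count("CG")


def cpg_density(seq: str) -> float:
    """CG dinucleotide count divided by sequence length (per nt)."""
    if len(seq) < 2:
        raise ValueError("sequence shorter than 2 nt has no defined CpG density")
    return cpg_count(seq) / len(seq)


def gc_content(seq: str) -> float:
    """Percent G+C over unambiguous bases (N excluded from the denominator)."""
    if GAP_CHARS & set(seq):
        raise ValueError("gapped sequence: strip alignment gaps before computing GC")
    if len(seq) == 0:
        raise ValueError("empty sequence has no GC content")
    denom = len(seq) - seq.count("N")
    if denom == 0:
        raise ValueError("all-N sequence: GC content undefined")
    return 100.0 * (seq.count("G") + seq.count("C")) / denom


def compose(seq: str) -> SeqComposition:
    """Compute all composition statistics for one ungapped sequence."""
    return SeqComposition(
        length=len(seq),
        cpg_count=cpg_count(seq),
        cpg_density=cpg_density(seq),
        gc_content=gc_content(seq),
    )
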