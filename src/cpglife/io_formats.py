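"""Readers and writers for the pipeline's external formats.

Handles four input formats — a 14-column BLAST tabular dialect for homology
hits, multi-record FASTA, Newick trees with branch lengths, and an AnAge-style
species trait CSV — plus the results TSV the pipeline emits.  Species names
are reconciled across all sources by a single normalization rule (whitespace
and underscore runs collapse to one underscore) so that hit files, the trait
table, and the tree can be joined by exact string match.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: Column order of the BLAST tabular dialect consumed by :func:`read_blast_tab`.
BLAST_COLUMNS = (
    "qseqid qlen qstart qend sacc sstart send evalue bitscore "
    "length pident qcovhsp qseq sseq"
).split()

#: IUPAC nucleotide codes tolerated in FASTA input (plus gap).
IUPAC_NT = set("ACGTUNRYSWKMBDHV-")

#: Human maximum lifespan is capped at 90 years by default: the species'
#: enormous census size makes its verified record (122 y) an outlier not
#: comparable to species sampled far more sparsely.
DEFAULT_LIFESPAN_OVERRIDES: dict[str, float] = {"Homo_sapiens": 90.0}

RESULTS_COLUMNS = [
    "locus", "gene", "n_species", "cpg_density_mean",
    "slope", "se", "t", "p", "q", "lambda", "direction",
]


class MalformedRowError(ValueError):
    """A tabular input row does not match the expected dialect."""


def normalize_species(name: str) -> str:
    """Collapse whitespace/underscore runs to single underscores and trim.

    Idempotent, case-preserving; makes "Homo sapiens" and "Homo_sapiens"
    identical so sources using either convention join cleanly.
    """
    return re.sub(r"[\s_]+", "_", name.strip())


@dataclass(frozen=True)
class HomologyHit:
    """One parsed BLAST tabular row: a species' hit for one promoter query.

    Coordinates are 1-based inclusive (BLAST convention); a minus-strand hit
    keeps ``s_start > s_end``.  ``q_seq``/``s_seq`` are the aligned sequences
    and therefore may contain gap characters.
    """

    query_id: str
    query_len: int
    q_start: int
    q_end: int
    subject_acc: str
    s_start: int
    s_end: int
    evalue: float
    bitscore: float
    aln_len: int
    pct_identity: float
    q_coverage: float
    q_seq: str
    s_seq: str
    species: str

    def __post_init__(self) -> None:
        if len(self.q_seq) != self.aln_len or len(self.s_seq) != self.aln_len:
            raise ValueError(
                f"hit {self.query_id}/{self.species}: aligned sequence length "
                f"({len(self.q_seq)}/{len(self.s_seq)}) != length field ({self.aln_len})"
            )
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValueError(f"pct_identity {self.pct_identity} outside [0, 100]")
        if self.evalue < 0:
            raise ValueError(f"negative evalue {self.evalue}")


def read_blast_tab(path: str | Path, species: str) -> list[HomologyHit]:
    """Parse a 14-column BLAST tabular file, attaching ``species`` to each row.

    The dialect is ``qseqid qlen qstart qend sacc sstart send evalue bitscore
    length pident qcovhsp qseq sseq``, tab-separated with no header.  Row
    order is preserved.  A row with a different column count, or a numeric
    field that fails to parse, raises :class:`MalformedRowError` naming the
    offending line.
    """
    species = normalize_species(species)
    hits: list[HomologyHit] = []
    with open(path, newline="") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(BLAST_COLUMNS):
                raise MalformedRowError(
                    f"{path}:{lineno}: expected {len(BLAST_COLUMNS)} tab-separated "
                    f"columns, found {len(fields)}"
                )
            try:
                hit = HomologyHit(
                    query_id=fields[0],
                    query_len=int(fields[1]),
                    q_start=int(fields[2]),
                    q_end=int(fields[3]),
                    subject_acc=fields[4],
                    s_start=int(fields[5]),
                    s_end=int(fields[6]),
                    evalue=float(fields[7]),
                    bitscore=float(fields[8]),
                    aln_len=int(fields[9]),
                    pct_identity=float(fields[10]),
                    q_coverage=float(fields[11]),
                    q_seq=fields[12].upper(),
                    s_seq=fields[13].upper(),
                    species=species,
                )
            except ValueError as exc:
                raise MalformedRowError(f"{path}:{lineno}: {exc}") from exc
            hits.append(hit)
    return hits


def write_blast_tab(path: str | Path, hits: Iterable[HomologyHit]) -> None:
    """Write hits back out in the same 14-column dialect."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    [
                        h.query_id, str(h.query_len), str(h.q_start), str(h.q_end),
                        h.subject_acc, str(h.s_start), str(h.s_end),
                        format_evalue(h.evalue), fmt_float(h.bitscore),
                        str(h.aln_len), fmt_float(h.pct_identity),
                        fmt_float(h.q_coverage), h.q_seq, h.s_seq,
                    ]
                )
                + "\n"
            )


def fmt_float(x: float) -> str:
    """Render a float compactly but losslessly enough for round-trips."""
    return repr(float(x))


def format_evalue(e: float) -> str:
    return repr(float(e))


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an ordered id→sequence map.

    Ids are the first whitespace-delimited header token; sequences are
    uppercased.  Characters outside the IUPAC set draw a warning but are
    retained; a duplicate id is an error.
    """
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"{path}: duplicate FASTA id {rec.id!r}")
        seq = str(rec.seq).upper()
        bad = set(seq) - IUPAC_NT
        if bad:
            logger.warning(
                "%s: record %s contains non-IUPAC characters %s (retained)",
                path, rec.id, sorted(bad),
            )
        records[rec.id] = seq
    return records


def write_fasta(path: str | Path, records: Mapping[str, str], width: int = 70) -> None:
    """Write an id→sequence map as FASTA with lines folded at ``width``."""
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in records.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


@dataclass
class Phylogeny:
    """A rooted tree with branch lengths, tip labels normalized.

    Thin wrapper over a dendropy tree; downstream code only needs tip labels
    and root-to-MRCA path lengths, both exposed here.
    """

    tree: dendropy.Tree

    @property
    def tip_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def __len__(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


def read_newick(path: str | Path) -> Phylogeny:
    """Read a single Newick tree; every non-root edge must carry a length.

    Tip labels are normalized (see :func:`normalize_species`); a collision
    after normalization is an error because the covariance matrix would be
    ambiguous.  Zero-length branches are accepted with a warning.
    """
    tree = dendropy.Tree.get(
        path=str(path), schema="newick", preserve_underscores=True
    )
    return _check_phylogeny(tree, source=str(path))


def phylogeny_from_string(newick: str) -> Phylogeny:
    tree = dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True
    )
    return _check_phylogeny(tree, source="<string>")


def _check_phylogeny(tree: dendropy.Tree, source: str) -> Phylogeny:
    seen: set[str] = set()
    for leaf in tree.leaf_node_iter():
        label = normalize_species(leaf.taxon.label)
        if label in seen:
            raise ValueError(
                f"{source}: duplicate tip label {label!r} after normalization"
            )
        seen.add(label)
        leaf.taxon.label = label
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue  # root edge length is meaningless for tip covariance
        if node.edge.length is None:
            raise ValueError(
                f"{source}: edge above {_node_desc(node)} has no branch length; "
                "phylogenetic covariance is undefined"
            )
        if node.edge.length < 0:
            raise ValueError(f"{source}: negative branch length at {_node_desc(node)}")
        if node.edge.length == 0:
            logger.warning("%s: zero-length branch at %s", source, _node_desc(node))
    return Phylogeny(tree)


def _node_desc(node: dendropy.Node) -> str:
    if node.taxon is not None:
        return node.taxon.label
    return f"internal node with {len(node.leaf_nodes())} descendant tips"


def write_newick(path: str | Path, phylo: Phylogeny) -> None:
    with open(path, "w") as fh:
        fh.write(phylo.as_newick() + "\n")


@dataclass
class TraitTable:
    """Species → maximum lifespan (years), with per-row provenance.

    ``provenance[sp]`` is ``observed`` for values taken as-is, ``override``
    for values replaced through the override map (human capped at 90 y by
    default), or ``inferred-from-relative`` when loaded from a column that
    flags AnAge substitutions.
    """

    lifespan_yrs: dict[str, float] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.lifespan_yrs)

    def species(self) -> list[str]:
        return list(self.lifespan_yrs)


def read_trait_table(
    path: str | Path,
    overrides: Mapping[str, float] | None = None,
) -> TraitTable:
    """Load a trait CSV with columns ``species`` and ``max_longevity_yrs``.

    Overrides are applied after loading and flagged; by default the single
    entry Homo_sapiens→90.  Rows with missing or nonpositive lifespan are
    dropped with a warning.  Lifespans stay in years — the natural-log
    transform happens at analysis time, not here.
    """
    if overrides is None:
        overrides = DEFAULT_LIFESPAN_OVERRIDES
    df = pd.read_csv(path)
    required = {"species", "max_longevity_yrs"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: trait CSV missing columns {sorted(missing)}")

    table = TraitTable()
    norm_overrides = {normalize_species(k): float(v) for k, v in overrides.items()}
    for _, row in df.iterrows():
        sp = normalize_species(str(row["species"]))
        years = row["max_longevity_yrs"]
        if pd.isna(years) or float(years) <= 0:
            logger.warning("%s: dropping %s (lifespan %r not positive)", path, sp, years)
            continue
        if sp in table.lifespan_yrs:
            raise ValueError(f"{path}: duplicate species {sp!r} after normalization")
        flag = str(row["provenance"]) if "provenance" in df.columns else "observed"
        table.lifespan_yrs[sp] = float(years)
        table.provenance[sp] = flag
    for sp, years in norm_overrides.items():
        if sp in table.lifespan_yrs:
            table.lifespan_yrs[sp] = years
            table.provenance[sp] = "override"
    return table


def write_trait_table(path: str | Path, table: TraitTable) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["species", "max_longevity_yrs", "provenance"])
        for sp, yrs in table.lifespan_yrs.items():
            w.writerow([sp, repr(yrs), table.provenance.get(sp, "observed")])


def read_alias_map(path: str | Path) -> dict[str, str]:
    """Load a two-column CSV mapping source species names to canonical ones.

    This is the user-supplied hook for nomenclature reconciliation (AnAge
    entries substituted by nearest relative, renamed species, etc.); the
    pipeline never guesses substitutions itself.
    """
    df = pd.read_csv(path)
    if not {"from", "to"} <= set(df.columns):
        raise ValueError(f"{path}: alias CSV needs columns 'from' and 'to'")
    return {
        normalize_species(str(r["from"])): normalize_species(str(r["to"]))
        for _, r in df.iterrows()
    }


def write_results_tsv(path: str | Path, results: pd.DataFrame) -> None:
    """Write the per-locus results table (one row per promoter)."""
    missing = set(RESULTS_COLUMNS) - set(results.columns)
    if missing:
        raise ValueError(f"results table missing columns {sorted(missing)}")
    results.to_csv(path, sep="\t", index=False, columns=RESULTS_COLUMNS)


def read_results_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"locus": str, "gene": str, "direction": str})
    missing = set(RESULTS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: results TSV missing columns {sorted(missing)}")
    return df
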