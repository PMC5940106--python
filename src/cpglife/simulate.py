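"""Truth-tagged synthetic data with the statistical structure the analysis
assumes: an ultrametric pure-birth tree, log-lifespans evolving by Brownian
motion with a Pagel-λ signal, per-locus CpG densities that are positively,
negatively, or un-correlated with lifespan in configurable proportions, and
promoter-like sequences realizing each density with an *exact* CpG count.

Defaults emulate the study regime the pipeline targets: ~5% of loci carry a
positive density–lifespan association and ~0.3% a negative one, promoters
are 600 nt (the −499..+100 query window), mean CpG density is promoter-like
(0.06 per nt), and the root lifespan is 28 years (the mammalian mean).
Effect sizes were calibrated once by simulation to give high per-locus
power at 64 tips and are frozen here.

Optionally the generator renders 14-column homology hit files, with sub-70%
identity decoy rows and duplicate lower-scoring rows, so the filtering
stages can be exercised against known truth: the genuine hit for every
(locus, species) carries subject accession ``chr1``; decoys and duplicates
carry ``decoy*``/``dup*`` accessions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import dendropy
import numpy as np

from . import io_formats, seq_stats
from .homology import LocusEntry, LocusTable
from .io_formats import HomologyHit, Phylogeny, TraitTable
from .pgls import lambda_transform, phylo_cov

logger = logging.getLogger(__name__)

DENSITY_CLAMP = (0.005, 0.45)


@dataclass
class SimConfig:
    """All knobs of the generator; defaults define the study conditions."""

    n_tips: int = 64
    n_loci: int = 400
    prop_pos: float = 0.05
    prop_neg: float = 0.003
    beta_pos: float = 0.02      # density units per log-year
    beta_neg: float = 0.02
    sigma2_bm: float = 0.25     # BM rate of log-lifespan on a depth-1 tree
    lambda_true: float = 1.0
    locus_phylo_noise_sd: float = 0.010   # density units (BM at tree depth 1)
    locus_iid_noise_sd: float = 0.0       # density units
    seq_len: int = 600
    gc_target: float = 52.0     # percent
    density_center: float = 0.06
    root_log_lifespan: float = math.log(28.0)
    n_dup_genes: int = 0
    emit_hits: bool = False
    decoy_fraction: float = 0.1
    dup_hit_fraction: float = 0.1
    identity_range: tuple[float, float] = (80.0, 100.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.prop_pos + self.prop_neg > 1.0:
            raise ValueError("prop_pos + prop_neg exceeds 1")
        if min(self.locus_phylo_noise_sd, self.locus_iid_noise_sd) < 0:
            raise ValueError("noise standard deviations must be nonnegative")
        if self.seq_len < 50:
            raise ValueError("seq_len below 50 nt is not promoter-like")
        if not 0.0 <= self.lambda_true <= 1.0:
            raise ValueError("lambda_true outside [0, 1]")


@dataclass
class LocusTruth:
    """Ground truth for one locus."""

    locus: str
    gene: str
    cls: str                    # positive | negative | null
    beta: float                 # signed slope actually planted (0 for null)
    density: dict[str, float] = field(default_factory=dict)     # realized
    cpg_count: dict[str, int] = field(default_factory=dict)


@dataclass
class TruthTable:
    """Ground truth for a full synthetic dataset."""

    config: SimConfig
    phylo: Phylogeny
    traits: TraitTable
    log_lifespan: dict[str, float]
    loci: dict[str, LocusTruth]

    def class_counts(self) -> dict[str, int]:
        counts = {"positive": 0, "negative": 0, "null": 0}
        for lt in self.loci.values():
            counts[lt.cls] += 1
        return counts


def gen_tree(n_tips: int, seed: int | np.random.Generator) -> Phylogeny:
    """Yule (pure-birth) topology rescaled to unit root-to-tip depth.

    Lineages split at exponential waiting times with per-lineage rate 1;
    the absolute rate is irrelevant because all branch lengths are rescaled
    so the tree is ultrametric with depth exactly 1.
    """
    if n_tips < 3:
        raise ValueError("need at least 3 tips")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    taxon_namespace = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxon_namespace)
    root = tree.seed_node
    birth: dict[int, float] = {}
    t = 0.0
    children = [dendropy.Node(), dendropy.Node()]
    for ch in children:
        root.add_child(ch)
        birth[id(ch)] = 0.0
    active = list(children)

    while len(active) < n_tips:
        t += rng.exponential(1.0 / len(active))
        k = int(rng.integers(len(active)))
        node = active.pop(k)
        node.edge.length = t - birth[id(node)]
        for _ in range(2):
            ch = dendropy.Node()
            node.add_child(ch)
            birth[id(ch)] = t
            active.append(ch)

    T = t + rng.exponential(1.0 / n_tips)
    width = max(4, len(str(n_tips)))
    for i, node in enumerate(active):
        node.edge.length = T - birth[id(node)]
        node.taxon = taxon_namespace.new_taxon(label=f"sp{i:0{width}d}")

    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length /= T
    return Phylogeny(tree)


def sim_bm(
    phylo: Phylogeny,
    root_value: float,
    sigma2: float,
    lam: float = 1.0,
    rng: int | np.random.Generator = 0,
) -> dict[str, float]:
    """Simulate a trait on the tree: BM for λ=1, scaled-covariance MVN else.

    Tip values are a multivariate normal draw with mean ``root_value`` and
    covariance σ²·V(λ) where V is the λ-transformed phylogenetic covariance.
    For λ=1 the draw is generated branchwise (Gaussian increments with
    variance σ²·branch length), which is exactly equivalent.
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be nonnegative")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    tips = sorted(phylo.tip_labels)
    if sigma2 == 0.0:
        return {sp: root_value for sp in tips}

    if lam == 1.0:
        values: dict[int, float] = {id(phylo.tree.seed_node): root_value}
        out: dict[str, float] = {}
        for node in phylo.tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            edge = node.edge.length or 0.0
            values[id(node)] = values[id(node.parent_node)] + rng.normal(
                0.0, math.sqrt(sigma2 * edge)
            )
            if node.is_leaf():
                out[node.taxon.label] = values[id(node)]
        return {sp: out[sp] for sp in tips}

    C = phylo_cov(phylo, tips).C
    V = sigma2 * lambda_transform(C, lam)
    L = np.linalg.cholesky(V + 1e-12 * np.mean(np.diag(V)) * np.eye(len(tips)))
    draw = root_value + L @ rng.standard_normal(len(tips))
    return {sp: float(v) for sp, v in zip(tips, draw)}


def gen_locus_density(
    trait: Mapping[str, float],
    cls: str,
    beta: float,
    phylo: Phylogeny,
    phylo_noise_sd: float = 0.010,
    iid_noise_sd: float = 0.0,
    rng: int | np.random.Generator = 0,
    center: float = 0.06,
) -> dict[str, float]:
    """Per-species CpG density tracking (or ignoring) the trait.

    density_i = α₀ + s·β·trait_i + phylo_noise_i + iid_noise_i with s = +1,
    −1 or 0 for class positive/negative/null; α₀ centres the mean density at
    ``center``.  Densities are clamped to a promoter-plausible range; a
    clamp touching more than 20% of species draws a warning because the
    planted effect is then attenuated.
    """
    if cls not in ("positive", "negative", "null"):
        raise ValueError(f"unknown locus class {cls!r}")
    if beta <= 0:
        raise ValueError("beta must be positive (sign comes from the class)")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    s = {"positive": 1.0, "negative": -1.0, "null": 0.0}[cls]
    species = sorted(trait)
    tvals = np.array([trait[sp] for sp in species])

    if phylo_noise_sd > 0:
        pn_map = sim_bm(phylo, 0.0, phylo_noise_sd**2, 1.0, rng)
        pn = np.array([pn_map[sp] for sp in species])
    else:
        pn = np.zeros(len(species))
    iid = rng.normal(0.0, iid_noise_sd, len(species)) if iid_noise_sd > 0 else np.zeros(len(species))

    alpha0 = center - s * beta * float(np.mean(tvals))
    dens = alpha0 + s * beta * tvals + pn + iid
    clamped = (dens < DENSITY_CLAMP[0]) | (dens > DENSITY_CLAMP[1])
    if clamped.mean() > 0.2:
        logger.warning(
            "density clamp hit %.0f%% of species; planted effect attenuated",
            100 * clamped.mean(),
        )
    dens = np.clip(dens, *DENSITY_CLAMP)
    return {sp: float(d) for sp, d in zip(species, dens)}


def density_to_sequence(
    density: float,
    seq_len: int,
    gc_target: float = 52.0,
    rng: int | np.random.Generator = 0,
) -> str:
    """Render a sequence whose CpG count is exactly round(density·seq_len).

    Construction: place that many disjoint CG dinucleotides at seeded random
    positions; fill the remaining positions with single bases chosen to hit
    ``gc_target`` percent G+C, never writing a G immediately after a C; then
    a repair scan guarantees no unplanned CpG survives.  G+C lands within
    ±2 percentage points of target whenever the planned CGs alone do not
    already exceed it.
    """
    if not 0.0 <= density < 0.5:
        raise ValueError("density outside [0, 0.5)")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n_cg = int(round(density * seq_len))
    if n_cg > seq_len // 2:
        raise ValueError(f"{n_cg} CpGs cannot fit in {seq_len} nt")

    seq = [""] * seq_len
    planned_starts: set[int] = set()
    if n_cg > 0:
        # choose n_cg disjoint pairs uniformly via the gap construction
        slots = rng.choice(seq_len - n_cg, size=n_cg, replace=False)
        slots.sort()
        for k, s0 in enumerate(slots):
            start = int(s0) + k
            planned_starts.add(start)
            seq[start] = "C"
            seq[start + 1] = "G"

    background = [i for i in range(seq_len) if seq[i] == ""]
    want_gc_total = gc_target / 100.0 * seq_len
    b_gc = int(round(want_gc_total - 2 * n_cg))
    b_gc = min(max(b_gc, 0), len(background))
    gc_positions = set(
        int(i) for i in rng.choice(len(background), size=b_gc, replace=False)
    ) if b_gc else set()

    for idx, pos in enumerate(background):
        if idx in gc_positions:
            base = "G" if rng.random() < 0.5 else "C"
            if base == "G" and pos > 0 and seq[pos - 1] == "C":
                base = "C"  # avoid forming an unplanned CpG; GC% unchanged
        else:
            base = "A" if rng.random() < 0.5 else "T"
        seq[pos] = base

    # repair scan: destroy any unplanned CpG (should not occur by construction)
    for i in range(seq_len - 1):
        if seq[i] == "C" and seq[i + 1] == "G" and i not in planned_starts:
            seq[i + 1] = "A"

    out = "".join(seq)
    realized = seq_stats.cpg_count(out)
    if realized != n_cg:
        raise AssertionError(
            f"sequence construction bug: {realized} CpGs realized, {n_cg} requested"
        )
    return out


def simulate_dataset(config: SimConfig) -> TruthTable:
    """Generate tree, lifespans, and per-locus densities in memory.

    Sequence rendering and file output are left to :func:`emit_dataset`;
    the truth table here already carries the *realized* (integer-count /
    seq_len) densities so downstream fits see exactly what the sequences
    would encode.
    """
    ss = np.random.SeedSequence(config.seed)
    s_tree, s_trait, s_classes, s_loci = ss.spawn(4)
    phylo = gen_tree(config.n_tips, np.random.default_rng(s_tree))
    log_lifespan = sim_bm(
        phylo, config.root_log_lifespan, config.sigma2_bm,
        config.lambda_true, np.random.default_rng(s_trait),
    )
    traits = TraitTable()
    for sp in sorted(log_lifespan):
        traits.lifespan_yrs[sp] = math.exp(log_lifespan[sp])
        traits.provenance[sp] = "observed"

    n_pos = int(round(config.prop_pos * config.n_loci))
    n_neg = int(round(config.prop_neg * config.n_loci))
    classes = ["positive"] * n_pos + ["negative"] * n_neg
    classes += ["null"] * (config.n_loci - len(classes))
    rng_cls = np.random.default_rng(s_classes)
    classes = [classes[i] for i in rng_cls.permutation(config.n_loci)]

    width = max(5, len(str(config.n_loci)))
    genes = [f"GENE{i:0{width}d}" for i in range(config.n_loci)]
    if config.n_dup_genes > 0:
        if config.n_dup_genes >= config.n_loci:
            raise ValueError("cannot duplicate more gene names than loci")
        dup_idx = rng_cls.choice(
            np.arange(1, config.n_loci), size=config.n_dup_genes, replace=False
        )
        for i in sorted(int(j) for j in dup_idx):
            genes[i] = genes[i - 1]

    loci: dict[str, LocusTruth] = {}
    locus_rngs = [np.random.default_rng(s) for s in s_loci.spawn(config.n_loci)]
    for i in range(config.n_loci):
        cls = classes[i]
        beta = {"positive": config.beta_pos, "negative": config.beta_neg, "null": 0.0}[cls]
        dens = gen_locus_density(
            log_lifespan, cls, beta if cls != "null" else 1.0, phylo,
            config.locus_phylo_noise_sd, config.locus_iid_noise_sd,
            locus_rngs[i], config.density_center,
        )
        locus_id = f"P{i:0{width}d}"
        truth = LocusTruth(
            locus=locus_id, gene=genes[i], cls=cls,
            beta={"positive": beta, "negative": -beta, "null": 0.0}[cls],
        )
        for sp, d in dens.items():
            count = int(round(d * config.seq_len))
            truth.cpg_count[sp] = count
            truth.density[sp] = count / config.seq_len
        loci[locus_id] = truth

    return TruthTable(
        config=config, phylo=phylo, traits=traits,
        log_lifespan=log_lifespan, loci=loci,
    )


def truth_to_locus_tables(truth: TruthTable) -> dict[str, LocusTable]:
    """LocusTables straight from truth densities (no sequence rendering)."""
    L = truth.config.seq_len
    tables: dict[str, LocusTable] = {}
    for locus_id, lt in truth.loci.items():
        table = LocusTable(promoter_id=locus_id, gene=lt.gene)
        for sp in lt.density:
            table.entries[sp] = LocusEntry(
                species=sp, sequence="", match_len=L,
                pct_identity=100.0,
                cpg_count=lt.cpg_count[sp],
                cpg_density=lt.density[sp],
                gc_content=float("nan"),
            )
        tables[locus_id] = table
    return tables


def emit_dataset(config: SimConfig, outdir: str | Path) -> TruthTable:
    """Write a complete dataset to ``outdir`` and return its truth table.

    Produces ``tree.nwk``, ``traits.csv``, ``truth.tsv``, one FASTA per
    locus under ``loci/``, and — when ``config.emit_hits`` — one 14-column
    hit table per species under ``hits/`` (genuine hit: subject accession
    ``chr1``; plus sub-70%-identity decoy rows and lower-scoring duplicate
    rows).  Byte-identical across runs with the same config.
    """
    outdir = Path(outdir)
    (outdir / "loci").mkdir(parents=True, exist_ok=True)
    truth = simulate_dataset(config)
    io_formats.write_newick(outdir / "tree.nwk", truth.phylo)
    io_formats.write_trait_table(outdir / "traits.csv", truth.traits)

    ss = np.random.SeedSequence(config.seed + 1_000_003)
    seq_rngs = np.random.SeedSequence(config.seed + 2_000_003).spawn(len(truth.loci))
    hit_rng = np.random.default_rng(ss)

    sequences: dict[str, dict[str, str]] = {}
    for (locus_id, lt), sseq in zip(truth.loci.items(), seq_rngs):
        rng = np.random.default_rng(sseq)
        recs = {
            sp: density_to_sequence(lt.density[sp], config.seq_len,
                                    config.gc_target, rng)
            for sp in sorted(lt.density)
        }
        sequences[locus_id] = recs
        io_formats.write_fasta(outdir / "loci" / f"{locus_id}.fa", recs)

    with open(outdir / "truth.tsv", "w") as fh:
        fh.write("locus\tgene\tclass\tbeta\tspecies\tdensity\tcpg_count\n")
        for locus_id, lt in truth.loci.items():
            for sp in sorted(lt.density):
                fh.write(
                    f"{locus_id}\t{lt.gene}\t{lt.cls}\t{lt.beta!r}\t{sp}\t"
                    f"{lt.density[sp]!r}\t{lt.cpg_count[sp]}\n"
                )

    if config.emit_hits:
        (outdir / "hits").mkdir(exist_ok=True)
        lo, hi = config.identity_range
        species_list = sorted(truth.traits.lifespan_yrs)
        for sp in species_list:
            rows: list[HomologyHit] = []
            for locus_id, lt in truth.loci.items():
                if sp not in lt.density:
                    continue
                seq = sequences[locus_id][sp]
                L = len(seq)
                sstart = int(hit_rng.integers(1, 10_000_000))
                base = dict(
                    query_id=locus_id, query_len=L, q_start=1, q_end=L,
                    s_start=sstart, s_end=sstart + L - 1,
                    evalue=1e-180, aln_len=L, q_coverage=100.0,
                    q_seq=seq, s_seq=seq, species=sp,
                )
                true_pid = float(hit_rng.uniform(lo, hi))
                rows.append(HomologyHit(
                    subject_acc="chr1", bitscore=2.0 * L,
                    pct_identity=round(true_pid, 2), **base,
                ))
                if hit_rng.random() < config.dup_hit_fraction:
                    rows.append(HomologyHit(
                        subject_acc=f"dup_{locus_id}", bitscore=1.5 * L,
                        pct_identity=round(float(hit_rng.uniform(70.0, max(70.05, true_pid))), 2),
                        **base,
                    ))
                if hit_rng.random() < config.decoy_fraction:
                    rows.append(HomologyHit(
                        subject_acc=f"decoy_{locus_id}", bitscore=1.0 * L,
                        pct_identity=round(float(hit_rng.uniform(40.0, 69.9)), 2),
                        **base,
                    ))
            io_formats.write_blast_tab(outdir / "hits" / f"{sp}.tsv", rows)

    return truth
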