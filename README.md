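# cpglife

Phylogenetic regression of promoter CpG density on species maximum lifespan.

## The problem

CpG dinucleotides are the substrate of DNA methylation, and methylation
patterns degrade with age. If high promoter CpG density buffers a gene
against age-related epigenetic drift, species that evolved longer lifespans
should carry denser CpG promoters at the genes whose regulation matters for
longevity. Testing this across species requires correcting for shared
ancestry: closely related species resemble each other in both lifespan and
genome composition simply because of common descent.

`cpglife` implements the full per-locus comparative analysis for this
question, aimed at molecular evolution researchers working from promoter
homology searches and a dated phylogeny:

1. **Homology filtering** — parse 14-column tabular homology hit files
   (`qseqid qlen qstart qend sacc sstart send evalue bitscore length pident
   qcovhsp qseq sseq`), keep a single best hit per promoter per species,
   apply percent-identity tiers (70/90/95/99%), and assemble per-locus
   multi-species sequence sets.
2. **Sequence statistics** — CpG count, per-nucleotide CpG density
   (count/length ∈ [0, 0.5]), and GC content.
3. **PGLS** — for each locus, regress log maximum lifespan on CpG density
   under phylogenetic generalized least squares with Pagel's λ estimated by
   maximum likelihood.
4. **Multiple testing and classification** — Benjamini–Hochberg q-values
   across all fitted loci; each locus called positive, negative, or not
   significant at q < 0.05.
5. **Set comparisons** — gene-level deduplication, overlap between datasets
   (e.g. a primate subset vs all mammals), and an exact binomial test of the
   positive:negative direction skew.
6. **Synthetic data** — a truth-tagged generator (Yule tree, Brownian-motion
   lifespans, planted per-locus effects, sequences realizing every CpG
   density exactly) so the entire pipeline is testable without any genome
   downloads.

## The model

For one locus with *n* species, let *y* = ln(maximum lifespan in years) and
*x* = promoter CpG density. The PGLS model is

    y = α + βx + ε,      ε ~ N(0, σ² V(λ)),

where V(λ) is the phylogenetic covariance: V_ii is the root-to-tip path
length of species *i*, V_ij the root-to-MRCA path length of *i* and *j*,
and λ ∈ [0, 1] multiplies the off-diagonal entries (λ = 0: phylogenetic
independence, i.e. OLS on an ultrametric tree; λ = 1: pure Brownian
motion). λ̂ maximizes the profile log-likelihood

    ℓ(λ) = −½ [ n log(2πσ̂²(λ)) + log|V(λ)| + n ],   σ̂²(λ) = e'V(λ)⁻¹e / n,

over a 21-point grid refined by bounded Brent search. The slope test is a
two-sided t-test with n − 2 degrees of freedom using the df-corrected
residual scale. Humans are capped at 90 years by default (the verified
record of 122 reflects an enormous census size, not a typical lifespan).

## Worked example

Simulate a 32-species, 200-promoter dataset with planted effects, then run
the analysis:

```sh
cpglife simulate --n-tips 32 --n-loci 200 --seed 1 --out demo
# wrote 200 loci for 32 species to demo (planted: 10 positive, 1 negative, 189 null)

cpglife run --loci-dir demo/loci --traits demo/traits.csv \
            --tree demo/tree.nwk --label primates-demo --out demo_results
# primates-demo: 200 fitted loci, 10 positive / 2 negative at q<0.05
```

All ten planted positive loci are recovered at q < 0.05 with positive
slopes; the one planted negative locus is recovered along with one null
false positive — consistent with BH control of the false discovery rate at
5%. `demo_results/results.tsv` has one row per promoter:

```
locus   gene  n_species  cpg_density_mean  slope   se     t      p      q      lambda  direction
P00000        32         0.0556            -3.71   7.72   -0.48  0.635  0.969  1.0     ns
P00001        32         0.0575            3.54    7.74   0.46   0.650  0.969  1.0     ns
```

Slopes are in log-years per unit CpG density; `lambda` is λ̂ for that locus
(here 1.0: the residual lifespan variation is strongly phylogenetic, as
simulated). `demo_results/report.json` records the audit trail: locus
counts through each filter stage, direction counts, mean species per locus,
and a config hash. `cpglife compare A/results.tsv B/results.tsv --out
cmp.json` then reports per-direction unique-gene counts, overlap, and the
exact binomial skew test.

Hit-table inputs work the same way via `--hits-dir` (one
`<species>.tsv` per genome) instead of `--loci-dir`, with best-hit culling
and the identity threshold applied first; `cpglife filter-hits` exposes
that stage alone, and `cpglife density` computes per-record CpG/GC tables
from any FASTA.

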