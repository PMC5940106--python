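# Methods

## Statistical model

Each promoter locus is analysed independently. For the *n* species with a
surviving homology match at the locus, a lifespan entry, and a tip in the
phylogeny, the model is

    ln(lifespan_i) = α + β · density_i + ε_i,
    ε ~ N(0, σ² V(λ)),

with V(λ) the tip covariance of the dated tree (V_ii = root-to-tip path
length, V_ij = root-to-MRCA path length) whose off-diagonal entries are
multiplied by Pagel's λ. The natural-log transform of lifespan is applied
at analysis time; trait tables stay in years. λ is profiled by maximum
likelihood over [0, 1]; σ² is the ML (divide-by-*n*) estimate inside the
profile, while the slope standard error uses the df-corrected (*n* − 2)
scale so the slope t-test keeps its classical degrees of freedom. This
pairing was validated by the all-null calibration simulations in the test
suite: the raw-p rejection rate at 0.05 sits inside the exact binomial 99%
band and the far tail (p < 1.25·10⁻⁴) is, if anything, slightly
conservative.

Assumptions worth stating explicitly:

- The tree is taken as known, with nonnegative branch lengths in arbitrary
  but consistent time units. λ rescales only the covariance structure, so
  any global rescaling of branch lengths cancels out of slope and p.
- Residual lifespan variation follows a multivariate normal with Pagel-λ
  structure. No other transforms (κ, δ, Ornstein–Uhlenbeck) are offered.
- CpG density is treated as measured without error — it is a deterministic
  function of the matched sequence.
- Loci are treated as independent tests for the purpose of FDR control.

A plain Pearson correlation between density and log lifespan is also
reported per locus purely as a diagnostic of how much the phylogenetic
correction mattered; the PGLS slope test is the p-value of record.

## Pipeline semantics

- **Best hit per (promoter, species):** maximum bitscore, ties broken by
  minimum e-value, then maximum alignment length, then smallest subject
  accession and start coordinate. The chain is total, so survivors are
  invariant to input row order.
- **Identity tiers:** survivor iff percent identity ≥ threshold (default
  70); the 70/90/95/99 tier counts are cumulative.
- **Density side:** CpG statistics are computed on the gap-stripped
  *subject* (species-side) sequence — the species' own promoter
  composition is the evolving trait. Density is per-nucleotide
  (count/length, hence in [0, 0.5]); the PGLS slope sign and p-value are
  invariant to any fixed positive rescaling of the predictor, so this
  convention is harmless, and the raw count is carried alongside.
  Observed/expected CpG ratios are deliberately not computed.
- **Ambiguity codes:** N never participates in a CpG; N is excluded from
  the GC denominator.
- **Species reconciliation:** names are normalized by collapsing
  whitespace/underscore runs to a single underscore; joins across hit
  files, trait table, and tree are exact after normalization. Nomenclature
  fixes or nearest-relative substitutions are supplied explicitly through
  an alias CSV, never guessed. A user-supplied exclusion list removes
  outlier species before summaries and fitting; there is no automatic
  outlier detection.
- **Lifespan overrides:** the default override map caps Homo_sapiens at
  90 years (the species' census size makes the 122-year record
  incomparable to sparsely sampled species); overrides are flagged in the
  table's provenance column.
- **Multiplicity:** Benjamini–Hochberg is applied over the loci that were
  actually fitted within one dataset; skipped loci (fewer than `min_n`
  complete cases, constant predictor, singular covariance) never consume
  multiplicity, and each dataset (e.g. a primate subset vs all mammals) is
  corrected separately. Significance is q < α with α = 0.05; significant
  loci split into positive/negative by slope sign, with an exactly-zero
  slope conservatively called not significant.
- **Direction skew:** exact two-sided binomial test (minimum-likelihood
  ordering) of the positive/negative split against 0.5, computed on
  promoter counts; gene-level deduplication applies to the cross-dataset
  overlap accounting, where promoters lacking a gene name are kept under
  their promoter id.

## Tunable parameters

| Parameter | Default | Units | Rationale |
|---|---|---|---|
| identity threshold | 70 | % | conservation floor for a usable match |
| α | 0.05 | — | FDR level for direction calls |
| `min_n` | 5 | species | below this a slope test is hopeless; exposed because real loci can match as few as 3 species |
| λ mode | ML | — | `fixed:<v>` available; `fixed:0` reproduces OLS |
| lifespan overrides | human → 90 | years | see above |

## Synthetic-data generator

The generator emulates the statistical regime the analysis assumes, with
every latent quantity recorded in a truth table:

- **Tree:** Yule (pure-birth) topology, branch lengths rescaled to unit
  root-to-tip depth (ultrametric). Species are `sp0000`-style labels.
- **Lifespans:** ln-lifespan evolves by Brownian motion from a root of
  ln(28) years — a mammal-like centre — with rate σ² = 0.25 per unit
  depth, giving roughly e^±1 spread around 28 years; a `lambda_true` knob
  generates λ-structured rather than pure-BM traits.
- **Locus densities:** density_i = α₀ + s·β·ln(lifespan_i) + noise_i with
  s ∈ {+1, −1, 0} by planted class; defaults plant 5% positive and 0.3%
  negative loci at β = 0.02 density units per log-year, centred at a
  promoter-like mean density of 0.06, clamped to [0.005, 0.45]. The locus
  noise is purely phylogenetic (BM with sd 0.010 at unit depth; iid sd
  defaults to 0): density is a deterministic function of sequence, so
  residual cross-species variation is evolutionary rather than
  measurement error. This choice also makes the per-locus null t-test
  exactly calibrated conditional on the shared lifespan draw — with an
  added iid component the whitened predictor is no longer exchangeable
  and the per-dataset rejection fraction varies widely between lifespan
  realizations. β was calibrated once by simulation (and then frozen) to
  give near-certain per-locus sign recovery at 64 tips.
- **Sequences:** the planted density is realized *exactly*: round(d·L)
  disjoint CG dinucleotides are placed uniformly at random (via the gap
  construction), remaining positions are filled toward the GC target with
  a rule that never writes G immediately after C, and a final repair scan
  guarantees no unplanned CpG. Realized CpG count equals the requested
  count in 100% of cases; GC lands within ±2 points of target whenever the
  planned CGs alone do not exceed it. Truth densities are stored as
  count/L, so sequence-route and truth-route analyses agree exactly.
- **Hit tables (optional):** per-species 14-column files in which the
  genuine hit carries subject accession `chr1` with identity drawn from a
  configurable range (default 80–100%), plus sub-70%-identity decoy rows
  and lower-bitscore duplicate rows to exercise the filtering stages.

What the generator does **not** emulate: promoter grammar (TATA boxes, CpG
island structure), indel evolution, deamination dynamics, alignment error,
missing data patterns (every species matches every locus unless filtered),
and AnAge-style trait noise. Passing tests therefore demonstrate the
statistical machinery is correct and calibrated under the stated model;
they do not certify behaviour under alignment artefacts or model
misspecification in real data.

## Numerical choices

- GLS is solved by whitening with the Cholesky factor of V — no explicit
  inverse; agreement with the closed-form estimator is held to 1e-8
  relative (measured ≈ 1e-13).
- The λ profile uses a 21-point grid then bounded Brent refinement in the
  best grid cell's neighbourhood (xatol 1e-8). Profiles flatter than 1e-6
  (e.g. star trees, where λ has no effect) report λ̂ = 1 flagged `flat`;
  optima within 1e-6 of a bound are flagged `at0`/`at1`.
- If the Cholesky diagonal implies a condition number above 1e12, or the
  factorization fails, one diagonal jitter of 1e-10·mean(diag) is applied;
  a still-singular matrix marks the locus unfit rather than raising.
- A perfect fit (zero residual variance) is flagged degenerate: the slope
  is exact, SE is 0, and the likelihood is reported infinite rather than
  fabricating a finite σ̂².
- Simulation problem sizes used by the tests and the acceptance script —
  64 tips × 400 loci for calibration, 100 loci for recovery checks, 20
  seeds for the global-null FDR check — were chosen as the smallest sizes
  at which the binomial/SE bands being asserted are meaningfully narrow.

## Known limitations

- λ is bounded to [0, 1]; values above 1 (over-dispersed phylogenetic
  signal) are not explored.
- Only a single predictor is supported; body-mass or developmental-time
  covariates are out of scope.
- The BH family is per run; meta-analysis across runs is the caller's
  responsibility.
- Minus-strand hits are consumed as query-oriented aligned sequences
  (s_start > s_end retained as metadata); no reverse-complementing is
  performed, so hit files must come from an aligner that reports
  query-oriented subject sequence, as tabular homology output does.
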