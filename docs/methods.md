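# Methods

This note documents the models, conventions, and numerical choices behind
`pprd`, and what the synthetic-data generator does and does not emulate.

## Coordinate and strand conventions

All coordinates are 0-based, half-open; BED input is consumed natively and
FASTA's 1-based convention is converted at the boundary. Strand is defined
relative to the plus strand of the target (consensus or genome contig). The
5′ coordinate of an **antisense** placement is the *highest* plus-strand
position covered by the read — the biological 5′ end of a minus-strand
read. This puts both strands on one axis, so the ping-pong geometry becomes
a simple arithmetic relation: a sense read with 5′ end at *p* and an
antisense read with 5′ end at *p* + 9 have an exact 10-nt 5′–5′ overlap.

## Read placement

Reads are placed by an in-package seed-and-verify Hamming search: a query
with ≤k mismatches must match one of k+1 disjoint seeds exactly
(pigeonhole), so candidate diagonals are collected from a seed table and
verified with an early-exit mismatch count. Only the best stratum (fewest
mismatches; ties kept) is returned, and `n_locations` counts all
best-stratum placements across the database. Identical read sequences are
collapsed with a `copies` count before placement. The default mismatch
ceiling is 0 for small RNA against consensus and genome databases; the
ceiling is a parameter (0–3) for robustness studies. The tie policy for
family tallies is fractional: a read hitting k distinct families
contributes `copies / k` to each. The ping-pong statistic deliberately
does **not** split weight across families (each family's pair search is
self-contained); this divergence is intentional and documented on the
function.

## Small-RNA statistics

- piRNA length window: [23, 29] nt inclusive by default; both bounds are
  parameters. The 18–22 nt reads are treated as one background class.
- `pirna_share` is the fraction of reads ≥23 nt in the 18–30 nt library.
- Antisense fraction is antisense weight / total weight; a family with no
  reads yields a missing value, never 0.
- Differential-abundance categories use an inclusive ≥2-fold rule on RPM;
  zero RPM values are replaced by a floor of `0.5 / library_size × 10⁶`
  for ratio formation only, so reported tables keep raw values while fold
  changes stay finite.
- The reporting filter for ping-pong tables (>50 reads and fraction >0.1
  in at least one library, strict inequalities) and the 10-nt offset are
  parameters with these defaults.
- An optional filter removes reads that map uniquely inside annotated
  cluster intervals before family tallies (cluster membership by 5′
  coordinate, half-open).

## Derepression calling

Raw weighted counts per family/gene are tested hybrid-vs-parent with a
conditional binomial test: given the row total t = x_h + x_p, x_h ~
Binomial(t, N_h/(N_h+N_p)) under the null of equal concentration, N being
effective library sizes. This test is exact under Poisson sampling; a
single-dispersion negative-binomial alternative (moments-estimated common
dispersion) is available behind a flag for overdispersed data. P-values
are BH-corrected per comparison. Fold changes use a 0.5 pseudocount on raw
counts and are threshold-inclusive (log2FC ≥ 1); a strict-greater flag is
provided. The significance-gated call requires both the fold rule and
q < α against **both** parents; the fold-only variant is always emitted
alongside (the gate can only remove calls).

Effective library sizes are median-of-ratios factors (the per-row
geometric-mean reference), rescaled to the mean column total. Total-count
normalization is composition-biased when a block of features shifts in one
direction — exactly the situation the caller is meant to detect (many TE
families derepressed in the hybrid) — and the median ratio is the standard
robust estimator for that situation.

## Cluster activity

Tallies per cluster × library under three schemes: `unique` (only
single-location reads, full copies), `weighted` (copies ×
in-cluster-placements / n_locations), `all` (full copies for any read
with ≥1 in-cluster placement); by construction unique ≤ weighted ≤ all.
Frequencies denominate over total piRNA-class (≥23 nt) reads in the
library. The hybrid expectation is the interspecific average
(fA + fB)/2; relative expression fH/expectation is classed overexpressed
at ≥2 and underexpressed at ≤0.5 (both inclusive). When one parent
contributes nothing measurable, the expectation is half the measurable
parent's level; a zero input is flagged rather than silently classified.
Cluster annotations live on the parent-A genome only, mirroring the
asymmetric assembly quality of real references; all libraries are tallied
against that annotation.

## Comparative statistics

The G-test is the plain likelihood ratio 2·Σ O·ln(O/E) with df 1 and no
Williams or continuity correction (the correction would change the
worked-example value). Pearson χ², Wilcoxon rank-sum (exact when the
smaller sample has n ≤ 8 without ties, normal approximation with tie
correction otherwise), pooled-variance t (df = nx + ny − 2), and Pearson r
delegate to scipy. Partial correlations come from the normalized inverse
of the correlation matrix; tests verify them against a
residual-regression oracle to 1e-10. The permutation test shuffles row
order independently in every column except a fixed reference column —
this preserves marginals and destroys all dependence — and flags an
observed partial correlation when it exceeds the 95th percentile of its
permuted distribution; results are reproducible under a seed. The
category-contrast helper reports per-category derepression proportions, an
R×2 χ², and pairwise two-proportion score z tests (df reported as
n₁ + n₂ − 2 for continuity with the conventional presentation).

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes, not
sequencing realism:

- **TE library**: random consensus sequences (log-uniform per-family
  abundance weights, range 2⁰–2⁵) with class/tissue/dependency-group
  metadata cycling through germline-presence states (both genomes /
  parent-A only / neither).
- **Genomes**: copies planted with independent per-site substitutions at
  the divergence rate (default 0.02/site/genome); every shared copy is
  guaranteed ≥1 diagnostic substitution when divergence > 0. Clusters are
  TE-dense intervals of concatenated antisense fragments, annotated on
  parent A only.
- **Small RNA**: piRNA-class reads are drawn on the consensus axis with a
  truncated-normal length profile (mean 26, sd 1.5, clipped to [23, 29]).
  A binomially drawn share of each family's reads is emitted as exact
  10-nt-overlap pairs (so the planted pairing probability π equals the
  expected participating fraction); the remaining reads are placed so they
  do **not** accidentally complete a 10-nt overlap with an existing
  opposite-strand 5′ end. Without this exclusion the estimator would be
  biased upward by chance pairings at realistic read densities and π would
  not be identifiable from the emitted reads; the cost is that the
  simulated background lacks the small spurious-overlap rate present in
  real libraries. Background reads (18–22 nt, default 40% of the library)
  are random sequence and therefore unmappable — real backgrounds contain
  genome-derived miRNAs/siRNAs. Cluster-derived reads are genomic
  substrings of parent-A cluster intervals; they also map to the consensus
  (antisense) and so dilute per-family ping-pong fractions, which is why
  recovery studies set `cluster_fraction=0`.
- **Mutant-like hybrid regime**: piRNA share dropped from 0.6 to 0.2 of
  reads, ping-pong probabilities scaled by 0.3, optional cluster-weight
  multipliers — the qualitative phenotype of effector-protein loss.
- **mRNA counts**: negative binomial with common dispersion (default
  0.01, a realistic value for high-count features in pooled, near-isogenic
  ovary libraries; 0 gives the Poisson limit). Hybrid mean = parental
  average × 2^planted-log2FC. The table includes a block of null
  protein-coding-gene-like rows so the TE-vs-gene contrast can be formed.
- **Genomic reads** for origin studies are sampled from insertion copies
  of both genomes and carry their copy's substitutions, so reads covering
  a diagnostic site are genome-unique at zero mismatches.

Consensus-axis piRNA reads are emitted with clean consensus sequence; this
guarantees zero-mismatch consensus mapping recovers them, but means the
small-RNA reads do not carry copy-specific divergence (origin-partition
studies use the genomic sampler instead). Every stage is fully determined
by `SimConfig.seed` through fixed per-purpose substreams.

What passing tests therefore show: the statistics recover planted
parameters under the generator's idealisations (error-free reads, clean
consensus piRNAs, no adapter/quality artefacts, no PCR duplicates). They
do not show robustness to sequencing error, annotation error, or
reference bias in real libraries.

## Problem sizes

The test suite and acceptance script run at desk scale chosen to make the
statistical checks sharp while staying quick: 10,000-read libraries for
ping-pong recovery (binomial σ ≈ 0.004–0.005), 20 simulation seeds × 270
features for caller recovery/FDR, 200 replicates × 199 permutations for
the permutation-calibration study, 1,000 genomic reads for the origin
partition, and genomes of a few hundred kilobases. These sizes are stated
here as the package's chosen study conditions.

## Known limitations

- The exact differential-expression method behind the original q-values is
  not specifiable from the published description; the conditional binomial
  (with an NB option) is this package's own choice, so q-values are not
  expected to match any particular external tool row-for-row.
- The two-proportion z test stands in for whatever regression-based z the
  original analysis used for category contrasts.
- No SAM/BAM emission; hit tables are TSV.
- The mapper is designed for desk-scale oracle-testable studies, not for
  production alignment throughput.
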