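# Methods

## The model

`mtvarload` implements a case-control association analysis for mitochondrial
DNA built around the *variant load* statistic: for individual $i$,

$$ L_i \;=\; \sum_{v \in V_i} s_v \cdot \mathbf{1}\{s_v > \tau\} \cdot
      \mathbf{1}\{f_v \ge h\} $$

where $V_i$ is the set of the individual's non-synonymous single-nucleotide
substitutions against the mitochondrial reference, $s_v \in [0,1]$ is a
pathogenicity score (a MutPred-style probability that the amino-acid change is
deleterious), $\tau$ is the score threshold (default 0.5, strictly exceeded;
0.7 for the high-confidence tier) and $f_v$ is the alternate-allele fraction
with homoplasmy cutoff $h$ (default 0.95). The load aggregates mildly
deleterious variation per person, so case-control differences can be tested
on a per-individual quantitative scale rather than only via haplogroup
frequencies.

The scores themselves are *inputs*: the package attaches them from a table
keyed by (position, alt) and never computes a pathogenicity prediction. The
packaged fixture carries thirteen common haplogroup-associated variants with
scores above 0.5 and population frequencies above 1%.

## Consequence annotation

Variants are classified against a 16,569-bp mitochondrial genome and a
37-gene map with the vertebrate mitochondrial genetic code (translation
table 2: TGA=Trp, ATA=Met, AGA/AGG=Stop). Design points:

* Coordinates are 1-based inclusive everywhere ("m.4216T>C" style); BED
  export converts to 0-based half-open on output only.
* Overlapping genes (ATP8/ATP6, ND4L/ND4, ATP6/CO3) produce one consequence
  call per gene, but scoring counts a substitution once — scores are keyed by
  position and alternate base, not by gene.
* The light-strand gene (MT-ND6) is reverse-complemented before translation.
* Genes ending in incomplete stop codons (completed by polyadenylation in
  vivo: ND1, ND2, CO3, ND3, ND4, CYB) have their trailing one or two bases
  reported as `untranslatable` rather than guessed.
* Codons containing N are `untranslatable`. Indels and multi-nucleotide
  alleles are rejected: the analysis is defined over single-nucleotide
  substitutions.

The packaged reference genome is a synthetic stand-in, as its docstring and
filename state: it has the true length, the real gene architecture, and real
reference codons planted at every fixture variant site (so, e.g., m.4216T>C
is ND1 Tyr304His), with pseudo-random sequence elsewhere. Everything the
package computes depends only on those properties, not on the remaining
bases.

## Haplogroup assignment

A deliberately simplified matcher: each of 15 top-level labels (C, D, G, H,
HV, I, J, K, N, R, T, U, V, W, X) has a flat set of defining (position, alt)
markers; a sample gets the label with the highest matched fraction, ties
broken by larger matched count (so K, whose marker set extends U's, wins when
fully matched) and then lexicographically. Samples matching nothing are
`unclassified`. This is not equivalent to phylogeny-walking tools
(Mitomaster/HaploGrep): no sub-haplogroup resolution, back-mutations and
private variants are ignored. It is sufficient to separate the 15 top-level
labels on data generated by the packaged simulator, which is all the
cohort-scale tables require.

## Rarity classes and unique variants

Population frequency bands: rare < 0.1%, common > 1%, otherwise
intermediate; absent frequency is `unknown`. The rare/common contingency
analysis uses only variants present in exactly one of the studied cohorts
("unique" variants, assessed against all cohorts, restricted to homoplasmic
non-synonymous variants — the uniqueness filter is applied after the
homoplasmy filter); intermediate-band variants are excluded from those
tables entirely but always count toward the load, whose definition has no
frequency filter. In the combination classification (none / single /
common-only / common+rare / rare-only) intermediate rarity is grouped with
common, and unknown-rarity qualifying variants are flagged while the class
is computed from the known ones.

## Statistical battery

* **Fisher's exact test (2x2)** — two-sided by the point-probability rule:
  sum hypergeometric probabilities of all margin-fixed tables no more
  probable than the observed one. This matches the convention of the major
  commercial packages; the mid-p variant is deliberately not offered. Zero
  margins return p = 1 with a degenerate flag. Computation is exact in log
  space (log-gamma factorials).
* **Fisher–Freeman–Halton (r x c)** — the same rule generalized. The number
  of margin-fixed tables is counted by bounded recursion; at or below
  `max_enumeration` (default 200,000) the test is fully enumerated, with a
  1e-9 log-space tolerance on the "no more probable" comparison to avoid
  floating-point tie misclassification. Larger tables (e.g. 15x2 haplogroup
  tables) use Monte Carlo: random pairing of row and column category labels
  (equivalent to sequential conditional hypergeometric filling), add-one
  estimator $\hat p = (1 + \#\{P \le P_{obs}\})/(1 + B)$ so $\hat p > 0$,
  with binomial standard error, replicate count and seed recorded in the
  result. Rows or columns with zero totals are dropped before testing.
* **Adjusted standardized residuals** — per cell,
  $r_{ij} = (O_{ij} - E_{ij}) / \sqrt{E_{ij}(1 - R_i/N)(1 - C_j/N)}$,
  approximately standard normal under independence; two-sided normal
  p-values and per-cell effect size $\phi_{ij} = r_{ij}/\sqrt{N}$. Cells in
  zero-total rows/columns are undefined (NaN). For 2x2 tables $|r_{ij}|$
  equals $\sqrt{\chi^2}$ (uncorrected), which the tests verify.
* **One-way ANOVA** — computed from group summaries
  (SSB $= \sum n_i(m_i - \bar m)^2$, SSW $= \sum (n_i-1)s_i^2$); the raw-data
  route summarizes and delegates, so raw and summary forms agree exactly.
  All-zero within-group variance with equal means is flagged degenerate.
* **Dunnett two-tailed many-to-one** — $t_i = (m_i - m_0) /
  \sqrt{MSE(1/n_i + 1/n_0)}$ with MSE pooled over all groups (df $= N-k$).
  The family-wise adjusted p is $P(\max_j |T_j| \ge |t_i|)$ under the
  equicorrelated multivariate t induced by the shared control
  ($\rho_{ij} = \sqrt{\lambda_i\lambda_j}$, $\lambda_i = n_i/(n_i+n_0)$),
  estimated by Monte Carlo over the joint null using the shared-control
  construction — treatment-mean normals, one control normal, one pooled
  chi-square scale — which handles unbalanced designs (100/100/100 vs 115)
  naturally. Add-one estimator, ≥ 10^5 replicates, seed recorded. The test
  suite cross-checks against an independent quadrature oracle (balanced
  design) and scipy's implementation.
* **Bonferroni** — min(1, p·m), with m at least the number of p-values; used
  for the haplogroup cell post-hoc family (m = number of haplogroup rows).

## Synthetic cohorts

The generator emulates the study conditions the analysis assumes: four
cohorts of 100/100/100/115 individuals; haplogroups drawn from the control
cohort's observed proportions over the 15 labels; each sample
deterministically inherits its haplogroup's markers and associated
high-scoring common variants; a Poisson(λ = 0.5) number of rare private
non-synonymous variants at uniformly drawn protein-coding positions outside
the fixture sites, with scores from Beta(2,2) rescaled to [0.3, 0.9] and
frequencies drawn below 0.1%; an optional case effect that with probability
π per sample adds one extra qualifying (score > 0.5) variant, so the mean
load shift is π·E[score]. All draws derive from one seed through per-sample
substreams keyed by (cohort index, sample index).

Numerical/design choices: within a sample, position collisions are re-drawn;
across samples a recurrent rare (position, alt) keeps the score and
frequency of its first occurrence, so the cohort-wide score table is
single-valued (a strict everywhere-unique rule would exhaust the ~7,500
candidate positions in large simulated cohorts). Effect-injected variants
always get a fresh key so their score is exactly the configured one.

What the generator does *not* emulate — and what passing tests therefore do
not show about real data: phylogenetic structure below the top-level
haplogroup, mutation-rate heterogeneity along the genome, heteroplasmy
drift, back-mutation, population stratification, and any realistic linkage
between markers and rare variation. Calibration results (type-I ≈ 5% for
the carrier Fisher test and load ANOVA; Dunnett power under an injected
0.22 mean-load shift) are statements about this generative model at the
study's sample sizes, not about any real cohort.

## Problem sizes and tolerances in the test suite

Exact-test reproductions of the published tables run by full enumeration in
under a second each; the 15x2 tables use 10^5 Monte Carlo replicates and are
compared within 3 standard errors. Type-I calibration uses 1000 simulated
two-cohort pairs; power uses 60 four-cohort replicates with the Dunnett
comparison at 10^5 replicates per call — sizes chosen to keep the suite
responsive while leaving binomial 3-SE bands tight enough to detect
miscalibration. The summary-based ANOVA on the published cohort summaries
gives F ≈ 2.27, p ≈ 0.08; this deliberately differs from a raw-data p
computed on unpublished per-sample loads, because the published summaries
are rounded to two decimals.

## Known limitations

* The haplogroup matcher is top-level only and fixture-dependent.
* "Operationally homoplasmic" has no universal definition; the 0.95 allele-
  fraction default is a common choice for short-read mtDNA data and is
  configurable. Heteroplasmic variants are excluded from loads but still
  reported by the proven-pathogenic screen at any fraction.
* The r x c Monte Carlo p is an estimate; its seed and standard error are
  part of the result, and decisions near a significance boundary should use
  more replicates.
* Scores and frequencies are taken at face value from their tables; no
  uncertainty in the pathogenicity predictor is propagated.
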