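# Methods

## Study design being modelled

A haploid wild population (~113 strains) is genotyped at bi-allelic SNPs on
seven linkage groups and expression-profiled by RNA-seq (RPKM). One focal
gene's expression is a proxy for a resistance trait. The pipeline asks two
questions: which SNPs co-inherit with high focal-gene expression (forward
GWAS), and which genes' expression tracks a focal SNP (reverse eQTL scan).

## Curation

Sites are kept when exactly two alleles are observed among non-missing
calls and the minor allele's frequency, computed over non-missing calls, is
**strictly greater** than the threshold (default 0.10). The boundary case
(MAF exactly at the threshold) is removed: "present at more than 10 %" is
read literally. A zero threshold is allowed as a vacuous filter. Missing
calls (`.`) never count as alleles and drop a strain from a locus's
contingency table only, not from the analysis.

## Phenotype binning

The binary proxy splits strains on the arithmetic mean of the focal gene's
RPKM over all strains in the expression table. Strictly above the mean is
"high"; ties go "low" because equality is not *higher* than average. With
real-valued RPKMs ties are vanishingly rare; an all-constant vector is a
degenerate error since no split exists. A descriptive four-group binning at
cut points (default 25/50/75 RPKM) uses left-closed/right-open interior
intervals, so a value exactly on a cut joins the interval above it.

## Fisher exact test

The two-sided P is the sum of hypergeometric point masses (margins fixed)
over all tables as or less probable than the observed one, ties included.
The implementation evaluates, per margin triple (row total, grand total,
column total), the whole support at once and caches it; the permutation
scan then reduces each shuffle to a table lookup keyed by the top-left
cell. Tie detection uses a 1e-10 relative tolerance on the floating-point
masses: for totals ≤ 30 the smallest relative gap between *distinct*
point masses is ~6e-9, so the tolerance admits exact ties and nothing
else. The test suite verifies the kernel against an exact-rational
enumeration oracle exhaustively for every table with total ≤ 30.

Sidedness: two-sided, the symmetric default, since either allele may
confer resistance; direction is carried separately by the `high_allele`
field (the allele whose proportion among "high" strains exceeds its
proportion among "low" strains; equal proportions report no direction).

## Permutation min-P significance

For each of B label shuffles (uniform over arrangements preserving the
high/low counts; distinctness across permutations is not enforced — with
B = 1000 and C(113, 46) arrangements, collisions are negligible) every
locus is retested and the minimum nominal P retained. Two outputs:

* **Literal cutoff rule.** Records with nominal P strictly larger than
  the smallest permuted minimum are removed; equality survives. The
  observed labelling is one of B+1 exchangeable labellings under a
  complete null, so the probability that any locus survives is at most
  ~1/(B+1). Discreteness of the Fisher support can only add ties at the
  cutoff, which the rule resolves in favour of retention; the calibration
  check therefore tests the survivor rate against the 1/(B+1) band rather
  than asserting exact equality. This single-minimum rule is more
  stringent than quantile-based FWER control, so conventional
  Westfall–Young adjusted P-values are reported alongside.
* **Westfall–Young adjusted P.** (1 + #{permuted minima ≤ p})/(B+1),
  monotone in p by construction, computed by binary search on the sorted
  minima and verified against a direct recount.

One integer seed drives the whole stream; shuffles are drawn sequentially,
so extending B keeps the earlier draws (cutoffs are monotone
non-increasing in B on the same seed).

## Reverse scan and correlation

The reverse scan splits each gene's expression by the focal SNP's two
genotype classes and applies the two-sided Mann–Whitney test: exact by
enumeration when the pooled sample is ≤ 12 and tie-free, otherwise the
normal approximation with tie and continuity corrections. U is reported as
min(U1, U2). The direction (`higher_expression_allele`) comes from group
medians; equal medians report no direction. Family-wise significance
reuses the min-P scheme with genotype labels shuffled and the minimum
taken over genes — chosen for internal consistency with the forward scan.

Gene–gene co-expression uses Spearman rank correlation (robust to RPKM
skew; invariant to monotone normalisation); a constant vector is a
degenerate error.

## Enrichment

Category over-representation is the one-sided upper-tail hypergeometric
test: P(X ≥ k) with N the universe size (default: all genes in the
expression table), K the category size within the universe, n the query
size. Genes without annotation stay in the universe and affect only N.
Annotation entries outside the universe are ignored so K cannot be
inflated. Benjamini–Hochberg values are attached for convenience. This
module is a generic stand-in for catalogue-based tools; it ships no
annotation database.

## qPCR quantification

Triplicates are accepted when every replicate lies within ±0.5 cycles of
the triplicate **median** (the rule's centre is not standardised; the
median is the robust choice) and summarised by the arithmetic mean.
Quantification assumes amplification efficiency 2 (the Livak model):
ΔCt = Ct(target) − Ct(reference) per sample, fold change = 2^−ΔΔCt against
a calibrator sample, or 2^−ΔCt when no calibrator exists. Exact algebraic
identities follow and are tested: self-fold = 1, reciprocal product = 1,
and 2^−ΔΔCt(s, c) = 2^−ΔCt(s)/2^−ΔCt(c).

## Synthetic populations

Defaults are the emulated study conditions: 113 strains, seven linkage
groups with realistic chromosome lengths, per-locus MAF uniform on
(0.05, 0.5) — deliberately straddling the 0.10 filter so curation is
exercised — and haploid carriage Bernoulli(MAF) per strain. Expression is
Normal on the log2 scale (RPKM = 2^log2), baseline 2^5 = 32 RPKM (a
moderately expressed gene), residual σ = 1 log2 unit. Planted effects are
additive on log2 expression: trans effects on the focal gene (default
β = 3σ), cis effects on a gene's own locus (default 2σ). The partner gene
adds a scaled copy of the focal gene's realised signal calibrated to a
target Pearson correlation on the log2 scale (default 0.8; Spearman is
marginally lower, as expected for bivariate normal data).
`causal_maf` optionally pins planted loci to a fixed MAF (0.4 in the
recovery studies) so power is evaluated at a known allele balance rather
than a random draw — at uniformly drawn MAFs a 2σ cis effect at MAF 0.05
(≈ 6 carriers) is not reliably the top record, which is a property of the
design, not of the implementation.

Deliberate simplifications: loci are unlinked (no LD), strains are
exchangeable (no population structure), and expression noise is
independent log-normal. None of the implemented statistics exploits LD or
structure, and independence makes the permutation error-rate arithmetic
exact — but it also means passing tests say nothing about confounding by
relatedness or about clumping of associated markers in real data.

## Verification problem sizes

The shipped checks use: an exhaustive Fisher sweep over all 2×2 tables
with total ≤ 30 (~46 000 tables) against exact rational enumeration;
family-wise calibration on 300 null populations of 113 strains × 200
post-filter loci at B = 100; and 100-replicate recovery studies for the
planted trans (β = 3σ, MAF 0.4, ~200 loci) and cis (2σ, MAF 0.4, 100
genes) effects. These sizes give 3-standard-error Monte-Carlo resolution
on the calibration band while keeping the whole suite under a minute.

## Numerical and interface choices

* P-values are serialised in scientific notation using the shortest
  representation that round-trips the exact double (at least three
  significant digits), so written tables read back bit-identically.
* Positions are 1-based; linkage groups accept roman numerals I–VII on
  input and are stored as integers 1–7.
* VCF input is read-only and restricted to haploid single-allele GT
  records; diploid genotypes raise a ploidy error rather than being
  collapsed.
* Locus allele pairs are ordered (major, minor) by observed count, ties
  broken alphabetically; pre-curation loci may carry one or three
  observed alleles and are simply removed by the bi-allelic filter.
* `run` aborts on the first failing stage, names it, and leaves a
  `MANIFEST.partial` listing outputs already written. Logs contain no
  timestamps so reruns are byte-identical.

## Known limitations

* No population-structure or kinship correction in the forward scan; on
  structured populations the permutation null (which shuffles labels
  freely) is anti-conservative.
* The literal cutoff depends on a single permutation extreme, so its
  survivor set has high run-to-run variance at small B; use the adjusted
  P column for stable inference.
* Mann–Whitney's exact branch is limited to pooled n ≤ 12 without ties;
  beyond that the normal approximation is used even where an exact
  network algorithm would be feasible.
* The enrichment module assumes a flat category map; hierarchical
  propagation (parent categories inheriting child members) is the
  caller's responsibility.
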