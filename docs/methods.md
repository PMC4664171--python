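# Methods

## Coordinates and analysis windows

All coordinates are hg19, 1-based and inclusive at both ends; the BED
exports convert to 0-based half-open.  A locus is an OA association
signal: index SNP, major/minor alleles, the risk (OA-associated) allele,
the LD block tagged by the SNP (r² > 0.8 interval, supplied as metadata,
never computed here), the joint/sex stratum in which the genetic
association was reported, and optionally a proxy SNP with its r² when the
index SNP was not directly genotyped.

The analysis window is symmetric about the index SNP.  It starts at the
default span (1 Mb) and grows in fixed steps (0.5 Mb) until it fully
contains the LD block, then is clipped at base 1.  This single rule
reproduces both observed regimes: loci whose block fits inside the centred
default window keep 1 Mb, while a locus with a wide, off-centre block
(rs10948172, block chr6:44,683,049–45,349,877 around a SNP at 44,777,691)
grows to 1.5 Mb.  Probes exactly on a window or block boundary are
included; intervals are inclusive throughout because the printed positions
are 1-based point coordinates.

Probe selection keeps probes on the window chromosome with
window.start ≤ position ≤ window.end, drops polymorphic CpGs (sites
created or destroyed by a SNP, whose apparent methylation tracks genotype
trivially), and sorts by position.  The resulting count m is the
denominator for the region-wise multiple-testing correction — i.e. m is
the *post-exclusion* probe count of the tested region.

SNP–CpG distances are reported in whole kilobases.  `floor` truncation is
the default because printed annotations of the form "107 kb from the SNP"
correspond to truncated kb at the published coordinates; `nearest` is
available and is used for block spans ("~667 kb").

For loci without published LD-block bounds the locus file carries "." and
the loader substitutes the degenerate block [position, position]; the
window rule then yields exactly the default span.

## Discovery scan

For each probe, methylation β (fraction methylated) is regressed on
minor-allele dosage g ∈ {0, 1, 2} by ordinary least squares, β-values
used directly (not M-values) and without covariates.  The p-value is the
two-sided t-test of slope = 0.  Missing genotypes or β-values are handled
by pairwise deletion per locus × probe.  Degenerate cases produce flagged
records, never exceptions, so a multi-locus run always completes: fewer
than three complete pairs → "insufficient"; a single dosage value among
the used samples → "monomorphic".  A probe with constant β has zero
covariance and is reported with slope exactly 0 and p = 1.  The matrix
implementation (one masked pass over all region probes) is the same code
path as the scalar API, and is cross-checked in the tests against
`scipy.stats.linregress` and a permutation oracle.

Benjamini–Hochberg correction is applied per region per analysis pass,
step-up with enforced monotonicity and a cap at 1, with denominator m =
the full region probe count.  Probes that were individually untestable
still count toward m (they enter as implicit p = 1, which provably cannot
lower any step-up minimum below the cap).  Significance is fixed at
adjusted p < 0.05.  Each stratified pass (all, OA, NOF, OA-knee, OA-hip,
males, females) is corrected independently; whether a stratified rescan
should instead reuse the all-samples denominator is ambiguous in practice,
and per-pass correction is the conservative, self-contained choice.

Direction is reported per risk-allele copy: risk-dosage = g when the risk
allele is the minor allele, else 2 − g, so the slope sign flips exactly
when the risk allele is the major allele.  "lower" means methylation falls
as risk-allele count rises.  Variance explained is 100·r² of the
univariate dosage model, identical to 100 × squared Pearson correlation.

The disease-group comparison (OA-knee / OA-hip / NOF at one probe) uses a
Kruskal–Wallis test, chosen for consistency with the replication stage;
groups with fewer than two values are dropped, and identical values in all
groups return H = 0, p = 1 directly (the tie-corrected statistic is
undefined there).

## Replication

Pyrosequencing percent methylation (scale [0, 100]; β = pct/100 at the
boundary with discovery) is measured in PCR duplicates.  A measurement is
excluded when |rep1 − rep2| > 5 percentage points — read strictly, so a
difference of exactly 5 is retained — otherwise the duplicate mean is
carried forward.  The threshold is interpreted as absolute percentage
points, not relative.

Each CpG (a discovery probe, or an additional assay CpG labelled by its
offset, e.g. `cg18099408+5bp`, which inherits its parent's locus and
direction) is tested with a Kruskal–Wallis test across genotype groups
(tie-corrected H, chi-squared approximation with groups − 1 df; groups
need ≥ 2 QC-passing samples).  Bonferroni correction uses k = number of
CpGs tested in the batch (configurable).  A CpG replicates when adjusted
p < 0.05 **and** its genotype trend matches the discovery direction; the
trend compares the two extreme risk-dosage group means, with gaps within
0.5 percentage points called "flat" (never a match).  The 0.5-point
tolerance is a design choice — well below assay noise, above float
round-off.

Loci whose significant CpGs show a disease-group methylation difference in
discovery (Kruskal–Wallis p < 0.05 across OA-knee/OA-hip/NOF) have the NOF
controls excluded from their replication test; this automatic rule is
switchable (`auto_exclude_nof`) and reproducible from the run metadata.

Replicated-fraction summaries (`fraction_percent`) truncate to the printed
precision rather than round, matching the convention by which 3 of 16 loci
is quoted as 18.7%.

## Expression integration

Relative expression is 2^−ΔCt with ΔCt = target Ct − mean housekeeping Ct
(18S, GAPDH, HPRT1 roles).  The measure is invariant under a common shift
of all four Ct values.  A missing housekeeping value is tolerated when at
least two remain (configurable to strict).  Outliers are removed by an
iterative two-sided Grubbs test at α = 0.05 (α, sidedness and iteration
are design choices): at each step the most extreme value is removed if
G = max|x − x̄|/s exceeds the critical value
((N−1)/√N)·√(t²/(N−2+t²)) with t = t_{α/(2N), N−2}, until no value
exceeds it; removal depends only on the value multiset, with ties broken
toward the larger value.  Methylation–expression correlation is Spearman's
ρ with tie handling and two-sided p (≥ 4 complete pairs required),
Bonferroni-corrected within locus over the CpGs tested per gene.  The eQTL
pass defaults to Kruskal–Wallis across genotype groups, with a t-test on
the two extreme genotype groups available (Welch by default, pooled
optionally).

## Synthetic cohorts

The generator's defaults are the study conditions: 99 discovery samples
(63 OA knee, 17 OA hip, 19 NOF, sex assigned 50/50), 16 loci with region
probe counts {431, 76, 197, 157, 135, 57, 123, 190, 655, 32, 385, 91, 92,
135, 71, 270}, MAFs between 0.18 and 0.45, a replication cohort of 40 OA +
5 NOF, and a 29-sample OA-knee expression panel.  Genotypes are
Binomial(2, MAF) (Hardy–Weinberg).  Methylation is generated on the logit
scale — β = expit(baseline + effect·risk-dosage + status/sex offsets +
N(0, σ)) — because additive generation on the β scale can escape [0, 1];
baselines are drawn uniformly in logit units over (−1.5, 1.5) (β roughly
0.18–0.82, the informative mid-range of array probes), and σ = 0.15 logit
by default.  Four loci carry planted effects of graded strength (−0.5,
−0.6, −0.55 and −0.25 logit per risk-allele copy; the weakest emulates a
signal that trends without always replicating), two with risk = minor and
two with risk = major allele; NOF offsets (−0.2 logit) and male offsets
(−0.15 logit) are planted at some of those probes, driving the automatic
NOF-exclusion rule.  Every 40th non-planted probe is flagged polymorphic
to exercise the exclusion path.  Pyrosequencing duplicates are two
independent N(100·β, 1.5²) draws truncated to [0, 100]; qPCR target Ct is
baseline 26 + link·β + N(0, 0.25) with housekeeping Cts around 10/18/24
(the expression link defaults to 0, mirroring a study in which no
expression correlate was found; tests plant nonzero links explicitly).

The truth ledger records each planted effect in logit units and as the
population least-squares β-scale slope per risk-allele copy — computed
from the Hardy–Weinberg-weighted regression of E[expit(baseline +
effect·d + ε)] on d, with the noise expectation evaluated by 64-node
Gauss–Hermite quadrature.  This is the exact estimand of the discovery
OLS slope, which is what makes "mean absolute recovery bias < 0.01"
a well-posed test.

A single root seed spawns named `SeedSequence` substreams (genotypes,
baselines, methylation, sex, replication, pyro, expression), so each stage
is independently regenerable and full runs are bit-reproducible.

What the generator does **not** emulate: probe-level measurement error and
chemistry biases of methylation arrays, batch effects, cell-type
heterogeneity, spatial correlation between neighbouring CpGs, and LD
between the index SNP and other variants in the window (probes are
conditionally independent given genotype).  Passing tests therefore
demonstrate the correctness and calibration of the statistics under the
assumed generative model, not robustness to those real-data features.
The default signal-to-noise (σ = 0.15 logit) yields stronger associations
(variance explained up to ~85%) than typical array data; power statements
should be read in that light.

## Problem sizes and numerical choices

The null-calibration study uses 200 seeded null cohorts (full 16-locus
geometry, 3 200 region scans) and checks the share of regions with any
BH-significant probe against the 5% level within binomial error; the
power/recovery study uses 100 seeded single-locus cohorts (197 probes,
planted −0.4 logit at MAF 0.35, n = 99).  These sizes put the Monte-Carlo
error well below the margins being tested while keeping a full run in the
tens of seconds.  Oracle-equivalence checks (BH vs brute-force step-up,
OLS and Kruskal–Wallis p vs permutation, Spearman p vs exhaustive rank
permutation, Grubbs vs its definition) run at n ≤ 12 where enumeration or
10⁴ shuffles are exact enough.

Numerical details: sums of squares are clamped at 0 against catastrophic
cancellation; a perfect fit with nonzero slope reports p = 0; BH sorting
is stable (mergesort) so ties are deterministic; distances use integer
arithmetic; percent truncation uses floor at the stated precision.

## Known limitations

- The scan assumes homoscedastic, approximately symmetric residuals on
  the β scale; for probes near 0 or 1 an M-value analysis would be more
  appropriate (out of scope by design).
- Trans-acting effects, genome-wide scans, LD/r² estimation, array
  normalization and coordinate lift-over are out of scope; LD blocks and
  proxy r² values are trusted inputs.
- Risk alleles for loci where the literature does not state one are
  labelled minor-allele-risk by convention in the packaged reference
  table; this affects only the sign bookkeeping at non-significant loci.
- The automatic NOF-exclusion rule keys on the discovery disease-group
  comparison at significant CpGs; with very small NOF groups the rule is
  underpowered and exclusion can be forced per locus via configuration.
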