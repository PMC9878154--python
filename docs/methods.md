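# Methods

This note documents the statistical models, parameter choices and numerical
conventions behind the two analysis arms, and what the synthetic-data
generators do and do not emulate.

## Coordinates and formats

All coordinates are 0-based half-open internally; conversion to VCF/GFF3
1-based conventions happens only in the I/O layer, so BED output needs no
arithmetic and round-trips are involutive. Only biallelic SNPs are analysed:
multi-allelic and non-SNP VCF records are skipped and counted rather than
decomposed, because both window statistics and the annotation summary are
defined on biallelic sites. When a GFF3 lacks UTR features they are derived
as exon minus CDS, split at the CDS extremes strand-awarely, so feature
mapping works on minimal GFF3 dialects.

## SNP quality control

Per-genotype masking (DP ≥ 4, GQ ≥ 10, both inclusive) precedes the
site-level filters, matching vcftools/PLINK semantics: a genotype failing
depth or quality contributes to the missing rate but never to allele
counts. The missing-rate bound is strict (< 0.1) and the MAF bound inclusive
(≥ 0.05); MAF uses only called alleles in its denominator — the only
defensible choice after masking. Removal reasons are charged in a fixed
order (all-missing, missing-rate, MAF) so flow-through counts are
reproducible. The filter is idempotent and monotone in its thresholds
(property-tested).

## Functional annotation

Classification follows the ANNOVAR-style precedence
Exonic > Splicing > 5′UTR/3′UTR > 5′UTR > 3′UTR > Intronic >
Upstream/Downstream > Upstream > Downstream > Intergenic, with 1 kb flanks
and a 2 bp splice-site reach into introns. "Upstream/Downstream" means
upstream of one gene and simultaneously downstream of a *different* gene
(geometrically a site cannot be both for one gene). Coding effects rebuild
the affected codon from the reference in coding orientation
(reverse-complemented on the minus strand) and translate with the standard
genetic code; when several transcripts disagree the most severe effect wins
(stop-gain > stop-loss > nonsynonymous > synonymous) so each SNP carries
exactly one category. The implementation is tested against a brute-force
oracle that translates the entire mutant CDS and diffs the protein.
Summary percentages use half-up rounding to 2 decimals and the ts/tv ratio
3 decimals, the conventions of published SNP tables; a zero transversion
count reports the ratio as NA.

## Sweep scan

Windows are 100 kb sliding by 50 kb, starting at 0 on every contig with the
trailing window truncated; windows with fewer than `min_snps = 10` SNPs are
excluded from ranking (large scans in this field analyse a subset of
possible windows for exactly this reason). Pooled heterozygosity is the
standard sweep-scan statistic
`Hp = 2 Σn_MAJ Σn_MIN / (Σn_MAJ + Σn_MIN)²` over the window's per-SNP
major/minor allele counts within a group; it lives in [0, 0.5] and is 0 iff
every SNP is monomorphic in the group.

Window F_ST is the two-population Weir–Cockerham (1984) estimator combined
as a ratio of sums, `Σa / Σ(a+b+c)`, the vcftools-compatible de-facto
standard. A site contributes only when both groups have ≥ 2 called diploid
genotypes. Negative per-window values are retained, not clamped: clamping
would distort the empirical quantiles used for outlier calling. Hudson's
estimator (Bhatia-style sample-size-corrected numerator, ratio of sums) is
available via `scan_windows(..., estimator="hudson")` as a sensitivity
check; on the synthetic data the two rank windows nearly identically.

Candidate windows are the conjunction of two empirical-quantile flags:
top 10% of F_ST (high tail, strict beyond a rank-`ceil((1-q)N)` order
statistic; ties share the threshold and do not count as beyond) and the
extreme 10% tail of Hp. Which Hp tail is biologically right is genuinely
ambiguous in the field's phrasing ("top" Hp values can mean rank by raw
value or by diversity loss); since a sweep depletes diversity in the
selected group, the default is the **low** tail of group 1's Hp, with both
the tail and the group exposed as configuration and both groups' Hp always
written to the window table. An auxiliary top-5% F_ST threshold and count
are reported alongside, as scans in this literature often quote both cuts.

## Methylation arm

Sites need ≥ 10 reads per sample; afterwards a per-sample coverage cap at
the 99.9th percentile (linear-interpolated quantile of that sample's
surviving sites) removes PCR-bias-like spikes. The cap drops coverage
**strictly above** the percentile value: an inclusive bound degenerates on
tied maxima (with uniform coverage it would drop every site), while the
strict rule matches the quantile-filter behaviour of the standard
methylKit-style workflow.

Tiles are non-overlapping 200 bp bins pooling both strands of CpG sites
only (`tile_contexts=("CG",)`): CHG/CHH methylation in vertebrate genomes
sits near the bisulfite error rate and would only dilute tile differences;
the contexts still flow through filtering and the global summaries. A tile
is testable when every sample covers ≥ 3 of its cytosines.

The per-tile test is the binomial-GLM likelihood-ratio test of a group
indicator on per-sample (methylated, unmethylated) counts — the test a
replicated methylKit-style analysis performs. Because the design matrix is
a single binary factor, the maximum-likelihood fit is exactly the
group-pooled proportion, so the deviance is evaluated in closed form (no
iteration can fail to converge); the closed form is verified against an
IRLS-fitted statsmodels GLM in the test suite. When either group has only
one covered sample the test falls back to Fisher's exact test on the pooled
2×2 table, flagged in the output. Group mean levels are coverage-weighted
(pooled counts), not means of per-sample ratios — stable at low coverage
and consistent with the pooled test. Multiple testing uses
Benjamini–Hochberg step-up q-values (deterministic, unlike SLIM-style
q-value estimation; users comparing against methylKit should expect small
differences). DMR calls require |difference| > 25 percentage points and
q < 0.01, both strict; hyper means higher in group 1 (the first label in
the groups file — in the motivating design, the group that accepts
artificial diets).

"Methylated cytosine" for the global summary is defined by a one-sided
binomial test of a site's pooled methylated calls against a bisulfite
error rate of 0.005 at BH α = 0.05, since site-level methylation status
has no universal definition; the percentage denominator is all reference
cytosines (C plus G bases). Context levels are reported both call-weighted
(primary) and site-averaged.

DMR feature mapping uses a 2 kb promoter and 1 kb downstream flank,
strand-aware; an intron lying entirely 5′ of the translation start is
labelled a 5′UTR intron (the class highlighted in regulatory analyses of
DMRs), all other introns are plain introns. A DMR may carry several labels,
one per overlapped feature; a DMR touching nothing within reach is
intergenic.

## Enrichment

A generic one-sided hypergeometric over-representation test over a
user-supplied term→gene map, BH-adjusted. The population defaults to all
genes in the supplied GFF3. No ontology ships with the package, and
term-level results depend entirely on the mapping provided.

## Synthetic data

The sweep generator draws per-site ancestral frequencies from
Uniform(0.1, 0.9) and per-group frequencies from the Balding–Nichols Beta
distribution with F = 0.02 background and F = 0.4 inside three planted
100 kb windows; inside those windows group 1 is additionally pushed to
frequency 0.98 with probability 0.8, reproducing both signatures a sweep
scan keys on (differentiation and diversity collapse). Sample sizes
(10 + 10 diploids), depth (Poisson mean 10), GQ (Normal 60 ± 10) and a 2%
missing rate emulate a ~10× resequencing panel. The generator produces no
linkage disequilibrium, recombination structure or demographic history —
passing recovery tests shows the scan statistics and thresholds work, not
that the method is calibrated for a specific demography.

The methylome generator emulates 3 vs 3 samples at negative-binomial depth
(mean 30, dispersion 5) over a 200 kb CpG-seeded contig (~1 CpG / 25 bp).
CpG baselines are bimodal (80% near 0.85, 20% near 0.05), the vertebrate
pattern; CHG/CHH sites are emitted near the error rate. Inside the forty
planted tiles the baseline is fixed at 0.5 so the two groups sit at
0.5 ± Δ/2 with Δ = 0.4 — with the bimodal baseline a +0.2 shift would clip
at 1.0 and silently shrink the planted effect below its nominal size. A
small fraction of sites receives 500× coverage to exercise the percentile
cap. Counts are pure binomial: there is no between-replicate overdispersion,
so the GLM's null calibration on this data is slightly conservative and
real tissue data may need the caveat that biological overdispersion is not
modelled.

Gene models are tiled every ~20 kb with 3–6 exons, a valid CDS (ATG start,
no internal stops, terminal stop, length divisible by 3) written into the
reference, and explicit UTRs. All generators are pure functions of
(parameters, seed); outputs are byte-identical across runs.

## Problem sizes and checks

The test suite validates estimators against independent oracles (per-site
straight-line Weir–Cockerham transcription on 1,000 random windows at
1e-10; full-CDS-translation diffing on ≥ 1,000 random coding SNPs;
hypergeometric-summation Fisher on 100 random tables) and scores parameter
recovery on a 20-seed battery of the default sweep conditions (recall and
truth-window enrichment of candidates) and on the default methylome plus a
20-seed null battery (recall, empirical FDR, zero-DMR null rate).
`scripts/acceptance.py` recomputes all of these from scratch and writes
them as JSON.

## Known limitations

- Hp and F_ST here are genotype-based; haplotype statistics (iHS, XP-EHH)
  are out of scope, as are permutation-based significance levels — outlier
  calling is purely empirical-quantile.
- The DMR test ignores biological overdispersion between replicates;
  methylKit's SLIM q-values and overdispersion correction will differ in
  detail.
- Indels are not annotated; transcript databases beyond the supplied GFF3
  are not consulted.
- The coverage percentile cap is per sample and applied after the depth
  floor; tools differ on both choices, so absolute site counts are not
  comparable across pipelines.
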