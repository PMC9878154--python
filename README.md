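# sweepmeth

Selective-sweep scanning and whole-genome bisulfite (WGBS) differential-
methylation calling for two-group resequencing designs, plus seeded
synthetic-data generators that plant sweeps and DMRs with known truth so the
whole pipeline can be validated without any external data.

The package was built around a common aquaculture-genomics study design:
two groups of diploid individuals that differ in a trait of interest (for
example fish that can vs. cannot be domesticated onto artificial diets) are
whole-genome resequenced and bisulfite sequenced, and the analyst asks (1)
which genomic windows look swept in one group and (2) which 200 bp tiles are
differentially methylated between the groups.

## What it computes

**Sweep arm.** After per-genotype masking (DP ≥ 4, GQ ≥ 10) and site filters
(missing rate < 0.1, MAF ≥ 0.05), SNPs are scanned in 100 kb windows sliding
by 50 kb. Each window gets

- pooled heterozygosity per group,
  `Hp = 2 Σn_MAJ Σn_MIN / (Σn_MAJ + Σn_MIN)²`,
  summing per-SNP major/minor allele counts over the window — a sweep
  collapses Hp in the selected group;
- two-population Weir–Cockerham (1984) F_ST as the ratio of summed variance
  components `Σa / Σ(a+b+c)` (Hudson's estimator is available behind a flag
  for sensitivity analysis);
- empirical-quantile outlier flags: windows in the top 10% of F_ST **and**
  the extreme 10% tail of Hp (low tail of the selected group by default)
  are candidate swept regions. Genes whose spans intersect candidate
  windows are reported, optionally with a hypergeometric over-representation
  test against a user-supplied term→gene map.

**Methylation arm.** Bismark-style per-cytosine reports are depth-filtered
(≥ 10×, per-sample 99.9th-percentile coverage cap), context-checked against
the reference (CG/CHG/CHH), summarised globally, and pooled into
non-overlapping 200 bp tiles. Each tile is tested for a group effect with a
binomial-GLM likelihood-ratio test (Fisher's exact fallback when a group has
a single sample), Benjamini–Hochberg adjusted, and called hyper-/hypo-
methylated when |difference| > 25 percentage points and q < 0.01. DMRs are
mapped onto gene features (promoter-2 kb, 5′UTR exon/intron, CDS, intron,
3′UTR, downstream-1 kb).

**Synthetic data.** Genotypes follow the Balding–Nichols model (per-group
allele frequencies Beta-distributed around an ancestral frequency with
divergence F, so E[F_ST] ≈ F); planted sweep windows get elevated F plus
near-fixation in group 1. Methylomes are binomial bisulfite counts over a
CpG-seeded reference with tile-level differences planted on the 200 bp grid.
Both emit machine-readable truth for recall/FDR scoring.

## Worked example

```sh
sweepmeth simulate sweep --out demo/sim --seed 7
# wrote 6 artifacts to demo/sim (9998 SNPs)

sweepmeth sweep --vcf demo/sim/variants.vcf --groups demo/sim/groups.tsv \
    --gff demo/sim/genes.gff3 --fasta demo/sim/reference.fa --outdir demo/scan
# 40 analyzed windows; 4 candidates; top-5% Fst threshold 0.658796 (2 beyond)

head -3 demo/scan/candidates.bed
# chr1  200000  300000
# chr1  600000  700000
# chr2  400000  500000
```

The simulator planted sweeps at chr1:200–300 kb, chr1:600–700 kb and
chr2:400–500 kb (`demo/sim/truth_windows.bed`); all three are recovered as
joint Hp/F_ST outliers (the fourth candidate is a half-overlapping shoulder
window), and `demo/scan/genes.txt` lists the genes the candidate windows
contain. `demo/scan/windows.tsv` carries the full per-window statistics and
`manifest.json` records every parameter and input checksum for the run.

The methylation arm runs the same way from `sweepmeth simulate methylome`
and `sweepmeth methyl`, or both arms at once from a YAML config via
`sweepmeth run-all`.

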