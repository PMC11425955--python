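# Methods

`csslmap` dissects drought resistance in a chromosome segment substitution
line (CSSL) population: an interspecific introgression panel in which each
line carries a few homozygous donor-genome segments (here *G. barbadense*
3-79) in an otherwise uniform recurrent background (*G. hirsutum* E22).
This note documents the models, their assumptions, the defaults and the
numerical choices, and what the synthetic test bench does and does not
establish about real data.

## Phenomics

**BLUP.** Per trait and irrigation condition the trial is modelled as

    value = mu + year + replicate(year) + line + error,

with year and replicate-within-year fixed and the line effect random,
`line ~ N(0, sigma_g^2)`. Variance components are estimated by EM
restricted maximum likelihood on the mixed-model equations (relative
tolerance 1e-8, at most 500 sweeps, variances floored at 1e-10 x the
phenotypic variance). The reported line value is the average fixed-effect
prediction plus the line BLUP; a line with no observations in a cell stays
missing rather than being imputed. EM was chosen because the
single-random-effect model admits a stable closed-form M-step; the
estimates are verified in the test suite against both a direct
V-inverse GLS solve at the optimum and statsmodels' MixedLM REML.

**DRC and MFVD.** The drought-resistance coefficient is
`DRC = drought value / control value`, computed from condition-wise BLUPs
(a per-year variant can be had by subsetting the observation table before
fitting). Cells with a nonpositive control value are flagged undefined,
never silently zeroed. The composite membership-function score rescales
each basis trait's DRC to [0, 1] over the population,
`(x - min)/(max - min)` for higher-is-better traits (mirrored otherwise),
and averages over the eight yield and fiber-quality basis traits
(BW, LW, LP, EBN, FUHML, FS, MV, FU), equally weighted. Micronaire (MV)
has an optimal band rather than a monotone preference in practice; by
default its DRC is treated higher-is-better like the rest, and the
orientation is a per-trait argument for users who want it inverted.

**Grading.** Five drought-resistance levels (I sensitive ... V tolerant)
are assigned by banding the MFVD distribution at the mean -/+ 1.5 and 0.5
SD by default (configurable cutoffs; intervals lower-inclusive on the
upper side). These default cutoffs are a conventional five-band scheme —
they are not claimed to reproduce any particular published level split.

**Correlation network.** One Pearson edge per unordered DRC trait pair
(14 traits -> 91 edges) with a two-sided p; an edge is "significant" when
p < 0.05 and |r| > 0.1. The threshold is deliberately on the signed
coefficient: a squared correlation cannot be negative, so a rule quoted as
"R^2 > 0.1 or R^2 < -0.1" is only coherent as a threshold on r.

**Physiology.** REC = C1/C2 x 100; MDA (nmol/g FW) = 25.8 x (A532 -
A600)/fresh weight; relative expression by 2^-(ddCt). These are direct
formula evaluations with flagged degeneracies (C2 = 0, nonpositive fresh
weight).

## Mixed-model GWAS

Markers are filtered at MAF > 0.05 and missing rate < 0.5 (recomputed from
the matrix, never trusted from metadata). Kinship is the centered
cross-product (VanRaden) estimator `K = WW'/c`, `c = sum 2p(1-p)`, with
mean imputation used *only* inside K. The association model per marker is

    y = mu + x*beta + u + e,   u ~ N(0, sg^2 K),  e ~ N(0, se^2 I).

K is eigendecomposed once; the variance ratio `delta = se^2/sg^2` is
profiled by REML on the intercept-only null (64-point grid on
log delta in [-10, 10], then bounded golden-section refinement to 1e-6)
and held fixed across markers — the standard "population parameters
previously determined" speed approximation. Per-marker inference is
generalized least squares with a two-sided Wald t at residual degrees of
freedom. Missing dosages are dropped pairwise per marker and handled
*exactly*: the inverse covariance of the observed subset is obtained from
the full-panel inverse by a low-rank Schur-complement correction, so no
imputation ever enters the scan. Degenerate markers (constant after
missing-drop, singular designs) are skipped with a recorded reason.
p-values are floored at the smallest positive double so `-log10 p` stays
finite.

Genome-wide thresholds follow the 1/M (suggestive) and 0.05/M
(significant) convention on the filtered marker count. Significant
markers closer than 1 Mb on a chromosome merge into one QTL interval whose
minimum-p marker is the highlighted SNP. Candidate screening intervals are
+/-300 kb flanks around a highlighted SNP, clipped to the chromosome and
united with the containing greedy r^2 >= 0.8 LD block when one exists.
The greedy block rule (extend while the next marker's r^2 with the block
seed stays above threshold) was chosen over Gabriel-style confidence
intervals because the panel is biallelic-dosage-coded and near-fixed;
it is documented as such, not as a clone of any specific LD tool.

## Bin-map linkage scan

Consecutive markers with identical dosage columns are merged into bins,
with boundaries at the midpoint between flanking distinct markers. Missing
calls act as wildcards during the comparison — with per-entry missingness
virtually every column would otherwise be unique and binning would
collapse; with complete data the rule is exact column identity. A line
unobserved across a whole bin is coded 0 (recurrent background), the
overwhelmingly likely CSSL state.

QTL are mapped by a stepwise-cofactor likelihood-ratio additive scan:
forward-backward stepwise regression over bins (partial-F entry p < 0.01,
drop p > 0.02, at most 50 cofactors) selects the genetic background; each
bin is then tested by a Gaussian likelihood-ratio test against the model
holding every selected cofactor except those within 5 Mb of the tested bin
(composite-interval style, so a QTL cannot absorb its own signal).
Support is `LOD = n ln(RSS0/RSS1) / (2 ln 10)`; the additive effect is the
per-donor-allele regression coefficient (half the homozygote contrast);
PVE is the sum-of-squares increment over the total. Heterozygous bins are
coded 1 (additive only; no dominance term). Runs of contiguous bins with
LOD >= 2.5 (configurable) merge into QTL intervals. This is a documented
reimplementation of the stepwise-LRT-additive idea, not a bit-compatible
clone of any existing linkage package.

## BSA ΔSNP-index with a CSSL-aware null

Extreme pools are the top and bottom 30 lines by MFVD (deterministic
tie-breaks; a tie class spanning both tails aborts). Per site the
SNP-index is the donor-read fraction per pool and
`delta = index_resistant - index_sensitive`; sites need parent-discordant
homozygous parents and >= 10 reads in both pools. Windows of 1.5 Mb slide
at 100 kb (the window size is the study's; the step is a conventional 15x
overlap choice); windows with fewer than a minimum number of sites are
flagged, not valued.

The significance band is Monte-Carlo, and its two CSSL-specific choices
are the package's main modelling decisions:

1. **Line-level sampling.** A null site at locus donor frequency p draws
   each pool's allele frequency as Binomial(n_units, p)/n_units with
   n_units = 30 *lines*, not 60 chromosomes. CSSLs are near-fixed, so a
   line's two chromosomes are copies of one draw; chromosome-level
   sampling would understate the pool-composition variance by half (in
   measurements on null panels it produced ~9% of windows beyond a
   nominal 99% band). An F2-style segregating pool can set
   `units_per_pool = 2 x pool_size`.
2. **Locus-specific frequency, window-shared composition.** p is the
   observed combined-pool frequency at the locus (low and locus-specific
   in a CSSL panel — the F2 assumption p = 0.5 does not apply), and
   within a window the pool-frequency draw is shared across sites while
   only read noise averages over them, because the same lines carry the
   same segment across the window. Treating window sites as independent
   would shrink the band by ~1/sqrt(n_sites) and badly inflate calls.

Bands (99% by default, 10 000 simulations, Poisson depths floored at 1
read) are tabulated on a rounded (p, depth, site-count) grid and cached.
Runs of windows beyond the band — bridging at most one sub-threshold gap
window — merge into intervals; the peak is the window with max |delta|.

## Integration and pyramiding

QTL from the three methods are named `q.<TRAIT>.<Chr>.<k>` with k the
1-based positional ordinal per trait and chromosome. Co-localization is
single-linkage grouping of same-chromosome intervals overlapping by >= 1
bp (most permissive; configurable). Haplotyping anchors each multi-method
group on its best GWAS highlighted SNP when one exists, else the genotyped
marker nearest the group's peak midpoint; calls are hap_donor /
hap_recurrent / het / unknown straight from the dosage. The resistant
haplotype at a QTL is the group with the larger mean of the associated DRC
trait (Welch's t for the contrast; ties unlabeled; het and unknown calls
excluded — they are rare in a near-fixed panel and their handling is
configurable only through the call table). Pyramiding counts resistant
haplotypes per line and reports the Pearson correlation of the count with
MFVD.

## The synthetic study generator

The generator is first-class, tested code; its defaults define the test
bench:

* 319 lines, 26 chromosomes of 80 Mb, 400 evenly spaced markers per
  chromosome (~10 400; a real resequencing panel has ~100x more — marker
  density is the one deliberately scaled-down axis), 1% missing calls;
* per line 1 + Poisson(3) homozygous donor segments with exponential mean
  length 30 Mb (floored at 2 Mb), snapped to marker positions,
  non-overlapping, capped at 10% donor genome per line — giving ~5% donor
  genome per line and locus donor frequencies around 0.05–0.12;
* 14 traits under 2 conditions x 2 years x 2 replicates with
  trait-condition means set to the field-plausible values of an upland
  cotton drought trial, and variance components (as CV of the control
  mean) genetic 2%, year 1%, replicate 0.5%, residual 3%;
* 5 drought-specific QTL on BW, LW, FUHML, FS and FU at markers with
  realized donor-homozygote frequency in [0.08, 0.35], per-allele drought
  effect 6% of the control mean and zero control effect. These are
  deliberately major-effect loci (~30–60% of DRC variance): at desk scale
  with 30/30 pools, anything weaker leaves extreme-pool enrichment inside
  an honestly calibrated 99% band, and the point of the bench is that all
  three mapping routes can demonstrably recover known truth;
* pooled depths Poisson(50) with binomial donor reads at the pool's
  observed frequency.

What passing the bench does **not** show about real data: the generator
draws polygenic line effects independently of the marker genome (so
population structure beyond segment sharing is absent), injects missing
calls completely at random, has no genotyping error, no marker-density
heterogeneity, no G x E beyond a shared year effect, and no
epistasis or dominance. Recovery rates measured here are upper bounds for
field data of the same size.

## Problem sizes and determinism

The default end-to-end run (phenomics, 9 GWAS scans, 9 linkage scans, BSA,
integration) takes ~30 s on one CPU; the calibration suites use a 300-line
~5000-marker null panel and 40 000 null sites. One global seed fans out to
per-stage child seeds through `numpy.random.SeedSequence`, and identical
config + seed reproduces byte-identical output files (fixed float
formatting, stable orderings).

## Known limitations

* The linkage scan's fixed entry threshold (p < 0.01) over thousands of
  bins admits noise cofactors under the null; the 50-cofactor cap and the
  5 Mb exclusion window bound the damage, but genome-wide LOD
  significance should be calibrated by permutation for real studies.
* LD blocks use a greedy seed rule; block edges depend on marker order
  within ties.
* The BSA band conditions on observed per-window frequency and depth; at
  very low site counts the tabulation grid is coarse.
* `percent_change` and DRC agree exactly on means only when computed from
  the same per-line aggregation (both use BLUPs here).
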