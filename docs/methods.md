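# Methods

## Scope and model overview

The package simulates the complete decision chain a breeding programme
faces when replacing a low-density SNP chip with a RADseq protocol:
predict the sequenced genome fraction, find the markers it recovers,
impute candidates back to the HD panel, and measure how imputation errors
propagate into single-step GBLUP rankings.  Everything runs on synthetic
data with known truth; no external genomes, arrays or binaries are
needed.

## In silico digestion

Recognition sites are IUPAC patterns matched case-insensitively on the
forward strand only; all overlapping matches are reported and `N` bases
never match.  Forward-only scanning is valid because `EnzymeSpec` only
accepts recognition sets closed under reverse complementation (all four
built-in enzymes are); non-closed patterns raise with instructions to
supply both strands as two enzymes.

Coordinates: a fragment runs from the **start** of its left recognition
site to the start of its right site (0-based half-open), matching the
definition of the sequencing windows as 150 bp *after the start position*
of a site.  Exact cut offsets within the recognition sequence are not
used anywhere downstream, so this convention is the internally consistent
choice.  Terminal segments before the first and after the last site are
not fragments (a sequenceable fragment needs sites at both ends); the
effect on counts is at most two per chromosome.  Size selection keeps
200 ≤ size ≤ 500 inclusive — the bound convention is fixed here because
"from 200 to 500 bp" does not dictate openness.  Double digests keep only
consecutive site pairs with different flanking enzymes; same-enzyme pairs
are unusable in ddRADseq library construction.

Per-chromosome-type summaries (fragments/Mb, SNPs/Mb, inter-SNP spacing)
use the sample standard deviation (n−1) across chromosomes of a type; the
single Z chromosome is reported without a spread.

## Window/marker overlap

Markers carry 1-based VCF positions, windows are 0-based half-open BED
intervals, so membership is `win_start < pos <= win_end`.  A marker
covered by both paired-end windows of a short (<300 bp) fragment counts
once.  Panel overlap matches on (chromosome, position), not marker names.
Printed percentages use half-up rounding of the exact quotient to two
decimals.

## Mutation impact

All alternate alleles are substituted jointly into the genome
(homozygous-alternate model) and sites are rescanned; destroyed = sites
matching only the reference, created = only the substituted sequence.
Counting is per site on the pooled variant set.  `het_mode="keep"`
instead retains reference sites (the reference haplotype still cuts) and
counts only creations; the default `"destroy"` is the
allele-dropout-pessimistic reading.  Fragment rebuilding applies
(reference − destroyed) ∪ created per enzyme and reruns the identical
single-/double-digest and size-selection rules, so empty deltas are an
exact identity and a delta followed by its inverse restores the reference
table.

## Quality control

The chain runs in a fixed order — individual call rate, monomorphic
markers, MAF, SNP call rate, Hardy–Weinberg, location, pedigree check —
with allele frequencies recomputed after every step; thresholds are
strict (`< 0.95`, `< 0.05`, `P < 1e-4`).  The HWE test is the two-sided
exact test conditional on allele counts (each heterozygote-count outcome
weighted by n!/(n_AA! n_Aa! n_aa!)·2^n_Aa; the p-value sums outcomes no
more probable than the observed), the flavour used by common GWAS QC
tools; a chi-square variant is available via `hwe_method="chi2"`.  The
Mendelian check counts opposing homozygotes per parent-offspring pair and
reports rather than removes, since no removal policy can be derived from
a chain in which that step removes nothing.

## Synthetic data generator

Defaults are the desk-scale study conditions; every stage draws from a
named substream of one master seed, so outputs are byte-reproducible.

* **Genome** — 8 chromosomes, ~14.4 Mb total: two macro (3.0/2.5 Mb,
  GC 0.40/0.41), two intermediate (1.5/1.2 Mb, GC 0.45), three micro
  (0.7/0.6/0.5 Mb, GC 0.52–0.54), one Z (2.0 Mb, GC 0.40).  Bases are
  i.i.d. at the target GC; the class structure (micro shorter and more
  GC-rich than macro) is what drives the per-type contrasts in
  restriction-site density.  Realized GC lands within ±0.02 of target.
* **Pedigree** — 100 founders, 4 generations (G0–G3) of 240 offspring
  each: 16 sires × 48 dams × 5 offspring/dam, so each sire leaves 15
  offspring and the "breeder" subset (≥ 10 offspring) is non-trivial.
  Matings are configuration-driven, not trait-selected.
* **Founder haplotypes and LD** — marker positions are uniform except for
  a fraction (`site_variant_rate`, default 0.05) planted inside TaqI/PstI
  recognition-site matches so the mutation-impact stage always has test
  material.  Alt-allele frequencies have MAF ~ U(0.05, 0.5).  LD comes
  from a copying process: each marker's latent uniform is copied from its
  left neighbour with probability `0.3^(d / (2·ld_decay_bp))` and redrawn
  otherwise; the allele is the indicator (latent < p).  For
  equal-frequency pairs this yields r² ≈ 0.3 at `ld_decay_bp` (default
  250 kb, the useful-LD extent reported for commercial layer lines) and
  geometric decay beyond.  A Markov copying process was chosen over
  coalescent simulation deliberately: it is desk-scale, directly tunable,
  and sufficient for imputation/overlap experiments; it does not
  reproduce coalescent allele-frequency/LD joint structure, recombination
  hotspots, or background relatedness among founders, so absolute
  accuracy values should not be read as field estimates — the trends are
  the object of study.
* **Gene drop** — each meiosis draws Poisson(rate·L) crossovers at
  uniform positions (default 3 × 10⁻⁸/bp, a chicken-like genome-wide
  average) and transmits a mosaic of the parent's two haplotypes;
  genotype = haplotype sum at every site by construction.  Z is simulated
  autosome-like; dosage-specific sex-chromosome inheritance is out of
  scope.
* **Variant set and HD panel** — `marker_density` 600/Mb (~8.6 k markers)
  emulates a sequence-level discoverable-variant set; `panel_fraction`
  0.35 of markers (~3 k) form the "HD chip".  The ratio matters more than
  the absolute counts: RADseq windows must recover enough chip markers
  for imputation to be non-degenerate, as they do at full scale.
* **Traits** — four traits named for the egg-quality measurements they
  emulate (EW, ESC, ESS, AH) with heritabilities 0.50/0.35/0.30/0.40,
  phenotypic variance 1, 100 QTL markers each.  TBV is the rescaled
  effect-weighted dosage; phenotype adds the trait mean, a batch effect
  (3 hatches, sd 0.3) and a Normal residual of variance (1−h²)σ²_P.
  ESC itself derives from colorimeter readings as 100 − (L* − a* − b*)
  (`derive_esc`).  Heritabilities are not published for the emulated
  line; values are typical literature ranges for these traits.

## Imputation

The imputer is a deterministic greedy haplotype-window matcher standing
in for production family-based imputation software, whose heuristics are
proprietary; the conclusions here depend on accuracy *trends*, not on any
specific program's internals.  The reference library is the deduplicated
phased truth of G0.  Windows of 64/32/16/8 typed markers (50% overlap)
are scanned coarse-to-fine: within a window the library haplotype with
fewest conflicts against the candidate's genotypes is chosen (g=0 forces
allele 0, g=2 forces 1, g=1 is compatible with either), then the best
mate consistent with the residual; only fully consistent pairs vote.
Ties break by parental-haplotype preference (the only pedigree use), then
library frequency, then index — hence determinism.  Votes are stitched by
per-marker majority (ties to the lower dosage); the first/last windows
also cover the untyped chromosome flanks; markers never covered by a
consistent pair fall back to round(2p).  Typed markers pass through
unchanged, so a fully typed candidate is a no-op by construction.

Accuracy is the SNP-wise Pearson correlation between true and imputed
codes across candidates; markers with zero variance in either vector have
no defined correlation and are excluded from the mean (and counted),
rather than scored 0 — the choice inflates means slightly at very low
panel density, where frequency-fill produces many constant markers, and
is therefore reported explicitly.

## Single-step GBLUP

Single-trait animal model y = Xb + Zu + e, fixed effects = intercept +
batch (repeated measures mean-collapsed).  A by the tabular method; A⁻¹
directly or by Henderson's rules with exact Mendelian-sampling variances;
G = MM′/(2Σp(1−p)) on centred dosages (VanRaden method 1); G blended
0.95G + 0.05A₂₂ before inversion, τ = ω = 1 — standard production
defaults.  The MME are solved densely; a rank-deficient fixed block is
constrained by zeroing dependent columns (pivoted QR) with a warning.
Variance components are inputs (the simulation truth by default),
mirroring the practice of fixing REML estimates before running scenario
evaluations; REML itself is out of scope.  With the blended G equal to
A₂₂ the H matrix collapses to A exactly, which the tests assert at 1e-8
against an independent GLS-form pedigree-BLUP oracle.

Scenarios: `Full_HD` (all phenotypes, all HD genotypes — including
non-breeding descendants), `Ancestry_true` (G0 phenotypes; G0+G1 true
HD), `Ancestry_imputed` (same, with G1 genotypes replaced by imputed
ones).  Rankings are compared by Spearman over the top-K of the reference
ranking and over the breeders (≥ 10 offspring), retention count in the
top-K, and Pearson vs `Full_HD` over breeders as relative accuracy.
Spearman uses average ranks for ties; optional bootstrap standard errors
(seeded, resampling individuals) are this package's own convention, as
the spread estimator behind published comparison tables is generally
unstated.  The multi-trait joint model is deliberately not implemented:
single-trait evaluations exercise the identical ranking machinery at a
fraction of the complexity, and traits are simulated independently.

## Problem sizes and determinism

The default population (~1,060 birds, ~8.6 k variants, ~3 k HD markers,
240 candidates) was sized so the full test suite and the acceptance
script each run in minutes on one CPU while every qualitative contrast
(per-chromosome-type densities, accuracy vs panel density, breeder vs
top-K reordering) remains clearly resolved.  All stochastic stages hash a
stage name with the master seed, so identical configurations give
byte-identical outputs and the acceptance JSON is reproducible bit for
bit for a given `--seed`.

## Known limitations

* I.i.d. genome composition: no CpG islands, repeats or isochores, so
  absolute enzyme site densities differ from real genomes (GC-poor
  recognition sites are relatively favoured on the AT-rich macro
  chromosomes).  Per-type contrasts driven by GC remain.
* No sequencing-read simulation: coverage, PCR bias, methylation
  sensitivity and allele dropout at the read level are outside scope; the
  heterozygote read-depth rule 1 − 2/2ⁿ is provided analytically.
* The imputer's accuracy is a lower bound on what segregation-aware
  production software achieves at equal marker counts; comparisons across
  panels within this package are the supported use.
* Founders are unrelated and non-inbred by construction; unknown-parent
  groups and metafounders are not implemented.
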