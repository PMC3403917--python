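# Methods

This note documents the statistical machinery in `cwqtl`, the choices
made where the design was genuinely open, and what the synthetic-data
tests do and do not demonstrate about real data.

## Mixed-model association (`cwqtl.mixed_gwas`)

**Model.** `y = Xb + u + e` with `Var(y) = σ²_a S + σ²_e I`, where `S`
is a normalized IBS relatedness matrix and `X` holds an intercept, age,
slaughter-year and slaughterhouse indicators, and optionally the dosages
of conditioning markers. Pseudoheritability is
`h² = σ²_a/(σ²_a + σ²_e)`.

**Marker QC.** SNP are kept when call rate > 95%, MAF > 0.01, and the
1-df Hardy–Weinberg chi-square p-value > 0.001 (observed vs expected
genotype counts at the estimated allele frequency). Monomorphic markers
fall under the MAF rule. Each exclusion is reported with its first
failing criterion.

**Kinship.** Raw IBS is the mean per-marker allele sharing (0, ½, 1
between dosages) over jointly called SNP. Normalization is Gower-style:
the raw matrix is double-centered and rescaled so its trace equals n,
then ridge-repaired to minimum eigenvalue ≥ 1e-8 (ridge logged). The
centering matters: the IBS kernel equals a constant baseline plus
row/column offsets plus a term proportional to the cross-product of
centered dosages (plus a small nonlinear remainder). The projection onto
the fixed-effect complement annihilates the constant and row/column
parts, so without centering the REML ratio is estimated against a
shrunken copy of the genetic covariance and pseudoheritability is
systematically inflated (we measured ≈ 0.84 for a planted 0.64 at any
marker count). With Gower centering the planted heritability is
recovered within ±0.03 on average at n = 1,200.

**REML.** The restricted likelihood is profiled over
`δ = σ²_e/σ²_a` using the nonzero eigenpairs of `M S M` (M the
projector off X): a 100-point log-grid on [1e-5, 1e5] followed by
bounded scalar refinement between the best grid neighbours (tolerance
1e-8 in log δ, ties toward larger δ, i.e. smaller h²). A flat likelihood
(e.g. S = I) is reported as h² unidentifiable. The spectral form is
tested to agree with the direct-determinant restricted likelihood to
1e-8 relative tolerance.

**Association tests.** EMMAX-style two-stage: variance parameters are
fixed at the null fit, each marker is tested by whitening
(`V^{-1/2}` from the eigendecomposition of S) and running a 1-df OLS
F-test on the rotated data; p-values use F(1, n − p) with p counting all
fixed-effect columns including the tested marker. Missing dosages are
mean-imputed per marker. Conditioning markers join the fixed design as
0/1/2 dosages and their own records are flagged collinear. Zero-variance
markers get p = 1 with a flag.

**Summaries.** λ_GC is the median 1-df chi-square equivalent of the
p-values divided by 0.4549; the Bonferroni threshold is α/m; the
variance-explained fraction of a set of conditioned-on loci is
`(h²_full − h²_conditioned)/h²_full`. Note this heritability-drop
fraction is not the strict variance-accounting share
`V_qtl/V_genetic` — conditioning changes the denominator of h² too —
and the package follows the heritability-drop convention throughout.
Pairwise r² between biallelic markers comes from the two-locus EM
haplotype frequencies (`D²/(p_A p_a p_B p_b)`), nan for monomorphic
markers.

## Half-sib interval mapping (`cwqtl.halfsib_qtl`)

Paternal transmission at a marker is deduced from allele content alone:
determined when the sire is heterozygous and exactly one of his alleles
is compatible with the offspring; ambiguous for homozygous sires or when
the offspring carries both sire alleles; a Mendelian-error flag when no
allele is shared. Prob(Q) at a grid position (2-cM default) uses only
the nearest informative marker on each side — exact under Haldane with
no interference — giving `t_L t_R / (t_L t_R + t̄_L t̄_R)` with
transmission terms `(1−r)` or `r` per flank, single-flank decay toward
½, and prior ½ with no information.

The scan F-statistic at each position is
`((RSS₀ − RSS₁)/1)/(RSS₁/(n − p))` for adding the Prob(Q) column to the
covariate design. Permutation thresholds shuffle trait values against
all fixed rows (simple Churchill–Doerge; the covariate–trait association
is deliberately broken as well — a logged caveat) and take empirical
(1−α) quantiles of the profile maxima. Bootstrap confidence regions
resample offspring with replacement, collect profile-peak positions
(leftmost tie-break), and accumulate grid positions by decreasing peak
frequency until the target mass is reached; contiguous runs merge, so
regions may be fragmented — the reason a highest-mass construction was
chosen over percentile intervals, which cannot fragment.

## LD mapping (`cwqtl.ld_mapping`)

Per window of two contiguous markers, haplotype frequencies are
estimated per phenotype group by EM for unphased genotypes (uniform
initialization over observed-allele haplotypes; convergence at max
frequency change < 1e-8 or 1,000 iterations; the observed-data
log-likelihood is asserted non-decreasing every iteration). Frequencies
become integer counts via largest-remainder rounding to 2N per group —
an explicit approximation, since an exact test needs counts. The overall
test is a 2×n Fisher exact test: full enumeration (DFS over fixed-margin
tables) when the candidate-table count is below a budget (2e5 default),
otherwise seeded Monte-Carlo with 1e5 Patefield draws and the add-one
estimator `(1 + hits)/(n_mc + 1)` so p > 0 always. Tracked haplotypes
(e.g. a sire's Q/q alleles per window) additionally get a 2×2 test of
that haplotype vs all others, skipped with an excluded flag when its
count is below 6 in **each** group (the exclusion is a conjunction).
2×2 tests use the standard two-sided hypergeometric rule (scipy),
cross-checked against full enumeration in the tests.

## QTN filtering (`cwqtl.qtn_filter`)

A candidate site passes when (1) all three segregating sires are
heterozygous, (2) the three Q-homozygotes share one homozygous genotype
and the q-homozygote is homozygous, and (3) the q-homozygote's allele
differs from the Q-homozygotes'. A missing call fails the criterion
that needs it (conservative). Criterion 2's shared-genotype reading is
required for criterion 3's "opposite alleles" to be well defined.
Annotation flags candidates intersecting coding or conserved interval
sets (1-based variant vs 0-based half-open BED conventions respected);
synonymous/nonsynonymous classification is accepted as an input table
rather than computed from codons, which would drag in a gene-model
parser out of proportion to its role. The coverage audit reports, per
animal, maximal subintervals of the targets with depth below 4 reads.

## Synthetic data (`cwqtl.synthetic_data`)

**What it emulates.** Paternal half-sib families nested in a general
population (default 60 sires × 20 offspring = 1,200), genome-wide SNP
with block LD (founder haplotypes are mosaics of 12 ancestral
haplotypes with an exponential switch process, LD decaying with cM),
three additive QTL, a polygenic background, fixed environmental
effects, and 15% phenotype-extreme selection with half-sib exclusion.

**Planted QTL.** Allele-substitution effects 28.4/35.3/35.0 kg at Q
frequencies 0.754/0.200/0.115 (≈947 kg² of QTL variance under HWE).
Each QTN is untyped but flanked by tag SNP constructed at r² targets
(1.0/0.85/0.70) against the carrier indicator, with a configurable
floor (0.65) asserted by direct haplotype counting.

**Variance mix.** The polygenic share of phenotypic variance (0.267)
and residual SD (30.6 kg) were chosen once, analytically, so the
planted components give h²_full = 0.636 and h²_conditioned = 0.423 —
i.e. a variance-explained fraction of ≈ one-third on the
heritability-drop scale — with a phenotypic SD ≈ 51 kg, realistic for
carcass weight. The polygenic value is a weighted sum of the genotyped
background SNP (weights i.i.d. normal, rescaled to the target variance)
so the IBS kinship genuinely captures it; the planted tag SNP get zero
weight, because the genetic effect of a QTL region is the QTN itself
and causal weights on its perfect-LD tags would silently inflate the
locus effect beyond the declared truth.

**Meiosis.** Haldane map function with independent crossovers:
transmission switches between adjacent loci are independent Bernoulli
draws at the Haldane recombination fraction, 0.5 across chromosome
boundaries. Dams are unrelated draws from the founder pool; sires take
pool haplotypes without replacement. The paternal haplotype of origin at
every locus is recorded as ground truth for Prob(Q).

**What it does not emulate.** Genotyping error, allele dropout and
microsatellite stutter; ascertainment of chip SNP; selection over
generations (one-generation gene drop only); dominance, epistasis and
genotype-by-environment interaction; linkage-map vs physical-map
discrepancies (1 cM ≡ 1 Mb here); realistic minor-allele-frequency
spectra (base frequencies are uniform on [0.15, 0.85]). Passing tests
therefore demonstrate the correctness and calibration of the estimators
under the declared generating model, not robustness to these real-data
complications.

## Effect estimation and pipeline (`cwqtl.effects`, `cwqtl.cli`)

Allele-substitution effects reuse the GLS scan on a single dosage
column, so `estimate_effect` and `gls_scan` cannot disagree; the SE is
`|β|/√F`. Two-marker Q-haplotype dosages count haplotype copies
directly for phase-unambiguous individuals and resolve double
heterozygotes by the most probable diplotype under the population EM
frequencies, ties toward the smaller Q dosage (conservative). The
pipeline estimates effects with the full-sample kinship (the same
two-stage mixed-model fit as the scan); a leave-one-chromosome-out
kinship helper is provided for users who want to guard against proximal
contamination when the tested locus's tags dominate a small marker
panel. Conditioned pseudoheritability refits REML with the QTL dosages
appended to the fixed effects.

The CLI exposes one subcommand per stage plus `all`; a stage command
runs its dependency closure, every output embeds the config hash and
seed, and identical config + seed yields bit-identical outputs.

## Numerical choices and degenerate inputs

- REML: grid 100 points, refinement tolerance 1e-8 in log δ; ties to
  larger δ. PSD ridge to eigenvalue ≥ 1e-8, logged.
- GLS: per-marker mean imputation; zero-variance markers p = 1,
  flagged; conditioning collinearity flagged, not fatal.
- EM: tolerance 1e-8 on max frequency change, cap 1,000 iterations,
  deterministic uniform start.
- Monte-Carlo 2×n: seed recorded; add-one correction.
- Bootstrap/permutation: seeds explicit; profile-peak ties leftmost;
  permutation quantiles use the "higher" interpolation (conservative).
- Problem sizes in the test suite (50 effect-recovery replicates at
  n = 1,200; null calibration at 5,000 markers; 200 permutation-validity
  and 100 bootstrap-coverage replicates with n_perm = 200 and
  n_boot = 500) were chosen to keep Monte-Carlo error well inside the
  asserted bands while the whole suite stays fast on one CPU.

## Known limitations

- The two-stage (EMMAX-style) approximation fixes variance components
  across markers; for very large single-marker effects an exact
  per-marker REML would differ slightly.
- Prob(Q) uses the nearest informative flank per side; with genotyping
  error (absent in the generator) multi-marker smoothing would be more
  robust.
- Haplotype counts enter exact tests after largest-remainder rounding
  of EM frequencies; the resulting p-values inherit the estimation
  uncertainty of the EM step.
- The SE of the allele-substitution effect ignores uncertainty in the
  variance components (standard for GLS-based GWAS); in our replicate
  checks it is, if anything, conservative.
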