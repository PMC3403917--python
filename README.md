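# cwqtl

Multi-stage QTL discovery for carcass weight in cattle, as a tested,
reusable Python pipeline. The package implements the full analysis chain
used to dissect a quantitative trait in paternal half-sib cattle
populations:

1. **Mixed-model GWAS** — marker QC (call rate, MAF, Hardy–Weinberg),
   an IBS genetic relatedness matrix, REML variance components via a
   one-time spectral decomposition, and per-marker generalized
   least-squares F-tests (the EMMAX-style two-stage approximation), with
   conditioned re-scans, genomic inflation (λ_GC), Bonferroni
   thresholds, and pairwise LD r².
2. **Half-sib regression interval mapping** — paternal-allele deduction
   from multi-allelic markers, Prob(Q) along a 2-cM grid under the
   Haldane map function, F-statistic profiles, permutation significance
   thresholds, and bootstrap confidence regions (possibly fragmented).
3. **Two-locus LD mapping** — EM haplotype-frequency estimation per
   phenotype group over sliding pairs of contiguous microsatellites,
   with 2×n and 2×2 Fisher exact tests and a low-count exclusion rule.
4. **Candidate-QTN filtering** — the three segregation-consistency
   criteria over a 7-animal resequencing panel (3 heterozygous sires,
   3 Q-homozygotes, 1 q-homozygote), interval annotation, and a
   sequencing-depth audit.
5. **Effect estimation** — allele-substitution effects (kg per Q allele)
   from QTN or two-marker Q-haplotype dosages through the same GLS
   machinery, plus pseudoheritability before/after conditioning and the
   variance-explained fraction.

No cattle data ship with the package; a first-class synthetic-data
generator (`cwqtl.synthetic_data`) creates pedigreed populations with
block LD, planted QTL tagged by SNP in strong LD, a polygenic background
realized at the genotyped SNP, fixed environmental effects, and
phenotype-extreme selection, so every stage is testable end to end with
known ground truth.

## The model

Phenotypes follow the linear mixed model

```
y = X b + u + e,     Var(y) = σ²_a S + σ²_e I
```

where `X` holds the fixed effects (age, slaughter year, slaughterhouse,
plus any conditioning marker dosages), `S` is the normalized IBS
relatedness matrix, and pseudoheritability is
`h² = σ²_a / (σ²_a + σ²_e)`. REML profiles the restricted likelihood
over `δ = σ²_e/σ²_a` using the spectral decomposition of `S` projected
off `X`; each marker is then tested with a 1-df GLS F-test holding the
variance parameters fixed. The half-sib scan regresses phenotype on
Prob(Q) — the probability the sire transmitted his Q haplotype at a
position, computed from the nearest informative flanking markers with
Haldane recombination fractions — and compares residual sums of squares
with and without the Prob(Q) column.

## Worked example

```python
import numpy as np
from cwqtl import mixed_gwas as mg, synthetic_data as sd
from cwqtl.effects import estimate_effect

cfg = sd.default_config(seed=1)          # ~1,200 steers, 3 planted QTL
genotypes, phenotypes, truth = sd.simulate_population(cfg)

qc_genotypes, _ = mg.snp_qc(genotypes)
kinship = mg.ibs_kinship(qc_genotypes)
X = mg.build_covariate_matrix(phenotypes)
vc = mg.reml_fit(phenotypes, X, kinship)
records = mg.gls_scan(phenotypes, X, kinship, qc_genotypes, vc)
threshold = mg.bonferroni_threshold(0.05, len(records))

print(f"pseudoheritability h2 = {vc.h2:.3f}")
print(f"Bonferroni threshold  = {threshold:.3g}")
top = min(records, key=lambda r: r.p_value)
print(f"top marker {top.marker_id}: beta = {top.beta:.1f} kg, p = {top.p_value:.2g}")

vc_cond = mg.reml_fit(phenotypes, np.column_stack([X, truth.qtl_dosage]), kinship)
frac = mg.variance_explained_fraction(vc.h2, vc_cond.h2)
print(f"h2 after conditioning = {vc_cond.h2:.3f}; QTL share = {frac:.2f}")

for qi, q in enumerate(cfg.qtl_specs):
    est = estimate_effect(phenotypes, X, kinship, vc, truth.qtl_dosage[:, qi])
    print(f"QTL {qi + 1}: {est.effect_kg_per_allele:.1f} +/- "
          f"{est.standard_error:.1f} kg/allele (planted {q.effect_kg_per_allele})")
```

Output:

```
pseudoheritability h2 = 0.598
Bonferroni threshold  = 0.000111
top marker tag_q1_0: beta = 34.8 kg, p = 1.8e-16
h2 after conditioning = 0.423; QTL share = 0.29
QTL 1: 24.1 +/- 4.1 kg/allele (planted 28.4)
QTL 2: 34.9 +/- 4.2 kg/allele (planted 35.3)
QTL 3: 36.0 +/- 4.8 kg/allele (planted 35.0)
```

The scan recovers the three planted loci genome-wide significantly; the
heritability drop after conditioning on the three QTL dosages attributes
roughly one-third of the genetic variance to them, and each
allele-substitution effect lands within two standard errors of the
planted value. The full pipeline is also exposed as a CLI:

```
cwqtl all --seed 1 --outdir runs/demo        # or any single stage:
cwqtl gwas --seed 1 --outdir runs/demo       # runs its dependency closure
```

Each run writes per-stage TSVs, a JSON run summary, and a log with the
seeds and config hash; identical config + seed gives bit-identical
outputs.

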