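# arraykit

A toolkit for designing and evaluating population-optimised SNP genotyping
arrays, and for running the downstream GWAS bookkeeping such arrays exist
for.  It is aimed at statistical geneticists who want to prototype or audit
biobank-scale array designs — which candidate variants genotype reliably,
which tagging markers buy the most imputation-based genome coverage, and
which association signals survive the standard selection rules — without
access to proprietary design pipelines or restricted cohort data.  Every
stage runs on synthetic phased panels generated by the package itself.

## What it computes

**Screening.** Candidate variants are validated against a truth platform by
the dosage r² / Fst rule: a variant validates iff

- r² = corr(screen dosages, truth genotypes)² ≥ 0.7, and
- Fst = (H_T − H_S)/H_T ≤ 0.025 (Nei's estimator over the two call sets),

with standard variant QC (call rate ≥ 95 %, exact Hardy–Weinberg P ≥ 10⁻⁶,
MAF ≥ 1 % or MAC ≥ 2) and an A/T–C/G strand-ambiguity exclusion policy.
The Hardy–Weinberg test is the exact conditional test on the heterozygote
count given allele totals.

**Design.** Tagging content is greedy maximum-coverage selection over
pairwise haplotype r²: a target (MAF ≥ 1 %) counts as covered when some
selected marker within ±250 kb has r² ≥ 0.8 with it.  Functional content
admits nonsynonymous variants with MAF ≥ 0.1 %, or rarer ones predicted
damaging by SIFT or PolyPhen-2 (HDIV/HVAR).  Everything is assembled into a
manifest with per-category counts (categories may overlap; the total is the
distinct-entry count).

**Evaluation.** A minimal Li–Stephens haplotype-copying HMM imputes all
reference variants from the manifest content; per-variant quality is the
IMPUTE-class info score

info = 1 − Σᵢ(fᵢ − eᵢ²) / (2N·θ̂(1−θ̂)),  eᵢ = pᵢ₁ + 2pᵢ₂,  fᵢ = pᵢ₁ + 4pᵢ₂,

and imputation-based genomic coverage is the fraction of reference variants
(MAF ≥ 1 %) typed directly or imputed at info ≥ 0.8, overall, by MAF
stratum (≥ 5 %, 1–5 %) and per 5 Mb window.  Duplicate/cross-platform
concordance and shared-content counting (identical chrom/pos/alleles)
round out the report.

**GWAS.** Friedewald LDL (TC − HDL − TG/5, masked at TG > 400 mg/dL),
ln-transformed traits (except total cholesterol), additive OLS association
with age/sex/area covariates, post-imputation filtering (info ≥ 0.4,
MAF ≥ 1 %), lead selection (P ≤ 5×10⁻⁸, MAF ≥ 1 %), nonsynonymous candidate
selection inside qualifying loci (locus lead P ≤ 5×10⁻⁷ plus a distinct
supporting signal P ≤ 10⁻⁴), and novelty annotation against a known-signal
catalog within a 1 Mb centred window.

## Worked example

```sh
arraykit simulate --out-dir demo --seed 3 --n-variants 400 --n-haplotypes 200
arraykit screen   --screen-vcf demo/genotypes.vcf --truth-vcf demo/genotypes.vcf \
                  --out-dir demo/screen
arraykit design   --panel-vcf demo/panel.vcf --annotations demo/annotations.tsv \
                  --validation demo/screen/validation_report.tsv --budget 40 \
                  --out-dir demo/design
arraykit evaluate --panel-vcf demo/panel.vcf --manifest demo/design/manifest.tsv \
                  --out-dir demo/eval
```

which prints

```
QC kept 397/400; validated 399/400
manifest: 113 markers (tag coverage 0.101 of 396 targets)
coverage overall 0.2886 (common 0.2992, low-frequency 0.1765)
```

Reading: 3 of 400 simulated variants failed QC and 1 failed dosage-r²/Fst
validation; the designed array holds 113 markers (40 tags plus functional
content); imputing 10 held-out samples from those markers captures ~29 % of
common reference variants at info ≥ 0.8 on this deliberately small panel —
coverage at desk scale is far below the >90 % a real array achieves on
human LD, but it responds to budget and LD exactly the way the real
quantity does.  `arraykit assoc` and `arraykit gwas-select` run the
association layer the same way:

```
planted var000398; top hit var000398 (P=1.03e-05)
```

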