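# Methods

This note records the models behind each stage, the defaults and why they
were chosen, and what the synthetic data does and does not establish.

## Data model

Variants are identified by `(chrom, pos, unordered allele pair)`.  Matching
across platforms requires literally identical positions and alleles; strand
flips are deliberately *not* reconciled, so an A/G marker never matches a
T/C one.  Indels are keyed the same way as SNVs — how indels should be
matched across platforms is genuinely ambiguous, and position-plus-alleles
is the least surprising convention.  Coordinates are 1-based; genomic
windows are half-open `[start, start + len)`.  Missing hard calls use a
dedicated sentinel (−1) and are never conflated with homozygous-reference.

## Synthetic panels

`simulate_panel` builds phased haplotypes as **founder mosaics**: founder
haplotypes are constructed first, and each output haplotype copies from a
random founder, switching to a fresh one with per-bp probability
`switch_rate` (default 1e-5, i.e. ~100 kb copying blocks).  A mosaic was
chosen over a full coalescent because tunable block LD is the only property
the downstream stages need, and it costs almost nothing.

Two details matter:

* **Spectrum fidelity.**  Founder allele counts are exact:
  `round(p * n_founders)` carriers (at least one), with `p` drawn from the
  requested MAF spectrum (default uniform on [0.01, 0.5]).  The realized
  panel MAF then deviates from the requested draw only by quantisation
  (≤ 1/2F) and founder-sampling noise (≈ √(pq/H)); at the default
  F = 100 founders and H = 1000 haplotypes the Kolmogorov–Smirnov distance
  to the requested spectrum stays well under 0.1.
* **Founder-level LD.**  Carriers are a random contiguous arc of a fixed
  circular ordering of the founders.  Overlapping and nested arcs make
  founder haplotypes themselves strongly correlated (any two sites have
  founder-level r governed by their arc overlap), and the output LD between
  two sites is that founder-level correlation attenuated by the probability
  that no founder switch occurred between them.  With independent random
  carrier sets instead, output r² would be bounded near 1/F everywhere and
  no tag could ever reach the r² ≥ 0.8 coverage rule — the arc construction
  is what makes block LD real.

`diverge_populations` redraws each variant's frequency from a
Balding–Nichols `Beta(p(1−F)/F, (1−p)(1−F)/F)` and resamples haplotypes
site-independently: a one-parameter, well-understood Fst knob for testing
the cross-platform frequency screen.  `simulate_genotyping` adds symmetric
genotyping error (a wrong call is either of the two other genotypes with
equal probability) and independent missingness, with blind duplicates
re-drawing both from a shared truth; the closed-form duplicate agreement
(1−e)² + e²/2 is what the concordance tests check against.
`simulate_phenotypes` is exactly the additive analysis model: Σβ·dosage +
covariate terms + Gaussian noise, mean-imputing missing dosages.

What the generator does **not** emulate: realistic recombination maps or
demographic history, genotype-intensity cluster artefacts, linked (rather
than site-independent) population divergence, and correlated
missingness.  Tests passing on this substrate show the algorithms are
correct and calibrated, not that a specific coverage or concordance level
would be attained on real human data.

## Screening

* **Hardy–Weinberg**: exact conditional test — the p-value is the total
  probability of heterozygote counts (given allele totals) no more probable
  than the observed one.  No mid-p correction, since only a hard threshold
  (P < 10⁻⁶) consumes it, and the plain exact test is the field standard
  for rare variants.  Implementation detail: for ≤ 32 diploids the
  distribution is computed in exact integer arithmetic (ties are then
  decided exactly); beyond that, log-gamma arithmetic with a 1e-9 log-space
  tie tolerance.  Both regimes are checked against a rational-arithmetic
  enumeration oracle.
* **Dosage r²** is sign-blind (squared Pearson correlation), so a perfectly
  allele-flipped assay scores 1.0; no effect-direction check is layered on
  top because the validation rule is defined through r² alone.  Constant
  vectors raise an error rather than returning 0 — an undefined correlation
  is not evidence of a bad assay.
* **Fst** defaults to Nei's (H_T − H_S)/H_T on the two call sets treated as
  two populations, defined as 0 when H_T = 0.  It is deterministic,
  closed-form testable, and symmetric.  A frequency-based Weir–Cockerham
  variant is available behind `ThresholdConfig.fst_estimator` for users who
  want sample-size weighting; it is not the default because the screening
  comparison has essentially equal n on both sides.
* Validation thresholds (r² ≥ 0.7, Fst ≤ 0.025) are inclusive on both
  boundaries, as are the QC thresholds (call rate ≥ 0.95, HWE P ≥ 1e-6,
  MAF ≥ 0.01, MAC ≥ 2).

## Design

Tag selection is greedy maximum coverage over a windowed pairwise-r² index
(window ±250 kb, coverage rule r² ≥ 0.8).  Pairwise r² lower-bounds the r²
achievable by imputation from the selected markers, so it is the standard
transparent proxy for proprietary "imputation-aware" objectives.  Greedy
max-coverage carries the classical (1 − 1/e) optimality guarantee, which
the tests verify against exhaustive optima on small instances.  Ties break
to the higher-MAF candidate, then the smaller position, making selection
fully deterministic.  Targets below 1 % MAF are excluded from the tagging
objective — rare content is the functional module's job.

A selected tag is **indispensable** (and may therefore stay on the array
despite A/T or C/G alleles) iff it covers some target that no other
candidate reaches at r² ≥ 0.8.  The per-category budget split on real
arrays reflects platform capacity, not an algorithmic rule, so `budget` is
a plain user parameter.

## Evaluation

The imputation engine is a haploid Li–Stephens copying HMM run per phased
target haplotype: hidden state = copied reference haplotype, switch
probability `1 − exp(−rho·d)` between adjacent sites (the transition family
composes exactly, so running over all sites equals typed-site-only
propagation), emission `1−eps` / `eps` at typed sites, uniform elsewhere.
The output at every site is the posterior expectation of the *copied*
reference allele; the two haploid posteriors of a diploid sample are
independent given phase and convolve into the genotype triple.  Defaults
`rho = 1e-6`/bp and `eps = 1e-3` give switch probabilities of a few percent
across typical marker gaps.  Unphased targets are out of scope by design
(targets are simulated phased); this keeps the exhaustive-path oracle exact
and the engine O(K) per site.

The info score is the observed/expected dosage-variance form given above:
1 for hard calls, 0 for posteriors equal to the HWE marginal, defined as 1
when θ̂ ∈ {0,1}.  Values are reported unclamped (they can be negative) and
the coverage threshold compares the raw value.

Coverage counts typed variants as covered (info 1): genomic coverage
measures variation captured directly *or* through LD/imputation, and the
denominator keeps typed variants for the same reason.  Windows are
half-open 5 Mb bins from position 1 per chromosome; a final partial bin
reports its own mean of the binary covered indicator.

## GWAS

Friedewald LDL (TC − HDL − TG/5, mg/dL) is missing when any input is
missing or TG exceeds 400 mg/dL (strict: TG = 400 still computes).  All
traits except total cholesterol are ln-transformed; lipid-lowering and
liver-medication flags blank their trait groups *before* transformation,
and LDL is recomputed from raw inputs first.  Medication lists themselves
are caller-supplied flags.

Association is OLS of the transformed trait on dosage with intercept, age,
sex (0/1) and one-hot recruitment area (first level reference — documented
so betas are reproducible).  Single-variant fits go through statsmodels;
the genome scan is a Frisch–Waugh–Lovell residualisation that is
algebraically identical per variant and is cross-checked against the
single-variant path in tests.

Signal selection: leads at P ≤ 5×10⁻⁸ with MAF ≥ 1 % (the ≤ boundary is
deliberate and unit-tested); nonsynonymous candidates need P < 10⁻⁴
(strict) and MAF > 0 inside a qualifying locus.  A locus is a ±500 kb
window — half the 1 Mb novelty window, the only explicit window the
selection rules define — around any variant with P ≤ 5×10⁻⁷ accompanied by
at least one *distinct* supporting variant at P ≤ 10⁻⁴ ("a lead signal and
one or more supporting signals" implies plural variants).  The
"MAF > 0" clause uses the discovery-sample frequency.  Novelty: a hit is
known iff a same-trait catalog entry lies within the 1 Mb centred window
(inclusive at ±500 kb); other-trait entries never mask novelty.
Replication is a join on variant and trait with a two-sided P < 0.05 and
same-direction success rule.

Nonsynonymous content counting supports both damaging rules — ≥ 1 predictor
or more than one predictor — because the two conventions coexist in
published array comparisons; the population-observed count additionally
requires population MAF > 0.

## Problem sizes and calibration checks

The heavyweight checks run at deliberately desk-scale sizes chosen so the
whole suite stays fast while keeping every statistical bound meaningful:
exhaustive HWE agreement at totals ≤ 30; r² oracles on hundreds of random
instances; end-to-end design→evaluate on a 5,000-variant, 240-haplotype
panel (coverage must rise from budget 50 to 200); GWAS calibration with a
5,000-variant null genome (lead set empty in ≥ 95/100 seeds) and 2,000
null variants at n = 500 (p-value KS distance < 0.05).

The planted-signal recovery study uses n = 2,000 samples and one
nonsynonymous causal variant inside a 30-variant high-LD block.  The
planted effect is sized by a power analysis, not taken from a typical GWAS
hit: recovering the variant through the candidate rule requires the locus
to contain a lead at P ≤ 5×10⁻⁷, i.e. |Z| ≥ 5.03, so ≥ 90 % per-seed power
needs non-centrality √(n·VE/(1−VE)) ≈ 6.4, giving VE ≈ 2 %.  A 1 %-VE
effect (non-centrality ≈ 4.5) would be recovered in only ~a third of seeds
— the demonstration is about the selection machinery, so the effect is
deliberately placed where the machinery has power.

## Known limitations

* The Weir–Cockerham option uses the frequency-only form (no observed
  heterozygosity term); Nei's estimator is the supported default.
* The LS engine assumes phased targets and a single reference panel; no
  pre-phasing, panel selection, or X/Y/MT handling.
* Coverage numbers on synthetic panels are not comparable to human-panel
  values: the mosaic generator's LD is far weaker than real human LD at
  tagging-relevant distances unless configured otherwise.
* No relatedness adjustment, genomic control, meta-analysis or conditional
  analysis in the association layer.
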