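# Methods

This note documents the models and procedures implemented in `nampower`,
the assumptions behind them, and the choices made where the design was
genuinely open.

## Founder panels

Two routes produce the panel of homozygous inbred founders (allele dosage
0/2) plus one designated common parent.

**Empirical route.** A genotype matrix is filtered to markers with minor
allele frequency ≥ 5 % (computed over non-missing calls) and missingness
≤ 20 %; remaining missing calls are excluded from frequency and LD
computations, never imputed (the simulation route produces none). Genetic
positions missing from the map are derived from physical positions at
0.674 Mb/cM, the linear conversion rate appropriate for the *B. napus*
genome. A small marker set can be expanded to a genome-wide panel:
markers are laid out evenly, per-chromosome counts proportional to
chromosome length (largest-remainder rounding so counts sum exactly), and
each new marker copies the founder alleles of one original SNP drawn
uniformly *with replacement* (the target count typically exceeds the
source count). Because the copied SNPs carry the original inter-marker LD
regardless of their new positions, the panel is passed through long-term
random mating — random union of gametes, selfing allowed, constant
population size — which erodes LD at a rate set by the new genetic map
while conserving expected allele frequencies; homozygous founder-like
lines are then re-derived as doubled haploids (one gamete per individual,
doubled). The default protocol is 3000 individuals for 250 generations;
any size/length can be configured.

**Synthetic route** (`synth_founders`). Per marker, an ancestral frequency
p₀ ~ U(0.15, 0.85) is split into two panel frequencies p₀ ∓ s·δ·min(p₀,1−p₀)
with a random sign s and the divergence parameter δ ∈ [0,1] (default 0.4).
Panel 1 emulates adapted and panel 2 exotic germplasm; the common parent is
drawn from panel-1 frequencies (an elite adapted line). Markers failing the
5 % MAF floor across all founders are re-drawn. Founder genotypes are
independent across markers, so the synthetic panel carries **no ancestral
LD**: all LD in the derived NAM populations is generated by linkage during
the crosses. That is the LD that drives joint mapping, but it means the
synthetic route does not reproduce the short-range ancestral LD decay of a
real diversity panel; the LD-decay regression applied to synthetic
*founders* estimates an essentially flat (unlinked) profile. Real data
also differ in having related founders, genotyping error and missingness.

## Meiosis and mating designs

Recombination follows Haldane's model: crossover counts per chromosome are
Poisson(length/100), positions uniform in cM, no interference. At marker
resolution this is implemented as independent Bernoulli "switch" events
between adjacent markers with probability r = (1−e^(−2d/100))/2 — exactly
equivalent under no interference, and vectorisable over whole populations.
`simulate_gamete` also provides the literal crossover construction for a
single parent; both paths are tested against the Haldane recombinant
fraction.

Designs (each subpopulation = one founder × common parent):

* **DH-NAM** — one doubled haploid per F₁ gamete; dosages ∈ {0,2}.
* **BC-NAM** — one backcross to the common parent (each BC₁ from an
  independent F₁ gamete; a single F₁ plant suffices since the parents are
  homozygous), then two selfing generations by single seed descent (one
  offspring per lineage per generation): BC₁S₂. Closed forms at
  donor-segregating loci: common-parent allele frequency 3/4,
  heterozygosity (1/2)·(1/2)² = 1/8.
* **RIL-NAM** — F₁ selfed four generations by SSD (F₅); residual
  heterozygosity (1/2)⁴ = 1/16 at segregating loci.

Unbalanced designs draw subpopulation sizes from Normal(total/n, sd),
round, clip at 1, and nudge random subpopulations by ±1 until the total is
exact. Subset scenarios are pure row selections.

## Traits

QTL positions are sampled without replacement from the marker set; effect
magnitudes follow the geometric series 100(1−a)[1, a, a², …] assigned to
QTLs in random order, with the canonical pairings a = 0.90 / 0.96 / 0.99
for 25 / 50 / 100 QTLs. One allele per QTL (chosen at random) carries the
full homozygous effect q, the other zero; heterozygotes are worth q/2 — a
purely dose-additive model, the minimal extension needed for the
heterozygotes of BC₁S₂ material since only homozygous founder effects are
defined by the series.

**QTL × genetic background interactions.** A chosen number of QTLs each
interact with a set of distinct non-QTL background markers through
bilinear terms on mean-centred dosages, one N(0,1) raw coefficient per
pair. All coefficients are rescaled by the single constant c solving
Var(c·I)/Var(A + c·I) = ρ for the target proportion ρ — a quadratic in c
solved in closed form with population (ddof 0) moments, so the realised
proportion is exact to numerical precision. Centring constants and the
scaling are computed in the realised mapping population, where the stated
proportion should hold; interacting QTLs keep their additive effects. The
interaction count settings follow the paired grid (1, 5, 10, 25 QTLs ×
background markers).

**Phenotypes.** y = g + e with e ~ N(0, (1−h²)σ_g²/h²), where σ_g² is the
variance of genotypic values among the parental inbreds of the scenario
(design founders + common parent), including interaction terms when
present. h² = 1 gives noise-free phenotypes. By construction the realised
founder-panel heritability equals h².

## Joint QTL mapping

Dosage is coded 0/1/2 copies of the alternate allele. The base design
always contains the subpopulation indicator block (which spans the
intercept). Nested models (S1/J1) give the marker — and each cofactor —
one column per subpopulation *in which it segregates*; across models
(S2/J2) one pooled column. The p-value of a marker is the F-test of full
vs reduced residual sums of squares, with degrees of freedom taken from
realised design ranks, so aliased columns degrade gracefully. Markers
monomorphic in the whole population, or whose term is entirely aliased
with the base, are flagged untested.

Implementation: markers are grouped by their excluded-cofactor set; per
group, an orthonormal basis of the base model (SVD, rank-tolerant) is
computed once and phenotype and marker columns are residualised against
it (Frisch–Waugh), which is algebraically exact and independent of
execution order. Rank tolerances for the residualised marker block are
anchored to the pre-residualisation column scale so that numerically
annihilated (aliased) columns are recognised. Tests verify agreement with
a brute-force OLS + F oracle to 1e-10.

**Cofactor selection.** Chromosomes are cut into half-open 1.5 cM
segments. Method 1 screens one uniformly-random polymorphic marker per
segment; method 2 re-screens all markers of segments holding a method-1
cofactor. The screen is an L1-penalised (LASSO) regression of the
subpopulation-mean-centred phenotype on the standardised candidate
dosages, with the penalty minimising 10-fold cross-validated error
(shuffled, seeded folds); markers with non-zero coefficients at that
penalty become cofactors. Centring the phenotype per subpopulation mirrors
the u_f terms of all mapping models. Cofactor selection is recomputed per
simulated trait.

**Degrees-of-freedom budget.** The cross-validated penalty can admit more
cofactors than a small population supports — in the nested models each
cofactor costs one column per segregating subpopulation, and the base
design can approach the sample size. The scan therefore enforces a
budget: the base model must leave room for the widest possible marker
term plus a minimum residual df of max(30, n/10); if the admitted
cofactors would overrun it, the weakest (smallest absolute LASSO
coefficient) are shed first, deterministically. At full-scale sample
sizes (thousands of individuals) the budget never binds; at desk scale it keeps the nested composite
model estimable instead of silently untestable.

**Exclusion rules.** When marker q is tested, cofactors on the same
chromosome within ±5 cM are dropped from its model. A cofactor whose
genotype column is *identical* to q is treated as q itself (the c ≠ q rule
at genotype level) and likewise dropped, keeping the test well-defined.

## Power estimation

For each scan, the threshold at an empirical type-I-error rate α\* is the
lower empirical α\*-quantile (order statistic at ⌈α\*·n⌉) of the non-QTL
marker p-values; a QTL counts as detected when its p-value is *strictly*
below the threshold (ties conservatively not detected). Untested markers
are excluded from both the non-QTL pool and the QTL denominator. The α\*
grid is {0.5, 0.1, 0.05, 0.01, 0.001, 1e-4, 1e-5} (0.05 included as in the
reported tables). D(%) is averaged over detected QTLs only, with the
estimate converted to the homozygote-difference scale (2× the fitted
dosage slope, oriented to the simulated effect allele; nested models
average the per-subpopulation estimates). Across runs the table reports
mean power, SE = sd/√runs, and the mean nominal α (the average of per-run
thresholds — the averaging convention chosen here, since threshold-vs-rate
averaging is not uniquely determined by the protocol).

## The scaled-down power study

A full-scale experiment (25 runs × 10,000 SNPs × up to 5,000
individuals × 4 models) is not desk-scale. The packaged study
(`nampower.experiments.scaled_power_experiment`) keeps its structure at a
reduced size: BC-NAM, 10 subpopulations × 50 individuals, 1,000 markers,
25 QTLs (a = 0.90), 10 runs, cofactor method 1. The synthetic genome is
10 chromosomes × 100 cM — chosen to preserve the *per-QTL genome length*
(≈ 40 cM of map per QTL) of the full-scale conditions, the ratio that
governs how strongly admitted cofactors overlap the tested QTL in linked
populations; compressing the genome instead (same markers, fewer cM)
makes every cofactor a close neighbour of every QTL and erases the
composite models' advantage as a pure scaling artefact. Scenario variants
(heritability 0.5 vs 0.8; interaction proportions 0.05/0.15/0.25 with
5 QTLs × 5 background markers) share founders, populations and
architectures — and, via a dedicated noise stream, the same phenotype
noise normals — through label-derived child seeds, so cross-scenario
comparisons are paired (common random numbers). Orderings and trends are
assessed at α\* = 0.01. Under interaction-inflated traits the
cross-validated LASSO admits ~100 cofactors, which at n = 500 pushes the
nested model hard against its df budget (the guard sheds most of them);
the trend variants therefore use the across-subpopulation composite model
J2, whose df cost is one column per cofactor; the trends themselves are
expected to be model-independent.

What passing shows — and does not. The scaled study demonstrates the
orderings and trends under linkage-only LD, balanced designs and clean
genotypes; it does not quantify power at full scale (absolute
power at n = 500 is necessarily lower), nor model behaviour under
ancestral LD, genotyping error, or selection during line development.
The smallest contrast — purely additive vs a 5 % interaction share — is
of the same order as the 10-run simulation noise even with pairing, so
its direction can flip between master seeds; the larger interaction
contrasts and the model orderings are stable.

## Numerical choices

* LD-decay regression: Hill–Weir drift–recombination expectation with the
  finite-sample term, E[r²] = ((10+C)/((2+C)(11+C)))·(1 + ((3+C)(12+12C+C²))
  /(n(2+C)(11+C))), C = k·distance; k fitted by least squares in log k;
  the r² = 0.1 crossing by bracketing + Brent to 1e-6 of the distance
  unit (the curve is monotone; if it never reaches 0.1 the distance is
  reported infinite with a flag). r² itself is the squared dosage
  correlation — identical to haplotype r² for fully homozygous lines and
  well-defined for partially heterozygous BC₁S₂ material. Only
  same-chromosome pairs enter the regression, subsampled to a seeded cap
  (default 200,000) for large panels.
* Modified Rogers distance: sqrt of the mean squared within-line
  allele-frequency difference over shared non-missing loci; Euclidean, so
  classical-scaling PCoA (via scikit-bio) applies; variance proportions
  are taken over positive eigenvalues.
* Randomness: one master seed; every stage draws from a child generator
  keyed by (seed, stage label, run index) via CRC-32-hashed labels, so
  adding a stage never perturbs another stage's stream and single runs are
  reproducible in isolation.

## Known limitations

* No dominance, no QTL×QTL epistasis, no genotype×environment terms.
* No selection, sterility or compatibility effects during population
  development; exactly one backcross generation for BC-NAM.
* Marker-based tests only (no interval positions between markers), no
  kinship/mixed-model correction, and only the empirical-quantile
  thresholding protocol (no permutation thresholds or FDR).
* The nested models' degrees-of-freedom demands make them unreliable below
  a few hundred individuals when many cofactors are admitted.
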