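# Methods

This note documents the models, algorithms and design choices behind
`sspig`, in the order a run executes them. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Population simulator (`sspig.simdata`)

The simulator generates the statistical structure the analysis assumes,
not a biologically detailed pig genome.

**Pedigree.** Discrete, non-overlapping generations; each mating produces a
full-sib litter of fixed size; sires and dams are drawn from the previous
generation. Under `truncation_selection`, parents are the top
`selection_proportion` of their generation ranked on a latent infinitesimal
breeding value (founders ~ N(0,1), offspring = parent mean + Mendelian
sampling with variance ½). Selecting on a latent index rather than the
marker-based TBV keeps pedigree simulation independent of the gene drop
while still concentrating ancestry (small effective size). An optional
crossbred cohort mates line sires to a second founder pool; crossbreds are
phenotyped for the crossbred-recorded traits only and are never sequenced.

**Markers and LD.** Markers are evenly spaced (so 55-kb windows contain a
predictable count); the chip is every k-th marker, mimicking evenly spaced
commercial chips. Founder haplotypes follow a first-order Markov chain
along each chromosome: allele frequencies are drawn per marker from
`founder_maf_range`, and the conditional Bernoulli probability is set so
adjacent markers have correlation `ld_decay_rho` (clipped to [0,1], which
slightly distorts extreme marginals). This gives controllable *local* LD —
enough to make window-based preselection meaningful — without coalescent
genealogies, which the analysis does not need. Descendants inherit
recombinant gametes: crossover counts are Poisson with 1 cM ≈ 1 Mbp and no
interference, positions uniform.

**QTL and phenotypes.** `n_qtl` markers get per-trait effects drawn from a
multivariate normal with the configured genetic correlations, then rescaled
per trait so the founder additive variance `2Σpⱼ(1−pⱼ)aⱼ²` equals the
target genetic variance. Phenotypic variance is 1 per trait, so
heritability, litter fraction and residual fraction partition it directly.
A record is CG effect + optional covariate term + TBV + litter effect +
residual; litter and residual draws respect the block-structural zeros
between purebred- and crossbred-recorded traits. Crossbred-trait effects
reuse the purebred QTL with effects correlated at
`purebred_crossbred_corr` (default 0.7).

**What the simulator does not emulate:** imputation error and genotype
uncertainty (genotypes are clean 0/1/2 calls), varying marker density,
selection on estimated breeding values across generations, maternal
effects, and realistic genome maps. Passing tests therefore demonstrate the
*methods* behave correctly under the assumed generative model, not that any
particular field dataset would show the same gains.

## Quality control (`sspig.qc`)

Marker rules, evaluated on the input matrix (not sequentially):
monomorphic; call rate < 0.90; MAF < 0.01; and a deviation between observed
and Hardy–Weinberg-expected genotype-class frequencies > 0.15, taken as the
max over the three classes (the statistic is not pinned down by convention,
so the strictest reading is used). Exclusion counts attribute each marker
to the first rule that fires, in that order. Individuals with more than 10%
missing calls are removed (strict inequality). An extra MAF ≥ 0.023 rule
applies to imputed-sequence panels, reflecting its post-imputation origin.
Parent–progeny conflicts are opposing homozygotes; an individual whose
conflict rate with a genotyped parent exceeds 1% (configurable — no
standard value exists) is flagged. `harmonize_animal_sets` intersects the
QC survivors across panels so every scenario within a comparison uses the
same animals.

## Relationship engine (`sspig.relmat`)

- `A⁻¹`: Henderson's rules with inbreeding from the Meuwissen–Luo ancestor
  walk; sparse CSR output.
- `A22`: obtained by sparse solves of `A⁻¹X = E` on the genotyped columns
  (full ancestral paths, the dense A never formed). The recursive-kinship
  tabular route exists separately and serves as the test oracle.
- `G`: VanRaden method 1 with observed allele frequencies among the
  genotyped animals (configurable to supplied frequencies); the weighted
  version inserts the diagonal D.
- Tuning solves the exact 2×2 system (additive constant a on all cells plus
  scale b) matching mean diagonal and mean off-diagonal of G to A22 — the
  two-parameter convention; blending adds 5% A22 by default, which also
  guarantees positive definiteness in practice.
- `dimensionality_98`: smallest k whose top-k eigenvalues reach 98% of the
  (negatives clipped) total — the criterion used to size APY cores.
- APY: stores `G_cc⁻¹`, `P = G_cc⁻¹G_cn` and the noncore diagonal
  `mᵢ = gᵢᵢ − g_ic G_cc⁻¹ g_ci`; the inverse acts as an operator and is
  never materialized (a `to_dense` exists for tests). `mᵢ ≤ 1e−10` raises —
  it means a noncore animal is fully explained by the core, which blending
  prevents. Core animals are a uniform random draw of size
  `dimensionality_98` of the chip-based G, drawn once per line/seed and
  reused across panels for comparability. APY replaces direct inversion
  above a configurable genotype count (2000 at desk scale). The approximation
  guarantee tested is at the GEBV level: solutions using the APY inverse
  correlate ≥ 0.99 with those from the direct inverse; the raw action of the
  two inverses on random vectors agrees much less, being dominated by
  near-null directions.
- `H⁻¹` is a lazily combined operator: `A⁻¹v` plus the scattered genotyped
  correction `(G⁻¹ − A22⁻¹)v₂`.

## GWAS (`sspig.gwas`)

Single-SNP mixed linear model with the spectral transformation: one
eigendecomposition of (blended) G diagonalizes the covariance, the REML
profile over the variance ratio is a 1-D bounded optimization (ratio capped
at 1e±6, which also handles the zero-residual limit), and each marker is
then tested by GLS with the null covariance held fixed — the EMMAX-style
approximation, standard for this use and orders of magnitude faster than
per-marker REML. The scanned marker is not removed from G (no
leave-one-chromosome-out; the source protocol gives no indication of it).
The response is the phenotype, with contemporary group (and covariate)
entering as fixed effects; monomorphic markers are flagged with p = 1.
Wald p-values come from the standard normal.

## Panels (`sspig.panels`)

Windows tile each chromosome as half-open 55-kb intervals anchored at
position 0; ties in p break by lower position, then marker id (conventions
chosen here; nothing canonical exists). Top40k keeps the lowest-p marker
per occupied window; ChipPlusSign adds to the chip, per window, the single
most significant variant at p ≤ 10⁻⁶; TopSign keeps only those. Multi-trait
models take the set union of their member traits' panels (chip provenance
wins on conflict). Panel-level QC (the genotype-frequency rule and
Mendelian checks) runs after construction, and the animal sets are
harmonized across the panels being compared.

## Single-step solver (`sspig.mme`)

Residuals are handled per animal: the inverse of the `R0` submatrix for the
animal's observed-trait subset enters the equations, which is the standard
multivariate-BLUP mechanism for missing traits and is what lets crossbreds
record only crossbred traits. The litter term uses `I ⊗ L0⁻¹` restricted to
traits with positive litter variance; the additive term applies
`H⁻¹ U Σ0⁻¹` as an operator. Contemporary-group levels with fewer than 2
records merge into a spill-over level to avoid singular designs. The system
is solved by conjugate gradients with a block-diagonal preconditioner
(per-animal and per-litter trait×trait blocks, scalar for fixed effects);
default stopping tolerance 1e−12 relative residual, with non-convergence
raising an error carrying diagnostics. A dense assembly path provides
prediction-error variances at small scale and backs the pedigree-only
evaluations used for deregression. Variance components are inputs — the
simulation truths by default — since the reference workflow takes them
from routine evaluation.

## BayesR weighting (`sspig.bayesr`)

Gibbs sampler over the four-component normal mixture with variances
(0, 1e−4, 1e−3, 1e−2)×σ²ₐ, σ²ₐ being the current sampled value. Per sweep,
each SNP's class is drawn from the marginal likelihood with the effect
integrated out, the effect from its normal full conditional, then class
proportions (Dirichlet) and both variances (scaled inverse chi-square).
Two numerical choices matter:

- The Dirichlet prior defaults to pseudo-counts `(0.96, 0.02, 0.01, 0.01) ×
  max(m/10, 4)`, a sparsity prior scaled to the panel. With a flat prior the
  null model is not identifiable: classes with near-zero variance carry no
  likelihood penalty, so markers drift freely among them, the class
  proportions never concentrate, and the additive-variance chain can
  collapse. The sparsity prior pins the null class without stopping real
  signals — a QTL's Bayes factor dominates the prior easily.
- The stored per-SNP variance at each kept iteration is the
  *conditional expected* class variance (Rao-Blackwellized over the class
  probabilities), not the sampled class's variance; this removes most
  Monte-Carlo noise from the posterior variances at no cost.

Posterior variances are averaged over post-burn-in iterations and rescaled
so trace(D) equals the number of SNPs; exact zeros are floored at 1% of the
mean before rescaling so the weighted G stays full rank. The pipeline
applies a single weighting round (BayesR → D → one weighted solve); the
response is the deregressed EBV of genotyped training animals, since raw
phenotypes carry fixed effects and the sampler sees genotyped animals only.
Default chain length 3000 with 1000 burn-in (shorter in tests; the desk
problems mix fast).

## Validation (`sspig.validation`)

The split takes whole last-generation litters with ≥ 5 full sibs as the
test set; training candidates with pedigree additive relationship ≥ 0.5 to
any test animal are excluded ("relationship" is read as the pedigree A —
computable for every candidate; a genomic variant is a one-line change).
The same training set serves GWAS and prediction. Deregression is
VanRaden-style: PA = parent EBV mean, `r²PA = (r²s + r²d)/4`,
`R* = (r² − r²PA)/(1 − r²PA)`, `dEBV = PA + (EBV − PA)/R*`; animals whose
R* is not positive are dropped with a warning. Reliabilities come from the
prediction-error variances of a single-trait pedigree-only (H = A) direct
solve, `r² = 1 − PEV/((1+F)σ²ₐ)`. Note the calibration direction: the
regression of dEBV on TBV is ≈ 1 (unbiased quasi-phenotype) while TBV on
EBV is ≈ 1 by the BLUP property; deregression *undoes shrinkage*, it does
not improve the TBV-on-prediction slope. Accuracy is cor(GEBV, dEBV); b₁
is the slope of dEBV regressed on GEBV (< 1 ⇒ inflation); standard errors
bootstrap test animals (pairs, not residuals) with 1000 replicates by
default.

## Pipeline and the desk-scale fixture (`sspig.pipeline`)

One simulated line is shared by all panel scenarios of a comparison:
same pedigree, same split, same GWAS, same APY core draw, and the genomic
animal set is the intersection of the panels' QC survivors, so accuracy
differences are paired. Prediction runs withhold the test litters'
phenotypes.

`desk_config` defines the reference line for scenario comparisons: two
50-Mbp chromosomes, 4000 sequence markers, an 1800-marker chip — one chip
marker per 55-kb window, the regime in which the evenly spaced chip matches
the preselection window count and suffices for the segregating chromosome
segments — ~1100 animals in four generations of 8-piglet litters, ~240
test animals. Two architectures span the contrast of interest:

- `few_qtl`: 12 large QTL kept off the chip — the case where preselection
  can capture causal variants the chip misses;
- `polygenic`: 800 small QTL, *not* excluded from chip positions — an
  infinitesimal-like trait whose causal variation the chip already tags.
  (Excluding hundreds of causal loci from the chip by construction would
  artificially blind it and manufacture gains that are a simulation
  artifact, not a property of preselection.)

Panel comparisons at desk scale use single-trait models per trait so that
Top40k stays size-matched to the chip — Top40k was designed as a chip-sized
panel, and at these marker counts a larger panel improves the genomic
relationship estimate regardless of how its markers are chosen, which would
confound the selection effect being measured. Gains are summarized per seed
as the mean over traits, the way line-level gains are usually reported.

## Known limitations

- REML estimation of full multi-trait variance components is out of scope;
  components are inputs.
- Reliability via dense PEV solves limits deregression to desk-scale
  pedigrees (tens of thousands of equations).
- The Markov-chain LD model has no long-range haplotype structure beyond
  what the pedigree induces; GWAS power and panel behaviour at desk scale
  are qualitative, not calibrated to any real line.
- Single weighting round for WssGBLUP (an n-round loop is a trivial
  extension but was not needed for the comparisons here).
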