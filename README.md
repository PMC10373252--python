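# sspig

Single-step genomic prediction (ssGBLUP / WssGBLUP) with GWAS-preselected
sequence variants, exercised end to end on simulated pig breeding
populations.

## The problem

Commercial pig breeding uses medium-density SNP chips (~40–50k markers) for
routine genomic evaluation. Whole-genome sequence data contain the causative
variants themselves, but using millions of variants directly rarely helps:
most are redundant, and evaluations that mix genotyped and non-genotyped
animals need a single relationship structure, not a marker regression.
A practical middle path is to *preselect* sequence variants by GWAS and feed
them into single-step GBLUP:

- **Chip** — the standard evenly spaced chip panel (baseline);
- **Top40k** — the lowest-p variant in each consecutive, non-overlapping
  55-kb window, whether or not it is significant (a chip-sized panel built
  from GWAS evidence);
- **ChipPlusSign** — the chip plus, per window, the most significant variant
  at p ≤ 10⁻⁶;
- **TopSign** — the windowed significant variants alone.

Whether preselection pays off depends on the genetic architecture: it helps
when a trait has large-effect variants missing from the chip, and does
little for fully polygenic traits that the chip already tags. This package
implements the whole comparison pipeline — and, because the motivating data
are proprietary breeding records, ships a population simulator so every
stage is testable from scratch.

## The model

Multi-trait mixed model per trait group

```
y = Xb + Wc + Zu + e
```

with contemporary-group fixed effects (plus optional covariates) in `b`, a
diagonal litter effect `c ~ N(0, I ⊗ L0)`, additive genetic effects
`u ~ N(0, H ⊗ Σ0)` and residuals `e ~ N(0, I ⊗ R0)`; litter and residual
covariances between purebred- and crossbred-recorded traits are structural
zeros. The realized relationship matrix enters through its inverse

```
H⁻¹ = A⁻¹ + [0 0; 0 G⁻¹ − A22⁻¹]
```

where `A⁻¹` is the sparse pedigree inverse (Henderson rules with
Meuwissen–Luo inbreeding), `A22` the pedigree relationships among genotyped
animals, and `G = MDM′ / 2Σpⱼ(1−pⱼ)` the VanRaden genomic matrix (D = I for
ssGBLUP, BayesR posterior SNP variances rescaled to trace(D) = nSNP for
WssGBLUP). G is tuned so its mean diagonal and off-diagonal match A22, then
blended with 5% A22. For large genotyped sets, `G⁻¹` uses the APY algorithm
with a random core sized by the number of eigenvalues explaining 98% of the
variation in G. The equations are solved by preconditioned conjugate
gradients with everything kept in operator form.

Validation follows the breeding-program protocol: whole last-generation
litters (≥ 5 full sibs) form the test set, training animals related ≥ 0.5
to any test animal are dropped, and GEBV of test animals (phenotypes
withheld) are compared with deregressed EBV — accuracy is their correlation
and dispersion is the slope b₁ of dEBV on GEBV, with bootstrap standard
errors.

## Worked example

```python
from sspig import pipeline

out = pipeline.run_panel_comparison(
    pipeline.desk_config("few_qtl", seed=11), panel_modes=("chip", "top40k"), seed=11
)
for mode, rep in out["reports"].items():
    print(mode)
    print(rep.round(3))
```

prints (one simulated line, ~1100 animals, 4000 sequence markers, 12 large
QTL kept off the chip):

```
chip
  scenario trait  accuracy  accuracy_se     b1  b1_se  n_test
0     chip   ADG     0.315        0.053  0.655  0.116     240
1     chip    BF     0.352        0.058  0.823  0.138     240
top40k
  scenario trait  accuracy  accuracy_se     b1  b1_se  n_test
0   top40k   ADG     0.315        0.054  0.652  0.116     240
1   top40k    BF     0.364        0.056  0.801  0.129     240
```

`accuracy` is cor(GEBV, dEBV) over the 240 withheld test animals; the two
scenarios share the simulation, split, GWAS and animal set, so the
differences are attributable to the panels. `b1 < 1` indicates inflated
(over-dispersed) GEBV, the usual situation for young selection candidates.
The `examples/` directory walks through each capability (simulation,
relationship matrices, GWAS + panels, the single-step solve, panel
comparison with BayesR weighting) as short narrative scripts.

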