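# sdmshift

Presence-only species distribution modelling for data-sparse regions:
fit maximum-entropy habitat-suitability models for many species at once,
project them onto future climates under bracketing dispersal assumptions,
stack the binarized maps into species-richness / gain / loss / turnover
surfaces, and test whether a protected-area network sits on the richness
hotspots it is meant to protect.

The package is aimed at conservation analysts who have occurrence records
and gridded environmental layers but no absence data — the common
situation in countries with sparse biodiversity databases. Everything
runs end-to-end on a built-in synthetic-landscape generator, so the whole
workflow is testable without downloading any data.

## The model

For one species with presence cells $x_1,\dots,x_m$ and a background
sample $B$ of landscape cells, the model is the Gibbs distribution over
the background,

$$q_\lambda(x) = \frac{e^{\lambda \cdot f(x)}}{Z_\lambda},\qquad
  Z_\lambda = \sum_{x \in B} e^{\lambda \cdot f(x)},$$

where $f(x)$ are feature expansions of the predictors (linear, quadratic,
pairwise product, and threshold indicators on continuous layers; one
indicator per habitat class). The weights maximize the L1-penalized
presence log-likelihood

$$\frac{1}{m}\sum_{i=1}^{m} \lambda \cdot f(x_i) \;-\; \ln Z_\lambda
  \;-\; \sum_j \beta_j |\lambda_j|,
  \qquad \beta_j = \beta_0\, s_j / \sqrt{m},$$

with $s_j$ the presence-sample SD of feature $j$ — the classic
maximum-entropy density estimate subject to relaxed feature-expectation
constraints. Suitability is reported on the logistic scale
$p = q e^H / (1 + q e^H)$, with $H$ the entropy of $q$ over the
background.

Downstream, each species is cross-validated ($k = 10$), each replicate is
binarized at its own 10% training-presence threshold, presence is awarded
by strict majority of the replicates (> $R/2$), and future maps are read
either as-is ("unlimited dispersal") or intersected with the current map
("no dispersal"). Summing per-species maps gives richness; per-cell
turnover is `SG + SL` (species gained plus species lost). Reserve
effectiveness is the paired difference in richness between random pixels
inside each reserve and those in its 50-km exterior buffer, tested with a
one-sample *t*-test against zero.

## Worked example

The numbered scripts under `analysis/` run the full study on the
built-in synthetic region (100 × 120 cells at 2.5 arc-minutes, ten
range-restricted species with 150 presences each, 25 reserves sited on
richness hotspots). `python analysis/03_fit_evaluate.py` prints:

```
10/10 species pass the filters (>= 10 cells, mean AUC >= 0.7)
AUC 0.872 +- 0.008 (range 0.82 to 0.91); TSS 0.625 (range 0.57 to 0.68)
background sample: 2000 cells; k = 10 replicates per species
```

— every species clears the inclusion filters, and the cross-validated
discrimination (AUC ≈ 0.87) sits close to the ceiling set by the known
true suitability surfaces. `python analysis/05_assess_protected_areas.py`
then prints:

```
25 reserves x 13 richness maps = 325 paired differences (65 rows used the small-reserve rule)
mean excess inside = 0.54 +- 0.04 species (t_324 = 12.6, p = 9.6e-30)
outside grand mean 2.19 -> 24% higher richness inside
```

— hotspot-sited reserves hold about 24% more predicted species than
their immediate surroundings, and the paired *t*-test over all 325
reserve × map combinations is decisively positive. The same workflow is
available as a CLI (`sdmshift simulate|prepare|fit|evaluate|project|
richness|pa-assess|run-all --config cfg.yaml --out outdir`) for
user-supplied rasters and occurrence files.

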