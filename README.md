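# npniche

Species niche occupation along plant-tissue **N:P stoichiometric
gradients**, for community ecologists working with presence/absence
vegetation-plot data.

Grassland and wetland communities sort along a gradient of relative N
vs P availability, indexed by the tissue N:P mass ratio (N-limited
below 13.5, P-limited above 16, co-limited between; K-limitation when
N:K > 2.1 and K:P < 3.4).  Working on `x = log10(N:P)`, the package
estimates for each sufficiently frequent species (≥ 10 occupied plots)

* niche **position** `p̂ = mean(x over occupied plots)`,
* niche **width** `ŵ = 2·sd(x over occupied plots)`,
* **extremity** `|p̂ − x̄|` (distance from the dataset mean), and
* **residual width** `ŵ − q̂₀.₅(p̂)`, the deviation from the median
  quadratic quantile regression of width on position,

and then tests, against a frequency-preserving bootstrap null model
(each plot keeps its observed richness; species are redrawn with
probabilities calibrated so replicate frequencies match observed ones):

1. **Modality** — is the niche-position distribution bimodal?  Single
   Gaussian vs two-component mixture, judged by `−2 ln Λ` and `ΔR²`
   against simulated critical values, plus averaged two-sample
   Kolmogorov–Smirnov comparisons with the null ensemble.
2. **Trade-off** — quadratic quantile regressions (τ = 0.50/0.75/0.90/
   0.95, exact LP solutions) of width on position, the null-ensemble
   regression band, and linear width-vs-extremity slopes on the
   N-(co-)limited and P-(co-)limited sides against their null slope
   distributions.
3. **Endangered species** — Mann–Whitney U on residual widths and
   one-sided Spearman correlations of residual width vs extremity,
   within endangered/non-endangered groups and the endangered group
   split by N- vs co/P-limited positions.

A synthetic-data generator with full ground truth (Gaussian response
curves, two-mode optima, tolerances narrowing toward the extremes,
heavy-tailed prevalence, endangered flags enriched at P-limited optima)
makes the whole chain verifiable by parameter recovery.  See
`docs/methods.md` for the statistical details.

## Worked example

```sh
python analysis/01_simulate_dataset.py
python analysis/02_run_niche_analysis.py
python analysis/03_render_figures.py
```

or equivalently `npniche simulate|analyze|report`.  On the default
synthetic dataset (seed 1) the analysis prints:

```
pool: 233 species, 18694 observations
niche positions: -2lnLambda=41.21, dR2=0.349, verdicts {'0.1': 'bimodal', '0.05': 'bimodal', '0.01': 'bimodal'}
null replicates unimodal: 100.0%; KS D-bar=0.358, p-bar=6.8e-13
median quantile fit coefficients [-0.619, 1.684, -0.787] (concave: True)
real curve below null band over 100% of the null-supported gradient
N_side: slope -0.187, one-sided p 0.631 (179 species)
P_side: slope -0.261, one-sided p 0.039 (66 species)
endangered vs non-endangered residual widths: U=4807.0, p=0.012
spearman[endangered]: rho=-0.038, p=0.626 (n=74)
spearman[non_endangered]: rho=-0.174, p=0.986 (n=159)
spearman[endangered_n_limited]: rho=-0.251, p=0.930 (n=36)
spearman[endangered_co_p_limited]: rho=0.451, p=0.002 (n=38)
```

Reading this: of 300 simulated species, 233 pass the 10-plot rule.
Their position distribution is judged bimodal at every level (the
likelihood-ratio statistic 41.2 and ΔR² 0.349 both exceed their
simulated critical values and the fitted mixture is genuinely
two-moded), while essentially every null replicate is judged unimodal —
the planted two-mode structure is detected and the null model does not
fake it.  The median width-position fit is concave (quadratic
coefficient −0.79) with real widths below the null band across the
supported gradient: real species are narrower than randomly assembled
ones.  The width decrease toward the P-limited extreme is stronger than
the null distribution of such decreases (one-sided p = 0.039) while the
N-side decrease is not (p = 0.63), and endangered species with co/P-
limited positions show the planted positive extremity-residual
correlation (ρ = 0.45).  `analysis/04_sensitivity_checks.py` shows both
signals vanish when the generating mechanism is switched off.

## Input formats

TSV/CSV with header rows: a plot table (`plot_id`, `plant_n`,
`plant_p`, `plant_k`, `biomass`, `mowing_frequency`, optional exclusion
flags), a species table (`species_id`, `endangered`, `is_tree`,
`ambiguous_identity`, optional `eiv_*` indicator columns), and a
community matrix either wide (plots × species, 0/1) or long
(`plot_id`, `species_id`).  Curation filters (woody plots, saline
plots, plots without tissue K, tree and ambiguous species) follow the
flags; community-mean Ellenberg indicator values are available per
plot.  Results are TSV tables plus one `summary.json` embedding every
statistic, seed and configuration value.
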