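# aridtrait

Tools for analysing **desiccation resistance** in insects — dung beetles in
particular — from gravimetric survival assays, and for asking whether the
traits behind it carry phylogenetic signal.

In a gravimetric assay each individual is held in dry air (≈70 % RH) and
weighed on a daytime schedule (09:00, 12:00, 15:00, 18:00; 3 h gaps during
the day, 15 h overnight) for up to 96 h, or until it dies. From the wet-mass
series, the alive/dead flag at each weighing and the post-mortem dry mass
`BM`, the package derives per individual:

- **DR** (desiccation resistance) = survival time / 96 h ∈ (0, 1];
- **WLR** (water loss rate) = −(OLS slope of water mass on time) / initial
  water content, in mg mg⁻¹ h⁻¹;
- **WLT** (water loss tolerance) = 100 × (initial wet mass − wet mass at
  death) / initial water content, in %;
- **fWC** (fractional water content) = initial water content / dry mass.

Death is only interval-observed, so survival time is the median of the
last-alive and first-dead weighing times, and the mass at death is the mean
of the two bracketing masses. Survivors are censored at 96 h with DR = 1 and
undefined physiological traits.

Two inference models are fitted from scratch:

- a **general effects** binomial GLMM (logit link),
  `DR ~ NS * log BM + WLR + WLT (+ fWC) + (1 | species)`, where DR enters as
  a count of survived half-hour units out of 192 and the species random
  intercept is integrated out by adaptive Gauss–Hermite quadrature;
- a **relative effects** binomial GLM,
  `DR ~ species + scaled BM + scaled WLR + scaled WLT`, where
  `scaled x = (x − species mean)/species mean` isolates within-species
  variation.

The comparative layer computes Felsenstein standardized independent
contrasts on a user-supplied bifurcating Newick tree, measures phylogenetic
signal as the **variance of the standardized contrasts** against a
tip-shuffle randomization null (low variance ⇒ related species resemble
each other), and correlates traits through the origin of their contrasts.

A synthetic-data module simulates the whole study design — pure-birth trees,
Brownian trait evolution, a mechanistic assay in which each individual loses
a fixed proportion of its initial water per hour and dies when its tolerable
fraction is gone, and GLMM-structured binomial data — with known ground
truth, so every stage is testable without any field data.

## Worked example

Run the full pipeline on the packaged demo configuration (an 8-species,
3-guild community of 137 individuals with species trait scales typical of
north temperate dung beetles):

```sh
aridtrait run --out demo_run
```

`demo_run/species_summary.csv` then contains, e.g.:

```
       species  n_dead  n_total  bm_mean  dr_mean  wlr_mean  wlt_mean
G_stercorarius      32       38  254.444    0.590     0.009    47.368
O_fracticornis      18       39   18.954    0.724     0.009    62.451
   C_erraticus       5        7    8.181    0.291     0.020    53.252
```

— per-species sample sizes, mean dry mass (mg), mean desiccation resistance
(proportion of the 96 h horizon survived by the individuals that died), and
mean water-loss rate/tolerance. `demo_run/general_fit.tsv` holds the general
effects GLMM after pruning (fWC, simulated with no effect, is dropped):

```
AIC	952.01
pseudo_R2 (squared Pearson corr, observed vs fitted)	0.909
random_intercept_sd	0.1316
term	estimate	SE	z	p	sig
wlr	-191.4872	6.3066	-30.363	1.701e-202	***
wlt	+0.0442	0.0015	+30.433	1.996e-203	***
roller	+1.7924	0.7254	+2.471	0.01348	*
```

Desiccation resistance falls steeply with water loss rate and rises with
water loss tolerance — the generating mechanism recovered from the observed
weighings. `signal.tsv` and `pic.tsv` report the contrast-variance signal
test and through-origin contrast correlations for DR, WLR, WLT, fWC, BM and
the (ordinally coded) nesting strategy.

Every stage is also scriptable:

```python
import aridtrait as at

cfg = at.default_config()
series, truth = at.simulate_assay(cfg.assay_config())
table, summary = at.derive_table(series, horizon_h=96.0)
table = at.scale_within_species(table)
design = at.build_general_design(table)
fit = at.glmm_fit(design)
print(at.fit_report(fit))
```

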