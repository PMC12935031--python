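# Methods

This note documents the models, defaults and numerical choices behind
`terracarbon`, and what the synthetic-study tests do and do not establish
about real data.

## Stock accounting

Horizon SOC density is `(SOC%/100) · BD_fine · 10` in kg C m⁻² cm⁻¹. The
factor 10 is the unit conversion for a 1 m² × 1 cm slab (10⁴ cm³ of fine
earth); it is written explicitly because the density formula is often
quoted without it, which silently scales stocks by 10×. Profile stocks are
thickness-weighted sums of horizon densities and are exactly invariant
under horizon refinement; horizons must tile the profile (overlaps and
gaps raise a geometry error listing the offending intervals).

The gravel correction to bulk density applies only when gravel exceeds 3 %
of sample mass — below that threshold the uncorrected value is used, since
the correction's sampling error exceeds its bias there. Pedotransfer
predictions (`BD = a·SOC + b·clay + c·silt + d`, OLS) are clipped to the
physical range 0.2–2.2 g cm⁻³ and clipping events are logged, guarding
against extrapolation far outside the calibration domain.

Layered gridded stocks are harmonized to a target depth by summing whole
layers and apportioning the straddling layer proportionally to thickness
(uniform density within a layer). Control stocks are truncated to the
site-mean terraced depth; a per-profile switch exists because the
alternative convention is equally defensible.

## Monte Carlo imputation

The bias model `field = α + β·gridded + ε`, `ε ~ N(0, σ²)` is calibrated
by OLS with σ estimated on n−2 degrees of freedom; outlier sites are
excluded only by an explicit, recorded list (no automatic rule). Gridded
uncertainty "±SE" is read as Gaussian with SD = SE, consistent with the
explicit normal used for measured sites.

Imputation draws are `α̂ + β̂·(mean + N(0, se)) + residual`. When the bias
model carries its calibration geometry, the residual comes from the OLS
predictive distribution — Student-t with n−2 df scaled by
`σ̂·sqrt(1 + 1/n + (x − x̄)²/Sxx)` — so the sampling uncertainty of α, β
and σ propagates into the posterior. This matters: with 10 calibration
sites, plug-in N(0, σ̂) draws cover the truth only ~89–90 % of the time at
a nominal 95 %, while the predictive draws restore nominal coverage (the
package's coverage experiment measures ~94–96 % over 200 replicate
worlds). A bias model constructed by hand without geometry falls back to
the plug-in draw.

Posterior intervals are empirical 2.5–97.5 percentiles with linear
interpolation between order statistics. The repeated ΔSOC–aridity
regression consumes one draw per site per repetition, in order, so the
number of repetitions cannot exceed M; both measured and imputed sites are
resampled within each repetition. P values are summarized as the median
and the fraction below 0.05.

## FTIR semi-quantification

Absorbance is log₁₀(1/R), the diffuse-reflectance convention. Masked
mineral regions (<1200, 1750–2000, >3000 cm⁻¹) are excluded from peak
search, endpoint search and the total-area normalization. Peak endpoints
are the nearest local minima flanking the in-window maximum, searched
within the band window extended by ±40 cm⁻¹ (band windows are narrow
relative to peak tails); a monotone tail takes the search-region boundary
as its minimum, and a side with no minimum structure falls back to the
maximum of the second derivative of a Savitzky–Golay-smoothed trace
(window 11, degree 3 — all configurable). Height is the maximum of the
absorbance above the chord between the endpoints, floored at zero; a flat
window yields zero height with a warning rather than an error.

The two aliphatic sub-bands are summed into one aliphatic height. Ratios
use area-normalized heights; since a global spectral scaling multiplies
heights and total area equally, ratios are exactly scale-invariant — this
is tested to machine precision. Adjacent bands overlap (the diffuse
carboxylic band shoulders the aromatic window), so chord-baseline heights
carry a few percent of systematic bias for heavily overlapping peaks; the
recovery tests bound the median absolute error at 5 % under the default
band placement. A global rubber-band baseline correction before
conversion is available but off by default.

## Attribution battery

* Stratification: binary humid/arid at aridity index (MAP/PET) 1.0 — AI
  exactly 1 classifies humid; ternary zones are [0.2, 0.5), [0.5, 0.65),
  [0.65, ∞), and AI < 0.2 is flagged extreme-arid and out of scope.
* t-tests are Welch (unequal variances). The correlation star table is
  per-cell unadjusted (*, **, *** at 0.05/0.01/0.001, blank above 0.05);
  no multiplicity correction is applied, matching the screening intent.
* PCA is always on the correlation matrix (standardized variables), which
  is what makes the eigenvalue > 1 retention rule meaningful. Varimax
  rotation is applied to the retained loadings; |loading| > 0.5 is the
  interpretation threshold. The retained count follows the rule rather
  than being fixed.
* Mixed models standardize response and predictors internally, so fixed
  effects read as relative importances. Selection is bidirectional
  stepwise by AIC (ML, not REML). R²m/R²c use the variance-decomposition
  definition (fixed / fixed+random over total). A singular random-effect
  fit falls back to fixed site effects with a warning.
* Variation partitioning reduces each block (ligand exchange: reactive
  oxides; cation bridging: exchangeable bases, TRB, pH; chemistry: C:N and
  FTIR ratios) to its first principal component, then combines the seven
  nested Ezekiel-adjusted R² values by inclusion–exclusion. Fractions sum
  to 1 identically; raw fractions may be slightly negative (a property of
  adjusted R²) and are reported raw alongside a clipped view.
* VIF pruning drops the largest-VIF variable until all are below 5, ties
  broken by column order. The random forest uses 500 trees and √p features
  per split by default, with 100 random 4:1 train/validation splits and
  permutation importance averaged across repetitions (the demo pipeline
  runs 20 splits of 100 trees to keep the end-to-end run short).
* The path model reduces each indicator block to its standardized first-PC
  composite (warning when it explains <75 % of block variance); with one
  composite per block the PLS estimation reduces to OLS among scores, so
  weighting scheme and mode are fully determined. Indirect effect =
  product of the mediated paths; total = direct + indirect by identity.
  Bootstrap SDs re-extract composites per resample (signs anchored to the
  full-sample weights); CV SDs come from k training folds, with
  out-of-fold predictions pooled for the cross-validated R².

## Productivity and synthesis

TPP is the plain daily sum of the phenology index from season start to end
inclusive (a rectangle rule, matching the "sum of daily values"
definition), which makes TPP exactly additive over season partitions.
Savitzky–Golay smoothing (degree 3, window 7) uses polynomial refits on
truncated edge windows and is exact on cubics. EVI uses G=2.5, C1=6,
C2=7.5, L=1; SAVI uses L=0.5 (and converges to NDVI as L→0). Season
bounds are taken as inputs; season detection is out of scope.

The synthesis filter applies the inclusion rules row-wise in a fixed
order (paired SOC present, control comparable, age ≥ 1 yr, not paddy, not
fluvial-gravel, not desert), logging the first failing rule — row-wise
evaluation makes the filter order-independent. The ΔSOC–aridity trend is
loess (tricube, locally linear, span 0.75 by default) with a pointwise
95 % band from refitting on fitted-values-plus-resampled-residuals; the
band is a confidence band for the smooth, so it covers a true curve only
where smoothing bias is small relative to noise.

## Synthetic world defaults

The generator's defaults emulate the study design the analysis targets:
14 sites evenly spanning AI 0.32–2.17 (7 arid, 7 humid at the default
spacing), one cut, fill and control profile per site, 10 cm horizons to
1 m. Site-level expected ΔSOC is linear in AI (slope 57 %/AI, intercept
−38 %, site SD 18 %), chosen so the arid end sits near zero-to-negative
change, the humid end strongly positive, the all-site mean near +40 %,
and the AI regression explains roughly 60 % of site variance. The gridded
product is linked to field truth by the default bias (α=5, β=0.8, σ=10 in
ΔSOC %), with 10 pixels of SD 8 % per site; the gridded truth is drawn
from the linear-projection conditional given field truth, so an OLS
regression of field on gridded recovers (α, β, σ) — this is what makes
the calibration-recovery and coverage experiments well posed.

SOC decays exponentially with depth (e-folding 35 cm, surface value
0.8 + 1.2·AI %). The fill position adds a Gaussian buried-topsoil bump
(height 30 % of surface SOC, centered at 50 cm, SD 12 cm) and the cut
position a surface depletion that weakens from 45 % at the arid end to
10 % at the humid end — reproducing the observed position contrast
(incomplete replacement in arid cut positions). Geochemical covariates
follow linear AI trends with lognormal noise (oxides and C:N up toward
humid; exchangeable bases, TRB, pH and crystalline oxides up toward arid)
and share latent per-sample oxide/cation signals with the respiration
response, whose weights shift from cation-dominated (arid) to
oxide-dominated (humid) — this is what gives the variation partitioning
its directional ground truth. Within-site profile correlation defaults to
independence and is exposed as a knob, since no empirical value is
available for it.

What passing tests show: the estimators are correct and calibrated under
a world whose assumptions (linear bias, Gaussian noise, exponential
decay, linear climate trends) they match. They do not show robustness to
real-data violations — spatially correlated profiles, non-Gaussian
residuals, depth-varying bias in gridded products, instrument drift in
spectra — which the generator deliberately omits.

## Problem sizes

The shipped experiments use 200 replicate worlds for interval coverage
(1000 imputed-site evaluations), 1000 calibration pairs for bias recovery,
1000 repetitions for the null regression and 100 worlds for the signal
regression, 100 random spectra for FTIR recovery, 50 random instances for
the variation-partitioning exactness check, and the default 14-site world
for the end-to-end directionality check. These sizes put Monte Carlo error
well inside each test's tolerance while keeping a full run to a couple of
minutes on one core.

## Known limitations

* The imputation assumes one global, depth-integrated linear bias between
  gridded and field ΔSOC; no spatial autocorrelation between sites and no
  hierarchical pooling.
* FTIR band heights are chord-baseline semi-quantities, not
  concentrations; strongly overlapping bands are biased low by a few
  percent by construction.
* The stepwise-AIC mixed model inherits the usual instability of stepwise
  selection at small site counts; the RC inputs mitigate but do not
  remove it.
* The loess bootstrap band ignores smoothing bias.
* With 14 site-level observations the path model's bootstrap and CV
  spreads are descriptive stability measures, not formal inference.
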