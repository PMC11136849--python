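# Methods

## Measurement model

All statistics in this package operate on quantifier/qualifier peak areas.
The synthetic generator, which defines the conditions under which the
pipeline is tested, produces a quantifier area for compound *i* in sample *s*
as

    A_is = R_i · c_is · f_i(m_s) · r_i^{[processed]} · d_{i,day(s)} · exp(ε_is)

with

- `R_i` — response factor (area units per ng/mL), lognormal across compounds
  with median 1000 and log-SD 0.5;
- `c_is` — concentration in the injected extract (ng/mL). Calibration
  standards are spiked into the final extract, so their `c` is the nominal
  level and the extraction-recovery factor does not apply; fortified,
  monitoring and blank samples are processed soils, so `c` is the soil
  concentration (nominal plus any incurred blank level) times the recovery,
  converted by the extract-volume-per-mass policy (1.0 mL/g by default:
  5 g soil into 5 mL solvent, making ng/mL and ng/g numerically equal);
- `f_i(m)` — multiplicative matrix factor of matrix *m* (≡ 1 in solvent),
  lognormal across compounds with soil-specific medians 1.3 (RFNo) to
  2.2 (SR, DC) and log-SD 0.45. The medians encode that the studied soils
  all showed net ion enhancement, weakest in the organically managed field
  soil; magnitudes were fixed once from the per-soil mean effects reported
  for the real method;
- `r_i` — extraction recovery, normal(0.9, 0.08) clipped to [0.4, 1]; the
  syringe standard (added after extraction) has r ≡ 1;
- `d_{i,day}` — per-(compound, day) lognormal day effect, log-SD 0.08 by
  default. Day effects are drawn independently per compound, not shared
  across the injection sequence: a multiplier common to an analyte and its
  internal standard cancels exactly in the area ratio, so a shared per-day
  factor cannot produce the empirically observed RSDR > RSDr under
  internal-standard quantification. Independent per-compound day effects do.
- `ε` — injection noise, normal with variance ln(1 + CV²) so the area CV
  equals the configured `injection_cv` (default 0.05). Multiplicative
  lognormal noise keeps areas positive and makes CVs, not SDs, roughly
  level-independent, as observed in MS practice.

Qualifier areas are the quantifier times a per-compound ion ratio (default
0.5) with 5% independent relative noise. S/N is emitted as area divided by a
constant per-compound baseline-noise area (10% of the response factor); no
chromatogram, peak shape, co-elution or carryover is simulated.

Compounds with a structure-identical (si) IL-IS share that standard's matrix
factors and extraction recovery exactly (they are the same molecule up to
isotope labels); the group-4 standard serves two metribuzin transformation
products, giving 11 si analytes for 10 IL-IS. Analytes quantified with a
non-structure-identical (nsi) IL-IS get independent draws.

## Calibration and quantification

Curves are unweighted OLS with intercept on the 5–100 ng/mL levels (the 0
level never enters a fit; weighting would change slopes and therefore the
matrix-effect values). Replicated levels are fitted as individual points
rather than level means, preserving the residual information that feeds the
slope variance. R² is the squared Pearson correlation (equivalently
1 − SSR/SST for an intercept model). The slope variance is the standard OLS
estimator variance, `s²/Sxx`. Quantification inverts the curve and converts
to ng/g; negative back-calculated values (blanks under a positive intercept)
are clipped to zero and flagged rather than rejected.

## Matrix effects and slope comparison

`ME = (b_matrix/b_solvent − 1)·100`, computed per (compound, matrix, mode)
from curves fitted on the same level set. The ±20% significance boundary is
strict. Distribution summaries use the sample SD (n−1) and
linear-interpolation quartiles (the common statistical-software default,
matching box-plot semantics).

Slope equality uses `t = (b₁−b₂)/√(s²_b₁+s²_b₂)` with `df = n₁+n₂−4`,
two parameters being estimated in each regression, and a two-sided p-value
(an equality null implies two-sidedness). With equal designs and equal
residual variances the statistic coincides exactly with the interaction-term
t-test of a pooled regression with group dummies, which the tests use as an
independent oracle. No Welch–Satterthwaite refinement and no
multiple-testing correction are applied. Monte-Carlo checks at 2000
repetitions show the test holds its nominal 5% size within the binomial
noise of the simulation.

## Validation statistics

- RSD is 100·(sample SD, n−1)/mean, requiring at least two values and a
  nonzero mean.
- RSDr uses the designated repeatability day's replicates (the first
  complete day by default; configurable, since the reference design does not
  say which day's quadruplicates define repeatability). RSDR pools all days'
  replicates (12 values in the reference design) rather than averaging daily
  RSDs, matching the within-laboratory-reproducibility reading of
  "changing conditions at different days".
- Relative recovery per level is the mean over all replicate recoveries of
  that level (12 in the reference design); absolute recovery references the
  IL-IS/syringe-standard area ratio of a processed sample to the same ratio
  in the matrix-matched calibration standards.
- The LOQ rule is strict on both S/N criteria (quantifier > 10,
  qualifier > 3) and scans levels in ascending order. In the synthetic
  pipeline the S/N series comes from the matrix-matched calibration levels
  (5–100 ng/mL), so simulated LOQs sit on that grid; the real method's
  dedicated dilution series (0.1–100 ng/mL) is supported by passing any
  level set to `determine_loq`. Levels are nominally ng/mL and the result is
  converted to ng/g through the units policy — the two scales coincide at
  the default 1.0 mL/g.
- Horwitz: `RSD_bl(%) = 2^(1 − 0.5·log₁₀C)` with C the dimensionless mass
  fraction (ng/g × 10⁻⁹) — the only convention under which 10 ng/g gives the
  ~30% discussed for trace organics — and `RSD_wl = ⅔·RSD_bl`.
- Compliance flags: RSDr ≤ 20%, RSDR ≤ 20%, relative recovery within
  70–120% at every level (extended fit-for-purpose range 60–140%),
  R² > 0.99, LOQ ≤ 50 ng/g. All thresholds live in one `Thresholds` object
  and every flag is monotone in its threshold.

## Monitoring screen

A residue is reported only when (i) retention time is within ±0.5 min of the
expected value, (ii) the observed qualifier/quantifier ratio is within ±50%
*relative* of the calibration ratio (the alternative absolute-percentage-point
reading of that tolerance is rejected; the SANTE food/feed ±30% preset is
available via `Thresholds`), (iii) the back-calculated concentration is at or
above the LOQ (trace signals below LOQ count as non-detects), and (iv) for
compounds flagged with incurred blank contamination, the concentration is
strictly above every concurrently processed blank. Residue sums per sample
use reported concentrations only (censored compounds contribute zero) and
exceedance of the 100/70 ng/g screening limits is strict. Concentrations are
treated as dry-weight; no moisture correction is applied.

## Packaged data

`table2.csv` is the published per-compound validation table (38 analytes;
RSDr/RSDR/relative recovery at 10/25/50 ng/g, LOQ, R²), checksum-verified on
load. Its printed RSD extrema carry a "ng/g" unit in the source even though
RSDs are percentages; the fixture stores them as percent. The printed table
contains 9 distinct IL-IS group labels. `registry_synthetic.csv` is a
labelled reconstruction of the acquisition compound list (the original is
not public): it realizes the documented design of 10 IL-IS groups and 11 si
analytes by assigning atrazine desethyl its own deuterated standard
(group 3), and invents plausible retention times in the 6–14 min elution
window. Structure-identical flags beyond the compounds explicitly named in
the published discussion are plausible assignments, not transcriptions.

## What the generator does and does not establish

Passing parameter-recovery tests shows the statistics are implemented
correctly and the pipeline inverts its own forward model: matrix effects
reproduce injected factors to < 0.1 pp noise-free, si-IL-IS internal-mode
MEs vanish, relative recovery equals 100·r_analyte/r_IL-IS, and the
reference design yields RSDR > RSDr with recoveries centred on 100%. It does
not establish performance on real chromatograms: integration errors,
co-elution, drifting retention times, heteroscedastic baselines, carryover
and matrix-dependent noise are all outside the model, and the generator's
noise decomposition (injection vs day vs extraction) was chosen to
reproduce the order of magnitude of the published RSDs, not their exact
per-compound values.

## Problem sizes

The default simulated study is the reference design itself: 6 calibration
levels × 6 matrices, 3 fortification levels × 4 replicates × 3 days, one
blank per day — 75 samples, ~7400 peak records, generated and analysed in
about a second. The slope-test size check uses 2000 Monte-Carlo repeats and
the monitoring screen 500 samples at prevalence 0.7.
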