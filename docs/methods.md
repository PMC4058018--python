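# Methods

## The counting model

A cytospin slide is imaged as a grid of three-channel 8-bit fields of view
(FOVs): DAPI (nuclei), CD45 (red, leukocytes) and a melanoma marker
(green; Melan-A or S100B). Counting proceeds per slide:

1. **Nuclear masks.** Each FOV's DAPI channel is thresholded with the
   iterative intermeans (isodata) rule: starting from the midpoint of the
   occupied range, iterate `t ← round((mean_below(t) + mean_above(t))/2)`
   (below = bins ≤ t) to its fixed point. The threshold is floored at a
   robust noise level (median + 6·1.4826·MAD of the channel) so that a
   nucleus-free FOV produces no spurious foreground when isodata splits
   pure noise. Connected components (8-connectivity) become candidate
   nuclei and are filtered on area ∈ [30, 5000] px², aspect ratio ≤ 2.5,
   circularity 4πA/P² ≥ 0.6 (perimeter from the standard crack-boundary
   estimator, clamped to ≤ 1), and margin score ≥ 0.15. The margin score —
   mean Gaussian-gradient magnitude on the object boundary divided by mean
   interior intensity — operationalizes the "well-defined nucleus margin"
   requirement scale-invariantly; with the synthetic generator's
   margin-sharpness knob (DAPI blur σ = 1/sharpness), sharpness ≥ 0.3
   passes and ≤ 0.2 fails at the 0.15 default, so the rule is testable in
   both directions.
2. **Measurement.** Each cell's red and green means are taken over a
   cytoplasmic annulus: the nucleus dilated by 4 px minus all nuclear
   foreground. Green is additionally measured over the nucleus, and the
   per-pixel CV of green in the annulus separates punctate (CV > 0.6)
   from uniform staining. Whether the original workflow measured whole-cell
   masks or annuli is not documented; the annulus is this package's choice
   (it isolates cytoplasmic signal from nuclear signal, which the
   Melan-A/S100B distinction needs).
3. **Global thresholds.** Following the user-selected-threshold step of the
   original workflow, one red and one green threshold per slide are derived
   as the intermeans split of the per-cell mean-intensity distributions.
   Patient mode multiplies the green threshold by a stringency factor
   (default 1.25) — a bias against green, because patient slides run a
   higher sandwich-assay background — and control mode divides by it. The
   direction of the bias is from the source workflow; the magnitude is a
   package default, config-exposed.
4. **Classification.** Six rules. Positive: nucleus present with adequate
   margin score; green above threshold; pattern consistent with the marker
   (Melan-A must be predominantly cytoplasmic, i.e. annulus mean > nuclear
   mean, uniform or punctate; S100B accepts nuclear and/or cytoplasmic
   green). Negative: red at or below threshold (red+green → "dual", red
   only → leukocyte — dual cells are reported, never counted as CMCs, and
   no attempt is made to resolve their identity); not anuclear debris; not
   touching a FOV border (border objects are excluded to avoid double
   counting across the acquisition grid). Cell size is not a criterion:
   patient CMCs are not reliably larger than leukocytes, only cultured
   cell lines are. The exact numeric cut-offs of the original rule set are
   not published; every value here is config-exposed.
5. **Debris.** Connected clusters of clearly suprathreshold green/red
   pixels (above the same robust noise floor) not overlapping any dilated
   nucleus, with area ≥ 20 px², are tallied as debris.

The four classes {green, red, yellow, null} partition the accepted
(nucleated, non-border) objects exactly; debris and border objects are
tallied separately.

## Enumeration and error

A slide deposits a fixed aliquot (default 50,000 cells) of the enriched
fraction, so `nCMC/mL = n_slide · (N_fraction / N_slide) / V_blood` with
V_blood the processed blood volume (per-sample field; 10 mL typical). The
only sampling error attached to a slide count n is Poisson, CV% = 100/√n,
reported at 2 significant figures (this rounding reproduces every printed
CV in the packaged cohort, including 101 → 9.95 → 10). Separation
bookkeeping: recovery = (Eluate+Retentate)/Feed with a 15% default
tolerance, depletion rate = 1 − Eluate/Feed leukocytes.

## Spike-in analysis

Recovery is summarized by OLS of recovered on spiked counts with 95%
t-intervals (the published analysis is a simple linear regression with a
confidence band; weighting is deliberately not applied). The published
"limit of sensitivity" is not defined operationally, so the package defines
LOD as the smallest spike level whose recovered counts strictly exceed the
maximum healthy-donor background in ≥ 95% of replicates (ties resolve
upward; `inf` when no tested level qualifies). This definition is the
package's own, config-exposed; no claim is made of numerically reproducing
the published 10 cells/mL.

## Cohort statistics

- **Exact Mann–Whitney** (combined n ≤ 25): the permutation distribution
  of the rank sum, conditional on observed ties, by dynamic-programming
  convolution over doubled midranks; two-sided p = 2·min(tails, 0.5).
  Larger samples use the normal approximation with tie correction.
- **Cox proportional hazards**, single covariate, by Newton–Raphson on the
  partial likelihood (Breslow ties default, Efron available). Patients
  marked alive at analysis are censored at their recorded survival months;
  all others are events. The covariate is the log count: the natural-log
  fit of the packaged cohort gives HR 1.461, 95% CI (0.91, 2.36), p 0.119
  — matching the published fit to printed rounding — while log10 gives HR
  2.40 at the identical Wald p; natural log is therefore the reporting
  default and both bases are emitted.
- **Log-rank** (via lifelines) and **Spearman** (via scipy) are standard
  steps wrapped with input validation. On the BRAF-V600E-positive
  cutaneous subgroup (n = 7) dichotomized at ≤ 100 CMC/mL, the standard
  log-rank gives p = 0.075 (Wilcoxon/Tarone-Ware/Peto weightings
  0.078–0.083), close to but not exactly the published p = 0.06; the
  formulation behind that value is not documented, so the discrepancy is
  reported rather than forced.
- **miR enrichment**: fold change Eluate vs Feed by ΔΔCt with U6 as the
  reference, 2^−ΔΔCt.

## The synthetic generators

`make_fov` renders non-overlapping cells by rejection sampling (≤ 1000
attempts per object, then a placement error naming the failing object;
touching-cell resolution is out of scope, matching the mostly non-touching
appearance of cytospin preparations). Nuclei are filled ellipses
(radius 4–7 px at the default scale, axis ratio ≥ 0.75) blurred with
σ = 1/margin_sharpness; stains are painted at 150/255 (foci 240) over a
4 px cytoplasmic shell; background is Gaussian (mean 8, sd 3) and all
channels clip to [0, 255]. CMC nuclei are drawn from the same size
distribution as leukocytes — the patient-like regime; enlarged cell-line
cells can be emulated by widening `nucleus_radius_range`. Debris is a
cluster of 3–6 small disks with no nucleus; its morphology is an
assumption, as the source material does not quantify debris. `make_slide`
distributes slide totals multinomially over FOVs (per-FOV counts are
Poisson-thinned with exact conservation). Objects are placed away from FOV
borders, so border exclusion rarely fires on synthetic slides.

The generators do **not** model optics (PSF, autofocus error), spectral
bleed-through, touching or overlapping cells, intensity heterogeneity
between cells of one class, or spatially varying background. Passing the
counting tests therefore shows the algorithm is correct under clean,
well-separated staining with the stated noise — not that it is robust to
the full artifact spectrum of real slides, where the manual review step of
the semi-automated workflow remains essential.

`simulate_separation` draws retained leukocytes Binomial(feed, efficiency)
with default efficiency 0.985 (the separator's measured 98–99% regime) and
zero CMC loss by default (spiked cells are observed fully recovered in the
Eluate). `make_cohort` draws lognormal counts (defaults: ln-mean 5.66 ≈
ln 287, ln-sd 1.7, matching the observed count spread) and exponential
survival with hazard `h₀·exp(β·ln count)` (defaults β = 0.38 ≈ ln 1.46,
h₀ = 0.005/month, censoring at 36 months).

## Problem sizes and numerical choices

Default synthetic FOVs are 384×384 px — a scaled-down field chosen so a
full slide (a few thousand cells over tens of FOVs) renders and counts in
seconds; accuracy checks span 5–500 true CMCs against 1000-leukocyte
backgrounds over 20 seeds, and control-specificity checks use ten
5000-cell marker-negative slides. The isodata iteration breaks bounded
oscillations (possible through rounding) by returning the current iterate;
tests accept any exact fixed point. Cox Newton–Raphson starts at β = 0,
converges at |step| < 1e-10 within 100 iterations, and raises an
informative error on monotone partial likelihoods (no finite MLE), zero
events, or constant covariates. Degenerate single-bin histograms raise in
`isodata_threshold` but yield an empty nucleus list in `nuclear_mask`
(a blank FOV is valid input). Thresholds on slides with fewer than 10
cells must be supplied explicitly.

## Known limitations

- Per-cell red thresholds derived from a *single-class* slide (e.g. all
  leukocytes) split the unimodal intensity peak, moving ~25% of
  leukocytes to the null class; CMC and dual tallies are unaffected. Use
  explicit thresholds for such degenerate slides.
- Debris tallies count connected clusters, which may fragment relative to
  the generator's seeded blob count; debris is reported, not accuracy-
  bounded.
- The exact published rule set (supplementary material) and its numeric
  cut-offs are unavailable; the six rules here are reconstructed from the
  published description and all cut-offs are configuration, not constants.
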