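# Methods

This note documents the models, conventions and numerical choices behind the
package, and what the synthetic-data generators do and do not emulate.

## ABR threshold model and cohort statistics

A threshold grid holds one subject-ear's ABR thresholds on the fixed tone
grid (2.0, 2.83, 4.0, 5.66, 8.0, 11.3, 16.0, 22.6, 32.0, 45.2 kHz) with
stimulus levels restricted to 10–100 dB SPL in 3 dB steps.  A threshold at
the 100 dB ceiling with no identified response is stored as a flagged
100 dB SPL value ("NR" in CSV); by default it participates in group means
(conservative, it biases means down rather than dropping the worst ears) but
is excluded from Shapiro–Wilk normality checks and from band means of
threshold *shifts*.  When both ears were measured, ears are averaged
elementwise before any cohort statistic, so each animal contributes once.

**Reference distributions.**  Per age group (n ≥ 4 required) the reference
carries per-frequency mean and SD (n−1 denominator), per-frequency 25th/75th
percentiles, and the same percentiles of the distribution of subject-mean
thresholds.  Percentiles use linear interpolation between closest order
statistics (the NumPy/spreadsheet default).  This convention is fixed rather
than configurable-by-accident: with quartile classification resting on P25
and P75, a silent change of percentile definition would relabel animals.

**Quartile classification.**  The default rule compares the subject-mean
threshold to the interquartile band of subject means: strictly below P25 →
lower, strictly above P75 → upper, otherwise normal.  The subject mean is a
single reproducible score and averages per-frequency noise down by √10.  An
alternative per-frequency rule (≥ 80% of frequencies outside the band, both
the fraction and the rule selectable) is provided because published
classifications of this kind are often described only loosely ("generally
below the 25th percentile").  Classification refuses grids with more than
half the frequencies missing.

**Threshold shifts.**  shift(f) = threshold(f) − juvenile reference mean(f).
Band means split at 8 kHz with 8 kHz inclusive in the low band.

**Rank tests.**  Two samples: Mann–Whitney U, two-sided.  Tie-free samples
with n₁·n₂ ≤ 400 use the exact null distribution.  Tied samples are handled
by full enumeration of all C(n₁+n₂, n₁) group assignments (two-sided p as
the fraction of assignments whose U deviates from n₁n₂/2 at least as much as
observed) whenever that count is ≤ 2·10⁵ — this covers every small-cohort
comparison in practice and makes identical samples return p = 1 exactly.
Larger tied problems fall back to the normal approximation with tie
correction; enumerating assignments is combinatorially impossible there
(C(40,20) ≈ 1.4·10¹¹).  Three or more samples: Kruskal–Wallis.  Degenerate
all-tied input returns p = 1 with a warning.  Shapiro–Wilk reports accompany
every comparison but never gate the rank tests; 0.05/0.001 significance
flags are presentation-layer only and no multiple-testing correction is
applied.

## Cytocochleogram construction

Coordinates in marker files are 0-based pixel centers (y down) with a
per-file µm/px scale; all derived quantities are µm and percent distance
from apex.  Segment arc length is the sum of vertex-to-vertex Euclidean
distances (consecutive duplicate vertices collapsed).  Markers are projected
to the true nearest point of the polyline — perpendicular projection onto
each segment clamped to its endpoints, ties broken toward the smaller arc
length — rather than snapped to the nearest vertex, since vertex spacing is
a digitization artifact.  Markers farther than 200 µm (configurable) from
the path are flagged orphans and excluded with a warning.

The three segments concatenate apical → middle → basal; positions are
normalized to [0, 100]% of the total length and binned into twenty 5% bins,
half-open [a, a+5) with the last bin closed.  loss% = 100·missing/(present+
missing) per bin and cell class.  A bin with no valid marker of a class, or
fully covered by a preparation-artifact span, is excluded (loss undefined)
rather than reported as 0%.  Artifact spans preserve the length axis — the
damaged stretch still contributes to total length so downstream positions
stay correct — they only suppress markers.  If a segment trace is lost
entirely its length may be imputed via configuration; results are then
flagged approximate.

**Place–frequency map.**  position% = anchor% + 82.5·log₁₀(f/anchor kHz).
Two presets: `muller2005` (the mouse map d(%) from base = 156.5 −
82.5·log₁₀ f, re-expressed from the apex; apex ↦ ≈ 4.84 kHz) and
`anchored_9khz` (same slope re-anchored so 40% from apex ↦ 9 kHz).  The two
disagree — the 40% ↦ 9 kHz reading is inconsistent with the standard CBA/J
formula, which puts ≈ 14.8 kHz at 40% — and the published sources for such
anchors are ambiguous, so both are provided and neither is asserted as
canonical; `anchored_9khz` is the default.  Band means over bins assign
each bin by its center frequency; the default is the unweighted mean of bin
loss over non-excluded bins, with a cell-count-weighted option (reported
figures of this kind rarely state which was used).

## Fluorescence quantification

Pipeline order: rolling ball → ROI isolation → 8-bit conversion → intensity
floor → AUC integration → normalization.

**Rolling ball.**  The background is the grayscale opening of the image with
a spherical-cap structuring element of radius r (heights √(r²−dx²−dy²),
intensity radius equal to the spatial radius), computed as an exact erosion
followed by dilation restricted to the image domain; no large-radius
downsampling approximation is used (irrelevant at r = 6).  The background is
clipped below at 0 and, for integer images, the subtracted result is rounded
back to the integer grid — so a constant image maps exactly to zero and an
isolated sub-ball-width spike survives at full value.  Opening is
idempotent, and the output never exceeds the input.

**8-bit conversion.**  16-bit images map by the fixed full-scale linear map
v ↦ round(v·255/65535), *not* per-image min-max stretching: image pairs
acquired with identical settings must remain comparable after conversion.
The display-range behavior is available as `mode="display_range"` for
completeness but breaks cross-image comparability.

**Floor at 75.**  Pixels below 75 counts are zeroed; pixels ≥ 75 *retain
their value*.  This is a floor, not a binarization — the AUC integrates
intensity, and binarizing would silently turn it into a pixel count.  The
boundary value 75 is kept.

**Normalization.**  AUC / number of OHCs (KCNQ4; at least 3 OHCs required)
or AUC / SV length (KCNQ1; the rectangle ROI's long-axis extent in px, or µm
when a scale is set).  Per-animal summaries average normalized intensity
over the apical, middle and midbasal turns.  Absolute intensities are only
comparable within images acquired and processed identically; the package
reports ratios between groups for that reason.

## Age associations

Simple OLS of the outcome on absolute age in days (never on age-group
index); slope is also reported per 50 days.  R² = r² for the simple fit; p
is the two-sided p for Pearson r from the t distribution with n−2 df.
Constant x is rejected; constant y returns slope 0 with r flagged undefined.
Group-fit comparison: Δ = intercept_B − intercept_A and ε = (slope_B −
slope_A) × age span — ε is defined operationally as the growth of the
between-group difference over the observed age range.  The shift-per-loss
coupling is the OLS slope of high-band threshold shift on OHC loss scaled to
dB per 10% loss, with its t-based 95% CI.  Regressions pool frequencies to
per-animal band means by default rather than treating frequencies as
repeated observations of one animal (no mixed-effects modeling is offered;
plain OLS is the method being reproduced).

## Synthetic-data generators

**Cohorts.**  Defaults are the study conditions: groups of 84/49/22 animals
at mean ages 34/80/188 days (age jitter SD 6/11/14 d), a planted "upper"
subgroup of 25% offset by +16 dB at all ages, band-specific progression of
8.0 dB per 50 days above 8 kHz and 1.5 dB below, and per-frequency Gaussian
noise with SD interpolating 12 dB (juvenile) → 18 dB (adult).  Noise is
independent across frequencies with no subject-level random effect; the
subject-mean classification score then has SD ≈ 12/√10 dB, which is the
regime the planted-subgroup recovery checks assume.  Thresholds are snapped
to the 3 dB level grid and clipped to [10, 100]; clipped ceiling hits are
flagged no-response.  Because 16 dB is not a multiple of 3, the noise-free
planted offset appears as 15 or 18 dB depending on where the baseline falls
on the grid.  The default juvenile audiogram (flat 30 dB SPL ≤ 8 kHz rising
to 45 dB at 45.2 kHz) is a configuration default chosen to sit far enough
above the 10 dB instrument floor that floor censoring (< 5% of draws) does
not compress the recorded within-group SD; it is not measured data.  At the
oldest age the fastest-progressing animals do reach the 100 dB ceiling, so
end-to-end slope estimates through the generator are attenuated relative to
the generating slope — a deliberate property of modeling the instrument,
visible in the README example.

**Spirals.**  A planar Archimedean spiral (~1.75 turns, ≤ 5 µm vertex
spacing) trimmed to the target arc length (default 5330 µm, matching the
~5.33 mm organ of Corti) and cut into three equal-arc segments.  Three OHC
rows at 6.5 µm pitch (≈ 2460 OHCs) and one IHC row at 7 µm (≈ 760), close to
real mouse counts; markers sit at small lateral offsets from the traced
junction line.  Each cell is missing with probability loss_profile(position%,
age), evaluated per cell class; artifact spans suppress markers while the
length axis is kept.  Geometry is otherwise irrelevant downstream — only arc
length and ordering matter — so no attempt is made at anatomical 3D shape.

**Fluorescence images.**  Deterministic structure (Gaussian puncta with
optional fixed positions, or a uniform stripe) on a constant-plus-gradient
background, additive Gaussian noise (Poisson shot noise behind a flag),
quantized to 8- or 16-bit with clipping (warned).  The ground-truth AUC and
normalized intensity are obtained by running the *same* quantification
pipeline on the noise-free twin, so recovery tests compare like with like.
No optics are simulated: no PSF, no z-stacks, no chromatic effects — passing
recovery tests shows the measurement chain is unbiased under the stated
noise, not that segmentation or acquisition artifacts of real confocal data
are handled.

**What passing tests show.**  The generators realize exactly the statistical
structure the analysis assumes (independent Gaussian noise, Bernoulli cell
loss, additive image noise).  Real cohorts have correlated within-subject
thresholds, spatially clustered hair-cell loss, and structured backgrounds;
results on synthetic data bound what the pipeline can do under its own
assumptions and verify the arithmetic, not the biology.

## Problem sizes and determinism

Every generator takes an explicit seed and is bit-reproducible given it.
The test suite and the acceptance script use desk-scale sizes chosen to keep
Monte-Carlo error well inside the asserted tolerances: full-size cohorts
(n = 84) for classification, one full-length spiral (~2500 OHC sites) for
binning recovery, 200 replicates for CI coverage, 20 images of 48×48 px for
the exact morphological-oracle comparison, and 256×256 px images for
quantification recovery.
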