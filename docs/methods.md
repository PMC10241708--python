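# Methods

This note documents the models, numerical choices and limitations of
`vesselquant`, in the spirit of a methods supplement. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Optical density and stain separation

Brightfield chromogens follow Beer–Lambert absorption, so per-channel
optical density `OD_c = log10(I0 / I_c)` with `I0 = 255` is linear in
the amount of deposited chromogen. Intensities are floored at 1 before
the logarithm (`I_floor = 1`), bounding OD at `log10(255) ≈ 2.407` while
preserving order; without the floor a fully opaque pixel would map to
infinite OD.

A pixel stained by several chromogens has OD vector `o = V·a`, where the
columns of `V` are unit color vectors (one per stain, non-negative,
Euclidean norm 1, full column rank enforced) and `a` the per-stain
amounts. Unmixing solves the least-squares problem per pixel and clips
negative amounts to zero; exact non-negative least squares is available
as a config option (`method="nnls"`) and differs only for pixels whose
noise pushes the unconstrained solution negative. Stain vectors are
*configuration*, not estimated from images: the defaults are brightfield
presets for a red chromogen (liquid-permanent-red-like, absorbing
green/blue) and a blue chromogen (absorbing red/green), unit-normalized.
Anyone with measured vectors for their scanner should override them in
the run config.

The "256-grade" stain layer maps `[0, od_max]` linearly onto 0–255 with
numpy's round-half-to-even and saturation above `od_max`. The default
`od_max = 2.0` covers realistic chromogen densities; the value only
rescales the binarization threshold, it does not affect OD-space
metrics.

Two error regimes matter for the round trip render→deconvolve. On the
continuous (float transmittance) forward model the unmixing is a linear-
algebra identity and errors are at machine precision. Through the 8-bit
scanner path, intensity rounding alone injects OD error that grows with
OD (≈ `0.5/(I·ln10)`, i.e. ~0.09 near OD 2), so quantized-path checks
use an RMSE criterion over typical amount ranges rather than a max-abs
one.

## Synthetic images

The generator emulates exactly the features the measurement chain is
sensitive to, and nothing else:

- **Vessels** are elliptical annuli: an open lumen (OD 0) surrounded by
  a CD34+ wall of thickness 1.5–3 µm (uniform), eccentricity up to 0.6,
  random orientation. Lumen diameters are log-normal (default median
  10 µm, log-sd 0.45), floored at 4 µm — strictly positive and
  right-skewed, like real vessel calibers. The ground-truth table
  reports the **outer** minimal caliper diameter (lumen + both walls),
  which is what the detector measures after hole filling.
- A configurable fraction of vessels (default 25%) get a **C-shaped
  wall** with a ≤ 4 px break — the incomplete-staining condition the
  repair stage exists for.
- Covered vessels carry an **α-SMA mural ring** (2 µm thick, OD 0.8)
  directly outside the wall; uncovered vessels a faint ring (OD 0.05).
  Exactly `round(f·n)` vessels are covered.
- **Distractors** (single CD34+ cells) are discs of 1–3 µm diameter,
  below the 4 µm size floor even after segmentation-induced blur;
  default on, 1.5 per vessel.
- Optional **stroma patches** (α-SMA OD 0.4 blobs) and a uniform
  background stromal OD (0.02) exercise the stromal metrics.
- Objects are placed with disjoint bounding circles, ≥ 12 px clearance
  (so a 3 px dilate/erode cycle can never merge neighbors) and placement
  is largest-first; failure after bounded retries raises a layout-
  infeasible error rather than silently overlapping.

Rendering adds Gaussian noise *in OD space* (sd in OD units) before
exponentiating to intensity, then rounds to 8 bits. Same seed ⇒
byte-identical layout and image.

Not simulated: scanner optics, focus artifacts, tissue folds, fat and
necrosis (QC exclusion is modeled only as a mask), nuclear texture,
CD34+ fibroblast-like staining, and genuinely touching vessels. Passing
recovery tests therefore show the chain is *self-consistent and exact on
clean geometry*, not that it is robust to every histological artifact; on
real slides the visual threshold choice and pathologist QC absorb that
variability.

## Segmentation

Threshold (`layer ≥ t`, with `t` fixed at 64 by default — the study-era
practice of choosing by visual evaluation — or by Otsu's criterion via an
exhaustive 0–255 between-class-variance sweep), then binary median filter
over a radius-2 disc, then the repair sequence dilate(r=3) → fill enclosed
holes → binary mean filter → binary median filter → erode(r=3).

Numerical conventions, each chosen to keep every stage binary-in/
binary-out and deterministic:

- A *mean* filter on a binary image is interpreted as a strict majority
  vote (> 0.5 after averaging); over a disc footprint with an odd pixel
  count this coincides with the binary median, so the mean+median pair
  of the repair sequence is applied as two successive majority votes.
- Filters pad by edge replication so constant masks are fixed points.
- Hole filling floods from the image border; holes open to the border
  are not filled.
- Erosion treats the image edge as foreground so border-touching objects
  are not doubly eroded after the matching dilation.
- Components are 8-connected (thin diagonal walls stay whole).
- The enlargement radius (3 px = 0.75 µm at 4 px/µm) closes staining
  breaks up to ~2× its width; it is config-exposed, not a claim about
  any particular historical parameter choice.

The size filter is a minimal-Feret floor of 4 µm — doubling as the
"don't count single CD34+ cells" rule — applied to repaired components.

## Minimal Feret diameter

Computed by rotating calipers on the convex hull of the *pixel corner
points* (each pixel contributes its four corners), so a single pixel is
1 px wide and rasterization bias is at most one pixel unit. The minimum
width of a convex polygon is attained with one jaw flush against a hull
edge, so scanning edges and taking the farthest-vertex distance is
exact. The independent test oracle computes widths purely by projection
(peak-to-peak of point projections), over a dense 3600-angle grid
augmented with the hull-edge normal directions: the grid alone can miss
the V-shaped minimum by ~10⁻³ of the object scale, while the normals pin
it exactly.

## Perivascular and stromal scoring

The perivascular band of a vessel is the set of non-vessel pixels within
10 px **Euclidean** distance of its footprint (2.5 µm at 4 px/µm; the
distance is specified in pixels, matching the original convention, with
µm available in config). Pixels near two vessels are assigned to the
nearer one, ties to the lower label, so no α-SMA is double-counted.
PVI is the median α-SMA OD over band pixels (per vessel, and pooled per
image); α-SMA outside bands is excluded from perivascular scoring.

FCV calls a vessel "covered" when its perivascular median OD strictly
exceeds a cutoff. The cutoff convention is deliberately **cohort-level**
(median of all vessels' perivascular ODs): a per-case median cutoff
would force FCV ≈ 0.5 for every case and carry no information; the
per-case option is retained in config for comparability. Stroma is
defined as α-SMA OD ≥ 0.15 (config) outside vessels and exclusions.

## Case aggregation and ICC

Default aggregation treats all passing cores of a case as one tissue
sample: vessel tables concatenated, areas summed, then density/median/
PVI/FCV computed on the pooled data (pooled stromal intensity uses an
area-weighted median of core medians, since pixel data are not retained
at this stage). The alternative median-of-cores mode summarizes each
core first. Both are reported because either reading is defensible;
they coincide for balanced cores.

Inter-core concordance is the one-way random-effects ICC(1,1),
`(MSB − MSW) / (MSB + (k0 − 1)·MSW)` with the unbalanced effective
replicate count `k0`, and an F-distribution confidence interval. Cores
are interchangeable replicates, which is why the one-way (agreement)
form is the right one; the estimate is cross-checked against an
independent implementation in the tests. Identical replicates (MSW = 0)
return ICC 1 with a degenerate CI.

## Cohort statistics

- **Dichotomization**: low iff value ≤ cohort median — the "low (0–50%)"
  group includes the median, matching the interval labels.
- **Spearman**: midrank ties; p from the t approximation for n > 10 and
  from full n! permutation enumeration for n ≤ 10.
- **Cox PH**: Newton–Raphson on the partial likelihood with step
  halving; Breslow tie handling by default (the common clinical-software
  default of the study era), Efron selectable; covariates centered for
  conditioning; convergence at |Δ log-lik| < 1e-9, max 50 iterations.
  Monotone likelihood (complete separation) and singular information
  raise explicit errors instead of returning a silently huge HR.
  Categorical covariates are dummy-coded against explicit reference
  levels (e.g. grade 1, N0, receptor-positive); missing covariates are
  handled complete-case per model with n reported.
- **Subgroup forest**: univariable HR of the size group per subgroup;
  subgroups with < 2 cases, a single group level or zero events are
  flagged not-estimable, never fitted.

## Synthetic cohorts

Per-case size is log-normal (median 10 µm, log-sd 0.35); the high group
is `size > cohort median`; event times are exponential with hazard
`h0·exp(β·high)` (`h0 = 0.01` per month ⇒ median ≈ 69 months at
baseline, a realistic disease-specific-survival scale); censoring is
independent exponential with its rate solved (Brent root finding) so the
expected censored fraction matches the request. Clinical covariates are
drawn independently of size — the null observed for clinicopathologic
factors — so adjusted models should recover the marginal effect, and do.
The exponential baseline is the simplest PH-consistent generator with a
closed-form truth; it does not model non-proportional hazards, competing
risks or covariate-dependent censoring.

In the image-backed pipeline, cases additionally differ in mean caliber
(between-case log-sd 0.3 vs within-case 0.3) and mural coverage, which
is what gives the per-core medians a realistic intraclass correlation;
per-core vessel counts are Poisson around the configured mean.

## Problem sizes

Defaults are desk-scale: 768×768 px cores at 4 px/µm (≈ 0.037 mm², a
sub-region of a 1 mm TMA core), ~8 vessels per core, 20–30 cases for
image runs; statistical calibration uses 300–500-case simulated cohorts
and 500–1000 replicates. These sizes keep every check fast while leaving
all estimators in their asymptotic comfort zone; nothing in the
implementation depends on them.

## Known limitations

- Stain vectors are assumed known; no automatic vector estimation.
- Vessels are simulated disjoint; merged/abutting real vessels would be
  segmented as one object.
- The 8-bit quantized path limits OD fidelity near saturation (see
  above); metrics are computed from the float OD maps wherever possible.
- PVI pooling across cores operates on per-vessel medians, not raw band
  pixels.
- No proportional-hazards diagnostics beyond the explicit convergence
  and separation checks; no competing-risks decomposition beyond
  cause-specific coding.
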