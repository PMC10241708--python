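# vesselquant

Quantitative morphometry of tumor blood vessels on dual-stained
brightfield IHC sections, and the survival analysis that links vessel
size to outcome.

Tumor angiogenesis produces vessels that are abnormal in number, size
and mural support. On a section double-stained for an endothelial
marker (CD34, red chromogen) and a pericyte/smooth-muscle marker
(α-SMA, blue chromogen), three tissue metrics summarize a tumor's
vasculature:

- **MVD** — microvessel density, detected vessels per mm² of tissue;
- **vessel median diameter** — the median, across a case's vessels, of
  each vessel's *minimal Feret diameter* (the smallest distance between
  two parallel tangents; robust to oblique sectioning of a tube);
- **perivascular α-SMA status** — the median α-SMA optical density in
  the 10-pixel band around each vessel (PVI), and the fraction of
  vessels whose perivascular OD exceeds a cohort-level cutoff (FCV).

Case metrics are dichotomized at the cohort median into "low (0–50%)"
and "high (> 50%)" groups and tested against disease-specific survival
with Kaplan–Meier curves, the log-rank test, and cause-specific Cox
proportional-hazards models (univariable and covariate-adjusted), with
hazard ratios `HR = exp(β)` and Wald inference per term.

Because slide cohorts of this kind are not publicly deposited, the
package ships a first-class synthetic-data module: vessels are rendered
as elliptical annuli under forward Beer–Lambert stain mixing
(`I_c = 255·10^(−Σ_s A_s V_s[c])`), so color deconvolution, segmentation
and morphometry can all be validated against exact ground truth; cohorts
are simulated with exponential event times under a proportional-hazards
dependence on the size group, so the statistics stage can be checked for
calibration and parameter recovery.

## The image-analysis chain

1. **Optical density**: `OD = log10(255 / I)` per channel (8-bit input,
   intensity floored at 1), linear in chromogen amount.
2. **Color deconvolution**: least-squares unmixing of each pixel's OD
   vector onto unit stain color vectors (configurable; NNLS optional),
   then a 256-grade 8-bit layer per stain.
3. **Vessel segmentation** on the CD34 layer: intensity threshold
   (fixed or Otsu) → binary median despeckle (r = 2 px) → repair of
   broken/hollow profiles (dilate, fill holes, mean+median smooth,
   erode) → 8-connected labeling with a 4 µm minimal-Feret floor that
   drops single CD34+ cells.
4. **Morphometry**: rotating-calipers minimal Feret per vessel, density
   per mm², Euclidean-distance perivascular bands (10 px), PVI/FCV,
   stromal α-SMA area and intensity.
5. **Case aggregation**: triplicate TMA cores pooled as one tissue
   sample (median-of-cores mode available); inter-core concordance via
   one-way random-effects ICC(1,1) with an F-based CI.
6. **Cohort statistics**: Spearman correlations, Mann–Whitney /
   Kruskal–Wallis, median dichotomization, KM/log-rank, Cox PH (Newton
   on the partial likelihood; Breslow ties by default, Efron optional),
   subgroup forest tables.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (30 cases × 3 cores, plus a 400-case clinical cohort with a true
size-group hazard ratio of 3):

```sh
python analysis/01_synthesize_cohort.py
python analysis/02_quantify_vessels.py
python analysis/03_core_concordance.py
python analysis/04_survival_analysis.py
```

which prints, among other things:

```
measured 90 images, 693 vessels (ground truth 693)
case median diameter recovery: 30/30 cases within 10% of truth (worst 0.015)
ICC(1,1) of per-core median diameter: 0.70 (95% CI 0.53-0.83, 30 cases / 90 cores)
[image cohort] log-rank chi2=7.63, p=0.0057
[image cohort] univariable Cox: HR=4.81 (95% CI 1.44-16.07), p=0.0107
[clinical cohort, n=400, true HR 3] univariable HR=3.09 (95% CI 2.38-4.01), p=1.7e-17
[clinical cohort] multivariable (adjusted) HR=3.16 (95% CI 2.43-4.11), p=1.2e-17
```

Read: every rendered vessel was re-detected; case-level median diameters
match ground truth within 1.5%; replicate cores agree (ICC 0.70); the
high-vessel-size group has significantly shorter disease-specific
survival; and a known HR of 3 is recovered by both unadjusted and
covariate-adjusted Cox models. Tables land in `results/`, images in
`scratch/` (regenerated on demand).

A `vesselquant` CLI wraps the same stages for config-driven runs:
`vesselquant all --config run.yaml` (see `vesselquant.pipeline.RunConfig`
for every knob; a seed is mandatory and identical config + seed gives
byte-identical outputs).

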