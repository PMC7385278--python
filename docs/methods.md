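# Methods

`fibroct` quantifies experimental lung fibrosis from micro-CT the way a
preclinical imaging group does for the bleomycin (BLM) mouse model: the
lung is segmented, its voxels are classified into aeration compartments
by fixed Hounsfield-unit (HU) bands, and the poorly-aerated fraction of
total lung volume serves as the in vivo fibrosis surrogate, validated
against ex vivo readouts (per-lobe Ashcroft grades, hydroxyproline).
Because no per-animal raw data are publicly deposited for this study
design, the package ships a synthetic phantom generator with exact
ground truth; every quantitative claim the test suite makes is made
against that ground truth.

## The density-mask model

CT attenuation in lung tissue reflects the air/tissue mix. The package
uses four disjoint HU bands that jointly cover the real line:

| compartment     | HU band          |
|-----------------|------------------|
| hyper-aerated   | < −900           |
| normo-aerated   | [−900, −500)     |
| poorly-aerated  | [−500, −100]     |
| non-aerated     | > −100           |

The normo and poor bands as conventionally printed both contain −500;
the package assigns the boundary to the poor band once (half-open
convention) so every voxel has exactly one class and the integer counts
partition the lung. Voxels outside [−900, −100] are not discarded but
reported as hyper-/non-aerated, which preserves the partition invariant
and exposes consolidation. Fractions are voxel counts per band divided
by the lung voxel count ("normalized on total lung volume"); volumes in
mm³ come from the isotropic voxel spacing (default 50 µm).

The denominator is the *parenchymal* lung: airway lumen is excluded
(lumen air would dilute the fractions and the airways are segmented
separately); vessel voxels are retained by default (configurable) since
vessels serve as alignment landmarks, not exclusions.

**Rind peel.** A segmented lung-mask surface voxel mixes parenchyma
(≈−700 HU) and chest wall (+40 HU) through partial-volume blur, and the
mixture lands in the poorly-aerated band regardless of the underlying
tissue. `quantify_volume` therefore erodes one voxel from the mask
before classifying (`peel_rind`), a standard densitometry peel. The
pure classifier `classify_aeration` never peels, so analyses on
ground-truth masks are exact: with all noise and blur at zero it
returns the true lesion fraction to machine precision.

## Segmentation

The commercial semi-automatic workflow is replaced by a fully automatic
chain whose manual inputs survive as optional overrides:

1. **Airway lumen** — seeded region growing below −850 HU from a
   trachea seed (auto-located as the largest interior air component's
   most superior slice centroid). Leak control: growth proceeds in
   wavefront generations; inside a tube the front tracks the lumen
   cross-section, so a front exceeding `leak_cap` (default 3×) times the
   median of recent established fronts aborts growth — the signature of
   escape into ambient air through a breach. The ramp-up from a point
   seed is excluded from the baseline.
2. **Lung** — voxels below −200 HU inside the body envelope (largest
   non-air component, hole-filled). Morphological closing (radius 2) is
   applied *before* connected-component selection so a crack cannot
   split the lung and cost a chunk at the keep-largest step; the largest
   one or two components are kept (left and right lung are separate
   compartments in the mouse), holes are filled (dense lesions and
   vessels stay inside), and the airway lumen is subtracted.
3. **Vessels** — voxels above −100 HU inside the closed, eroded lung
   hull and adjacent to parenchyma, minus a dilated airway-wall shell.
   Landmarks only; may be empty.
4. **Left/right split** — the sagittal plane through the carina, found
   as the most superior axial slice where the airway cross-section has
   two components; if the tree never bifurcates the split falls back to
   the lung centroid plane with a warning.

Thresholds (−200 body/lung, −850 airway) follow standard small-animal
densitometry practice and are exposed in `SegParams`.

## The phantom generator

The generator emulates the study conditions, not scanner physics
(no projection-domain simulation, no gating, no anatomical vasculature):

- **Geometry.** Five ellipsoid-derived lobes — left (Sx) and right
  cranial/middle/caudal/accessory (Dx Cr, Dx M, Dx Ca, Dx Ac) — inside
  a soft-tissue body, around a trachea that starts well below the body
  apex (the cap above it must survive blur or the chest would read as
  open) and bifurcates into a recursive binary airway tree
  (`airway_depth` generations; 0 = trachea only). The seed jitters lobe
  centres/sizes and branch angles so cohort animals are individuals.
  Ellipsoids are schematic by design: exact ground truth beats
  anatomical realism for validation.
- **Lesions.** Grown by iterative random dilation from seed loci until
  the lesion/lung voxel ratio hits the target exactly. The default 24
  loci reflect the "diffuse single fibroproliferative loci" morphology
  of the aspiration route; `clustering` tilts per-lobe seed weights
  (0 = volume-proportional, the uniform OA regime; ≈5 concentrates
  burden in few lobes, the patchy IT regime). Which lobes are hit in
  the IT regime varies animal to animal.
- **HU synthesis.** Compartment means at the band centres — parenchyma
  −700 ± 60 HU, lesion −300 ± 70 HU, air −1000, chest wall +40 — then
  Gaussian blur (σ 0.6 voxel, partial volume) and additive scanner noise
  (30 HU SD). SDs are small enough that well under 5% of noise-free
  voxels cross a band boundary, so recovery tests measure the pipeline,
  not irreducible class overlap. Unit texture/noise fields are drawn
  once per seed and scaled by the SDs, so raising a noise parameter
  rescales the same perturbation rather than redrawing it — noise
  ladders degrade monotonically.
- **Burden time course.** Zero before onset (day 3), linear rise to the
  peak fraction at day 14, exponential resolution afterwards (3%/day),
  continuous at the peak — the rise-peak-partial-resolution course of
  double-dose bleomycin injury. Default peak fraction 0.25.
- **Cohorts.** Groups of seven animals imaged at days 7/14/21/28. Each
  animal carries a lognormal susceptibility factor (CV 0.25) applied to
  the burden curve; saline animals have zero burden; a drug arm
  multiplies burden by `drug_burden_factor` (default 0.5) from
  treatment start (day 7). Per-animal rng streams derive from the
  master seed, so any animal regenerates identically in isolation.
- **Ex vivo linkage.** Per-lobe Ashcroft latent score = 0.5 + 12 ×
  lobe-local burden + N(0, 0.6), rounded and clipped to the 0–8 scale
  (peak-burden animals grade ≈3.5–4.5, saline grades 0–1);
  hydroxyproline (µg) = 60 + 300 × whole-lung burden + N(0, 10),
  floored at zero. The linkage is linear by construction — it validates
  the correlation machinery, not collagen biochemistry — and its noise
  controls the achievable R² given the burden spread.

What the phantoms do *not* emulate: real parenchymal texture,
breathing-phase variation, beam hardening, lobe fissures, anatomically
consistent lobe preferences of the IT route, and histology sampling
error (grades derive from true lobe burdens, not from simulated
sections). Passing tests therefore demonstrate the pipeline's
correctness and calibration under controlled conditions, not its
accuracy on scanner data.

## Ashcroft analytics

Grades are integers 0–8 (half grades rejected); severity classes are
mild (0–3), moderate (4), severe (5–8) — "severe ≥5" is the same set
given the scale bound. The total Ashcroft score of an animal is the
mean over its five lobes (all lobes required unless explicitly
overridden). The lobe-heterogeneity index is the variance of the lobe
medians (0 when all lobes share one median); alongside it the package
reports the across-lobe Kruskal–Wallis omnibus with Dunn's pairwise
comparisons. The "% moderate and severe lesions" readout used in
correlations is the frequency of grades ≥4 over the graded units
(per-lobe records by default).

## Statistics

- `linear_fit`: ordinary least squares on per-animal points,
  R² = 1 − SSres/SStot; constant y reports R² = 0 with a warning.
- `one_way_anova_dunnett` / `tukey_hsd`: omnibus F plus Dunnett
  many-to-one or Tukey all-pairs adjusted p values (scipy
  implementations; the Dunnett multivariate-t integration is seeded for
  reproducibility). Zero-variance degenerate inputs return p = 1.
- `two_way_anova_dunnett`: group × day ANOVA (statsmodels, type-II)
  with per-day Dunnett comparisons versus control; single-day designs
  collapse to the one-way analysis.
- `kruskal_dunn`: Kruskal–Wallis H with tie correction; Dunn's pairwise
  rank z tests with Bonferroni family adjustment (configurable to
  unadjusted). All-tied data return H = 0, p = 1.
- `treatment_effect`: two modes, both reported because published
  percent effects rarely state their reference —
  `inhibition_of_increase` = 100·(disease − treated)/(disease − saline)
  and `reduction_vs_disease` = 100·(disease − treated)/disease.
- `null_familywise_error`: Monte-Carlo calibration harness; each
  procedure's familywise type-I error under its Gaussian/exchangeable
  null (three groups of seven, 2000 replicates) must sit near the
  nominal 0.05.

## Problem sizes and numerical choices

Full-resolution analyses (recovery error, Dice, noise ladders) run on
128³ phantoms — the paper-scale 512-slice grids would carry the same
physics at 64× the memory for no extra validation power. Cohort-level
analyses (time courses, three-arm effect recovery) run at 64³ with the
full segmentation pipeline per scan; truth-only statistical studies use
48³. These sizes are the package's own choice of smallest grids at
which airway/lung geometry remains resolvable.

Voxel indexing is 0-based, axis order (z, y, x), spacing in µm
internally and mm in NIfTI/MetaImage headers. HU volumes are stored as
float32 (uint16 containers use slope 1 / intercept −1024); label masks
round-trip losslessly. The pipeline writes uncompressed `.nii` so
re-runs are byte-identical (gzip embeds timestamps). All pipeline
randomness derives from one master seed recorded in the run manifest
together with SHA-256 checksums of every output.

## Known limitations

- The airway leak-control heuristic keys on wavefront growth; a breach
  wider than the trachea, or a leak into a cavity of similar calibre,
  will not trip it.
- Carina detection assumes the first axial bifurcation is the main one;
  at 64³ and below the bronchi are often sub-voxel and the left/right
  split falls back to the centroid plane.
- The 2D "projection" analysis is a mean-intensity sagittal slab over
  in-lung voxels with configurable thickness; published 2D analyses
  rarely define their operator, and other choices (max-intensity, fixed
  anatomical planes) would shift the 2D-vs-3D correlation.
- Dice ≥ 0.95 and ±3-percentage-point recovery hold under default
  phantom noise; heavier noise (≥120 HU SD) degrades both, and the
  tests document the degradation rather than hide it.
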