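# Methods

This note documents the models, conventions and numerical choices behind
`osteochip`, in the order of the five analysis families.

## Conventions

All image volumes are ordered `(channel, z, y, x)`; every conversion
between micrometres and voxels passes through the stack's `voxel_size`
`(dz, dy, dx)`, default `(2.0, 0.42, 0.42)` μm — the geometry of a 20X
0.8 NA confocal acquisition at 0.42 μm/pixel with a 2 μm z step. The
pronounced z anisotropy (a voxel is ~23× taller than it is wide) shapes
several choices below. Tables are plain CSV (comma, `.` decimal, UTF-8);
stacks are OME-TIFF with explicit axis metadata. Connected components use
26-connectivity in 3-D throughout. Every CLI analysis writes a JSON
run-manifest (config, seed, package version) beside its outputs.

## 3-D single-cell nascent-protein quantification

**Procedure.** Nuclei are thresholded (Otsu per channel by default, fixed
values optional), lightly cleaned, split where merged, and volume-filtered;
the resulting labels seed a watershed on the inverted combined
actin + nascent intensity landscape that assigns every foreground voxel to
exactly one cell, restricted to the seed bounding box padded by
`crop_pad_um` (default 10 μm). Per cell, the extracellular (pericellular)
mask is the set difference `nascent AND NOT actin`: the actin mask is
treated as the cell-body mask, so whatever nascent signal survives the
subtraction lies outside the cell. Cells are classified *negative* (total
nascent voxels below `detection_min_voxels`, default 5), *restricted*
(signal present, subtraction empty) or *secreting* (extracellular voxels
remain). Volumes are voxel counts × voxel volume (μm³); mean intensities
are reported alongside but never drive classification.

**Numerical choices.**
- Morphological cleaning uses a lateral-only (in-plane) opening. A 3-D
  element erodes small nuclei to nothing because they span only 2–3 z
  slices at the default 2 μm step.
- Merged nuclei are split by watershed on the Euclidean distance transform
  (computed with physical sampling, so anisotropy is respected). Candidate
  markers are local maxima of the distance map; within each connected
  component they are accepted greedily in decreasing depth subject to a
  minimum physical separation (`nucleus_min_separation_um`, default 5 μm),
  which prevents plateau maxima from oversplitting a single nucleus.
- Cells whose territory touches the lateral image border are flagged
  (`border_touching`) and excluded from volume statistics but kept in the
  class counts, since truncated volumes would bias distributions while the
  phenotype call is usually still valid.
- Live/dead counting thresholds each channel, filters components below
  `min_object_volume_um3`, and counts double-positive objects once, as
  dead (a membrane that admits ethidium is compromised regardless of
  residual calcein signal).
- Collagen positivity: a cell is positive when its nearest-nucleus
  territory holds at least `collagen_min_overlap_voxels` voxels above the
  channel threshold; the fraction is over all segmented nuclei.

## Synthetic cell stacks

The generator renders geometric idealizations, not realistic morphologies:
an ellipsoidal nucleus (equivalent radius ~N(4.0, 0.4) μm with fixed
0.85 : 1 : 1.1 axis ratios), a filled actin cell body extending 2 μm beyond
the nucleus, and — depending on the drawn phenotype — nascent signal in
the cytoplasm only (*restricted*) or cytoplasm plus a 2 μm pericellular
shell (*secreting*). The actin body is filled rather than a hollow shell
because the analysis contract subtracts the actin mask as the cell-body
mask; a hollow shell would let intracellular nascent signal "leak" into
the extracellular mask by construction. Cells are placed by rejection
sampling with a 15% safety gap between outer extents, so rendered cells
never touch; a bounded attempt budget turns impossible requests into a
`GeometryInfeasibleError`. Gaussian read noise (default sd 3 on signal
amplitudes of 150–200) and optional Poisson shot noise are applied last;
all ground truth (class, centroid, voxel counts) is computed from the
noiseless masks.

What passing tests therefore show: the pipeline recovers phenotype
fractions and volumes exactly when masks are crisp and cells are disjoint,
and within a few percentage points under read noise. What they do not
show: robustness to touching cells, partial-volume effects, z-dependent
signal attenuation, optical PSF blur, or irregular cell shapes — none of
which the generator emulates (attenuation compensation is explicitly out
of scope).

## Hertz nanoindentation

A rigid sphere of radius R indenting an elastic half-space obeys
F(δ) = (4/3)·E/(1−ν²)·√R·δ^{3/2}. Because the law is linear in E, the fit
over the indentation window (default 1–4 μm) is closed-form least squares
of load against δ^{3/2} through the origin — deterministic, with no
initialization. Defaults: tip radius 25 μm, cantilever stiffness 0.5 N/m
(metadata only; compliance is assumed handled upstream by the instrument),
Poisson ratio ν = 0.5 for incompressible hydrogels, configurable. Re-zeroed
curves that do not span the window raise `InsufficientRangeError` rather
than silently fitting a narrower range.

Contact detection estimates the baseline from the first 20% of samples
(median and MAD-scaled sd with a floor of 1e−4 × load range, so noiseless
curves keep a nonzero band), finds the first sustained crossing above
baseline + 5 sd, then refines to sub-step precision by regressing
(F − baseline)^{2/3} — linear in position under the Hertz law — over loads
between 5% and 50% of the maximum excursion and extrapolating to zero. The
refinement is what brings noiseless recovery to machine precision and the
1%-noise bias below 1%; it falls back to the coarse crossing when the
regression is degenerate. Per-curve failures in array fitting are flagged
`accepted=False` with the error recorded, never dropped; summaries use
accepted entries only.

## Hydrogel diffusion

The chamber (width W = 1.2 mm, flanked by 250 μm channels) is modeled as
1-D diffusion with both edges held at the source concentration S and zero
interior initial condition. The profile is the exact fixed-boundary
solution — the two erfc fronts plus all their reflections — evaluated as
the Fourier sine series C/S = 1 − Σ_odd (4/mπ) sin(mπx/W) exp(−m²π²Dt/W²),
truncated adaptively (next mode < 1e−12). Before the fronts meet this
coincides with the bare two-front superposition; afterwards the reflection
terms keep the edges pinned at S instead of double-counting the overlap,
which matters from roughly t ≳ W²/(16D) (≈ 15 min at D = 100 μm²/s). The
same function serves the generator and the estimator, and is validated in
tests against an independent finite-difference solver.

Profiles are sampled at pixel pitch along the quantification line with
bilinear interpolation (transverse averaging optional). Saturation time is
the first sampled time at which the normalized chamber-center intensity
reaches 95% of the source level (configurable); the source level defaults
to the first frame's line-endpoint (perfusion-channel) intensity when not
supplied. Diffusivity is estimated by least squares over all informative
(non-flat, t > 0) frames jointly: for each candidate D the amplitude is
profiled out analytically (the model is linear in S), making the estimate
exactly invariant to intensity rescaling; D is located by a 61-point
log-spaced grid search on [0.1, 1e5] μm²/s refined with bounded scalar
minimization. Fewer than three informative frames (all-flat or
steady-state-only series) raise `NonIdentifiableError`. Background
subtraction is off by default; the generator assumes constant sources (the
perfusion channels are continuously replenished), a simplification over
possibly decaying boluses.

## Cytokine secretome pipeline

The pipeline order is fixed and exposed as a single composed entry point:
impute → variance-filter → z-score → decompose/cluster.

- **Imputation**: each missing entry is replaced by 10% of its analyte's
  minimum non-missing value, a below-detection-limit surrogate. A fully
  missing analyte is an error, named.
- **Variance filter**: analytes with sample variance strictly below 0.9
  (unbiased, n−1 denominator, computed on imputed pre-z-score
  concentrations) are removed. The threshold's scale is inherited from the
  concentration units and is a config value; it is only meaningful on data
  of comparable scale.
- **Z-scoring** uses the population (1/n) denominator (StandardScaler
  convention): columns end at mean 0, variance 1.
- **PCA** runs on the standardized sample × analyte matrix; component
  signs are fixed so each loading vector's largest-magnitude element is
  positive, removing eigenvector sign indeterminacy from results and
  tests. Analyte contributions to PC1/PC2 are squared loadings weighted by
  explained-variance fractions, normalized to sum to 1, ties broken
  alphabetically.
- **Clustering** uses correlation distance d = 1 − Pearson r between
  analyte columns with complete linkage (merge heights therefore
  non-decreasing); the dendrogram is exportable as Newick text.

The two-dataset design mirrors multiplex practice: the MFI (raw
fluorescence) table drives sample-space PCA — with the exogenously spiked
analytes IL-1β and TNF-α excluded, since their levels are
experimenter-controlled and would dominate sample clustering — while the
concentration table drives analyte clustering with the full post-filter
panel. The MFI path applies imputation and z-scoring but no variance
filter (the concentration-scale threshold does not transfer to
fluorescence units); the report records this asymmetry. Sample drops
(e.g. a technically failed well) are applied by row position to both
tables before any processing and logged.

The synthetic table generator produces the full factorial design (2 sexes
× 2 conditions × 2 compartments × 2 days × 3 replicates = 48 samples, 20
analytes) with log-normal values around fixed per-analyte baselines,
multiplicative factor effects (default: a broad inflammation signature
led by IL-6, IL-8 and the CCL chemokines, plus compartment-skewed IL-6/
IL-8), missing-completely-at-random gaps, and the two spiked analytes
strongly elevated in inflamed rows. It does not emulate donor-level random
effects, plate/batch effects, or detection-limit censoring.

## qPCR

Relative expression is exactly 2^(Ct_reference − Ct_target) against the
housekeeping gene, nothing more: no inter-plate or batch normalization is
applied, because only the single formula is defined for this assay. The
reciprocal identity (swapping the two Ct values inverts the fold change)
holds to floating precision and is property-tested.

## Problem sizes and runtime envelope

The test suite and the acceptance script run on one CPU in a few minutes:
classification recovery uses 100-cell stacks of 40 × 512 × 512 voxels
(3–5 seeds), exactness checks use a 20-cell noiseless stack, Hertz
recovery uses 20 curves per modulus at four moduli, diffusion uses the
default 11-frame series (10 noisy seeds), and the secretome design is the
full 48-sample table. These sizes were chosen as the smallest at which the
recovery statistics are stable; all generators scale to larger stacks and
longer series with the same code path.

## Known limitations

- Thresholding is global per channel (Otsu or fixed); no local/adaptive
  thresholding, so strong illumination gradients would bias masks.
- The watershed territory assignment assumes each cell's signal is
  connected to its seed; detached debris is left unassigned.
- The Hertz fit assumes a parabolic (sphere-on-half-space) contact with no
  adhesion or viscoelasticity; JKR/DMT corrections and relaxation models
  are out of scope.
- The diffusion model is 1-D and isotropic; lateral gradients along the
  chamber's long axis and photobleaching are not modeled.
- Hypothesis testing (ANOVA, Kruskal–Wallis etc.) is deliberately not
  re-implemented; summaries are exported for standard statistics tools.
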