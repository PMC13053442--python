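# Methods

## Scope and rationale

`myocap3d` re-implements, as a tested library, a quantitative workflow for
skeletal-muscle microstructure built around three arms:

1. **3D capillary morphometry** — from a confocal-style image stack of the
   capillary bed to a calibrated vector graph, and from that graph to the
   standard network parameters: length densities (LVm, LVf, LSf, LL), mean
   capillary length (MeanCap), branching density (Br_dens), exterior-angle
   tortuosity and structure-tensor anisotropy.
2. **2D fibre morphometry** — MyHC-based fibre typing from three serial
   immunostained sections (BA-D5 / SC-71 / 6H1), minimal Feret diameters,
   and the intramyocellular lipid (IMCL) area fraction from a Sudan-Black
   mask, measured on the same fibres that were typed.
3. **Cohort statistics** — linear mixed-effects group models with a subject
   random intercept for the repeated-fields design, two-way ANOVA with Tukey
   post hoc tests for fibre-level outcomes, paired within-subject
   intermuscular comparisons, and HbA1c association models.

Because the autopsy image material such workflows are applied to is not
publicly available, every component is exercised end-to-end on **synthetic
phantoms with exactly known vector ground truth**. The phantom generator is
first-class, tested code: its setpoints define the conditions under which
parameter recovery is demonstrated.

## Coordinate and unit conventions

All world coordinates are micrometres, ordered (x, y, z). Image volumes store
their data with axes (z, y, x); `voxel_size = (dx, dy, dz)`. Voxel centres
sit at `(i + 0.5)·d` along each axis. All densities are kept in base µm
powers internally; the customary reporting scale factors (LVm and Br_dens
×10⁻⁶, LVf and LSf ×10⁻⁴, tortuosity ×10⁻³) are applied only at
serialisation (`MorphometryResult.to_table_row`).

The default field emulates the confocal protocol: 387.5 × 387.5 × 100 µm
fields at 0.76 µm pixels and 1 µm optical steps. Axial shrinkage of thick
sections is modelled by compressing z world-coordinates by a factor in
(0, 1] before rasterisation; reconstruction undoes it with a multiplicative
z calibration applied to all z coordinates (and to the reference volume).

## The capillary phantom

The generator grows a spatial graph inside the field box:

- **Trunks** run through the box with directions drawn from an axially
  symmetric Watson-type density ∝ exp(κ·u_z²). κ (`orientation_kappa`,
  default 3.0) controls the orientation concentration and hence the
  anisotropy; the default produces anisotropy near 2.7–2.9, the range seen
  in highly ordered muscles. κ = 0 gives an isotropic network (anisotropy
  → 1).
- **Side branches** (length 15–35 µm, directions isotropic but rejected
  within ~25° of the parent trunk) each create exactly one degree-3 node, so
  the branch count is `round(target_NV · V)` by construction. Requesting
  branching below one branch point per field raises an infeasibility error
  rather than silently clamping.
- **Tortuosity** comes from a transverse sinusoidal perturbation
  (wavelength 40 µm, well above the 5 µm vectorisation step) with random
  phases; amplitude 0 gives exactly straight polylines. The exact
  exterior-angle tortuosity is strictly monotone in the amplitude, and
  `calibrate_tortuosity_amplitude` root-finds the amplitude that realises a
  prescribed setpoint on the generated graph.
- **Length calibration**: after trunks and branches are placed, a final
  branch-free filler trunk is trimmed at the exact arc length that makes the
  total vector length equal `target_LVm · V` (within 2%, usually much
  closer).
- **Clearance**: all centrelines keep a minimum distance of one tube
  diameter plus a margin (2·radius + 3 µm), enforced by KD-tree rejection
  sampling. Capillaries therefore meet only at branch points. This is a
  deliberate generator property: tubes that pass within a diameter of each
  other fuse at rasterisation, which would corrupt the prescribed branch
  count and make branch-density recovery meaningless.

Ground truth (`GroundTruth`) stores the exact graph and the `capmetrics`
outputs on it at the standard 5-µm vectorisation — the same code path the
pipeline's measurements use, so truth and measurement differ only by the
imaging round trip. Tortuosity in particular is *defined* on the 5-µm
vectorisation (the exterior-angle sum of a smooth curve depends on the
sampling step), matching how the metric is used in practice.

Rasterisation marks every voxel whose centre lies within `capillary_radius`
(default 2.5 µm, a typical muscle capillary calibre — a free parameter not
fixed by any imaging protocol) of a polyline, via an exact Euclidean
distance transform with anisotropic sampling. Output is an 8-bit stack
(foreground 200, background 20) with optional additive Gaussian noise
(default off, keeping phantom runs deterministic given the seed).

### What the phantom does and does not emulate

It reproduces the field geometry, voxel anisotropy, axial shrinkage,
density/branching/tortuosity/orientation ranges, and the two-level intensity
structure segmentation sees. It does **not** model the confocal PSF,
depth-dependent attenuation, staining heterogeneity, vessel calibre
variation, or true anastomotic loops. Passing recovery tests therefore
demonstrates correctness of the measurement chain on well-posed input, not
robustness to every imaging artefact of real stacks.

## Reconstruction

- **Segmentation**: Otsu threshold (or fixed), followed by a one-voxel-ball
  morphological closing (edge-padded so border tubes are not eroded) and
  removal of components below `min_object_volume` (default 100 µm³). A d′
  separability guard (class-mean gap over pooled within-class SD < 5) raises
  an explicit empty-segmentation signal on structureless input — thresholding
  pure noise would otherwise percolate into a giant spurious component.
- **Thinning**: topology-preserving 3D curve thinning (Lee et al. 1994, via
  scikit-image). The contract — unit-width 26-connected skeleton, subset of
  the input, component count and loops preserved — is asserted by tests
  rather than tied to one particular directional-pass scheme. Known
  degenerate input: thick *fused* prisms (not tube-like) can over-contract;
  capillary-like input never exercises this.
- **Graph extraction**: nodes at voxels with ≠2 skeleton neighbours;
  clusters of mutually 26-adjacent junction voxels merge into one node at
  their centroid (no distance-based merging); edges carry voxel-centre
  polylines in µm. Pure cycles receive an anchor node with a self-loop.
- **Spur pruning** (default 5 µm, one segment length): iteratively removes
  terminal whiskers and dissolves junctions reduced to degree 2. Together
  with chain smoothing this replaces the interactive manual refinement such
  pipelines traditionally rely on.
- **Chain smoothing** (default σ = 1.5 µm): a Gaussian filter along each
  chain's coordinates (endpoints pinned). Voxel-centre chains carry
  ±half-voxel digitisation jitter; at a 5 µm resampling step that jitter
  masquerades as turning angles and inflates tortuosity by tens of percent.
  The smoothing scale is set by the digitisation scale (about two voxels),
  far below the 40 µm wavelength of real capillary undulation, so true
  curvature is essentially untouched. `skeleton_to_graph` itself performs no
  smoothing (its output satisfies the exact voxel-chain length identity);
  smoothing is a separate, documented step of the standard pipeline.
- **Resampling**: arc-length resampling into 5-µm segments, endpoints
  preserved, final segment possibly shorter. Resampled length is monotone
  non-increasing in the step and converges to the polyline length as the
  step → 0.

Border handling: all skeleton length inside the imaged box counts; no
guard-zone correction is applied. This matches reporting per whole field but
biases tip-dominated metrics at very small fields — thinning retracts free
tube ends by roughly one radius, which is negligible for 100-µm-deep study
fields but visible in toy volumes. Recovery tolerances (length 5–10%,
branching and tortuosity 15%) are quoted at the study field geometry.

## Network parameters

- `MeanCap = (2/3)·L_V/N_V` is computed per field from the field's own
  totals, so the reference volume cancels exactly; cohort summaries average
  per-field MeanCap values.
- Exterior angle = turning angle between consecutive segment directions
  (0 for collinear continuation) — the only convention for which straight
  vessels contribute zero.
- The orientation tensor is length-weighted (`T = Σ ℓ·uuᵀ/Σ ℓ`); with
  uniform 5-µm segments this coincides with the unweighted version but is
  insensitive to the short final segment left by resampling. "Ratio of the
  principal eigenvalues" admits three readings; the default is
  λ₁ / mean(λ₂, λ₃) (1 for isotropy, matching the 1.6–2.8 range of real
  muscle), with `max_over_min` and `max_over_mid` available — the choice is
  a convention, not a recoverable fact.
- Fibre-normalised densities use the fibre model's totals: fibre axial
  length is the z-extent of the field per fibre (fibres run through the
  transverse field); fibre surface is lateral only (no end caps).
- Fibre geometry integrates polygon areas and perimeters trapezoidally over
  the traced planes and extends the first/last plane as constants to the
  stack bounds; diameter is the mean minimal Feret width over planes.

## Fibre typing and IMCL

The serial-section phantom assigns each fibre a type drawn from prescribed
probabilities over {1, 1/2a, 2a, 2a/2x, 2x} and renders the three antibody
channels by the standard positivity convention (type 1 → BA-D5⁺; 1/2a →
BA-D5⁺ SC-71⁺; 2a → SC-71⁺; 2a/2x → SC-71⁺ 6H1⁺; 2x → 6H1⁺). Lipid droplets
(2 px discs, last droplet trimmed) are placed until each fibre's
Sudan-positive fraction equals its drawn IMCL value exactly at pixel
resolution. Sections are mutually misaligned by small integer jitters to
exercise matching.

Analysis mirrors semi-automatic practice with deterministic rules:

- **Matching**: translation-only registration by centroid-cloud means, then
  mutual-nearest-centroid pairing gated at half the median equivalent
  diameter. Serial cryosections justify translation-only at phantom scale;
  unmatched fibres are reported, never dropped silently.
- **Positivity**: per-channel exact Otsu split of the per-fibre mean
  intensities (histogram-free — the histogram approximation misplaces the
  threshold badly for the small, imbalanced samples a section yields), with
  an Otsu-separability gate (η ≥ 0.92) that calls a unimodal channel
  all-negative with a warning instead of splitting noise.
- **Classification** is a total function on the 2³ positivity patterns:
  five patterns map to types, three (all-negative, all-positive,
  BA-D5⁺6H1⁺) to `unclassified`.
- **Minimal Feret**: rotating calipers on the convex hull of the pixel
  centres, plus one pixel width for the silhouette, in µm; border-touching
  fibres are flagged and excluded from summaries by default. An exhaustive
  angle sweep serves as the test oracle.
- **Summaries**: proportions over classified fibres (sum to 100%), per-type
  and pooled mean diameters, per-type IMCL; a warning is emitted below the
  customary floor of 100 analysed fibres per muscle.

## Cohort models

The simulator draws subject intercepts and field noise hierarchically
(defaults: 24 subjects per group, four muscles, five fields; age ≈ N(70,
10); BMI ≈ N(24.8, 2.7) CTRL vs N(31.9, 4.7) T2DM; HbA1c ≈ N(6.9, 1.1) in
T2DM), with optional injected group, age, BMI and HbA1c effects.

Group models are linear mixed-effects fits (REML) with a subject random
intercept and fixed effects group + age + BMI, with optional age², group×age
and fibre-diameter sensitivity terms. Statsmodels provides Wald z inference
only; p-values and CIs here use a between-within t approximation with
df = n_subjects − n_fixed_effects, which calibrates the type-I error to
0.05 ± 0.015 at the study design (asserted over 1000 null simulations). On
degenerate data (e.g. zero variance components) the fit falls back to OLS
on the same formula and is flagged singular. No multiplicity correction is
applied across muscles or outcomes (two-sided α = 0.05 throughout), matching
common reporting practice; this is a property of the analysis, stated here
once.

Within-subject hierarchy uses paired t-tests on subject × muscle means
(subjects with incomplete muscle sets excluded listwise from paired analyses
only) plus a repeated-measures mixed model
`value ~ group × muscle + age + BMI + (1|subject)`. Identical paired values
yield t = 0, p = 1 by convention. Cohort summaries report both over-subject
and over-field aggregation where the distinction matters, since reporting
conventions differ.

## Problem sizes used in the standard checks

Parameter-recovery checks run the full pipeline on complete
387.5 × 387.5 × 100 µm fields (510 × 510 × 100 voxels, ≈ 9 × 10³ µm of
capillary per field); statistical calibration uses 1000 null cohorts and 100
effect-recovery replicates at the 24 + 24 × 4 × 5 design; property checks
use reduced volumes where the property is scale-free. These sizes were
chosen so the whole suite runs comfortably on a single CPU while keeping
every check at the study's own geometry where geometry matters.

## Known limitations

- The generator's network topology (axial trunks + side branches) matches
  muscle capillarity statistics, not vascular biology; no anastomotic loop
  structure or flow-based topology is modelled.
- Tip retraction by thinning is uncorrected; absolute length is biased low
  by ~r per free end (≈3% at study geometry).
- Positivity calling assumes each informative channel is genuinely bimodal
  within a section; a section consisting entirely of one fibre type is
  called all-negative on its uniform channels (with a warning) because a
  two-class split has no negative reference.
- Mixed-model inference uses a between-within df approximation, not
  Satterthwaite/Kenward–Roger.
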