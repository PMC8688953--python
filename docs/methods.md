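# Methods

## Input model and conventions

Volumes are reconstructed micro-CT stacks whose voxel values are linear
attenuation coefficients in mm⁻¹ (attenuation at a fixed photon energy is a
proxy for mineral density).  The package assumes values are already
calibrated to mm⁻¹ and does not rescale them.  Axis 0 is the bone's
longitudinal axis with the proximal end at index 0; a `flip_orientation`
config flag (and CLI option) handles stacks scanned the other way.  Voxel
indices are 0-based and a section's axial extent is half-open
`[z_start, z_end)` in µm, so adjacent sections never share a slice.
Negative reconstruction-noise values are clipped to zero unless the volume
is explicitly flagged as noisy.  TIFF carries no trustworthy spacing, so a
spacing must be given explicitly; NRRD spacing comes from the header, an
explicit override always wins, and a missing spacing is an error, never a
silent default.

## Segmentation

Bone is separated from soft tissue/background by a single global Otsu
threshold per sample (never per slice), computed on the whole-volume
histogram (256 bins by default).  The implementation maximizes
between-class variance over all bin-edge cuts; when the objective ties
across an empty valley between well-separated modes, the middle of the tie
plateau is taken so the threshold stays clear of both modes.  A voxel is
bone iff its attenuation strictly exceeds the threshold.

Cortical bone is isolated by a fixed, deterministic morphological rule
applied per transverse slice (segmentation of this kind is traditionally
semi-automatic with expert checking; a fixed rule makes it reproducible):

1. morphological closing with a disk of radius 54 µm (seals porosity in the
   shell),
2. opening with a disk of radius 40 µm (strips trabecular struts thinner
   than ~80 µm from the cortical candidate),
3. keep the largest connected component,
4. intersect with the original bone mask.

Everything mineralized but not cortical is cancellous, so cortical and
cancellous voxels partition the bone mask exactly.  Radii are specified in
µm and converted to voxels through the spacing; they must lie between the
trabecular thickness and the cortical thickness of the specimen (the
defaults suit rodent long bones with ≥100 µm cortices and ≤80 µm
trabeculae).  3D-connected bone specks smaller than a minimum component
volume (default: 10 voxel volumes) are relabeled background as
reconstruction noise before the split.

The subcortical (Sc) region is the per-slice filled interior of the
cortical shell minus the shell itself; Sc.V is its voxel volume.  A slice
whose shell encloses nothing on the first pass is retried after one
closing at twice the closing radius; if the shell is still open the slice
contributes no Sc voxels and is reported, which deliberately
underestimates Sc.V rather than letting a fill leak across the image.

## Region delimitation

Slices are grouped into sections of ⌈100 µm / slice spacing⌉ whole slices
(no resampling, so voxel counts remain exact denominators); the last
section may be shorter.  Per section the profile records the arithmetic
mean attenuation over cortical voxels and the cancellous fraction of the
subcortical space.  The variation statistic between consecutive sections
with defined cortical means is

    Variation_i = 100 · (µ.Ct_i − µ.Ct_{i−1}) / µ.Ct_{i−1}  [%].

The borderline criterion uses |Variation| > 1 %: attenuation falls toward
the proximal end and rises toward the distal end, so the sign of the
crossing depends only on scan orientation.  The diaphysis is the longest
run of at least 3 consecutive sub-threshold pairs (ties resolved toward
the series centre).  The persistence requirement keeps a single
coincidentally quiet pair inside an EM-zone from opening a false
diaphysis.  Borderline planes are the shared faces between the flanking
above-threshold pair and the plateau; offsets are their distances from the
bone ends in % of sample length.  If no qualifying run exists the error
carries the full variation series for inspection.

The diaphyseal A/B split minimizes the two-segment piecewise-constant sum
of squared errors of the sectionwise cancellous fraction restricted to the
diaphysis, constrained so the proximal segment has the lower mean (the
proximal shaft carries trabeculae only as occasional inclusions).  A
constant series splits at the midpoint with a warning.  The split never
moves the EM borderlines.  The epiphysis/metaphysis subdivision of an
EM-zone requires a user-supplied epiphyseal-plate slice — the tool does
not detect the plate.

## Morphometry

* **TV** is the per-slice filled outer contour of the bone, so the marrow
  cavity counts toward total volume — this is what makes whole-sample
  BV/TV a meaningful compactness measure (~0.5–0.7) instead of 1.
* Attenuation summaries per compartment are **medians**, which are robust
  to partial-volume tails at compartment surfaces.
* **Tb.Th / Tb.Sp** are volume-weighted means of the maximal-inscribed-
  sphere diameter field over the cancellous voxels and over the non-bone
  subcortical space, conventionally in the distal epiphysis (the last
  990 µm of the bone, 110 slices at 9 µm).  **Tb.N = 1/(Tb.Th + Tb.Sp)**;
  the closed form is recorded as such in reports and is desk-verifiable on
  plate phantoms.
* **Tt.Ar / Ct.Ar / Ct.Th** average over a mid-diaphysis window of 900 µm
  (100 slices at 9 µm) centred at the diaphysis midpoint.  Ct.Th is twice
  the mean distance-transform value sampled on the cortical medial
  surface.  The default samples the medial surface per slice (2D skeleton
  of each cross-section); a 3D mode exists as a config switch but is not
  the default because 3D homotopic thinning of a tubular shell collapses
  to a curve — it samples the medial *axis* of the tube, not the medial
  surface of the cortical wall, and under-covers the shaft.  A shaft with
  no lumen is flagged `degenerate`: its medial surface collapses to the
  axis, where the distance transform equals the rod radius, so Ct.Th
  reports the full diameter.

### Local thickness

The local-thickness field assigns every foreground voxel the diameter of
the largest sphere that contains it and fits in the structure.  The
implementation processes radii in half-voxel bins in descending order;
each bin's coverage is "distance from the bin's centres ≤ r", computed as
a second distance transform rather than an explicit dilation, and the
field is never allowed below twice the voxel's own distance transform
(each voxel's own inscribed sphere is always admissible).  The binning
quantizes diameters to one voxel; against an exhaustive sphere-painting
oracle the mean (the reported metric) agrees to ~0.03 voxels, while rare
voxels at sphere surfaces can differ by up to ~2 voxels.  Fields are
computed inside the region's bounding box expanded by a 300 µm context
margin, so region borders do not artificially truncate spheres; beyond the
volume itself everything counts as background.

## Group statistics

Each parameter is compared between two groups with a Shapiro–Wilk
normality gate per group at α = 0.05 (the same α as the comparisons).  If
both groups pass, Welch's two-sided t-test; otherwise a two-sided
Mann–Whitney U — exact enumeration for tie-free samples with min(n) ≤ 8,
normal approximation with tie correction otherwise.  A constant group
(Shapiro–Wilk undefined) falls through to Mann–Whitney with a warning.
Differences are reported as 100·(flight − control)/control, rounded to one
decimal for display only.  No multiple-testing correction is applied by
default, matching common practice for these parameter tables; Bonferroni
and Benjamini–Hochberg switches exist.  Under the null (1000 seeded
replicates) the Welch branch's type-I error is ~5 %, within [3.5 %, 6.5 %].
Sample exclusions are an analyst decision, supported only through an
explicit exclusion list in the config.

## The synthetic phantom

The phantom emulates the specimen class the pipeline targets — a
humerus-scale long bone of an adult gerbil — with every voxel carrying a
generative label:

* length 15.9 mm; mid-shaft outer radius 626 µm and cortical thickness
  344 µm (chosen so the analytic mid-shaft cross-section is Tt.Ar
  ≈ 1.23 mm², Ct.Ar ≈ 0.98 mm², Ct.Th = 0.344 mm); outer radius flares to
  ~1 mm at the ends;
* cortical attenuation: plateau 1.304 mm⁻¹ along the diaphysis with
  geometric ramps through the EM-zones (constant percent change per
  section, ~1.7 % per 100 µm, comfortably beyond the 1 % borderline
  criterion — the spec-level constructibility constraint is validated at
  spec creation);
* planted borderlines at 18.5 % (proximal) and 15.6 % (distal) of length —
  the centre of the observed offset ranges for this bone;
* trabecular bone at 0.85 mm⁻¹ as rod lattices of 72 µm rods: a full 3D
  lattice at 330 µm pitch in both EM-zones, and sparse longitudinal rods
  only (400 µm pitch, sectionwise Cn.BV/Sc.V ≈ 2 %, flat) in the distal
  diaphysis beyond the planted A/B split at 60 % of length.  The distal
  half of the diaphysis is cylindrical so that fraction is genuinely
  step-like; transverse rod planes there would create periodic one-section
  spikes no real shaft shows;
* optional additive Gaussian noise (after labeling), seeded and bitwise
  reproducible.

What the phantom does **not** emulate: realistic trabecular architecture
statistics (plates, connectivity, anisotropy), beam hardening, ring
artifacts, partial-volume blur, or scanner noise physics beyond additive
Gaussian noise.  Passing the phantom suite therefore demonstrates the
correctness of the measurement pipeline, not the biological realism of any
particular parameter value.

## Problem sizes and numerical choices

The default phantom voxel is 18 µm (883×120×120 voxels) — geometry is
specified in µm, so results are spacing-invariant, and a 9 µm phantom is a
parameter away.  Tests and the acceptance script use 36 µm for replicated
runs (noise robustness over 100 seeds) and 45 µm for the 20-phantom
randomized property suite; window sizes in µm (900/990) are converted to
slices through the spacing.  Boundary recovery tolerance on phantoms is one
section (108 µm at these spacings) — the transition section straddles the
planted plane, so its variation is diluted and the quiet run can start one
section late.  Otsu ties are broken at the plateau middle; change-point
ties resolve to the smallest feasible SSE index; Mann–Whitney p-values and
Shapiro gates use scipy.

## Known limitations

* The delimitation assumes a straight bone axis aligned with axis 0;
  strongly curved bones would need reparameterization, which is out of
  scope.
* Cortical/cancellous separation relies on a scale gap between trabecular
  and cortical thickness; specimens without one (e.g. severely osteoporotic
  cortices) will need per-study morphological radii.
* Sc.V in slices where the cortex never closes is reported as zero and
  flagged, biasing Cn.BV/Sc.V upward in pathological slices.
* Local thickness is diameter-quantized to one voxel; thickness metrics at
  few-voxel trabeculae carry that resolution limit, as in any
  distance-transform morphometry at comparable voxel size.
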