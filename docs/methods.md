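# Methods

`coroct3d` reconstructs the 3D lumen surface, outer vessel wall and
calcified-plaque (CP) objects of a coronary artery segment from a
CT-angiography (CTA) volume, and provides the 3D comparison metrics used
to validate such reconstructions against a reference modality. This
note records the model, the numerical choices, and what the synthetic
validation does and does not demonstrate.

## Pipeline

Six stages, run in order by `pipeline.reconstruct`:

1. **Preprocessing.** Global contrast stretch saturating 1 % of the
   intensity histogram at each end; thresholding of the enhanced volume
   at 180 HU (the contrast-arrival level used to trigger clinical
   acquisitions); multiscale Frangi vesselness (α = β = 0.5, γ = half
   the maximum Hessian norm, scales 0.5–2.0 mm — coronary lumen radii).
   The candidate vessel mask is the morphological reconstruction of
   (threshold ∧ vesselness > 0.05) within the threshold mask: the
   vesselness marker selects which bright structure is the vessel,
   while reconstruction-by-dilation keeps the whole thresholded tube,
   because the Hessian response necessarily decays at tube ends.
2. **Rough borders and initial centerline.** 26-connected region
   growing from one user seed voxel; per-axial-slice boundary tracing of
   the grown mask; the area centroid of each slice region forms the
   initial centerline polyline; an 11-sample moving average smooths it
   (unsmoothed centerlines make neighbouring perpendicular planes
   intersect); a smoothing cubic B-spline (residual target 0.01 mm² per
   point) provides continuous first derivatives; stations are resampled
   every 0.2 mm of arc length, linearly continued by half a slice
   spacing per end so the reconstruction covers the full segmented
   extent.
3. **HU tissue model.** The HU distribution over the artery region is a
   four-component Gaussian mixture — lumen, CP, non-calcified plaque
   (NCP), background — p(x|λ) = Σᵢ wᵢ N(x; μᵢ, σᵢ). One representative
   point per class plus five random neighbours within a 1-pixel
   in-plane radius initialize the per-class means; expectation-
   maximization refines λ on HU samples from the rough lumen dilated by
   the expected wall thickness plus two voxels. Components are never
   reordered, so the class map survives the fit. Classification is by
   maximum posterior P(k|x) = w_k N(x;μ_k,σ_k)/Σᵢ wᵢN(x;μᵢ,σᵢ); exact
   ties resolve by priority lumen > CP > NCP > background.
4. **Radial sections.** At every station a cross-sectional image is
   resampled (trilinear) perpendicular to the spline tangent; in-plane
   axes are propagated by rotation-minimizing transport. Because
   centerline smoothing displaces stations off the lumen center, five
   center-of-mass correction passes move each section onto the lumen:
   the section is binarized to lumen-classified pixels, a small opening
   removes thin partial-volume ghosts (calcium's outer face passes
   through lumen-like HU), and the component under the image center
   defines the mass center. The corrected image is rebinned onto 120
   rays × 0.1 mm radial bins (bilinear).
5. **Walls and plaque regions.** Per ray, the region of interest ends
   just before the first bin below −130 HU (the "zero cross" — fat/air
   level bounding the artery). Bins are hard-labeled by the mixture;
   after a 3×3 wrap-aware majority vote, the lumen border is the first
   non-lumen bin outward of a 0.3 mm guard and the outer border the
   last non-background bin inside the ROI. Rays whose ROI contains
   calcium signal (> 500 HU) have an unmeasurable outer border (the
   soft-tissue band behind calcium is below resolution and bloom drags
   the border inward); they are filled by circular interpolation from
   clean rays, as are rays where a rule finds no bin. A section with
   more than 25 % failed rays is excluded from meshing. Both contours
   are circularly smoothed (7-ray window) with lumen ≤ outer enforced.
   CP regions are the 8-connected (seam-wrapping) components of bins
   with CP posterior > 0.5 inside the wall annulus (±0.2 mm margin for
   border uncertainty).
6. **Surfaces and objects.** Contours (120 points, consistent ray
   correspondence) are lofted: each sequential pair contributes 2N
   triangles, centroid fans cap the ends, so capped meshes are closed
   and the divergence-theorem volume is exact for the polyhedron.
   Plaque regions on consecutive stations with overlapping angular
   footprints are linked (union-find; same-station fragments re-merged);
   objects shorter than two stations are dropped; object boundaries are
   resampled to 64 points and lofted the same way.

## Sub-voxel border localization

A maximum-posterior label flips where the HU profile crosses the
*decision* level between two components. That level moves with the
mixture weights (i.e. with how much of each tissue the fit region
happens to contain), and under partial-volume blur the flip is therefore
displaced from the physical border by up to ~0.25 mm at 0.4 mm voxels —
e.g. the outer wall of a 2.5 mm phantom read 2.33 mm from labels alone.
All borders found by the label rules are therefore refined to the 50 %
crossing between the flanking plateau HU levels (medians over ~2 voxel
spacings, re-estimated in a second pass that skips the transition zone;
searches are bounded so the lumen edge cannot look past the outer border
and vice versa). The same half-amplitude principle localizes the plaque
objects' radial faces, their per-slice angular edges, and their end
faces along the centerline (the center-to-center station span otherwise
loses half a voxel of physical extent per end, deterministically). This
is the standard subpixel edge treatment in vessel-wall quantification;
without it the label-rule borders are biased by a class-abundance term
no amount of data reduces.

## Comparison metrics

Per plaque object: divergence-theorem volume; triangle-sum surface
area; maximum length = arc-length span along the centerline (with the
end-face refinement above); inner angle θ_In = mean over the object's
slices of the angular extent θᵢ of the smallest arc covering the
slice's plaque (wrap-aware, complement of the largest gap). Overlap
volume between two closed meshes is voxel counting at 0.05 mm pitch on
the intersection of their bounding boxes. Paired model agreement is
summarized by the Pearson correlation (with r²) and Bland–Altman mean
difference ± 1.96 sample SD. Both models are assumed expressed on a
common centerline; an optional station offset allows coarse alignment.

## Synthetic phantoms

`phantom.generate_phantom` builds a contrast-filled tube (straight or
helical; lumen radius optionally tapering linearly to model stenosis)
with a soft wall annulus, arc-shaped calcified deposits embedded in the
wall, and background. Voxels take the class of their center point —
no sub-voxel mixing — so class masks and the analytic quantities
(∫πr²ds volumes, arc volumes, extents) are exact; HU are drawn from
per-class Gaussians:

| class      | mean (HU) | std (HU) |
|------------|-----------|----------|
| lumen      | 350       | 40       |
| CP         | 800       | 80       |
| NCP        | 60        | 25       |
| background | −50       | 60       |

The lumen sits well above the 180 HU stage-1 threshold; the broad
background produces sub-−130 HU voxels so the zero-cross rule is
exercised. Defaults: 0.4 mm isotropic voxels (64-slice CTA scale),
20 mm segments, 1 mm wall, 2 mm margin. The three study arteries
(straight, helical R = 3 mm / pitch 30 mm, stenosed 1.8→1.2 mm) each
carry one CP arc — a calcium class point must exist for seeding.

What the phantoms do **not** emulate: cardiac motion, beam hardening
and blooming, streak artifacts, anisotropic slice profiles, partial-
volume mixing at tissue borders (interpolation during resampling is the
only blur), bifurcations and stents. Passing phantom tests therefore
demonstrates the geometric and statistical machinery, not clinical
accuracy on patient data.

## Initialization-sensitivity experiment

For each artery the geometric stages run once; for every ΔT in
{20, …, 200} HU each class point's HU value is shifted by ±ΔT with
probability ½ (the five neighbourhood samples are image-derived and
unaffected, so initialization means shift by about ΔT/6), the mixture
is refit, walls re-detected, meshes rebuilt, and
C = 100·(1 − |V_ΔT − V₀|/V₀) recorded for both wall volumes. The
reported statistic is the minimum C over 3 arteries × 2 walls × 10
offsets (60 measurements); `scripts/acceptance.py` recomputes it from
scratch for a given seed.

## Numerical choices

- EM: σ floor 1 HU, weight floor 10⁻⁶; initialization scale is a robust
  MAD estimate floored at 20 HU — six labeled samples are too few for a
  plain standard deviation, and a single outlying (perturbed) value
  otherwise inflates σ_init enough to let two components share one
  cluster. Convergence at log-likelihood gain < 10⁻⁹ per sample (≤ 500
  iterations): at the fit-region sample size a looser rule stops EM at
  initialization-dependent points far enough apart (~1 HU) to toggle
  downstream border labels.
- Polar geometry: 120 rays (3° steps), 0.1 mm radial bins, 5 mm maximum
  radius, 6 mm section half-width, 0.1 mm section pixels — resolves
  coronary-scale anatomy with several bins per voxel.
- Degenerate inputs: constant volumes pass through contrast enhancement
  with a warning; empty center-of-mass binarizations keep the previous
  offset; sections with both borders undefined on a ray interpolate
  circularly (`np.interp` with period); duplicate centerline points are
  dropped before spline fitting.
- Determinism: every random draw flows from an explicit seed (phantom
  noise, seed-neighbourhood sampling, perturbation signs); two runs with
  the same configuration are bit-identical.

## Known limitations

- The background tissue class overlaps NCP enough that no classifier
  can exceed ~87 % background accuracy under the default HU model (the
  Bayes bound for N(−50,60) vs N(60,25) at equal priors); this is a
  property of the tissue model, harmless to wall detection because the
  border rules key on first/last transitions, not on every bin.
- The outer wall behind calcium is interpolated, not measured; a true
  wall bulge under a calcified arc would be missed.
- Inner-angle accuracy degrades on strongly curved vessels (the helical
  phantom reads ~7° low on a 90° arc) because section obliquity spreads
  the arc across stations.
- Problem sizes used throughout the tests (20 mm segments at 0.4 mm
  voxels, 10⁴ samples per class for mixture checks) keep the full
  validation suite in the minutes range on one CPU.
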