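# Methods

This note documents the models, conventions and numerical choices behind
`histobridge`, in the order the pipeline runs them.

## Phantom model

The phantom emulates a trephine drill-hole defect through the flat cortical
plate of a long/flat bone, sectioned perpendicular to the plate.

**Section geometry** (defaults; all configurable in `PhantomConfig`):
a 10 × 6 mm frame; the periosteal margin 1.5 mm from the top; a 2 mm
cortical plate; an 8 mm drill hole centred horizontally; pixel pitch
1.283 µm/px at full resolution (examples and tests render at 10–20 µm/px,
which scales every structure consistently). Layout, top to bottom:
periosteal soft tissue, the cortical plate (old bone flanking the drill
hole), the marrow space. Inside the drill hole, new bone fills the plate
from the endosteal side up to `new_bone_fill_fraction` (default 0.7); the
unfilled top part is soft tissue continuous with the periosteum and is what
the periosteal-void parameter measures. Soft-tissue canals of configurable
widths (`canal_spec`, mm) breach the plate from the periosteal margin to
the marrow; an empty list leaves the plate intact.

**Medullary content.** Regenerated trabecular bone inside the medullary ROI
is rendered as osteon-scale axis-aligned square blocks (~0.15 mm side,
snapped to a power-of-two pixel grid) covering `trabecular_fill_fraction`
(default 0.3) of the band. Grid-aligned rectilinear shapes are used
deliberately: every phantom boundary is then resolvable by the quadtree
homogeneity criterion and stable under the surface-tension smoothing rule,
which is what makes the noiseless recovery test *exact* rather than
approximate. Substitute agglomerates are ellipses embedded in soft tissue
with a 1-pixel moat from bone and from each other (so they stay
8-disconnected); their pixel sets are trimmed to the exact requested pixel
count, making the configured mean area `BS.Pa.Ar` recoverable to one pixel.
The three emulated material regimes span the field's reported range: many
small agglomerates (~0.008 mm²), intermediate (~0.05 mm²), and a single
oversized compact agglomerate (~2.67 mm²).

**Colour model.** Classes are drawn as mean RGB with i.i.d. Gaussian
per-channel noise (default sd 10/255): soft tissue (243, 241, 237), old
bone light pink (236, 176, 190), new bone darker purple (165, 90, 155),
substitute grey-brown (130, 120, 110). The red−green difference is the
discriminating axis between bone (60 and 75) and soft tissue (≈2), matching
how the segmentation cascade separates classes; the old/new distinction is
carried primarily by geometry (below), with colour as an optional override.
The staining literature describes these colours only qualitatively, so the
values are canonical choices, not calibrated to any real slide.

**Volumes.** 3D phantoms are a bone slab (bone ≈ 30000, background ≈ 10000,
noise sd 1500 on a 16-bit scale) spanning the transverse extent, with
straight or tortuous (random-walk) canals through it and optional blind
pockets that indent without breaching. `true_bridged` is exactly "no canal
requested". Default voxel pitch 17.2 µm mirrors the emulated scanner
setting; tests use 100 µm so canal widths in voxels span 1–10 on a 64³
grid.

**Cohorts.** `generate_cohort` gives every animal one defect per treatment
(the within-animal randomised design) and one timepoint. Treatment regimes
act on the fill fraction and agglomerate parameters
(`DEFAULT_GROUP_REGIMES` encodes the five emulated treatment arms); an
animal-level random intercept (shared by all defects of an animal) and an
optional per-defect residual act on the fill fraction in percentage points.
Everything is driven by `numpy.random.default_rng(seed)`: the same config
yields bit-identical rasters.

## Segmentation cascade

1. **Quadtree split** (`homogeneity_tol`, default 120): square objects are
   quartered until the maximum per-channel colour variance is at or below
   tolerance, or the object is one pixel. Non-square frames split on a
   conceptual enclosing power-of-two square; children are clipped, so the
   leaf set tiles the frame exactly. The tolerance must exceed the image
   noise variance (default noise sd 10 → variance 100) or uniform regions
   split to pixels; 120 leaves headroom while still resolving sub-percent
   colour mixtures inside a leaf.
2. **Coarse classification.** The background reference colour is the
   area-weighted mean of the brightest leaves (≥ 95th brightness
   percentile) — background is the lightest material on a stained section.
   Leaves within `conservative_bg_tol` (default 25, Euclidean RGB) seed the
   background, grown into edge-adjacent leaves within `growth_tol`
   (default 50). Remaining leaves with mean red−green difference ≥
   `bone_rg_min` (default 25) are bone; the rest stay unclassified.
3. **Isolated-bone declassification.** A bone leaf bordered by fewer than
   two bone leaves (edge-sharing, counted once per neighbouring leaf) is
   declassified, in one simultaneous pass. A bone leaf with no non-bone
   neighbour at all (e.g. the single leaf of a solid-bone image) is kept:
   there is no surrounding evidence against it.
4. **Adaptive threshold** t = `rg_threshold_scale` × mean red−green
   difference over bone-leaf pixels. The scale defaults to 0.5: with a
   near-white background whose red−green difference is ≈ 0, half the bone
   mean is the midpoint between the two populations. A scale of 1.0 would
   place the threshold at the centre of the bone distribution itself and
   misclassify half of the bone pixels under noise.
5. **Pixel threshold and smoothing.** Pixels in bone/unclassified leaves
   with red−green ≥ t become bone; background leaves are never
   re-thresholded. Then `smooth_iters` (default 2) alternating grow/shrink
   passes constrained by surface tension: a pixel flips only when at least
   `flip_majority` (default 6) of its 8 neighbours hold the target class.
   Six is the smallest majority that leaves right-angle corners and 45°
   staircases of a correct mask fixed (with 5, every convex right-angle
   corner erodes), while still deleting 1–2-pixel noise islands. Connected
   components smaller than `min_island_px` (default 16) entirely enclosed
   by the other class are absorbed. Finally one simultaneous
   boundary-refinement pass: a boundary pixel flips iff that increases the
   absolute difference in local mean red−green between the classes within
   a 7×7 window; on constant-colour regions this is provably the identity,
   so it never perturbs a noiseless result.
6. **Old vs new bone** is split geometrically: bone within the drill-hole
   column span is new, outside is old. An optional colour override within a
   configurable band around the drill boundary reassigns bone pixels to
   the nearer of the two bone reference colours (off by default — the
   geometric rule is exact on phantoms and is the primary definition).
7. **Substitute overlay.** Substitute material cannot be isolated reliably
   by colour rules; a manual (here: ground-truth) mask overrides the
   automatic classes. Manual correction of the other classes is likewise
   modelled as an externally supplied mask, not interactive editing.

Conventions: 0-based coordinates, half-open rectangles; 8-connectivity for
pixel masks and components; 4-connectivity (shared edges) for leaf
adjacency. Invariants maintained at every stage: each pixel has exactly one
class; total pixel count is conserved; `smooth_iters=0` is the identity on
the thresholded mask; the bone count is non-increasing in t before
smoothing.

## ROIs and histomorphometry

Margins and drill boundaries are supplied (phantom truth or an annotation
file); automatic margin detection is deliberately out of scope for
measurement. mm→px conversion floors, so a nominal 1 mm band never exceeds
1 mm (at 1.283 µm/px, 1 mm → 779 rows). The cortical ROI is drill columns ×
rows between the margins; the medullary ROI starts 1 mm below the
endosteal margin (measured from the margin, the documented reading of the
band placement), is 1 mm high, follows the margin contour and spans the
drill breadth.

All quantities derive from integer pixel counts × pitch². The report keeps
the field's volumetric symbols (BS.V, nBV …) although sections measure
areas in mm². Agglomerates are 8-connected substitute components; a
component straddling an ROI boundary contributes its in-ROI area once
(clipping keeps the TV partition exact; zero agglomerates report a missing,
not zero, mean area). The periosteal void Ps.Vd.V counts soft-tissue pixels
whose component also reaches above the periosteal margin — topological
connectivity operationalises "penetrated from the periosteal region";
enclosed marrow spaces and endosteal-only soft tissue are excluded. The
class map carries an old-bone class; inside drill-spanning ROIs it is empty
by construction, and the report exposes it separately so that
nBV + BS.V + Vd.V (+ old bone) = TV holds exactly in pixels. Percentages
print at 0.1; integer summaries use round-half-up.

## Bridging

The void (sub-threshold) phase inside the cortical slab is flood-filled
from the periosteal face; the defect is non-bridging iff the fill reaches
the medullary face, and the shortest witness path is returned from the BFS
predecessor structure. Defaults: Otsu threshold on the *whole* volume
histogram (the slab alone can be single-phase and Otsu would split the
bone peak), 26-connectivity for the void — the strictest reading of "no
opening remains". Raising the threshold enlarges the void phase and can
only flip bridging → non-bridging, never the reverse. The binary
classification replaces a visual inspection protocol; "cavity formation"
(a depression without breach) is intentionally not part of the binary
outcome. Rates: per group × timepoint, percentage = round-half-up of
100·n_bridged/n_total; cross-timepoint group averages are computed on the
unrounded percentages, then rounded — the convention that reproduces
printed integer summaries such as (91.67 + 83.33)/2 → 88.

## Statistics

Per parameter × ROI × timepoint (fitted separately; no timepoint
interaction model): REML linear mixed model `value ~ treatment` with a
random animal intercept (statsmodels MixedLM). All pairwise contrasts are
adjusted single-step: p = P(max |T| ≥ |t|) under a multivariate t with the
contrasts' estimated correlation (scipy `multivariate_t` rectangle
probabilities with a fixed QMC seed; exact t for a single contrast).
Degrees of freedom use a containment-style rule N − rank(X) −
(n_animals − 1), tagged `df_method="containment"` in the output so
alternative conventions (e.g. Satterthwaite, which MixedLM does not
provide) can be swapped in and compared. When the animal variance collapses
to zero or each animal contributes a single observation the model falls
back to OLS with a warning; in the balanced two-group case this reduces the
adjusted p exactly to the two-sample pooled t-test. Degenerate all-equal
inputs short-circuit to zero contrasts with p = 1. Exclusions are applied
through an explicit table with reasons, and the per-group analysis n is
part of every report.

## Problem sizes used

Tests and the acceptance script size inputs so the full suite stays
desk-scale while every claim is still exercised end to end: segmentation
recovery on ten 1000 × 600 px sections at 10 µm/px plus two noiseless
sections; bridging on twenty 64³ volumes spanning straight canals 1–10
voxels wide, tortuous canals, blind pockets and intact plates; brute-force
oracle comparisons on 500 × 300 px sections; CI coverage on 200 simulated
cohorts of 12 animals × 5 treatments. Unit-test phantoms render at 20 µm/px.

## What the phantoms do and do not show

Phantom tests demonstrate that the implementation is correct against exact
ground truth under the stated generative model: Gaussian colour noise,
piecewise-constant stain colours, flat margins, rectilinear/elliptical
structures. They do not demonstrate robustness to real-slide variation —
stain batch effects, uneven illumination, tissue tears, out-of-focus
regions, decalcification artefacts — nor do they validate the biological
values of the emulated study, whose raw images are not available. The
reported biological means (e.g. composite fractions up to ~97%) serve only
as regime settings for the generator. The colour thresholds, homogeneity
tolerance and smoothing defaults are tuned to the phantom's noise model and
would need recalibration on real slides; the adaptive red−green threshold
is the only slide-specific adaptation in the cascade, by design.
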