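# Methods

This note documents the quantitative models and procedures implemented in
`sproutquant`, the choices behind their parameters, and what the synthetic
data generators do and do not emulate.

## Trajectory statistics

Cell positions `x_i(t)` (µm) are sampled on a uniform grid (10-minute
frames for monolayer/3D motility, hourly frames for sprout tips).  Two
descriptive statistics summarise motility:

* **Mean displacement over a lag.**  `d(τ) = ⟨|x_i(t+τ) − x_i(t)|⟩_{i,t}`,
  averaged over *every* track `i` and time `t` at which both endpoints were
  observed.  Windows overlap, so the pair population is serially
  correlated; the SEM is nevertheless computed over this pair population
  (see *Known limitations*).  An RMS variant `√⟨|Δx|²⟩` is available behind
  the `rms` flag; the default is the plain mean of magnitudes, which is the
  quantity plotted in µm in motility figures.
* **Time-dependent mean speed.**  `v(t) = ⟨|x_i(t+τ₀) − x_i(t)|⟩_i / τ₀`
  with a fixed lag `τ₀ = 1 h`, averaged over the cells present at both
  endpoints.  This is a *chord* speed: over one hour a cell's path is
  longer than its net displacement, so `v(t)` is a lower bound on the
  path speed, tight for strongly persistent motion.

Gaps in a track simply exclude the affected pairs.  No smoothing, gap
bridging, drift correction or imputation is applied anywhere.

Curves from independent experiments are pooled by merging the underlying
pair/cell populations (pooled mean and pooled SEM reconstructed from the
per-curve moments), never by averaging the per-experiment means.

## Modified Sholl analysis of sprout arbors

A spheroid aggregate embedded in a gel grows multicellular sprouts.  The
arbor is imaged as a brightfield z-stack: slice `k` sits at `z = k·dz`
with `dz = 20 µm` while the optics keep only ≈10 µm in focus, so axial
sampling is *gapped* — half the volume is never in focus.

1. **Focus-variance segmentation.**  In brightfield, in-focus cellular
   material carries high local intensity variance while out-of-focus
   structures blur into smooth shading.  Each slice is scored by the
   population variance of intensity in a square window (default 5 px) with
   reflected borders.  The threshold is chosen by the between-class-variance
   (Otsu) criterion on the *log*-variance distribution pooled over the whole
   stack — a single far-from-the-arbor slice may contain no foreground at
   all, which would defeat a per-slice criterion.  Two corrections make the
   mask quantitative:
   * *Support compensation.*  A window that merely touches a textured
     object already scores high, so the raw suprathreshold support is the
     object dilated by about half a window; the mask is eroded by
     `window // 2` px to undo this.  The window default of 5 px was set by
     a resolution argument: two tubes can only be separated if the gap
     between them exceeds roughly one window, and neighbouring sprouts in
     a dense arbor come within ~30 µm (15 px at 2 µm/px) of each other.
   * *Bimodality guard.*  Windowed variance estimates of pure noise scatter
     within a factor of a few (chi-square sampling spread); genuine texture
     sits orders of magnitude higher.  If the Otsu cut lands below 4× the
     median variance it is splitting a single mode and no foreground is
     declared.
2. **Voxel reconstruction.**  Every foreground pixel of slice `k` becomes a
   voxel centred at `z = k·dz` with z-extent equal to the depth of field.
   The inter-slice gap is left unfilled, matching the stated optics.
3. **Concentric cylinders.**  Vertical cylinders around the aggregate
   centre (radii 20–560 µm in 20 µm steps, 28 cylinders) are sampled at
   every z level and at angular increments of one pixel of arc.  A surface
   point is marked when it falls inside an occupied voxel.  Each cylinder
   is rolled out into a flat (z × arc) binary image.
4. **Particle counting.**  Connected patches on the rolled-out surface are
   individual sprout traversals: 8-connectivity, with the angular axis
   wrapping so a patch across the θ = 0 seam counts once, and with single
   blank z rows bridged (`z_gap_merge = 1`) because the gapped axial
   sampling can split one crossing between two imaged planes.  Patches
   under `min_patch_px = 4` px are speckle and ignored.
5. **Zone structure.**  Sprouts branch densely near the aggregate (the
   *branching zone*) and elongate radially beyond it (the *elongation
   zone*).  The boundary is the radius of maximal traversal count,
   restricted to radii outside the aggregate; ties break toward the
   smaller radius.  Cylinders inside the aggregate cut through the cell
   body and are flagged, never counted as sprouts.
6. **Length distributions.**  For group comparisons, each aggregate's
   counts are re-expressed against sprout length beyond its own zone
   boundary and divided by the control group's mean count at its boundary,
   so the control curve equals 1.0 at length zero by construction; SEM
   stripes are taken over aggregates.

The aggregate centre and radius default to the centroid and equivalent
radius of the largest connected component of the middle slice — a
reproducible stand-in for manual marking, and deliberately overridable,
since the blob includes the stubs of attached sprouts and overshoots the
true radius by a few tens of percent.

## Vessel and gelatin morphometry

Chorion vessel networks are treated as quasi-2D projections.  Per
microscopic field (865 × 650 µm):

* **density** — vessel pixels / total pixels after Otsu (or fixed)
  thresholding, speck removal and *small*-hole closing (at 75% density much
  of the background is enclosed by vessels and must stay background);
* **total length** — the skeleton (topological thinning) summed with
  lateral steps as one pixel and diagonal steps as √2 pixels, skipping
  diagonal links already connected through a lateral corner (so staircases
  are not double counted), plus the distance-transform value at every
  skeleton endpoint (thinning stops about one half-width short of a
  vessel end);
* **mean width** — twice the Euclidean distance transform averaged along
  the skeleton, minus half a pixel (the EDT measures centre-to-centre
  distances), with branch points excluded to avoid junction inflation.

On axis-aligned bar phantoms 4–40 µm wide these estimators recover width
within 0.7 µm and length within 0.5%.

Gelatin digestion is the fraction of pixels darker than the threshold
(proteolysis reads out as localised loss of fluorescence), after optional
small-object removal.

## Synthetic data generators

All generators are deterministic functions of (config, seed); one seed
fans out to independent substreams per component.

**Tracks** follow a persistent random walk: the heading performs rotational
diffusion with `⟨cos Δθ⟩ = exp(−t/P)`, per-step speeds are
gamma-distributed around the programmed mean (CV 0.2) or follow a
time-varying schedule.  The default persistence time `P = 8 h` reflects
the near-linear displacement-vs-lag curves endothelial cells show over the
10 min–5 h lag range; with it, the 1-hour chord-speed estimator
underestimates the programmed path speed by ≈2%, comfortably inside the
5% recovery band.  `P = ∞` gives exactly ballistic tracks for the
degenerate-limit tests.

**Arbors** are 3D tubes (default width 12 µm) radiating from a central
sphere (radius 100 µm) out to individual extents, branching only inside
the branching zone (outer edge 200 µm).  The rendering is stylised, not an
optics simulation: tube material within a slice's depth-of-field window is
drawn as high-amplitude per-pixel texture, nearby out-of-focus material as
a weak broad darkening, on a background of smooth illumination plus a flat
camera-noise floor.  That noise floor is what anchors the background mode
of the variance distribution above the tiny gradients of the defocused
shading.

The phantom is built to be *fully resolvable*, so that the geometric
ground truth (crossing counts and angles per analysis radius, enumerated
from the tube polylines, never from the pixels) is also what an ideal
detector would report:

* primary sprouts leave the aggregate at evenly spaced, jittered base
  angles (≥ ~29 µm of arc apart at the first sampled radius);
* a branch takes off steeply, reaching a constant-arc lateral lane
  (32 µm spacing) or an axial lane (≥ 80 µm of z separation) within 2 µm
  of radial growth, and spawn radii and tube endpoints are placed *between*
  sampled radii — at a cylinder exactly at a tube tip, "does the sprout
  traverse?" is ill-posed at pixel resolution;
* branch events beyond the lane budget of a crowded arbor are dropped
  (capacity falls as sprout number grows, as it must on a fixed
  perimeter).

What this phantom does **not** emulate: real point-spread functions,
sprouts that overlap in projection (the paper's own particle counting
would merge those too), lumen texture, anastomosis, or drifting
illumination.  Passing the recovery tests therefore demonstrates the
correctness of the counting machinery on resolvable arbors, not
segmentation performance on arbitrary microscopy.

**Vessel fields** accumulate random thick segments (biased to continue
from earlier endpoints so the network looks connected) until the realised
mask reaches the programmed density; the mask itself is kept as ground
truth.  **Gelatin fields** place non-overlapping dark disks until the
pixel-exact dark fraction reaches the target, with the final disk sized to
close the remainder.

## Numerical choices and degenerate inputs

* Physical units throughout: µm and hours.  Pixel indices are 0-based;
  the origin is the centre of pixel (0,0); slice `k` is at `z = k·dz`;
  frame 0 is `t = 0 h`.
* Lags must be positive multiples of the sampling interval (checked to
  1e-6 relative); time grids must be uniform to 1e-9 relative.
* SEM uses the sample standard deviation (ddof = 1) over the pair/cell
  population; a single observation reports SEM 0.
* Empty masks after thresholding warn and report zeros rather than raise;
  an all-zero traversal profile raises (`no sprouts detected`), as does an
  empty TrackSet.
* Radii whose cylinders leave the imaged field are truncated to it with a
  warning.
* CSV I/O is fixed to comma separators, '.' decimals, UTF-8 and mandatory
  headers; floats are written at 12 significant digits so grid uniformity
  survives a round trip.
* Run outputs embed a resolved-config sidecar with a config hash and the
  package version; wall-clock timestamps go to the log stream only, so
  reruns with the same seed and config are byte-identical.

## Problem sizes used by the test suite and acceptance script

Trajectory checks use 20 track sets of ≤ 1000 observations against a
brute-force double loop, and a 100-cell, 24 h recovery run.  Arbor
recovery uses 20 rendered arbors (5–25 sprouts, 600×600 px × 14 slices);
group comparison uses 20 aggregates per group at 20 vs 12 sprouts.
Morphometry closure uses one 865 × 650 µm field per programmed value.
These sizes make the whole suite run in a few minutes while keeping
n_pairs ≥ 10⁴ where scaling laws are asserted.

## Known limitations

* The displacement SEM is computed over overlapping (correlated) pairs
  and therefore understates the true uncertainty; it matches the
  error-stripe convention of the motility literature rather than an
  independent-sample SEM.
* Whether published displacement error stripes are taken over pairs or
  over cells is not documented; pairs are the default here.
* The chord-speed estimator is biased low for weakly persistent motion;
  interpret `v(t)` of diffusive tracks as a lag-dependent quantity, not a
  path speed.
* Sprout length is measured radially from the zone boundary; a curved
  sprout's arc length is underestimated.  Measuring from the aggregate
  surface instead is a one-line change (`length_distribution` operates on
  whatever boundary the profile carries).
* The vessel width estimator is a per-skeleton-point average; a
  per-segment average would weight long thin segments differently.  The
  choice is declared, not inferred from the original study.
* Patch counting merges sprouts that cross a cylinder closer than the
  segmentation resolution (~one variance window plus a tube width); the
  synthetic phantom avoids this regime by construction, real arbors need
  not.
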