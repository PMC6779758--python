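"""Modified Sholl analysis of multicellular sprout arbors from brightfield z-stacks.

The pipeline quantifies how many sprouts a fibrin-embedded endothelial
aggregate has grown, as a function of radial distance from the aggregate
centre:

1. each z-slice is segmented by *local intensity variance* — in-focus
   structures carry a high-variance texture, out-of-focus ones are smooth;
2. foreground pixels become voxels whose z-extent equals the optical
   depth of field, yielding a (gappy, when dz > depth of field) 3D
   reconstruction of the arbor;
3. concentric vertical cylinders (default radii 20–560 µm in 20 µm steps)
   are sampled through the volume, each rolled out into a flat
   (z × angular-arc) binary surface;
4. connected patches on a rolled-out surface mark where a sprout traverses
   that cylinder; particle counting (8-connectivity, wrapping in the
   angular coordinate, tolerant of one-slice z gaps) counts sprouts per
   radius;
5. the traversal-count profile splits the arbor into an inner *branching
   zone* and an outer *elongation zone*, with the boundary at the radius
   of maximal traversal count; cylinders inside the initial aggregate are
   flagged and excluded from zone logic.

Normalised sprout-length distributions compare groups of aggregates: counts
in the elongation zone, expressed against length beyond the zone boundary,
divided by the control group's mean count at its boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.morphology import remove_small_objects

__all__ = [
    "ImageStack",
    "BinaryVolume",
    "CylinderMap",
    "ArborProfile",
    "LengthDistribution",
    "local_variance_map",
    "segment_slice",
    "reconstruct_volume",
    "cylinder_traversals",
    "count_sprouts",
    "arbor_profile",
    "length_distribution",
    "analyze_stack",
    "default_radii",
]

#: default analysis radii in µm: 28 cylinders from 20 to 560 µm, 20 µm apart
def default_radii(start: float = 20.0, stop: float = 560.0, step: float = 20.0):
    return np.arange(start, stop + step / 2, step)


@dataclass
class ImageStack:
    """Ordered brightfield z-slices with their optical geometry.

    ``slices`` is a (n_slices, ny, nx) float array; slice k sits at
    z = k * dz.  ``dz`` may exceed ``depth_of_field`` (gapped axial
    sampling, as with 20 µm slice spacing and a ~10 µm depth of field).
    """

    slices: np.ndarray
    pixel_size: float
    dz: float
    depth_of_field: float

    def __post_init__(self):
        self.slices = np.asarray(self.slices, dtype=float)
        if self.slices.ndim != 3:
            raise ValueError("slices must be a (n_slices, ny, nx) array")
        for name in ("pixel_size", "dz", "depth_of_field"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def n_slices(self) -> int:
        return self.slices.shape[0]

    @property
    def shape(self):
        return self.slices.shape


@dataclass
class BinaryVolume:
    """Voxel occupancy grid reconstructed from a segmented stack.

    Voxels are pixel_size × pixel_size in xy; each occupied voxel is centred
    at its slice's z = k*dz with z-extent equal to the depth of field.  The
    physical origin is the centre of pixel (0, 0) of slice 0.
    """

    mask: np.ndarray  # (n_slices, ny, nx) bool
    pixel_size: float
    dz: float
    depth_of_field: float

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be a (n_slices, ny, nx) array")

    @property
    def n_occupied(self) -> int:
        return int(self.mask.sum())

    def footprint_um(self):
        """(width_x, width_y) of the xy footprint in µm."""
        _, ny, nx = self.mask.shape
        return nx * self.pixel_size, ny * self.pixel_size


@dataclass
class CylinderMap:
    """One concentric cylinder rolled out into a flat binary surface.

    ``surface`` has shape (n_slices, n_theta): rows are z levels, columns are
    angular samples spaced ``arc_step`` µm apart along the perimeter.  The
    angular axis wraps (theta = 0 and 2*pi are the same line on the
    cylinder).
    """

    radius: float
    surface: np.ndarray
    arc_step: float
    truncated: bool = False

    @property
    def n_theta(self) -> int:
        return self.surface.shape[1]


@dataclass
class ArborProfile:
    """Per-radius sprout traversal counts with zone structure.

    ``aggregate_mask`` flags radii inside the initial aggregate: cylinders
    there cut through the cell body, so their counts are excluded from
    the zone logic and the sprout statistics.  ``boundary_radius`` is the
    branching/elongation boundary: the smallest non-aggregate radius at
    which the traversal count is maximal (ties broken toward the centre).
    """

    radii: np.ndarray
    counts: np.ndarray
    aggregate_radius: float
    boundary_radius: float
    aggregate_mask: np.ndarray = field(default=None)

    def __post_init__(self):
        self.radii = np.asarray(self.radii, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if self.aggregate_mask is None:
            self.aggregate_mask = self.radii <= self.aggregate_radius

    def count_at(self, radius: float) -> int:
        """Traversal count at a grid radius; 0 beyond the profiled range."""
        hit = np.isclose(self.radii, radius)
        if not hit.any():
            if radius > self.radii[-1]:
                return 0
            raise ValueError(f"radius {radius} µm is not on the profile grid")
        return int(self.counts[hit][0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "radius_um": self.radii,
                "count": self.counts,
                "in_aggregate": self.aggregate_mask,
            }
        )


@dataclass
class LengthDistribution:
    """Normalised sprout counts vs. length beyond the zone boundary."""

    lengths: np.ndarray  # µm beyond each aggregate's boundary radius
    mean: np.ndarray  # group mean count / normalisation constant
    sem: np.ndarray
    n_aggregates: int
    normalization: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"length_um": self.lengths, "mean": self.mean, "sem": self.sem}
        )


def local_variance_map(slice_2d: np.ndarray, window: int) -> np.ndarray:
    """Per-pixel population variance of intensity in a square window.

    The border is handled by reflection.  Computed as E[x^2] - E[x]^2 with
    uniform filters, clipped at zero against round-off.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError(f"window must be an odd integer >= 3, got {window}")
    img = np.asarray(slice_2d, dtype=float)
    if not np.all(np.isfinite(img)):
        raise ValueError("slice contains non-finite values")
    mean = ndi.uniform_filter(img, size=window, mode="reflect")
    mean_sq = ndi.uniform_filter(img * img, size=window, mode="reflect")
    return np.maximum(mean_sq - mean * mean, 0.0)


def _drop_specks(mask: np.ndarray, min_size: int) -> np.ndarray:
    # remove components of fewer than min_size pixels
    return remove_small_objects(mask, max_size=min_size - 1)


def _disk(radius: int) -> np.ndarray:
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    return (yy * yy + xx * xx) <= radius * radius


def segment_slice(
    slice_2d: np.ndarray,
    window: int = 5,
    threshold="auto",
    min_size: int = 16,
    compensate: bool = True,
) -> np.ndarray:
    """Binary in-focus mask of one slice from its local-variance map.

    ``threshold="auto"`` picks the cut by the between-class-variance (Otsu)
    criterion on the log-variance map, which separates the smooth
    (out-of-focus / background) and textured (in-focus) populations; it
    needs a slice holding both.  A numeric threshold is applied directly to
    the variance map.  Because a window touching a textured object anywhere
    already carries high variance, the raw suprathreshold support is the
    object dilated by about half a window; ``compensate=True`` erodes the
    mask by window // 2 to undo this, recovering object boundaries to
    roughly a pixel.  Components smaller than ``min_size`` pixels are then
    removed.
    """
    vmap = local_variance_map(slice_2d, window)
    if threshold == "auto":
        vmax = float(vmap.max())
        if vmax <= 0:
            warnings.warn("slice has no intensity variance; empty mask")
            return np.zeros(vmap.shape, dtype=bool)
        mask = vmap > _auto_variance_threshold(vmap)
    else:
        mask = vmap > float(threshold)
    if compensate and mask.any():
        mask = ndi.binary_erosion(mask, structure=_disk(window // 2))
    if mask.any():
        mask = _drop_specks(mask, min_size)
    if not mask.any():
        warnings.warn("segmentation produced an empty mask")
    return mask


def _auto_variance_threshold(vmap: np.ndarray) -> float:
    """Between-class-variance (Otsu) cut on the log-variance distribution,
    returned on the plain variance scale.

    Guard against unimodal input: a windowed variance estimate scatters
    within a factor of a few around its mode (chi-square sampling spread),
    while genuine in-focus texture sits orders of magnitude above the
    background.  If the cut lands within 4x the median variance it is
    splitting a single mode, and no foreground is declared.
    """
    vmax = float(np.max(vmap))
    if vmax <= 0:
        return np.inf
    floor = 1e-12 * vmax
    cut = float(np.exp(threshold_otsu(np.log(vmap + floor))) - floor)
    if cut < 4.0 * float(np.median(vmap)):
        warnings.warn(
            "variance distribution is not bimodal; declaring no foreground"
        )
        return np.inf
    return cut


def reconstruct_volume(
    stack: ImageStack,
    window: int = 5,
    threshold="auto",
    min_size: int = 16,
    compensate: bool = True,
) -> BinaryVolume:
    """Segment every slice and assemble the voxel reconstruction.

    With ``threshold="auto"`` a single cut is chosen from the pooled
    log-variance distribution of the whole stack (a single slice far from
    the arbor may hold no in-focus structure at all, which would defeat a
    per-slice criterion) and applied to every slice.  Each foreground pixel
    of slice k becomes one occupied voxel centred at z = k * dz with
    z-extent equal to the depth of field; the inter-slice gap
    (dz - depth_of_field, when positive) is left unfilled.
    """
    if threshold == "auto":
        vmaps = np.stack([local_variance_map(s, window) for s in stack.slices])
        threshold = _auto_variance_threshold(vmaps)
    mask = np.stack(
        [
            segment_slice(s, window=window, threshold=threshold,
                          min_size=min_size, compensate=compensate)
            for s in stack.slices
        ]
    )
    return BinaryVolume(
        mask=mask,
        pixel_size=stack.pixel_size,
        dz=stack.dz,
        depth_of_field=stack.depth_of_field,
    )


def cylinder_traversals(
    volume: BinaryVolume,
    center: tuple,
    radii,
    arc_step: float | None = None,
) -> list:
    """Sample concentric vertical cylinders through the reconstruction.

    ``center`` is the aggregate centre in µm (x, y).  For each radius the
    cylinder surface is sampled at every z level and at angular increments of
    ``arc_step`` µm of arc (default: one pixel size); a surface point is
    marked when it falls inside an occupied voxel's xy footprint.  Radii
    reaching beyond the imaged field are truncated to it with a warning.
    """
    if arc_step is None:
        arc_step = volume.pixel_size
    radii = np.atleast_1d(np.asarray(radii, dtype=float))
    if np.any(radii <= 0) or np.any(np.diff(radii) <= 0):
        raise ValueError("radii must be positive and strictly increasing")
    nz, ny, nx = volume.mask.shape
    cx, cy = float(center[0]), float(center[1])
    px = volume.pixel_size
    if not (0 <= cx <= nx * px and 0 <= cy <= ny * px):
        raise ValueError("center lies outside the volume footprint")
    maps = []
    for r in radii:
        n_theta = max(8, int(np.ceil(2 * np.pi * r / arc_step)))
        theta = np.arange(n_theta) * (2 * np.pi / n_theta)
        xs = cx + r * np.cos(theta)
        ys = cy + r * np.sin(theta)
        ci = np.rint(xs / px).astype(int)
        ri = np.rint(ys / px).astype(int)
        inside = (ci >= 0) & (ci < nx) & (ri >= 0) & (ri < ny)
        truncated = not bool(inside.all())
        if truncated:
            warnings.warn(
                f"cylinder r = {r:g} µm extends beyond the imaged field; truncated"
            )
        surface = np.zeros((nz, n_theta), dtype=bool)
        if inside.any():
            surface[:, inside] = volume.mask[:, ri[inside], ci[inside]]
        maps.append(
            CylinderMap(radius=float(r), surface=surface, arc_step=arc_step,
                        truncated=truncated)
        )
    return maps


_EIGHT = np.ones((3, 3), dtype=bool)


def count_sprouts(cmap: CylinderMap, min_patch_px: int = 4, z_gap_merge: int = 1) -> int:
    """Count distinct sprout traversal patches on a rolled-out cylinder.

    Particle detection with 8-connectivity; the angular axis wraps, so a
    patch split across the theta = 0 seam is counted once.  Because the
    axial sampling is gapped (dz > depth of field), one sprout crossing the
    cylinder between two imaged planes can surface as patches separated by
    a single blank z row; ``z_gap_merge`` z rows of gap are bridged before
    labelling.  Patch area (in original surface pixels) must reach
    ``min_patch_px`` to count.
    """
    if min_patch_px < 1:
        raise ValueError("min_patch_px must be >= 1")
    surf = cmap.surface
    if not surf.any():
        return 0
    work = surf
    if z_gap_merge > 0:
        struct = np.ones((2 * z_gap_merge + 1, 1), dtype=bool)
        work = ndi.binary_closing(surf, structure=struct) | surf
    labels, n_labels = ndi.label(work, structure=_EIGHT)
    if n_labels == 0:
        return 0
    # merge labels across the angular seam
    parent = np.arange(n_labels + 1)

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    left, right = labels[:, 0], labels[:, -1]
    nz = labels.shape[0]
    for i in range(nz):
        if left[i] == 0:
            continue
        for j in (i - 1, i, i + 1):  # 8-connectivity across the seam
            if 0 <= j < nz and right[j] != 0:
                ra, rb = find(left[i]), find(right[j])
                if ra != rb:
                    parent[rb] = ra
    roots = np.array([find(l) for l in range(n_labels + 1)])
    merged = roots[labels]
    # area = original (unbridged) surface pixels per merged component
    areas = np.bincount(merged[surf], minlength=n_labels + 1)
    return int(np.count_nonzero(areas[1:] >= min_patch_px))


def arbor_profile(radii, counts, aggregate_radius: float) -> ArborProfile:
    """Zone structure from per-radius traversal counts.

    The branching/elongation boundary is the smallest radius outside the
    aggregate attaining the maximal traversal count.  Radii inside the
    aggregate are flagged and take no part in the zone logic.
    """
    radii = np.asarray(radii, dtype=float)
    counts = np.asarray(counts, dtype=int)
    if radii.shape != counts.shape:
        raise ValueError("radii and counts must have the same length")
    if aggregate_radius < 0:
        raise ValueError("aggregate_radius must be >= 0")
    outside = radii > aggregate_radius
    if not outside.any() or counts[outside].max() == 0:
        raise ValueError("no sprouts detected")
    cmax = counts[outside].max()
    boundary = radii[outside][counts[outside] == cmax][0]
    return ArborProfile(
        radii=radii,
        counts=counts,
        aggregate_radius=aggregate_radius,
        boundary_radius=float(boundary),
    )


def length_distribution(profiles, control_profiles, step: float | None = None):
    """Normalised sprout-number-vs-length curves for a group and its control.

    For each aggregate, elongation-zone counts are re-expressed against
    sprout length beyond that aggregate's own zone boundary (length 0 at the
    boundary); a sprout "longer than L" still traverses the cylinder at
    boundary + L.  Group curves are the per-length mean (with SEM over
    aggregates) divided by the control group's average count at its
    boundary, so the control curve equals 1.0 at length 0 by construction.

    Returns ``(group_curve, control_curve)`` as :class:`LengthDistribution`.
    """
    if not control_profiles:
        raise ValueError("control group is empty")
    norm = float(np.mean([p.count_at(p.boundary_radius) for p in control_profiles]))
    if norm == 0:
        raise ValueError("normalization constant is zero (no control sprouts)")

    def group_curve(group):
        if step is None:
            st = float(np.min(np.diff(group[0].radii)))
        else:
            st = step
        max_len = max(p.radii[-1] - p.boundary_radius for p in group)
        lengths = np.arange(0.0, max_len + st / 2, st)
        vals = np.zeros((len(group), lengths.size))
        for i, p in enumerate(group):
            for j, L in enumerate(lengths):
                r = p.boundary_radius + L
                vals[i, j] = p.count_at(r) if r <= p.radii[-1] + 1e-9 else 0
        mean = vals.mean(axis=0) / norm
        if len(group) > 1:
            sem = vals.std(axis=0, ddof=1) / np.sqrt(len(group)) / norm
        else:
            sem = np.zeros_like(mean)
        return LengthDistribution(
            lengths=lengths,
            mean=mean,
            sem=sem,
            n_aggregates=len(group),
            normalization=norm,
        )

    return group_curve(profiles), group_curve(control_profiles)


def analyze_stack(
    stack: ImageStack,
    center_um=None,
    aggregate_radius="auto",
    radii=None,
    window: int = 5,
    threshold="auto",
    min_size: int = 16,
    arc_step: float | None = None,
    min_patch_px: int = 4,
):
    """Full modified-Sholl pipeline on one z-stack.

    Returns ``(profile, cylinder_maps, volume)``.  ``center_um`` and
    ``aggregate_radius`` default to the centroid and equivalent radius of
    the largest connected component of the middle slice's mask — a
    reproducible stand-in for the manual aggregate marking; pass explicit
    values to override.
    """
    volume = reconstruct_volume(stack, window=window, threshold=threshold,
                                min_size=min_size)
    if center_um is None or aggregate_radius == "auto":
        mid = volume.mask[volume.mask.shape[0] // 2]
        labels, n = ndi.label(mid, structure=_EIGHT)
        if n == 0:
            raise ValueError("no sprouts detected")
        sizes = np.bincount(labels.ravel())[1:]
        big = int(np.argmax(sizes)) + 1
        rows, cols = np.nonzero(labels == big)
        auto_center = (cols.mean() * stack.pixel_size, rows.mean() * stack.pixel_size)
        auto_r = np.sqrt(sizes[big - 1] / np.pi) * stack.pixel_size
        if center_um is None:
            center_um = auto_center
        if aggregate_radius == "auto":
            aggregate_radius = auto_r
    if radii is None:
        radii = default_radii()
    maps = cylinder_traversals(volume, center_um, radii, arc_step=arc_step)
    counts = np.array([count_sprouts(m, min_patch_px=min_patch_px) for m in maps])
    profile = arbor_profile(radii, counts, float(aggregate_radius))
    return profile, maps, volume
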