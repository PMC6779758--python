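"""Synthetic data with exact ground truth for every analysis stage.

Four generators emulate the study's raw data classes:

* **Tracks** — persistent random walks: the direction decorrelates on a
  configurable persistence time while per-step speeds fluctuate around a
  programmed mean (optionally time-varying).  Emulates 10-minute-interval
  cell motility recordings and hourly sprout-tip tracks.
* **Sprout arbors** — tubes radiating in 3D from a central spherical
  aggregate, branching only inside a programmed branching zone, rendered as
  a defocused brightfield z-stack: in-focus tube cross-sections carry a
  high-variance texture, out-of-focus parts only a smooth shading.  The
  ground truth enumerates the exact cylinder crossings (angle, z, count)
  at every analysis radius from the tube geometry, never from the pixels.
* **Vessel fields** — random thick-segment networks rendered as bright
  fluorescence on a dark background, with the realised mask kept as truth.
* **Gelatin fields** — a bright substrate with non-overlapping dark
  digested patches of programmed total area.

All generators are deterministic functions of (config, seed): a single seed
fans out to independent substreams per component.

Geometry notes for the arbor phantom: primary sprouts leave the aggregate
surface at well-separated base angles; a branch takes off steeply (its
angular offset, expressed as a constant arc length, is reached within a few
µm of radial growth) so that distinct branches cross every *sampled*
cylinder radius at arcs at least ~32 µm apart and remain individually
countable.  Branch spawn radii are placed between sampling radii.  Sprout
extents are uniform beyond the branching-zone edge, which makes the
traversal-count profile rise through the branching zone, peak at the zone
edge and decay beyond it — the structure the zone-boundary detector looks
for.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .arbor import ImageStack, default_radii
from .morphometry import FieldImage
from .tracks import TrackSet

__all__ = [
    "TrackSimConfig",
    "ArborSimConfig",
    "VesselSimConfig",
    "GelatinSimConfig",
    "generate_tracks",
    "generate_arbor",
    "generate_vessel_field",
    "generate_gelatin",
]


def _substream(seed: int, *tags: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *tags]))


# ---------------------------------------------------------------------------
# trajectories


@dataclass
class TrackSimConfig:
    """Persistent-random-walk simulation parameters.

    ``persistence_time`` (h) is the direction decorrelation time:
    <cos(theta(t) - theta(0))> = exp(-t / persistence_time); ``math.inf``
    gives straight-line (ballistic) motion.  ``speed_cv`` is the
    coefficient of variation of per-step speeds (gamma-distributed);
    ``speed_schedule``, if given, maps time (h) to the mean speed at that
    time, overriding ``speed_mean``.  The defaults mirror a 24 h recording
    sampled every 10 minutes with strongly persistent endothelial motility.
    """

    n_cells: int = 100
    duration: float = 24.0  # h
    dt: float = 1.0 / 6.0  # h (10 min frames)
    speed_mean: float = 11.0  # µm/h
    speed_cv: float = 0.2
    persistence_time: float = 8.0  # h
    speed_schedule: object = None  # callable t -> µm/h, or None
    seed: int = 0
    arena: float = 1000.0  # µm, initial scatter of starting positions

    def validate(self):
        if self.n_cells < 1:
            raise ValueError("n_cells must be positive")
        for name in ("duration", "dt", "speed_mean", "persistence_time"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.speed_cv < 0:
            raise ValueError("speed_cv must be >= 0")
        n_steps = self.duration / self.dt
        if abs(n_steps - round(n_steps)) > 1e-9:
            raise ValueError("dt must divide duration")


def generate_tracks(cfg: TrackSimConfig):
    """Simulate a TrackSet of persistent random walks.

    Returns ``(tracks, ground_truth)`` where the ground truth records the
    programmed mean speed and the realised per-track mean step speed
    (path length / time), the quantity the 1 h-lag speed estimator
    approaches for strongly persistent motion.
    """
    cfg.validate()
    rng = _substream(cfg.seed, 1)
    n_steps = int(round(cfg.duration / cfg.dt))
    times = np.arange(n_steps + 1) * cfg.dt
    theta = np.empty((cfg.n_cells, n_steps))
    theta0 = rng.uniform(0, 2 * np.pi, size=cfg.n_cells)
    if math.isinf(cfg.persistence_time):
        theta[:] = theta0[:, None]
    else:
        sigma = np.sqrt(2.0 * cfg.dt / cfg.persistence_time)
        turns = rng.normal(0.0, sigma, size=(cfg.n_cells, n_steps))
        turns[:, 0] = 0.0
        theta = theta0[:, None] + np.cumsum(turns, axis=1)
    if cfg.speed_schedule is not None:
        mean_speed = np.asarray(
            [float(cfg.speed_schedule(t)) for t in times[:-1]]
        )[None, :]
    else:
        mean_speed = np.full((1, n_steps), cfg.speed_mean)
    if cfg.speed_cv > 0:
        shape = 1.0 / cfg.speed_cv**2
        speeds = rng.gamma(shape, scale=mean_speed / shape,
                           size=(cfg.n_cells, n_steps))
    else:
        speeds = np.broadcast_to(mean_speed, (cfg.n_cells, n_steps)).copy()
    steps = speeds[..., None] * cfg.dt * np.stack(
        [np.cos(theta), np.sin(theta)], axis=-1
    )
    start = rng.uniform(0, cfg.arena, size=(cfg.n_cells, 1, 2))
    pos = np.concatenate(
        [start, start + np.cumsum(steps, axis=1)], axis=1
    )
    tracks = TrackSet(times=times, positions=pos)
    truth = {
        "programmed_speed_mean": cfg.speed_mean,
        "per_track_mean_step_speed": speeds.mean(axis=1).tolist(),
        "mean_step_speed": float(speeds.mean()),
        "persistence_time": cfg.persistence_time,
    }
    return tracks, truth


# ---------------------------------------------------------------------------
# sprout arbors


@dataclass
class ArborSimConfig:
    """Geometry and rendering parameters of the synthetic sprout arbor."""

    n_sprouts: int = 12
    aggregate_radius: float = 100.0  # µm
    max_radius: float = 560.0  # µm, outermost analysis radius
    branching_zone_outer: float = 200.0  # µm, programmed zone boundary
    branch_probability: float = 0.35  # per primary sprout per 20 µm zone bin
    tube_width: float = 12.0  # µm
    pixel_size: float = 2.0  # µm/px
    dz: float = 20.0  # µm
    depth_of_field: float = 10.0  # µm
    n_slices: int = 14
    image_shape: tuple = (600, 600)  # (ny, nx) px
    radial_step: float = 20.0  # µm, analysis radius spacing
    extent_bins: tuple | None = None  # (lo, hi) µm grid bins for sprout extents
    render_aggregate: bool = True
    texture_amplitude: float = 0.35
    background_noise: float = 0.015  # per-pixel camera-noise std
    defocus_dip: float = 0.06  # peak darkening of out-of-focus shading
    seed: int = 0

    def validate(self):
        if not (0 < self.aggregate_radius < self.branching_zone_outer
                < self.max_radius):
            raise ValueError(
                "need 0 < aggregate_radius < branching_zone_outer < max_radius"
            )
        if self.tube_width <= 0:
            raise ValueError("tube_width must be positive")
        if not 0 <= self.branch_probability <= 1:
            raise ValueError("branch_probability must be in [0, 1]")
        if self.n_sprouts < 0:
            raise ValueError("n_sprouts must be >= 0")
        half_field = min(self.image_shape) * self.pixel_size / 2
        if self.max_radius > half_field:
            raise ValueError("max_radius exceeds the rendered field")

    @property
    def radii(self) -> np.ndarray:
        return default_radii(self.radial_step, self.max_radius, self.radial_step)

    @property
    def z_extent(self) -> float:
        return (self.n_slices - 1) * self.dz


@dataclass
class _Branch:
    """One tube, parameterised by radial distance from the aggregate centre.

    The angular coordinate ramps from the parent's base angle to a constant
    *arc* offset within ``_RAMP_UM`` µm of radial growth (a steep take-off,
    so the branch is laterally resolved from its parent at the very next
    sampled radius).  The axial coordinate likewise ramps from the spawn
    height to a target band and then drifts slowly inside it.
    """

    theta_base: float
    arc_offset: float  # µm of arc
    r_spawn: float
    extent: float
    z_start: float
    z_target: float
    z_slope: float
    z_band: float = 20.0  # max |z - z_target| after the ramp

    def theta(self, r):
        ramp = np.clip((np.asarray(r, dtype=float) - self.r_spawn) / _RAMP_UM, 0, 1)
        return self.theta_base + self.arc_offset * ramp / np.maximum(r, 1e-9)

    def z(self, r):
        r = np.asarray(r, dtype=float)
        ramp = np.clip((r - self.r_spawn) / _RAMP_UM, 0, 1)
        base = self.z_start + (self.z_target - self.z_start) * ramp
        drift = self.z_slope * np.maximum(r - self.r_spawn - _RAMP_UM, 0.0)
        return np.clip(base + drift, self.z_target - self.z_band,
                       self.z_target + self.z_band)


_RAMP_UM = 2.0  # radial distance over which a branch reaches its lane
_LANE_ARC = 32.0  # µm arc separation between angular branch lanes
_MIN_BASE_ARC = 29.0  # µm minimum resolvable arc between any two tubes


def _offgrid(rng, lo_bin: float, hi_bin: float, step: float) -> float:
    """A value in a random grid bin, kept >= 0.25*step away from grid points."""
    bins = np.arange(lo_bin, hi_bin + step / 2, step)
    return float(rng.choice(bins) + step * rng.uniform(0.3, 0.7))


def _build_branches(cfg: ArborSimConfig, rng) -> list:
    """Lay out primary sprouts and their zone-confined branches.

    Every tube crossing a sampled cylinder radius is separated from every
    other tube there either by at least one angular lane (~18 µm of arc) or
    by an axial gap of several slice spacings, so the phantom is fully
    resolvable by the particle counter and the geometric ground truth is
    also what an ideal detector would report.  Spawn radii and extents sit
    between sampled radii.  Branch capacity per sprout is whatever the
    lane budget at the first sampled radius allows; requested branch events
    beyond it are dropped.
    """
    n = cfg.n_sprouts
    if n == 0:
        return []
    z_mid = cfg.z_extent / 2  # 130 µm for the default 14-slice stack
    first_sampled = cfg.aggregate_radius + cfg.radial_step
    gap_arc = 2 * np.pi * first_sampled / n  # arc between adjacent bases
    if gap_arc < _MIN_BASE_ARC:
        raise ValueError(
            f"n_sprouts = {n} cannot be angularly resolved at "
            f"r = {first_sampled:g} µm; enlarge the aggregate or reduce n"
        )
    max_off = max(0.0, (gap_arc - _MIN_BASE_ARC) / 2)
    lanes_per_side = int(max_off // _LANE_ARC)
    # axial lanes sit well clear of the primaries' mid-depth band
    z_lanes = []
    if cfg.z_extent >= 240:
        z_lanes = [("z", z_mid - 115), ("z", z_mid + 115)]
    base = 2 * np.pi * np.arange(n) / n + rng.uniform(
        -0.05, 0.05, size=n
    ) * 2 * np.pi / n
    branches = []
    zone_bins = np.arange(cfg.aggregate_radius, cfg.branching_zone_outer,
                          cfg.radial_step)
    if cfg.extent_bins is not None:
        ext_lo_bin, ext_hi_bin = cfg.extent_bins
    else:
        ext_lo_bin, ext_hi_bin = (cfg.branching_zone_outer + cfg.radial_step,
                                  cfg.max_radius)
    for i in range(n):
        prim = _Branch(
            theta_base=base[i],
            arc_offset=0.0,
            r_spawn=cfg.aggregate_radius,
            extent=_offgrid(rng, ext_lo_bin, ext_hi_bin, cfg.radial_step),
            z_start=float(z_mid + rng.uniform(-10, 10)),
            z_target=float(z_mid + rng.uniform(-10, 10)),
            z_slope=float(rng.uniform(-0.045, 0.045)),
            z_band=20.0,
        )
        branches.append(prim)
        lanes = []
        for k in range(1, lanes_per_side + 1):
            lanes.extend([("theta", k), ("theta", -k)])
        lanes.extend(z_lanes)
        li = 0
        for b0 in zone_bins:
            if li >= len(lanes) or rng.uniform() >= cfg.branch_probability:
                continue
            kind, lane = lanes[li]
            li += 1
            r_spawn = float(b0 + cfg.radial_step * rng.uniform(0.35, 0.55))
            if kind == "theta":
                arc = lane * _LANE_ARC + float(rng.uniform(-2, 2))
                z_target = float(prim.z(r_spawn))
                z_band = 20.0
                z_slope = float(rng.uniform(-0.045, 0.045))
            else:
                arc = 0.0
                z_target = float(lane + rng.uniform(-3, 3))
                z_band = 6.0
                z_slope = float(rng.uniform(-0.01, 0.01))
            branches.append(
                _Branch(
                    theta_base=base[i],
                    arc_offset=arc,
                    r_spawn=r_spawn,
                    extent=_offgrid(rng, ext_lo_bin, ext_hi_bin,
                                    cfg.radial_step),
                    z_start=float(prim.z(r_spawn)),
                    z_target=z_target,
                    z_slope=z_slope,
                    z_band=z_band,
                )
            )
    return branches


def _arbor_ground_truth(cfg: ArborSimConfig, branches) -> dict:
    """Exact per-radius crossings from the tube geometry."""
    radii = cfg.radii
    counts, angles = [], []
    for r in radii:
        if r <= cfg.aggregate_radius:
            counts.append(0)
            angles.append([])
            continue
        th = [
            float(b.theta(r)) % (2 * np.pi)
            for b in branches
            if b.r_spawn < r <= b.extent
        ]
        counts.append(len(th))
        angles.append(sorted(th))
    return {
        "radii_um": radii.tolist(),
        "counts": counts,
        "crossing_angles_rad": angles,
        "boundary_radius_um": cfg.branching_zone_outer,
        "aggregate_radius_um": cfg.aggregate_radius,
        "n_primary": cfg.n_sprouts,
        "n_branches_total": len(branches),
    }


def _stamp_disks(shape, centers_px, radius_px) -> np.ndarray:
    """Boolean image with disks of radius_px at integer centres (row, col)."""
    out = np.zeros(shape, dtype=bool)
    if len(centers_px) == 0:
        return out
    pts = np.zeros(shape, dtype=bool)
    rows = np.clip(centers_px[:, 0], 0, shape[0] - 1)
    cols = np.clip(centers_px[:, 1], 0, shape[1] - 1)
    pts[rows, cols] = True
    rr = int(np.ceil(radius_px))
    yy, xx = np.mgrid[-rr : rr + 1, -rr : rr + 1]
    disk = (yy**2 + xx**2) <= radius_px**2
    return ndi.binary_dilation(pts, structure=disk)


def generate_arbor(cfg: ArborSimConfig):
    """Render a synthetic sprout arbor as a brightfield-like z-stack.

    Returns ``(stack, ground_truth)``.  The ground truth holds the exact
    crossing count and angles per analysis radius, the programmed zone
    boundary, the aggregate geometry and, per slice, the true in-focus
    mask (for segmentation-fidelity checks).
    """
    cfg.validate()
    rng = _substream(cfg.seed, 2)
    branches = _build_branches(cfg, rng)
    truth = _arbor_ground_truth(cfg, branches)
    ny, nx = cfg.image_shape
    px = cfg.pixel_size
    cx_um, cy_um = nx * px / 2, ny * px / 2
    truth["center_um"] = [cx_um, cy_um]
    z_mid = cfg.z_extent / 2
    half_w = cfg.tube_width / 2
    focus_half = (cfg.depth_of_field + cfg.tube_width) / 2

    # centreline points of every tube, sampled at <= ~0.7 µm of curve length
    # (the take-off ramp moves far in arc/z per µm of radius, so it is
    # sampled much more finely than the radial trunk)
    pts_xyz = []
    for b in branches:
        ramp_end = min(b.r_spawn + _RAMP_UM, b.extent)
        ramp_travel = abs(b.arc_offset) + abs(b.z_target - b.z_start) + _RAMP_UM
        rr_ramp = np.linspace(b.r_spawn, ramp_end, max(8, int(2 * ramp_travel)))
        rr_main = np.arange(ramp_end, b.extent, 0.7)
        rr = np.concatenate([rr_ramp, rr_main])
        th = b.theta(rr)
        pts_xyz.append(
            np.column_stack(
                [cx_um + rr * np.cos(th), cy_um + rr * np.sin(th), b.z(rr)]
            )
        )
    pts_xyz = np.vstack(pts_xyz) if pts_xyz else np.empty((0, 3))

    rng_noise = _substream(cfg.seed, 3)
    slices = []
    focus_masks = []
    base_ramp = (
        0.55
        + 0.05 * np.linspace(-1, 1, ny)[:, None]
        + 0.05 * np.linspace(-1, 1, nx)[None, :]
    )
    for k in range(cfg.n_slices):
        z_k = k * cfg.dz
        # smooth illumination field plus a flat camera-noise floor; the noise
        # floor sets the background mode of the variance distribution well
        # above the tiny gradients of the defocused shading
        img = (
            base_ramp
            + ndi.gaussian_filter(rng_noise.normal(0, 1.0, size=(ny, nx)), 10) * 0.05
            + rng_noise.normal(0, cfg.background_noise, size=(ny, nx))
        )
        # in-focus: tube material inside this slice's depth-of-field window
        if pts_xyz.size:
            sel = np.abs(pts_xyz[:, 2] - z_k) <= focus_half
            centers = np.column_stack(
                [
                    np.rint(pts_xyz[sel, 1] / px).astype(int),
                    np.rint(pts_xyz[sel, 0] / px).astype(int),
                ]
            )
            focus = _stamp_disks((ny, nx), centers, half_w / px)
            # out-of-focus halo: nearby tube material, rendered smooth
            sel_oof = (~sel) & (np.abs(pts_xyz[:, 2] - z_k) <= focus_half + 40)
            centers_oof = np.column_stack(
                [
                    np.rint(pts_xyz[sel_oof, 1] / px).astype(int),
                    np.rint(pts_xyz[sel_oof, 0] / px).astype(int),
                ]
            )
            oof = _stamp_disks((ny, nx), centers_oof, half_w / px + 4) & ~focus
        else:
            focus = np.zeros((ny, nx), dtype=bool)
            oof = focus
        # the aggregate: a textured sphere slab at the field centre
        dz_sphere = abs(z_k - z_mid)
        if cfg.render_aggregate and dz_sphere < cfg.aggregate_radius:
            disk_r = np.sqrt(cfg.aggregate_radius**2 - dz_sphere**2)
            yy, xx = np.mgrid[0:ny, 0:nx]
            agg = ((xx * px - cx_um) ** 2 + (yy * px - cy_um) ** 2) <= disk_r**2
            focus = focus | agg
        img = img - ndi.gaussian_filter(oof.astype(float), 8) * cfg.defocus_dip
        img[focus] += rng_noise.uniform(
            -cfg.texture_amplitude, cfg.texture_amplitude, size=int(focus.sum())
        )
        slices.append(img)
        focus_masks.append(focus)
    stack = ImageStack(
        slices=np.stack(slices) if slices else np.zeros((0, ny, nx)),
        pixel_size=px,
        dz=cfg.dz,
        depth_of_field=cfg.depth_of_field,
    )
    truth["focus_masks"] = np.stack(focus_masks) if focus_masks else None
    truth["centerline_points_um"] = pts_xyz
    return stack, truth


# ---------------------------------------------------------------------------
# vessel fields and gelatin substrates


@dataclass
class VesselSimConfig:
    """Random thick-segment vessel network with a programmed area density."""

    target_density: float = 0.3
    width_mean: float = 12.0  # µm
    width_sd: float = 3.0
    segment_length: float = 200.0  # µm, mean
    field_um: tuple = (865.0, 650.0)  # (x, y), one microscopic field
    pixel_size: float = 1.3  # µm/px
    vessel_intensity: float = 0.85
    background_intensity: float = 0.15
    noise_sd: float = 0.03
    seed: int = 0

    def validate(self):
        if not 0 <= self.target_density <= 1:
            raise ValueError("target_density must be in [0, 1]")
        if self.width_mean <= 0 or self.pixel_size <= 0:
            raise ValueError("width_mean and pixel_size must be positive")


def _thick_segment_mask(shape, p0, p1, half_w_px):
    """Pixels within half_w_px of the segment p0-p1 (px coordinates, row/col)."""
    length = float(np.hypot(*(np.asarray(p1) - np.asarray(p0))))
    n = max(2, int(length * 2))
    ts = np.linspace(0, 1, n)
    centers = np.rint(
        np.asarray(p0)[None, :] + ts[:, None] * (np.asarray(p1) - np.asarray(p0))
    ).astype(int)
    keep = (
        (centers[:, 0] >= -half_w_px)
        & (centers[:, 0] < shape[0] + half_w_px)
        & (centers[:, 1] >= -half_w_px)
        & (centers[:, 1] < shape[1] + half_w_px)
    )
    return _stamp_disks(shape, centers[keep], half_w_px)


def generate_vessel_field(cfg: VesselSimConfig):
    """Render a vessel network of programmed density.

    Random thick segments (biased to continue from earlier segment ends, so
    the network looks connected) accumulate until the mask density reaches
    the target.  Returns ``(field, ground_truth)`` with the realised binary
    mask and its exact density, plus segment-width bookkeeping.
    """
    cfg.validate()
    rng = _substream(cfg.seed, 4)
    nx = int(round(cfg.field_um[0] / cfg.pixel_size))
    ny = int(round(cfg.field_um[1] / cfg.pixel_size))
    mask = np.zeros((ny, nx), dtype=bool)
    widths = []
    endpoints = []
    guard = 0
    while mask.mean() < cfg.target_density and guard < 10000:
        guard += 1
        if endpoints and rng.uniform() < 0.7:
            p0 = endpoints[rng.integers(len(endpoints))]
        else:
            p0 = np.array([rng.uniform(0, ny), rng.uniform(0, nx)])
        ang = rng.uniform(0, 2 * np.pi)
        length_px = max(20.0, rng.normal(cfg.segment_length, cfg.segment_length / 4)) / cfg.pixel_size
        p1 = p0 + length_px * np.array([np.sin(ang), np.cos(ang)])
        w = max(3.0, rng.normal(cfg.width_mean, cfg.width_sd))
        mask |= _thick_segment_mask((ny, nx), p0, p1, w / 2 / cfg.pixel_size)
        widths.append(w)
        endpoints.append(p1)
    img = np.where(mask, cfg.vessel_intensity, cfg.background_intensity)
    img = img + rng.normal(0, cfg.noise_sd, size=img.shape)
    field = FieldImage(image=img, pixel_size=cfg.pixel_size)
    truth = {
        "mask": mask,
        "density": float(mask.mean()),
        "target_density": cfg.target_density,
        "segment_widths_um": widths,
    }
    return field, truth


@dataclass
class GelatinSimConfig:
    """Bright gelatin substrate with dark digested patches of known area."""

    target_fraction: float = 0.10
    patch_radius_range: tuple = (5.0, 25.0)  # µm
    field_um: tuple = (865.0, 650.0)
    pixel_size: float = 1.3
    substrate_intensity: float = 0.75
    digested_intensity: float = 0.15
    noise_sd: float = 0.03
    seed: int = 0

    def validate(self):
        if not 0 <= self.target_fraction <= 1:
            raise ValueError("target_fraction must be in [0, 1]")


def generate_gelatin(cfg: GelatinSimConfig):
    """Render a gelatin-digestion image with programmed digested fraction.

    Non-overlapping dark disks are placed until the pixel-exact digested
    fraction reaches the target (the last disk is sized to close the
    remainder).  Returns ``(field, ground_truth)`` with the realised dark
    mask and its exact fraction.
    """
    cfg.validate()
    rng = _substream(cfg.seed, 5)
    nx = int(round(cfg.field_um[0] / cfg.pixel_size))
    ny = int(round(cfg.field_um[1] / cfg.pixel_size))
    total_px = nx * ny
    dark = np.zeros((ny, nx), dtype=bool)
    forbidden = np.zeros((ny, nx), dtype=bool)  # dark patches + 2 px margin
    yy, xx = np.mgrid[0:ny, 0:nx]
    r_lo, r_hi = cfg.patch_radius_range
    attempts = 0
    while dark.mean() < cfg.target_fraction and attempts < 20000:
        attempts += 1
        remaining = (cfg.target_fraction - dark.mean()) * total_px
        r_max_fit = min(r_hi, np.sqrt(remaining / np.pi) * cfg.pixel_size)
        if r_max_fit < 2 * cfg.pixel_size:
            break
        r_um = rng.uniform(min(r_lo, r_max_fit), r_max_fit)
        r_px = r_um / cfg.pixel_size
        cy = rng.uniform(r_px, ny - r_px)
        cx = rng.uniform(r_px, nx - r_px)
        dist_sq = (yy - cy) ** 2 + (xx - cx) ** 2
        disk = dist_sq <= r_px**2
        if (disk & forbidden).any():
            continue  # keep patches disjoint so the bookkeeping stays exact
        dark |= disk
        forbidden |= dist_sq <= (r_px + 2) ** 2
    img = np.where(dark, cfg.digested_intensity, cfg.substrate_intensity)
    img = img + rng.normal(0, cfg.noise_sd, size=img.shape)
    field = FieldImage(image=img, pixel_size=cfg.pixel_size)
    truth = {
        "mask": dark,
        "digested_fraction": float(dark.mean()),
        "target_fraction": cfg.target_fraction,
    }
    return field, truth
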