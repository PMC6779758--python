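"""Modified-Sholl pipeline: variance segmentation, cylinder counting, zones."""

import numpy as np
import pytest

from sproutquant import (
    ArborProfile,
    BinaryVolume,
    CylinderMap,
    arbor_profile,
    analyze_stack,
    count_sprouts,
    cylinder_traversals,
    default_radii,
    generate_arbor,
    length_distribution,
    local_variance_map,
    reconstruct_volume,
    segment_slice,
)

from conftest import small_arbor_config


# ---------------------------------------------------------------- variance map


def test_variance_of_constant_slice_is_zero():
    assert np.all(local_variance_map(np.full((20, 20), 3.7), 5) == 0)


def test_variance_of_enumerated_patch_closed_form():
    # 3x3 window over values {0..8}: population variance = 60/9
    img = np.zeros((11, 11))
    img[4:7, 4:7] = np.arange(9).reshape(3, 3)
    vmap = local_variance_map(img, 3)
    assert vmap[5, 5] == pytest.approx(60.0 / 9.0, rel=1e-12)


def test_variance_matches_direct_window_recomputation(rng):
    img = rng.normal(size=(30, 40))
    w = 7
    vmap = local_variance_map(img, w)
    # scipy uniform_filter "reflect" duplicates the edge sample,
    # which is numpy pad mode "symmetric"
    padded = np.pad(img, w // 2, mode="symmetric")
    for r, c in [(0, 0), (3, 17), (29, 39), (15, 20)]:
        win = padded[r : r + w, c : c + w]
        assert vmap[r, c] == pytest.approx(win.var(), rel=1e-9, abs=1e-12)


@pytest.mark.parametrize("window", [2, 4, 1, -3])
def test_even_or_tiny_window_rejected(window):
    with pytest.raises(ValueError, match="window"):
        local_variance_map(np.zeros((5, 5)), window)


# ---------------------------------------------------------------- segmentation


def test_constant_slice_segments_empty():
    with pytest.warns(UserWarning):
        mask = segment_slice(np.ones((50, 50)), window=5)
    assert not mask.any()


def test_infinite_threshold_gives_empty_mask():
    rng = np.random.default_rng(0)
    img = rng.uniform(size=(50, 50))
    with pytest.warns(UserWarning):
        mask = segment_slice(img, window=5, threshold=np.inf)
    assert not mask.any()


@pytest.mark.parametrize("seed", range(10))
def test_textured_disk_on_smooth_ramp_iou(seed):
    """Auto segmentation recovers a textured disk with IoU >= 0.9."""
    rng = np.random.default_rng(seed)
    ny = nx = 240
    yy, xx = np.mgrid[0:ny, 0:nx]
    truth = ((yy - ny / 2) ** 2 + (xx - nx / 2) ** 2) <= 60**2
    img = 0.5 + 0.2 * xx / nx + rng.normal(0, 0.015, size=(ny, nx))
    img[truth] += rng.uniform(-0.35, 0.35, size=int(truth.sum()))
    mask = segment_slice(img, window=5)
    iou = (mask & truth).sum() / (mask | truth).sum()
    assert iou >= 0.9


# -------------------------------------------------------------- reconstruction


def test_reconstruction_stacks_per_slice_masks_and_geometry():
    cfg = small_arbor_config(seed=4)
    stack, _ = generate_arbor(cfg)
    vol = reconstruct_volume(stack)
    assert vol.mask.shape == stack.shape
    assert vol.dz == stack.dz
    assert vol.depth_of_field == stack.depth_of_field
    assert vol.n_occupied > 0


def test_empty_stack_reconstructs_to_zero_voxels():
    cfg = small_arbor_config(n_sprouts=0, render_aggregate=False, seed=1)
    stack, _ = generate_arbor(cfg)
    with pytest.warns(UserWarning):
        vol = reconstruct_volume(stack)
    assert vol.n_occupied == 0


def test_centerline_points_covered_by_occupied_voxels():
    """>= 95% of true tube centreline samples fall inside the reconstruction."""
    cfg = small_arbor_config(seed=6)
    stack, truth = generate_arbor(cfg)
    vol = reconstruct_volume(stack)
    pts = truth["centerline_points_um"]
    cols = np.clip(np.rint(pts[:, 0] / cfg.pixel_size).astype(int), 0,
                   vol.mask.shape[2] - 1)
    rows = np.clip(np.rint(pts[:, 1] / cfg.pixel_size).astype(int), 0,
                   vol.mask.shape[1] - 1)
    covered = vol.mask.any(axis=0)[rows, cols]
    assert covered.mean() >= 0.95


# ------------------------------------------------------------------- cylinders


def _paint_radial_tube(mask, center_px, angle, r0_px, r1_px, half_w_px, k):
    for r in np.arange(r0_px, r1_px, 0.5):
        c = int(round(center_px[0] + r * np.cos(angle)))
        rr = int(round(center_px[1] + r * np.sin(angle)))
        mask[k, rr - half_w_px : rr + half_w_px + 1,
             c - half_w_px : c + half_w_px + 1] = True


def _tube_volume(n_tubes, nz=5, size=300, r0=55, r1=140, seed=0):
    """Straight radial tubes painted directly into a voxel grid (px units)."""
    rng = np.random.default_rng(seed)
    mask = np.zeros((nz, size, size), dtype=bool)
    angles = 2 * np.pi * np.arange(n_tubes) / max(n_tubes, 1)
    angles += rng.uniform(0, 2 * np.pi / max(n_tubes, 1) / 3)
    for a in angles:
        _paint_radial_tube(mask, (size // 2, size // 2), a, r0, r1, 3, nz // 2)
    return BinaryVolume(mask=mask, pixel_size=2.0, dz=20.0, depth_of_field=10.0), angles


def test_default_radii_grid_matches_convention():
    radii = default_radii()
    assert radii.size == 28
    assert radii[0] == 20.0 and radii[-1] == 560.0
    assert np.all(np.diff(radii) == 20.0)


def test_single_radial_tube_yields_one_patch_per_crossed_radius():
    vol, _ = _tube_volume(1)
    maps = cylinder_traversals(vol, (300.0, 300.0), [140.0, 200.0, 260.0])
    counts = [count_sprouts(m) for m in maps]
    assert counts == [1, 1, 1]  # r0*px=110 < 140..260 < r1*px=280


def test_count_conservation_for_radial_tube_phantom():
    for n in (3, 12, 30):
        vol, _ = _tube_volume(n, seed=n)
        radii = np.arange(140.0, 280.0, 20.0)
        counts = [count_sprouts(m)
                  for m in cylinder_traversals(vol, (300.0, 300.0), radii)]
        assert counts == [n] * radii.size


def test_rotation_about_cylinder_axis_preserves_counts():
    vol, _ = _tube_volume(7, seed=3)
    rot = BinaryVolume(mask=np.rot90(vol.mask, axes=(1, 2)).copy(),
                       pixel_size=vol.pixel_size, dz=vol.dz,
                       depth_of_field=vol.depth_of_field)
    radii = np.arange(140.0, 280.0, 20.0)
    c0 = [count_sprouts(m) for m in cylinder_traversals(vol, (300.0, 300.0), radii)]
    # rot90 maps pixel (r, c) -> (size-1-c, r), so the centre shifts one row
    c1 = [count_sprouts(m) for m in cylinder_traversals(rot, (300.0, 298.0), radii)]
    assert c0 == c1


def test_halving_arc_step_preserves_counts():
    vol, _ = _tube_volume(9, seed=5)
    radii = np.arange(140.0, 280.0, 20.0)
    for arc in (2.0, 1.0):
        counts = [
            count_sprouts(m)
            for m in cylinder_traversals(vol, (300.0, 300.0), radii, arc_step=arc)
        ]
        assert counts == [9] * radii.size


def test_crossing_angles_match_ground_truth_within_one_arc_step():
    cfg = small_arbor_config(seed=8, n_sprouts=5)
    stack, truth = generate_arbor(cfg)
    vol = reconstruct_volume(stack)
    radii = np.asarray(truth["radii_um"])
    maps = cylinder_traversals(vol, truth["center_um"], radii)
    for m, angles in zip(maps, truth["crossing_angles_rad"]):
        if m.radius <= cfg.aggregate_radius or not angles:
            continue
        marked = m.surface.any(axis=0)
        cols = np.rint(np.asarray(angles) / (2 * np.pi) * m.n_theta).astype(int)
        # every true crossing angle lands on or next to a marked column
        for c in cols % m.n_theta:
            window = marked.take(range(c - 1, c + 2), mode="wrap")
            assert window.any()


def test_radius_beyond_footprint_truncates_with_warning():
    vol, _ = _tube_volume(2)
    with pytest.warns(UserWarning, match="truncated"):
        maps = cylinder_traversals(vol, (300.0, 300.0), [500.0])
    assert maps[0].truncated


def test_center_outside_volume_rejected():
    vol, _ = _tube_volume(2)
    with pytest.raises(ValueError, match="center"):
        cylinder_traversals(vol, (1e5, 0.0), [100.0])


# ------------------------------------------------------------ particle counting


def _cmap(surface):
    return CylinderMap(radius=100.0, surface=np.asarray(surface, bool), arc_step=2.0)


def test_empty_surface_counts_zero():
    assert count_sprouts(_cmap(np.zeros((5, 40)))) == 0


def test_two_patches_above_min_size_count_two():
    surf = np.zeros((10, 60), bool)
    surf[1:6, 5:10] = True  # 25 px
    surf[1:6, 30:35] = True  # 25 px
    assert count_sprouts(_cmap(surf), min_patch_px=9) == 2


def test_patch_split_across_angular_seam_counts_once():
    surf = np.zeros((6, 50), bool)
    surf[2:4, 47:] = True
    surf[2:4, :3] = True
    assert count_sprouts(_cmap(surf)) == 1


def test_min_patch_px_filters_specks():
    surf = np.zeros((6, 50), bool)
    surf[2, 10] = True  # single-pixel speckle
    surf[3:5, 30:34] = True  # 8 px patch
    assert count_sprouts(_cmap(surf), min_patch_px=4) == 1


def test_one_slice_axial_gap_is_bridged():
    # a sprout crossing between two imaged planes surfaces as rows k and k+2
    surf = np.zeros((8, 40), bool)
    surf[2, 10:16] = True
    surf[4, 10:16] = True
    assert count_sprouts(_cmap(surf)) == 1
    assert count_sprouts(_cmap(surf), z_gap_merge=0) == 2


# ------------------------------------------------------------------ zone logic


def test_boundary_at_first_radius_for_decreasing_counts():
    radii = np.arange(20.0, 180.0, 20.0)
    counts = np.array([9, 8, 7, 6, 5, 4, 3, 2])
    prof = arbor_profile(radii, counts, aggregate_radius=10.0)
    assert prof.boundary_radius == 20.0


def test_boundary_tie_breaks_toward_smaller_radius():
    prof = arbor_profile([20.0, 40.0, 60.0, 80.0], [3, 7, 7, 5],
                         aggregate_radius=10.0)
    assert prof.boundary_radius == 40.0


def test_aggregate_radii_excluded_from_zone_logic():
    # huge counts inside the aggregate must not set the boundary
    prof = arbor_profile([20.0, 40.0, 60.0, 80.0], [99, 4, 6, 2],
                         aggregate_radius=30.0)
    assert prof.boundary_radius == 60.0
    assert list(prof.aggregate_mask) == [True, False, False, False]


def test_all_zero_counts_rejected():
    with pytest.raises(ValueError, match="no sprouts"):
        arbor_profile([20.0, 40.0], [0, 0], aggregate_radius=10.0)


# ------------------------------------------------------- length distributions


def _profile(counts, radii=None, aggregate=100.0):
    radii = np.arange(120.0, 120.0 + 20.0 * len(counts), 20.0) if radii is None \
        else radii
    return arbor_profile(radii, counts, aggregate)


def test_control_curve_is_one_at_its_boundary():
    ctrl = [_profile([10, 8, 6, 4, 2]), _profile([12, 9, 7, 5, 3])]
    _, c = length_distribution(ctrl, ctrl)
    assert c.mean[0] == pytest.approx(1.0)
    assert c.normalization == pytest.approx(11.0)


def test_group_with_40pct_fewer_sprouts_scales_to_0_6():
    ctrl = [_profile([10, 10, 8, 6, 4])] * 4
    kd = [_profile([6, 6, 5, 4, 2])]
    g, c = length_distribution(kd, ctrl)
    assert g.mean[0] == pytest.approx(0.6)
    np.testing.assert_allclose(g.mean, np.array([6, 6, 5, 4, 2]) / 10.0)


def test_radii_beyond_every_sprout_extent_normalise_to_zero():
    ctrl = [_profile([10, 8, 0, 0, 0])]
    _, c = length_distribution(ctrl, ctrl)
    assert c.mean[-1] == 0.0


def test_zero_normalisation_rejected():
    # control counts vanish outside the aggregate at the boundary
    prof = ArborProfile(radii=np.array([120.0, 140.0]), counts=np.array([0, 0]),
                        aggregate_radius=100.0, boundary_radius=120.0)
    with pytest.raises(ValueError, match="[Nn]ormali[sz]ation"):
        length_distribution([prof], [prof])


def test_empty_control_group_rejected():
    with pytest.raises(ValueError, match="control"):
        length_distribution([_profile([3, 2, 1, 1, 0])], [])


# ------------------------------------------------------------------ end-to-end


def test_monotone_tail_beyond_boundary_for_branch_free_arbor():
    cfg = small_arbor_config(n_sprouts=5, branch_probability=0.0, seed=12)
    stack, truth = generate_arbor(cfg)
    profile, _, _ = analyze_stack(stack, center_um=truth["center_um"],
                                  aggregate_radius=cfg.aggregate_radius,
                                  radii=np.asarray(truth["radii_um"]))
    sel = profile.radii >= profile.boundary_radius
    tail = profile.counts[sel]
    assert np.all(np.diff(tail) <= 0)


def test_auto_center_and_aggregate_close_to_truth():
    cfg = small_arbor_config(n_sprouts=6, seed=13)
    stack, truth = generate_arbor(cfg)
    profile, _, _ = analyze_stack(stack, radii=np.asarray(truth["radii_um"]))
    # the middle-slice largest blob includes tube stubs attached to the
    # aggregate, so the equivalent radius overshoots somewhat
    assert cfg.aggregate_radius * 0.7 < profile.aggregate_radius < cfg.aggregate_radius * 1.6
    assert profile.boundary_radius in truth["radii_um"]
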