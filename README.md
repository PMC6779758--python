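# sproutquant

Quantitative analysis of endothelial cell motility and multicellular
sprout growth, for researchers running in-vitro angiogenesis assays
(spheroid sprouting in fibrin/collagen gels), time-lapse motility
recordings, chorion vessel imaging, and gelatin-degradation assays.

The package implements four analyses plus synthetic generators with exact
ground truth for every one of them:

* **Trajectory statistics** — mean cell displacement over a lag,
  `d(τ) = ⟨|x_i(t+τ) − x_i(t)|⟩_{i,t}`, and the time-dependent mean speed
  `v(t) = ⟨|x_i(t+τ₀) − x_i(t)|⟩_i / τ₀` with a one-hour lag, both with SEM
  stripes; missing observations exclude pairs, nothing is imputed.
* **Modified Sholl analysis** of sprout arbors: brightfield z-stacks
  (dz = 20 µm, ~10 µm depth of field) are segmented by local intensity
  variance (in-focus = textured, out-of-focus = smooth), reconstructed
  into a voxel volume, and probed with concentric vertical cylinders
  (radii 20–560 µm, 20 µm apart).  Connected patches on each rolled-out
  cylinder surface count the sprouts traversing that radius; the
  branching/elongation-zone boundary is the radius of maximal traversal
  count, and group comparisons use sprout-length distributions normalised
  to the control count at that boundary.
* **Vessel morphometry** — per-field density (vessel area / field area),
  mean segment width (distance transform along the skeleton) and total
  centreline length (skeleton path length).
* **Gelatin digestion** — the area fraction where fluorescence is lost.

## Worked example

```python
import numpy as np
import sproutquant as sq

# 1. simulate a 24 h motility recording (10-minute frames) and measure it
cfg = sq.TrackSimConfig(n_cells=100, duration=24.0, speed_mean=11.0, seed=1)
tracks, truth = sq.generate_tracks(cfg)
speed = sq.mean_speed_timeseries(tracks, tau0=1.0)
disp = sq.mean_displacement(tracks, lags=[1/6, 1.0, 5.0])

# 2. render a sprout arbor z-stack and run the modified Sholl analysis
acfg = sq.ArborSimConfig(n_sprouts=12, seed=1)
stack, gt = sq.generate_arbor(acfg)
profile, maps, volume = sq.analyze_stack(
    stack, center_um=gt["center_um"], aggregate_radius=acfg.aggregate_radius)

# 3. vessel morphometry on a field of programmed density
field, vt = sq.generate_vessel_field(sq.VesselSimConfig(target_density=0.75, seed=1))
stats = sq.vessel_stats(sq.vessel_mask(field), field.pixel_size)
```

This prints (via the obvious `print` statements):

```
mean speed over the recording: 10.78 um/h (programmed 11.0)
mean displacement at 10 min / 1 h / 5 h: 1.8 / 10.8 / 49.5 um
zone boundary: 200 um (programmed 200)
counts at 120..240 um: [16, 22, 25, 28, 31, 31, 28]
truth  at 120..240 um: [16, 22, 25, 28, 31, 31, 28]
vessel density 0.754, mean width 21.1 um, total length 30.0 mm
```

Reading the numbers: the measured speed (10.78 µm/h) sits ~2% below the
programmed 11 µm/h because a one-hour *chord* is slightly shorter than the
path of a persistently turning cell; displacement grows almost linearly
with lag (1.8 µm at 10 min ≈ 11 µm/h × 1/6 h), the signature of persistent
motion.  The traversal counts rise through the branching zone, peak at the
programmed 200 µm boundary, and match the generator's exact crossing
bookkeeping; the vessel density recovers the programmed 0.75 to well
within a percentage point.

## Command line

Every analysis is also a subcommand of `sproutquant`:

```sh
sproutquant simulate tracks --seed 3 --out sim/
sproutquant motility --tracks sim/tracks.csv --dt-min 10 --lags 10min:5h --out out/
sproutquant arbor --stack stack.tif --config arbor.json --out out/
sproutquant arbor-compare --group kd/ --control ctrl/ --out out/
sproutquant vessels --image field.tif --config vessels.json --out out/
sproutquant gelatin --image gel.tif --out out/
```

Track tables are CSV (`track_id,frame,t_hours,x_um,y_um`), stacks are
multi-page TIFF with a JSON sidecar for the geometry, and every run writes
its resolved configuration (with a config hash) next to its outputs.
Identical seed and config reproduce byte-identical outputs.

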