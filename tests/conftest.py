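import numpy as np
import pytest

from sproutquant import ArborSimConfig, TrackSet


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_random_trackset(seed, n_tracks=5, n_times=30, dt=1.0 / 6.0,
                         missing_frac=0.0):
    """Uncorrelated random-walk TrackSet, optionally with missing entries."""
    rng = np.random.default_rng(seed)
    times = np.arange(n_times) * dt
    steps = rng.normal(0, 5.0, size=(n_tracks, n_times - 1, 2))
    pos = np.concatenate(
        [np.zeros((n_tracks, 1, 2)), np.cumsum(steps, axis=1)], axis=1
    )
    pos += rng.uniform(0, 100, size=(n_tracks, 1, 2))
    if missing_frac > 0:
        holes = rng.uniform(size=(n_tracks, n_times)) < missing_frac
        pos[holes] = np.nan
    return TrackSet(times=times, positions=pos)


def make_straight_trackset(speed, n_tracks=3, n_times=31, dt=1.0 / 6.0):
    """Straight-line tracks at a given speed (µm/h), random headings."""
    rng = np.random.default_rng(0)
    times = np.arange(n_times) * dt
    ang = rng.uniform(0, 2 * np.pi, size=n_tracks)
    vel = speed * np.stack([np.cos(ang), np.sin(ang)], axis=1)  # (N, 2)
    pos = vel[:, None, :] * times[None, :, None]
    return TrackSet(times=times, positions=pos)


def small_arbor_config(**kw):
    """Reduced-size arbor phantom for unit tests (fast render)."""
    defaults = dict(
        n_sprouts=6,
        aggregate_radius=100.0,
        branching_zone_outer=160.0,
        max_radius=260.0,
        image_shape=(300, 300),
        n_slices=7,
        seed=0,
    )
    defaults.update(kw)
    return ArborSimConfig(**defaults)
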