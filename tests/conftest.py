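import logging

import numpy as np
import pandas as pd
import pytest

from fptrack.trajectories import Track

logging.getLogger("fptrack").setLevel(logging.ERROR)


def make_track(x, y, interval_s=7200.0, label="t", bird="b") -> Track:
    x = np.asarray(x, dtype=float)
    ts = pd.date_range("2020-01-01", periods=len(x), freq=pd.Timedelta(seconds=interval_s), tz="UTC")
    return Track(
        bird_id=bird,
        track_label=label,
        fixes=pd.DataFrame({"timestamp": ts, "x": x, "y": np.asarray(y, dtype=float)}),
        is_planar=True,
    )


def random_walk_track(seed: int, n: int = 80, step: float = 300.0, interval_s: float = 600.0) -> Track:
    rng = np.random.default_rng(seed)
    steps = rng.gamma(3.0, step / 3.0, n - 1)
    angles = rng.uniform(0, 2 * np.pi, n - 1)
    dx = np.concatenate([[0.0], steps * np.cos(angles)])
    dy = np.concatenate([[0.0], steps * np.sin(angles)])
    return make_track(np.cumsum(dx), np.cumsum(dy), interval_s=interval_s, label=f"rw{seed}")


@pytest.fixture
def straight_track():
    # constant speed 1 m/s, fix every 100 s
    n = 101
    return make_track(np.arange(n) * 100.0, np.zeros(n), interval_s=100.0, label="line")


@pytest.fixture(scope="session")
def small_study():
    """A reduced synthetic study shared across integration tests."""
    from fptrack.synthetic import SimConfig, SiteConfig, simulate_study

    cfg = SimConfig(
        seed=11,
        n_birds_per_site=2,
        track_days=60,
        sites=[
            SiteConfig("BAR", (30_000.0, 30_000.0), 0.0),
            SiteConfig("STR", (90_000.0, 30_000.0), 0.3),
        ],
    )
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def small_report(small_study):
    from fptrack.pipeline import RunConfig, run_pipeline

    return run_pipeline(
        small_study["tracks"],
        small_study["env"],
        small_study["elevation"],
        small_study["sites"],
        RunConfig(),
    )
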