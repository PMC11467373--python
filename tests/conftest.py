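import numpy as np
import pytest
from hypothesis import settings

from gridloc.io import TagSpec
from gridloc.synthetic import SceneConfig, TrialSpec, make_scene
from gridloc.workflow import WorkflowRunner

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")

DECAY_TRUTH = dict(a=68.0, S=0.01, K=-105.0)


def small_trials(n=2, duration=60.0, mode_cycle=("high_flight", "ground")):
    """Short trials sharing one tag, hourly offsets."""
    return [
        TrialSpec(
            f"t{i}",
            mode_cycle[i % len(mode_cycle)],
            duration=duration,
            tag=TagSpec("tag01"),
            t_offset=3600.0 * i,
        )
        for i in range(n)
    ]


@pytest.fixture(scope="session")
def noiseless_scene():
    """5x5 grid, exact decay law: the analytically transparent scene."""
    cfg = SceneConfig(
        n_rows=5, n_cols=5, drop_nodes=(), noise_sd=0.0, node_offset_sd=0.0,
        noise_ar1=0.0, seed=11,
    )
    return make_scene(cfg, small_trials(2), with_landscape=False)


@pytest.fixture(scope="session")
def noiseless_runner(noiseless_scene):
    return WorkflowRunner.from_scene(noiseless_scene, seed=5)


@pytest.fixture(scope="session")
def noisy_scene():
    """5x5 grid with AR(1) RSS noise and per-node offsets."""
    cfg = SceneConfig(
        n_rows=5, n_cols=5, drop_nodes=(), noise_sd=2.0, node_offset_sd=3.0,
        noise_ar1=0.6, seed=23,
    )
    return make_scene(cfg, small_trials(3, duration=120.0), with_landscape=False)


@pytest.fixture(scope="session")
def noisy_runner(noisy_scene):
    return WorkflowRunner.from_scene(noisy_scene, seed=7)


def brute_force_position(nodes: np.ndarray, d: np.ndarray, pad=500.0, coarse=10.0):
    """Independent localisation oracle: grid scan + local 1 m scan + polish.

    Deliberately separate from the package's solver and fallback.
    """
    lo = nodes.min(axis=0) - pad
    hi = nodes.max(axis=0) + pad

    def scan(xs, ys):
        best, bx, by = np.inf, None, None
        for xv in xs:
            r = np.sqrt((xv - nodes[:, 0]) ** 2 + (ys[:, None] - nodes[:, 1]) ** 2)
            obj = ((d - r) ** 2).sum(axis=1)
            j = int(np.argmin(obj))
            if obj[j] < best:
                best, bx, by = obj[j], xv, ys[j]
        return np.array([bx, by])

    p = scan(np.arange(lo[0], hi[0] + coarse, coarse), np.arange(lo[1], hi[1] + coarse, coarse))
    p = scan(np.arange(p[0] - 2 * coarse, p[0] + 2 * coarse + 1, 1.0),
             np.arange(p[1] - 2 * coarse, p[1] + 2 * coarse + 1, 1.0))
    # quadratic local polish via fine sampling
    p = scan(np.arange(p[0] - 1.0, p[0] + 1.001, 0.05), np.arange(p[1] - 1.0, p[1] + 1.001, 0.05))
    return p
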