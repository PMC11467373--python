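"""Synthetic scene generator: grids, tracks, RSS emission, censoring."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist

from gridloc.io import TagSpec
from gridloc.synthetic import (
    MODE_DEFAULTS,
    SceneConfig,
    TrialSpec,
    emit_rss,
    make_dem,
    make_grid,
    make_scene,
    simulate_track,
)


class TestMakeGrid:
    def test_7x7_lattice_at_150m(self):
        grid = make_grid(SceneConfig(drop_nodes=()))
        assert len(grid) == 49
        d = pdist(grid.positions)
        assert d.min() == pytest.approx(150.0, abs=1e-6)

    def test_dropout_of_three_ids_gives_46_nodes(self):
        grid = make_grid(SceneConfig())  # default drop list has 3 ids
        assert len(grid) == 46

    def test_2x2_hull_area_is_spacing_squared(self):
        grid = make_grid(SceneConfig(n_rows=2, n_cols=2, drop_nodes=()))
        assert grid.hull.area == pytest.approx(150.0**2, rel=1e-9)

    def test_too_small_grid_rejected(self):
        with pytest.raises(ValueError):
            make_grid(SceneConfig(n_rows=1, n_cols=3, drop_nodes=()))


class TestSimulateTrack:
    @pytest.fixture(scope="class")
    def setting(self):
        cfg = SceneConfig(n_rows=5, n_cols=5, drop_nodes=(), seed=0)
        grid = make_grid(cfg)
        dem = make_dem(cfg, grid, np.random.default_rng(0))
        return cfg, grid, dem

    def test_realised_speed_matches_spec_within_15_percent(self, setting):
        _, grid, dem = setting
        rng = np.random.default_rng(10)
        for mode in MODE_DEFAULTS:
            speeds = []
            for _ in range(20):
                spec = TrialSpec("t", mode, tag=TagSpec("a"))
                tr = simulate_track(spec, grid, dem, rng)
                steps = np.hypot(np.diff(tr["x"]), np.diff(tr["y"]))
                speeds.append(steps.sum() / (tr["t"].iloc[-1] - tr["t"].iloc[0]))
            assert np.mean(speeds) == pytest.approx(spec.speed_mean, rel=0.15)

    def test_fixes_stay_inside_reflective_boundary(self, setting):
        _, grid, dem = setting
        rng = np.random.default_rng(11)
        xmin, ymin, xmax, ymax = grid.hull.bounds
        for _ in range(5):
            tr = simulate_track(TrialSpec("t", "high_flight", tag=TagSpec("a")), grid, dem, rng)
            assert tr["x"].between(xmin, xmax).all()
            assert tr["y"].between(ymin, ymax).all()

    def test_too_short_duration_rejected(self, setting):
        _, grid, dem = setting
        with pytest.raises(ValueError):
            simulate_track(
                TrialSpec("t", "ground", duration=5.0, fix_interval=2.0, tag=TagSpec("a")),
                grid, dem, np.random.default_rng(0),
            )


class TestEmitRSS:
    def _noiseless(self, floor=-115.0):
        cfg = SceneConfig(
            n_rows=4, n_cols=4, drop_nodes=(), noise_sd=0.0, node_offset_sd=0.0,
            noise_ar1=0.0, detection_floor=floor, seed=3,
        )
        grid = make_grid(cfg)
        dem = make_dem(cfg, grid, np.random.default_rng(3))
        spec = TrialSpec("t0", "ground", duration=60.0, tag=TagSpec("tagX"))
        track = simulate_track(spec, grid, dem, np.random.default_rng(4))
        offsets = {n: 0.0 for n in grid.node_ids}
        det = emit_rss(track, spec, grid, cfg, None, offsets, np.random.default_rng(5), jitter=0.0)
        return cfg, grid, track, det

    def test_noiseless_rss_follows_decay_law_exactly(self):
        cfg, grid, track, det = self._noiseless()
        t = track["t"].to_numpy()
        for _, row in det.head(200).iterrows():
            te = row["timestamp_utc"].timestamp()
            px = np.interp(te, t, track["x"])
            py = np.interp(te, t, track["y"])
            nx, ny = grid.position_of(row["node_id"])
            expected = cfg.a * np.exp(-cfg.S * np.hypot(px - nx, py - ny)) + cfg.K
            assert row["rss_db"] == pytest.approx(expected, abs=1e-9)

    def test_floor_above_peak_rss_censors_everything(self):
        *_, det = self._noiseless(floor=-105.0 + 68.0 + 1.0)
        assert det.empty

    def test_no_emitted_read_below_detection_floor(self):
        scene = make_scene(
            SceneConfig(n_rows=4, n_cols=4, drop_nodes=(), noise_sd=3.0, seed=6),
            trials=[TrialSpec("t0", "ground", duration=60.0, tag=TagSpec("a"))],
            with_landscape=False,
        )
        assert (scene.detections["rss_db"] >= scene.config.detection_floor).all()

    def test_ground_mode_sees_fewer_nodes_than_high_flight_in_dense_cover(self):
        """Canopy attenuation censors weak reads for ground tags on the
        same path, mirroring height-dependent detectability.  The detection
        floor sits above the asymptote here so that range limits bite."""
        cfg = SceneConfig(n_rows=5, n_cols=5, drop_nodes=(), noise_sd=0.0,
                          node_offset_sd=0.0, noise_ar1=0.0, seed=7,
                          detection_floor=-104.0)
        scene = make_scene(cfg, trials=[TrialSpec("hf", "high_flight", duration=60.0,
                                                  tag=TagSpec("a"))], with_landscape=True)
        track = scene.tracks["hf"]
        ground_spec = TrialSpec("gr", "ground", duration=60.0, tag=TagSpec("a"))
        offsets = {n: 0.0 for n in scene.nodes.node_ids}
        det_hf = emit_rss(track, scene.trials[0], scene.nodes, cfg, scene.veg, offsets,
                          np.random.default_rng(8), jitter=0.0)
        det_gr = emit_rss(track, ground_spec, scene.nodes, cfg, scene.veg, offsets,
                          np.random.default_rng(8), jitter=0.0)
        nodes_hf = det_hf.groupby("timestamp_utc")["node_id"].nunique().mean()
        nodes_gr = det_gr.groupby("timestamp_utc")["node_id"].nunique().mean()
        assert nodes_gr < nodes_hf


class TestSceneAssembly:
    def test_same_seed_reproduces_scene_exactly(self):
        cfg = SceneConfig(n_rows=4, n_cols=4, drop_nodes=(), seed=9)
        trials = [TrialSpec("t0", "ground", duration=40.0, tag=TagSpec("a"))]
        s1 = make_scene(cfg, trials, with_landscape=False)
        s2 = make_scene(cfg, trials, with_landscape=False)
        assert s1.detections.equals(s2.detections)
        assert s1.tracks["t0"].equals(s2.tracks["t0"])

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SceneConfig(noise_ar1=1.0)
        with pytest.raises(ValueError):
            SceneConfig(spacing=-1.0)
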