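"""Distance inversion, node selection, multilateration, grouped consensus."""

from math import comb

import numpy as np
import pandas as pd
import pytest

from conftest import brute_force_position
from gridloc.decay import DecayModel, DecayModelSet
from gridloc.localisation import (
    grouped_kmeans_localise,
    invert_distance,
    localise_relocations,
    multilaterate,
    select_nodes,
)

MODEL = DecayModel(a=68.0, S=0.01, K=-105.0)


class TestInvertDistance:
    def test_rss_at_a_plus_K_gives_zero_distance(self):
        assert invert_distance(MODEL.a + MODEL.K, MODEL) == 0.0

    def test_inversion_forward_checks(self):
        d = invert_distance(-80.0, MODEL)
        assert d == pytest.approx(100.06, abs=0.05)
        assert float(MODEL.predict(d)) == pytest.approx(-80.0, abs=1e-9)

    def test_read_at_or_below_asymptote_excluded(self):
        assert invert_distance(MODEL.K, MODEL) is None
        assert invert_distance(-103.0, DecayModel(68.0, 0.01, -103.0)) is None

    def test_reads_above_zero_distance_rss_clamped_to_zero(self):
        assert invert_distance(MODEL.a + MODEL.K + 5.0, MODEL) == 0.0


def _estimates(rss, d=None, node_ids=None):
    n = len(rss)
    return pd.DataFrame(
        {
            "node_id": node_ids or [f"n{i}" for i in range(n)],
            "rss_used": rss,
            "d_hat": d if d is not None else np.linspace(10, 10 * n, n),
            "scope": "general",
        }
    )


class TestSelectNodes:
    def test_strongest3_sorts_by_rss(self):
        est = _estimates([-80.0, -85.0, -90.0, -95.0, -100.0])
        sub, ties = select_nodes(est, "strongest3")
        assert sub["node_id"].tolist() == ["n0", "n1", "n2"] and ties == 0

    def test_nearest3_sorts_by_distance(self):
        est = _estimates([-90.0] * 4, d=[40.0, 10.0, 30.0, 20.0])
        sub, _ = select_nodes(est, "nearest3")
        assert sub["node_id"].tolist() == ["n1", "n3", "n2"]

    def test_exactly_three_nodes_all_rules_coincide(self):
        est = _estimates([-80.0, -90.0, -85.0])
        for rule in ("all", "strongest3", "nearest3"):
            sub, _ = select_nodes(est, rule)
            assert sorted(sub["node_id"]) == ["n0", "n1", "n2"]

    def test_rank3_tie_broken_by_node_id_and_counted(self):
        est = _estimates([-80.0, -82.0, -85.0, -85.0], node_ids=["n3", "n2", "n9", "n1"])
        sub, ties = select_nodes(est, "strongest3")
        assert "n1" in sub["node_id"].tolist() and "n9" not in sub["node_id"].tolist()
        assert ties == 1

    def test_fewer_than_three_estimates_rejected(self):
        with pytest.raises(ValueError):
            select_nodes(_estimates([-80.0, -90.0]), "all")


class TestMultilaterate:
    def test_exact_distances_recover_the_point(self):
        nodes = np.array([[0.0, 0.0], [100.0, 0.0], [0.0, 100.0]])
        truth = np.array([30.0, 40.0])
        d = np.hypot(*(nodes - truth).T)
        np.testing.assert_allclose(d, [50.0, 80.6226, 67.0820], atol=1e-3)
        p, ok, collinear = multilaterate(nodes, d)
        assert ok and not collinear
        assert np.hypot(*(p - truth)) < 0.5
        oracle = brute_force_position(nodes, d)
        assert np.hypot(*(p - oracle)) < 0.5

    def test_equilateral_symmetry_returns_centroid(self):
        ang = np.array([90.0, 210.0, 330.0]) * np.pi / 180.0
        nodes = 100.0 * np.column_stack([np.cos(ang), np.sin(ang)])
        d = np.full(3, 100.0)
        p, ok, _ = multilaterate(nodes, d)
        assert ok
        np.testing.assert_allclose(p, [0.0, 0.0], atol=1e-3)

    def test_symmetric_distance_bias_cancels_at_centroid(self):
        ang = np.array([90.0, 210.0, 330.0]) * np.pi / 180.0
        nodes = 100.0 * np.column_stack([np.cos(ang), np.sin(ang)])
        d = np.full(3, 100.0) + 50.0
        p, ok, _ = multilaterate(nodes, d)
        assert np.hypot(*(p - np.zeros(2))) < 1.0
        # the +50 bias creates a ring of equally good minima, so compare
        # objective values against the oracle rather than positions
        def obj(q):
            return float(((d - np.hypot(*(nodes - q).T)) ** 2).sum())

        oracle = brute_force_position(nodes, d)
        assert obj(p) <= obj(oracle) + 1e-6

    def test_collinear_layout_flagged_but_attempted(self):
        nodes = np.array([[0.0, 0.0], [100.0, 0.0], [200.0, 0.0]])
        d = np.array([50.0, 50.0, 150.0])
        p, _, collinear = multilaterate(nodes, d)
        assert collinear and np.all(np.isfinite(p))

    def test_noisy_distances_agree_with_brute_force_oracle(self):
        rng = np.random.default_rng(12)
        nodes = rng.uniform(0, 600, (6, 2))
        truth = np.array([250.0, 300.0])
        d = np.hypot(*(nodes - truth).T) + rng.normal(0, 30.0, 6)
        d = np.maximum(d, 0.0)
        p, ok, _ = multilaterate(nodes, d)
        oracle = brute_force_position(nodes, d)
        assert np.hypot(*(p - oracle)) < 0.5


class TestGroupedKmeans:
    def _scene(self, n_nodes, truth=(300.0, 320.0), seed=0):
        rng = np.random.default_rng(seed)
        pos = {f"n{i}": rng.uniform(0, 600, 2) for i in range(n_nodes)}
        truth = np.asarray(truth)
        est = pd.DataFrame(
            {
                "node_id": list(pos),
                "rss_used": [float(MODEL.predict(np.hypot(*(pos[n] - truth)))) for n in pos],
                "d_hat": [float(np.hypot(*(pos[n] - truth))) for n in pos],
                "scope": "general",
            }
        )
        return est, pos, truth

    def test_seven_nodes_give_99_candidate_subsets(self):
        assert sum(comb(7, k) for k in range(3, 8)) == 99
        est, pos, truth = self._scene(7)
        p, diag = grouped_kmeans_localise(est, pos, seed=1)
        assert diag.n_candidates == 99
        assert sum(diag.cluster_sizes) == 99
        assert np.hypot(*(p - truth)) < 0.5

    def test_three_nodes_degenerate_to_plain_multilateration(self):
        est, pos, _ = self._scene(3)
        p, diag = grouped_kmeans_localise(est, pos, seed=1)
        nodes = np.array([pos[n] for n in est["node_id"]])
        p_direct, _, _ = multilaterate(nodes, est["d_hat"].to_numpy())
        assert diag.n_candidates == 1 and diag.k_chosen == 1
        np.testing.assert_allclose(p, p_direct, atol=1e-9)

    def test_more_than_seven_nodes_capped_at_strongest_seven(self):
        est, pos, _ = self._scene(10)
        _, diag = grouped_kmeans_localise(est, pos, seed=1)
        assert diag.n_candidates == 99

    def test_corrupted_node_rejected_more_often_than_all_nodes(self):
        """A -20 dB corrupted node scatters the subsets containing it; the
        consensus centroid should beat plain all-node multilateration in a
        clear majority of replicates."""
        wins = 0
        n_rep = 50
        for rep in range(n_rep):
            est, pos, truth = self._scene(7, seed=100 + rep)
            bad = est["rss_used"].idxmin()
            est.loc[bad, "rss_used"] -= 20.0
            est.loc[bad, "d_hat"] = float(MODEL.invert(est.loc[bad, "rss_used"]))
            nodes = np.array([pos[n] for n in est["node_id"]])
            p_all, _, _ = multilaterate(nodes, est["d_hat"].to_numpy())
            p_km, _ = grouped_kmeans_localise(est, pos, seed=rep)
            err_all = np.hypot(*(p_all - truth))
            err_km = np.hypot(*(p_km - truth))
            wins += err_km < err_all
        assert wins >= 0.7 * n_rep


class TestLocaliseRelocations:
    def test_relocations_with_fewer_than_three_valid_nodes_skipped(self):
        pos = {"n0": np.array([0.0, 0.0]), "n1": np.array([100.0, 0.0]), "n2": np.array([0.0, 100.0])}
        obs = pd.DataFrame(
            {
                "trial_id": "t0",
                "reloc_idx": [0, 0, 0, 1, 1],
                "node_id": ["n0", "n1", "n2", "n0", "n1"],
                "rss_max": [-80.0, -85.0, -90.0, -80.0, -85.0],
                "rss_avg": [-80.0, -85.0, -90.0, -80.0, -85.0],
            }
        )
        ms = DecayModelSet(general=MODEL)
        est = localise_relocations(obs, pos, ms, "general", "rss_max", "all_nodes")
        assert est["reloc_idx"].tolist() == [0]

    def test_asymptote_exclusion_respects_three_node_minimum(self):
        """Dropping sub-asymptote reads must not drop a relocation that
        still has three usable nodes."""
        pos = {f"n{i}": np.array([100.0 * i, 50.0 * (i % 2)]) for i in range(4)}
        obs = pd.DataFrame(
            {
                "trial_id": "t0",
                "reloc_idx": 0,
                "node_id": list(pos),
                "rss_max": [-80.0, -85.0, -90.0, MODEL.K - 1.0],
                "rss_avg": [-80.0, -85.0, -90.0, MODEL.K - 1.0],
            }
        )
        ms = DecayModelSet(general=MODEL)
        est = localise_relocations(obs, pos, ms, "general", "rss_max", "all_nodes")
        assert len(est) == 1 and est["n_nodes_used"].iloc[0] == 3
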