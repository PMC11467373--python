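"""Localisation: invert decay models to distances, then solve for position.

Four methods per relocation:

* ``all_nodes`` — multilateration over every node with a usable read;
* ``strongest3`` — trilateration with the three strongest-RSS nodes;
* ``nearest3`` — trilateration with the three nearest nodes in estimated
  distance;
* ``grouped_kmeans`` — multilaterate every >=3-node subset of the <=7
  strongest nodes (at most 99 candidates), cluster the candidate points
  with k-means, and return the centroid of the largest cluster.

Exclusion rules: reads at or below the model's horizontal asymptote are
uninformative and dropped; negative inverted distances are clamped to 0 m;
relocations seen by fewer than three usable nodes are skipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .decay import DecayModel, DecayModelSet

__all__ = [
    "invert_distance",
    "build_distance_estimates",
    "select_nodes",
    "multilaterate",
    "grid_search_position",
    "grouped_kmeans_localise",
    "localise_relocations",
    "ConsensusDiagnostics",
]

MAX_KMEANS_NODES = 7
KMEANS_RESTARTS = 10
KMEANS_KMAX = 5
ELBOW_FRACTION = 0.10
GRID_PAD = 500.0


def invert_distance(rss: float, model: DecayModel) -> float | None:
    """Estimated distance (m) for one read, or None when rss <= K."""
    if rss <= model.K:
        return None
    d = float(model.invert(rss))
    return d


def build_distance_estimates(
    node_ids,
    rss_values,
    model_set: DecayModelSet,
    scope: str,
    tag_id: str | None = None,
) -> pd.DataFrame:
    """Distance-estimate table for one relocation.

    One row per node whose read clears the scope-appropriate asymptote;
    columns ``node_id, rss_used, d_hat, scope``.
    """
    rows = []
    for node_id, rss in zip(node_ids, rss_values):
        model = model_set.model_for(scope, node_id=node_id, tag_id=tag_id)
        d = invert_distance(float(rss), model)
        if d is not None:
            rows.append((str(node_id), float(rss), d, model.scope))
    return pd.DataFrame(rows, columns=["node_id", "rss_used", "d_hat", "scope"])


def select_nodes(estimates: pd.DataFrame, rule: str):
    """Apply a node-selection rule; returns (subset, n_ties_broken).

    ``strongest3`` ranks by RSS descending, ``nearest3`` by estimated
    distance ascending, ``all`` keeps everything.  Rank ties are broken by
    lexicographic node id and counted when tied candidates straddle the
    cut.
    """
    if len(estimates) < 3:
        raise ValueError("need >= 3 distance estimates; relocation should be skipped")
    if rule == "all":
        return estimates, 0
    if rule == "strongest3":
        key, ascending = "rss_used", False
    elif rule == "nearest3":
        key, ascending = "d_hat", True
    else:
        raise ValueError(f"unknown selection rule {rule!r}")
    ordered = estimates.sort_values(
        [key, "node_id"], ascending=[ascending, True], kind="stable"
    )
    subset = ordered.head(3)
    boundary = subset[key].iloc[-1]
    n_tied_total = int((estimates[key] == boundary).sum())
    n_tied_sel = int((subset[key] == boundary).sum())
    return subset, max(0, n_tied_total - n_tied_sel)


def _residuals(p, nodes, d):
    r = np.hypot(p[0] - nodes[:, 0], p[1] - nodes[:, 1])
    return d - r


def _start_point(nodes: np.ndarray, d: np.ndarray) -> np.ndarray:
    w = 1.0 / (d + 1.0)
    return (nodes * w[:, None]).sum(axis=0) / w.sum()


def grid_search_position(nodes: np.ndarray, d: np.ndarray, pad: float = GRID_PAD):
    """Brute-force position search over the padded node bounding box.

    Coarse 20 m scan, 1 m scan in a local window, then a simplex polish —
    the deterministic fallback when the least-squares solver fails.
    """
    lo = nodes.min(axis=0) - pad
    hi = nodes.max(axis=0) + pad

    def objective_grid(xs, ys):
        gx, gy = np.meshgrid(xs, ys, indexing="ij")
        r = np.sqrt(
            (gx[..., None] - nodes[:, 0]) ** 2 + (gy[..., None] - nodes[:, 1]) ** 2
        )
        obj = ((d - r) ** 2).sum(axis=-1)
        i, j = np.unravel_index(np.argmin(obj), obj.shape)
        return np.array([xs[i], ys[j]])

    best = objective_grid(np.arange(lo[0], hi[0] + 20.0, 20.0), np.arange(lo[1], hi[1] + 20.0, 20.0))
    best = objective_grid(
        np.arange(best[0] - 25.0, best[0] + 26.0, 1.0),
        np.arange(best[1] - 25.0, best[1] + 26.0, 1.0),
    )
    res = minimize(
        lambda p: float((_residuals(p, nodes, d) ** 2).sum()),
        best,
        method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-12},
    )
    return res.x


def _is_collinear(nodes: np.ndarray, tol: float = 1e-6) -> bool:
    c = nodes - nodes.mean(axis=0)
    sv = np.linalg.svd(c, compute_uv=False)
    return bool(sv[-1] <= tol * max(sv[0], 1.0))


def _lm_solve(nodes, d, x0, tol=1e-8, max_iter=200):
    """Levenberg-Marquardt on the range residuals; returns (p, converged)."""
    p = x0.astype(float).copy()
    lam = 1e-3
    r = _residuals(p, nodes, d)
    obj = float(r @ r)
    for _ in range(max_iter):
        diff = p - nodes
        rng_ = np.maximum(np.hypot(diff[:, 0], diff[:, 1]), 1e-12)
        J = -diff / rng_[:, None]
        g = J.T @ r
        H = J.T @ J
        accepted = False
        for _ in range(20):
            A = H + lam * np.diag(np.maximum(np.diag(H), 1e-12))
            try:
                dp = np.linalg.solve(A, -g)
            except np.linalg.LinAlgError:
                return p, False
            r_new = _residuals(p + dp, nodes, d)
            obj_new = float(r_new @ r_new)
            if obj_new <= obj:
                p = p + dp
                r = r_new
                lam = max(lam * 0.3, 1e-12)
                accepted = True
                break
            lam *= 10.0
        if not accepted:
            # cannot improve: converged to numerical precision
            return p, True
        if obj - obj_new < tol * max(1.0, obj):
            return p, True
        obj = obj_new
    return p, False


def multilaterate(nodes: np.ndarray, d_hat: np.ndarray):
    """Nonlinear least-squares position from node positions and distances.

    Minimises sum_i (d_i - ||p - n_i||)^2 by Levenberg-Marquardt, started
    at the inverse-distance weighted centroid of the nodes (objective
    tolerance 1e-8, at most 200 iterations).  Returns ``(p_hat, converged,
    collinear)``; solver failure falls over to the brute-force grid search
    with ``converged=False``.
    """
    nodes = np.asarray(nodes, dtype=float)
    d_hat = np.asarray(d_hat, dtype=float)
    if len(nodes) < 3:
        raise ValueError("multilateration needs >= 3 nodes")
    collinear = _is_collinear(nodes)
    x0 = _start_point(nodes, d_hat)
    p, ok = _lm_solve(nodes, d_hat, x0)
    if ok and np.all(np.isfinite(p)):
        return p, True, collinear
    return grid_search_position(nodes, d_hat), False, collinear


@dataclass
class ConsensusDiagnostics:
    """Bookkeeping of one grouped k-means consensus localisation."""

    n_candidates: int
    k_chosen: int
    cluster_sizes: list[int] = field(default_factory=list)
    total_wss: float = float("nan")


def _kmeans_labels(points: np.ndarray, k: int, seed: int):
    from sklearn.cluster import KMeans

    km = KMeans(n_clusters=k, n_init=KMEANS_RESTARTS, random_state=seed)
    labels = km.fit_predict(points)
    return labels, float(km.inertia_)


def grouped_kmeans_localise(
    estimates: pd.DataFrame,
    node_positions: dict[str, np.ndarray],
    max_nodes: int = MAX_KMEANS_NODES,
    seed: int = 0,
    kmax: int = KMEANS_KMAX,
):
    """Consensus location from all >=3-node subsets of the strongest nodes.

    With 7 usable nodes the subset count is C(7,3)+...+C(7,7) = 99.  The
    candidate positions are clustered in the plane; k is chosen by an elbow
    rule (smallest k whose incremental within-cluster sum-of-squares gain
    over k-1 drops below 10% of the k=1 WSS) and the centroid of the
    largest cluster is returned (size ties -> tighter cluster).
    """
    if len(estimates) < 3:
        raise ValueError("need >= 3 distance estimates")
    top = estimates.sort_values(
        ["rss_used", "node_id"], ascending=[False, True], kind="stable"
    ).head(max_nodes)
    ids = top["node_id"].tolist()
    dmap = dict(zip(top["node_id"], top["d_hat"]))
    candidates = []
    for size in range(3, len(ids) + 1):
        for subset in combinations(ids, size):
            nodes = np.array([node_positions[n] for n in subset])
            d = np.array([dmap[n] for n in subset])
            p, ok, _ = multilaterate(nodes, d)
            if np.all(np.isfinite(p)):
                candidates.append(p)
    if not candidates:
        return None, ConsensusDiagnostics(0, 0)
    pts = np.asarray(candidates)
    n_cand = len(pts)
    wss1 = float(((pts - pts.mean(axis=0)) ** 2).sum())
    # candidates agreeing to ~1 cm are one consensus cluster
    n_distinct = len(np.unique(np.round(pts, 4), axis=0))
    kmax_eff = min(kmax, n_cand - 1, n_distinct)
    if kmax_eff < 2 or wss1 < 1e-4 * n_cand:
        centroid = pts.mean(axis=0)
        return centroid, ConsensusDiagnostics(n_cand, 1, [n_cand], wss1)
    wss = {1: wss1}
    labels_by_k = {1: np.zeros(n_cand, dtype=int)}
    for k in range(2, kmax_eff + 1):
        labels_by_k[k], wss[k] = _kmeans_labels(pts, k, seed)
    k_chosen = 1
    for k in range(2, kmax_eff + 1):
        if wss[k_chosen] - wss[k] >= ELBOW_FRACTION * wss1:
            k_chosen = k
        else:
            break
    labels = labels_by_k[k_chosen]
    sizes = np.bincount(labels, minlength=k_chosen)
    best_label, best_key = None, None
    for lab in range(k_chosen):
        members = pts[labels == lab]
        if len(members) == 0:
            continue
        within = float(((members - members.mean(axis=0)) ** 2).sum())
        key = (-sizes[lab], within)
        if best_key is None or key < best_key:
            best_key, best_label = key, lab
    members = pts[labels == best_label]
    diag = ConsensusDiagnostics(n_cand, int(k_chosen), sizes.tolist(), float(wss[k_chosen]))
    return members.mean(axis=0), diag


ESTIMATE_COLUMNS = [
    "trial_id",
    "reloc_idx",
    "method",
    "x_hat",
    "y_hat",
    "n_nodes_used",
    "converged",
    "rss_rank_ties_broken",
]


def localise_relocations(
    observations: pd.DataFrame,
    node_positions: dict[str, np.ndarray],
    model_set: DecayModelSet,
    scope: str,
    rss_col: str,
    method: str,
    tag_id: str | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Localise every relocation of one trial's observation table.

    ``observations`` is the signal_prep output (one row per relocation ×
    node) with the RSS column named by ``rss_col``.  Relocations with fewer
    than three usable nodes are skipped (no output row).
    """
    rows = []
    for (trial_id, reloc_idx), grp in observations.groupby(
        ["trial_id", "reloc_idx"], sort=True
    ):
        est = build_distance_estimates(
            grp["node_id"].to_numpy(), grp[rss_col].to_numpy(), model_set, scope, tag_id
        )
        if len(est) < 3:
            continue
        n_ties = 0
        if method == "grouped_kmeans":
            reloc_seed = (seed * 100003 + int(reloc_idx)) % (2**31 - 1)
            p, diag = grouped_kmeans_localise(est, node_positions, seed=reloc_seed)
            if p is None:
                continue
            n_used = min(len(est), MAX_KMEANS_NODES)
            converged = True
        else:
            rule = {"all_nodes": "all", "strongest3": "strongest3", "nearest3": "nearest3"}[
                method
            ]
            subset, n_ties = select_nodes(est, rule)
            nodes = np.array([node_positions[n] for n in subset["node_id"]])
            p, converged, _ = multilaterate(nodes, subset["d_hat"].to_numpy())
            n_used = len(subset)
        rows.append(
            (trial_id, int(reloc_idx), method, float(p[0]), float(p[1]), n_used, converged, n_ties)
        )
    return pd.DataFrame(rows, columns=ESTIMATE_COLUMNS)
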