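"""RSS–distance exponential decay calibration.

The received signal strength of a tag at distance d from a node is modelled
as

    RSS(d) = a * exp(-S * d) + K

with intercept-above-asymptote a (dB), decay factor S (1/m) and horizontal
asymptote K (dB).  Reads at or below K carry no distance information.

Fitting follows a two-step scheme: a nonlinear least-squares fit to the
pooled calibration data (initialised by a self-starting asymptotic-
regression heuristic), then per-node or per-tag refits started at the
general estimates; groups that are too small or fail to converge fall back
to the general model.  Parameter uncertainty comes from a case-resampling
bootstrap with percentile intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "DecayModel",
    "DecayFitError",
    "selfstart_decay",
    "fit_decay",
    "refit_by_group",
    "bootstrap_decay",
    "DecayModelSet",
]

MIN_GROUP_POINTS = 10
SELFSTART_EPS = 0.5  # dB offset guarding log(0) in the log-linearised start


class DecayFitError(RuntimeError):
    """Nonlinear fit failed; carries the self-start estimates."""

    def __init__(self, msg, init=None):
        super().__init__(msg)
        self.init = init


def _decay(d, a, S, K):
    return a * np.exp(-S * d) + K


@dataclass(frozen=True)
class DecayModel:
    """Fitted RSS–distance curve at one scope (general, one node, one tag)."""

    a: float
    S: float
    K: float
    scope: str = "general"
    n_points: int = 0
    resid_se: float = float("nan")
    fallback: bool = False

    def predict(self, distance):
        """Model RSS (dB) at distance (m); a + K exactly at d = 0."""
        return _decay(np.asarray(distance, dtype=float), self.a, self.S, self.K)

    def invert(self, rss):
        """Distance estimate for an RSS read, NaN when rss <= K.

        Inversion of the decay law: d = -ln((rss - K)/a)/S.  Reads above
        a + K would give negative distances and are clamped to 0 m (tag
        effectively at the node).
        """
        rss = np.asarray(rss, dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = (rss - self.K) / self.a
            d = np.where(ratio > 0, -np.log(np.maximum(ratio, 1e-300)) / self.S, np.nan)
        return np.where(np.isnan(d), np.nan, np.maximum(d, 0.0))


def selfstart_decay(rss, distance, eps: float = SELFSTART_EPS):
    """Self-start values (a0, S0, K0) for the asymptotic regression.

    K0 is the weakest observed RSS; a0 the dynamic range; S0 comes from a
    log-linearised regression of log(rss - K0 + eps) on distance.
    """
    rss = np.asarray(rss, dtype=float)
    distance = np.asarray(distance, dtype=float)
    K0 = float(rss.min())
    a0 = max(float(rss.max()) - K0, eps)
    z = np.log(rss - K0 + eps)
    slope = np.polyfit(distance, z, 1)[0]
    S0 = max(-float(slope), 1e-6)
    return a0, S0, K0


def fit_decay(
    rss,
    distance,
    scope: str = "general",
    p0: tuple[float, float, float] | None = None,
) -> DecayModel:
    """Unweighted nonlinear least squares fit of RSS(d) = a·exp(-S·d) + K."""
    rss = np.asarray(rss, dtype=float)
    distance = np.asarray(distance, dtype=float)
    if len(rss) < MIN_GROUP_POINTS:
        raise DecayFitError(f"need >= {MIN_GROUP_POINTS} calibration points, got {len(rss)}")
    if np.unique(distance).size < 2:
        raise DecayFitError("calibration points span fewer than 2 distinct distances")
    init = p0 if p0 is not None else selfstart_decay(rss, distance)
    try:
        popt, _ = curve_fit(_decay, distance, rss, p0=init, maxfev=10000)
    except (RuntimeError, ValueError) as exc:
        raise DecayFitError(f"decay fit did not converge: {exc}", init=init) from exc
    a, S, K = (float(v) for v in popt)
    if not np.all(np.isfinite(popt)):
        raise DecayFitError("decay fit produced non-finite parameters", init=init)
    if a <= 0 or S <= 0:
        # physically senseless (RSS must decrease with distance)
        raise DecayFitError(
            f"decay fit not physical (a={a:.3g}, S={S:.3g})", init=init
        )
    resid = rss - _decay(distance, a, S, K)
    dof = max(len(rss) - 3, 1)
    return DecayModel(a, S, K, scope, len(rss), float(np.sqrt(resid @ resid / dof)))


def refit_by_group(
    points: pd.DataFrame,
    group_col: str,
    general: DecayModel,
    min_points: int = MIN_GROUP_POINTS,
) -> dict[str, DecayModel]:
    """Per-group refits initialised at the general estimates.

    ``points`` needs columns ``rss``, ``distance`` and ``group_col``.
    Groups with fewer than ``min_points`` rows, or whose fit fails, get the
    general model with ``fallback=True``.
    """
    scope_kind = "node" if "node" in group_col else "tag"
    out: dict[str, DecayModel] = {}
    for gid, grp in points.groupby(group_col, sort=True):
        gid = str(gid)
        scope = f"{scope_kind}:{gid}"
        if len(grp) < min_points:
            out[gid] = DecayModel(
                general.a, general.S, general.K, scope, len(grp),
                general.resid_se, fallback=True,
            )
            continue
        try:
            m = fit_decay(
                grp["rss"].to_numpy(),
                grp["distance"].to_numpy(),
                scope=scope,
                p0=(general.a, general.S, general.K),
            )
            out[gid] = m
        except DecayFitError:
            out[gid] = DecayModel(
                general.a, general.S, general.K, scope, len(grp),
                general.resid_se, fallback=True,
            )
    return out


@dataclass
class BootstrapResult:
    """Case-resampling bootstrap of the decay parameters."""

    replicates: pd.DataFrame  # columns a, S, K, one row per converged replicate
    se: pd.Series
    ci_lower: pd.Series
    ci_upper: pd.Series
    n_boot: int
    n_failed: int
    warning: str | None = None

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"se": self.se, "ci_2.5%": self.ci_lower, "ci_97.5%": self.ci_upper}
        )


def bootstrap_decay(
    rss,
    distance,
    n_boot: int = 999,
    seed: int | None = None,
    level: float = 0.95,
) -> BootstrapResult:
    """Bootstrap SEs and percentile CIs by resampling calibration points."""
    rss = np.asarray(rss, dtype=float)
    distance = np.asarray(distance, dtype=float)
    rng = np.random.default_rng(seed)
    base = fit_decay(rss, distance)
    reps = []
    n_failed = 0
    n = len(rss)
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            m = fit_decay(rss[idx], distance[idx], p0=(base.a, base.S, base.K))
            reps.append((m.a, m.S, m.K))
        except DecayFitError:
            n_failed += 1
    reps = pd.DataFrame(reps, columns=["a", "S", "K"])
    warning = None
    if n_boot >= 1 and n_failed > 0.2 * n_boot:
        warning = f"{n_failed}/{n_boot} bootstrap replicates failed to converge"
    if len(reps) < 2:
        se = pd.Series(np.nan, index=["a", "S", "K"])
        lo = hi = se
        warning = warning or "too few replicates for an SE (n_boot < 2)"
    else:
        se = reps.std(ddof=1)
        alpha = (1.0 - level) / 2.0
        lo = reps.quantile(alpha)
        hi = reps.quantile(1.0 - alpha)
    return BootstrapResult(reps, se, lo, hi, n_boot, n_failed, warning)


@dataclass
class DecayModelSet:
    """General + per-group decay models for one calibration cell.

    One cell = one (rss_type × signal_smoother) combination; the set serves
    all three model scopes downstream.
    """

    general: DecayModel
    by_node: dict[str, DecayModel] = field(default_factory=dict)
    by_tag: dict[str, DecayModel] = field(default_factory=dict)

    @classmethod
    def fit(cls, points: pd.DataFrame, min_points: int = MIN_GROUP_POINTS) -> "DecayModelSet":
        """Two-step fit from a calibration table (rss, distance, node_id[, tag_id])."""
        general = fit_decay(points["rss"].to_numpy(), points["distance"].to_numpy())
        by_node = refit_by_group(points, "node_id", general, min_points)
        by_tag = (
            refit_by_group(points, "tag_id", general, min_points)
            if "tag_id" in points.columns
            else {}
        )
        return cls(general, by_node, by_tag)

    def model_for(self, scope: str, node_id: str | None = None, tag_id: str | None = None) -> DecayModel:
        if scope == "general":
            return self.general
        if scope == "node":
            return self.by_node.get(str(node_id), self.general)
        if scope == "tag":
            return self.by_tag.get(str(tag_id), self.general)
        raise ValueError(f"unknown model scope {scope!r}")

    def to_frame(self) -> pd.DataFrame:
        rows = [self.general] + list(self.by_node.values()) + list(self.by_tag.values())
        return pd.DataFrame(
            {
                "scope": [m.scope for m in rows],
                "a": [m.a for m in rows],
                "S": [m.S for m in rows],
                "K": [m.K for m in rows],
                "n_points": [m.n_points for m in rows],
                "resid_se": [m.resid_se for m in rows],
                "fallback": [m.fallback for m in rows],
            }
        )
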