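"""End-to-end workflow execution over the five-axis decision factorial.

A :class:`WorkflowRunner` holds one study's inputs (node grid, ground-truth
tracks, raw detections) and lazily computes each stage, caching everything
the 216 workflows share: matched observations are computed once, each
signal-smoothing variant once, each (rss_type × smoother) calibration cell
once, and each (rss_type × smoother × scope × method) localisation once —
track smoothing and error evaluation are cheap and run per workflow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .decay import DecayModelSet
from .io import NodeGrid, TagSpec, WorkflowConfig
from .localisation import localise_relocations
from .signal_prep import DEFAULT_MAX_GAP, DEFAULT_OUTLIER_DB, prepare_observations
from .smoothing import smooth_series
from .track_post import smooth_track

__all__ = ["WorkflowRunner"]

ERROR_COLUMNS = [
    "trial_id",
    "reloc_idx",
    "rss_type",
    "signal_smoother",
    "scope",
    "method",
    "track_smoother",
    "error_m",
]


@dataclass
class _TrialData:
    track: pd.DataFrame
    tag: TagSpec
    observations: pd.DataFrame


class WorkflowRunner:
    """Execute localisation workflows for one set of calibration trials."""

    def __init__(
        self,
        nodes: NodeGrid,
        tracks: dict[str, pd.DataFrame],
        detections: pd.DataFrame,
        tags: dict[str, TagSpec],
        max_gap: float = DEFAULT_MAX_GAP,
        outlier_db: float = DEFAULT_OUTLIER_DB,
        seed: int = 0,
    ):
        self.nodes = nodes
        self.node_positions = {
            n: np.array([x, y])
            for n, x, y in nodes.df[["node_id", "x", "y"]].itertuples(index=False)
        }
        self.seed = seed
        self.trials: dict[str, _TrialData] = {}
        for trial_id, track in tracks.items():
            tag = tags[trial_id]
            obs = prepare_observations(
                detections, track, tag_id=tag.tag_id, max_gap=max_gap, outlier_threshold=outlier_db
            )
            self.trials[trial_id] = _TrialData(track, tag, obs)
        self._smoothed: dict[str, dict[str, pd.DataFrame]] = {}
        self._model_sets: dict[tuple[str, str], DecayModelSet] = {}
        self._estimates: dict[tuple[str, str, str, str], dict[str, pd.DataFrame]] = {}

    @classmethod
    def from_scene(cls, scene, **kwargs) -> "WorkflowRunner":
        tags = {spec.trial_id: spec.tag for spec in scene.trials}
        return cls(scene.nodes, scene.tracks, scene.detections, tags, **kwargs)

    # -- signal smoothing ------------------------------------------------
    def observations(self, smoother: str) -> dict[str, pd.DataFrame]:
        """Per-trial observation tables with both RSS columns smoothed.

        Smoothing runs per (trial × node) series over relocation time,
        independently for the max and avg summaries; the kalman grid step
        is the tag's nominal emission interval.
        """
        if smoother in self._smoothed:
            return self._smoothed[smoother]
        out = {}
        for trial_id, td in self.trials.items():
            obs = td.observations.copy()
            if smoother != "none" and len(obs):
                t_by_idx = td.track["t"].to_numpy()
                for node_id, grp in obs.groupby("node_id", sort=False):
                    times = t_by_idx[grp["reloc_idx"].to_numpy()]
                    for col in ("rss_max", "rss_avg"):
                        vals, _ = smooth_series(
                            times,
                            grp[col].to_numpy(),
                            smoother,
                            step=td.tag.nominal_interval,
                            collision="max",
                        )
                        obs.loc[grp.index, col] = vals
            out[trial_id] = obs
        self._smoothed[smoother] = out
        return out

    # -- calibration -----------------------------------------------------
    def calibration_points(self, rss_type: str, smoother: str) -> pd.DataFrame:
        """Long (rss, true distance) table across trials, nodes and tags."""
        rss_col = f"rss_{rss_type}"
        parts = []
        for trial_id, obs in self.observations(smoother).items():
            if obs.empty:
                continue
            td = self.trials[trial_id]
            tx = td.track["x"].to_numpy()
            ty = td.track["y"].to_numpy()
            idx = obs["reloc_idx"].to_numpy()
            nx = np.array([self.node_positions[n][0] for n in obs["node_id"]])
            ny = np.array([self.node_positions[n][1] for n in obs["node_id"]])
            parts.append(
                pd.DataFrame(
                    {
                        "rss": obs[rss_col].to_numpy(),
                        "distance": np.hypot(tx[idx] - nx, ty[idx] - ny),
                        "node_id": obs["node_id"].to_numpy(),
                        "tag_id": td.tag.tag_id,
                        "trial_id": trial_id,
                    }
                )
            )
        if not parts:
            return pd.DataFrame(columns=["rss", "distance", "node_id", "tag_id", "trial_id"])
        return pd.concat(parts, ignore_index=True)

    def model_set(self, rss_type: str, smoother: str) -> DecayModelSet:
        key = (rss_type, smoother)
        if key not in self._model_sets:
            self._model_sets[key] = DecayModelSet.fit(self.calibration_points(*key))
        return self._model_sets[key]

    # -- localisation ----------------------------------------------------
    def estimates(self, rss_type: str, smoother: str, scope: str, method: str) -> dict[str, pd.DataFrame]:
        key = (rss_type, smoother, scope, method)
        if key in self._estimates:
            return self._estimates[key]
        model_set = self.model_set(rss_type, smoother)
        rss_col = f"rss_{rss_type}"
        out = {}
        for trial_id, obs in self.observations(smoother).items():
            td = self.trials[trial_id]
            est = localise_relocations(
                obs,
                self.node_positions,
                model_set,
                scope,
                rss_col,
                method,
                tag_id=td.tag.tag_id,
                seed=self.seed,
            )
            if len(est):
                est = est.assign(t=td.track["t"].to_numpy()[est["reloc_idx"].to_numpy()])
            out[trial_id] = est
        self._estimates[key] = out
        return out

    # -- evaluation ------------------------------------------------------
    def errors(self, wf: WorkflowConfig) -> pd.DataFrame:
        """Localisation error per relocation for one workflow."""
        ests = self.estimates(wf.rss_type, wf.signal_smoother, wf.model_scope, wf.loc_method)
        rows = []
        for trial_id, est in ests.items():
            if est.empty:
                continue
            td = self.trials[trial_id]
            track_est = est.rename(columns={"x_hat": "x", "y_hat": "y"})[
                ["reloc_idx", "t", "x", "y"]
            ]
            track_est = smooth_track(track_est, wf.track_smoother, step=td.tag.nominal_interval)
            idx = track_est["reloc_idx"].to_numpy()
            tx = td.track["x"].to_numpy()[idx]
            ty = td.track["y"].to_numpy()[idx]
            err = np.hypot(track_est["x"].to_numpy() - tx, track_est["y"].to_numpy() - ty)
            rows.append(
                pd.DataFrame(
                    {
                        "trial_id": trial_id,
                        "reloc_idx": idx,
                        "rss_type": wf.rss_type,
                        "signal_smoother": wf.signal_smoother,
                        "scope": wf.model_scope,
                        "method": wf.loc_method,
                        "track_smoother": wf.track_smoother,
                        "error_m": err,
                    }
                )
            )
        if not rows:
            return pd.DataFrame(columns=ERROR_COLUMNS)
        return pd.concat(rows, ignore_index=True)

    def error_table(self, workflows: list[WorkflowConfig] | None = None) -> pd.DataFrame:
        """Long repeated-measures error table over the workflow factorial.

        The output is mixed-model ready: one row per (relocation ×
        workflow) that produced an estimate, relocations nested in trials.
        """
        workflows = workflows if workflows is not None else WorkflowConfig.factorial()
        parts = [self.errors(wf) for wf in workflows]
        parts = [p for p in parts if len(p)]
        if not parts:
            return pd.DataFrame(columns=ERROR_COLUMNS)
        return pd.concat(parts, ignore_index=True)
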