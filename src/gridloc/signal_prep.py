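"""Match raw detections to ground-truth relocations and aggregate RSS.

Each detection is assigned to the relocation with the nearest timestamp,
provided the gap is at most 10 s (reception delays and clock mismatch);
ties go to the earlier relocation.  Per (relocation × node) the maximum and
the outlier-trimmed average RSS are computed: the max guards against signal
bouncing/multipathing dropouts, the average is re-computed after a single
pass removing reads 4.33 dB or more away from the plain mean.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["match_detections", "aggregate_rss", "prepare_observations"]

DEFAULT_MAX_GAP = 10.0
DEFAULT_OUTLIER_DB = 4.33

OBSERVATION_COLUMNS = [
    "trial_id",
    "reloc_idx",
    "node_id",
    "rss_max",
    "rss_avg",
    "n_reads",
    "n_outliers_removed",
]


def match_detections(
    det_times: np.ndarray,
    reloc_times: np.ndarray,
    max_gap: float = DEFAULT_MAX_GAP,
) -> np.ndarray:
    """Index of the nearest relocation per detection, or -1 if unmatched.

    ``reloc_times`` must be strictly increasing.  A detection exactly
    equidistant from two relocations is assigned to the earlier one; gaps
    strictly greater than ``max_gap`` seconds are unmatched.
    """
    det_times = np.asarray(det_times, dtype=float)
    reloc_times = np.asarray(reloc_times, dtype=float)
    if len(reloc_times) == 0:
        raise ValueError("relocation track is empty")
    if np.any(np.diff(reloc_times) <= 0):
        raise ValueError("relocation timestamps must be strictly increasing")
    if len(det_times) == 0:
        return np.empty(0, dtype=int)
    right = np.searchsorted(reloc_times, det_times, side="left")
    left = np.clip(right - 1, 0, len(reloc_times) - 1)
    right = np.clip(right, 0, len(reloc_times) - 1)
    d_left = np.abs(det_times - reloc_times[left])
    d_right = np.abs(det_times - reloc_times[right])
    # tie (d_left == d_right) resolves to the earlier fix
    idx = np.where(d_right < d_left, right, left)
    gap = np.minimum(d_left, d_right)
    idx[gap > max_gap] = -1
    return idx


def aggregate_rss(reads: np.ndarray, outlier_threshold: float = DEFAULT_OUTLIER_DB):
    """Summarise the RSS reads of one (relocation × node) cell.

    Returns ``(rss_max, rss_avg, n_reads, n_outliers_removed)``.  The max is
    over all reads; the average is recomputed once after removing reads
    ``outlier_threshold`` dB or more away from the plain mean.  If the rule
    would remove every read, the plain mean is kept unchanged.
    """
    reads = np.asarray(reads, dtype=float)
    if reads.size == 0:
        raise ValueError("aggregate_rss needs at least one read")
    rss_max = float(reads.max())
    mean_all = float(reads.mean())
    keep = np.abs(reads - mean_all) < outlier_threshold
    if not keep.any():
        return rss_max, mean_all, int(reads.size), 0
    n_out = int((~keep).sum())
    return rss_max, float(reads[keep].mean()), int(reads.size), n_out


def prepare_observations(
    detections: pd.DataFrame,
    track: pd.DataFrame,
    tag_id: str | None = None,
    max_gap: float = DEFAULT_MAX_GAP,
    outlier_threshold: float = DEFAULT_OUTLIER_DB,
) -> pd.DataFrame:
    """Full matching + aggregation for one trial.

    ``detections`` is a canonical detection table (optionally pre-filtered;
    pass ``tag_id`` to filter to the tested tag here), ``track`` a
    relocation table with columns ``trial_id, t``.  Returns the long
    observation table with one row per (relocation × detecting node).
    """
    det = detections
    if tag_id is not None:
        det = det.loc[det["tag_id"] == tag_id]
    trial_id = track["trial_id"].iloc[0]
    if det.empty:
        return pd.DataFrame(columns=OBSERVATION_COLUMNS)
    det_t = det["timestamp_utc"].astype("int64").to_numpy() / 1e9
    idx = match_detections(det_t, track["t"].to_numpy(), max_gap=max_gap)
    matched = pd.DataFrame(
        {
            "reloc_idx": idx,
            "node_id": det["node_id"].to_numpy(),
            "rss": det["rss_db"].to_numpy(),
        }
    ).loc[idx >= 0]
    if matched.empty:
        return pd.DataFrame(columns=OBSERVATION_COLUMNS)
    rows = []
    for (reloc_idx, node_id), grp in matched.groupby(
        ["reloc_idx", "node_id"], sort=True
    ):
        rss_max, rss_avg, n_reads, n_out = aggregate_rss(
            grp["rss"].to_numpy(), outlier_threshold
        )
        rows.append((trial_id, int(reloc_idx), node_id, rss_max, rss_avg, n_reads, n_out))
    return pd.DataFrame(rows, columns=OBSERVATION_COLUMNS)
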