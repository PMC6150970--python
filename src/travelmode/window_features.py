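"""Moving-window smoothing of epoch features and the travelled-distance
features, producing the final classifier feature matrix.

Travel signals fluctuate epoch to epoch (traffic lights, road crossings,
patchy GPS under cover), so each epoch-level accelerometer feature and the
GPS speed is smoothed over a centred moving window (default 4 minutes,
i.e. +/- 2 minutes around the epoch) with four statistics: mean, SD
(population), 10th and 90th percentile. sumSNR and the rail distance get a
window mean. Two further features capture displacement: the summed
fix-to-fix distance over the previous and over the next minute.

Windows never cross a recording gap: contiguity breaks whenever the next
epoch is more than one epoch length away, so smoothing cannot blur across
device-off periods. At segment edges the window shrinks to the epochs
available; a fully isolated epoch is its own window (SD 0). Epochs without a
GPS match contribute only accelerometer features to their neighbours'
windows (NaN-skipping statistics).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .epoch_features import ACCEL_FEATURES, EPOCH_SECONDS
from .geometry import haversine_m_vec
from .io_formats import MODES

log = logging.getLogger(__name__)

WINDOW_STATS = ("wmean", "wsd", "wp10", "wp90")
#: Epoch-level columns smoothed with all four window statistics.
SMOOTHED_COLUMNS = ACCEL_FEATURES + ["speed_kmh"]
#: GPS-quality columns smoothed with a window mean only.
MEAN_ONLY_COLUMNS = ["sum_snr", "rail_dist_m"]


def feature_matrix_columns() -> list:
    """The fixed, documented column order of the classifier matrix."""
    cols = list(ACCEL_FEATURES) + ["speed_kmh", "sum_snr", "rail_dist_m"]
    for stat in WINDOW_STATS:
        cols += [f"{stat}_{c}" for c in SMOOTHED_COLUMNS]
    cols += [f"wmean_{c}" for c in MEAN_ONLY_COLUMNS]
    cols += ["dist_prev_min_m", "dist_next_min_m"]
    return cols


def contiguous_segments(epoch_starts: pd.Series):
    """Split sorted epoch starts into runs of consecutive epochs; a gap
    larger than one epoch length starts a new run. Returns integer segment
    ids aligned with the input."""
    ts = pd.to_datetime(epoch_starts).to_numpy()
    if len(ts) == 0:
        return np.array([], dtype=int)
    gaps = np.diff(ts) > np.timedelta64(EPOCH_SECONDS, "s")
    return np.concatenate([[0], np.cumsum(gaps)])


def moving_window_stats(epochs: pd.DataFrame,
                        window_minutes: float = 4.0) -> pd.DataFrame:
    """Add centred moving-window statistics to a sorted single-participant
    epoch table.

    The window around an epoch holds every epoch of the same contiguous
    segment whose start lies within +/- window/2 of its start. Returns a
    copy with the ``wmean_* / wsd_* / wp10_* / wp90_*`` columns appended.
    """
    if window_minutes <= 0:
        raise ValueError("window_minutes must be positive")
    out = epochs.sort_values("epoch_start").reset_index(drop=True).copy()
    if out.empty:
        return out
    k = int(window_minutes * 60 / 2 // EPOCH_SECONDS)  # epochs per side
    size = 2 * k + 1
    seg = contiguous_segments(out["epoch_start"])
    new_cols = {}
    for col in SMOOTHED_COLUMNS + MEAN_ONLY_COLUMNS:
        grouped = out.groupby(seg, sort=False)[col]
        roll = lambda s: s.rolling(size, center=True, min_periods=1)
        new_cols[f"wmean_{col}"] = grouped.transform(lambda s: roll(s).mean())
        if col in SMOOTHED_COLUMNS:
            new_cols[f"wsd_{col}"] = grouped.transform(
                lambda s: roll(s).std(ddof=0))
            new_cols[f"wp10_{col}"] = grouped.transform(
                lambda s: roll(s).quantile(0.10))
            new_cols[f"wp90_{col}"] = grouped.transform(
                lambda s: roll(s).quantile(0.90))
    return pd.concat([out, pd.DataFrame(new_cols, index=out.index)], axis=1)


def distance_travelled(fixes: pd.DataFrame, t, direction: str,
                       span_s: float = 60.0) -> float:
    """Summed fix-to-fix great-circle distance (m) over the minute before
    (``direction="previous"``: fixes in [t - span, t]) or after
    (``"next"``: fixes in [t, t + span]) instant ``t``. Fewer than two fixes
    in the span give 0."""
    if direction not in ("previous", "next"):
        raise ValueError("direction must be 'previous' or 'next'")
    if len(fixes) == 0:
        return 0.0
    t = pd.Timestamp(t)
    lo = t - pd.Timedelta(seconds=span_s) if direction == "previous" else t
    hi = t if direction == "previous" else t + pd.Timedelta(seconds=span_s)
    sel = fixes[(fixes["timestamp"] >= lo) & (fixes["timestamp"] <= hi)]
    if len(sel) < 2:
        return 0.0
    lat = sel["lat"].to_numpy()
    lon = sel["lon"].to_numpy()
    return float(haversine_m_vec(lat[:-1], lon[:-1], lat[1:], lon[1:]).sum())


def add_distance_features(rows: pd.DataFrame, fixes: pd.DataFrame) -> pd.DataFrame:
    """Append ``dist_prev_min_m`` and ``dist_next_min_m`` (per epoch start)."""
    out = rows.copy()
    out["dist_prev_min_m"] = [
        distance_travelled(fixes, t, "previous") for t in out["epoch_start"]]
    out["dist_next_min_m"] = [
        distance_travelled(fixes, t, "next") for t in out["epoch_start"]]
    return out


def build_feature_rows(epochs: pd.DataFrame, fixes: pd.DataFrame,
                       window_minutes: float = 4.0) -> pd.DataFrame:
    """Full feature rows for one participant: window statistics plus the
    travelled-distance features."""
    return add_distance_features(
        moving_window_stats(epochs, window_minutes), fixes)


def assemble_feature_matrix(rows: pd.DataFrame, require_gps: bool = False):
    """Turn feature rows into the classifier inputs.

    Non-wear rows are always excluded; with ``require_gps`` rows lacking a
    GPS match are excluded too, otherwise their GPS-derived cells stay NaN
    (the tree learner handles missing values natively). Returns
    ``(matrix, labels, column_names)`` where ``labels`` is None for
    unlabelled rows; raises if nothing survives filtering.
    """
    cols = feature_matrix_columns()
    missing = [c for c in cols if c not in rows.columns]
    if missing:
        raise ValueError(f"schema error: missing feature columns {missing}")
    keep = ~rows["nonwear"].astype(bool)
    if require_gps:
        keep &= rows["has_gps"].astype(bool)
    kept = rows[keep]
    if kept.empty:
        raise ValueError("no rows left after filtering")
    log.info("assemble_feature_matrix: %d rows in, %d kept (%d excluded)",
             len(rows), len(kept), len(rows) - len(kept))
    matrix = kept[cols].astype(float).reset_index(drop=True)
    labels = None
    if "label" in kept.columns and kept["label"].notna().any():
        labels = kept["label"].reset_index(drop=True)
        bad = set(labels.dropna()) - set(MODES)
        if bad:
            raise ValueError(f"unknown labels {sorted(bad)}")
    return matrix, labels, cols
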