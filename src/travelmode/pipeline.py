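"""End-to-end orchestration: raw streams -> epoch features -> windowed
feature rows, with optional ground-truth label joins.

Every stage logs its input/output row counts so a run can be audited as a
conservation chain (read -> epoched -> wear -> GPS-matched -> windowed).
"""

from __future__ import annotations

import logging

import pandas as pd

from .epoch_features import build_epoch_features
from .io_formats import AccelData, GpsTrack, RailNetwork
from .window_features import build_feature_rows

log = logging.getLogger(__name__)


def participant_feature_rows(accel: AccelData, gps: GpsTrack | None,
                             network: RailNetwork | None, participant_id: str,
                             window_minutes: float = 4.0,
                             truth: pd.DataFrame | None = None) -> pd.DataFrame:
    """Feature rows for one participant; joins true mode labels when a
    truth table (participant_id, epoch_start, label) is supplied."""
    result = build_epoch_features(accel, gps, network, participant_id)
    if result.epochs.empty:
        return result.epochs
    fixes = gps.fixes if gps is not None else pd.DataFrame(
        columns=["timestamp", "lat", "lon"])
    rows = build_feature_rows(result.epochs, fixes, window_minutes)
    if truth is not None:
        lab = truth.loc[truth["participant_id"] == participant_id,
                        ["epoch_start", "label"]]
        rows = rows.merge(lab, on="epoch_start", how="left")
    log.info("features[%s]: %d samples -> %d epochs -> %d feature rows "
             "(%d GPS-matched, %d non-wear)", participant_id,
             result.n_samples, result.n_epochs_total, len(rows),
             int(rows["has_gps"].sum()), int(rows["nonwear"].sum()))
    return rows


def cohort_feature_rows(participants: dict, network: RailNetwork | None,
                        window_minutes: float = 4.0,
                        truth: pd.DataFrame | None = None) -> pd.DataFrame:
    """Concatenated feature rows for a cohort mapping
    participant_id -> (AccelData, GpsTrack)."""
    parts = [participant_feature_rows(accel, gps, network, pid,
                                      window_minutes, truth)
             for pid, (accel, gps) in participants.items()]
    return pd.concat(parts, ignore_index=True)
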