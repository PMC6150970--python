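"""Collapse raw accelerometry to 10-second epoch features, merge with GPS
fixes by timestamp, and flag non-wear time.

Per epoch and axis the summaries are: median absolute deviation from the
median (no consistency scaling), 10th and 90th percentiles (linear
interpolation, "type 7"), moment-based skewness (g1 = m3 / m2^1.5), excess
kurtosis (g2 = m4 / m2^2 - 3) and the FFT mean strength — the mean one-sided
magnitude spectrum excluding the DC bin, normalised by the sequence length.
Excluding DC keeps gravity from dominating the spectral feature; skewness and
kurtosis of a zero-variance block are 0 by convention.

Non-wear time follows the standard raw-accelerometry rule: any 60-minute
window (slid in 15-minute steps) whose per-axis sample standard deviation is
below 13 mg on at least two axes is non-wear; flagged intervals are the union
of qualifying windows and an epoch wholly inside them is marked ``nonwear``.

The epoch grid is anchored at UTC 10-second boundaries (floor). GPS fixes are
matched to the epoch whose window [start, start + 10 s) contains their
timestamp; with several candidates the first is used (devices here log every
10 s, so collisions are rare).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import distances_to_network_m, haversine_m
from .io_formats import AccelData, GpsTrack, RailNetwork

log = logging.getLogger(__name__)

EPOCH_SECONDS = 10
NONWEAR_WINDOW_MIN = 60
NONWEAR_STEP_MIN = 15
NONWEAR_SD_G = 0.013  # 13 mg

AXES = ("x", "y", "z")
AXIS_STATS = ("mad", "p10", "p90", "skew", "kurt", "fftmean")
#: Per-axis accelerometer feature names in construction order (18 columns).
ACCEL_FEATURES = [f"{s}_{a}" for a in AXES for s in AXIS_STATS]


def mad_from_median(values) -> float:
    """median(|v - median(v)|), unscaled."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("mad_from_median: empty input")
    return float(np.median(np.abs(v - np.median(v))))


def percentile(values, q) -> float:
    """Linear-interpolation quantile (numpy default, "type 7")."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("percentile: empty input")
    return float(np.percentile(v, q))


def skewness(values) -> float:
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("skewness: need >= 3 values")
    if np.ptp(v) == 0.0:
        return 0.0
    return float(stats.skew(v, bias=True))


def kurtosis(values) -> float:
    """Excess kurtosis; 0 for a zero-variance sequence."""
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("kurtosis: need >= 3 values")
    if np.ptp(v) == 0.0:
        return 0.0
    return float(stats.kurtosis(v, fisher=True, bias=True))


def fft_mean_strength(values, rate_hz: float | None = None) -> float:
    """Mean one-sided FFT magnitude of the demeaned signal, excluding the DC
    bin, normalised by the sequence length."""
    v = np.asarray(values, dtype=float)
    if v.size < 8:
        raise ValueError("fft_mean_strength: need >= 8 values")
    spec = np.abs(np.fft.rfft(v - v.mean()))
    return float(spec[1:].mean() / v.size)


def sum_snr(sat_snr) -> float:
    """Sum of per-satellite SNR values; an empty list sums to 0."""
    return float(np.sum(sat_snr)) if len(sat_snr) else 0.0


def resolve_speed(fix, prev_fix=None) -> float:
    """Speed in km/h for a GPS fix: the device-reported speed when present,
    otherwise the haversine distance to the previous fix over the elapsed
    time. No previous fix (or a non-positive time step) resolves to 0."""
    speed = fix.get("device_speed") if isinstance(fix, dict) else fix.device_speed
    if speed is not None and not pd.isna(speed):
        return float(speed)
    if prev_fix is None:
        return 0.0
    get = (lambda f, k: f.get(k)) if isinstance(prev_fix, dict) else getattr
    dt = (get(fix, "timestamp") - get(prev_fix, "timestamp")).total_seconds() \
        if isinstance(fix, dict) else (fix.timestamp - prev_fix.timestamp).total_seconds()
    if dt <= 0:
        warnings.warn("resolve_speed: non-positive time step; speed set to 0")
        return 0.0
    a = (get(prev_fix, "lat"), get(prev_fix, "lon")) if isinstance(prev_fix, dict) \
        else (prev_fix.lat, prev_fix.lon)
    b = (get(fix, "lat"), get(fix, "lon")) if isinstance(fix, dict) \
        else (fix.lat, fix.lon)
    return haversine_m(a, b) / dt * 3.6


def segment_epochs(samples: pd.DataFrame, sample_rate_hz: float = 30.0):
    """Assign samples to 10-s epochs (timestamp floored to the UTC grid).

    Returns a DataFrame with an added ``epoch_start`` column, and a Series
    mapping epoch_start -> complete flag (an epoch is complete when it holds
    at least 50 % of the expected ``rate * 10`` samples).
    """
    if samples.empty:
        return samples.assign(epoch_start=pd.Series(dtype="datetime64[ns, UTC]")), \
            pd.Series(dtype=bool)
    out = samples.copy()
    out["epoch_start"] = out["timestamp"].dt.floor(f"{EPOCH_SECONDS}s")
    counts = out.groupby("epoch_start").size()
    complete = counts >= 0.5 * sample_rate_hz * EPOCH_SECONDS
    return out, complete


def detect_nonwear(samples: pd.DataFrame, sample_rate_hz: float = 30.0,
                   sd_threshold_g: float = NONWEAR_SD_G):
    """Find non-wear intervals in a sorted sample stream.

    60-minute windows advance in 15-minute steps from the first sample's
    timestamp; a window qualifies when the per-axis standard deviation is
    below 13 mg on at least two axes. Returns a list of (start, end)
    pandas-Timestamp intervals (union of qualifying windows, merged).
    """
    if samples.empty:
        return []
    t0 = samples["timestamp"].iloc[0]
    t_end = samples["timestamp"].iloc[-1]
    win = pd.Timedelta(minutes=NONWEAR_WINDOW_MIN)
    step = pd.Timedelta(minutes=NONWEAR_STEP_MIN)
    ts = samples["timestamp"].astype("int64").to_numpy()  # ns since epoch
    axes = samples[["ax", "ay", "az"]].to_numpy()
    flagged = []
    start = t0
    while start + win <= t_end + pd.Timedelta(seconds=1.0 / sample_rate_hz):
        i = np.searchsorted(ts, start.value)
        j = np.searchsorted(ts, (start + win).value)
        if j - i >= 2:
            sd = axes[i:j].std(axis=0, ddof=1)
            if int((sd < sd_threshold_g).sum()) >= 2:
                flagged.append((start, start + win))
        start = start + step
    # merge overlapping / adjacent windows
    merged = []
    for s, e in flagged:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _axis_features(cube: np.ndarray) -> dict:
    """Vectorised per-axis summaries for a (n_epochs, n_samples, 3) block;
    numerically identical to the scalar feature functions."""
    out = {}
    med = np.median(cube, axis=1)
    m = cube.mean(axis=1)
    d = cube - m[:, None, :]
    m2 = (d ** 2).mean(axis=1)
    m3 = (d ** 3).mean(axis=1)
    m4 = (d ** 4).mean(axis=1)
    safe = np.where(m2 > 0, m2, 1.0)
    skew = np.where(m2 > 0, m3 / safe ** 1.5, 0.0)
    kurt = np.where(m2 > 0, m4 / safe ** 2 - 3.0, 0.0)
    spec = np.abs(np.fft.rfft(d, axis=1))
    fftmean = spec[:, 1:, :].mean(axis=1) / cube.shape[1]
    p10 = np.percentile(cube, 10, axis=1)
    p90 = np.percentile(cube, 90, axis=1)
    mad = np.median(np.abs(cube - med[:, None, :]), axis=1)
    for a, axis in enumerate(AXES):
        out[f"mad_{axis}"] = mad[:, a]
        out[f"p10_{axis}"] = p10[:, a]
        out[f"p90_{axis}"] = p90[:, a]
        out[f"skew_{axis}"] = skew[:, a]
        out[f"kurt_{axis}"] = kurt[:, a]
        out[f"fftmean_{axis}"] = fftmean[:, a]
    return out


def _epoch_in_intervals(epoch_start, intervals) -> bool:
    e = epoch_start + pd.Timedelta(seconds=EPOCH_SECONDS)
    return any(s <= epoch_start and e <= t for s, t in intervals)


@dataclass
class EpochFeatureResult:
    """Epoch feature table plus the stage counts a pipeline log reports."""

    epochs: pd.DataFrame
    n_samples: int
    n_epochs_total: int
    n_epochs_incomplete: int
    n_nonwear: int


def build_epoch_features(accel: AccelData, gps: GpsTrack | None,
                         network: RailNetwork | None,
                         participant_id: str) -> EpochFeatureResult:
    """Build one feature record per complete accelerometer epoch.

    The GPS fix whose timestamp falls inside [epoch_start, epoch_start + 10 s)
    is attached (first such fix); ``has_gps`` is false when none. Speed,
    sumSNR and rail distance are computed only for GPS-matched epochs; the
    non-wear flag comes from :func:`detect_nonwear` over the whole file.
    """
    samples, complete = segment_epochs(accel.samples, accel.sample_rate_hz)
    if samples.empty:
        return EpochFeatureResult(pd.DataFrame(), 0, 0, 0, 0)
    nonwear_iv = detect_nonwear(accel.samples, accel.sample_rate_hz)

    fixes = gps.fixes if gps is not None else pd.DataFrame(
        columns=["timestamp", "lat", "lon", "device_speed", "n_sat_used", "sat_snr"])
    fix_ts = (fixes["timestamp"].astype("int64").to_numpy()
              if len(fixes) else np.array([], dtype=np.int64))

    complete_starts = complete.index[complete]
    counts = samples.groupby("epoch_start").size()
    # epochs of equal length are summarised in one vectorised pass each;
    # results are identical to the per-epoch scalar functions above
    frames = []
    for n_samp, starts in complete_starts.to_series().groupby(
            counts.loc[complete_starts]):
        block = samples[samples["epoch_start"].isin(starts)]
        cube = (block[["ax", "ay", "az"]].to_numpy()
                .reshape(len(starts), int(n_samp), 3))
        frames.append(pd.DataFrame(_axis_features(cube),
                                   index=pd.Index(starts, name="epoch_start")))
    if not frames:
        return EpochFeatureResult(pd.DataFrame(), len(accel.samples),
                                  int(len(complete)), int((~complete).sum()), 0)
    feat = pd.concat(frames).sort_index()

    epochs = feat.reset_index()
    epochs.insert(0, "participant_id", participant_id)
    # first fix inside each epoch window [start, start + 10 s)
    starts_ns = epochs["epoch_start"].astype("int64").to_numpy()
    i_arr = np.searchsorted(fix_ts, starts_ns, side="left")
    j_arr = np.searchsorted(
        fix_ts, starts_ns + EPOCH_SECONDS * 1_000_000_000, side="left")
    has_gps = j_arr > i_arr
    lat = np.full(len(epochs), np.nan)
    lon = np.full(len(epochs), np.nan)
    speed = np.full(len(epochs), np.nan)
    snr = np.full(len(epochs), np.nan)
    for k in np.flatnonzero(has_gps):
        fix = fixes.iloc[i_arr[k]]
        prev = fixes.iloc[i_arr[k] - 1] if i_arr[k] > 0 else None
        lat[k], lon[k] = float(fix["lat"]), float(fix["lon"])
        speed[k] = resolve_speed(fix, prev)
        snr[k] = sum_snr(fix["sat_snr"])
    epochs = epochs.assign(has_gps=has_gps, lat=lat, lon=lon,
                           speed_kmh=speed, sum_snr=snr)
    epochs["nonwear"] = [
        _epoch_in_intervals(t, nonwear_iv) for t in epochs["epoch_start"]]
    if len(epochs) and network is not None:
        mask = epochs["has_gps"].to_numpy()
        rail = np.full(len(epochs), np.nan)
        if mask.any():
            pts = epochs.loc[mask, ["lat", "lon"]].to_numpy()
            rail[mask] = distances_to_network_m(pts, network)
        epochs["rail_dist_m"] = rail
    elif len(epochs):
        epochs["rail_dist_m"] = np.nan
    result = EpochFeatureResult(
        epochs=epochs,
        n_samples=len(accel.samples),
        n_epochs_total=int(len(complete)),
        n_epochs_incomplete=int((~complete).sum()),
        n_nonwear=int(epochs["nonwear"].sum()) if len(epochs) else 0,
    )
    log.info("epochs[%s]: %d samples -> %d epochs (%d incomplete dropped, "
             "%d non-wear)", participant_id, result.n_samples,
             result.n_epochs_total, result.n_epochs_incomplete, result.n_nonwear)
    return result
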