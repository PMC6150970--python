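"""Readers and writers for the three external data streams and the feature table.

Three delimited-text dialects are supported, documented in the README:

* **Raw accelerometer** — comma-separated ``timestamp,ax,ay,az`` with an
  optional free-form header block (ActiLife-style exports prepend device
  metadata). The header ends at the first line whose first field parses as a
  timestamp; a column-name line is skipped by the same rule. Axis values are
  in g.
* **GPS log** — comma-separated Qstarz-style columns ``UTC DATE, UTC TIME,
  LATITUDE, N/S, LONGITUDE, E/W, SPEED, NSAT, SAT INFO``. Hemisphere letters
  carry the coordinate sign; ``SAT INFO`` packs per-satellite records as
  semicolon-joined ``SID-ELE-AZI-SNR`` tokens. Unknown extra columns are
  ignored (real exports carry many).
* **Rail lines** — GeoJSON (RFC 7946) FeatureCollection of LineString /
  MultiLineString geometries in WGS84.

Timestamps are parsed as UTC; devices logging local time can be corrected
with a fixed per-file offset (``utc_offset_hours``) — never mix offsets
within one participant.

Malformed data rows are skipped and counted rather than fatal, mirroring the
robustness needed for field data; skip counts are exposed on the returned
objects and surfaced in logs by the CLI.
"""

from __future__ import annotations

import io
import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: Canonical travel-mode order. Fixed: it defines confusion-matrix layout and
#: argmax tie-breaking throughout the package.
MODES = ("walk", "cycle", "vehicle", "train", "stationary")

ACCEL_COLUMNS = ["timestamp", "ax", "ay", "az"]
GPS_COLUMNS = [
    "UTC DATE", "UTC TIME", "LATITUDE", "N/S", "LONGITUDE", "E/W",
    "SPEED", "NSAT", "SAT INFO",
]

#: Fixed feature-table column order (identity, features, label). GPS-derived
#: columns are empty when has_gps is false.
FEATURE_TABLE_ID_COLUMNS = ["participant_id", "epoch_start"]


@dataclass
class AccelData:
    """Tri-axial accelerometer samples for one file.

    ``samples`` holds columns ``timestamp`` (UTC), ``ax``/``ay``/``az`` (g),
    sorted and strictly increasing. ``sample_rate_hz`` is the declared rate;
    ``n_skipped`` counts rows dropped for parse failures.
    """

    samples: pd.DataFrame
    sample_rate_hz: float
    n_skipped: int = 0

    def __len__(self) -> int:
        return len(self.samples)


@dataclass
class GpsTrack:
    """GPS fixes for one file.

    ``fixes`` holds ``timestamp`` (UTC), ``lat``/``lon`` (decimal degrees,
    WGS84, signed), ``device_speed`` (km/h, NaN when absent), ``n_sat_used``
    and ``sat_snr`` (list of per-satellite SNR values, dB-Hz).
    """

    fixes: pd.DataFrame
    n_skipped: int = 0

    def __len__(self) -> int:
        return len(self.fixes)


@dataclass
class RailNetwork:
    """Rail-line geometry: a list of polylines, each an (n, 2) array of
    (lon, lat) vertices in WGS84."""

    polylines: list = field(default_factory=list)

    def __post_init__(self):
        self.polylines = [np.asarray(p, dtype=float) for p in self.polylines]
        for p in self.polylines:
            if p.ndim != 2 or p.shape[1] != 2 or p.shape[0] < 2:
                raise ValueError("each polyline needs >= 2 (lon, lat) vertices")
            if not np.isfinite(p).all():
                raise ValueError("rail-line coordinates must be finite")

    @property
    def n_vertices(self) -> int:
        return sum(len(p) for p in self.polylines)


def _as_text(source) -> io.TextIOBase:
    if isinstance(source, (str,)):
        return io.StringIO(source) if "\n" in source else open(source, "r")
    if isinstance(source, bytes):
        return io.StringIO(source.decode("utf-8"))
    if isinstance(source, io.TextIOBase):
        return source
    if hasattr(source, "read"):  # byte stream
        return io.TextIOWrapper(source, encoding="utf-8")
    return open(source, "r")


def _try_timestamp(tok: str):
    tok = tok.strip()
    if not tok:
        return None
    ts = pd.to_datetime(tok, utc=True, errors="coerce")
    return None if pd.isna(ts) else ts


def read_raw_accel(source, sample_rate_hz: float = 30.0,
                   utc_offset_hours: float = 0.0) -> AccelData:
    """Read a raw accelerometer export.

    Skips any header block (lines until the first whose leading field parses
    as a timestamp), then reads ``timestamp,ax,ay,az`` rows. Rows that fail
    numeric parse are skipped and counted.

    Raises ``ValueError`` on an empty file ("no samples"), non-monotone
    timestamps ("unsorted input"), or a median sampling interval deviating
    more than 1 % from the declared rate ("rate conflict").
    """
    if sample_rate_hz <= 0:
        raise ValueError("sample_rate_hz must be positive")
    rows, n_skipped, in_data = [], 0, False
    with _as_text(source) as fh:
        for line in fh:
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            parts = line.split(",")
            ts = _try_timestamp(parts[0])
            if ts is None:
                if in_data:
                    n_skipped += 1
                # else: header block (--- lines, key:value, column names)
                continue
            in_data = True
            try:
                ax, ay, az = (float(parts[i]) for i in (1, 2, 3))
            except (IndexError, ValueError):
                n_skipped += 1
                continue
            if not (np.isfinite(ax) and np.isfinite(ay) and np.isfinite(az)):
                n_skipped += 1
                continue
            rows.append((ts, ax, ay, az))
    if not rows:
        raise ValueError("no samples")
    df = pd.DataFrame(rows, columns=ACCEL_COLUMNS)
    if utc_offset_hours:
        df["timestamp"] = df["timestamp"] - pd.Timedelta(hours=utc_offset_hours)
    dt = df["timestamp"].diff().dt.total_seconds().iloc[1:]
    if (dt <= 0).any():
        raise ValueError("unsorted input: timestamps not strictly increasing")
    if len(dt):
        med = float(dt.median())
        expected = 1.0 / sample_rate_hz
        if abs(med - expected) > 0.01 * expected:
            raise ValueError(
                f"rate conflict: declared {sample_rate_hz} Hz but median "
                f"interval {med:.6f} s")
    if n_skipped:
        log.warning("read_raw_accel: skipped %d malformed rows", n_skipped)
    return AccelData(df, sample_rate_hz, n_skipped)


def write_raw_accel(data: AccelData, sink) -> None:
    """Write an accelerometer file in the documented dialect (header block,
    column names, then ``timestamp,ax,ay,az`` rows at 6 decimals)."""
    close = False
    if not hasattr(sink, "write"):
        sink, close = open(sink, "w"), True
    try:
        sink.write("--- raw tri-axial accelerometer export ---\n")
        sink.write(f"Sample Rate: {data.sample_rate_hz}\n")
        sink.write(",".join(ACCEL_COLUMNS) + "\n")
        for ts, ax, ay, az in data.samples.itertuples(index=False):
            sink.write(f"{ts.strftime('%Y-%m-%dT%H:%M:%S.%f')}Z,"
                       f"{ax:.6f},{ay:.6f},{az:.6f}\n")
    finally:
        if close:
            sink.close()


def parse_sat_info(fld: str):
    """Parse a ``SAT INFO`` field into a list of SNR values (dB-Hz).

    Satellites are semicolon-separated ``SID-ELE-AZI-SNR`` tokens, e.g.
    ``"#02-48-213-38;#05-67-120-42"`` -> ``[38.0, 42.0]``. Malformed tokens
    are skipped; the second return value counts them.
    """
    if fld is None or not str(fld).strip():
        return [], 0
    snrs, n_bad = [], 0
    for tok in str(fld).split(";"):
        tok = tok.strip()
        if not tok:
            continue
        parts = tok.split("-")
        try:
            snr = float(parts[3])
        except (IndexError, ValueError):
            n_bad += 1
            continue
        if snr < 0:
            n_bad += 1
            continue
        snrs.append(snr)
    if n_bad:
        warnings.warn(f"parse_sat_info: skipped {n_bad} malformed tokens")
    return snrs, n_bad


def read_gps_log(source, utc_offset_hours: float = 0.0) -> GpsTrack:
    """Read a Qstarz-style GPS log.

    Hemisphere letters set coordinate signs (S and W negative). Per-satellite
    SNRs come from :func:`parse_sat_info`. Missing mandatory columns raise
    ``ValueError`` ("dialect error"); extra columns are ignored.
    """
    with _as_text(source) as fh:
        df = pd.read_csv(fh, dtype=str, skipinitialspace=True)
    df.columns = [c.strip() for c in df.columns]
    missing = [c for c in GPS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"dialect error: missing columns {missing}")
    rows, n_skipped = [], 0
    for rec in df.itertuples(index=False):
        rec = dict(zip(df.columns, rec))
        ts = _try_timestamp(f"{rec['UTC DATE']} {rec['UTC TIME']}")
        if ts is None:
            n_skipped += 1
            continue
        try:
            lat = float(rec["LATITUDE"])
            lon = float(rec["LONGITUDE"])
        except (TypeError, ValueError):
            n_skipped += 1
            continue
        ns = str(rec["N/S"]).strip().upper()
        ew = str(rec["E/W"]).strip().upper()
        if ns == "S":
            lat = -abs(lat)
        if ew == "W":
            lon = -abs(lon)
        if not (-90 <= lat <= 90 and -180 <= lon <= 180):
            n_skipped += 1
            continue
        try:
            speed = float(rec["SPEED"])
        except (TypeError, ValueError):
            speed = np.nan
        try:
            nsat = int(float(rec["NSAT"]))
        except (TypeError, ValueError):
            nsat = 0
        sat = rec.get("SAT INFO")
        snrs, _ = parse_sat_info("" if pd.isna(sat) else sat)
        rows.append((ts, lat, lon, speed, nsat, snrs))
    out = pd.DataFrame(
        rows, columns=["timestamp", "lat", "lon", "device_speed",
                       "n_sat_used", "sat_snr"])
    if len(out) and (out["timestamp"].diff().dt.total_seconds().iloc[1:] < 0).any():
        raise ValueError("unsorted input: GPS timestamps decrease")
    if utc_offset_hours and len(out):
        out["timestamp"] = out["timestamp"] - pd.Timedelta(hours=utc_offset_hours)
    if n_skipped:
        log.warning("read_gps_log: skipped %d malformed rows", n_skipped)
    return GpsTrack(out, n_skipped)


def write_gps_log(track: GpsTrack, sink) -> None:
    """Write a GPS track in the documented Qstarz-style dialect."""
    close = False
    if not hasattr(sink, "write"):
        sink, close = open(sink, "w"), True
    try:
        sink.write(",".join(GPS_COLUMNS) + "\n")
        for rec in track.fixes.itertuples(index=False):
            ts = rec.timestamp
            ns = "S" if rec.lat < 0 else "N"
            ew = "W" if rec.lon < 0 else "E"
            speed = "" if pd.isna(rec.device_speed) else f"{rec.device_speed:.3f}"
            sat = ";".join(f"#{i + 1:02d}-45-180-{snr:g}"
                           for i, snr in enumerate(rec.sat_snr))
            sink.write(f"{ts.strftime('%Y/%m/%d')},{ts.strftime('%H:%M:%S')},"
                       f"{abs(rec.lat):.6f},{ns},{abs(rec.lon):.6f},{ew},"
                       f"{speed},{rec.n_sat_used},{sat}\n")
    finally:
        if close:
            sink.close()


def read_rail_lines(source) -> RailNetwork:
    """Read rail-line geometry from a GeoJSON FeatureCollection.

    LineString parts become polylines; MultiLineString parts are flattened.
    Non-line geometries are skipped with a warning; an empty result raises
    ``ValueError`` ("no rail lines").
    """
    if hasattr(source, "read"):
        obj = json.load(source)
    elif isinstance(source, str) and source.lstrip().startswith("{"):
        obj = json.loads(source)
    else:
        with open(source) as fh:
            obj = json.load(fh)
    feats = obj.get("features", [obj] if obj.get("type") != "FeatureCollection" else [])
    polylines, n_skipped = [], 0
    for feat in feats:
        geom = feat.get("geometry", feat)
        gtype = geom.get("type")
        if gtype == "LineString":
            polylines.append(np.asarray(geom["coordinates"], dtype=float))
        elif gtype == "MultiLineString":
            polylines.extend(np.asarray(p, dtype=float)
                             for p in geom["coordinates"])
        else:
            n_skipped += 1
    if n_skipped:
        warnings.warn(f"read_rail_lines: skipped {n_skipped} non-line geometries")
    if not polylines:
        raise ValueError("no rail lines")
    return RailNetwork(polylines)


def write_rail_lines(network: RailNetwork, sink) -> None:
    """Write a rail network as a GeoJSON FeatureCollection of LineStrings."""
    obj = {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature", "properties": {},
             "geometry": {"type": "LineString",
                          "coordinates": [[round(float(x), 6), round(float(y), 6)]
                                          for x, y in poly]}}
            for poly in network.polylines
        ],
    }
    if hasattr(sink, "write"):
        json.dump(obj, sink, sort_keys=True)
    else:
        with open(sink, "w") as fh:
            json.dump(obj, fh, sort_keys=True)


def write_feature_table(rows: pd.DataFrame, sink) -> None:
    """Write the per-epoch feature table as CSV with a fixed column order.

    ``participant_id`` and ``epoch_start`` lead, ``label`` (when present)
    trails; feature columns keep their construction order. Floats are written
    at full precision (round-trip safe)."""
    cols = list(rows.columns)
    ordered = [c for c in FEATURE_TABLE_ID_COLUMNS if c in cols]
    ordered += [c for c in cols if c not in ordered and c != "label"]
    if "label" in cols:
        ordered.append("label")
    out = rows[ordered].copy()
    if "epoch_start" in out.columns and len(out):
        out["epoch_start"] = pd.to_datetime(out["epoch_start"], utc=True).dt.strftime(
            "%Y-%m-%dT%H:%M:%SZ")
    out.to_csv(sink, index=False)


def read_feature_table(source, expected_columns=None) -> pd.DataFrame:
    """Read a feature table written by :func:`write_feature_table`.

    When ``expected_columns`` is given, any unknown column raises
    ``ValueError`` ("schema error"). Labels are validated against the five
    canonical modes."""
    df = pd.read_csv(source)
    if expected_columns is not None:
        unknown = [c for c in df.columns if c not in expected_columns]
        if unknown:
            raise ValueError(f"schema error: unknown columns {unknown}")
    if "epoch_start" in df.columns:
        df["epoch_start"] = pd.to_datetime(df["epoch_start"], utc=True)
    if "label" in df.columns:
        bad = set(df["label"].dropna()) - set(MODES)
        if bad:
            raise ValueError(f"schema error: unknown labels {sorted(bad)}")
    for c in ("has_gps", "nonwear"):
        if c in df.columns:
            df[c] = df[c].astype(bool)
    return df
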