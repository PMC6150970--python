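"""Synthetic multimodal travel traces: labelled accelerometer + GPS + rail
network data with the statistical structure the classifier exploits.

The simulator emits the exact file dialects the readers consume, so the full
pipeline is testable end to end without any study data. Each participant-day
is a recorded window (default 120 min) structured like a commuting day —
stationary periods, walking links, one rail leg, one cycle leg and one
vehicle leg — rather than 24 h of mostly idle samples; the study's training
examples are commute segments, so this is the regime that matters.

Mode signatures follow the contrasts the classifier is built on:

* speed (km/h): stationary ~0, walk 4-6, cycle 12-20, vehicle 20-60 with
  stop-go episodes (traffic lights), train 30-80 constrained to rail lines;
* accelerometer texture (hip-worn): walking is a strong ~2 Hz oscillation,
  cycling a moderate ~1.4 Hz one, vehicle and train low-amplitude vibration,
  stationary small postural fidgeting; gravity sits on the z axis with slow
  orientation jitter;
* GPS quality: open-air modes track many satellites at high SNR, metal-boxed
  modes (vehicle, train) attenuate sumSNR, and trains/indoor episodes drop
  fixes entirely.

Sitting still is simulated with ~30 mg of postural fidget — real wearers
are never below the 13 mg non-wear threshold — while inserted non-wear
blocks (device taken off, appended after the recorded window with
probability ``nonwear_prob``) are near-constant at ~0.5 mg and carry no GPS.

With ``degrade_train_cues`` the train class loses everything except its
accelerometer texture: speeds and satellite SNR are drawn from the vehicle
regimes and the path ignores the rail network. This is the negative control
showing that the rail-distance and sumSNR features, not some accidental
artefact, drive train/vehicle separation.

Every run is reproducible bit-for-bit from ``seed``; per-participant streams
come from spawned child seeds, so cohorts of different sizes share no
randomness across participants.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import EARTH_RADIUS_M
from .io_formats import (AccelData, GpsTrack, RailNetwork, write_gps_log,
                         write_rail_lines, write_raw_accel)

log = logging.getLogger(__name__)

ANCHOR_LAT, ANCHOR_LON = 51.5, -0.12  # urban study-area centre

SPEED_KMH = {  # (low, high) of per-segment base speed
    "stationary": (0.0, 0.2),
    "walk": (4.0, 6.0),
    "cycle": (12.0, 20.0),
    "vehicle": (20.0, 60.0),
    "train": (30.0, 80.0),
}

#: Per-mode accelerometer texture: (oscillation amplitude g, frequency Hz,
#: broadband noise SD g). Oscillation rides on x and z (hip axes), half
#: amplitude on y.
ACCEL_TEXTURE = {
    "stationary": (0.0, 0.0, 0.035),
    "walk": (0.35, 2.0, 0.030),
    "cycle": (0.12, 1.4, 0.025),
    "vehicle": (0.015, 0.4, 0.025),
    "train": (0.015, 0.4, 0.025),  # same texture: metal-box modes are
    # indistinguishable on the hip accelerometer; rail/SNR/speed separate them
}

#: Per-mode GPS regime: (n_sat low, n_sat high, SNR mean, SNR SD, dropout p).
GPS_REGIME = {
    "stationary": (4, 7, 20.0, 5.0, 0.30),
    "walk": (8, 11, 42.0, 4.0, 0.02),
    "cycle": (8, 11, 42.0, 4.0, 0.02),
    "vehicle": (6, 9, 30.0, 4.0, 0.05),
    "train": (5, 8, 24.0, 4.0, 0.25),
}


@dataclass
class SimConfig:
    """Cohort-level simulation settings (defaults are the study conditions)."""

    seed: int = 0
    n_participants: int = 10
    n_days: int = 2
    day_minutes: int = 120          # recorded window per day
    sample_rate_hz: float = 30.0
    extent_km: float = 10.0
    schedule: list | None = None    # explicit [(mode, minutes), ...] or None
    nonwear_prob: float = 0.3       # chance of a device-off block per day
    nonwear_minutes: int = 90
    gps_dropout_prob: float = 0.02  # extra, mode-independent fix loss
    device_speed_prob: float = 0.9  # fixes carrying a device speed field
    degrade_train_cues: bool = False

    def __post_init__(self):
        if self.n_participants < 1 or self.n_days < 1 or self.day_minutes < 10:
            raise ValueError("invalid cohort dimensions")


def simulate_rail_network(seed: int = 0, extent_km: float = 10.0) -> RailNetwork:
    """A small deterministic rail network: three gently-bending lines that
    meet near the centre of the extent (a hub), all vertices inside it."""
    rng = np.random.default_rng(seed)
    half = extent_km * 500.0  # metres from centre
    lines_xy = []
    for bearing in rng.uniform(0, np.pi, size=3) + np.array([0.0, np.pi / 3, 2 * np.pi / 3]):
        s = np.linspace(-half, half, 11)
        wiggle = rng.normal(0.0, half * 0.03, size=s.size).cumsum()
        wiggle -= wiggle[s.size // 2]  # all lines pass through the hub
        x = s * np.cos(bearing) - wiggle * np.sin(bearing)
        y = s * np.sin(bearing) + wiggle * np.cos(bearing)
        np.clip(x, -half, half, out=x)
        np.clip(y, -half, half, out=y)
        lines_xy.append(np.column_stack([x, y]))
    return RailNetwork([_xy_to_lonlat(xy) for xy in lines_xy])


def _xy_to_lonlat(xy: np.ndarray) -> np.ndarray:
    lat = ANCHOR_LAT + np.degrees(xy[:, 1] / EARTH_RADIUS_M)
    lon = ANCHOR_LON + np.degrees(
        xy[:, 0] / (EARTH_RADIUS_M * np.cos(np.radians(ANCHOR_LAT))))
    return np.column_stack([lon, lat])


def _lonlat_to_xy(lonlat: np.ndarray) -> np.ndarray:
    x = np.radians(lonlat[:, 0] - ANCHOR_LON) * EARTH_RADIUS_M * np.cos(
        np.radians(ANCHOR_LAT))
    y = np.radians(lonlat[:, 1] - ANCHOR_LAT) * EARTH_RADIUS_M
    return np.column_stack([x, y])


def default_schedule(rng: np.random.Generator, day_minutes: int) -> list:
    """A commuting-day mode schedule (mode, minutes), durations in whole
    10-s epochs, covering all five modes and filling the recorded window."""
    sc = day_minutes / 120.0  # segment lengths scale with the recorded window
    draw = lambda lo, hi: max(round(rng.uniform(lo, hi) * sc * 6) / 6, 1.0)
    segs = [
        ("stationary", draw(8, 14)),
        ("walk", draw(8, 12)),
        ("train", draw(12, 16)),
        ("walk", draw(4, 7)),
        ("stationary", draw(15, 25)),
        ("cycle", draw(8, 12)),
        ("stationary", draw(5, 10)),
        ("vehicle", draw(10, 15)),
    ]
    used = sum(m for _, m in segs)
    if used > day_minutes - 1:
        raise ValueError("schedule exceeds day length")
    segs.append(("stationary", day_minutes - used))
    return segs


class _RailRider:
    """Moves along a rail polyline by arc length, reflecting at the ends."""

    def __init__(self, network: RailNetwork, rng: np.random.Generator):
        poly = network.polylines[rng.integers(len(network.polylines))]
        self.xy = _lonlat_to_xy(poly)
        seg = np.diff(self.xy, axis=0)
        self.cum = np.concatenate([[0.0], np.hypot(*seg.T).cumsum()])
        self.pos = float(rng.uniform(0.2, 0.8) * self.cum[-1])
        self.sign = 1.0 if rng.random() < 0.5 else -1.0

    def step(self, dist_m: float) -> np.ndarray:
        self.pos += self.sign * dist_m
        if self.pos < 0 or self.pos > self.cum[-1]:
            self.sign = -self.sign
            self.pos = float(np.clip(self.pos, 0, self.cum[-1]))
        i = int(np.searchsorted(self.cum, self.pos, side="right") - 1)
        i = min(i, len(self.cum) - 2)
        frac = (self.pos - self.cum[i]) / max(self.cum[i + 1] - self.cum[i], 1e-9)
        return self.xy[i] + frac * (self.xy[i + 1] - self.xy[i])


def _simulate_positions(segments, network, rng, extent_km, degrade):
    """Per-second positions (x, y metres) and true speeds (km/h)."""
    half = extent_km * 500.0
    xy = rng.uniform(-half * 0.6, half * 0.6, size=2)
    heading = rng.uniform(0, 2 * np.pi)
    pos_list, speed_list = [], []
    for mode, minutes in segments:
        n = int(round(minutes * 60))
        speed_mode = "vehicle" if (degrade and mode == "train") else mode
        lo, hi = SPEED_KMH[speed_mode]
        base = rng.uniform(lo, hi)
        speeds = np.clip(base + rng.normal(0, (hi - lo) * 0.08, n), lo * 0.5, hi)
        if mode == "vehicle" or (degrade and mode == "train"):
            t = 0  # stop-go: red lights every 40-120 s, 10-30 s stops
            while t < n:
                t += int(rng.integers(40, 120))
                stop = int(rng.integers(10, 30))
                speeds[t:t + stop] = 0.0
                t += stop
        if mode == "stationary":
            speeds[:] = rng.uniform(*SPEED_KMH["stationary"], size=n)
        on_rail = mode == "train" and not degrade
        rider = _RailRider(network, rng) if on_rail else None
        for s in range(n):
            d = speeds[s] / 3.6  # metres this second
            if on_rail:
                xy = rider.step(d)
            elif mode == "stationary":
                xy = xy + rng.normal(0, 0.3, 2)
            else:
                heading += rng.normal(0, 0.05)
                step = d * np.array([np.cos(heading), np.sin(heading)])
                nxt = xy + step
                if np.abs(nxt).max() > half:  # bounce off the extent edge
                    heading += np.pi / 2
                    nxt = xy
                xy = nxt
            pos_list.append(xy.copy())
            speed_list.append(speeds[s])
    return np.asarray(pos_list), np.asarray(speed_list)


def _simulate_accel(segments, nonwear_minutes, rate_hz, rng):
    """30 Hz tri-axial signal for the schedule plus an optional trailing
    non-wear block; returns (n, 3) array in g."""
    per_mode = []
    for mode, minutes in segments:
        n = int(round(minutes * 60 * rate_hz))
        amp, freq, noise = ACCEL_TEXTURE[mode]
        noise *= rng.uniform(0.8, 1.25)  # per-segment device/posture variation
        t = np.arange(n) / rate_hz
        phase = rng.uniform(0, 2 * np.pi)
        f = freq * rng.uniform(0.9, 1.1) if freq else 0.0
        osc = amp * np.sin(2 * np.pi * f * t + phase) if amp else 0.0
        sig = np.empty((n, 3))
        sig[:, 0] = osc + rng.normal(0, noise, n)
        sig[:, 1] = 0.5 * np.asarray(osc) + rng.normal(0, noise, n)
        sig[:, 2] = 1.0 + 0.8 * np.asarray(osc) + rng.normal(0, noise, n)
        # slow orientation jitter on the gravity axis
        drift = rng.normal(0, 0.002, max(n // int(30 * rate_hz), 1) + 2).cumsum()
        sig[:, 2] += np.interp(t, np.linspace(0, t[-1] if n else 0, drift.size), drift)
        per_mode.append(sig)
    if nonwear_minutes:
        n = int(round(nonwear_minutes * 60 * rate_hz))
        still = np.tile(rng.normal([0.02, -0.01, 1.0], 0.005), (n, 1))
        still += rng.normal(0, 0.0005, (n, 3))
        per_mode.append(still)
    return np.vstack(per_mode)


def simulate_participant_week(config: SimConfig, participant_id: str,
                              network: RailNetwork,
                              seed: int | None = None):
    """One participant's files: ``(AccelData, GpsTrack, truth)``.

    ``truth`` holds one row per emitted epoch: participant, epoch start,
    true mode label and true non-wear flag.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    rate = config.sample_rate_hz
    accel_parts, gps_rows, truth_rows = [], [], []
    for day in range(config.n_days):
        t0 = (pd.Timestamp("2024-03-04 08:00:00", tz="UTC")
              + pd.Timedelta(days=day))
        segments = config.schedule or default_schedule(rng, config.day_minutes)
        if sum(m for _, m in segments) > 24 * 60:
            raise ValueError("schedule exceeds day length")
        nonwear_min = config.nonwear_minutes if rng.random() < config.nonwear_prob else 0

        sig = _simulate_accel(segments, nonwear_min, rate, rng)
        ts = t0 + pd.to_timedelta(np.arange(len(sig)) / rate, unit="s")
        accel_parts.append(pd.DataFrame(
            {"timestamp": ts, "ax": sig[:, 0], "ay": sig[:, 1], "az": sig[:, 2]}))

        xy, speeds = _simulate_positions(
            segments, network, rng, config.extent_km, config.degrade_train_cues)
        lonlat = _xy_to_lonlat(xy)
        sec_mode = np.concatenate([
            np.repeat(mode, int(round(minutes * 60)))
            for mode, minutes in segments])
        for s in range(2, len(xy), 10):  # one fix per epoch, 2 s in
            mode = sec_mode[s]
            regime = "vehicle" if (config.degrade_train_cues and mode == "train") \
                else mode
            lo, hi, mu, sd, drop = GPS_REGIME[regime]
            if rng.random() < drop + config.gps_dropout_prob:
                continue
            nsat = int(rng.integers(lo, hi + 1))
            snrs = np.clip(rng.normal(mu, sd, nsat), 5.0, 60.0).round(0)
            dev_speed = (round(max(speeds[s] + rng.normal(0, 0.3), 0.0), 3)
                         if rng.random() < config.device_speed_prob else np.nan)
            gps_rows.append((t0 + pd.Timedelta(seconds=s), lonlat[s, 1],
                             lonlat[s, 0], dev_speed, nsat, list(snrs)))

        n_sched_epochs = int(sum(m for _, m in segments) * 6)
        epoch_modes = sec_mode[::10][:n_sched_epochs]
        for k, mode in enumerate(epoch_modes):
            truth_rows.append((participant_id,
                               t0 + pd.Timedelta(seconds=10 * k), mode, False))
        for k in range(nonwear_min * 6):
            truth_rows.append((participant_id,
                               t0 + pd.Timedelta(seconds=10 * (n_sched_epochs + k)),
                               "stationary", True))

    accel = AccelData(pd.concat(accel_parts, ignore_index=True), rate)
    gps = GpsTrack(pd.DataFrame(
        gps_rows, columns=["timestamp", "lat", "lon", "device_speed",
                           "n_sat_used", "sat_snr"]))
    truth = pd.DataFrame(
        truth_rows, columns=["participant_id", "epoch_start", "label", "nonwear"])
    return accel, gps, truth


def simulate_cohort(config: SimConfig, outdir=None):
    """Simulate ``n_participants`` independent weeks over one shared rail
    network.

    Returns ``(network, participants, truth)`` where ``participants`` maps
    participant_id -> (AccelData, GpsTrack). With ``outdir`` the cohort is
    also written in the external dialects (one accel and one GPS file per
    participant, the network GeoJSON, the truth table and a manifest).
    """
    root = np.random.SeedSequence(config.seed)
    net_seed, *part_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                             for s in root.spawn(config.n_participants + 1)]
    network = simulate_rail_network(net_seed, config.extent_km)
    participants, truths = {}, []
    for i, pseed in enumerate(part_seeds, start=1):
        pid = f"P{i:03d}"
        accel, gps, truth = simulate_participant_week(config, pid, network,
                                                      seed=pseed)
        participants[pid] = (accel, gps)
        truths.append(truth)
        log.info("simulated %s: %d accel samples, %d GPS fixes", pid,
                 len(accel), len(gps))
    truth = pd.concat(truths, ignore_index=True)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        manifest = {"seed": config.seed, "participants": {}}
        write_rail_lines(network, outdir / "rail_network.geojson")
        for pid, (accel, gps) in participants.items():
            write_raw_accel(accel, outdir / f"{pid}_accel.csv")
            write_gps_log(gps, outdir / f"{pid}_gps.csv")
            manifest["participants"][pid] = {
                "accel": f"{pid}_accel.csv", "gps": f"{pid}_gps.csv"}
        tt = truth.copy()
        tt["epoch_start"] = tt["epoch_start"].dt.strftime("%Y-%m-%dT%H:%M:%SZ")
        tt.to_csv(outdir / "truth.csv", index=False)
        manifest["network"] = "rail_network.geojson"
        manifest["truth"] = "truth.csv"
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
    return network, participants, truth
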