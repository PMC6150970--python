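"""Distance primitives: great-circle distance, a local metric projection and
point-to-polyline distance for the distance-to-rail feature.

Rail distances are computed analytically in a local equirectangular frame
anchored at the query point: x = R * dlon * cos(lat0), y = R * dlat (radians).
At the <= 10 km scale of urban trips the projection error versus the
great-circle distance is below 0.5 %, which is negligible against GPS noise.
Earth radius is fixed at 6,371,000 m.
"""

from __future__ import annotations

import warnings

import numpy as np

EARTH_RADIUS_M = 6_371_000.0


def haversine_m(a, b) -> float:
    """Great-circle distance in metres between (lat, lon) pairs ``a`` and
    ``b`` (decimal degrees). Symmetric and non-negative."""
    lat1, lon1 = np.radians(np.asarray(a, dtype=float))
    lat2, lon2 = np.radians(np.asarray(b, dtype=float))
    dlat, dlon = lat2 - lat1, lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return float(2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0))))


def haversine_m_vec(lat1, lon1, lat2, lon2):
    """Vectorised great-circle distance (metres) over degree arrays."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(v, dtype=float))
                              for v in (lat1, lon1, lat2, lon2))
    h = (np.sin((lat2 - lat1) / 2.0) ** 2
         + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2.0) ** 2)
    return 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def project_local(points, anchor):
    """Project (lat, lon) points to metres in an equirectangular frame
    anchored at ``anchor``; the anchor maps to (0, 0).

    ``points`` is an (n, 2) array of (lat, lon). Points farther than ~100 km
    from the anchor trigger a warning (projection error grows with distance).
    Returns an (n, 2) array of (x, y) metres.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    lat0, lon0 = float(anchor[0]), float(anchor[1])
    x = EARTH_RADIUS_M * np.radians(pts[:, 1] - lon0) * np.cos(np.radians(lat0))
    y = EARTH_RADIUS_M * np.radians(pts[:, 0] - lat0)
    if np.hypot(x, y).max(initial=0.0) > 100_000.0:
        warnings.warn("project_local: points beyond ~100 km of anchor; "
                      "projection error may be significant")
    return np.column_stack([x, y])


def point_to_segment_m(p, s1, s2) -> float:
    """Euclidean distance from projected point ``p`` to the closed segment
    ``s1``–``s2`` (all in metres). A degenerate segment collapses to a
    point-to-point distance."""
    p, s1, s2 = (np.asarray(v, dtype=float) for v in (p, s1, s2))
    d = s2 - s1
    denom = float(d @ d)
    if denom == 0.0:
        return float(np.hypot(*(p - s1)))
    t = np.clip(float((p - s1) @ d) / denom, 0.0, 1.0)
    return float(np.hypot(*(p - (s1 + t * d))))


def _segments_local(network, anchor):
    """All network segments projected into the frame anchored at ``anchor``:
    returns (starts, ends) as (m, 2) arrays."""
    starts, ends = [], []
    for poly in network.polylines:
        # polylines store (lon, lat); projection wants (lat, lon)
        xy = project_local(poly[:, ::-1], anchor)
        starts.append(xy[:-1])
        ends.append(xy[1:])
    return np.vstack(starts), np.vstack(ends)


def distance_to_network_m(p, network) -> float:
    """Minimum distance in metres from (lat, lon) point ``p`` to any segment
    of the rail network, computed in a local frame anchored at ``p``."""
    if not network.polylines:
        raise ValueError("no rail lines")
    s1, s2 = _segments_local(network, p)
    return float(_min_dist_to_segments(np.zeros(2), s1, s2))


def _min_dist_to_segments(pt, s1, s2) -> float:
    d = s2 - s1
    denom = np.einsum("ij,ij->i", d, d)
    num = np.einsum("ij,ij->i", pt - s1, d)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
    t = np.clip(t, 0.0, 1.0)
    nearest = s1 + t[:, None] * d
    return float(np.hypot(*(pt - nearest).T).min())


def distances_to_network_m(points, network):
    """Vectorised :func:`distance_to_network_m` for an (n, 2) array of
    (lat, lon) points, using a single frame anchored at the points' centroid.

    Exact to the projection's accuracy when the point cloud and network span
    <= tens of km, which holds for a participant-day of urban travel.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if not network.polylines:
        raise ValueError("no rail lines")
    anchor = pts.mean(axis=0)
    xy = project_local(pts, anchor)
    s1, s2 = _segments_local(network, anchor)
    d = s2 - s1
    denom = np.einsum("ij,ij->i", d, d)
    out = np.empty(len(xy))
    for i, pt in enumerate(xy):
        num = np.einsum("ij,ij->i", pt - s1, d)
        with np.errstate(invalid="ignore", divide="ignore"):
            t = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
        t = np.clip(t, 0.0, 1.0)
        nearest = s1 + t[:, None] * d
        out[i] = np.hypot(*(pt - nearest).T).min()
    return out
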