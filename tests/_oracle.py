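"""Independent brute-force reference implementation of the matching chain.

Everything here is written as plain exhaustive loops with scalar math —
no window slicing, no shared helpers with the package — so that agreement
with the package is a meaningful check.  Distance uses its own haversine;
the shared contract is "within radius + 1e-9 degrees".
"""

from __future__ import annotations

import math

import numpy as np

DIST_TOL = 1e-9

NON_FOREST = 0
DEFORESTED = 1
NON_DEFORESTED = 2

RADIUS_NONE = 0
RADIUS_PRIMARY = 1
RADIUS_FALLBACK = 2


def haversine_deg(lat0, lon0, lat1, lon1):
    la0, lo0, la1, lo1 = map(math.radians, (lat0, lon0, lat1, lon1))
    h = (
        math.sin((la1 - la0) / 2) ** 2
        + math.cos(la0) * math.cos(la1) * math.sin((lo1 - lo0) / 2) ** 2
    )
    return math.degrees(2 * math.asin(math.sqrt(min(1.0, h))))


def euclid_deg(lat0, lon0, lat1, lon1):
    return math.hypot(lat1 - lat0, lon1 - lon0)


def brute_raw_attribution(
    dt, dt_mask, classes, elev, elev_mask, lat, lon,
    primary_radius=0.25, fallback_radius=0.50, elevation_band=50.0,
    degree_space=False,
):
    """Exhaustive all-pairs control search and mean subtraction.

    Returns (raw, raw_mask, radius_code, n_controls) arrays.
    """
    nr, nc = dt.shape
    dist = euclid_deg if degree_space else haversine_deg
    raw = np.full((nr, nc), np.nan)
    code = np.zeros((nr, nc), dtype=np.int8)
    ncontrols = np.zeros((nr, nc), dtype=np.int32)
    for i in range(nr):
        for j in range(nc):
            if classes[i, j] != DEFORESTED:
                continue
            if dt_mask[i, j] or elev_mask[i, j]:
                continue
            for radius, rcode in (
                (primary_radius, RADIUS_PRIMARY),
                (fallback_radius, RADIUS_FALLBACK),
            ):
                vals = []
                for r in range(nr):
                    for c in range(nc):
                        if classes[r, c] != NON_DEFORESTED:
                            continue
                        if dt_mask[r, c] or elev_mask[r, c]:
                            continue
                        if abs(elev[r, c] - elev[i, j]) > elevation_band:
                            continue
                        if dist(lat[i], lon[j], lat[r], lon[c]) > radius + DIST_TOL:
                            continue
                        vals.append(dt[r, c])
                if vals:
                    raw[i, j] = dt[i, j] - np.mean(np.asarray(vals))
                    code[i, j] = rcode
                    ncontrols[i, j] = len(vals)
                    break
    return raw, ~np.isfinite(raw), code, ncontrols


def brute_smooth(
    per_point, per_point_mask, classes, loss_pct, lat, lon,
    smooth_radius=0.10, min_loss=5.0, z_threshold=3.0,
    regional_mean=None, degree_space=False, include_center=True,
):
    """Exhaustive rolling-circle mean with a one-pass z screen."""
    nr, nc = per_point.shape
    dist = euclid_deg if degree_space else haversine_deg
    out = np.full((nr, nc), np.nan)
    fallback = np.zeros((nr, nc), dtype=bool)
    for i in range(nr):
        for j in range(nc):
            if classes[i, j] != DEFORESTED:
                continue
            members = []
            for r in range(nr):
                for c in range(nc):
                    if classes[r, c] != DEFORESTED or per_point_mask[r, c]:
                        continue
                    if not include_center and (r, c) == (i, j):
                        continue
                    if loss_pct[r, c] < min_loss:
                        continue
                    if dist(lat[i], lon[j], lat[r], lon[c]) > smooth_radius + DIST_TOL:
                        continue
                    members.append(per_point[r, c])
            if not members:
                if regional_mean is None:
                    raise ValueError("regional mean required")
                out[i, j] = regional_mean
                fallback[i, j] = True
                continue
            arr = np.asarray(members)
            mean = np.mean(arr)
            sd = np.std(arr)
            if sd > 0:
                arr = arr[np.abs(arr - mean) / sd <= z_threshold]
            out[i, j] = np.mean(arr)
    return out, fallback
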