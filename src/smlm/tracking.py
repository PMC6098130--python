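"""Single-particle tracking and diffusion analysis (Crocker-Grier style).

Detection: band-pass each frame (Gaussian smooth minus boxcar
background), find local maxima, refine to sub-pixel accuracy with an
intensity-weighted centroid.  Linking: frame-to-frame assignment
minimizing total squared displacement under a maximum-displacement bound,
with optional track memory across gap frames; tracks shorter than 10
points are discarded to limit statistical noise.  Diffusion coefficients
come from an unweighted least-squares line through the first three points
of each trajectory's time-averaged MSD curve (slope/4 for 2-D motion,
free intercept absorbing static localization error).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, uniform_filter
from scipy.optimize import linear_sum_assignment

__all__ = [
    "DiffusionEstimate",
    "detect_spots",
    "link_trajectories",
    "msd_curve",
    "diffusion_coefficient",
    "track_diffusion",
    "partition_tracks_by_mask",
]

_BIG = 1e12


@dataclass
class DiffusionEstimate:
    D: float  # µm²/s
    msd: np.ndarray  # µm², lags 1..3
    intercept: float
    negative: bool  # slope was negative; D reported as-is with this flag


def detect_spots(frame: np.ndarray, feature_radius: int = 3,
                 threshold: float = 1.0) -> pd.DataFrame:
    """Detect bright spots in one frame; sub-pixel (x, y) in pixel units.

    Coordinates follow the convention that the center of pixel (i, j) is
    (x=j, y=i); convert to physical units as ``(coord + 0.5) * pixel_size``.
    """
    if feature_radius < 1:
        raise ValueError("feature_radius must be >= 1")
    img = np.asarray(frame, float)
    bp = gaussian_filter(img, 1.0) - uniform_filter(img, 2 * feature_radius + 1)
    bp = np.clip(bp, 0, None)
    from skimage.feature import peak_local_max

    peaks = peak_local_max(bp, min_distance=int(feature_radius),
                           threshold_abs=float(threshold), exclude_border=False)
    rows = []
    r = int(feature_radius)
    for i, j in peaks:
        i0, i1 = max(0, i - r), min(img.shape[0], i + r + 1)
        j0, j1 = max(0, j - r), min(img.shape[1], j + r + 1)
        # refine on the raw image above its local floor: the bandpass is for
        # detection only and would bias the sub-pixel centroid
        win = img[i0:i1, j0:j1]
        win = np.clip(win - win.min(), 0, None)
        mass = win.sum()
        if mass <= 0:
            continue
        yy, xx = np.mgrid[i0:i1, j0:j1]
        rows.append(
            {
                "x": float((win * xx).sum() / mass),
                "y": float((win * yy).sum() / mass),
                "mass": float(mass),
            }
        )
    return pd.DataFrame(rows, columns=["x", "y", "mass"])


def _assign(prev_xy, new_xy, max_disp):
    """Optimal frame-to-frame assignment under a displacement bound.

    Returns list of (prev_index, new_index) links.  Cost is squared
    displacement; unlinked particles pay max_disp^2 (the Crocker-Grier
    birth/death cost), implemented by padding to a square problem.
    """
    na, nb = len(prev_xy), len(new_xy)
    if na == 0 or nb == 0:
        return []
    d2 = np.sum((prev_xy[:, None, :] - new_xy[None, :, :]) ** 2, axis=2)
    cost = np.where(d2 <= max_disp**2, d2, _BIG)
    size = na + nb
    full = np.full((size, size), 0.0)
    full[:na, :nb] = cost
    full[:na, nb:] = max_disp**2  # death
    full[na:, :nb] = max_disp**2  # birth
    rows, cols = linear_sum_assignment(full)
    return [
        (int(r), int(c))
        for r, c in zip(rows, cols)
        if r < na and c < nb and full[r, c] < _BIG
    ]


def link_trajectories(detections: Dict[int, pd.DataFrame], max_disp: float,
                      memory: int = 0, min_length: int = 10) -> pd.DataFrame:
    """Link per-frame detections into trajectories.

    ``detections`` maps frame index -> DataFrame with x, y columns (pixel
    or nm — linking is unit-agnostic; ``max_disp`` must match).  Returns a
    track table (track_id, frame, x, y) with tracks shorter than
    ``min_length`` discarded.  Unmatched tracks persist for ``memory``
    frames before being closed.
    """
    if max_disp <= 0:
        raise ValueError("max_disp must be positive")
    frames = sorted(detections)
    next_id = 0
    active = {}  # track_id -> (last_xy, last_frame)
    rows = []

    def start(frame, xy):
        nonlocal next_id
        tid = next_id
        next_id += 1
        active[tid] = (xy, frame)
        rows.append((tid, frame, xy[0], xy[1]))
        return tid

    for f in frames:
        det = detections[f]
        new_xy = det[["x", "y"]].to_numpy(dtype=float)
        tids = list(active)
        prev_xy = np.array([active[t][0] for t in tids]) if tids else np.empty((0, 2))
        links = _assign(prev_xy, new_xy, max_disp)
        linked_new = set()
        linked_prev = set()
        for r, c in links:
            tid = tids[r]
            active[tid] = (new_xy[c], f)
            rows.append((tid, f, new_xy[c, 0], new_xy[c, 1]))
            linked_new.add(c)
            linked_prev.add(r)
        for c in range(len(new_xy)):
            if c not in linked_new:
                start(f, new_xy[c])
        for r, tid in enumerate(tids):
            if r not in linked_prev and f - active[tid][1] > memory:
                del active[tid]
    tracks = pd.DataFrame(rows, columns=["track_id", "frame", "x", "y"])
    lengths = tracks.groupby("track_id").size()
    keep = lengths.index[lengths >= min_length]
    tracks = tracks[tracks["track_id"].isin(keep)]
    return tracks.sort_values(["track_id", "frame"]).reset_index(drop=True)


def msd_curve(track_xy: np.ndarray, max_lag: int = None) -> np.ndarray:
    """Time-averaged MSD per lag, over all ordered pairs at each lag.

    Input positions are for consecutive frames; output is in squared input
    units, ``msd[k-1]`` for lag k.
    """
    xy = np.asarray(track_xy, float)
    n = len(xy)
    if n < 4:
        raise ValueError("track too short for an MSD curve (need >= 4 points)")
    if max_lag is None:
        max_lag = n - 1
    out = np.empty(max_lag)
    for k in range(1, max_lag + 1):
        d = xy[k:] - xy[:-k]
        out[k - 1] = np.mean(np.sum(d * d, axis=1))
    return out


def diffusion_coefficient(msd_first3, dt: float = 0.05) -> DiffusionEstimate:
    """D from the first three MSD points (input in µm², dt in s).

    Unweighted least-squares line through (k dt, msd_k), k = 1..3, with a
    free intercept; ``D = slope / 4``.  Negative estimates are reported
    as-is with ``negative=True``.
    """
    msd = np.asarray(msd_first3, float)[:3]
    if len(msd) < 3 or not np.all(np.isfinite(msd)):
        raise ValueError("need three finite MSD values")
    t = dt * np.arange(1, 4)
    slope, intercept = np.polyfit(t, msd, 1)
    return DiffusionEstimate(float(slope / 4.0), msd, float(intercept),
                             bool(slope < 0))


def track_diffusion(tracks: pd.DataFrame, dt: float = 0.05,
                    unit_scale: float = 1e-3) -> pd.DataFrame:
    """Per-track D (µm²/s) from track coordinates.

    ``unit_scale`` converts coordinates to µm (1e-3 for nm input, 1 for µm).
    """
    rows = []
    for tid, g in tracks.groupby("track_id"):
        xy = g[["x", "y"]].to_numpy() * unit_scale
        est = diffusion_coefficient(msd_curve(xy, max_lag=3), dt)
        rows.append({"track_id": tid, "D": est.D, "negative": est.negative})
    return pd.DataFrame(rows, columns=["track_id", "D", "negative"])


def partition_tracks_by_mask(tracks: pd.DataFrame, mask: np.ndarray,
                             pixel_size: float, dt: float = 0.05,
                             unit_scale: float = 1e-3,
                             immobile_threshold: float = 0.01,
                             rule: str = "majority") -> dict:
    """Split tracks into inside/outside a region mask and compare mobility.

    A track is "inside" when at least 50% of its localizations fall on
    mask-true pixels (``rule`` may also be ``"any"`` or ``"all"``).
    ``pixel_size`` converts track coordinates to mask pixels.  Returns
    per-group track tables, median D (µm²/s), and the immobile fraction
    (D below ``immobile_threshold``).
    """
    mask = np.asarray(mask, bool)
    groups = {"inside": [], "outside": []}
    for tid, g in tracks.groupby("track_id"):
        j = (g["x"].to_numpy() / pixel_size).astype(int)
        i = (g["y"].to_numpy() / pixel_size).astype(int)
        valid = (i >= 0) & (i < mask.shape[0]) & (j >= 0) & (j < mask.shape[1])
        on = np.zeros(len(g), dtype=bool)
        on[valid] = mask[i[valid], j[valid]]
        frac = on.mean()
        if rule == "majority":
            inside = frac >= 0.5
        elif rule == "any":
            inside = on.any()
        elif rule == "all":
            inside = on.all()
        else:
            raise ValueError(f"unknown rule {rule!r}")
        groups["inside" if inside else "outside"].append(g)
    result = {}
    for name, gs in groups.items():
        sub = pd.concat(gs) if gs else pd.DataFrame(columns=tracks.columns)
        dtab = track_diffusion(sub, dt, unit_scale) if len(gs) else \
            pd.DataFrame(columns=["track_id", "D", "negative"])
        result[name] = {
            "tracks": sub,
            "D": dtab,
            "median_D": float(dtab["D"].median()) if len(dtab) else np.nan,
            "immobile_fraction": float((dtab["D"] < immobile_threshold).mean())
            if len(dtab) else np.nan,
        }
    return result
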