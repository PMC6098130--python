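"""Clustering-tendency statistics for ROI point patterns.

Two classical second-order summaries used on super-resolution
localization maps:

* the **Hopkins index**, comparing nearest-neighbor distances from uniform
  probe origins against those from the data itself — 0.5 for complete
  spatial randomness (CSR), approaching 1 for strong clustering;
* **Ripley's K** and the derived **H function** ``H(r) = L(r) - r`` with
  ``L = sqrt(K/pi)`` — zero in expectation under CSR, positive when points
  are clustered at scale r; the location of the H-function peak tracks the
  cluster radius and its height the in-cluster density.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .locio import ROI

__all__ = ["HopkinsResult", "RipleyCurve", "hopkins_index", "ripley_h"]


@dataclass
class HopkinsResult:
    value: float  # in [0, 1]; 0.5 under CSR
    m: int  # probe / sample count
    seed: int


@dataclass
class RipleyCurve:
    radii: np.ndarray
    K: np.ndarray
    L: np.ndarray
    H: np.ndarray

    @property
    def peak_r(self) -> float:
        return float(self.radii[int(np.argmax(self.H))])

    @property
    def peak_h(self) -> float:
        return float(np.max(self.H))


def hopkins_index(points, window: ROI, m: int = None, seed: int = 0,
                  probes=None, sample=None):
    """Hopkins clustering-tendency index with squared-distance (d=2) weighting.

    ``H = sum(U_i^2) / (sum(U_i^2) + sum(W_i^2))`` where U are
    nearest-data distances from ``m`` uniform probe origins in the window
    and W are nearest-neighbor distances from ``m`` data points sampled
    without replacement (self excluded).  Default
    ``m = min(ceil(0.1 n), 100)``.  ``probes`` (explicit probe origins)
    and ``sample`` (explicit data indices) override the seeded draws.
    """
    points = np.asarray(points, float)
    n = len(points)
    if n < 2:
        raise ValueError("Hopkins index undefined for fewer than 2 points")
    if m is None:
        m = len(probes) if probes is not None else min(int(np.ceil(0.1 * n)), 100)
    if not 1 <= m <= n:
        raise ValueError("require 1 <= m <= n")
    rng = np.random.default_rng(seed)
    tree = cKDTree(points)
    if probes is None:
        probes = np.column_stack(
            [
                rng.uniform(window.x0, window.x0 + window.side, m),
                rng.uniform(window.y0, window.y0 + window.side, m),
            ]
        )
    else:
        probes = np.asarray(probes, float)
    u, _ = tree.query(probes, k=1)
    if sample is None:
        sample = rng.choice(n, size=m, replace=False)
    else:
        sample = np.asarray(sample, int)
    w_d, _ = tree.query(points[sample], k=2)
    w = w_d[:, 1]  # first neighbor is the point itself
    u2, w2 = np.sum(u**2), np.sum(w**2)
    if u2 + w2 == 0:
        value = 0.5
    else:
        value = float(u2 / (u2 + w2))
    return HopkinsResult(value, m, seed)


def _isotropic_weights(points, d, window: ROI, n_angles: int = 720):
    """Ripley isotropic edge weights by angular quadrature.

    Weight 1/p where p is the fraction of the circle of radius d centered
    at the point that lies inside the window, evaluated on a uniform angle
    grid (resolution ~0.5 deg).
    """
    theta = np.linspace(0, 2 * np.pi, n_angles, endpoint=False)
    ct, st = np.cos(theta), np.sin(theta)
    cx = points[:, 0][:, None] + d[:, None] * ct[None, :]
    cy = points[:, 1][:, None] + d[:, None] * st[None, :]
    inside = (
        (cx >= window.x0)
        & (cx < window.x0 + window.side)
        & (cy >= window.y0)
        & (cy < window.y0 + window.side)
    )
    frac = inside.mean(axis=1)
    frac = np.clip(frac, 1e-6, None)
    return 1.0 / frac


def ripley_h(points, window: ROI, radii, correction: str = "toroidal"):
    """Ripley's K, L, and H on a square window.

    ``K(r) = A / (n (n-1)) * sum_{i != j} e_ij 1[d_ij <= r]`` with edge
    weights per ``correction``: ``toroidal`` (exact, periodic window),
    ``isotropic`` (Ripley circle-fraction weight, for ROIs cut from
    cells), or ``none``.
    """
    points = np.asarray(points, float)
    radii = np.asarray(radii, float)
    n = len(points)
    if n < 2:
        raise ValueError("Ripley's K requires at least 2 points")
    if np.max(radii) > window.side / 2:
        raise ValueError("max radius must not exceed half the window side")
    area = window.area
    if correction == "toroidal":
        # wrap onto [0, side): points on the upper boundary (or nudged just
        # outside the window by noise) land back inside the periodic box
        shifted = np.mod(points - [window.x0, window.y0], window.side)
        tree = cKDTree(shifted, boxsize=[window.side, window.side])
        # ordered-pair counts within each radius (self pairs subtracted)
        cum = tree.count_neighbors(tree, radii) - n
        K = area * cum / (n * (n - 1))
    else:
        tree = cKDTree(points)
        pairs = tree.query_pairs(float(np.max(radii)), output_type="ndarray")
        if len(pairs):
            d = np.linalg.norm(points[pairs[:, 0]] - points[pairs[:, 1]],
                               axis=1)
            if correction == "isotropic":
                w_i = _isotropic_weights(points[pairs[:, 0]], d, window)
                w_j = _isotropic_weights(points[pairs[:, 1]], d, window)
                w = w_i + w_j  # each unordered pair counted once per direction
            elif correction == "none":
                w = np.full(len(pairs), 2.0)
            else:
                raise ValueError(f"unknown correction {correction!r}")
            K = np.array([(w[d <= r]).sum() for r in radii])
            K = area * K / (n * (n - 1))
        else:
            K = np.zeros_like(radii)
    L = np.sqrt(K / np.pi)
    H = L - radii
    return RipleyCurve(radii, K, L, H)
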