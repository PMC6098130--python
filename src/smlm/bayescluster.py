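"""Model-based Bayesian nanocluster identification for localization ROIs.

Candidate clusterings of an ROI are proposed on a grid of
(radius, neighbor-threshold) pairs — points with more than T neighbors
within r are retained and grouped by single-linkage connected components
at linkage distance r — and each proposal is scored under a generative
model:

* background localizations are uniform over the ROI area;
* each cluster's localizations are isotropic Gaussian around an unknown
  center (flat prior over the ROI), with cluster spread ``s`` integrated
  over a log-uniform grid and each localization's effective variance
  inflated by its own localization uncertainty (``s^2 + sigma_i^2``);
* the allocation prior sends a localization to background with
  probability ``p_background`` and partitions clustered points with a
  symmetric Dirichlet(``alpha``) exchangeable prior.

The maximum-score proposal is returned with the four descriptors reported
for receptor nanoclusters: cluster count, per-cluster radius (2x the RMS
deviation of members from the centroid), molecules per cluster, and the
percentage of localizations in clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree
from scipy.special import gammaln, logsumexp

from .locio import ROI

__all__ = ["BayesConfig", "ClusterResult", "propose_clusterings",
           "score_clustering", "bayes_cluster", "cluster_descriptors"]


@dataclass
class BayesConfig:
    """Priors and proposal grids (defaults as used for IgM-BCR ROIs)."""

    alpha: float = 20.0
    p_background: float = 0.5
    r_grid: np.ndarray = field(
        default_factory=lambda: np.arange(5.0, 200.0, 10.0))
    # inclusive endpoints, like R's seq(): thresholds 0, 5, ..., 50
    t_grid: np.ndarray = field(
        default_factory=lambda: np.arange(0, 51, 5))
    spread_grid: np.ndarray = field(
        default_factory=lambda: np.geomspace(5.0, 150.0, 30))
    radius_factor: float = 2.0  # reported radius = factor x RMS deviation
    frame_limit: int = None  # optional: analyze only frames <= limit

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if not 0 < self.p_background < 1:
            raise ValueError("p_background must be in (0, 1)")
        if len(self.r_grid) == 0 or len(self.t_grid) == 0:
            raise ValueError("proposal grids must be non-empty")


@dataclass
class ClusterResult:
    labels: np.ndarray  # per-localization cluster id, 0 = background
    n_clusters: int
    radii: np.ndarray  # nm, one per cluster
    molecules_per_cluster: np.ndarray
    pct_in_clusters: float
    score: float


def _canonical(labels):
    """Relabel cluster ids in order of first appearance (background fixed at 0)."""
    out = np.zeros_like(labels)
    nxt = 1
    seen = {}
    for i, l in enumerate(labels):
        if l == 0:
            continue
        if l not in seen:
            seen[l] = nxt
            nxt += 1
        out[i] = seen[l]
    return out


def propose_clusterings(points, config: BayesConfig):
    """Candidate labelings from the (r, T) proposal grid, deduplicated.

    For each grid pair: points with strictly more than T neighbors within
    r are retained; clusters are the connected components of the retained
    points under the r-neighbor graph.  The all-background labeling is
    always included.
    """
    points = np.asarray(points, float)
    n = len(points)
    if n == 0:
        raise ValueError("empty ROI")
    tree = cKDTree(points)
    proposals = {}
    all_bg = np.zeros(n, dtype=int)
    proposals[all_bg.tobytes()] = all_bg
    for r in config.r_grid:
        pairs = tree.query_pairs(float(r), output_type="ndarray")
        counts = np.zeros(n, dtype=int)
        if len(pairs):
            np.add.at(counts, pairs[:, 0], 1)
            np.add.at(counts, pairs[:, 1], 1)
        for t in config.t_grid:
            keep = counts > t
            labels = np.zeros(n, dtype=int)
            idx = np.flatnonzero(keep)
            if len(idx):
                sub = pairs[keep[pairs[:, 0]] & keep[pairs[:, 1]]] if len(pairs) else np.empty((0, 2), int)
                remap = -np.ones(n, dtype=int)
                remap[idx] = np.arange(len(idx))
                if len(sub):
                    g = csr_matrix(
                        (np.ones(len(sub), bool),
                         (remap[sub[:, 0]], remap[sub[:, 1]])),
                        shape=(len(idx), len(idx)),
                    )
                    _, comp = connected_components(g, directed=False)
                else:
                    comp = np.arange(len(idx))
                labels[idx] = comp + 1
                labels = _canonical(labels)
            proposals[labels.tobytes()] = labels
    return list(proposals.values())


def _cluster_log_marginal(xy, sigma2, spread_grid, log_area):
    """Log marginal likelihood of one cluster's points.

    Center integrated analytically under a flat prior of density 1/A;
    spread integrated over the (equal-weight, log-spaced) grid.
    """
    out = np.empty(len(spread_grid))
    for i, s in enumerate(spread_grid):
        v = s * s + sigma2  # per-point effective variance
        iv = 1.0 / v
        siv = iv.sum()
        terms = 0.0
        for k in range(2):
            x = xy[:, k]
            q = np.sum(x * x * iv) - (np.sum(x * iv) ** 2) / siv
            terms += (
                -0.5 * np.sum(np.log(2 * np.pi * v))
                + 0.5 * np.log(2 * np.pi)
                - 0.5 * np.log(siv)
                - 0.5 * q
            )
        out[i] = terms - log_area  # flat center prior: density 1/A
    return logsumexp(out) - np.log(len(spread_grid))


def score_clustering(labels, points, uncertainties, window: ROI,
                     config: BayesConfig) -> float:
    """Log posterior score of a labeling; comparable across labelings of one ROI."""
    points = np.asarray(points, float)
    labels = np.asarray(labels, int)
    if len(labels) != len(points):
        raise ValueError("labeling size does not match ROI")
    sigma2 = np.asarray(uncertainties, float) ** 2
    log_area = np.log(window.area)
    n = len(points)
    n_bg = int(np.sum(labels == 0))
    n_cl = n - n_bg
    score = -n_bg * log_area  # uniform background density
    # allocation prior: Bernoulli(p_background) then Dirichlet-multinomial
    score += n_bg * np.log(config.p_background)
    score += n_cl * np.log1p(-config.p_background)
    ids = np.unique(labels[labels > 0])
    K = len(ids)
    if K:
        sizes = np.array([np.sum(labels == c) for c in ids])
        a = config.alpha
        score += (
            gammaln(K * a)
            - gammaln(K * a + n_cl)
            + np.sum(gammaln(a + sizes) - gammaln(a))
        )
        for c in ids:
            sel = labels == c
            score += _cluster_log_marginal(
                points[sel], sigma2[sel], config.spread_grid, log_area
            )
    return float(score)


def cluster_descriptors(labels, points, radius_factor: float = 2.0):
    """Descriptors of a labeling: radii, occupancies, % clustered."""
    labels = np.asarray(labels, int)
    points = np.asarray(points, float)
    ids = np.unique(labels[labels > 0])
    radii, mols = [], []
    for c in ids:
        sel = points[labels == c]
        centroid = sel.mean(axis=0)
        rms = np.sqrt(np.mean(np.sum((sel - centroid) ** 2, axis=1)))
        radii.append(radius_factor * rms)
        mols.append(len(sel))
    pct = 100.0 * np.sum(labels > 0) / len(labels) if len(labels) else 0.0
    return np.array(radii), np.array(mols, dtype=int), float(pct)


def bayes_cluster(roi, window: ROI = None, config: BayesConfig = None):
    """Identify nanoclusters in one ROI and extract descriptors.

    ``roi`` is a localization table (DataFrame with x, y, uncertainty) or a
    bare (n, 2) array (uncertainties then taken as 10 nm).  Score ties are
    broken toward fewer clusters (parsimony).
    """
    if config is None:
        config = BayesConfig()
    if isinstance(roi, pd.DataFrame):
        if config.frame_limit is not None:
            roi = roi[roi["frame"] <= config.frame_limit]
        points = roi[["x", "y"]].to_numpy()
        unc = roi["uncertainty"].to_numpy()
    else:
        points = np.asarray(roi, float)
        unc = np.full(len(points), 10.0)
    if len(points) == 0:
        raise ValueError("empty ROI")
    if len(points) < 10:
        raise ValueError("ROI must contain at least 10 localizations")
    if window is None:
        window = ROI(0.0, 0.0, max(points.max() - points.min(), 1.0))
    best = None
    for labels in propose_clusterings(points, config):
        s = score_clustering(labels, points, unc, window, config)
        k = labels.max()
        if best is None or s > best[0] + 1e-9 or (
            abs(s - best[0]) <= 1e-9 and k < best[1]
        ):
            best = (s, k, labels)
    score, _, labels = best
    radii, mols, pct = cluster_descriptors(labels, points,
                                           config.radius_factor)
    return ClusterResult(labels, int(labels.max()), radii, mols, pct, score)
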