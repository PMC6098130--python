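"""Five-step dSTORM localization post-processing and channel registration.

The workflow applies, strictly in order:

1. **remove_duplicates** — same-frame repeats of one molecule (a
   multi-emitter fitting artifact) collapsed within the uncertainty radius;
2. **filter_uncertainty** — localizations with uncertainty > 20 nm dropped;
3. **density_filter** — isolated localizations removed (at least two
   neighbors required within 50 nm);
4. **drift_correct** — stage drift estimated from fiducial beads and
   subtracted;
5. **merge_reblinks** — appearances of one molecule within 20 nm in
   consecutive frames merged to a single record.

plus least-squares polynomial channel registration for dual-color data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

__all__ = [
    "PipelineConfig",
    "PolynomialTransform",
    "remove_duplicates",
    "filter_uncertainty",
    "density_filter",
    "drift_correct",
    "merge_reblinks",
    "fit_polynomial_transform",
    "register_channels",
    "run_pipeline",
]


@dataclass
class PipelineConfig:
    """Parameters of the five post-processing steps (defaults as published)."""

    max_uncertainty: float = 20.0  # nm, step 2
    density_radius: float = 50.0  # nm, step 3
    min_neighbors: int = 2  # step 3
    merge_radius: float = 20.0  # nm, step 5
    merge_max_gap_frames: int = 0  # step 5: consecutive frames only
    drift_smooth_window: int = 11  # frames, step 4 moving average

    def __post_init__(self):
        if min(self.max_uncertainty, self.density_radius, self.merge_radius) <= 0:
            raise ValueError("radii must be positive")
        if self.min_neighbors < 0:
            raise ValueError("min_neighbors must be >= 0")


def _components_from_pairs(n, pairs):
    if not pairs:
        return np.arange(n), n
    pairs = np.asarray(list(pairs))
    data = np.ones(len(pairs), dtype=bool)
    g = csr_matrix((data, (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    ncomp, lab = connected_components(g, directed=False)
    return lab, ncomp


def remove_duplicates(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse same-frame repeats within the uncertainty radius (step 1).

    Two localizations in the same frame are duplicates when their distance
    is below the larger of their two uncertainties; duplicate groups are
    taken transitively (connected components) and the highest-intensity
    member of each group is retained.
    """
    if len(table) == 0:
        return table.copy()
    keep_idx = []
    for _, sub in table.groupby("frame", sort=True):
        n = len(sub)
        xy = sub[["x", "y"]].to_numpy()
        unc = sub["uncertainty"].to_numpy()
        tree = cKDTree(xy)
        cand = tree.query_pairs(float(unc.max()), output_type="ndarray")
        if len(cand):
            d = np.linalg.norm(xy[cand[:, 0]] - xy[cand[:, 1]], axis=1)
            thr = np.maximum(unc[cand[:, 0]], unc[cand[:, 1]])
            cand = cand[d < thr]
        lab, ncomp = _components_from_pairs(n, cand.tolist() if len(cand) else [])
        inten = sub["intensity"].to_numpy()
        order = np.lexsort((-inten, lab))  # best intensity first within comp
        first = np.ones(n, dtype=bool)
        first[1:] = lab[order][1:] != lab[order][:-1]
        keep_idx.extend(sub.index.to_numpy()[order[first]])
    return table.loc[sorted(keep_idx)].reset_index(drop=True)


def filter_uncertainty(table: pd.DataFrame, max_uncertainty: float = 20.0):
    """Eliminate localizations with uncertainty strictly above the cut (step 2)."""
    if max_uncertainty <= 0:
        raise ValueError("max_uncertainty must be positive")
    keep = table["uncertainty"].to_numpy() <= max_uncertainty
    return table.loc[keep].reset_index(drop=True)


def density_filter(table: pd.DataFrame, radius: float = 50.0,
                   min_neighbors: int = 2) -> pd.DataFrame:
    """Remove isolated localizations (step 3).

    Neighbor counts are computed in a single pass on the input table, not
    iteratively after removals; a record survives when at least
    ``min_neighbors`` *other* localizations lie within ``radius``.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if len(table) == 0:
        return table.copy()
    xy = table[["x", "y"]].to_numpy()
    tree = cKDTree(xy)
    counts = np.array(tree.query_ball_point(xy, radius, return_length=True)) - 1
    return table.loc[counts >= min_neighbors].reset_index(drop=True)


class DriftError(RuntimeError):
    pass


def _moving_average(a, w):
    # Savitzky-Golay order 1 == centered moving average in the interior,
    # with least-squares linear edge handling: exact on linear drift ramps.
    if w <= 1 or len(a) <= w:
        return a
    from scipy.signal import savgol_filter

    if w % 2 == 0:
        w += 1
    return savgol_filter(a, window_length=w, polyorder=1, axis=0,
                         mode="interp")


def drift_correct(table: pd.DataFrame, fiducial_ids=None,
                  smooth_window: int = 11, max_gap_warn: int = 10):
    """Estimate and subtract stage drift from fiducial beads (step 4).

    ``fiducial_ids`` selects fiducial rows: a boolean mask / index array, or
    None to use the table's ``fiducial`` column.  Per-frame drift is the
    mean fiducial displacement relative to the first frame (averaged over
    beads, each relative to its own first-frame position), linearly
    interpolated over frames without fiducials and smoothed with a
    ``smooth_window``-frame moving average.  Returns the corrected table
    and a DataFrame drift path (frame, dx, dy) with a ``fiducial_rms``
    attribute: the post-correction RMS residual of the beads.
    """
    if fiducial_ids is None:
        if "fiducial" not in table.columns:
            raise DriftError("no fiducials found: supply fiducial_ids or a "
                             "'fiducial' column")
        mask = table["fiducial"].to_numpy().astype(bool)
    else:
        arr = np.asarray(fiducial_ids)
        if arr.dtype == bool:
            mask = arr
        else:
            mask = np.zeros(len(table), dtype=bool)
            mask[arr] = True
    fid = table.loc[mask]
    if len(fid) == 0:
        raise DriftError("no fiducials found")
    frames = np.arange(table["frame"].min(), table["frame"].max() + 1)
    # identify beads: use fiducial_id when present, else one bead assumed
    if "fiducial_id" in fid.columns:
        groups = [g for _, g in fid.groupby("fiducial_id")]
    else:
        groups = [fid]
    disp_sum = np.zeros((len(frames), 2))
    disp_cnt = np.zeros(len(frames))
    for g in groups:
        g = g.sort_values("frame")
        ref = g[["x", "y"]].to_numpy()[0]
        idx = g["frame"].to_numpy() - frames[0]
        disp_sum[idx] += g[["x", "y"]].to_numpy() - ref
        disp_cnt[idx] += 1
    have = disp_cnt > 0
    if have.sum() < 0.9 * len(frames):
        gaps = len(frames) - have.sum()
        if gaps > max_gap_warn:
            warnings.warn(
                f"fiducials absent from {gaps} frames; drift interpolated",
                stacklevel=2,
            )
    drift = np.empty((len(frames), 2))
    mean_disp = disp_sum[have] / disp_cnt[have, None]
    for k in range(2):
        drift[:, k] = np.interp(frames, frames[have], mean_disp[:, k])
    drift = _moving_average(drift, smooth_window)
    drift -= drift[0]  # drift is zero at the first frame by definition
    out = table.copy()
    fidx = out["frame"].to_numpy() - frames[0]
    out["x"] = out["x"].to_numpy() - drift[fidx, 0]
    out["y"] = out["y"].to_numpy() - drift[fidx, 1]
    # post-correction residual of the beads around their mean positions
    res = []
    for g_idx, g in enumerate(groups):
        sel = out.loc[g.index, ["x", "y"]].to_numpy()
        res.append(sel - sel.mean(axis=0))
    res = np.concatenate(res)
    path = pd.DataFrame({"frame": frames, "dx": drift[:, 0], "dy": drift[:, 1]})
    path.attrs["fiducial_rms"] = float(np.sqrt(np.mean(np.sum(res**2, axis=1))))
    return out, path


def merge_reblinks(table: pd.DataFrame, merge_radius: float = 20.0,
                   max_gap: int = 0) -> pd.DataFrame:
    """Merge re-blinking molecules across frames (step 5).

    Appearance chains linking localizations in frames at most
    ``1 + max_gap`` apart and within ``merge_radius`` collapse to a single
    record at the inverse-variance-weighted mean position, with summed
    intensity, the first frame index, and combined uncertainty
    ``1/sqrt(sum 1/sigma_i^2)``.
    """
    n = len(table)
    if n == 0:
        return table.copy()
    xy = table[["x", "y"]].to_numpy()
    fr = table["frame"].to_numpy()
    tree = cKDTree(xy)
    cand = tree.query_pairs(merge_radius, output_type="ndarray")
    if len(cand):
        dgap = np.abs(fr[cand[:, 0]] - fr[cand[:, 1]])
        cand = cand[(dgap >= 1) & (dgap <= 1 + max_gap)]
    lab, ncomp = _components_from_pairs(n, cand.tolist() if len(cand) else [])
    unc = table["uncertainty"].to_numpy()
    wts = 1.0 / unc**2
    inten = table["intensity"].to_numpy()
    chan = table["channel"].to_numpy()
    rows = []
    order = np.argsort(lab, kind="stable")
    bounds = np.flatnonzero(np.diff(lab[order])) + 1
    for grp in np.split(order, bounds):
        w = wts[grp]
        rows.append(
            (
                fr[grp].min(),
                np.sum(xy[grp, 0] * w) / w.sum(),
                np.sum(xy[grp, 1] * w) / w.sum(),
                1.0 / np.sqrt(w.sum()),
                inten[grp].sum(),
                chan[grp[0]],
            )
        )
    out = pd.DataFrame(rows, columns=["frame", "x", "y", "uncertainty",
                                      "intensity", "channel"])
    out["frame"] = out["frame"].astype(int)
    out["channel"] = out["channel"].astype(int)
    return out.sort_values("frame", kind="stable").reset_index(drop=True)


@dataclass
class PolynomialTransform:
    """2-D polynomial warp ``(x, y) -> (x', y')`` of total degree ``degree``."""

    degree: int
    coef_x: np.ndarray  # one coefficient per monomial x^a y^b, a+b<=degree
    coef_y: np.ndarray

    def __call__(self, x, y):
        A = _design_matrix(np.asarray(x, float), np.asarray(y, float),
                           self.degree)
        return A @ self.coef_x, A @ self.coef_y


def _design_matrix(x, y, degree):
    cols = []
    for total in range(degree + 1):
        for a in range(total + 1):
            b = total - a
            cols.append(x**a * y**b)
    return np.column_stack(cols)


def fit_polynomial_transform(moving_xy, fixed_xy, degree: int = 2):
    """Least-squares polynomial mapping moving control points onto fixed ones."""
    moving_xy = np.asarray(moving_xy, float)
    fixed_xy = np.asarray(fixed_xy, float)
    A = _design_matrix(moving_xy[:, 0], moving_xy[:, 1], degree)
    if len(moving_xy) < A.shape[1]:
        raise ValueError(
            f"need at least {A.shape[1]} control points for degree {degree}"
        )
    if np.linalg.matrix_rank(A) < A.shape[1]:
        raise np.linalg.LinAlgError(
            "degenerate (e.g. collinear) control points: rank-deficient fit"
        )
    cx, *_ = np.linalg.lstsq(A, fixed_xy[:, 0], rcond=None)
    cy, *_ = np.linalg.lstsq(A, fixed_xy[:, 1], rcond=None)
    t = PolynomialTransform(degree, cx, cy)
    px, py = t(moving_xy[:, 0], moving_xy[:, 1])
    rms = float(np.sqrt(np.mean((px - fixed_xy[:, 0]) ** 2
                                + (py - fixed_xy[:, 1]) ** 2)))
    return t, rms


def register_channels(moving: pd.DataFrame, moving_points, fixed_points,
                      degree: int = 2):
    """Map a moving-channel table onto the fixed channel via fiducial pairs.

    ``moving_points``/``fixed_points`` are matched (m, 2) fiducial
    coordinates seen in both channels.  Returns the transformed table, the
    fitted :class:`PolynomialTransform`, and the control-point residual RMS.
    """
    t, rms = fit_polynomial_transform(moving_points, fixed_points, degree)
    out = moving.copy()
    out["x"], out["y"] = t(moving["x"].to_numpy(), moving["y"].to_numpy())
    return out, t, rms


def run_pipeline(table: pd.DataFrame, config: PipelineConfig = None):
    """Apply steps 1-5 in order; returns (table, per-step survivor counts).

    The drift step is skipped (recorded as None in the report) when the
    table carries no fiducial information, e.g. for pre-aligned synthetic
    ROIs.
    """
    if config is None:
        config = PipelineConfig()
    report = {"input": len(table)}
    t = remove_duplicates(table)
    report["remove_duplicates"] = len(t)
    t = filter_uncertainty(t, config.max_uncertainty)
    report["filter_uncertainty"] = len(t)
    t = density_filter(t, config.density_radius, config.min_neighbors)
    report["density_filter"] = len(t)
    has_fid = "fiducial" in t.columns and bool(np.asarray(t["fiducial"]).any())
    if has_fid:
        t, _path = drift_correct(t, smooth_window=config.drift_smooth_window)
        # beads are instrument references, not molecules
        t = t.loc[~t["fiducial"].astype(bool)].reset_index(drop=True)
        report["drift_correct"] = len(t)
    else:
        report["drift_correct"] = None
    t = merge_reblinks(t, config.merge_radius, config.merge_max_gap_frames)
    report["merge_reblinks"] = len(t)
    return t, report
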