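"""Synthetic ground-truth generators for every downstream analysis stage.

The generators emulate the data this package analyzes: nanoscale point
patterns on a B-cell membrane (clustered and completely spatially random),
localization tables with per-emitter precision, multi-frame blinking,
same-frame duplicates and stage drift, dual-color patterns with a
controllable colocalized fraction, membrane-confined Brownian trajectories
at video rate, and PSF-rendered camera frames.  Every generator is
deterministic for a fixed seed.

Units: coordinates in nm, time in seconds, diffusion coefficients in
µm²/s.  The default window is the 3 x 3 µm analysis ROI.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .locio import ROI, FieldGeometry, make_table

__all__ = [
    "GroundTruthPattern",
    "EmissionModel",
    "DriftModel",
    "TrackGroundTruth",
    "gen_csr",
    "gen_thomas",
    "emit_localizations",
    "gen_dual_color",
    "gen_brownian_tracks",
    "render_frames",
    "linear_drift",
]


@dataclass
class GroundTruthPattern:
    """True molecule positions with cluster labels (0 = background)."""

    positions: np.ndarray  # (n, 2) nm
    labels: np.ndarray  # (n,) int, 0 = background
    window: ROI
    n_clipped: int = 0  # offspring discarded at the window edge

    @property
    def n(self) -> int:
        return len(self.positions)


@dataclass
class EmissionModel:
    """Photophysics of a labeled molecule as seen by the localization fitter.

    ``mean_blinks`` is the expected number of appearances per molecule
    (>= 1); appearances occupy a consecutive run of frames starting at a
    random frame, so the post-processing merge step can collapse them.
    Per-appearance localization precision is drawn log-normal around
    ``uncertainty_mean`` (strictly positive, right-skewed, as in real
    SMLM fits); the draw is recorded in the ``uncertainty`` column and the
    position error is Gaussian with that sd.  ``duplicate_rate`` is the
    per-appearance probability of a spurious same-frame duplicate (the
    artifact of multi-emitter fitting that step 1 of the pipeline removes).
    """

    mean_blinks: float = 1.0
    uncertainty_mean: float = 10.0
    uncertainty_sd: float = 0.0
    reblink_jitter_sd: float = 0.0
    n_frames: int = 100
    duplicate_rate: float = 0.0

    def __post_init__(self):
        if self.mean_blinks < 1:
            raise ValueError("mean_blinks must be >= 1")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if min(self.uncertainty_mean, self.uncertainty_sd,
               self.reblink_jitter_sd, self.duplicate_rate) < 0:
            raise ValueError("rates and scales must be >= 0")


@dataclass
class DriftModel:
    """Stage drift as a function of frame, plus fiducial bead count.

    ``path(frame) -> (dx, dy)`` nm with ``path(1) == (0, 0)``.
    """

    path: Callable[[int], tuple] = field(default=lambda f: (0.0, 0.0))
    n_fiducials: int = 0


def linear_drift(rate_x: float, rate_y: float) -> Callable[[int], tuple]:
    """Linear drift of (rate_x, rate_y) nm/frame, zero at frame 1."""

    return lambda f: (rate_x * (f - 1), rate_y * (f - 1))


@dataclass
class TrackGroundTruth:
    """Ground truth for Brownian-motion trajectories.

    ``frame_interval`` defaults to 0.05 s (20 frames/s acquisition).
    ``true_positions`` is filled by :func:`gen_brownian_tracks` as an
    (n_particles, n_frames, 2) array in nm.
    """

    D_true: float = 0.03  # µm²/s
    frame_interval: float = 0.05  # s
    loc_noise_sd: float = 20.0  # nm
    n_frames: int = 20
    true_positions: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.D_true < 0:
            raise ValueError("D_true must be >= 0")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")


def gen_csr(n: int, window: ROI, seed: int) -> GroundTruthPattern:
    """Complete spatial randomness: ``n`` i.i.d. uniform points in ``window``."""
    rng = np.random.default_rng(seed)
    pos = np.column_stack(
        [
            rng.uniform(window.x0, window.x0 + window.side, n),
            rng.uniform(window.y0, window.y0 + window.side, n),
        ]
    )
    return GroundTruthPattern(pos, np.zeros(n, dtype=int), window)


def gen_thomas(
    n_clusters: int,
    cluster_sd: float,
    mean_mols_per_cluster: float,
    background_fraction: float,
    window: ROI,
    seed: int,
    n_background: Optional[int] = None,
) -> GroundTruthPattern:
    """Thomas (Neyman-Scott) cluster process plus uniform background.

    Parent centers are uniform in the window; each parent receives a
    Poisson(``mean_mols_per_cluster``) number of offspring displaced by an
    isotropic Gaussian of sd ``cluster_sd``.  Offspring falling outside the
    window are clipped and counted in ``n_clipped`` so descriptor-recovery
    tests can exclude edge-truncated clusters.  Background points are
    uniform; their number is chosen so background/total is approximately
    ``background_fraction`` (or set explicitly with ``n_background``).
    """
    if cluster_sd <= 0:
        raise ValueError("cluster_sd must be positive")
    if not 0 <= background_fraction <= 1:
        raise ValueError("background_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    lo = np.array([window.x0, window.y0])
    hi = lo + window.side
    parents = rng.uniform(lo, hi, size=(n_clusters, 2))
    positions = []
    labels = []
    n_clipped = 0
    for k in range(n_clusters):
        m = rng.poisson(mean_mols_per_cluster)
        off = parents[k] + rng.normal(0.0, cluster_sd, size=(m, 2))
        inside = np.all((off >= lo) & (off < hi), axis=1)
        n_clipped += int(m - inside.sum())
        off = off[inside]
        positions.append(off)
        labels.append(np.full(len(off), k + 1, dtype=int))
    n_clustered = sum(len(p) for p in positions)
    if n_background is None:
        if background_fraction >= 1.0:
            n_bg = rng.poisson(n_clusters * mean_mols_per_cluster)
        else:
            n_bg = int(round(
                background_fraction / (1.0 - background_fraction) * n_clustered
            ))
    else:
        n_bg = int(n_background)
    bg = rng.uniform(lo, hi, size=(n_bg, 2))
    positions.append(bg)
    labels.append(np.zeros(n_bg, dtype=int))
    pos = np.concatenate(positions) if positions else np.empty((0, 2))
    lab = np.concatenate(labels) if labels else np.empty(0, dtype=int)
    return GroundTruthPattern(pos, lab, window, n_clipped)


def _draw_uncertainty(rng, mean, sd, size):
    """Log-normal draw with the requested arithmetic mean and sd."""
    if sd == 0:
        return np.full(size, float(mean))
    s2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - 0.5 * s2
    return rng.lognormal(mu, np.sqrt(s2), size)


def emit_localizations(
    truth: GroundTruthPattern,
    em: EmissionModel,
    drift: DriftModel,
    seed: int,
):
    """Forward model from true molecules to a raw localization table.

    Each molecule turns on once at a uniform random frame and stays on for
    ``k ~ 1 + Poisson(mean_blinks - 1)`` consecutive frames (truncated at
    the movie end).  Each appearance is the true position plus a per-blink
    jitter, plus a Gaussian localization error whose sd is drawn from the
    uncertainty model and recorded in the ``uncertainty`` column, plus the
    stage drift of its frame.  Fiducial beads are appended in every frame,
    displaced by drift only, flagged with boolean ``fiducial`` and integer
    ``fiducial_id`` columns.  Same-frame duplicates are injected per
    appearance with probability ``duplicate_rate`` at a small offset and
    half the intensity.
    """
    rng = np.random.default_rng(seed)
    rows_frame, rows_x, rows_y, rows_u, rows_i = [], [], [], [], []
    rows_fid, rows_fid_id = [], []

    def add(frame, x, y, u, inten, fid=False, fid_id=-1):
        rows_frame.append(frame)
        rows_x.append(x)
        rows_y.append(y)
        rows_u.append(u)
        rows_i.append(inten)
        rows_fid.append(fid)
        rows_fid_id.append(fid_id)

    for p in truth.positions:
        k = 1 + rng.poisson(em.mean_blinks - 1.0)
        f0 = rng.integers(1, em.n_frames + 1)
        frames = np.arange(f0, min(f0 + k, em.n_frames + 1))
        jit = (
            rng.normal(0.0, em.reblink_jitter_sd, size=(len(frames), 2))
            if em.reblink_jitter_sd > 0
            else np.zeros((len(frames), 2))
        )
        unc = _draw_uncertainty(rng, em.uncertainty_mean, em.uncertainty_sd,
                                len(frames))
        err = rng.normal(0.0, 1.0, size=(len(frames), 2)) * unc[:, None]
        inten = rng.uniform(500.0, 2000.0, size=len(frames))
        for t, f in enumerate(frames):
            dx, dy = drift.path(int(f))
            x = p[0] + jit[t, 0] + err[t, 0] + dx
            y = p[1] + jit[t, 1] + err[t, 1] + dy
            add(int(f), x, y, unc[t], inten[t])
            if em.duplicate_rate > 0 and rng.random() < em.duplicate_rate:
                # duplicate within the uncertainty radius, dimmer
                ang = rng.uniform(0, 2 * np.pi)
                rad = rng.uniform(0, 0.5 * unc[t])
                add(int(f), x + rad * np.cos(ang), y + rad * np.sin(ang),
                    unc[t], 0.5 * inten[t])

    w = truth.window
    fid_pos = np.column_stack(
        [
            rng.uniform(w.x0, w.x0 + w.side, drift.n_fiducials),
            rng.uniform(w.y0, w.y0 + w.side, drift.n_fiducials),
        ]
    )
    for f in range(1, em.n_frames + 1):
        dx, dy = drift.path(f)
        for j in range(drift.n_fiducials):
            add(f, fid_pos[j, 0] + dx, fid_pos[j, 1] + dy, 2.0, 5e4,
                fid=True, fid_id=j)

    return make_table(
        rows_frame, rows_x, rows_y, rows_u, rows_i,
        fiducial=np.array(rows_fid, dtype=bool),
        fiducial_id=np.array(rows_fid_id, dtype=int),
    )


def gen_dual_color(
    n_each: int,
    coloc_fraction: float,
    displacement_sd: float,
    window: ROI,
    seed: int,
    cluster_sd: float = 50.0,
    mols_per_cluster: float = 100.0,
    background_fraction: float = 0.2,
):
    """Dual-color point patterns with a controllable colocalized fraction.

    Channel A is a clustered (nanocluster-like) pattern: uniform parent
    centers with Gaussian offspring of sd ``cluster_sd`` plus a uniform
    background share, mimicking receptor organization on the membrane.  A
    ``floor(n_each * coloc_fraction)`` share of channel-B points are
    randomly chosen channel-A points plus isotropic Gaussian offsets of sd
    ``displacement_sd``; the remainder are independent uniform.  Emulates
    the dual-label validation (same molecules imaged in two colors) at
    ``coloc_fraction=1`` and two unrelated species at 0.
    """
    if not 0 <= coloc_fraction <= 1:
        raise ValueError("coloc_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    lo = np.array([window.x0, window.y0])
    hi = lo + window.side
    n_bg = int(round(background_fraction * n_each))
    n_cl = n_each - n_bg
    k = max(1, int(np.ceil(n_cl / mols_per_cluster)))
    parents = rng.uniform(lo, hi, size=(k, 2))
    assign = rng.integers(0, k, size=n_cl)
    clustered = parents[assign] + rng.normal(0.0, cluster_sd, size=(n_cl, 2))
    a = np.vstack([clustered, rng.uniform(lo, hi, size=(n_bg, 2))])
    a = np.clip(a, lo, np.nextafter(hi, lo))
    a = a[rng.permutation(n_each)]  # paired subset below is then random
    n_pair = int(np.floor(n_each * coloc_fraction))
    paired = a[:n_pair] + rng.normal(0.0, displacement_sd, size=(n_pair, 2))
    indep = rng.uniform(lo, hi, size=(n_each - n_pair, 2))
    b = np.vstack([paired, indep])
    lab_b = np.concatenate(
        [np.ones(n_pair, dtype=int), np.zeros(n_each - n_pair, dtype=int)]
    )
    pat_a = GroundTruthPattern(a, np.zeros(n_each, dtype=int), window)
    pat_b = GroundTruthPattern(b, lab_b, window)
    return pat_a, pat_b


def gen_brownian_tracks(
    n_particles: int,
    truth: TrackGroundTruth,
    window: ROI,
    seed: int,
):
    """Simulate 2-D Brownian trajectories with reflecting window boundaries.

    Per-frame displacement components are i.i.d. Normal(0, sqrt(2 D dt));
    observed positions add Gaussian localization noise of sd
    ``loc_noise_sd``.  Returns the filled :class:`TrackGroundTruth` and a
    localization table with a ``particle`` column.
    """
    rng = np.random.default_rng(seed)
    nt = truth.n_frames
    lo = np.array([window.x0, window.y0])
    hi = lo + window.side
    step_sd = np.sqrt(2.0 * truth.D_true * 1e6 * truth.frame_interval)  # nm
    pos = np.empty((n_particles, nt, 2))
    pos[:, 0] = rng.uniform(lo, hi, size=(n_particles, 2))
    for t in range(1, nt):
        nxt = pos[:, t - 1] + rng.normal(0.0, step_sd, size=(n_particles, 2))
        # reflect at the window edges (repeat to handle large excursions)
        for _ in range(4):
            nxt = np.where(nxt < lo, 2 * lo - nxt, nxt)
            nxt = np.where(nxt > hi, 2 * hi - nxt, nxt)
        pos[:, t] = nxt
    obs = pos + rng.normal(0.0, truth.loc_noise_sd, size=pos.shape)
    frames = np.tile(np.arange(1, nt + 1), n_particles)
    particle = np.repeat(np.arange(n_particles), nt)
    table = make_table(
        frames,
        obs[:, :, 0].reshape(-1),
        obs[:, :, 1].reshape(-1),
        np.full(n_particles * nt, max(truth.loc_noise_sd, 1e-9)),
        particle=particle,
    )
    filled = TrackGroundTruth(
        truth.D_true, truth.frame_interval, truth.loc_noise_sd, nt,
        true_positions=pos,
    )
    return filled, table


def render_frames(
    positions_per_frame,
    geom: FieldGeometry,
    psf_sd: float,
    photons: float,
    bg_mean: float,
    seed: int,
    noise: bool = True,
) -> np.ndarray:
    """Render emitters into camera frames at ``camera_pixel`` resolution.

    ``positions_per_frame`` is a sequence of (m_f, 2) nm arrays, one per
    frame.  Each emitter is drawn as a pixel-integrated 2-D Gaussian PSF of
    sd ``psf_sd`` nm carrying ``photons`` expected photons, on a constant
    background of ``bg_mean`` counts/pixel; Poisson shot noise is applied
    to the whole frame unless ``noise=False``.
    """
    from scipy.special import erf

    if psf_sd <= 0:
        raise ValueError("psf_sd must be positive")
    rng = np.random.default_rng(seed)
    p = geom.camera_pixel
    ny = int(np.ceil(geom.height / p))
    nx = int(np.ceil(geom.width / p))
    ex = np.arange(nx + 1) * p
    ey = np.arange(ny + 1) * p
    stack = np.empty((len(positions_per_frame), ny, nx))
    for f, pts in enumerate(positions_per_frame):
        frame = np.full((ny, nx), float(bg_mean))
        for x, y in np.atleast_2d(pts) if len(pts) else []:
            cx = 0.5 * erf((ex - x) / (np.sqrt(2) * psf_sd))
            cy = 0.5 * erf((ey - y) / (np.sqrt(2) * psf_sd))
            frame += photons * np.outer(np.diff(cy), np.diff(cx))
        stack[f] = rng.poisson(frame) if noise else frame
    return stack
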