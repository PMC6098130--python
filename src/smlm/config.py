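"""Run configuration and the end-to-end demonstration workflow.

A :class:`RunConfig` mirrors the default parameters of every analysis
stage; :func:`run_demo` composes the full chain on synthetic data with
known ground truth — simulate a clustered receptor pattern, emit noisy
localizations, post-process, measure clustering (Hopkins, Ripley H,
Bayesian descriptors), colocalization, and mobility — and returns a
single JSON-serializable report.  One seed governs the whole run through
deterministic substream derivation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import bayescluster, clusterstats, coloc, postprocess, synthgen, tracking
from .locio import ROI

__all__ = ["RunConfig", "validate_config", "run_demo", "substream_seeds"]


@dataclass
class RunConfig:
    seed: int = 0
    # synthetic pattern
    window_side: float = 3000.0  # nm
    n_clusters: int = 5
    cluster_sd: float = 30.0  # nm
    mean_mols_per_cluster: float = 40.0
    background_fraction: float = 0.1
    # emission / pipeline
    mean_blinks: float = 2.0
    uncertainty_mean: float = 10.0
    uncertainty_sd: float = 3.0
    n_frames: int = 200
    duplicate_rate: float = 0.05
    max_uncertainty: float = 20.0
    density_radius: float = 50.0
    min_neighbors: int = 2
    merge_radius: float = 20.0
    # cluster statistics
    hopkins_m: int = 100
    ripley_rmax: float = 500.0
    alpha: float = 20.0
    p_background: float = 0.5
    # dual color
    n_each: int = 2000
    coloc_fraction: float = 0.5
    displacement_sd: float = 20.0
    cbc_rmax: float = 70.0
    # tracking
    n_tracks: int = 200
    D_true: float = 0.03  # µm²/s
    frame_interval: float = 0.05  # s
    track_frames: int = 20
    loc_noise_sd: float = 20.0  # nm
    log_level: str = "INFO"

    def validate(self):
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if not 0 < self.p_background < 1:
            raise ValueError("p_background must be in (0, 1)")
        if not 0 <= self.coloc_fraction <= 1:
            raise ValueError("coloc_fraction must be in [0, 1]")
        if self.D_true < 0:
            raise ValueError("D_true must be >= 0")
        if self.window_side <= 0 or self.frame_interval <= 0:
            raise ValueError("window_side and frame_interval must be positive")
        return self

    def to_dict(self):
        return dataclasses.asdict(self)


def validate_config(path) -> RunConfig:
    """Parse, default, and schema-check a YAML run configuration."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("config must be a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data).validate()


def substream_seeds(seed: int, n: int):
    """Independent per-stage integer seeds derived from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def run_demo(config: RunConfig, out_path=None) -> dict:
    """Simulate -> post-process -> quantify, with ground-truth comparisons."""
    config.validate()
    seeds = substream_seeds(config.seed, 6)
    window = ROI(0.0, 0.0, config.window_side)
    report = {"config": config.to_dict()}

    # --- clustered pattern through the localization pipeline ---
    truth = synthgen.gen_thomas(
        config.n_clusters, config.cluster_sd, config.mean_mols_per_cluster,
        config.background_fraction, window, seeds[0],
    )
    em = synthgen.EmissionModel(
        mean_blinks=config.mean_blinks,
        uncertainty_mean=config.uncertainty_mean,
        uncertainty_sd=config.uncertainty_sd,
        n_frames=config.n_frames,
        duplicate_rate=config.duplicate_rate,
    )
    drift = synthgen.DriftModel(synthgen.linear_drift(0.2, -0.1), n_fiducials=3)
    raw = synthgen.emit_localizations(truth, em, drift, seeds[1])
    pipe_cfg = postprocess.PipelineConfig(
        max_uncertainty=config.max_uncertainty,
        density_radius=config.density_radius,
        min_neighbors=config.min_neighbors,
        merge_radius=config.merge_radius,
    )
    clean, steps = postprocess.run_pipeline(raw, pipe_cfg)
    report["postprocess"] = {
        "true_molecules": int(truth.n),
        "raw_localizations": int(len(raw)),
        "steps": steps,
    }

    # --- clustering statistics on the cleaned ROI ---
    pts = clean[["x", "y"]].to_numpy()
    hop = clusterstats.hopkins_index(pts, window, m=config.hopkins_m,
                                     seed=seeds[2])
    radii = np.arange(25.0, config.ripley_rmax + 1, 25.0)
    rip = clusterstats.ripley_h(pts, window, radii)
    bay = bayescluster.bayes_cluster(
        clean, window,
        bayescluster.BayesConfig(alpha=config.alpha,
                                 p_background=config.p_background),
    )
    report["clusterstats"] = {
        "hopkins": hop.value,
        "ripley_peak_r": rip.peak_r,
        "ripley_peak_h": rip.peak_h,
    }
    report["bayescluster"] = {
        "true_n_clusters": int(config.n_clusters),
        "n_clusters": bay.n_clusters,
        "mean_radius": float(np.mean(bay.radii)) if bay.n_clusters else None,
        "mean_molecules_per_cluster": float(np.mean(bay.molecules_per_cluster))
        if bay.n_clusters else None,
        "pct_in_clusters": bay.pct_in_clusters,
    }

    # --- dual-color colocalization ---
    pa, pb = synthgen.gen_dual_color(
        config.n_each, config.coloc_fraction, config.displacement_sd,
        window, seeds[3],
    )
    res = coloc.cbc(pa.positions, pb.positions, r_max=config.cbc_rmax)
    _, med_nnd = coloc.nnd(pa.positions, pb.positions)
    report["coloc"] = {
        "coloc_fraction": config.coloc_fraction,
        "median_cbc": res.median,
        "median_nnd": med_nnd,
    }

    # --- mobility ---
    tg = synthgen.TrackGroundTruth(
        config.D_true, config.frame_interval, config.loc_noise_sd,
        config.track_frames,
    )
    _, table = synthgen.gen_brownian_tracks(config.n_tracks, tg, window,
                                            seeds[4])
    tracks = table.rename(columns={"particle": "track_id"})
    dtab = tracking.track_diffusion(tracks, dt=config.frame_interval)
    report["tracking"] = {
        "D_true": config.D_true,
        "median_D": float(dtab["D"].median()),
        "n_tracks": int(len(dtab)),
    }

    if out_path is not None:
        with open(out_path, "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    return report
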