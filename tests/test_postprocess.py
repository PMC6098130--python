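import numpy as np
import pandas as pd
import pytest

from smlm import postprocess, synthgen
from smlm.locio import ROI, make_table
from smlm.postprocess import (
    PipelineConfig,
    density_filter,
    drift_correct,
    fit_polynomial_transform,
    filter_uncertainty,
    merge_reblinks,
    register_channels,
    remove_duplicates,
    run_pipeline,
)


# ---------- brute-force reference implementations (test oracles) ----------

def brute_remove_duplicates(table):
    """O(n^2) duplicate collapse: larger-of-uncertainties rule, transitive."""
    keep = []
    for _, sub in table.groupby("frame"):
        idx = list(sub.index)
        parent = {i: i for i in idx}

        def find(i):
            while parent[i] != i:
                i = parent[i]
            return i

        for a in idx:
            for b in idx:
                if a >= b:
                    continue
                d = np.hypot(table.x[a] - table.x[b], table.y[a] - table.y[b])
                if d < max(table.uncertainty[a], table.uncertainty[b]):
                    parent[find(a)] = find(b)
        groups = {}
        for i in idx:
            groups.setdefault(find(i), []).append(i)
        for members in groups.values():
            keep.append(max(members, key=lambda i: table.intensity[i]))
    return table.loc[sorted(keep)].reset_index(drop=True)


def brute_density_filter(table, radius, min_neighbors):
    xy = table[["x", "y"]].to_numpy()
    keep = []
    for i in range(len(xy)):
        n = sum(
            1
            for j in range(len(xy))
            if j != i and np.hypot(*(xy[i] - xy[j])) <= radius
        )
        if n >= min_neighbors:
            keep.append(i)
    return table.iloc[keep].reset_index(drop=True)


def brute_merge(table, radius, max_gap):
    idx = list(table.index)
    parent = {i: i for i in idx}

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    for a in idx:
        for b in idx:
            if a >= b:
                continue
            gap = abs(table.frame[a] - table.frame[b])
            d = np.hypot(table.x[a] - table.x[b], table.y[a] - table.y[b])
            if 1 <= gap <= 1 + max_gap and d <= radius:
                parent[find(a)] = find(b)
    groups = {}
    for i in idx:
        groups.setdefault(find(i), []).append(i)
    rows = []
    for members in groups.values():
        w = 1.0 / table.uncertainty[members] ** 2
        rows.append(
            {
                "frame": table.frame[members].min(),
                "x": np.average(table.x[members], weights=w),
                "y": np.average(table.y[members], weights=w),
                "uncertainty": 1.0 / np.sqrt(w.sum()),
                "intensity": table.intensity[members].sum(),
            }
        )
    return pd.DataFrame(rows).sort_values(["frame", "x"]).reset_index(drop=True)


def random_fixture(rng, n=50, side=500.0, frames=5):
    return make_table(
        rng.integers(1, frames + 1, n),
        rng.uniform(0, side, n),
        rng.uniform(0, side, n),
        rng.uniform(5, 30, n),
        rng.uniform(100, 1000, n),
    )


# ------------------------------- step 1 -------------------------------

class TestRemoveDuplicates:
    def test_same_frame_pair_collapsed_keeping_brighter(self):
        t = make_table([3, 3], [100.0, 103.0], [100.0, 104.0], [10.0, 10.0],
                       [500.0, 900.0])
        out = remove_duplicates(t)
        assert len(out) == 1
        assert out.intensity[0] == 900.0

    def test_different_frames_not_duplicates(self):
        t = make_table([1, 2], [100.0, 100.0], [100.0, 100.0], [10.0, 10.0])
        assert len(remove_duplicates(t)) == 2

    def test_transitive_chain_collapses(self):
        # A-B and B-C within radius, A-C distant: one connected component
        t = make_table([1, 1, 1], [0.0, 9.0, 18.0], [0.0, 0.0, 0.0],
                       [10.0, 10.0, 10.0], [1.0, 2.0, 3.0])
        out = remove_duplicates(t)
        assert len(out) == 1
        assert out.intensity[0] == 3.0

    def test_matches_brute_force(self, rng):
        t = random_fixture(rng)
        out = remove_duplicates(t)
        ref = brute_remove_duplicates(t)
        assert np.array_equal(
            np.sort(out[["x", "y"]].to_numpy(), axis=0),
            np.sort(ref[["x", "y"]].to_numpy(), axis=0),
        )


# ------------------------------- step 2 -------------------------------

class TestFilterUncertainty:
    def test_boundary_and_counts(self, rng):
        t = make_table([1, 1, 1], [0.0, 10.0, 20.0], [0.0] * 3,
                       [25.0, 20.0, 15.0])
        out = filter_uncertainty(t, 20.0)
        # 25 nm eliminated; exactly 20 nm retained (strict > eliminates)
        assert list(out.uncertainty) == [20.0, 15.0]
        t2 = random_fixture(rng)
        out2 = filter_uncertainty(t2, 20.0)
        assert len(out2) == int((t2.uncertainty <= 20.0).sum())


# ------------------------------- step 3 -------------------------------

class TestDensityFilter:
    def test_isolated_point_removed(self):
        t = make_table([1, 1, 1], [0.0, 10.0, 500.0], [0.0, 0.0, 500.0],
                       [10.0] * 3)
        out = density_filter(t, 50.0, 1)
        assert 500.0 not in out.x.values

    def test_equilateral_triangle_retained(self):
        s = 30.0
        t = make_table([1] * 3, [0.0, s, s / 2], [0.0, 0.0, s * np.sqrt(3) / 2],
                       [10.0] * 3)
        assert len(density_filter(t, 50.0, 2)) == 3

    def test_matches_brute_force(self, rng):
        t = random_fixture(rng, side=300.0)
        out = density_filter(t, 50.0, 2)
        ref = brute_density_filter(t, 50.0, 2)
        assert np.array_equal(out[["x", "y"]].to_numpy(),
                              ref[["x", "y"]].to_numpy())


# ------------------------------- step 4 -------------------------------

class TestDriftCorrect:
    def test_zero_drift_is_identity(self, window):
        truth = synthgen.gen_csr(50, window, 1)
        em = synthgen.EmissionModel(n_frames=100)
        t = synthgen.emit_localizations(truth, em,
                                        synthgen.DriftModel(n_fiducials=2), 2)
        out, path = drift_correct(t)
        assert np.allclose(out.x, t.x, atol=1e-9)
        assert np.allclose(path[["dx", "dy"]].to_numpy(), 0.0, atol=1e-9)

    def test_linear_drift_inverted_exactly(self, window):
        truth = synthgen.gen_csr(20, window, 1)
        em = synthgen.EmissionModel(uncertainty_mean=1e-9, n_frames=500)
        drift = synthgen.DriftModel(synthgen.linear_drift(1.0, 0.5),
                                    n_fiducials=1)
        t = synthgen.emit_localizations(truth, em, drift, 3)
        out, path = drift_correct(t)
        assert path.attrs["fiducial_rms"] < 1e-6

    def test_noisy_fiducials_average_down(self, window):
        """With 3 beads of 5 nm jitter the residual shrinks ~ 1/sqrt(3)."""
        rng = np.random.default_rng(4)
        n_frames = 400
        frames = np.repeat(np.arange(1, n_frames + 1), 3)
        fid_id = np.tile([0, 1, 2], n_frames)
        base = np.array([[500.0, 500.0], [1500.0, 700.0], [900.0, 2000.0]])
        drift_true = 0.5 * (frames - 1)
        x = base[fid_id, 0] + drift_true + rng.normal(0, 5, len(frames))
        y = base[fid_id, 1] + rng.normal(0, 5, len(frames))
        t = make_table(frames, x, y, np.full(len(frames), 2.0),
                       fiducial=np.ones(len(frames), bool), fiducial_id=fid_id)
        out, path = drift_correct(t)
        est = path["dx"].to_numpy()
        err = est - 0.5 * (path["frame"].to_numpy() - 1)
        err -= err[0]
        # smoothed mean of 3 beads: well under the single-bead 5 nm jitter
        assert np.sqrt(np.mean(err**2)) < 5 / np.sqrt(3) * 1.2

    def test_error_without_fiducials(self, small_table):
        with pytest.raises(postprocess.DriftError):
            drift_correct(small_table)


# ------------------------------- step 5 -------------------------------

class TestMergeReblinks:
    def test_consecutive_frames_within_radius_merge(self):
        t = make_table([3, 4], [100.0, 110.0], [100.0, 110.0], [10.0, 10.0],
                       [500.0, 600.0])
        out = merge_reblinks(t, 20.0)
        assert len(out) == 1
        assert out.frame[0] == 3
        assert out.intensity[0] == 1100.0
        assert out.uncertainty[0] == pytest.approx(10.0 / np.sqrt(2))

    def test_beyond_radius_not_merged(self):
        t = make_table([3, 4], [100.0, 125.0], [100.0, 100.0], [10.0, 10.0])
        assert len(merge_reblinks(t, 20.0)) == 2

    def test_four_frame_chain_weighted_mean(self):
        t = make_table([1, 2, 3, 4], [0.0, 12.0, 24.0, 36.0], [0.0] * 4,
                       [10.0, 20.0, 10.0, 20.0], [1.0] * 4)
        out = merge_reblinks(t, 20.0)
        ref = brute_merge(t, 20.0, 0)
        assert len(out) == 1
        assert out.x[0] == pytest.approx(ref.x[0])
        assert out.uncertainty[0] == pytest.approx(ref.uncertainty[0])

    def test_matches_brute_force(self, rng):
        t = random_fixture(rng, side=200.0, frames=8)
        out = merge_reblinks(t, 20.0).sort_values(["frame", "x"]).reset_index(drop=True)
        ref = brute_merge(t, 20.0, 0)
        assert np.allclose(out[["x", "y", "uncertainty", "intensity"]],
                           ref[["x", "y", "uncertainty", "intensity"]])


# ---------------------------- registration ----------------------------

class TestRegisterChannels:
    def test_identity_pairs_zero_residual(self, rng):
        pts = rng.uniform(0, 3000, (12, 2))
        t, res = fit_polynomial_transform(pts, pts, degree=2)
        assert res < 1e-9

    def test_pure_translation_recovered(self, rng):
        pts = rng.uniform(0, 3000, (10, 2))
        moved = pts + [50.0, -30.0]
        t, res = fit_polynomial_transform(pts, moved, degree=1)
        assert res < 1e-9
        px, py = t(100.0, 200.0)
        assert px == pytest.approx(150.0) and py == pytest.approx(170.0)

    def test_degree2_warp_matches_normal_equations(self, rng):
        pts = rng.uniform(0, 3000, (12, 2))

        def warp(xy):
            x, y = xy[:, 0], xy[:, 1]
            return np.column_stack([
                5 + 1.001 * x + 1e-4 * y + 1e-7 * x * y + 2e-8 * x**2,
                -3 + 0.999 * y + 2e-4 * x + 1e-7 * y**2,
            ])

        fixed = warp(pts)
        t, res = fit_polynomial_transform(pts, fixed, degree=2)
        assert res < 1e-6
        # normal-equations oracle
        A = postprocess._design_matrix(pts[:, 0], pts[:, 1], 2)
        cx = np.linalg.solve(A.T @ A, A.T @ fixed[:, 0])
        assert np.allclose(t.coef_x, cx, rtol=1e-6, atol=1e-9)

    def test_collinear_points_rank_error(self):
        pts = np.column_stack([np.arange(10.0), np.arange(10.0)])
        with pytest.raises(np.linalg.LinAlgError):
            fit_polynomial_transform(pts, pts, degree=2)

    def test_register_channels_applies_transform(self, small_table, rng):
        pts = rng.uniform(0, 3000, (8, 2))
        out, t, res = register_channels(small_table, pts, pts + [10.0, 0.0],
                                        degree=1)
        assert np.allclose(out.x, small_table.x + 10.0)


# ------------------------------ pipeline ------------------------------

class TestPipeline:
    def test_empty_table(self):
        t = make_table([], [], [], [])
        out, report = run_pipeline(t)
        assert len(out) == 0
        assert report["input"] == 0

    def test_noise_free_input_unchanged(self, window):
        """Spaced molecules, one blink, no noise: the pipeline is the identity."""
        gx, gy = np.meshgrid(np.arange(100, 3000, 200),
                             np.arange(100, 3000, 200))
        x, y = gx.ravel()[:100], gy.ravel()[:100]
        # clustered enough for the density filter: triplets at each site
        xs = np.concatenate([x, x + 30, x + 15])
        ys = np.concatenate([y, y, y + 30])
        t = make_table(np.tile(np.arange(1, 101), 3) * 3, xs, ys,
                       np.full(300, 1e-3), np.ones(300))
        out, report = run_pipeline(t)
        assert len(out) == 300
        assert np.allclose(np.sort(out.x.to_numpy()), np.sort(xs))

    def test_each_step_is_a_contraction(self, rng, window):
        truth = synthgen.gen_thomas(5, 30, 40, 0.1, window, 1)
        em = synthgen.EmissionModel(mean_blinks=2, uncertainty_mean=10,
                                    uncertainty_sd=5, n_frames=300,
                                    duplicate_rate=0.1)
        t = synthgen.emit_localizations(truth, em, synthgen.DriftModel(), 2)
        _, report = run_pipeline(t)
        counts = [report["input"], report["remove_duplicates"],
                  report["filter_uncertainty"], report["density_filter"]]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_row_permutation_invariance(self, rng, window):
        truth = synthgen.gen_thomas(3, 30, 30, 0.1, window, 3)
        em = synthgen.EmissionModel(mean_blinks=2, uncertainty_mean=10,
                                    uncertainty_sd=5, n_frames=100)
        t = synthgen.emit_localizations(truth, em, synthgen.DriftModel(), 4)
        perm = t.sample(frac=1.0, random_state=0).reset_index(drop=True)
        a, _ = run_pipeline(t)
        b, _ = run_pipeline(perm)
        assert np.allclose(np.sort(a[["x", "y"]].to_numpy(), axis=0),
                           np.sort(b[["x", "y"]].to_numpy(), axis=0))

    def test_step_order_matters(self):
        """Density filter before the uncertainty filter changes the result:
        a poorly localized record can be the neighbor that rescues another."""
        t = make_table([1, 1, 1], [0.0, 40.0, 80.0], [0.0, 0.0, 0.0],
                       [10.0, 25.0, 10.0])
        in_order = density_filter(filter_uncertainty(t, 20.0), 50.0, 1)
        reordered = filter_uncertainty(density_filter(t, 50.0, 1), 20.0)
        assert len(in_order) == 0
        assert len(reordered) == 2
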